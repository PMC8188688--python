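"""Closed-form bench assay formulas: leaf water loss and relative qPCR.

These accompany the transcriptome pipeline so phenotype and validation
tables can be computed with the same conventions as the sequencing
analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

log = logging.getLogger(__name__)

__all__ = ["water_loss_rate", "CtQuartet", "fold_change_ddct"]


def water_loss_rate(fresh_weight: float, current_weight: float) -> float:
    """Relative water loss (FW - CW) / FW of a detached leaf.

    0 means no loss and 1 total loss.  A current weight above the fresh
    weight yields a negative rate, which is returned (with a warning)
    rather than clipped: it flags weighing noise.
    """
    if fresh_weight <= 0:
        raise ValueError(f"fresh weight must be positive, got {fresh_weight}")
    rate = (fresh_weight - current_weight) / fresh_weight
    if rate < 0:
        log.warning(
            "current weight %.4g exceeds fresh weight %.4g: negative water-loss "
            "rate %.4g (weighing noise?)",
            current_weight,
            fresh_weight,
            rate,
        )
    return rate


@dataclass(frozen=True)
class CtQuartet:
    """The four mean Ct values of a relative qPCR comparison."""

    ct_target_treated: float
    ct_ref_treated: float
    ct_target_control: float
    ct_ref_control: float

    def __post_init__(self) -> None:
        import math

        for name, v in self.__dict__.items():
            if not math.isfinite(v):
                raise ValueError(f"Ct value {name} is not finite: {v}")

    @property
    def ddct(self) -> float:
        return (self.ct_target_treated - self.ct_ref_treated) - (
            self.ct_target_control - self.ct_ref_control
        )


def fold_change_ddct(q: CtQuartet) -> float:
    """Relative expression by the 2^-ddCt method (target vs reference gene)."""
    return 2.0 ** (-q.ddct)
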
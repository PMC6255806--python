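"""Posterior summary containers shared across models."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class PosteriorSummary:
    """Median and central 95% credible interval of a posterior quantity.

    The credible interval is the 2.5%–97.5% quantile range of the draws.
    """

    median: float
    ci_low: float
    ci_high: float

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.median <= self.ci_high):
            raise ValueError(
                f"summary not ordered: {self.ci_low} <= {self.median} <= {self.ci_high}"
            )

    @classmethod
    def from_draws(cls, draws: np.ndarray) -> "PosteriorSummary":
        draws = np.asarray(draws, dtype=float).ravel()
        if draws.size == 0:
            raise ValueError("no draws to summarize")
        lo, med, hi = np.quantile(draws, [0.025, 0.5, 0.975])
        return cls(median=float(med), ci_low=float(lo), ci_high=float(hi))

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.median, self.ci_low, self.ci_high)
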
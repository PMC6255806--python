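"""End-to-end convenience: synthetic scenario -> counts -> fits -> pooling."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .records import aggregate_counts
from .simulate import ScenarioConfig, gen_samples
from .summaries import PosteriorSummary
from .trend import (
    CountryWeights,
    TrendModelConfig,
    TrendPosterior,
    fit_trend,
    pool_posteriors,
)

__all__ = ["StudyResult", "run_study"]


@dataclass
class StudyResult:
    counts: pd.DataFrame
    posteriors: dict[str, TrendPosterior]
    weights: CountryWeights
    pooled_alpha_draws: np.ndarray  # percent per year
    pooled_mean_rate_draws: np.ndarray  # probability scale

    @property
    def pooled_alpha(self) -> PosteriorSummary:
        return PosteriorSummary.from_draws(self.pooled_alpha_draws)

    @property
    def pooled_mean_rate_pct(self) -> PosteriorSummary:
        return PosteriorSummary.from_draws(self.pooled_mean_rate_draws * 100.0)

    @property
    def p_alpha_positive(self) -> float:
        return float(np.mean(self.pooled_alpha_draws > 0))


def run_study(
    scenario: ScenarioConfig,
    trend_config: TrendModelConfig | None = None,
) -> StudyResult:
    """Simulate plots, aggregate to counts, fit per-country trend models and
    pool posteriors with the scenario's forest-area weights."""
    trend_config = trend_config or TrendModelConfig()
    plots = gen_samples(scenario)
    counts = aggregate_counts(plots)
    posteriors: dict[str, TrendPosterior] = {}
    for i, country in enumerate(scenario.countries):
        sub = counts[counts["country"] == country.name]
        cfg = TrendModelConfig(
            **{
                **trend_config.__dict__,
                "seed": trend_config.seed + 1000 * (i + 1),
            }
        )
        posteriors[country.name] = fit_trend(sub, cfg)
    weights = CountryWeights(
        {c.name: c.forest_area_weight for c in scenario.countries}
    )
    pooled_alpha = pool_posteriors(posteriors, weights, "alpha", seed=trend_config.seed)
    pooled_rate = pool_posteriors(posteriors, weights, "mean_rate", seed=trend_config.seed)
    return StudyResult(
        counts=counts,
        posteriors=posteriors,
        weights=weights,
        pooled_alpha_draws=pooled_alpha,
        pooled_mean_rate_draws=pooled_rate,
    )
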
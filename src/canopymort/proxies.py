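"""Multi-proxy mortality analysis.

Three independent lines of evidence complement the satellite-based canopy
mortality estimate:

* fraction-type proxy series (wood removal, wind and bark-beetle disturbance,
  each expressed as a fraction of growing stock), whose temporal trends are
  estimated by Beta regression with a logit link;
* individual-tree mortality derived from ICP-style crown-condition surveys,
  where a tree is counted dead in year t if its defoliation was 100% in t and
  it was no longer included in the assessment in t+1; the resulting annual
  death counts feed the same binomial trend model used for the satellite data;
* Pearson correlations between the posterior annual canopy-mortality rates
  and each (fixed) proxy series, propagating canopy-rate posterior
  uncertainty.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, gammaln

from ._mcmc import halfnormal_logpdf, normal_logpdf, run_ensemble
from .summaries import PosteriorSummary
from .trend import ConvergenceWarning, TrendModelConfig, TrendPosterior, fit_trend

__all__ = [
    "ProxySeries",
    "BetaTrendConfig",
    "BetaTrendFit",
    "derive_tree_deaths",
    "tree_mortality_trend",
    "beta_trend",
    "correlate",
]

logger = logging.getLogger(__name__)

PROXY_NAMES = {
    "wood_removal",
    "wind",
    "bark_beetle",
    "canopy_mortality",
    "tree_mortality",
}


@dataclass(frozen=True)
class ProxySeries:
    """Annual fraction-type proxy: e.g. share of growing stock removed."""

    name: str
    years: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        years = np.asarray(self.years)
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "years", years)
        object.__setattr__(self, "values", values)
        if len(years) != len(values):
            raise ValueError("years and values must align")
        if np.any(np.diff(years) <= 0):
            raise ValueError("years must be strictly increasing")
        if np.any((values < 0) | (values > 1)):
            raise ValueError(f"proxy {self.name}: fractions must lie in [0, 1]")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"name": self.name, "year": self.years, "value": self.values}
        )


# --- ICP tree-death derivation ---------------------------------------------

def derive_tree_deaths(observations: pd.DataFrame) -> pd.DataFrame:
    """Annual tree-death counts from a defoliation survey panel.

    ``observations`` has columns plot_id, tree_id, year, defoliation and an
    optional boolean ``assessed`` (rows default to assessed).  A tree dies in
    year t iff its defoliation is 100% in t and it is not assessed in t+1.
    Trees that leave the panel with defoliation < 100% are censored (removed
    from the risk set without a death).  The final survey year carries no
    risk set (the rule needs one year of look-ahead), nor does any year whose
    successor is missing from the panel.

    Returns a table with columns year, n_at_risk, n_dead, n_censored,
    n_survived; n_dead + n_censored + n_survived = n_at_risk in every year.
    """
    required = {"plot_id", "tree_id", "year", "defoliation"}
    missing = required - set(observations.columns)
    if missing:
        raise ValueError(f"observations missing columns: {sorted(missing)}")
    obs = observations.copy()
    if "assessed" in obs.columns:
        obs = obs[obs["assessed"].astype(bool)]
    dup = obs.duplicated(["plot_id", "tree_id", "year"])
    if dup.any():
        first = obs[dup].iloc[0]
        raise ValueError(
            f"duplicate observation: plot {first['plot_id']} tree "
            f"{first['tree_id']} year {first['year']}"
        )
    if np.any((obs["defoliation"] < 0) | (obs["defoliation"] > 100)):
        raise ValueError("defoliation must lie in [0, 100]")

    years = np.sort(obs["year"].unique())
    if len(years) < 2:
        raise ValueError("observations must span at least 2 survey years")

    defol = obs.pivot(index=["plot_id", "tree_id"], columns="year", values="defoliation")
    defol = defol.reindex(columns=years)
    assessed = defol.notna().to_numpy()
    dvals = defol.to_numpy()

    rows = []
    dead_before = np.zeros(len(defol), dtype=bool)
    for j, year in enumerate(years[:-1]):
        if years[j + 1] != year + 1:
            # gap in the survey: absence in a skipped year is not informative
            continue
        at_risk = assessed[:, j] & ~dead_before
        full_defol = at_risk & (dvals[:, j] == 100.0)
        gone_next = ~assessed[:, j + 1]
        dead = full_defol & gone_next
        censored = at_risk & gone_next & ~full_defol
        survived = at_risk & ~gone_next
        dead_before = dead_before | dead
        rows.append(
            {
                "year": int(year),
                "n_at_risk": int(at_risk.sum()),
                "n_dead": int(dead.sum()),
                "n_censored": int(censored.sum()),
                "n_survived": int(survived.sum()),
            }
        )
    return pd.DataFrame(rows)


def tree_mortality_trend(
    counts: pd.DataFrame, config: TrendModelConfig | None = None
) -> TrendPosterior:
    """Trend in individual-tree mortality: the binomial trend model with
    trees at risk as trials and tree deaths as successes."""
    renamed = counts.rename(
        columns={"n_at_risk": "n_forest", "n_dead": "n_mortality"}
    )
    return fit_trend(renamed[["year", "n_forest", "n_mortality"]], config)


# --- beta-regression trend for fraction proxies -----------------------------

@dataclass(frozen=True)
class BetaTrendConfig:
    chains: int = 2  # independent ensembles
    walkers: int = 32
    draws_per_chain: int = 1500
    warmup: int = 1500
    thin: int = 5
    seed: int = 0
    prior_intercept: tuple[float, float] = (0.0, 5.0)
    prior_slope: tuple[float, float] = (0.0, 0.2)
    prior_log_precision: tuple[float, float] = (np.log(100.0), 3.0)
    rhat_threshold: float = 1.01
    ess_threshold: float = 400.0


@dataclass
class BetaTrendFit:
    """Beta-regression fit y_t ~ Beta(mean m_t, precision phi),
    logit(m_t) = a + b (t - t_bar)."""

    name: str
    years: np.ndarray
    intercept_draws: np.ndarray
    slope_draws: np.ndarray
    precision_draws: np.ndarray
    diagnostics: dict = field(default_factory=dict)
    converged: bool = True

    @property
    def trend(self) -> PosteriorSummary:
        """Fractional change of the proxy per year, percent."""
        return PosteriorSummary.from_draws((np.exp(self.slope_draws) - 1.0) * 100.0)

    def trend_draws(self) -> np.ndarray:
        return (np.exp(self.slope_draws) - 1.0) * 100.0


def _adjust_boundaries(values: np.ndarray, name: str) -> np.ndarray:
    if np.any((values <= 0) | (values >= 1)):
        n = len(values)
        logger.info(
            "proxy %s: boundary values adjusted via y' = (y*(n-1)+0.5)/n", name
        )
        return (values * (n - 1) + 0.5) / n
    return values


def beta_trend(series: ProxySeries, config: BetaTrendConfig | None = None) -> BetaTrendFit:
    """Logit-linear time trend of a fraction proxy under a Beta likelihood."""
    config = config or BetaTrendConfig()
    if len(series.years) < 5:
        raise ValueError("beta_trend needs at least 5 observations")
    y = _adjust_boundaries(series.values.astype(float), series.name)
    t = series.years.astype(float)
    tc = t - t.mean()
    log_y = np.log(y)
    log_1my = np.log1p(-y)

    (ma, sa), (mb, sb) = config.prior_intercept, config.prior_slope
    mp, sp = config.prior_log_precision

    def log_prob(theta: np.ndarray) -> np.ndarray:
        a, b, log_phi = theta[:, 0], theta[:, 1], theta[:, 2]
        phi = np.exp(np.clip(log_phi, -20, 20))
        m = expit(a[:, None] + b[:, None] * tc[None, :])
        p = m * phi[:, None]
        q = (1.0 - m) * phi[:, None]
        loglik = np.sum(
            gammaln(phi[:, None]) - gammaln(p) - gammaln(q)
            + (p - 1.0) * log_y[None, :] + (q - 1.0) * log_1my[None, :],
            axis=1,
        )
        return (
            loglik
            + normal_logpdf(a, ma, sa)
            + normal_logpdf(b, mb, sb)
            + normal_logpdf(log_phi, mp, sp)
        )

    a0 = float(np.log(y.mean() / (1.0 - y.mean())))

    def init(rng: np.random.Generator) -> np.ndarray:
        return np.column_stack(
            [
                a0 + 0.2 * rng.standard_normal(config.walkers),
                0.01 * rng.standard_normal(config.walkers),
                np.log(50.0) + rng.standard_normal(config.walkers),
            ]
        )

    res = run_ensemble(
        log_prob,
        init,
        ensembles=config.chains,
        warmup=config.warmup,
        steps=config.draws_per_chain,
        seed=config.seed + 1,
        thin=config.thin,
        param_names=["a", "b", "log_phi"],
        rhat_threshold=config.rhat_threshold,
        ess_threshold=config.ess_threshold,
    )
    if not res.converged:
        warnings.warn(
            f"beta trend for {series.name} did not converge: {res.diagnostics}",
            ConvergenceWarning,
            stacklevel=2,
        )
    return BetaTrendFit(
        name=series.name,
        years=series.years.copy(),
        intercept_draws=res.flat("a"),
        slope_draws=res.flat("b"),
        precision_draws=np.exp(res.flat("log_phi")),
        diagnostics=res.diagnostics,
        converged=res.converged,
    )


# --- correlation of canopy mortality with proxies ---------------------------

def correlate(
    canopy: TrendPosterior,
    proxy: ProxySeries,
    method: str = "posterior",
    seed: int = 0,
    n_boot: int = 2000,
) -> PosteriorSummary:
    """Pearson correlation between annual canopy mortality and a proxy.

    ``method="posterior"`` (default) computes r between each posterior draw's
    annual rates and the fixed proxy over the overlapping years, summarising
    across draws.  ``method="bootstrap"`` instead resamples overlapping years
    and correlates the posterior-median rates with the proxy.
    """
    years = np.asarray(canopy.years, dtype=int)
    common, idx_c, idx_p = np.intersect1d(
        years, np.asarray(proxy.years, dtype=int), return_indices=True
    )
    if len(common) < 5:
        raise ValueError(
            f"need >= 5 overlapping years, got {len(common)}"
        )
    rates = canopy.rate_draws()[:, idx_c]
    pvals = proxy.values[idx_p]

    if method == "posterior":
        r = _pearson_rows(rates, pvals)
        return PosteriorSummary.from_draws(r)
    if method == "bootstrap":
        med = np.median(rates, axis=0)
        rng = np.random.default_rng(seed)
        k = len(common)
        idx = rng.integers(0, k, size=(n_boot, k))
        r = _pearson_rows(med[idx], None, y_rows=pvals[idx])
        r = r[np.isfinite(r)]
        return PosteriorSummary.from_draws(r)
    raise ValueError(f"unknown method {method!r}")


def _pearson_rows(
    x: np.ndarray, y: np.ndarray | None, y_rows: np.ndarray | None = None
) -> np.ndarray:
    """Row-wise Pearson r of x (n, k) against y (k,) or paired rows y_rows."""
    xc = x - x.mean(axis=1, keepdims=True)
    if y_rows is None:
        yc = y - y.mean()
        denom = np.sqrt((xc**2).sum(axis=1) * (yc**2).sum())
        return (xc @ yc) / denom
    yc = y_rows - y_rows.mean(axis=1, keepdims=True)
    denom = np.sqrt((xc**2).sum(axis=1) * (yc**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        return (xc * yc).sum(axis=1) / denom
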
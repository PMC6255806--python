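"""Hierarchical binomial model for annual mortality rates and trends.

For one stratum (country) with ``y_t`` plots experiencing a mortality event
out of ``n_t`` forest plots at risk in year ``t``:

    y_t ~ Binomial(n_t, p_t)
    logit(p_t) = mu + beta * (t - t_bar) + eps_t,   eps_t ~ Normal(0, sigma)

Each year's rate thus emerges from a common population: a log-linear trend on
the logit scale plus exchangeable annual deviations.  The fractional change in
the mortality rate per year is alpha = exp(beta) - 1 (exact on the log scale
and an excellent approximation on the logit scale for rates well below 1),
reported in percent per year together with the posterior probability of a
positive trend P(alpha > 0).

Country posteriors are combined into a regional estimate by an area-weighted
mean of the posterior draws, honouring the stratified sampling design.

Sampling uses an affine-invariant ensemble MCMC with a non-centred
parameterisation of the annual deviations; walkers serve as chains for
split-R-hat and bulk-ESS diagnostics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from ._mcmc import halfnormal_logpdf, normal_logpdf, run_ensemble, softplus
from .summaries import PosteriorSummary

__all__ = [
    "TrendModelConfig",
    "TrendPosterior",
    "CountryWeights",
    "fit_trend",
    "annual_rates",
    "fractional_change",
    "p_positive",
    "pool_draws",
    "pool_posteriors",
    "ConvergenceWarning",
]


class ConvergenceWarning(UserWarning):
    pass


@dataclass(frozen=True)
class TrendModelConfig:
    """MCMC and prior settings for the rate-and-trend model.

    ``chains`` independent walker ensembles are run for ``draws_per_chain``
    post-warmup steps each (``walkers`` walkers per ensemble, draws stored
    every ``thin`` steps).  Priors are weakly informative on the logit scale:
    the baseline prior is centred near a 0.8% annual rate and all priors are
    overwhelmed by data at the design scale of thousands of plots per stratum.
    """

    chains: int = 2
    walkers: int = 80
    draws_per_chain: int = 2500
    warmup: int = 2500
    thin: int = 10
    seed: int = 0
    prior_baseline: tuple[float, float] = (-4.8, 1.5)
    prior_slope: tuple[float, float] = (0.0, 0.1)
    prior_sd_annual: float = 0.5
    rhat_threshold: float = 1.01
    ess_threshold: float = 400.0

    def __post_init__(self) -> None:
        if min(self.chains, self.draws_per_chain, self.warmup) <= 0:
            raise ValueError("chains, draws_per_chain and warmup must be positive")
        if self.rhat_threshold <= 1.0:
            raise ValueError("rhat_threshold must exceed 1")


@dataclass
class TrendPosterior:
    """Joint posterior draws of the rate-and-trend model for one stratum."""

    years: np.ndarray
    mu_draws: np.ndarray
    beta_draws: np.ndarray
    sigma_draws: np.ndarray
    eps_draws: np.ndarray  # (ndraw, nyears)
    diagnostics: dict = field(default_factory=dict)
    converged: bool = True

    def __post_init__(self) -> None:
        n = len(self.mu_draws)
        if not (
            len(self.beta_draws) == len(self.sigma_draws) == n
            and self.eps_draws.shape == (n, len(self.years))
        ):
            raise ValueError("draw vectors have inconsistent lengths")

    @property
    def ndraws(self) -> int:
        return len(self.mu_draws)

    def rate_draws(self) -> np.ndarray:
        """Annual mortality probabilities p_t, shape (ndraw, nyears)."""
        tc = self.years - self.years.mean()
        eta = (
            self.mu_draws[:, None]
            + self.beta_draws[:, None] * tc[None, :]
            + self.eps_draws
        )
        return expit(eta)

    def mean_rate_draws(self) -> np.ndarray:
        """Per-draw mean annual rate over the covered years."""
        return self.rate_draws().mean(axis=1)

    def alpha_draws(self) -> np.ndarray:
        """Fractional change in rate, percent per year."""
        return (np.exp(self.beta_draws) - 1.0) * 100.0


def _validate_counts(counts: pd.DataFrame) -> pd.DataFrame:
    required = {"year", "n_forest", "n_mortality"}
    missing = required - set(counts.columns)
    if missing:
        raise ValueError(f"counts table missing columns: {sorted(missing)}")
    counts = counts.sort_values("year").reset_index(drop=True)
    if counts["year"].duplicated().any():
        raise ValueError("duplicate years in counts table (one stratum expected)")
    if len(counts) < 5:
        raise ValueError("need at least 5 years of counts")
    n = counts["n_forest"].to_numpy()
    y = counts["n_mortality"].to_numpy()
    if not (np.all(n == n.astype(int)) and np.all(y == y.astype(int))):
        raise ValueError("counts must be integers")
    if np.any(n <= 0):
        raise ValueError("n_forest must be positive in every year")
    if np.any(y < 0) or np.any(y > n):
        raise ValueError("n_mortality must satisfy 0 <= n_mortality <= n_forest")
    return counts


def fit_trend(counts: pd.DataFrame, config: TrendModelConfig | None = None) -> TrendPosterior:
    """Fit the hierarchical binomial trend model to one stratum's counts.

    ``counts`` needs columns year, n_forest, n_mortality covering >= 5 years.
    Returns posterior draws; non-convergence (split-R-hat or bulk ESS beyond
    the configured bounds) is flagged on the result and warned, never silent.
    """
    config = config or TrendModelConfig()
    counts = _validate_counts(counts)
    years = counts["year"].to_numpy(dtype=float)
    n = counts["n_forest"].to_numpy(dtype=float)
    y = counts["n_mortality"].to_numpy(dtype=float)
    T = len(years)
    tc = years - years.mean()

    m0, s0 = config.prior_baseline
    mb, sb = config.prior_slope
    ssd = config.prior_sd_annual

    def log_prob(theta: np.ndarray) -> np.ndarray:
        mu = theta[:, 0]
        beta = theta[:, 1]
        log_sigma = theta[:, 2]
        z = theta[:, 3:]
        sigma = np.exp(log_sigma)
        eta = mu[:, None] + beta[:, None] * tc[None, :] + sigma[:, None] * z
        loglik = np.sum(y[None, :] * eta - n[None, :] * softplus(eta), axis=1)
        lp = (
            normal_logpdf(mu, m0, s0)
            + normal_logpdf(beta, mb, sb)
            + halfnormal_logpdf(sigma, ssd)
            + log_sigma  # Jacobian of the log transform
            - 0.5 * np.sum(z**2, axis=1)
        )
        return loglik + lp

    mu0 = float(logit((y.sum() + 0.5) / (n.sum() + 1.0)))
    mu0 = float(np.clip(mu0, m0 - 3 * s0, m0 + 3 * s0))
    ndim = 3 + T
    nwalkers = max(config.walkers, 2 * ndim + 2)

    def init(rng: np.random.Generator) -> np.ndarray:
        p0 = np.empty((nwalkers, ndim))
        p0[:, 0] = mu0 + 0.1 * rng.standard_normal(nwalkers)
        p0[:, 1] = 0.02 * rng.standard_normal(nwalkers)
        p0[:, 2] = np.log(0.1) + 0.3 * rng.standard_normal(nwalkers)
        p0[:, 3:] = 0.3 * rng.standard_normal((nwalkers, T))
        return p0

    names = ["mu", "beta", "log_sigma"] + [f"z[{i}]" for i in range(T)]
    res = run_ensemble(
        log_prob,
        init,
        ensembles=config.chains,
        warmup=config.warmup,
        steps=config.draws_per_chain,
        seed=config.seed + 1,
        thin=config.thin,
        param_names=names,
        rhat_threshold=config.rhat_threshold,
        ess_threshold=config.ess_threshold,
        check_names=["mu", "beta", "log_sigma"],
    )
    if not res.converged:
        warnings.warn(
            f"trend model did not meet convergence targets: {res.diagnostics}",
            ConvergenceWarning,
            stacklevel=2,
        )
    sigma_draws = np.exp(res.flat("log_sigma"))
    post = TrendPosterior(
        years=years,
        mu_draws=res.flat("mu"),
        beta_draws=res.flat("beta"),
        sigma_draws=sigma_draws,
        eps_draws=sigma_draws[:, None] * res.flat_block("z"),
        diagnostics=res.diagnostics,
        converged=res.converged,
    )
    return post


def annual_rates(post: TrendPosterior) -> pd.DataFrame:
    """Per-year posterior summaries of the annual mortality rate, in percent."""
    rates = post.rate_draws() * 100.0
    rows = []
    for j, year in enumerate(post.years):
        s = PosteriorSummary.from_draws(rates[:, j])
        rows.append(
            {
                "year": int(year),
                "median": s.median,
                "ci_low": s.ci_low,
                "ci_high": s.ci_high,
            }
        )
    return pd.DataFrame(rows)


def fractional_change(post: TrendPosterior) -> PosteriorSummary:
    """Posterior summary of alpha = exp(beta) - 1, in percent per year."""
    return PosteriorSummary.from_draws(post.alpha_draws())


def p_positive(post: TrendPosterior | np.ndarray) -> float:
    """Posterior probability of a positive trend, P(alpha > 0)."""
    draws = post.alpha_draws() if isinstance(post, TrendPosterior) else np.asarray(post)
    return float(np.mean(draws > 0))


@dataclass(frozen=True)
class CountryWeights:
    """Normalised pooling weights, proportional to country (forest) area."""

    weights: dict[str, float]

    def __post_init__(self) -> None:
        vals = np.array(list(self.weights.values()), dtype=float)
        if np.any(vals < 0):
            raise ValueError("weights must be non-negative")
        if abs(vals.sum() - 1.0) > 1e-12:
            raise ValueError(f"weights must sum to 1 (got {vals.sum()})")

    @classmethod
    def from_areas(cls, areas: dict[str, float]) -> "CountryWeights":
        total = float(sum(areas.values()))
        if total <= 0:
            raise ValueError("areas must have positive total")
        return cls({k: v / total for k, v in areas.items()})

    def __getitem__(self, country: str) -> float:
        return self.weights[country]

    def countries(self) -> list[str]:
        return list(self.weights)


def pool_draws(
    draws_by_country: dict[str, np.ndarray],
    weights: CountryWeights,
    seed: int = 0,
) -> np.ndarray:
    """Area-weighted mean of per-country posterior draws.

    Draw i of the pooled posterior is sum_c w_c * draw_{i,c}.  Draw vectors of
    unequal length are resampled (with replacement) to a common size first.
    """
    missing = [c for c in draws_by_country if c not in weights.weights]
    if missing:
        raise ValueError(f"countries missing from weights: {missing}")
    missing = [c for c in weights.countries() if c not in draws_by_country]
    if missing:
        raise ValueError(f"countries missing from posteriors: {missing}")

    arrays = {c: np.asarray(d, dtype=float) for c, d in draws_by_country.items()}
    sizes = {a.shape[0] for a in arrays.values()}
    if len(sizes) > 1:
        size = min(sizes)
        rng = np.random.default_rng(seed)
        arrays = {
            c: a if a.shape[0] == size else a[rng.integers(0, a.shape[0], size)]
            for c, a in arrays.items()
        }
    pooled = None
    for c, a in arrays.items():
        term = weights[c] * a
        pooled = term if pooled is None else pooled + term
    return pooled


def pool_posteriors(
    posts: dict[str, TrendPosterior],
    weights: CountryWeights,
    quantity: str = "alpha",
    seed: int = 0,
) -> np.ndarray:
    """Pooled draws of a derived quantity across country posteriors.

    quantity: "alpha" (percent/yr), "mean_rate" (period-mean annual
    probability) or "annual_rate" (per-year probabilities; requires identical
    year coverage across countries).
    """
    if quantity == "alpha":
        draws = {c: p.alpha_draws() for c, p in posts.items()}
    elif quantity == "mean_rate":
        draws = {c: p.mean_rate_draws() for c, p in posts.items()}
    elif quantity == "annual_rate":
        years = {tuple(p.years) for p in posts.values()}
        if len(years) > 1:
            raise ValueError("annual_rate pooling requires identical years")
        draws = {c: p.rate_draws() for c, p in posts.items()}
    else:
        raise ValueError(f"unknown quantity {quantity!r}")
    return pool_draws(draws, weights, seed=seed)
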
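"""Relating mortality to climate and forest structure at 5-year resolution.

Annual mortality rates and covariates (mean annual temperature, total annual
precipitation, growing stock, median stand age) are averaged to six fixed
5-year intervals per country.  Log mortality is then regressed on one
covariate at a time with a Bayesian hierarchical log-linear model,

    log(m_ci) = a_c + b_c * x_ci + e_ci,   e_ci ~ Normal(0, sigma_e),

where intercepts a_c (and, in the random-intercept-and-slope variant, slopes
b_c) vary between countries around partially pooled population means.  The
two variants are compared by Pareto-smoothed importance-sampling leave-one-out
cross-validation (PSIS-LOO), falling back to exact refit LOO when the
importance ratios are unreliable.

Covariates are standardised internally for sampling; reported slopes and
marginal effects are on the natural scale (percentage points of forest area
per covariate unit).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import arviz as az
import numpy as np
import pandas as pd

from ._mcmc import halfnormal_logpdf, normal_logpdf, run_ensemble
from .summaries import PosteriorSummary
from .trend import ConvergenceWarning

__all__ = [
    "INTERVALS",
    "interval_label",
    "make_panel",
    "CovariateConfig",
    "CovariateFit",
    "VariantComparison",
    "fit_covariate",
    "compare_variants",
    "marginal_effect",
]

logger = logging.getLogger(__name__)

# The six fixed intervals; the outer ones absorb the first and last study years.
INTERVALS: list[tuple[int, int]] = [
    (1984, 1989),
    (1990, 1994),
    (1995, 1999),
    (2000, 2004),
    (2005, 2009),
    (2010, 2015),
]

COVARIATE_NAMES = ["temperature", "precipitation", "growing_stock", "median_age"]

PANEL_COLUMNS = ["country", "interval"] + ["mortality"] + COVARIATE_NAMES


def interval_label(year: int) -> str:
    for lo, hi in INTERVALS:
        if lo <= year <= hi:
            return f"{lo}-{hi}"
    raise ValueError(f"year {year} outside the study period {INTERVALS[0][0]}-{INTERVALS[-1][1]}")


def make_panel(
    rates: pd.DataFrame,
    climate: pd.DataFrame,
    structure: pd.DataFrame,
) -> pd.DataFrame:
    """Country x 5-year-interval panel of mortality and covariates.

    ``rates`` needs columns country, year, mortality (annual rate in %;
    posterior medians); ``climate`` country, year, temperature, precipitation;
    ``structure`` country, year, growing_stock, median_age (annual or sparser
    — available years are averaged within their interval as-is).  Each panel
    cell is the arithmetic mean of the annual values inside its interval.
    """
    parts = []
    for df, cols in (
        (rates, ["mortality"]),
        (climate, ["temperature", "precipitation"]),
        (structure, ["growing_stock", "median_age"]),
    ):
        missing = {"country", "year", *cols} - set(df.columns)
        if missing:
            raise ValueError(f"input table missing columns: {sorted(missing)}")
        d = df[["country", "year", *cols]].copy()
        d["interval"] = d["year"].map(interval_label)  # errors on out-of-period years
        parts.append(
            d.groupby(["country", "interval"], as_index=False)[cols].mean()
        )
    panel = parts[0]
    for p in parts[1:]:
        panel = panel.merge(p, on=["country", "interval"], how="outer")
    order = {f"{lo}-{hi}": i for i, (lo, hi) in enumerate(INTERVALS)}
    panel["_o"] = panel["interval"].map(order)
    panel = panel.sort_values(["country", "_o"]).drop(columns="_o").reset_index(drop=True)
    return panel[PANEL_COLUMNS]


@dataclass(frozen=True)
class CovariateConfig:
    chains: int = 2  # independent ensembles
    walkers: int = 64
    draws_per_chain: int = 2000
    warmup: int = 2000
    thin: int = 8
    seed: int = 0
    prior_intercept: tuple[float, float] = (0.0, 5.0)
    prior_slope: tuple[float, float] = (0.0, 2.5)
    prior_sd_country: float = 1.0
    prior_sd_resid: float = 1.0
    rhat_threshold: float = 1.01
    ess_threshold: float = 400.0


@dataclass
class CovariateFit:
    """Posterior of one hierarchical log-linear covariate model."""

    covariate: str
    variant: str  # random_intercept | random_intercept_slope
    countries: list[str]
    x_mean: float
    x_sd: float
    # draws, all on the standardised-x scale except slope_nat_draws
    mu_b_draws: np.ndarray  # population slope (standardised x)
    a_draws: np.ndarray  # (ndraw, C) country intercepts
    b_draws: np.ndarray  # (ndraw, C) country slopes
    sigma_e_draws: np.ndarray
    r2_draws: np.ndarray
    loglik_pointwise: np.ndarray  # (walkers, steps, ncells)
    x_std: np.ndarray  # standardised covariate per cell
    country_idx: np.ndarray
    log_m: np.ndarray
    diagnostics: dict = field(default_factory=dict)
    converged: bool = True
    _loo: object | None = None

    @property
    def slope_nat_draws(self) -> np.ndarray:
        """Population slope per natural covariate unit (log-mortality scale)."""
        return self.mu_b_draws / self.x_sd

    @property
    def p_beta_positive(self) -> float:
        return float(np.mean(self.mu_b_draws > 0))

    @property
    def r2(self) -> PosteriorSummary:
        return PosteriorSummary.from_draws(self.r2_draws)

    def loo(self):
        if self._loo is None:
            idata = az.from_dict(
                posterior={"mu_b": self.mu_b_draws.reshape(self.loglik_pointwise.shape[:2])},
                log_likelihood={"log_m": self.loglik_pointwise},
            )
            self._loo = az.loo(idata, pointwise=True)
        return self._loo


def _prepare_panel(panel: pd.DataFrame, covariate: str) -> tuple:
    for col in ("country", "mortality", covariate):
        if col not in panel.columns:
            raise ValueError(f"panel missing column {covariate!r}" if col == covariate else f"panel missing column {col!r}")
    data = panel.dropna(subset=["mortality", covariate])
    if np.any(data["mortality"] <= 0):
        raise ValueError("mortality must be positive for log-linear fitting")
    counts = data.groupby("country").size()
    if (counts < 2).any():
        raise ValueError("need >= 2 intervals per country")
    countries = sorted(data["country"].unique())
    cidx = data["country"].map({c: i for i, c in enumerate(countries)}).to_numpy()
    x = data[covariate].to_numpy(dtype=float)
    log_m = np.log(data["mortality"].to_numpy(dtype=float))
    return countries, cidx, x, log_m


def fit_covariate(
    panel: pd.DataFrame,
    covariate: str,
    variant: str = "random_intercept_slope",
    config: CovariateConfig | None = None,
) -> CovariateFit:
    """Fit log(mortality) on one covariate with partially pooled country effects."""
    if variant not in ("random_intercept", "random_intercept_slope"):
        raise ValueError(f"unknown variant {variant!r}")
    config = config or CovariateConfig()
    countries, cidx, x, log_m = _prepare_panel(panel, covariate)
    C = len(countries)
    x_mean, x_sd = float(x.mean()), float(x.std())
    if x_sd == 0:
        raise ValueError(f"covariate {covariate!r} is constant")
    xs = (x - x_mean) / x_sd

    (ma, sa), (mb, sb) = config.prior_intercept, config.prior_slope
    sdc, sdr = config.prior_sd_country, config.prior_sd_resid
    slopes_vary = variant == "random_intercept_slope"
    # layout: mu_a, mu_b, log_sig_a, log_sig_e, [log_sig_b], za_c..., [zb_c...]
    base = 4 + (1 if slopes_vary else 0)
    ndim = base + C + (C if slopes_vary else 0)

    def unpack(theta):
        mu_a, mu_b = theta[:, 0], theta[:, 1]
        sig_a = np.exp(np.clip(theta[:, 2], -15, 10))
        sig_e = np.exp(np.clip(theta[:, 3], -15, 10))
        za = theta[:, base : base + C]
        a = mu_a[:, None] + sig_a[:, None] * za
        if slopes_vary:
            sig_b = np.exp(np.clip(theta[:, 4], -15, 10))
            zb = theta[:, base + C :]
            b = mu_b[:, None] + sig_b[:, None] * zb
        else:
            sig_b, zb = None, None
            b = np.repeat(mu_b[:, None], C, axis=1)
        return mu_a, mu_b, sig_a, sig_e, sig_b, za, zb, a, b

    def pointwise(theta):
        _, _, _, sig_e, _, _, _, a, b = unpack(theta)
        fitted = a[:, cidx] + b[:, cidx] * xs[None, :]
        resid = log_m[None, :] - fitted
        return (
            -0.5 * (resid / sig_e[:, None]) ** 2
            - np.log(sig_e[:, None])
            - 0.5 * np.log(2 * np.pi)
        )

    def log_prob(theta):
        mu_a, mu_b, sig_a, sig_e, sig_b, za, zb, a, b = unpack(theta)
        loglik = pointwise(theta).sum(axis=1)
        lp = (
            normal_logpdf(mu_a, ma, sa)
            + normal_logpdf(mu_b, mb, sb)
            + halfnormal_logpdf(sig_a, sdc) + theta[:, 2]
            + halfnormal_logpdf(sig_e, sdr) + theta[:, 3]
            - 0.5 * np.sum(za**2, axis=1)
        )
        if slopes_vary:
            lp = lp + halfnormal_logpdf(sig_b, sdc) + theta[:, 4]
            lp = lp - 0.5 * np.sum(zb**2, axis=1)
        return loglik + lp

    nwalkers = max(config.walkers, 2 * ndim + 2)

    def init(rng: np.random.Generator) -> np.ndarray:
        p0 = np.zeros((nwalkers, ndim))
        p0[:, 0] = log_m.mean() + 0.2 * rng.standard_normal(nwalkers)
        p0[:, 1] = 0.05 * rng.standard_normal(nwalkers)
        p0[:, 2] = np.log(0.3) + 0.3 * rng.standard_normal(nwalkers)
        p0[:, 3] = np.log(max(log_m.std(), 0.05)) + 0.3 * rng.standard_normal(nwalkers)
        if slopes_vary:
            p0[:, 4] = np.log(0.1) + 0.3 * rng.standard_normal(nwalkers)
        p0[:, base:] = 0.3 * rng.standard_normal((nwalkers, ndim - base))
        return p0

    names = ["mu_a", "mu_b", "lsa", "lse"] + (["lsb"] if slopes_vary else [])
    names += [f"za[{i}]" for i in range(C)]
    if slopes_vary:
        names += [f"zb[{i}]" for i in range(C)]
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
        check_names=["mu_a", "mu_b", "lse"],
    )
    if not res.converged:
        warnings.warn(
            f"covariate model ({covariate}, {variant}) did not converge: "
            f"{res.diagnostics}",
            ConvergenceWarning,
            stacklevel=2,
        )

    W, S, _ = res.chain.shape
    flat = res.chain.reshape(W * S, ndim)
    _, mu_b, _, sig_e, _, _, _, a, b = unpack(flat)
    fitted = a[:, cidx] + b[:, cidx] * xs[None, :]
    var_fit = fitted.var(axis=1)
    r2 = var_fit / (var_fit + sig_e**2)
    ll = pointwise(flat).reshape(W, S, len(xs))

    return CovariateFit(
        covariate=covariate,
        variant=variant,
        countries=countries,
        x_mean=x_mean,
        x_sd=x_sd,
        mu_b_draws=mu_b,
        a_draws=a,
        b_draws=b,
        sigma_e_draws=sig_e,
        r2_draws=r2,
        loglik_pointwise=ll,
        x_std=xs,
        country_idx=cidx,
        log_m=log_m,
        diagnostics=res.diagnostics,
        converged=res.converged,
    )


@dataclass(frozen=True)
class VariantComparison:
    selected: str
    elpd: dict[str, float]
    diff: float  # elpd(selected) - elpd(other)
    diff_se: float
    method: str  # psis | exact_refit


def _exact_loo_pointwise(fit: CovariateFit) -> np.ndarray:
    """Exact leave-one-out log predictive density per cell (refit per cell).

    Slow path, used only when PSIS importance ratios are unreliable.  Refits
    use reduced sampler settings; the per-cell predictive density is the
    posterior-mean likelihood of the held-out cell.
    """
    n = len(fit.x_std)
    x_nat = fit.x_std * fit.x_sd + fit.x_mean
    panel = pd.DataFrame(
        {
            "country": [fit.countries[i] for i in fit.country_idx],
            "mortality": np.exp(fit.log_m),
            fit.covariate: x_nat,
        }
    )
    cfg = CovariateConfig(
        chains=1, walkers=48, draws_per_chain=400, warmup=800, thin=2,
        ess_threshold=50,
    )
    out = np.empty(n)
    for i in range(n):
        sub = panel.drop(panel.index[i])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            f = fit_covariate(sub, fit.covariate, fit.variant, cfg)
        ci = f.countries.index(panel.iloc[i]["country"])
        xs_i = (x_nat[i] - f.x_mean) / f.x_sd
        mu = f.a_draws[:, ci] + f.b_draws[:, ci] * xs_i
        ll = (
            -0.5 * ((fit.log_m[i] - mu) / f.sigma_e_draws) ** 2
            - np.log(f.sigma_e_draws)
            - 0.5 * np.log(2 * np.pi)
        )
        out[i] = np.log(np.mean(np.exp(ll - ll.max()))) + ll.max()
    return out


def _loo_pointwise(fit: CovariateFit) -> tuple[np.ndarray, str]:
    loo = fit.loo()
    k = np.asarray(loo.pareto_k.values)
    if np.mean(k > 0.7) > 0.2:
        logger.warning(
            "PSIS unreliable for %s/%s (%.0f%% of cells with k>0.7); "
            "falling back to exact refit LOO",
            fit.covariate, fit.variant, 100 * np.mean(k > 0.7),
        )
        return _exact_loo_pointwise(fit), "exact_refit"
    return np.asarray(loo.loo_i.values), "psis"


def compare_variants(fit_a: CovariateFit, fit_b: CovariateFit) -> VariantComparison:
    """Select the variant with the higher out-of-sample predictive density.

    Both fits must be on the same panel cells.  Reports both expected log
    predictive densities and the standard error of their pointwise difference.
    """
    if len(fit_a.x_std) != len(fit_b.x_std):
        raise ValueError("fits are not on the same panel")
    pa, meth_a = _loo_pointwise(fit_a)
    pb, meth_b = _loo_pointwise(fit_b)
    elpd_a, elpd_b = float(pa.sum()), float(pb.sum())
    d = pa - pb
    diff_se = float(np.sqrt(len(d) * np.var(d)))
    if elpd_a >= elpd_b:
        sel, diff = fit_a.variant, elpd_a - elpd_b
    else:
        sel, diff = fit_b.variant, elpd_b - elpd_a
    return VariantComparison(
        selected=sel,
        elpd={fit_a.variant: elpd_a, fit_b.variant: elpd_b},
        diff=diff,
        diff_se=diff_se,
        method="psis" if meth_a == meth_b == "psis" else "exact_refit",
    )


def marginal_effect(fit: CovariateFit, delta: float) -> PosteriorSummary:
    """Average marginal effect of a covariate increment on the response scale.

    Per draw, the mean over panel cells of exp(log m_hat + b*delta) - m_hat,
    with b the population slope per natural unit; in percentage points of
    forest area experiencing mortality per ``delta`` covariate units.
    """
    fitted = fit.a_draws[:, fit.country_idx] + fit.b_draws[:, fit.country_idx] * fit.x_std[None, :]
    m_hat = np.exp(fitted)
    shift = np.exp(fitted + fit.slope_nat_draws[:, None] * delta)
    return PosteriorSummary.from_draws((shift - m_hat).mean(axis=1))
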
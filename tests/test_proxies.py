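"""Proxy trends, tree-death derivation and canopy-proxy correlations."""

import warnings

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit, logit

from canopymort.proxies import (
    ProxySeries,
    beta_trend,
    correlate,
    derive_tree_deaths,
    tree_mortality_trend,
)
from canopymort.trend import ConvergenceWarning, TrendPosterior

from conftest import FAST_BETA, FAST_TREND


def tree_row(plot, tree, year, defol):
    return {"plot_id": plot, "tree_id": tree, "year": year, "defoliation": defol}


class TestDeriveTreeDeaths:
    def test_full_defoliation_then_absence_is_a_death(self):
        obs = pd.DataFrame([
            tree_row("p1", "t1", 1999, 30.0),
            tree_row("p1", "t1", 2000, 100.0),
            tree_row("p1", "t2", 1999, 10.0),
            tree_row("p1", "t2", 2000, 15.0),
            tree_row("p1", "t2", 2001, 20.0),
        ])
        counts = derive_tree_deaths(obs)
        y2000 = counts[counts.year == 2000].iloc[0]
        assert (y2000.n_at_risk, y2000.n_dead) == (2, 1)

    def test_full_defoliation_but_still_assessed_is_not_a_death(self):
        obs = pd.DataFrame([
            tree_row("p1", "t1", 2000, 100.0),
            tree_row("p1", "t1", 2001, 100.0),
            tree_row("p1", "t1", 2002, 90.0),
        ])
        counts = derive_tree_deaths(obs)
        assert counts[counts.year == 2000].iloc[0].n_dead == 0
        # absent after 2002 would be unknowable: final year carries no risk set
        assert set(counts.year) == {2000, 2001}

    def test_departure_without_full_defoliation_is_censoring(self):
        obs = pd.DataFrame([
            tree_row("p1", "t1", 2000, 40.0),  # leaves alive
            tree_row("p1", "t2", 2000, 100.0),  # dies
            tree_row("p1", "t3", 2000, 10.0),
            tree_row("p1", "t3", 2001, 10.0),
        ])
        counts = derive_tree_deaths(obs)
        y = counts[counts.year == 2000].iloc[0]
        assert (y.n_at_risk, y.n_dead, y.n_censored, y.n_survived) == (3, 1, 1, 1)

    def test_matches_brute_force_scan_on_scripted_panel(self):
        rng = np.random.default_rng(12)
        years = np.arange(2000, 2008)
        rows, truth = [], {int(y): {"risk": 0, "dead": 0} for y in years[:-1]}
        for k in range(10):
            death_year = rng.choice([None, 2002, 2004, 2006], p=[0.4, 0.2, 0.2, 0.2])
            censor_year = rng.choice([None, 2005], p=[0.8, 0.2])
            for y in years:
                if death_year is not None and y > death_year:
                    break
                if censor_year is not None and death_year is None and y > censor_year:
                    break
                defol = 100.0 if y == death_year else float(rng.uniform(0, 90))
                rows.append(tree_row("p1", f"t{k}", int(y), defol))
        obs = pd.DataFrame(rows)
        # brute force: per tree, per year with a successor survey
        per_tree = {t: g.set_index("year")["defoliation"] for t, g in obs.groupby("tree_id")}
        dead_already = set()
        for y in years[:-1]:
            for t, d in per_tree.items():
                if t in dead_already or y not in d.index:
                    continue
                truth[int(y)]["risk"] += 1
                if d[y] == 100.0 and (y + 1) not in d.index:
                    truth[int(y)]["dead"] += 1
                    dead_already.add(t)
        counts = derive_tree_deaths(obs).set_index("year")
        for y in years[:-1]:
            y = int(y)
            if truth[y]["risk"] == 0:
                assert y not in counts.index or counts.loc[y, "n_at_risk"] == 0
            else:
                assert counts.loc[y, "n_at_risk"] == truth[y]["risk"]
                assert counts.loc[y, "n_dead"] == truth[y]["dead"]

    def test_full_accounting_each_year(self):
        from canopymort.simulate import gen_trees, paper_like

        cfg = paper_like(seed=3)
        cfg = type(cfg)(**{**cfg.__dict__, "trees": type(cfg.trees)(
            n_plots=40, trees_per_plot=20, base_death_prob=0.02,
            death_trend=0.0, years=(1995, 2005),
        )})
        counts = derive_tree_deaths(gen_trees(cfg))
        assert (
            counts.n_dead + counts.n_censored + counts.n_survived == counts.n_at_risk
        ).all()

    def test_duplicate_observation_rejected(self):
        obs = pd.DataFrame([
            tree_row("p1", "t1", 2000, 10.0),
            tree_row("p1", "t1", 2000, 20.0),
            tree_row("p1", "t1", 2001, 10.0),
        ])
        with pytest.raises(ValueError, match="duplicate"):
            derive_tree_deaths(obs)


class TestTreeMortalityTrend:
    def test_declining_hazard_recovered_against_mle_oracle(self):
        """-1.5%/yr death-hazard decline at 70,000 trees is recovered."""
        import statsmodels.api as sm

        rng = np.random.default_rng(5)
        years = np.arange(1990, 2011)
        p = 0.006 * 0.985 ** (years - 1990)
        n = 70_000
        counts = pd.DataFrame(
            {"year": years, "n_at_risk": n, "n_dead": rng.binomial(n, p)}
        )
        post = tree_mortality_trend(counts, FAST_TREND)
        alpha = (np.exp(np.median(post.beta_draws)) - 1) * 100
        tc = years - years.mean()
        glm = sm.GLM(
            np.column_stack([counts.n_dead, counts.n_at_risk - counts.n_dead]),
            sm.add_constant(tc),
            family=sm.families.Binomial(),
        ).fit()
        alpha_mle = (np.exp(glm.params[1]) - 1) * 100
        se_pct = (np.exp(glm.bse[1]) - 1) * 100
        assert alpha == pytest.approx(alpha_mle, abs=3 * se_pct)
        assert alpha < 0

    def test_constant_hazard_gives_no_trend(self):
        rng = np.random.default_rng(6)
        years = np.arange(1990, 2011)
        counts = pd.DataFrame(
            {"year": years, "n_at_risk": 50_000,
             "n_dead": rng.binomial(50_000, 0.005, len(years))}
        )
        post = tree_mortality_trend(counts, FAST_TREND)
        alpha = post.alpha_draws()
        assert np.quantile(alpha, 0.025) < 0 < np.quantile(alpha, 0.975)


class TestBetaTrend:
    def test_constant_series_has_no_trend(self):
        rng = np.random.default_rng(8)
        years = np.arange(1984, 2017)
        vals = rng.beta(0.015 * 4000, 0.985 * 4000, len(years))
        fit = beta_trend(ProxySeries("wood_removal", years, vals), FAST_BETA)
        t = fit.trend
        assert t.ci_low < 0 < t.ci_high
        assert abs(t.median) < 1.0

    def test_recovers_trend_against_quasilikelihood_oracle(self):
        """Low-noise logit-linear series: slope matches a quasi-binomial GLM."""
        import statsmodels.api as sm

        rng = np.random.default_rng(9)
        years = np.arange(1984, 2017)
        m = expit(logit(0.015) + np.log(1.014) * (years - 1984))
        vals = rng.beta(m * 20000, (1 - m) * 20000)
        fit = beta_trend(ProxySeries("wood_removal", years, vals), FAST_BETA)
        tc = years - years.mean()
        glm = sm.GLM(
            vals, sm.add_constant(tc), family=sm.families.Binomial()
        ).fit(scale="X2")
        slope_ql = glm.params[1]
        assert float(np.median(fit.slope_draws)) == pytest.approx(
            slope_ql, abs=3 * glm.bse[1] + 1e-3
        )
        assert fit.trend.median == pytest.approx(1.4, abs=0.5)

    def test_boundary_values_adjusted_not_rejected(self):
        years = np.arange(2000, 2010)
        vals = np.array([0.0, 0.01, 0.02, 0.01, 0.03, 0.02, 0.01, 0.02, 0.03, 0.02])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            fit = beta_trend(ProxySeries("wind", years, vals), FAST_BETA)
        assert np.isfinite(fit.trend.median)

    def test_raw_values_outside_unit_interval_rejected(self):
        years = np.arange(2000, 2010)
        with pytest.raises(ValueError):
            ProxySeries("wind", years, np.linspace(-0.1, 0.5, 10))

    def test_too_few_observations_rejected(self):
        s = ProxySeries("wind", np.arange(2000, 2004), np.full(4, 0.1))
        with pytest.raises(ValueError, match="5"):
            beta_trend(s, FAST_BETA)


def degenerate_posterior(values, years):
    """Single-draw posterior whose annual rates equal `values` (scaled)."""
    from scipy.special import logit as lg

    vals = np.asarray(values, dtype=float) / 1000.0
    years = np.asarray(years, dtype=float)
    tc = years - years.mean()
    eta = lg(vals)
    # encode entirely in eps: mu=0, beta=0
    return TrendPosterior(
        years=years,
        mu_draws=np.zeros(1),
        beta_draws=np.zeros(1),
        sigma_draws=np.ones(1),
        eps_draws=eta[None, :],
    )


class TestCorrelate:
    def test_toy_vectors_match_closed_form(self):
        """x=(1..5), y=(2,1,4,3,6): r = cov/(sd_x sd_y) = 2/sqrt(2*2.96)."""
        from scipy.stats import pearsonr

        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        y = np.array([2.0, 1.0, 4.0, 3.0, 6.0])
        post = degenerate_posterior(x, np.arange(2000, 2005))
        proxy = ProxySeries("wood_removal", np.arange(2000, 2005), y / 1000.0)
        r = correlate(post, proxy)
        closed_form = 2.0 / np.sqrt(2.0 * 2.96)
        assert r.median == pytest.approx(closed_form, abs=1e-12)
        assert r.median == pytest.approx(pearsonr(x, y).statistic, abs=1e-12)

    def test_proxy_equal_to_rates_gives_unit_correlation(self):
        vals = np.array([1.0, 2.0, 1.5, 3.0, 2.5, 4.0])
        years = np.arange(2000, 2006)
        post = degenerate_posterior(vals, years)
        proxy = ProxySeries("wood_removal", years, vals / 1000.0)
        assert correlate(post, proxy).median == pytest.approx(1.0)

    def test_negated_proxy_gives_minus_one(self):
        vals = np.array([1.0, 2.0, 1.5, 3.0, 2.5, 4.0])
        years = np.arange(2000, 2006)
        post = degenerate_posterior(vals, years)
        proxy = ProxySeries(
            "wood_removal", years, (vals.max() + vals.min() - vals) / 1000.0
        )
        assert correlate(post, proxy).median == pytest.approx(-1.0)

    def test_affine_rescaling_of_proxy_invariant(self):
        rng = np.random.default_rng(10)
        years = np.arange(2000, 2010)
        vals = rng.uniform(1, 5, len(years))
        post = degenerate_posterior(vals + rng.normal(0, 1, len(years)), years)
        base = rng.uniform(0.01, 0.05, len(years))
        r1 = correlate(post, ProxySeries("wind", years, base))
        r2 = correlate(post, ProxySeries("wind", years, 0.5 * base + 0.01))
        assert r1.median == pytest.approx(r2.median, abs=1e-12)
        assert -1 <= r1.median <= 1

    def test_insufficient_overlap_rejected(self):
        post = degenerate_posterior([1, 2, 3, 4, 5], np.arange(2000, 2005))
        proxy = ProxySeries("wind", np.arange(2003, 2007), np.full(4, 0.1))
        with pytest.raises(ValueError, match="overlap"):
            correlate(post, proxy)
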
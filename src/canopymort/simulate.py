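"""Synthetic study generator: every input the pipeline consumes, with known truth.

Emulates a stratified random sample of interpreted Landsat pixels over six
central-European countries: per country a fixed number of plots drawn across
forest and non-forest land, annual Bernoulli canopy-mortality events on forest
plots with an exponential-in-time hazard

    p_t = base_rate * (1 + alpha) ** (t - start_year),

a configurable stand-replacing fraction per event, linearly trending climate
and forest-structure covariates, beta-distributed mortality-proxy fractions
with logit-linear means, and ICP-style tree panels with an annual death
hazard.

The default scenario (:func:`paper_like`) encodes the published study design:
4000 plots in each of six countries over 1984-2016, country mean rates and
trends whose forest-area-weighted means give a pooled mean annual canopy
mortality of ~0.79% and a pooled trend of ~2.4% per year.

Sub-generators draw from independent streams spawned from the scenario seed
(fixed spawn keys), so adding or re-running one generator never perturbs
another's output.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .proxies import ProxySeries
from .records import (
    LandCover,
    LandUse,
    Process,
    SamplePlot,
    Segment,
    Vertex,
    write_samples,
)

__all__ = [
    "CountryScenario",
    "Trajectory",
    "ProxyScenario",
    "TreeScenario",
    "ScenarioConfig",
    "paper_like",
    "base_rate_for_mean",
    "gen_samples",
    "gen_covariates",
    "gen_proxies",
    "gen_trees",
    "write_scenario",
]

REGROWTH_YEARS = 5  # fixed duration of cosmetic post-stand-replacing regrowth


@dataclass(frozen=True)
class CountryScenario:
    name: str
    n_samples: int
    forest_fraction: float
    base_rate: float  # annual mortality probability at the start year
    alpha: float  # fractional trend per year (0.024 = +2.4%/yr)
    sr_fraction: float  # probability an event is stand-replacing
    forest_area_weight: float

    def __post_init__(self) -> None:
        for p in (self.forest_fraction, self.base_rate, self.sr_fraction):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{self.name}: probabilities must lie in [0, 1]")
        if self.n_samples <= 0:
            raise ValueError(f"{self.name}: n_samples must be positive")


@dataclass(frozen=True)
class Trajectory:
    """Linear covariate trajectory: start value + annual increment + noise."""

    start: float
    increment: float
    noise_sd: float = 0.0


@dataclass(frozen=True)
class ProxyScenario:
    name: str
    logit_start: float  # logit of the mean fraction in the first year
    logit_slope: float  # change of the logit mean per year
    precision: float  # beta precision phi
    pulse_years: tuple[int, ...] = ()
    pulse_factor: float = 1.0


@dataclass(frozen=True)
class TreeScenario:
    n_plots: int
    trees_per_plot: int
    base_death_prob: float
    death_trend: float  # fractional change in death probability per year
    years: tuple[int, int] = (1990, 2010)


@dataclass(frozen=True)
class ScenarioConfig:
    seed: int
    years: tuple[int, int] = (1984, 2016)
    countries: tuple[CountryScenario, ...] = ()
    covariates: dict[str, dict[str, Trajectory]] = field(default_factory=dict)
    proxies: tuple[ProxyScenario, ...] = ()
    trees: TreeScenario | None = None
    canopy_pulse_years: tuple[int, ...] = ()
    canopy_pulse_factor: float = 1.0

    def __post_init__(self) -> None:
        if self.years[0] >= self.years[1]:
            raise ValueError("years must be an increasing (start, end) pair")
        if self.countries:
            total = sum(c.forest_area_weight for c in self.countries)
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"forest_area_weights must sum to 1 (got {total})")

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng(
            np.random.SeedSequence(entropy=self.seed, spawn_key=(stream,))
        )

    def event_years(self) -> np.ndarray:
        y0, y1 = self.years
        return np.arange(y0 + 1, y1 + 1)

    def hazard(self, country: CountryScenario) -> np.ndarray:
        """Annual event probability per event year, pulses applied."""
        y0, _ = self.years
        t = self.event_years()
        p = country.base_rate * (1.0 + country.alpha) ** (t - y0)
        for py in self.canopy_pulse_years:
            p = np.where(t == py, p * self.canopy_pulse_factor, p)
        return np.clip(p, 0.0, 1.0)

    def mean_rate(self, country: CountryScenario) -> float:
        """Generating mean annual event probability over the event years."""
        return float(self.hazard(country).mean())

    def pooled_mean_rate(self) -> float:
        return float(
            sum(c.forest_area_weight * self.mean_rate(c) for c in self.countries)
        )

    def pooled_alpha(self) -> float:
        """Generating forest-area-weighted trend, percent per year."""
        return float(
            sum(c.forest_area_weight * c.alpha for c in self.countries) * 100.0
        )


def base_rate_for_mean(mean_rate: float, alpha: float, years: tuple[int, int]) -> float:
    """Start-year hazard whose event-year mean equals ``mean_rate``."""
    y0, y1 = years
    k = np.arange(1, y1 - y0 + 1)
    growth = np.mean((1.0 + alpha) ** k)
    return mean_rate / growth


# Country design: land / forest areas in Mha (public statistics; forest total
# ~30.6 Mha over ~92.4 Mha of land), mean annual canopy mortality rate (% of
# forest area) and its fractional trend (%/yr).  Rates for Poland, Austria and
# Czechia and trends for Germany and Slovakia follow the published country
# estimates; the remaining values were fixed so the forest-area-weighted means
# equal the pooled estimates (0.79% and ~2.4 %/yr).
_COUNTRY_DESIGN = {
    #             land    forest  rate   alpha
    "austria":     (8.4,   3.9,   1.17,  2.8),
    "czechia":     (7.9,   2.7,   1.17,  3.0),
    "germany":     (35.8,  11.4,  0.75,  1.47),
    "poland":      (31.3,  9.4,   0.53,  2.7),
    "slovakia":    (4.9,   1.9,   1.00,  4.14),
    "switzerland": (4.1,   1.3,   0.77,  2.9),
}

# Baseline climate / structure for the linear covariate trajectories
# (mean annual T in deg C, annual precip in mm, growing stock in m3/ha,
# median age in yr): central-European country-scale magnitudes with a warming
# trend and post-war forest recovery (rising stocks and age).
_COVARIATE_DESIGN = {
    "austria":     {"temperature": (6.5, 0.035, 0.45), "precipitation": (1100.0, 0.0, 80.0), "growing_stock": (290.0, 2.2, 4.0), "median_age": (60.0, 0.35, 1.5)},
    "czechia":     {"temperature": (7.5, 0.035, 0.45), "precipitation": (680.0, 0.0, 60.0), "growing_stock": (250.0, 2.0, 4.0), "median_age": (58.0, 0.30, 1.5)},
    "germany":     {"temperature": (8.3, 0.035, 0.40), "precipitation": (700.0, 0.0, 60.0), "growing_stock": (280.0, 2.4, 4.0), "median_age": (62.0, 0.30, 1.5)},
    "poland":      {"temperature": (7.8, 0.035, 0.50), "precipitation": (600.0, 0.0, 55.0), "growing_stock": (210.0, 2.3, 4.0), "median_age": (55.0, 0.40, 1.5)},
    "slovakia":    {"temperature": (7.0, 0.035, 0.50), "precipitation": (750.0, 0.0, 65.0), "growing_stock": (230.0, 2.1, 4.0), "median_age": (57.0, 0.30, 1.5)},
    "switzerland": {"temperature": (5.8, 0.040, 0.45), "precipitation": (1200.0, 0.0, 90.0), "growing_stock": (340.0, 1.5, 4.0), "median_age": (75.0, 0.25, 1.5)},
}


def paper_like(
    seed: int = 0,
    n_samples: int = 4000,
    sr_fraction: float = 0.4,
) -> ScenarioConfig:
    """The default scenario mirroring the published study design.

    Six countries x ``n_samples`` stratified plots over 1984-2016; mortality
    proxies for wood removal, wind and bark beetles (with the 1990/1999/2007
    storm pulses on the wind series); an ICP-style tree panel of 2423 plots.
    """
    years = (1984, 2016)
    forest_total = sum(v[1] for v in _COUNTRY_DESIGN.values())
    countries = []
    for name, (land, forest, rate_pct, alpha_pct) in _COUNTRY_DESIGN.items():
        alpha = alpha_pct / 100.0
        countries.append(
            CountryScenario(
                name=name,
                n_samples=n_samples,
                forest_fraction=forest / land,
                base_rate=base_rate_for_mean(rate_pct / 100.0, alpha, years),
                alpha=alpha,
                sr_fraction=sr_fraction,
                forest_area_weight=forest / forest_total,
            )
        )
    covariates = {
        name: {var: Trajectory(*vals) for var, vals in design.items()}
        for name, design in _COVARIATE_DESIGN.items()
    }
    proxies = (
        ProxyScenario("wood_removal", np.log(0.012 / 0.988), np.log(1.014), 3000.0),
        ProxyScenario(
            "wind", np.log(0.0008 / 0.9992), np.log(1.010), 800.0,
            pulse_years=(1990, 1999, 2007), pulse_factor=6.0,
        ),
        ProxyScenario("bark_beetle", np.log(0.0006 / 0.9994), np.log(1.025), 800.0),
    )
    trees = TreeScenario(
        n_plots=2423, trees_per_plot=32, base_death_prob=0.006,
        death_trend=-0.0145, years=(1990, 2010),
    )
    return ScenarioConfig(
        seed=seed, years=years, countries=tuple(countries),
        covariates=covariates, proxies=proxies, trees=trees,
    )


# --- sample plots -----------------------------------------------------------

def _forest_plot(
    plot_id: str,
    country: str,
    years: tuple[int, int],
    event_years: Sequence[int],
    sr_flags: Sequence[bool],
) -> SamplePlot:
    """Assemble contiguous segments for one forest plot from its event list.

    Between events the plot is stable (or regrowing for ``REGROWTH_YEARS``
    after a stand-replacing event).  The hazard applies in every year, so an
    event may truncate a regrowth phase; such an event necessarily ends
    non-treed.
    """
    y0, y1 = years
    fv = lambda yr, cover: Vertex(yr, LandUse.FOREST, cover)  # noqa: E731
    segments: list[Segment] = []
    cur = y0
    cover = LandCover.TREED
    regrow_until: int | None = None

    def fill_to(target: int) -> None:
        # stable / regrowth segments from cur to target (exclusive of events)
        nonlocal cur, cover, regrow_until
        if target <= cur:
            return
        if regrow_until is not None and cover is LandCover.NON_TREED:
            r_end = min(regrow_until, target)
            end_cover = LandCover.TREED if r_end >= regrow_until else LandCover.NON_TREED
            segments.append(Segment(fv(cur, cover), fv(r_end, end_cover), Process.REGROWTH))
            cur, cover = r_end, end_cover
            if cover is LandCover.TREED:
                regrow_until = None
        if target > cur:
            segments.append(Segment(fv(cur, cover), fv(target, cover), Process.STABLE))
            cur = target

    for e, sr in zip(event_years, sr_flags):
        fill_to(e - 1)
        pre_cover = cover
        end_cover = (
            LandCover.NON_TREED
            if (sr or pre_cover is LandCover.NON_TREED)
            else LandCover.TREED
        )
        segments.append(Segment(fv(e - 1, pre_cover), fv(e, end_cover), Process.MORTALITY))
        cur, cover = e, end_cover
        regrow_until = e + REGROWTH_YEARS if end_cover is LandCover.NON_TREED else None
    fill_to(y1)
    return SamplePlot(plot_id, country, tuple(segments))


def gen_samples(config: ScenarioConfig) -> list[SamplePlot]:
    """Stratified sample plots with Bernoulli annual mortality events."""
    rng = config.rng(0)
    y0, y1 = config.years
    plots: list[SamplePlot] = []
    for country in config.countries:
        n = country.n_samples
        is_forest = rng.random(n) < country.forest_fraction
        hazard = config.hazard(country)
        ev_years = config.event_years()
        u = rng.random((n, len(ev_years)))
        sr_u = rng.random((n, len(ev_years)))
        events = u < hazard[None, :]
        for i in range(n):
            pid = f"{country.name}-{i:05d}"
            if not is_forest[i]:
                plots.append(
                    SamplePlot(
                        pid,
                        country.name,
                        (
                            Segment(
                                Vertex(y0, LandUse.NON_FOREST, LandCover.NON_TREED),
                                Vertex(y1, LandUse.NON_FOREST, LandCover.NON_TREED),
                                Process.STABLE,
                            ),
                        ),
                    )
                )
                continue
            idx = np.nonzero(events[i])[0]
            plots.append(
                _forest_plot(
                    pid,
                    country.name,
                    config.years,
                    [int(ev_years[j]) for j in idx],
                    [bool(sr_u[i, j] < country.sr_fraction) for j in idx],
                )
            )
    return plots


# --- covariates -------------------------------------------------------------

def gen_covariates(config: ScenarioConfig) -> pd.DataFrame:
    """Annual covariate table: country, year, one column per variable."""
    rng = config.rng(1)
    y0, y1 = config.years
    years = np.arange(y0, y1 + 1)
    rows: list[pd.DataFrame] = []
    for country, variables in config.covariates.items():
        data = {"country": country, "year": years}
        for var, traj in variables.items():
            noise = traj.noise_sd * rng.standard_normal(len(years))
            data[var] = traj.start + traj.increment * (years - y0) + noise
        rows.append(pd.DataFrame(data))
    if not rows:
        return pd.DataFrame(columns=["country", "year"])
    return pd.concat(rows, ignore_index=True)


# --- proxies ----------------------------------------------------------------

def gen_proxies(config: ScenarioConfig) -> list[ProxySeries]:
    """Beta-distributed annual proxy fractions with logit-linear means."""
    rng = config.rng(2)
    y0, y1 = config.years
    years = np.arange(y0, y1 + 1)
    out = []
    for sc in config.proxies:
        mean = expit(sc.logit_start + sc.logit_slope * (years - y0))
        for py in sc.pulse_years:
            mean = np.where(years == py, np.minimum(mean * sc.pulse_factor, 0.99), mean)
        a = mean * sc.precision
        b = (1.0 - mean) * sc.precision
        values = rng.beta(a, b)
        out.append(ProxySeries(sc.name, years.copy(), values))
    return out


# --- tree panels ------------------------------------------------------------

def gen_trees(config: ScenarioConfig) -> pd.DataFrame:
    """ICP-style tree panel: plot_id, tree_id, year, defoliation.

    Trees die with annual probability base_death_prob*(1+death_trend)^(t-t0);
    a dying tree records 100% defoliation in its death year and is absent from
    all later surveys.  Survivors get sub-lethal defoliation values.
    """
    if config.trees is None:
        raise ValueError("scenario has no tree panel configured")
    rng = config.rng(3)
    sc = config.trees
    ty0, ty1 = sc.years
    years = np.arange(ty0, ty1 + 1)
    T = len(years)
    n_trees = sc.n_plots * sc.trees_per_plot
    p = sc.base_death_prob * (1.0 + sc.death_trend) ** (years - ty0)
    u = rng.random((n_trees, T))
    dies = u < p[None, :]
    # death year index per tree; T means "survives the panel"
    death_idx = np.where(dies.any(axis=1), dies.argmax(axis=1), T)

    plot_ids = np.repeat(
        [f"p{i:04d}" for i in range(sc.n_plots)], sc.trees_per_plot
    )
    tree_ids = np.tile(
        [f"t{j:02d}" for j in range(sc.trees_per_plot)], sc.n_plots
    )
    defol = np.clip(20.0 + 15.0 * rng.standard_normal((n_trees, T)), 0.0, 95.0)
    year_idx = np.arange(T)
    present = year_idx[None, :] <= death_idx[:, None]
    is_death_year = year_idx[None, :] == death_idx[:, None]
    defol = np.where(is_death_year, 100.0, defol)

    tree_rows, year_cols = np.nonzero(present)
    return pd.DataFrame(
        {
            "plot_id": plot_ids[tree_rows],
            "tree_id": tree_ids[tree_rows],
            "year": years[year_cols],
            "defoliation": defol[tree_rows, year_cols],
        }
    )


# --- scenario output --------------------------------------------------------

def write_scenario(config: ScenarioConfig, out_dir: str | Path) -> dict[str, Path]:
    """Write samples/covariates/proxies/trees CSVs plus a provenance JSON."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    paths["samples"] = out_dir / "samples.csv"
    write_samples(gen_samples(config), paths["samples"])

    paths["covariates"] = out_dir / "covariates.csv"
    gen_covariates(config).to_csv(paths["covariates"], index=False)

    proxies = gen_proxies(config)
    paths["proxies"] = out_dir / "proxies.csv"
    pd.concat([p.to_frame() for p in proxies], ignore_index=True).to_csv(
        paths["proxies"], index=False
    )

    if config.trees is not None:
        paths["trees"] = out_dir / "trees.csv"
        gen_trees(config).to_csv(paths["trees"], index=False)

    prov = {
        "seed": config.seed,
        "config": json.loads(json.dumps(dataclasses.asdict(config), default=str)),
        "package": "canopymort 0.1.0",
    }
    paths["provenance"] = out_dir / "provenance.json"
    paths["provenance"].write_text(json.dumps(prov, indent=2))
    return paths
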
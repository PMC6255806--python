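import numpy as np
import pandas as pd
import pytest

from canopymort.records import (
    LandCover,
    LandUse,
    Process,
    SamplePlot,
    Segment,
    Vertex,
)
from canopymort.simulate import (
    CountryScenario,
    ScenarioConfig,
    base_rate_for_mean,
)
from canopymort.proxies import BetaTrendConfig
from canopymort.trend import TrendModelConfig

# Reduced sampler settings for unit tests; acceptance tests use defaults
# where the full study scale is exercised.
FAST_TREND = TrendModelConfig(
    chains=1, walkers=76, draws_per_chain=900, warmup=1400, thin=4,
    rhat_threshold=1.03, ess_threshold=150.0,
)

FAST_BETA = BetaTrendConfig(
    chains=1, walkers=32, draws_per_chain=1500, warmup=1500, thin=3,
    rhat_threshold=1.03, ess_threshold=150.0,
)


def vertex(year, use="forest", cover="treed"):
    return Vertex(year, LandUse(use), LandCover(cover))


def segment(y0, y1, process="stable", use0="forest", cover0="treed",
            use1=None, cover1=None):
    use1 = use1 if use1 is not None else use0
    cover1 = cover1 if cover1 is not None else cover0
    return Segment(vertex(y0, use0, cover0), vertex(y1, use1, cover1), Process(process))


def stable_forest_plot(plot_id="p1", country="austria", y0=1984, y1=2016):
    return SamplePlot(plot_id, country, (segment(y0, y1),))


def single_country_scenario(
    seed, n_samples=500, mean_rate=0.0079, alpha=0.024, years=(1984, 2016),
    forest_fraction=1.0, sr_fraction=0.4,
):
    return ScenarioConfig(
        seed=seed,
        years=years,
        countries=(
            CountryScenario(
                name="stratum",
                n_samples=n_samples,
                forest_fraction=forest_fraction,
                base_rate=base_rate_for_mean(mean_rate, alpha, years),
                alpha=alpha,
                sr_fraction=sr_fraction,
                forest_area_weight=1.0,
            ),
        ),
    )


@pytest.fixture(scope="session")
def simulated_counts_with_trend():
    """Binomial counts from the exact trend-model data-generating process."""
    rng = np.random.default_rng(42)
    years = np.arange(1985, 2017)
    p = 0.008 * 1.024 ** (years - 1984)
    n = 8000
    return pd.DataFrame(
        {"year": years, "n_forest": n, "n_mortality": rng.binomial(n, p)}
    )
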
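"""Shared ensemble-MCMC driver.

All models in this package expose a vectorized log-posterior over a flat
parameter vector and are sampled with affine-invariant ensemble MCMC using
differential-evolution moves.  For convergence assessment, several fully
independent ensembles are run from overdispersed starts; split-R-hat is
computed on "superchains" (walker groups within each ensemble, so that
between-ensemble disagreement is detected), while bulk ESS is estimated from
the individual walker chains, which carry the autocorrelation structure.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable

import arviz as az
import emcee
import numpy as np

warnings.filterwarnings(
    "ignore", message=".*ArviZ is undergoing a major refactor.*"
)

_MOVES = [(emcee.moves.DEMove(), 0.8), (emcee.moves.DESnookerMove(), 0.2)]


@dataclass
class EnsembleResult:
    """Post-warmup draws with convergence diagnostics.

    chain has shape (total_walkers, kept_steps, ndim) with walkers from all
    ensembles concatenated; diagnostics maps parameter name to
    (rhat, ess_bulk).
    """

    chain: np.ndarray
    param_names: list[str]
    diagnostics: dict[str, tuple[float, float]] = field(default_factory=dict)
    converged: bool = True
    acceptance: float = float("nan")

    def flat(self, name: str) -> np.ndarray:
        j = self.param_names.index(name)
        return self.chain[:, :, j].reshape(-1)

    def flat_block(self, prefix: str) -> np.ndarray:
        """Flattened draws (ndraw, k) for parameters named prefix[i]."""
        idx = [
            j for j, n in enumerate(self.param_names) if n.startswith(prefix + "[")
        ]
        return self.chain[:, :, idx].reshape(-1, len(idx))


def _superchains(per_ensemble: list[np.ndarray], groups_per_ensemble: int) -> np.ndarray:
    """Concatenate walker groups into long pseudo-chains, time-major."""
    out = []
    for ch in per_ensemble:  # ch: (walkers, steps, ndim)
        for g in np.array_split(np.arange(ch.shape[0]), groups_per_ensemble):
            out.append(np.swapaxes(ch[g], 0, 1).reshape(-1, ch.shape[2]))
    return np.stack(out)  # (nchain, length, ndim)


def run_ensemble(
    log_prob: Callable[[np.ndarray], np.ndarray],
    init: Callable[[np.random.Generator], np.ndarray],
    *,
    ensembles: int = 2,
    warmup: int,
    steps: int,
    seed: int,
    thin: int = 10,
    param_names: list[str],
    rhat_threshold: float = 1.01,
    ess_threshold: float = 400.0,
    check_names: list[str] | None = None,
) -> EnsembleResult:
    """Sample with ``ensembles`` independent walker ensembles.

    ``init(rng)`` must return an overdispersed (walkers, ndim) start;
    ``log_prob`` takes a (walkers, ndim) array and returns (walkers,) log
    densities.  Fully deterministic given seed.
    """
    thin = max(1, min(thin, steps))
    per_ensemble: list[np.ndarray] = []
    acc = []
    for e in range(ensembles):
        rng = np.random.default_rng([seed % (2**31), e])
        p0 = init(rng)
        nwalkers, ndim = p0.shape
        sampler = emcee.EnsembleSampler(
            nwalkers, ndim, log_prob, vectorize=True, moves=_MOVES
        )
        sampler.random_state = np.random.RandomState(
            (seed * 1009 + 7919 * e + 13) % (2**32)
        ).get_state()
        state = sampler.run_mcmc(p0, warmup, progress=False)
        sampler.reset()
        sampler.run_mcmc(state, steps, progress=False)
        per_ensemble.append(np.swapaxes(sampler.get_chain(thin=thin), 0, 1))
        acc.append(np.mean(sampler.acceptance_fraction))

    chain = np.concatenate(per_ensemble, axis=0)
    names = check_names if check_names is not None else param_names
    idx = [param_names.index(n) for n in names]
    # at least 4 pseudo-chains for split-R-hat
    groups = max(2, 4 // ensembles)
    sc = _superchains(per_ensemble, groups)
    rhat = az.rhat(az.from_dict(posterior={n: sc[:, :, j] for n, j in zip(names, idx)}))
    ess = az.ess(
        az.from_dict(posterior={n: chain[:, :, j] for n, j in zip(names, idx)}),
        method="bulk",
    )
    diagnostics = {
        n: (float(rhat[n].values), float(ess[n].values)) for n in names
    }
    converged = all(
        r <= rhat_threshold and e >= ess_threshold for r, e in diagnostics.values()
    )
    return EnsembleResult(
        chain=chain,
        param_names=list(param_names),
        diagnostics=diagnostics,
        converged=converged,
        acceptance=float(np.mean(acc)),
    )


def softplus(x: np.ndarray) -> np.ndarray:
    """log(1 + exp(x)), numerically stable."""
    return np.logaddexp(0.0, x)


def halfnormal_logpdf(x: np.ndarray, scale: float) -> np.ndarray:
    return np.where(x > 0, -0.5 * (x / scale) ** 2, -np.inf)


def normal_logpdf(x: np.ndarray, mu: float, sd: float) -> np.ndarray:
    return -0.5 * ((x - mu) / sd) ** 2 - np.log(sd)
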
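"""Rate-constant estimation from weighted-ensemble recycling flux.

By the Hill relation, the steady-state probability flux from state A into
state B equals the inverse of the mean first-passage time:
``Flux(A -> B | SS) = 1 / MFPT``.  A recycling WE simulation records the
probability recycled into the target per resampling interval tau; dividing
the running mean of that series by tau (in seconds) yields a rate-constant
estimate in 1/s whose levelling-off signals convergence to the steady state.
For bimolecular processes the rate is further divided by the effective
concentration (yielding 1/M/s), and for equilibrium (non-recycling) runs the
flux is first normalised by the source-state population,
``Flux(A -> B | SS) / P_A^eq``.

Uncertainties for a single simulation come from Monte Carlo block
bootstrapping of the (autocorrelated) flux series; across replicate
simulations, Bayesian bootstrapping with flat Dirichlet weights yields
credibility regions.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .io import FluxSeries

logger = logging.getLogger(__name__)


@dataclass
class RateEvolution:
    """Per-iteration rate-constant estimates with optional uncertainty bounds."""

    x_axis: np.ndarray  # iteration index, or molecular time N*tau in seconds
    rate: np.ndarray  # 1/s (or 1/M/s when concentration-adjusted)
    ci_lo: np.ndarray | None = None
    ci_hi: np.ndarray | None = None
    mode: str = "nonequilibrium"


def mfpt_from_flux(steady_flux_per_tau: float, tau_seconds: float) -> float:
    """Mean first-passage time (seconds) from a steady-state flux per tau.

    ``MFPT = tau / flux``; identically ``mfpt * (flux / tau) = 1``.  A zero
    flux signals an unreached target and yields ``inf``.
    """
    if tau_seconds <= 0:
        raise ValueError("tau_seconds must be > 0")
    if steady_flux_per_tau < 0:
        raise ValueError("flux must be >= 0")
    if steady_flux_per_tau == 0:
        logger.warning("zero flux: target never reached, MFPT is infinite")
        return math.inf
    return tau_seconds / steady_flux_per_tau


def _running_mean(series: np.ndarray, window: int | None) -> np.ndarray:
    n = len(series)
    if window is None:
        return np.cumsum(series) / np.arange(1, n + 1)
    if not 1 <= window <= n:
        raise ValueError("window must lie in 1..len(series)")
    out = np.empty(n)
    csum = np.concatenate([[0.0], np.cumsum(series)])
    for i in range(n):
        lo = max(0, i + 1 - window)
        out[i] = (csum[i + 1] - csum[lo]) / (i + 1 - lo)
    return out


def rate_evolution(
    flux: FluxSeries,
    mode: str = "nonequilibrium",
    concentration_M: float | None = None,
    window: int | None = None,
    x_axis: str = "iterations",
    ci: bool = False,
    n_boot: int = 1000,
    block_len: int | None = None,
    level: float = 0.95,
    rng: np.random.Generator | int | None = None,
    use_red: bool = False,
) -> RateEvolution:
    """Convert a per-iteration flux series into evolving rate estimates.

    The default statistic is the cumulative mean of the flux over iterations
    ``1..i`` divided by tau (the levelling-off of which monitors steady-state
    convergence); ``window`` switches to a sliding-window mean.  In
    equilibrium mode each iteration's flux is divided by the cumulative mean
    source population over the same prefix before averaging.  ``ci=True``
    attaches block-bootstrap percentile bounds computed per plotted point on
    the corresponding flux prefix.  ``use_red`` substitutes the pre-computed
    RED-corrected flux series stored in the file.
    """
    if flux.tau_seconds <= 0:
        raise ValueError("tau must be > 0")
    if mode not in ("nonequilibrium", "equilibrium"):
        raise ValueError("mode must be 'nonequilibrium' or 'equilibrium'")
    series = flux.red_flux if use_red else flux.flux_per_tau
    if series is None:
        raise ValueError("no RED flux series present in this file")
    series = np.asarray(series, dtype=float)
    n = len(series)
    if n == 0:
        raise ValueError("empty flux series")

    if mode == "equilibrium":
        if flux.source_population is None:
            raise ValueError("equilibrium mode requires source populations")
        pop = np.asarray(flux.source_population, dtype=float)
        cum_pop = np.cumsum(pop) / np.arange(1, n + 1)
        series = series / cum_pop

    scale = flux.tau_seconds
    if concentration_M is not None:
        if concentration_M <= 0:
            raise ValueError("concentration must be > 0")
        scale = scale * concentration_M
    rate = _running_mean(series, window) / scale

    if x_axis == "iterations":
        x = np.arange(1, n + 1, dtype=float)
    elif x_axis == "time":
        x = np.arange(1, n + 1, dtype=float) * flux.tau_seconds
    else:
        raise ValueError("x_axis must be 'iterations' or 'time'")

    lo = hi = None
    if ci:
        rng = np.random.default_rng(rng)
        lo = np.full(n, np.nan)
        hi = np.full(n, np.nan)
        for i in range(n):
            prefix = series[: i + 1] / scale
            if window is not None:
                prefix = prefix[max(0, i + 1 - window) :]
            lo[i], hi[i] = block_bootstrap_ci(
                prefix, n_boot=n_boot, block_len=block_len, level=level, rng=rng
            )
    return RateEvolution(x_axis=x, rate=rate, ci_lo=lo, ci_hi=hi, mode=mode)


def default_block_len(n: int) -> int:
    """Default block length: floor(sqrt(n)), at least 1."""
    return max(1, int(math.isqrt(n)))


def block_bootstrap_replicates(
    series: np.ndarray,
    n_boot: int = 1000,
    block_len: int | None = None,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Means of circular-block-bootstrap resamples of an autocorrelated series.

    Each replicate concatenates ``ceil(n / block_len)`` contiguous blocks
    (wrapping at the end) drawn with replacement, truncated to length ``n``.
    """
    series = np.asarray(series, dtype=float)
    n = len(series)
    if n == 0:
        raise ValueError("empty series")
    if block_len is None:
        block_len = default_block_len(n)
    if not 1 <= block_len <= n:
        raise ValueError("block_len must lie in 1..len(series)")
    rng = np.random.default_rng(rng)
    n_blocks = math.ceil(n / block_len)
    starts = rng.integers(0, n, size=(n_boot, n_blocks))
    idx = (starts[:, :, None] + np.arange(block_len)) % n
    samples = series[idx.reshape(n_boot, -1)[:, :n]]
    return samples.mean(axis=1)


def block_bootstrap_ci(
    series: np.ndarray,
    n_boot: int = 1000,
    block_len: int | None = None,
    level: float = 0.95,
    rng: np.random.Generator | int | None = None,
    return_replicates: bool = False,
):
    """Percentile confidence interval of the mean via circular block bootstrap.

    Returns ``(lo, hi)`` at the requested level (default 95%), or
    ``(lo, hi, replicates)`` when ``return_replicates`` is set.
    """
    if not 0 < level < 1:
        raise ValueError("level must lie in (0, 1)")
    reps = block_bootstrap_replicates(series, n_boot, block_len, rng)
    alpha = 100.0 * (1.0 - level) / 2.0
    lo, hi = np.percentile(reps, [alpha, 100.0 - alpha])
    if return_replicates:
        return float(lo), float(hi), reps
    return float(lo), float(hi)


def bayes_bootstrap_ci(
    replicate_estimates: np.ndarray,
    n_draws: int = 1000,
    level: float = 0.95,
    rng: np.random.Generator | int | None = None,
) -> tuple[float, float]:
    """Bayesian-bootstrap credibility region across replicate simulations.

    Each draw samples flat-Dirichlet weights over the replicates and records
    the weighted mean; the region is the central percentile interval.
    """
    estimates = np.asarray(replicate_estimates, dtype=float)
    if len(estimates) < 2:
        raise ValueError("at least 2 replicate estimates required")
    if not 0 < level < 1:
        raise ValueError("level must lie in (0, 1)")
    rng = np.random.default_rng(rng)
    weights = rng.dirichlet(np.ones(len(estimates)), size=n_draws)
    draws = weights @ estimates
    alpha = 100.0 * (1.0 - level) / 2.0
    lo, hi = np.percentile(draws, [alpha, 100.0 - alpha])
    return float(lo), float(hi)
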
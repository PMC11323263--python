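"""Synthetic weighted-ensemble runs over toy stochastic dynamics.

Emulates the full WE bookkeeping — split/merge resampling across
progress-coordinate bins, recycling of target-reaching walkers back to a
basis state with weight preserved, per-iteration flux recording — on two toy
propagators:

``double_well``
    Overdamped one-dimensional dynamics in the dimensionless double-well
    potential ``U(x) = beta * (x^2 - 1)^2`` with unit mobility:
    ``x <- x - dt * U'(x) + sqrt(2 * diffusion * dt) * xi``.  With
    ``diffusion = 0`` this reduces to deterministic gradient descent toward
    the nearest well.

``discrete_chain``
    A symmetric nearest-neighbour random walk on states ``0..n_states-1``.
    Each step hops with total probability ``hop_prob`` (half left, half
    right) and otherwise stays; attempted moves off either end are reflected
    to the inward neighbour.  An optional absorbing threshold freezes the
    walker once reached, so that the per-interval recycled flux counts first
    passages exactly and the Hill relation holds without discretisation bias.

The discrete chain comes with an exact mean-first-passage-time oracle
(first-step analysis, a dense linear solve), which anchors the rate-recovery
tests: the long-run recycled flux per step of a recycling WE run must equal
``1 / MFPT``.

All randomness flows from a single root seed through named substreams
(dynamics, merge tie-breaks, recycling restarts) so each can be pinned
independently in tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence, Union

import numpy as np
import yaml

from .io import (
    Endpoint,
    FluxSeries,
    SegmentRecord,
    write_flux_file,
    write_we_file,
)


@dataclass(frozen=True)
class DoubleWell:
    """Overdamped dynamics in ``U(x) = beta * (x^2 - 1)^2``."""

    beta: float = 1.0
    diffusion: float = 1.0
    dt: float = 0.01

    def grad(self, x: float) -> float:
        return self.beta * 4.0 * x * (x * x - 1.0)


@dataclass(frozen=True)
class DiscreteChain:
    """Reflected nearest-neighbour walk on ``0..n_states-1``."""

    n_states: int = 8
    hop_prob: float = 0.5

    def __post_init__(self) -> None:
        if self.n_states < 2:
            raise ValueError("discrete chain needs at least 2 states")
        if not 0.0 <= self.hop_prob <= 1.0:
            raise ValueError("hop_prob must lie in [0, 1]")


Dynamics = Union[DoubleWell, DiscreteChain]


@dataclass
class WEConfig:
    """Study conditions for one synthetic WE run.

    Defaults mirror a standard fixed-bin WE setup: bins at even spacing along
    a 1-D progress coordinate with a target count of four trajectories per
    bin, recycling on, and one basis state carrying all initial weight.
    """

    bin_edges: np.ndarray
    dynamics: Dynamics
    n_iterations: int = 50
    target_count: int = 4
    tau_seconds: float = 100e-12
    frames_per_tau: int = 5
    target_condition: float | None = None
    source_condition: float | None = None
    basis_states: Sequence[tuple[float, float]] = field(
        default_factory=lambda: [(0.0, 1.0)]
    )
    recycle: bool = True
    record_auxdata: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        if self.bin_edges.ndim != 1 or len(self.bin_edges) < 2:
            raise ValueError("bin_edges must be a 1-D array of at least 2 edges")
        if np.any(np.diff(self.bin_edges) <= 0):
            raise ValueError("bin_edges must be strictly increasing")
        if self.target_count < 1:
            raise ValueError("target_count must be >= 1")
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")
        if self.frames_per_tau < 1:
            raise ValueError("frames_per_tau must be >= 1")
        wsum = sum(w for _, w in self.basis_states)
        if abs(wsum - 1.0) > 1e-12:
            raise ValueError(f"basis-state weights sum to {wsum}, expected 1")
        if self.recycle and self.target_condition is None:
            raise ValueError("recycling requires a target_condition")
        if self.source_condition is None:
            self.source_condition = self.target_condition

    @classmethod
    def from_file(cls, path: str | Path) -> "WEConfig":
        """Load a config from a plain key-value (YAML) file."""
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        dyn = raw.pop("dynamics")
        kind = dyn.pop("kind")
        if kind == "double_well":
            dynamics: Dynamics = DoubleWell(**dyn)
        elif kind == "discrete_chain":
            dynamics = DiscreteChain(**dyn)
        else:
            raise ValueError(f"unknown dynamics kind {kind!r}")
        if "basis_states" in raw:
            raw["basis_states"] = [tuple(b) for b in raw["basis_states"]]
        return cls(bin_edges=np.asarray(raw.pop("bin_edges"), float), dynamics=dynamics, **raw)


@dataclass
class Walker:
    """In-flight trajectory between resampling steps."""

    coord: float
    weight: float
    parent_ref: int  # >= 0: seg_id in the current iteration; < 0: basis origin


def propagate_segment(
    state: float,
    dynamics: Dynamics,
    frames: int,
    rng: np.random.Generator,
    absorb_at: float | None = None,
) -> np.ndarray:
    """Propagate one walker for ``frames`` steps; returns ``frames + 1`` values.

    The first element is the (inherited) input state.  If ``absorb_at`` is
    given, the walker freezes once its coordinate reaches the threshold.
    """
    if not math.isfinite(state):
        raise ValueError(f"non-finite starting state {state}")
    traj = np.empty(frames + 1, dtype=float)
    x = float(state)
    traj[0] = x
    for k in range(1, frames + 1):
        if absorb_at is not None and x >= absorb_at:
            traj[k] = x
            continue
        if isinstance(dynamics, DiscreteChain):
            r = rng.random()
            s = int(round(x))
            if r < dynamics.hop_prob / 2.0:
                s -= 1
            elif r < dynamics.hop_prob:
                s += 1
            if s < 0:
                s = 1  # reflect off the lower end to the inward neighbour
            elif s > dynamics.n_states - 1:
                s = dynamics.n_states - 2
            x = float(s)
        else:
            noise = math.sqrt(2.0 * dynamics.diffusion * dynamics.dt) * rng.standard_normal()
            x = x - dynamics.dt * dynamics.grad(x) + noise
            if not math.isfinite(x):
                raise FloatingPointError("trajectory diverged to a non-finite state")
        traj[k] = x
    return traj


def we_resample(
    walkers: Sequence[Walker],
    bin_edges: np.ndarray,
    target_count: int,
    rng: np.random.Generator | None = None,
) -> list[Walker]:
    """Split/merge walkers so every occupied bin holds exactly ``target_count``.

    Under-occupied bins split the largest-weight walker into two equal halves,
    one child at a time; over-occupied bins merge the two smallest-weight
    walkers, the survivor drawn from the pair proportionally to weight.  Total
    weight is conserved to machine precision.  The two open-ended outer bins
    (below the first and above the last edge) are resampled like any other.
    """
    if target_count < 1:
        raise ValueError("target_count must be >= 1")
    if len(walkers) == 0:
        return []
    if rng is None:
        rng = np.random.default_rng(0)
    total = sum(w.weight for w in walkers)
    if abs(total - 1.0) > 1e-12 * max(1.0, len(walkers)):
        raise ValueError(f"walker weights sum to {total!r}, expected 1")

    bins: dict[int, list[Walker]] = {}
    edges = np.asarray(bin_edges, dtype=float)
    for w in walkers:
        b = int(np.digitize(w.coord, edges))
        bins.setdefault(b, []).append(w)

    out: list[Walker] = []
    for b in sorted(bins):
        group = list(bins[b])
        while len(group) < target_count:
            i = max(range(len(group)), key=lambda k: (group[k].weight, -k))
            parent = group.pop(i)
            half = parent.weight / 2.0
            group.insert(i, Walker(parent.coord, half, parent.parent_ref))
            group.insert(i + 1, Walker(parent.coord, half, parent.parent_ref))
        while len(group) > target_count:
            order = sorted(range(len(group)), key=lambda k: (group[k].weight, k))
            i, j = sorted(order[:2])
            wi, wj = group[i], group[j]
            combined = wi.weight + wj.weight
            keep_i = rng.random() < wi.weight / combined
            survivor = wi if keep_i else wj
            group = [g for k, g in enumerate(group) if k not in (i, j)]
            group.insert(i, Walker(survivor.coord, combined, survivor.parent_ref))
        out.extend(group)
    return out


def _sample_basis(
    basis_states: Sequence[tuple[float, float]], rng: np.random.Generator
) -> tuple[int, float]:
    weights = np.array([w for _, w in basis_states])
    idx = int(rng.choice(len(basis_states), p=weights / weights.sum()))
    return idx, basis_states[idx][0]


def _aux_observable(pcoord: np.ndarray) -> np.ndarray:
    # monotone, gently nonlinear stand-in for a radius-of-gyration-like feature
    return 15.0 + 0.5 * pcoord + 0.1 * pcoord * pcoord


def run_we(
    config: WEConfig,
    west_path: str | Path = "west.h5",
    kinetics_path: str | Path = "kinetics.h5",
) -> tuple[Path, Path]:
    """Run a synthetic WE simulation and write its data files.

    Returns the paths of the trajectory-tree HDF5 file and the kinetics file.
    A fixed config and seed produce bit-identical payloads.
    """
    ss = np.random.SeedSequence(config.seed)
    rng_dyn, rng_merge, rng_recycle = (np.random.default_rng(c) for c in ss.spawn(3))

    walkers = [
        Walker(coord=c, weight=w, parent_ref=-(i + 1))
        for i, (c, w) in enumerate(config.basis_states)
    ]
    walkers = we_resample(walkers, config.bin_edges, config.target_count, rng_merge)

    absorb = config.target_condition if config.recycle else None
    iterations: list[tuple[list[SegmentRecord], dict[str, np.ndarray]]] = []
    flux = np.zeros(config.n_iterations)
    srcpop = (
        np.zeros(config.n_iterations) if config.source_condition is not None else None
    )

    for it in range(1, config.n_iterations + 1):
        n = len(walkers)
        pcoord = np.empty((n, config.frames_per_tau + 1, 1))
        for j, w in enumerate(walkers):
            pcoord[j, :, 0] = propagate_segment(
                w.coord, config.dynamics, config.frames_per_tau, rng_dyn, absorb_at=absorb
            )
        final = pcoord[:, -1, 0]
        weights = np.array([w.weight for w in walkers])

        recycled = np.zeros(n, dtype=bool)
        if config.recycle:
            recycled = final >= config.target_condition
            flux[it - 1] = weights[recycled].sum()
        if srcpop is not None:
            srcpop[it - 1] = weights[final < config.source_condition].sum()

        # continuation ensemble: recycled walkers restart at a basis state
        conts: list[Walker] = []
        for j, w in enumerate(walkers):
            if recycled[j]:
                b_idx, b_coord = _sample_basis(config.basis_states, rng_recycle)
                conts.append(Walker(b_coord, w.weight, -(b_idx + 1)))
            else:
                conts.append(Walker(float(final[j]), w.weight, j))
        new_walkers = we_resample(conts, config.bin_edges, config.target_count, rng_merge)
        surviving = {nw.parent_ref for nw in new_walkers if nw.parent_ref >= 0}

        records = []
        for j, w in enumerate(walkers):
            if recycled[j]:
                ep = Endpoint.RECYCLED
            elif j in surviving:
                ep = Endpoint.CONTINUES
            else:
                ep = Endpoint.MERGED
            records.append(
                SegmentRecord(
                    iteration=it,
                    seg_id=j,
                    weight=float(w.weight),
                    parent_id=w.parent_ref,
                    endpoint=ep,
                )
            )
        datasets: dict[str, np.ndarray] = {"pcoord": pcoord}
        if config.record_auxdata:
            datasets["auxdata/rog"] = _aux_observable(pcoord[:, :, 0])
        iterations.append((records, datasets))
        walkers = new_walkers

    west = write_we_file(
        west_path, iterations, attrs={"tau_seconds": config.tau_seconds}
    )
    kinetics = write_flux_file(
        kinetics_path,
        FluxSeries(
            tau_seconds=config.tau_seconds,
            flux_per_tau=flux,
            source_population=(
                np.clip(srcpop, np.finfo(float).tiny, 1.0) if srcpop is not None else None
            ),
        ),
    )
    return west, kinetics


def chain_mfpt_oracle(
    dynamics: DiscreteChain, source: int, target: int
) -> float:
    """Exact mean first-passage steps on the reflected chain, target absorbing.

    First-step analysis: solve ``(I - Q) E = 1`` over the non-absorbing
    states, where ``Q`` is the substochastic transition matrix of the walk.
    Returns ``inf`` when the target is unreachable (``hop_prob = 0``).
    """
    n = dynamics.n_states
    if not 0 <= source < n or not 0 <= target < n:
        raise ValueError("source and target must be valid states")
    if source == target:
        return 0.0
    if dynamics.hop_prob == 0.0:
        return math.inf

    states = [s for s in range(n) if s != target]
    index = {s: k for k, s in enumerate(states)}
    h = dynamics.hop_prob
    Q = np.zeros((len(states), len(states)))
    for s in states:
        left = s - 1 if s - 1 >= 0 else 1
        right = s + 1 if s + 1 <= n - 1 else n - 2
        for dest, p in ((left, h / 2.0), (right, h / 2.0), (s, 1.0 - h)):
            if p and dest != target:
                Q[index[s], index[dest]] += p
    try:
        E = np.linalg.solve(np.eye(len(states)) - Q, np.ones(len(states)))
    except np.linalg.LinAlgError:
        return math.inf
    return float(E[index[source]])
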
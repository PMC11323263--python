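"""Weight-aware probability distributions and free-energy surfaces.

Every frame of a WE trajectory segment inherits an equal share of its
segment's statistical weight (``w_seg / frames_per_seg``), so that the frame
weights of one iteration still sum to one.  Histograms renormalise over their
normalisation block: evolution matrices per iteration row, averaged 1-D/2-D
histograms over the whole selected iteration range.  Free-energy conversion
is the inverted natural log of the normalised histogram,
``F = -ln(P / P_max)`` (in units of kT, optionally scaled by ``k_B T`` in
kcal/mol), so the minimum finite value is exactly zero and empty bins are
masked as NaN.

Binning is half-open ``[e_i, e_{i+1})`` with the final bin closed.  Hexagonal
binning reproduces the standard dual-lattice geometry (two interleaved
rectangular lattices, nearest-centre assignment with the y-distance weighted
by 3 in scaled units) and reduces each occupied cell by a weighted mean.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.ndimage import gaussian_filter

from .io import WESimHandle, read_frame_series, read_seg_index

logger = logging.getLogger(__name__)

#: Boltzmann constant in kcal/(mol K)
KB_KCAL_PER_MOL_K = 0.0019872041

NORM_TOL = 1e-8


@dataclass
class HistogramResult:
    """Binned weighted probabilities or free energies with axis edges."""

    axis_edges: list[np.ndarray]
    values: np.ndarray
    units: str = "probability"  # probability | kT | kcal
    iter_range: tuple[int, int, int] | None = None

    def centers(self, axis: int = 0) -> np.ndarray:
        e = self.axis_edges[axis]
        return 0.5 * (e[:-1] + e[1:])


@dataclass
class WeightedPoints:
    """Per-frame values with their statistical weights and provenance ids."""

    x: np.ndarray
    w: np.ndarray
    y: np.ndarray | None = None
    z: np.ndarray | None = None
    c: np.ndarray | None = None
    ids: np.ndarray | None = None  # (n, 3) int: iteration, seg_id, frame

    def __post_init__(self) -> None:
        n = len(self.x)
        for name in ("w", "y", "z", "c"):
            arr = getattr(self, name)
            if arr is not None and len(arr) != n:
                raise ValueError(f"length of {name} does not match x")
        if np.any(self.w <= 0):
            raise ValueError("weights must be > 0")

    def __len__(self) -> int:
        return len(self.x)

    def axis(self, i: int) -> np.ndarray | None:
        return (self.x, self.y, self.z, self.c)[i]

    @classmethod
    def from_arrays(
        cls,
        x: np.ndarray,
        y: np.ndarray | None = None,
        z: np.ndarray | None = None,
        c: np.ndarray | None = None,
        w: np.ndarray | None = None,
    ) -> "WeightedPoints":
        """Build points from plain series (conventional-MD path).

        Without explicit weights every frame carries the same weight ``1/n``.
        """
        x = np.asarray(x, dtype=float).ravel()
        n = len(x)
        if w is None:
            w = np.full(n, 1.0 / n)
        return cls(
            x=x,
            w=np.asarray(w, dtype=float),
            y=None if y is None else np.asarray(y, dtype=float).ravel(),
            z=None if z is None else np.asarray(z, dtype=float).ravel(),
            c=None if c is None else np.asarray(c, dtype=float).ravel(),
        )


def _resolve_range(
    handle: WESimHandle, first_iter: int, last_iter: int | None, step_iter: int
) -> tuple[int, int, int]:
    if last_iter is None:
        last_iter = handle.n_iterations
    if not 1 <= first_iter <= last_iter <= handle.n_iterations:
        raise IndexError(
            f"iteration range {first_iter}..{last_iter} invalid for a file "
            f"with {handle.n_iterations} iterations"
        )
    if step_iter < 1:
        raise ValueError("step_iter must be >= 1")
    return first_iter, last_iter, step_iter


def collect_values(
    handle: WESimHandle,
    axes: Sequence[tuple[str, int]],
    first_iter: int = 1,
    last_iter: int | None = None,
    step_iter: int = 1,
    frame_stride: int = 1,
    seg_mask: Sequence[np.ndarray] | None = None,
) -> WeightedPoints:
    """Gather per-frame values, weights and ids over an iteration range.

    ``axes`` maps onto (x, y, z, c) in order; each entry is a
    ``(dataset_name, dim_index)`` pair.  Each kept frame carries
    ``w_seg / frames_per_seg``.  With ``frame_stride > 1`` every stride-th
    frame is kept and the weights are deliberately left unrenormalised.
    ``seg_mask`` (one boolean array per iteration, indexed ``iteration - 1``)
    drops segments before collection; downstream histogram normalisation then
    yields conditional distributions over the surviving lineages.
    """
    if not 1 <= len(axes) <= 4:
        raise ValueError("between 1 and 4 axes required")
    first_iter, last_iter, step_iter = _resolve_range(
        handle, first_iter, last_iter, step_iter
    )
    if frame_stride < 1:
        raise ValueError("frame_stride must be >= 1")

    cols: list[list[np.ndarray]] = [[] for _ in axes]
    weights: list[np.ndarray] = []
    ids: list[np.ndarray] = []
    fps = handle.frames_per_seg
    frame_sel = np.arange(0, fps, frame_stride)

    for it in range(first_iter, last_iter + 1, step_iter):
        records = read_seg_index(handle, it)
        w_seg = np.array([r.weight for r in records])
        keep = np.ones(len(records), dtype=bool)
        if seg_mask is not None:
            keep = np.asarray(seg_mask[it - 1], dtype=bool)
            if len(keep) != len(records):
                raise ValueError(f"seg_mask for iteration {it} has wrong length")
        seg_ids = np.nonzero(keep)[0]
        if len(seg_ids) == 0:
            continue
        for a, (name, dim) in enumerate(axes):
            vals = read_frame_series(handle, name, it, dim).values[:, :, 0]
            cols[a].append(vals[seg_ids][:, frame_sel].ravel())
        per_frame = np.repeat(w_seg[seg_ids] / fps, len(frame_sel))
        weights.append(per_frame)
        block_ids = np.empty((len(seg_ids) * len(frame_sel), 3), dtype=int)
        block_ids[:, 0] = it
        block_ids[:, 1] = np.repeat(seg_ids, len(frame_sel))
        block_ids[:, 2] = np.tile(frame_sel, len(seg_ids))
        ids.append(block_ids)

    if not weights:
        return WeightedPoints(
            x=np.empty(0), w=np.empty(0), ids=np.empty((0, 3), dtype=int)
        )
    stacked = [np.concatenate(c) for c in cols]
    out = {"x": stacked[0]}
    for key, arr in zip(("y", "z", "c"), stacked[1:]):
        out[key] = arr
    return WeightedPoints(
        w=np.concatenate(weights), ids=np.concatenate(ids), **out
    )


def _check_nonempty(points: WeightedPoints) -> None:
    if len(points) == 0:
        raise ValueError("no points in the selected range")


def hist1d_weighted(points: WeightedPoints, edges: np.ndarray) -> HistogramResult:
    """Weighted 1-D histogram, renormalised so the bins sum to one."""
    _check_nonempty(points)
    edges = np.asarray(edges, dtype=float)
    counts, _ = np.histogram(points.x, bins=edges, weights=points.w)
    total = counts.sum()
    if total == 0:
        raise ValueError("all points fall outside the histogram range")
    return HistogramResult(axis_edges=[edges], values=counts / total)


def hist2d_weighted(
    points: WeightedPoints, edges_x: np.ndarray, edges_y: np.ndarray
) -> HistogramResult:
    """Weighted 2-D histogram on the product grid, renormalised to one."""
    _check_nonempty(points)
    if points.y is None:
        raise ValueError("2-D histogram requires y values")
    edges_x = np.asarray(edges_x, dtype=float)
    edges_y = np.asarray(edges_y, dtype=float)
    counts, _, _ = np.histogram2d(
        points.x, points.y, bins=[edges_x, edges_y], weights=points.w
    )
    total = counts.sum()
    if total == 0:
        raise ValueError("all points fall outside the histogram range")
    return HistogramResult(axis_edges=[edges_x, edges_y], values=counts / total)


def default_edges(
    values: np.ndarray, bins: int = 100, histrange: tuple[float, float] | None = None
) -> np.ndarray:
    """Default binning: [min, max] of the data (or an explicit range)."""
    if histrange is None:
        lo, hi = float(np.min(values)), float(np.max(values))
        if lo == hi:  # degenerate data: open a tiny symmetric window
            lo, hi = lo - 0.5, hi + 0.5
    else:
        lo, hi = histrange
    return np.linspace(lo, hi, bins + 1)


def evolution_matrix(
    handle: WESimHandle,
    dataset: str = "pcoord",
    dim: int = 0,
    edges: np.ndarray | None = None,
    first_iter: int = 1,
    last_iter: int | None = None,
    step_iter: int = 1,
    bins: int = 100,
    histrange: tuple[float, float] | None = None,
    seg_mask: Sequence[np.ndarray] | None = None,
) -> HistogramResult:
    """Per-iteration 1-D weighted distributions stacked into a matrix.

    Row ``i`` is the normalised weighted histogram of iteration
    ``first_iter + i * step_iter``; every occupied row sums to one.
    """
    first_iter, last_iter, step_iter = _resolve_range(
        handle, first_iter, last_iter, step_iter
    )
    iters = list(range(first_iter, last_iter + 1, step_iter))
    if edges is None:
        allpts = collect_values(
            handle, [(dataset, dim)], first_iter, last_iter, step_iter,
            seg_mask=seg_mask,
        )
        _check_nonempty(allpts)
        edges = default_edges(allpts.x, bins=bins, histrange=histrange)
    edges = np.asarray(edges, dtype=float)

    matrix = np.zeros((len(iters), len(edges) - 1))
    for row, it in enumerate(iters):
        pts = collect_values(handle, [(dataset, dim)], it, it, seg_mask=seg_mask)
        if len(pts) == 0:
            logger.warning("iteration %d: no frames survive filtering", it)
            continue
        counts, _ = np.histogram(pts.x, bins=edges, weights=pts.w)
        total = counts.sum()
        if total == 0:
            logger.warning("iteration %d: all frames outside histogram range", it)
            continue
        matrix[row] = counts / total
    return HistogramResult(
        axis_edges=[edges],
        values=matrix,
        iter_range=(first_iter, last_iter, step_iter),
    )


def to_free_energy(
    hist: HistogramResult, units: str = "kT", temperature_K: float = 298.0
) -> HistogramResult:
    """Convert a probability histogram to free energies.

    ``F = -ln(P / P_max)`` in kT, multiplied by ``k_B T`` (kcal/mol) for kcal
    units.  The minimum finite value is exactly zero; empty bins become NaN.
    """
    if hist.units != "probability":
        raise ValueError(f"input must be in probability units, got {hist.units!r}")
    if units not in ("kT", "kcal"):
        raise ValueError("units must be 'kT' or 'kcal'")
    p = np.asarray(hist.values, dtype=float)
    pmax = p.max()
    if pmax <= 0:
        raise ValueError("histogram carries no probability mass")
    with np.errstate(divide="ignore"):
        f = -np.log(np.where(p > 0, p / pmax, np.nan))
    f[f == 0] = 0.0  # -log(1) is negative zero
    if units == "kcal":
        f = f * KB_KCAL_PER_MOL_K * temperature_K
    return HistogramResult(
        axis_edges=[e.copy() for e in hist.axis_edges],
        values=f,
        units=units,
        iter_range=hist.iter_range,
    )


def gaussian_smooth(hist: HistogramResult, sigma: float) -> HistogramResult:
    """Gaussian filter of the value array, sigma in bin units, reflective edges.

    ``sigma = 0`` is the bit-exact identity.  NaN (masked) cells are filled
    with the maximum finite value before filtering so contour lines close
    smoothly over empty regions.
    """
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if sigma == 0:
        return HistogramResult(
            axis_edges=[e.copy() for e in hist.axis_edges],
            values=hist.values.copy(),
            units=hist.units,
            iter_range=hist.iter_range,
        )
    vals = np.asarray(hist.values, dtype=float)
    nan_mask = np.isnan(vals)
    if nan_mask.any():
        fill = np.nanmax(vals)
        vals = np.where(nan_mask, fill, vals)
    smoothed = gaussian_filter(vals, sigma=sigma, mode="reflect")
    return HistogramResult(
        axis_edges=[e.copy() for e in hist.axis_edges],
        values=smoothed,
        units=hist.units,
        iter_range=hist.iter_range,
    )


# ---------------------------------------------------------------------------
# hexagonal binning
# ---------------------------------------------------------------------------

@dataclass
class HexbinResult:
    """Reduced values of occupied hexagonal cells."""

    centers: np.ndarray  # (n_cells, 2) in data coordinates
    values: np.ndarray
    counts: np.ndarray
    gridsize: int
    extent: tuple[float, float, float, float]
    nx: int
    ny: int


def hexbin_assign(
    x: np.ndarray,
    y: np.ndarray,
    gridsize: int,
    extent: tuple[float, float, float, float] | None = None,
) -> tuple[np.ndarray, dict]:
    """Assign points to the dual-lattice hexagonal grid.

    Returns integer cell keys of shape (n, 3): (lattice, ix, iy), plus the
    geometry needed to recover cell centres.  Lattice 0 has centres on
    integer scaled coordinates, lattice 1 on half-integer offsets; a point
    joins the nearer centre with the squared y-distance weighted by 3 (ties
    go to lattice 0).
    """
    if gridsize < 1:
        raise ValueError("gridsize must be >= 1")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if extent is None:
        extent = (float(x.min()), float(x.max()), float(y.min()), float(y.max()))
    xmin, xmax, ymin, ymax = extent
    nx = gridsize
    ny = max(1, int(nx / math.sqrt(3)))
    sx = nx / (xmax - xmin) if xmax > xmin else 1.0
    sy = ny / (ymax - ymin) if ymax > ymin else 1.0

    zx = (x - xmin) * sx
    zy = (y - ymin) * sy
    ix1 = np.floor(zx + 0.5).astype(int)
    iy1 = np.floor(zy + 0.5).astype(int)
    ix2 = np.floor(zx).astype(int)
    iy2 = np.floor(zy).astype(int)
    d1 = (zx - ix1) ** 2 + 3.0 * (zy - iy1) ** 2
    d2 = (zx - ix2 - 0.5) ** 2 + 3.0 * (zy - iy2 - 0.5) ** 2
    lat1 = d1 <= d2
    keys = np.empty((len(x), 3), dtype=int)
    keys[:, 0] = np.where(lat1, 0, 1)
    keys[:, 1] = np.where(lat1, ix1, ix2)
    keys[:, 2] = np.where(lat1, iy1, iy2)
    geom = {"extent": extent, "sx": sx, "sy": sy, "nx": nx, "ny": ny}
    return keys, geom


def hexbin_weighted(
    points: WeightedPoints,
    gridsize: int = 50,
    reduce: str = "weighted_mean",
    extent: tuple[float, float, float, float] | None = None,
) -> HexbinResult:
    """Reduce the colour feature over occupied hexagonal cells.

    ``weighted_mean`` computes ``sum(w * z) / sum(w)`` per cell (the WE
    path); ``mean`` a plain average (the conventional-MD path).  Empty cells
    are absent from the result.
    """
    _check_nonempty(points)
    if points.y is None:
        raise ValueError("hexbin requires y values")
    if reduce not in ("weighted_mean", "mean"):
        raise ValueError("reduce must be 'weighted_mean' or 'mean'")
    z = points.z if points.z is not None else np.ones(len(points))
    keys, geom = hexbin_assign(points.x, points.y, gridsize, extent)

    cells: dict[tuple[int, int, int], list[float]] = {}
    for k, (zi, wi) in zip(map(tuple, keys), zip(z, points.w)):
        acc = cells.setdefault(k, [0.0, 0.0, 0])
        if reduce == "weighted_mean":
            acc[0] += wi * zi
            acc[1] += wi
        else:
            acc[0] += zi
            acc[1] += 1.0
        acc[2] += 1

    order = sorted(cells)
    xmin, _, ymin, _ = geom["extent"]
    centers = np.empty((len(order), 2))
    values = np.empty(len(order))
    counts = np.empty(len(order), dtype=int)
    for r, key in enumerate(order):
        lat, ix, iy = key
        off = 0.5 if lat == 1 else 0.0
        centers[r, 0] = (ix + off) / geom["sx"] + xmin
        centers[r, 1] = (iy + off) / geom["sy"] + ymin
        num, den, cnt = cells[key]
        values[r] = num / den
        counts[r] = cnt
    return HexbinResult(
        centers=centers,
        values=values,
        counts=counts,
        gridsize=gridsize,
        extent=geom["extent"],
        nx=geom["nx"],
        ny=geom["ny"],
    )
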
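"""Rendering of the figure gallery from computed distribution objects.

Every pixel-producing call consumes only objects computed by the
distributions / tracing / kinetics modules; the numeric arrays handed to
matplotlib are kept on the returned :class:`PlotResult` so tests can verify
them against direct module calls.  Supported kinds: iteration-evolution
heat maps, 1-D lines, 2-D histograms, contour (line and filled) maps, 3-D
projected surfaces, scatter (plain, 3-D, 4-D colour), weighted hexbin and
joint plots with marginal side panels, plus GIF animation over iteration
windows and a user postprocess hook applied before saving.
"""

from __future__ import annotations

import importlib
import io as _io
import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Sequence

import matplotlib
import matplotlib.pyplot as plt
import numpy as np
from matplotlib.collections import PolyCollection
from PIL import Image

from . import distributions as dist
from .distributions import (
    HexbinResult,
    HistogramResult,
    WeightedPoints,
    collect_values,
    default_edges,
    evolution_matrix,
    gaussian_smooth,
    hexbin_weighted,
    hist1d_weighted,
    hist2d_weighted,
    to_free_energy,
)
from .io import WESimHandle
from .tracing import Trace, combine_masks, skip_basis_mask, successful_mask, trace_by_value, trace_lineage

logger = logging.getLogger(__name__)

KINDS = (
    "evolution",
    "line_1d",
    "hist2d",
    "contour",
    "contour_fill",
    "scatter",
    "hexbin",
    "proj3d",
    "proj4d",
    "joint",
)

_AXES_REQUIRED = {
    "evolution": 1,
    "line_1d": 1,
    "hist2d": 2,
    "contour": 2,
    "contour_fill": 2,
    "proj3d": 2,
    "joint": 2,
    "scatter": 2,
    "hexbin": 3,
    "proj4d": 4,
}

_DEFAULT_CMAPS = {
    "evolution": "viridis",
    "hist2d": "viridis",
    "contour": "gnuplot_r",
    "contour_fill": "gnuplot_r",
    "proj3d": "gnuplot_r",
    "joint": "gnuplot_r",
    "scatter": "viridis",
    "proj4d": "viridis",
    "hexbin": "viridis",
}


class PlotError(ValueError):
    """Invalid plot specification."""


class PostprocessError(RuntimeError):
    """A user postprocess hook could not be resolved or raised."""


@dataclass
class PlotSpec:
    """Declarative description of one figure."""

    kind: str = "hist2d"
    xname: str = "pcoord"
    xindex: int = 0
    yname: str | None = None
    yindex: int = 0
    zname: str | None = None
    zindex: int = 0
    cname: str | None = None
    cindex: int = 0
    first_iter: int = 1
    last_iter: int | None = None
    step_iter: int = 1
    frame_stride: int = 1
    p_units: str = "kT"  # probability | kT | kcal
    temperature_K: float = 298.0
    pmin: float | None = None
    pmax: float | None = None
    bins: int = 100
    histrange_x: tuple[float, float] | None = None
    histrange_y: tuple[float, float] | None = None
    cmap: str | None = None
    smoothing_level: float = 0.0
    contour_interval: float | None = None
    xlim: tuple[float, float] | None = None
    ylim: tuple[float, float] | None = None
    xlabel: str | None = None
    ylabel: str | None = None
    title: str | None = None
    style: str = "default"
    scatter_size: float = 5.0
    scatter_interval: int = 1
    hexbin_grid: int = 50
    trace_seg: tuple[int, int] | None = None
    trace_val: Sequence[float] | None = None
    succ_only: bool = False
    skip_basis: Sequence[bool] | None = None
    postprocess: str | Callable | None = None
    output: str | Path | None = None

    def validate(self) -> None:
        if self.kind not in KINDS:
            raise PlotError(f"unknown plot kind {self.kind!r}; choose from {KINDS}")
        axes = self.axes()
        need = _AXES_REQUIRED[self.kind]
        if len(axes) < need:
            raise PlotError(
                f"kind {self.kind!r} needs {need} axis dataset(s), got {len(axes)}"
            )
        if self.p_units not in ("probability", "kT", "kcal"):
            raise PlotError("p_units must be probability, kT or kcal")
        if self.smoothing_level < 0:
            raise PlotError("smoothing_level must be >= 0")
        if self.trace_seg is not None and self.trace_val is not None:
            raise PlotError("trace_seg and trace_val are mutually exclusive")

    def axes(self) -> list[tuple[str, int]]:
        """The (dataset, dim) pairs this spec consumes, in x,y,z,c order."""
        out = [(self.xname, self.xindex)]
        for name, idx in ((self.yname, self.yindex), (self.zname, self.zindex), (self.cname, self.cindex)):
            if name is None:
                break
            out.append((name, idx))
        return out


@dataclass
class PlotResult:
    """A rendered figure plus the numeric objects that produced it."""

    fig: matplotlib.figure.Figure
    ax: matplotlib.axes.Axes
    data: dict = field(default_factory=dict)

    def close(self) -> None:
        plt.close(self.fig)


def _segment_mask(spec: PlotSpec, handle: WESimHandle):
    masks = []
    if spec.succ_only:
        masks.append(successful_mask(handle))
    if spec.skip_basis is not None and any(spec.skip_basis):
        masks.append(skip_basis_mask(handle, spec.skip_basis))
    if not masks:
        return None
    return combine_masks(*masks)


def _points_from_source(spec: PlotSpec, source) -> WeightedPoints:
    axes = spec.axes()
    if isinstance(source, WESimHandle):
        return collect_values(
            source,
            axes,
            first_iter=spec.first_iter,
            last_iter=spec.last_iter,
            step_iter=spec.step_iter,
            frame_stride=spec.frame_stride,
            seg_mask=_segment_mask(spec, source),
        )
    arr = np.asarray(source, dtype=float)
    if arr.ndim == 1:
        arr = arr[:, None]
    if arr.shape[1] < len(axes):
        raise PlotError(
            f"kind {spec.kind!r} needs {len(axes)} columns, input has {arr.shape[1]}"
        )
    cols = [arr[:: spec.frame_stride, i] for i in range(len(axes))]
    names = ("x", "y", "z", "c")
    return WeightedPoints.from_arrays(**dict(zip(names, cols)))


def _maybe_free_energy(spec: PlotSpec, hist: HistogramResult) -> HistogramResult:
    if spec.p_units == "probability":
        return hist
    return to_free_energy(hist, units=spec.p_units, temperature_K=spec.temperature_K)


def compute_plot_data(spec: PlotSpec, source) -> dict:
    """Run the analysis pipeline for a spec; no drawing happens here."""
    spec.validate()
    data: dict = {}
    if spec.kind == "evolution":
        if not isinstance(source, WESimHandle):
            raise PlotError("evolution plots require a WE file")
        matrix = evolution_matrix(
            source,
            dataset=spec.xname,
            dim=spec.xindex,
            first_iter=spec.first_iter,
            last_iter=spec.last_iter,
            step_iter=spec.step_iter,
            bins=spec.bins,
            histrange=spec.histrange_x,
            seg_mask=_segment_mask(spec, source),
        )
        data["probability"] = matrix
        data["hist"] = _maybe_free_energy(spec, matrix)
        return data

    points = _points_from_source(spec, source)
    data["points"] = points
    if spec.kind == "line_1d":
        edges = default_edges(points.x, spec.bins, spec.histrange_x)
        hist = hist1d_weighted(points, edges)
        data["probability"] = hist
        data["hist"] = _maybe_free_energy(spec, hist)
    elif spec.kind in ("hist2d", "contour", "contour_fill", "proj3d", "joint"):
        edges_x = default_edges(points.x, spec.bins, spec.histrange_x)
        edges_y = default_edges(points.y, spec.bins, spec.histrange_y)
        hist = hist2d_weighted(points, edges_x, edges_y)
        data["probability"] = hist
        surface = _maybe_free_energy(spec, hist)
        if spec.smoothing_level and spec.kind in ("contour", "contour_fill", "proj3d"):
            surface = gaussian_smooth(surface, spec.smoothing_level)
        data["hist"] = surface
        if spec.kind == "joint":
            data["marginal_x"] = HistogramResult(
                axis_edges=[edges_x], values=hist.values.sum(axis=1)
            )
            data["marginal_y"] = HistogramResult(
                axis_edges=[edges_y], values=hist.values.sum(axis=0)
            )
    elif spec.kind == "hexbin":
        reduce = "weighted_mean" if isinstance(source, WESimHandle) else "mean"
        data["hexbin"] = hexbin_weighted(points, gridsize=spec.hexbin_grid, reduce=reduce)
    elif spec.kind in ("scatter", "proj4d"):
        pass  # the points themselves are the plotted object
    if spec.trace_seg is not None or spec.trace_val is not None:
        if not isinstance(source, WESimHandle):
            raise PlotError("traces require a WE file")
        axes = spec.axes()[: 2 if spec.yname else 1]
        if spec.trace_seg is not None:
            it, seg = spec.trace_seg
            data["trace"] = trace_lineage(source, it, seg, axes=axes)
        else:
            data["trace"] = trace_by_value(
                source, axes, spec.trace_val, spec.first_iter, spec.last_iter
            )
    return data


def _mask_values(spec: PlotSpec, values: np.ndarray) -> np.ma.MaskedArray:
    masked = np.ma.masked_invalid(values)
    if spec.pmax is not None:
        masked = np.ma.masked_greater(masked, spec.pmax)
    return masked


def _cmap(spec: PlotSpec) -> str:
    return spec.cmap or _DEFAULT_CMAPS.get(spec.kind, "viridis")


def _cbar_label(spec: PlotSpec) -> str:
    return {
        "probability": "probability",
        "kT": r"$-\ln\,(P/P_{max})$ [$k_B T$]",
        "kcal": r"$\Delta F$ [kcal/mol]",
    }[spec.p_units]


def _hex_vertices(hexes: HexbinResult) -> np.ndarray:
    xmin, xmax, ymin, ymax = hexes.extent
    sx = (xmax - xmin) / hexes.nx if xmax > xmin else 1.0
    sy = (ymax - ymin) / hexes.ny if ymax > ymin else 1.0
    unit = np.array(
        [[0.5, -0.25], [0.5, 0.25], [0.0, 0.5], [-0.5, 0.25], [-0.5, -0.25], [0.0, -0.5]]
    )
    poly = unit * np.array([sx, sy * 4.0 / 3.0])
    return hexes.centers[:, None, :] + poly[None, :, :]


def _draw(spec: PlotSpec, data: dict, fig=None, ax=None) -> PlotResult:
    if fig is None:
        if spec.kind in ("proj3d", "proj4d"):
            fig = plt.figure()
            ax = fig.add_subplot(projection="3d")
        elif spec.kind == "joint":
            fig = plt.figure()
            gs = fig.add_gridspec(
                2, 2, width_ratios=(4, 1), height_ratios=(1, 4),
                hspace=0.05, wspace=0.05,
            )
            ax = fig.add_subplot(gs[1, 0])
            ax_top = fig.add_subplot(gs[0, 0], sharex=ax)
            ax_right = fig.add_subplot(gs[1, 1], sharey=ax)
        else:
            fig, ax = plt.subplots()

    mappable = None
    if spec.kind == "evolution":
        hist = data["hist"]
        edges = hist.axis_edges[0]
        first, last, step = hist.iter_range
        iters = first + step * np.arange(hist.values.shape[0] + 1)
        vals = _mask_values(spec, hist.values)
        mappable = ax.pcolormesh(
            edges, iters - 0.5, vals, cmap=_cmap(spec),
            vmin=spec.pmin, vmax=spec.pmax, shading="flat",
        )
        ax.set_ylabel("WE iteration")
    elif spec.kind == "line_1d":
        hist = data["hist"]
        ax.plot(hist.centers(0), hist.values)
        ax.set_ylabel(_cbar_label(spec))
    elif spec.kind in ("hist2d", "contour", "contour_fill", "joint"):
        hist = data["hist"]
        vals = _mask_values(spec, hist.values).T
        cx, cy = hist.centers(0), hist.centers(1)
        if spec.kind == "hist2d":
            mappable = ax.pcolormesh(
                hist.axis_edges[0], hist.axis_edges[1], vals,
                cmap=_cmap(spec), vmin=spec.pmin, vmax=spec.pmax, shading="flat",
            )
        else:
            levels = None
            if spec.contour_interval is not None:
                top = spec.pmax if spec.pmax is not None else float(np.nanmax(hist.values))
                levels = np.arange(0.0, top + spec.contour_interval, spec.contour_interval)
            mappable = ax.contourf(
                cx, cy, vals, levels=levels, cmap=_cmap(spec),
                vmin=spec.pmin, vmax=spec.pmax,
            )
            if spec.kind == "contour":
                ax.contour(
                    cx, cy, vals, levels=levels, colors="k", linewidths=0.5
                )
        if spec.kind == "joint":
            mx, my = data["marginal_x"], data["marginal_y"]
            ax_top.plot(mx.centers(0), mx.values)
            ax_right.plot(my.values, my.centers(0))
            ax_top.tick_params(labelbottom=False)
            ax_right.tick_params(labelleft=False)
    elif spec.kind == "proj3d":
        hist = data["hist"]
        cx, cy = hist.centers(0), hist.centers(1)
        X, Y = np.meshgrid(cx, cy, indexing="ij")
        Z = np.asarray(_mask_values(spec, hist.values).filled(np.nan))
        mappable = ax.plot_surface(X, Y, Z, cmap=_cmap(spec), vmin=spec.pmin, vmax=spec.pmax)
        ax.set_zlabel(_cbar_label(spec))
    elif spec.kind == "scatter":
        pts = data["points"]
        sel = slice(None, None, spec.scatter_interval)
        mappable = ax.scatter(
            pts.x[sel], pts.y[sel], c=None if pts.z is None else pts.z[sel],
            s=spec.scatter_size, cmap=_cmap(spec),
        )
        if pts.z is None:
            mappable = None
    elif spec.kind == "proj4d":
        pts = data["points"]
        sel = slice(None, None, spec.scatter_interval)
        mappable = ax.scatter(
            pts.x[sel], pts.y[sel], pts.z[sel], c=pts.c[sel],
            s=spec.scatter_size, cmap=_cmap(spec),
        )
    elif spec.kind == "hexbin":
        hexes: HexbinResult = data["hexbin"]
        coll = PolyCollection(_hex_vertices(hexes), cmap=_cmap(spec))
        coll.set_array(hexes.values)
        ax.add_collection(coll)
        ax.autoscale_view()
        mappable = coll

    if "trace" in data:
        trace: Trace = data["trace"]
        if trace.values is not None:
            tx = trace.values[:, :, 0].ravel()
            color = "white" if spec.trace_seg is not None else "gold"
            if trace.values.shape[2] > 1:
                ax.plot(tx, trace.values[:, :, 1].ravel(), color=color, lw=1.5)
            elif spec.kind == "evolution":
                fps = trace.values.shape[1]
                ty = np.repeat([it for it, _ in trace.path], fps)
                ax.plot(tx, ty, color=color, lw=1.5)

    if mappable is not None and spec.kind != "joint":
        fig.colorbar(mappable, ax=ax, label=_cbar_label(spec) if spec.kind not in ("scatter", "proj4d", "hexbin") else None)
    if spec.xlim:
        ax.set_xlim(*spec.xlim)
    if spec.ylim:
        ax.set_ylim(*spec.ylim)
    ax.set_xlabel(spec.xlabel or spec.xname)
    if spec.ylabel:
        ax.set_ylabel(spec.ylabel)
    elif spec.yname and spec.kind != "evolution":
        ax.set_ylabel(spec.yname)
    if spec.title:
        ax.set_title(spec.title)
    return PlotResult(fig=fig, ax=ax, data=data)


def apply_postprocess(hook_ref: str | Callable, drawable: PlotResult) -> PlotResult:
    """Resolve and invoke a user hook ("module.function" or callable) once."""
    if callable(hook_ref):
        hook = hook_ref
        name = getattr(hook_ref, "__name__", repr(hook_ref))
    else:
        if "." not in hook_ref:
            raise PostprocessError(
                f"postprocess hook {hook_ref!r} must be 'module.function'"
            )
        mod_name, func_name = hook_ref.rsplit(".", 1)
        try:
            module = importlib.import_module(mod_name)
        except ImportError as exc:
            raise PostprocessError(
                f"cannot import module {mod_name!r} for hook {hook_ref!r}: {exc}"
            ) from exc
        try:
            hook = getattr(module, func_name)
        except AttributeError as exc:
            raise PostprocessError(
                f"module {mod_name!r} has no attribute {func_name!r}"
            ) from exc
        name = hook_ref
    try:
        hook(drawable)
    except Exception as exc:
        raise PostprocessError(f"postprocess hook {name!r} raised: {exc}") from exc
    return drawable


def render(spec: PlotSpec, source) -> PlotResult:
    """Compute, draw and (optionally) save one figure.

    ``source`` is a :class:`WESimHandle` or a plain numeric array (the
    conventional-MD path, uniform weights), or a list of such sources which
    are processed one per panel with shared normalisation conventions.  The
    figure handle is returned for further customisation; if a postprocess
    hook is configured it runs after drawing and before saving, and a
    failing hook prevents the file from being written.
    """
    spec.validate()
    if isinstance(source, (list, tuple)) and not isinstance(source, np.ndarray):
        sources = list(source)
    else:
        sources = [source]

    if spec.style and spec.style != "default":
        style = spec.style if Path(str(spec.style)).exists() else spec.style
        ctx = plt.style.context(style)
    else:
        import contextlib

        ctx = contextlib.nullcontext()

    with ctx:
        if len(sources) == 1:
            result = _draw(spec, compute_plot_data(spec, sources[0]))
        elif spec.kind == "line_1d":
            fig, ax = plt.subplots()
            datas = [compute_plot_data(spec, s) for s in sources]
            for i, d in enumerate(datas):
                hist = d["hist"]
                ax.plot(hist.centers(0), hist.values, label=f"input {i}")
            ax.legend()
            ax.set_xlabel(spec.xlabel or spec.xname)
            ax.set_ylabel(_cbar_label(spec))
            result = PlotResult(fig=fig, ax=ax, data={"inputs": datas})
        elif spec.kind == "joint":
            raise PlotError("joint plots accept a single input source")
        else:
            fig, axes = plt.subplots(1, len(sources), figsize=(5 * len(sources), 4))
            datas = []
            for s, a in zip(sources, np.atleast_1d(axes)):
                d = compute_plot_data(spec, s)
                _draw(spec, d, fig=fig, ax=a)
                datas.append(d)
            result = PlotResult(fig=fig, ax=np.atleast_1d(axes)[0], data={"inputs": datas})

    if spec.postprocess is not None:
        apply_postprocess(spec.postprocess, result)
    if spec.output is not None:
        result.fig.savefig(spec.output, dpi=100)
    return result


def gif_frame_count(first: int, last: int, avg_plus: int, step_iter: int) -> int:
    """Number of animation frames covering [first, last] in stepped windows."""
    span = last - first + 1 - avg_plus
    return math.ceil(span / step_iter)


def make_gif(
    spec: PlotSpec,
    source,
    gif_out: str | Path,
    avg_plus: int = 0,
    step_iter: int = 1,
    duration_ms: int = 200,
) -> Path:
    """Animate the distribution over sliding iteration windows into a GIF.

    Frame ``k`` averages iterations ``[first + k*step, first + k*step +
    avg_plus]``; the colour scale is shared across frames.
    """
    spec.validate()
    if not isinstance(source, WESimHandle):
        raise PlotError("GIF animation requires a WE file")
    first = spec.first_iter
    last = spec.last_iter if spec.last_iter is not None else source.n_iterations
    n_frames = gif_frame_count(first, last, avg_plus, step_iter)
    if n_frames < 1:
        raise PlotError("empty frame set: avg_plus exceeds the iteration range")

    images = []
    frame_data = []
    for k in range(n_frames):
        start = first + k * step_iter
        stop = min(start + avg_plus, last)
        frame_spec = replace(
            spec, first_iter=start, last_iter=stop, output=None, postprocess=None
        )
        result = _draw(frame_spec, compute_plot_data(frame_spec, source))
        result.ax.set_title(f"iterations {start}-{stop}")
        result.fig.canvas.draw()
        buf = np.asarray(result.fig.canvas.buffer_rgba())
        images.append(Image.fromarray(buf.copy()).convert("RGB"))
        frame_data.append(result.data)
        result.close()

    gif_out = Path(gif_out)
    images[0].save(
        gif_out,
        save_all=True,
        append_images=images[1:],
        duration=duration_ms,
        loop=0,
    )
    make_gif.last_frame_data = frame_data  # inspectable by tests
    return gif_out
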
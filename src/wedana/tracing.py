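"""Lineage algorithms over the WE segment tree.

Each segment stores the seg_id of its parent in the previous iteration
(negative values encode a basis-state origin), so the full history of any
walker is recovered by walking parent pointers back to iteration 1.  On top
of that single primitive sit the ensemble filters: keeping only lineages
that culminate in a recycling event (successful pathways) and dropping
lineages rooted in particular basis states.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .io import Endpoint, WESimHandle, read_frame_series, read_seg_index
from .distributions import collect_values

logger = logging.getLogger(__name__)


@dataclass
class Trace:
    """Ordered lineage of (iteration, seg_id) pairs ending at the anchor."""

    path: list[tuple[int, int]]
    anchor: tuple[int, int, int]  # iteration, seg_id, frame
    origin: int | None = None  # basis-state index of the lineage root
    values: np.ndarray | None = None  # (len(path), frames_per_seg, n_axes)

    def to_text(self) -> str:
        """Two-column text rendering: iteration, seg_id."""
        return "\n".join(f"{it} {seg}" for it, seg in self.path) + "\n"


def trace_lineage(
    handle: WESimHandle,
    iteration: int,
    seg_id: int,
    axes: Sequence[tuple[str, int]] | None = None,
) -> Trace:
    """Trace a segment's full ancestry back to iteration 1.

    Optionally extracts per-frame dataset values along the lineage for each
    ``(dataset, dim)`` in ``axes``.
    """
    handle._check_iteration(iteration)
    if not 0 <= seg_id < handle.segs_per_iter[iteration - 1]:
        raise IndexError(
            f"segment {seg_id} out of range for iteration {iteration} "
            f"({handle.segs_per_iter[iteration - 1]} segments)"
        )
    path: list[tuple[int, int]] = []
    origin: int | None = None
    it, seg = iteration, seg_id
    while it >= 1:
        path.append((it, seg))
        rec = read_seg_index(handle, it)[seg]
        if rec.parent_id < 0:
            origin = rec.basis_origin
            break
        seg = rec.parent_id
        it -= 1
    path.reverse()
    trace = Trace(
        path=path,
        anchor=(iteration, seg_id, handle.frames_per_seg - 1),
        origin=origin,
    )
    if axes is not None:
        trace.values = extract_trace_values(handle, trace, axes)
    return trace


def extract_trace_values(
    handle: WESimHandle, trace: Trace, axes: Sequence[tuple[str, int]]
) -> np.ndarray:
    """Per-frame dataset values along a lineage, shape (steps, frames, n_axes)."""
    out = np.empty((len(trace.path), handle.frames_per_seg, len(axes)))
    for k, (it, seg) in enumerate(trace.path):
        for a, (name, dim) in enumerate(axes):
            out[k, :, a] = read_frame_series(handle, name, it, dim).values[seg, :, 0]
    return out


def trace_by_value(
    handle: WESimHandle,
    axes: Sequence[tuple[str, int]],
    target_values: Sequence[float],
    first_iter: int = 1,
    last_iter: int | None = None,
    scale: bool = True,
) -> Trace:
    """Trace the lineage of the frame closest to the requested axis values.

    Distance is Euclidean after min-max scaling each axis over the collected
    range (so axes with different physical units are comparable); pass
    ``scale=False`` for raw distances.  Ties break toward the lowest
    (iteration, seg_id, frame).  The matched pair is logged so it can be
    reused in further analysis.
    """
    if len(axes) != len(target_values):
        raise ValueError("one target value per axis required")
    targets = np.asarray(target_values, dtype=float)
    if not np.all(np.isfinite(targets)):
        raise ValueError("target values must be finite")
    points = collect_values(handle, axes, first_iter, last_iter)
    if len(points) == 0:
        raise ValueError("no frames in the selected range")

    cols = np.column_stack([points.axis(i) for i in range(len(axes))])
    if scale:
        lo = cols.min(axis=0)
        span = cols.max(axis=0) - lo
        span[span == 0] = 1.0
        cols = (cols - lo) / span
        targets = (targets - lo) / span
    d2 = np.sum((cols - targets) ** 2, axis=1)
    # collection order is (iteration, seg_id, frame), so the first argmin
    # realises the documented tie-break
    best = int(np.argmin(d2))
    it, seg, frame = (int(v) for v in points.ids[best])
    logger.info("trace-by-value matched iteration %d, segment %d", it, seg)
    trace = trace_lineage(handle, it, seg, axes=axes)
    trace.anchor = (it, seg, frame)
    return trace


def successful_mask(handle: WESimHandle) -> list[np.ndarray]:
    """Mark segments lying on the ancestry of at least one recycling event.

    Returns one boolean array per iteration (indexed ``iteration - 1``).
    Computed by a single backward sweep: recycled segments are marked, and a
    marked segment marks its parent.  Equivalent to the union of the traced
    lineages of every recycled segment.
    """
    marks = [np.zeros(n, dtype=bool) for n in handle.segs_per_iter]
    for it in range(handle.n_iterations, 0, -1):
        records = read_seg_index(handle, it)
        for rec in records:
            if rec.endpoint == Endpoint.RECYCLED:
                marks[it - 1][rec.seg_id] = True
        if it > 1:
            for rec in records:
                if marks[it - 1][rec.seg_id] and rec.parent_id >= 0:
                    marks[it - 2][rec.parent_id] = True
    return marks


def segment_origins(handle: WESimHandle) -> list[np.ndarray]:
    """Basis-state index of each segment's lineage root, one array per iteration.

    A forward pass: segments with a negative parent decode their origin
    directly (``-(parent_id) - 1`` — including mid-run recycling restarts);
    the rest inherit the origin of their parent.
    """
    origins: list[np.ndarray] = []
    for it in range(1, handle.n_iterations + 1):
        records = read_seg_index(handle, it)
        cur = np.empty(len(records), dtype=int)
        for rec in records:
            if rec.parent_id < 0:
                cur[rec.seg_id] = rec.basis_origin
            else:
                cur[rec.seg_id] = origins[it - 2][rec.parent_id]
        origins.append(cur)
    return origins


def skip_basis_mask(
    handle: WESimHandle, skip_flags: Sequence[bool]
) -> list[np.ndarray]:
    """False for every segment whose lineage root is a skipped basis state.

    ``skip_flags`` has one boolean per basis state.  Downstream histograms
    renormalise the surviving weights within their normalisation block, so
    the result is the conditional distribution over the kept starting states.
    """
    skip = np.asarray(skip_flags, dtype=bool)
    origins = segment_origins(handle)
    max_origin = max((int(o.max()) for o in origins if len(o)), default=-1)
    if max_origin >= len(skip):
        raise ValueError(
            f"skip_flags has {len(skip)} entries but the file references "
            f"basis state {max_origin}"
        )
    return [~skip[o] for o in origins]


def combine_masks(*masks: Sequence[np.ndarray]) -> list[np.ndarray]:
    """Elementwise AND of per-iteration segment masks."""
    out = [np.asarray(m, dtype=bool).copy() for m in masks[0]]
    for other in masks[1:]:
        for i, m in enumerate(other):
            out[i] &= np.asarray(m, dtype=bool)
    return out
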
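"""Reading and writing weighted-ensemble (WE) simulation files.

This module is the single source of truth for the on-disk data model.
A WE run is stored in a hierarchical HDF5 file with the layout

    /iterations/iter_00000001/seg_index     structured: weight, parent_id, endpoint
    /iterations/iter_00000001/pcoord        float (n_segments, frames_per_seg, n_dims)
    /iterations/iter_00000001/auxdata/<x>   float (n_segments, frames_per_seg[, n_dims])

Iteration groups are contiguously numbered from 1.  Per-segment weights are
probabilities that sum to one within each iteration; ``parent_id >= 0`` points
at a segment of the previous iteration, while a negative value encodes a
basis-state origin as ``-(parent_id) - 1``.  The first stored frame of a
segment is the last frame of its parent, so ``frames_per_seg`` counts the
inherited starting frame plus the frames propagated during one resampling
interval tau.

Kinetics files carry per-iteration recycling flux into the target state
(datasets ``flux_per_tau``, optional ``source_population`` and ``red_flux``,
root attribute ``tau_seconds``).  Conventional-MD series are read from plain
text or NumPy/pickle containers.
"""

from __future__ import annotations

import logging
import pickle
from dataclasses import dataclass, field
from enum import IntEnum
from pathlib import Path
from typing import Mapping, Sequence

import h5py
import numpy as np

logger = logging.getLogger(__name__)

#: tolerance on per-iteration weight sums
WEIGHT_SUM_TOL = 1e-8

_ITER_FMT = "iter_{:08d}"
_SEG_DTYPE = np.dtype([("weight", "<f8"), ("parent_id", "<i8"), ("endpoint", "<i8")])
_CMD_EXTENSIONS = (".dat", ".txt", ".npy", ".npz", ".pkl")


class FormatError(ValueError):
    """An input file does not follow the documented on-disk dialect."""


class Endpoint(IntEnum):
    """Fate of a trajectory segment at the end of its iteration."""

    CONTINUES = 1
    MERGED = 2
    RECYCLED = 3


@dataclass(frozen=True)
class SegmentRecord:
    """One trajectory segment: its weight, parent link and endpoint status.

    ``parent_id >= 0`` is a seg_id in the previous iteration; a negative value
    means the segment started from basis state ``-(parent_id) - 1`` (either at
    the beginning of the run or after recycling).
    """

    iteration: int
    seg_id: int
    weight: float
    parent_id: int
    endpoint: Endpoint = Endpoint.CONTINUES

    @property
    def basis_origin(self) -> int | None:
        """Basis-state index if this segment has no simulated parent."""
        if self.parent_id < 0:
            return -self.parent_id - 1
        return None


@dataclass
class FrameSeries:
    """Per-frame values of one dataset for every segment of one iteration."""

    values: np.ndarray  # (n_segments, frames_per_seg, n_dims)
    dataset_name: str
    iteration: int


@dataclass
class FluxSeries:
    """Per-iteration probability flux into the target state.

    ``flux_per_tau`` is dimensionless probability recycled per resampling
    interval tau; ``source_population`` (optional) is the probability of the
    source state at the end of each iteration, used for equilibrium
    normalisation; ``red_flux`` (optional) is a pre-computed RED-corrected
    flux series that is read and plotted but never computed here.
    """

    tau_seconds: float
    flux_per_tau: np.ndarray
    source_population: np.ndarray | None = None
    red_flux: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.flux_per_tau = np.asarray(self.flux_per_tau, dtype=float)
        if np.any(self.flux_per_tau < 0):
            raise ValueError("flux_per_tau entries must be >= 0")
        if self.source_population is not None:
            self.source_population = np.asarray(self.source_population, dtype=float)
            if np.any(self.source_population <= 0) or np.any(self.source_population > 1):
                raise ValueError("source_population entries must lie in (0, 1]")
        if self.red_flux is not None:
            self.red_flux = np.asarray(self.red_flux, dtype=float)

    @property
    def n_iterations(self) -> int:
        return len(self.flux_per_tau)


@dataclass
class WESimHandle:
    """Indexed, validated view over a WE HDF5 file."""

    path: Path
    n_iterations: int
    segs_per_iter: list[int]
    dataset_catalog: dict[str, int]  # name -> per-frame dimensionality
    frames_per_seg: int
    _file: h5py.File = field(repr=False)

    # -- convenience delegates ------------------------------------------------
    def seg_index(self, iteration: int) -> list[SegmentRecord]:
        return read_seg_index(self, iteration)

    def frame_series(self, dataset_name: str, iteration: int, dim_index: int = 0) -> FrameSeries:
        return read_frame_series(self, dataset_name, iteration, dim_index)

    def iter_group(self, iteration: int) -> h5py.Group:
        self._check_iteration(iteration)
        return self._file["iterations"][_ITER_FMT.format(iteration)]

    def _check_iteration(self, iteration: int) -> None:
        if not 1 <= iteration <= self.n_iterations:
            raise IndexError(
                f"iteration {iteration} out of range 1..{self.n_iterations}"
            )

    def close(self) -> None:
        self._file.close()

    def __enter__(self) -> "WESimHandle":
        return self

    def __exit__(self, *exc) -> None:
        self.close()


def _dataset_ndim(ds: h5py.Dataset) -> int:
    if ds.ndim == 2:
        return 1
    if ds.ndim == 3:
        return ds.shape[2]
    raise FormatError(f"per-frame dataset {ds.name!r} must be 2- or 3-dimensional")


def open_we_file(path: str | Path, check_continuity: bool = False) -> WESimHandle:
    """Open and structurally validate a WE HDF5 file.

    Raises :class:`FormatError` for structural problems (missing or
    non-contiguous iteration groups, missing seg_index/pcoord).  Weight sums
    off by more than ``WEIGHT_SUM_TOL`` are logged as integrity warnings but do
    not abort the read, since third-party files may carry float drift.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        f = h5py.File(path, "r")
    except OSError as exc:
        raise FormatError(f"{path} is not an HDF5 file: {exc}") from exc

    if "iterations" not in f:
        f.close()
        raise FormatError(f"{path}: missing top-level 'iterations' group")
    names = sorted(f["iterations"].keys())
    n_iterations = len(names)
    if n_iterations == 0:
        f.close()
        raise FormatError(f"{path}: no iteration groups")
    expected = [_ITER_FMT.format(i) for i in range(1, n_iterations + 1)]
    if names != expected:
        f.close()
        raise FormatError(
            f"{path}: iteration groups must be contiguously numbered "
            f"iter_00000001..iter_{n_iterations:08d}"
        )

    segs_per_iter: list[int] = []
    catalog: dict[str, int] = {}
    frames_per_seg: int | None = None
    try:
        for i, name in enumerate(expected, start=1):
            g = f["iterations"][name]
            if "seg_index" not in g:
                raise FormatError(f"{path}: iteration {i} lacks 'seg_index'")
            seg = g["seg_index"]
            for fld in ("weight", "parent_id"):
                if seg.dtype.names is None or fld not in seg.dtype.names:
                    raise FormatError(
                        f"{path}: seg_index of iteration {i} lacks field {fld!r}"
                    )
            if "pcoord" not in g:
                raise FormatError(f"{path}: iteration {i} lacks 'pcoord'")
            n_segs = seg.shape[0]
            segs_per_iter.append(n_segs)
            w = seg["weight"][...]
            if np.any(w <= 0):
                logger.warning("%s: iteration %d has non-positive weights", path, i)
            if abs(w.sum() - 1.0) > WEIGHT_SUM_TOL:
                logger.warning(
                    "%s: iteration %d weights sum to %.12g (expected 1)",
                    path, i, w.sum(),
                )
            if i == 1:
                catalog["pcoord"] = _dataset_ndim(g["pcoord"])
                if "auxdata" in g:
                    for aux in sorted(g["auxdata"].keys()):
                        catalog[f"auxdata/{aux}"] = _dataset_ndim(g["auxdata"][aux])
                frames_per_seg = g["pcoord"].shape[1]
    except FormatError:
        f.close()
        raise

    handle = WESimHandle(
        path=path,
        n_iterations=n_iterations,
        segs_per_iter=segs_per_iter,
        dataset_catalog=catalog,
        frames_per_seg=int(frames_per_seg),
        _file=f,
    )
    if check_continuity:
        validate_continuity(handle)
    return handle


def read_seg_index(handle: WESimHandle, iteration: int) -> list[SegmentRecord]:
    """Return the per-segment table of one iteration in seg_id order."""
    g = handle.iter_group(iteration)
    seg = g["seg_index"][...]
    has_endpoint = "endpoint" in seg.dtype.names
    records = []
    for j in range(seg.shape[0]):
        ep = Endpoint(int(seg["endpoint"][j])) if has_endpoint else Endpoint.CONTINUES
        records.append(
            SegmentRecord(
                iteration=iteration,
                seg_id=j,
                weight=float(seg["weight"][j]),
                parent_id=int(seg["parent_id"][j]),
                endpoint=ep,
            )
        )
    return records


def read_frame_series(
    handle: WESimHandle,
    dataset_name: str,
    iteration: int,
    dim_index: int = 0,
) -> FrameSeries:
    """Read one dimension of a per-frame dataset for one iteration.

    Returns values of shape ``(n_segments, frames_per_seg, 1)``.
    """
    if dataset_name not in handle.dataset_catalog:
        raise KeyError(
            f"unknown dataset {dataset_name!r}; available: "
            f"{sorted(handle.dataset_catalog)}"
        )
    ndim = handle.dataset_catalog[dataset_name]
    if not 0 <= dim_index < ndim:
        raise IndexError(
            f"dim_index {dim_index} out of range for {dataset_name!r} "
            f"with {ndim} dimension(s)"
        )
    g = handle.iter_group(iteration)
    ds = g[dataset_name]
    values = ds[...]
    if values.ndim == 2:
        values = values[:, :, None]
    values = values[:, :, dim_index : dim_index + 1]
    return FrameSeries(values=values, dataset_name=dataset_name, iteration=iteration)


def _validate_iteration_payload(
    i: int,
    records: Sequence[SegmentRecord],
    datasets: Mapping[str, np.ndarray],
    prev_n_segs: int | None,
    frames_per_seg: int | None,
) -> int:
    n = len(records)
    if n == 0:
        raise ValueError(f"iteration {i}: empty segment list")
    w = np.array([r.weight for r in records])
    if abs(w.sum() - 1.0) > WEIGHT_SUM_TOL:
        raise ValueError(
            f"iteration {i}: weights sum to {w.sum():.12g}, expected 1 "
            f"within {WEIGHT_SUM_TOL}"
        )
    if prev_n_segs is not None:
        for r in records:
            if r.parent_id >= prev_n_segs:
                raise ValueError(
                    f"iteration {i}: parent_id {r.parent_id} exceeds segment "
                    f"count {prev_n_segs} of iteration {i - 1}"
                )
    if "pcoord" not in datasets:
        raise ValueError(f"iteration {i}: 'pcoord' dataset is required")
    for name, arr in datasets.items():
        arr = np.asarray(arr)
        if arr.ndim not in (2, 3) or arr.shape[0] != n:
            raise ValueError(
                f"iteration {i}: dataset {name!r} has shape {arr.shape}, "
                f"inconsistent with {n} segments"
            )
        if frames_per_seg is not None and arr.shape[1] != frames_per_seg:
            raise ValueError(
                f"iteration {i}: dataset {name!r} has {arr.shape[1]} frames, "
                f"expected {frames_per_seg}"
            )
    return np.asarray(datasets["pcoord"]).shape[1]


def write_we_file(
    path: str | Path,
    iterations: Sequence[tuple[Sequence[SegmentRecord], Mapping[str, np.ndarray]]],
    attrs: Mapping[str, float] | None = None,
) -> Path:
    """Write a WE HDF5 file; validates everything before touching the disk.

    ``iterations`` is a list of ``(segment records, dataset map)`` pairs, one
    per iteration starting at iteration 1.  The dataset map uses catalog names
    (``"pcoord"``, ``"auxdata/<x>"``).  Round-trips bit-exactly through
    :func:`open_we_file` on weights, parents, endpoints and datasets.
    """
    path = Path(path)
    # validate first so a bad payload never leaves a partial file behind
    prev_n = None
    frames = None
    for i, (records, datasets) in enumerate(iterations, start=1):
        frames = _validate_iteration_payload(i, records, datasets, prev_n, frames)
        prev_n = len(records)

    with h5py.File(path, "w") as f:
        root = f.create_group("iterations")
        if attrs:
            for k, v in attrs.items():
                f.attrs[k] = v
        for i, (records, datasets) in enumerate(iterations, start=1):
            g = root.create_group(_ITER_FMT.format(i))
            table = np.zeros(len(records), dtype=_SEG_DTYPE)
            for r in records:
                table["weight"][r.seg_id] = r.weight
                table["parent_id"][r.seg_id] = r.parent_id
                table["endpoint"][r.seg_id] = int(r.endpoint)
            g.create_dataset("seg_index", data=table)
            for name, arr in datasets.items():
                arr = np.asarray(arr, dtype=float)
                if arr.ndim == 2:
                    arr = arr[:, :, None]
                g.create_dataset(name, data=arr)
    return path


def add_derived_dataset(
    path: str | Path,
    name: str,
    per_iteration_values: Sequence[np.ndarray],
) -> None:
    """Append a derived per-frame dataset (e.g. ``auxdata/pc1``) to a WE file.

    Existing groups and datasets are left untouched; shapes are validated
    against each iteration's segment count before writing.
    """
    path = Path(path)
    with open_we_file(path) as handle:
        if len(per_iteration_values) != handle.n_iterations:
            raise ValueError(
                f"got {len(per_iteration_values)} arrays for "
                f"{handle.n_iterations} iterations"
            )
        for i, arr in enumerate(per_iteration_values, start=1):
            arr = np.asarray(arr)
            if arr.shape[0] != handle.segs_per_iter[i - 1] or arr.shape[1] != handle.frames_per_seg:
                raise ValueError(f"iteration {i}: array shape {arr.shape} inconsistent")
    with h5py.File(path, "a") as f:
        for i, arr in enumerate(per_iteration_values, start=1):
            arr = np.asarray(arr, dtype=float)
            if arr.ndim == 2:
                arr = arr[:, :, None]
            f["iterations"][_ITER_FMT.format(i)].create_dataset(name, data=arr)


def validate_continuity(handle: WESimHandle) -> None:
    """Check that each segment's first frame equals its parent's last frame.

    Applies to every catalogued dataset and every segment with a simulated
    parent (``parent_id >= 0``); raises :class:`FormatError` on violation.
    """
    prev: dict[str, np.ndarray] = {}
    for i in range(1, handle.n_iterations + 1):
        g = handle.iter_group(i)
        seg = g["seg_index"][...]
        pid = seg["parent_id"][...]
        cur: dict[str, np.ndarray] = {}
        for name in handle.dataset_catalog:
            arr = g[name][...]
            if arr.ndim == 2:
                arr = arr[:, :, None]
            cur[name] = arr
            mask = pid >= 0
            if i > 1 and mask.any():
                first = arr[mask, 0, :]
                parent_last = prev[name][pid[mask], -1, :]
                if not np.array_equal(first, parent_last):
                    raise FormatError(
                        f"{handle.path}: lineage discontinuity in {name!r} "
                        f"at iteration {i}"
                    )
        prev = cur


# ---------------------------------------------------------------------------
# kinetics files
# ---------------------------------------------------------------------------

def write_flux_file(path: str | Path, flux: FluxSeries) -> Path:
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.attrs["tau_seconds"] = flux.tau_seconds
        f.create_dataset("flux_per_tau", data=flux.flux_per_tau)
        if flux.source_population is not None:
            f.create_dataset("source_population", data=flux.source_population)
        if flux.red_flux is not None:
            f.create_dataset("red_flux", data=flux.red_flux)
    return path


def read_flux_file(path: str | Path, tau_seconds: float | None = None) -> FluxSeries:
    """Read a kinetics file; ``tau_seconds`` overrides the file metadata.

    Third-party files do not store tau consistently, so the resampling
    interval may be supplied by the caller; the file attribute is the
    fallback.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        f = h5py.File(path, "r")
    except OSError as exc:
        raise FormatError(f"{path} is not an HDF5 file: {exc}") from exc
    with f:
        if "flux_per_tau" not in f:
            raise FormatError(f"{path}: missing 'flux_per_tau' dataset")
        if tau_seconds is None:
            if "tau_seconds" not in f.attrs:
                raise ValueError(
                    f"{path} carries no tau_seconds attribute; pass tau_seconds"
                )
            tau_seconds = float(f.attrs["tau_seconds"])
        return FluxSeries(
            tau_seconds=tau_seconds,
            flux_per_tau=f["flux_per_tau"][...],
            source_population=(
                f["source_population"][...] if "source_population" in f else None
            ),
            red_flux=f["red_flux"][...] if "red_flux" in f else None,
        )


# ---------------------------------------------------------------------------
# conventional-MD series
# ---------------------------------------------------------------------------

def read_cmd_series(path: str | Path) -> np.ndarray:
    """Read a plain numeric series as an array of shape (n_frames, n_dims).

    Supported extensions: .dat/.txt (whitespace-delimited, one leading header
    line tolerated), .npy, .npz (first array), .pkl (plain numeric array
    payload only).
    """
    path = Path(path)
    ext = path.suffix.lower()
    if ext not in _CMD_EXTENSIONS:
        raise FormatError(
            f"unsupported extension {ext!r}; supported: {', '.join(_CMD_EXTENSIONS)}"
        )
    if ext in (".dat", ".txt"):
        try:
            arr = np.loadtxt(path, ndmin=2)
        except ValueError:
            arr = np.loadtxt(path, skiprows=1, ndmin=2)
    elif ext == ".npy":
        arr = np.load(path)
    elif ext == ".npz":
        with np.load(path) as npz:
            keys = npz.files
            key = "arr_0" if "arr_0" in keys else sorted(keys)[0]
            arr = npz[key]
    else:  # .pkl
        with open(path, "rb") as fh:
            obj = pickle.load(fh)
        arr = np.asarray(obj)
        if arr.dtype == object or not np.issubdtype(arr.dtype, np.number):
            raise FormatError(f"{path}: pickle payload is not a plain numeric array")
    arr = np.asarray(arr, dtype=float)
    if arr.ndim == 1:
        arr = arr[:, None]
    if arr.ndim != 2:
        raise FormatError(f"{path}: expected 1- or 2-dimensional data, got {arr.ndim}")
    return arr
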
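import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from wedana.distributions import (
    KB_KCAL_PER_MOL_K,
    WeightedPoints,
    collect_values,
    default_edges,
    evolution_matrix,
    gaussian_smooth,
    hexbin_assign,
    hexbin_weighted,
    hist1d_weighted,
    hist2d_weighted,
    to_free_energy,
)
from wedana.io import SegmentRecord, open_we_file, write_we_file


def _random_points(seed, n=200, with_yz=True):
    rng = np.random.default_rng(seed)
    w = rng.random(n)
    return WeightedPoints(
        x=rng.normal(size=n),
        y=rng.normal(size=n) if with_yz else None,
        z=rng.normal(size=n) if with_yz else None,
        w=w / w.sum(),
    )


# ---- collection -----------------------------------------------------------

def test_point_count_equals_segments_times_frames(chain_handle):
    pts = collect_values(chain_handle, [("pcoord", 0)])
    expected = sum(chain_handle.segs_per_iter) * chain_handle.frames_per_seg
    assert len(pts) == expected


def test_per_iteration_frame_weights_sum_to_one(chain_handle):
    pts = collect_values(chain_handle, [("pcoord", 0)])
    for it in range(1, chain_handle.n_iterations + 1):
        mask = pts.ids[:, 0] == it
        assert pts.w[mask].sum() == pytest.approx(1.0, abs=1e-8)


def test_frame_stride_keeps_every_other_frame_unrenormalised(chain_handle):
    full = collect_values(chain_handle, [("pcoord", 0)], first_iter=1, last_iter=1)
    strided = collect_values(
        chain_handle, [("pcoord", 0)], first_iter=1, last_iter=1, frame_stride=2
    )
    kept = np.isin(full.ids[:, 2], np.arange(0, chain_handle.frames_per_seg, 2))
    np.testing.assert_array_equal(strided.x, full.x[kept])
    np.testing.assert_array_equal(strided.w, full.w[kept])  # no renormalisation


def test_empty_range_returns_empty_points(chain_handle):
    mask = [np.zeros(n, dtype=bool) for n in chain_handle.segs_per_iter]
    pts = collect_values(chain_handle, [("pcoord", 0)], seg_mask=mask)
    assert len(pts) == 0


# ---- 1D / 2D histograms ---------------------------------------------------

def test_hist1d_direct_placement():
    pts = WeightedPoints(
        x=np.array([0.5, 1.5, 2.5]), w=np.array([0.5, 0.25, 0.25])
    )
    h = hist1d_weighted(pts, np.array([0.0, 1.0, 2.0, 3.0]))
    np.testing.assert_allclose(h.values, [0.5, 0.25, 0.25])
    assert h.units == "probability"


def test_hist1d_uniform_weights_match_plain_histogram():
    rng = np.random.default_rng(0)
    x = rng.normal(size=500)
    pts = WeightedPoints.from_arrays(x)
    edges = np.linspace(-3, 3, 20)
    h = hist1d_weighted(pts, edges)
    plain, _ = np.histogram(x, bins=edges)
    np.testing.assert_allclose(h.values, plain / plain.sum(), atol=1e-12)


def test_hist1d_matches_bruteforce_loop():
    pts = _random_points(3)
    edges = np.linspace(-2.5, 2.5, 11)
    h = hist1d_weighted(pts, edges)
    brute = np.zeros(10)
    total = 0.0
    for xi, wi in zip(pts.x, pts.w):
        for b in range(10):
            lo, hi = edges[b], edges[b + 1]
            if (lo <= xi < hi) or (b == 9 and xi == hi):
                brute[b] += wi
                total += wi
                break
    np.testing.assert_allclose(h.values, brute / total, atol=1e-12)


def test_hist1d_all_points_outside_range_errors():
    pts = WeightedPoints(x=np.array([10.0]), w=np.array([1.0]))
    with pytest.raises(ValueError, match="outside"):
        hist1d_weighted(pts, np.array([0.0, 1.0]))


def test_hist2d_matches_bruteforce_and_marginalises():
    pts = _random_points(4)
    ex = np.linspace(-2.5, 2.5, 8)
    ey = np.linspace(-3.0, 3.0, 9)
    h2 = hist2d_weighted(pts, ex, ey)
    brute = np.zeros((7, 8))
    for xi, yi, wi in zip(pts.x, pts.y, pts.w):
        bx = min(np.searchsorted(ex, xi, side="right") - 1, 6)
        by = min(np.searchsorted(ey, yi, side="right") - 1, 7)
        if 0 <= bx < 7 and 0 <= by < 8 and ex[0] <= xi <= ex[-1] and ey[0] <= yi <= ey[-1]:
            brute[bx, by] += wi
    brute /= brute.sum()
    np.testing.assert_allclose(h2.values, brute, atol=1e-12)
    # marginal over y equals the 1D histogram of x restricted to the box
    inside = (
        (pts.x >= ex[0]) & (pts.x <= ex[-1]) & (pts.y >= ey[0]) & (pts.y <= ey[-1])
    )
    pts_in = WeightedPoints(x=pts.x[inside], w=pts.w[inside])
    h1 = hist1d_weighted(pts_in, ex)
    np.testing.assert_allclose(h2.values.sum(axis=1), h1.values, atol=1e-12)


def test_hist2d_single_point_is_unit_cell():
    pts = WeightedPoints(x=np.array([0.5]), y=np.array([0.5]), w=np.array([0.3]))
    h = hist2d_weighted(pts, np.array([0.0, 1.0, 2.0]), np.array([0.0, 1.0]))
    np.testing.assert_allclose(h.values, [[1.0], [0.0]])


@settings(deadline=None, max_examples=25)
@given(st.integers(min_value=0, max_value=10_000))
def test_hist1d_normalisation_property(seed):
    pts = _random_points(seed, n=50, with_yz=False)
    h = hist1d_weighted(pts, np.linspace(-4, 4, 13))
    assert h.values.sum() == pytest.approx(1.0, abs=1e-8)
    assert np.all(h.values >= 0)


# ---- evolution ------------------------------------------------------------

def test_evolution_rows_sum_to_one_and_match_single_iteration(chain_handle):
    ev = evolution_matrix(chain_handle, bins=30)
    assert ev.values.shape[0] == chain_handle.n_iterations
    sums = ev.values.sum(axis=1)
    np.testing.assert_allclose(sums, 1.0, atol=1e-8)
    # a single-iteration range reproduces row 5
    one = evolution_matrix(
        chain_handle, bins=30, edges=ev.axis_edges[0], first_iter=6, last_iter=6
    )
    np.testing.assert_allclose(one.values[0], ev.values[5], atol=1e-12)


def test_evolution_unit_spike_for_frozen_iteration(tmp_path):
    rec = [SegmentRecord(1, 0, 1.0, -1)]
    pc = np.full((1, 3, 1), 2.0)
    path = write_we_file(tmp_path / "spike.h5", [(rec, {"pcoord": pc})])
    with open_we_file(path) as h:
        ev = evolution_matrix(h, edges=np.array([0.0, 1.0, 2.0, 3.0, 4.0]))
    np.testing.assert_allclose(ev.values, [[0.0, 0.0, 1.0, 0.0]])


# ---- free energy ----------------------------------------------------------

def test_free_energy_closed_form():
    from wedana.distributions import HistogramResult

    h = HistogramResult(
        axis_edges=[np.array([0.0, 1, 2, 3])], values=np.array([0.5, 0.25, 0.25])
    )
    f = to_free_energy(h, "kT")
    np.testing.assert_allclose(f.values, [0.0, math.log(2), math.log(2)])
    assert f.units == "kT"


def test_free_energy_uniform_is_zero_and_kcal_ratio():
    from wedana.distributions import HistogramResult

    h = HistogramResult(axis_edges=[np.linspace(0, 1, 5)], values=np.full(4, 0.25))
    assert np.all(to_free_energy(h, "kT").values == 0.0)

    h2 = HistogramResult(
        axis_edges=[np.linspace(0, 1, 4)], values=np.array([0.6, 0.3, 0.1])
    )
    f_kt = to_free_energy(h2, "kT").values
    f_kcal = to_free_energy(h2, "kcal", temperature_K=298.0).values
    nz = f_kt > 0
    np.testing.assert_allclose(
        f_kcal[nz] / f_kt[nz], KB_KCAL_PER_MOL_K * 298.0, rtol=1e-12
    )


def test_free_energy_floor_is_zero_and_empty_bins_masked(chain_handle):
    pts = collect_values(chain_handle, [("pcoord", 0)])
    h = hist1d_weighted(pts, np.linspace(-1, 7, 30))
    f = to_free_energy(h, "kT")
    finite = f.values[np.isfinite(f.values)]
    assert finite.min() == 0.0
    assert np.all(np.isnan(f.values[h.values == 0]))


def test_free_energy_requires_probability_input():
    from wedana.distributions import HistogramResult

    h = HistogramResult(
        axis_edges=[np.array([0.0, 1.0])], values=np.array([1.0]), units="kT"
    )
    with pytest.raises(ValueError):
        to_free_energy(h, "kT")


# ---- smoothing ------------------------------------------------------------

def test_smoothing_zero_sigma_is_identity():
    from wedana.distributions import HistogramResult

    vals = np.random.default_rng(0).random((6, 6))
    h = HistogramResult(axis_edges=[np.arange(7.0), np.arange(7.0)], values=vals)
    out = gaussian_smooth(h, 0.0)
    np.testing.assert_array_equal(out.values, vals)


def test_smoothing_spike_matches_discrete_kernel():
    from wedana.distributions import HistogramResult

    n = 41
    vals = np.zeros(n)
    vals[20] = 1.0
    h = HistogramResult(axis_edges=[np.arange(n + 1.0)], values=vals)
    out = gaussian_smooth(h, 2.0)
    # scipy's discrete Gaussian kernel: normalised samples of exp(-k^2/2s^2)
    radius = int(4 * 2.0 + 0.5)
    k = np.arange(-radius, radius + 1)
    kernel = np.exp(-0.5 * (k / 2.0) ** 2)
    kernel /= kernel.sum()
    np.testing.assert_allclose(out.values[20 - radius : 20 + radius + 1], kernel[::-1], atol=1e-12)


def test_smoothing_preserves_interior_mass():
    from wedana.distributions import HistogramResult

    vals = np.zeros((21, 21))
    vals[10, 10] = 1.0
    h = HistogramResult(axis_edges=[np.arange(22.0), np.arange(22.0)], values=vals)
    out = gaussian_smooth(h, 1.5)
    assert out.values.sum() == pytest.approx(1.0, abs=1e-8)


def test_smoothing_negative_sigma_rejected():
    from wedana.distributions import HistogramResult

    h = HistogramResult(axis_edges=[np.arange(3.0)], values=np.zeros(2))
    with pytest.raises(ValueError):
        gaussian_smooth(h, -1.0)


# ---- hexbin ---------------------------------------------------------------

def test_hexbin_two_point_weighted_mean():
    pts = WeightedPoints(
        x=np.array([0.5, 0.5]),
        y=np.array([0.5, 0.5]),
        z=np.array([1.0, 3.0]),
        w=np.array([0.75, 0.25]),
    )
    out = hexbin_weighted(pts, gridsize=2, extent=(0, 1, 0, 1))
    assert len(out.values) == 1
    assert out.values[0] == pytest.approx(1.5)


def test_hexbin_equal_weights_reduce_to_plain_mean():
    rng = np.random.default_rng(5)
    n = 300
    pts = WeightedPoints(
        x=rng.random(n), y=rng.random(n), z=rng.random(n), w=np.full(n, 1.0 / n)
    )
    wm = hexbin_weighted(pts, gridsize=8, reduce="weighted_mean")
    pm = hexbin_weighted(pts, gridsize=8, reduce="mean")
    np.testing.assert_allclose(wm.values, pm.values, atol=1e-12)


def test_hexbin_matches_bruteforce_cell_accumulation():
    pts = _random_points(9, n=400)
    gridsize = 10
    out = hexbin_weighted(pts, gridsize=gridsize)
    # brute force: per-point scalar assignment on the documented geometry
    xmin, xmax = pts.x.min(), pts.x.max()
    ymin, ymax = pts.y.min(), pts.y.max()
    nx, ny = gridsize, max(1, int(gridsize / math.sqrt(3)))
    sx, sy = nx / (xmax - xmin), ny / (ymax - ymin)
    cells = {}
    for xi, yi, zi, wi in zip(pts.x, pts.y, pts.z, pts.w):
        zx, zy = (xi - xmin) * sx, (yi - ymin) * sy
        ix1, iy1 = math.floor(zx + 0.5), math.floor(zy + 0.5)
        ix2, iy2 = math.floor(zx), math.floor(zy)
        d1 = (zx - ix1) ** 2 + 3 * (zy - iy1) ** 2
        d2 = (zx - ix2 - 0.5) ** 2 + 3 * (zy - iy2 - 0.5) ** 2
        key = (0, ix1, iy1) if d1 <= d2 else (1, ix2, iy2)
        num, den = cells.get(key, (0.0, 0.0))
        cells[key] = (num + wi * zi, den + wi)
    expected = np.array([n / d for _, (n, d) in sorted(cells.items())])
    np.testing.assert_allclose(out.values, expected, atol=1e-12)


def test_hexbin_invalid_gridsize():
    pts = _random_points(1)
    with pytest.raises(ValueError):
        hexbin_weighted(pts, gridsize=0)


# ---- WE/cMD consistency ---------------------------------------------------

def test_single_walker_file_matches_flattened_cmd_path(tmp_path):
    rng = np.random.default_rng(2)
    frames = 4
    series = []
    iterations = []
    last = 0.0
    for it in range(1, 6):
        traj = np.concatenate([[last], rng.normal(size=frames - 1)])
        last = traj[-1]
        rec = [SegmentRecord(it, 0, 1.0, 0 if it > 1 else -1)]
        iterations.append((rec, {"pcoord": traj[None, :]}))
        series.append(traj)
    path = write_we_file(tmp_path / "one.h5", iterations)
    edges = np.linspace(-3, 3, 15)
    with open_we_file(path) as h:
        we_pts = collect_values(h, [("pcoord", 0)])
        we_hist = hist1d_weighted(we_pts, edges)
    cmd_pts = WeightedPoints.from_arrays(np.concatenate(series))
    cmd_hist = hist1d_weighted(cmd_pts, edges)
    np.testing.assert_allclose(we_hist.values, cmd_hist.values, atol=1e-12)


def test_default_edges_cover_data_and_degenerate_input():
    e = default_edges(np.array([1.0, 3.0]), bins=4)
    assert e[0] == 1.0 and e[-1] == 3.0 and len(e) == 5
    e2 = default_edges(np.array([2.0, 2.0]), bins=4)
    assert e2[0] < 2.0 < e2[-1]
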
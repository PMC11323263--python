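import numpy as np
import pytest

import matplotlib

matplotlib.use("Agg")

from wedana.distributions import (
    collect_values,
    default_edges,
    evolution_matrix,
    hexbin_weighted,
    hist2d_weighted,
    to_free_energy,
)
from wedana.plotting import (
    PlotError,
    PlotSpec,
    PostprocessError,
    apply_postprocess,
    compute_plot_data,
    gif_frame_count,
    make_gif,
    render,
)


def test_evolution_render_consumes_the_evolution_matrix(chain_handle, tmp_path):
    out = tmp_path / "evo.png"
    spec = PlotSpec(kind="evolution", bins=24, output=out)
    result = render(spec, chain_handle)
    direct = evolution_matrix(chain_handle, bins=24)
    np.testing.assert_array_equal(result.data["probability"].values, direct.values)
    fe = to_free_energy(direct, "kT")
    np.testing.assert_array_equal(result.data["hist"].values, fe.values)
    assert out.exists() and out.stat().st_size > 0
    result.close()


def test_joint_panels_are_the_2d_histogram_and_its_marginals(chain_handle, tmp_path):
    spec = PlotSpec(
        kind="joint", yname="auxdata/rog", bins=20, p_units="probability",
        output=tmp_path / "joint.png",
    )
    result = render(spec, chain_handle)
    pts = collect_values(chain_handle, [("pcoord", 0), ("auxdata/rog", 0)])
    h2 = hist2d_weighted(
        pts, default_edges(pts.x, 20), default_edges(pts.y, 20)
    )
    np.testing.assert_allclose(result.data["probability"].values, h2.values)
    np.testing.assert_allclose(
        result.data["marginal_x"].values, h2.values.sum(axis=1), atol=1e-12
    )
    np.testing.assert_allclose(
        result.data["marginal_y"].values, h2.values.sum(axis=0), atol=1e-12
    )
    result.close()


def test_trace_overlay_coordinates_equal_trace_values(chain_handle, tmp_path):
    from wedana.tracing import trace_lineage

    last = chain_handle.n_iterations
    spec = PlotSpec(
        kind="hist2d", yname="auxdata/rog", bins=20,
        trace_seg=(last, 0), output=tmp_path / "trace.png",
    )
    result = render(spec, chain_handle)
    direct = trace_lineage(
        chain_handle, last, 0, axes=[("pcoord", 0), ("auxdata/rog", 0)]
    )
    np.testing.assert_array_equal(result.data["trace"].values, direct.values)
    # the overlay line's x/y data are exactly the trace values
    lines = [ln for ln in result.ax.get_lines() if ln.get_color() in ("white", "gold")]
    assert len(lines) == 1
    np.testing.assert_array_equal(lines[0].get_xdata(), direct.values[:, :, 0].ravel())
    np.testing.assert_array_equal(lines[0].get_ydata(), direct.values[:, :, 1].ravel())
    result.close()


@pytest.mark.parametrize(
    "kind,extra",
    [
        ("line_1d", {}),
        ("hist2d", {"yname": "auxdata/rog"}),
        ("contour", {"yname": "auxdata/rog", "smoothing_level": 1.0, "contour_interval": 1.0}),
        ("contour_fill", {"yname": "auxdata/rog"}),
        ("scatter", {"yname": "auxdata/rog", "zname": "pcoord"}),
        ("hexbin", {"yname": "auxdata/rog", "zname": "pcoord", "hexbin_grid": 12}),
        ("proj3d", {"yname": "auxdata/rog"}),
        ("proj4d", {"yname": "auxdata/rog", "zname": "pcoord", "cname": "auxdata/rog"}),
    ],
)
def test_each_plot_kind_writes_a_file(chain_handle, tmp_path, kind, extra):
    out = tmp_path / f"{kind}.png"
    spec = PlotSpec(kind=kind, bins=16, output=out, **extra)
    result = render(spec, chain_handle)
    assert out.exists() and out.stat().st_size > 0
    result.close()


def test_hexbin_arrays_match_distribution_module(chain_handle, tmp_path):
    spec = PlotSpec(
        kind="hexbin", yname="auxdata/rog", zname="pcoord", hexbin_grid=9,
        output=tmp_path / "hex.png",
    )
    result = render(spec, chain_handle)
    pts = collect_values(
        chain_handle, [("pcoord", 0), ("auxdata/rog", 0), ("pcoord", 0)]
    )
    direct = hexbin_weighted(pts, gridsize=9)
    np.testing.assert_array_equal(result.data["hexbin"].values, direct.values)
    np.testing.assert_array_equal(result.data["hexbin"].centers, direct.centers)
    result.close()


def test_incompatible_kind_and_axes_rejected_before_compute():
    with pytest.raises(PlotError, match="axis"):
        PlotSpec(kind="proj4d", yname="a").validate()
    with pytest.raises(PlotError, match="kind"):
        PlotSpec(kind="nope").validate()


def test_cmd_array_source_uses_uniform_weights(tmp_path):
    rng = np.random.default_rng(0)
    arr = rng.normal(size=(300, 2))
    spec = PlotSpec(
        kind="hist2d", yname="col1", p_units="probability", bins=10,
        output=tmp_path / "cmd.png",
    )
    result = render(spec, arr)
    pts = result.data["points"]
    assert np.allclose(pts.w, 1.0 / 300)
    result.close()


def test_same_spec_same_fixture_identical_arrays(chain_handle):
    spec = PlotSpec(kind="line_1d", bins=25)
    a = compute_plot_data(spec, chain_handle)
    b = compute_plot_data(spec, chain_handle)
    np.testing.assert_array_equal(a["hist"].values, b["hist"].values)


def test_multi_source_line_plot(chain_handle, well_handle, tmp_path):
    spec = PlotSpec(kind="line_1d", bins=12, output=tmp_path / "multi.png")
    result = render(spec, [chain_handle, well_handle])
    assert len(result.data["inputs"]) == 2
    assert (tmp_path / "multi.png").exists()
    result.close()


# ---- GIF animation --------------------------------------------------------

def test_gif_frame_count_formula():
    assert gif_frame_count(1, 10, avg_plus=1, step_iter=3) == 3
    assert gif_frame_count(1, 10, avg_plus=9, step_iter=1) == 1
    assert gif_frame_count(1, 5, avg_plus=5, step_iter=1) == 0


def test_gif_frames_match_subrange_histograms(chain_handle, tmp_path):
    from PIL import Image

    spec = PlotSpec(
        kind="hist2d", yname="auxdata/rog", bins=10, first_iter=1, last_iter=10,
        histrange_x=(-0.5, 5.5), histrange_y=(14.5, 19.0),
    )
    out = make_gif(spec, chain_handle, tmp_path / "evo.gif", avg_plus=1, step_iter=3)
    with Image.open(out) as img:
        assert img.n_frames == 3
    # frame 0 covers iterations 1..2
    pts = collect_values(
        chain_handle, [("pcoord", 0), ("auxdata/rog", 0)], first_iter=1, last_iter=2
    )
    direct = hist2d_weighted(
        pts, np.linspace(-0.5, 5.5, 11), np.linspace(14.5, 19.0, 11)
    )
    frame0 = make_gif.last_frame_data[0]
    np.testing.assert_allclose(frame0["probability"].values, direct.values)


def test_gif_with_empty_frame_set_errors(chain_handle, tmp_path):
    spec = PlotSpec(kind="hist2d", yname="auxdata/rog", first_iter=1, last_iter=4)
    with pytest.raises(PlotError, match="frame"):
        make_gif(spec, chain_handle, tmp_path / "x.gif", avg_plus=4)


# ---- postprocess hook -----------------------------------------------------

def _add_reference_line(result):
    result.ax.axhline(1.0, color="red", label="reference")


def test_hook_adds_reference_line(chain_handle, tmp_path):
    spec = PlotSpec(
        kind="line_1d", bins=10, postprocess=_add_reference_line,
        output=tmp_path / "hook.png",
    )
    result = render(spec, chain_handle)
    assert any(
        ln.get_label() == "reference" for ln in result.ax.get_lines()
    )
    result.close()


def test_identity_hook_output_identical_to_no_hook(chain_handle, tmp_path):
    spec_a = PlotSpec(kind="line_1d", bins=10, output=tmp_path / "a.png")
    spec_b = PlotSpec(
        kind="line_1d", bins=10, output=tmp_path / "b.png",
        postprocess=lambda result: None,
    )
    render(spec_a, chain_handle).close()
    render(spec_b, chain_handle).close()
    assert (tmp_path / "a.png").read_bytes() == (tmp_path / "b.png").read_bytes()


def test_failing_hook_names_itself_and_blocks_the_file(chain_handle, tmp_path):
    def exploding(result):
        raise RuntimeError("boom")

    spec = PlotSpec(
        kind="line_1d", bins=10, postprocess=exploding, output=tmp_path / "x.png"
    )
    with pytest.raises(PostprocessError, match="exploding"):
        render(spec, chain_handle)
    assert not (tmp_path / "x.png").exists()


def test_unresolvable_hook_import_path():
    from wedana.plotting import PlotResult
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots()
    try:
        with pytest.raises(PostprocessError, match="no_such_module"):
            apply_postprocess("no_such_module.func", PlotResult(fig, ax))
        with pytest.raises(PostprocessError, match="nope"):
            apply_postprocess("math.nope", PlotResult(fig, ax))
    finally:
        plt.close(fig)
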
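import dataclasses

import numpy as np
import pytest

from histocyte.errors import PlacementError, SceneValidationError
from histocyte.segment import project_mip
from histocyte.spectral import SpilloverMatrix
from histocyte.synthscene import (
    OpticsConfig,
    SceneConfig,
    build_scene,
    render_scene,
    render_single_stains,
)

PROFILES = {
    "A": {"M1": (200.0, 0.25)},
    "B": {"M2": (150.0, 0.25)},
    "N": {},
}


def _cfg(**over):
    base = dict(
        field_size=(120.0, 120.0),
        pixel_size=0.5,
        n_follicles=0,
        cell_density=5000.0,
        composition={"EF": {"A": 0.5, "B": 0.3, "N": 0.2}},
        phenotype_profiles=PROFILES,
        seed=3,
    )
    base.update(over)
    return SceneConfig(**base)


def _optics(**over):
    base = dict(
        channels=["DNA", "M1", "M2"],
        localization={"DNA": "nuclear", "M1": "nuclear", "M2": "surface"},
        autofluorescence=0.0,
        noise={"gaussian_sd": 0.0, "poisson_scale": 0.0},
    )
    base.update(over)
    return OpticsConfig(**base)


# ---------------------------------------------------------------------------
# build_scene
# ---------------------------------------------------------------------------
def test_determinism_same_seed_identical_different_seed_differs():
    c = _cfg()
    s1, s2 = build_scene(c), build_scene(c)
    assert s1.cells.equals(s2.cells)
    s3 = build_scene(_cfg(seed=4))
    assert not np.array_equal(
        s1.cells[["y_um", "x_um"]].to_numpy(), s3.cells[["y_um", "x_um"]].to_numpy()
    )


def test_no_follicles_gives_pure_ef_scene():
    s = build_scene(_cfg())
    assert s.follicles == []
    assert (s.cells["compartment"] == "EF").all()
    assert (s.cells["follicle_id"] == 0).all()


def test_composition_must_sum_to_one():
    with pytest.raises(SceneValidationError):
        _cfg(composition={"EF": {"A": 0.6, "B": 0.3}}).validate()


def test_unknown_phenotype_rejected():
    with pytest.raises(SceneValidationError):
        _cfg(composition={"EF": {"A": 0.5, "Zed": 0.5}}).validate()


def test_field_too_small_raises_placement_error():
    cfg = _cfg(
        n_follicles=3,
        follicle_axes_range=(60.0, 70.0),
        composition={c: {"A": 1.0} for c in ("EF", "MZ", "LZ", "DZ")},
    )
    with pytest.raises(PlacementError, match="follicle"):
        build_scene(cfg)


def test_follicle_placement_succeeds_across_seeds():
    """Reference geometry (9 large follicles) places for any seed, with
    non-overlapping ellipses and the configured clearance."""
    from histocyte.fixtures import load_fixture
    from histocyte.synthscene import _place_follicles

    fx = load_fixture("gc_reference")
    for seed in range(30):
        rng = np.random.default_rng(seed)
        fols = _place_follicles(fx.scene, rng)
        assert len(fols) == fx.scene.n_follicles
        for i, a in enumerate(fols):
            for b in fols[i + 1:]:
                d = np.hypot(a.outer.cy - b.outer.cy, a.outer.cx - b.outer.cx)
                # grid cells guarantee disjoint bounding circles
                assert d >= a.outer.a + b.outer.a - 1e-9
            h, w = fx.scene.field_size
            assert 0 < a.outer.cy < h and 0 < a.outer.cx < w


def test_poisson_disk_minimum_spacing():
    s = build_scene(_cfg())
    pts = s.cells[["y_um", "x_um"]].to_numpy()
    from scipy.spatial import cKDTree

    d, _ = cKDTree(pts).query(pts, k=2)
    assert d[:, 1].min() >= 0.8 * 2 * s.config.nucleus_radius[0] - 1e-9


def test_every_cell_in_exactly_one_compartment(gc_scene):
    regions, fids = gc_scene.compartment_of(
        gc_scene.cells["y_um"].to_numpy(), gc_scene.cells["x_um"].to_numpy()
    )
    assert (regions == gc_scene.cells["compartment"].to_numpy()).all()
    assert (fids == gc_scene.cells["follicle_id"].to_numpy()).all()
    follicular = np.isin(regions, ["MZ", "LZ", "DZ"])
    assert (fids[follicular] > 0).all() and (fids[~follicular] == 0).all()


def test_ground_truth_composition_recovers_configured_fractions(gc_small, gc_scene):
    """Multinomial law: per-compartment phenotype fractions within 3 sigma."""
    cells = gc_scene.cells
    assert len(cells) >= 2000
    for comp, mix in gc_small.scene.composition.items():
        sub = cells[cells["compartment"] == comp]
        n = len(sub)
        for pheno, frac in mix.items():
            got = (sub["phenotype"] == pheno).mean()
            sd = np.sqrt(max(frac * (1 - frac), 1e-9) / n)
            assert abs(got - frac) <= 3 * sd + 1e-9, (comp, pheno, got, frac)


# ---------------------------------------------------------------------------
# render_scene
# ---------------------------------------------------------------------------
def test_empty_scene_renders_all_zero():
    cfg = _cfg(composition={"EF": {"N": 1.0}})
    s = build_scene(cfg)
    img = render_scene(s, _optics())
    assert img.channel("M1").max() == 0
    assert img.channel("M2").max() == 0


def test_single_cell_marker_integral_matches_blob_oracle():
    """Integrated marker signal equals expression x blob area within 1%.

    Oracle: the soft-edged disk integral computed directly from geometry;
    Gaussian blur conserves total intensity away from borders.
    """
    cfg = _cfg(cell_density=70.0, composition={"EF": {"A": 1.0}}, seed=9)
    s = build_scene(cfg)
    assert s.n_cells == 1
    expr = float(s.cells["expr_M1"].iloc[0])
    r = float(s.cells["nucleus_radius_um"].iloc[0])
    img = render_scene(s, _optics())
    px = cfg.pixel_size
    measured = img.channel("M1").astype(np.float64).sum() * px * px
    # oracle: direct pixel integral of the unblurred soft disk
    rr = r / px
    n = int(np.ceil(rr)) + 3
    yy, xx = np.mgrid[-n:n + 1, -n:n + 1].astype(float)
    d = np.hypot(yy, xx)
    disk = np.clip(rr - d + 0.5, 0, 1)
    oracle = expr * disk.sum() * px * px
    assert measured == pytest.approx(oracle, rel=0.01)


def test_spillover_mixing_is_pixelwise_linear():
    """Observed render equals M^T applied to the identity-spillover render."""
    cfg = _cfg(seed=5)
    s = build_scene(cfg)
    m = SpilloverMatrix.from_pairs(
        ["DNA", "M1", "M2"], [("M1", "M2", 0.2), ("DNA", "M1", 0.1)]
    )
    base = render_scene(s, _optics())               # identity spillover
    mixed = render_scene(s, _optics(spillover=m))   # same optics, mixed
    flat = base.data.reshape(3, -1).astype(np.float64)
    expect = (m.values.T @ flat).reshape(base.data.shape)
    assert np.allclose(mixed.data, expect, atol=0.75)


def test_values_clipped_to_bit_depth():
    cfg = _cfg(phenotype_profiles={"A": {"M1": (1e9, 0.0)}, "B": {}, "N": {}})
    s = build_scene(cfg)
    img = render_scene(s, _optics(bit_depth=8))
    assert img.data.max() <= 255


# ---------------------------------------------------------------------------
# render_single_stains
# ---------------------------------------------------------------------------
def test_single_stains_one_per_fluorophore_and_isolated():
    s = build_scene(_cfg())
    optics = _optics()
    stains = render_single_stains(s, optics)
    assert set(stains) == set(optics.channels)
    # identity spillover, zero AF/noise: signal only in the stain's channel
    m1 = stains["M1"]
    assert m1.channel("M1").max() > 0
    assert m1.channel("M2").max() == 0
    assert m1.channel("DNA").max() == 0


def test_single_stain_foreground_ratio_reflects_spillover():
    m = SpilloverMatrix.from_pairs(["DNA", "M1", "M2"], [("M1", "M2", 0.2)])
    s = build_scene(_cfg())
    stains = render_single_stains(s, _optics(spillover=m))
    img = stains["M1"]
    fg = img.channel("M1") > np.quantile(img.channel("M1"), 0.99)
    ratio = img.channel("M2")[fg].sum() / img.channel("M1")[fg].sum()
    assert ratio == pytest.approx(0.2, abs=0.02)


# ---------------------------------------------------------------------------
# thin z-stack mode
# ---------------------------------------------------------------------------
def test_zstack_render_and_mip():
    s = build_scene(_cfg())
    optics = _optics(n_slices=3)
    stack = render_scene(s, optics)
    assert stack.is_stack and stack.data.shape[1] == 3
    flat = render_scene(s, _optics())
    mip = project_mip(stack)
    # center slice carries full weight, so the MIP recovers the 2D render
    assert np.allclose(mip.data, flat.data, atol=1e-4)


def test_fdc_mesh_confined_to_gc(structure_run):
    scene = structure_run["scene"]
    mask = scene.fdc_mask
    assert mask.any()
    h, w = mask.shape
    px = scene.config.pixel_size
    yy, xx = np.nonzero(mask)
    yum, xum = (yy + 0.5) * px, (xx + 0.5) * px
    in_gc = np.zeros(len(yum), dtype=bool)
    for f in scene.follicles:
        in_gc |= f.gc.contains(yum, xum)
    assert in_gc.mean() > 0.98


def test_sidecar_export_round_trip(tmp_path, gc_scene):
    import json

    import pandas as pd

    cells_csv = tmp_path / "cells.csv"
    geom_json = tmp_path / "geom.json"
    gc_scene.write(cells_csv, geom_json)
    back = pd.read_csv(cells_csv)
    assert len(back) == gc_scene.n_cells
    geom = json.loads(geom_json.read_text())
    assert len(geom["follicles"]) == len(gc_scene.follicles)
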
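import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from histocyte.errors import ConfigurationError, EstimationError
from histocyte.image import MultichannelImage
from histocyte.spectral import (
    SpilloverMatrix,
    compensate,
    estimate_spillover,
    remix,
    subtract_autofluorescence,
)
from histocyte.synthscene import build_scene, render_scene, render_single_stains

CH = ["a", "b", "c"]


def _mk_matrix():
    return SpilloverMatrix.from_pairs(
        CH, [("a", "b", 0.15), ("b", "a", 0.05), ("b", "c", 0.2), ("c", "b", 0.08)]
    )


def _synthetic_stains(matrix, scale=1.0, noise_sd=0.0, seed=0):
    """Single stains built directly from the linear mixing model."""
    rng = np.random.default_rng(seed)
    out = {}
    for i, f in enumerate(CH):
        true = np.zeros((3, 160, 160))
        blobs = np.zeros((160, 160))
        for _ in range(60):
            y, x = rng.integers(4, 156, 2)
            blobs[y - 2:y + 3, x - 2:x + 3] += rng.uniform(100, 300)
        true[i] = blobs * scale
        obs = np.einsum("fc,fyx->cyx", matrix.values, true) + 2.0
        if noise_sd:
            obs = obs + rng.normal(0, noise_sd, obs.shape)
        out[f] = MultichannelImage(np.clip(obs, 0, None), CH, 0.5)
    return out


# ---------------------------------------------------------------------------
# SpilloverMatrix container
# ---------------------------------------------------------------------------
def test_matrix_validation():
    with pytest.raises(ConfigurationError):
        SpilloverMatrix(np.array([[0.9, 0.0], [0.0, 1.0]]), ["a", "b"])
    with pytest.raises(ConfigurationError):
        SpilloverMatrix(np.array([[1.0, 1.2], [0.0, 1.0]]), ["a", "b"])


def test_matrix_csv_round_trip_bit_exact(tmp_path):
    m = _mk_matrix()
    m.values[0, 1] = 0.12345678901234567
    path = tmp_path / "m.csv"
    m.to_csv(path)
    back = SpilloverMatrix.from_csv(path)
    assert back.channel_names == CH
    assert np.array_equal(back.values, m.values)


# ---------------------------------------------------------------------------
# estimate_spillover
# ---------------------------------------------------------------------------
def test_identity_spillover_estimates_to_identity():
    stains = _synthetic_stains(SpilloverMatrix.identity(CH))
    est = estimate_spillover(stains)
    off = est.values[~np.eye(3, dtype=bool)]
    assert np.all(np.abs(off) < 1e-6)


def test_known_matrix_recovered_under_mild_noise():
    m = _mk_matrix()
    stains = _synthetic_stains(m, noise_sd=1.5, seed=1)
    est = estimate_spillover(stains)
    assert np.allclose(est.values, m.values, atol=0.02)


def test_all_background_image_raises_estimation_error():
    stains = _synthetic_stains(SpilloverMatrix.identity(CH))
    flat = np.full_like(stains["a"].data, 2.0)
    stains["a"] = MultichannelImage(flat, CH, 0.5)
    with pytest.raises(EstimationError, match="'a'"):
        estimate_spillover(stains)


def test_missing_single_stain_rejected():
    stains = _synthetic_stains(SpilloverMatrix.identity(CH))
    del stains["b"]
    with pytest.raises(ConfigurationError):
        estimate_spillover(stains)


@settings(deadline=None, max_examples=10)
@given(st.floats(min_value=0.25, max_value=20.0))
def test_estimate_is_scale_invariant(k):
    """Multiplying every single stain by k leaves the estimate unchanged."""
    m = _mk_matrix()
    base = estimate_spillover(_synthetic_stains(m)).values
    scaled = estimate_spillover(_synthetic_stains(m, scale=k)).values
    assert np.allclose(base, scaled, atol=5e-3)


def test_estimate_from_rendered_single_stains(gc_small):
    """End-to-end: stains rendered by the simulator recover the optics matrix."""
    import dataclasses

    cfg = dataclasses.replace(
        gc_small.scene, field_size=(220.0, 220.0), n_follicles=0,
        composition={"EF": {"calib": 1.0}},
        phenotype_profiles={"calib": {m: (220.0, 0.25)
                                      for m in gc_small.optics.channels
                                      if m != "DNA"}},
        cell_density=6000.0, seed=21,
    )
    scene = build_scene(cfg)
    stains = render_single_stains(scene, gc_small.optics)
    est = estimate_spillover(stains)
    assert np.allclose(est.values, gc_small.optics.spillover.values, atol=0.02)


# ---------------------------------------------------------------------------
# compensate
# ---------------------------------------------------------------------------
def test_identity_compensation_is_identity(gc_image):
    out = compensate(gc_image, SpilloverMatrix.identity(gc_image.channel_names))
    assert np.allclose(out.data, gc_image.data, atol=1e-4)
    assert out.metadata["compensated"] is True
    assert not gc_image.metadata.get("compensated", False)  # input untouched


def test_compensation_round_trip_against_unmixed_render(gc_small, gc_scene):
    """compensate(render(M)) matches the identity-spillover render <=1e-3 rel."""
    import dataclasses

    optics = dataclasses.replace(
        gc_small.optics,
        noise={"gaussian_sd": 0.0, "poisson_scale": 0.0},
        spillover=gc_small.optics.spillover,
    )
    mixed = render_scene(gc_scene, optics)
    unmixed = render_scene(gc_scene, optics, mix=False)
    comp = compensate(mixed, optics.spillover)
    denom = max(unmixed.data.max(), 1.0)
    rel = np.abs(comp.data - unmixed.data) / denom
    assert rel.max() <= 1e-3


def test_remix_recovers_observed(gc_compensated, gc_small, gc_image):
    back = remix(gc_compensated, gc_small.optics.spillover)
    # exact round trip wherever the non-negativity clamp did not engage;
    # clamped background pixels stay within the noise scale
    diff = np.abs(back.data - gc_image.data)
    unclamped = (gc_compensated.data > 0).all(axis=0)
    # float32 storage bounds the relative error on unclamped pixels
    tol = 1e-5 * np.abs(gc_image.data[:, unclamped]) + 1e-2
    assert (diff[:, unclamped] <= tol).all()
    # clamped pixels err by at most the spilled-in fraction of the
    # brightest co-channel signal
    off = gc_small.optics.spillover.values.copy()
    np.fill_diagonal(off, 0.0)
    assert diff.max() <= off.max() * float(gc_image.data.max()) + 1.0


def test_channel_mismatch_rejected(gc_image):
    m = SpilloverMatrix.identity(list("abcdefgh"))
    with pytest.raises(ConfigurationError):
        compensate(gc_image, m)


# ---------------------------------------------------------------------------
# subtract_autofluorescence
# ---------------------------------------------------------------------------
def _af_image():
    data = np.stack([
        np.full((8, 8), 10.0),       # AF reference
        np.full((8, 8), 20.0),       # exactly 2x AF
        np.full((8, 8), 5.0),
    ])
    return MultichannelImage(data, ["AF", "s1", "s2"], 1.0)


def test_af_zero_coefficients_identity():
    img = _af_image()
    out = subtract_autofluorescence(img, "AF", {"s1": 0.0, "s2": 0.0})
    assert np.array_equal(out.data, img.data)


def test_af_exact_cancellation_and_clamp():
    img = _af_image()
    out = subtract_autofluorescence(img, "AF", {"s1": 2.0, "s2": 2.0})
    assert np.all(out.channel("s1") == 0.0)   # exact cancellation
    assert np.all(out.channel("s2") == 0.0)   # clamped, never negative
    assert np.array_equal(out.channel("AF"), img.channel("AF"))


def test_af_unknown_channel_rejected():
    with pytest.raises(ConfigurationError):
        subtract_autofluorescence(_af_image(), "AF", {"nope": 1.0})
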
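"""Shared fixtures: scaled-down reference scenes run once per session.

The heavy artifacts (built scene, render, compensated image, segmentation,
gated cell table) are produced once and shared read-only across tests; any
test that needs to mutate them must copy first.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pytest
from scipy.spatial import cKDTree

from histocyte import (
    build_compartment_map,
    build_scene,
    build_tzone_mask,
    compensate,
    extract_features,
    render_scene,
    segment_nuclei,
)
from histocyte.compartment import assign_compartments
from histocyte.fixtures import load_fixture
from histocyte.gating import ThresholdSet, apply_gates, derive_thresholds
from histocyte.pipeline import RunConfig, run_pipeline


def _shrink(scene_cfg, **over):
    return dataclasses.replace(scene_cfg, **over)


@pytest.fixture(scope="session")
def gc_small():
    """GC-reactivity fixture scaled to ~2 follicles / ~2200 cells."""
    fx = load_fixture("gc_reference", seed=11)
    fx.scene = _shrink(
        fx.scene,
        field_size=(520.0, 520.0),
        n_follicles=2,
        follicle_axes_range=(85.0, 115.0),
        cell_density=9000.0,
        seed=11,
    )
    return fx


@pytest.fixture(scope="session")
def gc_scene(gc_small):
    return build_scene(gc_small.scene)


@pytest.fixture(scope="session")
def gc_image(gc_small, gc_scene):
    return render_scene(gc_scene, gc_small.optics)


@pytest.fixture(scope="session")
def gc_compensated(gc_small, gc_image):
    return compensate(gc_image, gc_small.optics.spillover)


@pytest.fixture(scope="session")
def gc_labels(gc_small, gc_compensated):
    return segment_nuclei(gc_compensated, "DNA",
                          **gc_small.pipeline["segmentation"])


@pytest.fixture(scope="session")
def gc_cells(gc_small, gc_compensated, gc_labels):
    return extract_features(gc_labels, gc_compensated,
                            **gc_small.pipeline["features"])


@pytest.fixture(scope="session")
def gc_cmap(gc_small, gc_compensated):
    cmap = build_compartment_map(
        gc_compensated, gc_small.panel.compartment["markers"],
        **gc_small.pipeline["compartment"],
    )
    cmap.tzone = build_tzone_mask(gc_compensated, cmap, "CD4")
    return cmap


@pytest.fixture(scope="session")
def gc_assigned(gc_cells, gc_cmap):
    return assign_compartments(gc_cells, gc_cmap)


@pytest.fixture(scope="session")
def gc_thresholds(gc_small, gc_assigned):
    ts = ThresholdSet()
    for ch, spec in gc_small.panel.thresholds.items():
        kwargs = {k: v for k, v in spec.items() if k != "method"}
        derive_thresholds(gc_assigned, ch, method=spec.get("method", "gmm"),
                          seed=11, into=ts, **kwargs)
    return ts


@pytest.fixture(scope="session")
def gc_gated(gc_small, gc_assigned, gc_thresholds):
    return apply_gates(gc_assigned, gc_small.panel.tree, gc_thresholds)


@pytest.fixture(scope="session")
def gc_match(gc_scene, gc_cells):
    """Match segmented cells to ground-truth cells by nearest centroid."""
    tree = cKDTree(gc_scene.cells[["y_um", "x_um"]].to_numpy())
    d, idx = tree.query(gc_cells.df[["y_um", "x_um"]].to_numpy())
    ok = d < 2.0
    return ok, idx


@pytest.fixture(scope="session")
def structure_small():
    fx = load_fixture("structure_reference", seed=7)
    fx.scene = _shrink(fx.scene, field_size=(450.0, 450.0), n_follicles=2,
                       follicle_axes_range=(75.0, 100.0), cell_density=8000.0,
                       seed=7)
    return fx


@pytest.fixture(scope="session")
def structure_run(structure_small, tmp_path_factory):
    fx = structure_small
    scene = build_scene(fx.scene)
    img = render_scene(scene, fx.optics)
    cimg = compensate(img, fx.optics.spillover)
    cmap = build_compartment_map(cimg, fx.panel.compartment["markers"],
                                 **fx.pipeline["compartment"])
    return {"fixture": fx, "scene": scene, "image": cimg, "cmap": cmap}


@pytest.fixture(scope="session")
def rnascope_run():
    """Full pipeline (including spots) on the RNAscope reference scene."""
    fx = load_fixture("rnascope_reference", seed=5)
    out = run_pipeline(RunConfig(fixture="rnascope_reference", seed=5,
                                 estimate_spillover=False))
    out["fixture_obj"] = fx
    return out


import yaml  # noqa: E402


@pytest.fixture(scope="session")
def tiny_fixture_yaml(tmp_path_factory):
    """A fast full-pipeline fixture written to disk for CLI runs."""
    root = tmp_path_factory.mktemp("fix")
    cfg = {
        "panel": "gc_reactivity",
        "scene": {
            "field_size": [420, 420],
            "pixel_size": 0.5,
            "seed": 3,
            "n_follicles": 1,
            "follicle_axes_range": [80, 100],
            "follicle_axis_ratio": [0.75, 0.95],
            "gc_fraction": 0.45,
            "dz_fraction": 0.45,
            "cell_density": 8000,
            "nucleus_radius": [3.0, 0.35],
            "composition": {
                "LZ": {"B_lz": 0.83, "CD4T": 0.05, "Tfh": 0.04, "Other": 0.08},
                "DZ": {"B_dz": 0.83, "CD4T": 0.05, "Tfh": 0.04, "Other": 0.08},
                "MZ": {"B_mz": 0.76, "CD4T": 0.1, "Other": 0.14},
                "EF": {"B_ef": 0.06, "CD4T": 0.2, "Other": 0.74},
            },
            "phenotype_profiles": {
                "B_mz": {"CD20": [60, 0.25]},
                "B_lz": {"CD20": [220, 0.25], "Ki67": [40, 0.25]},
                "B_dz": {"CD20": [60, 0.25], "Ki67": [220, 0.25]},
                "B_ef": {"CD20": [220, 0.25]},
                "CD4T": {"CD4": [200, 0.25], "PD1": [18, 0.3]},
                "Tfh": {"CD4": [200, 0.25], "PD1": [220, 0.25]},
                "Other": {},
            },
        },
        "optics": {
            "psf_sigma": 0.4,
            "autofluorescence": 2.0,
            "noise": {"gaussian_sd": 1.5, "poisson_scale": 1.0},
        },
        "pipeline": {
            "segmentation": {"smooth_sigma": 0.4, "peak_min_distance": 1.5},
            "compartment": {"density_sigma": 6.0, "cd20_threshold": 0.12,
                            "gc_threshold": 0.085, "ki67_threshold": 0.5,
                            "gc_opening": 2.0, "min_follicle_area": 8000},
        },
    }
    path = root / "tiny.yaml"
    path.write_text(yaml.safe_dump(cfg))
    return path


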
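"""End-to-end pipeline: simulate/load -> compensate -> segment -> gate -> report.

Stages run in a fixed order; every stage's parameters come from the fixture's
``pipeline`` section with flag overrides on top, and all randomness fans out
from a single seed.  Artifacts are returned in memory and optionally written
(CSV tables, OME-TIFF images, YAML thresholds, JSON provenance).
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import compartment as comp
from . import gating, rnascope, segment, spectral, synthscene
from .errors import ConfigurationError
from .fixtures import Fixture, load_fixture

__all__ = ["RunConfig", "run_pipeline", "calibration_config", "estimate_panel_spillover"]

log = logging.getLogger("histocyte")

_DEFAULT_STAGES = {
    "compensate": True,
    "autofluorescence": False,
    "mip": True,
    "segment": True,
    "compartments": True,
    "gates": True,
    "quantify": True,
    "rnascope": True,
}


@dataclass
class RunConfig:
    """One pipeline run: a scene fixture, a seed, stage toggles, output dir."""

    fixture: str | Path
    seed: int | None = None
    outdir: str | Path | None = None
    stages: dict = field(default_factory=dict)
    estimate_spillover: bool = True
    spillover_matrix: object | None = None  # precomputed SpilloverMatrix
    overrides: dict = field(default_factory=dict)

    def stage_enabled(self, name: str) -> bool:
        return self.stages.get(name, _DEFAULT_STAGES[name])


def calibration_config(fixture: Fixture, seed: int) -> synthscene.SceneConfig:
    """A small featureless scene expressing every panel marker, used to
    render the single-stain series for spillover estimation."""
    optics = fixture.optics
    profile = {
        m: (220.0, 0.25)
        for m in optics.channels
        if m not in ("DNA", "vRNA")
    }
    vrna = None
    if "vRNA" in optics.channels:
        vrna = {
            "cell_assoc_rate": {"calib": {"EF": 0.6}},
            "punctum_radius": 0.5,
            "punctum_level": 350.0,
            "extra_puncta_mean": 2.0,
        }
    return synthscene.SceneConfig(
        field_size=(250.0, 250.0),
        pixel_size=fixture.scene.pixel_size,
        n_follicles=0,
        cell_density=6000.0,
        composition={"EF": {"calib": 1.0}},
        phenotype_profiles={"calib": profile},
        nucleus_radius=fixture.scene.nucleus_radius,
        vrna=vrna,
        seed=(seed * 7919 + 13) % (2**31),
    )


def estimate_panel_spillover(fixture: Fixture, seed: int) -> spectral.SpilloverMatrix:
    """Estimate the panel's spillover matrix from synthetic single stains."""
    calib = synthscene.build_scene(calibration_config(fixture, seed))
    stains = synthscene.render_single_stains(calib, fixture.optics)
    q = fixture.pipeline.get("spillover_quantile", 0.98)
    return spectral.estimate_spillover(stains, foreground_quantile=q)


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the enabled stages on one fixture and return all artifacts."""
    t0 = time.time()
    fixture = load_fixture(cfg.fixture, seed=cfg.seed)
    if cfg.overrides:
        fixture.pipeline = _merged(fixture.pipeline, cfg.overrides)
    panel = fixture.panel
    seed = fixture.scene.seed
    out: dict = {"fixture": fixture.name, "panel": panel.name, "seed": seed}

    log.info("simulate: building scene %s (seed %d)", fixture.name, seed)
    scene = synthscene.build_scene(fixture.scene)
    image = synthscene.render_scene(scene, fixture.optics)
    out["scene"] = scene
    out["image_raw"] = image

    if cfg.stage_enabled("compensate"):
        if cfg.spillover_matrix is not None:
            matrix = cfg.spillover_matrix
        elif cfg.estimate_spillover:
            matrix = estimate_panel_spillover(fixture, seed)
        else:
            matrix = fixture.optics.spillover
        image = spectral.compensate(image, matrix)
        out["spillover"] = matrix
    else:
        log.info("stage compensate: skipped")

    if cfg.stage_enabled("autofluorescence") and "AF" in image.channel_names:
        coeffs = fixture.pipeline.get("af_coefficients", {})
        image = spectral.subtract_autofluorescence(image, "AF", coeffs)
    elif not cfg.stage_enabled("autofluorescence"):
        log.info("stage autofluorescence: skipped")

    if image.is_stack:
        if cfg.stage_enabled("mip"):
            image = segment.project_mip(image)
        else:
            raise ConfigurationError("z-stack input requires the mip stage")
    out["image"] = image

    if not cfg.stage_enabled("segment"):
        log.info("stage segment: skipped; stopping here")
        return out
    seg_params = fixture.pipeline.get("segmentation", {})
    labels = segment.segment_nuclei(image, "DNA", **seg_params)
    feat_params = fixture.pipeline.get("features", {})
    cells = segment.extract_features(labels, image, **feat_params)
    cells.provenance.update({"fixture": fixture.name, "seed": seed,
                             "parameter_hash": _hash_params(fixture.pipeline)})
    out["labels"] = labels
    out["cells"] = cells

    cmap = None
    if cfg.stage_enabled("compartments"):
        cpar = dict(fixture.pipeline.get("compartment", {}))
        markers = panel.compartment.get("markers", {"cd20": "CD20", "ki67": "Ki67"})
        polarity = panel.compartment.get("polarity", "high")
        cmap = comp.build_compartment_map(image, markers, polarity=polarity, **cpar)
        tz_marker = panel.compartment.get("tzone_marker")
        if tz_marker and tz_marker in image.channel_names:
            cmap.tzone = comp.build_tzone_mask(image, cmap, tz_marker)
        cells = comp.assign_compartments(cells, cmap)
        out["compartments"] = cmap
        out["cells"] = cells
        areas = comp.quantify_areas(cmap, image, panel.structural_markers or None)
        out["areas"] = areas
    else:
        log.info("stage compartments: skipped")

    if cfg.stage_enabled("gates"):
        ts = gating.ThresholdSet()
        for ch, spec in panel.thresholds.items():
            kwargs = {k: v for k, v in spec.items() if k != "method"}
            gating.derive_thresholds(
                cells, ch, method=spec.get("method", "gmm"), seed=seed,
                into=ts, **kwargs,
            )
        cells = gating.apply_gates(cells, panel.tree, ts)
        out["thresholds"] = ts
        out["cells"] = cells
    else:
        log.info("stage gates: skipped")

    if cfg.stage_enabled("quantify") and cfg.stage_enabled("gates") and cmap is not None:
        area = out.get("areas", {}).get("total_tissue_area_um2")
        out["quant"] = gating.quantify(
            cells, panel.quantification, tree=panel.tree, total_tissue_area_um2=area
        )

    if cfg.stage_enabled("rnascope") and panel.rnascope and cmap is not None:
        rpar = panel.rnascope
        spar = fixture.pipeline.get("spots", {})
        spots = rnascope.detect_spots(image, rpar.get("vrna_channel", "vRNA"), **spar)
        fdc_mask = None
        if "FDC" in image.channel_names:
            fdc_mask = comp.marker_hi_mask(image, "FDC")
        spots = rnascope.classify_spots(spots, cells, labels, fdc_mask)
        out["spots"] = spots
        out["vrna"] = rnascope.report_vrna(
            spots, cells, cmap,
            t_gate=rpar.get("t_gate", "T"),
            cd4hi_gate=rpar.get("cd4hi_gate", "T_CD4hi"),
            cd4dim_gate=rpar.get("cd4dim_gate", "T_CD4dim"),
        )
    elif panel.rnascope:
        log.info("stage rnascope: skipped")

    out["runtime_s"] = time.time() - t0
    if cfg.outdir is not None:
        _write_outputs(Path(cfg.outdir), out, fixture)
    return out


def _merged(base: dict, over: dict) -> dict:
    out = dict(base)
    for k, v in over.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merged(out[k], v)
        else:
            out[k] = v
    return out


def _hash_params(params: dict) -> str:
    return hashlib.sha256(json.dumps(params, sort_keys=True, default=str).encode()).hexdigest()[:12]


def _write_outputs(outdir: Path, out: dict, fixture: Fixture) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    prov = {
        "fixture": out["fixture"],
        "panel": out["panel"],
        "seed": out["seed"],
        "parameter_hash": _hash_params(fixture.pipeline),
        "runtime_s": out.get("runtime_s"),
    }
    with open(outdir / "provenance.json", "w") as fh:
        json.dump(prov, fh, indent=1)
    if "image" in out:
        out["image"].write(outdir / "image.ome.tiff")
    if "scene" in out:
        out["scene"].write(outdir / "cells_truth.csv", outdir / "geometry.json")
    if "cells" in out:
        out["cells"].to_csv(outdir / "cells.csv")
    if "spillover" in out:
        out["spillover"].to_csv(outdir / "spillover.csv")
    if "thresholds" in out:
        out["thresholds"].to_yaml(outdir / "thresholds.yaml")
    if "compartments" in out:
        out["compartments"].write(
            outdir / "regions.tiff", outdir / "follicles.tiff", outdir / "regions.json"
        )
    if "quant" in out:
        out["quant"].to_csv(outdir / "quantification.csv", index=False)
    if "areas" in out:
        out["areas"]["per_follicle"].to_csv(outdir / "areas_per_follicle.csv", index=False)
        with open(outdir / "areas_field.json", "w") as fh:
            json.dump({"field": out["areas"]["field"],
                       "total_tissue_area_um2": out["areas"]["total_tissue_area_um2"]}, fh, indent=1)
    if "spots" in out:
        out["spots"].to_csv(outdir / "spots.csv")
    if "vrna" in out:
        out["vrna"]["table"].to_csv(outdir / "vrna_report.csv", index=False)
        with open(outdir / "vrna_fdc_counts.json", "w") as fh:
            json.dump(out["vrna"]["fdc_bound_per_follicle"], fh)
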
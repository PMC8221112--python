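"""Shipped panel and scene fixtures plus their YAML loaders.

A *panel* fixture defines a marker/fluorophore set, per-channel threshold
methods, a hierarchical gate tree transcribed from the staining panel's
published gating strategy, a quantification spec and the compartment-mapping
marker roles.  A *scene* fixture pairs a panel with a synthetic tissue
configuration (geometry, compositions, expression profiles) and an optical
model, and is the unit the pipeline and the recovery tests operate on.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import yaml

from .errors import ConfigurationError
from .gating import GateTree
from .spectral import SpilloverMatrix
from .synthscene import OpticsConfig, SceneConfig

__all__ = ["Panel", "Fixture", "load_panel", "load_fixture", "list_panels", "list_fixtures"]


@dataclass
class Panel:
    name: str
    channels: list[str]
    localization: dict[str, str]
    spillover: SpilloverMatrix
    thresholds: dict[str, dict]
    tree: GateTree
    quantification: list[dict] = field(default_factory=list)
    compartment: dict = field(default_factory=dict)
    structural_markers: dict = field(default_factory=dict)
    rnascope: dict = field(default_factory=dict)

    @classmethod
    def from_dict(cls, d: dict) -> "Panel":
        channels = [c["name"] for c in d["channels"]]
        localization = {c["name"]: c.get("localization", "surface") for c in d["channels"]}
        pairs = [tuple(p) for p in d.get("spillover_pairs", [])]
        spill = SpilloverMatrix.from_pairs(channels, pairs)
        tree = GateTree.from_config(d.get("gates", []))
        thresholds = d.get("thresholds", {})
        for ch in thresholds:
            if ch not in channels:
                raise ConfigurationError(
                    f"panel {d['name']!r}: threshold spec for unknown channel {ch!r}"
                )
        for node in tree.walk():
            for term, _level in node.terms:
                if term not in channels and term not in ("volume", "sphericity"):
                    raise ConfigurationError(
                        f"panel {d['name']!r}: gate {node.name!r} references "
                        f"unknown channel {term!r}"
                    )
        return cls(
            name=d["name"],
            channels=channels,
            localization=localization,
            spillover=spill,
            thresholds=thresholds,
            tree=tree,
            quantification=d.get("quantification", []),
            compartment=d.get("compartment", {}),
            structural_markers=d.get("structural_markers", {}),
            rnascope=d.get("rnascope", {}),
        )


@dataclass
class Fixture:
    name: str
    panel: Panel
    scene: SceneConfig
    optics: OpticsConfig
    pipeline: dict = field(default_factory=dict)


def _fixture_root() -> Path:
    return Path(resources.files("histocyte") / "fixtures")


def _resolve(name_or_path: str | Path, subdir: str | None = None) -> Path:
    p = Path(name_or_path)
    if p.suffix in (".yaml", ".yml") and p.exists():
        return p
    root = _fixture_root()
    if subdir:
        cand = root / subdir / f"{name_or_path}.yaml"
    else:
        cand = root / f"{name_or_path}.yaml"
    if cand.exists():
        return cand
    raise ConfigurationError(f"no fixture named {name_or_path!r} (looked at {cand})")


def list_panels() -> list[str]:
    return sorted(p.stem for p in (_fixture_root() / "panels").glob("*.yaml"))


def list_fixtures() -> list[str]:
    return sorted(p.stem for p in _fixture_root().glob("*.yaml"))


def load_panel(name_or_path: str | Path) -> Panel:
    path = _resolve(name_or_path, subdir="panels")
    with open(path) as fh:
        return Panel.from_dict(yaml.safe_load(fh))


def load_fixture(name_or_path: str | Path, *, seed: int | None = None) -> Fixture:
    """Load a scene fixture; ``seed`` overrides the scene config's seed."""
    path = _resolve(name_or_path)
    with open(path) as fh:
        d = yaml.safe_load(fh)
    panel = load_panel(d["panel"])
    scene_dict = dict(d.get("scene", {}))
    if seed is not None:
        scene_dict["seed"] = int(seed)
    scene = SceneConfig.from_dict(scene_dict)
    unknown = set(scene.markers()) - set(panel.channels)
    if unknown:
        raise ConfigurationError(
            f"fixture {path.stem!r}: markers {sorted(unknown)} not in panel "
            f"{panel.name!r} ({panel.channels})"
        )
    optics_dict = dict(d.get("optics", {}))
    optics = OpticsConfig(
        channels=list(panel.channels),
        localization=dict(panel.localization),
        spillover=panel.spillover,
        **optics_dict,
    )
    return Fixture(
        name=path.stem,
        panel=panel,
        scene=scene,
        optics=optics,
        pipeline=d.get("pipeline", {}),
    )
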
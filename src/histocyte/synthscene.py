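"""Ground-truthed synthetic lymphoid tissue scenes and their renders.

A scene emulates a tonsil / lymph-node section: elliptical B-cell follicles
embedded in extrafollicular (EF) space, each follicle split into a mantle
zone (MZ) ring and a germinal center (GC) whose light zone (LZ) and dark
zone (DZ) are sub-ellipses.  Cells are nucleated blobs placed by
Poisson-disk sampling; each cell carries a phenotype drawn from the
per-compartment composition and a true marker-expression vector drawn from
log-normal phenotype profiles.  Optional extras: an FDC dendritic meshwork
confined to GCs and vRNA puncta (cell-associated or FDC-bound).

Rendering produces a multichannel fluorescence image: per-marker blobs
(nuclear disk or surface rim), linear fluorophore spillover, constant
autofluorescence, Gaussian PSF blur and Poisson-Gaussian noise.  Everything
is deterministic given the scene seed.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .errors import ConfigurationError, PlacementError, SceneValidationError
from .image import MultichannelImage
from .spectral import SpilloverMatrix

__all__ = [
    "SceneConfig",
    "OpticsConfig",
    "SceneGroundTruth",
    "build_scene",
    "render_scene",
    "render_single_stains",
]

COMPARTMENTS = ("EF", "MZ", "LZ", "DZ")


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------
@dataclass
class SceneConfig:
    """Parameters of a synthetic tissue scene (units: µm, cells/mm²)."""

    field_size: tuple[float, float] = (600.0, 600.0)
    pixel_size: float = 0.5
    n_follicles: int = 3
    follicle_axes_range: tuple[float, float] = (70.0, 110.0)
    follicle_axis_ratio: tuple[float, float] = (0.70, 0.95)
    follicle_margin: float = 8.0  # µm clearance between/around follicles
    gc_fraction: float = 0.35
    dz_fraction: float = 0.45
    composition: dict[str, dict[str, float]] = field(default_factory=dict)
    cell_density: float | dict[str, float] = 8000.0
    phenotype_profiles: dict[str, dict[str, tuple[float, float]]] = field(default_factory=dict)
    nucleus_radius: tuple[float, float] = (3.0, 0.35)
    dna_level: tuple[float, float] = (160.0, 0.15)
    fdc_density: float = 0.0
    fdc_level: float = 220.0
    vrna: dict | None = None
    seed: int = 0

    def density(self, compartment: str) -> float:
        if isinstance(self.cell_density, dict):
            return float(self.cell_density[compartment])
        return float(self.cell_density)

    def markers(self) -> list[str]:
        seen: list[str] = []
        for prof in self.phenotype_profiles.values():
            for m in prof:
                if m not in seen:
                    seen.append(m)
        return seen

    def validate(self) -> None:
        if self.pixel_size <= 0 or min(self.field_size) <= 0:
            raise SceneValidationError("field size and pixel size must be positive")
        if self.nucleus_radius[0] <= 0:
            raise SceneValidationError("nucleus radius must be positive")
        for frac in (self.gc_fraction, self.dz_fraction, self.fdc_density):
            if not 0.0 <= frac <= 1.0:
                raise SceneValidationError("fractions must lie in [0, 1]")
        comps = set(self.composition)
        if self.n_follicles == 0:
            required = {"EF"}
        else:
            required = set(COMPARTMENTS)
        if not required <= comps:
            raise SceneValidationError(
                f"composition must cover compartments {sorted(required)}; got {sorted(comps)}"
            )
        for comp, mix in self.composition.items():
            total = sum(mix.values())
            if abs(total - 1.0) > 1e-9:
                raise SceneValidationError(
                    f"composition for {comp} sums to {total!r}, expected 1.0"
                )
            if any(f < 0 for f in mix.values()):
                raise SceneValidationError(f"negative phenotype fraction in {comp}")
            unknown = set(mix) - set(self.phenotype_profiles)
            if unknown:
                raise SceneValidationError(
                    f"composition for {comp} names phenotypes without profiles: {sorted(unknown)}"
                )
        for comp in comps:
            if self.density(comp) <= 0:
                raise SceneValidationError("cell densities must be positive")

    @classmethod
    def from_dict(cls, d: dict) -> "SceneConfig":
        d = dict(d)
        for key in ("field_size", "follicle_axes_range", "follicle_axis_ratio",
                    "nucleus_radius", "dna_level"):
            if key in d:
                d[key] = tuple(d[key])
        profiles = {}
        for pheno, prof in d.get("phenotype_profiles", {}).items():
            profiles[pheno] = {m: tuple(v) for m, v in prof.items()}
        d["phenotype_profiles"] = profiles
        cfg = cls(**d)
        cfg.validate()
        return cfg


@dataclass
class OpticsConfig:
    """Optical model: channel set, PSF, spillover, background and noise."""

    channels: list[str]
    localization: dict[str, str]  # marker -> "nuclear" | "surface"
    psf_sigma: float = 0.4  # µm
    spillover: SpilloverMatrix | None = None
    autofluorescence: dict[str, float] | float = 2.0
    noise: dict = field(default_factory=lambda: {"gaussian_sd": 1.5, "poisson_scale": 1.0})
    bit_depth: int = 16
    n_slices: int = 1
    z_step: float = 1.0
    # surface/cytoplasmic staining renders as a thin shell hugging the
    # nucleus boundary (projected membrane); a wide shell would overlap
    # neighbouring nuclei at physiological packing
    surface_rim: float = 0.6       # µm outside the nucleus radius
    surface_rim_inner: float = 0.85  # inner edge as a fraction of the radius

    def __post_init__(self) -> None:
        if self.psf_sigma <= 0:
            raise ConfigurationError("psf_sigma must be positive")
        if self.spillover is None:
            self.spillover = SpilloverMatrix.identity(self.channels)
        if list(self.spillover.channel_names) != list(self.channels):
            raise ConfigurationError("spillover channel order must match optics channels")
        af = self.autofluorescence
        if isinstance(af, (int, float)):
            self.autofluorescence = {c: float(af) for c in self.channels}
        if any(v < 0 for v in self.autofluorescence.values()):
            raise ConfigurationError("autofluorescence levels must be non-negative")

    def af_vector(self) -> np.ndarray:
        return np.array([self.autofluorescence.get(c, 0.0) for c in self.channels])


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------
@dataclass
class Ellipse:
    cy: float
    cx: float
    a: float  # semi-axis along theta
    b: float
    theta: float

    def contains(self, y: np.ndarray, x: np.ndarray) -> np.ndarray:
        dy = np.asarray(y) - self.cy
        dx = np.asarray(x) - self.cx
        c, s = math.cos(self.theta), math.sin(self.theta)
        u = (dx * c + dy * s) / self.a
        v = (-dx * s + dy * c) / self.b
        return u * u + v * v <= 1.0

    @property
    def area(self) -> float:
        return math.pi * self.a * self.b

    def to_dict(self) -> dict:
        return {"cy": self.cy, "cx": self.cx, "a": self.a, "b": self.b, "theta": self.theta}


@dataclass
class Follicle:
    id: int
    outer: Ellipse
    gc: Ellipse
    dz: Ellipse

    def to_dict(self) -> dict:
        return {
            "id": self.id,
            "outer": self.outer.to_dict(),
            "gc": self.gc.to_dict(),
            "dz": self.dz.to_dict(),
        }


@dataclass
class SceneGroundTruth:
    """Scene geometry plus the per-cell oracle table.

    ``cells`` columns: ``cell_id, y_um, x_um, nucleus_radius_um, phenotype,
    compartment, follicle_id, vrna_puncta`` and one ``expr_<marker>`` column
    per panel marker (true expression, spillover-free).
    """

    config: SceneConfig
    cells: pd.DataFrame
    follicles: list[Follicle]
    fdc_mask: np.ndarray | None = None
    cell_puncta: pd.DataFrame | None = None      # y_um, x_um, cell_id
    fdc_bound_puncta: pd.DataFrame | None = None  # y_um, x_um, follicle_id

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    def territory_map(self) -> np.ndarray:
        """Nearest-cell index per pixel (0-based into ``cells``; -1 if empty).

        Surface/cytoplasmic staining is confined to the expressing cell's
        territory: in packed tissue the membrane lies at the midline between
        adjacent nuclei, so one cell's rim never paints a neighbour's nucleus.
        Cached after the first call.
        """
        if getattr(self, "_territory", None) is None:
            h, w = self.grid_shape()
            if self.n_cells == 0:
                self._territory = np.full((h, w), -1, dtype=np.int32)
                return self._territory
            px = self.config.pixel_size
            seeds = np.full((h, w), -1, dtype=np.int32)
            iy = np.clip((self.cells["y_um"].to_numpy() / px - 0.5).round().astype(int), 0, h - 1)
            ix = np.clip((self.cells["x_um"].to_numpy() / px - 0.5).round().astype(int), 0, w - 1)
            seeds[iy, ix] = np.arange(self.n_cells)
            _, (ny, nx) = ndi.distance_transform_edt(seeds < 0, return_indices=True)
            self._territory = seeds[ny, nx]
        return self._territory

    def grid_shape(self) -> tuple[int, int]:
        h = int(round(self.config.field_size[0] / self.config.pixel_size))
        w = int(round(self.config.field_size[1] / self.config.pixel_size))
        return h, w

    def compartment_of(self, y: np.ndarray, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Ground-truth (region, follicle_id) for points in µm coordinates."""
        y = np.atleast_1d(np.asarray(y, dtype=float))
        x = np.atleast_1d(np.asarray(x, dtype=float))
        region = np.full(y.shape, "EF", dtype=object)
        fid = np.zeros(y.shape, dtype=int)
        for fol in self.follicles:
            inside = fol.outer.contains(y, x)
            in_gc = fol.gc.contains(y, x) & inside
            in_dz = fol.dz.contains(y, x) & in_gc
            region[inside] = "MZ"
            region[in_gc] = "LZ"
            region[in_dz] = "DZ"
            fid[inside] = fol.id
        return region.astype(str), fid

    # -- sidecar export ---------------------------------------------------
    def write(self, cells_csv, geometry_json) -> None:
        self.cells.to_csv(cells_csv, index=False)
        geom = {
            "field_size": list(self.config.field_size),
            "pixel_size": self.config.pixel_size,
            "seed": self.config.seed,
            "follicles": [f.to_dict() for f in self.follicles],
        }
        with open(geometry_json, "w") as fh:
            json.dump(geom, fh, indent=1)


# ---------------------------------------------------------------------------
# scene construction
# ---------------------------------------------------------------------------
def _place_follicles(cfg: SceneConfig, rng: np.random.Generator) -> list[Follicle]:
    """Jittered-grid placement: guaranteed non-overlap with at least
    ``follicle_margin`` µm clearance between follicles, deterministic, and
    free of the rejection-sampling failures of dense random packing."""
    h, w = cfg.field_size
    n = cfg.n_follicles
    margin = cfg.follicle_margin
    cols = max(1, int(math.ceil(math.sqrt(n * w / h))))
    rows = max(1, int(math.ceil(n / cols)))
    while rows * cols < n:
        cols += 1
    cell_h, cell_w = h / rows, w / cols
    cells = [(r, c) for r in range(rows) for c in range(cols)]
    order = rng.permutation(len(cells))[:n]

    follicles: list[Follicle] = []
    for i, ci in enumerate(order):
        r, c = cells[ci]
        placed = False
        for _ in range(200):
            a = rng.uniform(*cfg.follicle_axes_range)
            b = a * rng.uniform(*cfg.follicle_axis_ratio)
            theta = rng.uniform(0, math.pi)
            half = a + margin / 2.0
            if 2 * half > min(cell_h, cell_w):
                continue  # redraw smaller axes
            cy = rng.uniform(r * cell_h + half, (r + 1) * cell_h - half)
            cx = rng.uniform(c * cell_w + half, (c + 1) * cell_w - half)
            s = math.sqrt(cfg.gc_fraction)
            gc = Ellipse(cy, cx, a * s, b * s, theta)
            sd = math.sqrt(cfg.dz_fraction)
            # DZ: sub-ellipse of the GC offset toward one pole
            off = 0.75 * gc.a * (1 - sd)
            dz = Ellipse(
                cy + off * math.sin(theta),
                cx + off * math.cos(theta),
                gc.a * sd,
                gc.b * sd,
                theta,
            )
            follicles.append(
                Follicle(id=i + 1, outer=Ellipse(cy, cx, a, b, theta), gc=gc, dz=dz)
            )
            placed = True
            break
        if not placed:
            raise PlacementError(
                f"could not place follicle {i}: field {cfg.field_size} too small "
                f"for {cfg.n_follicles} follicles of semi-axis "
                f"{cfg.follicle_axes_range} µm with margin {margin} µm"
            )
    return follicles


def _poisson_disk(
    cfg: SceneConfig,
    follicles: list[Follicle],
    targets: dict[str, int],
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, list[str], np.ndarray]:
    """Dart-throwing with a uniform grid; fills per-compartment quotas."""
    h, w = cfg.field_size
    spacing = 0.8 * 2.0 * cfg.nucleus_radius[0]
    nx = max(1, int(w // spacing))
    ny = max(1, int(h // spacing))
    cell_of: dict[tuple[int, int], list[int]] = {}
    ys: list[float] = []
    xs: list[float] = []
    regions: list[str] = []
    fids: list[int] = []
    remaining = {k: v for k, v in targets.items() if v > 0}
    total = sum(remaining.values())
    max_attempts = 400 * max(total, 1)
    attempts = 0

    def classify(py: float, px: float) -> tuple[str, int]:
        for fol in follicles:
            if fol.outer.contains(py, px):
                if fol.gc.contains(py, px):
                    if fol.dz.contains(py, px):
                        return "DZ", fol.id
                    return "LZ", fol.id
                return "MZ", fol.id
        return "EF", 0

    while remaining and attempts < max_attempts:
        attempts += 1
        py = rng.uniform(0, h)
        px = rng.uniform(0, w)
        reg, fid = classify(py, px)
        if reg not in remaining:
            continue
        gy = min(int(py / h * ny), ny - 1)
        gx = min(int(px / w * nx), nx - 1)
        clash = False
        for dy in (-1, 0, 1):
            for dx in (-1, 0, 1):
                for j in cell_of.get((gy + dy, gx + dx), ()):
                    if (ys[j] - py) ** 2 + (xs[j] - px) ** 2 < spacing * spacing:
                        clash = True
                        break
                if clash:
                    break
            if clash:
                break
        if clash:
            continue
        idx = len(ys)
        ys.append(py)
        xs.append(px)
        regions.append(reg)
        fids.append(fid)
        cell_of.setdefault((gy, gx), []).append(idx)
        remaining[reg] -= 1
        if remaining[reg] == 0:
            del remaining[reg]
    if remaining:
        raise PlacementError(
            f"could not place requested cells; unfilled quotas {remaining} "
            f"(density too high for the Poisson-disk spacing?)"
        )
    return np.array(ys), np.array(xs), regions, np.array(fids)


def _lognormal(rng: np.random.Generator, mean: float, cv: float, size: int) -> np.ndarray:
    if mean <= 0:
        return np.zeros(size)
    if cv <= 0:
        return np.full(size, mean)
    sigma2 = math.log(1.0 + cv * cv)
    mu = math.log(mean) - sigma2 / 2.0
    return rng.lognormal(mu, math.sqrt(sigma2), size)


def _fdc_mesh(
    cfg: SceneConfig, follicles: list[Follicle], rng: np.random.Generator
) -> np.ndarray:
    """Random dendritic skeleton dilated to ~1 px, confined to each GC."""
    h_px = int(round(cfg.field_size[0] / cfg.pixel_size))
    w_px = int(round(cfg.field_size[1] / cfg.pixel_size))
    mask = np.zeros((h_px, w_px), dtype=bool)
    if cfg.fdc_density <= 0:
        return mask
    yy, xx = np.mgrid[0:h_px, 0:w_px]
    yum = (yy + 0.5) * cfg.pixel_size
    xum = (xx + 0.5) * cfg.pixel_size
    for fol in follicles:
        gc_px = fol.gc.contains(yum, xum)
        area = int(gc_px.sum())
        if area == 0:
            continue
        target = cfg.fdc_density * area
        sub = np.zeros_like(mask)
        guard = 0
        while sub.sum() < target and guard < 4000:
            guard += 1
            # start a walker at a random GC pixel
            cand = np.flatnonzero(gc_px)
            start = cand[rng.integers(len(cand))]
            py, px = np.unravel_index(start, gc_px.shape)
            ang = rng.uniform(0, 2 * math.pi)
            for _ in range(rng.integers(30, 90)):
                sub[int(py) % h_px, int(px) % w_px] = True
                ang += rng.normal(0, 0.5)
                py += math.sin(ang)
                px += math.cos(ang)
                if not (0 <= py < h_px and 0 <= px < w_px) or not gc_px[int(py), int(px)]:
                    break
        sub = ndi.binary_dilation(sub, iterations=1) & gc_px
        mask |= sub
    return mask


def build_scene(config: SceneConfig) -> SceneGroundTruth:
    """Construct a deterministic ground-truth scene from a validated config."""
    config.validate()
    ss = np.random.SeedSequence([int(config.seed) & 0x7FFFFFFF, 0xA11CE])
    s_geom, s_place, s_pheno, s_expr, s_fdc, s_vrna = [
        np.random.default_rng(c) for c in ss.spawn(6)
    ]

    follicles = _place_follicles(config, s_geom) if config.n_follicles else []

    # analytic compartment areas (µm²) -> per-compartment cell quotas
    h, w = config.field_size
    field_area = h * w
    fol_area = sum(f.outer.area for f in follicles)
    areas = {
        "EF": field_area - fol_area,
        "MZ": fol_area * (1 - config.gc_fraction),
        "LZ": fol_area * config.gc_fraction * (1 - config.dz_fraction),
        "DZ": fol_area * config.gc_fraction * config.dz_fraction,
    }
    targets = {
        comp: int(round(areas[comp] * 1e-6 * config.density(comp)))
        for comp in COMPARTMENTS
        if comp in config.composition and areas[comp] > 0
    }

    ys, xs, regions, fids = _poisson_disk(config, follicles, targets, s_place)
    n = len(ys)
    radii = np.clip(
        s_place.normal(config.nucleus_radius[0], config.nucleus_radius[1], n),
        0.5 * config.nucleus_radius[0],
        1.6 * config.nucleus_radius[0],
    )

    # phenotypes: multinomial draw per compartment
    phenotype = np.empty(n, dtype=object)
    regions_arr = np.array(regions)
    for comp, mix in config.composition.items():
        idx = np.flatnonzero(regions_arr == comp)
        if len(idx) == 0:
            continue
        names = list(mix.keys())
        probs = np.array([mix[k] for k in names], dtype=float)
        probs = probs / probs.sum()
        phenotype[idx] = s_pheno.choice(names, size=len(idx), p=probs)

    markers = config.markers()
    expr = {m: np.zeros(n) for m in markers}
    for pheno, prof in config.phenotype_profiles.items():
        idx = np.flatnonzero(phenotype == pheno)
        if len(idx) == 0:
            continue
        for m, (mean, cv) in prof.items():
            expr[m][idx] = _lognormal(s_expr, mean, cv, len(idx))
    dna = _lognormal(s_expr, config.dna_level[0], config.dna_level[1], n)

    cells = pd.DataFrame(
        {
            "cell_id": np.arange(1, n + 1),
            "y_um": ys,
            "x_um": xs,
            "nucleus_radius_um": radii,
            "phenotype": phenotype.astype(str),
            "compartment": regions_arr,
            "follicle_id": fids,
            "expr_DNA": dna,
        }
    )
    for m in markers:
        cells[f"expr_{m}"] = expr[m]

    fdc_mask = _fdc_mesh(config, follicles, s_fdc)

    # vRNA ground truth
    cells["vrna_puncta"] = 0
    cell_puncta = None
    fdc_puncta = None
    if config.vrna:
        vr = config.vrna
        rates = vr.get("cell_assoc_rate", {})
        py, px, pid = [], [], []
        for pheno, comp_rates in rates.items():
            for scope, rate in comp_rates.items():
                comps = ("MZ", "LZ", "DZ") if scope == "F" else (scope,)
                sel = np.flatnonzero(
                    (cells["phenotype"] == pheno)
                    & cells["compartment"].isin(comps).to_numpy()
                )
                if len(sel) == 0:
                    continue
                pos = sel[s_vrna.random(len(sel)) < rate]
                counts = 1 + s_vrna.poisson(vr.get("extra_puncta_mean", 1.5), len(pos))
                cells.loc[pos, "vrna_puncta"] = counts
                # puncta are discrete, resolvable dots: enforce a minimum
                # separation of ~2 punctum diameters within each cell's rim
                min_sep = 2.2 * vr.get("punctum_radius", 0.5)
                for i, cnt in zip(pos, counts):
                    r0 = radii[i] + 0.3
                    r1 = radii[i] + 1.6
                    placed: list[tuple[float, float]] = []
                    guard = 0
                    while len(placed) < cnt and guard < 40 * cnt:
                        guard += 1
                        ang = s_vrna.uniform(0, 2 * math.pi)
                        rad = math.sqrt(s_vrna.uniform(r0 * r0, r1 * r1))
                        cy = ys[i] + rad * math.sin(ang)
                        cx = xs[i] + rad * math.cos(ang)
                        if all((cy - q[0]) ** 2 + (cx - q[1]) ** 2 >= min_sep**2
                               for q in placed):
                            placed.append((cy, cx))
                    cells.loc[i, "vrna_puncta"] = len(placed)
                    py.extend(p[0] for p in placed)
                    px.extend(p[1] for p in placed)
                    pid.extend([int(cells.loc[i, "cell_id"])] * len(placed))
        cell_puncta = pd.DataFrame({"y_um": py, "x_um": px, "cell_id": pid})
        cell_puncta = cell_puncta[
            (cell_puncta.y_um > 0) & (cell_puncta.y_um < h)
            & (cell_puncta.x_um > 0) & (cell_puncta.x_um < w)
        ].reset_index(drop=True)

        counts_cfg = vr.get("fdc_bound_count", 0)
        fy, fx, ffid = [], [], []
        if counts_cfg and fdc_mask.any():
            from scipy.spatial import cKDTree

            tree = cKDTree(np.column_stack([ys, xs])) if n else None
            mesh_idx = np.flatnonzero(fdc_mask.ravel())
            my, mx = np.unravel_index(mesh_idx, fdc_mask.shape)
            myum = (my + 0.5) * config.pixel_size
            mxum = (mx + 0.5) * config.pixel_size
            _, mfid = None, None
            for k, fol in enumerate(follicles):
                want = (
                    counts_cfg[k % len(counts_cfg)]
                    if isinstance(counts_cfg, (list, tuple))
                    else int(counts_cfg)
                )
                in_gc = fol.gc.contains(myum, mxum)
                cand = np.flatnonzero(in_gc)
                if tree is not None and len(cand):
                    # keep mesh-bound virions clear of the cytoplasmic rim so
                    # they are unambiguously not cell-associated
                    d, _ = tree.query(np.column_stack([myum[cand], mxum[cand]]))
                    cand = cand[d > config.nucleus_radius[0] + 2.5]
                if len(cand) == 0:
                    continue
                # greedy thinning keeps FDC-bound virions mutually resolvable
                min_sep = 2.2 * vr.get("punctum_radius", 0.5)
                order = s_vrna.permutation(cand)
                chosen: list[int] = []
                for c in order:
                    if len(chosen) >= want:
                        break
                    if all((myum[c] - myum[k]) ** 2 + (mxum[c] - mxum[k]) ** 2
                           >= min_sep**2 for k in chosen):
                        chosen.append(c)
                fy.extend(myum[chosen])
                fx.extend(mxum[chosen])
                ffid.extend([fol.id] * len(chosen))
        fdc_puncta = pd.DataFrame({"y_um": fy, "x_um": fx, "follicle_id": ffid})

    return SceneGroundTruth(
        config=config,
        cells=cells,
        follicles=follicles,
        fdc_mask=fdc_mask,
        cell_puncta=cell_puncta,
        fdc_bound_puncta=fdc_puncta,
    )


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------
def _add_disk(img: np.ndarray, cy: float, cx: float, radius: float, amp: float,
              pixel_size: float, inner: float = 0.0,
              territory: np.ndarray | None = None, owner: int = -1) -> None:
    """Accumulate a soft-edged disk (or ring when inner > 0) in place.

    With ``territory``/``owner`` the blob is clipped to the owner cell's
    territory pixels (membrane-at-midline rendering for surface markers).
    """
    if amp <= 0:
        return
    r_px = radius / pixel_size
    cy_px = cy / pixel_size - 0.5
    cx_px = cx / pixel_size - 0.5
    lo_y = max(int(cy_px - r_px - 2), 0)
    hi_y = min(int(cy_px + r_px + 3), img.shape[0])
    lo_x = max(int(cx_px - r_px - 2), 0)
    hi_x = min(int(cx_px + r_px + 3), img.shape[1])
    if lo_y >= hi_y or lo_x >= hi_x:
        return
    yy = np.arange(lo_y, hi_y)[:, None] - cy_px
    xx = np.arange(lo_x, hi_x)[None, :] - cx_px
    d = np.sqrt(yy * yy + xx * xx)
    w = np.clip(r_px - d + 0.5, 0.0, 1.0)
    if inner > 0:
        w_in = np.clip(inner / pixel_size - d + 0.5, 0.0, 1.0)
        w = np.clip(w - w_in, 0.0, 1.0)
    if territory is not None:
        w = w * (territory[lo_y:hi_y, lo_x:hi_x] == owner)
    img[lo_y:hi_y, lo_x:hi_x] += (amp * w).astype(img.dtype)


def _render_true(scene: SceneGroundTruth, optics: OpticsConfig,
                 only_marker: str | None = None) -> np.ndarray:
    """Spillover-free, noise-free, unblurred per-fluorophore signal."""
    cfg = scene.config
    h_px, w_px = scene.grid_shape()
    channels = optics.channels
    scene_markers = set(cfg.markers()) | {"DNA"}
    for m in scene_markers:
        if m not in channels and m != "DNA":
            raise ConfigurationError(
                f"scene marker {m!r} missing from optics channels {channels}"
            )
    true = np.zeros((len(channels), h_px, w_px), dtype=np.float32)
    cells = scene.cells
    ys = cells["y_um"].to_numpy()
    xs = cells["x_um"].to_numpy()
    radii = cells["nucleus_radius_um"].to_numpy()
    for ci, ch in enumerate(channels):
        if only_marker is not None and ch != only_marker:
            continue
        if ch == "DNA":
            amps = cells["expr_DNA"].to_numpy()
            for i in range(len(cells)):
                _add_disk(true[ci], ys[i], xs[i], radii[i], amps[i], cfg.pixel_size)
            continue
        if ch == "FDC" and scene.fdc_mask is not None and scene.fdc_mask.any():
            true[ci] += cfg.fdc_level * scene.fdc_mask
        if ch == "vRNA":
            pr = (cfg.vrna or {}).get("punctum_radius", 0.5)
            lvl = (cfg.vrna or {}).get("punctum_level", 300.0)
            for tab in (scene.cell_puncta, scene.fdc_bound_puncta):
                if tab is None:
                    continue
                for y, x in zip(tab["y_um"], tab["x_um"]):
                    _add_disk(true[ci], y, x, pr, lvl, cfg.pixel_size)
            continue
        col = f"expr_{ch}"
        if col not in cells.columns:
            continue
        amps = cells[col].to_numpy()
        loc = optics.localization.get(ch, "surface")
        hit = np.flatnonzero(amps > 0)
        terr = scene.territory_map() if (len(hit) and loc != "nuclear") else None
        for i in hit:
            if loc == "nuclear":
                _add_disk(true[ci], ys[i], xs[i], radii[i], amps[i], cfg.pixel_size)
            else:
                _add_disk(
                    true[ci], ys[i], xs[i], radii[i] + optics.surface_rim, amps[i],
                    cfg.pixel_size, inner=optics.surface_rim_inner * radii[i],
                    territory=terr, owner=i,
                )
    return true


def _apply_optics(true: np.ndarray, optics: OpticsConfig, pixel_size: float,
                  rng: np.random.Generator, *, mix: bool = True) -> np.ndarray:
    m = optics.spillover.values
    flat = true.reshape(true.shape[0], -1).astype(np.float64)
    obs = (m.T @ flat) if mix else flat
    obs = obs + optics.af_vector()[:, None]
    obs = obs.reshape(true.shape)
    sigma_px = optics.psf_sigma / pixel_size
    if sigma_px > 0:
        obs = np.stack([ndi.gaussian_filter(p, sigma_px) for p in obs])
    gauss_sd = float(optics.noise.get("gaussian_sd", 0.0))
    pscale = float(optics.noise.get("poisson_scale", 0.0))
    if pscale > 0:
        obs = rng.poisson(np.clip(obs, 0, None) * pscale) / pscale
    if gauss_sd > 0:
        obs = obs + rng.normal(0.0, gauss_sd, obs.shape)
    top = float(2 ** optics.bit_depth - 1)
    return np.clip(obs, 0.0, top).astype(np.float32)


def _stackify(plane_img: np.ndarray, optics: OpticsConfig) -> np.ndarray:
    """Spread a 2D render across a thin z-stack with triangular z-weights."""
    z = optics.n_slices
    centers = np.arange(z)
    peak = (z - 1) / 2.0
    wz = 1.0 - np.abs(centers - peak) / (peak + 1.0)
    return np.stack([plane_img * w for w in wz], axis=1)


def render_scene(
    scene: SceneGroundTruth,
    optics: OpticsConfig,
    *,
    mix: bool = True,
    noise_tag: int = 1,
) -> MultichannelImage:
    """Render the full-panel multichannel image of a scene.

    ``mix=False`` renders with identity spillover (useful as the oracle for
    compensation round-trip tests); everything else in the optical model is
    applied identically.
    """
    cfg = scene.config
    true = _render_true(scene, optics)
    if optics.n_slices > 1:
        true = _stackify(true, optics)
        rng = np.random.default_rng(
            np.random.SeedSequence([cfg.seed & 0x7FFFFFFF, 0xBEE, noise_tag])
        )
        planes = []
        for zi in range(optics.n_slices):
            planes.append(_apply_optics(true[:, zi], optics, cfg.pixel_size, rng, mix=mix))
        data = np.stack(planes, axis=1)
        return MultichannelImage(data, list(optics.channels), cfg.pixel_size,
                                 z_step=optics.z_step, metadata={"seed": cfg.seed})
    rng = np.random.default_rng(
        np.random.SeedSequence([cfg.seed & 0x7FFFFFFF, 0xBEE, noise_tag])
    )
    data = _apply_optics(true, optics, cfg.pixel_size, rng, mix=mix)
    return MultichannelImage(data, list(optics.channels), cfg.pixel_size,
                             metadata={"seed": cfg.seed})


def render_single_stains(
    scene: SceneGroundTruth, optics: OpticsConfig
) -> dict[str, MultichannelImage]:
    """Render one full multichannel image per fluorophore, with only that
    fluorophore's marker expressed — same optics (spillover, background,
    noise) as the full panel."""
    out: dict[str, MultichannelImage] = {}
    cfg = scene.config
    for tag, ch in enumerate(optics.channels):
        true = _render_true(scene, optics, only_marker=ch)
        rng = np.random.default_rng(
            np.random.SeedSequence([cfg.seed & 0x7FFFFFFF, 0x51A1, tag])
        )
        data = _apply_optics(true, optics, cfg.pixel_size, rng)
        out[ch] = MultichannelImage(data, list(optics.channels), cfg.pixel_size,
                                    metadata={"single_stain": ch})
    return out
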
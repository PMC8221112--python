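"""Microanatomical compartment mapping and structural area quantification.

Compartments are derived from marker staining, not geometry: B-cell
follicles are connected regions of high smoothed CD20 density; inside each
follicle the Ki67-dense region is the germinal center (GC), its densest
connected sub-region the dark zone (DZ), the remainder of the GC the light
zone (LZ) and the remainder of the follicle the mantle zone (MZ).  All
other tissue is extrafollicular (EF).  An optional T-cell zone (CD4-dense
EF) supports regulatory T-cell denominators.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import tifffile
from scipy import ndimage as ndi

from .errors import ConfigurationError, DataError
from .image import MultichannelImage
from .segment import CellTable

__all__ = [
    "CompartmentMap",
    "REGION_CODES",
    "build_compartment_map",
    "marker_hi_mask",
    "build_tzone_mask",
    "assign_compartments",
    "quantify_areas",
]

#: region codes used in the label image
REGION_CODES = {"EF": 0, "MZ": 1, "LZ": 2, "DZ": 3}
REGION_NAMES = {v: k for k, v in REGION_CODES.items()}


@dataclass
class CompartmentMap:
    """Pixelwise region codes (EF/MZ/LZ/DZ) and follicle instance ids."""

    region: np.ndarray        # uint8 codes per REGION_CODES
    follicle_ids: np.ndarray  # 0 = extrafollicular, k > 0 = follicle instance
    pixel_size: float
    tzone: np.ndarray | None = None  # boolean CD4-dense EF mask

    def __post_init__(self) -> None:
        if self.region.shape != self.follicle_ids.shape:
            raise DataError("region and follicle id images must share a shape")
        # invariants: follicular pixels carry a follicle id, EF pixels none
        fol = self.region > 0
        if (self.follicle_ids[fol] == 0).any() or (self.follicle_ids[~fol] != 0).any():
            raise DataError("region/follicle-id images are inconsistent")

    @property
    def n_follicles(self) -> int:
        return int(self.follicle_ids.max())

    def mask(self, scope: str, follicle_id: int | None = None) -> np.ndarray:
        """Boolean mask for a named scope (EF/MZ/LZ/DZ/GC/F/TZ/all)."""
        r = self.region
        if scope == "all":
            m = np.ones_like(r, dtype=bool)
        elif scope in REGION_CODES:
            m = r == REGION_CODES[scope]
        elif scope == "GC":
            m = (r == REGION_CODES["LZ"]) | (r == REGION_CODES["DZ"])
        elif scope == "F":
            m = r > 0
        elif scope == "TZ":
            if self.tzone is None:
                raise ConfigurationError("no T-cell-zone mask on this map")
            m = self.tzone
        else:
            raise ConfigurationError(f"unknown scope {scope!r}")
        if follicle_id is not None:
            m = m & (self.follicle_ids == follicle_id)
        return m

    def write(self, region_path, follicle_path, legend_path) -> None:
        tifffile.imwrite(region_path, self.region.astype(np.uint8))
        tifffile.imwrite(follicle_path, self.follicle_ids.astype(np.uint16))
        with open(legend_path, "w") as fh:
            json.dump({"region_codes": REGION_CODES, "pixel_size": self.pixel_size}, fh)


def _density(plane: np.ndarray, sigma_px: float) -> np.ndarray:
    return ndi.gaussian_filter(np.asarray(plane, dtype=np.float64), sigma_px)


def build_compartment_map(
    image: MultichannelImage,
    markers: dict[str, str] | None = None,
    *,
    density_sigma: float = 6.0,
    cd20_threshold: float = 0.40,
    gc_threshold: float = 0.085,
    ki67_threshold: float = 0.5,
    min_follicle_area: float = 8000.0,
    gc_opening: float = 2.0,
    gc_closing: float = 6.0,
    gc_sigma: float = 6.0,
    mask_smooth: float = 3.0,
    occupancy_pixel_cut: float = 0.035,
    polarity: str = "high",
) -> CompartmentMap:
    """Derive EF / follicle / MZ / LZ / DZ from CD20 and Ki67 staining.

    Follicles are detected on the *B-cell occupancy* field: CD20-positive
    pixels (above ``occupancy_pixel_cut`` x the image's bright level) are
    binarized and smoothed at ``density_sigma`` µm, giving the local areal
    fraction of B-cell staining — a measure that weighs CD20^dim mantle and
    CD20^hi light-zone B cells equally.  Pixels above ``cd20_threshold`` of
    the occupancy plateau (97th percentile) form follicle candidates; the
    mask is majority-smoothed at ``mask_smooth`` µm, filled, and components
    under ``min_follicle_area`` µm² are dropped.

    Within each follicle the GC is the smoothed-Ki67-dense region above
    ``gc_threshold`` of the follicle's Ki67 amplitude (morphologically opened
    at ``gc_opening`` µm), and the DZ is its largest connected sub-region
    above ``ki67_threshold`` — the intensity scale matters here because the
    LZ is Ki67^lo and the DZ Ki67^hi.

    ``polarity="low"`` detects follicles as occupancy *minima* of the
    follicle marker (used when follicles are the T-cell-marker-poor islands
    of an RNAscope panel); ``markers`` may omit ``ki67``, in which case
    follicles are not subdivided (all follicular pixels labeled MZ).
    """
    markers = markers or {"cd20": "CD20", "ki67": "Ki67"}
    name = markers.get("cd20")
    if name is None or name not in image.channel_names:
        raise ConfigurationError("compartment mapping needs a 'cd20' channel")
    ki67_name = markers.get("ki67")
    if ki67_name is not None and ki67_name not in image.channel_names:
        raise ConfigurationError(f"ki67 channel {ki67_name!r} not in image")
    if polarity not in ("high", "low"):
        raise ConfigurationError(f"unknown polarity {polarity!r}")
    if image.is_stack:
        raise DataError("build_compartment_map expects a 2D image")
    px = image.pixel_size
    ki67 = (_density(image.channel(ki67_name), gc_sigma / px)
            if ki67_name else None)

    region = np.zeros(image.shape_yx, dtype=np.uint8)
    fids = np.zeros(image.shape_yx, dtype=np.int32)

    marker_plane = _density(image.channel(markers["cd20"]), 1.0 / px)
    bright = np.quantile(marker_plane, 0.999)
    if bright <= 0:
        warnings.warn("flat follicle-marker channel; no follicles (all EF)")
        return CompartmentMap(region, fids, px)
    occupancy = ndi.gaussian_filter(
        (marker_plane > occupancy_pixel_cut * bright).astype(np.float32),
        density_sigma / px,
    )
    plateau = np.quantile(occupancy, 0.97)
    if plateau <= 0:
        warnings.warn("no follicle-marker occupancy; no follicles (all EF)")
        return CompartmentMap(region, fids, px)
    if polarity == "low":
        fol_mask = occupancy < cd20_threshold * plateau
    else:
        fol_mask = occupancy > cd20_threshold * plateau
    open_px = max(1, int(round(gc_opening / px)))
    if mask_smooth > 0:
        # majority vote over a mask_smooth-µm neighbourhood irons out
        # boundary wiggle from cell-scale density fluctuations
        fol_mask = ndi.gaussian_filter(fol_mask.astype(np.float32),
                                       mask_smooth / px) > 0.5
    fol_mask = ndi.binary_fill_holes(fol_mask)
    lab, n = ndi.label(fol_mask)
    if n == 0:
        warnings.warn("no follicles found (all EF)")
        return CompartmentMap(region, fids, px)
    sizes = ndi.sum_labels(np.ones_like(lab), lab, index=np.arange(1, n + 1))
    keep = np.flatnonzero(sizes * px * px >= min_follicle_area) + 1
    next_id = 0
    for old in keep:
        next_id += 1
        fmask = lab == old
        fids[fmask] = next_id
        region[fmask] = REGION_CODES["MZ"]
        if ki67 is None:
            continue
        k_bg = np.quantile(ki67[fmask], 0.05)
        k_amp = np.quantile(ki67[fmask], 0.995) - k_bg
        if k_amp <= 0:
            continue
        gc = fmask & (ki67 > k_bg + gc_threshold * k_amp)
        gc = ndi.binary_opening(gc, structure=_disk(open_px))
        if gc_closing > 0:
            # reclaim Ki67-poor bays inside the GC (pockets of non-B cells
            # dent the proliferation-density mask but belong to the GC);
            # EDT-based closing is much faster than a large structuring
            # element at identical result
            close_px = gc_closing / px
            dilated = ndi.distance_transform_edt(~gc) <= close_px
            gc = ndi.distance_transform_edt(dilated) > close_px
        gc = ndi.binary_fill_holes(gc) & fmask
        if not gc.any():
            continue
        # one GC per follicle: keep the largest connected candidate
        gl, gn = ndi.label(gc)
        if gn > 1:
            gsizes = ndi.sum_labels(np.ones_like(gl), gl, index=np.arange(1, gn + 1))
            gc = gl == (int(np.argmax(gsizes)) + 1)
        region[gc] = REGION_CODES["LZ"]
        dz = gc & (ki67 > k_bg + ki67_threshold * k_amp)
        if dz.any():
            dl, dn = ndi.label(dz)
            dsizes = ndi.sum_labels(np.ones_like(dl), dl, index=np.arange(1, dn + 1))
            dz = dl == (int(np.argmax(dsizes)) + 1)
            region[dz] = REGION_CODES["DZ"]
    if next_id == 0:
        warnings.warn("no follicles above the minimum area (all EF)")
        region[:] = 0
        fids[:] = 0
    return CompartmentMap(region, fids, px)


def _disk(r: int) -> np.ndarray:
    yy, xx = np.mgrid[-r:r + 1, -r:r + 1]
    return yy * yy + xx * xx <= r * r


def marker_hi_mask(
    image: MultichannelImage,
    channel: str,
    *,
    density_sigma: float = 1.0,
    threshold: float | None = None,
) -> np.ndarray:
    """Pixels with high signal for one structural marker (e.g. the FDC mesh).

    Default cutoff: half the 99.9th-percentile smoothed intensity — robust
    for sparse structures (a dendritic mesh covers well under 1% of a field).
    """
    if channel not in image.channel_names:
        raise ConfigurationError(f"no {channel!r} channel in image")
    sm = _density(image.channel(channel), density_sigma / image.pixel_size)
    if threshold is None:
        threshold = 0.5 * float(np.quantile(sm, 0.999))
    return sm > max(threshold, 1e-9)


def build_tzone_mask(
    image: MultichannelImage,
    cmap: CompartmentMap,
    cd4_channel: str = "CD4",
    *,
    density_sigma: float = 8.0,
    threshold: float = 0.3,
) -> np.ndarray:
    """CD4-dense extrafollicular pixels (the paracortical T-cell zone)."""
    if cd4_channel not in image.channel_names:
        raise ConfigurationError(f"no {cd4_channel!r} channel for T-zone mapping")
    cd4 = _density(image.channel(cd4_channel), density_sigma / image.pixel_size)
    ef = cmap.region == REGION_CODES["EF"]
    if not ef.any():
        return np.zeros_like(ef)
    bg = np.quantile(cd4[ef], 0.1)
    amp = np.quantile(cd4[ef], 0.99) - bg
    if amp <= 0:
        return np.zeros_like(ef)
    return ef & (cd4 > bg + threshold * amp)


def assign_compartments(cells: CellTable, cmap: CompartmentMap) -> CellTable:
    """Annotate each cell with the region / follicle at its centroid pixel."""
    df = cells.df.copy()
    if len(df) == 0:
        for col, val in (("region", pd.Series(dtype=str)),
                         ("follicle_id", pd.Series(dtype=int)),
                         ("tzone", pd.Series(dtype=bool))):
            df[col] = val
        return CellTable(df, dict(cells.provenance))
    px = cmap.pixel_size
    h, w = cmap.region.shape
    iy = np.clip((df["y_um"].to_numpy() / px - 0.5).round().astype(int), 0, h - 1)
    ix = np.clip((df["x_um"].to_numpy() / px - 0.5).round().astype(int), 0, w - 1)
    codes = cmap.region[iy, ix]
    df["region"] = np.vectorize(REGION_NAMES.get)(codes)
    df["follicle_id"] = cmap.follicle_ids[iy, ix]
    df["tzone"] = cmap.tzone[iy, ix] if cmap.tzone is not None else False
    return CellTable(df, dict(cells.provenance))


def quantify_areas(
    cmap: CompartmentMap,
    image: MultichannelImage,
    structural_markers: dict[str, str] | None = None,
    *,
    thresholds: dict[str, float] | None = None,
    density_sigma: float = 2.0,
    tissue_sigma: float = 10.0,
) -> dict:
    """Structural area report (µm²) per follicle and per field.

    Per follicle: follicle, MZ, GC areas and FDC^hi ∩ follicle area.  Per
    field: Collagen^hi and CD31^hi ∩ Collagen^hi areas stratified by EF/F/GC
    scope, and the total tissue area (nuclear-density support).  Marker keys
    (``fdc``, ``collagen``, ``cd31``, ``igd``) map to channel names; any may
    be omitted.  ``thresholds`` gives absolute cutoffs per marker key; by
    default a cutoff at half the 99th-percentile smoothed intensity is used.
    """
    structural_markers = structural_markers or {}
    thresholds = thresholds or {}
    px = cmap.pixel_size
    px2 = px * px
    known = {"fdc", "collagen", "cd31", "igd"}
    unknown = set(structural_markers) - known
    if unknown:
        raise ConfigurationError(f"unknown structural marker keys {sorted(unknown)}")

    hi_masks: dict[str, np.ndarray] = {}
    for key, ch in structural_markers.items():
        if ch not in image.channel_names:
            raise ConfigurationError(f"structural channel {ch!r} not in image")
        sm = _density(image.channel(ch), density_sigma / px)
        cut = thresholds.get(key)
        if cut is None:
            # half the bright level; p99.9 so sparse structures (mesh,
            # vessels) keep a meaningful cut
            cut = 0.5 * np.quantile(sm, 0.999)
        hi_masks[key] = sm > max(cut, 1e-9)
        if not np.any(sm > 0):
            hi_masks[key] = np.zeros_like(sm, dtype=bool)

    # tissue support from nuclear staining density
    if "DNA" in image.channel_names:
        dna = _density(image.channel("DNA"), tissue_sigma / px)
        tcut = thresholds.get("tissue", 0.1 * np.quantile(dna, 0.99))
        tissue = dna > tcut
    else:
        tissue = np.ones_like(cmap.region, dtype=bool)
    total_tissue_area = float(tissue.sum() * px2)

    per_follicle = []
    for fid in range(1, cmap.n_follicles + 1):
        fol = cmap.follicle_ids == fid
        mz = fol & (cmap.region == REGION_CODES["MZ"])
        gc = fol & ((cmap.region == REGION_CODES["LZ"]) | (cmap.region == REGION_CODES["DZ"]))
        row = {
            "follicle_id": fid,
            "follicle_um2": float(fol.sum() * px2),
            "mz_um2": float(mz.sum() * px2),
            "gc_um2": float(gc.sum() * px2),
        }
        if "fdc" in hi_masks:
            row["fdc_hi_um2"] = float((hi_masks["fdc"] & fol).sum() * px2)
        per_follicle.append(row)

    field_rows = {}
    for scope in ("EF", "F", "GC"):
        smask = cmap.mask(scope)
        entry = {}
        if "collagen" in hi_masks:
            entry["collagen_hi_um2"] = float((hi_masks["collagen"] & smask).sum() * px2)
            if "cd31" in hi_masks:
                vess = hi_masks["cd31"] & hi_masks["collagen"]
                entry["cd31_collagen_hi_um2"] = float((vess & smask).sum() * px2)
        field_rows[scope] = entry

    return {
        "per_follicle": pd.DataFrame(per_follicle),
        "field": field_rows,
        "total_tissue_area_um2": total_tissue_area,
    }
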
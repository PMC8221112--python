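"""Nuclear segmentation and per-cell feature extraction.

Cells are segmented from the nuclear-stain channel of a (projected) 2D
image: Gaussian smoothing, global threshold, hole filling, optional
distance-transform watershed to split touching nuclei, and an area filter.
Each labeled cell yields one record with mean channel intensities, centroid
(µm), area and circularity — the event table that downstream gating treats
exactly like cytometry data.  The area and circularity columns are exported
under the names ``volume`` and ``sphericity`` to mirror the vocabulary of
the cytometry-style spreadsheets this table feeds into.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.feature import peak_local_max
from skimage.filters import threshold_otsu
from skimage.measure import regionprops_table
from skimage.segmentation import find_boundaries, watershed

from .errors import DataError
from .image import MultichannelImage

__all__ = ["LabelMap", "CellTable", "project_mip", "segment_nuclei", "extract_features"]


@dataclass
class LabelMap:
    """Integer label image: 0 = background, k > 0 = cell k (contiguous)."""

    labels: np.ndarray
    pixel_size: float

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise DataError("label map must be 2D")

    @property
    def n_labels(self) -> int:
        return int(self.labels.max())


@dataclass
class CellTable:
    """Per-cell feature records plus provenance.

    ``df`` columns: ``cell_id, x_um, y_um, volume_um2, sphericity``, one
    ``mean_<channel>`` per channel, and (after compartment assignment /
    gating) ``region, follicle_id, tzone`` and ``gate_<node>`` booleans.
    """

    df: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def channels(self) -> list[str]:
        return [c[len("mean_"):] for c in self.df.columns if c.startswith("mean_")]

    def mean(self, channel: str) -> np.ndarray:
        return self.df[f"mean_{channel}"].to_numpy()

    def to_csv(self, path) -> None:
        self.df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, provenance: dict | None = None) -> "CellTable":
        return cls(pd.read_csv(path), provenance or {})


def project_mip(image: MultichannelImage) -> MultichannelImage:
    """Maximum-intensity projection of a z-stack onto a single plane."""
    if not image.is_stack:
        warnings.warn("project_mip called on a 2D image; returning it unchanged")
        return image
    data = image.data.max(axis=1)
    out = MultichannelImage(
        data, list(image.channel_names), image.pixel_size,
        metadata={**image.metadata, "projected": "mip"},
    )
    return out


def segment_nuclei(
    image: MultichannelImage,
    nuclear_channel: str = "DNA",
    *,
    smooth_sigma: float = 0.4,
    threshold: str | float = "otsu",
    min_area: float | None = None,
    max_area: float | None = None,
    split: bool = True,
    peak_min_distance: float = 1.5,
) -> LabelMap:
    """Segment nuclei from the nuclear-stain channel of a 2D image.

    Parameters are in physical units: ``smooth_sigma`` (µm), areas (µm²) and
    ``peak_min_distance`` (µm, minimum separation of watershed seeds).
    ``min_area`` defaults to the area of a 2 µm-radius circle (debris);
    ``max_area`` defaults to 4x the median component area (merged clumps).
    """
    if image.is_stack:
        image = project_mip(image)
    plane = np.asarray(image.channel(nuclear_channel), dtype=np.float64)
    if not np.all(np.isfinite(plane)):
        raise DataError("nuclear channel contains non-finite pixels")
    px = image.pixel_size
    smoothed = ndi.gaussian_filter(plane, smooth_sigma / px)
    if threshold == "otsu":
        if np.ptp(smoothed) == 0:
            warnings.warn("blank nuclear channel; empty segmentation")
            return LabelMap(np.zeros(plane.shape, dtype=np.int32), px)
        cut = threshold_otsu(smoothed)
    else:
        cut = float(threshold)
    fg = smoothed > cut
    fg = ndi.binary_fill_holes(fg)
    if not fg.any():
        warnings.warn("empty nuclear foreground; empty segmentation")
        return LabelMap(np.zeros(plane.shape, dtype=np.int32), px)

    if split:
        dist = ndi.distance_transform_edt(fg, sampling=px)
        peaks = peak_local_max(
            dist,
            min_distance=max(1, int(round(peak_min_distance / px))),
            labels=fg,
            exclude_border=False,
        )
        markers = np.zeros(plane.shape, dtype=np.int32)
        markers[tuple(peaks.T)] = np.arange(1, len(peaks) + 1)
        labels = watershed(-dist, markers, mask=fg)
    else:
        labels, _ = ndi.label(fg)

    # area filter in µm²
    if min_area is None:
        min_area = np.pi * 2.0 ** 2
    sizes = np.bincount(labels.ravel())
    sizes_um2 = sizes * px * px
    if max_area is None:
        valid = sizes_um2[1:][sizes_um2[1:] > 0]
        max_area = 4.0 * float(np.median(valid)) if len(valid) else np.inf
    keep = (sizes_um2 >= min_area) & (sizes_um2 <= max_area)
    keep[0] = False
    mapping = np.zeros(len(sizes), dtype=np.int32)
    mapping[keep] = np.arange(1, int(keep.sum()) + 1)
    return LabelMap(mapping[labels], px)


def _eroded_labels(labels: np.ndarray, erosion_px: float) -> np.ndarray:
    """Shrink every label by ~erosion_px, respecting watershed boundaries."""
    fg = labels > 0
    interior = fg & ~find_boundaries(labels, mode="thick")
    dist = ndi.distance_transform_edt(interior)
    return np.where(dist >= erosion_px, labels, 0)


def extract_features(
    labels: LabelMap,
    image: MultichannelImage,
    *,
    intensity_erosion: float = 0.0,
) -> CellTable:
    """Build the per-cell event table from a label map and an image.

    Mean intensities are computed over each label's member pixels (optionally
    over the label eroded by ``intensity_erosion`` µm, which suppresses
    bleed-in from the surface-marker rims of adjacent cells; labels that
    vanish under erosion fall back to their full pixel set).  Centroids are
    converted to µm with the pixel-center convention (index + 0.5), area is
    pixel count x pixel_size² and circularity ``4πA/P²`` uses the Crofton
    perimeter estimate.
    """
    if labels.labels.shape != image.shape_yx:
        raise DataError(
            f"label map shape {labels.labels.shape} does not match image {image.shape_yx}"
        )
    if image.is_stack:
        raise DataError("extract_features expects a 2D image; apply project_mip first")
    px = image.pixel_size
    lab = labels.labels
    if lab.max() == 0:
        cols = {"cell_id": [], "x_um": [], "y_um": [], "volume_um2": [], "sphericity": []}
        for ch in image.channel_names:
            cols[f"mean_{ch}"] = []
        return CellTable(pd.DataFrame(cols), {"pixel_size": px})

    intensity = np.moveaxis(np.asarray(image.data, dtype=np.float64), 0, -1)
    geo = regionprops_table(
        lab, properties=("label", "centroid", "area", "perimeter_crofton")
    )
    order = np.argsort(geo["label"])
    label_ids = geo["label"][order]
    area_px = geo["area"][order].astype(float)
    perim = geo["perimeter_crofton"][order]
    cy = (geo["centroid-0"][order] + 0.5) * px
    cx = (geo["centroid-1"][order] + 0.5) * px
    with np.errstate(divide="ignore", invalid="ignore"):
        circ = 4.0 * np.pi * area_px / np.maximum(perim, 1e-12) ** 2
    circ = np.clip(circ, None, 1.05)

    meas_lab = lab
    if intensity_erosion > 0:
        meas_lab = _eroded_labels(lab, intensity_erosion / px)
    inten = regionprops_table(meas_lab, intensity_image=intensity,
                              properties=("label", "intensity_mean"))
    n_ch = image.n_channels
    mean_by_label = {}
    for i, lid in enumerate(inten["label"]):
        mean_by_label[int(lid)] = [inten[f"intensity_mean-{c}"][i] for c in range(n_ch)]
    if intensity_erosion > 0 and len(mean_by_label) < len(label_ids):
        # fallback for labels erased by erosion
        full = regionprops_table(lab, intensity_image=intensity,
                                 properties=("label", "intensity_mean"))
        for i, lid in enumerate(full["label"]):
            mean_by_label.setdefault(
                int(lid), [full[f"intensity_mean-{c}"][i] for c in range(n_ch)]
            )

    data = {
        "cell_id": label_ids.astype(int),
        "x_um": cx,
        "y_um": cy,
        "volume_um2": area_px * px * px,
        "sphericity": circ,
    }
    means = np.array([mean_by_label[int(l)] for l in label_ids])
    for c, ch in enumerate(image.channel_names):
        data[f"mean_{ch}"] = means[:, c]
    df = pd.DataFrame(data)
    return CellTable(df, {"pixel_size": px, **image.metadata})
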
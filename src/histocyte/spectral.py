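"""Spillover estimation, compensation and autofluorescence subtraction.

Fluorescence bleed-through between detection channels is modeled linearly:
for a pixel with true per-fluorophore signal ``t`` the observed channel
vector is ``o = M^T t`` where ``M[f, g]`` is the fraction of fluorophore
``f``'s signal detected in channel ``g`` (diagonal = 1).  ``M`` is estimated
from single-stain images — tissue stained with one antibody-fluorophore
combination at a time, imaged under the same optical configuration as the
full panel — and compensation solves the linear system per pixel.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConditioningError, ConfigurationError, EstimationError
from .image import MultichannelImage

__all__ = [
    "SpilloverMatrix",
    "estimate_spillover",
    "compensate",
    "subtract_autofluorescence",
]

#: refuse to invert anything with a worse condition number than this
_MAX_CONDITION = 1e8


@dataclass
class SpilloverMatrix:
    """Square fluorophore-by-channel mixing matrix.

    ``values[f, g]`` is the fraction of fluorophore ``f`` signal collected in
    channel ``g``; the diagonal is exactly 1 and entries lie in [0, 1].
    """

    values: np.ndarray
    channel_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        n = self.values.shape[0]
        if self.values.ndim != 2 or self.values.shape[1] != n:
            raise ConfigurationError("spillover matrix must be square")
        if not self.channel_names:
            self.channel_names = [f"ch{i}" for i in range(n)]
        if len(self.channel_names) != n:
            raise ConfigurationError("one channel name per matrix row required")
        if not np.allclose(np.diag(self.values), 1.0):
            raise ConfigurationError("spillover diagonal must be 1")
        if self.values.min() < 0 or self.values.max() > 1:
            raise ConfigurationError("spillover entries must lie in [0, 1]")
        if np.linalg.cond(self.values) > _MAX_CONDITION:
            raise ConditioningError("spillover matrix is ill-conditioned")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @classmethod
    def identity(cls, channel_names: list[str]) -> "SpilloverMatrix":
        return cls(np.eye(len(channel_names)), list(channel_names))

    @classmethod
    def from_pairs(
        cls, channel_names: list[str], pairs: list[tuple[str, str, float]]
    ) -> "SpilloverMatrix":
        """Build from sparse ``(source_fluorophore, channel, coefficient)`` entries."""
        idx = {c: i for i, c in enumerate(channel_names)}
        m = np.eye(len(channel_names))
        for src, dst, coef in pairs:
            if src not in idx or dst not in idx:
                raise ConfigurationError(f"unknown channel in spillover pair {src}->{dst}")
            m[idx[src], idx[dst]] = float(coef)
        return cls(m, list(channel_names))

    # %.17g guarantees a bit-exact float64 round trip through text
    def to_csv(self, path) -> None:
        df = pd.DataFrame(self.values, index=self.channel_names, columns=self.channel_names)
        df.to_csv(path, float_format="%.17g")

    @classmethod
    def from_csv(cls, path) -> "SpilloverMatrix":
        df = pd.read_csv(path, index_col=0, float_precision="round_trip")
        return cls(df.to_numpy(dtype=np.float64), list(df.columns))


def _check_channels(image: MultichannelImage, matrix: SpilloverMatrix) -> None:
    if list(image.channel_names) != list(matrix.channel_names):
        raise ConfigurationError(
            "channel order mismatch between image "
            f"({image.channel_names}) and spillover matrix ({matrix.channel_names})"
        )


def estimate_spillover(
    single_stains: dict[str, MultichannelImage],
    foreground_quantile: float = 0.98,
    min_foreground: int = 100,
    method: str = "median_ratio",
) -> SpilloverMatrix:
    """Estimate the mixing matrix from one single-stain image per fluorophore.

    For fluorophore ``f`` the foreground is the set of pixels above
    ``foreground_quantile`` in f's own channel; each channel's background
    (median over non-foreground pixels) is subtracted, and entry ``[f, g]``
    is the robust slope of channel g against channel f over the foreground.

    Parameters
    ----------
    single_stains:
        Map fluorophore name -> full multichannel render of its single stain.
        All images must share a channel order that contains every key.
    foreground_quantile:
        Quantile in f's own channel above which pixels count as stained.
    min_foreground:
        Minimum number of foreground pixels; fewer raises `EstimationError`.
    method:
        ``"median_ratio"`` (default, robust to autofluorescence outliers) or
        ``"lstsq"`` for an ordinary least-squares slope through the origin.
    """
    if not single_stains:
        raise ConfigurationError("no single-stain images given")
    first = next(iter(single_stains.values()))
    channels = list(first.channel_names)
    for f, img in single_stains.items():
        if list(img.channel_names) != channels:
            raise ConfigurationError(f"single stain {f!r} has a different channel order")
        if f not in channels:
            raise ConfigurationError(f"fluorophore {f!r} not among channels {channels}")
    missing = [c for c in channels if c not in single_stains]
    if missing:
        raise ConfigurationError(f"missing single stains for {missing}")

    n = len(channels)
    m = np.eye(n)
    for f in channels:
        img = single_stains[f]
        fi = channels.index(f)
        planes = img.data.reshape(n, -1).astype(np.float64)
        own = planes[fi]
        cut = np.quantile(own, foreground_quantile)
        fg = own > cut
        if fg.sum() < min_foreground:
            raise EstimationError(
                f"single stain for {f!r}: only {int(fg.sum())} foreground pixels "
                f"above quantile {foreground_quantile} (need {min_foreground})"
            )
        bg = np.median(planes[:, ~fg], axis=1)
        x = own[fg] - bg[fi]
        ys = planes[:, fg] - bg[:, None]
        ok = x > 1e-9
        if ok.sum() < min_foreground:
            raise EstimationError(f"single stain for {f!r} has no positive foreground")
        x = x[ok]
        for g in range(n):
            if g == fi:
                continue
            if method == "median_ratio":
                slope = float(np.median(ys[g, ok] / x))
            elif method == "lstsq":
                slope = float(np.dot(ys[g, ok], x) / np.dot(x, x))
            else:
                raise ConfigurationError(f"unknown estimator {method!r}")
            m[fi, g] = max(0.0, min(1.0, slope))
    return SpilloverMatrix(m, channels)


def compensate(image: MultichannelImage, matrix: SpilloverMatrix) -> MultichannelImage:
    """Undo spillover: solve ``observed = M^T true`` per pixel, clamp at 0.

    The input image is left unmodified; the result carries
    ``metadata["compensated"] = True``.
    """
    _check_channels(image, matrix)
    planes = image.data.reshape(image.n_channels, -1).astype(np.float64)
    if np.linalg.cond(matrix.values) > _MAX_CONDITION:  # pragma: no cover - guarded in ctor
        raise ConditioningError("spillover matrix is ill-conditioned")
    true = np.linalg.solve(matrix.values.T, planes)
    np.maximum(true, 0.0, out=true)
    out = true.reshape(image.data.shape).astype(np.float32)
    return image.with_data(out, compensated=True)


def remix(image: MultichannelImage, matrix: SpilloverMatrix) -> MultichannelImage:
    """Apply mixing ``observed = M^T true`` (inverse of :func:`compensate`)."""
    _check_channels(image, matrix)
    planes = image.data.reshape(image.n_channels, -1).astype(np.float64)
    mixed = matrix.values.T @ planes
    return image.with_data(mixed.reshape(image.data.shape).astype(np.float32))


def subtract_autofluorescence(
    image: MultichannelImage,
    af_channel: str,
    coefficients: dict[str, float],
) -> MultichannelImage:
    """Subtract a scaled autofluorescence reference channel from the others.

    Each target channel ``c`` becomes ``max(0, c - coeff[c] * AF)``; the AF
    channel itself is passed through unchanged.
    """
    af_idx = image.channel_index(af_channel)
    for c, k in coefficients.items():
        if c not in image.channel_names:
            raise ConfigurationError(f"unknown channel {c!r} in AF coefficients")
        if k < 0:
            raise ConfigurationError(f"negative AF coefficient for channel {c!r}")
    af = image.data[af_idx].astype(np.float64)
    out = image.data.astype(np.float64).copy()
    for c, k in coefficients.items():
        ci = image.channel_index(c)
        if ci == af_idx:
            warnings.warn("AF channel listed among targets; leaving it unchanged")
            continue
        out[ci] = np.maximum(0.0, out[ci] - k * af)
    return image.with_data(out.astype(np.float32), af_subtracted=True)
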
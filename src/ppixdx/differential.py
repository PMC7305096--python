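"""Differential method: linear autofluorescence baseline subtraction.

The autofluorescence intensity in the 632-nm PpIX measurement band is
predicted per pixel by linear interpolation between the two flanking bands
(600/14 and 650/13 nm, all under 405-nm excitation) and subtracted from the
measured 632/22-nm intensity.  Tissue autofluorescence is nearly linear
across 600–650 nm, so the residual isolates PpIX; the node score is the
maximum residual over the node mask, optionally after a 3×3 median filter
that keeps the maximum robust to single-pixel noise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from sklearn.base import BaseEstimator, TransformerMixin

from .bands import (
    BAND_600_405,
    BAND_632_405,
    BAND_650_405,
    NodeRecord,
    Phase,
)
from .exceptions import ValidationError

_CW600 = BAND_600_405.center_wavelength
_CW650 = BAND_650_405.center_wavelength


@dataclass
class PpixMap:
    """Estimated PpIX intensity map: non-negative, zero outside the mask."""

    pixels: np.ndarray
    method: str
    node_id: str


def linear_baseline(i600, i650, target_cw: float):
    """Autofluorescence intensity at ``target_cw`` by linear interpolation.

    Works on scalars or per-pixel arrays; clipped at zero.  ``target_cw``
    must lie within [600, 650] — the method interpolates, never extrapolates.
    """
    if not _CW600 <= target_cw <= _CW650:
        raise ValidationError(
            f"target_cw must be in [{_CW600:g}, {_CW650:g}] nm, got {target_cw}"
        )
    i600 = np.asarray(i600, dtype=float)
    i650 = np.asarray(i650, dtype=float)
    w = (target_cw - _CW600) / (_CW650 - _CW600)
    out = np.clip(i600 + w * (i650 - i600), 0.0, None)
    return float(out) if out.ndim == 0 else out


def differential_map(
    record: NodeRecord, normalize_bandwidth: bool = False
) -> PpixMap:
    """Per-pixel PpIX estimate: max(0, I632 − baseline) inside the mask.

    The baseline is evaluated at the measurement band's center (632 nm).
    ``normalize_bandwidth`` divides each band by its FWHM first (off by
    default: raw band intensities, as measured).
    """
    imgs = {}
    for band in (BAND_600_405, BAND_632_405, BAND_650_405):
        px = record.get(band, Phase.PRE).pixels.astype(float)
        if normalize_bandwidth:
            px = px / band.fwhm
        imgs[band] = px
    baseline = linear_baseline(
        imgs[BAND_600_405], imgs[BAND_650_405], BAND_632_405.center_wavelength
    )
    resid = np.clip(imgs[BAND_632_405] - baseline, 0.0, None)
    resid[~record.mask] = 0.0
    return PpixMap(pixels=resid, method="differential", node_id=record.node_id)


def _smoothed_max(pixels: np.ndarray, mask: np.ndarray, smooth: bool) -> float:
    if smooth:
        pixels = ndimage.median_filter(pixels, size=3)
    return float(pixels[mask].max())


def differential_score(
    record: NodeRecord,
    smooth: bool = True,
    normalize_bandwidth: bool = False,
) -> float:
    """Node score: maximum of the (optionally 3×3-median-smoothed) PpIX map."""
    pmap = differential_map(record, normalize_bandwidth=normalize_bandwidth)
    return _smoothed_max(pmap.pixels, record.mask, smooth)


class DifferentialScorer(TransformerMixin, BaseEstimator):
    """sklearn-style transformer: node records → differential scores.

    ``transform`` accepts a sequence of :class:`NodeRecord` and returns an
    ``(n, 1)`` float array, so it composes with a downstream
    :class:`~ppixdx.diagnostics.CutoffClassifier` in a sklearn ``Pipeline``.
    """

    def __init__(self, smooth: bool = True, normalize_bandwidth: bool = False):
        self.smooth = smooth
        self.normalize_bandwidth = normalize_bandwidth

    def fit(self, X, y=None):  # stateless; present for API compatibility
        self.n_features_in_ = 1
        return self

    def transform(self, X) -> np.ndarray:
        scores = [
            differential_score(
                rec, smooth=self.smooth, normalize_bandwidth=self.normalize_bandwidth
            )
            for rec in X
        ]
        return np.asarray(scores, dtype=float).reshape(-1, 1)
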
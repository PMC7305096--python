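"""Optical band data model and node acquisition container.

A node is measured through a small bank of band-pass fluorescence filters
under one of two excitation wavelengths.  The device's standard filter set is
600/14, 632/22, 650/13 and 680/22 nm (center / FWHM); excitation is 405 nm
for the differential acquisition and 435 nm for the ratio acquisitions, with
405 nm also used as the photoconversion irradiation source.

`NodeRecord` bundles every acquisition of one lymph node cut surface: a
binary node mask, the per-band intensity images, the cumulative irradiation
fluence each image was taken at, and an optional ground-truth label.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
from scipy import ndimage
from skimage.morphology import disk

from .exceptions import MaskTooSmallError, MissingBandError, ValidationError

#: Allowed excitation wavelengths (nm).
EXCITATIONS = (405.0, 435.0)

METASTATIC = "metastatic"
NON_METASTATIC = "non_metastatic"


class Phase(str, Enum):
    """Acquisition phase relative to the 405-nm photoconversion irradiation."""

    PRE = "pre_irradiation"
    POST = "post_irradiation"


@dataclass(frozen=True, order=True)
class FilterBand:
    """One optical detection band: an ideal rectangular passband.

    Parameters
    ----------
    excitation : float
        Excitation wavelength in nm (405 or 435).
    center_wavelength : float
        Passband center (CW) in nm.
    fwhm : float
        Full width at half maximum in nm; the rectangular passband spans
        ``center_wavelength ± fwhm / 2``.
    """

    excitation: float
    center_wavelength: float
    fwhm: float

    def __post_init__(self) -> None:
        if self.fwhm <= 0:
            raise ValidationError(f"fwhm must be > 0, got {self.fwhm}")
        if float(self.excitation) not in EXCITATIONS:
            raise ValidationError(
                f"excitation must be one of {EXCITATIONS} nm, got {self.excitation}"
            )

    @property
    def lo(self) -> float:
        return self.center_wavelength - self.fwhm / 2.0

    @property
    def hi(self) -> float:
        return self.center_wavelength + self.fwhm / 2.0

    def __str__(self) -> str:  # e.g. "632/22@405"
        return (
            f"{self.center_wavelength:g}/{self.fwhm:g}@{self.excitation:g}"
        )


# The device's standard bands.
BAND_600_405 = FilterBand(405.0, 600.0, 14.0)
BAND_632_405 = FilterBand(405.0, 632.0, 22.0)
BAND_650_405 = FilterBand(405.0, 650.0, 13.0)
BAND_632_435 = FilterBand(435.0, 632.0, 22.0)
BAND_680_435 = FilterBand(435.0, 680.0, 22.0)

#: Bands used by the differential (linear baseline) method, 405-nm excitation.
DIFFERENTIAL_BANDS = (BAND_600_405, BAND_632_405, BAND_650_405)
#: Bands used by the ratio (photoconversion) method, 435-nm excitation.
RATIO_BANDS = (BAND_632_435, BAND_680_435)


@dataclass
class BandImage:
    """A single 2-D intensity map acquired through one filter band.

    Intensities are arbitrary units, non-negative, stored float32. The
    ``cumulative_fluence`` records how much 405-nm irradiation (J/cm²) the
    sample had received when the image was taken.
    """

    pixels: np.ndarray
    band: FilterBand
    cumulative_fluence: float
    pixel_size: float
    phase: Phase = Phase.PRE

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float32)
        if self.pixels.ndim != 2:
            raise ValidationError("pixels must be a 2-D array")
        if np.any(self.pixels < 0):
            raise ValidationError(
                f"band image {self.band} contains negative intensities"
            )
        if self.cumulative_fluence < 0:
            raise ValidationError("cumulative_fluence must be >= 0")
        if self.pixel_size <= 0:
            raise ValidationError("pixel_size must be > 0")
        self.phase = Phase(self.phase)


@dataclass
class NodeRecord:
    """All acquisitions of one lymph node.

    ``images`` is keyed by ``(FilterBand, Phase)``.  Post-irradiation images
    exist only for 435-nm-excited bands (the ratio method's second pass).
    """

    node_id: str
    mask: np.ndarray
    pixel_size: float
    images: dict[tuple[FilterBand, Phase], BandImage] = field(default_factory=dict)
    label: str | None = None

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        self.validate()

    def validate(self) -> None:
        if self.mask.ndim != 2:
            raise ValidationError("mask must be 2-D")
        if not self.mask.any():
            raise ValidationError(f"node {self.node_id}: mask has no foreground pixel")
        if self.pixel_size <= 0:
            raise ValidationError("pixel_size must be > 0")
        if self.label is not None and self.label not in (METASTATIC, NON_METASTATIC):
            raise ValidationError(
                f"label must be '{METASTATIC}' or '{NON_METASTATIC}', got {self.label!r}"
            )
        for (band, phase), img in self.images.items():
            phase = Phase(phase)
            if img.pixels.shape != self.mask.shape:
                raise ValidationError(
                    f"node {self.node_id}: image {band} shape {img.pixels.shape} "
                    f"!= mask shape {self.mask.shape}"
                )
            if not math.isclose(img.pixel_size, self.pixel_size):
                raise ValidationError(
                    f"node {self.node_id}: image {band} pixel_size {img.pixel_size} "
                    f"!= record pixel_size {self.pixel_size}"
                )
            if phase is not Phase(img.phase):
                raise ValidationError(
                    f"node {self.node_id}: key phase {phase.value} != image phase "
                    f"{Phase(img.phase).value} for band {band}"
                )
            if phase is Phase.POST and band.excitation != 435.0:
                raise ValidationError(
                    f"node {self.node_id}: post-irradiation image for non-435-nm "
                    f"band {band}"
                )

    def get(self, band: FilterBand, phase: Phase = Phase.PRE) -> BandImage:
        """Return the image for ``(band, phase)``; raise naming the band if absent."""
        key = (band, Phase(phase))
        try:
            return self.images[key]
        except KeyError:
            have = ", ".join(f"{b}:{p.value}" for b, p in sorted(
                self.images, key=lambda k: (k[0], k[1].value)))
            raise MissingBandError(
                f"node {self.node_id}: missing band {band} ({Phase(phase).value}); "
                f"available: {have or 'none'}"
            ) from None


def erode_mask(mask: np.ndarray, margin: float, pixel_size: float) -> np.ndarray:
    """Erode a binary mask by a physical margin (mm).

    The structuring element is an L2 disc of radius ``ceil(margin / pixel_size)``
    pixels, so the result is contained in the input (anti-extensive) and shrinks
    monotonically with the margin.  Used to cut off node edges before ratio
    analysis.

    Raises
    ------
    MaskTooSmallError
        If erosion empties the mask — the node is too small for this margin.
    """
    mask = np.asarray(mask, dtype=bool)
    if margin < 0:
        raise ValidationError(f"margin must be >= 0, got {margin}")
    if pixel_size <= 0:
        raise ValidationError("pixel_size must be > 0")
    radius = math.ceil(margin / pixel_size - 1e-12)
    if radius == 0:
        return mask.copy()
    eroded = ndimage.binary_erosion(mask, structure=disk(radius).astype(bool))
    if not eroded.any():
        raise MaskTooSmallError(
            f"erosion by margin {margin} mm ({radius} px) emptied the mask; "
            "use a smaller margin or exclude this node"
        )
    return eroded
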
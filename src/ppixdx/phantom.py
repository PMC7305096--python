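"""Synthetic lymph-node phantoms.

A phantom is a ground-truth tissue description on a pixel grid: one
concentration map (arbitrary units) per fluorophore, a binary node mask, and
the list of lesions (macro-/micro-metastases or inflammatory foci) that were
painted into it.  Phantoms support two physical operations:

* ``apply_photoconversion`` — first-order PpIX → PPp conversion under 405-nm
  irradiation: after fluence F, PpIX is multiplied by exp(-k·F) and a fraction
  η of the converted amount appears as fluorescent PPp.
* ``render_band_image`` — forward model of the camera: each pixel is the sum
  over fluorophores of concentration × (band integral of the emission
  density), plus optional shot-like and read noise, clipped at zero.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, replace
from typing import Mapping

import numpy as np

from .bands import METASTATIC, NON_METASTATIC, BandImage, FilterBand, Phase
from .exceptions import ValidationError
from .spectra import FluorophoreSpectrum, default_spectra

MACRO_METASTASIS = "macro_metastasis"
MICRO_METASTASIS = "micro_metastasis"
INFLAMMATION = "inflammation"
LESION_KINDS = (MACRO_METASTASIS, MICRO_METASTASIS, INFLAMMATION)

#: Diameter (mm) below which a metastatic lesion counts as a micro-metastasis.
MICRO_DIAMETER_MM = 2.0


@dataclass(frozen=True)
class PhotoconversionParams:
    """First-order PpIX→PPp photoconversion kinetics.

    rate_k : conversion constant per J/cm²; the default ln 2 halves PpIX per
        J/cm², so the standard 2 J/cm² dose converts 75 %.
    yield_eta : fraction of converted PpIX that becomes fluorescent PPp.
    """

    rate_k: float = float(np.log(2.0))
    yield_eta: float = 0.8

    def __post_init__(self) -> None:
        if self.rate_k < 0:
            raise ValidationError(f"rate_k must be >= 0, got {self.rate_k}")
        if not 0.0 <= self.yield_eta <= 1.0:
            raise ValidationError(f"yield_eta must be in [0, 1], got {self.yield_eta}")


@dataclass(frozen=True)
class LesionSpec:
    """A disc lesion: metastatic (macro/micro) or an inflammatory PpIX focus."""

    center: tuple[float, float]  # (row mm, col mm) from top-left pixel center
    diameter: float  # mm
    ppix_level: float  # a.u. concentration inside the disc
    kind: str

    def __post_init__(self) -> None:
        if self.kind not in LESION_KINDS:
            raise ValidationError(f"unknown lesion kind {self.kind!r}")
        if self.diameter <= 0:
            raise ValidationError("lesion diameter must be > 0")
        if self.ppix_level < 0:
            raise ValidationError("ppix_level must be >= 0")
        if self.kind == MICRO_METASTASIS and self.diameter >= MICRO_DIAMETER_MM:
            raise ValidationError(
                f"micro-metastasis requires diameter < {MICRO_DIAMETER_MM} mm, "
                f"got {self.diameter}"
            )
        if self.kind == MACRO_METASTASIS and self.diameter < MICRO_DIAMETER_MM:
            raise ValidationError(
                f"macro-metastasis requires diameter >= {MICRO_DIAMETER_MM} mm, "
                f"got {self.diameter}"
            )

    @property
    def is_metastatic(self) -> bool:
        return self.kind in (MACRO_METASTASIS, MICRO_METASTASIS)


@dataclass
class NoiseParams:
    """Camera noise: variance ``shot_gain × signal`` plus Gaussian read noise."""

    shot_gain: float = 0.005
    read_sigma: float = 0.005

    def __post_init__(self) -> None:
        if self.shot_gain < 0 or self.read_sigma < 0:
            raise ValidationError("noise parameters must be >= 0")

    @property
    def is_zero(self) -> bool:
        return self.shot_gain == 0.0 and self.read_sigma == 0.0


@dataclass
class NodePhantom:
    """Ground-truth description of one synthetic node."""

    node_id: str
    mask: np.ndarray
    pixel_size: float  # mm / px
    concentration_maps: dict[str, np.ndarray]
    lesions: tuple[LesionSpec, ...] = ()
    label: str = NON_METASTATIC

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        self.lesions = tuple(self.lesions)
        self.validate()

    def validate(self) -> None:
        if not self.mask.any():
            raise ValidationError(f"phantom {self.node_id}: empty mask")
        if self.pixel_size <= 0:
            raise ValidationError("pixel_size must be > 0")
        outside = ~self.mask
        for name, cmap in self.concentration_maps.items():
            cmap = np.asarray(cmap, dtype=float)
            self.concentration_maps[name] = cmap
            if cmap.shape != self.mask.shape:
                raise ValidationError(
                    f"phantom {self.node_id}: {name} map shape mismatch"
                )
            if np.any(cmap < 0):
                raise ValidationError(f"phantom {self.node_id}: {name} map negative")
            if np.any(cmap[outside] != 0):
                raise ValidationError(
                    f"phantom {self.node_id}: {name} nonzero outside mask"
                )
        has_met = any(l.is_metastatic for l in self.lesions)
        if (self.label == METASTATIC) != has_met:
            raise ValidationError(
                f"phantom {self.node_id}: label {self.label!r} inconsistent with "
                f"lesions {[l.kind for l in self.lesions]}"
            )


def apply_photoconversion(
    phantom: NodePhantom, params: PhotoconversionParams, fluence: float
) -> NodePhantom:
    """Return a new phantom after delivering ``fluence`` J/cm² of 405-nm light.

    Pixelwise: PpIX ← PpIX·exp(−k·F); PPp ← PPp + η·PpIX_before·(1−exp(−k·F)).
    All other maps unchanged; the input phantom is not modified.
    """
    if fluence < 0:
        raise ValidationError(f"fluence must be >= 0, got {fluence}")
    maps = {k: v.copy() for k, v in phantom.concentration_maps.items()}
    from .spectra import PPIX, PPP  # names, no cycle at import time

    survive = float(np.exp(-params.rate_k * fluence))
    ppix_before = maps.get(PPIX)
    if ppix_before is not None:
        maps[PPIX] = ppix_before * survive
        converted = ppix_before * (1.0 - survive)
        ppp = maps.get(PPP, np.zeros_like(ppix_before))
        maps[PPP] = ppp + params.yield_eta * converted
    return replace(phantom, concentration_maps=maps, lesions=phantom.lesions)


def render_band_image(
    phantom: NodePhantom,
    band: FilterBand,
    spectra: Mapping[str, FluorophoreSpectrum] | None = None,
    noise: NoiseParams | None = None,
    rng: np.random.Generator | None = None,
    cumulative_fluence: float = 0.0,
    phase: Phase = Phase.PRE,
) -> BandImage:
    """Forward-render one band image of a phantom.

    Pixel value = Σ_f concentration_f × ∫_band emission_density_f dλ, with
    noise added inside the mask (variance ``shot_gain × signal`` plus read
    noise), clipped at zero.
    """
    spectra = default_spectra() if spectra is None else spectra
    signal = np.zeros(phantom.mask.shape, dtype=float)
    for name, cmap in phantom.concentration_maps.items():
        spec = spectra.get(name)
        if spec is None:
            raise ValidationError(f"no spectrum registered for fluorophore {name!r}")
        coeff = spec.band_intensity(band)  # raises UnknownExcitationError if needed
        if coeff != 0.0:
            signal += coeff * cmap
    if noise is not None and not noise.is_zero:
        if rng is None:
            raise ValidationError("rng required when noise is enabled")
        sigma = np.sqrt(noise.shot_gain * signal + noise.read_sigma**2)
        signal = signal + phantom.mask * sigma * rng.standard_normal(signal.shape)
    np.clip(signal, 0.0, None, out=signal)
    signal[~phantom.mask] = 0.0
    return BandImage(
        pixels=signal.astype(np.float32),
        band=band,
        cumulative_fluence=cumulative_fluence,
        pixel_size=phantom.pixel_size,
        phase=phase,
    )


def copy_phantom(phantom: NodePhantom) -> NodePhantom:
    return copy.deepcopy(phantom)
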
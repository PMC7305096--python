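"""Fluorophore emission model.

Each fluorophore emits a sum of Gaussian peaks in wavelength, scaled by an
excitation-efficiency factor per excitation wavelength.  Defaults capture the
four chromophores relevant to 5-ALA node imaging:

* PpIX — strong red emission peaking ~635 nm under blue excitation, with a
  weaker vibronic shoulder near 705 nm; excitation efficiency drops between
  405 nm (Soret band) and 435 nm.
* PPp (photo-protoporphyrin) — the photo-oxidation product of PpIX, peak
  ~675 nm; the basis of the ratio method.
* FAD and collagen — broad tissue autofluorescence peaking near 520 and
  490 nm, whose red tail contaminates the PpIX bands.

Peak positions follow the published spectral facts; widths and amplitudes are
free model parameters with sensible defaults, all overridable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .bands import FilterBand
from .exceptions import UnknownExcitationError, ValidationError

PPIX = "PpIX"
PPP = "PPp"
FAD = "FAD"
COLLAGEN = "collagen"

#: Quadrature step (nm) for rectangular passband integration.
QUADRATURE_STEP = 0.5


@dataclass(frozen=True)
class EmissionPeak:
    """One Gaussian emission peak: density = amplitude * exp(-(λ-center)²/2σ²)."""

    center: float  # nm
    width: float  # Gaussian sigma, nm
    amplitude: float  # relative, dimensionless

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValidationError(f"peak width must be > 0, got {self.width}")
        if self.amplitude < 0:
            raise ValidationError("peak amplitude must be >= 0")


@dataclass(frozen=True)
class FluorophoreSpectrum:
    name: str
    peaks: tuple[EmissionPeak, ...]
    excitation_efficiency: Mapping[float, float] = field(
        default_factory=lambda: {405.0: 1.0, 435.0: 1.0}
    )

    def __post_init__(self) -> None:
        if not self.peaks:
            raise ValidationError(f"{self.name}: at least one emission peak required")
        if any(e < 0 for e in self.excitation_efficiency.values()):
            raise ValidationError(f"{self.name}: excitation efficiency must be >= 0")

    def efficiency(self, excitation: float) -> float:
        try:
            return self.excitation_efficiency[float(excitation)]
        except KeyError:
            avail = sorted(self.excitation_efficiency)
            raise UnknownExcitationError(
                f"{self.name}: no excitation efficiency for {excitation} nm; "
                f"available excitations: {avail}"
            ) from None

    def emission_density(self, wavelength, excitation: float):
        """Emission density (a.u./nm) at ``wavelength`` under ``excitation``.

        Vectorized over wavelength; always >= 0.
        """
        lam = np.asarray(wavelength, dtype=float)
        dens = np.zeros_like(lam)
        for p in self.peaks:
            dens = dens + p.amplitude * np.exp(-0.5 * ((lam - p.center) / p.width) ** 2)
        out = self.efficiency(excitation) * dens
        return float(out) if np.ndim(wavelength) == 0 else out

    def band_intensity(self, band: FilterBand) -> float:
        """Integral of the emission density over the band's rectangular passband.

        Midpoint quadrature at ``QUADRATURE_STEP`` nm; units a.u. (a.u./nm × nm)
        per unit fluorophore concentration.
        """
        n = max(1, round(band.fwhm / QUADRATURE_STEP))
        step = band.fwhm / n
        lam = band.lo + (np.arange(n) + 0.5) * step
        return float(np.sum(self.emission_density(lam, band.excitation)) * step)


def emission_density(spectrum: FluorophoreSpectrum, wavelength, excitation: float):
    """Module-level convenience wrapper around ``FluorophoreSpectrum.emission_density``."""
    return spectrum.emission_density(wavelength, excitation)


def default_spectra() -> dict[str, FluorophoreSpectrum]:
    """Default four-fluorophore model (fresh instances; mutate freely)."""
    return {
        PPIX: FluorophoreSpectrum(
            PPIX,
            (EmissionPeak(635.0, 10.0, 1.0), EmissionPeak(705.0, 15.0, 0.15)),
            {405.0: 1.0, 435.0: 0.6},
        ),
        PPP: FluorophoreSpectrum(PPP, (EmissionPeak(675.0, 12.0, 1.0),)),
        FAD: FluorophoreSpectrum(FAD, (EmissionPeak(520.0, 35.0, 1.0),)),
        COLLAGEN: FluorophoreSpectrum(COLLAGEN, (EmissionPeak(490.0, 40.0, 1.0),)),
    }


def band_coefficients(
    spectra: Mapping[str, FluorophoreSpectrum], band: FilterBand
) -> dict[str, float]:
    """Per-unit-concentration band intensity of every fluorophore in ``spectra``."""
    return {name: spec.band_intensity(band) for name, spec in spectra.items()}
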
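"""Synthetic node cohort generation.

The generator emulates the study design the pipeline is meant for: a cohort
of excised lymph nodes imaged on their cut surface, most non-metastatic, a
minority carrying a macro- (>= 2 mm) or micro- (< 2 mm) metastatic PpIX-rich
lesion, and a fraction of the negatives carrying a nonspecific inflammatory
PpIX focus (the false-positive source).  Micro-metastases are systematically
fainter than macro lesions.

Per node the acquisition sequence mirrors the device protocol:

1. differential bands (600/14, 632/22, 650/13 nm) under 405-nm excitation;
2. ratio bands (632/22, 680/22 nm) under 435-nm excitation, pre-irradiation;
3. 405-nm irradiation to the configured fluence (default 2 J/cm²);
4. ratio bands again, post-irradiation.

Acquisition exposures themselves are treated as delivering negligible
fluence; only the dedicated irradiation step photoconverts.

``expected_operating_point`` is a score-level model of the same cohort: it
draws node intensity levels straight from the configured distributions and
pushes them through the closed-form band algebra (no images, no noise, no
smoothing), yielding the sensitivity/specificity a Youden-calibrated
classifier should reach on an infinite cohort.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterator, Mapping

import numpy as np
import pandas as pd
from scipy import ndimage

from .bands import (
    DIFFERENTIAL_BANDS,
    METASTATIC,
    NON_METASTATIC,
    RATIO_BANDS,
    BandImage,
    NodeRecord,
    Phase,
)
from .exceptions import ValidationError
from .phantom import (
    INFLAMMATION,
    MACRO_METASTASIS,
    MICRO_DIAMETER_MM,
    MICRO_METASTASIS,
    LesionSpec,
    NodePhantom,
    NoiseParams,
    PhotoconversionParams,
    apply_photoconversion,
    render_band_image,
)
from .spectra import COLLAGEN, FAD, PPIX, PPP, FluorophoreSpectrum, default_spectra


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


@dataclass(frozen=True)
class LogNormalLevel:
    """Log-normal intensity level: ``median * exp(sigma_log * Z)``.

    A median of 0 degenerates to the constant 0 (used to switch a component
    off entirely).
    """

    median: float
    sigma_log: float

    def __post_init__(self) -> None:
        if self.median < 0 or self.sigma_log < 0:
            raise ValidationError("log-normal level parameters must be >= 0")

    def sample(self, rng: np.random.Generator, size=None):
        if self.median == 0.0:
            return np.zeros(size) if size is not None else 0.0
        return self.median * np.exp(self.sigma_log * rng.standard_normal(size))


@dataclass(frozen=True)
class CohortConfig:
    """Study conditions for one synthetic cohort.

    Defaults mirror the reference clinical cohort: 323 nodes with 41
    metastatic (prevalence 41/323), 6 of the 41 micro-metastatic.  Intensity
    levels are arbitrary units; autofluorescence is bright relative to lesion
    PpIX, which is precisely why baseline removal is needed.
    """

    n_nodes: int = 323
    metastasis_prevalence: float = 41.0 / 323.0
    micro_fraction: float = 6.0 / 41.0
    inflammation_rate: float = 0.2
    lesion_level: LogNormalLevel = LogNormalLevel(1.0, 0.6)
    micro_level: LogNormalLevel = LogNormalLevel(0.25, 0.6)
    inflammation_level: LogNormalLevel = LogNormalLevel(0.18, 0.7)
    background_ppix_level: LogNormalLevel = LogNormalLevel(0.0, 0.5)
    fad_level: LogNormalLevel = LogNormalLevel(3.0, 0.4)
    collagen_level: LogNormalLevel = LogNormalLevel(3.0, 0.4)
    texture_amplitude: float = 0.1
    noise: NoiseParams = field(default_factory=NoiseParams)
    pixel_size: float = 0.02
    node_diameter_range: tuple[float, float] = (3.0, 12.0)
    macro_diameter_range: tuple[float, float] = (2.0, 6.0)
    micro_diameter_range: tuple[float, float] = (0.5, 1.9)
    inflammation_diameter_range: tuple[float, float] = (0.5, 3.0)
    photoconversion: PhotoconversionParams = field(default_factory=PhotoconversionParams)
    fluence: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_nodes < 1:
            raise ValidationError("n_nodes must be >= 1")
        for name in ("metastasis_prevalence", "micro_fraction", "inflammation_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must be in [0, 1], got {v}")
        if self.pixel_size <= 0 or self.fluence < 0:
            raise ValidationError("pixel_size must be > 0 and fluence >= 0")
        lo, hi = self.node_diameter_range
        if not 0 < lo <= hi:
            raise ValidationError("invalid node_diameter_range")
        if self.micro_diameter_range[1] >= MICRO_DIAMETER_MM:
            raise ValidationError(
                f"micro-metastasis diameters must stay < {MICRO_DIAMETER_MM} mm"
            )

    def noiseless(self) -> "CohortConfig":
        """Same cohort with camera noise switched off."""
        return replace(self, noise=NoiseParams(0.0, 0.0))


# ---------------------------------------------------------------------------
# cohort plan

_MACRO, _MICRO, _INFLAMED, _CLEAN = "macro", "micro", "inflamed", "clean"


def _node_plans(config: CohortConfig, rng: np.random.Generator) -> list[str]:
    """Deterministic class counts (half-up rounding), order shuffled by rng."""
    n = config.n_nodes
    n_pos = _round_half_up(config.metastasis_prevalence * n)
    n_micro = _round_half_up(config.micro_fraction * n_pos)
    n_neg = n - n_pos
    n_inflamed = _round_half_up(config.inflammation_rate * n_neg)
    plans = (
        [_MACRO] * (n_pos - n_micro)
        + [_MICRO] * n_micro
        + [_INFLAMED] * n_inflamed
        + [_CLEAN] * (n_neg - n_inflamed)
    )
    rng.shuffle(plans)
    return plans


def _uniform_in_ellipse(
    rng: np.random.Generator, center: tuple[float, float], semi_axes: tuple[float, float]
) -> tuple[float, float]:
    r = math.sqrt(rng.uniform())
    theta = rng.uniform(0.0, 2.0 * math.pi)
    return (
        center[0] + r * semi_axes[0] * math.sin(theta),
        center[1] + r * semi_axes[1] * math.cos(theta),
    )


def build_phantom(
    node_id: str, status: str, config: CohortConfig, rng: np.random.Generator
) -> NodePhantom:
    """Sample one node phantom: elliptical mask, textured autofluorescence,
    and at most one disc lesion according to ``status``."""
    ps = config.pixel_size
    d1, d2 = rng.uniform(*config.node_diameter_range, size=2)
    major, minor = max(d1, d2), min(d1, d2)
    pad_px = int(round(0.3 / ps))
    b_px = minor / 2.0 / ps  # row semi-axis
    a_px = major / 2.0 / ps  # col semi-axis
    shape = (int(round(2 * b_px)) + 2 * pad_px, int(round(2 * a_px)) + 2 * pad_px)
    cr, cc = (shape[0] - 1) / 2.0, (shape[1] - 1) / 2.0
    rr, cc_grid = np.ogrid[: shape[0], : shape[1]]
    mask = ((rr - cr) / b_px) ** 2 + ((cc_grid - cc) / a_px) ** 2 <= 1.0

    def textured(level: float) -> np.ndarray:
        if level == 0.0:
            return np.zeros(shape)
        if config.texture_amplitude > 0:
            g = ndimage.gaussian_filter(rng.standard_normal(shape), sigma=8.0)
            sd = g.std()
            fld = 1.0 + config.texture_amplitude * (g / sd if sd > 0 else g)
            fld = np.clip(fld, 0.1, None)
        else:
            fld = np.ones(shape)
        return level * fld * mask

    maps = {
        FAD: textured(float(config.fad_level.sample(rng))),
        COLLAGEN: textured(float(config.collagen_level.sample(rng))),
        PPIX: np.zeros(shape),
        PPP: np.zeros(shape),
    }
    bg = float(config.background_ppix_level.sample(rng))
    if bg > 0:
        maps[PPIX] = bg * mask.astype(float)

    lesions: list[LesionSpec] = []
    if status != _CLEAN:
        kind, dia_range, level_dist = {
            _MACRO: (MACRO_METASTASIS, config.macro_diameter_range, config.lesion_level),
            _MICRO: (MICRO_METASTASIS, config.micro_diameter_range, config.micro_level),
            _INFLAMED: (
                INFLAMMATION,
                config.inflammation_diameter_range,
                config.inflammation_level,
            ),
        }[status]
        diameter = float(rng.uniform(*dia_range))
        # the disc (plus 0.1 mm clearance) must fit inside the ellipse
        fit_cap = 2.0 * (min(a_px, b_px) * ps - 0.15)
        diameter = min(diameter, fit_cap)
        diameter = max(diameter, dia_range[0] if dia_range[0] < fit_cap else fit_cap)
        radius = diameter / 2.0
        free = (b_px * ps - radius - 0.1, a_px * ps - radius - 0.1)
        free = (max(free[0], 0.0), max(free[1], 0.0))
        center = _uniform_in_ellipse(rng, (cr * ps, cc * ps), free)
        level = float(level_dist.sample(rng))
        lesions.append(LesionSpec(center, diameter, level, kind))
        rr_mm = rr * ps
        cc_mm = cc_grid * ps
        disc = (rr_mm - center[0]) ** 2 + (cc_mm - center[1]) ** 2 <= radius**2
        maps[PPIX] = maps[PPIX] + level * (disc & mask).astype(float)

    label = METASTATIC if status in (_MACRO, _MICRO) else NON_METASTATIC
    return NodePhantom(
        node_id=node_id,
        mask=mask,
        pixel_size=ps,
        concentration_maps=maps,
        lesions=tuple(lesions),
        label=label,
    )


def render_node(
    phantom: NodePhantom,
    config: CohortConfig,
    rng: np.random.Generator,
    spectra: Mapping[str, FluorophoreSpectrum] | None = None,
) -> NodeRecord:
    """Run the full acquisition sequence on a phantom and return the record."""
    spectra = default_spectra() if spectra is None else spectra
    noise = config.noise
    images: dict = {}
    for band in DIFFERENTIAL_BANDS:
        images[(band, Phase.PRE)] = render_band_image(
            phantom, band, spectra, noise, rng, cumulative_fluence=0.0, phase=Phase.PRE
        )
    for band in RATIO_BANDS:
        images[(band, Phase.PRE)] = render_band_image(
            phantom, band, spectra, noise, rng, cumulative_fluence=0.0, phase=Phase.PRE
        )
    converted = apply_photoconversion(phantom, config.photoconversion, config.fluence)
    for band in RATIO_BANDS:
        images[(band, Phase.POST)] = render_band_image(
            converted,
            band,
            spectra,
            noise,
            rng,
            cumulative_fluence=config.fluence,
            phase=Phase.POST,
        )
    return NodeRecord(
        node_id=phantom.node_id,
        mask=phantom.mask,
        pixel_size=phantom.pixel_size,
        images=images,
        label=phantom.label,
    )


def _truth_row(phantom: NodePhantom) -> dict:
    lesion = phantom.lesions[0] if phantom.lesions else None
    return {
        "node_id": phantom.node_id,
        "label": phantom.label,
        "lesion_kind": lesion.kind if lesion else "none",
        "diameter_mm": lesion.diameter if lesion else 0.0,
        "ppix_level": lesion.ppix_level if lesion else 0.0,
    }


def iter_cohort(
    config: CohortConfig,
    spectra: Mapping[str, FluorophoreSpectrum] | None = None,
    with_phantom: bool = False,
) -> Iterator[tuple]:
    """Yield ``(record, truth_row)`` (plus the phantom if requested) per node.

    Streaming: records can be scored and dropped one at a time, which keeps a
    large cohort's memory footprint at a single node's images.
    """
    spectra = default_spectra() if spectra is None else spectra
    ss = np.random.SeedSequence(config.seed)
    plan_ss, *node_ss = ss.spawn(config.n_nodes + 1)
    plans = _node_plans(config, np.random.default_rng(plan_ss))
    width = len(str(config.n_nodes))
    for i, (status, child) in enumerate(zip(plans, node_ss)):
        rng = np.random.default_rng(child)
        phantom = build_phantom(f"node_{i:0{width}d}", status, config, rng)
        record = render_node(phantom, config, rng, spectra)
        row = _truth_row(phantom)
        yield (record, row, phantom) if with_phantom else (record, row)


def generate_cohort(
    config: CohortConfig,
    spectra: Mapping[str, FluorophoreSpectrum] | None = None,
) -> tuple[list[NodeRecord], pd.DataFrame]:
    """Materialize the whole cohort (use :func:`iter_cohort` for large n)."""
    records, rows = [], []
    for record, row in iter_cohort(config, spectra):
        records.append(record)
        rows.append(row)
    return records, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# score-level model (independent of the image pipeline)


@dataclass(frozen=True)
class OperatingPoint:
    threshold: float
    sensitivity_pct: float
    specificity_pct: float


def _band_algebra(spectra: Mapping[str, FluorophoreSpectrum]) -> dict:
    """Closed-form band coefficients shared by both score formulas."""
    b600, b632, b650 = DIFFERENTIAL_BANDS
    r632, r680 = RATIO_BANDS
    frac = (b632.center_wavelength - b600.center_wavelength) / (
        b650.center_wavelength - b600.center_wavelength
    )

    def diff_coeff(name: str) -> float:
        s = spectra[name]
        i600, i632, i650 = (s.band_intensity(b) for b in (b600, b632, b650))
        return i632 - (i600 + frac * (i650 - i600))

    return {
        "diff_ppix": diff_coeff(PPIX),
        "diff_af": {f: diff_coeff(f) for f in (FAD, COLLAGEN)},
        "p632": spectra[PPIX].band_intensity(r632),
        "p680": spectra[PPIX].band_intensity(r680),
        "q632": spectra[PPP].band_intensity(r632),
        "q680": spectra[PPP].band_intensity(r680),
        "a632": {f: spectra[f].band_intensity(r632) for f in (FAD, COLLAGEN)},
        "a680": {f: spectra[f].band_intensity(r680) for f in (FAD, COLLAGEN)},
    }


def _model_scores(
    config: CohortConfig,
    alg: dict,
    rng: np.random.Generator,
    n: int,
    positive: bool,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw (differential, ratio) node scores from the score-level model."""
    fad = config.fad_level.sample(rng, n)
    col = config.collagen_level.sample(rng, n)
    bg = config.background_ppix_level.sample(rng, n)
    if positive:
        is_micro = rng.uniform(size=n) < config.micro_fraction
        level = np.where(
            is_micro,
            config.micro_level.sample(rng, n),
            config.lesion_level.sample(rng, n),
        )
    else:
        inflamed = rng.uniform(size=n) < config.inflammation_rate
        level = np.where(inflamed, config.inflammation_level.sample(rng, n), 0.0)

    af_resid = alg["diff_af"][FAD] * fad + alg["diff_af"][COLLAGEN] * col
    diff_lesion = np.maximum(0.0, alg["diff_ppix"] * (level + bg) + af_resid)
    diff_tissue = np.maximum(0.0, alg["diff_ppix"] * bg + af_resid)
    diff = np.maximum(diff_lesion, diff_tissue)

    s = math.exp(-config.photoconversion.rate_k * config.fluence)
    eta = config.photoconversion.yield_eta
    af632 = alg["a632"][FAD] * fad + alg["a632"][COLLAGEN] * col
    af680 = alg["a680"][FAD] * fad + alg["a680"][COLLAGEN] * col

    def delta(p0: np.ndarray) -> np.ndarray:
        ppp = eta * (1.0 - s) * p0
        pre = (alg["p680"] * p0 + af680) / (alg["p632"] * p0 + af632)
        post = (alg["p680"] * s * p0 + alg["q680"] * ppp + af680) / (
            alg["p632"] * s * p0 + alg["q632"] * ppp + af632
        )
        return post - pre

    ratio = np.maximum(delta(level + bg), delta(bg))
    return diff, ratio


def _point_at(pos: np.ndarray, neg: np.ndarray, threshold: float) -> OperatingPoint:
    return OperatingPoint(
        threshold=float(threshold),
        sensitivity_pct=100.0 * float(np.mean(pos >= threshold)),
        specificity_pct=100.0 * float(np.mean(neg < threshold)),
    )


def _youden_point(pos: np.ndarray, neg: np.ndarray) -> OperatingPoint:
    pos = np.sort(pos)
    neg = np.sort(neg)
    cand = np.unique(np.concatenate([pos, neg]))
    sens = 1.0 - np.searchsorted(pos, cand, side="left") / pos.size
    spec = np.searchsorted(neg, cand, side="left") / neg.size
    j = sens + spec - 1.0
    # max J; ties toward higher specificity, then higher threshold
    order = np.lexsort((cand, spec, j))
    best = order[-1]
    return OperatingPoint(
        threshold=float(cand[best]),
        sensitivity_pct=100.0 * float(sens[best]),
        specificity_pct=100.0 * float(spec[best]),
    )


def expected_operating_point(
    config: CohortConfig,
    spectra: Mapping[str, FluorophoreSpectrum] | None = None,
    n_draws: int = 200_000,
    seed: int = 12345,
    thresholds: Mapping[str, float] | None = None,
) -> dict[str, OperatingPoint]:
    """Sensitivity/specificity implied by the configured intensity
    distributions, per method.

    Node scores are drawn directly from the configured log-normal levels and
    evaluated with the closed-form band algebra (noise, smoothing and pixel
    geometry play no role), so this is the large-n operating point the image
    pipeline should recover.  With ``thresholds`` given (per method), the
    analytic overlap beyond each fixed threshold is returned; otherwise the
    Youden-optimal point.  Fixing the threshold is the sharper parameter-
    recovery comparison: the Youden objective of overlapping log-normal
    mixtures can have a broad plateau on which the argmax itself is not
    identifiable from a finite cohort, while the overlap at a given cutoff
    always is.
    """
    spectra = default_spectra() if spectra is None else spectra
    alg = _band_algebra(spectra)
    rng = np.random.default_rng(seed)
    diff_pos, ratio_pos = _model_scores(config, alg, rng, n_draws, positive=True)
    diff_neg, ratio_neg = _model_scores(config, alg, rng, n_draws, positive=False)
    draws = {"differential": (diff_pos, diff_neg), "ratio": (ratio_pos, ratio_neg)}
    out = {}
    for method, (pos, neg) in draws.items():
        if thresholds is not None and method in thresholds:
            out[method] = _point_at(pos, neg, thresholds[method])
        else:
            out[method] = _youden_point(pos, neg)
    return out
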
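import numpy as np
import pytest

from ppixdx import (
    BAND_600_405,
    BAND_632_405,
    BAND_632_435,
    BAND_680_435,
    BandImage,
    NoiseParams,
    Phase,
    PhotoconversionParams,
    RatioScorer,
    apply_photoconversion,
    ratio_delta,
    ratio_map,
    ratio_score,
    render_band_image,
)
from ppixdx.bands import RATIO_BANDS, NodeRecord
from ppixdx.exceptions import FluenceShortfallError, MissingBandError, ValidationError
from ppixdx.phantom import NodePhantom
from ppixdx.spectra import COLLAGEN, FAD, PPIX, PPP


def img(values, band=BAND_632_435, fluence=0.0, phase=Phase.PRE):
    return BandImage(np.atleast_2d(np.asarray(values, float)), band, fluence, 0.02, phase)


def ppix_phantom(level=1.0, fad=0.0, collagen=0.0, shape=(31, 31)):
    mask = np.ones(shape, bool)
    maps = {
        PPIX: np.full(shape, float(level)),
        PPP: np.zeros(shape),
        FAD: np.full(shape, float(fad)),
        COLLAGEN: np.full(shape, float(collagen)),
    }
    return NodePhantom("ph", mask, 0.02, maps)


def record_from_phantom(phantom, fluence=2.0, params=None):
    params = params or PhotoconversionParams()
    images = {}
    for band in RATIO_BANDS:
        images[(band, Phase.PRE)] = render_band_image(
            phantom, band, cumulative_fluence=0.0, phase=Phase.PRE
        )
    converted = apply_photoconversion(phantom, params, fluence)
    for band in RATIO_BANDS:
        images[(band, Phase.POST)] = render_band_image(
            converted, band, cumulative_fluence=fluence, phase=Phase.POST
        )
    return NodeRecord(phantom.node_id, phantom.mask, phantom.pixel_size, images)


class TestRatioMap:
    def test_equal_bands_give_unit_ratio(self):
        r = ratio_map(img(np.full((3, 3), 4.0), BAND_680_435),
                      img(np.full((3, 3), 4.0)), epsilon=0.5)
        np.testing.assert_allclose(r, 1.0)

    def test_floored_denominator(self):
        r = ratio_map(img([[3.0]], BAND_680_435), img([[0.0]]), epsilon=0.5)
        assert r[0, 0] == pytest.approx(6.0)

    def test_phase_mismatch_rejected(self):
        with pytest.raises(ValidationError, match="phase"):
            ratio_map(img([[1.0]], BAND_680_435, 2.0, Phase.POST), img([[1.0]]),
                      epsilon=0.1)

    def test_non_435_band_rejected(self):
        with pytest.raises(ValidationError, match="435"):
            ratio_map(img([[1.0]], BAND_680_435),
                      BandImage(np.ones((1, 1)), BAND_632_405, 0.0, 0.02), epsilon=0.1)

    def test_ratio_increases_at_lesion_after_photoconversion(self):
        ph = ppix_phantom(level=1.0, fad=3.0, collagen=3.0)
        rec = record_from_phantom(ph)
        eps = 1e-6
        pre = ratio_map(rec.get(BAND_680_435, Phase.PRE),
                        rec.get(BAND_632_435, Phase.PRE), eps)
        post = ratio_map(rec.get(BAND_680_435, Phase.POST),
                         rec.get(BAND_632_435, Phase.POST), eps)
        assert np.all(post[ph.mask] > pre[ph.mask])


class TestRatioDelta:
    def test_identical_pre_post_gives_zero(self, ratio_record):
        a = np.full((9, 9), 2.0)
        b = np.full((9, 9), 5.0)
        rec = ratio_record(b, a, b, a)
        maps = ratio_delta(rec, margin=0.0)
        np.testing.assert_allclose(maps.delta[maps.analysis_mask], 0.0)

    def test_photostable_phantom_gives_zero_delta(self):
        ph = ppix_phantom(level=0.0, fad=5.0, collagen=2.0)
        rec = record_from_phantom(ph)
        maps = ratio_delta(rec, margin=0.0)
        np.testing.assert_allclose(maps.delta[maps.analysis_mask], 0.0, atol=1e-12)

    def test_single_pixel_arithmetic(self, ratio_record):
        rec = ratio_record([[10.0]], [[2.0]], [[5.0]], [[6.0]])
        maps = ratio_delta(rec, margin=0.0, epsilon=1e-6)
        assert maps.delta[0, 0] == pytest.approx(1.0)

    def test_scale_invariance(self, ratio_record):
        rng = np.random.default_rng(4)
        arrays = [rng.uniform(1, 10, (9, 9)) for _ in range(4)]
        rec1 = ratio_record(*arrays)
        rec2 = ratio_record(*(7.0 * a for a in arrays))
        d1 = ratio_delta(rec1, margin=0.0, epsilon=1e-9).delta
        d2 = ratio_delta(rec2, margin=0.0, epsilon=1e-9).delta
        # ratios of float32 intensities agree to float32 precision
        np.testing.assert_allclose(d1, d2, rtol=1e-5, atol=1e-5)

    def test_fluence_shortfall_rejected(self, ratio_record):
        rec = ratio_record([[1.0]], [[1.0]], [[1.0]], [[1.0]], fluence=1.0)
        with pytest.raises(FluenceShortfallError, match="2"):
            ratio_delta(rec, margin=0.0, required_fluence=2.0)

    def test_missing_post_phase_named(self, ratio_record):
        rec = ratio_record([[1.0]], [[1.0]], [[1.0]], [[1.0]])
        del rec.images[(BAND_680_435, Phase.POST)]
        with pytest.raises(MissingBandError, match="post"):
            ratio_delta(rec, margin=0.0)


class TestRatioScore:
    def test_zero_delta_scores_zero(self, ratio_record):
        a = np.full((9, 9), 3.0)
        rec = ratio_record(a, a, a, a)
        assert ratio_score(rec, margin=0.0) == 0.0

    def test_unsmoothed_interior_max(self, ratio_record):
        pre680 = np.full((9, 9), 1.0)
        post680 = np.full((9, 9), 1.0)
        post680[4, 4] = 2.0
        ones = np.ones((9, 9))
        rec = ratio_record(ones, pre680, ones, post680)
        assert ratio_score(rec, margin=0.0, smooth=False) == pytest.approx(1.0)

    def test_margin_excludes_edge_maximum(self, ratio_record):
        pre680 = np.full((11, 11), 1.0)
        post680 = np.full((11, 11), 1.0)
        post680[0, 5] = 9.0  # hottest increment sits on the node edge
        post680[5, 5] = 2.0
        ones = np.ones((11, 11))
        rec = ratio_record(ones, pre680, ones, post680)
        score = ratio_score(rec, margin=2 * 0.02, smooth=False)
        assert score == pytest.approx(1.0)
        assert score < 8.0

    def test_smoothing_suppresses_hot_pixel(self, ratio_record):
        pre680 = np.full((9, 9), 1.0)
        post680 = np.full((9, 9), 1.0)
        post680[4, 4] = 50.0
        ones = np.ones((9, 9))
        rec = ratio_record(ones, pre680, ones, post680)
        assert ratio_score(rec, margin=0.0, smooth=True) == pytest.approx(0.0)

    def test_score_nondecreasing_in_fluence_and_saturating(self):
        ph = ppix_phantom(level=1.0, fad=3.0, collagen=3.0)
        scores = [
            ratio_score(record_from_phantom(ph, fluence=f), margin=0.0,
                        required_fluence=0.0)
            for f in (0.25, 0.5, 1.0, 2.0, 4.0, 8.0, 20.0, 40.0)
        ]
        assert all(b >= a - 1e-12 for a, b in zip(scores, scores[1:]))
        # once conversion is essentially complete the increment saturates
        assert scores[-1] - scores[-2] < 0.01 * scores[-1]


class TestRatioScorer:
    def test_transform_matches_function(self, ratio_record):
        ones = np.ones((9, 9))
        pre680 = np.full((9, 9), 1.0)
        post680 = np.full((9, 9), 1.5)
        recs = [ratio_record(ones, pre680, ones, post680)]
        out = RatioScorer(margin=0.0, smooth=False).fit(recs).transform(recs)
        assert out.shape == (1, 1)
        assert out[0, 0] == pytest.approx(0.5)
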
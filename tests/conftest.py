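import numpy as np
import pytest

from ppixdx import (
    BAND_632_435,
    BAND_680_435,
    BandImage,
    CohortConfig,
    DIFFERENTIAL_BANDS,
    NodeRecord,
    NoiseParams,
    Phase,
    generate_cohort,
)


@pytest.fixture(scope="session")
def small_cohort():
    """Eight default-noise nodes covering all lesion kinds."""
    config = CohortConfig(
        n_nodes=8,
        metastasis_prevalence=0.5,
        micro_fraction=0.5,
        inflammation_rate=0.5,
        node_diameter_range=(3.0, 6.0),
        seed=7,
    )
    records, truth = generate_cohort(config)
    return config, records, truth


@pytest.fixture(scope="session")
def noiseless_separated_cohort():
    """Noiseless cohort with no inflammation: positives and negatives separate."""
    config = CohortConfig(
        n_nodes=20,
        metastasis_prevalence=0.3,
        inflammation_rate=0.0,
        node_diameter_range=(3.0, 6.0),
        noise=NoiseParams(0.0, 0.0),
        seed=5,
    )
    records, truth = generate_cohort(config)
    return config, records, truth


@pytest.fixture
def diff_record():
    """Factory: NodeRecord carrying the three differential bands (405 nm, pre)."""

    def make(i600, i632, i650, mask=None, pixel_size=0.02, node_id="toy"):
        arrays = [np.atleast_2d(np.asarray(a, dtype=float)) for a in (i600, i632, i650)]
        if mask is None:
            mask = np.ones_like(arrays[0], dtype=bool)
        images = {
            (band, Phase.PRE): BandImage(arr, band, 0.0, pixel_size, Phase.PRE)
            for band, arr in zip(DIFFERENTIAL_BANDS, arrays)
        }
        return NodeRecord(node_id, mask, pixel_size, images)

    return make


@pytest.fixture
def ratio_record():
    """Factory: NodeRecord carrying the two ratio bands pre and post irradiation."""

    def make(pre632, pre680, post632, post680, mask=None, fluence=2.0,
             pixel_size=0.02, node_id="toy"):
        arrays = {
            (BAND_632_435, Phase.PRE, 0.0): pre632,
            (BAND_680_435, Phase.PRE, 0.0): pre680,
            (BAND_632_435, Phase.POST, fluence): post632,
            (BAND_680_435, Phase.POST, fluence): post680,
        }
        images = {}
        for (band, phase, flu), arr in arrays.items():
            arr = np.atleast_2d(np.asarray(arr, dtype=float))
            images[(band, phase)] = BandImage(arr, band, flu, pixel_size, phase)
        if mask is None:
            shape = next(iter(images.values())).pixels.shape
            mask = np.ones(shape, dtype=bool)
        return NodeRecord(node_id, mask, pixel_size, images)

    return make
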
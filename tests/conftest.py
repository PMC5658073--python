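import numpy as np
import pytest

import leaf2dcos as l2


@pytest.fixture(scope="session")
def tiny():
    """4 samples x 5 wavelengths micro-fixture with hand-checkable values."""
    return l2.make_fixture("tiny-4x5")


@pytest.fixture(scope="session")
def default100():
    """The default synthetic cohort: 100 leaves, planted bands at 548/713 nm."""
    return l2.make_fixture("default-100")


@pytest.fixture(scope="session")
def default100_bands(default100):
    """Bands selected by the full screening + 2DCOS path on the cohort."""
    spectra, nitrogen, _ = default100
    profile = l2.correlation_profile(spectra, nitrogen)
    kept = l2.apply_exclusions(
        l2.significant_regions(profile), l2.DEFAULT_EXCLUSIONS
    )
    maps = l2.CorrelationMaps.from_dynamic(
        l2.dynamic_spectra(spectra, nitrogen, window=kept)
    )
    return l2.select_bands(l2.detect_autopeaks(maps))


def grid_spectra(values, start=500, ids=None):
    """SpectrumSet helper on a short 1 nm grid starting at `start`."""
    values = np.asarray(values, dtype=float)
    ids = ids or [f"s{i}" for i in range(values.shape[0])]
    wl = np.arange(start, start + values.shape[1])
    return l2.SpectrumSet(wl, values, ids)
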
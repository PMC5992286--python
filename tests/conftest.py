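import numpy as np
import pytest

from mlfc.bands import DEFAULT_BANDS
from mlfc.signals import analytic, bandpass, trim_edges


@pytest.fixture(scope="session")
def bands():
    return {b.name: b for b in DEFAULT_BANDS}


@pytest.fixture(scope="session")
def downstream_phase():
    """Estimator-side phase extraction: band-pass, Hilbert, edge-trim."""

    def _extract(x, band, fs):
        return trim_edges(analytic(bandpass(x, band, fs)).phase, fs)

    return _extract


@pytest.fixture(scope="session")
def downstream_envelope():
    def _extract(x, band, fs):
        return trim_edges(analytic(bandpass(x, band, fs)).envelope, fs)

    return _extract


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
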
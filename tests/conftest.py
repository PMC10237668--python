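import numpy as np
import pytest

from soprosody.contours import fit_fpca, normalize_time
from soprosody.simulate import ContourGenParams, gen_contours


@pytest.fixture(scope="session")
def contour_set():
    """30 synthetic contours (15 per condition) plus their normalized forms."""
    contours = gen_contours(15, ContourGenParams(), seed=100)
    normalized = [normalize_time(c) for c in contours]
    return contours, normalized


@pytest.fixture(scope="session")
def fpca_model(contour_set):
    _, normalized = contour_set
    model, scores = fit_fpca(normalized, n_components=3)
    return model, scores


@pytest.fixture()
def rng():
    return np.random.default_rng(7)
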
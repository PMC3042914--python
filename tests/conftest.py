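import numpy as np
import pytest

from raretail.testing import toy_models, toy_scheme, toy_universe


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tiny_universe():
    """2-letter alphabet, 3+3 positions: 64 enumerable configurations."""
    return toy_universe(alphabet_size=2, length=3)


@pytest.fixture(scope="session")
def tiny_exact_pmf(tiny_universe):
    from raretail.oracles import exact_score_distribution

    return exact_score_distribution(tiny_universe)


@pytest.fixture(scope="session")
def tiny_window(tiny_exact_pmf):
    from raretail.wang_landau import ScoreWindow

    scores = sorted(s for s, _ in tiny_exact_pmf)
    return ScoreWindow(min(scores), max(scores))


@pytest.fixture(scope="session")
def tiny_support(tiny_exact_pmf, tiny_window):
    import numpy as np

    exact = np.zeros((1, tiny_window.n_bins))
    for (s, n), p in tiny_exact_pmf.items():
        exact[0, s - tiny_window.s_min] += p
    return exact > 0


@pytest.fixture(scope="session")
def tiny_exact_marginal(tiny_exact_pmf, tiny_window):
    import numpy as np

    exact = np.zeros(tiny_window.n_bins)
    for (s, n), p in tiny_exact_pmf.items():
        exact[s - tiny_window.s_min] += p
    return exact
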
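import numpy as np
import pytest

import dkisub as dk


@pytest.fixture(scope="session")
def reference_scheme():
    """The ordered 100-volume two-shell reference scheme (seeded)."""
    return dk.build_reference_scheme(0, n_restarts=20)


@pytest.fixture(scope="session")
def default_substrate():
    return dk.build_default_substrate()


@pytest.fixture(scope="session")
def ground_truth(default_substrate):
    return dk.ground_truth_metrics(default_substrate)


@pytest.fixture(scope="session")
def small_scheme():
    """A fast-to-build two-shell scheme for unit tests (12 + 16 dirs)."""
    scheme = dk.generate_multishell_scheme(
        n_per_shell={1: 12, 2: 16},
        bvalues={1: 1000.0, 2: 2000.0},
        n_b0=4,
        seed=5,
        n_restarts=2,
    )
    return dk.order_incremental_eem(scheme).rebase()


def unit_rows(n, seed):
    rng = np.random.default_rng(seed)
    v = rng.standard_normal((n, 3))
    return v / np.linalg.norm(v, axis=1, keepdims=True)
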
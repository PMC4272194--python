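import warnings

import numpy as np
import pytest

import stcar


@pytest.fixture(autouse=True)
def _quiet_warnings():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        yield


@pytest.fixture
def path3():
    """Path graph 1-2-3 on three areas."""
    return stcar.SpatialGraph(3, ((0, 1), (1, 2)))


@pytest.fixture
def grid22():
    """2x2 rook lattice: 4 areas, 4 edges."""
    return stcar.make_lattice(2, 2)


@pytest.fixture
def grid33():
    return stcar.make_lattice(3, 3)


@pytest.fixture
def small_dataset():
    """A small simulated panel on a 4x4 lattice, T=3."""
    g = stcar.make_lattice(4, 4)
    scen = stcar.Scenario(M=0.5, E_interval=(50, 100), separable=True, n_datasets=1)
    data, truth = stcar.generate_dataset(scen, g, 3, seed=42)
    return g, data, truth


def dense_gmrf_conditional(Q, tau, i, eps=1e-8):
    """Oracle: conditional mean coefficient vector and variance of cell i for a
    Gaussian with precision tau*(Q + eps*I), via covariance Schur complement."""
    n = Q.shape[0]
    cov = np.linalg.inv(tau * (Q + eps * np.eye(n)))
    rest = [j for j in range(n) if j != i]
    S_ii = cov[i, i]
    S_ir = cov[np.ix_([i], rest)]
    S_rr = cov[np.ix_(rest, rest)]
    coef = np.linalg.solve(S_rr, S_ir.ravel())
    var = S_ii - S_ir.ravel() @ coef
    return rest, coef, var
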
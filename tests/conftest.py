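import numpy as np
import pytest

from snha import CorrMatrix, DataMatrix, PlantedStructure, generate_planted


def make_corr(r, n=100, names=None, method="pearson"):
    r = np.asarray(r, dtype=float)
    if names is None:
        names = [chr(ord("A") + i) for i in range(r.shape[0])]
    return CorrMatrix.from_r(r, n=n, var_names=names, method=method)


@pytest.fixture
def corr4():
    """4 variables with |r|: AB=.9 BC=.7 CD=.5 AC=.6 AD=.3 BD=.4 (n=100).

    The greedy walk from A is A,B,C,D and its reversal from D retraces it,
    so the single chain A-B-C-D is expected.
    """
    r = np.array(
        [
            [1.0, 0.9, 0.6, 0.3],
            [0.9, 1.0, 0.7, 0.4],
            [0.6, 0.7, 1.0, 0.5],
            [0.3, 0.4, 0.5, 1.0],
        ]
    )
    return make_corr(r, n=100)


@pytest.fixture
def identity_corr():
    return make_corr(np.eye(5), n=50)


def random_corrmatrix(rng, n_var, n_obs=20):
    """A valid correlation matrix from random data with a shared latent
    factor (so that some, but not all, pairs are significant)."""
    latent = rng.standard_normal((n_obs, 1))
    X = rng.standard_normal((n_obs, n_var)) + latent * rng.uniform(0.0, 1.5)
    d = DataMatrix(X, [f"v{i}" for i in range(n_var)])
    from snha import correlation_matrix

    return correlation_matrix(d, method="pearson")


@pytest.fixture
def template_33x10():
    """A 33 x 10 table with two correlated blocks, shaped like a small
    athletics dataset; used as the template for null-model experiments."""
    names = tuple(f"v{i:02d}" for i in range(10))
    edges, coeffs = [], {}
    for hub, members in (("v00", ["v01", "v02", "v03", "v04"]),
                         ("v05", ["v06", "v07", "v08", "v09"])):
        for m in members:
            edges.append((hub, m))
            coeffs[(hub, m)] = 0.8
    ps = PlantedStructure(var_names=names, edges=tuple(edges), coefficients=coeffs,
                          noise_sd=0.8, n_obs=33, seed=42)
    return generate_planted(ps)
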
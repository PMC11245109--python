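import numpy as np
import pytest
import scipy.sparse as sp

from grnforge.exprmodel import ExpressionParams
from grnforge.netgen import GraphParams, GRNGraph, generate_network


def make_graph(edges, n, groups=None):
    """Build a GRNGraph directly from an edge list (test helper)."""
    edges = np.array(edges, dtype=np.int64).reshape(-1, 2)
    group_of = np.zeros(n, dtype=np.int64) if groups is None else np.asarray(groups)
    return GRNGraph(
        n_nodes=n,
        edges=edges,
        group_of=group_of,
        in_degree=np.bincount(edges[:, 1], minlength=n) if len(edges) else np.zeros(n, int),
        out_degree=np.bincount(edges[:, 0], minlength=n) if len(edges) else np.zeros(n, int),
    )


def isolated_params(sig_alpha=0.2, ell=0.8, s=0.0):
    """Single unregulated gene with sigma(alpha) and ell as given."""
    alpha = np.log(sig_alpha / (1 - sig_alpha))
    return ExpressionParams(
        alpha=np.array([alpha]), ell=np.array([ell]), beta=sp.csr_matrix((1, 1)), s=s
    )


def chain_params(beta12=2.0, sig_alpha=0.2, ell=0.8, s=0.0):
    """Two-gene chain 0 -> 1 with weight beta12."""
    alpha = np.log(sig_alpha / (1 - sig_alpha))
    beta = sp.csr_matrix(([beta12], ([0], [1])), shape=(2, 2))
    return ExpressionParams(
        alpha=np.full(2, alpha), ell=np.full(2, ell), beta=beta, s=s
    )


def scalar_fixed_point(alpha, betas_x, ell, x0=0.0, iters=10000):
    """Loop-free scalar oracle: iterate x <- sigma(alpha + drive) / ell."""
    import math

    x = x0
    for _ in range(iters):
        x = 1.0 / (1.0 + math.exp(-(alpha + betas_x(x)))) / ell
    return x


@pytest.fixture
def small_graph():
    return generate_network(
        GraphParams(n=30, k=3, w=9, p=0.5, delta_in=10, delta_out=3, seed=11)
    )
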
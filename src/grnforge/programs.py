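"""Gene programs from truncated SVD of simulated cell populations.

A cell population mixing unperturbed ("baseline") cells with cells from
knockout conditions is assembled by forward simulation, each gene is
z-normalized across cells, and the top ``k`` singular triplets are
computed (X ~ U S V^T).  Each gene singular vector defines one *program*:
the set of genes with the largest squared loadings.  Concordance between
two decompositions is measured by per-program maximum overlap counts and
by canonical correlation analysis (CCA), which for orthonormal loading
matrices reduces to the singular values of ``V^T V'``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exprmodel import ExpressionParams, SimConfig, advance, simulate_batch

__all__ = [
    "CellPopulationSpec",
    "ProgramSet",
    "assemble_cells",
    "znormalize",
    "truncated_svd",
    "define_programs",
    "program_overlap",
    "cca",
]


@dataclass(frozen=True)
class CellPopulationSpec:
    """Composition of a perturbed/unperturbed cell population.

    Defaults mirror the reference experiment: 75,328 cells of which
    roughly 8.1% are unperturbed, the remainder assigned uniformly at
    random to knockout conditions (about 35 cells per knockout for 2,000
    genes), simulated at analysis noise ``noise_s = 0.3``.
    """

    n_cells: int = 75328
    baseline_fraction: float = 0.081
    ko_conditions: tuple | None = None  # None = every gene
    noise_s: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells <= 0:
            raise ValueError("n_cells must be positive")
        if not (0.0 <= self.baseline_fraction <= 1.0):
            raise ValueError("baseline_fraction must be in [0, 1]")


@dataclass
class ProgramSet:
    """Gene singular vectors and their top-loading gene sets."""

    gene_singular_vectors: np.ndarray  # (n_genes, k)
    singular_values: np.ndarray
    programs: list  # per component, array of gene indices
    program_size: int


def assemble_cells(
    params: ExpressionParams,
    baseline,
    spec: CellPopulationSpec = CellPopulationSpec(),
    config: SimConfig = SimConfig(),
):
    """Simulate a mixed population of baseline and knockout cells.

    Baseline cells are consecutive forward steps from the baseline steady
    state at noise ``spec.noise_s``.  Each knockout condition is first
    re-equilibrated under the standard protocol (at the same noise), then
    its cells are consecutive post-convergence steps.  No gene filtering
    is applied.  Returns ``(cells, origin)`` where origin[c] is -1 for
    baseline cells and the knocked-out gene index otherwise.
    """
    n = params.n_genes
    rng = np.random.default_rng(spec.seed)
    sim_params = ExpressionParams(
        alpha=params.alpha, ell=params.ell, beta=params.beta,
        s=spec.noise_s, dt=params.dt,
    )
    n_base = int(round(spec.n_cells * spec.baseline_fraction))
    kos = np.arange(n) if spec.ko_conditions is None else np.asarray(spec.ko_conditions)
    assignment = rng.choice(kos, size=spec.n_cells - n_base) if spec.n_cells > n_base else np.empty(0, dtype=int)
    counts = {int(j): int(c) for j, c in zip(*np.unique(assignment, return_counts=True))}

    cells = np.empty((spec.n_cells, n))
    origin = np.empty(spec.n_cells, dtype=int)
    x0 = np.asarray(baseline.xbar, dtype=float)

    pos = 0
    if n_base:
        # stream tag n cannot collide with a knockout gene index (0..n-1);
        # re-equilibrate at the analysis noise so cells come from the
        # stationary distribution, matching the knockout conditions
        base_rng = np.random.default_rng(np.random.SeedSequence((spec.seed, n)))
        st = simulate_batch(sim_params, config=config, seeds=[base_rng], init=x0)[0]
        cells[:n_base] = advance(sim_params, st.final_state, n_base, base_rng)
        origin[:n_base] = -1
        pos = n_base

    used = sorted(counts)
    if used:
        seeds = [np.random.SeedSequence((spec.seed, int(j))) for j in used]
        rngs = [np.random.default_rng(sd) for sd in seeds]
        states = simulate_batch(
            sim_params, config=config, seeds=rngs, init=x0, ko_genes=used
        )
        for j, st, rg in zip(used, states, rngs):
            c = counts[j]
            ko_params = _with_row_zeroed(sim_params, j)
            cells[pos : pos + c] = advance(ko_params, st.final_state, c, rg)
            origin[pos : pos + c] = j
            pos += c
    assert pos == spec.n_cells
    return cells, origin


def _with_row_zeroed(params: ExpressionParams, gene: int) -> ExpressionParams:
    beta = params.beta.copy()
    lo, hi = beta.indptr[gene], beta.indptr[gene + 1]
    if hi > lo:
        beta.data[lo:hi] = 0.0
        beta.eliminate_zeros()
    return ExpressionParams(
        alpha=params.alpha, ell=params.ell, beta=beta, s=params.s, dt=params.dt
    )


def znormalize(matrix: np.ndarray) -> np.ndarray:
    """Scale each gene (column) to zero mean, unit variance across cells.

    Zero-variance genes map to all-zero columns.
    """
    matrix = np.asarray(matrix, dtype=float)
    if matrix.shape[0] < 2:
        raise ValueError("need at least 2 cells")
    mean = matrix.mean(axis=0)
    sd = matrix.std(axis=0)
    out = matrix - mean
    nz = sd > 0
    out[:, nz] /= sd[nz]
    out[:, ~nz] = 0.0
    return out


def truncated_svd(matrix: np.ndarray, n_components: int = 200, seed: int = 0):
    """Top singular triplets of a cell x gene matrix (X ~ U S V^T).

    Uses scikit-learn's randomized TruncatedSVD; singular values come out
    non-increasing and the rank-k product is the best rank-k approximation.
    """
    from sklearn.decomposition import TruncatedSVD

    matrix = np.asarray(matrix, dtype=float)
    if n_components > min(matrix.shape):
        raise ValueError("n_components exceeds matrix rank bound")
    if n_components == min(matrix.shape):
        # randomized solver requires strictly fewer components than features
        U_full, S_full, Vt_full = np.linalg.svd(matrix, full_matrices=False)
        return U_full[:, :n_components], S_full[:n_components], Vt_full[:n_components].T
    svd = TruncatedSVD(n_components=n_components, algorithm="randomized",
                       n_iter=7, random_state=seed)
    US = svd.fit_transform(matrix)
    S = svd.singular_values_.copy()
    V = svd.components_.T.copy()
    with np.errstate(divide="ignore", invalid="ignore"):
        U = np.where(S > 0, US / S, 0.0)
    return U, S, V


def define_programs(V: np.ndarray, program_size: int = 100) -> ProgramSet:
    """One program per gene singular vector: top squared loadings.

    Ties are broken deterministically toward the smaller gene index.
    """
    V = np.asarray(V, dtype=float)
    n_genes, k = V.shape
    size = min(program_size, n_genes)
    programs = []
    for c in range(k):
        order = np.argsort(-(V[:, c] ** 2), kind="stable")
        programs.append(np.sort(order[:size]))
    # column norms of V (singular values unknown here)
    return ProgramSet(
        gene_singular_vectors=V,
        singular_values=np.linalg.norm(V, axis=0),
        programs=programs,
        program_size=size,
    )


def program_overlap(reference: ProgramSet, other: ProgramSet) -> np.ndarray:
    """Max overlap count of each reference program with any other program."""
    n = reference.gene_singular_vectors.shape[0]
    if n != other.gene_singular_vectors.shape[0]:
        raise ValueError("program sets must share a gene universe")
    ref = np.zeros((len(reference.programs), n), dtype=bool)
    for i, p in enumerate(reference.programs):
        ref[i, p] = True
    oth = np.zeros((len(other.programs), n), dtype=bool)
    for j, p in enumerate(other.programs):
        oth[j, p] = True
    counts = ref.astype(np.int32) @ oth.T.astype(np.int32)
    return counts.max(axis=1)


def cca(V: np.ndarray, V_prime: np.ndarray, n_components: int | None = None) -> np.ndarray:
    """Canonical correlations between two gene-loading matrices.

    Both inputs are orthonormalized (QR) so whitening is the identity and
    the canonical correlations are the singular values of ``Q^T Q'``,
    non-increasing in [0, 1].
    """
    V = np.asarray(V, dtype=float)
    V_prime = np.asarray(V_prime, dtype=float)
    if V.shape[0] != V_prime.shape[0]:
        raise ValueError("gene dimensions differ")
    Q, _ = np.linalg.qr(V)
    Qp, _ = np.linalg.qr(V_prime)
    svals = np.linalg.svd(Q.T @ Qp, compute_uv=False)
    svals = np.clip(svals, 0.0, 1.0)
    if n_components is not None:
        svals = svals[:n_components]
    return svals
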
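"""In-silico knockout screens and effect summaries.

A knockout of gene *j* nullifies its outgoing regulatory effects (row *j*
of the weight matrix), the system is re-equilibrated from the baseline
steady state under the usual burn-in/convergence protocol, and the effect
on every other gene *i* is the log2 fold-change of steady-state means:

    log2FC_ji = log2( xbar_i | do x_j = 0 ) - log2( xbar_i )

Genes whose baseline expression is at or below the noise magnitude ``s``
are excluded from all summaries (their measured expression is dominated by
noise).  Effect magnitudes are taken as ``|log2FC|``: knocking out an
activator produces negative fold-changes that plainly count as effects.

Hub statistics follow the screen-wide definitions: a *hub KO* changes at
least ``count_thresh`` other expressed genes by more than ``effect_thresh``
in absolute log2 fold-change; a *hub target* is so changed by at least
``count_thresh`` knockouts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exprmodel import (
    ExpressionParams,
    SimConfig,
    SteadyState,
    advance,
    simulate_batch,
)

__all__ = [
    "PerturbationResult",
    "HubSummary",
    "CoexpressionSample",
    "EffectStrata",
    "knockout",
    "knockout_screen",
    "hub_counts",
    "stratify_effects",
    "sample_cells",
    "coexpression",
]


@dataclass
class PerturbationResult:
    """Gene x gene log2 fold-change matrix from a knockout screen.

    ``log2fc[r, i]`` is the effect of knocking out ``ko_genes[r]`` on gene
    *i*.  The diagonal (self-effects) and columns of genes not expressed at
    baseline are NaN; summaries are computed over the remaining entries.
    """

    log2fc: np.ndarray
    baseline: SteadyState
    expressed_mask: np.ndarray
    converged_per_ko: np.ndarray
    ko_genes: np.ndarray

    @property
    def n_genes(self) -> int:
        return self.log2fc.shape[1]

    def valid_mask(self) -> np.ndarray:
        """Boolean (n_ko, n) mask of pairs entering summaries.

        Requires the knocked-out gene and the target gene both expressed at
        baseline, and excludes self-pairs.
        """
        m = self.expressed_mask[self.ko_genes][:, None] & self.expressed_mask[None, :]
        m = m.copy()
        m[np.arange(len(self.ko_genes)), self.ko_genes] = False
        return m


@dataclass(frozen=True)
class HubSummary:
    n_hub_ko: int
    n_hub_target: int
    n_expressed: int
    effect_thresh: float = 0.1
    count_thresh: int = 100


@dataclass
class CoexpressionSample:
    """Cell x gene expression matrix with per-cell condition labels."""

    cells: np.ndarray
    origin: np.ndarray


@dataclass
class EffectStrata:
    """Knockout-effect magnitudes partitioned by network context."""

    by_distance: dict  # shortest-path distance -> array of |log2FC|
    fraction_above_by_distance: dict
    within_group: np.ndarray
    across_group: np.ndarray
    direct: np.ndarray  # pairs with an edge j -> i (distance 1)
    mediated: np.ndarray  # pairs without a direct edge
    threshold: float


def knockout(params: ExpressionParams, gene: int) -> ExpressionParams:
    """Copy of ``params`` with gene's outgoing weights (beta row) zeroed."""
    n = params.n_genes
    if not (0 <= gene < n):
        raise IndexError(f"gene {gene} out of range for n={n}")
    beta = params.beta.copy()
    lo, hi = beta.indptr[gene], beta.indptr[gene + 1]
    if hi > lo:
        beta.data[lo:hi] = 0.0
        beta.eliminate_zeros()
    return ExpressionParams(
        alpha=params.alpha.copy(), ell=params.ell.copy(), beta=beta,
        s=params.s, dt=params.dt,
    )


def knockout_screen(
    params: ExpressionParams,
    baseline: SteadyState,
    config: SimConfig = SimConfig(),
    seed: int = 0,
    genes=None,
    chunk_size: int = 1024,
) -> PerturbationResult:
    """Knock out each gene in turn and re-equilibrate from baseline.

    Each knockout condition gets its own RNG stream derived from
    ``(seed, gene)``, so screens are reproducible and independent of
    batching.  Post-knockout means are floored at machine epsilon before
    taking log2 (the expressed-gene filter keeps baseline means well above
    it).  Per-knockout non-convergence is recorded, not fatal.
    """
    n = params.n_genes
    genes = np.arange(n) if genes is None else np.asarray(genes, dtype=int)
    base = np.asarray(baseline.xbar, dtype=float)
    expressed = base > params.s
    eps = np.finfo(float).eps

    log2fc = np.full((len(genes), n), np.nan)
    converged = np.zeros(len(genes), dtype=bool)
    log_base = np.log2(np.maximum(base, eps))

    for start in range(0, len(genes), chunk_size):
        chunk = genes[start : start + chunk_size]
        seeds = [np.random.SeedSequence((seed, int(j))) for j in chunk]
        states = simulate_batch(
            params, config=config, seeds=seeds, init=base, ko_genes=chunk
        )
        for r, (j, ss) in enumerate(zip(chunk, states), start=start):
            row = np.log2(np.maximum(ss.xbar, eps)) - log_base
            row[~expressed] = np.nan
            row[j] = np.nan
            log2fc[r] = row
            converged[r] = ss.converged

    return PerturbationResult(
        log2fc=log2fc,
        baseline=baseline,
        expressed_mask=expressed,
        converged_per_ko=converged,
        ko_genes=genes,
    )


def hub_counts(
    result: PerturbationResult,
    effect_thresh: float = 0.1,
    count_thresh: int = 100,
) -> HubSummary:
    """Count hub knockouts and hub targets at the stated thresholds."""
    valid = result.valid_mask()
    exceed = np.zeros_like(valid)
    with np.errstate(invalid="ignore"):
        exceed[valid] = np.abs(result.log2fc[valid]) > effect_thresh
    n_hub_ko = int(np.sum(exceed.sum(axis=1) >= count_thresh))
    n_hub_target = int(np.sum(exceed.sum(axis=0) >= count_thresh))
    return HubSummary(
        n_hub_ko=n_hub_ko,
        n_hub_target=n_hub_target,
        n_expressed=int(result.expressed_mask.sum()),
        effect_thresh=effect_thresh,
        count_thresh=count_thresh,
    )


def stratify_effects(
    result: PerturbationResult,
    distances: np.ndarray,
    groups: np.ndarray,
    threshold: float = 0.01,
) -> EffectStrata:
    """Partition effect magnitudes by network distance and group identity.

    Every valid ordered pair lands in exactly one distance stratum
    (including infinity for unreachable pairs).  Direct pairs are those at
    distance 1 (an edge j -> i exists); mediated pairs have no direct edge.
    """
    valid = result.valid_mask()
    mag = np.abs(result.log2fc)
    d = np.asarray(distances, dtype=float)[result.ko_genes, :]
    g_src = np.asarray(groups)[result.ko_genes][:, None]
    g_tgt = np.asarray(groups)[None, :]

    by_distance: dict = {}
    frac: dict = {}
    dvals = np.unique(d[valid])
    for dv in dvals:
        sel = valid & (d == dv)
        vals = mag[sel]
        key = float(dv) if np.isinf(dv) else int(dv)
        by_distance[key] = vals
        frac[key] = float(np.mean(vals > threshold)) if len(vals) else np.nan

    same = g_src == g_tgt
    within = mag[valid & same]
    across = mag[valid & ~same]
    direct = mag[valid & (d == 1)]
    mediated = mag[valid & (d != 1)]
    return EffectStrata(
        by_distance=by_distance,
        fraction_above_by_distance=frac,
        within_group=within,
        across_group=across,
        direct=direct,
        mediated=mediated,
        threshold=threshold,
    )


def sample_cells(
    params: ExpressionParams,
    baseline: SteadyState,
    n_steps: int = 10000,
    seed: int = 0,
    label="baseline",
) -> CoexpressionSample:
    """Record one "cell" per forward step from the baseline steady state.

    The intrinsic noise of the model provides the cell-to-cell variability;
    lowly expressed genes are deliberately not filtered.
    """
    rng = np.random.default_rng(seed)
    x0 = np.asarray(baseline.xbar, dtype=float)
    cells = advance(params, x0, n_steps, rng)
    return CoexpressionSample(cells=cells, origin=np.array([label] * n_steps, dtype=object))


def coexpression(sample: CoexpressionSample) -> np.ndarray:
    """Pearson correlation of expression between genes across cells.

    Zero-variance genes get NaN rows/columns (correlation undefined); the
    diagonal is 1 for genes with nonzero variance.
    """
    cells = np.asarray(sample.cells, dtype=float)
    if cells.shape[0] < 2:
        raise ValueError("need at least 2 cells to compute coexpression")
    centered = cells - cells.mean(axis=0)
    sd = cells.std(axis=0)
    cov = centered.T @ centered / cells.shape[0]
    with np.errstate(divide="ignore", invalid="ignore"):
        corr = cov / np.outer(sd, sd)
    corr[sd == 0, :] = np.nan
    corr[:, sd == 0] = np.nan
    ok = sd > 0
    corr[np.diag_indices_from(corr)] = np.where(ok, 1.0, np.nan)
    return corr
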
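"""Matching simulated knockout screens to genome-scale Perturb-seq data.

The comparison statistic is the per-gene *effect fraction*: for each gene,
the fraction of the analyzed network it affects when perturbed (outgoing)
and the fraction of perturbations that affect it (incoming).  Real data
supply a perturbation x gene table of FDR-corrected Anderson–Darling
p-values thresholded at 0.05; simulated screens are thresholded at the top
3.16% of absolute log2 fold-changes so that the discovery rate matches the
empirical significance rate of the experimental table.  Distributions are
compared with the two-sample Kolmogorov–Smirnov test, and networks are
ranked by KS p-value against both the outgoing and incoming distributions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "EffectFractionDistributions",
    "MatchReport",
    "ExternalDataUnavailableError",
    "load_pairwise_pvalues",
    "effect_fractions_from_pvalues",
    "effect_fractions_from_screen",
    "ks_compare",
    "rank_best_matches",
]

#: empirical significance rate of the reference Perturb-seq table at
#: FDR-corrected p < 0.05; simulated screens are thresholded to match it
DEFAULT_SIGNIFICANCE_RATE = 0.0316


class ExternalDataUnavailableError(FileNotFoundError):
    """The optional external p-value table is not present."""


@dataclass
class EffectFractionDistributions:
    """Per-gene incoming/outgoing significant-effect fractions."""

    outgoing: np.ndarray
    incoming: np.ndarray
    n_analyzed: int

    def __post_init__(self) -> None:
        for arr in (self.outgoing, self.incoming):
            if len(arr) and (np.nanmin(arr) < 0 or np.nanmax(arr) > 1):
                raise ValueError("effect fractions must lie in [0, 1]")


@dataclass
class MatchReport:
    """Per-network KS comparison against a reference distribution pair."""

    ks_stat_outgoing: np.ndarray
    ks_p_outgoing: np.ndarray
    ks_stat_incoming: np.ndarray
    ks_p_incoming: np.ndarray
    rank_outgoing: np.ndarray  # 1 = largest p-value (best match)
    rank_incoming: np.ndarray
    selected: np.ndarray  # boolean best-match flags
    r: int  # smallest rank such that >= k networks are in the top r of both


def load_pairwise_pvalues(path, alpha: float = 0.05) -> pd.DataFrame:
    """Load a perturbation x gene FDR-corrected p-value table (gzip CSV).

    Rows are perturbations and columns measured genes, both keyed by
    ENSEMBL gene identifiers; row keys may carry suffixes after the gene id
    (e.g. guide annotations), which are stripped at matching time.  The
    table is restricted to perturbations targeting a primary transcript of
    a measured gene; when several perturbations hit one gene, the one with
    a significant effect on its own target transcript is kept (first such,
    else the first seen).  Expression-level filtering is assumed to have
    been applied upstream by the data provider.
    """
    import os

    if not os.path.exists(path):
        raise ExternalDataUnavailableError(
            f"external data unavailable: {path} (optional Perturb-seq table)"
        )
    table = pd.read_csv(path, index_col=0)
    table.columns = [c.split(".")[0] for c in table.columns]
    targets = pd.Index([str(r).split("_")[0].split(".")[0] for r in table.index])

    measured = set(table.columns)
    keep = targets.isin(measured)
    n_unmatched = int((~keep).sum())
    if n_unmatched:
        warnings.warn(
            f"dropped {n_unmatched} perturbations without a measured target gene"
        )
    table = table.loc[keep]
    targets = targets[keep]
    if table.empty:
        warnings.warn("no perturbations matched measured genes; empty table")
        table.index = targets
        return table

    # resolve duplicate targets: prefer a significant self-effect
    order = np.arange(len(table))
    chosen = []
    for gene, idx in pd.Series(order, index=targets).groupby(level=0):
        rows = idx.to_numpy()
        if len(rows) == 1:
            chosen.append(rows[0])
            continue
        self_p = table.iloc[rows][gene].to_numpy(dtype=float)
        sig = np.flatnonzero(self_p < alpha)
        chosen.append(rows[sig[0]] if len(sig) else rows[0])
        warnings.warn(
            f"target {gene} hit by {len(rows)} perturbations; kept one"
        )
    chosen = sorted(chosen)
    table = table.iloc[chosen]
    table.index = targets[chosen]
    return table


def effect_fractions_from_pvalues(
    table: pd.DataFrame, alpha: float = 0.05
) -> EffectFractionDistributions:
    """Per-gene effect fractions from a thresholded p-value table.

    The analyzed set is the intersection of perturbed and measured genes;
    fractions are counts of significant pairs (self excluded) over its size.
    """
    genes = [g for g in table.index if g in set(table.columns)]
    sq = table.loc[genes, genes].to_numpy(dtype=float)
    n = len(genes)
    if n == 0:
        return EffectFractionDistributions(
            outgoing=np.empty(0), incoming=np.empty(0), n_analyzed=0
        )
    sig = sq < alpha
    np.fill_diagonal(sig, False)
    return EffectFractionDistributions(
        outgoing=sig.sum(axis=1) / n,
        incoming=sig.sum(axis=0) / n,
        n_analyzed=n,
    )


def effect_fractions_from_screen(
    result, significance_rate: float = DEFAULT_SIGNIFICANCE_RATE
) -> EffectFractionDistributions:
    """Per-gene effect fractions from a simulated knockout screen.

    The significance threshold is the (1 - rate) quantile of pooled
    |log2FC| over valid expressed-gene pairs, so the discovery rate equals
    ``significance_rate`` up to one pair's resolution; pairs strictly above
    the order statistic are called significant.
    """
    valid = result.valid_mask()
    mag = np.abs(result.log2fc)
    vals = mag[valid]
    if len(vals) == 0:
        raise ValueError("screen has no valid expressed-gene pairs")
    if significance_rate >= 1.0:
        thresh = -np.inf
    else:
        thresh = float(np.quantile(vals, 1.0 - significance_rate))
    with np.errstate(invalid="ignore"):
        sig = (mag > thresh) & valid
    n = int(result.expressed_mask.sum())
    expressed_rows = result.expressed_mask[result.ko_genes]
    return EffectFractionDistributions(
        outgoing=sig.sum(axis=1)[expressed_rows] / n,
        incoming=sig.sum(axis=0)[result.expressed_mask] / n,
        n_analyzed=n,
    )


def ks_compare(sample_a, sample_b, method: str = "auto") -> dict:
    """Two-sample Kolmogorov–Smirnov test (max ECDF difference)."""
    sample_a = np.asarray(sample_a, dtype=float)
    sample_b = np.asarray(sample_b, dtype=float)
    if len(sample_a) == 0 or len(sample_b) == 0:
        raise ValueError("KS comparison requires nonempty samples")
    res = stats.ks_2samp(sample_a, sample_b, method=method)
    return {"statistic": float(res.statistic), "p_value": float(res.pvalue)}


def rank_best_matches(
    data: EffectFractionDistributions,
    simulated: list[EffectFractionDistributions],
    k_select: int = 1,
    method: str = "auto",
) -> MatchReport:
    """Rank simulated networks by KS similarity to the data distributions.

    Networks are ranked by descending KS p-value separately for the
    outgoing and incoming distributions (ties broken by network index);
    the selected set consists of networks within rank ``r`` on both, with
    ``r`` the smallest value giving at least ``k_select`` members.
    """
    n_net = len(simulated)
    if not (1 <= k_select <= n_net):
        raise ValueError("k_select must be in [1, number of networks]")
    stat_out = np.empty(n_net)
    p_out = np.empty(n_net)
    stat_in = np.empty(n_net)
    p_in = np.empty(n_net)
    for i, sim in enumerate(simulated):
        res = ks_compare(sim.outgoing, data.outgoing, method=method)
        stat_out[i], p_out[i] = res["statistic"], res["p_value"]
        res = ks_compare(sim.incoming, data.incoming, method=method)
        stat_in[i], p_in[i] = res["statistic"], res["p_value"]

    def ranks_desc(p):
        order = np.argsort(-p, kind="stable")  # ties -> lower network index first
        rk = np.empty(n_net, dtype=int)
        rk[order] = np.arange(1, n_net + 1)
        return rk

    rank_out = ranks_desc(p_out)
    rank_in = ranks_desc(p_in)
    for r in range(1, n_net + 1):
        selected = (rank_out <= r) & (rank_in <= r)
        if selected.sum() >= k_select:
            break
    return MatchReport(
        ks_stat_outgoing=stat_out,
        ks_p_outgoing=p_out,
        ks_stat_incoming=stat_in,
        ks_p_incoming=p_in,
        rank_outgoing=rank_out,
        rank_incoming=rank_in,
        selected=selected,
        r=int(r),
    )
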
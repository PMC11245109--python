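"""Edge recovery from pairwise statistics, and hub-fraction regression.

Two descriptive pairwise statistics — absolute knockout effect |log2FC|
and Pearson coexpression across cells — are joined with ground truth
(edges, |beta| weights, shortest-path distance) into one row per ordered
gene pair.  Enrichment of true edges among top-ranked pairs and Spearman
rank correlations quantify how well each statistic retrieves structure.

Across many networks, the fraction of expressed genes that are hub
knockouts (or hub targets) is regressed, after an empirical logit
transform, on the generating parameters [1, 1/p, k', w, delta_in,
delta_out], where k' recodes k = 1 (dissolved groups) as k = n since both
describe the absence of usable group structure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "RegressionReport",
    "build_pair_table",
    "edge_enrichment",
    "rank_correlations",
    "hub_fraction_regression",
]


@dataclass
class RegressionReport:
    response: str
    params: pd.Series
    pvalues: pd.Series
    r_squared: float
    n_obs: int

    def summary_text(self) -> str:
        lines = [f"OLS for {self.response} (r^2 = {self.r_squared:.3f}, n = {self.n_obs})"]
        for name in self.params.index:
            lines.append(
                f"  {name:>10s}  coef = {self.params[name]: .4g}   p = {self.pvalues[name]:.3g}"
            )
        return "\n".join(lines)


def build_pair_table(graph, params, result, coexpr: np.ndarray) -> pd.DataFrame:
    """One row per ordered gene pair (regulator, target), regulator != target.

    Columns: ``has_edge``, ``weight`` (|beta_ji|, 0 off edges),
    ``log2fc_abs``, ``coexpression``, ``distance``.
    """
    n = graph.n_nodes
    if params.n_genes != n or result.n_genes != n or coexpr.shape != (n, n):
        raise ValueError("inputs must all describe the same network")
    from .netgen import shortest_path_distances

    dist = shortest_path_distances(graph)
    adj = graph.adjacency().toarray().astype(bool)
    beta_abs = np.abs(params.beta.toarray())

    # align screen rows (ko order) onto a full n x n magnitude matrix
    mag = np.full((n, n), np.nan)
    mag[result.ko_genes, :] = np.abs(result.log2fc)

    j_idx, i_idx = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
    off = j_idx != i_idx
    return pd.DataFrame(
        {
            "regulator": j_idx[off],
            "target": i_idx[off],
            "has_edge": adj[off],
            "weight": beta_abs[off],
            "log2fc_abs": mag[off],
            "coexpression": coexpr[off],
            "distance": dist[off],
        }
    )


def edge_enrichment(table: pd.DataFrame, statistic: str, top_quantile: float = 0.05) -> float:
    """Fold enrichment of true edges among top-|statistic| pairs.

    (edge fraction among the top ``top_quantile`` of pairs ranked by the
    absolute statistic) / (overall edge fraction).
    """
    if not (0 < top_quantile <= 1):
        raise ValueError("top_quantile must be in (0, 1]")
    vals = table[statistic].abs()
    ok = vals.notna()
    vals = vals[ok]
    edges = table.loc[ok, "has_edge"]
    if len(vals) == 0:
        raise ValueError("no usable pairs")
    cutoff = vals.quantile(1.0 - top_quantile)
    top = vals >= cutoff
    if top.sum() == 0:
        raise ValueError("empty top quantile")
    overall = edges.mean()
    if overall == 0:
        raise ValueError("table contains no edges")
    return float(edges[top].mean() / overall)


def rank_correlations(table: pd.DataFrame) -> dict:
    """Spearman rank correlations between pair statistics.

    Returns effect-vs-weight and coexpression-vs-weight on edge pairs, and
    coexpression-vs-effect over all pairs and on edge pairs.
    """
    def rho(a, b):
        ok = a.notna() & b.notna()
        if ok.sum() < 2:
            raise ValueError("subset smaller than 2 pairs")
        return float(stats.spearmanr(a[ok], b[ok]).statistic)

    edge = table[table["has_edge"]]
    return {
        "log2fc_vs_weight_edges": rho(edge["log2fc_abs"], edge["weight"]),
        "coexpr_vs_weight_edges": rho(edge["coexpression"].abs(), edge["weight"]),
        "coexpr_vs_log2fc_all": rho(table["coexpression"].abs(), table["log2fc_abs"]),
        "coexpr_vs_log2fc_edges": rho(edge["coexpression"].abs(), edge["log2fc_abs"]),
    }


def _empirical_logit(count: np.ndarray, n: np.ndarray) -> np.ndarray:
    # pseudo-count fix keeps boundary fractions (0 or n) finite
    frac = (count + 0.5) / (n + 1.0)
    return np.log(frac / (1.0 - frac))


def hub_fraction_regression(
    summaries, graph_params, n_genes_for_k1: int | None = None
) -> dict:
    """OLS of logit hub fractions on the generating parameters.

    Parameters
    ----------
    summaries : list of HubSummary
        One per network, aligned with ``graph_params``.
    graph_params : list of GraphParams
    n_genes_for_k1 : int, optional
        Recode value for k = 1 networks (defaults to each network's n).

    Returns ``{"hub_ko": RegressionReport, "hub_target": RegressionReport}``
    with hub counts divided by expressed-gene counts before the empirical
    logit transform.
    """
    import statsmodels.api as sm

    if len(summaries) != len(graph_params):
        raise ValueError("one summary per parameter set required")
    rows = []
    for s, gp in zip(summaries, graph_params):
        kprime = (n_genes_for_k1 or gp.n) if gp.k == 1 else gp.k
        rows.append(
            {
                "inv_p": 1.0 / gp.p,
                "k_prime": float(kprime),
                "w": float(gp.w),
                "delta_in": float(gp.delta_in),
                "delta_out": float(gp.delta_out),
                "n_hub_ko": s.n_hub_ko,
                "n_hub_target": s.n_hub_target,
                "n_expressed": s.n_expressed,
            }
        )
    df = pd.DataFrame(rows)
    X = sm.add_constant(df[["inv_p", "k_prime", "w", "delta_in", "delta_out"]])
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise ValueError("design matrix is rank deficient "
                         "(need >= 2 distinct values per regressor)")
    out = {}
    for resp, col in (("hub_ko", "n_hub_ko"), ("hub_target", "n_hub_target")):
        y = _empirical_logit(df[col].to_numpy(float), df["n_expressed"].to_numpy(float))
        fit = sm.OLS(y, X).fit()
        out[resp] = RegressionReport(
            response=resp,
            params=fit.params,
            pvalues=fit.pvalues,
            r_squared=float(fit.rsquared),
            n_obs=int(fit.nobs),
        )
    return out
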
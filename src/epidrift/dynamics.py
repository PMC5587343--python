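"""Methylation drift dynamics: per-probe slopes, ranking, variability.

Methylation measured over many passages is summarized per probe by the
slope of an ordinary least-squares fit of beta against passage number — a
direct estimate of methylation change per passage in culture.  Slopes near
zero mean stable methylation; strongly positive slopes mark progressive
hypermethylation.  Probes are then ranked genome-wide (gene-linked probes
only) and candidate-gene island probes checked against the top percentile.
A separate ranking orders probes by cross-sample variance, since genes
under drift are expected to be among the most variable in both expression
and methylation.
"""
from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats as sps

from .concordance import hypergeom_overlap_pvalue
from .types import BetaMatrix, ExprMatrix, ProbeAnnotation, SampleTable

logger = logging.getLogger(__name__)


def fit_methylation_slopes(
    beta: BetaMatrix,
    samples: SampleTable,
    ann: ProbeAnnotation,
) -> pd.DataFrame:
    """OLS slope of beta vs passage for every probe, NaNs excluded pairwise.

    Returns a DataFrame indexed by probe_id with ``gene, slope, intercept,
    n_samples, in_cpg_island``.  Requires >= 3 distinct passage values.
    """
    shared = [s for s in beta.data.columns if s in samples.data.index]
    if not shared:
        raise ValueError("no samples shared between beta matrix and sample table")
    x = samples.data.loc[shared, "passage"].to_numpy(dtype=float)
    if len(np.unique(x)) < 3:
        raise ValueError("need >= 3 distinct passage values for regression")
    y = beta.data[shared].to_numpy()

    mask = np.isfinite(y)
    n = mask.sum(axis=1)
    xm = np.where(mask, x[None, :], 0.0)
    ym = np.where(mask, y, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        sx, sy = xm.sum(1), ym.sum(1)
        sxx = (xm * xm).sum(1)
        sxy = (xm * ym).sum(1)
        denom = sxx - sx**2 / n
        slope = (sxy - sx * sy / n) / denom
        intercept = sy / n - slope * sx / n
    bad = (n < 3) | ~np.isfinite(slope)
    slope[bad] = np.nan
    intercept[bad] = np.nan

    ann_sub = ann.data.reindex(beta.data.index)
    out = pd.DataFrame(
        {
            "gene": ann_sub["gene"].fillna(""),
            "slope": slope,
            "intercept": intercept,
            "n_samples": n,
            "in_cpg_island": ann_sub["in_cpg_island"].fillna(False).astype(bool),
        },
        index=beta.data.index,
    )
    logger.info("fit_methylation_slopes: %d probes, %d evaluable", len(out), int((~bad).sum()))
    return out


def rank_slopes(
    records: pd.DataFrame,
    candidate_genes: set[str] | None = None,
    top_percent: float = 1.0,
) -> tuple[pd.DataFrame, dict]:
    """Rank gene-linked probes by descending slope.

    ``rank`` is ordinal (1 = most positive slope; ties broken by probe_id
    for determinism); ``percentile`` uses competition ranking so tied
    slopes share a percentile.  ``top_flag`` marks probes within the top
    ``top_percent`` of the distribution.  The summary reports a slope
    histogram and, when ``candidate_genes`` is given, an island vs
    non-island contrast of the candidates' probes (island probes are the
    ones expected to drift; non-island probes should be relatively
    stable).
    """
    if records.empty:
        raise ValueError("no slope records to rank")
    uni = records[(records["gene"] != "") & records["slope"].notna()].copy()
    n_uni = len(uni)
    if n_uni == 0:
        raise ValueError("no gene-linked probes with a fitted slope")
    order = (
        uni.assign(_pid=uni.index)
        .sort_values("_pid", kind="mergesort")
        .sort_values("slope", ascending=False, kind="mergesort")
    )
    rank = pd.Series(np.arange(1, n_uni + 1), index=order.index)
    comp = pd.Series(
        sps.rankdata(-uni["slope"].to_numpy(), method="min"), index=uni.index
    )
    uni["rank"] = rank.reindex(uni.index).astype(int)
    uni["percentile"] = 100.0 * comp / n_uni
    uni["top_flag"] = uni["percentile"] <= top_percent

    counts, edges = np.histogram(uni["slope"].to_numpy(), bins=50)
    summary: dict = {
        "universe_size": n_uni,
        "histogram": {"counts": counts.tolist(), "bin_edges": edges.tolist()},
    }
    if candidate_genes is not None:
        cand = uni[uni["gene"].isin(candidate_genes)]
        isl = cand[cand["in_cpg_island"]]
        non = cand[~cand["in_cpg_island"]]
        summary["candidates"] = {
            "island_probes": len(isl),
            "island_top_fraction": float(isl["top_flag"].mean()) if len(isl) else None,
            "island_mean_slope": float(isl["slope"].mean()) if len(isl) else None,
            "non_island_probes": len(non),
            "non_island_top_fraction": float(non["top_flag"].mean()) if len(non) else None,
            "non_island_mean_slope": float(non["slope"].mean()) if len(non) else None,
            "per_gene_top_fraction": {
                g: float(sub.loc[sub["in_cpg_island"], "top_flag"].mean())
                for g, sub in cand.groupby("gene")
                if sub["in_cpg_island"].any()
            },
        }
    return uni, summary


def _variance_rank(values: pd.Series) -> pd.DataFrame:
    """Descending variance rank with the same tie rules as slope ranking."""
    n = len(values)
    order = (
        values.rename("variance")
        .to_frame()
        .assign(_pid=values.index)
        .sort_values("_pid", kind="mergesort")
        .sort_values("variance", ascending=False, kind="mergesort")
    )
    rank = pd.Series(np.arange(1, n + 1), index=order.index)
    comp = pd.Series(sps.rankdata(-values.to_numpy(), method="min"), index=values.index)
    return pd.DataFrame(
        {
            "variance": values,
            "rank": rank.reindex(values.index).astype(int),
            "percentile": 100.0 * comp / n,
        }
    )


def variability_ranking(
    expr: ExprMatrix,
    beta: BetaMatrix,
    ann: ProbeAnnotation,
    island_only: bool = True,
    candidate_genes: set[str] | None = None,
    top_decile: float = 10.0,
) -> dict:
    """Rank probes by cross-sample variance in expression and methylation.

    Variance is the unbiased sample variance, computed on the log2 scale
    for expression and on raw beta for methylation (island probes only by
    default).  When ``candidate_genes`` is given, enrichment of candidate
    probes in the top decile is tested with a one-sided hypergeometric
    upper tail.
    """
    if expr.data.shape[1] < 3 or beta.data.shape[1] < 3:
        raise ValueError("need >= 3 samples for a variance ranking")
    gene_e = ann.data["gene"].reindex(expr.data.index).fillna("")
    gene_b = ann.data["gene"].reindex(beta.data.index).fillna("")
    expr_var = expr.data.var(axis=1, ddof=1)
    b = beta.data
    if island_only:
        island = ann.data["in_cpg_island"].reindex(b.index).fillna(False).astype(bool)
        b = b.loc[island[island].index]
        gene_b = gene_b.loc[b.index]
    beta_var = b.var(axis=1, ddof=1)

    expr_rank = _variance_rank(expr_var).assign(gene=gene_e)
    beta_rank = _variance_rank(beta_var).assign(gene=gene_b)

    out: dict = {"expression": expr_rank, "methylation": beta_rank}
    if candidate_genes is not None:
        enrich = {}
        for kind, table in (("expression", expr_rank), ("methylation", beta_rank)):
            top = table["percentile"] <= top_decile
            is_cand = table["gene"].isin(candidate_genes)
            overlap = int((top & is_cand).sum())
            enrich[kind] = {
                "candidate_probes": int(is_cand.sum()),
                "candidate_probes_in_top_decile": overlap,
                "p_value": hypergeom_overlap_pvalue(
                    overlap, len(table), int(is_cand.sum()), int(top.sum())
                ),
            }
        out["enrichment"] = enrich
    return out
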
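"""The hypermethylation/silencing screen.

Samples passing QC are split into low- and high-passage groups, and for
every gene-linked methylation probe three quantities are computed across
the groups:

* ``delta_beta`` — high-group aggregate beta minus low-group aggregate
  (group means by default; medians optional),
* ``expr_fold`` — ratio of group medians of *linear* (2^log2) expression,
  oriented so values > 1 mean lower expression at high passage,
* ``meth_expr_corr`` — Pearson correlation between the probe's beta and
  its gene's expression across all matched samples.

A probe is a candidate when ``delta_beta > delta_beta_cutoff`` *and*
``expr_fold > fold_cutoff`` (strict inequalities; defaults 0.2 and 1.5,
levels at which fewer than ~5% of probes move by chance on real arrays).
Candidate genes are genes with at least one candidate probe.  A separate
validation step tests candidate genes on an independent passage-annotated
expression compendium with per-probe Wilcoxon rank-sum tests under
Benjamini-Hochberg FDR control.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .types import (
    BetaMatrix,
    ExprMatrix,
    GroupAssignment,
    ProbeAnnotation,
    SampleTable,
)

logger = logging.getLogger(__name__)

MODES = ("strict", "permissive")


def assign_groups(samples: SampleTable, mode: str = "strict") -> GroupAssignment:
    """Label QC-passing samples as low/high passage.

    strict:      low = passage <= 25, high = passage >= 50 (rest excluded);
    permissive:  low = passage <= 25, high = passage > 25.
    Samples failing QC are excluded in either mode.
    """
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}")
    df = samples.data
    p = df["passage"]
    labels = pd.Series("excluded", index=df.index, dtype=object)
    labels[p <= 25] = "low"
    if mode == "strict":
        labels[p >= 50] = "high"
        labels[(p > 25) & (p < 50)] = "excluded"
    else:
        labels[p > 25] = "high"
    labels[~df["qc_pass"].astype(bool)] = "excluded"
    ga = GroupAssignment(mode=mode, labels=labels)
    counts = ga.counts()
    if counts["low"] == 0 or counts["high"] == 0:
        raise ValueError(f"empty passage group under mode={mode!r}: {counts}")
    logger.info("assign_groups(%s): %s", mode, counts)
    return ga


def _representative_expr_probe(expr: ExprMatrix, ann: ProbeAnnotation) -> pd.Series:
    """gene -> expression probe with the highest mean expression."""
    gene = ann.data["gene"].reindex(expr.data.index).fillna("")
    df = pd.DataFrame(
        {"gene": gene, "mean": expr.data.mean(axis=1), "probe": expr.data.index}
    )
    df = df[df["gene"] != ""]
    # stable sorts: mean ties broken by probe id for determinism
    df = df.sort_values("probe", kind="mergesort").sort_values(
        ["gene", "mean"], ascending=[True, False], kind="mergesort"
    )
    top = df.drop_duplicates("gene", keep="first")
    return pd.Series(top["probe"].to_numpy(), index=top["gene"].to_numpy())


def _nan_pearson_rows(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Row-wise Pearson correlation with pairwise NaN exclusion."""
    mask = np.isfinite(x) & np.isfinite(y)
    n = mask.sum(axis=1)
    xm = np.where(mask, x, 0.0)
    ym = np.where(mask, y, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        sx, sy = xm.sum(1), ym.sum(1)
        cov = (xm * ym).sum(1) - sx * sy / n
        vx = (xm * xm).sum(1) - sx**2 / n
        vy = (ym * ym).sum(1) - sy**2 / n
        r = cov / np.sqrt(vx * vy)
    r[(n < 3) | ~np.isfinite(r)] = np.nan
    return np.clip(r, -1.0, 1.0)


def screen_probes(
    beta: BetaMatrix,
    expr: ExprMatrix,
    ann: ProbeAnnotation,
    groups: GroupAssignment,
    delta_beta_cutoff: float = 0.2,
    fold_cutoff: float = 1.5,
    beta_aggregate: str = "mean",
    min_group_n: int = 3,
) -> pd.DataFrame:
    """Per-probe screen records.

    Returns a DataFrame indexed by methylation probe_id with columns
    ``gene, delta_beta, expr_fold, meth_expr_corr, quadrant, evaluable,
    candidate``.  ``quadrant`` labels the scatter corner the probe falls
    in (``hyper_down`` for hypermethylated/silenced, ``hypo_up`` for the
    mirror corner, ``other`` otherwise); only ``hyper_down`` probes
    passing both strict cutoffs are flagged candidates.  Probes with
    fewer than ``min_group_n`` usable samples per group are marked
    unevaluable.
    """
    if beta_aggregate not in ("mean", "median"):
        raise ValueError("beta_aggregate must be 'mean' or 'median'")
    rep = _representative_expr_probe(expr, ann)
    gene = ann.data["gene"].reindex(beta.data.index).fillna("")
    keep = gene.index[(gene != "") & gene.isin(rep.index)]
    b = beta.data.loc[keep]
    g = gene.loc[keep]

    low = [s for s in groups.low if s in b.columns and s in expr.data.columns]
    high = [s for s in groups.high if s in b.columns and s in expr.data.columns]
    if not low or not high:
        raise ValueError("no shared samples between matrices and groups")

    agg = getattr(np, f"nan{beta_aggregate}")
    with np.errstate(invalid="ignore"):
        blo = agg(b[low].to_numpy(), axis=1)
        bhi = agg(b[high].to_numpy(), axis=1)
    delta_beta = bhi - blo

    e = expr.data.loc[rep.loc[g].to_numpy()]
    lin = np.power(2.0, e.to_numpy())
    med_low = np.median(lin[:, [e.columns.get_loc(s) for s in low]], axis=1)
    med_high = np.median(lin[:, [e.columns.get_loc(s) for s in high]], axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        expr_fold = med_low / med_high

    both = low + high
    corr = _nan_pearson_rows(
        b[both].to_numpy(), e[both].to_numpy()
    )

    n_low = np.isfinite(b[low].to_numpy()).sum(axis=1)
    n_high = np.isfinite(b[high].to_numpy()).sum(axis=1)
    evaluable = (n_low >= min_group_n) & (n_high >= min_group_n)

    hyper_down = (delta_beta > delta_beta_cutoff) & (expr_fold > fold_cutoff)
    hypo_up = (-delta_beta > delta_beta_cutoff) & (1.0 / expr_fold > fold_cutoff)
    quadrant = np.where(hyper_down, "hyper_down", np.where(hypo_up, "hypo_up", "other"))
    candidate = hyper_down & evaluable

    out = pd.DataFrame(
        {
            "gene": g,
            "delta_beta": np.where(evaluable, delta_beta, np.nan),
            "expr_fold": np.where(evaluable, expr_fold, np.nan),
            "meth_expr_corr": corr,
            "quadrant": np.where(evaluable, quadrant, "unevaluable"),
            "evaluable": evaluable,
            "candidate": candidate,
        },
        index=b.index,
    ).sort_index()
    logger.info(
        "screen_probes: %d probes, %d candidates (%d genes)",
        len(out),
        int(out["candidate"].sum()),
        out.loc[out["candidate"], "gene"].nunique(),
    )
    return out


def candidate_gene_set(records: pd.DataFrame) -> tuple[set[str], dict]:
    """Genes with at least one candidate probe, with probe/gene counts."""
    cand = records[records["candidate"]]
    genes = set(cand["gene"])
    report = {
        "candidate_probes": int(len(cand)),
        "candidate_genes": len(genes),
        "probes_screened": int(records["evaluable"].sum()),
    }
    return genes, report


def validate_expression_compendium(
    expr: ExprMatrix,
    samples: SampleTable,
    genes: set[str],
    ann: ProbeAnnotation,
    mode: str = "permissive",
    alpha: float = 0.05,
    min_group_n: int = 3,
) -> tuple[pd.DataFrame, set[str]]:
    """Wilcoxon rank-sum validation of candidate genes on an expression compendium.

    For every expression probe of the candidate genes, a two-sided
    Wilcoxon rank-sum (Mann-Whitney) test compares low- vs high-passage
    samples; p-values are Benjamini-Hochberg corrected across the tested
    probes.  A gene is *validated* when at least one of its probes has
    q < ``alpha`` with a lower high-group mean.
    """
    groups = assign_groups(samples, mode=mode)
    low = [s for s in groups.low if s in expr.data.columns]
    high = [s for s in groups.high if s in expr.data.columns]
    gene = ann.data["gene"].reindex(expr.data.index).fillna("")
    probes = gene.index[gene.isin(genes)]
    rows = []
    for p in probes:
        x = expr.data.loc[p, low].to_numpy(dtype=float)
        y = expr.data.loc[p, high].to_numpy(dtype=float)
        x, y = x[np.isfinite(x)], y[np.isfinite(y)]
        if len(x) < min_group_n or len(y) < min_group_n:
            continue
        if np.ptp(np.concatenate([x, y])) == 0:
            pval = 1.0
        else:
            pval = float(stats.mannwhitneyu(x, y, alternative="two-sided").pvalue)
        rows.append(
            {
                "probe_id": p,
                "gene": gene[p],
                "mean_low": float(np.mean(x)),
                "mean_high": float(np.mean(y)),
                "p_value": pval,
            }
        )
    result = pd.DataFrame(
        rows, columns=["probe_id", "gene", "mean_low", "mean_high", "p_value"]
    ).set_index("probe_id")
    if len(result):
        result["q_value"] = multipletests(result["p_value"], method="fdr_bh")[1]
    else:
        result["q_value"] = pd.Series(dtype=float)
    hit = result[(result["q_value"] < alpha) & (result["mean_high"] < result["mean_low"])]
    validated = set(hit["gene"])
    logger.info(
        "validate_expression_compendium: %d/%d genes validated (q<%.3g)",
        len(validated),
        len(genes),
        alpha,
    )
    return result, validated
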
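"""Shared preprocessing: expression floor, beta range-scaling, probe filters.

These operations mirror standard array preprocessing for matched
methylation/expression screens: low-intensity expression values are raised
to a fixed detection floor, beta values are range-scaled against control
DNA of known methylation level, and probes on the sex chromosomes or on
genes unexpressed in almost all samples of both passage groups are removed
before any statistic is computed.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .types import (
    SEX_CHROMOSOMES,
    BetaMatrix,
    ControlBetas,
    ExprMatrix,
    GroupAssignment,
    ProbeAnnotation,
    SampleTable,
)

logger = logging.getLogger(__name__)


def apply_expression_floor(m: ExprMatrix, floor: float) -> ExprMatrix:
    """Raise every expression value below ``floor`` to ``floor``.

    The floor is a noise threshold: values at the floor are treated as
    "unexpressed" downstream.  Works equally for log2 microarray values and
    linear FPKM tables (e.g. floor 0.5 for RNA-seq); the scale is whatever
    the matrix carries.
    """
    if not np.isfinite(floor):
        raise ValueError("floor must be finite")
    data = m.data.clip(lower=floor)
    return ExprMatrix(data, floor=floor)


@dataclass
class RangeScaleReport:
    """Side information from :func:`range_scale_betas`."""

    unusable_probes: list[str] = field(default_factory=list)
    half_control_max_abs_deviation: float | None = None


def range_scale_betas(
    m: BetaMatrix,
    controls: ControlBetas,
    min_dynamic_range: float = 0.1,
) -> tuple[BetaMatrix, RangeScaleReport]:
    """Range-scale betas to unmethylated/fully-methylated control samples.

    ``beta' = (beta - u) / (f - u)`` clipped to [0, 1], where ``u`` and
    ``f`` are the control levels (scalar or per-probe).  Probes whose
    control dynamic range ``f - u`` falls below ``min_dynamic_range`` are
    flagged unusable and their values set to NaN.  When a half-methylated
    control is supplied its scaled level is reported (it should be near
    0.5); a deviation is reported, not an error.
    """
    probes = m.data.index

    def _per_probe(x) -> np.ndarray:
        if np.isscalar(x):
            return np.full(len(probes), float(x))
        return pd.Series(x).reindex(probes).to_numpy(dtype=float)

    u = _per_probe(controls.unmethylated)
    f = _per_probe(controls.fully_methylated)
    rng_ = f - u
    unusable = ~(rng_ >= min_dynamic_range)
    report = RangeScaleReport(unusable_probes=list(probes[unusable]))

    with np.errstate(invalid="ignore", divide="ignore"):
        scaled = (m.data.to_numpy() - u[:, None]) / rng_[:, None]
    scaled = np.clip(scaled, 0.0, 1.0)
    scaled[unusable, :] = np.nan

    if controls.half_methylated is not None:
        h = _per_probe(controls.half_methylated)
        with np.errstate(invalid="ignore", divide="ignore"):
            h_scaled = (h - u) / rng_
        ok = ~unusable & np.isfinite(h_scaled)
        if ok.any():
            report.half_control_max_abs_deviation = float(
                np.max(np.abs(h_scaled[ok] - 0.5))
            )

    out = BetaMatrix(pd.DataFrame(scaled, index=probes, columns=m.data.columns))
    if report.unusable_probes:
        logger.info(
            "range_scale_betas: %d probes below dynamic range %.3g",
            len(report.unusable_probes),
            min_dynamic_range,
        )
    return out, report


@dataclass
class FilterResult:
    beta: BetaMatrix
    expr: ExprMatrix
    report: dict


def filter_probes(
    beta: BetaMatrix,
    expr: ExprMatrix,
    ann: ProbeAnnotation,
    samples: SampleTable,
    groups: GroupAssignment,
    unexpressed_fraction: float = 0.80,
    max_missing_fraction: float = 0.50,
) -> FilterResult:
    """Remove sex-chromosome probes and genes unexpressed in both groups.

    A gene counts as unexpressed in a sample when all of its expression
    probes sit exactly at the declared floor; the gene (with all its
    methylation and expression probes) is dropped iff the unexpressed
    fraction exceeds ``unexpressed_fraction`` in *both* the low and the
    high group.  Methylation probes missing in more than
    ``max_missing_fraction`` of either group's samples are also dropped.
    The result is invariant to probe and sample order.
    """
    low = [s for s in groups.low if s in expr.data.columns]
    high = [s for s in groups.high if s in expr.data.columns]
    if not low or not high:
        raise ValueError("each passage group must contain at least one sample")
    if expr.floor is None:
        raise ValueError("expression floor must be applied before filtering")

    chrom = ann.data["chromosome"]
    sex_probes = set(chrom.index[chrom.isin(SEX_CHROMOSOMES)])
    n_sex_beta = len(sex_probes & set(beta.data.index))
    n_sex_expr = len(sex_probes & set(expr.data.index))

    beta_df = beta.data.drop(index=[p for p in beta.data.index if p in sex_probes])
    expr_df = expr.data.drop(index=[p for p in expr.data.index if p in sex_probes])

    gene_of = ann.data["gene"]
    # unexpressed fraction per expression probe, worst (lowest) per gene:
    # a gene is unexpressed in a sample when all its probes are at the floor
    at_floor = expr_df == expr.floor
    probe_gene = gene_of.reindex(expr_df.index).fillna("")
    gene_unexpr_low = (
        at_floor[low].groupby(probe_gene).all().mean(axis=1)
        if low
        else pd.Series(dtype=float)
    )
    gene_unexpr_high = at_floor[high].groupby(probe_gene).all().mean(axis=1)
    both = (gene_unexpr_low > unexpressed_fraction) & (
        gene_unexpr_high > unexpressed_fraction
    )
    dropped_genes = sorted(g for g in both.index[both] if g != "")

    keep_expr = ~probe_gene.isin(dropped_genes)
    expr_df = expr_df.loc[keep_expr]
    beta_gene = gene_of.reindex(beta_df.index).fillna("")
    beta_df = beta_df.loc[~beta_gene.isin(dropped_genes)]

    # missingness filter on methylation probes, per group
    low_b = [s for s in groups.low if s in beta_df.columns]
    high_b = [s for s in groups.high if s in beta_df.columns]
    n_missing_dropped = 0
    if low_b and high_b:
        miss_low = beta_df[low_b].isna().mean(axis=1)
        miss_high = beta_df[high_b].isna().mean(axis=1)
        too_missing = (miss_low > max_missing_fraction) | (
            miss_high > max_missing_fraction
        )
        n_missing_dropped = int(too_missing.sum())
        beta_df = beta_df.loc[~too_missing]

    report = {
        "sex_chromosome_probes_removed": {"beta": n_sex_beta, "expr": n_sex_expr},
        "unexpressed_genes_removed": len(dropped_genes),
        "unexpressed_gene_ids": dropped_genes,
        "high_missing_beta_probes_removed": n_missing_dropped,
        "beta_probes_retained": int(beta_df.shape[0]),
        "expr_probes_retained": int(expr_df.shape[0]),
    }
    logger.info("filter_probes: %s", {k: v for k, v in report.items() if k != "unexpressed_gene_ids"})
    return FilterResult(
        beta=BetaMatrix(beta_df.sort_index()),
        expr=ExprMatrix(expr_df.sort_index(), floor=expr.floor),
        report=report,
    )
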
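"""Validation-assay computations: knockdown DE filter and McrBC qPCR.

``de_filter`` reproduces a duplicate-vs-duplicate RNA-seq differential
expression rule on FPKM-like values: after flooring at a detection
threshold, a gene passes when the fold change between arm means exceeds 2
*and* each knockdown replicate individually shows a fold change above 1.5
over the controls, in a consistent direction.

``mcrbc_quantify`` scores methylation from McrBC-digestion qPCR: McrBC
cuts methylated-CpG DNA, so a methylated locus loses template in the
digested reaction and its Ct rises relative to the mock (undigested)
reaction.  delta-Ct = Ct(digested) - Ct(mock); each cycle is a twofold
template loss.  A digested reaction that fails to amplify while the mock
amplifies is itself evidence of full methylation.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


def de_filter(
    expr_kd: pd.DataFrame,
    expr_ctrl: pd.DataFrame,
    floor: float = 0.5,
    mean_fold_cutoff: float = 2.0,
    replicate_fold_cutoff: float = 1.5,
    replicate_mode: str = "vs_control_mean",
) -> pd.DataFrame:
    """Two-replicate differential-expression filter on linear expression.

    Parameters
    ----------
    expr_kd, expr_ctrl:
        Gene x replicate tables of linear (FPKM-like) values; same gene
        index, two (or more) replicates per arm.
    floor:
        Detection floor applied to every value first.
    replicate_mode:
        ``"vs_control_mean"`` (default): each knockdown replicate's fold
        is taken against the control-arm mean.  ``"each_vs_each"``: every
        knockdown replicate must clear the cutoff against every control
        replicate.

    Returns a DataFrame indexed by gene with ``mean_kd, mean_ctrl,
    mean_fold, min_replicate_fold, direction, passes``.  ``mean_fold`` is
    the larger arm mean over the smaller; ``direction`` is ``down`` when
    the knockdown arm is lower.  ``passes`` requires mean_fold >
    ``mean_fold_cutoff`` and every replicate fold > ``replicate_fold_cutoff``
    with all replicates on the same side of the comparison.
    """
    if replicate_mode not in ("vs_control_mean", "each_vs_each"):
        raise ValueError("unknown replicate_mode")
    if not expr_kd.index.equals(expr_ctrl.index):
        expr_ctrl = expr_ctrl.reindex(expr_kd.index)
        if expr_ctrl.isna().any().any():
            raise ValueError("knockdown and control tables must share gene index")
    kd = np.maximum(expr_kd.to_numpy(dtype=float), floor)
    ct = np.maximum(expr_ctrl.to_numpy(dtype=float), floor)
    mean_kd = kd.mean(axis=1)
    mean_ct = ct.mean(axis=1)
    down = mean_kd < mean_ct
    mean_fold = np.where(down, mean_ct / mean_kd, mean_kd / mean_ct)

    if replicate_mode == "vs_control_mean":
        # fold of each kd replicate vs the control mean, direction-consistent
        rep_fold = np.where(down[:, None], mean_ct[:, None] / kd, kd / mean_ct[:, None])
    else:
        ratio = ct[:, None, :] / kd[:, :, None]  # gene x kd_rep x ctrl_rep
        rep = np.where(down[:, None, None], ratio, 1.0 / ratio)
        rep_fold = rep.reshape(rep.shape[0], -1)
    min_rep = rep_fold.min(axis=1)
    passes = (mean_fold > mean_fold_cutoff) & (min_rep > replicate_fold_cutoff)

    out = pd.DataFrame(
        {
            "mean_kd": mean_kd,
            "mean_ctrl": mean_ct,
            "mean_fold": mean_fold,
            "min_replicate_fold": min_rep,
            "direction": np.where(down, "down", "up"),
            "passes": passes,
        },
        index=expr_kd.index,
    )
    logger.info(
        "de_filter: %d/%d genes pass (%d down, %d up)",
        int(passes.sum()),
        len(out),
        int((passes & down).sum()),
        int((passes & ~down).sum()),
    )
    return out


@dataclass
class McrBCRecord:
    sample_id: str
    ct_digested: float | None
    ct_mock: float | None
    delta_ct: float | None
    methylated_call: bool | None  # None when unevaluable (mock failed)


def mcrbc_quantify(
    ct_table: pd.DataFrame,
    call_threshold_ct: float = 3.0,
) -> pd.DataFrame:
    """Score methylation from digested/mock qPCR Ct pairs.

    ``ct_table`` must have columns ``ct_digested`` and ``ct_mock`` indexed
    by sample; NaN encodes a failed amplification.  ``delta_ct =
    ct_digested - ct_mock`` where both amplified.  A sample is called
    methylated when ``delta_ct >= call_threshold_ct`` (default 3 cycles,
    ~8-fold template loss) or when the digested reaction failed while the
    mock amplified.  Samples whose mock reaction failed are unevaluable.
    """
    for col in ("ct_digested", "ct_mock"):
        if col not in ct_table.columns:
            raise ValueError(f"ct_table missing column {col!r}")
    dig = ct_table["ct_digested"].astype(float)
    mock = ct_table["ct_mock"].astype(float)
    if ((dig <= 0) | (mock <= 0)).any():
        raise ValueError("Ct values must be positive (use NaN for no amplification)")
    delta = dig - mock
    evaluable = mock.notna()
    methylated = pd.Series(pd.NA, index=ct_table.index, dtype="boolean")
    methylated[evaluable & dig.isna()] = True  # no product after digestion
    both = evaluable & dig.notna()
    methylated[both] = delta[both] >= call_threshold_ct
    out = pd.DataFrame(
        {
            "ct_digested": dig,
            "ct_mock": mock,
            "delta_ct": delta,
            "evaluable": evaluable,
            "methylated_call": methylated,
        }
    )
    logger.info(
        "mcrbc_quantify: %d/%d evaluable, %d methylated",
        int(evaluable.sum()),
        len(out),
        int((methylated == True).sum()),  # noqa: E712 — boolean dtype with NA
    )
    return out
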
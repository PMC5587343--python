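"""Expression-based karyotype QC (simplified e-karyotyping).

Chromosome-scale copy-number gains shift the expression of essentially all
genes on the affected chromosome by roughly the dosage ratio (log2(3/2) for
a trisomy).  After centering each gene on its cross-sample median, a moving
window of genes along each autosome is averaged per sample; a sustained
window mean far from zero flags a chromosome-scale aberration.  Samples
with globally dispersed (noisy) centered profiles are flagged as well.

This is a deliberately simplified reimplementation of expression-based
virtual karyotyping: median centering, overlapping fixed-size gene windows
and two thresholds, with no segmentation or breakpoint model.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .types import AUTOSOMES, ExprMatrix, ProbeAnnotation, SampleTable

logger = logging.getLogger(__name__)

#: Default global-noise cutoff: per-sample median absolute deviation of the
#: centered profile.  Calibrated once as the 99th percentile of the
#: dispersion of simulated diploid samples under generator defaults.
DEFAULT_NOISE_THRESHOLD = 0.17


@dataclass
class KaryotypeCall:
    """One flagged window (or noise flag) for one sample."""

    sample_id: str
    chromosome: str
    window_start_index: int
    window_score: float  # mean centered log2 expression in the window
    aberrant: bool
    global_noise: float


@dataclass
class KaryotypeResult:
    calls: list[KaryotypeCall]
    qc_pass: pd.Series  # sample_id -> bool
    noise: pd.Series  # per-sample MAD of centered values

    def calls_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "sample_id": c.sample_id,
                    "chromosome": c.chromosome,
                    "window_start_index": c.window_start_index,
                    "window_score": c.window_score,
                    "aberrant": c.aberrant,
                    "global_noise": c.global_noise,
                }
                for c in self.calls
            ],
            columns=[
                "sample_id",
                "chromosome",
                "window_start_index",
                "window_score",
                "aberrant",
                "global_noise",
            ],
        )


def ekaryotype_scan(
    expr: ExprMatrix,
    ann: ProbeAnnotation,
    window_genes: int = 100,
    call_threshold: float = 0.3,
    noise_threshold: float = DEFAULT_NOISE_THRESHOLD,
) -> KaryotypeResult:
    """Scan for chromosome-scale expression shifts and noisy samples.

    Per gene, expression is centered by its cross-sample median; per
    sample, genes are ordered by position within each autosome and a
    window of ``window_genes`` genes (advancing one gene at a time) is
    averaged.  A sample fails QC if any window's \\|mean\\| >=
    ``call_threshold`` (in log2 units) or its global dispersion (MAD of
    centered values) >= ``noise_threshold``.  Chromosomes with fewer genes
    than the window are skipped with a warning.  Sex chromosomes are not
    scanned (their dosage reflects sex, not aberration).
    """
    if expr.data.shape[1] < 10:
        raise ValueError("need >= 10 samples for a stable centering reference")
    data = expr.data
    ann_sub = ann.data.reindex(data.index).dropna(subset=["chromosome"])
    centered = data.sub(data.median(axis=1), axis=0)

    # flag the strongest window per (sample, chromosome); only flagged
    # windows are reported to keep the call table small
    mad = (centered - centered.median()).abs().median()
    mad.name = "global_noise"

    samples = list(data.columns)
    worst: dict[str, tuple[str, int, float]] = {}  # sample -> (chrom, start, score)
    for chrom in AUTOSOMES:
        probes = ann_sub.index[ann_sub["chromosome"] == chrom]
        if len(probes) == 0:
            continue
        if len(probes) < window_genes:
            warnings.warn(
                f"chromosome {chrom}: {len(probes)} genes < window {window_genes}; skipped",
                stacklevel=2,
            )
            continue
        ordered = ann_sub.loc[probes].sort_values("position").index
        vals = centered.loc[ordered].to_numpy()  # genes x samples
        csum = np.cumsum(vals, axis=0)
        csum = np.vstack([np.zeros((1, vals.shape[1])), csum])
        win = (csum[window_genes:] - csum[:-window_genes]) / window_genes
        peak = np.argmax(np.abs(win), axis=0)
        for j, s in enumerate(samples):
            score = float(win[peak[j], j])
            if s not in worst or abs(score) > abs(worst[s][2]):
                worst[s] = (chrom, int(peak[j]), score)

    calls: list[KaryotypeCall] = []
    qc = {}
    for s in samples:
        noisy = bool(mad[s] >= noise_threshold)
        chrom, start, score = worst.get(s, ("", 0, 0.0))
        aberrant = bool(abs(score) >= call_threshold)
        qc[s] = not (aberrant or noisy)
        if aberrant or noisy:
            calls.append(
                KaryotypeCall(
                    sample_id=s,
                    chromosome=chrom,
                    window_start_index=start,
                    window_score=score,
                    aberrant=aberrant,
                    global_noise=float(mad[s]),
                )
            )
    qc_pass = pd.Series(qc, name="qc_pass").reindex(samples)
    logger.info(
        "ekaryotype_scan: %d/%d samples pass QC", int(qc_pass.sum()), len(samples)
    )
    return KaryotypeResult(calls=calls, qc_pass=qc_pass, noise=mad)


def apply_qc(samples: SampleTable, result: KaryotypeResult) -> SampleTable:
    """Record the scan's qc_pass flags into a sample table."""
    return samples.with_qc(result.qc_pass)
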
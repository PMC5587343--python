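"""Synthetic matched methylation/expression datasets with planted drift.

The generator emulates the statistical structure of matched array compendia
of cultured human pluripotent stem-cell lines sampled over many passages:

* CpG-island probes sit in a low-beta mode (mean ~0.1) and non-island
  probes in a high-beta mode (mean ~0.85), giving the familiar bimodal
  beta distribution of methylation arrays.
* A chosen set of *drift genes* gains island methylation linearly with
  passage number, ``beta(p) = clip(beta0 + slope * p + noise, 0, 1)``, and
  their expression is silenced in proportion to the *realized* methylation
  gain of the sample, so the methylation-expression correlation of drift
  genes is negative by construction.
* A few samples carry a trisomy-like expression gain (default
  ``log2(1.5)``, the dosage of three copies versus two) on a single
  autosome, for the expression-karyotype QC stage to catch.
* A second, independent "platform" shares a configurable fraction of the
  gene universe (drift genes always shared) with fresh samples, probes and
  noise, mirroring a two-dataset replication design.

Every stage of the pipeline can therefore be scored against exact ground
truth.  Identical seeds give bit-identical outputs.
"""
from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .types import (
    AUTOSOMES,
    CHROMOSOMES,
    BetaMatrix,
    ExprMatrix,
    ProbeAnnotation,
    SampleTable,
)

# beta-distribution shapes of the two baseline modes (support stays in [0,1])
_ISLAND_SHAPE = (1.5, 13.5)  # mean 0.10 — unmethylated CpG islands
_OPEN_SEA_SHAPE = (8.5, 1.5)  # mean 0.85 — methylated non-island CpGs


@dataclass(frozen=True)
class SimConfig:
    """Generator parameters.

    Defaults realize the screen's reference conditions: 6 cell lines, each
    sampled at 5 low (<=25) and 5 high (>=50) passages for 30 + 30 samples;
    20 drift genes among 10,000; a drift slope of 0.004 beta units per
    passage (planted between-group delta-beta ~0.32 at this passage
    spread); and expression silencing of 10 log2 units per unit of beta
    gained (~9-fold between groups).
    """

    n_lines: int = 6
    passages_per_line: tuple[int, ...] = (5, 10, 15, 20, 25, 75, 85, 95, 105, 115)
    n_genes: int = 10_000
    probes_per_gene: int = 2  # islands first: ceil(n/2) island, rest open sea
    n_drift_genes: int = 20
    drift_slope: float = 0.004  # beta units per passage
    drift_expr_log2fc: float = 10.0  # log2 silencing per unit of realized beta gain
    beta_noise_sd: float = 0.03
    expr_noise_sd: float = 0.25  # log2 units
    n_aneuploid_samples: int = 2
    aneuploid_log2fc: float = math.log2(1.5)
    platform_overlap_fraction: float = 0.6
    unexpressed_gene_fraction: float = 0.05
    expr_floor: float = 5.0  # log2; used to place unexpressed genes below it
    beta_missing_fraction: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_lines < 1 or not self.passages_per_line:
            raise ValueError("need at least one line and one passage")
        if any(p < 0 for p in self.passages_per_line):
            raise ValueError("passages must be non-negative")
        if not 0 <= self.n_drift_genes <= self.n_genes:
            raise ValueError("n_drift_genes must be within [0, n_genes]")
        if self.probes_per_gene < 1:
            raise ValueError("probes_per_gene must be >= 1")
        if min(self.beta_noise_sd, self.expr_noise_sd) < 0 or self.drift_slope < 0:
            raise ValueError("noise sds and drift_slope must be >= 0")
        if not 0 <= self.platform_overlap_fraction <= 1:
            raise ValueError("platform_overlap_fraction must be in [0,1]")
        n_samples = self.n_lines * len(self.passages_per_line)
        if self.n_aneuploid_samples > n_samples:
            raise ValueError("more aneuploid samples than samples")


@dataclass
class GroundTruth:
    """What was planted: the answer key for every pipeline stage."""

    drift_genes: frozenset[str]
    drift_island_probes: tuple[str, ...]
    aneuploid_samples: dict[str, tuple[str, float]]  # sample -> (chromosome, log2fc)
    true_slopes: pd.Series  # per methylation probe, beta units / passage

    def to_json_dict(self) -> dict:
        return {
            "drift_genes": sorted(self.drift_genes),
            "drift_island_probes": list(self.drift_island_probes),
            "aneuploid_samples": {
                s: {"chromosome": c, "log2fc": f}
                for s, (c, f) in self.aneuploid_samples.items()
            },
            "true_slopes": {p: float(v) for p, v in self.true_slopes.items() if v != 0},
        }


@dataclass
class SimResult:
    beta: BetaMatrix
    expr: ExprMatrix
    samples: SampleTable
    annotation: ProbeAnnotation
    truth: GroundTruth
    gene_table: pd.DataFrame  # gene -> chromosome, position, base_expr, expressed


def _rng_for(cfg: SimConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(cfg.seed, spawn_key=(stream,)))


def _make_gene_table(
    cfg: SimConfig, rng: np.random.Generator, prefix: str, n_genes: int
) -> pd.DataFrame:
    genes = [f"{prefix}{i:06d}" for i in range(n_genes)]
    # gene density per chromosome: autosomes equal, X lighter, Y sparse
    weights = np.array([1.0] * 22 + [0.7, 0.08])
    weights /= weights.sum()
    chrom = rng.choice(np.array(CHROMOSOMES), size=n_genes, p=weights)
    df = pd.DataFrame({"chromosome": chrom}, index=pd.Index(genes, name="gene"))
    df["position"] = (df.groupby("chromosome").cumcount() + 1) * 50_000
    base = rng.normal(8.0, 1.5, n_genes)
    unexpressed = rng.random(n_genes) < cfg.unexpressed_gene_fraction
    base = np.where(unexpressed, cfg.expr_floor - 2.0, base)
    df["base_expr"] = base
    df["expressed"] = ~unexpressed
    return df


def _pick_drift_genes(
    gene_table: pd.DataFrame, cfg: SimConfig, rng: np.random.Generator
) -> frozenset[str]:
    # drift (hypermethylation -> silencing) is only observable for genes
    # expressed clearly above the detection floor, so ground-truth drift
    # genes are planted among detectably expressed autosomal genes
    eligible = gene_table.index[
        gene_table["expressed"]
        & gene_table["chromosome"].isin(AUTOSOMES)
        & (gene_table["base_expr"] >= cfg.expr_floor + 2.0)
    ]
    if len(eligible) < cfg.n_drift_genes:
        raise ValueError("not enough expressed autosomal genes for drift set")
    picked = rng.choice(np.array(sorted(eligible)), cfg.n_drift_genes, replace=False)
    return frozenset(str(g) for g in picked)


def _generate(
    gene_table: pd.DataFrame,
    drift_genes: frozenset[str],
    cfg: SimConfig,
    rng: np.random.Generator,
    *,
    meth_prefix: str,
    expr_prefix: str,
    line_prefix: str,
    meth_platform: str,
) -> SimResult:
    genes = gene_table.index.to_numpy()
    G = len(genes)
    ppg = cfg.probes_per_gene
    n_island = math.ceil(ppg / 2)
    island_slot = np.array([True] * n_island + [False] * (ppg - n_island))

    # --- samples -----------------------------------------------------------
    rows = []
    for li in range(cfg.n_lines):
        line = f"{line_prefix}{li + 1:02d}"
        sex = "female" if li % 2 == 0 else "male"
        ctype = "hESC" if li % 3 != 2 else "hiPSC"
        for p in cfg.passages_per_line:
            rows.append((f"{line}_p{p:03d}", line, int(p), sex, ctype, True))
    samples_df = pd.DataFrame(
        rows, columns=["sample_id", "cell_line", "passage", "sex", "cell_type", "qc_pass"]
    ).set_index("sample_id")
    passages = samples_df["passage"].to_numpy(dtype=float)
    S = len(samples_df)

    # --- methylation -------------------------------------------------------
    drift_gene_mask = np.isin(genes, sorted(drift_genes))
    beta0 = np.where(
        island_slot[None, :],
        rng.beta(*_ISLAND_SHAPE, size=(G, ppg)),
        rng.beta(*_OPEN_SEA_SHAPE, size=(G, ppg)),
    )
    drift_probe_mask = drift_gene_mask[:, None] & island_slot[None, :]
    mu = beta0[:, :, None] + (
        drift_probe_mask[:, :, None] * cfg.drift_slope * passages[None, None, :]
    )
    mu = np.clip(mu, 0.0, 1.0)
    if cfg.beta_noise_sd > 0:
        beta_vals = np.clip(mu + rng.normal(0.0, cfg.beta_noise_sd, mu.shape), 0.0, 1.0)
    else:
        beta_vals = mu

    meth_ids = np.array(
        [f"{meth_prefix}{gi:06d}_{k}" for gi in range(G) for k in range(ppg)]
    )

    # --- expression --------------------------------------------------------
    base = gene_table["base_expr"].to_numpy()
    expr_vals = base[:, None] + (
        rng.normal(0.0, cfg.expr_noise_sd, (G, S)) if cfg.expr_noise_sd > 0 else 0.0
    )
    # silencing coupled to the sample's realized island methylation gain
    gain = np.maximum(beta_vals[:, 0, :] - beta0[:, 0, None], 0.0)
    expr_vals = expr_vals - drift_gene_mask[:, None] * cfg.drift_expr_log2fc * gain

    # --- trisomy-like expression shifts ------------------------------------
    aneuploid: dict[str, tuple[str, float]] = {}
    if cfg.n_aneuploid_samples > 0:
        chrom_counts = gene_table["chromosome"].value_counts()
        eligible = sorted(
            c for c in AUTOSOMES if chrom_counts.get(c, 0) >= 150
        ) or sorted(c for c in AUTOSOMES if chrom_counts.get(c, 0) > 0)
        idx = rng.choice(S, cfg.n_aneuploid_samples, replace=False)
        chroms = rng.choice(np.array(eligible), cfg.n_aneuploid_samples)
        gene_chrom = gene_table["chromosome"].to_numpy()
        for si, ch in zip(idx, chroms):
            on_chrom = gene_chrom == ch
            expr_vals[on_chrom, si] += cfg.aneuploid_log2fc
            aneuploid[str(samples_df.index[si])] = (str(ch), float(cfg.aneuploid_log2fc))

    if cfg.beta_missing_fraction > 0:
        mask = rng.random(beta_vals.shape) < cfg.beta_missing_fraction
        beta_vals = np.where(mask, np.nan, beta_vals)

    # --- assemble tables ---------------------------------------------------
    beta_df = pd.DataFrame(
        beta_vals.reshape(G * ppg, S), index=meth_ids, columns=samples_df.index
    )
    expr_ids = np.array([f"{expr_prefix}{gi:06d}" for gi in range(G)])
    expr_df = pd.DataFrame(expr_vals, index=expr_ids, columns=samples_df.index)

    gene_rep = np.repeat(genes, ppg)
    ann_meth = pd.DataFrame(
        {
            "gene": gene_rep,
            "chromosome": np.repeat(gene_table["chromosome"].to_numpy(), ppg),
            "position": np.repeat(gene_table["position"].to_numpy(), ppg)
            + np.tile(np.arange(ppg) * 100, G),
            "in_cpg_island": np.tile(island_slot, G),
            "platform": meth_platform,
        },
        index=pd.Index(meth_ids, name="probe_id"),
    )
    ann_expr = pd.DataFrame(
        {
            "gene": genes,
            "chromosome": gene_table["chromosome"].to_numpy(),
            "position": gene_table["position"].to_numpy(),
            "in_cpg_island": False,
            "platform": "expr_array",
        },
        index=pd.Index(expr_ids, name="probe_id"),
    )
    annotation = ProbeAnnotation(pd.concat([ann_meth, ann_expr]))

    true_slopes = pd.Series(
        np.where(drift_probe_mask, cfg.drift_slope, 0.0).reshape(-1),
        index=meth_ids,
        name="true_slope",
    )
    truth = GroundTruth(
        drift_genes=drift_genes,
        drift_island_probes=tuple(meth_ids[drift_probe_mask.reshape(-1)]),
        aneuploid_samples=aneuploid,
        true_slopes=true_slopes,
    )
    return SimResult(
        beta=BetaMatrix(beta_df),
        expr=ExprMatrix(expr_df, floor=None),
        samples=SampleTable(samples_df),
        annotation=annotation,
        truth=truth,
        gene_table=gene_table,
    )


def simulate_dataset(cfg: SimConfig) -> SimResult:
    """Generate the primary platform (27K-style methylation + expression)."""
    cfg.validate()
    rng = _rng_for(cfg, 0)
    gene_table = _make_gene_table(cfg, rng, "G", cfg.n_genes)
    drift = _pick_drift_genes(gene_table, cfg, rng)
    return _generate(
        gene_table,
        drift,
        cfg,
        rng,
        meth_prefix="cgA",
        expr_prefix="eA",
        line_prefix="L",
        meth_platform="meth27k",
    )


def simulate_second_platform(base: SimResult, cfg: SimConfig) -> SimResult:
    """Generate an independent replication platform (450K-style).

    Shares exactly ``round(platform_overlap_fraction * n_genes)`` genes
    with the base dataset (drift genes always among them); the remaining
    genes are new symbols.  Samples, probes and noise are fresh.
    """
    cfg.validate()
    rng = _rng_for(cfg, 1)
    n_shared = round(cfg.platform_overlap_fraction * cfg.n_genes)
    drift = base.truth.drift_genes
    if n_shared < len(drift):
        raise ValueError("overlap fraction too small to share all drift genes")
    others = np.array(sorted(set(base.gene_table.index) - drift))
    extra = rng.choice(others, n_shared - len(drift), replace=False)
    shared = sorted(drift | {str(g) for g in extra})

    n_new = cfg.n_genes - n_shared
    new_table = _make_gene_table(cfg, rng, "H", n_new) if n_new else None
    shared_table = base.gene_table.loc[shared].copy()
    if new_table is not None:
        new_table = new_table.copy()
        new_table["position"] += 7  # avoid exact collisions with shared genes
        gene_table = pd.concat([shared_table, new_table])
    else:
        gene_table = shared_table
    return _generate(
        gene_table,
        drift,
        cfg,
        rng,
        meth_prefix="cgB",
        expr_prefix="eB",
        line_prefix="M",
        meth_platform="meth450k",
    )


def write_simulation(result: SimResult, outdir: str | Path, cfg: SimConfig | None = None) -> None:
    """Write the five TSV artifacts plus the ground-truth JSON."""
    from . import io as eio

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    eio.write_matrix(result.beta, outdir / "beta.tsv")
    eio.write_matrix(result.expr, outdir / "expression.tsv")
    eio.write_sample_table(result.samples, outdir / "samples.tsv")
    eio.write_probe_annotation(result.annotation, outdir / "annotation.tsv")
    payload = {"ground_truth": result.truth.to_json_dict()}
    if cfg is not None:
        payload["config"] = asdict(cfg)
    (outdir / "ground_truth.json").write_text(json.dumps(payload, indent=2))
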
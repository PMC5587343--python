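"""End-to-end pipeline: simulate/load → QC → screen → dynamics → concordance.

A single declarative config (YAML mapping or :class:`PipelineConfig`)
drives every stage with one root seed; identical config + seed produces
byte-identical outputs.  Each stage logs its parameters and headline
counts into a consolidated JSON/Markdown report under the run directory.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import concordance, dynamics, io as eio, karyotype, screen as escreen
from .preprocess import apply_expression_floor, filter_probes
from .simulate import SimConfig, SimResult, simulate_dataset, simulate_second_platform
from .types import ExprMatrix

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


class ConfigError(ValueError):
    """The config does not validate against the schema."""


@dataclass
class PipelineConfig:
    seed: int = 0
    simulate: SimConfig | None = None
    inputs: dict | None = None  # beta/expression/samples/annotation paths (+ "second")
    group_mode: str = "strict"
    expression_floor: float = 5.0
    delta_beta_cutoff: float = 0.2
    fold_cutoff: float = 1.5
    fdr_alpha: float = 0.05
    ekaryotype_window_genes: int = 100
    ekaryotype_call_threshold: float = 0.3
    ekaryotype_noise_threshold: float = karyotype.DEFAULT_NOISE_THRESHOLD

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        raw = dict(raw)
        sim = raw.pop("simulate", None)
        ek = raw.pop("ekaryotype", {}) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys {sorted(unknown)}")
        cfg = cls(**raw)
        if sim is not None:
            seed = sim.pop("seed", cfg.seed)
            try:
                cfg.simulate = SimConfig(seed=seed, **sim)
            except TypeError as exc:
                raise ConfigError(f"invalid simulate block: {exc}") from exc
        for key, attr in (
            ("window_genes", "ekaryotype_window_genes"),
            ("call_threshold", "ekaryotype_call_threshold"),
            ("noise_threshold", "ekaryotype_noise_threshold"),
        ):
            if key in ek:
                setattr(cfg, attr, ek[key])
        cfg.validate()
        return cfg

    def validate(self) -> None:
        for name in (
            "delta_beta_cutoff",
            "fold_cutoff",
            "fdr_alpha",
            "ekaryotype_call_threshold",
            "ekaryotype_noise_threshold",
        ):
            if not getattr(self, name) > 0:
                raise ConfigError(f"{name} must be positive")
        if self.group_mode not in escreen.MODES:
            raise ConfigError(f"group_mode must be one of {escreen.MODES}")
        if (self.simulate is None) == (self.inputs is None):
            raise ConfigError("config needs exactly one of 'simulate' or 'inputs'")
        if self.simulate is not None:
            try:
                self.simulate.validate()
            except ValueError as exc:
                raise ConfigError(str(exc)) from exc
        if self.inputs is not None:
            self._validate_inputs(self.inputs)
            if "second" in self.inputs:
                self._validate_inputs(self.inputs["second"])

    @staticmethod
    def _validate_inputs(inputs: dict) -> None:
        for key in ("beta", "expression", "samples", "annotation"):
            if key not in inputs:
                raise ConfigError(f"inputs missing {key!r}")
            path = Path(inputs[key])
            if not path.exists():
                raise ConfigError(f"input file not found: {path}")
        # schema check before any computation: sample table must carry passage
        with Path(inputs["samples"]).open() as fh:
            header = fh.readline().rstrip("\n").split("\t")
        if "passage" not in header:
            raise ConfigError(
                f"{Path(inputs['samples']).name}: missing 'passage' column"
            )


def load_config(path: str | Path) -> PipelineConfig:
    import yaml

    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ConfigError("config file must contain a mapping")
    return PipelineConfig.from_dict(raw)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _load_platform(inputs: dict) -> SimResult | tuple:
    beta = eio.read_matrix(inputs["beta"], "beta")
    expr = eio.read_matrix(inputs["expression"], "expression")
    samples = eio.read_sample_table(inputs["samples"])
    ann = eio.read_probe_annotation(inputs["annotation"])
    hashes = {k: _sha256(Path(v)) for k, v in inputs.items() if k != "second"}
    return beta, expr, samples, ann, hashes


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (set, frozenset)):
        return sorted(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def run_pipeline(cfg: PipelineConfig, outdir: str | Path) -> dict:
    """Run every stage in order and write outputs under ``outdir``.

    Returns the consolidated report dict (also written to report.json /
    report.md).  A stage failure raises :class:`PipelineError` naming the
    stage; outputs of completed stages are retained.
    """
    cfg.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "seed": cfg.seed,
        "parameters": {
            "group_mode": cfg.group_mode,
            "expression_floor": cfg.expression_floor,
            "delta_beta_cutoff": cfg.delta_beta_cutoff,
            "fold_cutoff": cfg.fold_cutoff,
            "fdr_alpha": cfg.fdr_alpha,
            "ekaryotype": {
                "window_genes": cfg.ekaryotype_window_genes,
                "call_threshold": cfg.ekaryotype_call_threshold,
                "noise_threshold": cfg.ekaryotype_noise_threshold,
            },
        },
        "stages": {},
    }

    stage = "simulate" if cfg.simulate is not None else "load"
    try:
        if cfg.simulate is not None:
            base = simulate_dataset(cfg.simulate)
            second = simulate_second_platform(base, cfg.simulate)
            beta, expr, samples, ann = base.beta, base.expr, base.samples, base.annotation
            report["stages"][stage] = {
                "config": dataclasses.asdict(cfg.simulate),
                "n_samples": len(samples.data),
                "n_meth_probes": len(beta.data),
                "n_expr_probes": len(expr.data),
            }
            truth = base.truth
        else:
            beta, expr, samples, ann, hashes = _load_platform(cfg.inputs)
            second = None
            truth = None
            report["stages"][stage] = {"input_sha256": hashes}
            if "second" in cfg.inputs:
                b2, e2, s2, a2, h2 = _load_platform(cfg.inputs["second"])
                second = SimResult(b2, e2, s2, a2, truth=None, gene_table=None)
                report["stages"][stage]["second_input_sha256"] = h2

        stage = "qc"
        expr_floored = apply_expression_floor(expr, cfg.expression_floor)
        qc = karyotype.ekaryotype_scan(
            expr_floored,
            ann,
            window_genes=cfg.ekaryotype_window_genes,
            call_threshold=cfg.ekaryotype_call_threshold,
            noise_threshold=cfg.ekaryotype_noise_threshold,
        )
        samples = karyotype.apply_qc(samples, qc)
        qc.calls_frame().to_csv(outdir / "karyotype_calls.tsv", sep="\t", index=False)
        eio.write_sample_table(samples, outdir / "samples_qc.tsv")
        report["stages"]["qc"] = {
            "samples_pass": int(qc.qc_pass.sum()),
            "samples_fail": int((~qc.qc_pass).sum()),
            "failed_samples": sorted(qc.qc_pass.index[~qc.qc_pass]),
        }

        stage = "screen"
        groups = escreen.assign_groups(samples, mode=cfg.group_mode)
        filt = filter_probes(beta, expr_floored, ann, samples, groups)
        records = escreen.screen_probes(
            filt.beta,
            filt.expr,
            ann,
            groups,
            delta_beta_cutoff=cfg.delta_beta_cutoff,
            fold_cutoff=cfg.fold_cutoff,
        )
        candidates, cand_report = escreen.candidate_gene_set(records)
        records.to_csv(outdir / "screen_records.tsv", sep="\t", index_label="probe_id")
        (outdir / "candidate_genes.txt").write_text(
            "\n".join(sorted(candidates)) + ("\n" if candidates else "")
        )
        filter_report = {
            k: v for k, v in filt.report.items() if k != "unexpressed_gene_ids"
        }
        report["stages"]["screen"] = {
            "groups": groups.counts(),
            "filter": filter_report,
            **cand_report,
            "candidate_genes": sorted(candidates),
        }
        genes_a = {g for g in records.loc[records["evaluable"], "gene"] if g}

        if second is not None:
            stage = "screen_second"
            qc2 = karyotype.ekaryotype_scan(
                apply_expression_floor(second.expr, cfg.expression_floor),
                second.annotation,
                window_genes=cfg.ekaryotype_window_genes,
                call_threshold=cfg.ekaryotype_call_threshold,
                noise_threshold=cfg.ekaryotype_noise_threshold,
            )
            samples2 = karyotype.apply_qc(second.samples, qc2)
            groups2 = escreen.assign_groups(samples2, mode=cfg.group_mode)
            expr2 = apply_expression_floor(second.expr, cfg.expression_floor)
            filt2 = filter_probes(second.beta, expr2, second.annotation, samples2, groups2)
            records2 = escreen.screen_probes(
                filt2.beta,
                filt2.expr,
                second.annotation,
                groups2,
                delta_beta_cutoff=cfg.delta_beta_cutoff,
                fold_cutoff=cfg.fold_cutoff,
            )
            candidates2, cand_report2 = escreen.candidate_gene_set(records2)
            records2.to_csv(
                outdir / "screen_records_second.tsv", sep="\t", index_label="probe_id"
            )
            report["stages"]["screen_second"] = {
                "groups": groups2.counts(),
                **cand_report2,
                "candidate_genes": sorted(candidates2),
            }

            stage = "intersect"
            genes_b = {g for g in records2.loc[records2["evaluable"], "gene"] if g}
            universe = genes_a & genes_b
            overlap = concordance.intersect_candidates(
                candidates & universe, candidates2 & universe, len(universe)
            )
            report["stages"]["intersect"] = overlap.to_json_dict()
            report["stages"]["intersect"]["universe_note"] = (
                "universe = genes evaluable on both platforms after filtering"
            )
            (outdir / "overlap.json").write_text(
                json.dumps(overlap.to_json_dict(), indent=2, sort_keys=True)
            )

            stage = "validate_compendium"
            val, validated = escreen.validate_expression_compendium(
                expr2,
                samples2,
                candidates,
                second.annotation,
                mode="permissive",
                alpha=cfg.fdr_alpha,
            )
            val.to_csv(outdir / "compendium_validation.tsv", sep="\t")
            report["stages"]["validate_compendium"] = {
                "tested_probes": len(val),
                "validated_genes": sorted(validated),
                "n_validated": len(validated),
                "n_candidates": len(candidates),
            }

            stage = "slopes"
            slope_beta, slope_samples, slope_ann = filt2.beta, samples2, second.annotation
        else:
            stage = "slopes"
            slope_beta, slope_samples, slope_ann = filt.beta, samples, ann

        slopes = dynamics.fit_methylation_slopes(slope_beta, slope_samples, slope_ann)
        ranked, slope_summary = dynamics.rank_slopes(slopes, candidate_genes=candidates)
        ranked.drop(columns=["_pid"], errors="ignore").to_csv(
            outdir / "slopes.tsv", sep="\t", index_label="probe_id"
        )
        report["stages"]["slopes"] = {
            "universe_size": slope_summary["universe_size"],
            "candidates": slope_summary.get("candidates"),
        }

        stage = "variability"
        var = dynamics.variability_ranking(
            filt.expr, filt.beta, ann, candidate_genes=candidates
        )
        var["expression"].to_csv(
            outdir / "variability_expression.tsv", sep="\t", index_label="probe_id"
        )
        var["methylation"].to_csv(
            outdir / "variability_methylation.tsv", sep="\t", index_label="probe_id"
        )
        report["stages"]["variability"] = var.get("enrichment")

        stage = "cluster"
        cluster_report = []
        for kind, matrix in (("expression", filt.expr), ("methylation", filt.beta)):
            cols = [s for s in matrix.data.columns if groups.labels.get(s) in ("low", "high")]
            sub = type(matrix)(matrix.data[cols])
            res = concordance.hierarchical_cluster(sub, distance="pearson")
            test = concordance.branch_composition_test(
                res.branches, groups, data_kind=kind, distance="pearson"
            )
            (outdir / f"dendrogram_{kind}.nwk").write_text(res.to_newick() + "\n")
            cluster_report.append(test.to_json_dict())
        report["stages"]["cluster"] = cluster_report

        if truth is not None:
            tp = len(candidates & truth.drift_genes)
            report["ground_truth_evaluation"] = {
                "planted_drift_genes": len(truth.drift_genes),
                "recovered": tp,
                "sensitivity": tp / len(truth.drift_genes) if truth.drift_genes else None,
                "precision": tp / len(candidates) if candidates else None,
            }
    except Exception as exc:  # noqa: BLE001 — rewrap with the failing stage named
        if isinstance(exc, PipelineError):
            raise
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    (outdir / "report.json").write_text(
        json.dumps(report, indent=2, sort_keys=True, default=_json_default)
    )
    (outdir / "report.md").write_text(_render_markdown(report))
    return report


def _render_markdown(report: dict) -> str:
    lines = ["# epidrift pipeline report", ""]
    lines.append(f"Seed: {report['seed']}")
    lines.append("")
    lines.append("## Parameters")
    lines.append("```json")
    lines.append(json.dumps(report["parameters"], indent=2, sort_keys=True))
    lines.append("```")
    for name, payload in report["stages"].items():
        lines.append("")
        lines.append(f"## Stage: {name}")
        lines.append("```json")
        lines.append(json.dumps(payload, indent=2, sort_keys=True, default=_json_default))
        lines.append("```")
    if "ground_truth_evaluation" in report:
        lines.append("")
        lines.append("## Ground-truth evaluation")
        lines.append("```json")
        lines.append(json.dumps(report["ground_truth_evaluation"], indent=2, sort_keys=True))
        lines.append("```")
    return "\n".join(lines) + "\n"
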
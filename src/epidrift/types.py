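"""Core data containers for matched methylation/expression analysis.

The screen operates on four aligned tables:

* :class:`BetaMatrix` — probe x sample DNA-methylation beta values in [0, 1]
  (fraction of methylated signal at a CpG probe).  Missing measurements are
  carried as NaN and excluded pairwise downstream.
* :class:`ExprMatrix` — probe x sample log2 expression values, optionally
  floored at a fixed detection threshold.
* :class:`SampleTable` — per-sample metadata: cell line, passage number
  (rounds of replating, a proxy for time in culture), sex, cell type and a
  QC flag filled in by the expression-karyotype scan.
* :class:`ProbeAnnotation` — probe → gene mapping with genomic coordinates,
  CpG-island membership and originating platform.

All containers are thin, validated wrappers around :class:`pandas.DataFrame`
so the usual pandas idioms keep working on ``.data``.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

AUTOSOMES: tuple[str, ...] = tuple(str(i) for i in range(1, 23))
SEX_CHROMOSOMES: tuple[str, ...] = ("X", "Y")
CHROMOSOMES: tuple[str, ...] = AUTOSOMES + SEX_CHROMOSOMES

SEXES = ("female", "male", "unknown")
CELL_TYPES = ("hESC", "hiPSC", "other")
PLATFORMS = ("meth27k", "meth450k", "expr_array", "rnaseq")

SAMPLE_COLUMNS = ("cell_line", "passage", "sex", "cell_type", "qc_pass")
ANNOTATION_COLUMNS = ("gene", "chromosome", "position", "in_cpg_island", "platform")


class ValidationError(ValueError):
    """Raised when a container violates one of its invariants."""


def normalize_chromosome(name: object) -> str:
    """Normalize a chromosome label to the bare ``1``..``22``, ``X``, ``Y`` form.

    Accepts labels with or without a ``chr`` prefix, case-insensitively.
    """
    s = str(name).strip()
    if s.lower().startswith("chr"):
        s = s[3:]
    if s in ("x", "y"):
        s = s.upper()
    if s not in CHROMOSOMES:
        raise ValidationError(f"unknown chromosome {name!r}")
    return s


def _check_unique(index: pd.Index, what: str) -> None:
    if index.duplicated().any():
        dups = index[index.duplicated()].unique().tolist()[:5]
        raise ValidationError(f"duplicate {what}: {dups}")


@dataclass
class SampleTable:
    """Per-sample metadata, indexed by unique ``sample_id``."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        _check_unique(df.index, "sample_id")
        missing = [c for c in SAMPLE_COLUMNS if c not in df.columns]
        if missing:
            raise ValidationError(f"sample table missing columns {missing}")
        if (df["passage"] < 0).any():
            bad = df.index[df["passage"] < 0].tolist()
            raise ValidationError(f"negative passage for samples {bad}")
        for col, allowed in (("sex", SEXES), ("cell_type", CELL_TYPES)):
            bad = set(df[col]) - set(allowed)
            if bad:
                raise ValidationError(f"invalid {col} values {sorted(bad)}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    def with_qc(self, qc_pass: pd.Series) -> "SampleTable":
        """Return a copy with the ``qc_pass`` column replaced."""
        df = self.data.copy()
        df["qc_pass"] = qc_pass.reindex(df.index).fillna(False).astype(bool)
        return SampleTable(df)


@dataclass
class ProbeAnnotation:
    """Probe → gene mapping, indexed by ``probe_id``.

    ``gene`` may be the empty string for probes not linked to a gene;
    such probes are excluded from gene-level ranking universes.
    Positions are 1-based, following array-annotation convention.
    probe ids must be unique within each platform.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        missing = [c for c in ANNOTATION_COLUMNS if c not in df.columns]
        if missing:
            raise ValidationError(f"probe annotation missing columns {missing}")
        for plat, sub in df.groupby("platform"):
            _check_unique(sub.index, f"probe_id on platform {plat}")
        bad_plat = set(df["platform"]) - set(PLATFORMS)
        if bad_plat:
            raise ValidationError(f"unknown platforms {sorted(bad_plat)}")
        df["chromosome"] = [normalize_chromosome(c) for c in df["chromosome"]]
        if (df["position"] < 0).any():
            raise ValidationError("negative probe position")

    def subset(self, probe_ids) -> "ProbeAnnotation":
        return ProbeAnnotation(self.data.loc[list(probe_ids)].copy())

    def gene_of(self) -> pd.Series:
        return self.data["gene"]


@dataclass
class BetaMatrix:
    """Probe x sample methylation beta values; NaN marks missing."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        _check_unique(self.data.index, "probe_id")
        _check_unique(self.data.columns, "sample_id")
        vals = self.data.to_numpy(dtype=float)
        with np.errstate(invalid="ignore"):
            bad = (vals < 0) | (vals > 1)
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValidationError(
                f"beta value out of [0,1] at probe {self.data.index[i]!r}, "
                f"sample {self.data.columns[j]!r}: {vals[i, j]}"
            )
        self.data = self.data.astype(float)

    @property
    def probes(self) -> list[str]:
        return list(self.data.index)

    @property
    def samples(self) -> list[str]:
        return list(self.data.columns)


@dataclass
class ExprMatrix:
    """Probe x sample expression values (log2 scale unless noted).

    ``floor`` records the detection threshold applied by
    :func:`epidrift.preprocess.apply_expression_floor`; values equal to the
    floor are treated as "unexpressed" by downstream filters.
    """

    data: pd.DataFrame
    floor: float | None = None

    def __post_init__(self) -> None:
        _check_unique(self.data.index, "probe_id")
        _check_unique(self.data.columns, "sample_id")
        self.data = self.data.astype(float)
        if self.floor is not None:
            vals = self.data.to_numpy()
            with np.errstate(invalid="ignore"):
                below = vals < self.floor - 1e-12
            if below.any():
                i, j = np.argwhere(below)[0]
                raise ValidationError(
                    f"expression below declared floor at probe "
                    f"{self.data.index[i]!r}, sample {self.data.columns[j]!r}"
                )

    @property
    def probes(self) -> list[str]:
        return list(self.data.index)

    @property
    def samples(self) -> list[str]:
        return list(self.data.columns)


@dataclass
class ControlBetas:
    """Control-sample beta levels used for range-scaling.

    Each field is either a scalar applied to every probe or a per-probe
    :class:`pandas.Series`.  ``half_methylated`` is check-only: after
    scaling it should land near 0.5 and the deviation is reported.
    """

    unmethylated: float | pd.Series
    fully_methylated: float | pd.Series
    half_methylated: float | pd.Series | None = None

    def __post_init__(self) -> None:
        u, m = self.unmethylated, self.fully_methylated
        if np.isscalar(u) and np.isscalar(m):
            if not u < m:
                raise ValidationError("unmethylated control must be < fully methylated")
        else:
            u_s = pd.Series(u) if not np.isscalar(u) else None
            m_s = pd.Series(m) if not np.isscalar(m) else None
            if u_s is not None and m_s is not None:
                both = u_s.index.intersection(m_s.index)
                if (u_s.loc[both] >= m_s.loc[both]).any():
                    raise ValidationError(
                        "unmethylated control >= fully methylated for some probes"
                    )


@dataclass
class GroupAssignment:
    """Passage-group labels for the screen.

    ``mode='strict'`` assigns low = passage <= 25 and high = passage >= 50
    (intermediate passages excluded); ``mode='permissive'`` assigns
    low = passage <= 25 and high = passage > 25.
    """

    mode: str
    labels: pd.Series  # sample_id -> {"low", "high", "excluded"}

    def __post_init__(self) -> None:
        bad = set(self.labels) - {"low", "high", "excluded"}
        if bad:
            raise ValidationError(f"invalid group labels {sorted(bad)}")

    @property
    def low(self) -> list[str]:
        return list(self.labels.index[self.labels == "low"])

    @property
    def high(self) -> list[str]:
        return list(self.labels.index[self.labels == "high"])

    def counts(self) -> dict[str, int]:
        return {
            "low": int((self.labels == "low").sum()),
            "high": int((self.labels == "high").sum()),
            "excluded": int((self.labels == "excluded").sum()),
        }
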
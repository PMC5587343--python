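"""TSV readers/writers for the matrix and metadata tables.

Formats
-------
Matrices are tab-separated with probe ids in the first column (header cell
``probe_id``) and sample ids across the header row.  Empty cells denote
missing measurements and round-trip as NaN.  The sample table and probe
annotation use fixed, documented column names (see
:data:`epidrift.types.SAMPLE_COLUMNS` / :data:`~epidrift.types.ANNOTATION_COLUMNS`).

Writers emit floats with ``repr`` precision so a write/read round-trip is
bit-exact.
"""
from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .types import (
    ANNOTATION_COLUMNS,
    SAMPLE_COLUMNS,
    BetaMatrix,
    ExprMatrix,
    ProbeAnnotation,
    SampleTable,
)


class ParseError(ValueError):
    """Raised for malformed input files; the message names the offending cell."""


def read_matrix(path: str | Path, kind: str, floor: float | None = None) -> BetaMatrix | ExprMatrix:
    """Read a probe x sample TSV matrix.

    Parameters
    ----------
    path:
        TSV file with ``probe_id`` as the first header cell.
    kind:
        ``"beta"`` (values validated to [0, 1]) or ``"expression"``.
    floor:
        Declared expression floor, recorded on the returned
        :class:`~epidrift.types.ExprMatrix` (ignored for betas).
    """
    if kind not in ("beta", "expression"):
        raise ValueError(f"kind must be 'beta' or 'expression', got {kind!r}")
    path = Path(path)
    with path.open() as fh:
        header = fh.readline().rstrip("\n").split("\t")
    if not header or header[0] != "probe_id":
        raise ParseError(
            f"{path.name}: first header cell must be 'probe_id', got {header[:1]!r}"
        )
    raw = pd.read_csv(path, sep="\t", dtype=str, index_col=0, keep_default_na=False)
    if raw.index.duplicated().any():
        dups = raw.index[raw.index.duplicated()].unique().tolist()[:5]
        raise ParseError(f"{path.name}: duplicate probe ids {dups}")
    if raw.columns.duplicated().any():
        dups = raw.columns[raw.columns.duplicated()].unique().tolist()[:5]
        raise ParseError(f"{path.name}: duplicate sample ids {dups}")
    # parse with Python float(): correctly rounded, so repr-precision
    # writes round-trip bit-exactly (pandas' fast parser can be 1 ulp off)
    _bad = object()

    def _parse(x: str):
        if x == "":
            return np.nan  # missing measurement, not zero
        try:
            return float(x)
        except ValueError:
            return _bad

    parsed = raw.map(_parse)
    bad = parsed.map(lambda v: v is _bad).to_numpy()
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ParseError(
            f"{path.name}: non-numeric cell at probe {raw.index[i]!r}, "
            f"column {raw.columns[j]!r}: {raw.iat[i, j]!r}"
        )
    numeric = parsed.astype(float)
    if kind == "beta":
        vals = numeric.to_numpy()
        with np.errstate(invalid="ignore"):
            out = (vals < 0) | (vals > 1)
        if out.any():
            i, j = np.argwhere(out)[0]
            raise ParseError(
                f"{path.name}: value out of [0,1] at probe {numeric.index[i]!r}, "
                f"sample {numeric.columns[j]!r}: {vals[i, j]}"
            )
        return BetaMatrix(numeric)
    return ExprMatrix(numeric, floor=floor)


def write_matrix(matrix: BetaMatrix | ExprMatrix, path: str | Path) -> None:
    """Write a matrix as TSV; NaN becomes an empty cell."""
    df = matrix.data.copy()
    df.index.name = "probe_id"
    # repr-precision floats guarantee a bit-exact round trip
    df.to_csv(path, sep="\t", na_rep="", float_format=lambda v: repr(float(v)))


def read_sample_table(path: str | Path) -> SampleTable:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.name != "sample_id":
        raise ParseError(f"{Path(path).name}: first column must be 'sample_id'")
    if "qc_pass" not in df.columns:
        df["qc_pass"] = True
    df["passage"] = df["passage"].astype(int)
    df["qc_pass"] = df["qc_pass"].astype(bool)
    return SampleTable(df[list(SAMPLE_COLUMNS)])


def write_sample_table(samples: SampleTable, path: str | Path) -> None:
    df = samples.data.copy()
    df.index.name = "sample_id"
    df.to_csv(path, sep="\t")


def read_probe_annotation(path: str | Path) -> ProbeAnnotation:
    df = pd.read_csv(path, sep="\t", index_col=0, dtype={"gene": str, "chromosome": str})
    if df.index.name != "probe_id":
        raise ParseError(f"{Path(path).name}: first column must be 'probe_id'")
    df["gene"] = df["gene"].fillna("")
    df["position"] = df["position"].astype(int)
    df["in_cpg_island"] = df["in_cpg_island"].astype(bool)
    return ProbeAnnotation(df[list(ANNOTATION_COLUMNS)])


def write_probe_annotation(ann: ProbeAnnotation, path: str | Path) -> None:
    df = ann.data.copy()
    df.index.name = "probe_id"
    df.to_csv(path, sep="\t")
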
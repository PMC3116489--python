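"""File I/O for expression matrices, labels, rankings and ROC tables.

The on-disk formats are deliberately minimal plain text:

* expression matrix — tab- or comma-delimited, rows = probes, first column
  the probe id, remaining column headers either ``t<time>_r<rep>`` or
  described by an external design file (columns ``column``, ``time``,
  ``replicate``); missing values are empty cells or ``NA`` only;
* label file — two columns (probe_id, 0/1);
* ranking — TSV (rank, probe_id, score, lml_h1, lml_h0, converged) with
  scores at full double precision so re-ranking is byte-reproducible;
* ROC table — a ``# auc=`` summary line, then (threshold, fpr, tpr) rows.
"""

from __future__ import annotations

import io
import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .evaluate import ROCCurve
from .gp_core import TimeCourseProfile
from .ranking import RankRecord
from .simulate import SimulatedDataset

__all__ = [
    "ExpressionMatrix",
    "ParseError",
    "read_expression_matrix",
    "write_expression_matrix",
    "dataset_to_matrix",
    "read_labels",
    "write_labels",
    "write_ranking",
    "read_scores",
    "write_roc",
]

_COLUMN_RE = re.compile(r"^t(?P<time>-?\d+(?:\.\d+)?)_r(?P<rep>\d+)$")
_FLOAT_FMT = "%.17g"


class ParseError(ValueError):
    """Malformed input file; the message names the offending line."""


@dataclass
class ExpressionMatrix:
    """In-memory expression matrix with a per-column (time, replicate) design."""

    probe_ids: list[str]
    design: list[tuple[float, int]]
    values: np.ndarray  # (n_probes, n_columns); NaN marks missing
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.probe_ids), len(self.design)):
            raise ValueError("values shape must be (len(probe_ids), len(design))")
        if len(set(self.probe_ids)) != len(self.probe_ids):
            raise ValueError("probe_ids must be unique")
        for t, r in self.design:
            if not math.isfinite(t):
                raise ValueError("design times must be finite")
            if r < 1:
                raise ValueError("replicate_index must be >= 1")

    def to_profiles(self) -> list[TimeCourseProfile]:
        times = np.array([t for t, _ in self.design], dtype=float)
        out = []
        for i, pid in enumerate(self.probe_ids):
            row = self.values[i]
            out.append(TimeCourseProfile(pid, times, row, np.isnan(row)))
        return out


def _column_header(time: float, rep: int) -> str:
    return f"t{time:g}_r{rep}"


def _parse_design_header(columns: Sequence[str]) -> list[tuple[float, int]]:
    design = []
    for c in columns:
        m = _COLUMN_RE.match(c)
        if m is None:
            raise ParseError(
                f"line 1: column header {c!r} does not match 't<time>_r<rep>' "
                "and no design file was given"
            )
        design.append((float(m.group("time")), int(m.group("rep"))))
    return design


def _read_design_file(path: str | Path) -> dict[str, tuple[float, int]]:
    df = pd.read_csv(path, sep=None, engine="python", dtype=str)
    required = {"column", "time", "replicate"}
    if not required.issubset(df.columns):
        raise ParseError(f"design file {path}: needs columns {sorted(required)}")
    return {
        str(row["column"]): (float(row["time"]), int(row["replicate"]))
        for _, row in df.iterrows()
    }


def read_expression_matrix(path: str | Path, design_spec: str | Path | None = None) -> ExpressionMatrix:
    """Read a tab- or comma-delimited expression matrix.

    Missing values are empty cells or ``NA``; anything else non-numeric is a
    parse error naming its line.  Column order follows the file.
    """
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
    sep = "\t" if "\t" in first else ","
    try:
        df = pd.read_csv(
            path, sep=sep, dtype=str, keep_default_na=False,
            skip_blank_lines=False, engine="python",
        )
    except pd.errors.ParserError as e:
        raise ParseError(f"{path}: {e}") from None
    if df.shape[1] < 2:
        raise ParseError(f"{path} line 1: expected a probe-id column plus data columns")
    header = list(df.columns)
    probe_col, data_cols = header[0], header[1:]
    if design_spec is not None:
        mapping = _read_design_file(design_spec)
        try:
            design = [mapping[c] for c in data_cols]
        except KeyError as e:
            raise ParseError(f"{path} line 1: column {e.args[0]!r} missing from design file") from None
    else:
        design = _parse_design_header(data_cols)

    probe_ids = df[probe_col].astype(str).tolist()
    seen: dict[str, int] = {}
    for i, pid in enumerate(probe_ids):
        if pid in seen:
            raise ParseError(f"{path} line {i + 2}: duplicate probe id {pid!r} (first at line {seen[pid] + 2})")
        seen[pid] = i

    values = np.empty((len(probe_ids), len(data_cols)))
    for j, col in enumerate(data_cols):
        raw = df[col].to_numpy(dtype=object)
        for i, cell in enumerate(raw):
            cell = cell.strip() if isinstance(cell, str) else cell
            if cell in ("", "NA"):
                values[i, j] = np.nan
                continue
            try:
                values[i, j] = float(cell)
            except (TypeError, ValueError):
                raise ParseError(
                    f"{path} line {i + 2}: cell {cell!r} in column {col!r} is not numeric "
                    "(missing values must be empty or 'NA')"
                ) from None
    return ExpressionMatrix(
        probe_ids, design, values,
        provenance={"path": str(path), "design_spec": None if design_spec is None else str(design_spec)},
    )


def write_expression_matrix(matrix: ExpressionMatrix, path: str | Path) -> None:
    """Write a TSV matrix with ``t<time>_r<rep>`` headers; NaN becomes 'NA'."""
    with open(path, "w") as fh:
        cols = "\t".join(_column_header(t, r) for t, r in matrix.design)
        fh.write(f"probe_id\t{cols}\n")
        for pid, row in zip(matrix.probe_ids, matrix.values):
            cells = "\t".join("NA" if math.isnan(v) else _FLOAT_FMT % v for v in row)
            fh.write(f"{pid}\t{cells}\n")


def dataset_to_matrix(dataset: SimulatedDataset) -> ExpressionMatrix:
    """Pack a simulated dataset into an ExpressionMatrix (shared design).

    Replicate indices are assigned in observation order within each repeated
    time coordinate.
    """
    ref = dataset.profiles[0]
    design: list[tuple[float, int]] = []
    counts: dict[float, int] = {}
    for t in ref.times:
        counts[t] = counts.get(t, 0) + 1
        design.append((float(t), counts[t]))
    values = np.vstack([p.values for p in dataset.profiles])
    # mark any masked entries as NaN
    for i, p in enumerate(dataset.profiles):
        values[i, p.missing_mask] = np.nan
    return ExpressionMatrix([p.probe_id for p in dataset.profiles], design, values,
                            provenance={"source": "simulated"})


def write_labels(probe_ids: Sequence[str], labels: Sequence[int], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("probe_id\tlabel\n")
        for pid, lab in zip(probe_ids, labels):
            fh.write(f"{pid}\t{int(lab)}\n")


def read_labels(path: str | Path) -> dict[str, int]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"probe_id", "label"}.issubset(df.columns):
        raise ParseError(f"{path} line 1: expected columns probe_id, label")
    out: dict[str, int] = {}
    for i, row in df.iterrows():
        lab = row["label"].strip()
        if lab not in ("0", "1"):
            raise ParseError(f"{path} line {i + 2}: label must be 0 or 1, got {lab!r}")
        out[str(row["probe_id"])] = int(lab)
    return out


def write_ranking(records: Sequence[RankRecord], path: str | Path) -> None:
    """TSV of ranked records, sorted by rank, full double precision."""
    recs = sorted(records, key=lambda r: r.rank)
    with open(path, "w") as fh:
        fh.write("rank\tprobe_id\tscore\tlml_h1\tlml_h0\tconverged\n")
        for r in recs:
            fh.write(
                f"{r.rank}\t{r.probe_id}\t{_FLOAT_FMT % r.score}\t"
                f"{_FLOAT_FMT % r.lml_h1}\t{_FLOAT_FMT % r.lml_h0}\t"
                f"{int(r.best_fit.converged)}\n"
            )


def read_scores(path: str | Path) -> dict[str, float]:
    """Read (probe_id, score) pairs from a ranking TSV or a two-column file."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if {"probe_id", "score"}.issubset(df.columns):
        pid_col, score_col = "probe_id", "score"
    elif df.shape[1] == 2:
        pid_col, score_col = df.columns[0], df.columns[1]
    else:
        raise ParseError(f"{path} line 1: expected probe_id/score columns")
    return {str(p): float(s) for p, s in zip(df[pid_col], df[score_col])}


def write_roc(roc: ROCCurve, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# auc={_FLOAT_FMT % roc.auc}\n")
        fh.write("threshold\tfpr\ttpr\n")
        for thr, f, t in zip(roc.thresholds, roc.fpr, roc.tpr):
            fh.write(f"{_FLOAT_FMT % thr}\t{_FLOAT_FMT % f}\t{_FLOAT_FMT % t}\n")
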
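"""Readers and writers for the flat evidence template and result tables.

The template dialect (normative copy in ``templates/evidence_template.csv``):

    Evidence,Weight,<Prop 1>,...,<Prop N>
    Evidence 1,10,90%,0,0
    ...

One row per evidence body.  The first column holds free-text row labels, the
required ``Weight`` column holds raw (un-normalized) importances, and the
remaining columns are the frame's propositions in order.  Belief cells may
be decimals (``0.9``) or percent strings (``90%``); blanks read as zero.
CSV is RFC-4180-style UTF-8; XLSX uses the first worksheet only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence, Union

import numpy as np
import pandas as pd

from .core import EvidenceBody, Frame, validate_evidence
from .engine import FusionResult, er_fuse
from .errors import InputFormatError, UnknownAlgorithmError, ValidationError
from .rules import dempster_fuse, murphy_fuse, yager_fuse

logger = logging.getLogger(__name__)

WEIGHT_COLUMN = "Weight"
UNCERTAINTY_COLUMN = "Uncertainty"

#: Recognized algorithm tags (case-insensitive) -> canonical name.
ALGORITHM_ALIASES = {
    "er": "ER",
    "demp": "Dempster",
    "dempster": "Dempster",
    "yager": "Yager",
    "murphy": "Murphy",
}


@dataclass(frozen=True)
class EvidenceTable:
    """A parsed flat evidence file: frame, rows, raw weights."""

    frame: Frame
    evidence: tuple[EvidenceBody, ...]
    weights: np.ndarray
    source: str = "in-memory"

    def __post_init__(self):
        w = np.asarray(self.weights, dtype=float)
        w.flags.writeable = False
        object.__setattr__(self, "weights", w)
        object.__setattr__(self, "evidence", tuple(self.evidence))
        if len(self.evidence) != self.weights.shape[0]:
            raise ValidationError(
                f"{len(self.evidence)} evidence rows but "
                f"{self.weights.shape[0]} weights in {self.source}"
            )

    @property
    def n_evidence(self) -> int:
        return len(self.evidence)

    @property
    def dbf(self) -> np.ndarray:
        """The degrees-of-belief matrix, evidence rows x proposition columns."""
        return np.vstack([ev.beliefs for ev in self.evidence])


def parse_belief_cell(value, *, where: str = "") -> float:
    """Parse one belief cell: decimal, percent string, or blank (= 0).

    Comma-decimal strings ("0,9") are rejected rather than misparsed.
    """
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return 0.0
    if isinstance(value, (int, float, np.integer, np.floating)):
        return float(value)
    text = str(value).strip()
    if not text:
        return 0.0
    scale = 1.0
    if text.endswith("%"):
        text = text[:-1].strip()
        scale = 0.01
    try:
        return float(text) * scale
    except ValueError:
        raise InputFormatError(
            f"non-numeric cell {value!r}{' at ' + where if where else ''}"
        ) from None


def _raw_header(path: Path) -> list[str]:
    """First-row cell texts, before pandas mangles duplicate names."""
    suffix = path.suffix.lower()
    if suffix == ".csv":
        import csv

        with open(path, encoding="utf-8", newline="") as fh:
            return next(csv.reader(fh), [])
    import openpyxl

    ws = openpyxl.load_workbook(path, read_only=True).worksheets[0]
    first = next(ws.iter_rows(max_row=1, values_only=True), ())
    return ["" if c is None else str(c) for c in first]


def _read_raw_table(path: Path) -> pd.DataFrame:
    suffix = path.suffix.lower()
    try:
        if suffix == ".csv":
            return pd.read_csv(path, dtype=object, encoding="utf-8")
        if suffix == ".xlsx":
            return pd.read_excel(path, dtype=object, sheet_name=0)
    except FileNotFoundError:
        raise InputFormatError(f"file not found: {path}") from None
    except Exception as exc:
        raise InputFormatError(f"cannot parse {path}: {exc}") from exc
    raise InputFormatError(f"unsupported file type {suffix!r} (expect .csv or .xlsx)")


def read_evidence_table(path: Union[str, Path]) -> EvidenceTable:
    """Read and validate a flat evidence file (CSV or XLSX)."""
    path = Path(path)
    df = _read_raw_table(path)
    if df.empty or df.shape[1] < 2:
        raise InputFormatError(f"empty or header-only table in {path}")
    raw_header = _raw_header(path)
    if len(set(raw_header)) != len(raw_header):
        raise InputFormatError(f"duplicate proposition headers in {path}")
    columns = [str(c) for c in df.columns]
    if WEIGHT_COLUMN not in columns:
        raise InputFormatError(f"missing required {WEIGHT_COLUMN!r} column in {path}")
    label_col = columns[0] if columns[0] != WEIGHT_COLUMN else None
    prop_cols = [c for c in columns if c != WEIGHT_COLUMN and c != label_col]
    if not prop_cols:
        raise InputFormatError(f"no proposition columns in {path}")
    if len(set(prop_cols)) != len(prop_cols):
        raise InputFormatError(f"duplicate proposition headers in {path}")
    frame = Frame(tuple(prop_cols))

    evidence: list[EvidenceBody] = []
    weights: list[float] = []
    for idx, row in df.iterrows():
        label = str(row[label_col]) if label_col else f"Evidence {idx + 1}"
        beliefs = [
            parse_belief_cell(row[c], where=f"{path} row {label!r}, column {c!r}")
            for c in prop_cols
        ]
        try:
            evidence.append(validate_evidence(beliefs, label=label))
        except ValidationError as exc:
            raise ValidationError(f"{exc} (file {path})") from exc
        weights.append(
            parse_belief_cell(
                row[WEIGHT_COLUMN], where=f"{path} row {label!r}, column 'Weight'"
            )
        )
    return EvidenceTable(
        frame=frame,
        evidence=tuple(evidence),
        weights=np.asarray(weights, dtype=float),
        source=str(path),
    )


def resolve_algorithm(tag: str) -> str:
    """Map a case-insensitive algorithm tag to its canonical name."""
    canonical = ALGORITHM_ALIASES.get(str(tag).strip().lower())
    if canonical is None:
        valid = ", ".join(sorted(set(ALGORITHM_ALIASES)))
        raise UnknownAlgorithmError(
            f"unknown algorithm {tag!r}; valid tags: {valid}"
        )
    return canonical


def fuse_table(table: EvidenceTable, algorithm: str = "ER") -> FusionResult:
    """Run one fusion rule over a parsed table.

    The weighted recursion uses the table's weights; the weight-free rules
    discard them (with a logged warning)."""
    canonical = resolve_algorithm(algorithm)
    if canonical == "ER":
        return er_fuse(list(table.evidence), table.weights, table.frame)
    rule = {
        "Dempster": dempster_fuse,
        "Yager": yager_fuse,
        "Murphy": murphy_fuse,
    }[canonical]
    return rule(list(table.evidence), table.frame, weights=table.weights)


def run_from_file(path: Union[str, Path], algorithm: str = "ER") -> FusionResult:
    """Read a flat evidence file and fuse it with the requested rule."""
    resolve_algorithm(algorithm)  # fail fast before touching the file
    return fuse_table(read_evidence_table(path), algorithm)


def _result_row(result: FusionResult, precision: int | None):
    values = list(result.beliefs) + [result.uncertainty]
    if precision is not None:
        values = [round(v, precision) for v in values]
    return values


def write_result(
    result: FusionResult,
    path: Union[str, Path],
    precision: int | None = None,
) -> None:
    """Write one fused result as a one-row CSV (propositions + uncertainty).

    Values are written at full precision unless ``precision`` is given."""
    write_result_table({"Result": result}, path, precision=precision, label_header=None)


def write_result_table(
    results: Mapping[str, FusionResult],
    path: Union[str, Path],
    precision: int | None = None,
    label_header: str | None = "Object",
) -> None:
    """Write labeled fused results, one row per object."""
    results = dict(results)
    if not results:
        raise ValidationError("no results to write")
    frames = {r.frame for r in results.values()}
    if len(frames) != 1:
        raise ValidationError("results span different frames")
    frame = next(iter(frames))
    columns = list(frame.propositions) + [UNCERTAINTY_COLUMN]
    rows = {label: _result_row(r, precision) for label, r in results.items()}
    df = pd.DataFrame.from_dict(rows, orient="index", columns=columns)
    df.index.name = label_header
    df.to_csv(path, index=label_header is not None, encoding="utf-8")


def read_result(path: Union[str, Path]) -> FusionResult:
    """Read back a one-row result CSV written by :func:`write_result`."""
    df = pd.read_csv(path, encoding="utf-8")
    if UNCERTAINTY_COLUMN not in df.columns:
        raise InputFormatError(f"missing {UNCERTAINTY_COLUMN!r} column in {path}")
    prop_cols = [c for c in df.columns if c not in (UNCERTAINTY_COLUMN, "Object")]
    row = df.iloc[0]
    return FusionResult(
        beliefs=np.asarray([float(row[c]) for c in prop_cols]),
        uncertainty=float(row[UNCERTAINTY_COLUMN]),
        algorithm="unknown",
        frame=Frame(tuple(prop_cols)),
    )


def evidence_table_from_arrays(
    dbf,
    weights,
    propositions: Sequence[str] | None = None,
    labels: Sequence[str] | None = None,
) -> EvidenceTable:
    """Build a table from a DBF matrix and raw weights (programmatic entry)."""
    dbf = np.asarray(dbf, dtype=float)
    if dbf.ndim != 2:
        raise ValidationError("DBF must be a 2-d matrix (evidence x propositions)")
    n_e, n_p = dbf.shape
    frame = (
        Frame(tuple(str(p) for p in propositions))
        if propositions is not None
        else Frame.generic(n_p)
    )
    if frame.n_propositions != n_p:
        raise ValidationError(
            f"{len(frame.propositions)} proposition labels for {n_p} DBF columns"
        )
    if labels is None:
        labels = [f"Evidence {i + 1}" for i in range(n_e)]
    evidence = tuple(
        validate_evidence(dbf[i], label=str(labels[i])) for i in range(n_e)
    )
    return EvidenceTable(
        frame=frame,
        evidence=evidence,
        weights=np.asarray(weights, dtype=float),
    )
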
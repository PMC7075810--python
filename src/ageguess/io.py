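"""Readers and writers for the plain-text formats the toolkit consumes.

Beta matrices travel as TSV with a sample-id header row and one probe per
row, either plain or in the GEO series-matrix dialect (``!``-prefixed
comment lines, table body between ``!series_matrix_table_begin`` and
``!series_matrix_table_end``).  Metadata and annotation are small CSVs.
"""

from __future__ import annotations

import csv
import logging
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .datamodel import FeatureAnnotation, MethylomeMatrix, SampleMetadata
from .errors import FormatError, ValidationError

logger = logging.getLogger(__name__)

MISSING_TOKENS = {"", "na", "null", "nan"}
#: token written for a missing beta value
MISSING_OUT = "NA"

_TABLE_BEGIN = "!series_matrix_table_begin"
_TABLE_END = "!series_matrix_table_end"

Dialect = Literal["plain_tsv", "geo_series_matrix"]


def read_beta_matrix(path: str | Path, dialect: Dialect = "plain_tsv") -> MethylomeMatrix:
    """Parse a beta-value matrix from TSV.

    The first row is the sample header; each subsequent row is a probe id
    followed by one beta value per sample.  Empty fields and ``NA``/``null``
    (case-insensitive) become missing values.  Ragged rows, duplicate ids
    and out-of-range values raise precise errors.
    """
    text = Path(path).read_text(encoding="utf-8")
    if dialect == "geo_series_matrix":
        lines, offset = _extract_geo_table(text, path)
    elif dialect == "plain_tsv":
        lines = text.splitlines()
        offset = 0
    else:
        raise ValueError(f"unknown dialect {dialect!r}")

    lines = [ln for ln in lines if ln != ""]
    if not lines:
        raise FormatError(f"{path}: no table content")

    header = lines[0].rstrip("\n").split("\t")
    sample_ids = [_unquote(s) for s in header[1:]]
    n_cols = len(header)

    probe_ids: list[str] = []
    rows: list[np.ndarray] = []
    for k, ln in enumerate(lines[1:], start=2):
        fields = ln.split("\t")
        if len(fields) != n_cols:
            raise FormatError(
                f"{path}: line {k + offset}: expected {n_cols} fields, "
                f"got {len(fields)}"
            )
        probe_ids.append(_unquote(fields[0]))
        rows.append(_parse_row(fields[1:], path, k + offset))
    values = (
        np.vstack(rows) if rows else np.empty((0, len(sample_ids)), dtype=np.float64)
    )
    return MethylomeMatrix(probe_ids, sample_ids, values)


def _extract_geo_table(text: str, path: str | Path) -> tuple[list[str], int]:
    lines = text.splitlines()
    begin = end = None
    for i, ln in enumerate(lines):
        s = ln.strip().lower()
        if s == _TABLE_BEGIN:
            begin = i
        elif s == _TABLE_END:
            end = i
    if begin is None or end is None or end <= begin:
        raise FormatError(f"{path}: missing series-matrix table sentinels")
    body = [ln for ln in lines[begin + 1 : end] if not ln.startswith("!")]
    return body, begin + 1


def _unquote(s: str) -> str:
    s = s.strip()
    if len(s) >= 2 and s[0] == '"' and s[-1] == '"':
        s = s[1:-1]
    return s


def _parse_row(fields: Sequence[str], path: str | Path, lineno: int) -> np.ndarray:
    out = np.empty(len(fields), dtype=np.float64)
    for j, f in enumerate(fields):
        f = _unquote(f)
        if f.lower() in MISSING_TOKENS:
            out[j] = np.nan
            continue
        try:
            out[j] = float(f)
        except ValueError as exc:
            raise FormatError(
                f"{path}: line {lineno}: non-numeric value {f!r}"
            ) from exc
    return out


def write_beta_matrix(matrix: MethylomeMatrix, path: str | Path) -> None:
    """Write a matrix as plain TSV; :func:`read_beta_matrix` inverts it.

    Values use Python's shortest round-trip float rendering, so the
    read-back matrix is bit-identical.
    """
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("probe_id\t" + "\t".join(matrix.sample_ids) + "\n")
        for i, p in enumerate(matrix.probe_ids):
            row = matrix.values[i]
            cells = [MISSING_OUT if np.isnan(v) else repr(float(v)) for v in row]
            fh.write(p + "\t" + "\t".join(cells) + "\n")


_SEX_MAP = {
    "m": "male",
    "male": "male",
    "f": "female",
    "female": "female",
    "unknown": "unknown",
    "u": "unknown",
    "": "unknown",
}


def read_metadata(path: str | Path) -> list[SampleMetadata]:
    """Read sample metadata CSV with columns (sample_id, age, sex).

    Unrecognised sex strings map to ``unknown`` with a logged warning;
    a non-numeric or non-positive age is a hard validation error.
    """
    df = _read_csv(path, ["sample_id", "age", "sex"])
    records: list[SampleMetadata] = []
    for row in df.itertuples(index=False):
        sid = str(row.sample_id)
        try:
            age = float(row.age)
        except (TypeError, ValueError) as exc:
            raise ValidationError(
                f"{path}: sample {sid!r}: non-numeric age {row.age!r}"
            ) from exc
        raw_sex = "" if pd.isna(row.sex) else str(row.sex).strip().lower()
        sex = _SEX_MAP.get(raw_sex)
        if sex is None:
            logger.warning(
                "read_metadata: sample %r: unrecognised sex %r mapped to unknown",
                sid,
                row.sex,
            )
            sex = "unknown"
        records.append(SampleMetadata(sid, age, sex))
    _check_one_per_id([r.sample_id for r in records], path, "sample_id")
    return records


def read_annotation(path: str | Path) -> list[FeatureAnnotation]:
    """Read probe annotation CSV with columns (probe_id, chromosome, gene)."""
    df = _read_csv(path, ["probe_id", "chromosome"])
    has_gene = "gene" in df.columns
    records: list[FeatureAnnotation] = []
    for row in df.itertuples(index=False):
        gene = None
        if has_gene and not pd.isna(row.gene) and str(row.gene).strip():
            gene = str(row.gene).strip()
        records.append(
            FeatureAnnotation(str(row.probe_id), str(row.chromosome).strip(), gene)
        )
    _check_one_per_id([r.probe_id for r in records], path, "probe_id")
    return records


def _read_csv(path: str | Path, required: list[str]) -> pd.DataFrame:
    df = pd.read_csv(path, dtype=str)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")
    return df


def _check_one_per_id(ids: list[str], path: str | Path, what: str) -> None:
    seen: set[str] = set()
    for x in ids:
        if x in seen:
            raise FormatError(f"{path}: duplicate {what} {x!r}")
        seen.add(x)


def write_metadata(metadata: Iterable[SampleMetadata], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["sample_id", "age", "sex"])
        for m in metadata:
            w.writerow([m.sample_id, repr(float(m.age)), m.sex])


def write_annotation(annotation: Iterable[FeatureAnnotation], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["probe_id", "chromosome", "gene"])
        for a in annotation:
            w.writerow([a.probe_id, a.chromosome, a.gene or ""])


def write_probe_list(probes: Sequence[str], path: str | Path) -> None:
    Path(path).write_text("\n".join(probes) + ("\n" if probes else ""), "utf-8")


def read_probe_list(path: str | Path) -> list[str]:
    return [ln.strip() for ln in Path(path).read_text("utf-8").splitlines() if ln.strip()]
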
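"""Core in-memory containers for methylome data.

A methylome experiment is represented by three aligned pieces: a dense
probes x samples matrix of beta values (methylation fractions in [0, 1],
NaN marks a missing measurement), per-sample metadata carrying the
chronological age (the regression target) and sex, and per-probe
annotation carrying the chromosome assignment used to drop sex-chromosome
probes before any age modelling.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np

from .errors import AlignmentError, AnnotationError, RangeError, ValidationError

logger = logging.getLogger(__name__)

#: tolerance for floating round-trip noise just outside [0, 1]
BETA_CLAMP_TOL = 1e-9

Sex = Literal["male", "female", "unknown"]


@dataclass
class MethylomeMatrix:
    """Dense probes x samples beta-value matrix.

    Parameters
    ----------
    probe_ids
        Row identifiers (e.g. ``cg00000029``); unique, order preserved.
    sample_ids
        Column identifiers; unique, order preserved.
    values
        ``(n_probes, n_samples)`` float array; ``NaN`` marks missing.
    """

    probe_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.probe_ids = [str(p) for p in self.probe_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2 or self.values.shape != (
            len(self.probe_ids),
            len(self.sample_ids),
        ):
            raise ValidationError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.probe_ids)} probes x {len(self.sample_ids)} samples"
            )
        _check_unique(self.probe_ids, "probe")
        _check_unique(self.sample_ids, "sample")
        self._check_range()

    def _check_range(self) -> None:
        vals = self.values
        # tolerate tiny float noise at the boundaries, then enforce strictly
        np.clip(vals, 0.0, 1.0, out=vals, where=_near_unit(vals))
        bad = np.nonzero((vals < 0.0) | (vals > 1.0))
        if bad[0].size:
            i, j = bad[0][0], bad[1][0]
            raise RangeError(
                f"beta value {vals[i, j]!r} out of [0, 1] at probe "
                f"{self.probe_ids[i]!r}, sample {self.sample_ids[j]!r}"
            )

    @property
    def n_probes(self) -> int:
        return len(self.probe_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def probe_index(self) -> dict[str, int]:
        return {p: i for i, p in enumerate(self.probe_ids)}

    def select_probes(self, probes: Sequence[str]) -> "MethylomeMatrix":
        """Return a sub-matrix restricted to ``probes`` in the given order."""
        idx = self.probe_index()
        missing = [p for p in probes if p not in idx]
        if missing:
            raise KeyError(f"unknown probe id {missing[0]!r}")
        rows = [idx[p] for p in probes]
        return MethylomeMatrix(list(probes), list(self.sample_ids), self.values[rows])

    def select_samples(self, samples: Sequence[str]) -> "MethylomeMatrix":
        idx = {s: j for j, s in enumerate(self.sample_ids)}
        missing = [s for s in samples if s not in idx]
        if missing:
            raise KeyError(f"unknown sample id {missing[0]!r}")
        cols = [idx[s] for s in samples]
        return MethylomeMatrix(list(self.probe_ids), list(samples), self.values[:, cols])

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, MethylomeMatrix):
            return NotImplemented
        return (
            self.probe_ids == other.probe_ids
            and self.sample_ids == other.sample_ids
            and np.array_equal(self.values, other.values, equal_nan=True)
        )


def _near_unit(vals: np.ndarray) -> np.ndarray:
    with np.errstate(invalid="ignore"):
        return ((vals > -BETA_CLAMP_TOL) & (vals < 0.0)) | (
            (vals > 1.0) & (vals < 1.0 + BETA_CLAMP_TOL)
        )


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen: set[str] = set()
    for x in ids:
        if x in seen:
            raise ValidationError(f"duplicate {what} id {x!r}")
        seen.add(x)


@dataclass(frozen=True)
class SampleMetadata:
    """One sample's chronological age (years, > 0) and sex."""

    sample_id: str
    age: float
    sex: Sex = "unknown"

    def __post_init__(self) -> None:
        if not np.isfinite(self.age) or self.age <= 0:
            raise ValidationError(
                f"sample {self.sample_id!r}: age must be finite and positive, "
                f"got {self.age!r}"
            )
        if self.sex not in ("male", "female", "unknown"):
            raise ValidationError(f"sample {self.sample_id!r}: bad sex {self.sex!r}")


@dataclass(frozen=True)
class FeatureAnnotation:
    """One probe's chromosome label and optional gene symbol."""

    probe_id: str
    chromosome: str
    gene: str | None = None

    def __post_init__(self) -> None:
        if not self.chromosome:
            raise ValidationError(f"probe {self.probe_id!r}: empty chromosome label")


def normalize_chromosome(label: str) -> str:
    """Canonical chromosome label: strip a leading ``chr`` prefix, uppercase."""
    label = label.strip()
    if label.lower().startswith("chr"):
        label = label[3:]
    return label.upper()


def ages_vector(metadata: Sequence[SampleMetadata]) -> np.ndarray:
    return np.array([m.age for m in metadata], dtype=np.float64)


def align_samples(
    matrix: MethylomeMatrix, metadata: Sequence[SampleMetadata]
) -> tuple[MethylomeMatrix, list[SampleMetadata]]:
    """Restrict matrix and metadata to their common samples, matrix order.

    Raises :class:`AlignmentError` when no sample id is shared.  The number
    of ids dropped from either side is logged.
    """
    by_id = {m.sample_id: m for m in metadata}
    common = [s for s in matrix.sample_ids if s in by_id]
    if not common:
        raise AlignmentError("matrix and metadata share no sample ids")
    dropped_matrix = matrix.n_samples - len(common)
    dropped_meta = len(by_id) - len(common)
    if dropped_matrix or dropped_meta:
        logger.info(
            "align_samples: dropped %d matrix samples and %d metadata records "
            "outside the intersection",
            dropped_matrix,
            dropped_meta,
        )
    return matrix.select_samples(common), [by_id[s] for s in common]


def exclude_sex_chromosomes(
    matrix: MethylomeMatrix,
    annotation: Iterable[FeatureAnnotation],
    unannotated: Literal["drop", "keep", "error"] = "drop",
) -> MethylomeMatrix:
    """Remove probes annotated to chromosome X or Y.

    Chromosome labels are normalised (``chrX`` == ``x`` == ``X``) before the
    comparison.  Probes with no annotation record are handled according to
    ``unannotated``: dropped with a warning (default), kept, or rejected.
    Probe order is otherwise preserved; the operation is idempotent.
    """
    chrom = {a.probe_id: normalize_chromosome(a.chromosome) for a in annotation}
    keep: list[str] = []
    n_unannotated = 0
    for p in matrix.probe_ids:
        c = chrom.get(p)
        if c is None:
            if unannotated == "error":
                raise AnnotationError(f"probe {p!r} has no annotation record")
            n_unannotated += 1
            if unannotated == "keep":
                keep.append(p)
            continue
        if c not in ("X", "Y"):
            keep.append(p)
    if n_unannotated and unannotated == "drop":
        logger.warning(
            "exclude_sex_chromosomes: dropped %d unannotated probe(s)", n_unannotated
        )
    return matrix.select_probes(keep)


def median_impute(values: np.ndarray, medians: np.ndarray | None = None) -> np.ndarray:
    """Fill NaN entries of a probes x samples block with per-probe medians.

    ``medians`` lets callers impute held-out samples with statistics computed
    on training samples only.  A probe with no observed value at all is
    filled with 0.5 (the uninformative midpoint of the beta scale).
    """
    out = np.array(values, dtype=np.float64, copy=True)
    if medians is None:
        medians = probe_medians(out)
    medians = np.where(np.isfinite(medians), medians, 0.5)
    nan_i, nan_j = np.nonzero(np.isnan(out))
    out[nan_i, nan_j] = medians[nan_i]
    return out


def probe_medians(values: np.ndarray) -> np.ndarray:
    """Per-probe medians over observed entries (NaN-aware), 0.5 fallback."""
    import warnings

    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", "All-NaN slice", RuntimeWarning)
        med = np.nanmedian(values, axis=1)
    return np.where(np.isfinite(med), med, 0.5)
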
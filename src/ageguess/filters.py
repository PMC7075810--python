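"""Univariate association filters between CpG beta values and age.

Four scores are available: the Maximal Information Coefficient (MIC,
the primary filter), the absolute Pearson correlation (PCC), a
histogram-based mutual-information estimate (MI), and the univariate
regression F-statistic (FR).  Signed scores are ranked by absolute value,
since age-hypomethylation is as informative as hypermethylation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from math import ceil
from pathlib import Path
from typing import Literal, Sequence

import numpy as np

from .datamodel import MethylomeMatrix
from .errors import ValidationError
from .mic import MicConfig, mic

logger = logging.getLogger(__name__)

Method = Literal["MIC", "PCC", "MI", "FR"]

#: finite stand-in for the infinite F of a perfect fit; larger than any
#: achievable finite F so ranking order is preserved
F_PERFECT_SENTINEL = 1e300


@dataclass
class FeatureRanking:
    """Probe scores for one method, descending, ties broken by probe id."""

    method: Method
    entries: list[tuple[str, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.entries = sorted(self.entries, key=lambda e: (-e[1], e[0]))

    def top(self, k: int) -> list[str]:
        return [p for p, _ in self.entries[:k]]

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("rank\tprobe_id\tscore\tmethod\n")
            for r, (p, s) in enumerate(self.entries, start=1):
                fh.write(f"{r}\t{p}\t{s!r}\t{self.method}\n")


def pearson(x: np.ndarray, y: np.ndarray) -> float:
    """Sample Pearson correlation; 0 with a warning when either side is constant."""
    x, y = _pair(x, y)
    sx, sy = x.std(), y.std()
    if sx == 0.0 or sy == 0.0:
        logger.warning("pearson: zero-variance input, returning r = 0")
        return 0.0
    r = float(np.mean((x - x.mean()) * (y - y.mean())) / (sx * sy))
    return max(-1.0, min(1.0, r))


def f_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """Univariate regression F = r^2 (n-2) / (1 - r^2), sentinel for perfect fits."""
    x, y = _pair(x, y)
    r = pearson(x, y)
    r2 = r * r
    if r2 >= 1.0:
        return F_PERFECT_SENTINEL
    return float(r2 * (x.size - 2) / (1.0 - r2))


def mutual_information_score(
    x: np.ndarray, y: np.ndarray, bins: int | None = None
) -> float:
    """Histogram mutual information in nats with equal-frequency binning.

    Both variables are discretised into ``bins`` quantile bins (default
    ceil(n**(1/3)), which keeps cell occupancy healthy) and the plug-in MI
    of the contingency table is computed with the Miller-Madow bias
    correction (r-1)(c-1)/(2n) subtracted, so independent inputs score
    near zero.  Clipped at 0.
    """
    x, y = _pair(x, y)
    n = x.size
    if bins is None:
        bins = max(2, ceil(n ** (1.0 / 3.0)))
    bx = _quantile_bins(x, bins)
    by = _quantile_bins(y, bins)
    joint = np.zeros((bx.max() + 1, by.max() + 1), dtype=np.float64)
    np.add.at(joint, (bx, by), 1.0)
    joint /= n
    px = joint.sum(axis=1)
    py = joint.sum(axis=0)
    nz = joint > 0
    mi = float((joint[nz] * np.log(joint[nz] / np.outer(px, py)[nz])).sum())
    mi -= ((px > 0).sum() - 1) * ((py > 0).sum() - 1) / (2.0 * n)
    return max(0.0, mi)


def _quantile_bins(v: np.ndarray, bins: int) -> np.ndarray:
    edges = np.unique(np.quantile(v, np.linspace(0, 1, bins + 1)[1:-1]))
    return np.searchsorted(edges, v, side="right")


def _pair(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=np.float64).ravel()
    y = np.asarray(y, dtype=np.float64).ravel()
    if x.shape != y.shape:
        raise ValidationError(f"length mismatch: {x.size} vs {y.size}")
    if x.size < 3:
        raise ValidationError(f"need at least 3 samples, got {x.size}")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValidationError("inputs must be finite")
    return x, y


def score_feature(
    x: np.ndarray, y: np.ndarray, method: Method, mic_config: MicConfig | None = None
) -> float:
    """Association score of one feature with the target, non-negative."""
    if method == "MIC":
        return mic(x, y, mic_config)
    if method == "PCC":
        return abs(pearson(x, y))
    if method == "MI":
        return mutual_information_score(x, y)
    if method == "FR":
        return f_statistic(x, y)
    raise ValidationError(f"unknown filter method {method!r}")


def rank_features(
    matrix: MethylomeMatrix,
    ages: Sequence[float] | np.ndarray,
    method: Method = "MIC",
    mic_config: MicConfig | None = None,
) -> FeatureRanking:
    """Score every probe's association with age and rank descending.

    Missing beta values are handled pairwise: each probe is scored on its
    observed samples only.  A probe with too few observations to score is
    assigned 0 with a warning.  Ties are broken by ascending probe id, so
    the ranking is fully deterministic.
    """
    ages = np.asarray(ages, dtype=np.float64)
    if ages.size != matrix.n_samples:
        raise ValidationError(
            f"ages length {ages.size} != {matrix.n_samples} samples"
        )
    mic_config = mic_config or MicConfig()
    min_needed = mic_config.min_n if method == "MIC" else 3
    entries: list[tuple[str, float]] = []
    vals = matrix.values
    has_nan = bool(np.isnan(vals).any())
    for i, probe in enumerate(matrix.probe_ids):
        x = vals[i]
        if has_nan:
            obs = ~np.isnan(x)
            if obs.sum() < min_needed:
                logger.warning(
                    "rank_features: probe %r has %d observed values, scored 0",
                    probe,
                    int(obs.sum()),
                )
                entries.append((probe, 0.0))
                continue
            entries.append((probe, score_feature(x[obs], ages[obs], method, mic_config)))
        else:
            entries.append((probe, score_feature(x, ages, method, mic_config)))
    return FeatureRanking(method=method, entries=entries)
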
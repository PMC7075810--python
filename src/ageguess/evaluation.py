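"""Regression metrics, repeated k-fold cross-validation, and the
cross-gender and training-size experiments.

The headline metric throughout is MAD, the mean absolute deviation in
years between predicted and chronological age.  Model-size trade-offs use
the integrated evaluation index EI = MAD + FNum/100, which charges 0.01
per retained feature.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import KFold, train_test_split

from .datamodel import MethylomeMatrix, median_impute, probe_medians
from .errors import ShapeError, UndefinedMetricError, ValidationError
from .regress import RegressorConfig, fit

__all__ = [
    "mad",
    "mse",
    "rmse",
    "r2",
    "ei",
    "EvaluationReport",
    "repeated_kfold_cv",
    "CrossGenderMatrix",
    "cross_gender_evaluate",
    "learning_curve",
]


def _check(y_true, y_pred) -> tuple[np.ndarray, np.ndarray]:
    y_true = np.asarray(y_true, dtype=np.float64).ravel()
    y_pred = np.asarray(y_pred, dtype=np.float64).ravel()
    if y_true.shape != y_pred.shape:
        raise ShapeError(f"length mismatch: {y_true.size} vs {y_pred.size}")
    if y_true.size == 0:
        raise ShapeError("empty prediction set")
    if not (np.isfinite(y_true).all() and np.isfinite(y_pred).all()):
        raise ValidationError("non-finite values in metric input")
    return y_true, y_pred


def mad(y_true, y_pred) -> float:
    """Mean absolute deviation, years."""
    y_true, y_pred = _check(y_true, y_pred)
    return float(np.mean(np.abs(y_true - y_pred)))


def mse(y_true, y_pred) -> float:
    """Mean squared error, years^2."""
    y_true, y_pred = _check(y_true, y_pred)
    return float(np.mean((y_true - y_pred) ** 2))


def rmse(y_true, y_pred) -> float:
    """Root mean squared error, years; always >= MAD."""
    return float(np.sqrt(mse(y_true, y_pred)))


def r2(y_true, y_pred) -> float:
    """Coefficient of determination; undefined for constant y_true."""
    y_true, y_pred = _check(y_true, y_pred)
    ss_tot = float(np.sum((y_true - y_true.mean()) ** 2))
    if ss_tot == 0.0:
        raise UndefinedMetricError("r2 undefined: y_true has zero variance")
    ss_res = float(np.sum((y_true - y_pred) ** 2))
    return 1.0 - ss_res / ss_tot


def ei(mad_value: float, fnum: int) -> float:
    """Integrated evaluation index: MAD + FNum/100."""
    if mad_value < 0 or fnum < 0:
        raise ValidationError("ei requires mad_value >= 0 and fnum >= 0")
    return float(mad_value) + fnum / 100.0


@dataclass
class EvaluationReport:
    """Pooled cross-validated performance of one feature set."""

    mad: float
    mse: float
    rmse: float
    r2: float
    ei: float
    n_features: int
    folds: int
    repeats: int
    seed: int
    sample_ids: list[str] = field(default_factory=list)
    y_true: list[float] = field(default_factory=list)
    y_pred: list[float] = field(default_factory=list)
    fold_mads: list[float] = field(default_factory=list)

    def mad_se(self) -> float:
        """Standard error of MAD across folds (repeats pooled)."""
        fm = np.asarray(self.fold_mads)
        if fm.size < 2:
            return 0.0
        return float(fm.std(ddof=1) / np.sqrt(fm.size))

    def to_json(self, path: str | Path | None = None) -> str:
        d = {
            "mad": self.mad,
            "mse": self.mse,
            "rmse": self.rmse,
            "r2": self.r2,
            "ei": self.ei,
            "n_features": self.n_features,
            "folds": self.folds,
            "repeats": self.repeats,
            "seed": self.seed,
        }
        text = json.dumps(d, indent=1, sort_keys=True)
        if path is not None:
            Path(path).write_text(text, "utf-8")
        return text

    def predictions_csv(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("sample_id,real_age,pred_age\n")
            for s, t, p in zip(self.sample_ids, self.y_true, self.y_pred):
                fh.write(f"{s},{t!r},{p!r}\n")


def derive_seed(seed: int, *salts: int) -> int:
    """Deterministic sub-seed below 2**31, stable across platforms."""
    mask = (1 << 64) - 1
    h = (int(seed) * 0x9E3779B97F4A7C15) & mask
    for s in salts:
        h = ((h ^ (int(s) + 1)) * 0xBF58476D1CE4E5B9) & mask
    return h % (2**31)


def repeated_kfold_cv(
    matrix: MethylomeMatrix,
    ages: Sequence[float] | np.ndarray,
    probes: Sequence[str],
    config: RegressorConfig,
    folds: int = 10,
    repeats: int = 10,
    seed: int = 0,
) -> EvaluationReport:
    """Repeated k-fold CV of a linear age model on a probe subset.

    Each repeat draws a fresh shuffled fold partition from a repeat-specific
    seed.  Within a fold, imputation medians and standardisation statistics
    come from the training folds only.  Per-sample predictions are averaged
    over repeats and the metrics are computed on the pooled means, matching
    how per-sample predicted ages are usually plotted against real ages.
    """
    ages = np.asarray(ages, dtype=np.float64)
    n = matrix.n_samples
    if ages.size != n:
        raise ValidationError(f"ages length {ages.size} != {n} samples")
    if folds < 2 or folds > n:
        raise ValidationError(f"folds must be in [2, {n}], got {folds}")
    if not probes:
        raise ValidationError("empty probe set")
    sub = matrix.select_probes(probes)
    V = sub.values  # probes x samples
    preds = np.zeros((repeats, n), dtype=np.float64)
    fold_mads: list[float] = []
    for r in range(repeats):
        kf = KFold(n_splits=folds, shuffle=True, random_state=derive_seed(seed, r))
        for train_idx, test_idx in kf.split(np.arange(n)):
            med = probe_medians(V[:, train_idx])
            Xtr = median_impute(V[:, train_idx], med).T
            Xte = median_impute(V[:, test_idx], med).T
            model = fit(Xtr, ages[train_idx], config, probe_ids=list(probes))
            preds[r, test_idx] = model.predict(Xte)
            fold_mads.append(
                float(np.mean(np.abs(preds[r, test_idx] - ages[test_idx])))
            )
    y_pred = preds.mean(axis=0)
    m = mad(ages, y_pred)
    s = mse(ages, y_pred)
    return EvaluationReport(
        mad=m,
        mse=s,
        rmse=float(np.sqrt(s)),
        r2=r2(ages, y_pred),
        ei=ei(m, len(probes)),
        n_features=len(probes),
        folds=folds,
        repeats=repeats,
        seed=seed,
        sample_ids=list(sub.sample_ids),
        y_true=[float(a) for a in ages],
        y_pred=[float(p) for p in y_pred],
        fold_mads=fold_mads,
    )


@dataclass
class CrossGenderMatrix:
    """MAD (years) of each biomarker set evaluated on each dataset."""

    model_names: list[str]
    dataset_names: list[str]
    values: np.ndarray  # models x datasets

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.model_names, columns=self.dataset_names
        )

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="biomarker_set")


def cross_gender_evaluate(
    datasets: Mapping[str, tuple[MethylomeMatrix, np.ndarray]],
    biomarker_sets: Mapping[str, Sequence[str]],
    config: RegressorConfig,
    folds: int = 10,
    repeats: int = 10,
    seed: int = 0,
) -> CrossGenderMatrix:
    """Cross-validated MAD of every biomarker set on every dataset.

    Cell (i, j) refits the regressor on dataset j restricted to biomarker
    set i, so the comparison isolates how age-informative each probe set is
    within each population rather than how one fitted model transfers.
    """
    model_names = list(biomarker_sets)
    dataset_names = list(datasets)
    out = np.empty((len(model_names), len(dataset_names)), dtype=np.float64)
    for i, mname in enumerate(model_names):
        probes = list(biomarker_sets[mname])
        if not probes:
            raise ValidationError(f"biomarker set {mname!r} is empty")
        for j, dname in enumerate(dataset_names):
            matrix, ages = datasets[dname]
            have = set(matrix.probe_ids)
            for p in probes:
                if p not in have:
                    raise ValidationError(
                        f"probe {p!r} of set {mname!r} absent from dataset {dname!r}"
                    )
            # one shared seed: cells must depend only on their (set, dataset)
            # pair so that relabelling datasets permutes columns identically
            report = repeated_kfold_cv(
                matrix, ages, probes, config, folds=folds, repeats=repeats, seed=seed
            )
            out[i, j] = report.mad
    return CrossGenderMatrix(model_names, dataset_names, out)


def learning_curve(
    matrix: MethylomeMatrix,
    ages: Sequence[float] | np.ndarray,
    probes: Sequence[str],
    configs: Mapping[str, RegressorConfig],
    fractions: Sequence[float] = (0.2, 0.4, 0.6, 0.8, 1.0),
    test_fraction: float = 0.3,
    seed: int = 0,
    stratify_by_age: bool = True,
) -> pd.DataFrame:
    """Test-set performance as a function of training-set size.

    One random split (stratified by age decile by default) reserves
    ``test_fraction`` of samples as a fixed test set.  For each fraction,
    a nested subset of the training samples is used — larger fractions
    contain smaller ones — so the curves are monotone-comparable.
    Returns a tidy table (regressor, fraction, n_train, mad, rmse, r2).
    """
    ages = np.asarray(ages, dtype=np.float64)
    n = matrix.n_samples
    if ages.size != n:
        raise ValidationError(f"ages length {ages.size} != {n} samples")
    fractions = sorted(set(float(f) for f in fractions))
    if not fractions or fractions[0] <= 0 or fractions[-1] > 1:
        raise ValidationError("fractions must lie in (0, 1]")
    idx = np.arange(n)
    strat = None
    if stratify_by_age:
        strat = pd.qcut(ages, q=min(10, max(2, n // 10)), duplicates="drop").codes
    train_idx, test_idx = train_test_split(
        idx, test_size=test_fraction, random_state=derive_seed(seed, 0), stratify=strat
    )
    if np.ceil(fractions[0] * train_idx.size) < 2:
        raise ValidationError(
            f"fraction {fractions[0]} leaves fewer than 2 training samples"
        )
    rng = np.random.default_rng(derive_seed(seed, 1))
    order = rng.permutation(train_idx)

    sub = matrix.select_probes(probes)
    V = sub.values
    rows: list[dict] = []
    for name, cfg in configs.items():
        for frac in fractions:
            k = int(np.ceil(frac * order.size))
            tr = np.sort(order[:k])
            med = probe_medians(V[:, tr])
            Xtr = median_impute(V[:, tr], med).T
            Xte = median_impute(V[:, test_idx], med).T
            model = fit(Xtr, ages[tr], cfg, probe_ids=list(probes))
            pred = model.predict(Xte)
            rows.append(
                {
                    "regressor": name,
                    "fraction": frac,
                    "n_train": k,
                    "mad": mad(ages[test_idx], pred),
                    "rmse": rmse(ages[test_idx], pred),
                    "r2": r2(ages[test_idx], pred),
                }
            )
    return pd.DataFrame(rows)


def learning_curve_difference(
    table: pd.DataFrame, a: str = "svr", b: str = "ridge"
) -> pd.DataFrame:
    """Metric differences (a minus b) per fraction from a learning-curve table."""
    ta = table[table["regressor"] == a].set_index("fraction")
    tb = table[table["regressor"] == b].set_index("fraction")
    out = pd.DataFrame(
        {
            "fraction": ta.index,
            "mad_diff": (ta["mad"] - tb["mad"]).values,
            "rmse_diff": (ta["rmse"] - tb["rmse"]).values,
            "r2_diff": (ta["r2"] - tb["r2"]).values,
        }
    ).reset_index(drop=True)
    return out
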
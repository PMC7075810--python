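"""Linear regression backends: epsilon-insensitive SVR and ridge.

Both models are linear in the beta values, which is what makes the
per-feature "feature importance" vector well defined: importance is the
absolute coefficient on the standardised scale, so features are compared
on equal footing regardless of their raw dynamic range.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
from sklearn.linear_model import Ridge
from sklearn.svm import LinearSVR

from .errors import FitError, ShapeError, ValidationError

logger = logging.getLogger(__name__)

Kind = Literal["svr", "ridge"]


@dataclass(frozen=True)
class RegressorConfig:
    """Hyperparameters of the linear regressors.

    svr_c
        SVR penalty C (dimensionless), > 0.
    svr_epsilon
        Width of the insensitivity tube, in years.
    ridge_lambda
        L2 penalty on the (standardised) coefficients.
    standardize
        Whether to z-score features on the training data before fitting;
        on by default because SVR importance is scale-sensitive.
    """

    kind: Kind = "svr"
    svr_c: float = 1.0
    svr_epsilon: float = 0.1
    svr_loss: Literal["epsilon_insensitive", "squared_epsilon_insensitive"] = (
        "epsilon_insensitive"
    )
    ridge_lambda: float = 1.0
    standardize: bool = True
    tol: float = 1e-4
    max_iter: int = 10_000

    def __post_init__(self) -> None:
        if self.kind not in ("svr", "ridge"):
            raise ValidationError(f"unknown regressor kind {self.kind!r}")
        if self.svr_loss not in (
            "epsilon_insensitive",
            "squared_epsilon_insensitive",
        ):
            raise ValidationError(f"unknown svr loss {self.svr_loss!r}")
        if self.svr_c <= 0:
            raise ValidationError("svr_c must be > 0")
        if self.svr_epsilon < 0:
            raise ValidationError("svr_epsilon must be >= 0")
        if self.ridge_lambda < 0:
            raise ValidationError("ridge_lambda must be >= 0")


@dataclass
class RegressionModel:
    """A fitted linear age predictor.

    ``coefficients`` are on the raw beta scale (years per unit beta) with
    ``intercept`` in years, so prediction is simply ``X @ coef + b``.
    When the model was fitted with standardisation, the per-probe training
    means and standard deviations are retained; the standardised-scale
    coefficient used for feature importance is ``coef * sd``.
    """

    probe_ids: list[str]
    coefficients: np.ndarray
    intercept: float
    config: RegressorConfig
    means: np.ndarray | None = None
    sds: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=np.float64)
        if self.coefficients.shape != (len(self.probe_ids),):
            raise ValidationError("one coefficient per probe required")
        if self.config.standardize and (self.means is None or self.sds is None):
            raise ValidationError("standardized model must carry means/sds")

    def predict(
        self, X: np.ndarray, probe_ids: Sequence[str] | None = None
    ) -> np.ndarray:
        """Predicted ages for a samples x probes block.

        If ``probe_ids`` is given, the column order is checked against the
        model's probe order.
        """
        X = np.asarray(X, dtype=np.float64)
        if X.ndim != 2 or X.shape[1] != len(self.probe_ids):
            raise ShapeError(
                f"expected {len(self.probe_ids)} feature columns, got "
                f"{X.shape[1] if X.ndim == 2 else X.shape}"
            )
        if probe_ids is not None:
            for mine, theirs in zip(self.probe_ids, probe_ids):
                if mine != theirs:
                    raise ShapeError(
                        f"feature column mismatch: expected {mine!r}, got {theirs!r}"
                    )
        return X @ self.coefficients + self.intercept

    def standardized_coefficients(self) -> np.ndarray:
        if self.config.standardize:
            return self.coefficients * self.sds
        return self.coefficients

    # --- serialization -------------------------------------------------
    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "config": asdict(self.config),
            "probe_ids": self.probe_ids,
            "coefficients": [repr(float(c)) for c in self.coefficients],
            "intercept": repr(float(self.intercept)),
            "means": None if self.means is None else [repr(float(v)) for v in self.means],
            "sds": None if self.sds is None else [repr(float(v)) for v in self.sds],
        }
        text = json.dumps(payload, indent=1, sort_keys=True)
        if path is not None:
            Path(path).write_text(text, "utf-8")
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "RegressionModel":
        p = Path(str(source))
        text = p.read_text("utf-8") if p.exists() else str(source)
        d = json.loads(text)
        cfg = RegressorConfig(**d["config"])
        return cls(
            probe_ids=list(d["probe_ids"]),
            coefficients=np.array([float(c) for c in d["coefficients"]]),
            intercept=float(d["intercept"]),
            config=cfg,
            means=None if d["means"] is None else np.array([float(v) for v in d["means"]]),
            sds=None if d["sds"] is None else np.array([float(v) for v in d["sds"]]),
        )


def fit(
    X: np.ndarray,
    y: np.ndarray,
    config: RegressorConfig,
    probe_ids: Sequence[str] | None = None,
) -> RegressionModel:
    """Fit a linear model of age on beta values.

    X is samples x features with no missing values (impute upstream);
    y is chronological age in years.  Standardisation statistics, when
    enabled, come from this training data only and are stored in the model.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64).ravel()
    if X.ndim != 2:
        raise FitError(f"X must be 2-D, got shape {X.shape}")
    n, p = X.shape
    if n < 2:
        raise FitError(f"need at least 2 samples, got {n}")
    if p < 1:
        raise FitError("need at least 1 feature")
    if y.shape != (n,):
        raise FitError(f"y length {y.size} != {n} samples")
    if not (np.isfinite(X).all() and np.isfinite(y).all()):
        raise FitError("non-finite values in input")
    if probe_ids is None:
        probe_ids = [f"f{j}" for j in range(p)]
    elif len(probe_ids) != p:
        raise FitError("probe_ids length must match feature count")

    means = sds = None
    Xs = X
    if config.standardize:
        means = X.mean(axis=0)
        sds = X.std(axis=0)
        sds = np.where(sds > 0, sds, 1.0)  # constant columns pass through
        Xs = (X - means) / sds

    if config.kind == "ridge":
        est = Ridge(alpha=config.ridge_lambda, fit_intercept=True, solver="svd")
        est.fit(Xs, y)
        coef_s = np.asarray(est.coef_, dtype=np.float64).ravel()
        intercept_s = float(np.atleast_1d(est.intercept_)[0])
    else:
        # liblinear regularises any internal bias term, which wrecks fits
        # when the target mean (ages ~60y) is large; instead the problem is
        # centred, solved without an intercept, and the intercept restored
        # analytically.  The classic L1 epsilon-insensitive loss only has a
        # dual solver; the squared variant admits the faster primal one.
        dual = config.svr_loss == "epsilon_insensitive"
        est = LinearSVR(
            C=config.svr_c,
            epsilon=config.svr_epsilon,
            loss=config.svr_loss,
            fit_intercept=False,
            tol=config.tol,
            max_iter=config.max_iter,
            dual=dual,
            random_state=0,
        )
        xm = Xs.mean(axis=0)
        ym = float(y.mean())
        import warnings as _warnings

        from sklearn.exceptions import ConvergenceWarning

        with _warnings.catch_warnings(record=True) as caught:
            _warnings.simplefilter("always", ConvergenceWarning)
            est.fit(Xs - xm, y - ym)
        if any(issubclass(w.category, ConvergenceWarning) for w in caught):
            # hitting the configured iteration cap is an accepted trade-off
            logger.debug("LinearSVR stopped at the %d-iteration cap", config.max_iter)
        coef_s = np.asarray(est.coef_, dtype=np.float64).ravel()
        intercept_s = ym - float(coef_s @ xm)
    if config.standardize:
        coef = coef_s / sds
        intercept = intercept_s - float((coef * means).sum())
    else:
        coef, intercept = coef_s, intercept_s
    return RegressionModel(
        probe_ids=list(probe_ids),
        coefficients=coef,
        intercept=intercept,
        config=config,
        means=means,
        sds=sds,
    )


def feature_importance(model: RegressionModel) -> np.ndarray:
    """Non-negative per-probe weight: |standardised-scale coefficient|."""
    return np.abs(model.standardized_coefficients())


def svr_objective(model: RegressionModel, X: np.ndarray, y: np.ndarray) -> float:
    """Epsilon-insensitive training loss plus L2 penalty of a linear model."""
    cfg = model.config
    resid = np.abs(model.predict(np.asarray(X, dtype=np.float64)) - y)
    hinge = np.maximum(resid - cfg.svr_epsilon, 0.0).sum()
    w = model.standardized_coefficients()
    return float(0.5 * (w @ w) + cfg.svr_c * hinge)
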
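"""Independent reference implementations used to cross-check the package.

Everything here is deliberately written from first principles (brute-force
enumeration, closed forms, direct sklearn calls) and never imports the
code paths it is used to verify.
"""

from __future__ import annotations

from itertools import combinations
from math import log2

import numpy as np
from sklearn.model_selection import KFold
from sklearn.svm import LinearSVR


def exhaustive_mic(x: np.ndarray, y: np.ndarray, alpha: float = 0.6) -> float:
    """MIC by full enumeration of all admissible grids.

    Cuts are placed at midpoints between consecutive distinct sorted
    values; every (p, q) grid with p*q <= n**alpha and p, q >= 2 is
    scored.  Exponential in grid size — small n only.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = x.size
    budget = n**alpha

    def cut_positions(v: np.ndarray) -> list[float]:
        sv = np.unique(v)
        return [(sv[i] + sv[i + 1]) / 2 for i in range(len(sv) - 1)]

    cx, cy = cut_positions(x), cut_positions(y)
    best = 0.0
    p = 2
    while p * 2 <= budget:
        q = 2
        while p * q <= budget:
            if len(cx) >= p - 1 and len(cy) >= q - 1:
                for xc in combinations(cx, p - 1):
                    bx = np.searchsorted(xc, x)
                    for yc in combinations(cy, q - 1):
                        by = np.searchsorted(yc, y)
                        joint = np.zeros((p, q))
                        np.add.at(joint, (bx, by), 1.0)
                        joint /= n
                        px, py = joint.sum(1), joint.sum(0)
                        nz = joint > 0
                        mi = float(
                            (joint[nz] * np.log2(joint[nz] / np.outer(px, py)[nz])).sum()
                        )
                        best = max(best, mi / log2(min(p, q)))
            q += 1
        p += 1
    return best


def ridge_closed_form(
    X: np.ndarray, y: np.ndarray, lam: float
) -> tuple[np.ndarray, float]:
    """Centred normal-equations ridge: (Xc'Xc + lam I)^-1 Xc'(y - ybar)."""
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    xm = X.mean(axis=0)
    Xc = X - xm
    yc = y - y.mean()
    p = X.shape[1]
    coef = np.linalg.solve(Xc.T @ Xc + lam * np.eye(p), Xc.T @ yc)
    intercept = float(y.mean() - xm @ coef)
    return coef, intercept


def metrics_reference(y_true: np.ndarray, y_pred: np.ndarray) -> dict[str, float]:
    """Element-wise loop recomputation of MAD/MSE/RMSE/R2."""
    n = len(y_true)
    abs_sum = 0.0
    sq_sum = 0.0
    for a, b in zip(y_true, y_pred):
        abs_sum += abs(a - b)
        sq_sum += (a - b) ** 2
    mean_t = sum(y_true) / n
    ss_tot = sum((a - mean_t) ** 2 for a in y_true)
    return {
        "mad": abs_sum / n,
        "mse": sq_sum / n,
        "rmse": (sq_sum / n) ** 0.5,
        "r2": 1.0 - sq_sum / ss_tot,
    }


def sklearn_svr_cv_mad(
    X: np.ndarray,
    y: np.ndarray,
    cols: list[int],
    folds: int,
    seed: int,
    kind: str = "svr",
    repeats: int = 1,
    repeat_seeds: list[int] | None = None,
) -> float:
    """Pooled repeated-CV MAD via direct sklearn calls (no package code).

    Standardisation is fitted on the training folds; per-sample predictions
    are averaged over repeats and MAD taken on the pooled means.
    """
    from sklearn.linear_model import Ridge

    Xs = X[:, cols]
    n = Xs.shape[0]
    seeds = repeat_seeds if repeat_seeds is not None else [seed] * repeats
    preds = np.zeros((len(seeds), n))
    for r, s in enumerate(seeds):
        kf = KFold(n_splits=folds, shuffle=True, random_state=s)
        for tr, te in kf.split(np.arange(n)):
            mu = Xs[tr].mean(axis=0)
            sd = Xs[tr].std(axis=0)
            sd = np.where(sd > 0, sd, 1.0)
            if kind == "svr":
                # centred fit with the intercept restored analytically,
                # mirroring the declared linear-SVR model
                est = LinearSVR(
                    C=1.0,
                    epsilon=0.1,
                    loss="squared_epsilon_insensitive",
                    dual=False,
                    fit_intercept=False,
                    tol=1e-4,
                    max_iter=10_000,
                    random_state=0,
                )
                Ztr = (Xs[tr] - mu) / sd
                Zte = (Xs[te] - mu) / sd
                xm = Ztr.mean(axis=0)
                ym = y[tr].mean()
                est.fit(Ztr - xm, y[tr] - ym)
                preds[r, te] = (Zte - xm) @ est.coef_ + ym
            else:
                est = Ridge(alpha=1.0, solver="svd")
                est.fit((Xs[tr] - mu) / sd, y[tr])
                preds[r, te] = est.predict((Xs[te] - mu) / sd)
    return float(np.mean(np.abs(preds.mean(axis=0) - y)))


def greedy_backfs_reference(
    X: np.ndarray,
    y: np.ndarray,
    probe_ids: list[str],
    folds: int,
    level_seed_fn,
    refine_seed: int,
    refine_repeat_seeds: list[int],
) -> tuple[list[tuple[int, float, str | None]], list[str]]:
    """Per-level exhaustive-removal greedy minimising EI = MAD + m/100.

    ``level_seed_fn(m)`` must return the fold seed shared by all candidate
    removals at the level that produces an m-feature set.  Returns the
    recorded (n_features, EI, removed) rows and the arg-min subset.
    """
    current = sorted(probe_ids)
    col = {p: j for j, p in enumerate(probe_ids)}
    records: list[tuple[int, float, str | None]] = []
    subsets: list[list[str]] = []

    def cv_mad(probes: list[str], seed: int, repeat_seeds=None) -> float:
        return sklearn_svr_cv_mad(
            X, y, [col[p] for p in probes], folds, seed, repeat_seeds=repeat_seeds
        )

    m0 = len(current)
    records.append(
        (m0, cv_mad(current, refine_seed, refine_repeat_seeds) + m0 / 100.0, None)
    )
    subsets.append(list(current))
    while len(current) > 1:
        m = len(current)
        seed = level_seed_fn(m - 1)
        best_probe, best_mad = None, np.inf
        for p in current:
            cand = [q for q in current if q != p]
            v = cv_mad(cand, seed)
            if v < best_mad:
                best_mad, best_probe = v, p
        current = [q for q in current if q != best_probe]
        level_mad = cv_mad(current, refine_seed, refine_repeat_seeds)
        records.append((m - 1, level_mad + (m - 1) / 100.0, best_probe))
        subsets.append(list(current))
    best = min(range(len(records)), key=lambda i: (records[i][1], records[i][0]))
    return records, subsets[best]


def loss_rfe_reference(
    X: np.ndarray,
    y: np.ndarray,
    probe_ids: list[str],
    n_features: int,
    folds: int,
    level_seed_fn,
    kind: str = "ridge",
) -> list[str]:
    """Per-step exhaustive single-removal RFE scored by CV MAD."""
    current = sorted(probe_ids)
    col = {p: j for j, p in enumerate(probe_ids)}
    while len(current) > n_features:
        seed = level_seed_fn(len(current) - 1)
        best_probe, best_mad = None, np.inf
        for p in current:
            cand = [q for q in current if q != p]
            v = sklearn_svr_cv_mad(X, y, [col[q] for q in cand], folds, seed, kind=kind)
            if v < best_mad:
                best_mad, best_probe = v, p
        current = [q for q in current if q != best_probe]
    return current
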
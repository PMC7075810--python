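"""Maximal Information Coefficient (MIC) estimation.

MIC measures dependence between two real variables by searching over
two-dimensional grids: for every grid shape (xcells, ycells) whose cell
count stays within the budget B(n) = n**alpha, the mutual information of
the induced discretisation is maximised over cut placements and normalised
by log2(min(xcells, ycells)); MIC is the maximum normalised value over all
admissible shapes.  A noiseless functional relationship scores 1, and
statistical independence scores near 0.

The search follows the MINE scheme: one axis is held at a fixed partition
(an equipartition of its ranks into q rows, or — when the number of
candidate cut placements is small — every possible placement), and the
other axis is optimised exactly by dynamic programming over candidate cut
positions between consecutive distinct values.  Both orientations are
tried and the larger score kept, which makes the estimate symmetric.
Because cuts depend only on rank order, the score is invariant under
strictly increasing transforms of either variable.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb, floor, log2

import numpy as np
from numba import njit

from .errors import ValidationError

__all__ = ["MicConfig", "mic"]


@dataclass(frozen=True)
class MicConfig:
    """Parameters of the MIC grid search.

    alpha
        Grid-budget exponent: the total cell count of any grid is bounded
        by ``n ** alpha``.  0.6 is the community-standard default.
    clump_factor
        Cap on candidate cuts along the optimised axis: at most
        ``clump_factor * xcells`` candidate boundaries are kept (adjacent
        value-groups are merged into "superclumps" beyond that).
    min_n
        Smallest sample count accepted.
    enum_cut_limit
        When the number of ways to place the fixed-axis cuts,
        C(boundaries, q-1), is at or below this limit, every placement is
        evaluated instead of the single rank equipartition.  This makes
        the estimator exact for small n at negligible cost.
    """

    alpha: float = 0.6
    clump_factor: int = 15
    min_n: int = 8
    enum_cut_limit: int = 60

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha < 1.0):
            raise ValidationError(f"alpha must be in (0, 1), got {self.alpha}")
        if self.clump_factor < 1:
            raise ValidationError("clump_factor must be >= 1")


def mic(x: np.ndarray, y: np.ndarray, config: MicConfig | None = None) -> float:
    """MIC score of two equal-length real vectors, in [0, 1]."""
    config = config or MicConfig()
    x = np.asarray(x, dtype=np.float64).ravel()
    y = np.asarray(y, dtype=np.float64).ravel()
    if x.shape != y.shape:
        raise ValidationError(f"length mismatch: {x.size} vs {y.size}")
    n = x.size
    if n < config.min_n:
        raise ValidationError(f"need at least {config.min_n} samples, got {n}")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValidationError("inputs must be finite")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return 0.0  # a constant axis carries no information

    budget = float(n) ** config.alpha
    if budget < 4.0:
        return 0.0  # no admissible grid with at least 2 cells per axis
    score = max(
        _best_over_fixed_axis(x, y, budget, config),
        _best_over_fixed_axis(y, x, budget, config),
    )
    return float(min(1.0, max(0.0, score)))


def _best_over_fixed_axis(
    opt: np.ndarray, fixed: np.ndarray, budget: float, config: MicConfig
) -> float:
    """Max normalised MI with `fixed` partitioned into rows and `opt` optimised."""
    n = opt.size
    order_f = np.argsort(fixed, kind="stable")
    f_sorted = fixed[order_f]
    # runs of tied values on the fixed axis: cuts may only fall between runs
    run_starts = np.flatnonzero(np.r_[True, f_sorted[1:] != f_sorted[:-1]])
    run_sizes = np.diff(np.r_[run_starts, n])
    n_runs = run_sizes.size
    order_o = np.argsort(opt, kind="stable")

    if n_runs - 1 > config.enum_cut_limit:
        # every q falls back to the rank equipartition: single jitted sweep
        o_sorted = opt[order_o]
        clump_id = np.cumsum(np.r_[0, o_sorted[1:] != o_sorted[:-1]]).astype(np.int64)
        run_of_sample = np.repeat(np.arange(n_runs, dtype=np.int64), run_sizes)
        run_idx = np.empty(n, dtype=np.int64)
        run_idx[order_f] = run_of_sample
        return float(
            _fast_best(
                run_sizes.astype(np.int64),
                run_idx[order_o],
                clump_id,
                float(budget),
                config.clump_factor,
            )
        )

    best = 0.0
    q = 2
    while q * 2 <= budget:
        p_max = floor(budget / q)
        if n_runs >= q:
            for rows in _fixed_partitions(run_sizes, q, config.enum_cut_limit):
                row_of_sample = np.empty(n, dtype=np.int64)
                row_of_sample[order_f] = np.repeat(rows, run_sizes)
                best = max(
                    best,
                    _optimize_axis(
                        opt, order_o, row_of_sample, q, p_max, config.clump_factor
                    ),
                )
        q += 1
    return best


def _fixed_partitions(run_sizes: np.ndarray, q: int, enum_limit: int):
    """Yield row assignments (one row index per run) for the fixed axis."""
    n_runs = run_sizes.size
    n_cuts = n_runs - 1
    if 0 < comb(n_cuts, q - 1) <= enum_limit:
        for cuts in combinations(range(1, n_runs), q - 1):
            rows = np.zeros(n_runs, dtype=np.int64)
            for r, c in enumerate(cuts):
                rows[c:] = r + 1
            yield rows
    else:
        yield _equipartition(run_sizes, q)


def _equipartition(run_sizes: np.ndarray, q: int) -> np.ndarray:
    """Assign tied-value runs to q rows targeting n/q samples per row."""
    n = int(run_sizes.sum())
    n_runs = run_sizes.size
    rows = np.empty(n_runs, dtype=np.int64)
    row = 0
    curr = 0  # samples in the open row
    assigned = 0  # samples in closed rows
    for g in range(n_runs):
        s = int(run_sizes[g])
        rows_left = q - row
        runs_left = n_runs - g
        if curr > 0 and rows_left > 1 and runs_left >= rows_left:
            desired = (n - assigned) / rows_left
            # close the row if that lands nearer the target than including s
            if (curr + s - desired) > (desired - curr):
                row += 1
                assigned += curr
                curr = 0
        rows[g] = row
        curr += s
    return rows


def _optimize_axis(
    opt: np.ndarray,
    order_o: np.ndarray,
    row_of_sample: np.ndarray,
    q: int,
    p_max: int,
    clump_factor: int,
) -> float:
    """Exact DP over column cuts given fixed rows; returns best normalised MI."""
    n = opt.size
    o_sorted = opt[order_o]
    clump_starts = np.flatnonzero(np.r_[True, o_sorted[1:] != o_sorted[:-1]])
    clump_sizes = np.diff(np.r_[clump_starts, n])
    m = clump_sizes.size
    if m < 2:
        return 0.0
    rows_sorted = row_of_sample[order_o]
    joint = np.zeros((m, q), dtype=np.int64)
    np.add.at(joint, (np.repeat(np.arange(m), clump_sizes), rows_sorted), 1)

    cap = clump_factor * p_max
    if m > cap:
        joint = _superclump(joint, cap)
        m = joint.shape[0]

    row_tot = joint.sum(axis=0).astype(np.float64)
    nz = row_tot[row_tot > 0] / n
    h_rows = float(-(nz * np.log2(nz)).sum())
    q_eff = int((row_tot > 0).sum())
    if q_eff < 2:
        return 0.0
    return float(_dp_best(joint, n, min(p_max, m), h_rows, q_eff))


def _superclump(joint: np.ndarray, cap: int) -> np.ndarray:
    """Merge adjacent clumps down to about `cap`, balancing sample counts."""
    sizes = joint.sum(axis=1)
    n = int(sizes.sum())
    target = n / cap
    out_rows: list[np.ndarray] = []
    acc = np.zeros(joint.shape[1], dtype=np.int64)
    acc_n = 0
    for i in range(joint.shape[0]):
        acc += joint[i]
        acc_n += int(sizes[i])
        if acc_n >= target:
            out_rows.append(acc)
            acc = np.zeros(joint.shape[1], dtype=np.int64)
            acc_n = 0
    if acc_n > 0:
        out_rows.append(acc)
    return np.vstack(out_rows)


@njit(cache=True)
def _equipartition_nb(run_sizes, q):  # pragma: no cover - jitted
    n_runs = run_sizes.size
    n = 0
    for g in range(n_runs):
        n += run_sizes[g]
    rows = np.empty(n_runs, dtype=np.int64)
    row = 0
    curr = 0
    assigned = 0
    for g in range(n_runs):
        s = run_sizes[g]
        rows_left = q - row
        runs_left = n_runs - g
        if curr > 0 and rows_left > 1 and runs_left >= rows_left:
            desired = (n - assigned) / rows_left
            if (curr + s - desired) > (desired - curr):
                row += 1
                assigned += curr
                curr = 0
        rows[g] = row
        curr += s
    return rows


@njit(cache=True)
def _fast_best(run_sizes, run_idx_opt, clump_id_opt, budget, clump_factor):
    """Equipartition-only grid sweep, fully jitted.  # pragma: no cover"""
    n = run_idx_opt.size
    m0 = clump_id_opt[n - 1] + 1
    n_runs = run_sizes.size
    best = 0.0
    q = 2
    while 2 * q <= budget:
        p_max = int(budget / q)
        if n_runs < q:
            q += 1
            continue
        rows_of_run = _equipartition_nb(run_sizes, q)
        joint = np.zeros((m0, q), dtype=np.int64)
        for i in range(n):
            joint[clump_id_opt[i], rows_of_run[run_idx_opt[i]]] += 1

        cap = clump_factor * p_max
        if m0 > cap:
            target = n / cap
            merged = np.zeros((m0, q), dtype=np.int64)
            out = 0
            acc_n = 0
            for i in range(m0):
                for r in range(q):
                    merged[out, r] += joint[i, r]
                    acc_n += joint[i, r]
                if acc_n >= target:
                    out += 1
                    acc_n = 0
            if acc_n > 0:
                out += 1
            joint = merged[:out]

        m = joint.shape[0]
        if m >= 2:
            h_rows = 0.0
            q_eff = 0
            for r in range(q):
                tot = 0.0
                for i in range(m):
                    tot += joint[i, r]
                if tot > 0.0:
                    q_eff += 1
                    h_rows -= (tot / n) * np.log2(tot / n)
            if q_eff >= 2:
                s = _dp_best(joint, n, min(p_max, m), h_rows, q_eff)
                if s > best:
                    best = s
        q += 1
    return best


@njit(cache=True)
def _dp_best(joint, n, p_max, h_rows, q_eff):  # pragma: no cover - jitted
    m, q = joint.shape
    cum = np.zeros((m + 1, q), dtype=np.int64)
    for i in range(m):
        for r in range(q):
            cum[i + 1, r] = cum[i, r] + joint[i, r]

    # lut[k] = (k/n) log2(k/n); column counts are integers, so entropy
    # terms come from a table instead of repeated log calls
    lut = np.zeros(n + 1, dtype=np.float64)
    for k in range(1, n + 1):
        lut[k] = (k / n) * np.log2(k / n)

    # phi[j, i]: contribution of a column spanning clumps [j, i)
    phi = np.zeros((m + 1, m + 1), dtype=np.float64)
    for j in range(m):
        for i in range(j + 1, m + 1):
            tot = 0
            s = 0.0
            for r in range(q):
                c = cum[i, r] - cum[j, r]
                tot += c
                s += lut[c]
            phi[j, i] = s - lut[tot]

    NEG = -1e18
    f_prev = np.full(m + 1, NEG)
    for i in range(1, m + 1):
        f_prev[i] = phi[0, i]
    best = 0.0
    for t in range(2, p_max + 1):
        f_cur = np.full(m + 1, NEG)
        for i in range(t, m + 1):
            hi = NEG
            for j in range(t - 1, i):
                v = f_prev[j] + phi[j, i]
                if v > hi:
                    hi = v
            f_cur[i] = hi
        mi = h_rows + f_cur[m]
        if mi < 0.0:
            mi = 0.0
        denom = np.log2(min(t, q_eff))
        s = mi / denom
        if s > best:
            best = s
        f_prev = f_cur
    return best
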
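"""The three-step feature-selection algorithm and baseline selectors.

Step 1 ranks every autosomal CpG by its MIC association with age and
keeps the top ``step1_top_k``.  Step 2 runs recursive feature elimination
under a linear SVR: per iteration the model is refitted on all samples,
the ``step2_k`` lowest-importance features are dropped, and the current
set is scored by cross-validated MAD; the set with the best MAD wins.
Step 3 (backward feature screening, "backFS") greedily removes, per
level, the single feature whose removal minimises EI = MAD + FNum/100,
and returns the subset at the global EI minimum — trading a year of
error against 100 features.

Baselines cover three filters (F-statistic, mutual information, absolute
Pearson) and three performance-loss RFE variants driven by L1, L2, and
SVR regressors.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
from sklearn.linear_model import Lasso

from .datamodel import (
    FeatureAnnotation,
    MethylomeMatrix,
    SampleMetadata,
    ages_vector,
    align_samples,
    exclude_sex_chromosomes,
    median_impute,
)
from .errors import PipelineError, ValidationError
from .evaluation import EvaluationReport, derive_seed, ei, repeated_kfold_cv
from .filters import FeatureRanking, rank_features
from .mic import MicConfig
from .regress import RegressionModel, RegressorConfig, feature_importance, fit

logger = logging.getLogger(__name__)

BaselineMethod = Literal["FR", "MI", "PCC", "L1-RFE", "L2-RFE", "SVR-RFE"]


@dataclass(frozen=True)
class AgeGuessConfig:
    """Settings for the full three-step pipeline.

    search_repeats controls how many CV repeats score candidate subsets
    during steps 2 and 3 (1 keeps the quadratic step-3 search affordable);
    report_repeats is used for the final report only.
    """

    step1_top_k: int = 10_000
    step2_k: int = 50
    step2_floor: int = 50
    cv_folds: int = 10
    search_repeats: int = 1
    report_repeats: int = 10
    seed: int = 0
    regressor: RegressorConfig = field(default_factory=RegressorConfig)
    mic: MicConfig = field(default_factory=MicConfig)
    unannotated_policy: Literal["drop", "keep", "error"] = "drop"
    #: score candidate subsets with the squared epsilon-insensitive SVR loss
    #: (primal solver), which is far lighter than the classic dual; the final
    #: model and report always use the configured loss
    fast_search: bool = True
    #: step-2 parsimony: treat subsets whose CV MAD lies within one standard
    #: error (across folds) of the minimum as ties and return the smallest
    step2_one_se: bool = True
    #: CV repeats used to re-estimate each step-3 level's recorded EI after
    #: the greedy removal is chosen; the global minimum is then read off
    #: low-noise estimates while the per-level candidate comparisons stay
    #: single-repeat (they share a fold partition, so noise largely cancels)
    step3_refine_repeats: int = 10

    def search_regressor(self) -> RegressorConfig:
        if self.fast_search and self.regressor.kind == "svr":
            return replace(self.regressor, svr_loss="squared_epsilon_insensitive")
        return self.regressor

    def __post_init__(self) -> None:
        if not (self.step1_top_k >= self.step2_k >= 1):
            raise ValidationError("need step1_top_k >= step2_k >= 1")
        if self.cv_folds < 2:
            raise ValidationError("cv_folds must be >= 2")
        if self.step2_floor < 1:
            raise ValidationError("step2_floor must be >= 1")


@dataclass
class TraceRecord:
    n_features: int
    metric_name: str  # "MAD" or "EI"
    metric_value: float
    removed: tuple[str, ...] = ()


@dataclass
class SelectionTrace:
    """Per-iteration bookkeeping of an elimination schedule."""

    step: str
    records: list[TraceRecord] = field(default_factory=list)

    def validate(self) -> None:
        ns = [r.n_features for r in self.records]
        if any(b >= a for a, b in zip(ns, ns[1:])):
            raise ValidationError(f"{self.step}: n_features not strictly decreasing")
        if any(not np.isfinite(r.metric_value) for r in self.records):
            raise ValidationError(f"{self.step}: non-finite metric value")

    def removed_probes(self) -> list[str]:
        out: list[str] = []
        for r in self.records:
            out.extend(r.removed)
        return out

    def to_tsv_rows(self) -> list[str]:
        rows = []
        for i, r in enumerate(self.records):
            rows.append(
                f"{self.step}\t{i}\t{r.n_features}\t{r.metric_name}\t"
                f"{r.metric_value!r}\t{';'.join(r.removed)}"
            )
        return rows


def write_traces(traces: Sequence[SelectionTrace], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("step\titeration\tn_features\tmetric_name\tmetric_value\tremoved_probes\n")
        for t in traces:
            for row in t.to_tsv_rows():
                fh.write(row + "\n")


@dataclass
class AgeGuessResult:
    """End-to-end outcome: the biomarker panel plus full provenance."""

    selected_probes: list[str]
    step1_ranking: FeatureRanking
    step2_trace: SelectionTrace
    step3_trace: SelectionTrace
    step2_survivors: list[str]
    final_model: RegressionModel
    final_report: EvaluationReport


def step1_mic_filter(
    matrix: MethylomeMatrix,
    ages: np.ndarray,
    config: AgeGuessConfig,
) -> tuple[MethylomeMatrix, FeatureRanking]:
    """Keep the top ``step1_top_k`` probes by MIC with age, ordered by rank."""
    ranking = rank_features(matrix, ages, "MIC", config.mic)
    keep = ranking.top(min(config.step1_top_k, matrix.n_probes))
    return matrix.select_probes(keep), ranking


def _cv_report(
    matrix: MethylomeMatrix,
    ages: np.ndarray,
    probes: Sequence[str],
    config: AgeGuessConfig,
    seed: int,
    repeats: int,
) -> EvaluationReport:
    return repeated_kfold_cv(
        matrix,
        ages,
        probes,
        config.search_regressor(),
        folds=config.cv_folds,
        repeats=repeats,
        seed=seed,
    )


def _cv_mad(
    matrix: MethylomeMatrix,
    ages: np.ndarray,
    probes: Sequence[str],
    config: AgeGuessConfig,
    seed: int,
    repeats: int,
) -> float:
    return _cv_report(matrix, ages, probes, config, seed, repeats).mad


def step2_svr_rfe(
    matrix: MethylomeMatrix,
    ages: np.ndarray,
    config: AgeGuessConfig,
) -> tuple[list[str], SelectionTrace]:
    """Recursive feature elimination by SVR feature importance.

    Per iteration, the regressor is refitted on all samples with the
    current features; the ``step2_k`` lowest-importance features (fewer on
    the terminal batch) are removed until ``step2_floor`` remain.  Every
    evaluated set is scored by repeated-CV MAD.  By default the smallest
    set within one fold-level standard error of the minimum MAD is
    returned (``step2_one_se``); disabling that flag gives the strict
    minimum, ties favouring fewer features.
    """
    current = list(matrix.probe_ids)
    if config.step2_floor > len(current):
        raise ValidationError(
            f"step2_floor {config.step2_floor} exceeds {len(current)} features"
        )
    X_full = median_impute(matrix.values).T
    probe_col = {p: j for j, p in enumerate(matrix.probe_ids)}
    seed2 = derive_seed(config.seed, 2)
    trace = SelectionTrace(step="step2")
    sets: list[list[str]] = []

    ses: list[float] = []
    removed_last: tuple[str, ...] = ()
    while True:
        report = _cv_report(matrix, ages, current, config, seed2, config.search_repeats)
        trace.records.append(
            TraceRecord(len(current), "MAD", report.mad, removed_last)
        )
        ses.append(report.mad_se())
        sets.append(list(current))
        if len(current) <= config.step2_floor:
            break
        cols = [probe_col[p] for p in current]
        model = fit(X_full[:, cols], ages, config.search_regressor(), probe_ids=current)
        importance = feature_importance(model)
        batch = min(config.step2_k, len(current) - config.step2_floor)
        # lowest importance first; ties resolved by ascending probe id
        order = sorted(range(len(current)), key=lambda j: (importance[j], current[j]))
        drop = sorted(current[j] for j in order[:batch])
        dropset = set(drop)
        current = [p for p in current if p not in dropset]
        removed_last = tuple(drop)

    best = min(
        range(len(trace.records)),
        key=lambda i: (trace.records[i].metric_value, trace.records[i].n_features),
    )
    if config.step2_one_se:
        # parsimony: the smallest subset whose CV MAD is within one fold-level
        # standard error of the minimum counts as tied with it
        threshold = trace.records[best].metric_value + ses[best]
        best = min(
            (i for i in range(len(trace.records))
             if trace.records[i].metric_value <= threshold),
            key=lambda i: (trace.records[i].n_features, trace.records[i].metric_value),
        )
    trace.validate()
    return sets[best], trace


def step3_backfs(
    matrix: MethylomeMatrix,
    ages: np.ndarray,
    config: AgeGuessConfig,
) -> tuple[list[str], SelectionTrace]:
    """Greedy backward feature screening minimising EI = MAD + FNum/100.

    At each level with m features, every (m-1)-subset is scored by
    repeated-CV MAD on a fold partition fixed for the level, so candidate
    removals are compared on identical splits.  The feature whose removal
    yields the lowest EI goes (ties remove the lexicographically smallest
    probe id); the subset at the global EI minimum over all levels —
    including the untouched starting set — is returned.
    """
    current = sorted(matrix.probe_ids)
    if len(current) < 2:
        raise ValidationError("step3 needs at least 2 features")
    seed3 = derive_seed(config.seed, 3)
    refine_seed = derive_seed(config.seed, 5)
    refine = max(config.step3_refine_repeats, config.search_repeats)
    trace = SelectionTrace(step="step3")
    sets: list[list[str]] = []

    m0 = len(current)
    mad0 = _cv_mad(matrix, ages, current, config, refine_seed, refine)
    trace.records.append(TraceRecord(m0, "EI", ei(mad0, m0)))
    sets.append(list(current))

    while len(current) > 1:
        m = len(current)
        level_seed = derive_seed(seed3, m - 1)
        best_probe = None
        best_mad = np.inf
        for p in current:  # current is kept sorted: ties fall to smallest id
            cand = [q for q in current if q != p]
            cand_mad = _cv_mad(matrix, ages, cand, config, level_seed, config.search_repeats)
            if cand_mad < best_mad:
                best_mad, best_probe = cand_mad, p
        current = [q for q in current if q != best_probe]
        level_mad = _cv_mad(matrix, ages, current, config, refine_seed, refine)
        trace.records.append(
            TraceRecord(m - 1, "EI", ei(level_mad, m - 1), (best_probe,))
        )
        sets.append(list(current))

    best = min(
        range(len(trace.records)),
        key=lambda i: (trace.records[i].metric_value, trace.records[i].n_features),
    )
    trace.validate()
    return sets[best], trace


def run_ageguess(
    matrix: MethylomeMatrix,
    metadata: Sequence[SampleMetadata],
    annotation: Sequence[FeatureAnnotation],
    config: AgeGuessConfig,
) -> AgeGuessResult:
    """Full pipeline: align, drop sex chromosomes, select, fit, report."""
    matrix, metadata = align_samples(matrix, metadata)
    matrix = exclude_sex_chromosomes(matrix, annotation, config.unannotated_policy)
    if matrix.n_probes == 0:
        raise PipelineError("no probes left after sex-chromosome exclusion")
    ages = ages_vector(metadata)

    reduced, ranking = step1_mic_filter(matrix, ages, config)
    logger.info("step1: kept %d / %d probes", reduced.n_probes, matrix.n_probes)
    survivors, trace2 = step2_svr_rfe(reduced, ages, config)
    logger.info("step2: best CV MAD at %d features", len(survivors))
    selected, trace3 = step3_backfs(matrix.select_probes(survivors), ages, config)
    logger.info("step3: EI minimum at %d features", len(selected))

    X = median_impute(matrix.select_probes(selected).values).T
    final_model = fit(X, ages, config.regressor, probe_ids=selected)
    final_report = repeated_kfold_cv(
        matrix,
        ages,
        selected,
        config.regressor,
        folds=config.cv_folds,
        repeats=config.report_repeats,
        seed=derive_seed(config.seed, 4),
    )
    return AgeGuessResult(
        selected_probes=selected,
        step1_ranking=ranking,
        step2_trace=trace2,
        step3_trace=trace3,
        step2_survivors=survivors,
        final_model=final_model,
        final_report=final_report,
    )


def _loss_rfe(
    matrix: MethylomeMatrix,
    ages: np.ndarray,
    n_features: int,
    config: AgeGuessConfig,
    reg_config: RegressorConfig,
) -> list[str]:
    """Performance-loss RFE: drop the feature whose removal hurts CV MAD least."""
    current = sorted(matrix.probe_ids)
    seed = derive_seed(config.seed, 7)
    while len(current) > n_features:
        level_seed = derive_seed(seed, len(current) - 1)
        best_probe = None
        best_mad = np.inf
        for p in current:
            cand = [q for q in current if q != p]
            cand_mad = repeated_kfold_cv(
                matrix,
                ages,
                cand,
                reg_config,
                folds=config.cv_folds,
                repeats=config.search_repeats,
                seed=level_seed,
            ).mad
            if cand_mad < best_mad:
                best_mad, best_probe = cand_mad, p
        current = [q for q in current if q != best_probe]
    return current


def baseline_select(
    matrix: MethylomeMatrix,
    ages: np.ndarray,
    method: BaselineMethod,
    n_features: int,
    config: AgeGuessConfig | None = None,
) -> list[str]:
    """Select ``n_features`` probes with one of the six baseline methods.

    Filters (FR, MI, PCC) take the top of their univariate ranking; the
    RFE variants eliminate one feature per step — the one whose removal
    induces the least cross-validated MAD loss under the named regressor
    (L1-penalised linear, ridge, or linear SVR) — until ``n_features``
    remain.
    """
    config = config or AgeGuessConfig()
    if n_features > matrix.n_probes:
        raise ValidationError(
            f"n_features {n_features} exceeds {matrix.n_probes} probes"
        )
    if method in ("FR", "MI", "PCC"):
        ranking = rank_features(matrix, ages, method, config.mic)
        return ranking.top(n_features)
    if method == "L2-RFE":
        reg = replace(config.regressor, kind="ridge")
        return _loss_rfe(matrix, ages, n_features, config, reg)
    if method == "SVR-RFE":
        reg = replace(config.regressor, kind="svr")
        return _loss_rfe(matrix, ages, n_features, config, reg)
    if method == "L1-RFE":
        return _l1_rfe(matrix, ages, n_features, config)
    raise ValidationError(f"unknown baseline method {method!r}")


def _l1_rfe(
    matrix: MethylomeMatrix,
    ages: np.ndarray,
    n_features: int,
    config: AgeGuessConfig,
    alpha: float = 0.01,
) -> list[str]:
    """Performance-loss RFE scored by an L1-penalised linear regressor."""
    from sklearn.model_selection import KFold

    current = sorted(matrix.probe_ids)
    seed = derive_seed(config.seed, 8)
    V = matrix.values
    col = {p: j for j, p in enumerate(matrix.probe_ids)}

    def lasso_cv_mad(probes: list[str], level_seed: int) -> float:
        cols = [col[p] for p in probes]
        X = median_impute(V[cols]).T
        n = X.shape[0]
        preds = np.zeros(n)
        kf = KFold(n_splits=config.cv_folds, shuffle=True, random_state=level_seed)
        for tr, te in kf.split(np.arange(n)):
            mu, sd = X[tr].mean(axis=0), X[tr].std(axis=0)
            sd = np.where(sd > 0, sd, 1.0)
            est = Lasso(alpha=alpha, max_iter=10_000)
            est.fit((X[tr] - mu) / sd, ages[tr])
            preds[te] = est.predict((X[te] - mu) / sd)
        return float(np.mean(np.abs(preds - ages)))

    while len(current) > n_features:
        level_seed = derive_seed(seed, len(current) - 1)
        best_probe, best_mad = None, np.inf
        for p in current:
            cand = [q for q in current if q != p]
            m = lasso_cv_mad(cand, level_seed)
            if m < best_mad:
                best_mad, best_probe = m, p
        current = [q for q in current if q != best_probe]
    return current
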
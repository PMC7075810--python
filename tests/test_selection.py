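import numpy as np
import pytest

from ageguess.datamodel import (
    FeatureAnnotation,
    MethylomeMatrix,
    SampleMetadata,
    median_impute,
)
from ageguess.errors import PipelineError, ValidationError
from ageguess.evaluation import derive_seed
from ageguess.filters import rank_features
from ageguess.regress import feature_importance, fit
from ageguess.selection import (
    AgeGuessConfig,
    baseline_select,
    run_ageguess,
    step1_mic_filter,
    step2_svr_rfe,
    step3_backfs,
)

from conftest import make_planted_matrix
from oracles import greedy_backfs_reference, loss_rfe_reference, sklearn_svr_cv_mad


class TestStep1:
    def test_top_k_by_mic_rank(self):
        matrix, ages, _ = make_planted_matrix(60, 17, 3, seed=2)
        cfg = AgeGuessConfig(step1_top_k=5, step2_k=2, step2_floor=2)
        reduced, ranking = step1_mic_filter(matrix, ages, cfg)
        assert reduced.probe_ids == ranking.top(5)
        assert reduced.n_probes == 5

    def test_top_k_saturates_at_probe_count(self):
        matrix, ages, _ = make_planted_matrix(40, 5, 2, seed=3)
        cfg = AgeGuessConfig(step1_top_k=1000, step2_k=2, step2_floor=2)
        reduced, _ = step1_mic_filter(matrix, ages, cfg)
        assert set(reduced.probe_ids) == set(matrix.probe_ids)

    def test_planted_probes_survive_filter(self):
        matrix, ages, planted = make_planted_matrix(150, 200, 3, seed=11)
        cfg = AgeGuessConfig(step1_top_k=10, step2_k=2, step2_floor=2)
        reduced, _ = step1_mic_filter(matrix, ages, cfg)
        assert set(planted) <= set(reduced.probe_ids)


class TestStep2:
    def test_terminal_batch_capped_at_floor(self):
        matrix, ages, _ = make_planted_matrix(40, 3, 3, seed=4)
        cfg = AgeGuessConfig(step1_top_k=50, step2_k=50, step2_floor=2, cv_folds=4)
        survivors, trace = step2_svr_rfe(matrix, ages, cfg)
        assert [r.n_features for r in trace.records] == [6, 2]
        assert len(trace.records[1].removed) == 4

    def test_trace_bookkeeping_is_complete(self):
        matrix, ages, _ = make_planted_matrix(50, 16, 4, seed=6)
        cfg = AgeGuessConfig(step1_top_k=20, step2_k=6, step2_floor=3, cv_folds=5)
        survivors, trace = step2_svr_rfe(matrix, ages, cfg)
        ns = [r.n_features for r in trace.records]
        assert ns == sorted(ns, reverse=True) and len(set(ns)) == len(ns)
        removed = [p for r in trace.records for p in r.removed]
        terminal = [
            p for p in matrix.probe_ids if p not in set(removed)
        ]
        assert sorted(removed + terminal) == sorted(matrix.probe_ids)
        assert set(survivors) <= set(matrix.probe_ids)

    def test_floor_above_feature_count_rejected(self):
        matrix, ages, _ = make_planted_matrix(30, 2, 2, seed=5)
        cfg = AgeGuessConfig(step1_top_k=50, step2_k=2, step2_floor=10)
        with pytest.raises(ValidationError):
            step2_svr_rfe(matrix, ages, cfg)

    def test_matches_independent_schedule_replay(self):
        """Removal order and min-MAD subset equal a from-scratch replay of
        the same schedule coded directly against sklearn."""
        matrix, ages, planted = make_planted_matrix(120, 96, 4, seed=3)
        cfg = AgeGuessConfig(
            step1_top_k=100, step2_k=5, step2_floor=2, cv_folds=10,
            seed=3, step2_one_se=False,
        )
        survivors, trace = step2_svr_rfe(matrix, ages, cfg)
        assert set(planted) <= set(survivors)

        # ---- independent replay ----
        X = matrix.values.T
        ids = list(matrix.probe_ids)
        col = {p: j for j, p in enumerate(ids)}
        fold_seed = derive_seed(derive_seed(3, 2), 0)
        current = list(ids)
        best_mad, best_set = np.inf, None
        replay_removed = []
        while True:
            m = sklearn_svr_cv_mad(X, ages, [col[p] for p in current], 10, fold_seed)
            if (m, len(current)) < (best_mad, len(best_set or [])):
                best_mad, best_set = m, list(current)
            if len(current) <= 2:
                break
            model = fit(
                X[:, [col[p] for p in current]],
                ages,
                cfg.search_regressor(),
                probe_ids=current,
            )
            imp = feature_importance(model)
            order = sorted(range(len(current)), key=lambda j: (imp[j], current[j]))
            batch = min(5, len(current) - 2)
            drop = sorted(current[j] for j in order[:batch])
            replay_removed.append(tuple(drop))
            current = [p for p in current if p not in set(drop)]
        assert [r.removed for r in trace.records[1:]] == replay_removed
        assert sorted(survivors) == sorted(best_set)


class TestStep3:
    def _config(self, seed=5, **kw):
        kw.setdefault("step1_top_k", 50)
        kw.setdefault("step2_k", 2)
        kw.setdefault("step2_floor", 2)
        kw.setdefault("cv_folds", 5)
        return AgeGuessConfig(seed=seed, **kw)

    def test_keeps_the_predictive_feature_and_drops_noise(self):
        rng = np.random.default_rng(0)
        n = 60
        ages = np.linspace(20, 90, n)
        good = 0.1 + 0.005 * ages
        noise = rng.uniform(0.2, 0.8, size=n)
        matrix = MethylomeMatrix(
            ["good", "noise"], [f"s{i}" for i in range(n)],
            np.vstack([good, noise]),
        )
        selected, trace = step3_backfs(matrix, ages, self._config())
        assert selected == ["good"]
        best = min(trace.records, key=lambda r: (r.metric_value, r.n_features))
        assert best.n_features == 1

    def test_all_noise_minimises_at_small_counts(self):
        rng = np.random.default_rng(1)
        n = 200
        ages = rng.uniform(20, 90, n)
        rows = rng.uniform(0.3, 0.7, size=(6, n))
        matrix = MethylomeMatrix(
            [f"nz{j}" for j in range(6)], [f"s{i}" for i in range(n)], rows
        )
        selected, trace = step3_backfs(matrix, ages, self._config(seed=2))
        assert len(selected) <= 2  # the FNum penalty dominates pure noise

    def test_matches_independent_greedy_oracle(self):
        matrix, ages, _ = make_planted_matrix(50, 5, 3, seed=5)
        cfg = self._config(seed=5, cv_folds=5)
        selected, trace = step3_backfs(matrix, ages, cfg)

        seed3 = derive_seed(cfg.seed, 3)
        refine_seed = derive_seed(cfg.seed, 5)
        records, subset = greedy_backfs_reference(
            matrix.values.T,
            ages,
            list(matrix.probe_ids),
            folds=5,
            level_seed_fn=lambda m: derive_seed(derive_seed(seed3, m), 0),
            refine_seed=None,
            refine_repeat_seeds=[derive_seed(refine_seed, r) for r in range(10)],
        )
        assert [r.removed for r in trace.records[1:]] == [
            (rec[2],) for rec in records[1:]
        ]
        assert selected == subset
        for mine, ref in zip(trace.records, records):
            assert mine.metric_value == pytest.approx(ref[1], abs=1e-9)

    def test_requires_two_features(self):
        matrix, ages, _ = make_planted_matrix(30, 0, 1, seed=1)
        with pytest.raises(ValidationError):
            step3_backfs(matrix, ages, self._config())


class TestBaselines:
    def test_pcc_top_one_finds_perfect_probe(self):
        matrix, ages, planted = make_planted_matrix(60, 10, 1, seed=8, noise_sd=0.001)
        out = baseline_select(matrix, ages, "PCC", 1)
        assert out == planted

    @pytest.mark.parametrize("method", ["FR", "MI", "PCC", "L2-RFE"])
    def test_selecting_all_probes_is_identity(self, method):
        matrix, ages, _ = make_planted_matrix(40, 4, 2, seed=9)
        out = baseline_select(matrix, ages, method, matrix.n_probes)
        assert set(out) == set(matrix.probe_ids)

    def test_unknown_method_rejected(self):
        matrix, ages, _ = make_planted_matrix(30, 2, 1, seed=1)
        with pytest.raises(ValidationError):
            baseline_select(matrix, ages, "BEST", 1)
        with pytest.raises(ValidationError):
            baseline_select(matrix, ages, "PCC", 99)

    def test_l2_rfe_matches_exhaustive_per_step_oracle(self):
        matrix, ages, _ = make_planted_matrix(40, 3, 2, seed=10)
        cfg = AgeGuessConfig(step1_top_k=50, step2_k=2, step2_floor=2, cv_folds=5, seed=10)
        out = baseline_select(matrix, ages, "L2-RFE", 2, cfg)
        seed = derive_seed(cfg.seed, 7)
        ref = loss_rfe_reference(
            matrix.values.T,
            ages,
            list(matrix.probe_ids),
            n_features=2,
            folds=5,
            level_seed_fn=lambda m: derive_seed(derive_seed(seed, m), 0),
            kind="ridge",
        )
        assert out == ref

    def test_l1_rfe_returns_requested_count(self):
        matrix, ages, planted = make_planted_matrix(50, 4, 2, seed=12)
        out = baseline_select(matrix, ages, "L1-RFE", 3)
        assert len(out) == 3 and len(set(out)) == 3


def _small_dataset(seed=21):
    matrix, ages, planted = make_planted_matrix(60, 90, 6, seed=seed)
    metadata = [
        SampleMetadata(s, float(a), "male" if i % 2 else "female")
        for i, (s, a) in enumerate(zip(matrix.sample_ids, ages))
    ]
    annotation = [FeatureAnnotation(p, str(1 + i % 22)) for i, p in enumerate(matrix.probe_ids)]
    return matrix, metadata, annotation, planted


@pytest.fixture(scope="module")
def result_pair():
    matrix, metadata, annotation, planted = _small_dataset()
    cfg = AgeGuessConfig(
        step1_top_k=30, step2_k=10, step2_floor=10, cv_folds=5, seed=21
    )
    r1 = run_ageguess(matrix, metadata, annotation, cfg)
    r2 = run_ageguess(matrix, metadata, annotation, cfg)
    return r1, r2, planted


class TestRunAgeGuess:
    def test_identical_seeds_give_identical_runs(self, result_pair):
        r1, r2, _ = result_pair
        assert r1.selected_probes == r2.selected_probes
        assert [rec.__dict__ for rec in r1.step2_trace.records] == [
            rec.__dict__ for rec in r2.step2_trace.records
        ]
        assert [rec.__dict__ for rec in r1.step3_trace.records] == [
            rec.__dict__ for rec in r2.step3_trace.records
        ]
        assert r1.final_report.mad == r2.final_report.mad

    def test_nesting_invariants(self, result_pair):
        r1, _, _ = result_pair
        step1_set = set(r1.step1_ranking.top(30))
        assert set(r1.selected_probes) <= set(r1.step2_survivors) <= step1_set

    def test_selection_ei_is_step3_minimum(self, result_pair):
        r1, _, _ = result_pair
        best = min(r.metric_value for r in r1.step3_trace.records)
        mine = [
            r.metric_value
            for r in r1.step3_trace.records
            if r.n_features == len(r1.selected_probes)
        ]
        assert best in mine

    def test_recovers_planted_probes(self, result_pair):
        r1, _, planted = result_pair
        assert len(set(planted) & set(r1.selected_probes)) >= len(planted) - 1

    def test_all_sex_chromosome_probes_is_pipeline_error(self):
        matrix, metadata, _, _ = _small_dataset()
        annotation = [FeatureAnnotation(p, "X") for p in matrix.probe_ids]
        cfg = AgeGuessConfig(step1_top_k=30, step2_k=10, step2_floor=10, seed=0)
        with pytest.raises(PipelineError):
            run_ageguess(matrix, metadata, annotation, cfg)
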
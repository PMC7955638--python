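"""Training-set construction, the max-min-margin LP, k-fold, consolidation."""

import numpy as np
import pytest

from polyresolve.corpus import ingest_table
from polyresolve.match import N_ALGORITHMS, SearchPackage
from polyresolve.optimize import (
    FoldResult,
    MarginVector,
    TrainingSet,
    build_training_set,
    consolidate,
    evaluate_accuracy,
    first_pass,
    kfold_validate,
    optimize_weights,
    train_weights,
)
from polyresolve.synth import DEFAULT_SPECS, generate_corpus_object, generate_queries


def mv(*positions, neg=(), sp_id=0, wrong_id="w"):
    x = [0] * N_ALGORITHMS
    for p in positions:
        x[p - 1] = 1
    for p in neg:
        x[p - 1] = -1
    return MarginVector(x=tuple(x), sp_id=sp_id, wrong_id=wrong_id)


def ts_of(xs, rcs=()):
    return TrainingSet(xs=list(xs), rcs=[(i, rc) for i, rc in enumerate(rcs)])


def rc_flags(*positions):
    return tuple(1 if i + 1 in positions else 0 for i in range(N_ALGORITHMS))


class TestFirstPass:
    def test_shared_abbreviation_query_yields_two_candidates(self, example_corpus, pva_query):
        entries = first_pass([pva_query], example_corpus)
        assert len(entries[0].candidates) == 2
        assert entries[0].truth_id == "poly(vinyl alcohol)"

    def test_sole_candidate_becomes_rc(self, example_corpus):
        sp = SearchPackage(polfil="pol", chemical_name="Polystyrene", label="Polystyrene")
        ts = build_training_set(first_pass([sp], example_corpus))
        assert len(ts.rcs) == 1 and not ts.xs

    def test_query_matching_nothing_is_excluded(self, example_corpus):
        sp = SearchPackage(polfil="pol", chemical_name="notachemical", label="Polystyrene")
        entries = first_pass([sp], example_corpus)
        assert entries[0].truth_id is None
        assert build_training_set(entries).excluded == [0]

    def test_unlabeled_query_rejected(self, example_corpus):
        with pytest.raises(ValueError, match="label"):
            first_pass([SearchPackage(polfil="pol", chemical_name="x")], example_corpus)


class TestBuildTrainingSet:
    def test_margin_vector_is_truth_minus_wrong(self, example_corpus, pva_query):
        ts = build_training_set(first_pass([pva_query], example_corpus))
        assert len(ts.xs) == 1
        assert ts.xs[0].x == mv(9, 10).x  # +1 exactly at the two BOC algorithms
        assert ts.xs[0].wrong_id == "poly(vinyl acetate)"

    def test_identical_truth_and_wrong_vectors_flagged_irrecoverable(self):
        rows = [
            {"standard_name": n, "usmiles": "", "density": "", "abbreviations": "",
             "synonyms": "acme resin", "trade_names": ""}
            for n in ("Alpha polymer", "Beta polymer")
        ]
        corpus = ingest_table(rows)
        sp = SearchPackage(polfil="pol", chemical_name="acme resin", label="Alpha polymer")
        ts = build_training_set(first_pass([sp], corpus))
        assert ts.irrecoverable == [(0, "beta polymer")]
        assert not ts.xs


class TestOptimizeWeights:
    def test_single_positive_direction_hits_the_box_bound(self):
        res = optimize_weights(ts_of([mv(1)]), w_max=2.0)
        assert res.status == "ok"
        assert res.margin == pytest.approx(2.0)
        assert res.w[0] == pytest.approx(2.0)

    def test_sign_forced_instance_is_non_separable(self):
        res = optimize_weights(ts_of([mv(neg=(1,))]))
        assert res.status == "non_separable"
        assert res.margin <= 0
        assert res.binding == (0,)

    def test_rc_constraint_keeps_truth_score_positive(self):
        res = optimize_weights(ts_of([mv(1)], rcs=[rc_flags(2)]), epsilon=0.1)
        assert np.dot(res.w, rc_flags(2)) >= 0.1 - 1e-9

    def test_empty_training_set_rejected(self):
        with pytest.raises(ValueError):
            optimize_weights(ts_of([]))

    def test_matches_grid_search_oracle_on_small_instances(self):
        # 3 active dimensions, 5 margin vectors, exhaustive 0.1-step grid
        rng = np.random.default_rng(7)
        w_max, step = 2.0, 0.1
        axis = np.arange(0, w_max + step / 2, step)
        grid = np.stack(np.meshgrid(axis, axis, axis), -1).reshape(-1, 3)
        for _ in range(25):
            X3 = rng.integers(-1, 2, size=(5, 3))
            xs = [
                MarginVector(x=tuple(int(v) for v in row) + (0,) * 9, sp_id=i, wrong_id="w")
                for i, row in enumerate(X3)
            ]
            lp = optimize_weights(ts_of(xs), w_max=w_max).margin
            grid_best = np.min(grid @ X3.T, axis=1).max()
            assert grid_best <= lp + 1e-8
            assert lp - grid_best <= 3 * step / 2 + 1e-8  # Lipschitz slack of the grid


class TestKfold:
    @pytest.fixture()
    def big_ts(self):
        xs = [mv(9, 10, sp_id=i) for i in range(100)] + [
            mv(2, 11, sp_id=100 + i) for i in range(60)
        ]
        return ts_of(xs, rcs=[rc_flags(2, 9, 10, 11)])

    def test_160_xs_in_10_folds_of_16(self, big_ts):
        folds = kfold_validate(big_ts, k=10, seed=3)
        assert len(folds) == 10
        assert all(len(f.omitted) == 16 for f in folds)
        omitted = sorted(i for f in folds for i in f.omitted)
        assert omitted == list(range(160))

    def test_leave_one_out_holdout_is_single_margin(self):
        xs = [mv(1), mv(2), mv(1, 2)]
        folds = kfold_validate(ts_of(xs), k=3, seed=0)
        X = np.array([m.x for m in xs])
        for f in folds:
            (j,) = f.omitted
            assert f.holdout_score == pytest.approx(float(X[j] @ np.array(f.w)))

    def test_fold_omitting_the_negation_of_a_retained_x_fails(self):
        xs = [mv(1, sp_id=i) for i in range(5)] + [mv(neg=(1,), sp_id=5)]
        folds = kfold_validate(ts_of(xs), k=6, seed=1)
        bad = [f for f in folds if 5 in f.omitted]
        assert len(bad) == 1
        assert bad[0].holdout_score < 0 and not bad[0].passed

    @pytest.mark.parametrize("k", [1, 0, 200])
    def test_k_out_of_range(self, big_ts, k):
        with pytest.raises(ValueError):
            kfold_validate(big_ts, k=k, seed=0)

    def test_partition_is_seed_deterministic(self, big_ts):
        a = kfold_validate(big_ts, k=10, seed=5)
        b = kfold_validate(big_ts, k=10, seed=5)
        c = kfold_validate(big_ts, k=10, seed=6)
        assert [f.omitted for f in a] == [f.omitted for f in b]
        assert [f.omitted for f in a] != [f.omitted for f in c]


class TestConsolidate:
    def w12(self, *vals):
        return tuple(vals) + (0.0,) * (N_ALGORITHMS - len(vals))

    def test_identical_folds_returned_unchanged(self):
        ts = ts_of([mv(1), mv(1)])
        w = self.w12(1.0)
        folds = [
            FoldResult(fold=i, w=w, min_train_score=1, holdout_score=1, omitted=(i - 1,))
            for i in (1, 2)
        ]
        cons = consolidate(folds, ts)
        assert cons.adopted and cons.w_star == w

    def test_modal_vector_adopted_when_deviating_folds_pass_under_it(self):
        ts = ts_of([mv(1, sp_id=i) for i in range(10)])
        w_modal, w_dev = self.w12(2.0), self.w12(1.5)
        folds = [
            FoldResult(fold=i + 1, w=(w_modal if i < 8 else w_dev),
                       min_train_score=2, holdout_score=2, omitted=(i,))
            for i in range(10)
        ]
        cons = consolidate(folds, ts)
        assert cons.adopted and cons.w_star == w_modal
        audit_devs = [a for a in cons.audit if not a["conforming"]]
        assert len(audit_devs) == 2
        assert all(a["holdout_score_under_w_star"] == pytest.approx(2.0) for a in audit_devs)

    def test_zero_holdout_under_w_star_rejected(self):
        # the omitted x is orthogonal to w*: recomputed score 0 is not positive
        ts = ts_of([mv(1), mv(2)])
        w_star = self.w12(1.0)
        folds = [
            FoldResult(fold=1, w=w_star, min_train_score=1, holdout_score=0, omitted=(1,)),
        ]
        cons = consolidate(folds, ts)
        assert cons.status == "rejected" and cons.failing_folds == (1,)

    def test_all_distinct_folds_is_no_consensus(self):
        ts = ts_of([mv(1), mv(1), mv(1)])
        folds = [
            FoldResult(fold=i, w=self.w12(float(i)), min_train_score=1,
                       holdout_score=1, omitted=(i - 1,))
            for i in (1, 2, 3)
        ]
        cons = consolidate(folds, ts)
        assert cons.status == "no_consensus" and cons.w_star is None


class TestEndToEnd:
    def test_recovery_on_separable_synthetic_data(self):
        corpus = generate_corpus_object(20, 2, seed=21)
        queries = generate_queries(corpus, DEFAULT_SPECS, 60, seed=22)
        report = train_weights(queries, corpus, k=5, seed=23)
        assert report["consolidation_status"] == "adopted"
        assert report["margin"] > 0
        w = tuple(report["weights"])
        assert evaluate_accuracy(queries, corpus, w) == 1.0
        held_out = generate_queries(corpus, DEFAULT_SPECS, 30, seed=24)
        assert evaluate_accuracy(held_out, corpus, w) == 1.0

    def test_positive_margin_implies_resolver_returns_truth(self):
        # ties the LP objective's sign convention to resolver behavior
        corpus = generate_corpus_object(20, 2, seed=31)
        queries = generate_queries(corpus, DEFAULT_SPECS, 60, seed=32)
        entries = first_pass(queries, corpus)
        ts = build_training_set(entries)
        res = optimize_weights(ts)
        assert res.margin > 0
        from polyresolve.match import resolve

        for m in ts.xs:
            sp = queries[m.sp_id]
            r = resolve(sp, corpus, res.w)
            assert r.status == "resolved" and r.winner == sp.label.casefold()

    def test_scaling_a_feasible_w_never_reduces_margins(self):
        ts = ts_of([mv(9, 10), mv(2, 11), mv(12, neg=(5,))])
        res = optimize_weights(ts, w_max=2.0)
        X = np.array([m.x for m in ts.xs], dtype=float)
        w = np.array(res.w)
        assert np.all(X @ (1.5 * w) >= X @ w - 1e-12)
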
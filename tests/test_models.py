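"""Metrics, random forest, descriptor selection, FFNN ensemble and ASNN."""

import numpy as np
import pytest

from bondscope.dataset import LabeledBond, build_records, enumerate_bonds
from bondscope.descriptors import build_catalog
from bondscope.errors import ConfigError
from bondscope.graph import parse_structure
from bondscope.models import (
    EnsembleConfig,
    EnsembleModel,
    FeedForwardNet,
    LinearNormalizer,
    RFConfig,
    asnn_predict,
    baseline_fixed_values,
    evaluate,
    loo_metrics,
    select_descriptors,
    train_ensemble,
    train_rf,
)


class TestEvaluate:
    def test_perfect_predictions(self):
        m = evaluate([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert m.rmsd == 0 and m.mad == 0 and m.max_error == 0 and m.r2 == 1.0

    def test_closed_form_example(self):
        m = evaluate([0.0, 2.0], [0.0, 0.0])
        assert m.rmsd == pytest.approx(np.sqrt(2))
        assert m.mad == 1.0 and m.max_error == 2.0
        assert m.r2 is None  # zero-variance truths flagged

    def test_constant_mean_prediction_has_zero_r2(self):
        truth = np.array([1.0, 2.0, 3.0, 4.0])
        m = evaluate(np.full(4, truth.mean()), truth)
        assert m.r2 == pytest.approx(0.0)

    def test_invariants_on_random_inputs(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            pred, truth = rng.normal(size=(2, 30))
            m = evaluate(pred, truth)
            assert m.max_error >= m.rmsd >= m.mad >= 0
            assert m.r2 <= 1


class TestRandomForest:
    def test_constant_target_perfect_oob(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(60, 4))
        res = train_rf(X, np.full(60, 7.0), RFConfig(n_trees=50, seed=0),
                       compute_importance=False)
        assert res.oob_metrics.rmsd == pytest.approx(0.0, abs=1e-12)

    def test_single_informative_column_recovered(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(500, 8))
        y = X[:, 0].copy()
        res = train_rf(X, y, RFConfig(n_trees=1000, seed=0),
                       importance_max_trees=60)
        assert res.oob_metrics.r2 > 0.9
        assert int(np.argmax(res.importances)) == 0

    def test_duplicated_rows_do_not_degrade_oob_metrics(self):
        # duplicating rows gives every sample an out-of-bag twin, so the
        # OOB error can only improve (it roughly halves here)
        rng = np.random.default_rng(3)
        X = rng.normal(size=(200, 5))
        y = 2 * X[:, 0] + rng.normal(0, 0.2, 200)
        base = train_rf(X, y, RFConfig(n_trees=300, seed=0),
                        compute_importance=False).oob_metrics.rmsd
        doubled = train_rf(np.vstack([X, X]), np.concatenate([y, y]),
                           RFConfig(n_trees=300, seed=0),
                           compute_importance=False).oob_metrics.rmsd
        assert doubled <= base + 0.05

    def test_empty_design_matrix_rejected(self):
        with pytest.raises(ConfigError):
            train_rf(np.empty((10, 0)), np.zeros(10))


class TestSelectDescriptors:
    def test_identity_when_k_equals_p_and_threshold_one(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(50, 6))
        kept = select_descriptors(np.arange(6, 0, -1), 6, X, corr_threshold=1.0)
        assert sorted(kept) == list(range(6))

    def test_identical_column_removed(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(50, 3))
        X[:, 2] = X[:, 0]
        kept = select_descriptors([3.0, 2.0, 1.0], 3, X)
        assert list(kept) == [0, 1]

    def test_five_near_duplicates_among_top_90(self):
        # mirrors the selection workflow: 100 descriptors, the top 90 kept
        # by importance contain 5 near-copies -> 85 survive
        rng = np.random.default_rng(6)
        X = rng.normal(size=(300, 100))
        for src, dup in zip(range(5), range(50, 55)):
            X[:, dup] = X[:, src] + rng.normal(0, 1e-3, 300)
        importances = np.linspace(100, 1, 100)
        kept = select_descriptors(importances, 90, X, corr_threshold=0.95)
        assert len(kept) == 85
        assert not set(range(50, 55)) & set(kept)


class TestEnsemble:
    def test_single_member_constant_target(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(30, 3))
        model = train_ensemble(X, np.full(30, 85.0),
                               EnsembleConfig(n_members=1, seed=0))
        assert model.predict(X) == pytest.approx(np.full(30, 85.0))

    def test_noiseless_linear_target_learned(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(300, 4))
        y = 3.0 * X[:, 0] - 2.0 * X[:, 1] + 5.0
        X_test = rng.normal(size=(100, 4))
        y_test = 3.0 * X_test[:, 0] - 2.0 * X_test[:, 1] + 5.0
        model = train_ensemble(X, y, EnsembleConfig(n_members=25, seed=1))
        rmsd = evaluate(model.predict(X_test), y_test).rmsd
        assert rmsd < 0.05 * y.std()

    def test_same_seed_bit_identical_members(self):
        rng = np.random.default_rng(9)
        X = rng.normal(size=(100, 3))
        y = X.sum(axis=1)
        cfg = EnsembleConfig(n_members=3, seed=11)
        a = train_ensemble(X, y, cfg)
        b = train_ensemble(X, y, cfg)
        for na, nb in zip(a.members, b.members):
            assert (na.w1 == nb.w1).all() and (na.w2 == nb.w2).all()

    def test_normalization_bounds_from_training_only(self):
        rng = np.random.default_rng(10)
        X = rng.uniform(0, 1, size=(50, 2))
        model = train_ensemble(X, X[:, 0] * 10, EnsembleConfig(n_members=2, seed=0))
        assert model.x_norm.lo == pytest.approx(X.min(axis=0))
        assert model.x_norm.hi == pytest.approx(X.max(axis=0))

    def test_normalizer_round_trip(self):
        rng = np.random.default_rng(11)
        values = rng.normal(size=(40, 3))
        norm = LinearNormalizer.fit(values)
        transformed = norm.transform(values)
        assert transformed.min() >= 0.1 - 1e-12
        assert transformed.max() <= 0.9 + 1e-12
        assert norm.inverse(transformed) == pytest.approx(values)


class _FixedOutputEnsemble(EnsembleModel):
    """Test double with hand-set member outputs for queries."""

    def __init__(self, query_outputs, **kwargs):
        super().__init__(**kwargs)
        self._query_outputs = np.atleast_2d(query_outputs)

    def member_outputs(self, X):
        return self._query_outputs


def _toy_model(query_outputs, memory_outputs, residuals, k=2):
    from bondscope.models import _centered_ranks

    memory_outputs = np.asarray(memory_outputs, dtype=float)
    residuals = np.asarray(residuals, dtype=float)
    return _FixedOutputEnsemble(
        query_outputs,
        members=[],
        x_norm=LinearNormalizer(lo=np.zeros(1), hi=np.ones(1)),
        y_norm=LinearNormalizer(lo=np.zeros(1), hi=np.ones(1)),
        memory_vectors=np.zeros((len(residuals), 1)),
        memory_labels=memory_outputs.mean(axis=1) + residuals,
        memory_outputs=memory_outputs,
        memory_residuals=residuals,
        memory_ranks=_centered_ranks(memory_outputs),
        config=EnsembleConfig(n_members=3, k_neighbors=k),
    )


class TestAsnn:
    def test_exact_recall_of_memory_case(self):
        rng = np.random.default_rng(12)
        X = rng.normal(size=(80, 3))
        y = X[:, 0] * 4 + np.sin(X[:, 1]) * 3
        model = train_ensemble(X, y, EnsembleConfig(n_members=5, seed=3))
        recalled = asnn_predict(model, X[:10], k=1)
        assert recalled == pytest.approx(y[:10])

    def test_zero_residual_memory_equals_plain_mean(self):
        rng = np.random.default_rng(13)
        X = rng.normal(size=(40, 2))
        y = X[:, 0]
        model = train_ensemble(X, y, EnsembleConfig(n_members=4, seed=5))
        model.memory_residuals = np.zeros_like(model.memory_residuals)
        assert asnn_predict(model, X[:7], k=3) == pytest.approx(model.predict(X[:7]))

    def test_hand_computed_three_case_memory(self):
        # member outputs make the query's ranks match cases 0 and 1 and
        # anti-correlate with case 2; residuals (+1, +1, -2), k=2 -> +1
        memory = [[1.0, 2.0, 3.0], [10.0, 20.0, 30.0], [3.0, 2.0, 1.0]]
        model = _toy_model(
            query_outputs=[5.0, 6.0, 7.0],
            memory_outputs=memory,
            residuals=[1.0, 1.0, -2.0],
            k=2,
        )
        prediction = asnn_predict(model, np.zeros((1, 1)), k=2)
        assert prediction[0] == pytest.approx(6.0 + 1.0)

    def test_full_memory_with_zero_mean_residuals_degenerates(self):
        memory = [[1.0, 2.0, 3.0], [10.0, 20.0, 30.0], [3.0, 2.0, 1.0]]
        model = _toy_model(
            query_outputs=[5.0, 6.0, 7.0],
            memory_outputs=memory,
            residuals=[1.0, 1.0, -2.0],  # zero mean
        )
        prediction = asnn_predict(model, np.zeros((1, 1)), k=3)
        assert prediction[0] == pytest.approx(6.0)

    def test_extend_memory_without_retraining(self):
        rng = np.random.default_rng(14)
        X = rng.normal(size=(60, 3))
        y = X[:, 0] * 2
        model = train_ensemble(X, y, EnsembleConfig(n_members=4, seed=6))
        members_before = [net.get_params().copy() for net in model.members]
        X_new = rng.normal(size=(10, 3))
        model.extend_memory(X_new, X_new[:, 0] * 2)
        assert model.memory_outputs.shape[0] == 70
        for net, before in zip(model.members, members_before):
            assert (net.get_params() == before).all()
        recalled = asnn_predict(model, X_new[:3], k=1)
        assert recalled == pytest.approx(X_new[:3, 0] * 2)

    def test_bad_k_rejected(self):
        model = _toy_model([1.0, 2.0, 3.0], [[1.0, 2.0, 3.0]], [0.5])
        with pytest.raises(ConfigError):
            asnn_predict(model, np.zeros((1, 1)), k=5)


class TestBaseline:
    def _records(self, labels, smiles="CN"):
        g = parse_structure(smiles)
        bond = next(
            (i, j) for i, j in enumerate_bonds(g)
            if {g.elements[i], g.elements[j]} == {"C", "N"}
        )
        catalog = build_catalog("cn-point-only", max_sphere=1)
        return build_records(
            [LabeledBond(g, bond, v) for v in labels], catalog,
            mol_ids=list(range(len(labels))),
        )

    def test_single_class_mean(self):
        predictor = baseline_fixed_values(self._records([80.0, 90.0]))
        values, fallback = predictor.predict(self._records([0.0]))
        assert values[0] == pytest.approx(85.0)
        assert not fallback.any()

    def test_unseen_class_falls_back_to_global_mean(self):
        predictor = baseline_fixed_values(self._records([80.0, 90.0]))
        g = parse_structure("CO")
        bond = next(
            (i, j) for i, j in enumerate_bonds(g)
            if {g.elements[i], g.elements[j]} == {"C", "O"}
        )
        catalog = build_catalog("cn-point-only", max_sphere=1)
        test_records = build_records([LabeledBond(g, bond, None)], catalog)
        with pytest.warns(UserWarning, match="unseen"):
            values, fallback = predictor.predict(test_records)
        assert values[0] == pytest.approx(85.0)
        assert fallback.all()

    def test_empty_training_set_rejected(self):
        with pytest.raises(ConfigError):
            baseline_fixed_values([])


class TestLeaveOneOut:
    def test_loo_on_exactly_learnable_target(self):
        rng = np.random.default_rng(15)
        X = rng.normal(size=(25, 2))
        y = X[:, 0]

        def trainer(X_fit, y_fit):
            from sklearn.linear_model import LinearRegression

            model = LinearRegression().fit(X_fit, y_fit)
            return model.predict

        metrics = loo_metrics(trainer, X, y)
        assert metrics.rmsd < 1e-9


class TestRecoveryProperties:
    def test_oob_rmsd_shrinks_with_more_data(self, recovery_design, rf_recovery):
        """Surrogate recovery error decreases with training-set size."""
        from conftest import RECOVERY_RF

        X, y, _ = recovery_design
        rng = np.random.default_rng(0)
        subset = rng.choice(X.shape[0], size=800, replace=False)
        small = train_rf(
            X[subset], y[subset],
            RFConfig(seed=3, **{**RECOVERY_RF, "n_trees": 200}),
            compute_importance=False,
        )
        # allow a little sampling noise on top of the full-data RMSD
        assert small.oob_metrics.rmsd > rf_recovery.oob_metrics.rmsd + 0.1
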
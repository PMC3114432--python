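"""Single-hidden-layer perceptron: activation, scaling, training,
hidden-size selection, imputation and partial dependence."""

import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from protimpute._seeds import substream
from protimpute.imputer import (
    HIDDEN_SIZE_RANGE,
    MLPModel,
    activation,
    forward,
    impute,
    inverse_scale_target,
    partial_dependence,
    r_squared,
    scale_inputs,
    select_hidden_size,
    train,
)


class TestActivation:
    def test_zero_at_origin(self):
        assert activation(0.0) == 0.0

    def test_asymptotes(self):
        assert activation(50.0) == pytest.approx(1.0)
        assert activation(-50.0) == pytest.approx(-1.0)

    @given(st.floats(-20, 20))
    @settings(max_examples=50, deadline=None)
    def test_odd_symmetry_and_closed_form(self, v):
        assert activation(-v) == pytest.approx(-activation(v), abs=1e-12)
        expected = (1 - np.exp(-v)) / (1 + np.exp(-v))
        assert activation(v) == pytest.approx(expected, abs=1e-12)


class TestScaling:
    def test_midpoint_maps_to_zero(self):
        out = scale_inputs(np.array([[5.0]]), (np.array([0.0]), np.array([10.0])))
        assert out[0, 0] == 0.0

    def test_out_of_range_extends_linearly(self):
        out = scale_inputs(np.array([[20.0]]), (np.array([0.0]), np.array([10.0])))
        assert out[0, 0] == pytest.approx(3.0)

    def test_round_trip(self, rng):
        y = rng.uniform(2, 9, 50)
        ys = 2 * (y - 2) / 7 - 1
        np.testing.assert_allclose(inverse_scale_target(ys, (2.0, 9.0)), y, rtol=1e-12)

    def test_constant_column_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            scale_inputs(np.ones((3, 1)), (np.array([1.0]), np.array([1.0])))


def _random_model(rng, n_in=3, n_hidden=4):
    return MLPModel(
        predictor_names=[f"x{i}" for i in range(n_in)],
        input_min=np.zeros(n_in),
        input_max=np.ones(n_in),
        input_mean=np.full(n_in, 0.5),
        target_min=-2.0,
        target_max=3.0,
        W1=rng.normal(size=(n_hidden, n_in)),
        b1=rng.normal(size=n_hidden),
        w2=rng.normal(size=n_hidden),
        b2=float(rng.normal()),
        n_hidden=n_hidden,
        seed=0,
        training_log=[],
    )


class TestForward:
    def test_zero_network_predicts_target_midpoint(self):
        m = MLPModel(
            predictor_names=["x"], input_min=np.array([0.0]),
            input_max=np.array([1.0]), input_mean=np.array([0.5]),
            target_min=2.0, target_max=6.0,
            W1=np.zeros((3, 1)), b1=np.zeros(3), w2=np.zeros(3), b2=0.0,
            n_hidden=3, seed=0, training_log=[],
        )
        assert forward(m, np.array([0.3])) == pytest.approx(4.0)

    def test_hand_computed_tiny_network(self):
        # 2 inputs, 1 hidden unit; verify against hand arithmetic
        m = MLPModel(
            predictor_names=["a", "b"],
            input_min=np.array([0.0, 0.0]), input_max=np.array([2.0, 2.0]),
            input_mean=np.array([1.0, 1.0]),
            target_min=0.0, target_max=10.0,
            W1=np.array([[1.0, -1.0]]), b1=np.array([0.5]),
            w2=np.array([2.0]), b2=0.1, n_hidden=1, seed=0, training_log=[],
        )
        x = np.array([1.0, 0.5])  # scaled: (0.0, -0.5); v = 0 + 0.5 + 0.5 = 1.0
        h = np.tanh(0.5)
        ys = 2.0 * h + 0.1
        expected = (ys + 1) / 2 * 10
        assert forward(m, x) == pytest.approx(expected, rel=1e-12)

    def test_matches_loop_oracle(self, rng):
        """Vectorized forward equals an explicit per-unit loop to 1e-12."""
        for _ in range(5):
            m = _random_model(rng)
            X = rng.uniform(-0.5, 1.5, size=(7, 3))
            got = forward(m, X)
            for i in range(7):
                xs = [
                    2 * (X[i, j] - m.input_min[j]) / (m.input_max[j] - m.input_min[j]) - 1
                    for j in range(3)
                ]
                acc = m.b2
                for hcol in range(m.n_hidden):
                    v = m.b1[hcol]
                    for j in range(3):
                        v += m.W1[hcol, j] * xs[j]
                    acc += m.w2[hcol] * np.tanh(v / 2)
                expected = (acc + 1) / 2 * (m.target_max - m.target_min) + m.target_min
                assert got[i] == pytest.approx(expected, abs=1e-12)

    def test_batch_equals_rowwise(self, rng):
        m = _random_model(rng)
        X = rng.uniform(0, 1, size=(5, 3))
        batch = forward(m, X)
        rows = [forward(m, X[i]) for i in range(5)]
        np.testing.assert_allclose(batch, rows, rtol=1e-15)

    def test_dimension_mismatch(self, rng):
        with pytest.raises(ValueError, match="predictors"):
            forward(_random_model(rng), np.array([1.0]))


class TestTrain:
    def test_noiseless_linear_function(self, rng):
        x = rng.uniform(-1, 1, 200)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            m = train(x, 2 * x, 5, seed=1)
        assert m.r_squared >= 0.999

    def test_sine_with_noise(self, rng):
        x = rng.uniform(-1, 1, 400)
        y = np.sin(3 * x) + rng.normal(0, 0.1, 400)
        m = train(x, y, 8, seed=1)
        assert m.r_squared >= 0.9

    def test_same_seed_bit_identical(self, rng):
        x = rng.uniform(-1, 1, 120)
        y = x**2 + rng.normal(0, 0.05, 120)
        m1 = train(x, y, 6, seed=9)
        m2 = train(x, y, 6, seed=9)
        assert np.array_equal(m1.W1, m2.W1)
        assert np.array_equal(m1.w2, m2.w2)
        assert m1.b2 == m2.b2
        assert m1.training_log == m2.training_log

    def test_missing_values_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            train(np.array([1.0, np.nan]), np.array([1.0, 2.0]), 5, seed=0)

    def test_json_round_trip(self, rng, tmp_path):
        x = rng.uniform(-1, 1, 60)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            m = train(x, 2 * x, 5, seed=3, max_epochs=100)
        m.to_json(tmp_path / "m.json")
        back = MLPModel.from_json(tmp_path / "m.json")
        np.testing.assert_array_equal(back.W1, m.W1)
        assert back.predictor_names == m.predictor_names
        x_new = rng.uniform(-1, 1, 10)
        np.testing.assert_allclose(
            forward(back, x_new[:, None]), forward(m, x_new[:, None]), rtol=1e-15
        )


class TestSelectHiddenSize:
    @pytest.fixture(scope="class")
    def data(self):
        r = np.random.default_rng(5)
        X = r.uniform(-1, 1, size=(120, 2))
        y = np.tanh(X[:, 0]) + 0.3 * X[:, 1] + r.normal(0, 0.05, 120)
        return X, y

    def test_selection_is_reproducible_and_in_range(self, data):
        X, y = data
        kw = dict(sizes=(5, 6, 7), K=5, seed=3, max_epochs=200)
        best1, cv1 = select_hidden_size(X, y, **kw)
        best2, cv2 = select_hidden_size(X, y, **kw)
        assert best1 == best2
        assert best1 in HIDDEN_SIZE_RANGE
        assert cv1.fold_errors == cv2.fold_errors

    def test_cv_bookkeeping(self, data):
        X, y = data
        best, cv = select_hidden_size(X, y, sizes=(5, 6), K=5, seed=3, max_epochs=100)
        for size, errs in cv.fold_errors.items():
            assert len(errs) == 5
            assert cv.mean_errors[size] == pytest.approx(np.mean(errs))

    def test_folds_partition_rows(self):
        n, K = 57, 10
        perm = substream(3, "cv-folds").permutation(n)
        folds = np.array_split(perm, K)
        flat = np.concatenate(folds)
        assert sorted(flat) == list(range(n))
        assert max(len(f) for f in folds) - min(len(f) for f in folds) <= 1

    def test_too_many_folds_rejected(self, data):
        X, y = data
        with pytest.raises(ValueError, match="folds"):
            select_hidden_size(X[:5], y[:5], sizes=(5,), K=10, seed=0)


class TestRSquared:
    def test_perfect_and_mean_predictions(self, rng):
        y = rng.normal(size=30)
        assert r_squared(y, y) == pytest.approx(1.0)
        assert r_squared(y, np.full(30, y.mean())) == pytest.approx(0.0)

    def test_hand_example(self):
        assert r_squared([1, 2, 3], [1, 2, 4]) == pytest.approx(0.5)

    def test_constant_y_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            r_squared([2, 2, 2], [1, 2, 3])

    def test_invariant_to_predictor_rescaling(self, rng):
        """Rescaling predictors leaves the trained fit's R^2 unchanged
        (the scaler maps both to the same internal range)."""
        x = rng.uniform(0, 1, 150)
        y = 3 * x + rng.normal(0, 0.1, 150)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            m1 = train(x, y, 5, seed=4, max_epochs=300)
            m2 = train(1000 * x + 77, y, 5, seed=4, max_epochs=300)
        assert m1.r_squared == pytest.approx(m2.r_squared, abs=1e-10)


class TestImpute:
    @pytest.fixture(scope="class")
    def model_and_features(self):
        r = np.random.default_rng(8)
        X = pd.DataFrame(
            {"a": r.uniform(0, 1, 150), "b": r.uniform(0, 1, 150)},
            index=[f"g{i}" for i in range(150)],
        )
        y = 2 + X["a"] * 3 + r.normal(0, 0.05, 150)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            m = train(X.to_numpy(), y.to_numpy(), 5, seed=2,
                      predictor_names=["a", "b"], max_epochs=500)
        return m, X, y

    def test_measured_values_pass_through(self, model_and_features):
        m, X, y = model_and_features
        measured = pd.Series(np.nan, index=X.index)
        measured.iloc[:10] = y.iloc[:10]
        out = impute(m, X, measured_log2=measured)
        assert out["measured_flag"].iloc[:10].all()
        np.testing.assert_allclose(
            out["log2_abundance"].iloc[:10], y.iloc[:10], rtol=1e-12
        )
        assert not out["measured_flag"].iloc[10:].any()

    def test_linear_scale_consistency(self, model_and_features):
        m, X, _ = model_and_features
        out = impute(m, X)
        np.testing.assert_allclose(
            out["linear_abundance"], np.exp2(out["log2_abundance"]), rtol=1e-12
        )

    def test_incomplete_rows_skipped_with_warning(self, model_and_features):
        m, X, _ = model_and_features
        X2 = X.copy()
        X2.iloc[0, 0] = np.nan
        with pytest.warns(UserWarning, match="missing predictors"):
            out = impute(m, X2)
        assert X2.index[0] not in out.index

    def test_rank_correlation_with_withheld_truth(self, reference_dataset):
        """Imputed abundances track the withheld true latent abundances."""
        from scipy.stats import spearmanr

        from protimpute.pipeline import _predictor_frame, fit_condition_model

        ds = reference_dataset
        cond = ds.config.conditions[0]
        prot = __import__("protimpute").collapse_replicates(ds.observed_proteome, 1)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            m, _ = fit_condition_model(
                ds.features, prot.series(cond), cond,
                K=5, sizes=(5, 6, 7), seed=0, max_epochs=600,
            )
            out = impute(m, _predictor_frame(ds.features, cond, m.predictor_names))
        undetected = ds.missing_mask[cond]
        genes = out.index[undetected.reindex(out.index).fillna(False)]
        truth = ds.latent_protein_log2[cond].reindex(genes)
        rho = spearmanr(out.loc[genes, "log2_abundance"], truth).statistic
        assert rho > 0.7


class TestPartialDependence:
    def test_flat_when_predictor_unused(self, rng):
        m = _random_model(rng)
        m.W1[:, 2] = 0.0  # kill input x2
        curve = partial_dependence(m, "x2", np.linspace(0, 1, 11))
        assert np.ptp(curve.to_numpy()) == pytest.approx(0.0, abs=1e-12)

    def test_continuity_on_fine_grid(self, rng):
        m = _random_model(rng)
        grid = np.linspace(0, 1, 2001)
        curve = partial_dependence(m, "x0", grid).to_numpy()
        assert np.max(np.abs(np.diff(curve))) < 0.05

    def test_monotone_single_index_model(self, rng):
        m = _random_model(rng, n_in=2, n_hidden=1)
        m.W1 = np.array([[1.5, 0.0]])
        m.w2 = np.array([2.0])
        curve = partial_dependence(m, "x0", np.linspace(0, 1, 50)).to_numpy()
        assert (np.diff(curve) > 0).all()

    def test_unknown_predictor_and_margin(self, rng):
        m = _random_model(rng)
        with pytest.raises(ValueError, match="unknown"):
            partial_dependence(m, "zz", np.linspace(0, 1, 5))
        with pytest.raises(ValueError, match="allowed range"):
            partial_dependence(m, "x0", np.linspace(-5, 5, 5))
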
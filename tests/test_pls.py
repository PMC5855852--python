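"""NIPALS PLS, LOO cross-validation, model statistics and contributions."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from sklearn.cross_decomposition import PLSRegression

from qsar3d.pls import (PLSQsar, field_contributions, loo_cross_validate,
                        model_statistics, nipals_pls1, pls_fit)


def random_problem(rng, n=10, p=6, noise=0.0):
    X = rng.normal(size=(n, p))
    beta = rng.normal(size=p)
    y = X @ beta + noise * rng.normal(size=n)
    return X, y


class TestNipalsFit:
    def test_exact_fit_of_single_column_relation(self, rng):
        # centered orthogonal columns: the first latent direction is exactly
        # the informative column, so one component already fits perfectly
        Q, _ = np.linalg.qr(np.column_stack([np.ones(12), rng.normal(size=(12, 4))]))
        X = Q[:, 1:]  # orthonormal and orthogonal to the ones vector
        y = 3.0 * X[:, 1]
        model = pls_fit(X, y, n_components=1)
        assert model.r2_ == pytest.approx(1.0, abs=1e-10)

    def test_full_rank_pls_equals_least_squares(self, rng):
        X, y = random_problem(rng, 10, 6, noise=0.3)
        model = pls_fit(X, y, n_components=6)
        Xc = np.column_stack([np.ones(10), X])
        beta = np.linalg.lstsq(Xc, y, rcond=None)[0]
        assert np.allclose(model.predict(X), Xc @ beta, atol=1e-8)

    def test_matches_reference_pls_implementation(self, rng):
        """Dual route: our NIPALS against sklearn's PLSRegression."""
        X, y = random_problem(rng, 15, 8, noise=0.5)
        for c in (1, 3, 5):
            ours = pls_fit(X, y, n_components=c)
            ref = PLSRegression(n_components=c, scale=False).fit(X, y.reshape(-1, 1))
            assert np.allclose(ours.predict(X), ref.predict(X).ravel(), atol=1e-8)

    def test_row_permutation_leaves_coefficients_unchanged(self, rng):
        X, y = random_problem(rng, 12, 5, noise=0.2)
        perm = rng.permutation(12)
        m1 = pls_fit(X, y, 3)
        m2 = pls_fit(X[perm], y[perm], 3)
        assert np.allclose(m1.coef_, m2.coef_, atol=1e-10)
        assert m1.intercept_ == pytest.approx(m2.intercept_, abs=1e-10)

    def test_constant_y_rejected(self, rng):
        X = rng.normal(size=(8, 3))
        with pytest.raises(ValueError, match="constant"):
            pls_fit(X, np.ones(8), 1)

    def test_component_bounds_enforced(self, rng):
        X, y = random_problem(rng, 6, 3)
        with pytest.raises(ValueError, match="n_components"):
            PLSQsar(n_components=7).fit(X, y, cross_validate=False)

    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(shift=st.floats(-10, 10, allow_nan=False))
    def test_centering_consistency(self, shift):
        rng = np.random.default_rng(11)
        X, y = random_problem(rng, 10, 4, noise=0.2)
        m1 = pls_fit(X, y, 2)
        m2 = pls_fit(X, y + shift, 2)
        assert np.allclose(m1.coef_, m2.coef_, atol=1e-9)
        assert m2.intercept_ - m1.intercept_ == pytest.approx(shift, abs=1e-9)


class TestModelArchive:
    def test_save_load_round_trip_reproduces_predictions(self, rng, tmp_path):
        X, y = random_problem(rng, 14, 5, noise=0.2)
        model = PLSQsar(n_components=3).fit(X, y)
        p = tmp_path / "model.json"
        model.save(p)
        back = PLSQsar.load(p)
        assert np.allclose(back.predict(X), model.predict(X), atol=1e-12)
        assert back.q2_ == pytest.approx(model.q2_)
        assert back.r2_ == pytest.approx(model.r2_)

    def test_unknown_schema_rejected(self, tmp_path):
        p = tmp_path / "bad.json"
        p.write_text('{"schema_version": 99}')
        with pytest.raises(ValueError, match="schema"):
            PLSQsar.load(p)


class TestLooCrossValidation:
    def test_noiseless_linear_signal_cross_validates_cleanly(self, rng):
        X = rng.normal(size=(10, 3))
        y = X @ np.array([2.0, -1.0, 0.5])
        q2s, onc = loo_cross_validate(X, y, max_components=3)
        assert q2s[onc - 1] > 0.99
        assert q2s[-1] > 0.99  # full-rank LOO is near-perfect without noise

    def test_pure_noise_rarely_cross_validates(self):
        """y independent of X: median max-q² over repeats stays low."""
        rng = np.random.default_rng(99)
        best = []
        for _ in range(100):
            X = rng.normal(size=(12, 5))
            y = rng.normal(size=12)
            q2s, _ = loo_cross_validate(X, y, max_components=5)
            best.append(q2s.max())
        assert np.median(best) <= 0.2

    def test_tiny_sample_caps_components(self, rng):
        X = rng.normal(size=(3, 4))
        y = np.array([0.0, 1.0, 2.5])
        q2s, onc = loo_cross_validate(X, y, max_components=10)
        assert len(q2s) == 1 and onc == 1

    def test_q2_never_exceeds_r2_on_training_data(self, rng):
        X, y = random_problem(rng, 14, 6, noise=0.5)
        model = PLSQsar(n_components=None, max_components=6).fit(X, y)
        assert model.q2_ <= model.r2_ + 1e-12

class TestModelStatistics:
    @pytest.mark.parametrize("r2,n,c,f_expected", [(0.958, 27, 6, 76.0), (0.912, 27, 5, 43.4)])
    def test_fisher_value_from_r2(self, r2, n, c, f_expected):
        # construct residuals realizing the given r² and recompute F
        y = np.linspace(0, 1, n)
        ss_tot = ((y - y.mean()) ** 2).sum()
        resid = np.sqrt((1 - r2) * ss_tot / n)
        y_fit = y - resid * np.where(np.arange(n) % 2 == 0, 1, -1)
        # center fitted residuals so r² is exact
        r2_got, see, f = model_statistics(y, y_fit, c)
        assert r2_got == pytest.approx(r2, abs=1e-9)
        assert f == pytest.approx(f_expected, abs=0.15)

    def test_perfect_fit_gives_zero_see_infinite_f(self):
        y = np.arange(10.0)
        r2, see, f = model_statistics(y, y, 2)
        assert r2 == 1.0 and see == 0.0 and np.isinf(f)

    def test_see_undefined_for_tiny_n(self):
        with pytest.raises(ValueError, match="SEE"):
            model_statistics(np.arange(3.0), np.arange(3.0), 2)


class TestContributions:
    def test_single_field_is_100_percent(self, rng):
        c = field_contributions(rng.normal(size=5), np.ones(5), np.array(["S"] * 5))
        assert c["S"] == pytest.approx(100.0)

    def test_duplicated_blocks_split_evenly(self, rng):
        b = rng.normal(size=4)
        s = np.abs(rng.normal(size=4)) + 0.1
        c = field_contributions(np.concatenate([b, b]), np.concatenate([s, s]),
                                np.array(["S"] * 4 + ["E"] * 4))
        assert c["S"] == pytest.approx(50.0, abs=0.1)
        assert c["S"] + c["E"] == pytest.approx(100.0, abs=1e-9)

    def test_planted_steric_signal_dominates(self, rng):
        n = 30
        S = rng.normal(size=(n, 10))
        E = 0.05 * rng.normal(size=(n, 10))  # near-dead block
        y = S @ np.concatenate([np.ones(3), np.zeros(7)]) + 0.05 * rng.normal(size=n)
        X = np.hstack([S, E])
        model = PLSQsar(n_components=3).fit(X, y, cross_validate=False)
        contrib = field_contributions(model.coef_, X.std(axis=0, ddof=1),
                                      np.array(["S"] * 10 + ["E"] * 10))
        assert contrib["S"] > 80.0
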
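"""Comparator methods: PDS, SBC, GLSW, CCACT, MSC."""

import numpy as np
import pytest

from plsct import (
    apply_glsw,
    apply_pds,
    apply_sbc,
    fit_ccact,
    fit_glsw,
    fit_pds,
    fit_sbc,
    msc_correct,
    transfer_ccact,
    PDSModel,
    SBCModel,
    GLSWModel,
    CCACTModel,
)
from plsct.exceptions import PairingError, ParameterError

from _oracles import canonical_correlations_reference, ols_normal_equations


@pytest.fixture
def paired_blocks():
    rng = np.random.default_rng(21)
    Sm = rng.normal(size=(12, 15))
    Ss = 1.03 * Sm + 0.02 + 0.05 * rng.normal(size=(12, 15))
    return Sm, Ss


class TestPDS:
    def test_self_regression_reproduces_master(self, paired_blocks):
        Sm, _ = paired_blocks
        model = fit_pds(Sm, Sm, window=5)
        np.testing.assert_allclose(apply_pds(model, Sm), Sm, atol=1e-8)

    def test_window_one_is_per_channel_ols(self, paired_blocks):
        Sm, Ss = paired_blocks
        model = fit_pds(Sm, Ss, window=1)
        for j in range(Sm.shape[1]):
            coef, b0 = ols_normal_equations(Ss[:, [j]], Sm[:, j])
            assert model.F[j, j] == pytest.approx(coef[0], rel=1e-8)
            assert model.intercepts[j] == pytest.approx(b0, rel=1e-8)

    def test_window_three_matches_normal_equations_oracle(self, paired_blocks):
        Sm, Ss = paired_blocks
        p = Sm.shape[1]
        model = fit_pds(Sm, Ss, window=3)
        for j in range(p):
            lo, hi = max(0, j - 1), min(p, j + 2)
            coef, b0 = ols_normal_equations(Ss[:, lo:hi], Sm[:, j])
            np.testing.assert_allclose(model.F[lo:hi, j], coef, rtol=1e-8)
            assert model.intercepts[j] == pytest.approx(b0, rel=1e-8)

    @pytest.mark.parametrize("p,window", [(9, 3), (9, 7), (5, 5), (4, 7)])
    def test_band_structure_including_edges(self, p, window):
        rng = np.random.default_rng(p * window)
        Sm = rng.normal(size=(10, p))
        Ss = rng.normal(size=(10, p))
        model = fit_pds(Sm, Ss, window=window)
        half = (window - 1) // 2
        for i in range(p):
            for j in range(p):
                if abs(i - j) > half:
                    assert model.F[i, j] == 0.0

    def test_rejects_even_window_and_unpaired_blocks(self, paired_blocks):
        Sm, Ss = paired_blocks
        with pytest.raises(ParameterError):
            fit_pds(Sm, Ss, window=4)
        with pytest.raises(PairingError):
            fit_pds(Sm[:5], Ss[:6], window=3)

    def test_json_round_trip(self, tmp_path, paired_blocks):
        Sm, Ss = paired_blocks
        model = fit_pds(Sm, Ss, window=3)
        model.to_json(tmp_path / "pds.json")
        back = PDSModel.from_json(tmp_path / "pds.json")
        np.testing.assert_array_equal(back.F, model.F)
        np.testing.assert_array_equal(back.intercepts, model.intercepts)


class TestSBC:
    def test_exact_affine_recovery(self):
        y = np.linspace(3.0, 9.0, 20)
        yhat = 1.2 * y + 3.0
        model = fit_sbc(yhat, y)
        assert model.slope == pytest.approx(1.2, abs=1e-10)
        assert model.bias == pytest.approx(3.0, abs=1e-10)
        np.testing.assert_allclose(apply_sbc(model, yhat), y, atol=1e-10)

    def test_identity_predictions(self):
        y = np.arange(10.0)
        model = fit_sbc(y, y)
        assert (model.slope, model.bias) == (pytest.approx(1.0), pytest.approx(0.0))

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_ols_oracle_under_noise(self, seed):
        rng = np.random.default_rng(seed)
        y = rng.normal(10.0, 2.0, size=50)
        yhat = 0.9 * y - 1.5 + 0.3 * rng.normal(size=50)
        model = fit_sbc(yhat, y)
        coef, b0 = ols_normal_equations(y[:, None], yhat)
        assert model.slope == pytest.approx(coef[0], rel=1e-8)
        assert model.bias == pytest.approx(b0, rel=1e-8)

    def test_unit_rescaling_covariance(self):
        """Rescaling property units transforms slope/bias covariantly."""
        rng = np.random.default_rng(4)
        y = rng.normal(10.0, 2.0, size=30)
        yhat = 1.1 * y + 0.4 + 0.1 * rng.normal(size=30)
        m1 = fit_sbc(yhat, y)
        a, b = 2.5, -3.0  # y' = a y + b, yhat' = a yhat + b
        m2 = fit_sbc(a * yhat + b, a * y + b)
        assert m2.slope == pytest.approx(m1.slope, rel=1e-10)
        np.testing.assert_allclose(
            apply_sbc(m2, a * yhat + b), a * apply_sbc(m1, yhat) + b, atol=1e-8
        )


class TestGLSW:
    def test_zero_difference_gives_identity(self, paired_blocks):
        Sm, _ = paired_blocks
        model = fit_glsw(Sm, Sm, alpha=0.02)
        np.testing.assert_allclose(model.G, np.eye(Sm.shape[1]), atol=1e-12)
        np.testing.assert_allclose(apply_glsw(model, Sm), Sm, atol=1e-12)

    def test_single_direction_shrunk_spectrally(self):
        rng = np.random.default_rng(9)
        d = rng.normal(size=8)
        d /= np.linalg.norm(d)
        Sm = rng.normal(size=(6, 8))
        Ss = Sm - 0.5 * np.outer(np.ones(6), d)  # one difference direction
        model = fit_glsw(Sm, Ss, alpha=0.02)
        s = np.linalg.norm(Sm - Ss, ord="fro")  # singular value of D
        expected = 1.0 / np.sqrt(s**2 / 0.02 + 1.0)
        np.testing.assert_allclose(model.G @ d, expected * d, atol=1e-10)
        v_perp = np.linalg.svd(np.outer(d, d) - np.eye(8))[0][:, 0]
        v_perp -= (v_perp @ d) * d
        np.testing.assert_allclose(model.G @ v_perp, v_perp, atol=1e-10)

    def test_shrinkage_monotone_in_alpha(self, paired_blocks):
        Sm, Ss = paired_blocks
        prev = None
        for alpha in (1.0, 0.1, 0.02, 0.001):
            model = fit_glsw(Sm, Ss, alpha=alpha)
            top = model.shrink[0]  # strongest difference direction
            if prev is not None:
                assert top < prev
            prev = top

    def test_alpha_must_be_positive(self, paired_blocks):
        with pytest.raises(ParameterError):
            fit_glsw(*paired_blocks, alpha=0.0)

    def test_json_round_trip(self, tmp_path, paired_blocks):
        model = fit_glsw(*paired_blocks)
        model.to_json(tmp_path / "glsw.json")
        back = GLSWModel.from_json(tmp_path / "glsw.json")
        np.testing.assert_allclose(back.G, model.G, atol=0)


class TestCCACT:
    def test_identical_blocks_correlations_one_and_identity(self, paired_blocks):
        Sm, _ = paired_blocks
        rank = np.linalg.matrix_rank(Sm - Sm.mean(axis=0))
        model = fit_ccact(Sm, Sm, c=rank)
        np.testing.assert_allclose(model.correlations, 1.0, atol=1e-8)
        np.testing.assert_allclose(transfer_ccact(model, Sm), Sm, atol=1e-6)

    @pytest.mark.parametrize("seed", range(10))
    def test_correlations_match_generalized_eigenvalue_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = 12
        Z = rng.normal(size=(n, 3))
        Xa = Z @ rng.normal(size=(3, 8)) + 0.3 * rng.normal(size=(n, 8))
        Xb = Z @ rng.normal(size=(3, 8)) + 0.3 * rng.normal(size=(n, 8))
        model = fit_ccact(Xa, Xb, c=3)
        ref = canonical_correlations_reference(Xa, Xb)
        np.testing.assert_allclose(model.correlations, ref[:3], atol=1e-8)
        assert np.all(np.diff(model.correlations) <= 1e-12)
        assert np.all((model.correlations >= 0) & (model.correlations <= 1 + 1e-12))

    def test_single_shared_factor_rank_one_transfer(self):
        rng = np.random.default_rng(33)
        t = rng.normal(size=20)
        pm = rng.normal(size=10)
        ps = rng.normal(size=10)
        Sm = np.outer(t, pm)
        Ss = np.outer(t, ps)
        model = fit_ccact(Sm, Ss, c=1)
        out = transfer_ccact(model, Ss)
        np.testing.assert_allclose(out, Sm, atol=1e-8)

    def test_json_round_trip(self, tmp_path, paired_blocks):
        model = fit_ccact(*paired_blocks, c=2)
        model.to_json(tmp_path / "cca.json")
        back = CCACTModel.from_json(tmp_path / "cca.json")
        np.testing.assert_allclose(
            transfer_ccact(back, paired_blocks[1]),
            transfer_ccact(model, paired_blocks[1]),
            atol=0,
        )


class TestMSC:
    def test_affine_distortion_removed_exactly(self):
        rng = np.random.default_rng(2)
        ref = np.abs(rng.normal(size=12)) + 1.0
        x = 2.0 * ref + 0.5
        np.testing.assert_allclose(msc_correct(x, ref)[0], ref, atol=1e-10)

    def test_reference_is_fixed_point(self):
        rng = np.random.default_rng(3)
        ref = rng.normal(size=9) + 5.0
        np.testing.assert_allclose(msc_correct(ref, ref)[0], ref, atol=1e-10)

    def test_batch_equals_row_wise(self):
        rng = np.random.default_rng(4)
        ref = rng.normal(size=9) + 5.0
        X = rng.normal(size=(6, 9)) + 5.0
        batch = msc_correct(X, ref)
        rows = np.vstack([msc_correct(X[i], ref) for i in range(6)])
        np.testing.assert_allclose(batch, rows, atol=1e-12)
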
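"""Spline completion and (M)FPCA: recovery, orthonormality, reconstruction."""

import numpy as np
import pandas as pd
import pytest

import _oracles
from radkinetics import kinetics, synthetic


def _table_from_values(values_by_voi, months=(0, 2, 6)):
    rows = []
    for voi, vals in values_by_voi.items():
        for month, v in zip(months, vals):
            rows.append(
                {
                    "voi_id": voi,
                    "patient_id": voi,
                    "label": "ORN",
                    "timepoint_month": month,
                    "f001": v,
                }
            )
    return pd.DataFrame(rows)


class TestSplineCompletion:
    def test_collinear_points_reproduce_the_line(self):
        table = _table_from_values({"V1": (0.0, 2.0, 6.0)})
        dense = kinetics.spline_complete(table)
        np.testing.assert_allclose(dense.values[0, 0], np.arange(7.0), atol=1e-12)

    def test_curves_interpolate_observations_exactly(self, rng):
        table = _table_from_values(
            {f"V{i}": tuple(rng.standard_normal(3)) for i in range(5)}
        )
        dense = kinetics.spline_complete(table)
        for i, voi in enumerate(dense.voi_ids):
            obs = table[table.voi_id == voi].sort_values("timepoint_month")["f001"]
            np.testing.assert_allclose(
                dense.values[i, 0, [0, 2, 6]], obs.to_numpy(), atol=1e-12
            )

    def test_month_one_matches_tridiagonal_natural_spline_oracle(self):
        y = (1.0, 3.0, 2.0)
        table = _table_from_values({"V1": y})
        dense = kinetics.spline_complete(table)
        expected = _oracles.natural_spline_3pt((0.0, 2.0, 6.0), y, 1.0)
        assert dense.values[0, 0, 1] == pytest.approx(expected, abs=1e-12)

    def test_extrapolation_refused(self):
        table = _table_from_values({"V1": (1.0, 2.0, 3.0)})
        with pytest.raises(ValueError, match="extrapolation"):
            kinetics.spline_complete(table, grid=np.arange(0.0, 9.0))

    def test_missing_observation_rejected(self):
        table = _table_from_values({"V1": (1.0, 2.0, 3.0)})
        with pytest.raises(ValueError, match="observed months"):
            kinetics.spline_complete(table[table.timepoint_month != 2])


class TestUFPCA:
    def test_rank_one_curves_recover_single_component(self, fpca_fixture):
        grid, w = fpca_fixture["grid"], fpca_fixture["weights"]
        phi = fpca_fixture["phi"][1]
        rng = np.random.default_rng(0)
        a = rng.standard_normal(40)
        curves = 2.0 + a[:, None] * phi
        res = kinetics.ufpca(curves, grid, pve_threshold=0.99)
        assert res.eigenvalues.shape[0] == 1
        assert res.pve[0] == pytest.approx(1.0)
        assert abs(np.sum(w * res.eigenfunctions[0] * phi)) == pytest.approx(1.0, abs=1e-8)

    def test_eigenstructure_recovery_from_known_basis(self, fpca_fixture):
        res = kinetics.ufpca(fpca_fixture["curves"], fpca_fixture["grid"])
        lam = res.eigenvalues
        assert abs(lam[0] / lam[1] - 4.0) / 4.0 < 0.25
        w = fpca_fixture["weights"]
        for m in range(2):
            cos = np.sum(w * res.eigenfunctions[m] * fpca_fixture["phi"][m])
            assert abs(cos) > 0.95

    def test_equal_weights_coincide_with_plain_pca(self, rng):
        grid = np.arange(5.0)
        curves = rng.standard_normal((30, 5))
        h = 1.0
        res = kinetics.ufpca(curves, grid, pve_threshold=1.0, weights=np.full(5, h))
        C = np.cov(curves, rowvar=False)
        evals = np.sort(np.linalg.eigvalsh(C))[::-1]
        np.testing.assert_allclose(res.eigenvalues, h * evals[: len(res.eigenvalues)], atol=1e-10)

    def test_eigenfunctions_orthonormal_under_quadrature(self, fpca_fixture):
        res = kinetics.ufpca(fpca_fixture["curves"], fpca_fixture["grid"], pve_threshold=1.0)
        gram = (res.eigenfunctions * res.weights) @ res.eigenfunctions.T
        np.testing.assert_allclose(gram, np.eye(gram.shape[0]), atol=1e-8)

    def test_sign_convention_is_deterministic(self, fpca_fixture):
        r1 = kinetics.ufpca(fpca_fixture["curves"], fpca_fixture["grid"])
        r2 = kinetics.ufpca(fpca_fixture["curves"].copy(), fpca_fixture["grid"])
        np.testing.assert_array_equal(r1.eigenfunctions, r2.eigenfunctions)
        np.testing.assert_array_equal(r1.scores, r2.scores)


class TestMFPCA:
    def test_single_feature_degenerates_to_ufpca(self, fpca_fixture):
        uni = kinetics.ufpca(fpca_fixture["curves"], fpca_fixture["grid"], pve_threshold=1.0)
        multi = kinetics.mfpca([uni], pve_threshold=1.0)
        np.testing.assert_allclose(
            multi.eigenvalues, uni.eigenvalues[: len(multi.eigenvalues)], atol=1e-8
        )
        # scores match up to sign/order
        corr = np.corrcoef(multi.scores[:, 0], uni.scores[:, 0])[0, 1]
        assert abs(corr) == pytest.approx(1.0, abs=1e-10)

    def test_duplicated_feature_loads_equally(self, fpca_fixture):
        uni = kinetics.ufpca(fpca_fixture["curves"], fpca_fixture["grid"])
        multi = kinetics.mfpca([uni, uni], pve_threshold=0.9)
        c1 = multi.eigenvectors[0]
        b1, b2 = multi.score_blocks
        np.testing.assert_allclose(np.abs(c1[b1]), np.abs(c1[b2]), atol=1e-8)
        # PVE against a direct eigendecomposition of the duplicated matrix
        Xi = np.hstack([uni.scores, uni.scores])
        evals = np.sort(np.linalg.eigvalsh((Xi.T @ Xi) / (Xi.shape[0] - 1)))[::-1]
        assert multi.pve[0] == pytest.approx(evals[0] / evals.clip(min=0).sum(), abs=1e-10)

    def test_total_variance_is_conserved(self, fpca_fixture):
        uni = kinetics.ufpca(fpca_fixture["curves"], fpca_fixture["grid"], pve_threshold=1.0)
        multi = kinetics.mfpca([uni, uni], M=2 * uni.scores.shape[1])
        Xi = np.hstack([uni.scores, uni.scores])
        total = np.sum(np.var(Xi, axis=0, ddof=1))
        assert multi.eigenvalues.sum() == pytest.approx(total, rel=1e-8)

    def test_scores_have_zero_mean(self, fpca_fixture):
        uni = kinetics.ufpca(fpca_fixture["curves"], fpca_fixture["grid"])
        multi = kinetics.mfpca([uni])
        scale = np.sqrt(multi.eigenvalues[0])
        assert np.all(np.abs(multi.scores.mean(axis=0)) < 1e-8 * max(scale, 1))

    def test_multivariate_score_recovery_on_two_feature_fixture(self):
        """Two features sharing 2 latent components: recovered scores correlate
        with the truth at |r| > 0.9 per component."""
        grid = np.arange(7.0)
        w = synthetic.trapezoid_weights(grid)
        b1 = np.ones_like(grid)
        b1 /= np.sqrt(np.sum(w * b1**2))
        raw = grid - grid.mean()
        raw -= b1 * np.sum(w * raw * b1)
        b2 = raw / np.sqrt(np.sum(w * raw**2))
        rng = np.random.default_rng(21)
        rho_true = rng.standard_normal((200, 2)) * np.sqrt([4.0, 1.0])
        # feature 1 responds to both components, feature 2 mostly to the second
        curves1 = rho_true[:, 0][:, None] * b1 + 0.4 * rho_true[:, 1][:, None] * b2
        curves2 = rho_true[:, 1][:, None] * b2 + 0.4 * rho_true[:, 0][:, None] * b1
        curves1 += 0.05 * rng.standard_normal(curves1.shape)
        curves2 += 0.05 * rng.standard_normal(curves2.shape)
        uni = [kinetics.ufpca(c, grid) for c in (curves1, curves2)]
        multi = kinetics.mfpca(uni, M=2)
        for m in range(2):
            r = max(
                abs(np.corrcoef(multi.scores[:, k], rho_true[:, m])[0, 1])
                for k in range(2)
            )
            assert r > 0.9


class TestReconstruction:
    def test_full_rank_noiseless_reconstruction_is_lossless(self, fpca_fixture):
        grid = fpca_fixture["grid"]
        curves, _ = synthetic.generate_curves_from_basis(
            grid, fpca_fixture["phi"], (4.0, 1.0), n=50, noise_sd=0.0, seed=9
        )
        uni = kinetics.ufpca(curves, grid, pve_threshold=1.0)
        multi = kinetics.mfpca([uni], M=uni.scores.shape[1])
        rec = kinetics.reconstruct(multi)
        np.testing.assert_allclose(rec[:, 0, :], curves, atol=1e-8)

    def test_zero_components_reconstruct_the_mean(self, fpca_fixture):
        uni = kinetics.ufpca(fpca_fixture["curves"], fpca_fixture["grid"])
        multi = kinetics.mfpca([uni])
        rec = kinetics.reconstruct(multi, M=0)
        np.testing.assert_allclose(rec[:, 0, :], np.tile(uni.mean, (rec.shape[0], 1)))

    def test_reconstruction_error_monotone_in_components(self, fpca_fixture):
        uni = kinetics.ufpca(fpca_fixture["curves"], fpca_fixture["grid"], pve_threshold=1.0)
        multi = kinetics.mfpca([uni], M=uni.scores.shape[1])
        errs = []
        for M in range(multi.scores.shape[1] + 1):
            rec = kinetics.reconstruct(multi, M=M)
            errs.append(np.mean((rec[:, 0, :] - fpca_fixture["curves"]) ** 2))
        assert all(b <= a + 1e-12 for a, b in zip(errs, errs[1:]))

    def test_single_component_relative_mse_matches_spectral_identity(self, fpca_fixture):
        """Truncating to M=1 leaves ~ lambda2/(lambda1+lambda2) = 1/5 of the variance."""
        curves = fpca_fixture["curves"]
        uni = kinetics.ufpca(curves, fpca_fixture["grid"], pve_threshold=1.0)
        multi = kinetics.mfpca([uni], M=uni.scores.shape[1])
        rec1 = kinetics.reconstruct(multi, M=1)[:, 0, :]
        centered = curves - curves.mean(axis=0)
        rel = np.sum((rec1 - curves) ** 2) / np.sum(centered**2)
        assert rel == pytest.approx(0.2, abs=0.08)


class TestTrajectoryScores:
    def test_score_table_shape_and_determinism(self, default_cohort):
        table, _ = default_cohort
        feats = [c for c in table.columns if c.startswith("f")][:6]
        s1, r1, _ = kinetics.fit_trajectory_scores(table, feats)
        s2, r2, _ = kinetics.fit_trajectory_scores(table, feats)
        pd.testing.assert_frame_equal(s1, s2)
        assert list(s1.columns[:3]) == ["voi_id", "patient_id", "label"]
        assert s1.shape[0] == table["voi_id"].nunique()
        assert r1.scores.shape[1] >= 1
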
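"""First-level GLM, contrasts, second-level inference and smoothing."""

from __future__ import annotations

import numpy as np
import pytest
from scipy import stats

from oscoupler.glm import (
    BoldRun,
    DesignMatrix,
    FirstLevelCoupling,
    GLMConfig,
    GroupDifference,
    StatMap,
    build_design,
    canonical_hrf,
    contrast_t,
    dct_highpass_basis,
    fit_first_level,
    group_fcontrast,
    group_onesample,
    smooth_volume,
)
from oscoupler.simulate import SimConfig, cohort_truth, simulate_bold


def _run(T=40, shape=(4, 4, 3), tr=2.1, seed=0, data=None):
    rng = np.random.default_rng(seed)
    mask = np.ones(shape, dtype=bool)
    if data is None:
        data = rng.normal(100.0, 1.0, size=(*shape, T))
    return BoldRun(
        data=data, affine=np.diag([3.0, 3.0, 3.0, 1.0]), tr=tr, mask=mask,
        motion=rng.normal(0, 0.1, size=(T, 6)),
        wm=rng.normal(70, 0.5, size=T), csf=rng.normal(30, 0.5, size=T),
    )


class TestDesign:
    def test_dct_column_count_at_defaults(self):
        """T=185, TR=2.1 s, 128 s cutoff: exactly 6 drift columns — the
        number of DCT periods longer than the cutoff by direct enumeration."""
        T, tr, cutoff = 185, 2.1, 128.0
        expected = sum(1 for k in range(1, T) if 2 * T * tr / k > cutoff)
        basis = dct_highpass_basis(T, tr, cutoff)
        assert basis.shape[1] == expected == 6

    def test_dct_columns_orthogonal(self):
        basis = dct_highpass_basis(185, 2.1, 128.0)
        gram = basis.T @ basis
        off = gram - np.diag(np.diag(gram))
        assert np.abs(off).max() < 1e-8

    def test_impulse_regressor_reproduces_hrf(self):
        run = _run(T=30)
        series = np.zeros(30)
        series[0] = 1.0
        design = build_design(
            series, run, GLMConfig(zscore_modulator=False)
        )
        hrf = canonical_hrf(run.tr)
        expected = np.zeros(30)
        expected[: hrf.size] = hrf
        assert np.allclose(design.X[:, 0], expected)

    def test_constant_series_flagged_degenerate(self):
        run = _run()
        with pytest.warns(UserWarning, match="degenerate"):
            design = build_design(np.ones(run.n_volumes), run)
        assert design.degenerate
        assert np.allclose(design.X[:, 0], 0.0)

    def test_interest_mean_centered(self, rng):
        run = _run()
        design = build_design(rng.uniform(1, 5, run.n_volumes), run)
        # z-scored modulator has zero mean before convolution; after
        # convolution with a finite kernel the column mean stays near zero
        assert abs(design.X[:, 0].mean()) < 0.2

    def test_collinear_confounds_rejected(self):
        run = _run()
        run.wm = run.csf.copy()  # perfectly collinear nuisances
        with pytest.raises(ValueError, match="collinear"):
            build_design(np.random.default_rng(1).uniform(size=run.n_volumes), run)

    def test_wrong_length_rejected(self):
        run = _run(T=40)
        with pytest.raises(ValueError, match="length"):
            build_design(np.ones(30), run)


class TestFirstLevelFit:
    def test_noiseless_recovery(self):
        """y = 2*interest + 5 exactly: beta_interest = 2, intercept = 5."""
        run = _run(T=60, seed=3)
        rng = np.random.default_rng(4)
        series = rng.uniform(0, 2, size=60)
        design = build_design(series, run)
        y = 2.0 * design.X[:, 0] + 5.0
        run.data[...] = y[None, None, None, :]
        res = fit_first_level(run, design)
        i_interest = design.names.index("interest")
        i_const = design.names.index("intercept")
        assert np.allclose(res.beta[i_interest], 2.0, atol=1e-8)
        assert np.allclose(res.beta[i_const], 5.0, atol=1e-8)

    def test_matches_normal_equations_oracle(self):
        """100 random small instances at rho=0 agree with the explicit
        normal-equations solve to 1e-8."""
        rng = np.random.default_rng(42)
        for _ in range(100):
            T, P, V = 20, 3, 5
            X = rng.normal(size=(T, P))
            Y = rng.normal(size=(V, T))
            shape = (V, 1, 1)
            run = BoldRun(
                data=Y.reshape(*shape, T), affine=np.eye(4), tr=2.0,
                mask=np.ones(shape, bool), motion=np.zeros((T, 6)),
                wm=np.zeros(T), csf=np.zeros(T),
            )
            design = DesignMatrix(X=X, names=["a", "b", "c"], interest_index=0,
                                  hp_cutoff=128.0)
            res = fit_first_level(run, design, ar1=0.0)
            expected = np.linalg.solve(X.T @ X, X.T @ Y.T)
            assert np.abs(res.beta - expected).max() < 1e-8

    def test_gls_equals_ols_at_rho_zero(self, rng):
        run = _run(T=50, seed=6)
        design = build_design(rng.uniform(size=50), run)
        a = fit_first_level(run, design, ar1=0.0)
        pinv = np.linalg.pinv(design.X)
        expected = run.masked_series() @ pinv.T
        assert np.allclose(a.beta, expected.T)

    def test_prewhitening_reduces_residual_autocorrelation(self):
        cfg = SimConfig(seed=14, n_per_group=2, coupling_table=[], alff_rois=[])
        truth = cohort_truth(cfg)
        run = simulate_bold(cfg, truth, 0)
        design = build_design(truth.band_power["sub00"]["alpha"], run)
        res = fit_first_level(run, design)
        assert 0.15 < res.rho < 0.45  # generator plants rho = 0.3

    def test_beta_recovery_on_cohort(self):
        """Planted thalamic coupling (0.8 %/z): subject-averaged ROI beta
        recovered within 10%."""
        cfg = SimConfig(seed=8, n_per_group=10)
        truth = cohort_truth(cfg)
        roi = truth.roi_mask("thalamus")
        means = []
        for i, sid in enumerate(truth.subjects[:10]):  # planted group
            run = simulate_bold(cfg, truth, i)
            res = FirstLevelCoupling(run, truth.band_power[sid]["alpha"]).fit()
            means.append(np.nanmean(res.beta_map("interest").values[roi]))
        assert np.mean(means) == pytest.approx(0.8, rel=0.10)


class TestContrasts:
    def _fitted(self, seed=0):
        run = _run(T=50, seed=seed)
        series = np.random.default_rng(seed + 1).uniform(size=50)
        design = build_design(series, run)
        return fit_first_level(run, design), design

    def test_sign_flip(self):
        res, design = self._fitted()
        c = np.zeros(len(design.names))
        c[0] = 1.0
        t1 = contrast_t(res, c).in_mask()
        t2 = contrast_t(res, -c).in_mask()
        assert np.allclose(t1, -t2)

    def test_t_squared_equals_f(self):
        res, design = self._fitted()
        c = np.zeros(len(design.names))
        c[0] = 1.0
        t = res.contrast_t(c).in_mask()
        f = res.contrast_f(c).in_mask()
        assert np.allclose(t**2, f)

    def test_noiseless_t_saturates(self):
        run = _run(T=60, seed=3)
        series = np.random.default_rng(4).uniform(0, 2, size=60)
        design = build_design(series, run)
        run.data[...] = (2.0 * design.X[:, 0] + 5.0)[None, None, None, :]
        res = fit_first_level(run, design)
        c = np.zeros(len(design.names))
        c[0] = 1.0
        tmap = contrast_t(res, c)
        # residual variance is numerically ~0: t rails at the finite cap
        assert np.all(tmap.in_mask() >= 1e5)

    def test_invariance_to_regressor_scale(self, rng):
        run = _run(T=50, seed=9)
        series = rng.uniform(size=50)
        t1 = FirstLevelCoupling(run, series).fit().tvalues().in_mask()
        t2 = FirstLevelCoupling(run, 3.7 * series).fit().tvalues().in_mask()
        assert np.allclose(t1, t2)


class TestSecondLevel:
    def _maps(self, data):
        """data: n_subjects x n_voxels -> StatMaps on a flat grid."""
        V = data.shape[1]
        mask = np.ones((V, 1, 1), bool)
        return [
            StatMap(values=row.reshape(V, 1, 1), stat="beta", df=None,
                    mask=mask, affine=np.eye(4))
            for row in data
        ]

    def test_onesample_matches_scipy(self, rng):
        data = rng.normal(0.3, 1.0, size=(8, 5))
        tmap = group_onesample(self._maps(data))
        expected = stats.ttest_1samp(data, 0.0, axis=0).statistic
        assert np.allclose(tmap.in_mask(), expected)
        assert tmap.df == (7,)

    def test_onesample_symmetric_pairs_zero(self):
        data = np.vstack([np.ones((2, 4)), -np.ones((2, 4))])
        tmap = group_onesample(self._maps(data))
        assert np.allclose(tmap.in_mask(), 0.0)

    def test_onesample_identical_maps_saturate(self):
        data = np.full((4, 3), 2.5)
        tmap = group_onesample(self._maps(data))
        assert np.all(tmap.in_mask() >= 1e5)
        assert tmap.saturated.any()

    def test_fcontrast_matches_scipy_ttest(self, rng):
        data = rng.normal(size=(12, 6))
        groups = ["a"] * 6 + ["b"] * 6
        fmap = group_fcontrast(self._maps(data), groups)
        t = stats.ttest_ind(data[:6], data[6:], axis=0).statistic
        assert np.allclose(fmap.in_mask(), t**2)
        assert fmap.df == (1, 10)

    def test_identical_groups_give_zero_f(self, rng):
        half = rng.normal(size=(4, 5))
        data = np.vstack([half, half])
        fmap = group_fcontrast(self._maps(data), ["a"] * 4 + ["b"] * 4)
        assert np.allclose(fmap.in_mask(), 0.0)

    def test_small_group_rejected(self, rng):
        data = rng.normal(size=(3, 4))
        with pytest.raises(ValueError, match="two subjects"):
            group_fcontrast(self._maps(data), ["a", "a", "b"])

    def test_model_results_wrapper(self, rng):
        data = rng.normal(size=(8, 5))
        data[:4] += 2.0
        res = GroupDifference(self._maps(data), ["a"] * 4 + ["b"] * 4).fit()
        assert res.fmap.stat == "F"
        assert "F" in res.summary()


class TestSmoothing:
    def test_zero_fwhm_identity(self):
        run = _run()
        assert smooth_volume(run, 0.0) is run

    def test_constant_image_unchanged(self):
        """Mask-aware renormalization keeps a constant image constant even
        at mask edges."""
        shape = (10, 10, 8)
        mask = np.zeros(shape, bool)
        mask[2:8, 2:8, 2:6] = True
        data = np.where(mask, 5.0, 0.0)[..., None] * np.ones(4)
        run = BoldRun(
            data=data, affine=np.diag([3.0, 3, 3, 1]), tr=2.1, mask=mask,
            motion=np.zeros((4, 6)), wm=np.zeros(4), csf=np.zeros(4),
        )
        out = smooth_volume(run, 8.0)
        assert np.allclose(out.data[mask], 5.0)

    def test_delta_image_kernel_fwhm(self):
        """The impulse response's measured full width at half maximum is the
        requested FWHM within half a voxel."""
        shape = (31, 31, 31)
        data = np.zeros((*shape, 1))
        data[15, 15, 15, 0] = 1.0
        run = BoldRun(
            data=data, affine=np.diag([3.0, 3, 3, 1]), tr=2.1,
            mask=np.ones(shape, bool), motion=np.zeros((1, 6)),
            wm=np.zeros(1), csf=np.zeros(1),
        )
        out = smooth_volume(run, 8.0)
        profile = out.data[:, 15, 15, 0]
        half = profile.max() / 2
        above = np.flatnonzero(profile >= half)
        # linear interpolation at the crossings
        lo, hi = above[0], above[-1]
        f = lambda i, j: i + (half - profile[i]) / (profile[j] - profile[i]) * (j - i)
        width_vox = f(hi, hi + 1) - f(lo, lo - 1)
        assert width_vox * 3.0 == pytest.approx(8.0, abs=1.5)

    def test_negative_fwhm_rejected(self):
        with pytest.raises(ValueError):
            smooth_volume(_run(), -1.0)


class TestTypeIControl:
    def test_voxelwise_exceedance_at_nominal_rate(self):
        """Null cohorts: group-F p < 0.005 exceedance equals the nominal
        rate within a binomial band over ~1e5 voxel draws."""
        count = 0
        total = 0
        for s in range(37):
            cfg = SimConfig(seed=3000 + s, n_per_group=4,
                            coupling_table=[], alff_rois=[])
            truth = cohort_truth(cfg)
            maps, groups = [], []
            for i, sid in enumerate(truth.subjects):
                run = simulate_bold(cfg, truth, i)
                res = FirstLevelCoupling(
                    run, truth.band_power[sid]["alpha"]
                ).fit()
                maps.append(res.beta_map("interest"))
                groups.append(truth.groups[sid])
            fmap = group_fcontrast(maps, groups)
            thr = stats.f.isf(0.005, *fmap.df)
            vals = fmap.in_mask()
            count += int((vals > thr).sum())
            total += vals.size
        rate = count / total
        assert total >= 1e5
        assert abs(rate - 0.005) < 0.001
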
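"""Band power against analytic signals; group ICA against planted sources."""

import numpy as np
import pandas as pd
import pytest

from microdyn import Recording
from microdyn.spectral import (
    DEFAULT_BANDS,
    BandDefinition,
    PowerMatrix,
    band_power,
    build_power_matrices,
    ica_decompose,
    ica_sweep,
    orient_and_zscore,
    theta_beta_ratio,
)
from microdyn.spectral import test_components as component_tests

BANDS = {b.name: b for b in DEFAULT_BANDS}


def _rec(data, fs=250.0):
    data = np.atleast_2d(np.asarray(data, dtype=float))
    return Recording(
        data=data, fs=fs, channel_names=[f"c{i}" for i in range(data.shape[0])]
    )


class TestBandPower:
    def test_sinusoid_power_is_half_amplitude_squared(self):
        t = np.arange(0, 60.0, 1 / 250.0)
        a = 3.0
        rec = _rec([a * np.sin(2 * np.pi * 9.0 * t), np.zeros_like(t)])
        low_alpha = band_power(rec, BANDS["low_alpha"])
        assert low_alpha[0] == pytest.approx(a ** 2 / 2, rel=0.05)
        for other in ("beta", "gamma", "delta"):
            assert band_power(rec, BANDS[other])[0] < 0.01 * low_alpha[0]

    def test_white_noise_band_sum_below_variance(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(30000)
        rec = _rec([x, x])
        total = np.var(x)
        band_sum = sum(band_power(rec, b)[0] for b in DEFAULT_BANDS)
        assert band_sum <= total
        # the six bands tile 1-45 Hz of a 125 Hz Nyquist range
        assert band_sum == pytest.approx(total * 44.0 / 125.0, rel=0.1)

    def test_zero_channel_has_zero_power(self):
        rec = _rec(np.zeros((2, 5000)))
        for b in DEFAULT_BANDS:
            assert band_power(rec, b)[0] == 0.0

    def test_short_recording_rejected(self):
        rec = _rec(np.zeros((2, 100)))
        with pytest.raises(ValueError, match="window"):
            band_power(rec, BANDS["delta"])


class TestTbr:
    def test_arithmetic_and_identity(self):
        np.testing.assert_allclose(
            theta_beta_ratio(np.array([6.0]), np.array([3.0])), [2.0]
        )
        same = np.array([1.5, 2.5])
        np.testing.assert_allclose(theta_beta_ratio(same, same), [1.0, 1.0])

    def test_scale_invariance(self):
        rng = np.random.default_rng(1)
        rec = _rec(rng.standard_normal((3, 10000)))
        doubled = _rec(2 * rec.data)
        for r in (rec, doubled):
            pass
        tbr1 = theta_beta_ratio(
            band_power(rec, BANDS["theta"]), band_power(rec, BANDS["beta"])
        )
        tbr2 = theta_beta_ratio(
            band_power(doubled, BANDS["theta"]), band_power(doubled, BANDS["beta"])
        )
        np.testing.assert_allclose(tbr1, tbr2, rtol=1e-9)

    def test_zero_beta_names_channel(self):
        with pytest.raises(ValueError, match="1"):
            theta_beta_ratio(np.array([1.0, 1.0]), np.array([2.0, 0.0]))


class TestPowerMatrices:
    def test_shapes_and_band_count(self, small_cohort_clean, small_cohort):
        ids = list(small_cohort.metadata["subject_id"])
        mats = build_power_matrices(small_cohort_clean, ids)
        assert len(mats) == 7
        assert set(mats) == {b.name for b in DEFAULT_BANDS} | {"tbr"}
        for pm in mats.values():
            assert pm.values.shape == (10, 91)
            assert list(pm.values.index) == ids

    def test_identical_recordings_identical_rows(self, small_cohort_clean):
        recs = [small_cohort_clean[0], small_cohort_clean[0]]
        mats = build_power_matrices(recs, ["a", "b"])
        for pm in mats.values():
            np.testing.assert_array_equal(
                pm.values.iloc[0].to_numpy(), pm.values.iloc[1].to_numpy()
            )

    def test_scale_equivariance(self, small_cohort_clean):
        recs = small_cohort_clean[:2]
        scaled = [
            Recording(
                data=3.0 * r.data, fs=r.fs, channel_names=r.channel_names
            )
            for r in recs
        ]
        m1 = build_power_matrices(recs, ["a", "b"])
        m2 = build_power_matrices(scaled, ["a", "b"])
        for band in m1:
            factor = 1.0 if band == "tbr" else 9.0
            np.testing.assert_allclose(
                m2[band].values.to_numpy(),
                factor * m1[band].values.to_numpy(),
                rtol=1e-9,
            )


def _planted_matrix(n_subj=60, n_ch=120, seed=0, shift=0.0, groups=None):
    """Two Laplacian spatial sources with Gaussian loadings + noise."""
    rng = np.random.default_rng(seed)
    s = rng.laplace(size=(2, n_ch))
    a = rng.standard_normal((n_subj, 2)) * [2.0, 1.5]
    if shift:
        a[groups == 1, 0] += shift
    x = a @ s + 0.05 * rng.standard_normal((n_subj, n_ch))
    x = x - x.min() + 1.0
    return (
        PowerMatrix(
            values=pd.DataFrame(
                x,
                index=[f"S{i}" for i in range(n_subj)],
                columns=[f"c{i}" for i in range(n_ch)],
            ),
            band="delta",
        ),
        s,
    )


class TestIca:
    def test_recovers_planted_sources(self):
        hits = 0
        for seed in range(10):
            pm, s = _planted_matrix(seed=seed)
            res = ica_decompose(pm, 2, seed=seed)
            got = res.spatial_maps.to_numpy()
            corr = np.abs(np.corrcoef(np.vstack([got, s]))[:2, 2:])
            if corr.max(axis=1).min() > 0.95:
                hits += 1
        assert hits >= 9

    def test_reconstruction_is_rank_m_approximation(self):
        pm, _ = _planted_matrix(seed=3)
        res = ica_decompose(pm, 2, seed=0)
        x = pm.values.to_numpy()
        xc = x - x.mean(axis=0, keepdims=True)
        u, sv, vt = np.linalg.svd(xc, full_matrices=False)
        rank2 = (u[:, :2] * sv[:2]) @ vt[:2]
        recon = res.loadings.to_numpy() @ res.spatial_maps.to_numpy()
        assert np.linalg.norm(recon - rank2) < 1e-6 * np.linalg.norm(rank2)

    def test_same_seed_reproducible(self):
        pm, _ = _planted_matrix(seed=4)
        a = ica_decompose(pm, 3, seed=9)
        b = ica_decompose(pm, 3, seed=9)
        np.testing.assert_array_equal(
            a.loadings.to_numpy(), b.loadings.to_numpy()
        )

    def test_sweep_covers_requested_orders(self):
        pm, _ = _planted_matrix(seed=5)
        sweep = ica_sweep(pm, components=range(5, 8), seed=0)
        assert sorted(sweep) == [5, 6, 7]
        for m, res in sweep.items():
            assert res.loadings.shape[1] == m

    def test_invalid_component_count(self):
        pm, _ = _planted_matrix(n_subj=10, seed=0)
        with pytest.raises(ValueError):
            ica_decompose(pm, 11, seed=0)


class TestOrientation:
    def _result(self, seed=0):
        groups = np.repeat([0, 1], 30)
        pm, _ = _planted_matrix(seed=seed, shift=2.0, groups=groups)
        res = ica_decompose(pm, 2, seed=0)
        return res, pd.Series(groups.astype(str), index=res.loadings.index)

    def test_reference_group_mean_is_higher_after_orientation(self):
        res, groups = self._result()
        oriented = orient_and_zscore(res, groups, "0")
        ref_mean = oriented.loadings[groups == "0"].mean(axis=0)
        other = oriented.loadings[groups == "1"].mean(axis=0)
        assert (ref_mean >= other).all()

    def test_orientation_idempotent_and_model_preserved(self):
        res, groups = self._result(seed=1)
        once = orient_and_zscore(res, groups, "0")
        twice = orient_and_zscore(once, groups, "0")
        np.testing.assert_allclose(
            once.loadings.to_numpy(), twice.loadings.to_numpy()
        )
        np.testing.assert_allclose(
            res.loadings.to_numpy() @ res.spatial_maps.to_numpy(),
            once.loadings.to_numpy() @ once.spatial_maps.to_numpy(),
            atol=1e-9,
        )

    def test_zmaps_standardized(self):
        res, groups = self._result(seed=2)
        oriented = orient_and_zscore(res, groups, "0")
        z = oriented.zmaps.to_numpy()
        np.testing.assert_allclose(z.mean(axis=1), 0.0, atol=1e-9)
        np.testing.assert_allclose(z.std(axis=1), 1.0, atol=1e-9)


class TestComponentTests:
    def test_z_threshold_rule(self):
        rng = np.random.default_rng(0)
        groups = np.repeat(["a", "b"], 20)
        pm, _ = _planted_matrix(
            n_subj=40, seed=6, shift=3.0, groups=(groups == "b").astype(int)
        )
        res = ica_decompose(pm, 2, seed=0)
        # overwrite one zmap with a known pattern to pin the threshold rule
        z = res.zmaps.to_numpy()
        z[0] = 0.0
        z[0, 0], z[0, 1], z[0, 2] = 2.5, -2.1, 0.3
        res.zmaps.iloc[:, :] = z
        table = component_tests(
            res, pd.Series(groups, index=res.loadings.index)
        )
        sig = table[table["significant"]]
        assert len(sig) >= 1
        if "IC1" in sig.index:
            assert set(sig.loc["IC1", "selected_channels"]) == {"c0", "c1"}

    def test_permuting_subjects_changes_no_statistic(self):
        groups = np.repeat([0, 1], 30)
        pm, _ = _planted_matrix(seed=7, shift=1.0, groups=groups)
        res = ica_decompose(pm, 2, seed=0)
        gs = pd.Series(groups.astype(str), index=res.loadings.index)
        t1 = component_tests(res, gs)["p"]

        perm = np.random.default_rng(1).permutation(60)
        res.loadings = res.loadings.iloc[perm]
        t2 = component_tests(res, gs)["p"]
        np.testing.assert_allclose(t1.to_numpy(), t2.to_numpy(), rtol=1e-9)

    def test_single_group_rejected(self):
        pm, _ = _planted_matrix(seed=8)
        res = ica_decompose(pm, 2, seed=0)
        gs = pd.Series("x", index=res.loadings.index)
        with pytest.raises(ValueError):
            component_tests(res, gs)
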
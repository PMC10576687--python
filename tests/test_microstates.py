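"""Microstate machinery against hand-computed and brute-force oracles."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from microdyn import (
    LabelSequence,
    MicrostateModel,
    Recording,
    backfit,
    cluster_microstates,
    compute_gev,
    compute_gfp,
    extract_features,
    features_to_frame,
    find_gfp_peaks,
    group_level_model,
    make_templates,
    reorient_to_abcd,
    spatial_correlation,
)
from microdyn.microstates import FEATURE_COLUMNS, GfpSeries, _best_permutation


def _rec(data, fs=250.0):
    data = np.asarray(data, dtype=float)
    return Recording(
        data=data, fs=fs, channel_names=[f"c{i}" for i in range(data.shape[0])]
    )


class TestGfp:
    @pytest.mark.parametrize(
        "column, expected",
        [
            ([1.0, -1.0], 1.0),
            ([3.0, 1.0, 2.0], np.sqrt(2.0 / 3.0)),
            ([5.0, 5.0, 5.0], 0.0),
        ],
    )
    def test_hand_computed_values(self, column, expected):
        rec = _rec(np.array(column)[:, None])
        assert compute_gfp(rec).values[0] == pytest.approx(expected)

    def test_single_channel_rejected(self):
        with pytest.raises(ValueError):
            compute_gfp(_rec(np.ones((1, 5))))

    def test_matches_spatial_sd_definition(self):
        rng = np.random.default_rng(0)
        data = rng.standard_normal((7, 50))
        expected = data.std(axis=0, ddof=0)
        np.testing.assert_allclose(compute_gfp(_rec(data)).values, expected)


class TestGfpPeaks:
    @pytest.mark.parametrize(
        "series, expected",
        [
            ([0, 1, 0, 2, 0], [1, 3]),
            ([0, 1, 2, 3, 4], []),
            ([0, 2, 2, 0], [1]),
        ],
    )
    def test_examples(self, series, expected):
        gfp = GfpSeries(values=np.array(series, dtype=float), fs=250.0)
        assert find_gfp_peaks(gfp).tolist() == expected

    @settings(max_examples=50, deadline=None)
    @given(
        st.lists(st.integers(min_value=0, max_value=5), min_size=3, max_size=30)
    )
    def test_matches_bruteforce_on_integer_series(self, values):
        gfp = GfpSeries(values=np.array(values, dtype=float), fs=1.0)
        brute = [
            t
            for t in range(1, len(values) - 1)
            if values[t - 1] < values[t] >= values[t + 1]
        ]
        assert find_gfp_peaks(gfp).tolist() == brute


class TestSpatialCorrelation:
    def test_identity_sign_and_orthogonality(self):
        rng = np.random.default_rng(1)
        u = rng.standard_normal(20)
        assert spatial_correlation(u, u) == pytest.approx(1.0)
        assert spatial_correlation(u, -u, polarity_invariant=True) == pytest.approx(1.0)
        assert spatial_correlation(u, -u, polarity_invariant=False) == pytest.approx(-1.0)
        v = rng.standard_normal(20)
        u0, v0 = u - u.mean(), v - v.mean()
        v_orth = v0 - (v0 @ u0) / (u0 @ u0) * u0
        assert spatial_correlation(u, v_orth + v_orth.mean()) == pytest.approx(
            0.0, abs=1e-9
        )

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            spatial_correlation(np.ones(5), np.arange(5.0))


class TestClustering:
    def test_recovers_two_orthogonal_templates(self):
        rng = np.random.default_rng(3)
        t1 = np.concatenate([np.ones(10), -np.ones(10)])
        t2 = np.concatenate([np.ones(5), -np.ones(10), np.ones(5)])
        t1, t2 = t1 / np.linalg.norm(t1), t2 / np.linalg.norm(t2)
        signs = rng.choice([-1, 1], size=200)
        scales = rng.uniform(0.5, 2.0, size=200)
        which = rng.integers(2, size=200)
        maps = np.where(which[:, None] == 0, t1, t2) * (signs * scales)[:, None]
        model = cluster_microstates(maps, k=2, n_restarts=5, seed=0)
        for t in (t1, t2):
            assert max(
                spatial_correlation(m, t) for m in model.maps
            ) > 0.999
        assert model.gev > 0.999

    def test_more_restarts_never_lower_gev(self, noiseless_subject):
        rec, _ = noiseless_subject
        peaks = find_gfp_peaks(compute_gfp(rec))
        noisy = rec.data.T[peaks][:400] + np.random.default_rng(0).normal(
            0, 0.5, size=(400, 91)
        )
        gevs = [
            cluster_microstates(noisy, k=4, n_restarts=n, seed=7).gev
            for n in (1, 5, 20)
        ]
        assert gevs == sorted(gevs)

    def test_k_below_two_rejected(self):
        with pytest.raises(ValueError):
            cluster_microstates(np.eye(8), k=1)


class TestGev:
    def test_brute_force_oracle(self, true_model, noiseless_subject):
        """GEV equals the explicit per-sample formula evaluated in a loop."""
        rec, _ = noiseless_subject
        sub = Recording(
            data=rec.data[:, :500] + np.random.default_rng(1).normal(
                0, 1.0, size=(91, 500)
            ),
            fs=rec.fs,
            channel_names=rec.channel_names,
        )
        seq = backfit(sub, true_model)
        got = compute_gev(true_model, sub, seq)

        gfp = compute_gfp(sub).values
        num = 0.0
        for t in range(500):
            v = sub.data[:, t]
            corr = spatial_correlation(v, true_model.maps[seq.labels[t]])
            num += gfp[t] ** 2 * corr ** 2
        expected = num / np.sum(gfp ** 2)
        assert got == pytest.approx(expected, abs=1e-12)

    def test_perfect_fit_gives_one(self, true_model, noiseless_subject):
        rec, labels = noiseless_subject
        assert compute_gev(true_model, rec, labels) == pytest.approx(1.0, abs=1e-9)

    def test_shuffled_labels_explain_less(self, true_model, noiseless_subject):
        rec, labels = noiseless_subject
        rng = np.random.default_rng(5)
        shuffled = LabelSequence(
            labels=rng.permutation(labels.labels), fs=labels.fs
        )
        assert compute_gev(true_model, rec, shuffled) < compute_gev(
            true_model, rec, labels
        )

    def test_all_zero_recording_rejected(self, true_model):
        rec = _rec(np.zeros((91, 10)))
        seq = LabelSequence(labels=np.zeros(10, dtype=int), fs=250.0)
        with pytest.raises(ValueError):
            compute_gev(true_model, rec, seq)


class TestGroupLevel:
    def test_identical_subjects_give_their_maps(self, true_model):
        models = [true_model] * 5
        group = group_level_model(models, k=4, n_restarts=10, seed=0)
        for m in true_model.maps:
            assert max(
                spatial_correlation(g, m) for g in group.maps
            ) > 0.999

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            group_level_model([], k=4)


class TestReorient:
    def test_identity_when_already_ordered(self, templates91, true_model):
        labeled, mean = reorient_to_abcd([true_model], templates91)
        assert labeled[0].labels == ["A", "B", "C", "D"]
        for i, t in enumerate(templates91):
            assert spatial_correlation(labeled[0].maps[i], t.values) > 0.999

    def test_recovers_shuffle_and_sign_flip(self, templates91, true_model):
        perm = [2, 0, 3, 1]
        flips = np.array([1.0, -1.0, 1.0, -1.0])
        shuffled = MicrostateModel(
            maps=true_model.maps[perm] * flips[:, None],
            gev=0.9,
            k=4,
        )
        labeled, _ = reorient_to_abcd([shuffled], templates91)
        assert labeled[0].labels == ["A", "B", "C", "D"]
        for i, t in enumerate(templates91):
            assert spatial_correlation(labeled[0].maps[i], t.values) > 0.999

    def test_exhaustive_matching_beats_greedy(self):
        """Exhaustive 4! assignment never scores below greedy matching."""
        rng = np.random.default_rng(11)
        for _ in range(100):
            maps = rng.standard_normal((4, 12))
            refs = rng.standard_normal((4, 12))
            _, best = _best_permutation(maps, refs)
            corr = np.array(
                [
                    [spatial_correlation(maps[i], refs[j]) for j in range(4)]
                    for i in range(4)
                ]
            )
            greedy_score, used = 0.0, set()
            for j in range(4):
                i = max(
                    (i for i in range(4) if i not in used),
                    key=lambda i: corr[i, j],
                )
                used.add(i)
                greedy_score += corr[i, j]
            assert best >= greedy_score - 1e-12

    def test_wrong_k_rejected(self, templates91):
        bad = MicrostateModel(maps=np.eye(3, 10), gev=0.5, k=3)
        with pytest.raises(ValueError):
            reorient_to_abcd([bad], templates91)


class TestBackfit:
    def test_noiseless_labels_recovered_exactly(
        self, true_model, noiseless_subject
    ):
        rec, labels = noiseless_subject
        seq = backfit(rec, true_model)
        carrier_alive = compute_gfp(rec).values > 1e-9
        assert np.array_equal(
            seq.labels[carrier_alive], labels.labels[carrier_alive]
        )

    def test_polarity_flip_leaves_labels_unchanged(
        self, true_model, noiseless_subject
    ):
        rec, _ = noiseless_subject
        flipped = Recording(
            data=-rec.data, fs=rec.fs, channel_names=rec.channel_names
        )
        np.testing.assert_array_equal(
            backfit(rec, true_model).labels,
            backfit(flipped, true_model).labels,
        )

    def test_single_map_labels_everything_zero(self, noiseless_subject):
        rec, _ = noiseless_subject
        model = MicrostateModel(
            maps=make_templates(91, seed=2)[0].values[None, :], gev=0.5, k=1
        )
        assert np.all(backfit(rec, model).labels == 0)

    def test_peak_restricted_variant_matches_at_peaks(
        self, true_model, noiseless_subject
    ):
        rec, labels = noiseless_subject
        seq = backfit(rec, true_model, restrict_to_peaks=True)
        peaks = find_gfp_peaks(compute_gfp(rec))
        np.testing.assert_array_equal(
            seq.labels[peaks], labels.labels[peaks]
        )
        # between peaks the nearest-peak fill coarsely tracks the generator
        # (boundaries move to the nearest peak, so agreement is not exact)
        assert (seq.labels == labels.labels).mean() > 0.8

    def test_windowed_variant_agrees_away_from_troughs(
        self, true_model, noiseless_subject
    ):
        rec, labels = noiseless_subject
        seq = backfit(rec, true_model, evidence_half_width=1)
        gfp = compute_gfp(rec).values
        strong = gfp > np.median(gfp)
        agree = (seq.labels[strong] == labels.labels[strong]).mean()
        assert agree > 0.995


class TestFeatures:
    def test_run_length_arithmetic(self):
        seq = LabelSequence(labels=np.array([0, 0, 0, 0, 1, 1]), fs=250.0)
        f = extract_features(seq)
        assert f.duration_ms[0] == pytest.approx(16.0)
        assert f.duration_ms[1] == pytest.approx(8.0)
        assert f.coverage_frac[0] == pytest.approx(2.0 / 3.0)
        assert f.occurrence_hz[0] == pytest.approx(1.0 / 0.024)

    def test_transition_counting(self):
        seq = LabelSequence(
            labels=np.array([0, 0, 1, 1, 2, 2, 0]), fs=250.0
        )
        f = extract_features(seq)
        assert f.transitions[0, 1] == 1.0
        assert f.transitions[1, 2] == 1.0
        assert f.transitions[2, 0] == 1.0
        assert f.transitions.sum() == pytest.approx(3.0)

    def test_flattened_vector_has_24_features(self, uniform_markov):
        from microdyn import simulate_label_sequence

        seq = simulate_label_sequence(
            uniform_markov, 250.0, 5000, rng=np.random.default_rng(0)
        )
        f = extract_features(seq)
        assert f.flatten().size == 24
        assert len(FEATURE_COLUMNS) == 24
        frame = features_to_frame([f], ["S001"])
        assert list(frame.columns) == FEATURE_COLUMNS

    def test_absent_state_gets_zeros(self):
        seq = LabelSequence(labels=np.array([0, 0, 1, 1]), fs=250.0)
        f = extract_features(seq)
        assert f.duration_ms[3] == 0.0
        assert f.occurrence_hz[3] == 0.0
        assert f.transitions[3].sum() == 0.0

    @settings(max_examples=40, deadline=None)
    @given(
        st.lists(st.integers(min_value=0, max_value=3), min_size=2, max_size=200)
    )
    def test_conservation_laws(self, labels):
        seq = LabelSequence(labels=np.array(labels), fs=250.0)
        f = extract_features(seq)
        assert f.coverage_frac.sum() == pytest.approx(1.0, abs=1e-9)
        for row in f.transitions:
            assert row.sum() == pytest.approx(1.0, abs=1e-9) or row.sum() == 0.0

    def test_coverage_consistent_with_occurrence_times_duration(
        self, uniform_markov
    ):
        from microdyn import simulate_label_sequence

        seq = simulate_label_sequence(
            uniform_markov, 250.0, 30000, rng=np.random.default_rng(4)
        )
        f = extract_features(seq)
        recon = f.occurrence_hz * f.duration_ms / 1000.0
        np.testing.assert_allclose(recon, f.coverage_frac, rtol=0.02)
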
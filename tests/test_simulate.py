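import numpy as np
import pytest

import qeeg
from qeeg.errors import ValidationError
from qeeg.simulate import (
    BandSpec,
    DEFAULT_BAND_FRACTIONS,
    _spectral_envelope,
    compensated_band_weights,
    expected_measured_fractions,
    synth_cohort,
    synth_signal,
)
from qeeg.spectral import band_rpsd, welch_psd


class TestBandSpec:
    def test_canonical_edges_enforced(self):
        BandSpec("alpha", 8.0, 13.0)
        with pytest.raises(ValidationError):
            BandSpec("alpha", 8.0, 12.0)
        with pytest.raises(ValidationError):
            BandSpec("gamma", 30.0, 45.0)


class TestSynthSignal:
    def test_fraction_validation(self):
        with pytest.raises(ValidationError):
            synth_signal((0.5, 0.5, 0.5, 0.5), 0.5, 8.0, 1000.0, seed=0)
        with pytest.raises(ValidationError):
            synth_signal((1.0, 0.0, 0.0, 0.0), 1.5, 8.0, 1000.0, seed=0)
        with pytest.raises(ValidationError):
            synth_signal((1.0, 0.0, 0.0, 0.0), 0.5, 2.0, 1000.0, seed=0)
        with pytest.raises(ValidationError):
            synth_signal((1.0, 0.0, 0.0, 0.0), 0.5, 8.0, 50.0, seed=0)

    def test_unit_variance_and_length(self):
        x = synth_signal((0.25, 0.25, 0.25, 0.25), 0.5, 8.0, 1000.0, seed=3)
        assert x.shape == (8000,)
        assert x.std() == pytest.approx(1.0, abs=1e-12)

    def test_pure_alpha_is_alpha(self):
        x = synth_signal((0.0, 0.0, 1.0, 0.0), 0.0, 8.0, 1000.0, seed=1)
        f, p = welch_psd(x, 1000.0)
        r, _ = band_rpsd(f, p)
        assert r["alpha"] >= 0.99

    def test_equal_fractions_recovered(self):
        acc = np.zeros(4)
        for seed in range(20):
            x = synth_signal((0.25,) * 4, 0.6, 20.0, 1000.0, seed=seed,
                             compensate=False)
            f, p = welch_psd(x, 1000.0)
            r, _ = band_rpsd(f, p)
            acc += [r[b] for b in qeeg.BAND_NAMES]
        acc /= 20
        assert np.max(np.abs(acc - 0.25)) < 0.02

    def test_reported_t0_profile_recovered(self):
        """Baseline affected-hemisphere profile round-trips through Welch."""
        target = np.array([46.3, 25.1, 18.2, 11.3])
        fr = target / target.sum()
        acc = np.zeros(4)
        for seed in range(20):
            x = synth_signal(fr, 0.2, 20.0, 1000.0, seed=seed)
            f, p = welch_psd(x, 1000.0)
            r, _ = band_rpsd(f, p)
            acc += [r[b] for b in qeeg.BAND_NAMES]
        acc = 100 * acc / 20
        assert np.max(np.abs(acc - target)) < 2.0

    def test_determinism(self):
        a = synth_signal((0.4, 0.3, 0.2, 0.1), 0.5, 8.0, 1000.0, seed=9)
        b = synth_signal((0.4, 0.3, 0.2, 0.1), 0.5, 8.0, 1000.0, seed=9)
        np.testing.assert_array_equal(a, b)


class TestEnvelopeAndCompensation:
    def test_envelope_integrates_to_fractions(self):
        fracs = np.array([0.46, 0.25, 0.18, 0.11])
        node_f, node_d = _spectral_envelope(fracs)
        fine = np.linspace(1.0, 30.0, 29_001)
        dens = np.interp(fine, node_f, node_d)
        for (lo, hi), f_b in zip(qeeg.BANDS.values(), fracs):
            mask = (fine >= lo) & (fine <= hi)
            integral = np.trapezoid(dens[mask], fine[mask])
            assert integral == pytest.approx(f_b, rel=1e-3)
        assert np.all(node_d >= 0)

    def test_compensated_weights_fix_expected_fractions(self):
        target = np.array([0.459, 0.249, 0.180, 0.112])
        naive = expected_measured_fractions(target, 0.3)
        g = compensated_band_weights(target, 0.3)
        fixed = expected_measured_fractions(g, 0.3)
        assert np.max(np.abs(fixed - target)) < 1e-3
        assert np.max(np.abs(fixed - target)) < np.max(np.abs(naive - target))


class TestCohortSpecValidation:
    def test_fraction_sum_enforced(self):
        bad = dict(DEFAULT_BAND_FRACTIONS)
        bad[("experimental", "T0", "affected")] = (0.5, 0.3, 0.3, 0.1)
        with pytest.raises(ValidationError):
            qeeg.CohortSpec(band_fractions=bad)

    def test_counts_and_complexity_bounds(self):
        with pytest.raises(ValidationError):
            qeeg.CohortSpec(n_per_group=1)
        with pytest.raises(ValidationError):
            qeeg.CohortSpec(complexity_level={
                (g, s): 1.5 for g in ("experimental", "control")
                for s in ("T0", "T1")})


class TestSynthCohort:
    def test_counts(self, small_cohort):
        assert len(small_cohort.subjects) == 6
        assert len(small_cohort.recordings) == 12
        groups = [s.group for s in small_cohort.subjects]
        assert groups.count("experimental") == 3
        assert groups.count("control") == 3

    def test_determinism_bit_identical(self):
        spec = qeeg.CohortSpec(n_per_group=2, seed=5)
        a, b = synth_cohort(spec), synth_cohort(spec)
        for ra, rb in zip(a.recordings, b.recordings):
            np.testing.assert_array_equal(ra.data, rb.data)
        assert [s.nihss_t1 for s in a.subjects] == \
               [s.nihss_t1 for s in b.subjects]

    def test_extending_cohort_preserves_existing_subjects(self):
        small = synth_cohort(qeeg.CohortSpec(n_per_group=2, seed=5))
        # larger cohort: the control block starts at a different index, so
        # compare the experimental subjects, whose indices are shared
        big = synth_cohort(qeeg.CohortSpec(n_per_group=3, seed=5))
        np.testing.assert_array_equal(
            small.recording("s001", "T0").data,
            big.recording("s001", "T0").data)

    def test_affected_side_matches_infarct(self, small_cohort):
        truth = small_cohort.true_features
        for subj in small_cohort.subjects:
            rows = truth[(truth.subject_id == subj.subject_id)]
            assert set(rows.infarct_side) == {subj.infarct_side}

    def test_nihss_within_bounds(self):
        cohort = synth_cohort(qeeg.CohortSpec(n_per_group=20, seed=2))
        for s in cohort.subjects:
            assert 5 <= s.nihss_t0 <= 20
            assert s.nihss_t1 >= 0

    def test_artifact_injection_trips_epoch_rejection(self):
        spec = qeeg.CohortSpec(n_per_group=2, seed=3, artifact_rate=4.0,
                               artifact_amp_uv=800.0)
        cohort = synth_cohort(spec)
        ptp = [np.ptp(r.data, axis=1).max() for r in cohort.recordings]
        assert max(ptp) > 500.0  # spikes present and large

    def test_target_correlation_in_fisher_interval(self):
        """Designed feature <-> dNIHSS link lands near r = 0.632 (n = 40)."""
        cohort = synth_cohort(qeeg.CohortSpec(n_per_group=40, seed=13))
        truth = cohort.true_features
        t1 = truth[truth.session == "T1"].set_index("subject_id")
        feats, deltas = [], []
        for s in cohort.subjects:
            if s.group != "experimental":
                continue
            row = t1.loc[s.subject_id]
            feats.append(row.true_alpha / row.true_beta)
            deltas.append(s.delta_nihss)
        r = np.corrcoef(feats, deltas)[0, 1]
        # 99% Fisher interval around 0.632 at n=40: (0.311, 0.824)
        assert 0.40 <= r <= 0.80
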
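import itertools

import numpy as np
import pytest

import qeeg
from qeeg.errors import (
    DegenerateSignalWarning,
    MissingChannelError,
    ValidationError,
)
from qeeg.nonlinear import (
    ApEnConfig,
    LZCConfig,
    apen,
    binarize,
    hemisphere_features,
    lz76_complexity,
    lz76_normalized,
    lzc,
)

from _oracles import apen_oracle, lz76_oracle


class TestBinarize:
    def test_median_threshold(self):
        np.testing.assert_array_equal(binarize([1, 3, 2, 5]), [0, 1, 0, 1])

    def test_mean_threshold(self):
        np.testing.assert_array_equal(
            binarize([0, 0, 0, 10], method="mean"), [0, 0, 0, 1])

    def test_constant_is_all_zeros_with_warning(self):
        with pytest.warns(DegenerateSignalWarning):
            out = binarize([7.0, 7.0, 7.0, 7.0])
        np.testing.assert_array_equal(out, [0, 0, 0, 0])

    def test_length_preserved(self, rng):
        x = rng.standard_normal(501)
        assert binarize(x).size == 501


class TestLZ76:
    def test_definitional_values(self):
        assert lz76_complexity([0]) == 1
        assert lz76_complexity([1]) == 1
        for n in (2, 5, 50):
            assert lz76_complexity([0] * n) == 2
        # value frozen from the brute-force oracle
        seq = [0, 0, 0, 1, 1, 0, 1, 0, 0, 1, 0, 0, 0, 1, 0, 1]
        assert lz76_oracle(seq) == 6
        assert lz76_complexity(seq) == 6

    def test_exhaustive_oracle_equivalence_short(self):
        for n in range(1, 11):
            for bits in itertools.product((0, 1), repeat=n):
                assert lz76_complexity(bits) == lz76_oracle(bits), bits

    def test_non_binary_rejected(self):
        with pytest.raises(ValidationError):
            lz76_complexity([0, 1, 2])

    def test_fair_coin_normalization(self, rng):
        seq = rng.integers(0, 2, 20_000)
        assert 0.85 <= lz76_normalized(seq) <= 1.15

    def test_periodic_sequence_near_zero(self):
        seq = np.tile([0, 1], 10_000)
        assert lz76_normalized(seq) < 0.05

    def test_monotone_transform_invariance(self, rng):
        x = rng.standard_normal(2000)
        cfg = LZCConfig(analysis_fs=None)
        assert lzc(x, cfg) == lzc(np.exp(x), cfg) == lzc(x ** 3, cfg)


class TestApEn:
    def test_constant_series_is_zero_with_warning(self):
        with pytest.warns(DegenerateSignalWarning):
            assert apen(np.ones(100), ApEnConfig(analysis_fs=None)) == 0.0

    def test_alternating_series_is_regular(self):
        x = np.tile([1.0, -1.0], 500)
        assert apen(x, ApEnConfig(analysis_fs=None)) <= 0.01

    def test_oracle_equivalence_and_ordering(self, rng):
        cfg = ApEnConfig(analysis_fs=None)
        worst = 0.0
        vals = []
        for _ in range(50):
            x = rng.standard_normal(100)
            a = apen(x, cfg)
            worst = max(worst, abs(a - apen_oracle(x)))
            vals.append(a)
        assert worst <= 1e-10
        # white noise is far less regular than the alternating series
        assert min(vals) > apen(np.tile([1.0, -1.0], 500), cfg)

    def test_oracle_equivalence_large_n(self, rng):
        x = rng.standard_normal(4000)
        cfg = ApEnConfig(analysis_fs=None)
        assert abs(apen(x, cfg) - apen_oracle(x)) <= 1e-10

    def test_scale_invariance(self, rng):
        x = rng.standard_normal(500)
        cfg = ApEnConfig(analysis_fs=None)
        assert apen(7.7 * x, cfg) == pytest.approx(apen(x, cfg), rel=1e-12)

    def test_too_short_rejected(self):
        with pytest.raises(ValidationError):
            apen(np.arange(3.0), ApEnConfig(m=2, analysis_fs=None))


class TestComplexityOrdering:
    def test_periodic_narrowband_broadband(self, rng):
        """Both measures order periodic < narrowband < broadband."""
        fs = 1000.0
        t = np.arange(4000) / fs
        periodic = np.sin(2 * np.pi * 10 * t)
        spec = np.fft.rfft(rng.standard_normal(4000))
        freqs = np.fft.rfftfreq(4000, 1 / fs)
        narrow = np.fft.irfft(
            np.where((freqs >= 9) & (freqs < 11), spec, 0), 4000)
        spec2 = np.fft.rfft(rng.standard_normal(4000))
        broad = np.fft.irfft(
            np.where((freqs >= 1) & (freqs < 30), spec2, 0), 4000)
        lcfg, acfg = LZCConfig(analysis_fs=200.0), ApEnConfig(analysis_fs=200.0)
        l_vals = [lzc(x, lcfg, fs=fs) for x in (periodic, narrow, broad)]
        a_vals = [apen(x, acfg, fs=fs) for x in (periodic, narrow, broad)]
        assert l_vals[0] < l_vals[1] < l_vals[2]
        assert a_vals[0] < a_vals[1] < a_vals[2]

    def test_complexity_level_monotone_on_grid(self):
        """Generator knob: higher complexity_level never lowers LZC/ApEn."""
        fracs = (0.45, 0.25, 0.19, 0.11)
        lcfg, acfg = LZCConfig(), ApEnConfig()
        l_means, a_means = [], []
        for cl in (0.0, 0.5, 1.0):
            ls, as_ = [], []
            for seed in range(5):
                x = qeeg.synth_signal(fracs, cl, 8.0, 1000.0, seed=seed)
                ls.append(lzc(x, lcfg, fs=1000.0))
                as_.append(apen(x, acfg, fs=1000.0))
            l_means.append(np.mean(ls))
            a_means.append(np.mean(as_))
        assert l_means[0] < l_means[1] < l_means[2]
        assert a_means[0] < a_means[1] < a_means[2]


class TestHemisphereFeatures:
    def _features(self, values):
        import pandas as pd
        rows = []
        for ch, v in values.items():
            rows.append({"subject_id": "s01", "session": "T1",
                         "channel": ch, "lzc": v})
        return pd.DataFrame(rows)

    def test_left_infarct_selects_odd_electrodes(self):
        subj = qeeg.SubjectRecord("s01", "experimental", "left", 60, "F",
                                  13, 6)
        assert subj.affected_channels() == ("C3", "P3", "O1")
        feats = self._features({c: 0.5 for c in qeeg.REQUIRED_CHANNELS})
        hemi = hemisphere_features(feats, [subj])
        assert hemi.loc[0, "lzc"] == pytest.approx(0.5)

    def test_mean_across_regions(self):
        subj = qeeg.SubjectRecord("s01", "control", "right", 60, "M", 10, 8)
        vals = {"C3": 9.9, "P3": 9.9, "O1": 9.9,
                "C4": 0.3, "P4": 0.5, "O2": 0.7}
        hemi = hemisphere_features(self._features(vals), [subj])
        assert hemi.loc[0, "lzc"] == pytest.approx(0.5)  # right-side mean
        assert hemi.loc[0, "delta_nihss"] == 2

    def test_missing_electrode_named(self):
        subj = qeeg.SubjectRecord("s01", "control", "left", 60, "M", 10, 8)
        feats = self._features({"C3": 0.5, "P3": 0.5})  # O1 absent
        with pytest.raises(MissingChannelError, match="O1"):
            hemisphere_features(feats, [subj])
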
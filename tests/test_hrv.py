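import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from toipulse import hrv
from toipulse.pulse import PeakTrain


class TestRriFromPeaks:
    def test_uniform_peaks(self):
        rri = hrv.rri_from_peaks(PeakTrain(peak_times_s=[0.0, 1.0, 2.0]))
        np.testing.assert_allclose(rri.rri_ms, [1000.0, 1000.0])

    def test_irregular_peaks(self):
        rri = hrv.rri_from_peaks(PeakTrain(peak_times_s=[0.0, 0.8, 1.7]))
        np.testing.assert_allclose(rri.rri_ms, [800.0, 900.0])

    def test_single_peak_rejected(self):
        with pytest.raises(ValueError):
            hrv.rri_from_peaks(PeakTrain(peak_times_s=[1.0]))

    def test_implausible_intervals_flagged_not_raised(self):
        rri = hrv.RRISeries(rri_ms=np.array([100.0, 1000.0, 1000.0]))
        assert "implausible_rri" in rri.flags


class TestHeartRate:
    @pytest.mark.parametrize("rri_ms, bpm", [
        ([1000.0] * 5, 60.0),
        ([833.333] * 4, 72.0000288),
        ([800.0, 900.0], 60000.0 / 850.0),  # 70.588...
    ])
    def test_formula(self, rri_ms, bpm):
        assert hrv.heart_rate(np.asarray(rri_ms)) == pytest.approx(bpm, rel=1e-6)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            hrv.heart_rate(np.array([]))


class TestPoincare:
    def test_constant_series_degenerate(self):
        s = hrv.poincare(np.full(10, 1000.0))
        assert s.sd1_ms == 0.0 and s.sd2_ms == 0.0
        assert s.sd_ratio is None
        assert "sd_ratio_undefined" in s.flags

    def test_alternating_series_hand_case(self):
        # successive-difference SD carries everything; identity-line SD is 0
        s = hrv.poincare(np.array([1000.0, 900.0, 1000.0, 900.0]))
        assert s.sd1_ms == pytest.approx(81.65, abs=0.005)
        assert s.sd2_ms == 0.0
        assert s.sd_ratio is None

    def test_mixed_series_hand_case(self):
        s = hrv.poincare(np.array([1000.0, 950.0, 1000.0, 1050.0, 1000.0]))
        assert s.sd1_ms == pytest.approx(40.82, abs=0.005)
        assert s.sd2_ms == pytest.approx(28.87, abs=0.005)
        assert s.sd_ratio == pytest.approx(1.414, abs=0.0005)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            hrv.poincare(np.array([1000.0, 900.0]))

    def test_sd1_matches_projection_oracle_exactly(self, rng):
        for _ in range(100):
            v = rng.normal(1000.0, 50.0, size=rng.integers(5, 60))
            sd1_oracle, _ = hrv.poincare_projection_oracle(v)
            s = hrv.poincare(v)
            assert s.sd1_ms == pytest.approx(sd1_oracle, rel=1e-9)

    def test_sd2_formula_converges_to_projection_oracle(self, rng):
        # full-series formula and lag-cloud oracle agree to O(1/n)
        for _ in range(20):
            v = rng.normal(1000.0, 60.0, size=3000)
            _, sd2_oracle = hrv.poincare_projection_oracle(v)
            s = hrv.poincare(v)
            assert s.sd2_ms == pytest.approx(sd2_oracle, rel=0.02)

    def test_sd2_exact_geometric_identity(self, rng):
        # with the lag cloud's marginal variances the rotation identity is exact
        for _ in range(100):
            v = rng.normal(1000.0, 50.0, size=rng.integers(5, 60))
            x, y = v[:-1], v[1:]
            d = x - y
            marginal = 0.5 * (x.var(ddof=1) + y.var(ddof=1))
            sd2_sq = 2.0 * marginal - 0.5 * d.var(ddof=1)
            _, sd2_oracle = hrv.poincare_projection_oracle(v)
            assert np.sqrt(max(sd2_sq, 0.0)) == pytest.approx(sd2_oracle,
                                                              rel=1e-9)

    @settings(derandomize=True, max_examples=30)
    @given(scale=st.floats(0.1, 10.0), seed=st.integers(0, 500))
    def test_homogeneity(self, scale, seed):
        v = np.random.default_rng(seed).normal(1000.0, 40.0, size=30)
        s1, s2 = hrv.poincare(v), hrv.poincare(scale * v)
        assert s2.sd1_ms == pytest.approx(scale * s1.sd1_ms, rel=1e-9)
        assert s2.sd2_ms == pytest.approx(scale * s1.sd2_ms, rel=1e-9)
        if s1.sd_ratio is not None:
            assert s2.sd_ratio == pytest.approx(s1.sd_ratio, rel=1e-9)

    @settings(derandomize=True, max_examples=30)
    @given(shift=st.floats(-200.0, 500.0), seed=st.integers(0, 500))
    def test_translation_invariance(self, shift, seed):
        v = np.random.default_rng(seed).normal(1000.0, 40.0, size=30)
        s1, s2 = hrv.poincare(v), hrv.poincare(v + shift)
        assert s2.sd1_ms == pytest.approx(s1.sd1_ms, rel=1e-7)
        assert s2.sd2_ms == pytest.approx(s1.sd2_ms, rel=1e-6)

    def test_nonnegative(self, rng):
        for _ in range(50):
            v = rng.normal(900.0, 80.0, size=rng.integers(3, 40))
            s = hrv.poincare(v)
            assert s.sd1_ms >= 0.0 and s.sd2_ms >= 0.0


class TestTachogramCorrelation:
    def test_identical_series_correlate_perfectly(self, rng):
        t = np.cumsum(rng.uniform(0.8, 1.2, size=50))
        rri = hrv.RRISeries(rri_ms=1000.0 * np.diff(t), t_s=t[1:])
        assert hrv.tachogram_correlation(rri, rri) == pytest.approx(1.0)

    def test_requires_times(self):
        a = hrv.RRISeries(rri_ms=np.array([900.0, 1000.0, 950.0]))
        with pytest.raises(ValueError):
            hrv.tachogram_correlation(a, a)
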
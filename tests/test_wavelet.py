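import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import rsndyn as r
from rsndyn.wavelet import (
    PERIOD_BANDS,
    PHASE_PREFIX,
    PhaseClass,
    classify_phase,
    surrogate_threshold,
    time_of_coherence,
)


class TestMorletCwt:
    def test_power_ridge_at_planted_period(self):
        dt, T = 2.0, 512
        t = np.arange(T) * dt
        x = np.cos(2 * np.pi * t / 20.0)
        W, periods, coi = r.morlet_cwt(x, dt)
        ridge = periods[np.argmax((np.abs(W) ** 2).mean(axis=1))]
        step = periods[1] / periods[0]
        assert 20.0 / step <= ridge <= 20.0 * step

    def test_zero_signal_zero_coefficients(self):
        W, _, _ = r.morlet_cwt(np.zeros(128), 2.0)
        assert np.allclose(W, 0.0)

    def test_linearity_in_amplitude(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=128)
        W1, _, _ = r.morlet_cwt(x, 2.0)
        W2, _, _ = r.morlet_cwt(2 * x, 2.0)
        assert np.allclose(W2, 2 * W1, atol=1e-12)

    def test_short_record_truncates_with_warning(self):
        rng = np.random.default_rng(1)
        with pytest.warns(UserWarning, match="truncating"):
            _, periods, _ = r.morlet_cwt(rng.normal(size=100), 2.0, max_period=128.0)
        assert periods[-1] <= 100.0  # 100 samples * 2 s / 2

    def test_record_too_short_rejected(self):
        with pytest.raises(ValueError, match="too short"):
            r.morlet_cwt(np.zeros(32), 2.0)


class TestCoherencePair:
    def test_self_coherence_near_one_inside_coi(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=208)
        scal = r.coherence_pair(x, x, 2.0)
        assert scal.coherence[scal.coi_mask].min() >= 0.99

    def test_quarter_period_delay_gives_lead_phase(self):
        dt, T = 1.0, 512
        t = np.arange(T) * dt
        x = np.cos(2 * np.pi * t / 20.0)
        y = np.cos(2 * np.pi * (t - 5.0) / 20.0)  # y delayed: signal 1 leads
        scal = r.coherence_pair(x, y, dt, max_period=64.0)
        k = np.argmin(np.abs(scal.periods - 20.0))
        ridge_phase = scal.phase[k, scal.coi_mask[k]]
        assert np.allclose(ridge_phase, np.pi / 2, atol=0.1)
        assert classify_phase(float(np.median(ridge_phase))) is PhaseClass.LEADING

    def test_null_coherence_moderate(self):
        rng = np.random.default_rng(3)
        scal = r.coherence_pair(rng.normal(size=2000), rng.normal(size=2000), 1.0)
        assert scal.coherence[scal.coi_mask].mean() < 0.5

    def test_phase_antisymmetric_under_swap(self):
        """LEADING for (A,B) equals LAGGING for (B,A) on the same data."""
        rng = np.random.default_rng(4)
        x, y = rng.normal(size=208), rng.normal(size=208)
        ab = r.coherence_pair(x, y, 2.0)
        ba = r.coherence_pair(y, x, 2.0)
        assert np.allclose(ab.phase, -ba.phase, atol=1e-10)
        assert np.allclose(ab.coherence, ba.coherence, atol=1e-12)

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError, match="equal length"):
            r.coherence_pair(np.zeros(128), np.zeros(129), 2.0)


class TestPhaseClassification:
    @pytest.mark.parametrize(
        "theta,expected",
        [
            (0.0, PhaseClass.IN_PHASE),
            (np.pi, PhaseClass.ANTI_PHASE),
            (np.pi / 2, PhaseClass.LEADING),
            (-np.pi / 2, PhaseClass.LAGGING),
            (np.pi / 4, PhaseClass.LEADING),  # lower boundary closed
            (-np.pi / 4, PhaseClass.IN_PHASE),
            (3 * np.pi / 4, PhaseClass.ANTI_PHASE),
            (-3 * np.pi / 4, PhaseClass.LAGGING),
        ],
    )
    def test_quadrants_and_boundaries(self, theta, expected):
        assert classify_phase(theta) is expected

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            classify_phase(4.0)

    @settings(derandomize=True, max_examples=200, deadline=None)
    @given(theta=st.floats(min_value=-np.pi + 1e-9, max_value=np.pi))
    def test_partition_completeness(self, theta):
        """Every angle in (-pi, pi] maps to exactly one of the four classes."""
        assert classify_phase(theta) in PHASE_PREFIX


class TestSignificance:
    def test_identical_inputs_almost_fully_significant(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=208)
        scal = r.coherence_pair(x, x, 2.0)
        mask = r.significance_mask(x, x, scal, n_surrogates=60, seed=0)
        assert mask[scal.coi_mask].mean() >= 0.99

    def test_seed_determinism(self):
        rng = np.random.default_rng(6)
        x, y = rng.normal(size=208), rng.normal(size=208)
        scal = r.coherence_pair(x, y, 2.0)
        m1 = r.significance_mask(x, y, scal, n_surrogates=60, seed=3).copy()
        m2 = r.significance_mask(x, y, scal, n_surrogates=60, seed=3)
        assert np.array_equal(m1, m2)

    def test_too_few_surrogates_rejected(self):
        with pytest.raises(ValueError, match="50"):
            surrogate_threshold(0.3, 0.3, 208, 2.0, n_surrogates=10)


class TestTimeOfCoherence:
    def test_all_false_mask_gives_zero(self):
        rng = np.random.default_rng(7)
        scal = r.coherence_pair(rng.normal(size=208), rng.normal(size=208), 2.0)
        scal.sig_mask = np.zeros_like(scal.coi_mask)
        assert time_of_coherence(scal).to_numpy().sum() == 0.0

    def test_requires_significance_mask(self):
        rng = np.random.default_rng(8)
        scal = r.coherence_pair(rng.normal(size=208), rng.normal(size=208), 2.0)
        with pytest.raises(ValueError, match="significance"):
            time_of_coherence(scal)

    def test_planted_window_recovered(self):
        """50% planted 20 s in-phase oscillation -> ~50% in band [16,32)."""
        ts = r.gen_phase_locked_pair(20.0, 0.5, 0.0, T=416, dt=2.0, noise_sd=0.5, seed=3)
        x, y = ts.values[:, 0], ts.values[:, 1]
        scal = r.coherence_pair(x, y, 2.0)
        thr = surrogate_threshold(0.3, 0.3, 416, 2.0, n_surrogates=100, seed=0)
        r.significance_mask(x, y, scal, threshold=thr)
        toc = time_of_coherence(scal)
        assert toc.loc["s3", "ip"] == pytest.approx(50.0, abs=10.0)

    def test_phase_split_sums_to_total(self):
        """Per band, the four phase classes partition the significant time."""
        ts = r.gen_phase_locked_pair(20.0, 0.7, 0.4, T=208, dt=2.0, noise_sd=0.8, seed=5)
        x, y = ts.values[:, 0], ts.values[:, 1]
        scal = r.coherence_pair(x, y, 2.0)
        thr = surrogate_threshold(0.3, 0.3, 208, 2.0, n_surrogates=60, seed=1)
        r.significance_mask(x, y, scal, threshold=thr)
        toc = time_of_coherence(scal)
        usable = scal.sig_mask & scal.coi_mask
        T = len(scal.times)
        for k, (lo, hi) in enumerate(PERIOD_BANDS):
            in_band = (scal.periods >= lo) & (
                (scal.periods <= hi * (1 + 1e-9)) if k == len(PERIOD_BANDS) - 1 else (scal.periods < hi)
            )
            total = 100.0 * usable[in_band].any(axis=0).sum() / T
            assert toc.iloc[k].sum() == pytest.approx(total, abs=1e-9)


class TestWcohFeatures:
    def test_n2_count_and_grammar(self):
        ts = r.gen_phase_locked_pair(20.0, 0.5, 0.0, T=208, dt=2.0, noise_sd=0.5, seed=0,
                                     network_labels=("MVISU", "DMN"))
        feats = r.wcoh_features(ts, n_surrogates=60, seed=0)
        assert len(feats) == 20
        assert "ip_MVISU-DMN_s2" in feats.index
        assert all(f.split("_")[0] in ("ip", "ap", "lead", "lag") for f in feats.index)

    def test_feature_count_formula(self):
        # N=4 -> 4 phases * 5 bands * 6 pairs = 120
        ts = r.gen_var_session(np.eye(4) * 0.3, 208, seed=1)
        cache = r.ThresholdCache(208, 2.0, n_surrogates=60, seed=0, max_period=128.0)
        feats = r.wcoh_features(ts, cache=cache)
        assert len(feats) == 120
        assert np.all((feats.values >= 0) & (feats.values <= 100))
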
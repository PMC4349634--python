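import numpy as np
import pytest

from spikesta.corrmodel import MexicanHat
from spikesta.sta import (
    baseline_correct,
    confidence_band,
    eeg_sta,
    extract_segments,
    grouped_covariation,
    induced_rms,
    peak_bootstrap_test,
    peak_to_peak,
    shift_predictor,
    shuffle_spikes,
)

FS = 10000.0


def _session_with_kernel(rng, n_trials=40, n_samp=1200, spikes_per_trial=4, amp=5.0, noise=1.0):
    """EEG = iid noise + a short kernel at each spike (on-grid latencies)."""
    kernel = amp * np.array([0.0, -0.5, 1.0, -0.5, 0.0])
    eeg = rng.standard_normal((n_trials, n_samp)) * noise
    spikes = []
    for i in range(n_trials):
        # continuous latencies (no common grid across trials, so nothing is
        # stimulus-locked), kept at least 6 ms apart
        while True:
            centers = np.sort(rng.integers(100, n_samp - 100, spikes_per_trial))
            if spikes_per_trial < 2 or np.all(np.diff(centers) >= 60):
                break
        for c in centers:
            eeg[i, c - 2 : c + 3] += kernel
        spikes.append(centers / FS * 1000.0)
    return eeg, spikes, kernel


def test_segment_grid_has_61_inclusive_samples():
    eeg = np.zeros((2, 500))
    segs, lags = extract_segments(eeg, FS, [[25.0], [30.0]], 3.0)
    assert segs.shape == (2, 61)
    assert lags[0] == -3.0 and lags[-1] == 3.0 and lags[30] == 0.0


def test_spike_too_close_to_trial_edge_dropped():
    eeg = np.zeros((1, 100))  # 10 ms trial
    segs, _ = extract_segments(eeg, FS, [[9.0]], 3.0)  # 1 ms from the end
    assert segs.shape[0] == 0


def test_noiseless_segments_equal_embedded_kernel(rng):
    eeg, spikes, kernel = _session_with_kernel(rng, noise=0.0)
    segs, lags = extract_segments(eeg, FS, spikes, 3.0)
    center = segs.shape[1] // 2
    assert np.allclose(segs[:, center - 2 : center + 3], kernel)
    assert np.allclose(segs[:, : center - 2], 0.0)


def test_sta_mean_and_sem():
    seg = np.tile(np.arange(5.0), (10, 1))
    res = eeg_sta(seg, np.arange(5.0))
    assert np.allclose(res.mean, np.arange(5.0))
    assert np.allclose(res.sem, 0.0)
    a = np.ones((2, 5))
    a[1] *= -1
    assert np.allclose(eeg_sta(a, np.arange(5.0)).mean, 0.0)
    with pytest.raises(ValueError):
        eeg_sta(np.empty((0, 5)), np.arange(5.0))


def test_sta_sem_matches_sampling_theory(rng):
    sigma, n = 2.0, 500
    seg = rng.standard_normal((n, 61)) * sigma
    res = eeg_sta(seg, np.linspace(-3, 3, 61))
    assert np.all(np.abs(res.sem / (sigma / np.sqrt(n)) - 1.0) < 0.2)


def test_sta_linear_in_eeg(rng):
    eeg1 = rng.standard_normal((6, 400))
    eeg2 = rng.standard_normal((6, 400))
    spikes = [[10.0, 25.0]] * 6
    s1, lags = extract_segments(eeg1, FS, spikes, 3.0)
    s2, _ = extract_segments(eeg2, FS, spikes, 3.0)
    s12, _ = extract_segments(2 * eeg1 - 3 * eeg2, FS, spikes, 3.0)
    assert np.allclose(
        eeg_sta(s12, lags).mean, 2 * eeg_sta(s1, lags).mean - 3 * eeg_sta(s2, lags).mean
    )


def test_shuffle_assigns_different_trials(rng):
    spikes = [[5.0, 10.0], [7.0], [3.0, 8.0, 12.0]]
    shuffled = shuffle_spikes(spikes, rng)
    assert sum(len(s) for s in shuffled) == 6
    pooled_orig = sorted(t for tr in spikes for t in tr)
    pooled_new = sorted(t for tr in shuffled for t in tr)
    assert pooled_new == pooled_orig  # latencies conserved


def test_predictor_equals_sta_when_eeg_identical_across_trials(rng):
    row = rng.standard_normal(800)
    eeg = np.tile(row, (10, 1))
    spikes = [[12.0, 40.0]] * 10
    segs, lags = extract_segments(eeg, FS, spikes, 3.0)
    sta = eeg_sta(segs, lags)
    pred = shift_predictor(eeg, FS, spikes, 3.0, n_shuffles=5, rng=rng)
    assert np.allclose(pred.mean, sta.mean)


def test_predictor_recovers_evoked_component(rng):
    # latency-locked spikes + a purely evoked (trial-invariant) EEG component:
    # the predictor equals the STA of the evoked waveform exactly
    t = np.arange(900) / FS * 1000.0
    evoked = 50.0 * np.sin(2 * np.pi * 600.0 * t / 1000.0) * np.exp(-((t - 40.0) ** 2) / 50.0)
    eeg = np.tile(evoked, (12, 1))
    spikes = [[40.0]] * 12
    segs, lags = extract_segments(eeg, FS, spikes, 3.0)
    pred = shift_predictor(eeg, FS, spikes, 3.0, n_shuffles=10, rng=rng)
    assert np.allclose(pred.mean, segs.mean(axis=0))
    corrected = baseline_correct(eeg_sta(segs, lags), pred)
    assert np.allclose(corrected.mean, 0.0, atol=1e-9)


def test_shuffling_abolishes_spike_locked_kernel(rng):
    eeg, spikes, _ = _session_with_kernel(rng, n_trials=60, amp=5.0, noise=1.0)
    segs, lags = extract_segments(eeg, FS, spikes, 3.0)
    sta = eeg_sta(segs, lags)
    pred = shift_predictor(eeg, FS, spikes, 3.0, n_shuffles=50, rng=rng)
    assert peak_to_peak(pred) < 0.3 * peak_to_peak(sta)


def test_baseline_correction_additivity(rng):
    eeg, spikes, _ = _session_with_kernel(rng)
    segs, lags = extract_segments(eeg, FS, spikes, 3.0)
    sta = eeg_sta(segs, lags)
    pred = shift_predictor(eeg, FS, spikes, 3.0, n_shuffles=10, rng=rng)
    corrected = baseline_correct(sta, pred)
    assert corrected.baseline_corrected
    assert np.allclose(corrected.mean + pred.mean, sta.mean)
    self_corr = baseline_correct(sta, sta)
    assert np.allclose(self_corr.mean, 0.0)
    bad = eeg_sta(segs[:, :-2], lags[:-2])
    with pytest.raises(ValueError):
        baseline_correct(sta, bad)


def test_confidence_band_width():
    seg = np.vstack([np.ones(5), -np.ones(5)] * 50)  # per-lag SD exactly 1 (ddof≈)
    lo, hi = confidence_band(seg, level_multiplier=2.58, n_effective=1)
    sd = seg.std(axis=0, ddof=1)
    assert np.allclose(hi - lo, 2 * 2.58 * sd)
    zlo, zhi = confidence_band(np.zeros((10, 5)))
    assert np.allclose(zhi - zlo, 0.0)


def test_confidence_band_scales_inverse_sqrt_n(rng):
    seg = rng.standard_normal((4000, 7))
    lo1, hi1 = confidence_band(seg[:1000])
    lo4, hi4 = confidence_band(seg)
    ratio = np.mean((hi4 - lo4) / (hi1 - lo1))
    assert abs(ratio - 0.5) < 0.05


def test_peak_to_peak_basic_and_mexhat(mexhat_60):
    assert peak_to_peak(np.full(10, 3.0)) == 0.0
    assert peak_to_peak(np.linspace(-2.0, 5.0, 50)) == 7.0
    t = np.linspace(-3, 3, 6001)
    analytic = 60.0 * (1 + 2 * np.exp(-1.5))
    assert abs(peak_to_peak(mexhat_60(t)) - analytic) < 1e-3 * analytic
    assert abs(analytic - 86.7756) < 1e-3


def test_peak_window_validation(rng):
    seg = rng.standard_normal((20, 61))
    lags = np.linspace(-3, 3, 61)
    with pytest.raises(ValueError):
        peak_bootstrap_test(seg, seg, lags, peak_window=(-5.0, 0.5), rng=rng)
    with pytest.raises(ValueError):
        peak_to_peak(seg.mean(0), lags, window=(-5.0, 0.5))


def test_peak_bootstrap_detects_embedded_kernel(rng):
    lags = np.linspace(-3, 3, 61)
    kernel = np.zeros(61)
    kernel[29:32] = [-0.4, 1.0, -0.4]  # peak inside [-0.3, 0.5] ms
    unshuf = kernel + rng.standard_normal((5000, 61))
    shuf = rng.standard_normal((5000, 61))
    p = peak_bootstrap_test(unshuf, shuf, lags, n_boot=2000, rng=np.random.default_rng(0))
    assert p < 0.01


def test_peak_bootstrap_deterministic(rng):
    seg = rng.standard_normal((200, 61))
    shuf = rng.standard_normal((400, 61))
    lags = np.linspace(-3, 3, 61)
    p1 = peak_bootstrap_test(seg, shuf, lags, n_boot=500, rng=np.random.default_rng(42))
    p2 = peak_bootstrap_test(seg, shuf, lags, n_boot=500, rng=np.random.default_rng(42))
    assert p1 == p2


def test_grouped_covariation_perfect_scaling():
    n, L = 150, 20
    amps = np.linspace(1.0, 10.0, n)
    base = np.zeros(L)
    base[8], base[12] = 1.0, -1.0
    waveforms = amps[:, None] * base[None, :]
    segments = 0.05 * waveforms
    res = grouped_covariation(waveforms, segments, grouping="amplitude", n_groups=15)
    assert res.group_spike_amp.size == 15
    assert res.r == pytest.approx(1.0)
    assert res.p < 1e-10


def test_grouped_covariation_null_level():
    base = np.zeros(20)
    base[8], base[12] = 1.0, -1.0
    hits = 0
    for seed in range(100):
        rng = np.random.default_rng(seed)
        waveforms = rng.uniform(1, 10, 200)[:, None] * base[None, :]
        segments = rng.standard_normal((200, 20))
        res = grouped_covariation(waveforms, segments, grouping="amplitude", n_groups=10)
        hits += res.p > 0.05
    assert hits >= 90


def test_grouped_covariation_validation(rng):
    w = rng.standard_normal((10, 5))
    s = rng.standard_normal((10, 8))
    with pytest.raises(ValueError):
        grouped_covariation(w, s, n_groups=1)
    with pytest.raises(ValueError):
        grouped_covariation(w, s, n_groups=11)


def test_induced_rms():
    assert np.allclose(induced_rms(np.full((5, 10), -3.0)), 3.0)
    assert np.allclose(induced_rms(np.empty((0, 10))), 0.0)
    rng = np.random.default_rng(0)
    x = rng.standard_normal((2000, 50)) * 4.0
    assert np.all(np.abs(induced_rms(x) / 4.0 - 1.0) < 0.05)
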
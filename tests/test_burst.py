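import numpy as np
import pytest

from spikesta.burst import burst_bootstrap_ci, estimate_neuron_count, predict_burst
from spikesta.corrmodel import MexicanHat
from spikesta.filtering import HIGHFREQ, fourier_bandpass, upsample_linear
from spikesta.spectral import multitaper_psd
from spikesta.spikes import compute_psth, prune_min_separation
from spikesta.sta import extract_segments
from spikesta.synthetic import RateProfile, SessionConfig, simulate_session

BIN = 0.1  # ms


def _comb_psth(n_bins=1000, period_ms=1000.0 / 600.0, t0=50):
    psth = np.zeros(n_bins)
    idx = np.round(np.arange(t0, n_bins - 200, period_ms / BIN)).astype(int)
    psth[idx] = 1.0
    return psth


def _sampled_hat(width_ms=2.2, amp=60.0, half=150):
    hat = MexicanHat.from_amplitude_width(amp, width_ms)
    t = np.arange(-half, half + 1) * BIN
    return hat(t)


def test_unit_mass_psth_shifts_kernel():
    sta = _sampled_hat(half=30)
    psth = np.zeros(400)
    psth[200] = 1.0
    pred = predict_burst([psth], [sta], bin_width_ms=BIN, sta_dt_ms=BIN)
    assert np.allclose(pred.mean[200 - 30 : 200 + 31], sta)
    assert np.allclose(pred.mean[:100], 0.0)


def test_identical_cells_average_to_single_cell():
    sta = _sampled_hat(half=30)
    psth = _comb_psth(600)
    single = predict_burst([psth], [sta], BIN, BIN)
    double = predict_burst([psth, psth], [sta, sta], BIN, BIN)
    assert np.allclose(single.mean, double.mean)


def test_prediction_linear_in_psth():
    sta = _sampled_hat(half=30)
    psths = [_comb_psth(600), 0.5 * _comb_psth(600)]
    p1 = predict_burst([psths[0]], [sta], BIN, BIN)
    p2 = predict_burst([2.0 * psths[0]], [sta], BIN, BIN)
    assert np.allclose(p2.mean, 2.0 * p1.mean)


def test_bin_width_mismatch_rejected():
    with pytest.raises(ValueError):
        predict_burst([np.zeros(100)], [np.zeros(11)], bin_width_ms=0.1, sta_dt_ms=0.2)
    with pytest.raises(ValueError):
        predict_burst([np.zeros(100)], [np.zeros(10)], BIN, BIN)  # even-length STA


def test_comb_prediction_spectrum_peaks_at_comb_rate():
    # spikes repeating every 1.667 ms drive a ~600 Hz line; with a kernel whose
    # own spectrum peaks below 600 Hz the fundamental dominates.  A multitaper
    # estimate smears a line into a plateau of the concentration bandwidth, so
    # the peak is only localised to within half the bandwidth.
    psth = _comb_psth(1000)
    sta = _sampled_hat(width_ms=2.2)
    pred = predict_burst([psth], [sta], BIN, BIN)
    est = multitaper_psd(pred.mean, fs=10000.0, bandwidth=600.0)
    f_peak = est.freqs[np.argmax(est.power)]
    assert abs(f_peak - 600.0) <= 300.0
    at = lambda f: est.power[np.argmin(np.abs(est.freqs - f))]
    assert at(600.0) > 10.0 * at(1800.0)  # the fundamental dominates the harmonics


def test_prediction_spectrum_factorizes():
    # linear convolution theorem: |F(pred)|^2 = |F(psth)|^2 |F(sta)|^2
    psth = _comb_psth(800)
    sta = _sampled_hat(width_ms=1.0, half=100)
    full = np.convolve(psth, sta, mode="full")
    n = full.size
    sp_pred = np.abs(np.fft.rfft(full, n)) ** 2
    sp_prod = (
        np.abs(np.fft.rfft(psth, n)) ** 2 * np.abs(np.fft.rfft(sta, n)) ** 2
    )
    mask = sp_prod > 1e-6 * sp_prod.max()  # away from spectral zeros
    rel = np.abs(sp_pred[mask] - sp_prod[mask]) / sp_prod[mask]
    assert rel.max() < 0.01


def test_bootstrap_band_zero_width_without_noise():
    sta_segments = np.tile(_sampled_hat(half=30), (40, 1))  # identical segments
    psth = _comb_psth(400)
    res = burst_bootstrap_ci([(psth, sta_segments)], n_boot=50,
                             rng=np.random.default_rng(0), bin_width_ms=BIN)
    assert np.allclose(res.ci_hi - res.ci_lo, 0.0)
    assert np.allclose(res.mean, predict_burst([psth], [sta_segments.mean(0)], BIN, BIN).mean)


def test_bootstrap_band_contains_point_estimate(rng):
    cells = []
    for _ in range(5):
        segs = _sampled_hat(half=30) + rng.standard_normal((60, 61)) * 5.0
        cells.append((_comb_psth(400), segs))
    res = burst_bootstrap_ci(cells, n_boot=300, rng=np.random.default_rng(2), bin_width_ms=BIN)
    inside = (res.mean >= res.ci_lo) & (res.mean <= res.ci_hi)
    assert inside.mean() >= 0.9


def test_bootstrap_band_deterministic(rng):
    segs = _sampled_hat(half=30) + rng.standard_normal((30, 61))
    cells = [(_comb_psth(300), segs)]
    a = burst_bootstrap_ci(cells, n_boot=100, rng=np.random.default_rng(9), bin_width_ms=BIN)
    b = burst_bootstrap_ci(cells, n_boot=100, rng=np.random.default_rng(9), bin_width_ms=BIN)
    assert np.array_equal(a.ci_lo, b.ci_lo) and np.array_equal(a.ci_hi, b.ci_hi)


def test_neuron_count_ratio_basics():
    t = np.arange(200) * BIN
    pred = np.sin(2 * np.pi * t / 5.0)
    assert estimate_neuron_count(200.0 * pred, pred, t, t, (0.0, 20.0)) == pytest.approx(200.0)
    assert estimate_neuron_count(pred, pred, t, t, (0.0, 20.0)) == pytest.approx(1.0)
    # scale-free in the recorded signal
    assert estimate_neuron_count(7.0 * pred, pred, t, t, (0.0, 20.0)) == pytest.approx(7.0)
    with pytest.raises(ValueError):
        estimate_neuron_count(pred, np.zeros_like(pred), t, t, (0.0, 20.0))
    with pytest.raises(ValueError):
        estimate_neuron_count(pred, pred, t, t, (100.0, 120.0))


def test_neuron_count_recovered_on_multi_cell_session():
    # forward-simulate a session whose EEG sums kernels of 50 identical cells;
    # the recorded/predicted burst ratio should recover the cell count
    n_cells, n_trials = 50, 200
    kernel = MexicanHat.from_amplitude_width(60.0, 0.45, 0.05)
    profile = RateProfile.driven(trial_length_ms=60.0)
    cfg = SessionConfig(
        n_trials=n_trials,
        trial_length_ms=60.0,
        noise_sd_hf=0.0,
        sep_template=None,
        kernel=[kernel] * n_cells,
        psth_profile=profile,
        unit_noise_sd_uv=0.0,
        rng_seed=17,
    )
    sess = simulate_session(cfg)
    eeg_up = upsample_linear(
        fourier_bandpass(sess.eeg, sess.fs_eeg, HIGHFREQ), sess.fs_eeg, 10000.0
    )
    recorded = eeg_up.mean(axis=0)
    t_up = np.arange(recorded.size) / 10000.0 * 1000.0
    psths, stas = [], []
    for train in sess.spikes:
        pruned = [prune_min_separation(t, 6.0) for t in train.trials]
        segs, lags = extract_segments(eeg_up, 10000.0, pruned, 3.0)
        stas.append(segs.mean(axis=0))
        psths.append(compute_psth(train, BIN, (0.0, 60.0)))
    pred = predict_burst(psths, stas, BIN, BIN)
    n_est = estimate_neuron_count(recorded, pred.mean, t_up, pred.time_ms, (6.0, 25.0))
    assert abs(n_est - n_cells) / n_cells < 0.2
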
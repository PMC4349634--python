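import numpy as np
import pytest

from spikesta.corrmodel import MexicanHat
from spikesta.spikes import compute_psth
from spikesta.synthetic import (
    RateProfile,
    SessionConfig,
    cross_correlogram,
    expected_sta_kernel,
    simulate_correlated_pair,
    simulate_session,
    simulate_spike_trains,
)


def test_zero_rate_gives_no_spikes():
    prof = RateProfile.constant(0.0, 0.0, 300.0)
    train = simulate_spike_trains(prof, 50, rng=np.random.default_rng(0))
    assert train.n_spikes == 0


def test_poisson_spike_count_statistics():
    # late-window conditions: constant 20 sp/s over 90 ms, 1000 trials
    prof = RateProfile.constant(20.0, 200.0, 290.0)
    train = simulate_spike_trains(prof, 1000, refractory_ms=1.0, rng=np.random.default_rng(7))
    expected = 20.0 * 0.090 * 1000
    assert abs(train.n_spikes - expected) < 3 * np.sqrt(expected)


def test_refractory_period_enforced():
    prof = RateProfile.constant(400.0, 0.0, 100.0)
    train = simulate_spike_trains(prof, 20, refractory_ms=2.0, rng=np.random.default_rng(1))
    for t in train.trials:
        if t.size > 1:
            assert np.all(np.diff(t) >= 2.0)


def test_spike_train_determinism():
    prof = RateProfile.driven(trial_length_ms=100.0)
    a = simulate_spike_trains(prof, 20, rng=np.random.default_rng(5))
    b = simulate_spike_trains(prof, 20, rng=np.random.default_rng(5))
    for ta, tb in zip(a.trials, b.trials):
        assert np.array_equal(ta, tb)


def test_negative_rates_rejected():
    with pytest.raises(ValueError):
        RateProfile(times_ms=[0.0, 100.0], rates_hz=[5.0, -1.0])


def test_session_determinism():
    cfg = dict(n_trials=8, trial_length_ms=100.0, rng_seed=11)
    a = simulate_session(SessionConfig(**cfg))
    b = simulate_session(SessionConfig(**cfg))
    assert np.array_equal(a.eeg, b.eeg)
    assert np.array_equal(a.unit, b.unit)


def test_noiseless_embedding_reproduces_kernel_exactly():
    # with zero noise and no evoked response the EEG is exactly the sum of
    # kernels at the true spike times
    kernel = MexicanHat.from_amplitude_width(60.0, 0.45, 0.05)
    cfg = SessionConfig(
        n_trials=5,
        trial_length_ms=120.0,
        noise_sd_hf=0.0,
        sep_template=None,
        kernel=kernel,
        psth_profile=RateProfile.constant(30.0, 0.0, 120.0),
        unit_noise_sd_uv=0.0,
        rng_seed=3,
    )
    sess = simulate_session(cfg)
    fs = sess.fs_eeg
    t = np.arange(sess.eeg.shape[1]) / fs * 1000.0
    recon = np.zeros_like(sess.eeg)
    for trial, times in enumerate(sess.spikes[0].trials):
        for t_spk in times:
            recon[trial] += np.where(np.abs(t - t_spk) < 5.0, kernel(t - t_spk), 0.0)
    assert np.allclose(sess.eeg, recon, atol=1e-9)


def test_zero_trials_rejected():
    with pytest.raises(ValueError):
        SessionConfig(n_trials=0)


def test_kernel_longer_than_trial_rejected():
    wide = MexicanHat.from_amplitude_width(60.0, 200.0)
    with pytest.raises(ValueError):
        simulate_session(SessionConfig(n_trials=2, trial_length_ms=100.0, kernel=wide))


def test_hf_noise_sd_calibrated():
    from spikesta.filtering import HIGHFREQ, fourier_bandpass

    cfg = SessionConfig(n_trials=40, trial_length_ms=200.0, kernel=None,
                        sep_template=None, rng_seed=2)
    sess = simulate_session(cfg)
    hf = fourier_bandpass(sess.eeg, sess.fs_eeg, HIGHFREQ)
    assert abs(np.std(hf) / 700.0 - 1.0) < 0.02


def test_empirical_psth_matches_profile():
    prof = RateProfile.constant(30.0, 0.0, 100.0)
    train = simulate_spike_trains(prof, 3000, refractory_ms=0.0, rng=np.random.default_rng(9))
    psth = compute_psth(train, 5.0, (0.0, 100.0))
    expected = 30.0 * 5.0 / 1000.0
    se = np.sqrt(expected / 3000)
    assert np.max(np.abs(psth.rate - expected)) < 3 * se


def test_expected_sta_kernel_reflects_band_limiting():
    kernel = MexicanHat.from_amplitude_width(60.0, 0.45, 0.0)
    lags, wav = expected_sta_kernel(kernel)
    assert lags.size == wav.size == 61
    p2p = wav.max() - wav.min()
    assert 0.3 * kernel.peak_to_peak < p2p < kernel.peak_to_peak  # attenuated, not lost


def _fit_correlogram_amplitude(lags, rates, b_ms2, exclude=None):
    """Linear LSQ for baseline + a * exp(-lag^2/b); returns (a_hat, se_a)."""
    g = np.exp(-(lags**2) / b_ms2)
    X = np.column_stack([np.ones_like(g), g])
    beta, res, *_ = np.linalg.lstsq(X, rates, rcond=None)
    resid = rates - X @ beta
    sigma2 = resid @ resid / (rates.size - 2)
    cov = sigma2 * np.linalg.inv(X.T @ X)
    return beta[1], np.sqrt(cov[1, 1])


def test_uncorrelated_pair_has_flat_correlogram():
    rng = np.random.default_rng(21)
    t1, t2 = simulate_correlated_pair(50.0, 0.0, 17.0, 200.0, rng)
    lags, rates = cross_correlogram(t1, t2, max_lag_ms=60.0, bin_ms=2.0)
    base = 50.0
    se = np.sqrt(base / (t1.size * 0.002))
    assert np.all(np.abs(rates - base) < 5 * se)


def test_strong_correlation_amplitude_recovered():
    rng = np.random.default_rng(4)
    a_true, t_xcf = 2.0, 17.0
    t1, t2 = simulate_correlated_pair(20.0, a_true, t_xcf, 600.0, rng)
    lags, rates = cross_correlogram(t1, t2, max_lag_ms=80.0, bin_ms=1.0)
    b = (t_xcf / 2.0) ** 2 / np.log(2.0)
    a_hat, se = _fit_correlogram_amplitude(lags, rates, b)
    assert abs(a_hat - a_true) < 3 * se
    assert abs(a_hat - a_true) < 0.5 * a_true  # and actually informative


def test_weak_published_synchrony_consistent():
    # at the published synchrony level the amplitude estimate is noisy but unbiased
    rng = np.random.default_rng(8)
    t1, t2 = simulate_correlated_pair(20.0, 0.008, 17.0, 400.0, rng)
    lags, rates = cross_correlogram(t1, t2, max_lag_ms=80.0, bin_ms=1.0)
    a_hat, se = _fit_correlogram_amplitude(lags, rates, (17.0 / 2) ** 2 / np.log(2.0))
    assert abs(a_hat - 0.008) < 3 * se


def test_correlated_pair_determinism_and_feasibility():
    a = simulate_correlated_pair(20.0, 1.0, 10.0, 50.0, np.random.default_rng(3))
    b = simulate_correlated_pair(20.0, 1.0, 10.0, 50.0, np.random.default_rng(3))
    assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])
    with pytest.raises(ValueError):
        # required shared-event rate would exceed the firing rate itself
        simulate_correlated_pair(1.0, 100.0, 17.0, 10.0, np.random.default_rng(0))
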
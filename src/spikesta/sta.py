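"""Spike-triggered EEG averaging with shift-predictor nulls and bootstrap tests.

The spike-triggered average (STA) is the mean EEG segment around each retained
spike (lag 0 = the spike's first negative peak).  Stimulus-locked structure
that would survive even without spike/EEG coupling is estimated by the *shift
predictor*: each spike keeps its within-trial latency but is reassigned to a
uniformly drawn *different* trial; the mean STA over such shuffles is
subtracted as a baseline.  Peak significance uses a two-sample bootstrap
comparing maximal absolute STA amplitudes before and after shuffling.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import stats


@dataclass
class STAResult:
    lags: np.ndarray  # ms, symmetric about 0 (lag 0 = spike's first negative peak)
    mean: np.ndarray  # nV per lag
    sem: np.ndarray  # nV per lag
    n_segments: int
    predictor_mean: np.ndarray | None = None
    band: tuple[np.ndarray, np.ndarray] | None = None  # (lo, hi) per lag
    baseline_corrected: bool = False


def _spikes_to_flat(spikes_by_trial) -> tuple[np.ndarray, np.ndarray]:
    times = [np.asarray(t, dtype=float) for t in spikes_by_trial]
    trial_ids = np.concatenate(
        [np.full(t.size, i, dtype=int) for i, t in enumerate(times)]
    ) if times else np.empty(0, int)
    flat = np.concatenate(times) if times else np.empty(0)
    return flat, trial_ids


def extract_segments(
    eeg_trials: np.ndarray,
    fs: float,
    spikes_by_trial,
    half_window_ms: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Extract one EEG segment per spike (± half_window around the spike).

    ``eeg_trials`` is (n_trials, n_samples) already at the analysis rate
    (nominally 10 kHz after linear upsampling); spikes are expected to be
    pruned to a minimum separation matching the window (6 ms for ±3 ms,
    30 ms for ±15 ms).  Spikes whose window exceeds the trial are dropped.
    The lag grid includes both endpoints.  Returns ``(segments, lags_ms)``.
    """
    eeg_trials = np.asarray(eeg_trials, dtype=float)
    n_trials, n_samp = eeg_trials.shape
    half = int(round(half_window_ms * fs / 1000.0))
    times, trial_ids = _spikes_to_flat(spikes_by_trial)
    centers = np.round(times * fs / 1000.0).astype(int)
    ok = (centers >= half) & (centers < n_samp - half)
    centers, trial_ids = centers[ok], trial_ids[ok]
    lags = np.arange(-half, half + 1) / fs * 1000.0
    if centers.size == 0:
        return np.empty((0, 2 * half + 1)), lags
    offs = np.arange(-half, half + 1)
    segments = eeg_trials[trial_ids[:, None], centers[:, None] + offs[None, :]]
    return segments, lags


def eeg_sta(segments: np.ndarray, lags: np.ndarray) -> STAResult:
    """Per-lag mean and standard error across extracted segments."""
    segments = np.asarray(segments, dtype=float)
    if segments.shape[0] < 1:
        raise ValueError("need at least one segment")
    n = segments.shape[0]
    mean = segments.mean(axis=0)
    sem = segments.std(axis=0, ddof=1) / np.sqrt(n) if n > 1 else np.zeros_like(mean)
    return STAResult(lags=np.asarray(lags, dtype=float), mean=mean, sem=sem, n_segments=n)


def shuffle_spikes(spikes_by_trial, rng: np.random.Generator) -> list[np.ndarray]:
    """Reassign each spike to a uniformly drawn *different* trial, keeping its latency."""
    n_trials = len(spikes_by_trial)
    if n_trials < 2:
        raise ValueError("shuffling requires at least 2 trials")
    times, trial_ids = _spikes_to_flat(spikes_by_trial)
    draw = rng.integers(0, n_trials - 1, size=times.size)
    new_ids = draw + (draw >= trial_ids)
    out = [[] for _ in range(n_trials)]
    for t, i in zip(times, new_ids):
        out[i].append(t)
    return [np.sort(np.array(lst)) for lst in out]


def shift_predictor(
    eeg_trials: np.ndarray,
    fs: float,
    spikes_by_trial,
    half_window_ms: float,
    n_shuffles: int = 100,
    rng: np.random.Generator | None = None,
    return_segments: bool = False,
):
    """Mean STA over ``n_shuffles`` trial-shuffled spike assignments.

    With ``return_segments=True`` also returns the pooled shuffled segments
    (one block per shuffle), which downstream bootstrap tests resample.
    """
    n_trials = len(spikes_by_trial)
    if n_trials < 2:
        raise ValueError("shift predictor requires at least 2 trials")
    rng = rng if rng is not None else np.random.default_rng()
    eeg_trials = np.asarray(eeg_trials, dtype=float)
    n_samp = eeg_trials.shape[1]
    half = int(round(half_window_ms * fs / 1000.0))
    lags = np.arange(-half, half + 1) / fs * 1000.0
    offs = np.arange(-half, half + 1)
    times, trial_ids = _spikes_to_flat(spikes_by_trial)
    centers = np.round(times * fs / 1000.0).astype(int)
    ok = (centers >= half) & (centers < n_samp - half)
    centers, trial_ids = centers[ok], trial_ids[ok]
    means = []
    pooled = []
    total = 0
    for _ in range(n_shuffles):
        draw = rng.integers(0, n_trials - 1, size=centers.size)
        new_ids = draw + (draw >= trial_ids)
        segs = eeg_trials[new_ids[:, None], centers[:, None] + offs[None, :]]
        if segs.shape[0] == 0:
            continue
        means.append(segs.mean(axis=0))
        total += segs.shape[0]
        if return_segments:
            pooled.append(segs)
    if not means:
        raise ValueError("no shuffled segments could be extracted")
    pooled_arr = np.vstack(pooled) if return_segments else None
    stack = np.vstack(means)
    predictor_mean = stack.mean(axis=0)
    if return_segments:
        sem = pooled_arr.std(axis=0, ddof=1) / np.sqrt(pooled_arr.shape[0])
    else:
        sem = stack.std(axis=0, ddof=1) if stack.shape[0] > 1 else np.zeros_like(predictor_mean)
    result = STAResult(lags=lags, mean=predictor_mean, sem=sem, n_segments=total)
    return (result, pooled_arr) if return_segments else result


def baseline_correct(sta: STAResult, predictor: STAResult) -> STAResult:
    """Subtract the shift-predictor mean (stimulus-locked baseline) from the STA.

    By the caller's contract this is *not* applied to the late-window
    (200–290 ms) STA nor to wideband STA spectra.
    """
    if sta.lags.shape != predictor.lags.shape or not np.allclose(sta.lags, predictor.lags):
        raise ValueError("lag grids of STA and predictor do not match")
    return replace(
        sta,
        mean=sta.mean - predictor.mean,
        predictor_mean=predictor.mean.copy(),
        baseline_corrected=True,
    )


def confidence_band(
    segments: np.ndarray,
    level_multiplier: float = 2.58,
    n_effective: int | None = None,
    center: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-lag ± multiplier × SEM band (2.58 SEM ≈ 99% confidence limits).

    ``n_effective`` sets the segment count entering the SEM (e.g. the
    *unshuffled* spike count when the spread is estimated from a larger pool
    of shuffled segments); ``center`` defaults to the segment mean.
    """
    segments = np.asarray(segments, dtype=float)
    if segments.shape[0] < 2:
        raise ValueError("need at least 2 segments")
    n = n_effective if n_effective is not None else segments.shape[0]
    sem = segments.std(axis=0, ddof=1) / np.sqrt(n)
    c = segments.mean(axis=0) if center is None else np.asarray(center, dtype=float)
    return c - level_multiplier * sem, c + level_multiplier * sem


def peak_to_peak(sta, lags: np.ndarray | None = None, window: tuple[float, float] | None = None) -> float:
    """max − min of the mean waveform, optionally restricted to a lag window."""
    if isinstance(sta, STAResult):
        y, t = sta.mean, sta.lags
    else:
        y = np.asarray(sta, dtype=float)
        t = np.asarray(lags, dtype=float) if lags is not None else None
    if window is not None:
        if t is None:
            raise ValueError("window requires lags")
        if window[0] < t[0] - 1e-9 or window[1] > t[-1] + 1e-9:
            raise ValueError("window outside lag grid")
        sel = (t >= window[0]) & (t <= window[1])
        y = y[sel]
    return float(y.max() - y.min())


def _bootstrap_peaks(
    seg: np.ndarray, n_boot: int, n_resample: int, rng: np.random.Generator, chunk: int = 200
) -> np.ndarray:
    peaks = np.empty(n_boot)
    done = 0
    while done < n_boot:
        m = min(chunk, n_boot - done)
        idx = rng.integers(0, seg.shape[0], size=(m, n_resample))
        peaks[done : done + m] = np.abs(seg[idx].mean(axis=1)).max(axis=1)
        done += m
    return peaks


def peak_bootstrap_test(
    unshuffled_segments: np.ndarray,
    shuffled_segments: np.ndarray,
    lags: np.ndarray,
    peak_window: tuple[float, float] = (-0.3, 0.5),
    n_boot: int = 5000,
    rng: np.random.Generator | None = None,
    resample_observed: bool = False,
) -> float:
    """Bootstrap test of the STA peak amplitude against the trial-shuffled null.

    ``n_boot`` shuffled EEG-STAs are formed from random combinations (drawn
    with repetition, segment count conserved at the unshuffled count) of the
    shuffled-trigger segments; p is the fraction of replicates in which the
    maximal absolute shuffled-STA amplitude within ``peak_window`` exceeds the
    maximal absolute amplitude of the unshuffled STA.  With
    ``resample_observed=True`` the unshuffled peak is also re-drawn per
    replicate (a pairwise comparison of both empirical peak distributions,
    which is markedly conservative for the max statistic).  No
    multiple-comparison correction is applied.
    """
    lags = np.asarray(lags, dtype=float)
    if peak_window[0] < lags[0] - 1e-9 or peak_window[1] > lags[-1] + 1e-9:
        raise ValueError("peak window outside lag grid")
    rng = rng if rng is not None else np.random.default_rng()
    sel = (lags >= peak_window[0]) & (lags <= peak_window[1])
    u = np.ascontiguousarray(np.asarray(unshuffled_segments, dtype=float)[:, sel])
    s = np.ascontiguousarray(np.asarray(shuffled_segments, dtype=float)[:, sel])
    if u.shape[0] == 0 or s.shape[0] == 0:
        raise ValueError("both segment pools must be non-empty")
    n_resample = u.shape[0]
    pk_s = _bootstrap_peaks(s, n_boot, n_resample, rng)
    if resample_observed:
        pk_u = _bootstrap_peaks(u, n_boot, n_resample, rng)
    else:
        pk_u = np.abs(u.mean(axis=0)).max()
    return float(np.mean(pk_s > pk_u))


@dataclass
class GroupedCovariation:
    group_spike_amp: np.ndarray
    group_sta_amp: np.ndarray
    r: float
    p: float


def grouped_covariation(
    waveforms: np.ndarray,
    segments: np.ndarray,
    grouping: str = "amplitude",
    n_groups: int = 15,
    key: np.ndarray | None = None,
    corr: str | None = None,
    sta_measure: str = "p2p",
    reference_mean: np.ndarray | None = None,
) -> GroupedCovariation:
    """Covariation between grouped spike-waveform and STA amplitudes.

    Spikes are sorted by the grouping key (waveform peak-to-peak amplitude,
    time/order of occurrence, or an explicit ``key``) and split into
    ``n_groups`` equally sized ordered groups (remainder dropped).  Per group,
    the spike waveforms and EEG segments are averaged and their peak-to-peak
    amplitudes correlated (Pearson by default; Spearman for
    ``grouping='pooled_percentile'``).  With ``sta_measure='fixed_lags'`` the
    group STA amplitude is the difference of values at the peak/trough lags of
    ``reference_mean`` (the overall average), as used for pooled percentile
    groups.
    """
    waveforms = np.asarray(waveforms, dtype=float)
    segments = np.asarray(segments, dtype=float)
    n = waveforms.shape[0]
    if segments.shape[0] != n:
        raise ValueError("waveforms and segments must be paired")
    if n_groups < 2:
        raise ValueError("need at least 2 groups")
    if n_groups > n:
        raise ValueError("more groups than spikes")
    if key is None:
        if grouping in ("amplitude", "pooled_percentile"):
            key = waveforms.max(axis=1) - waveforms.min(axis=1)
        elif grouping == "time":
            key = np.arange(n, dtype=float)
        else:
            raise ValueError(f"unknown grouping {grouping!r}")
    order = np.argsort(np.asarray(key, dtype=float), kind="stable")
    g = n // n_groups
    order = order[: g * n_groups].reshape(n_groups, g)
    spike_amp = np.empty(n_groups)
    sta_amp = np.empty(n_groups)
    if sta_measure == "fixed_lags":
        ref = segments.mean(axis=0) if reference_mean is None else np.asarray(reference_mean)
        i_pk, i_tr = int(np.argmax(ref)), int(np.argmin(ref))
    for i, idx in enumerate(order):
        wm = waveforms[idx].mean(axis=0)
        sm = segments[idx].mean(axis=0)
        spike_amp[i] = wm.max() - wm.min()
        if sta_measure == "fixed_lags":
            sta_amp[i] = sm[i_pk] - sm[i_tr]
        else:
            sta_amp[i] = sm.max() - sm.min()
    if corr is None:
        corr = "spearman" if grouping == "pooled_percentile" else "pearson"
    if corr == "pearson":
        r, p = stats.pearsonr(spike_amp, sta_amp)
    else:
        r, p = stats.spearmanr(spike_amp, sta_amp)
    return GroupedCovariation(group_spike_amp=spike_amp, group_sta_amp=sta_amp, r=float(r), p=float(p))


def induced_rms(eeg_trials: np.ndarray, window: slice | None = None) -> np.ndarray:
    """Root of the trial-averaged squared signal per time point (induced power).

    Squaring before averaging prevents cancellation of oscillations that are
    not phase-locked across trials.
    """
    eeg_trials = np.atleast_2d(np.asarray(eeg_trials, dtype=float))
    if window is not None:
        eeg_trials = eeg_trials[:, window]
    if eeg_trials.shape[0] == 0:
        return np.zeros(eeg_trials.shape[1])
    return np.sqrt(np.mean(eeg_trials**2, axis=0))
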
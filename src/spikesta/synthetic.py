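"""Seeded synthetic sessions emulating simultaneous micro-electrode + epidural-EEG recordings.

A session consists of ~1000 stimulation trials (median-nerve style, 3 Hz
repetition → 333 ms trials).  Each trial carries

* an epidural EEG channel at 6 kHz: band-limited (3–3000 Hz) noise whose
  800–3000 Hz band has a configurable SD (default 700 nV), a stimulus-locked
  somatosensory evoked potential with a high-frequency burst at 8–18 ms, and a
  tens-to-hundreds-of-nV Mexican-hat kernel inserted at each true spike time;
* a micro-electrode channel at 24 kHz with a stereotyped extracellular spike
  waveform (first negative peak at the spike time) in Gaussian noise.

Spike trains are inhomogeneous Poisson with an absolute refractory period; the
default rate profile has an early driven response (5–50 ms) with peaks
repeating at ~600 Hz and a stationary late window (200–290 ms).

The generator's noise has no 1/f (low-frequency) structure beyond the
acquisition band limits; ``SessionConfig.flat_noise_spectrum`` flags this
stand-in explicitly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .corrmodel import MexicanHat
from .filtering import HIGHFREQ, FilterSpec, fourier_bandpass, upsample_linear
from .spikes import SpikeTrain


@dataclass
class RateProfile:
    """Piecewise-linear firing-rate envelope (spikes/s) over the trial."""

    times_ms: np.ndarray
    rates_hz: np.ndarray

    def __post_init__(self) -> None:
        self.times_ms = np.asarray(self.times_ms, dtype=float)
        self.rates_hz = np.asarray(self.rates_hz, dtype=float)
        if self.times_ms.size != self.rates_hz.size or self.times_ms.size < 2:
            raise ValueError("profile needs matching times and rates (>= 2 points)")
        if np.any(np.diff(self.times_ms) <= 0):
            raise ValueError("profile times must be strictly increasing")
        if np.any(self.rates_hz < 0):
            raise ValueError("negative rates rejected")

    def rate(self, t_ms: np.ndarray) -> np.ndarray:
        return np.interp(t_ms, self.times_ms, self.rates_hz)

    @property
    def max_rate(self) -> float:
        return float(self.rates_hz.max())

    @classmethod
    def constant(cls, rate_hz: float, t0: float = 0.0, t1: float = 333.0) -> "RateProfile":
        return cls(times_ms=np.array([t0, t1]), rates_hz=np.array([rate_hz, rate_hz]))

    @classmethod
    def driven(
        cls,
        trial_length_ms: float = 333.0,
        baseline_hz: float = 8.0,
        burst_peak_hz: float = 150.0,
        burst_freq_hz: float = 600.0,
        burst_onset_ms: float = 6.0,
        burst_end_ms: float = 20.0,
        broad_peak_hz: float = 20.0,
        dt_ms: float = 0.05,
    ) -> "RateProfile":
        """Early driven response (peaks repeating at ~600 Hz) + stationary late rate.

        Baseline defaults to 8 spikes/s (≈ the per-cell late-window rate implied
        by ~32 000 late spikes over 40 cells × ~1000 trials × 90 ms); the early
        5–50 ms window carries a broad driven component plus sharp bumps
        repeating every 1/600 s, emulating a PSTH locked to the evoked
        high-frequency burst.
        """
        t = np.arange(0.0, trial_length_ms + dt_ms / 2, dt_ms)
        r = np.full_like(t, baseline_hz)
        r += broad_peak_hz * np.exp(-((t - 25.0) ** 2) / (2 * 15.0**2)) * ((t > 5.0) & (t < 50.0))
        period = 1000.0 / burst_freq_hz
        for tk in np.arange(burst_onset_ms, burst_end_ms, period):
            env = burst_peak_hz * np.exp(-((tk - 12.0) ** 2) / (2 * 4.0**2))
            r += env * np.exp(-((t - tk) ** 2) / (2 * 0.25**2))
        return cls(times_ms=t, rates_hz=r)


def simulate_spike_trains(
    psth_profile: RateProfile,
    n_trials: int,
    refractory_ms: float = 1.0,
    rng: np.random.Generator | None = None,
    t0_ms: float | None = None,
    t1_ms: float | None = None,
    cell_id: str = "cell0",
) -> SpikeTrain:
    """Inhomogeneous-Poisson spike trains with an absolute refractory period.

    Spikes are drawn by thinning a homogeneous process at the profile's peak
    rate; the refractory period is then enforced by deleting the later spike
    of any pair closer than ``refractory_ms``.
    """
    if refractory_ms < 0:
        raise ValueError("refractory must be non-negative")
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    rng = rng if rng is not None else np.random.default_rng()
    t0 = psth_profile.times_ms[0] if t0_ms is None else t0_ms
    t1 = psth_profile.times_ms[-1] if t1_ms is None else t1_ms
    lam_max = psth_profile.max_rate
    trials: list[np.ndarray] = []
    span_s = (t1 - t0) / 1000.0
    for _ in range(n_trials):
        if lam_max <= 0:
            trials.append(np.empty(0))
            continue
        n = rng.poisson(lam_max * span_s)
        cand = np.sort(rng.uniform(t0, t1, size=n))
        keep = rng.uniform(0.0, lam_max, size=n) < psth_profile.rate(cand)
        times = cand[keep]
        if refractory_ms > 0 and times.size > 1:
            kept = [times[0]]
            for t in times[1:]:
                if t - kept[-1] >= refractory_ms:
                    kept.append(t)
            times = np.array(kept)
        trials.append(times)
    return SpikeTrain(trials=trials, cell_id=cell_id, trial_length_ms=t1)


@dataclass(frozen=True)
class SEPTemplate:
    """Stimulus-locked evoked waveform: a slow SEP wave plus an 8–18 ms HF burst.

    Amplitudes are in nV; the defaults give a wideband SEP of a few tens of µV
    and an evoked 600-Hz burst of a few µV peak-to-peak, i.e. orders of
    magnitude above the per-spike kernel, which is what makes the
    shift-predictor baseline correction necessary.
    """

    slow_amp_nv: float = 20000.0
    slow_peak_ms: float = 10.0
    slow_width_ms: float = 8.0
    burst_amp_nv: float = 2000.0
    burst_freq_hz: float = 600.0
    burst_window_ms: tuple[float, float] = (8.0, 18.0)

    def waveform(self, t_ms: np.ndarray) -> np.ndarray:
        t = np.asarray(t_ms, dtype=float)
        u = (t - self.slow_peak_ms) / self.slow_width_ms
        slow = self.slow_amp_nv * u * np.exp(-(u**2) / 2.0)  # biphasic, near zero mean
        w0, w1 = self.burst_window_ms
        inside = (t >= w0) & (t <= w1)
        hann = np.where(inside, 0.5 * (1 - np.cos(2 * np.pi * (t - w0) / (w1 - w0))), 0.0)
        burst = self.burst_amp_nv * hann * np.sin(2 * np.pi * self.burst_freq_hz * (t - w0) / 1000.0)
        return slow + burst


@dataclass(frozen=True)
class UnitWaveform:
    """Stereotyped extracellular spike shape (µV), first negative peak at t = 0."""

    neg_amp_uv: float = 300.0
    neg_width_ms: float = 0.1
    pos_frac: float = 0.4
    pos_delay_ms: float = 0.3
    pos_width_ms: float = 0.2

    def waveform(self, t_ms: np.ndarray) -> np.ndarray:
        t = np.asarray(t_ms, dtype=float)
        neg = -self.neg_amp_uv * np.exp(-(t**2) / (2 * self.neg_width_ms**2))
        pos = self.pos_frac * self.neg_amp_uv * np.exp(
            -((t - self.pos_delay_ms) ** 2) / (2 * self.pos_width_ms**2)
        )
        return neg + pos


def _default_kernel() -> MexicanHat:
    # grand-average single-spike kernel: 60 nV peak, 0.45 ms side-lobe
    # separation, 0.05 ms latency
    return MexicanHat.from_amplitude_width(60.0, 0.45, 0.05)


@dataclass
class SessionConfig:
    """Parameters of one synthetic recording session.

    ``kernel`` and ``psth_profile`` may be single objects (one cell, the
    default, matching single-unit sessions) or equal-length lists for
    multi-cell sessions.  ``kernel`` entries may also be 1-D arrays sampled at
    ``fs_eeg`` (centred), inserted with fractional-delay linear interpolation.
    """

    n_trials: int = 1031
    trial_length_ms: float = 333.0
    fs_eeg: float = 6000.0
    fs_unit: float = 24000.0
    stim_time_ms: float = 0.0
    noise_sd_hf: float = 700.0  # nV in the 800-3000 Hz band
    noise_band: FilterSpec = field(default_factory=lambda: FilterSpec(3.0, 3000.0))
    hf_band: FilterSpec = field(default_factory=lambda: HIGHFREQ)
    kernel: object = field(default_factory=_default_kernel)
    psth_profile: object = None
    sep_template: SEPTemplate | None = field(default_factory=SEPTemplate)
    refractory_ms: float = 1.0
    unit_noise_sd_uv: float = 30.0
    unit_waveform: UnitWaveform = field(default_factory=UnitWaveform)
    depth_mm: float = 2.18
    rng_seed: int = 0
    flat_noise_spectrum: bool = True  # no 1/f structure: an explicit stand-in

    def __post_init__(self) -> None:
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")
        if self.trial_length_ms <= 0:
            raise ValueError("trial_length must be positive")
        if self.fs_eeg <= 0 or self.fs_unit <= 0:
            raise ValueError("sampling rates must be positive")
        if self.noise_sd_hf < 0:
            raise ValueError("noise_sd_hf must be non-negative")
        if self.psth_profile is None:
            self.psth_profile = RateProfile.driven(trial_length_ms=self.trial_length_ms)

    @property
    def kernels(self) -> list:
        k = self.kernel
        return list(k) if isinstance(k, (list, tuple)) else [k]

    @property
    def profiles(self) -> list[RateProfile]:
        p = self.psth_profile
        profs = list(p) if isinstance(p, (list, tuple)) else [p]
        if len(profs) == 1 and len(self.kernels) > 1:
            profs = profs * len(self.kernels)
        if len(profs) != len(self.kernels):
            raise ValueError("kernel and psth_profile lists must have equal length")
        return profs


@dataclass
class SessionRecording:
    """Per-trial EEG (nV) and micro-electrode (µV) arrays plus ground truth."""

    eeg: np.ndarray  # (n_trials, n_samples_eeg)
    unit: np.ndarray  # (n_trials, n_samples_unit)
    fs_eeg: float
    fs_unit: float
    stim_time_ms: float
    trial_length_ms: float
    spikes: list  # list[SpikeTrain], one per cell (ground truth when synthetic)
    truth: dict | None = None
    config: SessionConfig | None = None

    @property
    def n_trials(self) -> int:
        return self.eeg.shape[0]


def _kernel_half_support_ms(kernel, fs_eeg: float) -> float:
    if kernel is None:  # cell couples to the unit channel only, not to the EEG
        return 0.0
    if isinstance(kernel, MexicanHat):
        return max(5.0 * np.sqrt(kernel.b), 1.0)
    arr = np.asarray(kernel, dtype=float)
    return arr.size / fs_eeg * 1000.0 / 2.0


def _insert_kernel(eeg: np.ndarray, fs: float, kernel, train: SpikeTrain, scale: float = 1.0) -> None:
    """Add the per-spike surface kernel at every true spike time, in place."""
    if kernel is None:
        return
    n_samp = eeg.shape[1]
    half_ms = _kernel_half_support_ms(kernel, fs)
    half = int(np.ceil(half_ms * fs / 1000.0))
    offs = np.arange(-half, half + 1)
    if isinstance(kernel, MexicanHat):
        sample_kernel = kernel
    else:
        arr = np.asarray(kernel, dtype=float)
        k_t = (np.arange(arr.size) - (arr.size - 1) / 2.0) / fs * 1000.0

        def sample_kernel(t_ms):  # fractional-delay linear interpolation
            return np.interp(t_ms, k_t, arr, left=0.0, right=0.0)

    for trial, times in enumerate(train.trials):
        for t_spk in times:
            center = int(round(t_spk * fs / 1000.0))
            idx = center + offs
            ok = (idx >= 0) & (idx < n_samp)
            t_samp = idx[ok] / fs * 1000.0
            eeg[trial, idx[ok]] += scale * sample_kernel(t_samp - t_spk)


def simulate_session(config: SessionConfig) -> SessionRecording:
    """Generate one seeded session with the statistical structure the analysis assumes."""
    fs, fsu = config.fs_eeg, config.fs_unit
    n_samp = int(round(config.trial_length_ms * fs / 1000.0))
    n_samp_u = int(round(config.trial_length_ms * fsu / 1000.0))
    for k in config.kernels:
        if 2 * _kernel_half_support_ms(k, fs) >= config.trial_length_ms:
            raise ValueError("kernel longer than trial")
    rng = np.random.default_rng(config.rng_seed)

    trains = [
        simulate_spike_trains(
            prof, config.n_trials, config.refractory_ms, rng,
            t0_ms=0.0, t1_ms=config.trial_length_ms, cell_id=f"cell{i}",
        )
        for i, prof in enumerate(config.profiles)
    ]

    if config.noise_sd_hf > 0:
        white = rng.standard_normal((config.n_trials, n_samp))
        shaped = fourier_bandpass(white, fs, config.noise_band)
        hf_sd = float(np.std(fourier_bandpass(shaped, fs, config.hf_band)))
        eeg = shaped * (config.noise_sd_hf / hf_sd)
    else:
        eeg = np.zeros((config.n_trials, n_samp))

    t_grid = np.arange(n_samp) / fs * 1000.0
    if config.sep_template is not None:
        eeg += config.sep_template.waveform(t_grid - config.stim_time_ms)

    for kernel, train in zip(config.kernels, trains):
        _insert_kernel(eeg, fs, kernel, train)

    unit = (
        rng.standard_normal((config.n_trials, n_samp_u)) * config.unit_noise_sd_uv
        if config.unit_noise_sd_uv > 0
        else np.zeros((config.n_trials, n_samp_u))
    )
    wf = config.unit_waveform
    half_u = int(np.ceil(1.5 * fsu / 1000.0))
    offs_u = np.arange(-half_u, half_u + 1)
    for trial, times in enumerate(trains[0].trials):
        for t_spk in times:
            center = int(round(t_spk * fsu / 1000.0))
            idx = center + offs_u
            ok = (idx >= 0) & (idx < n_samp_u)
            unit[trial, idx[ok]] += wf.waveform(idx[ok] / fsu * 1000.0 - t_spk)

    truth = {
        "kernels": config.kernels,
        "depth_mm": config.depth_mm,
        "noise_sd_hf": config.noise_sd_hf,
        "rng_seed": config.rng_seed,
    }
    return SessionRecording(
        eeg=eeg,
        unit=unit,
        fs_eeg=fs,
        fs_unit=fsu,
        stim_time_ms=config.stim_time_ms,
        trial_length_ms=config.trial_length_ms,
        spikes=trains,
        truth=truth,
        config=config,
    )


def expected_sta_kernel(
    kernel: MexicanHat,
    fs_eeg: float = 6000.0,
    band: FilterSpec = HIGHFREQ,
    half_window_ms: float = 3.0,
    fs_out: float = 10000.0,
    n_phases: int = 64,
    buffer_ms: float = 200.0,
) -> tuple[np.ndarray, np.ndarray]:
    """The waveform an unbiased spike-triggered average is expected to recover.

    A sharp kernel is attenuated by the acquisition chain: sampling at
    ``fs_eeg``, band-pass filtering, 10 kHz linear upsampling, and alignment of
    each spike to the nearest output sample.  This routine computes the
    expectation of the aligned segment over a uniform spike phase relative to
    the EEG sampling grid, by direct evaluation (independent of the STA code
    path).  Returns ``(lags_ms, waveform_nV)``.
    """
    n = int(round(buffer_ms * fs_eeg / 1000.0))
    t = np.arange(n) / fs_eeg * 1000.0
    n_out = int(np.floor((n - 1) * fs_out / fs_eeg)) + 1
    t_out = np.arange(n_out) / fs_out * 1000.0
    half = int(round(half_window_ms * fs_out / 1000.0))
    t_mid = buffer_ms / 2.0
    accum = np.zeros(2 * half + 1)
    for phase in np.arange(n_phases) / n_phases:
        t_spk = t_mid + phase / fs_eeg * 1000.0
        if not isinstance(kernel, MexicanHat):
            raise TypeError("expected_sta_kernel requires a MexicanHat kernel")
        x = kernel(t - t_spk)  # same evaluation as the session generator
        xf = fourier_bandpass(x, fs_eeg, band)
        xu = upsample_linear(xf, fs_eeg, fs_out)
        # lag 0 = output sample nearest the spike time, as in segment extraction
        center = int(round(t_spk * fs_out / 1000.0))
        accum += xu[center - half : center + half + 1]
    lags = (np.arange(-half, half + 1)) / fs_out * 1000.0
    return lags, accum / n_phases


def simulate_correlated_pair(
    rate_hz: float,
    a_xcf: float,
    t_xcf_ms: float,
    duration_s: float,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Two spike trains (times in ms) with a Gaussian cross-correlogram excess.

    Implemented via jittered shared events: a mother Poisson process of rate
    ``r_shared`` is copied into both trains with independent Gaussian jitter of
    SD sqrt(b_xcf)/2, which yields an excess coincidence rate (per trigger
    spike) of peak ``a_xcf`` (1/s) and half-amplitude width ``t_xcf_ms``.
    """
    if rate_hz <= 0 or duration_s <= 0:
        raise ValueError("rate and duration must be positive")
    if a_xcf < 0:
        raise ValueError("a_xcf must be non-negative")
    if t_xcf_ms <= 0:
        raise ValueError("t_xcf must be positive")
    rng = rng if rng is not None else np.random.default_rng()
    b = (t_xcf_ms / 2.0) ** 2 / np.log(2.0)  # ms^2
    sigma_s = np.sqrt(b) / 2.0 / 1000.0
    r_shared = a_xcf * rate_hz * 2.0 * np.sqrt(np.pi) * sigma_s
    if r_shared > rate_hz:
        raise ValueError("infeasible correlation: required shared rate exceeds firing rate")
    n_shared = rng.poisson(r_shared * duration_s)
    mother = rng.uniform(0.0, duration_s, n_shared)
    out = []
    for _ in range(2):
        jittered = mother + rng.normal(0.0, sigma_s, n_shared)
        jittered = jittered[(jittered >= 0) & (jittered < duration_s)]
        n_ind = rng.poisson((rate_hz - r_shared) * duration_s)
        indep = rng.uniform(0.0, duration_s, n_ind)
        out.append(np.sort(np.concatenate((jittered, indep))) * 1000.0)
    return out[0], out[1]


def cross_correlogram(
    t1_ms: np.ndarray,
    t2_ms: np.ndarray,
    max_lag_ms: float = 60.0,
    bin_ms: float = 1.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Empirical cross-correlogram: coincidence rate (1/s) per trigger spike vs lag."""
    t1 = np.asarray(t1_ms, dtype=float)
    t2 = np.sort(np.asarray(t2_ms, dtype=float))
    n_bins = int(round(2 * max_lag_ms / bin_ms))
    edges = -max_lag_ms + np.arange(n_bins + 1) * bin_ms
    abs_edges = (t1[:, None] + edges[None, :]).ravel()
    counts = np.searchsorted(t2, abs_edges).reshape(t1.size, -1)
    hist = np.diff(counts, axis=1).sum(axis=0).astype(float)
    rate = hist / (t1.size * bin_ms / 1000.0)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return centers, rate


__all__ = [
    "RateProfile",
    "SEPTemplate",
    "UnitWaveform",
    "SessionConfig",
    "SessionRecording",
    "simulate_spike_trains",
    "simulate_session",
    "simulate_correlated_pair",
    "cross_correlogram",
    "expected_sta_kernel",
    "replace",
]
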
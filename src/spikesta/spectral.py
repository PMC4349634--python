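"""Log-spaced spectral estimation, bootstrap frequency tests, multitaper PSD.

The log-spaced estimator evaluates power on a grid of frequencies equidistant
on a logarithmic scale (8 per octave).  For each grid frequency the signal is
truncated to an integer number of periods, multiplied by a Hann window of the
same length, and projected directly onto a sine/cosine pair at that frequency;
this truncation minimises spectral leakage for short waveforms such as
spike-triggered averages.  The resulting spectrum is smoothed with a
half-octave moving average in the frequency domain.

Power is normalised as amplitude-squared of the windowed projection
(2|c| / Σw, squared), so a unit sine at a grid frequency reports power 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.signal.windows import dpss, hann


@dataclass
class SpectrumEstimate:
    freqs: np.ndarray  # Hz, strictly increasing
    power: np.ndarray  # signal-units^2 per frequency
    smoothed: bool = False

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.power = np.asarray(self.power, dtype=float)
        if np.any(np.diff(self.freqs) <= 0):
            raise ValueError("frequencies must be strictly increasing")


def log_frequency_grid(f_min: float, f_max: float, freqs_per_octave: int = 8) -> np.ndarray:
    """Frequencies from f_min up to f_max with constant ratio 2^(1/freqs_per_octave)."""
    if f_min <= 0 or f_max <= f_min:
        raise ValueError("need 0 < f_min < f_max")
    n = int(np.floor(freqs_per_octave * np.log2(f_max / f_min))) + 1
    return f_min * 2.0 ** (np.arange(n) / freqs_per_octave)


class LogSpectrumBasis:
    """Precomputed projection basis for repeated log-spaced spectra of equal-length signals.

    Each grid frequency contributes a Hann-windowed sine/cosine pair truncated
    to an integer number of periods; spectra of many waveforms then reduce to
    two matrix products.
    """

    def __init__(
        self,
        n_samples: int,
        fs: float,
        freqs_per_octave: int = 8,
        f_min: float | None = None,
        f_max: float | None = None,
    ):
        duration = n_samples / fs
        if f_min is None:
            # a log grid cannot start at 0; the lowest resolvable frequency
            # has two periods in the record
            f_min = 2.0 / duration
        if f_min < 2.0 / duration - 1e-12:
            raise ValueError("f_min below 2 / duration")
        if f_max is None:
            f_max = fs / 2.0
        self.fs = fs
        self.n_samples = n_samples
        self.freqs = log_frequency_grid(f_min, f_max, freqs_per_octave)
        cos_b = np.zeros((n_samples, self.freqs.size))
        sin_b = np.zeros((n_samples, self.freqs.size))
        self.scale = np.zeros(self.freqs.size)
        t = np.arange(n_samples) / fs
        for j, f in enumerate(self.freqs):
            n_per = int(np.floor(duration * f))
            length = int(np.floor(n_per / f * fs))
            length = min(length, n_samples)
            if n_per < 1 or length < 2:
                continue
            w = hann(length, sym=False)
            arg = 2 * np.pi * f * t[:length]
            cos_b[:length, j] = w * np.cos(arg)
            sin_b[:length, j] = w * np.sin(arg)
            self.scale[j] = 2.0 / w.sum()
        self._cos = cos_b
        self._sin = sin_b

    def power(self, x: np.ndarray) -> np.ndarray:
        """Raw (unsmoothed) power for waveform(s) ``x`` of shape (..., n_samples)."""
        x = np.asarray(x, dtype=float)
        c = x @ self._cos
        s = x @ self._sin
        return (c**2 + s**2) * self.scale**2


def half_octave_smooth(freqs: np.ndarray, power: np.ndarray) -> np.ndarray:
    """Moving average over the grid frequencies within [f·2^(-1/4), f·2^(1/4)]."""
    freqs = np.asarray(freqs, dtype=float)
    power = np.asarray(power, dtype=float)
    out = np.empty_like(power)
    lo = freqs * 2.0 ** (-0.25)
    hi = freqs * 2.0 ** (0.25)
    for j, f in enumerate(freqs):
        sel = (freqs >= lo[j]) & (freqs <= hi[j])
        out[..., j] = power[..., sel].mean(axis=-1)
    return out


def logspaced_spectrum(
    x: np.ndarray,
    fs: float,
    freqs_per_octave: int = 8,
    f_min: float | None = None,
    f_max: float | None = None,
    smooth: bool = True,
) -> SpectrumEstimate:
    """Log-spaced truncated-Hann spectrum of a single waveform."""
    x = np.asarray(x, dtype=float)
    basis = LogSpectrumBasis(x.shape[-1], fs, freqs_per_octave, f_min, f_max)
    power = basis.power(x)
    if smooth:
        power = half_octave_smooth(basis.freqs, power)
    return SpectrumEstimate(freqs=basis.freqs, power=power, smoothed=smooth)


def spectral_bootstrap_test(
    spike_segments: np.ndarray,
    shuffled_segments: np.ndarray,
    fs: float,
    n_boot: int = 500,
    rng: np.random.Generator | None = None,
    freqs_per_octave: int = 8,
    chunk: int = 100,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Frequency-wise two-tailed bootstrap test of the STA spectrum against the shuffled null.

    ``n_boot`` spectra are computed from STAs of shuffled-trigger segments
    resampled with repetition (segment count conserved at the spike-triggered
    count); per frequency, p is twice the smaller tail fraction of bootstrap
    spectra beyond the unshuffled spectrum.  Returns
    ``(freqs, p_values, observed_power)``.
    """
    spike_segments = np.asarray(spike_segments, dtype=float)
    shuffled_segments = np.asarray(shuffled_segments, dtype=float)
    if spike_segments.shape[0] == 0 or shuffled_segments.shape[0] == 0:
        raise ValueError("both segment sets must be non-empty")
    if n_boot < 100:
        warnings.warn("n_boot < 100 gives coarse p-values", stacklevel=2)
    rng = rng if rng is not None else np.random.default_rng()
    basis = LogSpectrumBasis(spike_segments.shape[1], fs, freqs_per_octave)
    obs = half_octave_smooth(basis.freqs, basis.power(spike_segments.mean(axis=0)))
    n_resample = spike_segments.shape[0]
    n_above = np.zeros(basis.freqs.size)
    n_below = np.zeros(basis.freqs.size)
    done = 0
    while done < n_boot:
        m = min(chunk, n_boot - done)
        idx = rng.integers(0, shuffled_segments.shape[0], size=(m, n_resample))
        boot_means = shuffled_segments[idx].mean(axis=1)
        boot_pow = half_octave_smooth(basis.freqs, basis.power(boot_means))
        n_above += (boot_pow >= obs).sum(axis=0)
        n_below += (boot_pow <= obs).sum(axis=0)
        done += m
    # add-one continuity keeps p > 0 and approximately uniform under the null
    p = 2.0 * np.minimum((n_above + 1) / (n_boot + 1), (n_below + 1) / (n_boot + 1))
    return basis.freqs, np.minimum(p, 1.0), obs


def multitaper_psd(x: np.ndarray, fs: float, bandwidth: float = 600.0) -> SpectrumEstimate:
    """Slepian-taper power spectral density with the given concentration bandwidth.

    ``bandwidth`` is the full spectral concentration bandwidth 2W (Hz); the
    time-bandwidth product is NW = duration · W and the taper count is
    floor(2·NW) − 1.  One-sided density normalised so that ∑PSD·Δf equals the
    signal variance (Parseval).
    """
    x = np.asarray(x, dtype=float)
    n = x.shape[-1]
    if n < 8:
        raise ValueError("signal too short")
    duration = n / fs
    nw = duration * bandwidth / 2.0
    if nw < 1.0:
        raise ValueError("bandwidth incompatible with duration (NW < 1)")
    k = max(int(np.floor(2 * nw)) - 1, 1)
    tapers = dpss(n, nw, k)  # rows normalised to unit energy
    spectra = np.abs(np.fft.rfft(tapers * x[..., None, :], axis=-1)) ** 2 / fs
    psd = spectra.mean(axis=-2)
    if n % 2 == 0:
        psd[..., 1:-1] *= 2.0
    else:
        psd[..., 1:] *= 2.0
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    return SpectrumEstimate(freqs=freqs[1:], power=psd[..., 1:], smoothed=False)


def band_power(x: np.ndarray, fs: float, band: tuple[float, float]) -> float:
    """Total periodogram power within [lo, hi] Hz."""
    x = np.asarray(x, dtype=float)
    spec = np.abs(np.fft.rfft(x)) ** 2
    freqs = np.fft.rfftfreq(x.size, d=1.0 / fs)
    sel = (freqs >= band[0]) & (freqs <= band[1])
    return float(spec[sel].sum()) / x.size**2


def desync_ratio(
    x: np.ndarray,
    fs: float,
    fast_band: tuple[float, float] = (15.0, 75.0),
    slow_band: tuple[float, float] = (1.0, 10.0),
) -> float:
    """Band-power ratio of fast (15–75 Hz) to slow (1–10 Hz) oscillations.

    A ratio well above 1 indicates a desynchronized (awake) EEG.  The evoked
    average must already be subtracted by the caller.
    """
    return band_power(x, fs, fast_band) / band_power(x, fs, slow_band)
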
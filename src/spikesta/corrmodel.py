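"""Closed-form model of the correlated-population contribution to the EEG-STA.

The single-spike EEG correlate is parameterized as a Mexican hat

    g_STA(t) = (a_STA / b_STA) * (2 - 4 (t - t_STA)^2 / b_STA) * exp(-(t - t_STA)^2 / b_STA)

(a zero-mean triphasic function, the negative second derivative of a Gaussian),
with peak amplitude A_STA = 2 a_STA / b_STA and side-lobe separation
T_STA = sqrt(6 b_STA).  Pairwise spike synchrony is parameterized by a
Gaussian cross-correlogram excess

    f_xcf(t) = a_xcf * exp(-t^2 / b_xcf)

with peak coincidence rate A_xcf = a_xcf (coincidences/s per trigger spike)
and half-amplitude width T_xcf = 2 sqrt(b_xcf ln 2).  The expected EEG-STA
contribution of N neurons correlated with the trigger neuron is the
convolution N * (f_xcf ∗ g_STA), which is again a Mexican hat — broader and
much smaller — with

    A_cSTA = 2 sqrt(pi) N a_xcf a_STA sqrt(b_xcf b_STA) / (b_xcf + b_STA)^{3/2}
    T_cSTA = sqrt(6 (b_xcf + b_STA))

All internal time units are ms; coincidence rates are converted from 1/s at
the boundary so that amplitudes come out in nV when a_STA is in nV·ms².
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

_P2P_FACTOR = 1.0 + 2.0 * np.exp(-1.5)  # peak-to-peak / peak amplitude of a Mexican hat


@dataclass(frozen=True)
class MexicanHat:
    """Mexican-hat kernel; ``a`` in nV·ms², ``b`` in ms², ``t0`` in ms."""

    a: float
    b: float
    t0: float = 0.0

    def __post_init__(self) -> None:
        if self.b <= 0:
            raise ValueError("b must be positive")

    @property
    def amplitude(self) -> float:
        """Peak amplitude A = 2a/b (nV)."""
        return 2.0 * self.a / self.b

    @property
    def width(self) -> float:
        """Side-lobe separation T = sqrt(6 b) (ms)."""
        return float(np.sqrt(6.0 * self.b))

    @property
    def peak_to_peak(self) -> float:
        """Analytic peak-to-peak: A · (1 + 2 e^{-3/2})."""
        return self.amplitude * _P2P_FACTOR

    @classmethod
    def from_amplitude_width(cls, amplitude: float, width: float, t0: float = 0.0) -> "MexicanHat":
        """Build from peak amplitude (nV) and side-lobe separation (ms)."""
        if amplitude <= 0 or width <= 0:
            raise ValueError("amplitude and width must be positive")
        b = width**2 / 6.0
        return cls(a=amplitude * b / 2.0, b=b, t0=t0)

    def __call__(self, t_ms: np.ndarray) -> np.ndarray:
        tau2 = (np.asarray(t_ms, dtype=float) - self.t0) ** 2
        return (self.a / self.b) * (2.0 - 4.0 * tau2 / self.b) * np.exp(-tau2 / self.b)


@dataclass(frozen=True)
class GaussianCrossCorrelogram:
    """Gaussian cross-correlogram excess; ``a`` in coincidences/s, ``b`` in ms²."""

    a: float
    b: float

    def __post_init__(self) -> None:
        if self.a < 0:
            raise ValueError("a must be non-negative")
        if self.b <= 0:
            raise ValueError("b must be positive")

    @property
    def peak(self) -> float:
        """Peak excess coincidence rate A_xcf (1/s)."""
        return self.a

    @property
    def width(self) -> float:
        """Half-amplitude width T_xcf = 2 sqrt(b ln 2) (ms)."""
        return 2.0 * float(np.sqrt(self.b * np.log(2.0)))

    @classmethod
    def from_peak_width(cls, a_xcf: float, t_xcf: float) -> "GaussianCrossCorrelogram":
        if t_xcf <= 0:
            raise ValueError("width must be positive")
        if a_xcf < 0:
            raise ValueError("peak rate must be non-negative")
        return cls(a=a_xcf, b=(t_xcf / 2.0) ** 2 / np.log(2.0))

    def __call__(self, t_ms: np.ndarray) -> np.ndarray:
        """Excess coincidence rate (1/s) at lag t (ms)."""
        return self.a * np.exp(-np.asarray(t_ms, dtype=float) ** 2 / self.b)


def gaussian_from_peak_width(a_xcf: float, t_xcf: float) -> GaussianCrossCorrelogram:
    return GaussianCrossCorrelogram.from_peak_width(a_xcf, t_xcf)


def mexhat_from_amp_width(a_sta: float, t_sta_width: float, t0: float = 0.0) -> MexicanHat:
    return MexicanHat.from_amplitude_width(a_sta, t_sta_width, t0)


@dataclass(frozen=True)
class CorrelationSTA:
    """Predicted EEG-STA contribution of the correlated population."""

    n_neurons: float
    hat: MexicanHat  # closed-form waveform parameters

    @property
    def amplitude(self) -> float:
        """A_cSTA in nV."""
        return self.hat.amplitude

    @property
    def width(self) -> float:
        """T_cSTA in ms."""
        return self.hat.width

    def waveform(self, t_ms: np.ndarray) -> np.ndarray:
        return self.hat(t_ms)


def correlation_sta_closed_form(
    hat: MexicanHat, xcf: GaussianCrossCorrelogram, n_neurons: float
) -> CorrelationSTA:
    """Closed-form convolution N · (f_xcf ∗ g_STA).

    The result is a Mexican hat with b = b_xcf + b_STA and
    a = N · a_xcf[1/ms] · a_STA · sqrt(pi · b_xcf · b_STA / (b_xcf + b_STA)).
    """
    if n_neurons < 0:
        raise ValueError("n_neurons must be non-negative")
    a_xcf_per_ms = xcf.a / 1000.0  # coincidences/s -> 1/ms
    b_c = xcf.b + hat.b
    a_c = n_neurons * a_xcf_per_ms * hat.a * np.sqrt(np.pi * xcf.b * hat.b / b_c)
    return CorrelationSTA(n_neurons=n_neurons, hat=MexicanHat(a=a_c, b=b_c, t0=hat.t0))


def jitter_sweep(
    hat: MexicanHat, a_xcf: float, n_neurons: float, jitter_grid_ms: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """A_cSTA (nV) and T_cSTA (ms) as a function of the correlation jitter T_xcf."""
    jitter_grid_ms = np.asarray(jitter_grid_ms, dtype=float)
    if np.any(jitter_grid_ms <= 0):
        raise ValueError("jitter grid must be positive")
    amps = np.empty_like(jitter_grid_ms)
    widths = np.empty_like(jitter_grid_ms)
    for i, t_xcf in enumerate(jitter_grid_ms):
        c = correlation_sta_closed_form(
            hat, GaussianCrossCorrelogram.from_peak_width(a_xcf, t_xcf), n_neurons
        )
        amps[i] = c.amplitude
        widths[i] = c.width
    return amps, widths


def _mexhat_func(t, a, b, t0):
    tau2 = (t - t0) ** 2
    return (a / b) * (2.0 - 4.0 * tau2 / b) * np.exp(-tau2 / b)


def fit_mexican_hat(
    waveform: np.ndarray, lags_ms: np.ndarray, initial: MexicanHat | None = None
) -> MexicanHat:
    """Least-squares Mexican-hat fit to an STA waveform.

    The initial guess is derived from the waveform's extrema when not given:
    the peak lag seeds t0, the side-lobe separation seeds b, and the peak
    height seeds a.
    """
    y = np.asarray(waveform, dtype=float)
    t = np.asarray(lags_ms, dtype=float)
    if y.size != t.size:
        raise ValueError("waveform and lags must have equal length")
    if np.allclose(y, y[0]):
        raise ValueError("degenerate (constant) waveform cannot be fitted")
    if initial is None:
        i_pk = int(np.argmax(y))
        t0 = t[i_pk]
        amp = y[i_pk]
        left = y[:i_pk]
        right = y[i_pk:]
        t_left = t[: i_pk][np.argmin(left)] if left.size else t[0]
        t_right = t[i_pk:][np.argmin(right)] if right.size else t[-1]
        span = t[-1] - t[0]
        # cap the guess at span/3 (nothing wider is fittable on this window)
        width = float(np.clip(t_right - t_left, 2.0 * (t[1] - t[0]), span / 3.0))
        b0 = width**2 / 6.0
        initial = MexicanHat(a=max(amp, 1e-12) * b0 / 2.0, b=b0, t0=t0)
    span = t[-1] - t[0]
    if span < 3.0 * initial.width:
        raise ValueError("waveform must cover at least 3x the initial width")
    try:
        popt, _ = curve_fit(
            _mexhat_func,
            t,
            y,
            p0=[initial.a, initial.b, initial.t0],
            bounds=([-np.inf, 1e-12, t[0]], [np.inf, np.inf, t[-1]]),
            maxfev=20000,
        )
    except RuntimeError as err:
        resid = float(np.sqrt(np.mean((_mexhat_func(t, initial.a, initial.b, initial.t0) - y) ** 2)))
        raise RuntimeError(f"Mexican-hat fit did not converge (rms residual {resid:.3g})") from err
    return MexicanHat(a=float(popt[0]), b=float(popt[1]), t0=float(popt[2]))
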
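"""Spike detection, alignment, pruning, PSTHs and the late-window stationarity test.

Spike times are kept in milliseconds relative to trial (stimulus) onset and
aligned to the first negative peak of the extracellular waveform.  Spike
sorting proper (cluster cutting) is out of scope; detection here is plain
amplitude thresholding against a robust noise estimate, which suffices for
synthetic sessions containing one ground-truth cell per channel.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal, stats


@dataclass
class SpikeQC:
    isi_violation: bool = False
    waveform_inconsistency: bool = False


@dataclass
class SpikeTrain:
    """Per-trial spike times (ms) with optional aligned waveform snippets (µV)."""

    trials: list  # list of 1-D float arrays, strictly increasing within trial
    cell_id: str = "cell0"
    waveforms: np.ndarray | None = None  # (n_spikes, n_samples), rows in pooled order
    align_sample: int | None = None  # index of the first negative peak in each snippet
    qc: SpikeQC = field(default_factory=SpikeQC)
    trial_length_ms: float | None = None

    def __post_init__(self) -> None:
        self.trials = [np.asarray(t, dtype=float) for t in self.trials]
        for t in self.trials:
            if t.size > 1 and np.any(np.diff(t) <= 0):
                raise ValueError("spike times must be strictly increasing within a trial")

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    @property
    def n_spikes(self) -> int:
        return int(sum(t.size for t in self.trials))

    def pooled(self) -> np.ndarray:
        """All spike times concatenated across trials (trial order)."""
        if not self.trials:
            return np.empty(0)
        return np.concatenate(self.trials)


def robust_sd(x: np.ndarray) -> float:
    """Noise SD estimate via the median absolute deviation (MAD × 1.4826)."""
    x = np.asarray(x, dtype=float)
    return 1.4826 * float(np.median(np.abs(x - np.median(x))))


def detect_and_align(
    trace: np.ndarray,
    fs: float,
    threshold_sd: float = 2.0,
    snippet_ms: tuple[float, float] = (0.5, 1.0),
    min_peak_distance_ms: float = 0.3,
) -> SpikeTrain:
    """Threshold detection on one extracellular trace, aligned to the negative peak.

    The threshold is ``threshold_sd`` times the MAD-based SD of the trace;
    every local minimum below the negative threshold is a detected spike, with
    at most one detection per ``min_peak_distance_ms`` (the deepest wins, so a
    single spike's noisy trough is not double-counted).  Trains with any
    inter-spike interval < 1 ms are flagged ``qc.isi_violation``.  Assumes
    extracellular waveforms with a single dominant negative lobe; multi-lobed
    units would need cluster cutting, which is out of scope.
    """
    trace = np.asarray(trace, dtype=float)
    if not np.all(np.isfinite(trace)):
        raise ValueError("trace must be finite")
    if threshold_sd <= 0:
        raise ValueError("threshold_sd must be positive")
    x = trace - np.median(trace)
    thr = threshold_sd * robust_sd(trace)
    if thr == 0.0:  # noiseless trace: any strictly negative excursion counts
        scale = np.max(np.abs(x)) if x.size else 0.0
        thr = 1e-9 * scale
    if thr == 0.0:
        peaks_arr = np.empty(0, dtype=int)
    else:
        distance = max(1, int(round(min_peak_distance_ms * fs / 1000.0)))
        peaks_arr, _ = signal.find_peaks(-x, height=thr, distance=distance)
    times = peaks_arr / fs * 1000.0
    pre = int(round(snippet_ms[0] * fs / 1000.0))
    post = int(round(snippet_ms[1] * fs / 1000.0))
    wf = np.zeros((peaks_arr.size, pre + post + 1))
    for row, p in enumerate(peaks_arr):
        lo, hi = p - pre, p + post + 1
        src = trace[max(lo, 0) : min(hi, trace.size)]
        wf[row, max(lo, 0) - lo : max(lo, 0) - lo + src.size] = src
    qc = SpikeQC(isi_violation=bool(times.size > 1 and np.any(np.diff(times) < 1.0)))
    return SpikeTrain(
        trials=[times],
        waveforms=wf,
        align_sample=pre,
        qc=qc,
        trial_length_ms=trace.size / fs * 1000.0,
    )


def detect_session(unit_trials: np.ndarray, fs: float, **kwargs) -> SpikeTrain:
    """Run :func:`detect_and_align` on each trial of a (trials × samples) array."""
    trials, wfs = [], []
    qc = SpikeQC()
    align = None
    for row in np.asarray(unit_trials, dtype=float):
        st = detect_and_align(row, fs, **kwargs)
        trials.append(st.trials[0])
        wfs.append(st.waveforms)
        align = st.align_sample
        qc.isi_violation = qc.isi_violation or st.qc.isi_violation
    waveforms = np.vstack(wfs) if wfs else None
    n_samp = unit_trials.shape[1] if np.ndim(unit_trials) == 2 else None
    return SpikeTrain(
        trials=trials,
        waveforms=waveforms,
        align_sample=align,
        qc=qc,
        trial_length_ms=None if n_samp is None else n_samp / fs * 1000.0,
    )


def prune_min_separation(times: np.ndarray, min_isi: float) -> np.ndarray:
    """Remove every spike whose nearest *original* neighbour is closer than ``min_isi``.

    Both members of a close pair are removed, because a neighbour within the
    averaging window on either side contaminates the extracted segment.  The
    boundary is inclusive: spikes separated by exactly ``min_isi`` are kept.
    """
    times = np.asarray(times, dtype=float)
    if times.size <= 1:
        return times.copy()
    gaps = np.diff(times)
    prev_ok = np.concatenate(([True], gaps >= min_isi))
    next_ok = np.concatenate((gaps >= min_isi, [True]))
    return times[prev_ok & next_ok]


@dataclass
class PSTH:
    """Post-stimulus time histogram in spikes per trial per bin."""

    bin_edges: np.ndarray  # ms, length n_bins + 1
    rate: np.ndarray  # spikes / trial / bin
    n_trials: int

    def __post_init__(self) -> None:
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.rate = np.asarray(self.rate, dtype=float)
        if np.any(self.rate < 0):
            raise ValueError("PSTH rate must be non-negative")

    @property
    def bin_width(self) -> float:
        return float(self.bin_edges[1] - self.bin_edges[0])

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def rate_hz(self) -> np.ndarray:
        """Rate in spikes/s."""
        return self.rate / self.bin_width * 1000.0


def compute_psth(train: SpikeTrain, bin_width: float, window: tuple[float, float]) -> PSTH:
    """Trial-averaged spike counts in half-open bins [t, t + Δ) over ``window``."""
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    t0, t1 = window
    if t1 <= t0:
        raise ValueError("window must be increasing")
    if train.trial_length_ms is not None and (t0 < 0 or t1 > train.trial_length_ms + 1e-9):
        raise ValueError("window outside trial")
    n_bins = int(round((t1 - t0) / bin_width))
    edges = t0 + np.arange(n_bins + 1) * bin_width
    pooled = train.pooled()
    pooled = pooled[(pooled >= t0) & (pooled < edges[-1])]  # half-open bins
    counts, _ = np.histogram(pooled, bins=edges)
    return PSTH(bin_edges=edges, rate=counts / max(train.n_trials, 1), n_trials=train.n_trials)


def uniformity_test(pooled_times: np.ndarray, window: tuple[float, float]) -> tuple[float, float]:
    """One-sample Kolmogorov–Smirnov test of pooled spike times against uniformity.

    Used to verify stationarity of the late post-stimulus window: if the
    pooled spike times in the window are uniform, the rate carries no residual
    stimulus-locked trend.
    """
    t0, t1 = window
    if t1 <= t0:
        raise ValueError("empty window")
    times = np.asarray(pooled_times, dtype=float)
    times = times[(times >= t0) & (times <= t1)]
    if times.size < 2:
        raise ValueError("need at least 2 spikes in the window")
    res = stats.kstest(times, stats.uniform(loc=t0, scale=t1 - t0).cdf)
    return float(res.statistic), float(res.pvalue)
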
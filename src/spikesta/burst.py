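"""Prediction of the evoked high-frequency EEG burst from PSTHs and EEG-STAs.

Replacing every expected spike by the cell's single-spike EEG correlate and
averaging across cells amounts to convolving each per-cell PSTH (in expected
spikes per trial per 0.1 ms bin) with that cell's EEG-STA (nV per spike) and
taking the arithmetic mean across cells.  Because the PSTH is in spikes per
bin per trial, the convolution yields nV without extra factors, and the ratio
of recorded to predicted burst amplitudes is a dimensionless estimate of the
number of contributing neurons.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .spikes import PSTH


@dataclass
class BurstPrediction:
    time_ms: np.ndarray  # post-stimulus time of each PSTH bin centre
    mean: np.ndarray  # nV
    ci_lo: np.ndarray | None = None
    ci_hi: np.ndarray | None = None
    n_cells: int = 0


def _psth_arrays(psths) -> tuple[list[np.ndarray], np.ndarray, float]:
    rates, centers, width = [], None, None
    for p in psths:
        if isinstance(p, PSTH):
            rates.append(p.rate)
            centers, width = p.centers, p.bin_width
        else:
            rates.append(np.asarray(p, dtype=float))
    if centers is None:
        centers = np.arange(rates[0].size, dtype=float)
        width = 1.0
    return rates, centers, width


def predict_burst(psths, stas, bin_width_ms: float = 0.1, sta_dt_ms: float = 0.1) -> BurstPrediction:
    """Convolve per-cell PSTHs with per-cell STAs and average across cells.

    ``psths``: per-cell PSTH objects or arrays of expected spikes per trial per
    bin; ``stas``: per-cell STA waveforms (nV) on an odd-length lag grid whose
    sample interval equals the PSTH bin width (lag 0 at the centre, mapped onto
    the spike bin).
    """
    if len(psths) != len(stas) or len(psths) == 0:
        raise ValueError("need equally many (>=1) PSTHs and STAs")
    rates, centers, width = _psth_arrays(psths)
    if isinstance(psths[0], PSTH) and abs(width - bin_width_ms) > 1e-9:
        raise ValueError("PSTH bin width does not match bin_width_ms")
    if abs(bin_width_ms - sta_dt_ms) > 1e-9:
        raise ValueError("PSTH bin width must equal the STA sample interval")
    preds = []
    for rate, sta in zip(rates, stas):
        sta = np.asarray(sta, dtype=float)
        if sta.size % 2 != 1:
            raise ValueError("STA waveform must have odd length (symmetric lag grid)")
        preds.append(np.convolve(rate, sta, mode="same"))
    mean = np.mean(preds, axis=0)
    return BurstPrediction(time_ms=centers, mean=mean, n_cells=len(psths))


def burst_bootstrap_ci(
    cells: list[tuple[np.ndarray, np.ndarray]],
    n_boot: int = 500,
    rng: np.random.Generator | None = None,
    percentiles: tuple[float, float] = (5.0, 95.0),
    bin_width_ms: float = 0.1,
) -> BurstPrediction:
    """Bootstrap confidence band for the predicted burst.

    ``cells`` holds per-cell ``(psth_rate, segments)`` pairs, where
    ``segments`` are the spike-triggered EEG segments of that cell (the STA is
    their mean).  Each replicate draws cells with repetition to the original
    count; for every drawn cell the spikes (segments) are resampled with
    repetition (count conserved) to recompute its STA before convolution.  The
    band is the pointwise 5th/95th percentile over replicates, so it captures
    both EEG-STA estimation noise and the limited sampling of neurons.
    """
    if len(cells) < 1:
        raise ValueError("need at least one cell")
    rng = rng if rng is not None else np.random.default_rng()
    n_cells = len(cells)
    rates = [np.asarray(r, dtype=float) for r, _ in cells]
    segs = [np.asarray(s, dtype=float) for _, s in cells]
    point = predict_burst(
        rates, [s.mean(axis=0) for s in segs], bin_width_ms=bin_width_ms, sta_dt_ms=bin_width_ms
    )
    boots = np.empty((n_boot, point.mean.size))
    for b in range(n_boot):
        acc = np.zeros(point.mean.size)
        for ci in rng.integers(0, n_cells, size=n_cells):
            s = segs[ci]
            sta = s[rng.integers(0, s.shape[0], size=s.shape[0])].mean(axis=0)
            acc += np.convolve(rates[ci], sta, mode="same")
        boots[b] = acc / n_cells
    lo, hi = np.percentile(boots, percentiles, axis=0)
    return BurstPrediction(
        time_ms=point.time_ms, mean=point.mean, ci_lo=lo, ci_hi=hi, n_cells=n_cells
    )


def estimate_neuron_count(
    recorded: np.ndarray,
    predicted: np.ndarray,
    time_recorded_ms: np.ndarray,
    time_predicted_ms: np.ndarray,
    window_ms: tuple[float, float],
) -> float:
    """Peak-to-peak amplitude ratio of recorded to predicted burst within a window.

    A rough lower bound on the number of neurons generating the recorded
    burst, assuming the predicted single-population response scales linearly
    with neuron count.
    """
    t0, t1 = window_ms
    tr = np.asarray(time_recorded_ms, dtype=float)
    tp = np.asarray(time_predicted_ms, dtype=float)
    sel_r = (tr >= t0) & (tr <= t1)
    sel_p = (tp >= t0) & (tp <= t1)
    if not sel_r.any() or not sel_p.any():
        raise ValueError("window does not overlap both time axes")
    rec = np.asarray(recorded, dtype=float)[sel_r]
    pre = np.asarray(predicted, dtype=float)[sel_p]
    p2p_pred = pre.max() - pre.min()
    if p2p_pred == 0:
        raise ValueError("predicted burst has zero amplitude")
    return float((rec.max() - rec.min()) / p2p_pred)
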
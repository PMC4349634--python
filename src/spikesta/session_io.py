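"""Session container I/O.

A session is a directory holding ``meta.json`` (sampling rates, units, trial
count, seed), raw little-endian 32-bit float arrays ``eeg.f32`` / ``unit.f32``
(row-major, trials × samples), a ``spikes.csv`` table (cell_id, trial,
time_ms) and an optional ``truth.json`` with generator ground truth.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .corrmodel import MexicanHat
from .spikes import SpikeTrain
from .synthetic import SessionRecording

_META = "meta.json"
_EEG = "eeg.f32"
_UNIT = "unit.f32"
_SPIKES = "spikes.csv"
_TRUTH = "truth.json"


def _kernel_to_json(kernel) -> dict:
    if isinstance(kernel, MexicanHat):
        return {"type": "mexican_hat", "a": kernel.a, "b": kernel.b, "t0": kernel.t0}
    return {"type": "array", "values": np.asarray(kernel, dtype=float).tolist()}


def _kernel_from_json(d: dict):
    if d["type"] == "mexican_hat":
        return MexicanHat(a=d["a"], b=d["b"], t0=d["t0"])
    return np.asarray(d["values"], dtype=float)


def write_session(session: SessionRecording, path: str | Path) -> Path:
    """Write a session container; arrays as float32 little-endian raw files."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    meta = {
        "n_trials": int(session.n_trials),
        "n_samples_eeg": int(session.eeg.shape[1]),
        "n_samples_unit": int(session.unit.shape[1]),
        "fs_eeg": float(session.fs_eeg),
        "fs_unit": float(session.fs_unit),
        "stim_time_ms": float(session.stim_time_ms),
        "trial_length_ms": float(session.trial_length_ms),
        "units": {"eeg": "nV", "unit": "uV"},
        "seed": None if session.config is None else int(session.config.rng_seed),
    }
    (path / _META).write_text(json.dumps(meta, indent=1))
    session.eeg.astype("<f4").tofile(path / _EEG)
    session.unit.astype("<f4").tofile(path / _UNIT)
    rows = []
    for train in session.spikes:
        for trial, times in enumerate(train.trials):
            for t in times:
                rows.append((train.cell_id, trial, t))
    pd.DataFrame(rows, columns=["cell_id", "trial", "time_ms"]).to_csv(
        path / _SPIKES, index=False
    )
    if session.truth is not None:
        truth = dict(session.truth)
        truth["kernels"] = [_kernel_to_json(k) for k in truth.get("kernels", [])]
        (path / _TRUTH).write_text(json.dumps(truth, indent=1))
    return path


def read_spikes_csv(path: str | Path, n_trials: int, trial_length_ms: float) -> list[SpikeTrain]:
    """Read a (cell_id, trial, time_ms) table into per-cell spike trains."""
    df = pd.read_csv(path)
    trains = []
    for cell_id, group in df.groupby("cell_id", sort=True):
        trials = [np.empty(0)] * n_trials
        for trial, sub in group.groupby("trial"):
            trials[int(trial)] = np.sort(sub["time_ms"].to_numpy(dtype=float))
        trains.append(
            SpikeTrain(trials=trials, cell_id=str(cell_id), trial_length_ms=trial_length_ms)
        )
    return trains


def read_session(path: str | Path) -> SessionRecording:
    """Read a session container back; validates metadata/array consistency."""
    path = Path(path)
    meta_path = path / _META
    if not meta_path.exists():
        raise FileNotFoundError(f"missing session metadata file: {meta_path}")
    meta = json.loads(meta_path.read_text())
    n_trials = int(meta["n_trials"])
    shapes = {}
    for name, key in ((_EEG, "n_samples_eeg"), (_UNIT, "n_samples_unit")):
        fpath = path / name
        if not fpath.exists():
            raise FileNotFoundError(f"missing session array file: {fpath}")
        arr = np.fromfile(fpath, dtype="<f4")
        n_samp = int(meta[key])
        if arr.size != n_trials * n_samp:
            raise ValueError(
                f"{name}: {arr.size} values inconsistent with "
                f"{n_trials} trials x {n_samp} samples in {_META}"
            )
        shapes[name] = arr.reshape(n_trials, n_samp).astype(float)
    for key, fs_key in (("n_samples_eeg", "fs_eeg"), ("n_samples_unit", "fs_unit")):
        expected = int(round(meta["trial_length_ms"] * meta[fs_key] / 1000.0))
        if int(meta[key]) != expected:
            raise ValueError(
                f"metadata inconsistent: {key}={meta[key]} but trial_length_ms x "
                f"{fs_key} implies {expected}"
            )
    spikes = read_spikes_csv(path / _SPIKES, n_trials, meta["trial_length_ms"]) if (
        path / _SPIKES
    ).exists() else []
    truth = None
    if (path / _TRUTH).exists():
        truth = json.loads((path / _TRUTH).read_text())
        if "kernels" in truth:
            truth["kernels"] = [_kernel_from_json(k) for k in truth["kernels"]]
    return SessionRecording(
        eeg=shapes[_EEG],
        unit=shapes[_UNIT],
        fs_eeg=float(meta["fs_eeg"]),
        fs_unit=float(meta["fs_unit"]),
        stim_time_ms=float(meta["stim_time_ms"]),
        trial_length_ms=float(meta["trial_length_ms"]),
        spikes=spikes,
        truth=truth,
        config=None,
    )


def sta_to_csv(sta, path: str | Path) -> None:
    """Write an STA waveform as CSV (lag_ms, mean_nV, sem_nV)."""
    pd.DataFrame(
        {"lag_ms": sta.lags, "mean_nV": sta.mean, "sem_nV": sta.sem}
    ).to_csv(path, index=False)


def spectrum_to_csv(freqs, power, path: str | Path, p_values=None) -> None:
    """Write a spectrum as CSV (freq_hz, power[, p_value])."""
    data = {"freq_hz": freqs, "power": power}
    if p_values is not None:
        data["p_value"] = p_values
    pd.DataFrame(data).to_csv(path, index=False)
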
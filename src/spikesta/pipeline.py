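"""End-to-end analysis pipeline producing a machine-readable report.

Stages (in order): band-pass filter whole trials → prune close spikes →
upsample to 10 kHz → spike-triggered average → shift predictor → baseline
correction → confidence band and bootstrap peak test → spectral analysis →
evoked-burst prediction → closed-form correlation model → dipole forward
model.  Every stage draws from a per-purpose child stream of one session-level
seed, so a report is reproducible from (container, config, seed).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import yaml

from . import burst as burst_mod
from . import corrmodel, dipole, spectral
from . import sta as sta_mod
from .filtering import HIGHFREQ, WIDEBAND, FilterSpec, fourier_bandpass, upsample_linear
from .session_io import read_session
from .spikes import compute_psth, prune_min_separation, uniformity_test
from .synthetic import SessionConfig, simulate_session

#: band presets: (filter, STA half-window ms, minimum spike separation ms)
BAND_PRESETS = {
    "highfreq": (HIGHFREQ, 3.0, 6.0),
    "wideband": (WIDEBAND, 15.0, 30.0),
}

FS_ANALYSIS = 10000.0


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def load_config(config) -> dict:
    if isinstance(config, (str, Path)):
        with open(config) as fh:
            return yaml.safe_load(fh)
    return dict(config)


def _get_session(cfg: dict, seed: int):
    sess_cfg = cfg.get("session", {"simulate": {}})
    if "load" in sess_cfg:
        return read_session(sess_cfg["load"])
    overrides = dict(sess_cfg.get("simulate", {}))
    overrides.setdefault("rng_seed", seed)
    return simulate_session(SessionConfig(**overrides))


def _analyse_cell(eeg_up, train, half_window, min_sep, sta_opts, rng):
    pruned = [prune_min_separation(t, min_sep) for t in train.trials]
    segments, lags = sta_mod.extract_segments(eeg_up, FS_ANALYSIS, pruned, half_window)
    if segments.shape[0] == 0:
        raise ValueError(f"no retainable spikes for {train.cell_id}")
    sta = sta_mod.eeg_sta(segments, lags)
    predictor, shuffled = sta_mod.shift_predictor(
        eeg_up, FS_ANALYSIS, pruned, half_window,
        n_shuffles=sta_opts.get("n_shuffles", 100), rng=rng, return_segments=True,
    )
    corrected = sta_mod.baseline_correct(sta, predictor)
    band = sta_mod.confidence_band(shuffled, n_effective=segments.shape[0])
    window = tuple(sta_opts.get("peak_window", (-0.3, 0.5)))
    p_value = sta_mod.peak_bootstrap_test(
        segments, shuffled, lags, peak_window=window,
        n_boot=sta_opts.get("n_boot", 5000), rng=rng,
    )
    return {
        "pruned": pruned,
        "segments": segments,
        "shuffled": shuffled,
        "lags": lags,
        "sta": sta,
        "predictor": predictor,
        "corrected": corrected,
        "band": band,
        "p_value": p_value,
    }


def run_pipeline(config) -> dict:
    """Run the configured stages on a simulated or loaded session; returns the report."""
    cfg = load_config(config)
    seed = int(cfg.get("seed", 0))
    ss = np.random.SeedSequence(seed)
    rng_shuffle, rng_spec, rng_burst = (np.random.default_rng(s) for s in ss.spawn(3))

    band_name = cfg.get("band", "highfreq")
    if band_name not in BAND_PRESETS:
        raise ValueError(f"unknown band preset {band_name!r}; choose from {sorted(BAND_PRESETS)}")
    band_spec, half_window, min_sep = BAND_PRESETS[band_name]

    session = _get_session(cfg, seed)
    report: dict = {
        "seed": seed,
        "band": band_name,
        "session": {
            "n_trials": session.n_trials,
            "trial_length_ms": session.trial_length_ms,
            "fs_eeg": session.fs_eeg,
            "n_cells": len(session.spikes),
        },
        "config_echo": _jsonable({k: v for k, v in cfg.items() if k != "session"}),
    }

    eeg_f = fourier_bandpass(session.eeg, session.fs_eeg, band_spec)
    eeg_up = upsample_linear(eeg_f, session.fs_eeg, FS_ANALYSIS)

    sta_opts = cfg.get("sta", {})
    cells = []
    cell_results = []
    for train in session.spikes:
        res = _analyse_cell(eeg_up, train, half_window, min_sep, sta_opts, rng_shuffle)
        cell_results.append((train, res))
        cells.append(
            {
                "cell_id": train.cell_id,
                "n_spikes": train.n_spikes,
                "n_segments": res["segments"].shape[0],
                "p2p_nV": sta_mod.peak_to_peak(res["corrected"]),
                "predictor_p2p_nV": sta_mod.peak_to_peak(res["predictor"]),
                "p_value": res["p_value"],
            }
        )
    report["cells"] = cells

    # grand average pools spikes (segments) across cells
    all_segments = np.vstack([res["segments"] for _, res in cell_results])
    all_shuffled = np.vstack([res["shuffled"] for _, res in cell_results])
    lags = cell_results[0][1]["lags"]
    grand = sta_mod.eeg_sta(all_segments, lags)
    grand_pred_mean = np.mean(
        [res["predictor"].mean for _, res in cell_results], axis=0
    )
    grand_corrected_mean = grand.mean - grand_pred_mean
    band_lo, band_hi = sta_mod.confidence_band(
        all_shuffled, n_effective=all_segments.shape[0]
    )
    report["grand_average"] = {
        "n_segments": int(all_segments.shape[0]),
        "p2p_nV": float(grand_corrected_mean.max() - grand_corrected_mean.min()),
        "band_halfwidth_nV": float(np.mean((band_hi - band_lo) / 2.0)),
        "sem_at_extrema_nV": [
            float(grand.sem[int(np.argmax(grand_corrected_mean))]),
            float(grand.sem[int(np.argmin(grand_corrected_mean))]),
        ],
    }

    # late-window STA: stationary spikes, no baseline correction by contract
    late = tuple(cfg.get("late_window", (200.0, 290.0)))
    if session.trial_length_ms >= late[1]:
        late_spikes = []
        for i in range(session.n_trials):
            per_trial = [
                res["pruned"][i][(res["pruned"][i] >= late[0]) & (res["pruned"][i] <= late[1])]
                for _, res in cell_results
            ]
            late_spikes.append(np.sort(np.concatenate(per_trial)))
        late_seg, _ = sta_mod.extract_segments(eeg_up, FS_ANALYSIS, late_spikes, half_window)
        pooled_late = np.concatenate(
            [t[(t >= late[0]) & (t <= late[1])] for train, _ in cell_results for t in train.trials]
        )
        late_block = {"n_segments": int(late_seg.shape[0])}
        if late_seg.shape[0] >= 2:
            late_sta = sta_mod.eeg_sta(late_seg, lags)
            late_block["p2p_nV"] = sta_mod.peak_to_peak(late_sta)
            late_block["baseline_corrected"] = False
        if pooled_late.size >= 2:
            d_stat, p_uniform = uniformity_test(pooled_late, late)
            late_block["ks_d"] = d_stat
            late_block["ks_p"] = p_uniform
        report["late_window"] = late_block

    spec_cfg = cfg.get("spectral", {})
    if spec_cfg.get("enable", True):
        freqs, p_vals, obs = spectral.spectral_bootstrap_test(
            all_segments,
            all_shuffled,
            FS_ANALYSIS,
            n_boot=spec_cfg.get("n_boot", 500),
            rng=rng_spec,
        )
        hf = freqs >= 800.0
        report["spectral"] = {
            "freqs_hz": freqs,
            "p_values": p_vals,
            "observed_power": obs,
            "frac_significant_above_800Hz": float(np.mean(p_vals[hf] < 0.01)) if hf.any() else None,
        }

    burst_cfg = cfg.get("burst", {})
    if burst_cfg.get("enable", True) and band_name == "highfreq":
        window = tuple(burst_cfg.get("window_ms", (0.0, 50.0)))
        window = (window[0], min(window[1], session.trial_length_ms))
        bin_w = 0.1
        psths = []
        seg_list = []
        for train, res in cell_results:
            psth = compute_psth(train, bin_w, window)
            psths.append(psth)
            seg_list.append(res["segments"])
        stas = [s.mean(axis=0) for s in seg_list]
        pred = burst_mod.predict_burst(psths, stas, bin_width_ms=bin_w, sta_dt_ms=bin_w)
        ci = burst_mod.burst_bootstrap_ci(
            [(p.rate, s) for p, s in zip(psths, seg_list)],
            n_boot=burst_cfg.get("n_boot", 500),
            rng=rng_burst,
            bin_width_ms=bin_w,
        )
        # recorded burst: trial-averaged high-frequency EEG on the same grid
        t_up = np.arange(eeg_up.shape[1]) / FS_ANALYSIS * 1000.0
        recorded = eeg_up.mean(axis=0)
        ratio_window = tuple(burst_cfg.get("ratio_window_ms", (5.0, 20.0)))
        n_est = burst_mod.estimate_neuron_count(
            recorded, pred.mean, t_up, pred.time_ms, ratio_window
        )
        report["burst"] = {
            "n_cells": pred.n_cells,
            "time_ms": pred.time_ms,
            "predicted_nV": pred.mean,
            "ci_lo_nV": ci.ci_lo,
            "ci_hi_nV": ci.ci_hi,
            "neuron_count_estimate": n_est,
        }

    corr_cfg = cfg.get("correlation_model", {})
    a_xcf = corr_cfg.get("a_xcf", 0.008)
    t_xcf = corr_cfg.get("t_xcf_ms", 17.0)
    n_neurons = float(corr_cfg.get("n_neurons", 1e7))
    corr_block: dict = {"a_xcf_per_s": a_xcf, "t_xcf_ms": t_xcf, "n_neurons": n_neurons}
    hat = None
    if corr_cfg.get("fit_kernel", True):
        try:
            hat = corrmodel.fit_mexican_hat(grand_corrected_mean, lags)
            corr_block["fitted"] = {
                "A_STA_nV": hat.amplitude,
                "T_STA_ms": hat.width,
                "t_STA_ms": hat.t0,
            }
        except (ValueError, RuntimeError) as err:
            corr_block["fit_error"] = str(err)
    if hat is None or hat.amplitude <= 0:
        hat = corrmodel.MexicanHat.from_amplitude_width(
            corr_cfg.get("a_sta_nv", 60.0), corr_cfg.get("t_sta_ms", 0.45),
            corr_cfg.get("t0_ms", 0.05),
        )
    xcf = corrmodel.GaussianCrossCorrelogram.from_peak_width(a_xcf, t_xcf)
    csta = corrmodel.correlation_sta_closed_form(hat, xcf, n_neurons)
    corr_block["A_cSTA_nV"] = csta.amplitude
    corr_block["T_cSTA_ms"] = csta.width
    report["correlation_model"] = corr_block

    dip_cfg = cfg.get("dipole", {})
    q_lo = dip_cfg.get("q_lo", 0.78)
    q_hi = dip_cfg.get("q_hi", 2.97)
    common = dict(
        eta_ohm_m=dip_cfg.get("eta_ohm_m", 2.47),
        theta_rad=dip_cfg.get("theta_rad", 0.0),
        h_mm=dip_cfg.get("h_mm", getattr(session.config, "depth_mm", 2.18) if session.config else 2.18),
        d_mm=dip_cfg.get("d_mm", 10.0),
    )
    v_lo = dipole.dipole_potential(dipole.DipoleParams(q_nA_mm=q_lo, **common))
    v_hi = dipole.dipole_potential(dipole.DipoleParams(q_nA_mm=q_hi, **common))
    scalp = dipole.scalp_extrapolation(v_lo, v_hi)
    noise = getattr(session.config, "noise_sd_hf", 700.0) if session.config else 700.0
    report["dipole"] = {
        "r_mm": dipole.electrode_distance(common["h_mm"], common["d_mm"]),
        "V_lo_nV": v_lo,
        "V_hi_nV": v_hi,
        "V_lo_nV_trunc": float(np.trunc(v_lo)),
        "V_hi_nV_trunc": float(np.trunc(v_hi)),
        "scalp_lo_nV": scalp[0],
        "scalp_hi_nV": scalp[1],
        "snr_epidural_db": dipole.snr_db(report["grand_average"]["p2p_nV"], noise)
        if report["grand_average"]["p2p_nV"] > 0
        else None,
        "snr_scalp_db": dipole.snr_db(scalp[1], dipole.noise_over_band(10.0, 1000.0)),
    }

    # desynchronization check on the wideband EEG with the evoked average removed
    residual = session.eeg - session.eeg.mean(axis=0)
    report["desync_ratio"] = spectral.desync_ratio(residual.ravel(), session.fs_eeg)

    return _jsonable(report)


def write_report(report: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(report, indent=1))
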
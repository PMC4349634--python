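"""Dipole-approximation forward model of a spike's epidural EEG potential.

A cortical action potential is modelled as a current dipole of moment Q at
depth h below the dura; the bipolar epidural montage (electrode separation d)
sees the source at distance r = sqrt(h² + d²/4).  In a homogeneous medium of
resistivity η the potential along the dipole axis is

    V = boundary_factor · (η / 4π) · Q cosθ / r²

where the boundary factor (default 4) accounts for the resistivity boundary at
the dura and the bipolar montage.  Computing in Ω·mm, nA·mm and mm yields nV
without additional constants.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


def electrode_distance(h_mm: float, d_mm: float) -> float:
    """Source-electrode distance r = sqrt(h² + d²/4) for a bipolar montage."""
    if h_mm < 0 or d_mm < 0:
        raise ValueError("depth and separation must be non-negative")
    return float(np.sqrt(h_mm**2 + d_mm**2 / 4.0))


@dataclass(frozen=True)
class DipoleParams:
    """Dipole moment Q (nA·mm), resistivity η (Ω·m), geometry (mm, rad)."""

    q_nA_mm: float
    eta_ohm_m: float = 2.47
    theta_rad: float = 0.0
    h_mm: float = 2.18
    d_mm: float = 10.0
    boundary_factor: float = 4.0

    def __post_init__(self) -> None:
        if self.q_nA_mm < 0:
            raise ValueError("Q must be non-negative")
        if self.eta_ohm_m <= 0:
            raise ValueError("resistivity must be positive")
        if self.boundary_factor <= 0:
            raise ValueError("boundary factor must be positive")

    @property
    def r_mm(self) -> float:
        return electrode_distance(self.h_mm, self.d_mm)


def dipole_potential(p: DipoleParams) -> float:
    """Epidural potential in nV of a dipole seen at distance r (inverse-square)."""
    r = p.r_mm
    if r == 0:
        raise ValueError("source-electrode distance must be positive")
    eta_ohm_mm = p.eta_ohm_m * 1000.0
    return float(p.boundary_factor * eta_ohm_mm / (4.0 * np.pi) * p.q_nA_mm * np.cos(p.theta_rad) / r**2)


def scalp_extrapolation(
    v_lo_nv: float,
    v_hi_nv: float,
    burst_attenuation: float = 10.0,
    neuron_ratio: float = 10.0,
) -> tuple[float, float]:
    """Extrapolate epidural single-spike bounds to the human scalp.

    The scalp burst is ~10× smaller than the epidural one and the responding
    human population ~10× larger, so each bound is divided by their product
    (default 100).
    """
    if burst_attenuation <= 0 or neuron_ratio <= 0:
        raise ValueError("attenuation factors must be positive")
    f = burst_attenuation * neuron_ratio
    return v_lo_nv / f, v_hi_nv / f


def snr_db(signal_amp: float, noise_amp: float) -> float:
    """10·log10(signal/noise) in dB (amplitude convention used throughout)."""
    if signal_amp <= 0 or noise_amp <= 0:
        raise ValueError("amplitudes must be positive")
    return float(10.0 * np.log10(signal_amp / noise_amp))


def noise_over_band(density_nv_per_sqrt_hz: float = 10.0, bandwidth_hz: float = 1000.0) -> float:
    """Total noise amplitude (nV) of a flat spectral density over a band."""
    if density_nv_per_sqrt_hz < 0 or bandwidth_hz < 0:
        raise ValueError("density and bandwidth must be non-negative")
    return float(density_nv_per_sqrt_hz * np.sqrt(bandwidth_hz))
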
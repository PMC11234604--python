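"""Model-free ("conventional") estimates of the mechanical parameters.

These are the textbook bedside estimators the model-based estimates are
compared against:

* total peripheral resistance   R_sys ≈ MAP / CO
* total arterial compliance     C_ao ≈ SV / PP
* maximal ventricular elastance E_max ≈ ESP / ESV ≈ P_brachial,sys / ESV
  (the ESPVR volume intercept V_d is neglected, making this load dependent)

plus the waveform calibration that produces the pressure trace MAP is
averaged from, and small error-propagation helpers for measurement
uncertainty.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .personalization import MeasurementSet, bsa


@dataclass
class ConventionalEstimates:
    """Conventional parameter estimates for one participant-day.

    ``*_indexed`` values are divided by body surface area (per-m² units),
    matching the indexing convention used for model-based estimates.
    """

    R_sys_conv: float  # mmHg s/mL
    C_ao_conv: float  # mL/mmHg
    E_max_conv: float  # mmHg/mL
    R_sys_conv_indexed: float
    C_ao_conv_indexed: float
    E_max_conv_indexed: float
    modality: str
    day: str
    participant_id: str


def calibrate_waveform(raw: np.ndarray, P_sys_m: float, P_dia_m: float) -> np.ndarray:
    """Affine rescale of an (arbitrary-unit) pressure trace so its extrema
    match the measured brachial systolic/diastolic pressures."""
    raw = np.asarray(raw, dtype=float)
    lo, hi = float(np.min(raw)), float(np.max(raw))
    if hi - lo <= 0:
        raise ValueError("raw trace is constant; cannot calibrate a zero-range waveform")
    return P_dia_m + (raw - lo) * (P_sys_m - P_dia_m) / (hi - lo)


def mean_arterial_pressure(p: np.ndarray, t: np.ndarray) -> float:
    """Time-weighted (trapezoidal) mean of a calibrated pressure trace over one cycle."""
    p = np.asarray(p, dtype=float)
    t = np.asarray(t, dtype=float)
    if len(p) < 2 or len(t) != len(p):
        raise ValueError("need at least two samples with matching time stamps")
    return float(np.trapezoid(p, t) / (t[-1] - t[0]))


def conv_rsys(MAP: float, CO: float) -> float:
    """Total peripheral resistance MAP/CO (mmHg·s/mL); CO in mL/s."""
    if CO <= 0:
        raise ValueError("CO must be positive")
    return MAP / CO


def conv_cao(SV: float, PP: float) -> float:
    """Total arterial compliance SV/PP (mL/mmHg); PP = brachial SBP − DBP."""
    if PP <= 0:
        raise ValueError("pulse pressure must be positive")
    if SV <= 0:
        raise ValueError("SV must be positive")
    return SV / PP


def conv_emax(P_br_sys: float, ESV: float) -> float:
    """Maximal elastance P_brachial,sys/ESV (mmHg/mL), neglecting V_d."""
    if ESV <= 0:
        raise ValueError("ESV must be positive")
    return P_br_sys / ESV


def propagated_sem(sd_single: float, n: int) -> float:
    """Uncertainty (SD) of an n-measurement arithmetic mean: sd/sqrt(n).

    Assumes independent measurements with identical SD (Gauss error
    propagation through the mean)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if sd_single < 0:
        raise ValueError("sd must be non-negative")
    return sd_single / math.sqrt(n)


def relative_uncertainty(delta: float, mean: float) -> float:
    """Uncertainty as a percentage of a typical value: 100·delta/mean."""
    if mean <= 0:
        raise ValueError("mean must be positive")
    return 100.0 * delta / mean


def conventional_estimates(m: MeasurementSet) -> ConventionalEstimates:
    """All three conventional estimates (raw and BSA-indexed) for one
    measurement set.  MAP is the trapezoidal average of the calibrated
    pressure waveform; CO = SV/T with the measured stroke volume."""
    map_ = mean_arterial_pressure(m.waveform.P_ao, m.waveform.t)
    co = m.SV_m / m.T
    pp = m.P_sys_m - m.P_dia_m
    r = conv_rsys(map_, co)
    c = conv_cao(m.SV_m, pp)
    e = conv_emax(m.P_sys_m, m.ESV_m)
    b = bsa(m.height, m.weight)
    return ConventionalEstimates(
        R_sys_conv=r,
        C_ao_conv=c,
        E_max_conv=e,
        R_sys_conv_indexed=r / b,
        C_ao_conv_indexed=c / b,
        E_max_conv_indexed=e / b,
        modality=m.modality,
        day=m.day,
        participant_id=m.participant_id,
    )
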
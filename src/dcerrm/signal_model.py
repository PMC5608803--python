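"""FLASH signal model, PD-reference T1 estimation, and Rayleigh-corrected SNR.

The spoiled gradient-echo steady-state signal is

    S = M0_eff * sin(theta) * (1 - E1) / (1 - E1 * cos(theta)),  E1 = exp(-TR/T1),

where ``M0_eff`` absorbs proton density, coil sensitivity and TE decay.
Pairing one long-TR, small-flip-angle (PD-weighted) reference scan with the
short-TR dynamic scan allows the per-frame inversion

    T1(t) = -TR_DCE / ln[ (S_REF sin(th_DCE) - S_DCE(t) sin(th_REF))
                          / (S_REF sin(th_DCE) - S_DCE(t) sin(th_REF) cos(th_DCE)) ],

valid whenever the log argument lies in (0, 1).  The inversion assumes the
reference signal is proportional to M0_eff * sin(th_REF) (i.e. fully relaxed);
with a finite reference TR the estimate carries a deterministic, monotone
bias which the synthetic generator can reproduce (reference_mode="protocol").

SNR is defined on magnitude images as mu_signal / sigma_corr with
sigma_corr = sigma_Rayleigh / 0.655: the standard deviation measured in a
signal-free background region follows a Rayleigh distribution whose spread
understates the per-channel Gaussian noise by sqrt((4 - pi)/2) ~ 0.655.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .protocol import AcquisitionProtocol
from .series import DynamicSeries

__all__ = [
    "RAYLEIGH_CORRECTION",
    "RelaxationState",
    "flash_signal",
    "estimate_t1",
    "r1_from_t1",
    "estimate_r10",
    "snr",
]

#: std of a Rayleigh variate relative to the per-channel Gaussian sigma,
#: sqrt((4 - pi) / 2) rounded to the conventional three digits.
RAYLEIGH_CORRECTION = 0.655


@dataclass(frozen=True)
class RelaxationState:
    """Pre-contrast (native) longitudinal relaxation rate R10 in s^-1."""

    r10: float

    def __post_init__(self) -> None:
        if not self.r10 > 0:
            raise ValueError("r10 must be positive")


def flash_signal(m0_eff, t1_ms, tr_ms: float, fa_deg: float):
    """Steady-state spoiled gradient-echo signal.

    Accepts scalars or arrays for ``m0_eff`` and ``t1_ms``.  ``fa_deg`` = 0 is
    accepted as the degenerate no-excitation limit (zero signal); angles
    outside [0, 90] and non-positive T1/TR are domain errors.
    """
    t1 = np.asarray(t1_ms, dtype=float)
    if tr_ms <= 0:
        raise ValueError("tr_ms must be positive")
    if np.any(t1 <= 0):
        raise ValueError("t1_ms must be positive")
    if not (0 <= fa_deg <= 90):
        raise ValueError("fa_deg must lie in [0, 90] degrees")
    fa = np.deg2rad(fa_deg)
    e1 = np.exp(-tr_ms / t1)
    s = np.asarray(m0_eff, dtype=float) * np.sin(fa) * (1.0 - e1) / (1.0 - e1 * np.cos(fa))
    if s.ndim == 0:
        return float(s)
    return s


def estimate_t1(s_ref: float, s_dce: DynamicSeries,
                protocol: AcquisitionProtocol) -> DynamicSeries:
    """Per-frame T1 (ms) from the PD-reference inversion.

    Frames where the log argument falls outside the open interval (0, 1) —
    zero or negative signal differences, or signal consistent with infinite
    T1 — are marked invalid rather than returned as numbers.  An all-invalid
    input yields an all-invalid output, not an exception.
    """
    if not s_ref > 0:
        raise ValueError("s_ref must be positive")
    if np.any(s_dce.values[s_dce.valid] < 0):
        raise ValueError("dynamic signal values must be non-negative")

    th_ref = np.deg2rad(protocol.fa_ref_deg)
    th_dce = np.deg2rad(protocol.fa_dce_deg)
    s = s_dce.values
    num = s_ref * np.sin(th_dce) - s * np.sin(th_ref)
    den = s_ref * np.sin(th_dce) - s * np.sin(th_ref) * np.cos(th_dce)

    with np.errstate(divide="ignore", invalid="ignore"):
        arg = num / den
        valid = s_dce.valid & np.isfinite(arg) & (arg > 0) & (arg < 1)
        t1 = np.where(valid, -protocol.tr_dce_ms / np.log(np.where(valid, arg, 0.5)), np.nan)
    return s_dce.with_values(t1, unit="ms", valid=valid)


def r1_from_t1(t1_series: DynamicSeries) -> DynamicSeries:
    """Valuewise R1 = 1/T1 with ms -> s conversion; validity propagates."""
    t1 = t1_series.values
    valid = t1_series.valid & np.isfinite(t1) & (t1 > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        r1 = np.where(valid, 1000.0 / t1, np.nan)
    return t1_series.with_values(r1, unit="s^-1", valid=valid)


def estimate_r10(r1_series: DynamicSeries, n_baseline: int) -> RelaxationState | None:
    """Native relaxation rate: mean of valid R1 over the first baseline frames.

    Returns ``None`` (a flagged failure, handled by the caller) when no
    baseline frame is valid.  The mean is taken in rate space, matching the
    rate-space kinetic model downstream.
    """
    if not 1 <= n_baseline <= len(r1_series):
        raise ValueError("n_baseline out of range for this series")
    vals = r1_series.values[:n_baseline]
    mask = r1_series.valid[:n_baseline]
    if not mask.any():
        return None
    return RelaxationState(r10=float(vals[mask].mean()))


def snr(mu_signal: float, sigma_rayleigh: float) -> float:
    """Magnitude-image SNR with the Rayleigh background correction.

    ``sigma_rayleigh`` is the standard deviation measured in a signal-free
    background region; dividing by 0.655 converts it to the per-channel
    Gaussian sigma before forming mu/sigma.
    """
    if not sigma_rayleigh > 0:
        raise ValueError("sigma_rayleigh must be positive")
    return float(mu_signal) / (float(sigma_rayleigh) / RAYLEIGH_CORRECTION)
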
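"""Arterial input function models for the synthetic-data generator.

The reference-region analysis itself never measures or assumes an AIF — that
is its point — but the generator and the standard-Tofts validation oracle
need a plasma concentration curve.  Two literature forms are provided:

* ``biexponential`` — Weinmann-type decay, Cp(t') = D (a1 e^{-m1 t'} +
  a2 e^{-m2 t'}) with amplitudes in kg/L and rates in min^-1, scaled by the
  injected dose D (mmol/kg); zero before the bolus arrival.
* ``parker`` — the population mixed-Gaussian-plus-sigmoid form, scaled
  linearly from its nominal 0.1 mmol/kg dose.

An optional exponential dispersion kernel (time constant in seconds)
emulates bolus broadening from slow manual tail-vein administration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .series import DynamicSeries

__all__ = ["AifSpec", "make_aif"]

# Weinmann biexponential defaults (kg/L and min^-1)
_BIEXP_DEFAULTS = {"a1": 3.99, "a2": 4.78, "m1": 0.144, "m2": 0.0111}

# Parker population parameters (minutes; nominal dose 0.1 mmol/kg)
_PARKER = {
    "A1": 0.809, "A2": 0.330,          # mmol min
    "T1": 0.17046, "T2": 0.365,        # min
    "sigma1": 0.0563, "sigma2": 0.132, # min
    "alpha": 1.050, "beta": 0.1685,    # mmol, min^-1
    "s": 38.078, "tau": 0.483,         # min^-1, min
}
_PARKER_NOMINAL_DOSE = 0.1


@dataclass(frozen=True)
class AifSpec:
    """Configuration of a synthetic arterial input function.

    ``dose`` is the injected contrast dose in mmol/kg (0.2 = double dose);
    ``arrival_time`` (s) is when the bolus reaches the tissue feeding vessels;
    ``dispersion`` (s) is the time constant of an optional exponential
    broadening kernel (0 disables it).  ``params`` overrides individual model
    parameters.
    """

    model: str = "biexponential"
    dose: float = 0.2
    arrival_time: float = 39.96
    dispersion: float = 0.0
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.model not in ("biexponential", "parker"):
            raise ValueError(f"unknown AIF model {self.model!r}")
        if self.dose < 0:
            raise ValueError("dose must be non-negative")
        if self.arrival_time < 0:
            raise ValueError("arrival_time must be non-negative")
        if self.dispersion < 0:
            raise ValueError("dispersion must be non-negative")
        bad = set(self.params) - (set(_BIEXP_DEFAULTS) | set(_PARKER))
        if bad:
            raise ValueError(f"unknown AIF parameters: {sorted(bad)}")
        for v in self.params.values():
            if v < 0:
                raise ValueError("AIF parameters must be non-negative")


def _biexp(t_min: np.ndarray, spec: AifSpec) -> np.ndarray:
    p = {**_BIEXP_DEFAULTS, **{k: v for k, v in spec.params.items() if k in _BIEXP_DEFAULTS}}
    return spec.dose * (p["a1"] * np.exp(-p["m1"] * t_min)
                        + p["a2"] * np.exp(-p["m2"] * t_min))


def _parker(t_min: np.ndarray, spec: AifSpec) -> np.ndarray:
    p = {**_PARKER, **{k: v for k, v in spec.params.items() if k in _PARKER}}
    gauss = sum(
        p[f"A{n}"] / (p[f"sigma{n}"] * np.sqrt(2 * np.pi))
        * np.exp(-((t_min - p[f"T{n}"]) ** 2) / (2 * p[f"sigma{n}"] ** 2))
        for n in (1, 2)
    )
    sigmoid = p["alpha"] * np.exp(-p["beta"] * t_min) / (1 + np.exp(-p["s"] * (t_min - p["tau"])))
    return (spec.dose / _PARKER_NOMINAL_DOSE) * (gauss + sigmoid)


def _evaluate(times_s: np.ndarray, spec: AifSpec) -> np.ndarray:
    tp = (times_s - spec.arrival_time) / 60.0  # post-arrival time, minutes
    form = _biexp if spec.model == "biexponential" else _parker
    with np.errstate(under="ignore"):
        cp = np.where(tp >= 0, form(np.clip(tp, 0, None), spec), 0.0)
    return cp


def make_aif(spec: AifSpec, times, time_unit: str = "s") -> DynamicSeries:
    """Plasma concentration (mM) sampled on ``times``.

    With a nonzero dispersion the analytic form is convolved with a
    normalised exponential kernel on a fine internal grid (50 ms) before
    resampling, so the output grid spacing does not limit the broadening.
    """
    times = np.asarray(times, dtype=float)
    times_s = times * 60.0 if time_unit == "min" else times
    if spec.dispersion > 0:
        dt = 0.05
        fine = np.arange(0.0, float(times_s.max()) + dt, dt)
        cp_fine = _evaluate(fine, spec)
        kern_t = np.arange(0.0, 8 * spec.dispersion + dt, dt)
        kern = np.exp(-kern_t / spec.dispersion)
        kern /= kern.sum()
        cp_fine = np.convolve(cp_fine, kern)[: fine.size]
        cp = np.interp(times_s, fine, cp_fine)
    else:
        cp = _evaluate(times_s, spec)
    return DynamicSeries(times=times, values=cp, unit="mM", time_unit=time_unit)
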
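# dcerrm

Reference-region pharmacokinetic analysis of dynamic contrast-enhanced MRI
(DCE-MRI), built for longitudinal small-animal studies — such as tracking
microvessel proliferation in an injured growth plate (physis) — where no
usable artery lies in the field of view.

## The problem and the model

DCE-MRI estimates microvascular function by following a gadolinium bolus
through tissue.  The standard Tofts model

    Ct(T) = Ktrans · ∫₀ᵀ Cp(t) · e^(−(Ktrans/ve)(T−t)) dt

needs the arterial plasma concentration Cp(t) (the arterial input function,
AIF), which small fields of view often cannot provide.  The **reference
region model (RRM)** eliminates Cp by writing the Tofts model for both the
tissue of interest (TOI) and a reference tissue (RR) — skeletal muscle with
fixed literature kinetics K^trans,RR = 0.045 min⁻¹, v_e,RR = 0.08 — and
relating their longitudinal relaxation-rate curves directly:

    R1,TOI(T) = R·(R1,RR(T) − R10,RR)
              + R·[K^trans,RR/v_e,RR − K^trans,TOI/v_e,TOI]
                  · ∫₀ᵀ (R1,RR(t) − R10,RR) · e^(−(K^trans,TOI/v_e,TOI)(T−t)) dt
              + R10,TOI,        R = K^trans,TOI / K^trans,RR.

R1(t) = 1/T1(t) is mapped per frame from a short-TR dynamic FLASH scan and a
single long-TR, small-flip-angle PD-weighted reference scan:

    T1(t) = −TR_DCE / ln[ (S_REF·sin θ_DCE − S_DCE(t)·sin θ_REF)
                          / (S_REF·sin θ_DCE − S_DCE(t)·sin θ_REF·cos θ_DCE) ].

The package provides this full chain (T1 mapping → R1 curves → bounded
two-parameter least-squares RRM fit), Rayleigh-corrected SNR
(SNR = μ_signal / (σ_Rayleigh / 0.655)), a digital phantom / longitudinal
cohort generator with Rician noise, Bonferroni-adjusted Welch day-pair
statistics, and an AIF-based Tofts fitter used purely as a validation
oracle.

## Worked example

`examples/02_reference_region_fit.py` simulates muscle and lesion curves
from a shared bolus and recovers the lesion kinetics without using it:

```
true lesion kinetics : Ktrans = 0.2000 min^-1, ve = 0.3000
reference-region fit : Ktrans = 0.2000 min^-1, ve = 0.3000  (ratio R = 4.445, RMS misfit 1.38e-04 s^-1)
AIF-based Tofts fit  : Ktrans = 0.2000 min^-1, ve = 0.3000
```

The reference-region estimate matches both the implanted truth and the
oracle that was given the true plasma curve; `ratio R` is the fitted
K^trans,TOI expressed in units of the muscle K^trans,RR.
`examples/04_cohort_statistics.py` runs the whole longitudinal design
(5 animals × days 1–82) and reports which day pairs differ after Bonferroni
adjustment — with the default generator trajectory the day-42 peak is
flagged at p < 0.01 against day 14, while ve shows no significant pair.
The other examples cover T1-map bias (`01`) and the volumetric phantom
pipeline with SNR measurement (`03`).

A thin CLI mirrors the library for shell use:
`dcerrm simulate | t1map | fit | snr | cohort-stats` (see `--help`).

## Layout

- `src/dcerrm/signal_model.py` — FLASH model, PD-reference T1 inversion, SNR
- `src/dcerrm/kinetics.py` — Tofts and RRM forward models, both fitters
- `src/dcerrm/aif.py`, `src/dcerrm/phantom.py` — synthetic bolus, phantoms, cohorts
- `src/dcerrm/pipeline.py` — volumetric pipeline and longitudinal statistics
- `src/dcerrm/cli.py` — command-line interface
- `docs/methods.md` — model assumptions, numerical choices, limitations
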
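"""Volumetric phantom -> full pipeline -> parameter maps and SNR.

Generates a noisy digital phantom (muscle reference block + lesion block on
a background of pure Rician noise, calibrated to baseline SNR 80), runs the
voxelwise reference-region pipeline and measures the Rayleigh-corrected SNR
the way it is done on real magnitude images.
"""

import numpy as np

from dcerrm import PhantomSpec, TissueKinetics, run_fit, simulate_phantom, snr

spec = PhantomSpec(shape=(16, 16, 2), kinetics_toi=TissueKinetics(0.2, 0.3),
                   target_snr=80.0, seed=42)
ds = simulate_phantom(spec)

# SNR measurement: tissue baseline mean vs Rayleigh background std
baseline = ds.dynamic[ds.mask == 1][:, : spec.protocol.n_baseline]
sigma_rayleigh = float(ds.dynamic[ds.mask == 0].std(ddof=1))
measured_snr = snr(float(baseline.mean()), sigma_rayleigh)
print(f"target SNR 80 -> measured {measured_snr:.1f} "
      f"(per-channel sigma used: {ds.sigma:.3f})")

out = run_fit(ds.reference, ds.dynamic, ds.mask, ds.protocol, mode="voxelwise")
s = out.summary
print(f"lesion ROI ({s.n_voxels} voxels, {s.frac_flagged:.0%} flagged):")
print(f"  Ktrans median [IQR] = {s.ktrans_median:.4f} "
      f"[{s.ktrans_q25:.4f}, {s.ktrans_q75:.4f}] min^-1   (truth 0.2)")
print(f"  ve     median [IQR] = {s.ve_median:.4f} "
      f"[{s.ve_q25:.4f}, {s.ve_q75:.4f}]          (truth 0.3)")
print(f"parameter maps: {sorted(out.maps)} on grid {out.maps['ktrans'].shape}")
print(f"finite Ktrans voxels: {int(np.isfinite(out.maps['ktrans']).sum())}")
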
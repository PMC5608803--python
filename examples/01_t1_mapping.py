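"""PD-reference T1 mapping: forward FLASH signal and its per-frame inversion.

Simulates the dynamic spoiled gradient-echo signal of tissues with known T1
together with the PD-weighted reference scan, then inverts the pair back to
T1.  With an idealised (fully relaxed) reference the inversion is exact; the
actual TR = 100 ms reference scan leaves a small deterministic bias.
"""

import numpy as np

from dcerrm import AcquisitionProtocol, DynamicSeries, estimate_t1, flash_signal

protocol = AcquisitionProtocol()   # TR_ref 100 ms / 5 deg, TR_dce 8.09 ms / 30 deg
m0 = 1000.0

print("true T1 (ms)   ideal-ref estimate   TR=100ms-ref estimate")
for t1_true in (200.0, 500.0, 1000.0, 2000.0, 3000.0):
    s_dyn = flash_signal(m0, t1_true, protocol.tr_dce_ms, protocol.fa_dce_deg)
    series = DynamicSeries(times=np.array([0.0]), values=np.array([s_dyn]))

    ideal_ref = m0 * np.sin(np.deg2rad(protocol.fa_ref_deg))
    protocol_ref = flash_signal(m0, t1_true, protocol.tr_ref_ms, protocol.fa_ref_deg)

    est_ideal = estimate_t1(ideal_ref, series, protocol).values[0]
    est_real = estimate_t1(protocol_ref, series, protocol).values[0]
    print(f"{t1_true:9.0f}      {est_ideal:12.3f}        {est_real:12.3f}")

print("\nThe ideal-reference column reproduces the true T1 to machine")
print("precision; the finite-TR reference underestimates long T1 because the")
print("PD scan is not fully relaxed — a monotone bias that cancels between")
print("tissues in the reference-region analysis.")
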
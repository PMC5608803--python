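"""Longitudinal cohort: simulate 5 animals x 7 days and test day differences.

The generator implants a lesion Ktrans trajectory that is low on day 1,
rises from day 3, is elevated by day 7, peaks on day 42 and falls by day 82,
with log-normal between-animal spread and noise at baseline SNR 80.  Every
animal-day curve pair is fitted with the reference-region model and all day
pairs are compared with Welch tests under Bonferroni adjustment.
"""

from dcerrm import CohortSpec, analyze_cohort, cohort_report, simulate_cohort

cohort = simulate_cohort(CohortSpec(seed=7))
table = analyze_cohort(cohort)

print("per-day median of fitted Ktrans (min^-1) vs implanted day means:")
day_medians = table.groupby("day")[["ktrans_median", "ktrans_true_min^-1"]].median()
print(day_medians.rename(columns={"ktrans_median": "fitted",
                                  "ktrans_true_min^-1": "implanted"}).round(4))

report = cohort_report(table[table["usable"]])
kt = report["ktrans_median"]
sig = kt[kt["tier"] != "none"]
print(f"\nKtrans: {len(kt)} day pairs tested, {len(sig)} significant after "
      f"Bonferroni:")
print(sig.to_string(index=False))
ve = report["ve_median"]
print(f"\nve: {len(ve)} day pairs tested, "
      f"{(ve['tier'] != 'none').sum()} significant — ve carries no "
      f"longitudinal signal in this design.")
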
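"""Simulate and analyze a paired retinal-vein-occlusion cohort.

Generates a 20-animal cohort with stochastic per-animal saturations (temporal
vein occluded between baseline and one hour; nasal vessels as internal
controls), runs the full detection/OD/unmixing pipeline on every frame, then
summarizes arms and runs paired two-tailed t-tests. The occluded arms show the
induced drops (vein ~7.4 points, artery ~4.5) at very small p; the control
arms do not.
"""

from oximap import analyze_cohort, make_rvo_cohort, run_paired_study, rvo_baseline_cohort
from oximap.study_stats import summarize_arms

spec = rvo_baseline_cohort(n_animals=20, noise_sigma=0.01, seed=42)
cohort = make_rvo_cohort(spec)
measurements = analyze_cohort(cohort)
print(f"analyzed {len(cohort.scenes)} frames -> {len(measurements)} vessel measurements")

summary = summarize_arms(measurements)
print("\narm summaries (mean +/- SD %):")
for _, row in summary.iterrows():
    print(f"  {row.timepoint:>8} {row.region:>8} {row.kind:<6} "
          f"{row.mean_so2:5.1f} +/- {row.sd_so2:4.1f} (n={row.n})")

print("\npaired t-tests, baseline vs one hour post-occlusion:")
tests = run_paired_study(measurements)
for _, row in tests.iterrows():
    print(f"  {row.region:>8} {row.kind:<6} drop {row.mean_diff:+5.1f} points, "
          f"t({row.df}) = {row.t:6.2f}, p = {row.p:.2e}")
print("\ntemporal arms drop significantly; nasal control arms stay flat")
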
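"""The whole study in one call: simulate, split, delineate, compare, report.

`run_study` simulates 80 controls and 40 PD cases, screens eligibility,
splits the controls into teaching/validating halves, freezes zones on the
teaching mean map, and runs every comparison.  With `outdir` set it also
writes the report tables; the same pipeline runs from the shell as
`ppct run-study --seed 7 --out study/`.
"""

from ppct import RunConfig, run_study

report = run_study(RunConfig(seed=7))

print("teaching zone cube counts:", report.teaching_zone_counts)
print("\npercent increase of PD over controls:")
for _, row in report.percent_differences.iterrows():
    print(f"  {row.variable:18s} {row.percent_increase:+5.1f}%")

sig = report.comparison[report.comparison.significant_bonferroni.notna()]
n_sig = int(sig.significant_bonferroni.sum())
print(f"\nregional tests passing Bonferroni (p < 0.005): {n_sig} of {len(sig)}")
print(f"subjects excluded by eligibility: {len(report.excluded)}")

# The zone percent-increase profile (largest in zone 2, smallest in zone 5)
# is the signature of a constant additive thickening on an outward-growing
# thickness profile.
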
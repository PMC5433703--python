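"""Case-control comparison: PD eyes vs healthy controls on frozen zones.

Zones are delineated on an independent teaching cohort; the validating
controls and the PD cohort are then compared zone by zone (pooled t-test)
and region by region (Bonferroni-corrected at 0.05/10 = 0.005).
"""

from ppct import (
    CohortSpec,
    ZoneBinSpec,
    build_geometry,
    compare_groups,
    delineate_zones,
    mean_thickness_map,
    percent_difference,
    quadrant_partition,
    sector_partition,
    select_onh_mask,
    simulate_cohort,
    total_partition,
)

geometry = build_geometry()
mask = select_onh_mask(geometry)

teaching, _ = simulate_cohort(CohortSpec(n_per_group=40, seed=0))
zonemap = delineate_zones(mean_thickness_map(teaching), ZoneBinSpec(), mask)

controls, control_recs = simulate_cohort(
    CohortSpec(n_per_group=40, seed=1), cohort_role="validating")
cases, case_recs = simulate_cohort(
    CohortSpec(n_per_group=40, seed=2), group="PD", cohort_role="case")

partitions = [total_partition(geometry, mask),
              quadrant_partition(geometry, mask),
              sector_partition(geometry, mask)]
table = compare_groups(cases, case_recs, controls, control_recs,
                       zonemap, partitions, geometry, mask)

zone_rows = table[table.block == "zone"]
print("variable            PD mean   control mean   p        increase")
for _, row in zone_rows.iterrows():
    pct = percent_difference(row.case_mean, row.control_mean)
    print(f"{row.variable:18s} {row.case_mean:8.2f} {row.control_mean:12.2f}"
          f"   {row.p:.2e}  {pct:+5.1f}%")

# The simulated 30 um PD thickening is significant in every zone; the
# percent increase falls with distance from the nerve head because the same
# absolute offset is divided by a larger control thickness.
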
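"""Field statistics over a simulated season of co-located observations.

Generates a full synthetic survey (occupancy structured by shore,
lognormal copy abundance, species-specific run timing, inhibition by
stream type) and runs the comparison statistics: Phi agreement between
eDNA and each companion data set, permutation Spearman of copies against
ichthyoplankton counts, the early/late Mann-Whitney split per species,
and the Marascuilo procedure across rivers.
"""

import numpy as np

from alosaedna import ScenarioConfig, simulate_survey, survey_stats

survey, truth = simulate_survey(ScenarioConfig(), np.random.default_rng(17))
stats = survey_stats(survey, n_perm=1000, seed=17)
stats.pop("_spearman_null", None)

print(f"records: {stats['n_records']}, detections: "
      f"{int(survey['edna_detected'].sum())}")
print(f"Phi eDNA-ichthyoplankton: {stats['phi_edna_ichthyo']:.2f}")
print(f"Phi eDNA-adult:           {stats['phi_edna_adult']:.2f}")
sp = stats["spearman"]
print(f"Spearman rho = {sp['rho']:.2f}  (analytic p = {sp['p_analytic']:.2g}, "
      f"permutation p = {sp['p_permutation']:.2g})")
ll = stats["loglog"]
print(f"log-log regression: slope = {ll['slope']:.2f}, R^2 = {ll['r2']:.2f}")
for species, res in stats["temporal_split"].items():
    print(f"{species}: early median {res['median_early']:.0f} vs late "
          f"{res['median_late']:.0f} copies, Mann-Whitney p = {res['p']:.3g}")
print()
print("eDNA agrees more strongly with ichthyoplankton than with adult")
print("sightings (higher Phi), copies track counts on the rank scale, and")
print("the early/late split recovers the alewife-first run phenology.")
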
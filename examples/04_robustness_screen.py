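"""Screen a planted cohort for mutation-resistant, high-expression promoters.

Plants 10 promoters of each robustness class (resistant / declining /
volatile) in a known fitness landscape, mutates each for 100 generations,
predicts expression along every lineage with the ground-truth landscape,
clusters the trajectories and ranks the mutation-resistant candidates.
"""

from collections import Counter

from promscreen import (
    MutationConfig,
    expression_trajectories,
    oracle_predictor,
    plant_cohort,
    simulate_cohort,
)
from promscreen.screen import build_report, trajectory_density_summary

landscape, cohort = plant_cohort(n_per_class=10, seed=1)
trajs = simulate_cohort(cohort.sequences, MutationConfig(generations=100, seed=2))
tm = expression_trajectories(oracle_predictor(landscape), trajs)
report = build_report(tm, seed=0)

recovered = Counter(report.clusters.labels)
agreement = sum(t == p for t, p in zip(cohort.labels, report.clusters.labels))
print(f"recovered cluster sizes: {dict(recovered)}")
print(f"label agreement with planted classes: {agreement}/{len(cohort.labels)}")
print(f"selected mutation-resistant promoters (ranked): {list(report.selected)}")

density = trajectory_density_summary(tm, n_bins=10)
top_bin = density[density.generation == 100].nlargest(1, "count")
print("generation-100 expression mode:",
      top_bin[["bin_low", "bin_high", "count"]].to_string(index=False, header=False))
# Resistant promoters lose expression in small steps (redundant weak sites),
# declining ones collapse in one large step, volatile ones jump both ways;
# the selection lists founders that stayed high without large collapses.
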
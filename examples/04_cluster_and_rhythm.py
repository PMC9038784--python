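"""Cluster metabolite temporal profiles and test them for diel rhythm.

Clusters the Z-scored per-cell profiles of a synthetic 281-peak table by
variance-weighted fuzzy c-means (cluster number chosen by the Xie-Beni
index) and runs the cosinor/permutation rhythm test on each cluster's
members.
"""

import numpy as np

from dielflux import ExperimentDesign, generate_metabolite_table, znormalize
from dielflux.clustering import assign_members, replicate_variance_weights, vs_cluster
from dielflux.rhythm import phase_class, rhythm_test

design = ExperimentDesign()
matrix, truth = generate_metabolite_table(design, seed=2)

profiles, weights = replicate_variance_weights(matrix)
model = vs_cluster(profiles, c_candidates=range(2, 9), weights=weights, seed=2)
labels = assign_members(model, threshold=0.5)
print(f"selected c = {model.c} clusters (Xie-Beni {model.xie_beni:.4f})")
print(labels.value_counts().to_string())

z, _ = znormalize(matrix.per_cell())
res = rhythm_test(z, matrix.sample_times, matrix.replicates, n_perm=199, seed=2)
table = res.table.join(labels)
for cl, grp in table.groupby("cluster"):
    frac = grp.periodic.mean()
    phase = grp.loc[grp.periodic, "phase"].mean()
    note = f", mean peak phase {phase:.1f} h ({phase_class(phase)})" if frac > 0.5 else ""
    print(f"{cl}: {frac * 100:.0f}% diel-periodic{note}")
# Clusters matching the diel archetypes show ~100% periodicity with noon /
# mid-afternoon peak phases; the monotone clusters are mostly aperiodic.
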
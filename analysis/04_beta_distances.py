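"""Pairwise beta diversity of all samples.

Computes normalized weighted UniFrac (the clustering metric) and
Jensen-Shannon divergence matrices; both go to scratch/ (they are large)
for the clustering and distance-ratio steps.
"""

from pathlib import Path

from pneumotyper.beta import distance_matrix, read_tree, write_distance_matrix
from pneumotyper.table import read_otu_table

table = read_otu_table("scratch/rarefied_counts.tsv")
tree = read_tree("scratch/cohort/tree.nwk")

for metric, path in [("wunifrac", "scratch/dist_wunifrac.tsv"),
                     ("jsd", "scratch/dist_jsd.tsv")]:
    dm = distance_matrix(table, tree, metric=metric)
    write_distance_matrix(dm, path)
    print(f"{metric}: {len(dm.ids)} x {len(dm.ids)} matrix, "
          f"mean off-diagonal distance "
          f"{dm.data.sum() / (len(dm.ids) * (len(dm.ids) - 1)):.3f} -> {path}")
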
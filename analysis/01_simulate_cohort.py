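"""Generate the synthetic longitudinal cohort the downstream analyses run on.

The default world mirrors the study design: 695 infants sampled at 1 week,
1 month and 3 months; five planted pneumotypes with the published per-visit
prevalences; genus succession calibrated to Staphylococcus 49/22/10 %,
Streptococcus 17/31/29 % and Moraxella 9/13/23 % of reads; per-subject core
OTUs carrying 90/81/63 % of reads; siblings tilting infants toward the
Moraxella and mixed types.

Writes the raw tables to scratch/cohort/ (inputs for 02-09) and the
Table-1-style cohort summary to results/cohort_summary.tsv.
"""

import argparse
import json
from pathlib import Path

from pneumotyper.simulate import default_config, generate_cohort
from pneumotyper.table import cohort_summary

parser = argparse.ArgumentParser()
parser.add_argument("--n-subjects", type=int, default=695)
parser.add_argument("--seed", type=int, default=1)
args = parser.parse_args()

out = Path("scratch/cohort")
out.mkdir(parents=True, exist_ok=True)
results = Path("results")
results.mkdir(exist_ok=True)

cohort = generate_cohort(default_config(n_subjects=args.n_subjects, seed=args.seed))
cohort.table.write(out / "counts.tsv", out / "taxonomy.tsv")
cohort.tree.write(str(out / "tree.nwk"))
cohort.metadata.to_csv(out / "metadata.tsv", sep="\t", index=False)
(out / "truth.json").write_text(json.dumps({
    "pneumotype": {f"{s}|{t}": v for (s, t), v in cohort.truth["pneumotype"].items()},
    "core_otus": {s: sorted(v) for s, v in cohort.truth["core_otus"].items()},
    "dominant_otus": cohort.truth["dominant_otus"],
    "core_share": cohort.truth["core_share"],
    "seed": args.seed,
}, indent=2, sort_keys=True))

summary = cohort_summary(cohort.metadata)
summary.to_csv(results / "cohort_summary.tsv", sep="\t", index=False)

n_subj = cohort.metadata["subject_id"].nunique()
print(f"cohort: {cohort.table.n_samples} samples from {n_subj} subjects, "
      f"{len(cohort.table.otu_ids)} OTUs -> scratch/cohort/")
print(summary[summary.group == "all_subjects"][["field", "label"]].to_string(index=False))
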
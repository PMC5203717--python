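"""Quality control and rarefaction of the raw OTU table.

Excludes samples below 2000 reads and Shannon-diversity outliers (> 5 sd
above the cohort mean), then subsamples every remaining sample to an even
depth of 2000 reads.  All downstream analyses use the even table
(scratch/rarefied_counts.tsv); the exclusion tally goes to
results/qc_report.json.
"""

import argparse
import json
from pathlib import Path

from pneumotyper.table import (
    exclude_diversity_outliers,
    filter_min_depth,
    rarefy,
    read_otu_table,
)

parser = argparse.ArgumentParser()
parser.add_argument("--depth", type=int, default=2000)
parser.add_argument("--seed", type=int, default=1)
args = parser.parse_args()

src = Path("scratch/cohort")
table = read_otu_table(src / "counts.tsv", src / "taxonomy.tsv")
n0 = table.n_samples

table, depth_report = filter_min_depth(table, args.depth)
table, sdi_report = exclude_diversity_outliers(table, z=5)
table = rarefy(table, args.depth, seed=args.seed)
table.write(Path("scratch/rarefied_counts.tsv"))

report = {
    "initial_samples": n0,
    "excluded_low_depth": len(depth_report),
    "excluded_sdi_outliers": len(sdi_report),
    "final_samples": table.n_samples,
    "rarefaction_depth": args.depth,
    "rarefaction_seed": args.seed,
}
Path("results/qc_report.json").write_text(json.dumps(report, indent=2))
print(f"kept {table.n_samples}/{n0} samples "
      f"({len(depth_report)} shallow, {len(sdi_report)} diversity outliers); "
      f"rarefied to {args.depth} reads")
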
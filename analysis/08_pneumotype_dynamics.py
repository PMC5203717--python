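"""Pneumotype dynamics: transition tables between consecutive visits,
chi-squared dependence, agreement comparison between the two spans, and the
stable-fraction test against the product-of-marginals null.

Writes results/transitions_*.tsv and results/dynamics.json.
"""

import json
from pathlib import Path

import pandas as pd

from pneumotyper.table import read_metadata
from pneumotyper.trajectory import (
    agreement_comparison,
    dependence_test,
    stability_test,
    transition_counts,
)

meta = read_metadata("scratch/cohort/metadata.tsv")
labels = pd.read_csv("scratch/pneumotype_labels.tsv", sep="\t", index_col=0).iloc[:, 0]
meta = meta[meta["sample_id"].isin(labels.index)]
assignments = meta[["subject_id", "timepoint"]].copy()
assignments["pneumotype"] = labels.loc[meta["sample_id"]].to_numpy()

report = {}
for t1, t2 in [("W1", "M1"), ("M1", "M3")]:
    tab = transition_counts(assignments, t1, t2)
    tab.to_csv(f"results/transitions_{t1}_{t2}.tsv", sep="\t")
    dep = dependence_test(tab)
    report[f"{t1}->{t2}"] = {"n": int(tab.to_numpy().sum()), "dependence": dep}
    print(f"{t1} -> {t2}: n = {tab.to_numpy().sum()}, "
          f"chi2 = {dep['chi2']:.1f}, p = {dep['p_value']:.3g}")

agr = agreement_comparison(assignments)
report["agreement"] = {
    "per_pair": agr["per_pair"].to_dict(orient="records"),
    "p_value": agr["p_value"],
}
print("\nagreement per span:")
print(agr["per_pair"].round(3).to_string(index=False))
print(f"difference between spans: chi2 p = {agr['p_value']:.3g}")

stab = stability_test(assignments)
report["stability"] = {
    "n": stab["n"],
    "observed_proportion": stab["observed_proportion"],
    "expected_proportion": stab["expected_proportion"],
    "p_value": stab["p_value"],
    "per_pneumotype": stab["per_pneumotype"].to_dict(orient="records"),
}
print(f"\nfully stable infants: {100 * stab['observed_proportion']:.1f}% observed "
      f"vs {100 * stab['expected_proportion']:.1f}% expected under independence "
      f"(chi2 p = {stab['p_value']:.3g})")

Path("results/dynamics.json").write_text(json.dumps(report, indent=2, default=str))
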
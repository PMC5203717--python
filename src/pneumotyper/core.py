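"""Per-subject core microbiota: the OTUs present in all three of an
infant's samples, and how much of each sample's reads they carry.

Core membership is evaluated on the rarefied (even-depth) table with a
presence threshold of count >= 1.  Subjects missing any of the three
time-points are excluded.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .table import TIMEPOINTS, OtuTable


@dataclass
class CoreProfile:
    subject_id: str
    core_otus: frozenset
    core_abundance: dict  # timepoint -> fraction of reads from core OTUs

    @property
    def n_core(self) -> int:
        return len(self.core_otus)


def core_otus(subject_samples: dict) -> frozenset:
    """OTUs with count > 0 in every one of the subject's three samples.

    ``subject_samples`` maps timepoint -> count Series (index = OTU ids).
    """
    missing = [t for t in TIMEPOINTS if t not in subject_samples]
    if missing:
        raise ValueError(f"missing timepoint(s) {missing}; subject skipped")
    present = None
    for t in TIMEPOINTS:
        mask = subject_samples[t] > 0
        present = mask if present is None else (present & mask)
    return frozenset(present.index[present])


def core_abundance(subject_samples: dict, core: frozenset) -> dict:
    """Fraction of each sample's reads belonging to the core set."""
    out = {}
    for t, counts in subject_samples.items():
        total = counts.sum()
        in_core = counts[counts.index.isin(core)].sum()
        out[t] = float(in_core / total) if total > 0 else 0.0
    return out


def core_profiles(table: OtuTable, metadata: pd.DataFrame) -> list[CoreProfile]:
    """Core profile for every subject with samples at all three time-points."""
    meta = metadata[metadata["sample_id"].isin(table.sample_ids)]
    profiles = []
    for subject, sub in meta.groupby("subject_id"):
        tps = dict(zip(sub["timepoint"], sub["sample_id"]))
        if set(TIMEPOINTS) - set(tps):
            continue
        samples = {t: table.counts.loc[tps[t]] for t in TIMEPOINTS}
        core = core_otus(samples)
        profiles.append(CoreProfile(str(subject), core, core_abundance(samples, core)))
    return profiles


def profiles_frame(profiles: list[CoreProfile]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "subject_id": p.subject_id,
            "n_core": p.n_core,
            **{f"core_abundance_{t}": p.core_abundance[t] for t in TIMEPOINTS},
        }
        for p in profiles
    )


def _paired_wilcoxon(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided paired Wilcoxon signed-rank; p = 1 when all pairs tie."""
    diff = x - y
    if np.all(diff == 0):
        return 1.0
    return float(stats.wilcoxon(x, y, zero_method="wilcox").pvalue)


def core_trend_test(profiles: list[CoreProfile]) -> pd.DataFrame:
    """Paired Wilcoxon tests of core abundance between consecutive visits."""
    if len(profiles) < 10:
        raise ValueError("need at least 10 complete subjects")
    abund = {
        t: np.array([p.core_abundance[t] for p in profiles]) for t in TIMEPOINTS
    }
    rows = []
    for t1, t2 in zip(TIMEPOINTS[:-1], TIMEPOINTS[1:]):
        rows.append(
            {
                "from": t1,
                "to": t2,
                "median_from": float(np.median(abund[t1])),
                "median_to": float(np.median(abund[t2])),
                "p_value": _paired_wilcoxon(abund[t1], abund[t2]),
            }
        )
    return pd.DataFrame(rows)


def core_by_stability(profiles: list[CoreProfile], stable: dict) -> dict:
    """Compare core abundance between stable and changing subjects.

    ``stable`` maps subject_id -> bool (same pneumotype at all three
    visits).  Per time-point: two-sample Wilcoxon rank-sum (with continuity
    correction); overall: one-way ANOVA of core abundance on stability,
    pooling all subject x time-point values.
    """
    grp = {True: [], False: []}
    for p in profiles:
        if p.subject_id in stable:
            grp[bool(stable[p.subject_id])].append(p)
    if min(len(grp[True]), len(grp[False])) < 2:
        raise ValueError("each stability group needs at least 2 subjects")
    per_tp = []
    for t in TIMEPOINTS:
        a = np.array([p.core_abundance[t] for p in grp[True]])
        b = np.array([p.core_abundance[t] for p in grp[False]])
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
        per_tp.append(
            {
                "timepoint": t,
                "median_stable": float(np.median(a)),
                "median_changing": float(np.median(b)),
                "p_value": float(res.pvalue),
            }
        )
    pooled_a = np.concatenate(
        [[p.core_abundance[t] for t in TIMEPOINTS] for p in grp[True]]
    )
    pooled_b = np.concatenate(
        [[p.core_abundance[t] for t in TIMEPOINTS] for p in grp[False]]
    )
    anova = stats.f_oneway(pooled_a, pooled_b)
    return {
        "per_timepoint": pd.DataFrame(per_tp),
        "anova_F": float(anova.statistic),
        "anova_p": float(anova.pvalue),
        "n_stable": len(grp[True]),
        "n_changing": len(grp[False]),
    }
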
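"""Pneumotype dynamics: transition tables, dependence and stability tests,
and the within- vs between-subject distance-ratio permutation test.

``assignments`` throughout is a tidy frame with columns ``subject_id``,
``timepoint`` and ``pneumotype`` (one row per sample that received a
cluster label).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from skbio import DistanceMatrix

from .table import TIMEPOINTS


def _wide(assignments: pd.DataFrame) -> pd.DataFrame:
    return assignments.pivot(
        index="subject_id", columns="timepoint", values="pneumotype"
    )


def transition_counts(assignments: pd.DataFrame, t_from: str, t_to: str,
                      labels=None) -> pd.DataFrame:
    """k x k table of subjects moving from label i (rows) to label j."""
    wide = _wide(assignments)[[t_from, t_to]].dropna()
    for col in wide.columns:  # pivot casts int labels to float via NaN
        if wide[col].dtype.kind == "f" and (wide[col] == wide[col].astype(int)).all():
            wide[col] = wide[col].astype(int)
    if labels is None:
        labels = sorted(set(wide[t_from]) | set(wide[t_to]))
    tab = pd.crosstab(wide[t_from], wide[t_to])
    return tab.reindex(index=labels, columns=labels, fill_value=0)


def dependence_test(matrix: pd.DataFrame) -> dict:
    """Pearson chi-squared test of independence on a transition table.

    Zero-margin rows/columns are dropped with a warning; a low-expected-count
    flag is raised when any expected cell is < 5.  Yates correction applies
    only to 2 x 2 tables.
    """
    tab = matrix.copy()
    zero_rows = tab.index[tab.sum(axis=1) == 0]
    zero_cols = tab.columns[tab.sum(axis=0) == 0]
    if len(zero_rows) or len(zero_cols):
        warnings.warn(
            f"dropping zero-margin rows {list(zero_rows)} / columns {list(zero_cols)}"
        )
        tab = tab.drop(index=zero_rows, columns=zero_cols)
    if tab.to_numpy().sum() < 20:
        warnings.warn("fewer than 20 subjects in the transition table")
    correction = tab.shape == (2, 2)
    res = stats.chi2_contingency(tab.to_numpy(), correction=correction)
    return {
        "chi2": float(res.statistic),
        "p_value": float(res.pvalue),
        "dof": int(res.dof),
        "low_expected": bool((res.expected_freq < 5).any()),
        "yates": correction,
    }


def agreement_comparison(assignments: pd.DataFrame) -> dict:
    """Fraction of subjects keeping their pneumotype over each consecutive
    time span, and a 2 x 2 chi-squared test of whether the two spans differ."""
    wide = _wide(assignments)
    rows = []
    counts = []
    for t1, t2 in zip(TIMEPOINTS[:-1], TIMEPOINTS[1:]):
        sub = wide[[t1, t2]].dropna()
        same = int((sub[t1] == sub[t2]).sum())
        rows.append(
            {"pair": f"{t1}->{t2}", "n": len(sub), "same": same,
             "agreement": same / len(sub) if len(sub) else np.nan}
        )
        counts.append([same, len(sub) - same])
    table = np.asarray(counts)
    if np.all(table[:, 1] == 0) or np.all(table[:, 0] == 0) or \
            table[0].tolist() == table[1].tolist():
        # degenerate or identical rows: no evidence of a difference
        chi2, p = 0.0, 1.0
    else:
        res = stats.chi2_contingency(table, correction=True)
        chi2, p = float(res.statistic), float(res.pvalue)
    return {"per_pair": pd.DataFrame(rows), "chi2": chi2, "p_value": p}


def stability_test(assignments: pd.DataFrame, per_pneumotype: bool = True) -> dict:
    """Observed vs expected-under-independence fraction of fully stable
    subjects (same pneumotype at W1, M1 and M3).

    The null keeps the marginal pneumotype frequencies of each visit and
    assumes the three visits are independent: expected stable proportion
    = sum_k p_k(W1) p_k(M1) p_k(M3).  A 1-df chi-squared goodness-of-fit
    test compares (stable, not stable) to its expectation; the same test is
    run per pneumotype on (stable as k, rest).
    """
    wide = _wide(assignments)[TIMEPOINTS].dropna()
    n = len(wide)
    if n < 20:
        warnings.warn("fewer than 20 subjects with all three time-points")
    labels = sorted(set(np.concatenate([wide[t].to_numpy() for t in TIMEPOINTS])))
    marg = {t: wide[t].value_counts(normalize=True).reindex(labels, fill_value=0.0)
            for t in TIMEPOINTS}
    stable_mask = (wide[TIMEPOINTS[0]] == wide[TIMEPOINTS[1]]) & (
        wide[TIMEPOINTS[1]] == wide[TIMEPOINTS[2]]
    )

    def gof(observed: int, expected_prop: float) -> float:
        f_exp = np.array([expected_prop, 1 - expected_prop]) * n
        if f_exp.min() <= 0:  # degenerate expectation
            return 1.0 if observed == round(f_exp[0]) else 0.0
        return float(
            stats.chisquare([observed, n - observed], f_exp=f_exp).pvalue
        )

    expected = float(sum(marg["W1"][k] * marg["M1"][k] * marg["M3"][k] for k in labels))
    out = {
        "n": n,
        "observed_stable": int(stable_mask.sum()),
        "observed_proportion": float(stable_mask.mean()),
        "expected_proportion": expected,
        "p_value": gof(int(stable_mask.sum()), expected),
        "stable_subjects": wide.index[stable_mask].tolist(),
    }
    if per_pneumotype:
        rows = []
        for k in labels:
            e_k = float(marg["W1"][k] * marg["M1"][k] * marg["M3"][k])
            o_k = int((stable_mask & (wide[TIMEPOINTS[0]] == k)).sum())
            rows.append(
                {"pneumotype": k, "observed": o_k, "expected": e_k * n,
                 "p_value": gof(o_k, e_k)}
            )
        out["per_pneumotype"] = pd.DataFrame(rows)
    return out


# -- within- vs between-subject distance ratio ----------------------------

def _cross_matrix(dist: DistanceMatrix, metadata: pd.DataFrame,
                  t_from: str, t_to: str):
    """Subjects x t_to-samples distance block for subjects sampled at both
    time-points.  Row s corresponds to subject s's t_from sample; column j
    to subject j's t_to sample (same subject ordering)."""
    meta = metadata[metadata["sample_id"].isin(dist.ids)]
    wide = meta.pivot(index="subject_id", columns="timepoint", values="sample_id")
    if t_from not in wide.columns or t_to not in wide.columns:
        raise ValueError(f"no samples for time pair {t_from}->{t_to}")
    wide = wide[[t_from, t_to]].dropna()
    if len(wide) < 10:
        raise ValueError("need >= 10 subjects with samples at both time-points")
    idx = {s: i for i, s in enumerate(dist.ids)}
    rows = [idx[s] for s in wide[t_from]]
    cols = [idx[s] for s in wide[t_to]]
    return dist.data[np.ix_(rows, cols)], wide.index.to_numpy()


def _loo_medians(C: np.ndarray) -> np.ndarray:
    """LOO[i, j] = median of row i of C excluding column j (vectorized)."""
    n, m = C.shape
    order = np.argsort(C, axis=1, kind="stable")
    srt = np.take_along_axis(C, order, axis=1)
    rank = np.empty_like(order)
    np.put_along_axis(rank, order, np.arange(m)[None, :].repeat(n, axis=0), axis=1)
    r = m - 1  # size after exclusion
    if r % 2 == 1:
        mid = r // 2
        lo = srt[:, mid][:, None]
        hi = srt[:, mid + 1][:, None]
        return np.where(rank <= mid, hi, lo)
    lo1, lo2 = srt[:, r // 2 - 1][:, None], srt[:, r // 2][:, None]
    hi = srt[:, r // 2 + 1][:, None]
    below = rank <= r // 2 - 1
    above = rank >= r // 2 + 1
    med_below = (lo2 + hi) / 2      # excluded value sat at or below lower mid
    med_above = (lo1 + lo2) / 2     # excluded value above upper mid
    med_mid = (lo1 + hi) / 2        # excluded value was the upper mid itself
    out = np.where(below, med_below, np.where(above, med_above, med_mid))
    return out


def distance_ratio(dist: DistanceMatrix, metadata: pd.DataFrame,
                   t_from: str, t_to: str, denom: str = "median") -> dict:
    """Median over subjects of r_s = d(own t_from, own t_to) /
    median_{s' != s} d(own t_from, s' t_to).

    ``denom='mean'`` switches the denominator to the mean of the
    cross-subject distances.
    """
    C, subjects = _cross_matrix(dist, metadata, t_from, t_to)
    n = len(subjects)
    own = np.diag(C)
    if denom == "median":
        denom_vals = _loo_medians(C)[np.arange(n), np.arange(n)]
    elif denom == "mean":
        denom_vals = (C.sum(axis=1) - own) / (n - 1)
    else:
        raise ValueError("denom must be 'median' or 'mean'")
    keep = denom_vals > 0
    if not keep.all():
        warnings.warn(
            f"dropping {int((~keep).sum())} subject(s) with zero denominator"
        )
    ratios = own[keep] / denom_vals[keep]
    return {
        "time_pair": f"{t_from}->{t_to}",
        "subjects": subjects[keep],
        "ratios": ratios,
        "median_ratio": float(np.median(ratios)),
        "n_subjects": int(keep.sum()),
        "denominator": denom,
    }


def ratio_permutation_test(dist: DistanceMatrix, metadata: pd.DataFrame,
                           t_from: str, t_to: str, n_perm: int = 10_000,
                           seed: int = 0, denom: str = "median",
                           tail: str = "two") -> dict:
    """Permutation test of whether the median distance ratio differs from 1.

    Each permutation reassigns every subject's "own" later-visit column to a
    uniformly random column (the true one included, independently across
    subjects) and recomputes the median ratio.  One-sided p is the add-one
    fraction of permuted medians <= the observed; two-sided doubles the
    smaller tail (capped at 1).
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    if denom != "median":
        raise NotImplementedError("permutation test implemented for the median denominator")
    C, subjects = _cross_matrix(dist, metadata, t_from, t_to)
    n = len(subjects)
    LOO = _loo_medians(C)
    with np.errstate(invalid="ignore", divide="ignore"):
        R = np.where(LOO > 0, C / np.where(LOO > 0, LOO, 1.0), np.nan)
    obs = float(np.nanmedian(np.diag(R)))
    rng = np.random.default_rng(seed)
    cols = rng.integers(0, n, size=(n_perm, n))
    perm_medians = np.nanmedian(R[np.arange(n)[None, :], cols], axis=1)
    p_low = (1 + np.sum(perm_medians <= obs)) / (1 + n_perm)
    p_high = (1 + np.sum(perm_medians >= obs)) / (1 + n_perm)
    if tail == "one":
        p = p_low
    elif tail == "two":
        p = min(1.0, 2 * min(p_low, p_high))
    else:
        raise ValueError("tail must be 'one' or 'two'")
    return {
        "time_pair": f"{t_from}->{t_to}",
        "median_ratio": obs,
        "p_value": float(p),
        "p_lower": float(p_low),
        "n_perm": n_perm,
        "n_subjects": n,
        "tail": tail,
        "scheme": "per-subject uniform reassignment of the own column, "
                  "true column included, independent across subjects",
    }
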
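"""Indicator-OTU analysis (group-size-corrected IndVal).

For an OTU and a cluster g the group-equalized indicator value is

    A = mean_g / sum_h mean_h        (specificity; mean relative abundance
                                      per cluster, so cluster sizes do not
                                      bias the comparison)
    B = prevalence of the OTU in g   (fidelity; fraction of g's samples
                                      with count > 0)
    IndVal = sqrt(A * B)

Each OTU is assigned to its best single cluster (combinations of clusters
are not considered) and significance comes from cluster-label permutations
of the max-over-clusters statistic.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .table import OtuTable


def _indval_matrices(X: np.ndarray, P: np.ndarray, groups: np.ndarray, k: int):
    """A, B and IndVal as (k x n_otus) arrays.

    X: relative abundances (n x p); P: presence 0/1 (n x p); groups: 0..k-1.
    """
    means = np.zeros((k, X.shape[1]))
    prev = np.zeros((k, X.shape[1]))
    for g in range(k):
        sel = groups == g
        means[g] = X[sel].mean(axis=0)
        prev[g] = P[sel].mean(axis=0)
    colsum = means.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        A = np.where(colsum > 0, means / np.where(colsum > 0, colsum, 1.0), 0.0)
    return A, prev, np.sqrt(A * prev)


def indval_g(table: OtuTable, labels: pd.Series, otu_id: str, cluster) -> dict:
    """A, B and IndVal of one OTU for one cluster."""
    X = table.relative_abundance().to_numpy()
    P = (table.counts.to_numpy() > 0).astype(float)
    lab = labels.loc[table.sample_ids].to_numpy()
    clusters = np.unique(lab)
    if cluster not in clusters:
        raise ValueError(f"cluster {cluster!r} is empty or unknown")
    groups = np.searchsorted(clusters, lab)
    A, B, IV = _indval_matrices(X, P, groups, len(clusters))
    j = table.otu_ids.index(otu_id)
    g = int(np.searchsorted(clusters, cluster))
    absent = not np.any(P[:, j])
    return {
        "A": float(A[g, j]),
        "B": float(B[g, j]),
        "indval": float(IV[g, j]),
        "absent_everywhere": bool(absent),
    }


def indicator_analysis(table: OtuTable, labels: pd.Series, n_perm: int = 999,
                       seed: int = 0, alpha: float = 0.05) -> pd.DataFrame:
    """Best single-cluster IndVal per OTU with a permutation p-value.

    The permutation statistic is the maximum IndVal over clusters, compared
    against the observed best-cluster IndVal (add-one convention), as in the
    standard group-equalized indicator-species test.  Output is sorted by
    IndVal within cluster; ``significant`` flags p <= alpha.
    """
    X = table.relative_abundance().to_numpy()
    P = (table.counts.to_numpy() > 0).astype(float)
    lab = labels.loc[table.sample_ids].to_numpy()
    clusters = np.unique(lab)
    k = len(clusters)
    groups = np.searchsorted(clusters, lab)

    A, B, IV = _indval_matrices(X, P, groups, k)
    best = IV.argmax(axis=0)
    cols = np.arange(IV.shape[1])
    obs = IV[best, cols]

    rng = np.random.default_rng(seed)
    exceed = np.zeros(IV.shape[1])
    for _ in range(n_perm):
        permuted = rng.permutation(groups)
        _, _, IVp = _indval_matrices(X, P, permuted, k)
        exceed += IVp.max(axis=0) >= obs - 1e-12
    pvals = (1 + exceed) / (1 + n_perm)

    out = pd.DataFrame(
        {
            "otu_id": table.otu_ids,
            "cluster": clusters[best],
            "A": A[best, cols],
            "B": B[best, cols],
            "indval": obs,
            "p_value": pvals,
            "absent_everywhere": ~P.any(axis=0),
            "genus": table.taxonomy.loc[table.otu_ids, "genus"].to_numpy(),
        }
    )
    out.loc[out["absent_everywhere"], ["A", "B", "indval"]] = 0.0
    out["significant"] = out["p_value"] <= alpha
    return out.sort_values(
        ["cluster", "indval"], ascending=[True, False]
    ).reset_index(drop=True)
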
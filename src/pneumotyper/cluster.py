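"""PAM (k-medoids) clustering of samples into community state types.

Samples are partitioned directly on a beta-diversity distance matrix with
the classic BUILD + SWAP algorithm, the number of clusters is chosen by the
average silhouette width (ASW), and the chosen partition is validated with a
label-permutation test on the size-normalized within-cluster distance sum.

Everything here is deterministic for a given distance matrix: BUILD seeds
the medoids greedily and all ties break toward the lowest sample index.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skbio import DistanceMatrix
from sklearn.metrics import silhouette_samples


@dataclass
class PneumotypeModel:
    """A fitted PAM partition.

    ``labels`` maps sample id -> cluster 1..k (cluster numbers follow the
    medoids sorted by sample index).  ``asw_by_k`` is filled by
    :func:`select_k`.
    """

    k: int
    medoids: list[str]
    labels: pd.Series
    silhouette_per_sample: pd.Series | None = None
    average_silhouette_width: float | None = None
    asw_by_k: pd.Series | None = field(default=None, repr=False)
    total_cost: float | None = None


#: exact enumeration is used whenever C(n, k) is at most this many subsets;
#: BUILD + SWAP is a local search and can miss the optimum on tiny instances
_EXACT_LIMIT = 20_000


def _pam_exact(D: np.ndarray, k: int):
    from itertools import combinations

    n = D.shape[0]
    best = (np.inf, None)
    for subset in combinations(range(n), k):
        cost = D[:, subset].min(axis=1).sum()
        if cost < best[0] - 1e-15:
            best = (cost, subset)
    return list(best[1])


def _pam_indices(D: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray, float]:
    """Minimum-cost medoids: exhaustive for tiny instances (guaranteeing the
    exact-optimum contract at small n), BUILD + SWAP otherwise; returns
    (medoids, labels, cost)."""
    n = D.shape[0]
    if math.comb(n, k) <= _EXACT_LIMIT:
        medoids = sorted(_pam_exact(D, k))
        Dmed = D[:, medoids]
        labels = np.argmin(Dmed, axis=1)
        labels[medoids] = np.arange(k)
        return np.asarray(medoids), labels, float(Dmed[np.arange(n), labels].sum())
    # BUILD: first medoid minimizes total distance; then greedily add the
    # point with the largest cost reduction (ties -> lowest index via argmin
    # /argmax first-occurrence).
    medoids = [int(np.argmin(D.sum(axis=0)))]
    dmin = D[:, medoids[0]].copy()
    while len(medoids) < k:
        gains = np.maximum(dmin[:, None] - D, 0.0).sum(axis=0)
        gains[medoids] = -np.inf
        h = int(np.argmax(gains))
        medoids.append(h)
        dmin = np.minimum(dmin, D[:, h])

    medoids = sorted(medoids)
    while True:
        Dmed = D[:, medoids]                     # n x k
        order = np.argsort(Dmed, axis=1, kind="stable")
        nearest = order[:, 0]
        d1 = Dmed[np.arange(n), nearest]
        d2 = Dmed[np.arange(n), order[:, 1]] if k > 1 else np.full(n, np.inf)
        cost = d1.sum()
        best = (0.0, None, None)
        candidates = np.setdiff1d(np.arange(n), medoids)
        for j in range(k):
            # cost if medoid j is removed: points whose nearest was j fall
            # back to their second-nearest, unless the new medoid is closer
            base = np.where(nearest == j, d2, d1)
            new_costs = np.minimum(base[:, None], D[:, candidates]).sum(axis=0)
            i = int(np.argmin(new_costs))
            delta = cost - new_costs[i]
            if delta > best[0] + 1e-12:
                best = (delta, j, int(candidates[i]))
        if best[1] is None:
            break
        medoids[best[1]] = best[2]
        medoids = sorted(medoids)

    Dmed = D[:, medoids]
    labels = np.argmin(Dmed, axis=1)
    labels[medoids] = np.arange(k)  # a medoid always belongs to its own cluster
    return np.asarray(medoids), labels, float(Dmed[np.arange(n), labels].sum())


def pam(dist: DistanceMatrix, k: int) -> PneumotypeModel:
    """Partition around medoids; deterministic, ties to the lowest index."""
    n = len(dist.ids)
    if not 2 <= k < n:
        raise ValueError(f"k must satisfy 2 <= k < n samples (k={k}, n={n})")
    med_idx, lab_idx, cost = _pam_indices(dist.data, k)
    ids = np.asarray(dist.ids)
    labels = pd.Series(lab_idx + 1, index=ids, name="pneumotype")
    return PneumotypeModel(
        k=k, medoids=[str(s) for s in ids[med_idx]], labels=labels, total_cost=cost
    )


def silhouette(dist: DistanceMatrix, labels: pd.Series):
    """Per-sample silhouette widths s(i) and their mean (ASW).

    s(i) = (b - a) / max(a, b); singleton clusters and all-identical points
    get s(i) = 0.
    """
    lab = labels.loc[list(dist.ids)].to_numpy()
    if len(np.unique(lab)) < 2:
        raise ValueError("silhouette requires at least 2 clusters")
    s = silhouette_samples(dist.data, lab, metric="precomputed")
    per_sample = pd.Series(s, index=list(dist.ids), name="silhouette")
    return per_sample, float(s.mean())


def select_k(dist: DistanceMatrix, k_range=range(2, 11)) -> PneumotypeModel:
    """Fit PAM for each k and keep the partition maximizing the ASW.

    Ties go to the smaller k.  The returned model carries the full
    k -> ASW table.
    """
    ks = sorted(k_range)
    if ks[-1] >= len(dist.ids):
        raise ValueError("max(k_range) must be < number of samples")
    models, asws = [], []
    for k in ks:
        model = pam(dist, k)
        per_sample, asw = silhouette(dist, model.labels)
        model.silhouette_per_sample = per_sample
        model.average_silhouette_width = asw
        models.append(model)
        asws.append(asw)
    best = int(np.argmax(asws))  # first occurrence -> smallest k on ties
    chosen = models[best]
    chosen.asw_by_k = pd.Series(asws, index=ks, name="asw")
    return chosen


def within_cluster_statistic(D: np.ndarray, lab: np.ndarray) -> float:
    """Sum over clusters of (within-cluster pairwise distance sum / size)."""
    total = 0.0
    for c in np.unique(lab):
        idx = np.flatnonzero(lab == c)
        total += D[np.ix_(idx, idx)].sum() / (2 * len(idx))
    return total


def cluster_optimality_test(dist: DistanceMatrix, labels: pd.Series,
                            n_perm: int = 10_000, seed: int = 0) -> dict:
    """Permutation test that no same-size regrouping has tighter clusters.

    The statistic is the size-normalized within-cluster pairwise distance
    sum; the null permutes labels while preserving cluster sizes.  The
    add-one p-value is the fraction of permutations at least as tight as the
    observed grouping.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    D = dist.data
    lab = labels.loc[list(dist.ids)].to_numpy()
    t_obs = within_cluster_statistic(D, lab)
    rng = np.random.default_rng(seed)
    hits = 0
    t_perm = np.empty(n_perm)
    for i in range(n_perm):
        t_perm[i] = within_cluster_statistic(D, rng.permutation(lab))
        hits += t_perm[i] <= t_obs
    return {
        "statistic": t_obs,
        "p_value": (1 + hits) / (1 + n_perm),
        "n_perm": n_perm,
        "null_mean": float(t_perm.mean()),
        "null_min": float(t_perm.min()),
        "scheme": "size-preserving label permutations of the "
                  "size-normalized within-cluster distance sum",
    }
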
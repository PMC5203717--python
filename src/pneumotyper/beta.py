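"""Beta diversity kernels: weighted UniFrac and Jensen-Shannon divergence.

Weighted UniFrac between two communities is

    W(a, b) = sum_e  l_e * | A_e - B_e |

over the branches ``e`` of a rooted tree whose tips are OTUs, where ``l_e``
is the branch length and ``A_e``, ``B_e`` are the fractions of each sample's
reads descending from the branch.  The normalized variant divides by

    D = sum_tips d_j * (A_j + B_j),

``d_j`` being the root-to-tip path length, which bounds the distance in
[0, 1].  Branch fractions are obtained in a single pass by multiplying the
relative-abundance matrix with a sparse branch x tip incidence matrix, so
the full pairwise matrix over hundreds of samples stays cheap.

Jensen-Shannon divergence uses natural logarithms (0 <= JSD <= ln 2); its
square root is a metric and is exposed as the ``distance`` variant.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.spatial.distance import jensenshannon
from skbio import DistanceMatrix, TreeNode


def read_tree(path) -> TreeNode:
    """Read a rooted newick tree with branch lengths."""
    return TreeNode.read(str(path), format="newick")


class TreeIndex:
    """Branch x tip incidence of a rooted tree, aligned to a list of OTU ids.

    Attributes
    ----------
    lengths:
        branch length per non-root node (None treated as 0).
    incidence:
        sparse (n_branches x n_otus) 0/1 matrix; entry (e, j) = 1 when tip j
        descends from branch e.
    tip_depths:
        root-to-tip path length per OTU.
    """

    def __init__(self, tree: TreeNode, otu_ids) -> None:
        otu_ids = list(otu_ids)
        col = {o: j for j, o in enumerate(otu_ids)}
        tip_names = {t.name for t in tree.tips()}
        missing = [o for o in otu_ids if o not in tip_names]
        if missing:
            raise ValueError(f"OTU {missing[0]!r} is not a tip of the tree")

        lengths = []
        rows, cols = [], []
        tipsets: dict[int, list[int]] = {}
        for node in tree.postorder(include_self=True):
            if node.is_tip():
                tipsets[id(node)] = [col[node.name]] if node.name in col else []
            else:
                merged: list[int] = []
                for child in node.children:
                    merged.extend(tipsets[id(child)])
                tipsets[id(node)] = merged
            if not node.is_root():
                e = len(lengths)
                lengths.append(float(node.length or 0.0))
                for j in tipsets[id(node)]:
                    rows.append(e)
                    cols.append(j)
        self.otu_ids = otu_ids
        self.lengths = np.asarray(lengths)
        self.incidence = sp.csr_matrix(
            (np.ones(len(rows)), (rows, cols)),
            shape=(len(lengths), len(otu_ids)),
        )
        # root-to-tip depth = sum of branch lengths on the path = column sum
        # of the length-weighted incidence matrix
        self.tip_depths = np.asarray(
            self.incidence.multiply(self.lengths[:, None]).sum(axis=0)
        ).ravel()

    def branch_fractions(self, rel_abundance: np.ndarray) -> np.ndarray:
        """Per-branch descendant read fractions for each row of compositions."""
        return np.asarray(rel_abundance @ self.incidence.T.toarray())


def _as_composition(v) -> np.ndarray:
    x = np.asarray(v, dtype=float)
    total = x.sum()
    if total <= 0:
        raise ValueError("zero-total sample in beta-diversity kernel")
    return x / total


def weighted_unifrac(a, b, tree: TreeNode, otu_ids=None, normalized: bool = True,
                     index: TreeIndex | None = None) -> float:
    """Weighted UniFrac between two count (or composition) vectors.

    ``otu_ids`` names the entries of ``a``/``b``; defaults to the tree's tip
    order.  Counts are renormalized internally, so rarefied and raw tables
    behave identically.
    """
    if index is None:
        if otu_ids is None:
            otu_ids = [t.name for t in tree.tips()]
        index = TreeIndex(tree, otu_ids)
    pa, pb = _as_composition(a), _as_composition(b)
    fa, fb = index.branch_fractions(np.vstack([pa, pb]))
    raw = float(np.abs(fa - fb) @ index.lengths)
    if not normalized:
        return raw
    denom = float(index.tip_depths @ (pa + pb))
    return raw / denom if denom > 0 else 0.0


def jensen_shannon(p, q, variant: str = "divergence") -> float:
    """Jensen-Shannon divergence (natural log) or its square-root distance.

    Zeros contribute nothing (0 * ln 0 = 0); inputs are renormalized.
    """
    pp = _as_composition(p)
    qq = _as_composition(q)
    dist = float(jensenshannon(pp, qq))  # sqrt(JSD), base e
    if variant == "distance":
        return dist
    if variant == "divergence":
        return dist * dist
    raise ValueError("variant must be 'divergence' or 'distance'")


def distance_matrix(table, tree: TreeNode | None = None, metric: str = "wunifrac",
                    normalized: bool = True, jsd_variant: str = "divergence") -> DistanceMatrix:
    """All pairwise sample distances for an :class:`~pneumotyper.table.OtuTable`.

    ``metric`` is ``wunifrac`` (requires ``tree``) or ``jsd``.
    """
    counts = table.counts.to_numpy(dtype=float)
    totals = counts.sum(axis=1)
    if np.any(totals <= 0):
        bad = table.counts.index[totals <= 0][0]
        raise ValueError(f"zero-total sample {bad!r}")
    P = counts / totals[:, None]
    n = P.shape[0]
    if metric == "wunifrac":
        if tree is None:
            raise ValueError("metric 'wunifrac' requires a phylogenetic tree")
        index = TreeIndex(tree, table.otu_ids)
        E = index.branch_fractions(P)
        El = E * index.lengths  # length-weighted fractions
        D = np.zeros((n, n))
        for i in range(n):
            D[i, i + 1:] = np.abs(El[i + 1:] - El[i]).sum(axis=1)
        if normalized:
            m = P @ index.tip_depths
            denom = m[:, None] + m[None, :]
            with np.errstate(invalid="ignore", divide="ignore"):
                upper = np.triu(D, 1)
                upper = np.where(denom > 0, upper / denom, 0.0)
            D = np.triu(upper, 1)
        D = D + D.T
    elif metric == "jsd":
        from scipy.spatial.distance import pdist, squareform

        D = squareform(pdist(P, metric="jensenshannon"))
        if jsd_variant == "divergence":
            D = D * D
        elif jsd_variant != "distance":
            raise ValueError("jsd_variant must be 'divergence' or 'distance'")
    else:
        raise ValueError(f"unknown metric {metric!r}")
    np.fill_diagonal(D, 0.0)
    return DistanceMatrix(D, ids=table.sample_ids)


def write_distance_matrix(dm: DistanceMatrix, path) -> None:
    pd.DataFrame(dm.data, index=dm.ids, columns=dm.ids).rename_axis(
        "sample_id"
    ).to_csv(path, sep="\t")


def read_distance_matrix(path) -> DistanceMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return DistanceMatrix(df.to_numpy(), ids=[str(i) for i in df.index])
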
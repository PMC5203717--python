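"""Shared fixtures: toy tables, random trees and synthetic cohorts.

Heavy cohorts are session-scoped so the recovery and calibration tests can
share them.  All randomness is seeded; seeds were fixed when the tests were
written.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from skbio import TreeNode

from pneumotyper.beta import distance_matrix
from pneumotyper.cluster import select_k
from pneumotyper.simulate import (
    SimConfig,
    default_config,
    generate_cohort,
    generate_tree,
    truth_assignments,
)
from pneumotyper.table import OtuTable, filter_min_depth, rarefy


@pytest.fixture
def toy_table() -> OtuTable:
    counts = pd.DataFrame(
        [[5, 0, 3], [0, 7, 2], [1, 1, 1]],
        index=["s1", "s2", "s3"],
        columns=["OTU1", "OTU2", "OTU3"],
    )
    taxonomy = pd.DataFrame(
        {
            "domain": ["Bacteria"] * 3,
            "phylum": ["Firmicutes", "Firmicutes", "Proteobacteria"],
            "class": [""] * 3,
            "order": [""] * 3,
            "family": [""] * 3,
            "genus": ["Streptococcus", "Streptococcus", "Moraxella"],
        },
        index=["OTU1", "OTU2", "OTU3"],
    )
    return OtuTable(counts, taxonomy)


def random_tree_and_pair(rng, n_tips=10):
    """A random rooted tree plus two random composition vectors on its tips."""
    tree = generate_tree(n_otus=n_tips, seed=int(rng.integers(2**31)))
    a = rng.dirichlet(np.ones(n_tips) * 0.5)
    b = rng.dirichlet(np.ones(n_tips) * 0.5)
    return tree, a, b


def brute_force_wunifrac(a, b, tree: TreeNode, otu_ids, normalized=False) -> float:
    """Independent oracle: enumerate every branch, collect its descendant
    tips recursively, and sum l_b * |A_b - B_b|."""
    a = np.asarray(a, float) / np.sum(a)
    b = np.asarray(b, float) / np.sum(b)
    idx = {o: i for i, o in enumerate(otu_ids)}

    def tips_under(node):
        if node.is_tip():
            return [node.name]
        out = []
        for ch in node.children:
            out.extend(tips_under(ch))
        return out

    total = 0.0
    for node in tree.traverse(include_self=False):
        length = node.length or 0.0
        tips = [idx[t] for t in tips_under(node) if t in idx]
        fa = sum(a[i] for i in tips)
        fb = sum(b[i] for i in tips)
        total += length * abs(fa - fb)
    if not normalized:
        return total
    denom = 0.0
    for tip in tree.tips():
        d = 0.0
        node = tip
        while node.parent is not None:
            d += node.length or 0.0
            node = node.parent
        i = idx[tip.name]
        denom += d * (a[i] + b[i])
    return total / denom if denom > 0 else 0.0


def exhaustive_pam_cost(D: np.ndarray, k: int) -> float:
    """Independent oracle: minimum assignment cost over all medoid subsets."""
    from itertools import combinations

    n = D.shape[0]
    return min(
        D[:, list(subset)].min(axis=1).sum() for subset in combinations(range(n), k)
    )


# -- session-scoped synthetic cohorts -------------------------------------

@pytest.fixture(scope="session")
def cohort300():
    """Default world, 300 subjects: the recovery cohort."""
    return generate_cohort(default_config(n_subjects=300, seed=42))


@pytest.fixture(scope="session")
def recovery_bundle(cohort300):
    """QC'd + rarefied table, weighted UniFrac distances, fitted model and
    planted labels for the recovery cohort."""
    tab, _ = filter_min_depth(cohort300.table, 2000)
    tab = rarefy(tab, 2000, seed=7)
    dm = distance_matrix(tab, cohort300.tree, metric="wunifrac")
    model = select_k(dm, range(2, 11))
    truth = truth_assignments(cohort300).set_index("sample_id")["pneumotype"]
    return {"table": tab, "dm": dm, "model": model, "truth": truth,
            "cohort": cohort300}


@pytest.fixture(scope="session")
def big_cohort():
    """Large cohort (n = 4000 subjects) for law-of-large-numbers checks on
    the generator; at this size the +-2-point genus tolerance is >= 3 sd."""
    return generate_cohort(default_config(n_subjects=4000, seed=7))


def simple_config(n_subjects=50, k_types=2, seed=0, **overrides) -> SimConfig:
    """A hand-built minimal world: flat genus profiles, uniform marginals,
    identity-free transitions unless overridden."""
    genera = ["Staphylococcus", "Streptococcus", "Moraxella", "Corynebacterium",
              "Gemella"][: max(2, min(5, overrides.pop("n_genera", 5)))]
    k = k_types
    profiles = overrides.pop("profiles", None)
    if profiles is None:
        profiles = np.full((k, len(genera)), 1.0 / len(genera))
    uniform = np.full(k, 1.0 / k)
    cfg = SimConfig(
        n_subjects=n_subjects,
        genera=genera,
        pneumotypes=[f"T{i+1}" for i in range(k)],
        profiles=profiles,
        marginals={t: uniform.copy() for t in ("W1", "M1", "M3")},
        initial_probs_by_siblings={True: uniform.copy(), False: uniform.copy()},
        transitions={
            "W1->M1": overrides.pop("T1", np.full((k, k), 1.0 / k)),
            "M1->M3": overrides.pop("T2", np.full((k, k), 1.0 / k)),
        },
        seed=seed,
        **overrides,
    )
    cfg.validate()
    return cfg
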
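"""Alpha diversity: Shannon index, observed richness, rarefaction curves.

Natural logarithms throughout, so Shannon values are in nats.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .table import OtuTable


def shannon(counts) -> float:
    """Shannon diversity H = -sum p_i ln p_i over the positive proportions."""
    x = np.asarray(counts, dtype=float)
    total = x.sum()
    if total <= 0:
        raise ValueError("Shannon index undefined for an all-zero sample")
    p = x[x > 0] / total
    return float(-(p * np.log(p)).sum())


def observed_richness(counts) -> int:
    """Number of OTUs with a strictly positive count."""
    return int((np.asarray(counts) > 0).sum())


def alpha_table(table: OtuTable) -> pd.DataFrame:
    """Per-sample Shannon index and observed richness."""
    rows = [
        {
            "sample_id": sid,
            "shannon": shannon(row),
            "observed_richness": observed_richness(row),
        }
        for sid, row in zip(table.sample_ids, table.counts.to_numpy())
    ]
    return pd.DataFrame(rows)


def rarefaction_curve(counts, depths, replicates: int = 10, seed: int = 0) -> pd.DataFrame:
    """Mean richness and Shannon index at each subsampling depth.

    Each depth is subsampled ``replicates`` times without replacement
    (multivariate hypergeometric), seeded.
    """
    x = np.asarray(counts, dtype=np.int64)
    total = int(x.sum())
    depths = sorted(int(d) for d in depths)
    if depths and depths[-1] > total:
        raise ValueError(f"depth {depths[-1]} exceeds sample total {total}")
    rng = np.random.default_rng(seed)
    rows = []
    for d in depths:
        rich = np.empty(replicates)
        shan = np.empty(replicates)
        for r in range(replicates):
            sub = rng.multivariate_hypergeometric(x, d)
            rich[r] = observed_richness(sub)
            shan[r] = shannon(sub)
        rows.append(
            {"depth": d, "mean_richness": rich.mean(), "mean_shannon": shan.mean()}
        )
    return pd.DataFrame(rows)
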
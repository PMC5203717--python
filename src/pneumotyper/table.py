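"""OTU count tables, sample metadata, quality filters and rarefaction.

The universal currency of the pipeline is the :class:`OtuTable`: a samples x
OTUs matrix of non-negative integer read counts plus a per-OTU taxonomic
lineage (domain..genus, possibly partial).  Sample metadata carries the
longitudinal design: each infant (subject) is sampled at up to three clinical
visits, 1 week (``W1``), 1 month (``M1``) and 3 months (``M3``) of age.

All text I/O is plain TSV so tables round-trip through pandas.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

RANKS = ["domain", "phylum", "class", "order", "family", "genus"]

TIMEPOINTS = ["W1", "M1", "M3"]

#: DNA-concentration bins (ng/ul) used to stratify low-biomass samples.
#: Half-open [lower, upper); the top bin is closed below at 4.58.
DNA_CONC_BINS = [
    (0.1, "extremely_low"),
    (0.33, "very_low"),
    (0.8, "low"),
    (1.79, "medium"),
    (4.58, "high"),
    (math.inf, "very_high"),
]

METADATA_COLUMNS = [
    "sample_id", "subject_id", "timepoint", "age_days", "sex", "siblings",
    "csection", "antibiotics", "exclusively_breastfed", "mother_asthma",
    "birth_month", "dna_conc",
]


@dataclass
class OtuTable:
    """Samples x OTUs count matrix with taxonomy.

    Parameters
    ----------
    counts:
        DataFrame indexed by sample id with OTU ids as columns; entries are
        non-negative integers (read counts).
    taxonomy:
        DataFrame indexed by OTU id with columns ``domain`` .. ``genus``;
        unknown ranks are empty strings.  May cover a superset of the OTUs
        in ``counts``.
    """

    counts: pd.DataFrame
    taxonomy: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.counts.index.has_duplicates:
            dups = self.counts.index[self.counts.index.duplicated()].tolist()
            raise ValueError(f"duplicate sample ids: {dups}")
        if self.counts.columns.has_duplicates:
            dups = self.counts.columns[self.counts.columns.duplicated()].tolist()
            raise ValueError(f"duplicate OTU ids: {dups}")
        arr = self.counts.to_numpy()
        if arr.size and not np.issubdtype(arr.dtype, np.integer):
            # accept float storage only when every entry is integral
            if not np.all(np.isfinite(arr)) or np.any(arr != np.floor(arr)):
                r, c = np.argwhere((arr != np.floor(arr)) | ~np.isfinite(arr))[0]
                raise ValueError(
                    "non-integer count at sample "
                    f"{self.counts.index[r]!r}, OTU {self.counts.columns[c]!r}"
                )
            self.counts = self.counts.astype(np.int64)
            arr = self.counts.to_numpy()
        if arr.size and arr.min() < 0:
            r, c = np.argwhere(arr < 0)[0]
            raise ValueError(
                f"negative count at sample {self.counts.index[r]!r}, "
                f"OTU {self.counts.columns[c]!r}"
            )
        if self.taxonomy is None:
            self.taxonomy = pd.DataFrame(
                "", index=self.counts.columns, columns=RANKS
            )

    # -- basic views ------------------------------------------------------
    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def otu_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def n_samples(self) -> int:
        return self.counts.shape[0]

    def depths(self) -> pd.Series:
        """Total reads per sample."""
        return self.counts.sum(axis=1)

    def relative_abundance(self) -> pd.DataFrame:
        """Row-normalised counts (rows with zero total stay all-zero)."""
        totals = self.counts.sum(axis=1).to_numpy(dtype=float)
        totals[totals == 0] = 1.0
        return self.counts.div(totals, axis=0)

    def genus(self, otu_id: str) -> str:
        return str(self.taxonomy.loc[otu_id, "genus"])

    def select_samples(self, sample_ids) -> "OtuTable":
        return OtuTable(self.counts.loc[list(sample_ids)], self.taxonomy)

    # -- I/O --------------------------------------------------------------
    def write(self, counts_path, taxonomy_path=None) -> None:
        self.counts.rename_axis("sample_id").to_csv(counts_path, sep="\t")
        if taxonomy_path is not None:
            lineage = self.taxonomy[RANKS].agg(";".join, axis=1)
            lineage.rename("lineage").rename_axis("otu_id").to_csv(
                taxonomy_path, sep="\t"
            )


def parse_lineage(lineage: str) -> dict[str, str]:
    """Split a semicolon-separated lineage into rank -> name (missing -> '')."""
    parts = [p.strip() for p in str(lineage).split(";")]
    return {rank: (parts[i] if i < len(parts) else "") for i, rank in enumerate(RANKS)}


def read_otu_table(counts_path, taxonomy_path=None) -> OtuTable:
    """Read a counts TSV (rows = samples, header = OTU ids) and a taxonomy TSV.

    The taxonomy file maps ``otu_id`` to a semicolon-separated lineage
    (domain;phylum;...;genus); trailing ranks may be absent.
    """
    counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    if counts.shape[0] == 0:
        raise ValueError("no samples in counts file")
    counts.index = counts.index.astype(str)
    counts.columns = counts.columns.astype(str)
    taxonomy = None
    if taxonomy_path is not None:
        tax_raw = pd.read_csv(
            taxonomy_path, sep="\t", index_col=0, header=0, dtype=str
        )
        lineages = tax_raw.iloc[:, 0].fillna("")
        taxonomy = pd.DataFrame(
            [parse_lineage(lin) for lin in lineages],
            index=lineages.index.astype(str),
        )[RANKS]
        taxonomy = taxonomy.reindex(counts.columns, fill_value="")
    return OtuTable(counts, taxonomy)


def read_metadata(path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "subject_id": str})
    return validate_metadata(meta)


def validate_metadata(meta: pd.DataFrame) -> pd.DataFrame:
    bad = set(meta["timepoint"]) - set(TIMEPOINTS)
    if bad:
        raise ValueError(f"unknown timepoints: {sorted(bad)}; expected {TIMEPOINTS}")
    dup = meta.duplicated(subset=["subject_id", "timepoint"])
    if dup.any():
        raise ValueError(
            "more than one sample per (subject, timepoint): "
            f"{meta.loc[dup, ['subject_id', 'timepoint']].to_records(index=False)}"
        )
    return meta


# -- QC filters -----------------------------------------------------------

def filter_min_depth(table: OtuTable, min_depth: int = 2000):
    """Drop samples with fewer than ``min_depth`` reads.

    Returns the filtered table and an exclusion report listing removed
    samples with their depths.
    """
    if min_depth < 1:
        raise ValueError("min_depth must be >= 1")
    depths = table.depths()
    keep = depths >= min_depth
    report = pd.DataFrame(
        {"sample_id": depths.index[~keep], "depth": depths[~keep].to_numpy()}
    ).reset_index(drop=True)
    return OtuTable(table.counts.loc[keep], table.taxonomy), report


def exclude_diversity_outliers(table: OtuTable, z: float = 5.0):
    """Drop samples whose Shannon index exceeds ``mean + z * sd``.

    The mean and standard deviation are computed once over all samples (a
    single pass, not iterated).  With fewer than two samples, or a zero
    standard deviation, nothing is removed.
    """
    from .diversity import shannon

    if table.n_samples < 2:
        raise ValueError("need at least 2 samples")
    sdi = np.array([shannon(row) for row in table.counts.to_numpy()])
    mean, sd = sdi.mean(), sdi.std(ddof=1)
    if sd == 0 or not np.isfinite(z):
        cutoff = np.inf
    else:
        cutoff = mean + z * sd
    keep = sdi <= cutoff
    report = pd.DataFrame(
        {
            "sample_id": np.asarray(table.sample_ids)[~keep],
            "shannon": sdi[~keep],
            "cutoff": cutoff,
        }
    ).reset_index(drop=True)
    return OtuTable(table.counts.loc[keep], table.taxonomy), report


def rarefy(table: OtuTable, depth: int = 2000, seed: int = 0) -> OtuTable:
    """Subsample every sample to exactly ``depth`` reads without replacement.

    One multivariate-hypergeometric draw per sample; deterministic for a
    given seed.  Samples shallower than ``depth`` raise (filter first).
    """
    rng = np.random.default_rng(seed)
    counts = table.counts.to_numpy()
    out = np.zeros_like(counts)
    for i, sid in enumerate(table.sample_ids):
        total = counts[i].sum()
        if total < depth:
            raise ValueError(f"sample {sid!r} has {total} reads < depth {depth}")
        out[i] = rng.multivariate_hypergeometric(counts[i], depth)
    rare = pd.DataFrame(out, index=table.counts.index, columns=table.counts.columns)
    return OtuTable(rare, table.taxonomy)


def aggregate_rank(table: OtuTable, rank: str) -> OtuTable:
    """Sum OTU counts into taxa at ``rank`` (phylum..genus).

    OTUs with an empty name at that rank are pooled into ``unclassified``.
    Per-sample totals are conserved exactly.
    """
    if rank not in RANKS:
        raise ValueError(f"rank must be one of {RANKS}")
    names = table.taxonomy.loc[table.otu_ids, rank].replace("", "unclassified")
    agg = table.counts.T.groupby(names.to_numpy()).sum().T
    tax = pd.DataFrame("", index=agg.columns, columns=RANKS)
    tax[rank] = agg.columns
    return OtuTable(agg, tax)


def categorize_dna_concentration(conc: float) -> str:
    """Bin a DNA concentration (ng/ul) into the six low-biomass categories."""
    if conc < 0:
        raise ValueError(f"negative DNA concentration: {conc}")
    for upper, label in DNA_CONC_BINS:
        if conc < upper:
            return label
    raise AssertionError("unreachable")


# -- cohort summaries -----------------------------------------------------

def round_half_up(x: float, decimals: int = 0) -> float:
    """Round half away from zero (the convention of the printed tables)."""
    factor = 10.0 ** decimals
    return math.floor(abs(x) * factor + 0.5) / factor * (1 if x >= 0 else -1)


def format_count_percent(count: int, denom: int, decimals: int = 0) -> str:
    """Render ``count (pct%)`` with a given number of percent decimals."""
    pct = 0.0 if denom == 0 else 100.0 * count / denom
    pct = round_half_up(pct, decimals)
    return f"{count} ({pct:.{decimals}f}%)"


SUBJECT_FIELDS = ["sex", "siblings", "csection", "mother_asthma"]
VISIT_FIELDS = ["antibiotics", "exclusively_breastfed"]


def cohort_summary(
    metadata: pd.DataFrame,
    by: str | None = None,
    decimals: int = 0,
    denominators: dict | None = None,
) -> pd.DataFrame:
    """Count/percentage summary of the cohort covariates.

    Subject-level fields (sex, siblings, C-section, maternal asthma) are
    counted once per subject; visit-level fields (antibiotics, exclusive
    breastfeeding) once per sample within each time-point.  ``by`` adds a
    second stratification column (e.g. a pneumotype label column present in
    ``metadata``).  ``denominators`` may override the denominator for a
    specific ``(field, group)`` cell, to handle missing covariate data.

    Returns a tidy frame with columns field/group/n/denominator/percent/label.
    """
    if metadata.empty:
        raise ValueError("empty metadata")
    denominators = denominators or {}
    rows = []

    def add(fieldname, group, sub: pd.DataFrame, level: str):
        vals = sub[fieldname]
        if fieldname == "sex":  # report boys, matching the printed tables
            n = int((vals == "male").sum())
        else:
            n = int(sum(bool(v) for v in vals if pd.notna(v)))
        denom = denominators.get((fieldname, group), int(vals.notna().sum()))
        pct = 0.0 if denom == 0 else round_half_up(100.0 * n / denom, decimals)
        rows.append(
            {
                "field": fieldname,
                "group": group,
                "level": level,
                "n": n,
                "denominator": denom,
                "percent": pct,
                "label": format_count_percent(n, denom, decimals),
            }
        )

    subjects = metadata.sort_values("timepoint").drop_duplicates("subject_id")
    for fieldname in SUBJECT_FIELDS:
        if fieldname not in metadata.columns:
            continue
        if by is None:
            add(fieldname, "all_subjects", subjects, "subject")
        else:
            for g, sub in metadata.groupby(by):
                add(fieldname, g, sub, "sample")
    for fieldname in VISIT_FIELDS:
        if fieldname not in metadata.columns:
            continue
        group_cols = ["timepoint"] if by is None else ["timepoint", by]
        for g, sub in metadata.groupby(group_cols):
            add(fieldname, g if len(g) > 1 else g[0], sub, "sample")
    return pd.DataFrame(rows)
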
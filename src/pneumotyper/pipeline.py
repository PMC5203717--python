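"""End-to-end analysis: QC -> rarefaction -> diversity -> distances ->
pneumotype clustering -> indicators -> core microbiota -> dynamics ->
distance-ratio test, with a machine-readable JSON report.

Reports are deterministic for a given configuration and seed: every
stochastic stage derives its own seed from the run seed, all tables are
written with fixed float formatting, and the JSON is dumped with sorted
keys.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import beta, cluster, core, diversity, indicators, simulate, table, trajectory

REPORT_VERSION = "1.0"


@dataclass
class RunConfig:
    """Configuration of a full pipeline run (file inputs or simulation)."""

    counts_path: str | None = None
    taxonomy_path: str | None = None
    tree_path: str | None = None
    metadata_path: str | None = None
    simulate: bool = False
    n_subjects: int = 300
    rarefaction_depth: int = 2000
    min_depth: int = 2000
    sdi_outlier_z: float = 5.0
    metric: str = "wunifrac"
    normalized_unifrac: bool = True
    k: int | None = None          # None -> silhouette selection over k_range
    k_range: tuple = (2, 10)
    n_perm_optimality: int = 1000
    n_perm_indicators: int = 999
    n_perm_ratio: int = 1000
    seed: int = 0
    out_dir: str = "results/pipeline"


def _stage_seed(seed: int, offset: int) -> int:
    """Stable per-stage substream seed (< 2**31)."""
    return (seed * 1_000_003 + offset) % (2**31)


def run_full_pipeline(config: RunConfig) -> dict:
    """Execute every stage and return (and write) the report bundle."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "version": REPORT_VERSION,
        "seed": config.seed,
        "stages": {},
    }

    # -- inputs -----------------------------------------------------------
    if config.simulate:
        cfg = simulate.default_config(
            n_subjects=config.n_subjects, seed=_stage_seed(config.seed, 1)
        )
        cohort = simulate.generate_cohort(cfg)
        tab, tree, metadata = cohort.table, cohort.tree, cohort.metadata
        report["stages"]["simulate"] = {
            "n_subjects": config.n_subjects,
            "seed": cfg.seed,
            "n_samples": tab.n_samples,
        }
    else:
        if config.counts_path is None or config.metadata_path is None:
            raise ValueError("need counts and metadata paths (or simulate=True)")
        tab = table.read_otu_table(config.counts_path, config.taxonomy_path)
        metadata = table.read_metadata(config.metadata_path)
        tree = beta.read_tree(config.tree_path) if config.tree_path else None
        cohort = None
    if config.metric == "wunifrac" and tree is None:
        raise ValueError("metric 'wunifrac' requires a phylogenetic tree (tree_path)")

    # -- QC + rarefaction -------------------------------------------------
    tab, depth_report = table.filter_min_depth(tab, config.min_depth)
    tab, sdi_report = table.exclude_diversity_outliers(tab, config.sdi_outlier_z)
    rare_seed = _stage_seed(config.seed, 2)
    tab = table.rarefy(tab, config.rarefaction_depth, seed=rare_seed)
    metadata = metadata[metadata["sample_id"].isin(tab.sample_ids)].reset_index(drop=True)
    report["stages"]["qc"] = {
        "excluded_low_depth": int(len(depth_report)),
        "excluded_sdi_outliers": int(len(sdi_report)),
        "rarefaction_depth": config.rarefaction_depth,
        "rarefaction_seed": rare_seed,
        "n_samples": tab.n_samples,
    }

    # -- alpha diversity --------------------------------------------------
    alpha = diversity.alpha_table(tab)
    alpha.to_csv(out / "alpha_diversity.tsv", sep="\t", index=False,
                 float_format="%.10g")
    report["stages"]["alpha"] = {
        "mean_shannon": float(alpha["shannon"].mean()),
        "mean_richness": float(alpha["observed_richness"].mean()),
    }

    # -- distances --------------------------------------------------------
    dm = beta.distance_matrix(
        tab, tree, metric=config.metric, normalized=config.normalized_unifrac
    )
    beta.write_distance_matrix(dm, out / "distance_matrix.tsv")
    report["stages"]["beta"] = {"metric": config.metric, "n_samples": len(dm.ids)}

    # -- clustering -------------------------------------------------------
    if config.k is None:
        model = cluster.select_k(dm, range(config.k_range[0], config.k_range[1] + 1))
    else:
        model = cluster.pam(dm, config.k)
        per_sample, asw = cluster.silhouette(dm, model.labels)
        model.silhouette_per_sample, model.average_silhouette_width = per_sample, asw
    model.labels.rename_axis("sample_id").to_csv(out / "pneumotype_labels.tsv", sep="\t")
    opt_seed = _stage_seed(config.seed, 3)
    optimality = cluster.cluster_optimality_test(
        dm, model.labels, n_perm=config.n_perm_optimality, seed=opt_seed
    )
    report["stages"]["cluster"] = {
        "k": model.k,
        "medoids": model.medoids,
        "average_silhouette_width": model.average_silhouette_width,
        "asw_by_k": (
            {int(k): float(v) for k, v in model.asw_by_k.items()}
            if model.asw_by_k is not None else None
        ),
        "optimality": {**optimality, "seed": opt_seed},
    }

    # -- indicator OTUs ---------------------------------------------------
    ind_seed = _stage_seed(config.seed, 4)
    ind = indicators.indicator_analysis(
        tab, model.labels, n_perm=config.n_perm_indicators, seed=ind_seed
    )
    ind.to_csv(out / "indicator_otus.tsv", sep="\t", index=False,
               float_format="%.10g")
    top = ind.groupby("cluster").first()
    report["stages"]["indicators"] = {
        "seed": ind_seed,
        "n_perm": config.n_perm_indicators,
        "top_by_cluster": {
            str(c): {"otu_id": r["otu_id"], "indval": float(r["indval"]),
                     "p_value": float(r["p_value"]), "genus": r["genus"]}
            for c, r in top.iterrows()
        },
    }

    # -- core microbiota --------------------------------------------------
    profiles = core.core_profiles(tab, metadata)
    core_frame = core.profiles_frame(profiles)
    core_frame.to_csv(out / "core_profiles.tsv", sep="\t", index=False,
                      float_format="%.10g")
    report["stages"]["core"] = {"n_complete_subjects": len(profiles)}
    assignments = metadata[["subject_id", "timepoint"]].copy()
    assignments["pneumotype"] = model.labels.loc[metadata["sample_id"]].to_numpy()
    if len(profiles) >= 10:
        trend = core.core_trend_test(profiles)
        report["stages"]["core"]["trend"] = trend.to_dict(orient="records")
        stab = trajectory.stability_test(assignments, per_pneumotype=False)
        stable_ids = set(stab["stable_subjects"])
        complete = {p.subject_id for p in profiles}
        stable_map = {s: (s in stable_ids) for s in complete}
        if 2 <= sum(stable_map.values()) and 2 <= sum(not v for v in stable_map.values()):
            comp = core.core_by_stability(profiles, stable_map)
            report["stages"]["core"]["by_stability"] = {
                "anova_F": comp["anova_F"], "anova_p": comp["anova_p"],
                "n_stable": comp["n_stable"], "n_changing": comp["n_changing"],
                "per_timepoint": comp["per_timepoint"].to_dict(orient="records"),
            }

    # -- dynamics ---------------------------------------------------------
    traj: dict = {}
    for t1, t2 in [("W1", "M1"), ("M1", "M3")]:
        counts_tab = trajectory.transition_counts(assignments, t1, t2)
        counts_tab.to_csv(out / f"transitions_{t1}_{t2}.tsv", sep="\t")
        traj[f"{t1}->{t2}"] = {
            "n": int(counts_tab.to_numpy().sum()),
            "dependence": trajectory.dependence_test(counts_tab),
        }
    traj["agreement"] = {
        "per_pair": trajectory.agreement_comparison(assignments)["per_pair"]
        .to_dict(orient="records"),
        "p_value": trajectory.agreement_comparison(assignments)["p_value"],
    }
    stab_full = trajectory.stability_test(assignments)
    traj["stability"] = {
        k: v for k, v in stab_full.items() if k not in ("per_pneumotype", "stable_subjects")
    }
    traj["stability"]["per_pneumotype"] = (
        stab_full["per_pneumotype"].to_dict(orient="records")
    )
    report["stages"]["trajectory"] = traj

    # -- distance-ratio test ----------------------------------------------
    ratio_seed = _stage_seed(config.seed, 5)
    ratios = {}
    for t1, t2 in [("W1", "M1"), ("M1", "M3")]:
        try:
            ratios[f"{t1}->{t2}"] = trajectory.ratio_permutation_test(
                dm, metadata, t1, t2, n_perm=config.n_perm_ratio, seed=ratio_seed
            )
        except ValueError as err:
            ratios[f"{t1}->{t2}"] = {"error": str(err)}
    report["stages"]["ratio"] = {**ratios, "seed": ratio_seed}

    report_path = out / "report.json"
    report_path.write_text(json.dumps(report, indent=2, sort_keys=True,
                                      default=_json_default) + "\n")
    return report


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
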
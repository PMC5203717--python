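"""Synthetic longitudinal airway-cohort generator.

Emulates the structure the analysis assumes: ~695 infants sampled at 1 week
(W1), 1 month (M1) and 3 months (M3); five community state types, four
dominated by Staphylococcus, Streptococcus, Moraxella and Corynebacterium
and one mixed/diverse type; Markov pneumotype transitions between visits;
a per-subject persistent ("core") set of OTUs carrying a declining share of
reads (0.90 / 0.81 / 0.63 by default); Dirichlet-multinomial count noise;
log-normal sequencing depth with a floor; per-visit missingness; and
covariates, with older siblings tilting infants toward the Moraxella and
mixed types.

The default configuration is calibrated so that the *expected* cohort-level
genus trajectories equal the stated succession: Staphylococcus 49/22/10 %,
Streptococcus 17/31/29 % and Moraxella 9/13/23 % of reads at W1/M1/M3.
Pneumotype marginals per visit are taken from the observed per-visit cluster
sizes, genus profiles are solved by a minimum-norm correction so the
mixture reproduces the three genus trajectories exactly, and transition
matrices are sticky-diagonal blends consistent with those marginals.

Composition construction (per sample, pneumotype k at visit t with core
share rho_t): every genus g with profile share s contributes rho_t * s to
the subject's persistent OTU of that genus and (1 - rho_t) * s spread over
a per-sample random subset of the genus's transient OTUs.  Genus totals --
and hence the expected genus trajectory -- are exact by construction, and
the expected fraction of reads on persistent OTUs is exactly rho_t.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skbio import TreeNode

from .table import RANKS, TIMEPOINTS, OtuTable, parse_lineage

GENERA = [
    "Staphylococcus", "Streptococcus", "Moraxella", "Corynebacterium",
    "Gemella", "Dolosigranulum", "Haemophilus", "Prevotella", "Neisseria",
    "Enterococcus",
]

GENUS_LINEAGES = {
    "Staphylococcus": "Bacteria;Firmicutes;Bacilli;Bacillales;Staphylococcaceae;Staphylococcus",
    "Streptococcus": "Bacteria;Firmicutes;Bacilli;Lactobacillales;Streptococcaceae;Streptococcus",
    "Moraxella": "Bacteria;Proteobacteria;Gammaproteobacteria;Pseudomonadales;Moraxellaceae;Moraxella",
    "Corynebacterium": "Bacteria;Actinobacteria;Actinobacteria;Corynebacteriales;Corynebacteriaceae;Corynebacterium",
    "Gemella": "Bacteria;Firmicutes;Bacilli;Bacillales;Bacillales_XI;Gemella",
    "Dolosigranulum": "Bacteria;Firmicutes;Bacilli;Lactobacillales;Carnobacteriaceae;Dolosigranulum",
    "Haemophilus": "Bacteria;Proteobacteria;Gammaproteobacteria;Pasteurellales;Pasteurellaceae;Haemophilus",
    "Prevotella": "Bacteria;Bacteroidetes;Bacteroidia;Bacteroidales;Prevotellaceae;Prevotella",
    "Neisseria": "Bacteria;Proteobacteria;Betaproteobacteria;Neisseriales;Neisseriaceae;Neisseria",
    "Enterococcus": "Bacteria;Firmicutes;Bacilli;Lactobacillales;Enterococcaceae;Enterococcus",
}

PNEUMOTYPES = ["I", "II", "III", "IV", "V"]

#: Per-visit pneumotype sample counts used as the marginal distribution of
#: community types at each visit (I..V).
VISIT_CLUSTER_COUNTS = {
    "W1": np.array([297, 87, 51, 24, 85], dtype=float),
    "M1": np.array([137, 211, 89, 53, 131], dtype=float),
    "M3": np.array([54, 196, 165, 30, 178], dtype=float),
}

#: Stated cohort-level genus trajectories (fraction of reads at W1/M1/M3).
GENUS_TRAJECTORIES = {
    "Staphylococcus": np.array([0.49, 0.22, 0.10]),
    "Streptococcus": np.array([0.17, 0.31, 0.29]),
    "Moraxella": np.array([0.09, 0.13, 0.23]),
}

# Base genus profiles per pneumotype (rows = pneumotype, cols = GENERA);
# the three constrained genera get a minimum-norm correction at config time.
_BASE_PROFILES = np.array(
    #  Sta   Str   Mor   Cor   Gem   Dol   Hae   Pre   Nei   Ent
    [[0.80, 0.05, 0.02, 0.03, 0.02, 0.02, 0.02, 0.01, 0.02, 0.01],   # I
     [0.05, 0.75, 0.04, 0.03, 0.03, 0.02, 0.03, 0.02, 0.02, 0.01],   # II
     [0.03, 0.08, 0.75, 0.03, 0.02, 0.02, 0.03, 0.01, 0.02, 0.01],   # III
     [0.04, 0.04, 0.02, 0.78, 0.02, 0.03, 0.02, 0.01, 0.03, 0.01],   # IV
     [0.05, 0.10, 0.05, 0.03, 0.24, 0.12, 0.14, 0.12, 0.10, 0.05]]   # V
)


@dataclass
class SimConfig:
    """Full description of the simulated world.  See module docstring."""

    n_subjects: int = 695
    genera: list = field(default_factory=lambda: list(GENERA))
    otus_per_genus: int = 15
    core_eligible_per_genus: int = 3
    pneumotypes: list = field(default_factory=lambda: list(PNEUMOTYPES))
    profiles: np.ndarray = None          # (k_types x n_genera), rows sum to 1
    #: expected post-tilt genus shares per pneumotype; equals ``profiles``
    #: when no tilt compensation was applied
    target_profiles: np.ndarray = None
    marginals: dict = None               # timepoint -> (k_types,) probs
    initial_probs_by_siblings: dict = None  # bool -> (k_types,) probs
    transitions: dict = None             # "W1->M1"/"M1->M3" -> (k x k)
    dirichlet_concentration: float = 300.0
    core_share: dict = field(
        default_factory=lambda: {"W1": 0.90, "M1": 0.81, "M3": 0.63}
    )
    core_choice_probs: tuple = (0.6, 0.25, 0.15)
    transient_active_per_genus: int = 4
    tree_within_genus_scale: float = 0.12
    tree_between_genus_scale: float = 0.5
    #: sd of the per-subject lognormal genus tilt, persistent across visits;
    #: this is what makes an infant's samples mutually more similar than
    #: samples from different infants, independent of pneumotype
    #: persistence.  The renormalization bias it induces on cohort genus
    #: means is compensated numerically during profile calibration.
    subject_genus_tilt_sd: float = 0.3
    depth_sdlog: float = 1.1
    depth_meanlog: float = math.log(2000) + 1.645 * 1.1  # P(depth < 2000) = 5 %
    depth_floor: int = 500
    missingness: dict = field(
        default_factory=lambda: {"W1": 0.22, "M1": 0.11, "M3": 0.10}
    )
    covariates: dict = field(
        default_factory=lambda: {
            "siblings": 0.56, "csection": 0.22, "male": 0.512,
            "mother_asthma": 0.26,
            "antibiotics": {"W1": 0.02, "M1": 0.04, "M3": 0.05},
            "exclusively_breastfed": {"W1": 0.88, "M1": 0.76, "M3": 0.63},
            "age_days": {"W1": (8.0, 3.0), "M1": (32.0, 5.0), "M3": (93.0, 6.0)},
        }
    )
    sibling_logodds: dict = field(default_factory=lambda: {"III": 1.0, "V": 0.8})
    seed: int = 0

    # -- derived ----------------------------------------------------------
    @property
    def otu_ids(self) -> list:
        return [
            f"{g}_OTU{i}" for g in self.genera
            for i in range(1, self.otus_per_genus + 1)
        ]

    @property
    def genus_of_otu(self) -> dict:
        return {o: o.rsplit("_OTU", 1)[0] for o in self.otu_ids}

    def core_eligible(self, genus: str) -> list:
        return [f"{genus}_OTU{i}" for i in range(1, self.core_eligible_per_genus + 1)]

    def transient(self, genus: str) -> list:
        return [
            f"{genus}_OTU{i}"
            for i in range(self.core_eligible_per_genus + 1, self.otus_per_genus + 1)
        ]

    def dominant_otu(self, pneumotype: str) -> str:
        """The planted strongest indicator OTU of a pneumotype: OTU1 of the
        genus with the highest expected specificity A (share in this type
        relative to its summed share across types; fidelity B is the same
        for every genus's OTU1, so A decides)."""
        k = self.pneumotypes.index(pneumotype)
        prof = self.target_profiles if self.target_profiles is not None else self.profiles
        specificity = prof[k] / prof.sum(axis=0)
        return f"{self.genera[int(np.argmax(specificity))]}_OTU1"

    def validate(self) -> None:
        k = len(self.pneumotypes)
        if self.profiles.shape != (k, len(self.genera)):
            raise ValueError("profiles shape does not match pneumotypes x genera")
        if not np.allclose(self.profiles.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("profile rows must sum to 1")
        if (self.profiles < 0).any():
            raise ValueError("negative profile entries")
        for t, p in self.marginals.items():
            if not math.isclose(p.sum(), 1.0, abs_tol=1e-9):
                raise ValueError(f"marginals[{t}] do not sum to 1")
        for name, T in self.transitions.items():
            if not np.allclose(T.sum(axis=1), 1.0, atol=1e-9) or (T < 0).any():
                raise ValueError(f"transition matrix {name} rows must be probabilities")
        for probs in self.initial_probs_by_siblings.values():
            if not math.isclose(probs.sum(), 1.0, abs_tol=1e-9) or (probs < 0).any():
                raise ValueError("initial pneumotype probabilities invalid")
        if not self.dirichlet_concentration > 0:
            raise ValueError("dirichlet_concentration must be > 0")
        genera = set(self.genera)
        for otu, g in self.genus_of_otu.items():
            if g not in genera:
                raise ValueError(f"OTU {otu!r} maps to unknown genus {g!r}")


def _transition_from_marginals(p_from: np.ndarray, p_to: np.ndarray,
                               alpha: float) -> np.ndarray:
    """Sticky-diagonal transition matrix alpha*I + (1-alpha)*1 q^T whose
    stationary pass maps p_from onto p_to exactly."""
    q = (p_to - alpha * p_from) / (1 - alpha)
    if (q < 0).any():
        raise ValueError("alpha too large for these marginals")
    return alpha * np.eye(len(p_from)) + (1 - alpha) * np.tile(q, (len(p_from), 1))


def _tilt_compensate(profiles: np.ndarray, tilt_sd: float,
                     n_draws: int = 40_000, seed: int = 12345) -> np.ndarray:
    """Pre-compensate the renormalization bias of the per-subject lognormal
    genus tilt: returns q such that E[normalize(q * w)] = profiles row-wise,
    with w ~ iid lognormal(0, tilt_sd).  Deterministic fixed point against a
    fixed Monte-Carlo sample of tilts."""
    if tilt_sd == 0:
        return profiles.copy()
    rng = np.random.default_rng(seed)
    W = rng.lognormal(0.0, tilt_sd, size=(n_draws, profiles.shape[1]))
    out = np.empty_like(profiles)
    for i, target in enumerate(profiles):
        q = target.copy()
        for _ in range(60):
            tilted = q * W
            mean = (tilted / tilted.sum(axis=1, keepdims=True)).mean(axis=0)
            err = np.abs(mean - target).max()
            q = np.clip(q * target / mean, 1e-6, None)
            q = q / q.sum()
            if err < 1e-6:
                break
        out[i] = q
    return out


def _solve_profiles(marginals: dict) -> np.ndarray:
    """Correct the base profiles so that the pneumotype mixture reproduces
    the stated genus trajectories exactly."""
    profiles = _BASE_PROFILES.copy()
    A = np.vstack([marginals[t] for t in TIMEPOINTS])  # 3 x k
    constrained = []
    from scipy.optimize import minimize

    floor = 0.005  # keeps every per-genus persistent OTU safely detectable
    for genus, target in GENUS_TRAJECTORIES.items():
        j = GENERA.index(genus)
        s0 = profiles[:, j]
        res = minimize(
            lambda s: np.sum((s - s0) ** 2 / s0),
            x0=np.maximum(s0, floor),
            jac=lambda s: 2 * (s - s0) / s0,
            method="SLSQP",
            bounds=[(floor, 0.95)] * len(s0),
            constraints={"type": "eq", "fun": lambda s: A @ s - target,
                         "jac": lambda s: A},
        )
        if not res.success or np.abs(A @ res.x - target).max() > 1e-8:
            raise ValueError(f"could not calibrate {genus} profile: {res.message}")
        profiles[:, j] = res.x
        constrained.append(j)
    # re-balance the unconstrained genera so every row sums to 1 again
    free = [j for j in range(profiles.shape[1]) if j not in constrained]
    for row in profiles:
        residual = 1.0 - row[constrained].sum()
        row[free] *= residual / row[free].sum()
    if (profiles < 0.004).any():
        raise ValueError("profiles need every genus above the persistence floor")
    return profiles


def _sibling_tilt(pi: np.ndarray, prevalence: float, logodds: np.ndarray):
    """Conditional pneumotype probabilities given sibling status whose
    mixture equals the target marginal pi (fixed-point solve)."""
    w = np.exp(logodds)
    u = pi.copy()
    for _ in range(500):
        with_sib = u * w / (u * w).sum()
        without = u / u.sum()
        mix = prevalence * with_sib + (1 - prevalence) * without
        ratio = pi / mix
        u = u * ratio
        if np.abs(mix - pi).max() < 1e-12:
            break
    return {True: u * w / (u * w).sum(), False: u / u.sum()}


def default_config(n_subjects: int = 695, seed: int = 0, **overrides) -> SimConfig:
    """The calibrated default world (see module docstring)."""
    marginals = {
        t: c / c.sum() for t, c in VISIT_CLUSTER_COUNTS.items()
    }
    cfg = SimConfig(n_subjects=n_subjects, seed=seed, **overrides)
    cfg.marginals = marginals
    cfg.target_profiles = _solve_profiles(marginals)
    cfg.profiles = _tilt_compensate(cfg.target_profiles, cfg.subject_genus_tilt_sd)
    # stickiness chosen so the expected same-pneumotype agreement is ~28 %
    # (W1->M1) and ~34 % (M1->M3), as in the study cohort
    cfg.transitions = {
        "W1->M1": _transition_from_marginals(marginals["W1"], marginals["M1"], 0.082),
        "M1->M3": _transition_from_marginals(marginals["M1"], marginals["M3"], 0.146),
    }
    logodds = np.array(
        [cfg.sibling_logodds.get(k, 0.0) for k in cfg.pneumotypes]
    )
    cfg.initial_probs_by_siblings = _sibling_tilt(
        marginals["W1"], cfg.covariates["siblings"], logodds
    )
    cfg.validate()
    return cfg


def expected_genus_share(config: SimConfig, timepoint: str, genus: str) -> float:
    """Expected cohort-level share of reads from a genus at a visit (the
    subject tilt is mean-compensated, so the target profiles apply)."""
    j = config.genera.index(genus)
    prof = config.target_profiles if config.target_profiles is not None else config.profiles
    return float(config.marginals[timepoint] @ prof[:, j])


# -- tree ----------------------------------------------------------------

def _join_random(nodes: list, rng, scale: float, min_length: float = 0.0) -> TreeNode:
    nodes = list(nodes)
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        parent = TreeNode()
        a.length = min_length + float(rng.exponential(scale)) + 1e-6
        b.length = min_length + float(rng.exponential(scale)) + 1e-6
        parent.extend([a, b])
        nodes.append(parent)
    return nodes[0]


def generate_tree(n_otus: int = None, seed: int = 0, otu_ids=None,
                  genus_of=None, within_scale: float = 0.03,
                  between_scale: float = 0.5) -> TreeNode:
    """Random rooted coalescent-style tree with exponential branch lengths.

    OTUs of the same genus coalesce within one random subtree (short
    branches), so phylogenetic distance correlates with taxonomy.  The
    genus subtrees attach to a star-like backbone with stems of at least
    ``between_scale``: the signature genera of airway communities belong to
    different families and phyla, so every pair must be comparably deeply
    separated rather than left to the luck of a random coalescent.  Either
    ``n_otus`` (tips named OTU1..n, one genus) or explicit ``otu_ids`` +
    ``genus_of``.
    """
    if otu_ids is None:
        if n_otus is None or n_otus < 2:
            raise ValueError("need n_otus >= 2 or explicit otu_ids")
        otu_ids = [f"OTU{i}" for i in range(1, n_otus + 1)]
    if len(otu_ids) < 2:
        raise ValueError("need at least 2 OTUs")
    genus_of = genus_of or {o: "genus1" for o in otu_ids}
    rng = np.random.default_rng(seed)
    subtrees = []
    for genus in dict.fromkeys(genus_of[o] for o in otu_ids):
        tips = [TreeNode(name=o) for o in otu_ids if genus_of[o] == genus]
        sub = _join_random(tips, rng, within_scale)
        if len(tips) > 1:
            # normalize the subtree so its deepest tip sits 3 * within_scale
            # below the genus root: within-genus spread must stay well below
            # the between-genus stems whatever the coalescent drew
            depth = max(
                sum(n.length for n in tip.ancestors() if n.length) + tip.length
                for tip in sub.tips()
            )
            factor = 3 * within_scale / depth
            for node in sub.traverse(include_self=False):
                node.length *= factor
        subtrees.append(sub)
    if len(subtrees) == 1:
        root = subtrees[0]
    else:
        root = TreeNode()
        for sub in subtrees:
            sub.length = between_scale * (1.0 + float(rng.exponential(0.3)))
        root.extend(subtrees)
    root.length = None
    return root


# -- cohort ---------------------------------------------------------------

@dataclass
class SyntheticCohort:
    table: OtuTable
    tree: TreeNode
    metadata: pd.DataFrame
    truth: dict
    config: SimConfig


def generate_cohort(config: SimConfig) -> SyntheticCohort:
    """Draw a full cohort from the configured world (fully seeded)."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    otu_ids = config.otu_ids
    otu_index = {o: j for j, o in enumerate(otu_ids)}
    genera = config.genera
    k_types = len(config.pneumotypes)
    tmats = [config.transitions["W1->M1"], config.transitions["M1->M3"]]

    tree = generate_tree(
        otu_ids=otu_ids, genus_of=config.genus_of_otu,
        seed=int(rng.integers(2**31)),
        within_scale=config.tree_within_genus_scale,
        between_scale=config.tree_between_genus_scale,
    )

    cov = config.covariates
    records, count_rows, sample_ids = [], [], []
    truth_pt, truth_core, compositions = {}, {}, {}

    for s in range(config.n_subjects):
        subject = f"S{s + 1:04d}"
        siblings = bool(rng.random() < cov["siblings"])
        csection = bool(rng.random() < cov["csection"])
        male = bool(rng.random() < cov["male"])
        asthma = bool(rng.random() < cov["mother_asthma"])
        birth_month = int(rng.integers(1, 13))
        tilt = rng.lognormal(0.0, config.subject_genus_tilt_sd, size=len(genera))
        persistent = {
            g: config.core_eligible(g)[
                rng.choice(config.core_eligible_per_genus,
                           p=config.core_choice_probs)
            ]
            for g in genera
        }
        truth_core[subject] = frozenset(persistent.values())

        pt = int(rng.choice(k_types, p=config.initial_probs_by_siblings[siblings]))
        for vi, t in enumerate(TIMEPOINTS):
            if vi > 0:
                pt = int(rng.choice(k_types, p=tmats[vi - 1][pt]))
            truth_pt[(subject, t)] = config.pneumotypes[pt]
            missing = rng.random() < config.missingness[t]

            # draw per-visit quantities unconditionally so the stream of
            # random numbers -- and hence the cohort -- is reproducible
            antibiotics = bool(rng.random() < cov["antibiotics"][t])
            breastfed = bool(rng.random() < cov["exclusively_breastfed"][t])
            mu, sd = cov["age_days"][t]
            age = max(1, int(round(rng.normal(mu, sd))))
            dna = float(rng.lognormal(0.0, 1.5))

            rho = config.core_share[t]
            shares = config.profiles[pt] * tilt
            shares = shares / shares.sum()
            x = np.zeros(len(otu_ids))
            for gi, g in enumerate(genera):
                share = shares[gi]
                if share <= 0:
                    continue
                x[otu_index[persistent[g]]] += rho * share
                pool = config.transient(g)
                active = rng.choice(len(pool), size=config.transient_active_per_genus,
                                    replace=False)
                for a in active:
                    x[otu_index[pool[a]]] += (1 - rho) * share / len(active)

            if np.isfinite(config.dirichlet_concentration):
                comp = np.zeros_like(x)
                support = x > 0
                comp[support] = rng.dirichlet(
                    config.dirichlet_concentration * x[support]
                )
            else:
                comp = x / x.sum()

            depth = max(config.depth_floor,
                        int(round(rng.lognormal(config.depth_meanlog,
                                                config.depth_sdlog))))
            counts = rng.multinomial(depth, comp)

            if missing:
                continue
            sid = f"{subject}_{t}"
            sample_ids.append(sid)
            count_rows.append(counts)
            compositions[sid] = comp
            records.append(
                {
                    "sample_id": sid, "subject_id": subject, "timepoint": t,
                    "age_days": age, "sex": "male" if male else "female",
                    "siblings": siblings, "csection": csection,
                    "antibiotics": antibiotics,
                    "exclusively_breastfed": breastfed,
                    "mother_asthma": asthma, "birth_month": birth_month,
                    "dna_conc": dna,
                }
            )

    counts = pd.DataFrame(
        np.asarray(count_rows, dtype=np.int64), index=sample_ids, columns=otu_ids
    )
    taxonomy = pd.DataFrame(
        [parse_lineage(GENUS_LINEAGES.get(config.genus_of_otu[o],
                                          f"Bacteria;;;;;{config.genus_of_otu[o]}"))
         for o in otu_ids],
        index=otu_ids,
    )[RANKS]
    table = OtuTable(counts, taxonomy)
    metadata = pd.DataFrame(records)
    truth = {
        "pneumotype": truth_pt,
        "core_otus": truth_core,
        "dominant_otus": {
            pt: config.dominant_otu(pt) for pt in config.pneumotypes
        },
        "compositions": pd.DataFrame(compositions, index=otu_ids).T,
        "core_share": dict(config.core_share),
    }
    return SyntheticCohort(table, tree, metadata, truth, config)


def truth_assignments(cohort: SyntheticCohort) -> pd.DataFrame:
    """Planted pneumotype labels as a tidy assignments frame (emitted
    samples only)."""
    rows = [
        {"subject_id": sub, "timepoint": t,
         "pneumotype": cohort.truth["pneumotype"][(sub, t)],
         "sample_id": f"{sub}_{t}"}
        for (sub, t) in cohort.truth["pneumotype"]
        if f"{sub}_{t}" in set(cohort.table.sample_ids)
    ]
    return pd.DataFrame(rows)
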
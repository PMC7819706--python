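"""Synthetic genome-scale test data with planted age trends.

The generator emulates the statistical structure a pfam phylostratigraphy
study assumes, with every knob explicit and every artifact reproducible
from a seed:

- a clade-labeled ultrametric species tree (animals, plants, fungi, an
  Excavata outgroup and another protist group) calibrated at the standard
  ancient nodes (FECA 2230 MY, LECA 2101 MY, plant vs animal+fungi split
  1496 MY);
- pfam birth/loss histories from LUCA-aged families down to young
  clade-specific ones, with Poisson losses along branches;
- per-instance protein sequences whose hydrophobic fraction, hydrophobic
  clustering and mean disorder drift with true age at configurable
  lineage-specific rates.  Clustering is planted through the *arrangement*
  of hydrophobic residues (a two-state Markov chain whose persistence is
  calibrated to a target psi by simulation), independently of composition;
  disorder propensities are a monotone function of local hydrophilicity, so
  disorder and composition co-vary qualitatively as in real proteins;
- injected contaminants with uniformly random sparse presence and no age
  trend, plus "fodder" families that exercise the annotation and keyword
  filters.

The generator performs no molecular-evolution simulation (no substitution
or indel process); it targets the statistical structure of the analysis,
nothing more.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .age_assignment import StratumConfig
from .io import Dataset, write_dataset  # noqa: F401  (write_dataset is part of this surface)
from .sequence_metrics import HYDROPHOBIC, STANDARD_AA, psi_from_signs, surrogate_disorder
from .tree import TimeTree

__all__ = [
    "SimulationConfig",
    "simulate_species_tree",
    "simulate_pfam_histories",
    "simulate_sequences",
    "inject_contaminants",
    "simulate_dataset",
    "write_dataset",
    "calibrate_persistence",
]

_HYDRO = [aa for aa in STANDARD_AA if aa in HYDROPHOBIC]
_POLAR = [aa for aa in STANDARD_AA if aa not in HYDROPHOBIC]

# Roughly proteome-like baseline composition (alphabetical single-letter order).
_BASELINE = {
    "A": 0.074, "C": 0.025, "D": 0.054, "E": 0.054, "F": 0.047, "G": 0.074,
    "H": 0.029, "I": 0.038, "K": 0.058, "L": 0.076, "M": 0.018, "N": 0.045,
    "P": 0.050, "Q": 0.034, "R": 0.042, "S": 0.081, "T": 0.062, "V": 0.068,
    "W": 0.013, "Y": 0.033,
}


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one synthetic dataset.

    Defaults describe the package's standard synthetic study: ~60 species,
    ~800 pfams spanning LUCA to recent strata, a universal negative
    clustering trend, a disorder trend confined to animal-born pfams, and a
    small cohort of random-presence contaminants.
    """

    seed: int = 0
    # tree shape
    n_animal: int = 24
    n_plant: int = 16
    n_fungi: int = 12
    n_excavata: int = 4
    n_other: int = 4
    animal_fungi_split: float = 1105.0
    stratum: StratumConfig = field(default_factory=StratumConfig)
    # pfam counts per stratum
    n_luca: int = 80
    n_post_luca: int = 120
    n_feca: int = 60
    n_backbone: int = 120
    n_animal_born: int = 280
    n_plant_born: int = 90
    n_fungi_born: int = 50
    n_contaminants: int = 40
    n_filter_fodder: int = 30
    contaminant_k_min: int = 6
    contaminant_k_max: int = 14
    # loss process
    loss_rate_per_100my: float = 0.02
    # sequences
    length_min: int = 100
    length_max: int = 300
    flank_min: int = 5
    flank_max: int = 40
    baseline_composition: tuple[float, ...] = tuple(_BASELINE[aa] for aa in STANDARD_AA)
    # planted trends; ages enter in BY so slopes read "per billion years"
    isd_intercept: tuple[tuple[str, float], ...] = (
        ("animal", 0.36), ("plant", 0.26), ("fungus", 0.24), ("ancient", 0.22),
    )
    isd_slope_per_by: tuple[tuple[str, float], ...] = (
        ("animal", -0.062), ("plant", 0.0), ("fungus", 0.0), ("ancient", 0.0),
    )
    hydrophobic_slope_per_by: tuple[tuple[str, float], ...] = (
        ("animal", 0.015), ("plant", 0.0), ("fungus", 0.0), ("ancient", 0.0),
    )
    psi_intercept: float = 1.10
    psi_slope_per_by: float = -0.039
    recruitment_tilt_per_by: float = 0.0
    # young clade-born pfams drift along lineage-specific amino-acid
    # preference axes (animal: serine/proline-rich when young; plant:
    # cysteine/acidic-rich when young), uncorrelated with recruitment order
    lineage_comp_tilt_per_by: float = 0.25
    lineage_tilt_aas: tuple[tuple[str, str], ...] = (
        ("animal", "SP"), ("plant", "CED"), ("fungus", "GN"),
    )
    # pfam-level biological scatter
    isd_noise_sd: float = 0.03
    psi_noise_sd: float = 0.05
    hydrophobic_noise_sd: float = 0.02
    disorder_hydro_delta: float = 0.15
    residue_disorder_noise_sd: float = 0.05
    flank_disorder: float = 0.45
    tm_fraction: float = 0.10
    n_cooccur_pairs: int = 10

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        stratum_kwargs = raw.pop("stratum", None)
        cfg = cls(**raw)
        if stratum_kwargs:
            cfg = replace(cfg, stratum=StratumConfig(**stratum_kwargs))
        return cfg

    def baseline(self) -> np.ndarray:
        vec = np.asarray(self.baseline_composition, dtype=float)
        return vec / vec.sum()


# ----------------------------------------------------------------- species tree

def _random_clade(rng, names, crown_age):
    """Random recursive bipartition; returns nested (children, age) tuples."""
    if len(names) == 1:
        return names[0]
    k = 1 if len(names) == 2 else int(rng.integers(1, len(names) - 1))
    left, right = list(names[:k]), list(names[k:])
    left_age = crown_age * rng.uniform(0.45, 0.85) if len(left) > 1 else 0.0
    right_age = crown_age * rng.uniform(0.45, 0.85) if len(right) > 1 else 0.0
    return (
        (_random_clade(rng, left, left_age), left_age),
        (_random_clade(rng, right, right_age), right_age),
        crown_age,
    )


def simulate_species_tree(config: SimulationConfig) -> tuple[TimeTree, pd.DataFrame]:
    """Clade-labeled ultrametric tree with the standard calibration nodes.

    Root = FECA (Excavata vs. the rest, 2230 MY); LECA at 2101 MY separates
    the other-protist group; plants split from animals+fungi at 1496 MY and
    animals from fungi at ``config.animal_fungi_split`` MY.  Within-clade
    topology and node ages are random but reproducible from the seed.
    """
    for n in (config.n_animal, config.n_plant, config.n_fungi, config.n_excavata,
              config.n_other):
        if n < 2:
            raise ValueError("every clade needs at least two leaves")
    rng = np.random.default_rng((config.seed, 101))
    cfgs = config.stratum

    names = {
        "animal": [f"ani{i:03d}" for i in range(config.n_animal)],
        "plant": [f"pla{i:03d}" for i in range(config.n_plant)],
        "fungus": [f"fun{i:03d}" for i in range(config.n_fungi)],
        "protist-excavata": [f"exc{i:03d}" for i in range(config.n_excavata)],
        "other": [f"oth{i:03d}" for i in range(config.n_other)],
    }

    parent: list[int] = []
    age: list[float] = []
    leaf_names: dict[str, int] = {}

    def add(node_age, parent_idx):
        parent.append(parent_idx)
        age.append(node_age)
        return len(parent) - 1

    def build(sub, parent_idx):
        if isinstance(sub, str):
            leaf_names[sub] = add(0.0, parent_idx)
            return
        left, right, crown = sub
        idx = add(crown, parent_idx)
        for child, child_age in (left, right):
            if isinstance(child, str):
                leaf_names[child] = add(0.0, idx)
            else:
                build(child, idx)

    def clade(label, crown_frac_of):
        crown = crown_frac_of * rng.uniform(0.55, 0.85)
        return _random_clade(rng, names[label], crown), crown

    root = add(cfgs.feca_excavata_age, -1)
    (exc_sub, exc_crown) = clade("protist-excavata", cfgs.feca_excavata_age)
    leca = add(cfgs.leca_age, root)
    exc_idx = add(exc_crown, root)
    build_children_of = [(exc_sub, exc_idx)]
    (oth_sub, oth_crown) = clade("other", cfgs.leca_age)
    oth_idx = add(oth_crown, leca)
    build_children_of.append((oth_sub, oth_idx))
    split1496 = add(cfgs.animal_plant_split, leca)
    (pla_sub, pla_crown) = clade("plant", cfgs.animal_plant_split)
    pla_idx = add(pla_crown, split1496)
    build_children_of.append((pla_sub, pla_idx))
    split_af = add(config.animal_fungi_split, split1496)
    (ani_sub, ani_crown) = clade("animal", config.animal_fungi_split)
    ani_idx = add(ani_crown, split_af)
    build_children_of.append((ani_sub, ani_idx))
    (fun_sub, fun_crown) = clade("fungus", config.animal_fungi_split)
    fun_idx = add(fun_crown, split_af)
    build_children_of.append((fun_sub, fun_idx))
    for sub, idx in build_children_of:
        left, right, _ = sub
        for child, child_age in (left, right):
            if isinstance(child, str):
                leaf_names[child] = add(0.0, idx)
            else:
                build(child, idx)

    tree = TimeTree(parent, age, leaf_names)
    rows = [
        {"species_id": sp, "clade_label": label,
         "is_focal": label in ("animal", "plant", "fungus")}
        for label, group in names.items()
        for sp in group
    ]
    return tree, pd.DataFrame(rows)


# --------------------------------------------------------------- pfam histories

def _branch_losses(tree, birth_node, rate_per_100my, rng):
    """Sample loss branches below a birth node; returns the set of lost leaves
    and the list of maximal loss nodes."""
    lost_nodes = []
    lost_leaves = np.zeros(tree.n_leaves, dtype=bool)
    stack = list(tree.children[birth_node])
    while stack:
        node = stack.pop()
        p = tree.parent[node]
        length = tree.age[p] - tree.age[node]
        if rng.poisson(rate_per_100my * length / 100.0) > 0:
            lost_nodes.append(node)
            lost_leaves |= tree.leaves_below[node]
            continue  # everything below is gone; nested losses are moot
        stack.extend(tree.children[node])
    return lost_leaves, lost_nodes


def simulate_pfam_histories(
    tree: TimeTree, species: pd.DataFrame, config: SimulationConfig
) -> pd.DataFrame:
    """Birth/loss histories for every non-contaminant pfam.

    Each pfam is born at a node chosen for its stratum; the true age is the
    midpoint of the branch above the birth node (or the stratum calibration
    age for pre-tree strata); losses prune whole subtrees at the configured
    Poisson rate.  Pfams left with fewer than two species are redrawn.
    """
    rng = np.random.default_rng((config.seed, 202))
    cfgs = config.stratum
    clades = dict(zip(species["species_id"], species["clade_label"]))
    leaf_order = tree.leaf_names

    def clade_nodes(label):
        members = tree.presence_vector(
            [sp for sp, cl in clades.items() if cl == label]
        )
        nodes = [
            i for i in range(tree.n_nodes)
            if not tree.is_leaf[i]
            and tree.leaves_below[i][members].any()
            and not tree.leaves_below[i][~members].any()
        ]
        return nodes

    # Backbone births stay at/above the kingdom split so that every pfam
    # younger than the split was genuinely born inside one kingdom.
    backbone = []
    for target_age in (cfgs.leca_age, cfgs.animal_plant_split):
        matches = np.flatnonzero(
            (~tree.is_leaf) & (np.abs(tree.age - target_age) < 1e-6)
        )
        backbone.append(int(matches[0]))

    node_pool = {
        "animal": clade_nodes("animal"),
        "plant": clade_nodes("plant"),
        "fungus": clade_nodes("fungus"),
    }

    specs = (
        [("luca", None)] * config.n_luca
        + [("post_luca", None)] * config.n_post_luca
        + [("feca", None)] * config.n_feca
        + [("backbone", None)] * config.n_backbone
        + [("clade", "animal")] * config.n_animal_born
        + [("clade", "plant")] * config.n_plant_born
        + [("clade", "fungus")] * config.n_fungi_born
    )
    rows = []
    for i, (stratum, clade_label) in enumerate(specs):
        pfam_id = f"PF{i:05d}"
        for _attempt in range(200):
            if stratum in ("luca", "post_luca", "feca"):
                birth = tree.root
                true_age = {
                    "luca": cfgs.luca_age,
                    "post_luca": cfgs.post_luca_age,
                    "feca": cfgs.feca_excavata_age,
                }[stratum]
                lineage = "ancient"
            elif stratum == "backbone":
                birth = backbone[int(rng.integers(len(backbone)))]
                pa = tree.parent_age(birth)
                true_age = (tree.age[birth] + pa) / 2.0
                lineage = "ancient"
            else:
                birth = node_pool[clade_label][
                    int(rng.integers(len(node_pool[clade_label])))
                ]
                pa = tree.parent_age(birth)
                true_age = (tree.age[birth] + pa) / 2.0
                lineage = clade_label
            lost, lost_nodes = _branch_losses(
                tree, birth, config.loss_rate_per_100my, rng
            )
            present = tree.leaves_below[birth] & ~lost
            if present.sum() >= 2:
                break
        else:  # pragma: no cover - unreachable at sane loss rates
            raise RuntimeError(f"could not generate a surviving history for {pfam_id}")
        presence = [leaf_order[j] for j in np.flatnonzero(present)]
        in_bact = in_arch = False
        if stratum == "luca":
            in_bact = in_arch = True
        elif stratum == "post_luca":
            in_bact = bool(rng.integers(2))
            in_arch = not in_bact
        rows.append(
            {
                "pfam_id": pfam_id,
                "stratum": stratum,
                "birth_lineage": lineage,
                "birth_node": birth,
                "true_age_my": float(true_age),
                "n_losses": len(lost_nodes),
                "presence": ";".join(sorted(presence)),
                "in_bacteria": in_bact,
                "in_archaea": in_arch,
                "is_contaminant": False,
                "is_fodder": False,
            }
        )
    return pd.DataFrame(rows)


def inject_contaminants(
    tree: TimeTree, config: SimulationConfig, start_index: int
) -> pd.DataFrame:
    """Extra pfams with uniformly random sparse presence and no age trend."""
    rng = np.random.default_rng((config.seed, 303))
    if 2 * config.contaminant_k_max >= tree.n_leaves:
        raise ValueError("contaminant sparsity must stay below half the species")
    rows = []
    for i in range(config.n_contaminants):
        k = int(rng.integers(config.contaminant_k_min, config.contaminant_k_max + 1))
        chosen = rng.choice(tree.n_leaves, size=k, replace=False)
        presence = [tree.leaf_names[j] for j in sorted(chosen)]
        rows.append(
            {
                "pfam_id": f"PF{start_index + i:05d}",
                "stratum": "contaminant",
                "birth_lineage": "none",
                "birth_node": -1,
                "true_age_my": np.nan,
                "n_losses": 0,
                "presence": ";".join(presence),
                "in_bacteria": False,
                "in_archaea": False,
                "is_contaminant": True,
                "is_fodder": False,
            }
        )
    return pd.DataFrame(rows)


# ------------------------------------------------------- psi <-> persistence map

@functools.lru_cache(maxsize=64)
def _persistence_curve(
    q_bucket: int, length: int, block_size: int, reps: int, seed: int
) -> tuple[tuple[float, ...], tuple[float, ...]]:
    """Mean psi as a function of Markov persistence, by simulation.

    ``q_bucket`` is the hydrophobic fraction times 20, rounded (0.05 grid).
    Returns (rho_grid, mean_psi_grid) with psi made monotone in rho.
    """
    q = q_bucket / 20.0
    rhos = np.linspace(-0.25, 0.85, 23)
    rng = np.random.default_rng((seed, q_bucket, 808))
    means = []
    for rho in rhos:
        lo = max(-q / (1 - q), -(1 - q) / q) + 1e-6
        r = max(rho, lo)
        states = np.empty((reps, length), dtype=bool)
        states[:, 0] = rng.random(reps) < q
        stay = q + (1 - q) * r
        enter = q * (1 - r)
        u = rng.random((reps, length - 1))
        for t in range(1, length):
            prob = np.where(states[:, t - 1], stay, enter)
            states[:, t] = u[:, t - 1] < prob
        signs = np.where(states, 1, -1)
        psis = [psi_from_signs(row, block_size).psi for row in signs]
        vals = [p for p in psis if p is not None]
        means.append(float(np.mean(vals)))
    means = np.maximum.accumulate(means)  # enforce monotonicity for inversion
    return tuple(rhos), tuple(means)


def calibrate_persistence(
    target_psi: float,
    hydrophobic_fraction: float,
    length: int = 150,
    block_size: int = 6,
    reps: int = 500,
    seed: int = 12345,
) -> float:
    """Markov persistence whose expected psi matches ``target_psi``.

    Uses a cached simulated curve per hydrophobic-fraction bucket; targets
    outside the attainable range are clamped to the curve's ends.
    """
    q_bucket = int(round(np.clip(hydrophobic_fraction, 0.05, 0.8) * 20))
    length = block_size * max(2, round(length / block_size))
    rhos, means = _persistence_curve(q_bucket, length, block_size, reps, seed)
    return float(np.interp(target_psi, means, rhos))


# ------------------------------------------------------------------- sequences

def _markov_signs(rng, n_seq, length, q, rho):
    lo = max(-q / (1 - q), -(1 - q) / q) + 1e-6
    rho = max(rho, lo)
    states = np.empty((n_seq, length), dtype=bool)
    states[:, 0] = rng.random(n_seq) < q
    stay = q + (1 - q) * rho
    enter = q * (1 - rho)
    u = rng.random((n_seq, length - 1))
    for t in range(1, length):
        prob = np.where(states[:, t - 1], stay, enter)
        states[:, t] = u[:, t - 1] < prob
    return states


@functools.lru_cache(maxsize=16)
def _lineage_direction(lineage: str, named_aas: str) -> np.ndarray:
    """Deterministic 20-dim preference axis: named amino acids get weight 10,
    the rest smaller pseudo-random weights seeded by the lineage name."""
    rng = np.random.default_rng(list(lineage.encode()))
    d = rng.uniform(-5.0, 5.0, 20)
    for aa in named_aas:
        d[STANDARD_AA.index(aa)] = 10.0
    return d


def _targets_for(row, config: SimulationConfig, rng) -> dict:
    """Planted per-pfam property targets from lineage and true age."""
    isd_int = dict(config.isd_intercept)
    isd_slp = dict(config.isd_slope_per_by)
    h_slp = dict(config.hydrophobic_slope_per_by)
    base = config.baseline()
    base_h = float(base[[STANDARD_AA.index(aa) for aa in _HYDRO]].sum())
    neutral = bool(row["is_contaminant"]) or not np.isfinite(row["true_age_my"])
    if neutral:
        age_by, lineage = 0.0, "ancient"
    else:
        age_by, lineage = row["true_age_my"] / 1000.0, row["birth_lineage"]
    isd = isd_int[lineage] + isd_slp[lineage] * age_by
    isd += rng.normal(0.0, config.isd_noise_sd)
    h = base_h + h_slp[lineage] * age_by + rng.normal(0.0, config.hydrophobic_noise_sd)
    psi = config.psi_intercept + config.psi_slope_per_by * age_by
    psi += rng.normal(0.0, config.psi_noise_sd)
    if neutral:
        psi = 1.0 + rng.normal(0.0, config.psi_noise_sd)
    # within-class composition, optionally tilted along recruitment order:
    # amino-acid availability tracks recruitment order until the LECA and is
    # frozen afterwards, so pre-LECA pfams carry an age-proportional tilt
    # (late-recruited amino acids depleted in the oldest strata) while every
    # younger pfam inherits the final, LECA-era availability level
    comp = base.copy()
    if config.recruitment_tilt_per_by != 0.0 and not neutral:
        from .trends import load_aa_properties

        ranks = load_aa_properties()["recruitment_rank"].to_numpy(dtype=float)
        frozen_age = max(age_by, config.stratum.leca_age / 1000.0)
        # abundance-compensated exponent: the resulting slope in percentage
        # points per BY is ~ -0.1 * tilt * (rank - mean), linear in rank,
        # while the multiplicative form keeps every fraction positive
        comp = comp * np.exp(
            -config.recruitment_tilt_per_by
            * frozen_age
            * (ranks - ranks.mean())
            / (1000.0 * comp)
        )
        comp = comp / comp.sum()
    # lineage-specific preference drift in clade-born pfams: a fixed
    # per-lineage axis over all 20 amino acids (the named amino acids
    # strongest, e.g. serine/proline in animals), decaying with age, with
    # the same abundance compensation as the recruitment tilt
    tilt_aas = dict(config.lineage_tilt_aas).get(lineage)
    if tilt_aas is not None and not neutral and config.lineage_comp_tilt_per_by != 0.0:
        direction = _lineage_direction(lineage, tilt_aas)
        comp = comp * np.exp(
            -config.lineage_comp_tilt_per_by * age_by * direction / (1000.0 * comp)
        )
        comp = comp / comp.sum()
    hydro_idx = [STANDARD_AA.index(aa) for aa in _HYDRO]
    polar_idx = [STANDARD_AA.index(aa) for aa in _POLAR]
    h = float(np.clip(h, 0.08, 0.75))
    hydro_p = comp[hydro_idx] / comp[hydro_idx].sum()
    polar_p = comp[polar_idx] / comp[polar_idx].sum()
    return {
        "isd": float(np.clip(isd, 0.02, 0.98)),
        "h": h,
        "psi": float(np.clip(psi, 0.78, 2.5)),
        "hydro_p": hydro_p,
        "polar_p": polar_p,
    }


def simulate_sequences(
    truth: pd.DataFrame, config: SimulationConfig
) -> tuple[pd.DataFrame, dict]:
    """Domain sequences and per-residue disorder propensities per instance.

    Returns ``(truth_with_targets, domains)`` where ``domains`` maps
    ``(pfam_id, species_id)`` to ``(sequence, propensity_vector)``.
    """
    rng = np.random.default_rng((config.seed, 404))
    domains: dict[tuple[str, str], tuple[str, np.ndarray]] = {}
    hydro_arr = np.array(_HYDRO)
    polar_arr = np.array(_POLAR)
    target_rows = []
    for _, row in truth.iterrows():
        targets = _targets_for(row, config, rng)
        species = row["presence"].split(";") if row["presence"] else []
        n = len(species)
        length = int(rng.integers(config.length_min, config.length_max + 1))
        # the persistence curve is calibrated once at a fixed representative
        # length; any residual length dependence of psi is independent of age
        rho = calibrate_persistence(targets["psi"], targets["h"])
        if n:
            states = _markov_signs(rng, n, length, targets["h"], rho)
            hydro_draw = rng.choice(len(hydro_arr), size=(n, length), p=targets["hydro_p"])
            polar_draw = rng.choice(len(polar_arr), size=(n, length), p=targets["polar_p"])
            letters = np.where(states, hydro_arr[hydro_draw], polar_arr[polar_draw])
            centered = states.astype(float) - states.mean(axis=1, keepdims=True)
            prop = (
                targets["isd"]
                - config.disorder_hydro_delta * centered
                + rng.normal(0.0, config.residue_disorder_noise_sd, size=(n, length))
            )
            prop = np.clip(prop, 0.0, 1.0)
            for j, sp in enumerate(species):
                domains[(row["pfam_id"], sp)] = ("".join(letters[j]), prop[j])
        target_rows.append(
            {
                "pfam_id": row["pfam_id"],
                "target_isd": targets["isd"],
                "target_psi": targets["psi"],
                "target_hfrac": targets["h"],
                "domain_length": length,
            }
        )
    truth = truth.merge(pd.DataFrame(target_rows), on="pfam_id")
    return truth, domains


# ------------------------------------------------------------------ full dataset

def _fodder_rows(tree: TimeTree, config: SimulationConfig, start_index: int):
    """Families designed to be dropped by the annotation/keyword filters."""
    rng = np.random.default_rng((config.seed, 505))
    kinds = [
        ("prokaryote_only", "Domain of bacterial cell walls.", "prokaryote-annotated"),
        ("unannotated", "A domain lacking curated species information.",
         "no species annotation"),
        ("eukaryote_only", "Protein targeted to the chloroplast membrane.",
         "organelle keyword"),
        ("shared_with_prokaryotes", "Major viral capsid shell protein.",
         "exclusion keyword"),
        ("eukaryote_only", None, "no abstract"),
        ("eukaryote_only", "Domain found in a single lineage so far.",
         "single species"),
    ]
    rows = []
    for i in range(config.n_filter_fodder):
        annot, abstract, expected = kinds[i % len(kinds)]
        k = 1 if expected == "single species" else 3
        chosen = rng.choice(tree.n_leaves, size=k, replace=False)
        rows.append(
            {
                "pfam_id": f"PF{start_index + i:05d}",
                "stratum": "fodder",
                "birth_lineage": "none",
                "birth_node": -1,
                "true_age_my": np.nan,
                "n_losses": 0,
                "presence": ";".join(tree.leaf_names[j] for j in sorted(chosen)),
                "in_bacteria": False,
                "in_archaea": False,
                "is_contaminant": False,
                "is_fodder": True,
                "fodder_annotation": annot,
                "fodder_abstract": abstract,
                "expected_drop_reason": expected,
            }
        )
    return pd.DataFrame(rows)


def _metadata_for(truth: pd.DataFrame, config: SimulationConfig) -> pd.DataFrame:
    rng = np.random.default_rng((config.seed, 606))
    benign_shared = (
        "Widely conserved catalytic domain found in bacterial and eukaryotic "
        "proteins; well characterized in yeast and human."
    )
    benign_euk = "Conserved domain of unknown function found across metazoa and plants."
    rows = []
    for _, row in truth.iterrows():
        if row.get("is_fodder", False):
            rows.append(
                {
                    "pfam_id": row["pfam_id"],
                    "taxonomic_annotation": row["fodder_annotation"],
                    "in_bacteria": False,
                    "in_archaea": False,
                    "abstract_text": row["fodder_abstract"],
                }
            )
            continue
        shared = bool(row["in_bacteria"] or row["in_archaea"])
        rows.append(
            {
                "pfam_id": row["pfam_id"],
                "taxonomic_annotation": (
                    "shared_with_prokaryotes" if shared else "eukaryote_only"
                ),
                "in_bacteria": bool(row["in_bacteria"]),
                "in_archaea": bool(row["in_archaea"]),
                "abstract_text": benign_shared if shared else benign_euk,
            }
        )
    return pd.DataFrame(rows)


def simulate_dataset(config: SimulationConfig | None = None) -> Dataset:
    """Generate a complete synthetic dataset (tree, pfams, genes, metrics inputs).

    Every emitted pfam appears in the truth table and vice versa; the truth
    table records birth strata, true ages, planted targets and contaminant /
    fodder flags.
    """
    config = config or SimulationConfig()
    rng = np.random.default_rng((config.seed, 707))
    tree, species = simulate_species_tree(config)
    truth = simulate_pfam_histories(tree, species, config)
    n_real = len(truth)
    contaminants = inject_contaminants(tree, config, start_index=n_real)
    fodder = _fodder_rows(tree, config, start_index=n_real + len(contaminants))
    truth = pd.concat([truth, contaminants, fodder], ignore_index=True)
    truth, domains = simulate_sequences(truth, config)
    metadata = _metadata_for(truth, config)
    clades = dict(zip(species["species_id"], species["clade_label"]))

    # pick TM pfams and co-occurring pairs among animal-born families
    real_ids = truth.loc[~truth["is_contaminant"] & ~truth["is_fodder"], "pfam_id"]
    n_tm = int(round(config.tm_fraction * len(real_ids)))
    tm_pfams = set(rng.choice(real_ids.to_numpy(), size=n_tm, replace=False))
    animal_ids = truth.loc[
        (truth["birth_lineage"] == "animal") & ~truth["is_contaminant"], "pfam_id"
    ].to_numpy()
    n_pairs = min(config.n_cooccur_pairs, len(animal_ids) // 2)
    paired = rng.choice(animal_ids, size=2 * n_pairs, replace=False)
    partner = {}
    for a, b in zip(paired[:n_pairs], paired[n_pairs:]):
        partner[a], partner[b] = b, a
    truth["tm_true"] = truth["pfam_id"].isin(tm_pfams)
    truth["cooccur_partner"] = truth["pfam_id"].map(partner).fillna("")

    # assemble genes: usually one domain per gene; partnered pfams share a
    # gene in species carrying both
    by_species: dict[str, list[str]] = {}
    for pfam_id, sp in domains:
        by_species.setdefault(sp, []).append(pfam_id)
    sequences: dict[tuple[str, str], str] = {}
    disorder: dict[tuple[str, str], np.ndarray] = {}
    ann_rows = []
    helix_rows = []
    aa_pool = np.array(list(STANDARD_AA))
    base = config.baseline()

    def flank(length):
        return "".join(rng.choice(aa_pool, size=length, p=base))

    for sp in sorted(by_species):
        done = set()
        for pfam_id in sorted(by_species[sp]):
            if pfam_id in done:
                continue
            members = [pfam_id]
            mate = partner.get(pfam_id)
            if mate and (mate, sp) in domains:
                members.append(mate)
            done.update(members)
            gene_id = "g" + "+".join(members)
            nter = flank(int(rng.integers(config.flank_min, config.flank_max + 1)))
            cter = flank(int(rng.integers(config.flank_min, config.flank_max + 1)))
            parts, props, pos = [nter], [], len(nter)
            props.append(
                np.clip(
                    config.flank_disorder
                    + rng.normal(0, config.residue_disorder_noise_sd, len(nter)),
                    0, 1,
                )
            )
            for m, member in enumerate(members):
                seq, prop = domains[(member, sp)]
                start = pos + 1
                end = pos + len(seq)
                ann_rows.append(
                    {"species_id": sp, "gene_id": gene_id, "pfam_id": member,
                     "start": start, "end": end}
                )
                if member in tm_pfams and len(seq) >= 60:
                    for off in (4, len(seq) - 25):
                        helix_rows.append(
                            {"species_id": sp, "gene_id": gene_id,
                             "helix_start": start + off,
                             "helix_end": start + off + 20}
                        )
                parts.append(seq)
                props.append(prop)
                pos = end
                if m < len(members) - 1:
                    linker = flank(int(rng.integers(8, 20)))
                    parts.append(linker)
                    props.append(
                        np.clip(
                            config.flank_disorder
                            + rng.normal(
                                0, config.residue_disorder_noise_sd, len(linker)
                            ),
                            0, 1,
                        )
                    )
                    pos += len(linker)
            parts.append(cter)
            props.append(
                np.clip(
                    config.flank_disorder
                    + rng.normal(0, config.residue_disorder_noise_sd, len(cter)),
                    0, 1,
                )
            )
            gene_seq = "".join(parts)
            propensity = np.concatenate(props)
            sequences[(sp, gene_id)] = gene_seq
            disorder[(sp, gene_id)] = surrogate_disorder(
                gene_seq, propensity, window=7
            ).scores
            # occasional sub-threshold helix on an ordinary gene
            if pfam_id not in tm_pfams and rng.random() < 0.03:
                helix_rows.append(
                    {"species_id": sp, "gene_id": gene_id,
                     "helix_start": 2, "helix_end": 16}
                )

    annotations = pd.DataFrame(
        ann_rows, columns=["species_id", "gene_id", "pfam_id", "start", "end"]
    )
    helices = pd.DataFrame(
        helix_rows, columns=["species_id", "gene_id", "helix_start", "helix_end"]
    )
    luca = set(truth.loc[truth["stratum"] == "luca", "pfam_id"])
    stratum = replace(config.stratum, luca_pfam_list=frozenset(luca))
    return Dataset(
        tree=tree,
        species=species,
        annotations=annotations,
        sequences=sequences,
        disorder=disorder,
        metadata=metadata,
        helices=helices,
        luca_pfams=luca,
        stratum=stratum,
        truth=truth,
    )
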
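"""Dating pfam domains and genes on a calibrated time tree.

A pfam's origin is placed halfway between the MRCA of the species carrying
it and that node's parent.  Strata older than the species tree are handled
by calibration rules: pfams on a curated LUCA list are dated 4090 MY; pfams
shared between eukaryotes and exactly one prokaryotic domain (bacteria XOR
archaea) are dated 3145 MY, the halfway point between LUCA (4090 MY) and the
emergence of eukaryotes (2200 MY); pfams present in non-protist eukaryotes
and in at least one Excavata species are placed at the first eukaryotic
common ancestor, 2230 MY.  Genes are dated by their oldest retained pfam.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .tree import TimeTree

__all__ = [
    "StratumConfig",
    "AgeAssignment",
    "pfam_mrca_age",
    "assign_ancient_stratum",
    "assign_age",
    "gene_age",
    "lineage_tag",
    "age_class_summary",
]

#: Clade labels whose members contribute property datapoints.
FOCAL_CLADES = ("animal", "plant", "fungus")


@dataclass(frozen=True)
class StratumConfig:
    """Calibration ages (MY) for the ancient strata and lineage cutoffs."""

    luca_age: float = 4090.0
    eukaryote_emergence_age: float = 2200.0
    feca_excavata_age: float = 2230.0
    leca_age: float = 2101.0
    animal_plant_split: float = 1496.0
    luca_pfam_list: frozenset[str] = frozenset()

    @property
    def post_luca_age(self) -> float:
        """Halfway between LUCA and the emergence of eukaryotes (3145 MY)."""
        return (self.luca_age + self.eukaryote_emergence_age) / 2.0

    def __post_init__(self):
        if not (
            self.luca_age
            > self.post_luca_age
            > self.feca_excavata_age
            > self.leca_age
            > self.animal_plant_split
        ):
            raise ValueError("stratum ages must decrease from LUCA to the kingdom split")


@dataclass(frozen=True)
class AgeAssignment:
    pfam_id: str
    age_my: float
    age_class: str
    lineage_tag: str
    n_species: int


def pfam_mrca_age(tree: TimeTree, presence: set[str]) -> float:
    """Midpoint age between the presence MRCA and its parent node.

    For a single-species pfam the MRCA is the leaf itself, so the age is
    half the terminal branch's parent age.  If the MRCA is the root (no
    parent exists), the root age is returned; callers should normally have
    applied the ancient-strata rules first.
    """
    if not presence:
        raise ValueError("presence set is empty")
    node = tree.mrca(presence)
    parent = tree.parent_age(node)
    if parent is None:
        return float(tree.age[node])
    return (float(tree.age[node]) + parent) / 2.0


def assign_ancient_stratum(
    pfam_id: str,
    in_eukaryotes: bool,
    in_bacteria: bool,
    in_archaea: bool,
    cfg: StratumConfig,
) -> float | None:
    """Stratum age for pfams predating the eukaryote tree, else ``None``.

    LUCA-listed pfams (and pfams found in all three domains of life) date to
    ``cfg.luca_age``; pfams shared with exactly one prokaryotic domain date
    to the post-LUCA midpoint.  Eukaryote-only pfams return ``None`` and are
    dated on the tree.
    """
    if not in_eukaryotes:
        raise ValueError(f"pfam {pfam_id}: not present in eukaryotes")
    if pfam_id in cfg.luca_pfam_list:
        return cfg.luca_age
    if in_bacteria and in_archaea:
        # present in all three domains: parsimony places it in LUCA
        return cfg.luca_age
    if in_bacteria != in_archaea:
        return cfg.post_luca_age
    return None


def assign_age(
    tree: TimeTree,
    presence: set[str],
    clades: dict[str, str],
    cfg: StratumConfig,
    pfam_id: str = "",
    in_bacteria: bool = False,
    in_archaea: bool = False,
) -> float:
    """Full dating rule: ancient strata, then the Excavata rule, then the tree.

    ``clades`` maps species to clade labels (``animal``, ``plant``,
    ``fungus``, ``protist-excavata``, ``other``).
    """
    ancient = assign_ancient_stratum(pfam_id, True, in_bacteria, in_archaea, cfg)
    if ancient is not None:
        return ancient
    labels = {clades.get(sp, "other") for sp in presence}
    if "protist-excavata" in labels and labels & set(FOCAL_CLADES):
        return cfg.feca_excavata_age
    return pfam_mrca_age(tree, presence)


def gene_age(pfam_ages: list[float]) -> float:
    """A gene is as old as its oldest retained pfam."""
    if not pfam_ages:
        raise ValueError("gene has no retained pfams; it should have been excluded")
    return max(pfam_ages)


def lineage_tag(age_my: float, kingdom_presence: set[str], cfg: StratumConfig) -> str:
    """Classify a dated pfam into the lineage subsets used for trend fits.

    ``ancient``: older than the LECA; ``recent_animal`` / ``recent_plant``:
    younger than the kingdom split and present in exactly one of the two
    kingdoms; ``intermediate``: between the two cutoffs; ``other`` otherwise.
    """
    if age_my > cfg.leca_age:
        return "ancient"
    if cfg.animal_plant_split <= age_my <= cfg.leca_age:
        return "intermediate"
    has_animal = "animal" in kingdom_presence
    has_plant = "plant" in kingdom_presence
    if has_animal and not has_plant:
        return "recent_animal"
    if has_plant and not has_animal:
        return "recent_plant"
    return "other"


def age_class_summary(datapoints: pd.DataFrame, value_col: str = "value") -> pd.DataFrame:
    """Quantile table per age class (one class per distinct assigned age).

    Returns one row per class with n, median, quartiles and the 9%/91%
    quantiles (linear interpolation between order statistics), plus a flag
    for singleton classes, mirroring how weighted box plots are summarized.
    """
    if datapoints.empty:
        raise ValueError("no datapoints")
    rows = []
    for age_class, grp in datapoints.groupby("age_class", sort=True):
        vals = grp[value_col].dropna().to_numpy()
        q = np.quantile(vals, [0.09, 0.25, 0.5, 0.75, 0.91])
        rows.append(
            {
                "age_class": age_class,
                "n": vals.size,
                "q09": q[0],
                "q25": q[1],
                "median": q[2],
                "q75": q[3],
                "q91": q[4],
                "singleton": vals.size == 1,
            }
        )
    return pd.DataFrame(rows)
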
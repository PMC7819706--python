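"""Pfam exclusion pipeline: annotation, keyword, and Dollo contamination filters.

Contamination and horizontal transfer inflate apparent domain ages, so pfams
are screened before dating: (i) pfams annotated as prokaryote-only, or with
no species annotation at all, are dropped; (ii) keyword screens on the
family abstract drop organelle-derived families and, for families shared
with prokaryotes, virus/bacteria-flavoured abstracts unless a eukaryotic
"rescue" term also appears; (iii) pfams present in fewer than two species
are dropped; (iv) a Dollo-parsimony Monte-Carlo test drops pfams whose
phylogenetic scatter looks like random contamination: the number of losses
implied by a single-gain history is compared with the loss count of random
same-size species subsets, and the pfam is rejected when its z-score
exceeds -2 (i.e. it is *not* significantly more clade-coherent than chance).
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from .tree import TimeTree

__all__ = [
    "PfamMetadata",
    "DolloTestResult",
    "FilterDecision",
    "annotation_filter",
    "keyword_filter",
    "two_species_filter",
    "dollo_losses",
    "DolloNull",
    "contamination_test",
    "EXCLUSION_TERMS",
    "RESCUE_TERMS",
    "ORGANELLE_TERMS",
]

# '*' in the published term lists is a prefix wildcard inside a
# case-insensitive substring search, so the stems alone suffice.
EXCLUSION_TERMS = (
    "viral", "virus", "bacter", "capsid", "bacillus", "pilus", "pilin",
    "mitochondria", "chloroplast",
)
RESCUE_TERMS = (
    "eukary", "vertebrat", "fung", "metazoa", "plant", "mammal", "insect",
    "yeast", "human", "all organisms", "antibod", "immune",
)
ORGANELLE_TERMS = ("mitochondria", "chloroplast")


@dataclass(frozen=True)
class PfamMetadata:
    pfam_id: str
    taxonomic_annotation: str  # eukaryote_only | shared_with_prokaryotes | prokaryote_only | unannotated
    abstract_text: str | None = None

    def __post_init__(self):
        allowed = {
            "eukaryote_only",
            "shared_with_prokaryotes",
            "prokaryote_only",
            "unannotated",
        }
        if self.taxonomic_annotation not in allowed:
            raise ValueError(
                f"pfam {self.pfam_id}: unknown annotation "
                f"{self.taxonomic_annotation!r}"
            )


@dataclass(frozen=True)
class FilterDecision:
    keep: bool
    reason: str


@dataclass(frozen=True)
class DolloTestResult:
    pfam_id: str
    k: int
    observed_losses: int | None
    null_mean: float | None
    null_sd: float | None
    z: float | None
    rejected: bool
    tested: bool
    n_reps: int
    seed: int | None
    note: str = ""


def annotation_filter(metadata: PfamMetadata) -> FilterDecision:
    """Drop pfams annotated prokaryote-only or lacking species annotation."""
    if metadata.taxonomic_annotation == "prokaryote_only":
        return FilterDecision(False, "prokaryote-annotated")
    if metadata.taxonomic_annotation == "unannotated":
        return FilterDecision(False, "no species annotation")
    return FilterDecision(True, "kept")


def keyword_filter(metadata: PfamMetadata) -> FilterDecision:
    """Abstract keyword screen (applies after :func:`annotation_filter`).

    Families without an abstract are dropped.  Eukaryote-only families are
    dropped when the abstract mentions an organelle.  Families shared with
    prokaryotes are dropped when any exclusion term matches and no rescue
    term does.  All matching is case-insensitive substring search.
    """
    if not metadata.abstract_text:
        return FilterDecision(False, "no abstract")
    text = metadata.abstract_text.lower()
    if metadata.taxonomic_annotation == "eukaryote_only":
        if any(term in text for term in ORGANELLE_TERMS):
            return FilterDecision(False, "organelle keyword")
        return FilterDecision(True, "kept")
    if any(term in text for term in EXCLUSION_TERMS):
        if any(term in text for term in RESCUE_TERMS):
            return FilterDecision(True, "kept (rescued)")
        return FilterDecision(False, "exclusion keyword")
    return FilterDecision(True, "kept")


def two_species_filter(presence: set[str]) -> FilterDecision:
    """Drop pfams present in fewer than two species."""
    if len(presence) < 2:
        return FilterDecision(False, "single species")
    return FilterDecision(True, "kept")


def dollo_losses(tree: TimeTree, presence: set[str]) -> int:
    """Loss count under single-gain (Dollo) parsimony.

    The gain is placed at the MRCA of the presence set; losses are the
    maximal subtrees below the MRCA that contain no presence species.
    """
    vec = tree.presence_vector(presence)
    if not vec.any():
        raise ValueError("presence set is empty")
    return int(_losses_matrix(tree, vec[None, :])[0])


def _losses_matrix(tree: TimeTree, presence: np.ndarray) -> np.ndarray:
    """Vectorized Dollo loss counts for a (reps, n_leaves) presence matrix."""
    counts = tree.subtree_counts(presence)  # (reps, n_nodes)
    k = presence.sum(axis=1)
    # MRCA per rep: largest node index (deepest, given topological order)
    # whose subtree holds all k presence leaves.
    holds_all = counts == k[:, None]
    mrca = tree.n_nodes - 1 - np.argmax(holds_all[:, ::-1], axis=1)
    parent = tree.parent
    child_mask = parent >= 0
    child_idx = np.flatnonzero(child_mask)
    parent_idx = parent[child_idx]
    empty_child = counts[:, child_idx] == 0
    nonempty_parent = counts[:, parent_idx] > 0
    # node is inside the MRCA subtree iff mrca is an ancestor-or-self;
    # with topological order: node >= mrca and mrca's leaf set contains its
    # leaf set.  Use the precomputed leaves_below incidence.
    # A count-0 node c lies inside subtree(mrca) iff a representative leaf
    # below c is below the mrca (subtrees nest or are disjoint, and a count-0
    # node cannot be an ancestor of the mrca).
    below = tree.leaves_below  # (n_nodes, n_leaves)
    rep_leaf = np.argmax(below[child_idx], axis=1)
    inside = below[np.asarray(mrca)][:, rep_leaf]
    return (empty_child & nonempty_parent & inside).sum(axis=1)


class DolloNull:
    """Cached Monte-Carlo null of Dollo loss counts for random k-subsets.

    One null distribution is simulated per (tree, k, n_reps, seed) and
    reused across pfams, mirroring a per-k simulation design.
    """

    def __init__(self, tree: TimeTree, n_reps: int = 1000, seed: int = 0):
        if n_reps < 100:
            raise ValueError("n_reps must be >= 100")
        self.tree = tree
        self.n_reps = n_reps
        self.seed = seed
        self._cache: dict[int, tuple[float, float]] = {}

    def moments(self, k: int) -> tuple[float, float]:
        if k not in self._cache:
            rng = np.random.default_rng((self.seed, k))
            S = self.tree.n_leaves
            # uniform k-subsets via random keys (vectorized sampling w/o replacement)
            idx = np.argpartition(rng.random((self.n_reps, S)), k, axis=1)[:, :k]
            reps = np.zeros((self.n_reps, S), dtype=bool)
            np.put_along_axis(reps, idx, True, axis=1)
            losses = _losses_matrix(self.tree, reps)
            self._cache[k] = (float(losses.mean()), float(losses.std(ddof=0)))
        return self._cache[k]


def contamination_test(
    tree: TimeTree,
    presence: set[str],
    pfam_id: str = "",
    n_reps: int = 1000,
    seed: int = 0,
    null: DolloNull | None = None,
) -> DolloTestResult:
    """Dollo z-test against a random-contamination null.

    Applies only to pfams present in fewer than half the species; wider
    pfams are returned untested and kept.  The pfam is rejected when
    ``z > -2``: its loss count is not clearly below what uniformly random
    presence would imply.  A degenerate null (sd = 0, possible on tiny
    trees) keeps the pfam with a note.
    """
    k = len(presence)
    S = tree.n_leaves
    if 2 * k >= S:
        return DolloTestResult(
            pfam_id, k, None, None, None, None, rejected=False, tested=False,
            n_reps=0, seed=None, note="not tested (k >= S/2), kept",
        )
    if null is None:
        null = DolloNull(tree, n_reps=n_reps, seed=seed)
    observed = dollo_losses(tree, presence)
    mean, sd = null.moments(k)
    if sd == 0.0:
        return DolloTestResult(
            pfam_id, k, observed, mean, sd, None, rejected=False, tested=True,
            n_reps=null.n_reps, seed=null.seed, note="degenerate null (sd=0), kept",
        )
    z = (observed - mean) / sd
    return DolloTestResult(
        pfam_id, k, observed, mean, sd, z, rejected=z > -2.0, tested=True,
        n_reps=null.n_reps, seed=null.seed,
    )
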
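"""Exclusion filters, Dollo loss counting and the contamination z-test."""

import itertools

import numpy as np
import pytest

from phylostrat.quality_filters import (
    DolloNull,
    PfamMetadata,
    annotation_filter,
    contamination_test,
    dollo_losses,
    keyword_filter,
    two_species_filter,
)
from phylostrat.tree import TimeTree

from conftest import make_balanced_tree


def meta(annotation, abstract):
    return PfamMetadata("PFX", annotation, abstract)


class TestAnnotationFilter:
    def test_prokaryote_only_dropped(self):
        assert not annotation_filter(meta("prokaryote_only", "x")).keep

    def test_unannotated_dropped(self):
        assert not annotation_filter(meta("unannotated", "x")).keep

    @pytest.mark.parametrize("a", ["eukaryote_only", "shared_with_prokaryotes"])
    def test_annotated_pass_through(self, a):
        assert annotation_filter(meta(a, "x")).keep

    def test_unknown_annotation_rejected(self):
        with pytest.raises(ValueError):
            meta("viral", "x")


class TestKeywordFilter:
    def test_viral_capsid_dropped(self):
        d = keyword_filter(meta("shared_with_prokaryotes", "a viral capsid protein"))
        assert not d.keep

    def test_rescue_term_keeps(self):
        d = keyword_filter(
            meta("shared_with_prokaryotes", "bacterial and yeast homologs")
        )
        assert d.keep

    def test_prefix_wildcard_matches_derived_forms(self):
        assert not keyword_filter(
            meta("shared_with_prokaryotes", "found in one bacterium only")
        ).keep
        assert keyword_filter(
            meta("shared_with_prokaryotes", "bacterium and eukaryotic cells")
        ).keep

    def test_eukaryote_only_organelle_dropped(self):
        assert not keyword_filter(
            meta("eukaryote_only", "imported into the chloroplast")
        ).keep

    def test_eukaryote_only_ignores_prokaryote_terms(self):
        assert keyword_filter(
            meta("eukaryote_only", "distantly similar to a viral protein")
        ).keep

    def test_missing_abstract_dropped(self):
        assert not keyword_filter(meta("eukaryote_only", None)).keep

    def test_matching_is_case_insensitive(self):
        assert not keyword_filter(
            meta("shared_with_prokaryotes", "A Viral Replication Factor")
        ).keep


class TestTwoSpeciesFilter:
    @pytest.mark.parametrize("n,kept", [(1, False), (2, True), (435, True)])
    def test_boundary(self, n, kept):
        assert two_species_filter({f"s{i}" for i in range(n)}).keep is kept


class TestDolloLosses:
    def test_everything_present_no_losses(self, four_leaf_tree):
        assert dollo_losses(four_leaf_tree, {"A", "B", "C", "D"}) == 0

    def test_single_leaf_no_losses(self, four_leaf_tree):
        assert dollo_losses(four_leaf_tree, {"A"}) == 0

    def test_two_opposite_leaves_two_losses(self, four_leaf_tree):
        assert dollo_losses(four_leaf_tree, {"A", "C"}) == 2

    def test_exhaustive_oracle_on_small_trees(self, rng):
        """Dollo counts must equal brute-force minimal losses over every
        single-gain history, on every presence subset of several small trees."""
        for n_leaves in (4, 5, 6, 7, 8):
            tree = _random_tree(rng, n_leaves)
            best = _oracle_min_losses(tree)
            leaves = tree.leaf_names
            for r in range(1, n_leaves + 1):
                for combo in itertools.combinations(leaves, r):
                    code = sum(
                        1 << i for i, name in enumerate(leaves) if name in combo
                    )
                    assert dollo_losses(tree, set(combo)) == best[code], combo


def _random_tree(rng, n_leaves, root_age=1000.0):
    """Random topology, ultrametric ages, built directly in arrays."""
    parent, age = [-1], [root_age]
    leaf_names = {}

    def split(names, idx, node_age):
        k = 1 if len(names) == 2 else int(rng.integers(1, len(names) - 1))
        for part in (names[:k], names[k:]):
            child_age = node_age * rng.uniform(0.3, 0.8) if len(part) > 1 else 0.0
            parent.append(idx)
            age.append(child_age)
            child = len(parent) - 1
            if len(part) == 1:
                leaf_names[part[0]] = child
            else:
                split(part, child, child_age)

    split([f"t{i}" for i in range(n_leaves)], 0, root_age)
    return TimeTree(parent, age, leaf_names)


def _oracle_min_losses(tree):
    """Brute force: enumerate every gain node and every loss subset of its
    strict descendants; record the minimal loss count per surviving-leaf set."""
    leaves = tree.leaf_names
    leaf_bit = {name: 1 << i for i, name in enumerate(leaves)}
    ancestors = {}  # strict ancestors per node
    for node in range(tree.n_nodes):
        path, p = set(), tree.parent[node]
        while p >= 0:
            path.add(int(p))
            p = tree.parent[p]
        ancestors[node] = path
    best = {}
    for gain in range(tree.n_nodes):
        desc = [n for n in range(tree.n_nodes) if gain in ancestors[n]]
        pos = {n: i for i, n in enumerate(desc)}
        gain_leaves = [
            (name, leaf_bit[name],
             sum(1 << pos[a] for a in (ancestors[tree.leaf_index[name]] | {tree.leaf_index[name]}) if a in pos))
            for name in leaves
            if tree.leaf_index[name] == gain or gain in ancestors[tree.leaf_index[name]]
        ]
        for mask in range(1 << len(desc)):
            code = 0
            for _name, bit, path_mask in gain_leaves:
                if not (mask & path_mask):
                    code |= bit
            n_losses = mask.bit_count()
            if code and (code not in best or n_losses < best[code]):
                best[code] = n_losses
    return best


@pytest.fixture(scope="module")
def tree16():
    return make_balanced_tree(depth=4, root_age=320.0)


class TestContaminationTest:
    def test_wide_pfams_not_tested(self, tree16):
        res = contamination_test(tree16, set(tree16.leaf_names[:8]), n_reps=200)
        assert not res.tested and not res.rejected and "not tested" in res.note

    def test_clade_restricted_pfam_kept(self, tree16):
        # an entire 4-leaf clade: leaves below one depth-2 node
        node = tree16.children[tree16.children[tree16.root][0]][0]
        sub = {tree16.leaf_names[i] for i in np.flatnonzero(tree16.leaves_below[node])}
        res = contamination_test(tree16, sub, n_reps=500, seed=3)
        assert res.tested and res.z is not None
        assert res.z <= -2 and not res.rejected

    def test_scattered_pfam_rejected(self, tree16, rng):
        rejected = 0
        null = DolloNull(tree16, n_reps=500, seed=3)
        for _ in range(20):
            sub = set(rng.choice(tree16.leaf_names, size=5, replace=False))
            res = contamination_test(tree16, sub, null=null)
            rejected += res.rejected
        assert rejected >= 14  # scattered presence mostly looks like contamination

    def test_null_mean_increasing_over_sparse_k(self, balanced_tree_64):
        """The expected random-presence loss count grows with k while
        presence is sparse (it saturates and dips again as k approaches
        half the species, where the test no longer applies anyway)."""
        null = DolloNull(balanced_tree_64, n_reps=800, seed=5)
        means = [null.moments(k)[0] for k in range(2, 17)]
        assert all(b >= a - 1e-9 for a, b in zip(means, means[1:]))

    def test_degenerate_null_keeps_with_note(self):
        tiny = TimeTree.from_newick("((A:1,B:1):1,(C:1,D:1):1);")
        res = contamination_test(tiny, {"A"}, n_reps=200, seed=0)
        # k=1 always implies 0 losses in the null -> sd == 0
        assert res.tested and res.null_sd == 0.0 and not res.rejected
        assert "degenerate" in res.note

    def test_small_replicate_count_rejected(self, tree16):
        with pytest.raises(ValueError):
            DolloNull(tree16, n_reps=50)


class TestFilterOrderStability:
    def test_pure_predicates_commute(self):
        """Each filter is a pure predicate of its own inputs, so the set of
        pfams surviving all of them is order-independent."""
        metas = [
            meta("eukaryote_only", "a fine domain"),
            meta("prokaryote_only", "a fine domain"),
            meta("shared_with_prokaryotes", "viral polymerase"),
            meta("shared_with_prokaryotes", "viral protein studied in human"),
        ]
        presences = [{"a", "b"}, {"a"}, {"a", "b"}, {"a", "b", "c"}]

        def survives(m, p):
            checks = [
                lambda: annotation_filter(m).keep,
                lambda: annotation_filter(m).keep and keyword_filter(m).keep,
                lambda: two_species_filter(p).keep,
            ]
            return all(c() for c in checks)

        forward = [survives(m, p) for m, p in zip(metas, presences)]
        reverse = [
            two_species_filter(p).keep
            and keyword_filter(m).keep
            and annotation_filter(m).keep
            for m, p in zip(metas, presences)
        ]
        assert forward == reverse == [True, False, False, True]
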
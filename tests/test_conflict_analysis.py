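import numpy as np
import pandas as pd
import pytest

import divconflict as dc
from divconflict import (
    INFORMATIVE_ONLY,
    STRICT,
    conflict_rate_correlation,
    conflict_through_time,
    per_branch_conflict,
)
from divconflict.conflict_analysis import ConflictProfile
from divconflict.tree_core import TreeError

from conftest import cherry_gene_tree


# --------------------------------------------------------------------------
# Independent brute-force oracle: a naive double loop over branches x genes
# that re-derives every split from scratch, shared with the acceptance suite.
# --------------------------------------------------------------------------

def naive_leaf_labels(node):
    if node.is_leaf:
        return {node.label}
    out = set()
    for child in node.children:
        out |= naive_leaf_labels(child)
    return out


def naive_splits(tree):
    taxa = naive_leaf_labels(tree.root)
    splits = set()
    stack = list(tree.root.children)
    while stack:
        node = stack.pop()
        stack.extend(node.children)
        if node.is_leaf:
            continue
        side = frozenset(naive_leaf_labels(node))
        other = frozenset(taxa - side)
        if len(side) >= 2 and len(other) >= 2:
            splits.add(frozenset((side, other)))
    return splits


def brute_force_counts(species_tree, gene_trees):
    """Per-branch (congruent, conflicting, uninformative) counts."""
    taxa = naive_leaf_labels(species_tree.tree.root)
    rows = {}
    stack = list(species_tree.tree.root.children)
    branches = []
    while stack:
        node = stack.pop()
        stack.extend(node.children)
        if node.is_leaf:
            continue
        side = frozenset(naive_leaf_labels(node))
        other = frozenset(taxa - side)
        if len(side) >= 2 and len(other) >= 2:
            branches.append((side, other))
    gene_data = [(naive_leaf_labels(g.root), naive_splits(g))
                 for g in gene_trees]
    results = []
    for side, other in branches:
        congruent = conflicting = uninformative = 0
        for gtaxa, gsplits in gene_data:
            a = frozenset(side & gtaxa)
            b = frozenset(other & gtaxa)
            if len(a) < 2 or len(b) < 2:
                uninformative += 1
            elif frozenset((a, b)) in gsplits:
                congruent += 1
            else:
                conflicting += 1
        results.append((side, congruent, conflicting, uninformative))
    return results


def make_gene_set(n_matching, n_discordant):
    return [cherry_gene_tree("AB|CD") for _ in range(n_matching)] + \
        [cherry_gene_tree("AC|BD") for _ in range(n_discordant)]


class TestPerBranchConflict:
    def test_identical_gene_trees_give_zero_conflict(self, balanced_quartet):
        genes = [cherry_gene_tree("AB|CD") for _ in range(10)]
        for policy in (STRICT, INFORMATIVE_ONLY):
            profile = per_branch_conflict(balanced_quartet, genes, policy)
            assert np.allclose(profile.conflict_proportion, 0.0)

    def test_enumerated_mixture(self, balanced_quartet):
        """60 congruent + 40 discordant gene trees: proportion 0.40 on the
        internal branch under both policies."""
        genes = make_gene_set(60, 40)
        for policy in (STRICT, INFORMATIVE_ONLY):
            profile = per_branch_conflict(balanced_quartet, genes, policy)
            assert profile.conflict_proportion == pytest.approx(0.40)

    def test_missing_taxon_moves_mass_between_policies(self, balanced_quartet):
        """10 of the 40 discordant trees lack taxon D: their induced split is
        uninformative, so STRICT stays 0.40 but the informative-only rate is
        30/90."""
        genes = [cherry_gene_tree("AB|CD") for _ in range(60)]
        genes += [cherry_gene_tree("AC|BD") for _ in range(30)]
        genes += [dc.parse_newick("((A:1,C:1):1,B:2);") for _ in range(10)]
        strict = per_branch_conflict(balanced_quartet, genes, STRICT)
        informative = per_branch_conflict(balanced_quartet, genes,
                                          INFORMATIVE_ONLY)
        assert strict.conflict_proportion == pytest.approx(0.40)
        assert informative.conflict_proportion == pytest.approx(30 / 90)
        table = strict.table.iloc[0]
        assert (table.n_congruent, table.n_conflicting,
                table.n_uninformative) == (60, 30, 10)

    def test_unknown_tip_names_label_and_gene(self, balanced_quartet):
        genes = [cherry_gene_tree("AB|CD"),
                 dc.parse_newick("((A:1,B:1):1,(C:1,Z:1):1);")]
        with pytest.raises(TreeError, match=r"gene tree 1.*Z"):
            per_branch_conflict(balanced_quartet, genes)

    def test_strict_dominates_informative_only(self, rng):
        species = dc.simulate_yule_tree(12, 1.0, seed=99)
        genes = dc.simulate_msc_gene_trees(
            species, dc.MSCConfig(effective_population_size=20_000,
                                  n_genes=30, seed=4))
        strict = per_branch_conflict(species, genes, STRICT)
        informative = per_branch_conflict(species, genes, INFORMATIVE_ONLY)
        assert (strict.conflict_proportion >=
                informative.conflict_proportion - 1e-12).all()
        assert ((strict.conflict_proportion >= 0)
                & (strict.conflict_proportion <= 1)).all()

    def test_matches_brute_force_on_random_fixtures(self, rng):
        """Exact count equality against the naive reimplementation on random
        8-taxon species trees with random taxon deletion in the gene trees."""
        for rep in range(5):
            species = dc.simulate_yule_tree(8, 1.0,
                                            seed=int(rng.integers(2 ** 31)))
            genes = dc.simulate_msc_gene_trees(
                species, dc.MSCConfig(effective_population_size=8_000,
                                      n_genes=20,
                                      seed=int(rng.integers(2 ** 31))))
            pruned = []
            for gene in genes:
                labels = gene.tip_labels()
                keep = [l for l in labels if rng.random() > 0.2]
                if len(keep) < 3:
                    keep = labels[:3]
                dated = dc.compute_node_ages(gene)
                pruned.append(dc.prune_to_tips(dated, keep).tree)
            profile = per_branch_conflict(species, pruned)
            oracle = brute_force_counts(species, pruned)
            taxa = frozenset(species.tree.tip_labels())
            got = {}
            for row in profile.table.itertuples():
                side = frozenset(row.clade_tips.split(";"))
                key = frozenset((side, taxa - side))
                counts = (row.n_congruent, row.n_conflicting,
                          row.n_uninformative)
                got.setdefault(key, []).append(counts)
            want = {}
            for side, n_con, n_dis, n_unin in oracle:
                key = frozenset((frozenset(side), taxa - frozenset(side)))
                want.setdefault(key, []).append((n_con, n_dis, n_unin))
            for key in want:
                assert sorted(got[key]) == sorted(want[key])
            assert set(got) == set(want)


class TestConflictThroughTime:
    def fabricate_profile(self, rows):
        table = pd.DataFrame(rows, columns=["child_age", "parent_age",
                                            "duration", "p_strict",
                                            "p_informative"])
        table["duration"] = table["parent_age"] - table["child_age"]
        return ConflictProfile(table=table, n_genes=100, policy=STRICT)

    def fabricate_tree(self, root_age):
        return dc.compute_node_ages(dc.parse_newick(
            f"((A:{root_age - 1},B:{root_age - 1}):1,C:{root_age});"))

    def test_single_spanning_branch_fills_every_slice(self):
        profile = self.fabricate_profile(
            [{"child_age": 0.0, "parent_age": 10.0, "p_strict": 0.3,
              "p_informative": 0.3}])
        series = conflict_through_time(profile, self.fabricate_tree(10.0),
                                       slice_width=2.5)
        assert len(series.table) == 4
        assert np.allclose(series.mean_conflict, 0.3)

    def test_mean_over_crossing_branches(self):
        profile = self.fabricate_profile(
            [{"child_age": 0.0, "parent_age": 10.0, "p_strict": 0.2,
              "p_informative": 0.2},
             {"child_age": 0.0, "parent_age": 10.0, "p_strict": 0.6,
              "p_informative": 0.6}])
        series = conflict_through_time(profile, self.fabricate_tree(10.0),
                                       slice_width=2.5)
        assert np.allclose(series.mean_conflict, 0.4)

    def test_branch_contributes_only_to_overlapping_slices(self):
        profile = self.fabricate_profile(
            [{"child_age": 7.0, "parent_age": 9.0, "p_strict": 1.0,
              "p_informative": 1.0}])
        series = conflict_through_time(profile, self.fabricate_tree(10.0),
                                       slice_width=2.5)
        assert list(series.table["older_bound"]) == [7.5, 10.0]

    def test_oldest_slice_may_be_narrow(self):
        profile = self.fabricate_profile(
            [{"child_age": 0.0, "parent_age": 9.0, "p_strict": 0.5,
              "p_informative": 0.5}])
        series = conflict_through_time(profile, self.fabricate_tree(9.0),
                                       slice_width=2.5)
        oldest = series.table.iloc[-1]
        assert oldest["older_bound"] == pytest.approx(9.0)
        assert oldest["older_bound"] - oldest["younger_bound"] == \
            pytest.approx(1.5)

    def test_invalid_slice_width(self):
        profile = self.fabricate_profile(
            [{"child_age": 0.0, "parent_age": 1.0, "p_strict": 0.0,
              "p_informative": 0.0}])
        with pytest.raises(ValueError):
            conflict_through_time(profile, self.fabricate_tree(5.0),
                                  slice_width=0.0)


class TestConflictRateCorrelation:
    def fabricate(self, durations, proportions):
        table = pd.DataFrame({
            "child_age": 0.0,
            "parent_age": durations,
            "duration": durations,
            "p_strict": proportions,
            "p_informative": proportions,
        })
        return ConflictProfile(table=table, n_genes=100, policy=STRICT)

    def test_exact_linear_relation_gives_unit_r_squared(self):
        durations = np.array([0.1, 1.0, 10.0, 100.0])
        proportions = 0.8 - 0.2 * np.log10(durations)
        result = conflict_rate_correlation(self.fabricate(durations,
                                                          proportions))
        assert result["r_squared"] == pytest.approx(1.0)
        assert result["slope"] == pytest.approx(-0.2)

    def test_constant_conflict_gives_zero_r_squared(self):
        result = conflict_rate_correlation(
            self.fabricate([0.5, 1.0, 2.0, 4.0], [0.3, 0.3, 0.3, 0.3]))
        assert result == {"slope": 0.0, "r_squared": 0.0, "p_value": 1.0}

    def test_identity_transform(self):
        durations = np.array([1.0, 2.0, 3.0, 4.0])
        proportions = 0.1 * durations
        result = conflict_rate_correlation(
            self.fabricate(durations, proportions),
            duration_transform="identity")
        assert result["slope"] == pytest.approx(0.1)

    def test_too_few_branches_rejected(self):
        with pytest.raises(ValueError):
            conflict_rate_correlation(self.fabricate([1.0, 2.0], [0.1, 0.2]))
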
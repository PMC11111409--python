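"""Per-branch gene-tree conflict, its through-time aggregation, and the
conflict–duration regression.

A gene tree is *congruent* with a species-tree branch when the branch's
bipartition, restricted to the gene tree's taxon set, is informative and
displayed by the gene tree; *uninformative* when the restriction leaves
fewer than two taxa on a side; *conflicting* otherwise.  Two proportions are
reported per branch:

* ``strict`` — (conflicting + uninformative) / n_genes, the literal reading
  of "gene trees that do not share a congruent bipartition";
* ``informative-only`` — conflicting / (conflicting + congruent), which
  keeps taxon-poor gene trees from inflating conflict.

Terminal branches and the root edge carry no informative bipartition and are
excluded throughout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .tree_core import (
    DatedTree,
    TimeSlice,
    Tree,
    TreeError,
    UNINFORMATIVE,
    branch_bipartitions,
    induced_bipartition,
    tree_bipartitions,
)

__all__ = [
    "STRICT",
    "INFORMATIVE_ONLY",
    "ConflictProfile",
    "ConflictSeries",
    "per_branch_conflict",
    "conflict_through_time",
    "conflict_rate_correlation",
]

STRICT = "strict"
INFORMATIVE_ONLY = "informative-only"
_POLICIES = (STRICT, INFORMATIVE_ONLY)


@dataclass
class ConflictProfile:
    """Per-branch conflict counts for the internal branches of a species
    tree.

    ``table`` has one row per internal non-root branch: branch id, the
    branch's clade (smaller bipartition side, sorted and semicolon-joined),
    parent/child ages, duration, the three counts, and both proportions.  ``policy`` selects which proportion
    :attr:`conflict_proportion` exposes.
    """

    table: pd.DataFrame
    n_genes: int
    policy: str = STRICT

    @property
    def conflict_proportion(self) -> np.ndarray:
        column = "p_strict" if self.policy == STRICT else "p_informative"
        return self.table[column].to_numpy()

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False, float_format="%.10g")


@dataclass
class ConflictSeries:
    """Mean per-branch conflict of the branches crossing each time slice.

    Only slices crossed by at least one internal branch appear.
    """

    table: pd.DataFrame
    slice_width: float
    policy: str

    @property
    def midpoints(self) -> np.ndarray:
        return self.table["midpoint"].to_numpy()

    @property
    def mean_conflict(self) -> np.ndarray:
        return self.table["mean_conflict"].to_numpy()

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False, float_format="%.10g")


def per_branch_conflict(species_tree: DatedTree, gene_trees: list[Tree],
                        policy: str = STRICT) -> ConflictProfile:
    """Classify every gene tree against every internal species-tree branch.

    Raises :class:`TreeError` naming the offending label and gene index if a
    gene tree contains a tip absent from the species tree.
    """
    if policy not in _POLICIES:
        raise ValueError(f"policy must be one of {_POLICIES}")
    species_taxa = species_tree.tree.taxon_set()
    branch_bips = branch_bipartitions(species_tree.tree)
    branches = list(branch_bips.items())

    gene_info = []
    for gi, gtree in enumerate(gene_trees):
        taxa = gtree.taxon_set()
        unknown = taxa - species_taxa
        if unknown:
            raise TreeError(
                f"gene tree {gi} has tips not in the species tree: "
                f"{sorted(unknown)}")
        keys = {b.key for b in tree_bipartitions(gtree)}
        gene_info.append((taxa, keys))

    rows = []
    for bi, (node, bip) in enumerate(branches):
        n_con = n_dis = n_unin = 0
        for taxa, keys in gene_info:
            induced = induced_bipartition(bip, taxa)
            if induced is UNINFORMATIVE:
                n_unin += 1
            elif induced.key in keys:
                n_con += 1
            else:
                n_dis += 1
        n_genes = len(gene_trees)
        informative = n_con + n_dis
        child_age = species_tree.age(node)
        parent_age = species_tree.age(node.parent)
        small = min((bip.side_a, bip.side_b),
                    key=lambda s: (len(s), tuple(sorted(s))))
        rows.append({
            "branch": f"b{bi}",
            "clade_tips": ";".join(sorted(small)),
            "clade_size": len(small),
            "child_age": child_age,
            "parent_age": parent_age,
            "duration": parent_age - child_age,
            "n_congruent": n_con,
            "n_conflicting": n_dis,
            "n_uninformative": n_unin,
            "p_strict": (n_dis + n_unin) / n_genes if n_genes else 0.0,
            "p_informative": n_dis / informative if informative else 0.0,
        })
    table = pd.DataFrame(rows, columns=[
        "branch", "clade_tips", "clade_size", "child_age", "parent_age",
        "duration", "n_congruent", "n_conflicting", "n_uninformative",
        "p_strict", "p_informative"])
    return ConflictProfile(table=table, n_genes=len(gene_trees), policy=policy)


def conflict_through_time(profile: ConflictProfile, species_tree: DatedTree,
                          slice_width: float = 2.5) -> ConflictSeries:
    """Average per-branch conflict within contiguous time slices.

    Slices are anchored at the present (the oldest slice, reaching the root,
    may be narrower); each slice averages the active conflict proportion over
    the internal branches whose half-open age span overlaps it.
    """
    if slice_width <= 0:
        raise ValueError("slice_width must be positive")
    root_age = species_tree.root_age
    child = profile.table["child_age"].to_numpy()
    parent = profile.table["parent_age"].to_numpy()
    props = profile.conflict_proportion
    rows = []
    younger = 0.0
    while younger < root_age:
        older = min(younger + slice_width, root_age)
        sl = TimeSlice(older_bound=older, younger_bound=younger)
        mask = (child < sl.older_bound) & (parent > sl.younger_bound) & (parent > child)
        if mask.any():
            rows.append({
                "older_bound": older,
                "younger_bound": younger,
                "midpoint": sl.midpoint,
                "mean_conflict": float(props[mask].mean()),
                "n_branches": int(mask.sum()),
            })
        younger = younger + slice_width
    table = pd.DataFrame(rows, columns=[
        "older_bound", "younger_bound", "midpoint", "mean_conflict",
        "n_branches"])
    return ConflictSeries(table=table, slice_width=slice_width,
                          policy=profile.policy)


def conflict_rate_correlation(profile: ConflictProfile,
                              duration_transform: str = "log10") -> dict:
    """OLS regression of per-branch conflict on (transformed) branch duration.

    Branch duration proxies the local diversification rate (fast-diversifying
    regions of the tree have short internal branches), so a negative slope
    means conflict rises with diversification.  Returns slope, r² and the
    two-sided p-value of the slope; zero variance in either variable yields
    slope 0, r² 0 and p-value 1.
    """
    if duration_transform not in ("log10", "identity"):
        raise ValueError("duration_transform must be 'log10' or 'identity'")
    durations = profile.table["duration"].to_numpy()
    props = profile.conflict_proportion
    mask = durations > 0
    x = durations[mask]
    y = props[mask]
    if x.size < 3:
        raise ValueError("need at least 3 branches with positive duration")
    if duration_transform == "log10":
        x = np.log10(x)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return {"slope": 0.0, "r_squared": 0.0, "p_value": 1.0}
    fit = stats.linregress(x, y)
    return {"slope": float(fit.slope),
            "r_squared": float(fit.rvalue ** 2),
            "p_value": float(fit.pvalue)}
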
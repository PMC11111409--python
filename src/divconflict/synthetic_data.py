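"""Synthetic inputs for the pipeline.

Three generators cover everything the downstream analyses consume:

* :func:`simulate_bd_tree` — forward-time birth–death species trees with
  piecewise-constant (episodic) speciation and extinction rates, conditioned
  on an exact number of extant tips by whole-replicate rejection sampling.
* :func:`simulate_msc_gene_trees` — gene trees evolving inside an ultrametric
  species tree under the censored multispecies coalescent, one haploid sample
  per species.
* :func:`generate_taxonomy` — a complete species-level tree with monophyletic
  genera and families plus a checklist-style diversity table, together with
  the genus-sampled tree obtained by keeping one (or a few) representative
  tips per sampled genus.  The complete tree is kept as ground truth for
  validating the sampling-fraction estimator.

The MSC clock: a species-tree branch of duration ``t`` Myr spans
``t * g / (2 * Ne)`` coalescent units, where ``g`` is the number of
generations per Myr and ``Ne`` the (haploid-equivalent) effective population
size.  ``g`` defaults to 10,000, under which ``Ne = 5,000`` makes one Myr of
branch equal one coalescent unit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, NamedTuple

import numpy as np
import pandas as pd

from .tree_core import (
    DatedTree,
    Node,
    Tree,
    TreeError,
    compute_node_ages,
)

__all__ = [
    "RateSchedule",
    "MSCConfig",
    "TaxonomyTable",
    "TaxonomySample",
    "EXPERIMENT_PRESETS",
    "experiment_preset",
    "simulate_bd_tree",
    "simulate_bd_forward",
    "simulate_yule_tree",
    "tree_from_branching_ages",
    "prune_extinct",
    "prune_to_tips",
    "simulate_msc_gene_trees",
    "generate_taxonomy",
    "DEFAULT_ORIGIN_AGE",
]

#: Origin age (Ma) of the simulated 100-tip species trees.  The source
#: experiments fix the rate breakpoints at 6 and 2 Ma but not the origin; a
#: 10-Ma origin makes the expected extant count under the experiment-1
#: schedule (~e^{4.8} ≈ 120) bracket the 100-tip target, keeping the
#: rejection sampler efficient.
DEFAULT_ORIGIN_AGE = 10.0


# ---------------------------------------------------------------------------
# Rate schedules
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RateSchedule:
    """Piecewise-constant speciation/extinction rates over age intervals.

    ``breakpoints`` are interior boundary ages in strictly descending order;
    they split time into ``len(breakpoints) + 1`` intervals ordered from the
    oldest (ages above the first breakpoint) to the youngest (ages below the
    last breakpoint, down to the present).  ``lam`` and ``mu`` give the
    speciation and extinction rate (species Myr^-1) per interval in the same
    order.
    """

    breakpoints: tuple[float, ...]
    lam: tuple[float, ...]
    mu: tuple[float, ...]

    def __post_init__(self):
        object.__setattr__(self, "breakpoints", tuple(float(b) for b in self.breakpoints))
        object.__setattr__(self, "lam", tuple(float(x) for x in self.lam))
        object.__setattr__(self, "mu", tuple(float(x) for x in self.mu))
        if list(self.breakpoints) != sorted(self.breakpoints, reverse=True):
            raise ValueError("breakpoints must be strictly descending")
        if len(set(self.breakpoints)) != len(self.breakpoints):
            raise ValueError("breakpoints must be strictly descending")
        n = len(self.breakpoints) + 1
        if len(self.lam) != n or len(self.mu) != n:
            raise ValueError("need one rate per interval (len(breakpoints)+1)")
        if any(x < 0 for x in self.lam + self.mu):
            raise ValueError("rates must be non-negative")

    @classmethod
    def constant(cls, lam: float, mu: float = 0.0) -> "RateSchedule":
        return cls((), (lam,), (mu,))

    def interval_index(self, age: float) -> int:
        for i, bp in enumerate(self.breakpoints):
            if age > bp:
                return i
        return len(self.breakpoints)

    def rate_at(self, age: float) -> tuple[float, float]:
        i = self.interval_index(age)
        return self.lam[i], self.mu[i]

    def next_breakpoint_below(self, age: float) -> float:
        for bp in self.breakpoints:
            if bp < age:
                return bp
        return 0.0

    @property
    def pure_birth(self) -> bool:
        return all(m == 0.0 for m in self.mu)

    def net_rate_integral(self, older: float, younger: float) -> float:
        """Integral of lambda(t) - mu(t) over ages [younger, older]."""
        total = 0.0
        hi = older
        while hi > younger:
            lo = max(self.next_breakpoint_below(hi), younger)
            lam, mu = self.rate_at(hi)
            total += (lam - mu) * (hi - lo)
            hi = lo
        return total


@dataclass(frozen=True)
class MSCConfig:
    """Multispecies-coalescent settings.

    ``effective_population_size`` is the haploid-equivalent Ne: the pairwise
    coalescence rate is one per ``2 * Ne`` generations.
    """

    effective_population_size: float = 5_000.0
    generations_per_myr: float = 10_000.0
    n_genes: int = 100
    seed: int | np.random.Generator | None = None

    def __post_init__(self):
        if self.effective_population_size <= 0:
            raise ValueError("effective population size must be positive")
        if self.generations_per_myr <= 0:
            raise ValueError("generations per Myr must be positive")
        if self.n_genes <= 0:
            raise ValueError("n_genes must be positive")

    @property
    def pair_coalescence_rate(self) -> float:
        """Coalescence rate per lineage pair per Myr."""
        return self.generations_per_myr / (2.0 * self.effective_population_size)


_EXP1_SCHEDULE = RateSchedule((6.0, 2.0), (0.75, 0.075, 0.75), (0.0, 0.0, 0.0))

#: The simulation experiments: episodic schedules with shifts at 6 and 2 Ma.
#: experiment1 shifts the speciation rate with no extinction; experiment2
#: keeps the same net rates but drives the 6–2 Ma slowdown with extinction;
#: the no-present-recovery variant keeps the elevated extinction rate running
#: to the present (isolating the pull of the present); high-ne repeats
#: experiment1 with a tenfold larger effective population size.
EXPERIMENT_PRESETS: dict[str, tuple[RateSchedule, MSCConfig]] = {
    "experiment1": (_EXP1_SCHEDULE, MSCConfig()),
    "experiment2": (
        RateSchedule((6.0, 2.0), (0.75, 0.75, 0.75), (0.0, 0.675, 0.0)),
        MSCConfig(),
    ),
    "experiment2-no-present-recovery": (
        RateSchedule((6.0, 2.0), (0.75, 0.75, 0.75), (0.0, 0.675, 0.675)),
        MSCConfig(),
    ),
    "high-ne": (_EXP1_SCHEDULE, MSCConfig(effective_population_size=50_000.0)),
}


def experiment_preset(name: str) -> tuple[RateSchedule, MSCConfig]:
    try:
        return EXPERIMENT_PRESETS[name]
    except KeyError:
        raise ValueError(
            f"unknown preset {name!r}; choose from {sorted(EXPERIMENT_PRESETS)}"
        ) from None


# ---------------------------------------------------------------------------
# Birth–death species trees
# ---------------------------------------------------------------------------


def _attempt_forward(schedule: RateSchedule, origin_age: float, rng,
                     lineage_cap: int, reject_above: int | None):
    """One unconditioned forward pass; returns lineage records or None.

    Records are parallel lists (parent index, start age, end age, kind).
    Event times come from interval-wise thinning of an exponential clock,
    which is exact for piecewise-constant rates.  ``reject_above`` aborts as
    soon as the lineage count exceeds the target when no future extinction
    can reduce it (pure-birth schedules only).
    """
    parent = [-1]
    start = [origin_age]
    end = [math.nan]
    kind = [""]
    active = [0]
    age = origin_age
    pure_birth = schedule.pure_birth
    while active and age > 0.0:
        n = len(active)
        lam, mu = schedule.rate_at(age)
        next_bp = schedule.next_breakpoint_below(age)
        total = n * (lam + mu)
        if total <= 0.0:
            if next_bp <= 0.0:
                break
            age = next_bp
            continue
        wait = rng.exponential(1.0 / total)
        if age - wait <= next_bp:
            age = next_bp
            if age <= 0.0:
                break
            continue
        age -= wait
        j = int(rng.integers(n))
        i = active[j]
        active[j] = active[-1]
        active.pop()
        end[i] = age
        if rng.random() < lam / (lam + mu):
            kind[i] = "spec"
            for _ in range(2):
                parent.append(i)
                start.append(age)
                end.append(math.nan)
                kind.append("")
                active.append(len(parent) - 1)
            if len(active) > lineage_cap:
                return None
            if pure_birth and reject_above is not None and len(active) > reject_above:
                return None
        else:
            kind[i] = "ext"
    for i in active:
        end[i] = 0.0
        kind[i] = "tip"
    return parent, start, end, kind


def _records_to_dated(records, tip_age_tolerance: float) -> DatedTree:
    parent, start, end, kinds = records
    nodes: list[Node] = []
    tip_counter = 0
    for idx in range(len(parent)):
        if kinds[idx] == "spec":
            nodes.append(Node())
        else:
            tip_counter += 1
            nodes.append(Node(label=f"t{tip_counter}"))
    for idx in range(1, len(parent)):
        nodes[parent[idx]].add_child(nodes[idx])
        nodes[idx].length = start[idx] - end[idx]
    root = nodes[0]
    root.length = None
    ages = {id(nodes[i]): end[i] for i in range(len(nodes))}
    return DatedTree(Tree(root), ages, tip_age_tolerance)


def simulate_bd_forward(schedule: RateSchedule, origin_age: float,
                        seed=None, lineage_cap: int = 100_000) -> DatedTree | None:
    """One unconditioned forward birth–death replicate from a single origin
    lineage; returns ``None`` if the process dies or never branches.

    Useful for expectation checks that conditioning on a tip count would
    bias."""
    rng = np.random.default_rng(seed)
    rec = _attempt_forward(schedule, origin_age, rng, lineage_cap, None)
    if rec is None or rec[3][0] != "spec":
        return None
    return _records_to_dated(rec, 1e-9)


def simulate_bd_tree(schedule: RateSchedule, n_extant: int,
                     origin_age: float = DEFAULT_ORIGIN_AGE,
                     retain_extinct: bool = True, seed=None,
                     max_rejections: int = 2_000_000,
                     lineage_cap: int | None = None) -> DatedTree:
    """Simulate an episodic birth–death species tree with exactly
    ``n_extant`` surviving tips.

    The process starts from one lineage at ``origin_age`` and runs forward in
    time; whole replicates are rejected until exactly ``n_extant`` lineages
    survive to the present.  The returned tree is rooted at the first
    speciation event (the origin stem is dropped).  With
    ``retain_extinct=True`` the complete tree (extinct tips included) is
    returned, otherwise the reconstructed extant-only tree.
    """
    if n_extant < 2:
        raise ValueError("n_extant must be at least 2")
    if origin_age <= 0:
        raise ValueError("origin_age must be positive")
    rng = np.random.default_rng(seed)
    cap = lineage_cap if lineage_cap is not None else max(50 * n_extant, 1_000)
    for _ in range(max_rejections):
        rec = _attempt_forward(schedule, origin_age, rng, cap, n_extant)
        if rec is None:
            continue
        parent, start, end, kinds = rec
        extant = sum(1 for k, e in zip(kinds, end) if k == "tip")
        if extant != n_extant or kinds[0] != "spec":
            continue
        dated = _records_to_dated(rec, 1e-9)
        if retain_extinct:
            return dated
        return prune_extinct(dated)
    raise TreeError(
        f"no replicate with exactly {n_extant} extant tips after "
        f"{max_rejections} attempts; the schedule may make the target "
        "practically unreachable (e.g. extinction dominating speciation)")


def simulate_yule_tree(n_tips: int, birth_rate: float, seed=None) -> DatedTree:
    """A reconstructed pure-birth (Yule) tree with exactly ``n_tips`` tips.

    The process runs forward from the crown (two lineages) until the tip
    count reaches ``n_tips``; the present is placed after a further censored
    Exp(n*lambda) wait so no branch has zero length.  Branching waits with
    ``k`` lineages are Exp(k*lambda), i.e. the exact Yule law.
    """
    if n_tips < 2:
        raise ValueError("need at least 2 tips")
    if birth_rate <= 0:
        raise ValueError("birth rate must be positive")
    rng = np.random.default_rng(seed)
    root = Node()
    split_time = {id(root): 0.0}
    active = [root.add_child(Node()), root.add_child(Node())]
    t = 0.0
    k = 2
    while k < n_tips:
        t += rng.exponential(1.0 / (birth_rate * k))
        j = int(rng.integers(k))
        node = active[j]
        active[j] = active[-1]
        active.pop()
        split_time[id(node)] = t
        active.append(node.add_child(Node()))
        active.append(node.add_child(Node()))
        k += 1
    present = t + rng.exponential(1.0 / (birth_rate * n_tips))
    tree = Tree(root, validate=False)
    ages: dict[int, float] = {}
    tip_counter = 0
    for node in tree.preorder():
        if node.is_leaf:
            tip_counter += 1
            node.label = f"t{tip_counter}"
            ages[id(node)] = 0.0
        else:
            ages[id(node)] = present - split_time[id(node)]
    for node in tree.preorder():
        if node.parent is not None:
            node.length = ages[id(node.parent)] - ages[id(node)]
    tree.validate()
    return DatedTree(tree, ages)


def tree_from_branching_ages(ages_desc, labels=None) -> DatedTree:
    """Build an ultrametric comb (caterpillar) tree with the given internal
    node ages, oldest first.  Handy for likelihood oracles where only the
    branching ages matter."""
    ages_desc = [float(a) for a in ages_desc]
    if len(ages_desc) < 1:
        raise ValueError("need at least one branching age")
    if list(ages_desc) != sorted(ages_desc, reverse=True):
        raise ValueError("ages must be in descending order")
    if ages_desc[-1] <= 0:
        raise ValueError("branching ages must be positive")
    n_tips = len(ages_desc) + 1
    if labels is None:
        labels = [f"t{i + 1}" for i in range(n_tips)]
    root = Node()
    cur = root
    for i, age in enumerate(ages_desc):
        if i > 0:
            nxt = Node(length=ages_desc[i - 1] - age)
            cur.add_child(nxt)
            cur = nxt
        cur.add_child(Node(label=labels[i], length=age))
    cur.add_child(Node(label=labels[-1], length=ages_desc[-1]))
    return compute_node_ages(Tree(root))


# ---------------------------------------------------------------------------
# Pruning
# ---------------------------------------------------------------------------


def prune_to_tips(dated: DatedTree, labels) -> DatedTree:
    """Reconstructed view: keep only the given tips, suppressing the
    degree-2 nodes left behind (branch lengths are summed via node ages)."""
    keep = set(labels)
    have = set(dated.tree.tip_labels())
    missing = keep - have
    if missing:
        raise TreeError(f"labels not in tree: {sorted(missing)}")
    if len(keep) < 2:
        raise TreeError("pruning must retain at least two tips")
    ages: dict[int, float] = {}

    def rec(node: Node) -> Node | None:
        if node.is_leaf:
            if node.label not in keep:
                return None
            clone = Node(label=node.label)
            ages[id(clone)] = dated.age(node)
            return clone
        kids = [k for k in (rec(c) for c in node.children) if k is not None]
        if not kids:
            return None
        if len(kids) == 1:
            return kids[0]
        clone = Node(label=node.label, support=node.support)
        ages[id(clone)] = dated.age(node)
        for k in kids:
            clone.add_child(k)
        return clone

    new_root = rec(dated.tree.root)
    if new_root is None or new_root.is_leaf:
        raise TreeError("pruning left no internal structure")
    for node in Tree(new_root, validate=False).preorder():
        if node.parent is not None:
            node.length = ages[id(node.parent)] - ages[id(node)]
    return DatedTree(Tree(new_root), ages, dated.tip_age_tolerance)


def prune_extinct(dated: DatedTree) -> DatedTree:
    """Drop extinct tips, returning the reconstructed (ultrametric) tree."""
    extant = [t.label for t in dated.extant_tips()]
    if not extant:
        raise TreeError("all tips are extinct; nothing to reconstruct")
    if len(extant) == dated.tree.n_tips:
        return dated.copy()
    return prune_to_tips(dated, extant)


# ---------------------------------------------------------------------------
# Multispecies coalescent
# ---------------------------------------------------------------------------


def _simulate_one_gene(species: DatedTree, pair_rate: float, rng) -> Tree:
    ages: dict[int, float] = {}
    surviving: dict[int, list[Node]] = {}
    root_id = id(species.tree.root)
    for snode in species.tree.postorder():
        if snode.is_leaf:
            tip = Node(label=snode.label)
            ages[id(tip)] = species.age(snode)
            lineages = [tip]
        else:
            lineages = []
            for child in snode.children:
                lineages.extend(surviving[id(child)])
        top = math.inf if snode.parent is None else species.age(snode.parent)
        a = species.age(snode)
        k = len(lineages)
        while k > 1:
            wait = rng.exponential(1.0 / (pair_rate * k * (k - 1) / 2.0))
            if a + wait >= top:
                break
            a += wait
            i = int(rng.integers(k))
            j = int(rng.integers(k - 1))
            if j >= i:
                j += 1
            anc = Node()
            ages[id(anc)] = a
            for child in (lineages[i], lineages[j]):
                anc.add_child(child)
                child.length = a - ages[id(child)]
            lineages = [l for idx, l in enumerate(lineages) if idx not in (i, j)]
            lineages.append(anc)
            k -= 1
        surviving[id(snode)] = lineages
    (root,) = surviving[root_id]
    root.length = None
    return Tree(root)


def simulate_msc_gene_trees(species_tree: DatedTree, config: MSCConfig) -> list[Tree]:
    """Simulate gene trees inside an ultrametric species tree under the
    censored multispecies coalescent.

    One haploid sample per species; within each species-tree branch, lineage
    pairs coalesce at rate ``g / (2 Ne)`` per Myr, lineages remaining at a
    parent node merge with the sibling population, and lineages surviving
    above the root coalesce freely.  Gene trees carry branch lengths in Myr
    and the species-tree tip labels.
    """
    if not species_tree.is_ultrametric():
        raise TreeError("species tree must be ultrametric (extant tips only)")
    rng = np.random.default_rng(config.seed)
    rate = config.pair_coalescence_rate
    return [_simulate_one_gene(species_tree, rate, rng)
            for _ in range(config.n_genes)]


# ---------------------------------------------------------------------------
# Taxonomy generator
# ---------------------------------------------------------------------------


class TaxonomyTable:
    """Checklist-style diversity table: one row per checklist species.

    Columns: ``tip`` (tree tip label for sampled species, a placeholder name
    otherwise), ``genus``, ``family``, ``sampled`` (bool),
    ``genus_species_count`` (checklist species per genus) and
    ``family_genus_count`` (checklist genera per family).
    """

    COLUMNS = ["tip", "genus", "family", "sampled",
               "genus_species_count", "family_genus_count"]

    def __init__(self, frame: pd.DataFrame):
        missing = [c for c in self.COLUMNS if c not in frame.columns]
        if missing:
            raise ValueError(f"taxonomy table missing columns: {missing}")
        self.frame = frame.reset_index(drop=True)
        self._validate()

    def _validate(self) -> None:
        bad = self.frame.groupby("genus")["family"].nunique()
        if (bad > 1).any():
            raise ValueError("a genus maps to more than one family")
        counts = self.frame.groupby("genus").agg(
            declared=("genus_species_count", "first"),
            rows=("tip", "size"),
            sampled=("sampled", "sum"),
        )
        if (counts["declared"] < counts["sampled"]).any():
            raise ValueError("checklist species count below sampled tip count")

    # -- lookups -----------------------------------------------------------

    def genera(self) -> list[str]:
        return sorted(self.frame["genus"].unique())

    def families(self) -> list[str]:
        return sorted(self.frame["family"].unique())

    def family_of(self, genus: str) -> str:
        return self.frame.loc[self.frame["genus"] == genus, "family"].iloc[0]

    def species_count(self, genus: str) -> int:
        return int(self.frame.loc[self.frame["genus"] == genus,
                                  "genus_species_count"].iloc[0])

    def sampled_tips(self, genus: str | None = None) -> list[str]:
        sel = self.frame["sampled"]
        if genus is not None:
            sel = sel & (self.frame["genus"] == genus)
        return sorted(self.frame.loc[sel, "tip"])

    def is_genus_sampled(self, genus: str) -> bool:
        return bool(self.frame.loc[self.frame["genus"] == genus, "sampled"].any())

    def genera_of_family(self, family: str) -> list[str]:
        return sorted(self.frame.loc[self.frame["family"] == family, "genus"].unique())

    @property
    def total_species(self) -> int:
        return int(self.frame.groupby("genus")["genus_species_count"].first().sum())

    # -- I/O ---------------------------------------------------------------

    def to_tsv(self, path) -> None:
        self.frame.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "TaxonomyTable":
        frame = pd.read_csv(path, sep="\t")
        frame["sampled"] = frame["sampled"].astype(bool)
        return cls(frame)


class TaxonomySample(NamedTuple):
    """Genus-sampled tree, its checklist table, and the retained complete
    ground-truth tree."""

    tree: DatedTree
    taxonomy: TaxonomyTable
    complete_tree: DatedTree


def _draw_count(spec, rng) -> int:
    if isinstance(spec, int):
        value = spec
    elif callable(spec):
        value = int(spec(rng))
    else:
        name, param = spec
        if name == "geometric":
            value = int(rng.geometric(param))
        elif name == "poisson":
            value = 1 + int(rng.poisson(param))
        else:
            raise ValueError(f"unknown distribution spec {spec!r}")
    if value < 1:
        raise ValueError("counts must be positive")
    return value


def _truncated_exp_ages(k: int, max_age: float, rate: float, rng) -> list[float]:
    """``k`` i.i.d. ages on (0, max_age) with density ∝ rate·e^{-rate·a}
    (uniform in the rate → 0 limit): the speciation-age law of a pure-birth
    clade conditioned on its extant tip count."""
    u = rng.random(k)
    if rate * max_age < 1e-9:
        ages = u * max_age
    else:
        ages = -np.log(1.0 - u * (1.0 - math.exp(-rate * max_age))) / rate
    return list(ages)


def _conditioned_clade(n: int, rng, ages: dict[int, float],
                       origin_age: float | None = None,
                       crown_age: float | None = None) -> Node:
    """Reconstructed pure-birth clade with exactly ``n`` extant tips.

    Either the stem ``origin_age`` is given (the crown age is drawn from the
    conditioned process with growth rate ln(n)/origin) or the ``crown_age``
    is fixed (interior ages drawn with rate ln(n/2)/crown).  Branching ages
    are i.i.d. truncated-exponential and each new lineage attaches uniformly
    among the lineages already present — the standard conditioned-Yule
    construction."""
    if n == 1:
        tip = Node()
        ages[id(tip)] = 0.0
        return tip
    if crown_age is None:
        rate = math.log(n) / origin_age
        events = sorted(_truncated_exp_ages(n - 1, origin_age, rate, rng),
                        reverse=True)
        crown = events[0]
        rest = events[1:]
    else:
        crown = crown_age
        if n > 2:
            rate = math.log(n / 2.0) / crown
            rest = sorted(_truncated_exp_ages(n - 2, crown, rate, rng),
                          reverse=True)
        else:
            rest = []
    root = Node()
    ages[id(root)] = crown
    lineages = [root.add_child(Node()), root.add_child(Node())]
    for tip in lineages:
        ages[id(tip)] = 0.0
    for a in rest:
        j = int(rng.integers(len(lineages)))
        x = lineages[j]
        parent = x.parent
        inner = Node()
        ages[id(inner)] = a
        parent.children[parent.children.index(x)] = inner
        inner.parent = parent
        inner.add_child(x)
        y = Node()
        ages[id(y)] = 0.0
        inner.add_child(y)
        lineages.append(y)
    return root


def generate_taxonomy(n_families: int = 10,
                      genera_per_family=("geometric", 0.12),
                      species_per_genus=("geometric", 0.08),
                      genus_sampling_prob: float = 0.6,
                      species_per_sampled_genus: int = 1,
                      seed=None,
                      root_age: float = 100.0) -> TaxonomySample:
    """Simulate a complete species-level tree with monophyletic families and
    genera, then sample genera and representative tips to emulate a
    genus-level checklist-calibrated phylogeny.

    The tree is built hierarchically — a family skeleton with its crown
    fixed at ``root_age``, genus clades grown from family stems, species
    clades from genus stems, each level a reconstructed pure-birth clade
    conditioned on its tip count — which makes every genus and family
    monophyletic by construction.  The default distributions are scaled to
    checklist-like shape: right-skewed genus counts (mean ≈ 8 genera per
    family) and species counts (mean ≈ 12 species per genus), so most
    unsampled diversity is nested inside well-sampled families rather than
    subtending them.  Each genus is sampled with probability
    ``genus_sampling_prob``; in every family at least ``min(2, n_genera)``
    genera are force-sampled so each family retains a crown group in the
    sampled tree, mirroring a complete family-level backbone.
    ``species_per_sampled_genus`` representative tips are kept per sampled
    genus (default one, the genus-level pruning convention).
    """
    if not 0.0 <= genus_sampling_prob <= 1.0:
        raise ValueError("genus_sampling_prob must be in [0, 1]")
    if species_per_sampled_genus < 1:
        raise ValueError("species_per_sampled_genus must be >= 1")
    if n_families < 1:
        raise ValueError("need at least one family")
    rng = np.random.default_rng(seed)

    fam_names = [f"fam{f + 1:02d}" for f in range(n_families)]
    genus_names: dict[str, list[str]] = {}
    species_counts: dict[str, int] = {}
    for f, fam in enumerate(fam_names):
        n_gen = _draw_count(genera_per_family, rng)
        genus_names[fam] = [f"g{f + 1:02d}_{g + 1:02d}" for g in range(n_gen)]
        for genus in genus_names[fam]:
            species_counts[genus] = _draw_count(species_per_genus, rng)

    ages: dict[int, float] = {}

    def expand(tip_node: Node | None, sub_n: int,
               crown_age: float | None = None) -> Node:
        """Replace ``tip_node`` with a conditioned clade of ``sub_n`` tips
        originating at the tip's stem (its parent's age), or build a free
        clade with a fixed crown age."""
        if crown_age is not None:
            clade = _conditioned_clade(sub_n, rng, ages, crown_age=crown_age)
        elif sub_n == 1:
            ages[id(tip_node)] = 0.0
            return tip_node
        else:
            stem = ages[id(tip_node.parent)]
            clade = _conditioned_clade(sub_n, rng, ages, origin_age=stem)
        if tip_node is not None and tip_node.parent is not None:
            parent = tip_node.parent
            parent.children[parent.children.index(tip_node)] = clade
            clade.parent = parent
        return clade

    def clade_leaves(node: Node) -> list[Node]:
        return [n for n in Tree(node, validate=False).preorder() if n.is_leaf]

    # family skeleton (crown pinned at root_age)
    genus_leaf: dict[str, Node] = {}
    if n_families >= 2:
        root = _conditioned_clade(n_families, rng, ages, crown_age=root_age)
        for fam, leaf in zip(fam_names, clade_leaves(root)):
            genera = genus_names[fam]
            if len(genera) == 1:
                genus_leaf[genera[0]] = leaf
            else:
                clade = expand(leaf, len(genera))
                for genus, gleaf in zip(genera, clade_leaves(clade)):
                    genus_leaf[genus] = gleaf
    else:
        # single family: its genus-level clade is the whole tree
        genera = genus_names[fam_names[0]]
        if len(genera) == 1:
            genus_leaf[genera[0]] = None  # species clade becomes the tree
            root = None
        else:
            root = _conditioned_clade(len(genera), rng, ages,
                                      crown_age=root_age)
            for genus, gleaf in zip(genera, clade_leaves(root)):
                genus_leaf[genus] = gleaf

    species_tips: dict[str, list[Node]] = {}
    for fam in fam_names:
        for genus in genus_names[fam]:
            gleaf = genus_leaf[genus]
            count = species_counts[genus]
            if gleaf is None:  # sole genus of a sole family
                if count < 2:
                    raise TreeError("a one-family, one-genus, one-species "
                                    "taxonomy has no tree to build")
                clade = _conditioned_clade(count, rng, ages,
                                           crown_age=root_age)
                root = clade
            else:
                clade = expand(gleaf, count)
            tips = clade_leaves(clade) if not clade.is_leaf else [clade]
            for s, tip in enumerate(tips):
                tip.label = f"{genus}_sp{s + 1:03d}"
            species_tips[genus] = tips

    if root is None or root.is_leaf:
        raise TreeError("degenerate taxonomy: the complete tree has <2 tips")
    for node in Tree(root, validate=False).preorder():
        node.length = None if node.parent is None else \
            ages[id(node.parent)] - ages[id(node)]
    complete = DatedTree(Tree(root), ages)

    # genus sampling with a forced family backbone
    sampled_genera: set[str] = set()
    for fam in fam_names:
        genera = genus_names[fam]
        n_forced = min(2, len(genera))
        forced = rng.choice(len(genera), size=n_forced, replace=False)
        for gi, genus in enumerate(genera):
            if gi in forced or rng.random() < genus_sampling_prob:
                sampled_genera.add(genus)

    sampled_tip_labels: set[str] = set()
    for genus in sorted(sampled_genera):
        tips = species_tips[genus]
        n_keep = min(species_per_sampled_genus, len(tips))
        chosen = rng.choice(len(tips), size=n_keep, replace=False)
        sampled_tip_labels.update(tips[int(i)].label for i in chosen)

    if len(sampled_tip_labels) < 2:
        raise TreeError("sampling produced fewer than two tips")
    sampled_tree = prune_to_tips(complete, sampled_tip_labels)

    rows = []
    for f, fam in enumerate(fam_names):
        for genus in genus_names[fam]:
            for tip in species_tips[genus]:
                rows.append({
                    "tip": tip.label,
                    "genus": genus,
                    "family": fam,
                    "sampled": tip.label in sampled_tip_labels,
                    "genus_species_count": species_counts[genus],
                    "family_genus_count": len(genus_names[fam]),
                })
    taxonomy = TaxonomyTable(pd.DataFrame(rows, columns=TaxonomyTable.COLUMNS))
    return TaxonomySample(sampled_tree, taxonomy, complete)
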
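"""Rooted-tree data model, Newick I/O, node ages, bipartitions and time slices.

Conventions used throughout the package:

* Ages are measured backwards from the present in Myr (0 = present; the root
  carries the maximum age).
* Branch spans and time slices follow the half-open convention
  ``[younger, older)``: a branch whose child node sits exactly on a slice's
  older bound does not cross that slice, so adjacent slices never double
  count a branch endpoint.
* Tips whose age is within ``tip_age_tolerance`` of the present are extant;
  everything else is extinct.  Non-ultrametric trees are valid inputs.
"""

from __future__ import annotations

import gzip
import io
import math
from dataclasses import dataclass
from typing import Iterable, Iterator, Sequence

import dendropy

__all__ = [
    "TreeError",
    "NewickParseError",
    "Node",
    "Tree",
    "DatedTree",
    "Bipartition",
    "UNINFORMATIVE",
    "TimeSlice",
    "DEFAULT_TIP_AGE_TOLERANCE",
    "parse_newick",
    "serialize_newick",
    "read_trees",
    "write_trees",
    "compute_node_ages",
    "tree_bipartitions",
    "branch_bipartitions",
    "induced_bipartition",
    "branches_crossing_slice",
    "mrca",
]

DEFAULT_TIP_AGE_TOLERANCE = 1e-6


class TreeError(ValueError):
    """Invalid tree structure or tree operation."""


class NewickParseError(TreeError):
    """Malformed Newick input; ``offset`` is the character position."""

    def __init__(self, message: str, offset: int | None = None):
        if offset is not None:
            message = f"{message} (at character offset {offset})"
        super().__init__(message)
        self.offset = offset


class Node:
    """One node of a rooted tree.

    ``length`` is the length of the branch subtending the node (``None`` for
    the root), ``support`` an optional numeric support value on internal
    nodes, preserved but never interpreted.
    """

    __slots__ = ("label", "length", "support", "children", "parent")

    def __init__(self, label=None, length=None, support=None, children=None):
        self.label = label
        self.length = length
        self.support = support
        self.children: list[Node] = []
        self.parent: Node | None = None
        if children:
            for child in children:
                self.add_child(child)

    def add_child(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    def remove_child(self, child: "Node") -> None:
        self.children.remove(child)
        child.parent = None

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def __repr__(self):  # pragma: no cover - debugging aid
        kind = "leaf" if self.is_leaf else f"internal({len(self.children)})"
        return f"<Node {self.label!r} {kind}>"


class Tree:
    """A rooted tree with branch lengths and unique tip labels."""

    def __init__(self, root: Node, validate: bool = True):
        self.root = root
        if validate:
            self.validate()

    # -- traversal ---------------------------------------------------------

    def preorder(self) -> Iterator[Node]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def postorder(self) -> Iterator[Node]:
        out: list[Node] = []
        stack = [self.root]
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(node.children)
        return iter(reversed(out))

    def leaves(self) -> list[Node]:
        return [n for n in self.preorder() if n.is_leaf]

    def internal_nodes(self) -> list[Node]:
        return [n for n in self.preorder() if not n.is_leaf]

    @property
    def n_tips(self) -> int:
        return len(self.leaves())

    def tip_labels(self) -> list[str]:
        return [n.label for n in self.leaves()]

    def taxon_set(self) -> frozenset[str]:
        return frozenset(self.tip_labels())

    # -- structure ---------------------------------------------------------

    def validate(self) -> None:
        seen: set[int] = set()
        labels: set[str] = set()
        for node in self.preorder():
            if id(node) in seen:
                raise TreeError("cycle detected: node reachable twice")
            seen.add(id(node))
            for child in node.children:
                if child.parent is not node:
                    raise TreeError("inconsistent parent link")
                if child.length is not None and child.length < 0:
                    raise TreeError(f"negative branch length {child.length}")
            if node.is_leaf:
                if not node.label:
                    raise TreeError("leaf without a tip label")
                if node.label in labels:
                    raise TreeError(f"duplicate tip label {node.label!r}")
                labels.add(node.label)
        if self.root.parent is not None:
            raise TreeError("root must not have a parent")

    def copy(self) -> "Tree":
        mapping: dict[int, Node] = {}
        for node in self.postorder():
            clone = Node(node.label, node.length, node.support)
            for child in node.children:
                clone.add_child(mapping[id(child)])
            mapping[id(node)] = clone
        return Tree(mapping[id(self.root)], validate=False)

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"<Tree with {self.n_tips} tips>"


# ---------------------------------------------------------------------------
# Newick I/O
# ---------------------------------------------------------------------------


def _prescan_newick(text: str) -> None:
    """Cheap structural scan so parse errors can name a character offset."""
    depth = 0
    in_quote = False
    semicolon = None
    for i, ch in enumerate(text):
        if ch == "'":
            in_quote = not in_quote
            continue
        if in_quote:
            continue
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth -= 1
            if depth < 0:
                raise NewickParseError("unbalanced ')'", offset=i)
        elif ch == ";":
            semicolon = i
            if depth != 0:
                raise NewickParseError("unbalanced '(' before ';'", offset=i)
            break
    if in_quote:
        raise NewickParseError("unterminated quoted label", offset=len(text))
    if semicolon is None:
        if depth != 0:
            raise NewickParseError("unbalanced '('", offset=len(text))
        raise NewickParseError("missing terminating ';'", offset=len(text))


def _from_dendropy(dnode: "dendropy.Node") -> Node:
    if dnode.is_leaf():
        label = dnode.taxon.label if dnode.taxon is not None else dnode.label
        node = Node(label=label, length=dnode.edge.length)
    else:
        support = None
        label = None
        raw = dnode.label
        if raw is not None:
            try:
                support = float(raw)
            except (TypeError, ValueError):
                label = raw
        node = Node(label=label, length=dnode.edge.length, support=support)
        for dchild in dnode.child_nodes():
            node.add_child(_from_dendropy(dchild))
    return node


def parse_newick(text: str) -> Tree:
    """Parse a single rooted Newick statement into a :class:`Tree`.

    Internal-node labels that parse as numbers are stored as support values;
    other internal labels are kept as node labels.  Malformed input raises
    :class:`NewickParseError` naming the character offset where the scan
    failed; duplicate tip labels raise as well.
    """
    stripped = text.strip()
    if not stripped:
        raise NewickParseError("empty input", offset=0)
    _prescan_newick(stripped)
    try:
        dtree = dendropy.Tree.get(
            data=stripped,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several error classes
        raise NewickParseError(f"newick parse failed: {exc}", offset=0) from exc
    root = _from_dendropy(dtree.seed_node)
    root.length = None
    return Tree(root)


def _format_length(value: float, precision: int) -> str:
    s = f"{value:.{precision}f}"
    if "." in s:
        s = s.rstrip("0").rstrip(".")
    return s or "0"


def _min_tip(node: Node, cache: dict[int, str]) -> str:
    key = id(node)
    if key not in cache:
        if node.is_leaf:
            cache[key] = node.label
        else:
            cache[key] = min(_min_tip(c, cache) for c in node.children)
    return cache[key]


def serialize_newick(tree: Tree, precision: int = 10) -> str:
    """Serialize with canonical child ordering.

    Children are ordered lexicographically by their smallest descendant tip
    label, so topologically equal trees serialize to identical strings.  The
    default precision (10 decimal places; trailing zeros are stripped) keeps
    round-tripped ultrametric trees within the extant-tip age tolerance even
    on deep paths.
    """
    cache: dict[int, str] = {}

    def render(node: Node) -> str:
        if node.is_leaf:
            out = node.label
        else:
            kids = sorted(node.children, key=lambda c: _min_tip(c, cache))
            out = "(" + ",".join(render(c) for c in kids) + ")"
            if node.support is not None:
                out += _format_length(node.support, precision)
            elif node.label:
                out += node.label
        if node.length is not None:
            out += ":" + _format_length(node.length, precision)
        return out

    return render(tree.root) + ";"


def _open_text(path, mode: str):
    path = str(path)
    if path.endswith(".gz"):
        return io.TextIOWrapper(gzip.open(path, mode + "b"))
    return open(path, mode + "t" if mode in ("r", "w") else mode)


def read_trees(path) -> list[Tree]:
    """Read one Newick statement per line (plain or gzip-compressed)."""
    trees = []
    with _open_text(path, "r") as fh:
        for line in fh:
            line = line.strip()
            if line:
                trees.append(parse_newick(line))
    return trees


def write_trees(trees: Iterable[Tree], path, precision: int = 10) -> None:
    with _open_text(path, "w") as fh:
        for tree in trees:
            fh.write(serialize_newick(tree, precision=precision) + "\n")


# ---------------------------------------------------------------------------
# Node ages
# ---------------------------------------------------------------------------


class DatedTree:
    """A tree with per-node ages (Ma before present) and extant flags.

    ``ages`` maps every node to its age; the root age is the maximum
    root-to-tip path length.  Tips with age at most ``tip_age_tolerance``
    are extant.
    """

    def __init__(self, tree: Tree, ages: dict[int, float],
                 tip_age_tolerance: float = DEFAULT_TIP_AGE_TOLERANCE):
        self.tree = tree
        self._ages = ages
        self.tip_age_tolerance = tip_age_tolerance
        self.root_age = ages[id(tree.root)]
        if not self.root_age > 0:
            raise TreeError("root age must be positive")

    def age(self, node: Node) -> float:
        return self._ages[id(node)]

    def set_age(self, node: Node, age: float) -> None:
        self._ages[id(node)] = age

    def is_extant(self, tip: Node) -> bool:
        return self.age(tip) <= self.tip_age_tolerance

    def extant_tips(self) -> list[Node]:
        return [t for t in self.tree.leaves() if self.is_extant(t)]

    def extinct_tips(self) -> list[Node]:
        return [t for t in self.tree.leaves() if not self.is_extant(t)]

    def is_ultrametric(self) -> bool:
        return not self.extinct_tips()

    def branches(self) -> Iterator[tuple[Node, float, float]]:
        """Yield (child_node, child_age, parent_age) for every non-root node."""
        for node in self.tree.preorder():
            if node.parent is not None:
                yield node, self.age(node), self.age(node.parent)

    def internal_ages(self, exclude_root: bool = False) -> list[float]:
        nodes = self.tree.internal_nodes()
        if exclude_root:
            nodes = [n for n in nodes if n is not self.tree.root]
        return [self.age(n) for n in nodes]

    def copy(self) -> "DatedTree":
        new_tree = self.tree.copy()
        pairs = zip(self.tree.preorder(), new_tree.preorder())
        ages = {id(new): self.age(old) for old, new in pairs}
        return DatedTree(new_tree, ages, self.tip_age_tolerance)


def compute_node_ages(tree: Tree,
                      tip_age_tolerance: float = DEFAULT_TIP_AGE_TOLERANCE
                      ) -> DatedTree:
    """Date a tree from its branch lengths.

    The age of a node is the maximum root-to-tip path length minus the
    root-to-node path length; tips older than ``tip_age_tolerance`` are
    flagged extinct (non-ultrametric trees are valid inputs).
    """
    depth: dict[int, float] = {id(tree.root): 0.0}
    for node in tree.preorder():
        for child in node.children:
            if child.length is None:
                raise TreeError("non-root node without a branch length")
            depth[id(child)] = depth[id(node)] + child.length
    height = max(depth[id(leaf)] for leaf in tree.leaves())
    ages = {key: height - d for key, d in depth.items()}
    return DatedTree(tree, ages, tip_age_tolerance)


# ---------------------------------------------------------------------------
# Bipartitions
# ---------------------------------------------------------------------------


class _Uninformative:
    """Sentinel for induced splits with fewer than two labels on a side."""

    def __repr__(self):
        return "UNINFORMATIVE"

    def __bool__(self):
        return False


UNINFORMATIVE = _Uninformative()


class Bipartition:
    """Unordered split of a reference taxon set into two disjoint sides."""

    __slots__ = ("side_a", "side_b", "_key")

    def __init__(self, side_a: Iterable[str], side_b: Iterable[str]):
        a = frozenset(side_a)
        b = frozenset(side_b)
        if not a or not b:
            raise TreeError("bipartition sides must be non-empty")
        if a & b:
            raise TreeError("bipartition sides must be disjoint")
        self.side_a = a
        self.side_b = b
        self._key = frozenset((a, b))

    @property
    def taxa(self) -> frozenset[str]:
        return self.side_a | self.side_b

    @property
    def key(self) -> frozenset[frozenset[str]]:
        """Order-free identity of the split, usable as a set/dict key."""
        return self._key

    @property
    def is_informative(self) -> bool:
        return len(self.side_a) >= 2 and len(self.side_b) >= 2

    def __eq__(self, other):
        return isinstance(other, Bipartition) and self._key == other._key

    def __hash__(self):
        return hash(self._key)

    def __repr__(self):  # pragma: no cover - debugging aid
        a = ",".join(sorted(self.side_a))
        b = ",".join(sorted(self.side_b))
        return f"Bipartition({a} | {b})"


def branch_bipartitions(tree: Tree) -> dict[Node, Bipartition]:
    """Map each internal non-root branch to its informative bipartition.

    The branch is identified by its child node.  The root edge and trivial
    splits (a singleton side) are excluded, so a star tree yields an empty
    mapping.
    """
    taxa = tree.taxon_set()
    clade: dict[int, frozenset[str]] = {}
    for node in tree.postorder():
        if node.is_leaf:
            clade[id(node)] = frozenset((node.label,))
        else:
            clade[id(node)] = frozenset().union(
                *(clade[id(c)] for c in node.children))
    result: dict[Node, Bipartition] = {}
    for node in tree.preorder():
        if node.parent is None or node.is_leaf:
            continue
        side = clade[id(node)]
        other = taxa - side
        if len(side) >= 2 and len(other) >= 2:
            result[node] = Bipartition(side, other)
    return result


def tree_bipartitions(tree: Tree) -> set[Bipartition]:
    """The set of informative bipartitions displayed by a tree."""
    return set(branch_bipartitions(tree).values())


def induced_bipartition(bip: Bipartition, taxa: Iterable[str]):
    """Restrict a bipartition to a taxon subset.

    Returns :data:`UNINFORMATIVE` when either restricted side has fewer than
    two labels; raises :class:`TreeError` if ``taxa`` is not a subset of the
    bipartition's reference taxon set.
    """
    taxa = frozenset(taxa)
    if not taxa <= bip.taxa:
        extra = sorted(taxa - bip.taxa)
        raise TreeError(f"taxa not in the reference set: {extra}")
    a = bip.side_a & taxa
    b = bip.side_b & taxa
    if len(a) < 2 or len(b) < 2:
        return UNINFORMATIVE
    return Bipartition(a, b)


# ---------------------------------------------------------------------------
# Time slices
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TimeSlice:
    """Half-open age interval [younger_bound, older_bound), in Ma."""

    older_bound: float
    younger_bound: float

    def __post_init__(self):
        if not self.older_bound > self.younger_bound >= 0:
            raise TreeError(
                f"invalid time slice [{self.older_bound}, {self.younger_bound})")

    @property
    def width(self) -> float:
        return self.older_bound - self.younger_bound

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.older_bound + self.younger_bound)


def branches_crossing_slice(tree: DatedTree, sl: TimeSlice) -> list[Node]:
    """Branches whose age span [child, parent) overlaps the slice.

    Overlap of two half-open intervals is non-empty iff
    ``child_age < older_bound`` and ``parent_age > younger_bound``; a branch
    ending exactly on the slice's older bound is therefore excluded.
    """
    out = []
    for node, child_age, parent_age in tree.branches():
        if parent_age > child_age and \
                child_age < sl.older_bound and parent_age > sl.younger_bound:
            out.append(node)
    return out


# ---------------------------------------------------------------------------
# Misc helpers shared by other modules
# ---------------------------------------------------------------------------


def mrca(tree: Tree, labels: Sequence[str]) -> Node:
    """Most recent common ancestor of a set of tip labels."""
    wanted = set(labels)
    if not wanted:
        raise TreeError("mrca of an empty label set")
    by_label = {leaf.label: leaf for leaf in tree.leaves()}
    missing = wanted - by_label.keys()
    if missing:
        raise TreeError(f"labels not in tree: {sorted(missing)}")
    paths = []
    for label in wanted:
        node = by_label[label]
        path = []
        while node is not None:
            path.append(node)
            node = node.parent
        paths.append(list(reversed(path)))
    anc = None
    for level in zip(*paths):
        first = level[0]
        if all(n is first for n in level):
            anc = first
        else:
            break
    return anc
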
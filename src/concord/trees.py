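"""Tree containers: taxon indexing, Newick I/O, splits and quadripartitions.

A concordance analysis revolves around the internal branches of a reference
tree.  Removing an internal branch x splits the taxa into the bipartition
A∪B | C∪D, where A, B are the leaf sets of the two subtrees on one endpoint
of x and C, D those on the other.  The two nearest-neighbor-interchange
alternatives of x are the branches y = A∪C | B∪D and z = A∪D | B∪C.  This
module provides the tree wrapper, the canonicalized :class:`Bipartition`,
the :class:`Quadripartition` around each internal branch, and the
virtual-root transformation used for rooted analyses.

Newick parsing and serialization are delegated to :mod:`dendropy`; all
set-level combinatorics are done on integer taxon positions from a shared
:class:`TaxonIndex`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import dendropy

from .errors import NewickParseError, PolytomyError, ValidationError

#: Reserved leaf label used by :func:`add_virtual_root`; rejected in user data.
VIRTUAL_ROOT_LABEL = "__ROOT__"


class TaxonIndex:
    """Fixed ordered mapping from taxon label to integer position.

    All trees and alignments taking part in one analysis share a single
    index so that taxon sets can be manipulated as sets of small integers.
    """

    __slots__ = ("labels", "position")

    def __init__(self, labels: Sequence[str]):
        labels = list(labels)
        if len(set(labels)) != len(labels):
            dupes = sorted({x for x in labels if labels.count(x) > 1})
            raise ValidationError(f"duplicate taxon labels: {dupes}")
        self.labels: list[str] = labels
        self.position: dict[str, int] = {lab: i for i, lab in enumerate(labels)}

    def __len__(self) -> int:
        return len(self.labels)

    def __contains__(self, label: str) -> bool:
        return label in self.position

    def __getitem__(self, label: str) -> int:
        try:
            return self.position[label]
        except KeyError:
            raise ValidationError(f"taxon {label!r} not in index") from None

    def label_of(self, pos: int) -> str:
        return self.labels[pos]

    def labels_of(self, positions: Iterable[int]) -> list[str]:
        return sorted(self.labels[p] for p in positions)

    def universe(self) -> frozenset[int]:
        return frozenset(range(len(self.labels)))

    def extended_with(self, label: str) -> "TaxonIndex":
        """Return a new index with one extra label appended at the end."""
        if label in self.position:
            raise ValidationError(f"label {label!r} already present in index")
        return TaxonIndex(self.labels + [label])

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"TaxonIndex({len(self.labels)} taxa)"


@dataclass(frozen=True)
class Bipartition:
    """A two-way split of a taxon set, canonicalized for orientation-free equality.

    ``members`` is the side of the split that does *not* contain the
    lowest-numbered taxon of ``universe``; construction enforces this, so two
    splits are equal iff they divide the same universe the same way.
    """

    members: frozenset[int]
    universe: frozenset[int]

    @staticmethod
    def of(side: Iterable[int], universe: Iterable[int]) -> "Bipartition":
        side = frozenset(side)
        universe = frozenset(universe)
        if not side or side == universe:
            raise ValidationError("a bipartition needs two nonempty sides")
        if not side <= universe:
            raise ValidationError("split side must be a subset of its universe")
        if min(universe) in side:
            side = universe - side
        return Bipartition(side, universe)

    @property
    def complement(self) -> frozenset[int]:
        return self.universe - self.members

    def is_trivial(self) -> bool:
        """True when one side has fewer than two taxa."""
        return min(len(self.members), len(self.universe) - len(self.members)) < 2


@dataclass(frozen=True)
class Quadripartition:
    """The four clades A, B, C, D surrounding an internal branch x.

    A and B hang off one endpoint of x, C and D off the other; the split of
    x is A∪B | C∪D.  Orientation is deterministic: A (resp. C) is the clade
    containing the lowest taxon position on its endpoint, which pins down
    which NNI alternative is reported as DF1 (y = A∪C | B∪D) versus
    DF2 (z = A∪D | B∪C).
    """

    branch_id: int
    A: frozenset[int]
    B: frozenset[int]
    C: frozenset[int]
    D: frozenset[int]

    def split(self) -> Bipartition:
        return Bipartition.of(self.A | self.B, self.A | self.B | self.C | self.D)

    def restrict(self, present: frozenset[int]):
        """Intersect the four clades with ``present``; ``None`` if not decisive.

        A tree (or subsampled taxon set) is *decisive* for the branch only if
        it retains at least one taxon from each of A, B, C and D.
        """
        a, b = self.A & present, self.B & present
        if not a or not b:
            return None
        c, d = self.C & present, self.D & present
        if not c or not d:
            return None
        return (a, b, c, d)


def restrict_quadripartition(quad: Quadripartition, present: frozenset[int]):
    """Functional alias of :meth:`Quadripartition.restrict`."""
    return quad.restrict(frozenset(present))


@dataclass
class _Branch:
    branch_id: int
    node: dendropy.Node  # child node of the branch in the as-parsed tree
    split: Bipartition
    clade: frozenset[int]
    length: float | None
    label: str | None


class Tree:
    """A phylogenetic tree bound to a :class:`TaxonIndex`.

    Wraps a :class:`dendropy.Tree`.  Rootedness is structural: a tree whose
    seed (top) node has exactly two children is treated as rooted; anything
    else is an unrooted tree written with an arbitrary basal trifurcation.
    Split extraction always works on unrooted semantics, so the rooted and
    trifurcating writings of one unrooted topology yield identical splits.
    """

    def __init__(self, dtree: dendropy.Tree, index: TaxonIndex):
        self._dtree = dtree
        self.index = index
        labels = [lf.taxon.label for lf in dtree.leaf_node_iter()]
        if len(set(labels)) != len(labels):
            dupes = sorted({x for x in labels if labels.count(x) > 1})
            raise ValidationError(f"duplicate leaf labels in tree: {dupes}")
        unknown = [x for x in labels if x not in index]
        if unknown:
            raise ValidationError(f"leaf labels not in taxon index: {sorted(unknown)}")
        self._branches: list[_Branch] | None = None
        self._rooted_branches: list[_Branch] | None = None
        self._clades: dict[int, frozenset[int]] | None = None

    # ------------------------------------------------------------------ basics
    @property
    def dendropy_tree(self) -> dendropy.Tree:
        return self._dtree

    @property
    def is_rooted(self) -> bool:
        return len(self._dtree.seed_node.child_nodes()) == 2

    @property
    def n_leaves(self) -> int:
        return sum(1 for _ in self._dtree.leaf_node_iter())

    @property
    def leaf_positions(self) -> frozenset[int]:
        return frozenset(
            self.index[lf.taxon.label] for lf in self._dtree.leaf_node_iter()
        )

    def clone(self) -> "Tree":
        return Tree(self._dtree.clone(depth=1), self.index)

    # ------------------------------------------------------------- clade table
    def _clade_map(self) -> dict[int, frozenset[int]]:
        """Leaf-position set below every node, keyed by ``id(node)``."""
        if self._clades is None:
            clades: dict[int, frozenset[int]] = {}
            for nd in self._dtree.postorder_node_iter():
                if nd.is_leaf():
                    clades[id(nd)] = frozenset((self.index[nd.taxon.label],))
                else:
                    acc: set[int] = set()
                    for ch in nd.child_nodes():
                        acc |= clades[id(ch)]
                    clades[id(nd)] = frozenset(acc)
            self._clades = clades
        return self._clades

    # ------------------------------------------------------------------ splits
    def bipartitions(self) -> frozenset[Bipartition]:
        """The nontrivial splits of the tree over its own leaf set.

        Invariant under re-rooting and child rotation; polytomies are fine
        (they simply induce fewer splits).
        """
        universe = self.leaf_positions
        if len(universe) < 4:
            return frozenset()
        clades = self._clade_map()
        out: set[Bipartition] = set()
        seed = self._dtree.seed_node
        for nd in self._dtree.preorder_node_iter():
            if nd is seed or nd.is_leaf():
                continue
            clade = clades[id(nd)]
            if 2 <= len(clade) <= len(universe) - 2:
                out.add(Bipartition.of(clade, universe))
        return frozenset(out)

    # ---------------------------------------------------------------- branches
    def _enumerate_branches(self, rooted: bool) -> list[_Branch]:
        universe = self.leaf_positions
        clades = self._clade_map()
        seed = self._dtree.seed_node
        branches: list[_Branch] = []
        seen: set[Bipartition] = set()
        next_id = 1
        for nd in self._dtree.preorder_node_iter():
            if nd is seed or nd.is_leaf():
                continue
            clade = clades[id(nd)]
            if rooted:
                if len(clade) < 2:
                    continue
                split = (
                    Bipartition.of(clade, universe)
                    if len(clade) <= len(universe) - 2
                    else None
                )
            else:
                if not (2 <= len(clade) <= len(universe) - 2):
                    continue
                split = Bipartition.of(clade, universe)
                if split in seen:
                    continue
                seen.add(split)
            branches.append(
                _Branch(
                    branch_id=next_id,
                    node=nd,
                    split=split,
                    clade=clade,
                    length=nd.edge.length,
                    label=nd.label,
                )
            )
            next_id += 1
        return branches

    def branches(self) -> list[_Branch]:
        """Internal branches of the unrooted topology, with stable ids.

        Ids are assigned in preorder over the as-parsed tree; each id
        corresponds to one nontrivial split (the duplicate root-child edge
        of a binary-root writing is merged into one branch).
        """
        if self._branches is None:
            self._branches = self._enumerate_branches(rooted=False)
        return self._branches

    def rooted_branches(self) -> list[_Branch]:
        """Internal branches of a rooted tree, one per internal non-root node.

        The two branches incident to the root stay distinct even though they
        induce the same unrooted split (``split`` is ``None`` where the
        unrooted restriction is trivial).  Only meaningful for structurally
        rooted trees.
        """
        if not self.is_rooted:
            raise ValidationError("rooted_branches requires a rooted tree")
        if self._rooted_branches is None:
            self._rooted_branches = self._enumerate_branches(rooted=True)
        return self._rooted_branches

    def branch_by_id(self, branch_id: int, rooted: bool = False) -> _Branch:
        table = self.rooted_branches() if rooted else self.branches()
        for br in table:
            if br.branch_id == branch_id:
                return br
        raise ValidationError(f"no internal branch with id {branch_id}")

    # --------------------------------------------------------- quadripartitions
    def _check_bifurcating(self) -> None:
        seed = self._dtree.seed_node
        for nd in self._dtree.preorder_node_iter():
            if nd.is_leaf():
                continue
            k = len(nd.child_nodes())
            if nd is seed:
                ok = k in (2, 3)
            else:
                ok = k == 2
            if not ok:
                raise PolytomyError(
                    "quadripartitions require a fully bifurcating tree; "
                    f"found a node with {k} children"
                )

    def quadripartitions(self) -> list[Quadripartition]:
        """One :class:`Quadripartition` per internal branch (unrooted view).

        Requires a fully bifurcating tree with at least four leaves; an
        n-leaf tree yields exactly n − 3 quadripartitions.
        """
        universe = self.leaf_positions
        if len(universe) < 4:
            raise ValidationError("need at least 4 taxa for quadripartitions")
        self._check_bifurcating()
        clades = self._clade_map()
        seed = self._dtree.seed_node
        out: list[Quadripartition] = []
        for br in self.branches():
            nd = br.node
            kids = nd.child_nodes()
            if len(kids) != 2:  # cannot happen after the bifurcation check
                raise PolytomyError("internal branch endpoint is a polytomy")
            a, b = clades[id(kids[0])], clades[id(kids[1])]
            parent = nd.parent_node
            others = [ch for ch in parent.child_nodes() if ch is not nd]
            if parent is seed and len(others) == 2:
                c, d = clades[id(others[0])], clades[id(others[1])]
            elif parent is seed and len(others) == 1:
                # binary-root writing: the true other endpoint is the sibling
                sib = others[0]
                sk = sib.child_nodes()
                if len(sk) != 2:
                    raise PolytomyError("sibling of root branch is a polytomy")
                c, d = clades[id(sk[0])], clades[id(sk[1])]
            else:
                c = clades[id(others[0])]
                d = universe - clades[id(parent)]
            if min(b) < min(a):
                a, b = b, a
            if min(d) < min(c):
                c, d = d, c
            out.append(Quadripartition(br.branch_id, a, b, c, d))
        return out

    # ------------------------------------------------------------------ output
    def to_newick(
        self, labels: Mapping[int, str] | None = None, rooted: bool = False
    ) -> str:
        """Serialize to Newick, optionally overriding internal branch labels.

        ``labels`` maps branch ids to label strings placed on the child node
        of each branch; ``rooted`` selects the rooted id space
        (:meth:`rooted_branches`) instead of the unrooted one.
        """
        if not labels:
            tree = self._dtree
        else:
            table = self.rooted_branches() if rooted else self.branches()
            known = {br.branch_id for br in table}
            bad = set(labels) - known
            if bad:
                raise ValidationError(f"unknown branch ids: {sorted(bad)}")
            tree = self._dtree.clone(depth=1)
            # clone preserves traversal order, so re-derive the id -> node map
            clone_nodes = list(tree.preorder_node_iter())
            orig_nodes = list(self._dtree.preorder_node_iter())
            node_map = {id(o): c for o, c in zip(orig_nodes, clone_nodes)}
            for br in table:
                if br.branch_id in labels:
                    node_map[id(br.node)].label = labels[br.branch_id]
        text = tree.as_string(
            schema="newick",
            suppress_rooting=True,
            unquoted_underscores=True,
        )
        return text.strip() + "\n"


def write_annotated_newick(tree: Tree, labels: Mapping[int, str]) -> str:
    """Newick string with per-branch label strings (functional form)."""
    return tree.to_newick(labels=labels)


# ---------------------------------------------------------------------- parsing
def parse_newick(text: str, index: TaxonIndex | None = None) -> Tree:
    """Parse one Newick tree.

    If ``index`` is omitted a new :class:`TaxonIndex` is built from the
    tree's leaf labels in sorted order, so the same topology written with
    rotated children maps to the same positions.
    """
    ns = dendropy.TaxonNamespace()
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            taxon_namespace=ns,
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several reader subclasses
        if "Duplicate taxon labels" in str(exc):
            raise ValidationError(f"duplicate leaf labels: {exc}") from None
        raise NewickParseError(f"malformed Newick: {exc}") from None
    labels = [lf.taxon.label for lf in dtree.leaf_node_iter()]
    if index is None:
        index = TaxonIndex(sorted(set(labels)))
        if len(set(labels)) != len(labels):
            # let Tree.__init__ produce the duplicate-label diagnostic
            pass
    return Tree(dtree, index)


def parse_newick_list(text: str, index: TaxonIndex | None = None) -> list[Tree]:
    """Parse a multi-Newick string, one tree per non-blank line."""
    trees: list[Tree] = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line:
            continue
        try:
            trees.append(parse_newick(line, index=index))
        except NewickParseError as exc:
            raise NewickParseError(f"line {lineno}: {exc}") from None
        except ValidationError as exc:
            raise ValidationError(f"line {lineno}: {exc}") from None
    return trees


# ----------------------------------------------------------------- virtual root
def add_virtual_root(tree: Tree, index: TaxonIndex | None = None) -> Tree:
    """Turn a rooted tree into an unrooted one carrying a virtual-root leaf.

    The virtual leaf (label ``__ROOT__``) is attached at the root position,
    so the two clades flanking the original root become distinguishable
    splits of the unrooted tree.  Applying the same transformation to a set
    of rooted gene trees and running the unrooted machinery yields rooted
    concordance semantics.  ``index`` may supply a pre-extended taxon index
    shared across trees; otherwise the tree's own index is extended.
    """
    if not tree.is_rooted:
        raise ValidationError("add_virtual_root requires a rooted (degree-2 root) tree")
    if any(
        lf.taxon.label == VIRTUAL_ROOT_LABEL
        for lf in tree.dendropy_tree.leaf_node_iter()
    ):
        raise ValidationError(
            f"reserved label {VIRTUAL_ROOT_LABEL!r} occurs in user data"
        )
    if index is None:
        index = (
            tree.index
            if VIRTUAL_ROOT_LABEL in tree.index
            else tree.index.extended_with(VIRTUAL_ROOT_LABEL)
        )
    elif VIRTUAL_ROOT_LABEL not in index:
        raise ValidationError("supplied index lacks the virtual-root label")
    new_index = index
    dtree = tree.dendropy_tree.clone(depth=1)
    taxon = dtree.taxon_namespace.require_taxon(label=VIRTUAL_ROOT_LABEL)
    leaf = dendropy.Node(taxon=taxon)
    dtree.seed_node.add_child(leaf)
    return Tree(dtree, new_index)
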
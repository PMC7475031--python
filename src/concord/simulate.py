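"""Synthetic trees and alignments with controlled discordance.

The generators here are first-class tools for exercising the concordance
engines under known conditions: uniformly random topologies, gene trees
derived from a reference by per-branch NNI perturbation and taxon dropout,
and alignments under three simple regimes (no signal, no homoplasy, and an
explicit per-branch pattern mixture).  They intentionally avoid realistic
substitution models — the engines are model-agnostic and tests need known
expectations, not realism.
"""

from __future__ import annotations

import numpy as np
import dendropy

from .alignment import Alignment
from .errors import ValidationError
from .trees import TaxonIndex, Tree


def _default_labels(n: int) -> list[str]:
    width = len(str(n))
    return [f"t{str(i + 1).zfill(width)}" for i in range(n)]


def random_tree(n_taxa: int, seed: int, labels: list[str] | None = None) -> Tree:
    """Uniformly random unrooted bifurcating topology, unit branch lengths.

    Built by sequential random edge attachment: starting from the
    three-taxon star, each further taxon subdivides a uniformly chosen
    existing edge, which makes every labeled topology equiprobable.
    """
    if n_taxa < 4:
        raise ValidationError("need at least 4 taxa")
    labels = list(labels) if labels is not None else _default_labels(n_taxa)
    if len(labels) != n_taxa:
        raise ValidationError("label count does not match n_taxa")
    rng = np.random.default_rng(seed)
    index = TaxonIndex(sorted(labels))
    ns = dendropy.TaxonNamespace()
    dtree = dendropy.Tree(taxon_namespace=ns)
    seed_node = dtree.seed_node
    edges: list[dendropy.Node] = []  # each non-seed node represents its parent edge
    for lab in labels[:3]:
        leaf = seed_node.new_child(taxon=ns.require_taxon(label=lab))
        edges.append(leaf)
    for lab in labels[3:]:
        attach = edges[int(rng.integers(0, len(edges)))]
        parent = attach.parent_node
        parent.remove_child(attach)
        mid = parent.new_child()
        mid.add_child(attach)
        leaf = mid.new_child(taxon=ns.require_taxon(label=lab))
        edges.extend([mid, leaf])
    for ed in dtree.preorder_edge_iter():
        if ed.head_node is not seed_node:
            ed.length = 1.0
    return Tree(dtree, index)


def _nni_once(
    seed_node: dendropy.Node, clone_node: dendropy.Node, rng: np.random.Generator
) -> None:
    """Apply one NNI across the branch above ``clone_node`` in place.

    Swaps a uniformly chosen child subtree of the branch's head with one
    concrete subtree on the other endpoint; the two choices produce the two
    NNI alternatives with equal probability.
    """
    kids = clone_node.child_nodes()
    parent = clone_node.parent_node
    others = [ch for ch in parent.child_nodes() if ch is not clone_node]
    if parent is seed_node and len(others) == 1:
        # binary-root writing: real other endpoint is the sibling
        sk = others[0].child_nodes()
        partner = sk[0]
    else:
        partner = others[0]
    swap = kids[int(rng.integers(0, 2))]
    q = partner.parent_node
    clone_node.remove_child(swap)
    q.remove_child(partner)
    clone_node.add_child(partner)
    q.add_child(swap)


def perturb_gene_trees(
    ref: Tree,
    n: int,
    p: float,
    d: float,
    seed: int,
    branch_ids: list[int] | None = None,
) -> list[Tree]:
    """Gene trees derived from ``ref`` by NNI injection and taxon dropout.

    Each gene tree starts as a copy of the reference; every targeted
    internal branch independently undergoes a random NNI (either neighbor
    with equal probability) with probability ``p``; then every taxon is
    dropped with probability ``d``.  Dropout patterns leaving fewer than
    four taxa are redrawn, keeping the number of trees fixed.
    ``branch_ids`` restricts the NNI injection to particular reference
    branches (default: all internal branches).
    """
    if not (0.0 <= p <= 1.0 and 0.0 <= d <= 1.0):
        raise ValidationError("p and d must be probabilities")
    rng = np.random.default_rng(seed)
    branches = ref.branches()
    if branch_ids is not None:
        wanted = set(branch_ids)
        known = {br.branch_id for br in branches}
        if not wanted <= known:
            raise ValidationError(f"unknown branch ids: {sorted(wanted - known)}")
        branches = [br for br in branches if br.branch_id in wanted]
    orig_nodes = list(ref.dendropy_tree.preorder_node_iter())
    n_leaves = ref.n_leaves
    labels_by_pos = {
        ref.index[lf.taxon.label]: lf.taxon.label
        for lf in ref.dendropy_tree.leaf_node_iter()
    }
    positions = sorted(labels_by_pos)
    out: list[Tree] = []
    for _ in range(n):
        clone = ref.dendropy_tree.clone(depth=1)
        node_map = {
            id(o): c for o, c in zip(orig_nodes, clone.preorder_node_iter())
        }
        for br in branches:
            if rng.random() < p:
                _nni_once(clone.seed_node, node_map[id(br.node)], rng)
        if d > 0.0:
            while True:
                keep_mask = rng.random(n_leaves) >= d
                if keep_mask.sum() >= 4:
                    break
            keep_labels = {
                labels_by_pos[pos] for pos, k in zip(positions, keep_mask) if k
            }
            if len(keep_labels) < n_leaves:
                taxa = [
                    lf.taxon
                    for lf in clone.leaf_node_iter()
                    if lf.taxon.label in keep_labels
                ]
                clone.retain_taxa(taxa)
        out.append(Tree(clone, ref.index))
    return out


def _exact_counts(weights: tuple[float, ...], L: int) -> list[int]:
    """Largest-remainder apportionment of L sites to mixture components."""
    if abs(sum(weights) - 1.0) > 1e-9:
        raise ValidationError("mixture proportions must sum to 1")
    raw = [w * L for w in weights]
    counts = [int(np.floor(r)) for r in raw]
    short = L - sum(counts)
    order = sorted(range(len(raw)), key=lambda i: raw[i] - np.floor(raw[i]), reverse=True)
    for i in order[:short]:
        counts[i] += 1
    return counts


def simulate_alignment(
    tree: Tree,
    L: int,
    regime: str = "random",
    seed: int = 1,
    mixture: tuple[float, float, float] | None = None,
    branch_id: int | None = None,
) -> Alignment:
    """Simulate a DNA alignment on the leaves of ``tree``.

    Regimes:

    * ``"random"`` — i.i.d. uniform nucleotides, no tree signal; sCF tends
      to one third on every branch as L grows.
    * ``"nohomoplasy"`` — each column carries a single binary substitution
      on one uniformly chosen internal branch; all decisive sites support
      the tree, so sCF is 100% wherever decisive sites exist.
    * ``"mixture"`` — columns supporting the focal branch ``branch_id`` and
      its two NNI alternatives in the exact proportions ``mixture``
      (largest-remainder rounding); every quartet around that branch then
      sees identical proportions.
    """
    rng = np.random.default_rng(seed)
    leaves = sorted(tree.leaf_positions)
    taxa = [tree.index.label_of(p) for p in leaves]
    row_of = {p: i for i, p in enumerate(leaves)}
    n = len(taxa)
    nucs = np.frombuffer(b"ACGT", dtype=np.uint8)

    if regime == "random":
        data = nucs[rng.integers(0, 4, size=(n, L))]
    elif regime == "nohomoplasy":
        quads = tree.quadripartitions()
        data = np.empty((n, L), dtype=np.uint8)
        for j in range(L):
            quad = quads[int(rng.integers(0, len(quads)))]
            s1, s2 = rng.choice(4, size=2, replace=False)
            side = quad.A | quad.B
            col = np.full(n, nucs[s2], dtype=np.uint8)
            for pos in side:
                col[row_of[pos]] = nucs[s1]
            data[:, j] = col
    elif regime == "mixture":
        if mixture is None:
            raise ValidationError("mixture regime needs explicit proportions")
        if branch_id is None:
            raise ValidationError("mixture regime needs a focal branch_id")
        quad = next(
            q for q in tree.quadripartitions() if q.branch_id == branch_id
        )
        counts = _exact_counts(tuple(mixture), L)
        sides = [quad.A | quad.B, quad.A | quad.C, quad.A | quad.D]
        cols: list[np.ndarray] = []
        for side, k in zip(sides, counts):
            for _ in range(k):
                s1, s2 = rng.choice(4, size=2, replace=False)
                col = np.full(n, nucs[s2], dtype=np.uint8)
                for pos in side:
                    col[row_of[pos]] = nucs[s1]
                cols.append(col)
        perm = rng.permutation(L)
        data = np.stack(cols, axis=1)[:, perm]
    else:
        raise ValidationError(f"unknown regime {regime!r}")
    return Alignment(taxa=taxa, data=data, alphabet="dna")
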
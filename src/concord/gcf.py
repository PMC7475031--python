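"""Gene concordance factors.

For each internal branch x of a reference tree and each input (gene) tree
Ti, the quadripartition A, B, C, D around x is restricted to the taxa of
Ti.  Ti is *decisive* for x when all four restricted clades are nonempty.
A decisive tree falls into exactly one of four categories:

* concordant — the restricted split Ai∪Bi | Ci∪Di is a branch of Ti;
* DF1 — Ti instead contains the first NNI alternative y = Ai∪Ci | Bi∪Di;
* DF2 — Ti contains the second alternative z = Ai∪Di | Bi∪Ci;
* paraphyly — Ti contains none of the three, i.e. at least one of the four
  clades is not monophyletic in Ti.

The gene concordance factor gCF(x) is the percentage of decisive trees that
are concordant; gDF1, gDF2 and gDFP are the percentages of the other three
categories, so the four proportions sum to one on every branch with at
least one decisive tree.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

from .errors import ValidationError
from .trees import (
    VIRTUAL_ROOT_LABEL,
    Bipartition,
    Quadripartition,
    Tree,
    add_virtual_root,
)


class GeneTreeClass(enum.Enum):
    """Category of one (gene tree, reference branch) pair."""

    CONCORDANT = "C"
    DF1 = "D1"
    DF2 = "D2"
    PARAPHYLY = "P"
    NOT_DECISIVE = "NA"

    @property
    def code(self) -> str:
        return self.value


@dataclass(frozen=True)
class GeneBranchRecord:
    """Per-branch gene concordance summary.

    Percentages are ``None`` (reported as NA) when no input tree is decisive
    for the branch; counts always satisfy
    ``gCF_N + gDF1_N + gDF2_N + gDFP_N == gN``.
    """

    branch_id: int
    gCF: float | None
    gDF1: float | None
    gDF2: float | None
    gDFP: float | None
    gCF_N: int
    gDF1_N: int
    gDF2_N: int
    gDFP_N: int
    gN: int


@dataclass
class GcfResult:
    records: dict[int, GeneBranchRecord]
    #: classification matrix: one dict per gene tree, branch_id -> GeneTreeClass
    matrix: list[dict[int, GeneTreeClass]]


def _split_present(
    side_a: frozenset[int], side_b: frozenset[int], splits: frozenset[Bipartition]
) -> bool:
    """Is the split side_a | side_b displayed by a tree on exactly these taxa?

    A split with a singleton side exists in every tree on that leaf set, so
    it counts as present; this cannot contradict any topology.
    """
    if len(side_a) < 2 or len(side_b) < 2:
        return True
    return Bipartition.of(side_a, side_a | side_b) in splits


def classify_gene_tree(
    gene_splits: frozenset[Bipartition],
    gene_taxa: frozenset[int],
    quad: Quadripartition,
) -> GeneTreeClass:
    """Classify one gene tree against one reference branch.

    ``gene_splits`` must be the nontrivial splits of the gene tree over
    ``gene_taxa``.  Ties between degenerate restricted splits are broken in
    the order x, y, z, favoring concordance.
    """
    restricted = quad.restrict(gene_taxa)
    if restricted is None:
        return GeneTreeClass.NOT_DECISIVE
    a, b, c, d = restricted
    if _split_present(a | b, c | d, gene_splits):
        return GeneTreeClass.CONCORDANT
    if _split_present(a | c, b | d, gene_splits):
        return GeneTreeClass.DF1
    if _split_present(a | d, b | c, gene_splits):
        return GeneTreeClass.DF2
    return GeneTreeClass.PARAPHYLY


def compute_gcf(ref: Tree, gene_trees: list[Tree]) -> GcfResult:
    """Gene concordance factors for every internal branch of ``ref``.

    The reference tree must be bifurcating with at least four taxa; gene
    trees may be multifurcating and may each cover any subset of the
    reference taxa (trees not decisive for a branch are excluded from that
    branch's denominator).  Deterministic: no randomness is involved.
    """
    if not gene_trees:
        raise ValidationError("need at least one gene tree")
    ref_taxa = ref.leaf_positions
    if len(ref_taxa) < 4:
        raise ValidationError("reference tree needs at least 4 taxa")
    quads = ref.quadripartitions()

    prepared: list[tuple[frozenset[Bipartition], frozenset[int]]] = []
    for i, gt in enumerate(gene_trees):
        taxa = gt.leaf_positions
        extra = taxa - ref_taxa
        if extra:
            labels = gt.index.labels_of(extra)
            raise ValidationError(
                f"gene tree {i + 1} contains taxa absent from the reference "
                f"tree: {labels}"
            )
        prepared.append((gt.bipartitions(), taxa))

    matrix: list[dict[int, GeneTreeClass]] = [{} for _ in gene_trees]
    records: dict[int, GeneBranchRecord] = {}
    for quad in quads:
        counts = {cat: 0 for cat in GeneTreeClass}
        for i, (splits, taxa) in enumerate(prepared):
            cat = classify_gene_tree(splits, taxa, quad)
            matrix[i][quad.branch_id] = cat
            counts[cat] += 1
        g_n = sum(
            counts[c]
            for c in (
                GeneTreeClass.CONCORDANT,
                GeneTreeClass.DF1,
                GeneTreeClass.DF2,
                GeneTreeClass.PARAPHYLY,
            )
        )
        def pct(c: GeneTreeClass) -> float | None:
            return 100.0 * counts[c] / g_n if g_n > 0 else None

        records[quad.branch_id] = GeneBranchRecord(
            branch_id=quad.branch_id,
            gCF=pct(GeneTreeClass.CONCORDANT),
            gDF1=pct(GeneTreeClass.DF1),
            gDF2=pct(GeneTreeClass.DF2),
            gDFP=pct(GeneTreeClass.PARAPHYLY),
            gCF_N=counts[GeneTreeClass.CONCORDANT],
            gDF1_N=counts[GeneTreeClass.DF1],
            gDF2_N=counts[GeneTreeClass.DF2],
            gDFP_N=counts[GeneTreeClass.PARAPHYLY],
            gN=g_n,
        )
    return GcfResult(records=records, matrix=matrix)


def compute_gcf_rooted(ref_rooted: Tree, gene_trees_rooted: list[Tree]) -> GcfResult:
    """Gene concordance factors on a rooted reference tree.

    A virtual-root leaf is attached to the reference and to every gene tree,
    after which the unrooted machinery runs on the augmented taxon set.  The
    two branches incident to the root induce distinct splits of the
    augmented trees, so they can receive different gCF values; branches away
    from the root get the same values as in an unrooted analysis.  Results
    are keyed by the branch ids of the rooted reference tree.
    """
    if not ref_rooted.is_rooted:
        raise ValidationError("rooted mode requires a rooted reference tree")
    for i, gt in enumerate(gene_trees_rooted):
        if not gt.is_rooted:
            raise ValidationError(
                f"gene tree {i + 1} is unrooted; use the unrooted analysis "
                "or root every gene tree"
            )
    base = ref_rooted.index
    ext = base if VIRTUAL_ROOT_LABEL in base else base.extended_with(VIRTUAL_ROOT_LABEL)
    ref_v = add_virtual_root(ref_rooted, index=ext)
    genes_v = [add_virtual_root(gt, index=ext) for gt in gene_trees_rooted]
    res = compute_gcf(ref_v, genes_v)

    # map augmented-tree branch ids back to rooted-reference branch ids via
    # the side of each split that excludes the virtual leaf
    vpos = ext[VIRTUAL_ROOT_LABEL]
    clade_to_rooted = {br.clade: br.branch_id for br in ref_rooted.rooted_branches()}
    id_map: dict[int, int] = {}
    for br in ref_v.branches():
        clade = br.split.members if vpos not in br.split.members else br.split.complement
        id_map[br.branch_id] = clade_to_rooted[clade]
    records = {
        id_map[bid]: GeneBranchRecord(
            branch_id=id_map[bid],
            gCF=rec.gCF,
            gDF1=rec.gDF1,
            gDF2=rec.gDF2,
            gDFP=rec.gDFP,
            gCF_N=rec.gCF_N,
            gDF1_N=rec.gDF1_N,
            gDF2_N=rec.gDF2_N,
            gDFP_N=rec.gDFP_N,
            gN=rec.gN,
        )
        for bid, rec in res.records.items()
    }
    matrix = [
        {id_map[bid]: cat for bid, cat in row.items()} for row in res.matrix
    ]
    return GcfResult(records=records, matrix=matrix)
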
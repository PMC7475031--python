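"""Independent brute-force oracles used to cross-check the engines.

Everything here is deliberately written from scratch against the
definitions, without touching the package's tree or alignment machinery:
a tiny recursive Newick reader, split enumeration by clade collection, the
gene-tree category rule tested by set equality, and a per-column site
classifier with exhaustive quartet enumeration.
"""

from __future__ import annotations

import itertools
import re

_TOKEN = re.compile(r"\(|\)|,|;|[^(),;]+")


def parse_nested(newick: str):
    """Parse Newick into nested tuples of leaf labels (lengths/labels dropped)."""
    tokens = [t for t in _TOKEN.findall(newick.strip()) if t != ";"]
    pos = 0

    def node():
        nonlocal pos
        if tokens[pos] == "(":
            pos += 1
            kids = [node()]
            while tokens[pos] == ",":
                pos += 1
                kids.append(node())
            assert tokens[pos] == ")", "unbalanced newick in oracle"
            pos += 1
            # optional internal label / branch length
            if pos < len(tokens) and tokens[pos] not in "(),":
                pos += 1
            return tuple(kids)
        tok = tokens[pos]
        pos += 1
        return tok.split(":")[0]

    out = node()
    assert pos == len(tokens)
    return out


def leaf_set(nested) -> frozenset[str]:
    if isinstance(nested, str):
        return frozenset((nested,))
    return frozenset().union(*(leaf_set(k) for k in nested))


def enumerate_splits(newick: str) -> set[frozenset[frozenset[str]]]:
    """All nontrivial splits of a tree, as unordered pairs of label sets."""
    nested = parse_nested(newick)
    universe = leaf_set(nested)
    splits: set[frozenset[frozenset[str]]] = set()

    def walk(node):
        if isinstance(node, str):
            return
        clade = leaf_set(node)
        if 2 <= len(clade) <= len(universe) - 2:
            splits.add(frozenset((clade, universe - clade)))
        for k in node:
            walk(k)

    # skip the top node itself (its clade is the universe) but walk children
    for k in nested:
        walk(k)
    return splits


def classify_gene_tree_oracle(
    newick: str,
    A: set[str],
    B: set[str],
    C: set[str],
    D: set[str],
) -> str:
    """Category ('C', 'D1', 'D2', 'P' or 'NA') by brute-force split lookup."""
    taxa = leaf_set(parse_nested(newick))
    a, b, c, d = taxa & A, taxa & B, taxa & C, taxa & D
    if not (a and b and c and d):
        return "NA"
    splits = enumerate_splits(newick)

    def present(s1: frozenset[str], s2: frozenset[str]) -> bool:
        if len(s1) < 2 or len(s2) < 2:
            return True
        return frozenset((s1, s2)) in splits

    if present(frozenset(a | b), frozenset(c | d)):
        return "C"
    if present(frozenset(a | c), frozenset(b | d)):
        return "D1"
    if present(frozenset(a | d), frozenset(b | c)):
        return "D2"
    return "P"


def classify_column_oracle(a: str, b: str, c: str, d: str) -> str:
    """Site category by the four-taxon parsimony rule ('C','D1','D2','NA')."""
    chars = [a.upper(), b.upper(), c.upper(), d.upper()]
    if any(ch not in "ACGT" for ch in chars):
        return "NA"
    a, b, c, d = chars
    if a == b and c == d and a != c:
        return "C"
    if a == c and b == d and a != b:
        return "D1"
    if a == d and b == c and a != b:
        return "D2"
    return "NA"


def scf_oracle_exhaustive(
    seqs: dict[str, str],
    A: set[str],
    B: set[str],
    C: set[str],
    D: set[str],
):
    """Mean (sCF, sDF1, sDF2) percentages over every quartet, or None.

    Mirrors the definition directly: per quartet, classify every column,
    drop quartets without decisive columns, average the proportions.
    """
    sums = [0.0, 0.0, 0.0]
    m_eff = 0
    for qa, qb, qc, qd in itertools.product(sorted(A), sorted(B), sorted(C), sorted(D)):
        counts = {"C": 0, "D1": 0, "D2": 0}
        for col in zip(seqs[qa], seqs[qb], seqs[qc], seqs[qd]):
            cat = classify_column_oracle(*col)
            if cat != "NA":
                counts[cat] += 1
        n_dec = sum(counts.values())
        if n_dec == 0:
            continue
        m_eff += 1
        sums[0] += counts["C"] / n_dec
        sums[1] += counts["D1"] / n_dec
        sums[2] += counts["D2"] / n_dec
    if m_eff == 0:
        return None
    return tuple(100.0 * s / m_eff for s in sums)
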
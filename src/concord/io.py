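"""Readers for alignments, partition tables and tree files.

External coordinates follow ecosystem conventions: partition ranges are
1-based inclusive (RAxML style) while everything internal is 0-based
half-open.  FASTA and sequential relaxed PHYLIP are supported for
alignments (Biopython does the format parsing); tree files are plain
Newick, one tree per non-blank line for gene-tree files.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path

from Bio import AlignIO, SeqIO

from .alignment import Alignment
from .errors import ValidationError
from .trees import TaxonIndex, Tree, parse_newick, parse_newick_list


@dataclass(frozen=True)
class Locus:
    name: str
    ranges: tuple[tuple[int, int], ...]  # 1-based inclusive

    def slices(self) -> list[tuple[int, int]]:
        """0-based half-open intervals."""
        return [(lo - 1, hi) for lo, hi in self.ranges]

    @property
    def length(self) -> int:
        return sum(hi - lo + 1 for lo, hi in self.ranges)


@dataclass
class PartitionTable:
    loci: list[Locus]

    def __iter__(self):
        return iter(self.loci)

    def __len__(self) -> int:
        return len(self.loci)

    def names(self) -> list[str]:
        return [loc.name for loc in self.loci]


def _sniff_format(path: Path) -> str:
    with open(path) as fh:
        for line in fh:
            if line.strip():
                return "fasta" if line.lstrip().startswith(">") else "phylip"
    raise ValidationError(f"{path}: empty alignment file")


def read_alignment(path, format: str = "auto", alphabet: str | None = None) -> Alignment:
    """Read a FASTA or sequential relaxed-PHYLIP alignment.

    The alphabet (DNA vs amino acid) is auto-detected from character
    frequencies unless given explicitly.
    """
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"alignment file not found: {path}")
    fmt = format if format != "auto" else _sniff_format(path)
    if fmt == "fasta":
        records = list(SeqIO.parse(str(path), "fasta"))
        if not records:
            raise ValidationError(f"{path}: no sequences found")
        taxa = [r.id for r in records]
        seqs = [str(r.seq) for r in records]
    elif fmt == "phylip":
        try:
            msa = AlignIO.read(str(path), "phylip-relaxed")
        except ValueError as exc:
            raise ValidationError(f"{path}: cannot parse PHYLIP: {exc}") from None
        taxa = [r.id for r in msa]
        seqs = [str(r.seq) for r in msa]
    else:
        raise ValidationError(f"unknown alignment format {fmt!r}")
    return Alignment.from_strings(taxa, seqs, alphabet=alphabet)


_PARTITION_RE = re.compile(
    r"^\s*(?P<type>[A-Za-z0-9_+]+)\s*,\s*(?P<name>\S+)\s*=\s*(?P<ranges>[0-9,\s\-]+)$"
)


def read_partitions(path, L: int) -> PartitionTable:
    """Parse a RAxML-style partition file against alignment length ``L``.

    Lines look like ``DNA, locus1 = 1-500`` (multiple comma-separated
    ranges allowed).  Codon-position strides (``1-500\\3``) are rejected.
    Loci are returned sorted by their first coordinate.
    """
    path = Path(path)
    loci: list[Locus] = []
    seen_names: set[str] = set()
    covered: list[tuple[int, int, str]] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if "\\" in line or "/" in line.split("=", 1)[-1]:
                raise ValidationError(
                    f"{path}:{lineno}: codon-position strides are not supported"
                )
            mo = _PARTITION_RE.match(line)
            if not mo:
                raise ValidationError(f"{path}:{lineno}: cannot parse partition line")
            name = mo.group("name")
            if name in seen_names:
                raise ValidationError(f"{path}:{lineno}: duplicate locus name {name!r}")
            seen_names.add(name)
            ranges: list[tuple[int, int]] = []
            for chunk in mo.group("ranges").split(","):
                chunk = chunk.strip()
                if not chunk:
                    continue
                parts = chunk.split("-")
                if len(parts) == 1:
                    lo = hi = int(parts[0])
                elif len(parts) == 2:
                    lo, hi = int(parts[0]), int(parts[1])
                else:
                    raise ValidationError(f"{path}:{lineno}: bad range {chunk!r}")
                if not (1 <= lo <= hi <= L):
                    raise ValidationError(
                        f"{path}:{lineno}: range {lo}-{hi} outside alignment "
                        f"length {L}"
                    )
                for plo, phi, pname in covered:
                    if lo <= phi and plo <= hi:
                        raise ValidationError(
                            f"{path}:{lineno}: range {lo}-{hi} overlaps locus "
                            f"{pname!r}"
                        )
                covered.append((lo, hi, name))
                ranges.append((lo, hi))
            if not ranges:
                raise ValidationError(f"{path}:{lineno}: no ranges given")
            loci.append(Locus(name=name, ranges=tuple(ranges)))
    if not loci:
        raise ValidationError(f"{path}: no partitions found")
    loci.sort(key=lambda loc: loc.ranges[0][0])
    return PartitionTable(loci=loci)


def read_reference_tree(path) -> Tree:
    """Read the reference tree; its leaves define the shared taxon index."""
    text = Path(path).read_text()
    tree = parse_newick(text)
    if len(tree.leaf_positions) < 4:
        raise ValidationError("reference tree needs at least 4 taxa")
    return tree


def read_gene_trees(path, index: TaxonIndex, prune_unknown: bool = False) -> list[Tree]:
    """Read a multi-Newick gene-tree file against a shared taxon index.

    Each gene tree must cover a subset of the indexed taxa.  Unknown labels
    are an error unless ``prune_unknown`` is set, in which case the
    offending leaves are removed (never silently: the caller receives trees
    whose leaf sets it can compare against the originals).
    """
    text = Path(path).read_text()
    if not prune_unknown:
        trees = parse_newick_list(text, index=index)
    else:
        trees = []
        for lineno, line in enumerate(text.splitlines(), start=1):
            line = line.strip()
            if not line:
                continue
            raw = parse_newick(line)  # own index; labels unrestricted
            keep = [
                lf.taxon
                for lf in raw.dendropy_tree.leaf_node_iter()
                if lf.taxon.label in index
            ]
            if len(keep) < len(list(raw.dendropy_tree.leaf_node_iter())):
                if len(keep) < 3:
                    raise ValidationError(
                        f"line {lineno}: fewer than 3 indexed taxa remain after pruning"
                    )
                raw.dendropy_tree.retain_taxa(keep)
            trees.append(Tree(raw.dendropy_tree, index))
    if not trees:
        raise ValidationError(f"{path}: no gene trees found")
    return trees
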
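"""Tabulated and annotated-tree outputs.

One analysis produces up to five files under a user prefix:

* ``<prefix>.cf.stat``       — per-branch table with the 16 concordance and
  discordance values plus the decisive-tree and decisive-site counts;
* ``<prefix>.cf.stat_tree``  — per-gene-tree classification matrix;
* ``<prefix>.cf.stat_loci``  — per-locus mean concordant-site counts;
* ``<prefix>.cf.tree``       — reference tree with combined
  ``bootstrap/gCF/sCF`` branch labels;
* ``<prefix>.cf.branch``     — reference tree with every statistic embedded
  as a structured ``[&key=value]`` comment per branch.

All tables are tab-separated with ``#``-prefixed header comments,
percentages to two decimals, counts as integers (gene level) or
two-decimal means (site level), and literal ``NA`` for undefined values —
a branch with no decisive gene trees is a different fact from one with 0%
concordance.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import pandas as pd

from .errors import ValidationError
from .gcf import GcfResult, GeneBranchRecord, GeneTreeClass
from .scf import ScfResult, SiteBranchRecord
from .trees import Tree

CF_STAT_COLUMNS = [
    "ID",
    "gCF", "gCF_N", "gDF1", "gDF1_N", "gDF2", "gDF2_N", "gDFP", "gDFP_N", "gN",
    "sCF", "sCF_N", "sDF1", "sDF1_N", "sDF2", "sDF2_N", "sN",
    "Length", "Label",
]


@dataclass
class BranchStatRow:
    """One ``.cf.stat`` row: the joined gene- and site-level summary."""

    branch_id: int
    gene: GeneBranchRecord | None
    site: SiteBranchRecord | None
    length: float | None
    label: str | None


def collect_rows(
    ref: Tree,
    gcf_result: GcfResult | None = None,
    scf_result: ScfResult | None = None,
    rooted: bool = False,
) -> list[BranchStatRow]:
    """Join engine outputs into one row per internal branch of ``ref``.

    ``rooted`` switches to the rooted branch-id space (one row per internal
    non-root node, the two root-incident branches kept distinct).
    """
    rows = []
    table = ref.rooted_branches() if rooted else ref.branches()
    for br in table:
        rows.append(
            BranchStatRow(
                branch_id=br.branch_id,
                gene=gcf_result.records.get(br.branch_id) if gcf_result else None,
                site=scf_result.records.get(br.branch_id) if scf_result else None,
                length=br.length,
                label=br.label,
            )
        )
    return rows


def _pct(v: float | None) -> str:
    return "NA" if v is None else f"{v:.2f}"


def _meanct(v: float | None) -> str:
    return "NA" if v is None else f"{v:.2f}"


def write_cf_stat(rows: list[BranchStatRow], path) -> None:
    """Write the per-branch statistics table (``.cf.stat``)."""
    lines = [
        "# Concordance-factor statistics, one row per internal branch of the reference tree.",
        "# ID: branch identifier (preorder over the reference tree)",
        "# gCF/gDF1/gDF2/gDFP: % of decisive gene trees that are concordant /",
        "#   match the first NNI alternative / the second / neither (paraphyly)",
        "# gCF_N/gDF1_N/gDF2_N/gDFP_N: the corresponding gene-tree counts",
        "# gN: number of gene trees decisive for the branch",
        "# sCF/sDF1/sDF2: mean % of decisive sites concordant with the branch /",
        "#   its first / second NNI alternative, over sampled quartets",
        "# sCF_N/sDF1_N/sDF2_N: mean concordant/discordant site counts per quartet",
        "# sN: mean number of decisive sites per quartet",
        "# Length: branch length from the reference tree; Label: pre-existing branch label",
        "# NA: statistic undefined (no decisive gene trees / no contributing quartets)",
        "\t".join(CF_STAT_COLUMNS),
    ]
    for row in rows:
        g, s = row.gene, row.site
        cells = [str(row.branch_id)]
        if g is not None:
            cells += [
                _pct(g.gCF), str(g.gCF_N), _pct(g.gDF1), str(g.gDF1_N),
                _pct(g.gDF2), str(g.gDF2_N), _pct(g.gDFP), str(g.gDFP_N),
                str(g.gN),
            ]
        else:
            cells += ["NA"] * 9
        if s is not None:
            cells += [
                _pct(s.sCF), _meanct(s.sCF_N), _pct(s.sDF1), _meanct(s.sDF1_N),
                _pct(s.sDF2), _meanct(s.sDF2_N), _meanct(s.sN),
            ]
        else:
            cells += ["NA"] * 7
        cells.append("NA" if row.length is None else f"{row.length:g}")
        cells.append(row.label if row.label else "NA")
        lines.append("\t".join(cells))
    Path(path).write_text("\n".join(lines) + "\n")


def read_cf_stat(path) -> pd.DataFrame:
    """Re-read a ``.cf.stat`` file (round-trip helper)."""
    return pd.read_csv(path, sep="\t", comment="#", na_values="NA")


def write_tree_table(matrix: list[dict[int, GeneTreeClass]], path) -> None:
    """Write the per-gene-tree classification matrix (``.cf.stat_tree``).

    One row per gene tree, one column per branch; cells are C (concordant),
    D1/D2 (the NNI alternatives), P (paraphyly) or NA (not decisive).
    """
    if not matrix:
        raise ValidationError("empty classification matrix")
    branch_ids = sorted(matrix[0])
    lines = [
        "# Per-gene-tree classification against every internal branch.",
        "# C: concordant; D1/D2: first/second NNI alternative; P: paraphyly;",
        "# NA: gene tree not decisive for the branch.",
        "\t".join(["Tree"] + [str(b) for b in branch_ids]),
    ]
    for i, row in enumerate(matrix, start=1):
        lines.append("\t".join([str(i)] + [row[b].code for b in branch_ids]))
    Path(path).write_text("\n".join(lines) + "\n")


def write_loci_table(per_locus: Mapping[str, Mapping[int, float | None]], path) -> None:
    """Write per-locus mean concordant-site counts (``.cf.stat_loci``)."""
    if per_locus is None:
        raise ValidationError(
            "per-locus table requested but no partition table was supplied"
        )
    names = list(per_locus)
    branch_ids = sorted(per_locus[names[0]]) if names else []
    lines = [
        "# Mean number of sites per quartet, within each locus, concordant with",
        "# each internal branch (NA: branch had no contributing quartets).",
        "\t".join(["Locus"] + [str(b) for b in branch_ids]),
    ]
    for name in names:
        vals = per_locus[name]
        lines.append(
            "\t".join(
                [name]
                + [
                    "NA" if vals[b] is None else f"{vals[b]:.2f}"
                    for b in branch_ids
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


def _short(v: float | None) -> str:
    return "NA" if v is None else f"{v:.1f}"


def build_label_tree(
    ref: Tree,
    gcf_result: GcfResult | None = None,
    scf_result: ScfResult | None = None,
    rooted: bool = False,
) -> tuple[str, str]:
    """Build the two annotated Newick strings.

    Returns ``(combined, full)``: ``combined`` carries per-branch labels of
    the form ``bootstrap/gCF/sCF`` (parts present only for statistics that
    were computed, appended after any pre-existing support label);
    ``full`` embeds every computed value as a ``[&key=value]`` comment.
    """
    table = ref.rooted_branches() if rooted else ref.branches()
    labels: dict[int, str] = {}
    for br in table:
        parts: list[str] = []
        if br.label:
            parts.append(br.label)
        if gcf_result is not None:
            rec = gcf_result.records.get(br.branch_id)
            parts.append(_short(rec.gCF if rec else None))
        if scf_result is not None:
            rec = scf_result.records.get(br.branch_id)
            parts.append(_short(rec.sCF if rec else None))
        if parts:
            labels[br.branch_id] = "/".join(parts)
    combined = ref.to_newick(labels=labels, rooted=rooted)

    full_tree = ref.clone()
    full_table = full_tree.rooted_branches() if rooted else full_tree.branches()
    for br in full_table:
        ann = br.node.annotations
        if gcf_result is not None:
            g = gcf_result.records.get(br.branch_id)
            if g is not None:
                for k in ("gCF", "gDF1", "gDF2", "gDFP"):
                    v = getattr(g, k)
                    ann.add_new(k, "NA" if v is None else round(v, 2))
                for k in ("gCF_N", "gDF1_N", "gDF2_N", "gDFP_N", "gN"):
                    ann.add_new(k, getattr(g, k))
        if scf_result is not None:
            s = scf_result.records.get(br.branch_id)
            if s is not None:
                for k in ("sCF", "sDF1", "sDF2", "sCF_N", "sDF1_N", "sDF2_N", "sN"):
                    v = getattr(s, k)
                    ann.add_new(k, "NA" if v is None else round(v, 2))
    full = full_tree.dendropy_tree.as_string(
        schema="newick",
        suppress_rooting=True,
        unquoted_underscores=True,
        suppress_annotations=False,
    ).strip() + "\n"
    return combined, full
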
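# Methods

## The statistics

`concord` annotates every internal branch *x* of a bifurcating reference
tree *T* with measures of genealogical concordance computed from two kinds
of data: a set of input (gene) trees, and a multiple sequence alignment.

Removing *x* splits the reference taxa into the bipartition A∪B | C∪D,
where A and B are the leaf sets of the two subtrees attached to one
endpoint of *x*, and C and D those attached to the other. The two
nearest-neighbor-interchange (NNI) rearrangements across *x* produce the
alternative branches y = A∪C | B∪D and z = A∪D | B∪C; x, y, z are the only
three ways a tree on these four clades can resolve their relationship.

**Gene concordance factor (gCF).** For gene tree T_i with taxon set S_i,
let A_i = A ∩ S_i (similarly B_i, C_i, D_i). T_i is *decisive* for *x* when
all four intersections are nonempty — only then could T_i contain *x* at
all, which is what makes the measure robust to incomplete taxon coverage.
A decisive tree is

* **concordant** if A_i∪B_i | C_i∪D_i is a split of T_i,
* **DF1** if the restricted y-split is,
* **DF2** if the restricted z-split is,
* **paraphyletic (DFP)** otherwise (at least one of the four clades is not
  monophyletic in T_i).

gCF(x) is the percentage of decisive trees that are concordant; gDF1, gDF2
and gDFP the percentages of the other categories. The four percentages sum
to 100 on every branch with gN > 0 decisive trees, and the corresponding
counts sum to gN exactly (integer arithmetic; no rounding is involved
before formatting).

**Site concordance factor (sCF).** A quartet q = (a, b, c, d) draws one
taxon from each of A, B, C, D. Alignment column j is *decisive* for q when
all four characters are definite states and the column is
parsimony-informative on the quartet — exactly two states, each occurring
twice; these are the only four-taxon patterns for which the three quartet
topologies differ in parsimony score. A decisive column supports x when
a_j = b_j ≠ c_j = d_j, y when a_j = c_j ≠ b_j = d_j, and z when
a_j = d_j ≠ b_j = c_j; there is no paraphyletic class for sites, so
sCF + sDF1 + sDF2 = 100 identically. CF_q(x) is the fraction of decisive
columns supporting x; sCF(x) is the mean CF_q over m sampled quartets.

**Rooted mode.** For a rooted reference with rooted gene trees, a reserved
virtual leaf (`__ROOT__`) is attached at every root and the unrooted
machinery is run on the augmented taxon set. The two branches incident to
the root then induce distinct splits and can receive different gCF values;
all other branches get the same values as the unrooted analysis. Site
concordance cannot distinguish the two sides of the root (no site "carries"
the virtual taxon), so in combined rooted runs both root-incident branches
report the statistics of their shared unrooted split.

## Conventions the definitions leave open

* **DF1 versus DF2 orientation.** Which NNI alternative is "first" is not
  determined by the definitions. We orient deterministically: A (resp. C)
  is the clade containing the lowest-indexed taxon on its endpoint of the
  branch, with taxon indices assigned by sorted label order. Outputs are
  therefore reproducible across runs and machines, but DF1/DF2 labels are
  this package's convention and need not match other implementations.
* **Multifurcating gene trees** are accepted; a polytomy that resolves none
  of x, y, z classifies the tree as DFP. The reference tree itself must be
  bifurcating (polytomies adjacent to an internal branch are rejected with
  an error), because the quadripartition and its NNI alternatives are only
  well defined there.
* **Degenerate restricted splits.** If a restricted split has a side with
  fewer than two taxa it exists in every tree on those leaves and is
  treated as present; ties are broken in the order x, y, z, favoring
  concordance. With all four restricted clades nonempty such splits cannot
  actually arise, but the rule makes the classifier total.
* **Quartet sampling.** When |A|·|B|·|C|·|D| ≤ m, all distinct quartets are
  enumerated once and the result is deterministic and seed-independent;
  otherwise m quartets are drawn with each component independent and
  uniform, duplicates allowed (an unbiased estimator of the exhaustive
  mean). Default m = 100, giving sub-percent Monte-Carlo error on typical
  data. Each branch uses an RNG substream derived from (seed, branch id),
  so results do not depend on branch iteration order.
* **Quartets with no decisive site** have CF_q = 0/0; they are excluded
  from the mean (the effective denominator m_effective is reported). A
  branch where every quartet is excluded reports NA — distinct from 0%.
* **Missing data.** Gaps (`-`, `.`), `?`, and all ambiguity codes (`N`,
  IUPAC partial codes; `X`/`B`/`Z`/`J` for proteins) are treated as absent:
  the parsimony rule needs definite states, and resolving ambiguities would
  require a substitution model the statistic deliberately avoids.
* **NA accounting.** A branch with gN = 0 (or m_effective = 0) prints
  literal `NA` for its percentages, never 0: "no decisive data" and "0%
  concordance" are different statements.

## Synthetic data

`concord.simulate` generates the controlled inputs the test-suite and the
acceptance script run on:

* `random_tree(n, seed)` — uniformly random unrooted bifurcating topology
  by sequential random edge attachment, unit branch lengths.
* `perturb_gene_trees(ref, n, p, d, seed)` — each gene tree is a copy of
  the reference in which every targeted internal branch independently
  undergoes a random NNI (either neighbor with probability ½) with
  probability p, followed by independent taxon dropout with probability d.
  Dropout masks leaving fewer than four taxa are redrawn (the NNI outcomes
  are kept), so the number of trees stays fixed and the per-branch NNI
  expectation E[1 − gCF/100] = p is preserved.
* `simulate_alignment(tree, L, regime, seed)` — three regimes: `random`
  (i.i.d. uniform nucleotides, no signal: sCF approaches 33⅓% on every
  branch as L grows, since a decisive column is equally likely to support
  any of the three quartet topologies), `nohomoplasy` (each column carries
  one binary substitution on a uniformly chosen internal branch; every
  decisive site is then concordant, as any tree split restricted to a
  quartet spanning branch x is either trivial or equal to the x-split), and
  `mixture` (columns supporting x, y, z of one focal branch in exact,
  largest-remainder-rounded proportions; every quartet around that branch
  sees identical proportions, so sCF/sDF1/sDF2 equal the mixture weights
  exactly).

What the generators deliberately omit: realistic substitution models (GTR,
rate heterogeneity, branch-length variation), coalescent gene-tree
distributions, alignment error, and within-locus recombination. Passing
tests therefore demonstrate that the estimators recover known quantities
under controlled discordance and missingness — not that any particular
biological dataset will show high concordance.

## Problem sizes and numerical choices

The default test-suite and the acceptance script use 8–32 taxa, 100–2,000
gene trees and alignments of 200–50,000 sites, sizes at which the binomial
or Monte-Carlo standard errors of the checked quantities are comfortably
inside the asserted tolerances (e.g. ±3 points on recovering p from
2,000 trees, where the standard error is about 1 point; ±2 points on the
33% random-alignment limit at L = 50,000 and m = 100). Percentages are
computed in double precision from integer counts; tables print percentages
to two decimals, gene-level counts as integers and site-level means to two
decimals. Identity checks (proportion sums) hold to 1e−9 before any
formatting.

## Known limitations

* Interleaved PHYLIP and NEXUS inputs are not supported (FASTA and
  sequential relaxed PHYLIP are).
* No per-locus tree inference: gene trees must be supplied, already
  estimated.
* Codon-position partition strides are rejected rather than expanded.
* The `.cf.*` output layouts are stable and documented but not
  byte-compatible with other software that reports the same statistics.
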
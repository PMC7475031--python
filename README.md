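# concord

Gene and site concordance factors for phylogenomic reference trees.

Bootstrap values and posterior probabilities measure sampling variance in
support of a branch, not how much of the underlying data actually agrees
with it: in phylogenomic datasets, branches routinely reach 100% bootstrap
while large fractions of gene trees and alignment sites support conflicting
resolutions (incomplete lineage sorting, introgression, estimation error).
`concord` quantifies that underlying agreement for every internal branch
*x* of a reference tree:

* **gCF(x)** — the percentage of *decisive* gene trees that contain *x*. A
  gene tree is decisive when it retains at least one taxon from each of the
  four clades A, B, C, D surrounding *x* (split A∪B | C∪D), so gene trees
  with incomplete taxon coverage are handled without bias. Discordant
  decisive trees are split into gDF1 and gDF2 (the two
  nearest-neighbor-interchange alternatives y = A∪C | B∪D and
  z = A∪D | B∪C) and gDFP (none of the three: some clade is paraphyletic),
  with gCF + gDF1 + gDF2 + gDFP = 100%.
* **sCF(x)** — the mean, over m random quartets (one taxon from each of
  A, B, C, D), of the percentage of decisive alignment sites supporting
  {a,b} | {c,d}. A site is decisive when all four characters are definite
  and the column is parsimony-informative on the quartet; decisive sites
  support exactly one of the three quartet topologies, so
  sCF + sDF1 + sDF2 = 100%. An alignment with no signal gives sCF ≈ 33% —
  values near one third mean "no site-level information", not "strong
  conflict".

The package is aimed at phylogeneticists who already have a reference tree
plus per-locus gene trees and/or a concatenated alignment, and want
branch-level concordance annotations alongside their bootstrap values.

## Worked example

A balanced 8-taxon reference with a deliberately discordant central branch:
ten gene trees (6 concordant with the central branch, 2 containing the
first NNI alternative, 1 the second, 1 paraphyletic) and a 1,000-site
alignment whose decisive columns support the central branch's three
resolutions in proportions 50 / 30 / 20:

```
concord --ref ref.nwk --gene-trees genes.nwk --aln aln.fasta --prefix demo --seed 1
```

`demo.cf.stat` (header comments omitted):

```
ID  gCF    gCF_N gDF1  gDF1_N gDF2  gDF2_N gDFP  gDFP_N gN  sCF    sCF_N  sDF1  sDF1_N sDF2  sDF2_N sN
1   90.00  9     0.00  0      0.00  0      10.00 1      10  100.00 250.00 0.00  0.00   0.00  0.00   250.00
2   90.00  9     0.00  0      0.00  0      10.00 1      10  100.00 250.00 0.00  0.00   0.00  0.00   250.00
3   60.00  6     20.00 2      10.00 1      10.00 1      10  50.00  500.00 30.00 300.00 20.00 200.00 1000.00
4   90.00  9     0.00  0      0.00  0      10.00 1      10  100.00 250.00 0.00  0.00   0.00  0.00   250.00
5   90.00  9     0.00  0      0.00  0      10.00 1      10  100.00 250.00 0.00  0.00   0.00  0.00   250.00
```

Branch 3 is the central branch: 6 of 10 decisive gene trees contain it
(gCF = 60), two contain alternative y (gDF1 = 20), one alternative z
(gDF2 = 10) and one neither (gDFP = 10); at the site level, 50% of the
1,000 decisive sites per quartet support it, 30% and 20% the alternatives.
The single paraphyletic gene tree breaks the monophyly of *every* clade, so
the four peripheral cherries each score gCF = 90. `demo.cf.tree` carries
the same information as `gCF/sCF` branch labels (after any existing
bootstrap label):

```
((a1,a2)90.0/100.0,(b1,b2)90.0/100.0,((c1,c2)90.0/100.0,(d1,d2)90.0/100.0)60.0/50.0);
```

`demo.cf.branch` embeds all sixteen concordance/discordance values plus gN
and sN as structured `[&key=value]` comments per branch, and `--verbose`
additionally writes the per-gene-tree classification matrix
(`.cf.stat_tree`) and, with `--partitions`, per-locus concordant-site means
(`.cf.stat_loci`).

The same functionality is available as a library
(`concord.compute_gcf`, `concord.compute_scf`,
`concord.compute_gcf_rooted`, `concord.simulate.*`); see `docs/methods.md`
for definitions, conventions and limitations.

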
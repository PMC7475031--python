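"""Site concordance factors.

For an internal branch x with surrounding clades A, B, C, D, a quartet
q = (a, b, c, d) draws one taxon from each clade.  An alignment column j is
*decisive* for q when all four characters are definite states and the
column is parsimony-informative on the quartet — exactly two states, each
occurring twice.  A decisive column supports exactly one of the three
quartet topologies:

* concordant with x when a = b ≠ c = d,
* DF1 (the NNI alternative y) when a = c ≠ b = d,
* DF2 (the alternative z) when a = d ≠ b = c.

CF_q(x) is the fraction of decisive columns that are concordant; the site
concordance factor sCF(x) is the mean CF_q over m sampled quartets, and
sDF1/sDF2 are the analogous means, so sCF + sDF1 + sDF2 = 100% on every
branch with at least one contributing quartet.  Quartets without any
decisive column have an undefined CF_q and are dropped from the means.
"""

from __future__ import annotations

import enum
import itertools
from dataclasses import dataclass

import numpy as np

from .alignment import Alignment
from .errors import ValidationError
from .trees import Quadripartition, Tree


class SiteClass(enum.Enum):
    CONCORDANT = "C"
    DF1 = "D1"
    DF2 = "D2"
    NOT_DECISIVE = "NA"


@dataclass(frozen=True)
class QuartetSample:
    """One taxon position from each of A, B, C, D (in that order)."""

    a: int
    b: int
    c: int
    d: int

    def __iter__(self):
        return iter((self.a, self.b, self.c, self.d))


@dataclass(frozen=True)
class SiteBranchRecord:
    """Per-branch site concordance summary (means over sampled quartets).

    All statistics are ``None`` (reported as NA) when no sampled quartet had
    a decisive site (``m_effective == 0``).
    """

    branch_id: int
    sCF: float | None
    sDF1: float | None
    sDF2: float | None
    sCF_N: float | None
    sDF1_N: float | None
    sDF2_N: float | None
    sN: float | None
    m_effective: int


@dataclass
class ScfResult:
    records: dict[int, SiteBranchRecord]
    #: per-locus mean concordant-site counts: {locus_name: {branch_id: mean}};
    #: None unless a partition table was supplied
    per_locus: dict[str, dict[int, float | None]] | None = None


def classify_site(chars, alphabet: str = "dna") -> SiteClass:
    """Classify one 4-character column (a, b, c, d) by the parsimony rule.

    Scalar reference implementation; the engine uses a vectorized
    equivalent.  Characters outside the alphabet that are not recognized
    missing/ambiguity codes raise a validation error.
    """
    from .alignment import _MASKS  # local import to keep the public surface tidy

    mask = _MASKS[alphabet]
    ups = [str(ch).upper() for ch in chars]
    if len(ups) != 4 or any(len(ch) != 1 for ch in ups):
        raise ValidationError("classify_site expects exactly four characters")
    known_missing = set("-.?NXOUBZJRYSWKMDHV*")
    for ch in ups:
        if not mask[ord(ch)] and ch not in known_missing:
            raise ValidationError(f"unrecognized character {ch!r}")
    if not all(mask[ord(ch)] for ch in ups):
        return SiteClass.NOT_DECISIVE
    a, b, c, d = ups
    if a == b and c == d and a != c:
        return SiteClass.CONCORDANT
    if a == c and b == d and a != b:
        return SiteClass.DF1
    if a == d and b == c and a != b:
        return SiteClass.DF2
    return SiteClass.NOT_DECISIVE


def _quartet_site_classes(
    aln: Alignment, rows: tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Boolean per-site arrays (concordant, df1, df2) for one quartet."""
    ra, rb, rc, rd = rows
    definite = aln.definite_mask()
    present = definite[ra] & definite[rb] & definite[rc] & definite[rd]
    conc = present & (ra == rb) & (rc == rd) & (ra != rc)
    df1 = present & (ra == rc) & (rb == rd) & (ra != rb)
    df2 = present & (ra == rd) & (rb == rc) & (ra != rb)
    return conc, df1, df2


def quartet_cf(
    aln: Alignment,
    q: QuartetSample,
    index,
    site_range: tuple[int, int] | None = None,
) -> tuple[int, int, int, int]:
    """Counts (n_concordant, n_df1, n_df2, n_decisive) for one quartet.

    ``index`` is the shared TaxonIndex translating quartet positions to
    alignment rows; ``site_range`` is a 0-based half-open interval for
    per-locus counting (default: all sites).
    """
    rows = tuple(aln.row(index.label_of(p)) for p in q)
    conc, df1, df2 = _quartet_site_classes(aln, rows)
    if site_range is not None:
        lo, hi = site_range
        conc, df1, df2 = conc[lo:hi], df1[lo:hi], df2[lo:hi]
    n_c, n_1, n_2 = int(conc.sum()), int(df1.sum()), int(df2.sum())
    return n_c, n_1, n_2, n_c + n_1 + n_2


def sample_quartets(
    quad: Quadripartition, m: int, rng: np.random.Generator
) -> list[QuartetSample]:
    """Sample m quartets around a branch, or enumerate all when few exist.

    When |A|·|B|·|C|·|D| ≤ m every distinct quartet is returned exactly once
    (deterministic, seed-independent); otherwise m quartets are drawn with
    each component independent and uniform, duplicates permitted.
    """
    if m < 1:
        raise ValidationError("quartet count m must be >= 1")
    sets = [sorted(quad.A), sorted(quad.B), sorted(quad.C), sorted(quad.D)]
    if any(not s for s in sets):
        raise ValidationError("quadripartition has an empty clade")
    total = 1
    for s in sets:
        total *= len(s)
    if total <= m:
        return [QuartetSample(*combo) for combo in itertools.product(*sets)]
    draws = [rng.integers(0, len(s), size=m) for s in sets]
    return [
        QuartetSample(sets[0][i], sets[1][j], sets[2][k], sets[3][l])
        for i, j, k, l in zip(*draws)
    ]


def _branch_rng(seed: int, branch_id: int) -> np.random.Generator:
    # substream per branch so results do not depend on iteration order
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(branch_id,)))


def compute_scf(
    ref: Tree,
    aln: Alignment,
    m: int = 100,
    seed: int = 1,
    partitions=None,
    on_missing: str = "error",
) -> ScfResult:
    """Site concordance factors for every internal branch of ``ref``.

    Draws up to ``m`` quartets per branch (exhaustive when fewer exist),
    computes CF_q per quartet over the whole alignment, and averages over
    the quartets with at least one decisive site.  With a partition table,
    per-locus mean concordant-site counts are computed over the same
    contributing quartets.  ``on_missing`` controls taxa present in the tree
    but absent from the alignment: ``"error"`` (default) or ``"exclude"``
    (drop them from the sampling pools; a branch whose pool empties gets an
    all-NA record).
    """
    if on_missing not in ("error", "exclude"):
        raise ValidationError("on_missing must be 'error' or 'exclude'")
    index = ref.index
    missing = sorted(
        index.label_of(p) for p in ref.leaf_positions if index.label_of(p) not in aln
    )
    if missing and on_missing == "error":
        raise ValidationError(
            f"taxa in the reference tree but not in the alignment: {missing}"
        )
    present = frozenset(
        p for p in ref.leaf_positions if index.label_of(p) in aln
    )

    loci: list[tuple[str, list[tuple[int, int]]]] | None = None
    if partitions is not None:
        loci = [(loc.name, loc.slices()) for loc in partitions]

    records: dict[int, SiteBranchRecord] = {}
    per_locus: dict[str, dict[int, float | None]] | None = (
        {name: {} for name, _ in loci} if loci is not None else None
    )
    for quad in ref.quadripartitions():
        bid = quad.branch_id
        restricted = quad.restrict(present)
        if restricted is None:
            records[bid] = SiteBranchRecord(bid, *([None] * 7), m_effective=0)
            if per_locus is not None:
                for name, _ in loci:
                    per_locus[name][bid] = None
            continue
        sub = Quadripartition(bid, *restricted)
        rng = _branch_rng(seed, bid)
        quartets = sample_quartets(sub, m, rng)
        rows_cache = {
            p: aln.row(index.label_of(p))
            for p in frozenset(itertools.chain.from_iterable(quartets))
        }
        cf_sum = df1_sum = df2_sum = 0.0
        n_c_sum = n_1_sum = n_2_sum = n_d_sum = 0.0
        m_eff = 0
        locus_sums: dict[str, float] = (
            {name: 0.0 for name, _ in loci} if loci is not None else {}
        )
        for q in quartets:
            conc, df1, df2 = _quartet_site_classes(
                aln, (rows_cache[q.a], rows_cache[q.b], rows_cache[q.c], rows_cache[q.d])
            )
            n_c, n_1, n_2 = int(conc.sum()), int(df1.sum()), int(df2.sum())
            n_d = n_c + n_1 + n_2
            if n_d == 0:
                continue
            m_eff += 1
            cf_sum += n_c / n_d
            df1_sum += n_1 / n_d
            df2_sum += n_2 / n_d
            n_c_sum += n_c
            n_1_sum += n_1
            n_2_sum += n_2
            n_d_sum += n_d
            if loci is not None:
                for name, slices in loci:
                    locus_sums[name] += float(
                        sum(int(conc[lo:hi].sum()) for lo, hi in slices)
                    )
        if m_eff == 0:
            records[bid] = SiteBranchRecord(bid, *([None] * 7), m_effective=0)
            if per_locus is not None:
                for name, _ in loci:
                    per_locus[name][bid] = None
            continue
        records[bid] = SiteBranchRecord(
            branch_id=bid,
            sCF=100.0 * cf_sum / m_eff,
            sDF1=100.0 * df1_sum / m_eff,
            sDF2=100.0 * df2_sum / m_eff,
            sCF_N=n_c_sum / m_eff,
            sDF1_N=n_1_sum / m_eff,
            sDF2_N=n_2_sum / m_eff,
            sN=n_d_sum / m_eff,
            m_effective=m_eff,
        )
        if per_locus is not None:
            for name, _ in loci:
                per_locus[name][bid] = locus_sums[name] / m_eff
    return ScfResult(records=records, per_locus=per_locus)
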
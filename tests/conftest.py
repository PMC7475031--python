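import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make `oracles` importable

import concord as C


@pytest.fixture
def eight_taxon_ref():
    """Balanced 8-taxon reference: clades (a1,a2) (b1,b2) (c1,c2) (d1,d2)."""
    return C.parse_newick("((a1,a2),(b1,b2),((c1,c2),(d1,d2)));")


@pytest.fixture
def central_branch(eight_taxon_ref):
    """The quadripartition whose split is a1a2b1b2 | c1c2d1d2."""
    want = frozenset(eight_taxon_ref.index[x] for x in ("a1", "a2", "b1", "b2"))
    for q in eight_taxon_ref.quadripartitions():
        if q.A | q.B == want or q.C | q.D == want:
            return q
    raise AssertionError("central branch not found")


def as_label_pairs(tree):
    """Package splits as unordered label-set pairs, for oracle comparison."""
    idx = tree.index
    return {
        frozenset(
            (
                frozenset(idx.label_of(p) for p in s.members),
                frozenset(idx.label_of(p) for p in s.complement),
            )
        )
        for s in tree.bipartitions()
    }
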
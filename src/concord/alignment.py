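"""Multiple-sequence-alignment container used by the site-concordance engine.

Sequences are stored as a dense uint8 matrix of upper-cased ASCII codes.
Only *definite* states take part in the four-taxon parsimony rule: the four
nucleotides for DNA, the twenty standard residues for amino acids.  Gaps
(``-``, ``.``), ``?`` and all ambiguity codes (``N``, ``R``, ``Y``, …, and
``X``/``B``/``Z``/``J`` for proteins) are treated as absent characters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError

DNA_STATES = "ACGT"
AA_STATES = "ACDEFGHIKLMNPQRSTVWY"

_DNA_ISH = set("ACGTUN-?.")


def _state_mask(states: str) -> np.ndarray:
    mask = np.zeros(256, dtype=bool)
    for ch in states:
        mask[ord(ch)] = True
    return mask


_MASKS = {"dna": _state_mask(DNA_STATES), "aa": _state_mask(AA_STATES)}


def detect_alphabet(seqs: list[str]) -> str:
    """Crude but robust DNA/AA sniffing by character content."""
    counted = 0
    dna_like = 0
    for s in seqs:
        for ch in s.upper():
            counted += 1
            if ch in _DNA_ISH:
                dna_like += 1
    if counted == 0:
        raise ValidationError("empty alignment")
    return "dna" if dna_like / counted >= 0.9 else "aa"


@dataclass
class Alignment:
    """Equal-length character rows over a declared alphabet."""

    taxa: list[str]
    data: np.ndarray  # (n_taxa, L) uint8 of upper-case ASCII codes
    alphabet: str  # "dna" or "aa"
    _row_of: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if self.alphabet not in _MASKS:
            raise ValidationError(f"unknown alphabet {self.alphabet!r}")
        if self.data.ndim != 2 or self.data.shape[0] != len(self.taxa):
            raise ValidationError("alignment matrix does not match taxon list")
        if len(set(self.taxa)) != len(self.taxa):
            dupes = sorted({t for t in self.taxa if self.taxa.count(t) > 1})
            raise ValidationError(f"duplicate taxa in alignment: {dupes}")
        self._row_of = {t: i for i, t in enumerate(self.taxa)}

    @classmethod
    def from_strings(
        cls, taxa: list[str], seqs: list[str], alphabet: str | None = None
    ) -> "Alignment":
        if len(taxa) != len(seqs):
            raise ValidationError("taxon and sequence counts differ")
        if not seqs:
            raise ValidationError("empty alignment")
        lengths = {len(s) for s in seqs}
        if len(lengths) != 1:
            ref_len = len(seqs[0])
            for t, s in zip(taxa, seqs):
                if len(s) != ref_len:
                    raise ValidationError(
                        f"sequence for {t!r} has length {len(s)}, expected {ref_len}"
                    )
        if alphabet is None:
            alphabet = detect_alphabet(seqs)
        data = np.frombuffer(
            "".join(s.upper() for s in seqs).encode("ascii"), dtype=np.uint8
        ).reshape(len(seqs), -1)
        return cls(taxa=list(taxa), data=data.copy(), alphabet=alphabet)

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def length(self) -> int:
        return int(self.data.shape[1])

    def __contains__(self, taxon: str) -> bool:
        return taxon in self._row_of

    def row(self, taxon: str) -> np.ndarray:
        try:
            return self.data[self._row_of[taxon]]
        except KeyError:
            raise ValidationError(f"taxon {taxon!r} has no alignment row") from None

    def definite_mask(self) -> np.ndarray:
        """Boolean (256,) lookup marking definite (unambiguous) states."""
        return _MASKS[self.alphabet]

    def sequence(self, taxon: str) -> str:
        return self.row(taxon).tobytes().decode("ascii")
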
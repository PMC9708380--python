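"""Codon alphabets.

Two alphabets are supported: ``sense61`` (the 61 sense codons of the
standard genetic code; stop codons are dropped when counting) and
``all64`` (every triplet). Codon order is lexicographic and fixed, so
count vectors from different genes/clusters are always comparable
position-wise.
"""

from __future__ import annotations

BASES = "ACGT"
STOP_CODONS = ("TAA", "TAG", "TGA")

ALL64 = tuple(a + b + c for a in BASES for b in BASES for c in BASES)
SENSE61 = tuple(c for c in ALL64 if c not in STOP_CODONS)

ALPHABETS: dict[str, tuple[str, ...]] = {"sense61": SENSE61, "all64": ALL64}

CODON_INDEX: dict[str, dict[str, int]] = {
    name: {codon: i for i, codon in enumerate(codons)}
    for name, codons in ALPHABETS.items()
}

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def alphabet_size(alphabet_id: str) -> int:
    return len(ALPHABETS[alphabet_id])


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]
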
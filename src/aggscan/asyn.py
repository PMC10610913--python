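"""Reference sequences for human α-synuclein (aSyn).

The canonical 140-residue protein sequence (UniProt P37840) is the default
substrate for every stage of the pipeline.  The nucleotide sequence shipped
here is a *synthetic* coding sequence obtained by deterministic reverse
translation: every downstream protein-level quantity (library size, variant
naming, enrichment scores, residue classes) is independent of the codon
choice, which only matters for generating realistic read data.

Codons were picked with a third base of A or T wherever the amino acid allows
it, so that almost no wild-type codon coincides with a degenerate library
codon (which end in G or C).  The unavoidable exceptions are the single-codon
amino acids: aSyn carries internal Met at residues 5, 116 and 127 whose ATG
is itself an NNS codon, so those positions contribute 31 rather than 32
distinct codon variants.  Protein-level counts are unaffected.
"""

from __future__ import annotations

from .library import CodingSequence

#: Canonical human α-synuclein protein sequence, UniProt P37840 (140 aa).
ASYN_AA = (
    "MDVFMKGLSKAKEGVVAAAEKTKQGVAEAAGKTKEGVLYVGSKTKEGVVHGVATVAEKTK"
    "EQVTNVGGAVVTGVTAVAQKTVEGAGSIAAATGFVKKDQLGKNEEGAPQEGILEDMPVDP"
    "DNEAYEMPSEEGYQDYEPEA"
)

# Third-base A/T codon per amino acid (single-codon Met/Trp excepted).
_REVERSE_CODON = {
    "A": "GCT", "R": "AGA", "N": "AAT", "D": "GAT", "C": "TGT",
    "Q": "CAA", "E": "GAA", "G": "GGT", "H": "CAT", "I": "ATT",
    "L": "CTT", "K": "AAA", "M": "ATG", "F": "TTT", "P": "CCT",
    "S": "TCT", "T": "ACT", "W": "TGG", "Y": "TAT", "V": "GTT",
}


def reverse_translate(aa: str) -> str:
    """Deterministic reverse translation using the fixed codon table above."""
    return "".join(_REVERSE_CODON[x] for x in aa)


def asyn_reference(name: str = "aSyn_P37840_synthetic_cds") -> CodingSequence:
    """The aSyn reference as a :class:`CodingSequence` (synthetic CDS)."""
    return CodingSequence(name=name, nt=reverse_translate(ASYN_AA))
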
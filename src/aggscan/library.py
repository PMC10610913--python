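"""NNS single-codon saturation library enumeration.

A saturation library replaces each codon of a wild-type coding sequence with
the 32 NNS degenerate codons (N = A/C/G/T, S = G/C).  NNS covers all 20 amino
acids plus the TAG stop, so at every mutable position the library encodes 19
missense products, one stop, and synonymous wild-type codons.  Collapsing the
codon-level library by translated product yields the protein-variant database
used to match sequencing reads and to keep count bookkeeping honest.
"""

from __future__ import annotations

import hashlib
import re
from dataclasses import dataclass, field
from functools import cached_property
from typing import Iterable, Iterator

import pandas as pd
from Bio.Seq import Seq

STOP = "*"
AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"

#: The 32 NNS codons (third base G or C), lexicographic order.
NNS_CODONS: tuple[str, ...] = tuple(
    a + b + c for a in "ACGT" for b in "ACGT" for c in "GC"
)

_DNA_RE = re.compile(r"^[ACGT]+$")


def translate_codon(codon: str) -> str:
    """Translate one codon under the standard genetic code ('*' for stop)."""
    return str(Seq(codon).translate())


@dataclass(frozen=True)
class CodingSequence:
    """A protein-coding DNA sequence with 1-based residue numbering.

    A single trailing stop codon is tolerated and trimmed from the protein;
    internal stops and non-ACGT characters are rejected.
    """

    name: str
    nt: str

    def __post_init__(self) -> None:
        if not _DNA_RE.match(self.nt):
            raise ValueError(f"{self.name}: CDS contains non-ACGT characters")
        if len(self.nt) % 3:
            raise ValueError(f"{self.name}: CDS length {len(self.nt)} not divisible by 3")
        aa = str(Seq(self.nt).translate())
        body = aa[:-1] if aa.endswith(STOP) else aa
        if STOP in body:
            raise ValueError(f"{self.name}: internal stop codon in CDS")

    @cached_property
    def aa(self) -> str:
        aa = str(Seq(self.nt).translate())
        return aa[:-1] if aa.endswith(STOP) else aa

    def __len__(self) -> int:
        return len(self.aa)

    def codon(self, position: int) -> str:
        """Codon at 1-based residue ``position``."""
        if not 1 <= position <= len(self.aa) + (len(self.nt) // 3 > len(self.aa)):
            raise IndexError(f"codon position {position} outside CDS")
        return self.nt[3 * (position - 1): 3 * position]

    @classmethod
    def from_fasta(cls, path) -> "CodingSequence":
        from Bio import SeqIO

        rec = next(SeqIO.parse(str(path), "fasta"))
        return cls(name=rec.id, nt=str(rec.seq).upper())


@dataclass(frozen=True)
class CodonVariant:
    """One full-gene variant carrying a single substituted codon."""

    position: int          # 1-based codon index
    codon: str             # the substituted NNS codon
    product: str           # amino acid or '*'
    gene_nt: str           # full variant CDS


@dataclass(frozen=True)
class VariantKey:
    """Protein-level identity of a variant: (position, substitution).

    ``is_wt_synonymous`` marks keys whose product equals the wild-type amino
    acid (reached through a synonymous NNS codon); downstream counting pools
    these into the wild-type reference bucket.
    """

    position: int
    substitution: str
    is_wt_synonymous: bool = False

    def __post_init__(self) -> None:
        if self.substitution != STOP and self.substitution not in AA_ALPHABET:
            raise ValueError(f"unknown substitution {self.substitution!r}")


_VARIANT_RE = re.compile(r"^([A-Y])(\d+)([A-Y*=])$")


def variant_to_string(key: VariantKey, wt: CodingSequence) -> str:
    """Canonical variant name, e.g. ``E13K`` or ``K10*``; synonymous ``E13=``."""
    wt_aa = wt.aa[key.position - 1]
    if key.substitution == wt_aa and not key.is_wt_synonymous:
        raise ValueError(
            f"substitution equals WT residue {wt_aa}{key.position} "
            "but key is not flagged synonymous"
        )
    sub = "=" if key.is_wt_synonymous else key.substitution
    return f"{wt_aa}{key.position}{sub}"


def parse_variant(text: str, wt: CodingSequence) -> VariantKey:
    """Inverse of :func:`variant_to_string` (validates the WT residue)."""
    m = _VARIANT_RE.match(text.strip())
    if not m:
        raise ValueError(f"cannot parse variant name {text!r}")
    wt_aa, pos, sub = m.group(1), int(m.group(2)), m.group(3)
    if not 1 <= pos <= len(wt.aa):
        raise ValueError(f"{text}: position outside protein")
    if wt.aa[pos - 1] != wt_aa:
        raise ValueError(f"{text}: WT residue at {pos} is {wt.aa[pos - 1]}, not {wt_aa}")
    if sub == "=":
        return VariantKey(pos, wt_aa, is_wt_synonymous=True)
    if sub == wt_aa:
        raise ValueError(f"{text}: substitution equals WT residue; use '{wt_aa}{pos}='")
    return VariantKey(pos, sub)


@dataclass
class VariantDatabase:
    """All expected single-codon gene variants, collapsed to protein level."""

    wt: CodingSequence
    mutable_range: tuple[int, int]
    codon_variants: list[CodonVariant]
    protein_variants: dict[VariantKey, frozenset[str]]

    @cached_property
    def gene_to_key(self) -> dict[str, VariantKey]:
        """Exact-match lookup from full gene string to protein variant."""
        out: dict[str, VariantKey] = {}
        for key, genes in self.protein_variants.items():
            for g in genes:
                out[g] = key
        return out

    def non_wt_keys(self) -> list[VariantKey]:
        return [k for k in self.protein_variants if not k.is_wt_synonymous]

    @property
    def n_protein_variants(self) -> int:
        """Distinct non-WT protein variants (missense + stop)."""
        return len(self.non_wt_keys())

    def positions(self) -> range:
        return range(self.mutable_range[0], self.mutable_range[1] + 1)

    def to_frame(self) -> pd.DataFrame:
        """TSV-ready listing: one row per protein variant."""
        rows = []
        for key in sorted(self.protein_variants, key=lambda k: (k.position, k.substitution)):
            genes = sorted(self.protein_variants[key])
            digest = hashlib.sha256("".join(genes).encode()).hexdigest()[:12]
            rows.append(
                {
                    "position": key.position,
                    "wt_aa": self.wt.aa[key.position - 1],
                    "substitution": key.substitution,
                    "is_wt_synonymous": key.is_wt_synonymous,
                    "n_codons": len(genes),
                    "gene_nt_sha256_12": digest,
                }
            )
        return pd.DataFrame(rows)

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def enumerate_nns(
    wt: CodingSequence, mutable_range: tuple[int, int] | None = None
) -> VariantDatabase:
    """Enumerate the NNS saturation library over ``mutable_range``.

    Defaults to residues 2..len(aa): the initiator Met is excluded from
    mutagenesis.  Codons identical to the wild-type codon are skipped (they
    would reproduce the wild-type gene string, not a variant); synonymous
    non-identical codons are kept and flagged ``is_wt_synonymous``.
    """
    n_aa = len(wt.aa)
    if mutable_range is None:
        mutable_range = (min(2, n_aa), n_aa)
    first, last = mutable_range
    if not (1 <= first <= last <= n_aa):
        raise ValueError(f"mutable range {mutable_range} outside protein 1..{n_aa}")

    codon_variants: list[CodonVariant] = []
    protein_variants: dict[VariantKey, set[str]] = {}
    for pos in range(first, last + 1):
        wt_codon = wt.codon(pos)
        wt_aa = wt.aa[pos - 1]
        prefix = wt.nt[: 3 * (pos - 1)]
        suffix = wt.nt[3 * pos:]
        for codon in NNS_CODONS:
            if codon == wt_codon:
                continue
            product = translate_codon(codon)
            gene = prefix + codon + suffix
            codon_variants.append(CodonVariant(pos, codon, product, gene))
            key = VariantKey(pos, product, is_wt_synonymous=(product == wt_aa))
            protein_variants.setdefault(key, set()).add(gene)

    frozen = {k: frozenset(v) for k, v in protein_variants.items()}
    db = VariantDatabase(wt, (first, last), codon_variants, frozen)
    all_genes = [cv.gene_nt for cv in codon_variants]
    assert len(all_genes) == len(set(all_genes)), "gene strings not unique"
    return db


def iter_gene_sequences(db: VariantDatabase) -> Iterator[tuple[VariantKey, str]]:
    for key, genes in db.protein_variants.items():
        for g in sorted(genes):
            yield key, g
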
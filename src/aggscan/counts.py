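"""Exact-match variant counting of merged amplicon reads from sorted pools.

Each read is trimmed to the gene region between two constant anchor strings
(the invariant primer tails flanking the amplified gene), then matched
*exactly* against the enumerated variant database.  Reads equal to the
wild-type gene, or to a wild-type-synonymous codon variant, are pooled into a
single wild-type count; everything else that fails exact lookup (sequencing
errors, multi-mutants, junk) is tallied as unmatched.  No error-tolerant
rescue is attempted: a one-mismatch rescue would alias neighbouring variants.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd
from Bio.Seq import reverse_complement
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .library import VariantDatabase, VariantKey, parse_variant, variant_to_string

POOL_LABELS = ("input_library", "fret_pos", "fret_neg")

#: Constant flanks of the amplicon (from the amplification primer tails).
#: The 5' anchor ends just before the initiator ATG so the region between the
#: anchors is the complete coding sequence.
DEFAULT_ANCHOR5 = "GCTAGCGCCGCCACC"
DEFAULT_ANCHOR3 = "GTTCTGCTGGCTCCGCTGC"


def trim_to_gene(
    read: str,
    anchor5: str = DEFAULT_ANCHOR5,
    anchor3: str = DEFAULT_ANCHOR3,
    expected_length: int | None = None,
) -> str | None:
    """Extract the gene region strictly between the two anchors.

    Returns ``None`` when either anchor is absent (in both orientations) or
    the extracted region has the wrong length (indels).  Reads arriving in
    reverse-complement orientation are re-oriented via the anchors.
    """
    for seq in (read, reverse_complement(read)):
        i = seq.find(anchor5)
        if i < 0:
            continue
        start = i + len(anchor5)
        j = seq.find(anchor3, start)
        if j < 0:
            continue
        gene = seq[start:j]
        if expected_length is not None and len(gene) != expected_length:
            return None
        return gene
    return None


@dataclass
class CountTable:
    """Per-pool exact-match counts over a variant database."""

    pool_label: str
    counts: dict[VariantKey, int]
    wt_count: int
    unmatched: int

    @property
    def total(self) -> int:
        return self.wt_count + sum(self.counts.values()) + self.unmatched

    @property
    def matched(self) -> int:
        return self.total - self.unmatched

    def to_frame(self, db: VariantDatabase) -> pd.DataFrame:
        rows = [
            {
                "variant": variant_to_string(k, db.wt),
                "pool": self.pool_label,
                "count": c,
            }
            for k, c in sorted(
                self.counts.items(), key=lambda kv: (kv[0].position, kv[0].substitution)
            )
        ]
        rows.append({"variant": "WT", "pool": self.pool_label, "count": self.wt_count})
        rows.append(
            {"variant": "__unmatched__", "pool": self.pool_label, "count": self.unmatched}
        )
        return pd.DataFrame(rows)

    def write_tsv(self, path, db: VariantDatabase) -> None:
        self.to_frame(db).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, db: VariantDatabase) -> "CountTable":
        df = pd.read_csv(path, sep="\t")
        pools = df["pool"].unique()
        if len(pools) != 1:
            raise ValueError(f"expected one pool per table, found {list(pools)}")
        counts: dict[VariantKey, int] = {}
        wt = unmatched = 0
        for _, row in df.iterrows():
            name, c = row["variant"], int(row["count"])
            if name == "WT":
                wt = c
            elif name == "__unmatched__":
                unmatched = c
            else:
                counts[parse_variant(name, db.wt)] = c
        return cls(str(pools[0]), counts, wt, unmatched)


def count_reads(
    genes: Iterable[str | None], db: VariantDatabase, pool_label: str
) -> CountTable:
    """Count trimmed gene sequences against the database.

    Each read increments exactly one bucket: the protein variant whose gene
    set contains it, the wild-type bucket (WT string or synonymous codon
    variant), or unmatched.
    """
    lookup = db.gene_to_key
    wt_nt = db.wt.nt
    counts: dict[VariantKey, int] = {}
    wt_count = unmatched = 0
    n = 0
    for gene in genes:
        n += 1
        if gene is None:
            unmatched += 1
            continue
        if gene == wt_nt:
            wt_count += 1
            continue
        key = lookup.get(gene)
        if key is None:
            unmatched += 1
        elif key.is_wt_synonymous:
            wt_count += 1
        else:
            counts[key] = counts.get(key, 0) + 1
    if n == 0:
        raise ValueError(f"{pool_label}: empty read set")
    return CountTable(pool_label, counts, wt_count, unmatched)


def count_fastq(
    path,
    db: VariantDatabase,
    pool_label: str,
    anchor5: str = DEFAULT_ANCHOR5,
    anchor3: str = DEFAULT_ANCHOR3,
) -> CountTable:
    """Trim and count a FASTQ file of merged reads (quality scores ignored)."""
    expected = len(db.wt.nt)

    def genes():
        with open(path) as fh:
            for _title, seq, _qual in FastqGeneralIterator(fh):
                yield trim_to_gene(seq.upper(), anchor5, anchor3, expected)

    return count_reads(genes(), db, pool_label)


def frequencies(ct: CountTable) -> tuple[dict[VariantKey, float], float]:
    """Per-variant and wild-type frequencies among *matched* reads.

    The denominator excludes unmatched reads, making downstream enrichment
    ratios invariant to pool-specific junk rates.
    """
    denom = ct.matched
    if denom <= 0:
        raise ValueError(
            f"{ct.pool_label}: no reads matched the variant database "
            f"({ct.unmatched} unmatched) — check anchors and reference sequence"
        )
    freqs = {k: c / denom for k, c in ct.counts.items()}
    return freqs, ct.wt_count / denom
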
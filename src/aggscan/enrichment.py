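"""Relative-enrichment scoring and the substitution x position matrix.

For a variant *i*, relative enrichment compares its frequency shift between a
selected pool and the input library to the wild type's shift::

    RE_i = log10(f_i_sel / f_i_inlib) - log10(f_WT_sel / f_WT_inlib)

RE > 0 means the variant is over-represented after selection relative to wild
type (higher aggregation propensity in the FRET-positive comparison); RE < 0
means depletion.  Variants not observed deeply enough in the input library
are masked rather than imputed.

Stop codons provide an internal control: a stop before the C-terminal
fluorophore tag makes FRET physically impossible, so any apparent presence of
stop variants in the FRET-positive gate reflects sorter error, which is what
the stop-codon false-discovery estimates quantify.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from math import log10
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .counts import CountTable, frequencies
from .library import STOP, VariantDatabase, VariantKey, parse_variant, variant_to_string

#: Fixed display row order of the 20 substitutions (top to bottom).
DISPLAY_ORDER = "RHKDESTNQCGPAVILMFYW"


class Status(str, Enum):
    SCORED = "scored"
    MISSING_LOW_COUNT = "missing_low_count"
    MISSING_ABSENT = "missing_absent"


@dataclass
class EnrichmentRecord:
    key: VariantKey
    f_sel: float
    f_inlib: float
    re: float | None
    status: Status
    input_count: int = 0
    sel_count: int = 0


def relative_enrichment(
    f_sel: float, f_inlib: float, f_wt_sel: float, f_wt_inlib: float
) -> float:
    """Closed-form RE (log10).  All four frequencies must be positive."""
    for name, f in (
        ("f_sel", f_sel), ("f_inlib", f_inlib),
        ("f_wt_sel", f_wt_sel), ("f_wt_inlib", f_wt_inlib),
    ):
        if f <= 0:
            raise ValueError(f"{name} must be > 0 (got {f}); zero counts are masked, not scored")
    return log10(f_sel / f_inlib) - log10(f_wt_sel / f_wt_inlib)


def score_records(
    sel: CountTable,
    inlib: CountTable,
    db: VariantDatabase,
    min_input_count: int = 10,
    pseudocount: float = 0.0,
) -> list[EnrichmentRecord]:
    """Score every non-WT protein variant in the database.

    Variants with input count below ``min_input_count`` are masked as
    ``missing_low_count``; variants absent from the input library entirely are
    ``missing_absent``.  ``pseudocount`` (off by default) is added to both
    pools' counts for sensitivity analysis only.
    """
    f_sel, f_wt_sel = frequencies(sel)
    f_in, f_wt_in = frequencies(inlib)
    if f_wt_sel <= 0 or f_wt_in <= 0:
        raise ValueError("wild-type reads absent from a pool; RE undefined")
    records: list[EnrichmentRecord] = []
    for key in db.non_wt_keys():
        n_in = inlib.counts.get(key, 0)
        n_sel = sel.counts.get(key, 0)
        if n_in == 0 and pseudocount == 0:
            status = Status.MISSING_ABSENT
            re = None
        elif n_in < min_input_count:
            status = Status.MISSING_LOW_COUNT
            re = None
        elif n_sel == 0 and pseudocount == 0:
            status = Status.MISSING_LOW_COUNT
            re = None
        else:
            fs = (n_sel + pseudocount) / sel.matched
            fi = (n_in + pseudocount) / inlib.matched
            re = relative_enrichment(fs, fi, f_wt_sel, f_wt_in)
            status = Status.SCORED
        records.append(
            EnrichmentRecord(key, f_sel.get(key, 0.0), f_in.get(key, 0.0),
                             re, status, n_in, n_sel)
        )
    return records


def records_to_frame(records: Iterable[EnrichmentRecord], db: VariantDatabase) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "variant": variant_to_string(r.key, db.wt),
            "position": r.key.position,
            "substitution": r.key.substitution,
            "f_sel": r.f_sel,
            "f_inlib": r.f_inlib,
            "input_count": r.input_count,
            "sel_count": r.sel_count,
            "re": np.nan if r.re is None else r.re,
            "status": r.status.value,
        }
        for r in records
    )


class EnrichmentMatrix:
    """20-substitution x position grid of RE values with a missing-data mask.

    Rows follow :data:`DISPLAY_ORDER`; the stop row is held separately (it is
    used for false-discovery estimation, not display).  Cell states: scored
    (finite value), ``wt`` (the wild-type residue's own row), or one of the
    missing states.
    """

    def __init__(self, db: VariantDatabase):
        self.db = db
        self.positions = list(db.positions())
        n = len(self.positions)
        self.values = np.full((len(DISPLAY_ORDER), n), np.nan)
        self.stop_row = np.full(n, np.nan)
        self.state = np.full((len(DISPLAY_ORDER), n), Status.MISSING_ABSENT.value, dtype=object)
        self._col = {p: i for i, p in enumerate(self.positions)}
        for p in self.positions:
            wt_aa = db.wt.aa[p - 1]
            if wt_aa in DISPLAY_ORDER:
                self.state[DISPLAY_ORDER.index(wt_aa), self._col[p]] = "wt"

    def set(self, key: VariantKey, re: float | None, status: Status) -> None:
        col = self._col[key.position]
        if key.substitution == STOP:
            if re is not None:
                self.stop_row[col] = re
            return
        row = DISPLAY_ORDER.index(key.substitution)
        if self.state[row, col] == "wt":
            raise ValueError(f"cell {key} is the wild-type residue")
        if self.state[row, col] == Status.SCORED.value or np.isfinite(self.values[row, col]):
            raise ValueError(f"duplicate record for {key}")
        if re is not None:
            self.values[row, col] = re
            self.state[row, col] = Status.SCORED.value
        else:
            self.state[row, col] = status.value

    def n_missing(self) -> int:
        return int(np.sum((self.state != "wt") & (self.state != Status.SCORED.value)))

    def row(self, substitution: str) -> np.ndarray:
        """One substitution's RE profile across positions (NaN where masked)."""
        if substitution == STOP:
            return self.stop_row.copy()
        if substitution not in DISPLAY_ORDER:
            raise KeyError(f"unknown substitution {substitution!r}")
        return self.values[DISPLAY_ORDER.index(substitution)].copy()

    def to_frame(self) -> pd.DataFrame:
        """Figure-style table: rows in display order, 'NA' missing, 'WT' reference."""
        cells = []
        for i, aa in enumerate(DISPLAY_ORDER):
            row = []
            for j in range(len(self.positions)):
                if self.state[i, j] == "wt":
                    row.append("WT")
                elif self.state[i, j] == Status.SCORED.value:
                    row.append(repr(float(self.values[i, j])))
                else:
                    row.append("NA")
            cells.append(row)
        return pd.DataFrame(cells, index=list(DISPLAY_ORDER), columns=self.positions)

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="substitution")

    @classmethod
    def read_tsv(cls, path, db: VariantDatabase) -> "EnrichmentMatrix":
        df = pd.read_csv(
            path, sep="\t", index_col=0, dtype=str, keep_default_na=False
        )
        m = cls(db)
        for aa in DISPLAY_ORDER:
            i = DISPLAY_ORDER.index(aa)
            for p in m.positions:
                cell = df.loc[aa, str(p)]
                j = m._col[p]
                if cell == "WT":
                    if m.state[i, j] != "wt":
                        raise ValueError(f"unexpected WT cell at {aa}{p}")
                elif cell == "NA":
                    m.state[i, j] = Status.MISSING_LOW_COUNT.value
                else:
                    m.values[i, j] = float(cell)
                    m.state[i, j] = Status.SCORED.value
        return m


def build_matrix(
    records: Iterable[EnrichmentRecord], db: VariantDatabase
) -> EnrichmentMatrix:
    """Arrange scored records into the display matrix (stop row kept aside)."""
    m = EnrichmentMatrix(db)
    for r in records:
        m.set(r.key, r.re, r.status)
    return m


# ---------------------------------------------------------------------------
# Stop-codon false-discovery estimates


def stop_codon_fdr(records: Iterable[EnrichmentRecord]) -> float:
    """Fraction of scored stop variants with RE > 0 in the FRET+ comparison.

    A truncation upstream of the fluorophore cannot FRET, so a stop variant
    that nevertheless appears enriched is a false discovery.
    """
    stops = [r.re for r in records if r.key.substitution == STOP and r.re is not None]
    if not stops:
        raise ValueError("no scored stop variants; cannot estimate FDR")
    return sum(1 for re in stops if re > 0) / len(stops)


def stop_read_enrichment(records: Iterable[EnrichmentRecord]) -> float:
    """Alternative estimate: total stop frequency in the selected pool over
    total stop frequency in the input library (an unlogged enrichment ratio)."""
    f_sel = f_in = 0.0
    seen = False
    for r in records:
        if r.key.substitution == STOP:
            seen = True
            f_sel += r.f_sel
            f_in += r.f_inlib
    if not seen or f_in == 0:
        raise ValueError("no stop variants observed in the input library")
    return f_sel / f_in


def sorter_error_from_stops(
    pos: CountTable,
    neg: CountTable,
    db: VariantDatabase,
    pos_gate_fraction: float,
) -> float:
    """Calibrated sorter-error estimate from stop-codon reads in both gates.

    Stop-carrying cells are FRET-incapable, so the fraction of them sorted
    into the positive gate *is* the sorter error.  Read frequencies in each
    sorted pool estimate per-gate cell composition; weighting by the recorded
    gate occupancy (``pos_gate_fraction`` = fraction of sorted cells in the
    FRET+ gate) converts them back to cell numbers:

        eps_hat = f+_stop * w+ / (f+_stop * w+  +  f-_stop * (1 - w+))
    """
    if not 0 < pos_gate_fraction < 1:
        raise ValueError("pos_gate_fraction must be in (0, 1)")
    fp, _ = frequencies(pos)
    fn, _ = frequencies(neg)
    stop_keys = [k for k in db.non_wt_keys() if k.substitution == STOP]
    f_pos = sum(fp.get(k, 0.0) for k in stop_keys)
    f_neg = sum(fn.get(k, 0.0) for k in stop_keys)
    num = f_pos * pos_gate_fraction
    den = num + f_neg * (1 - pos_gate_fraction)
    if den == 0:
        raise ValueError("no stop-codon reads in either sorted pool")
    return num / den
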
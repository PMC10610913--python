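"""Chemical shift perturbation (CSP) analysis of paired ¹H-¹⁵N peak lists.

Two assigned HSQC peak lists (e.g. wild type and a point mutant) are compared
per residue.  Shift changes are signed differences (reference minus variant);
the combined perturbation down-weights the nitrogen dimension by its larger
shift range::

    CSP = sqrt( ΔδH² + (ΔδN / 5)² )      [ppm]

Residues flagged low-confidence are excluded from the mean CSP.  The
"perturbed region" call is a simple outlier rule: residues with CSP above
mean + k·SD, merged into runs tolerating single-residue gaps at unassigned
positions (prolines have no amide proton and are always absent).
"""

from __future__ import annotations

from dataclasses import dataclass
from math import sqrt

import numpy as np
import pandas as pd

PEAKLIST_COLUMNS = ["residue", "aa", "dH", "dN", "confidence"]
N_SCALE = 5.0   # nitrogen shift-range scaling in the combined CSP


@dataclass
class PeakList:
    """Assigned ¹H-¹⁵N peaks: residue -> (δH, δN) with confidence flags."""

    label: str
    shifts: dict[int, tuple[float, float]]
    confidence: dict[int, str]

    def __post_init__(self) -> None:
        bad = set(self.confidence.values()) - {"high", "low"}
        if bad:
            raise ValueError(f"unknown confidence labels {bad}")

    @classmethod
    def from_tsv(cls, path, label: str | None = None) -> "PeakList":
        df = pd.read_csv(path, sep="\t")
        missing = [c for c in PEAKLIST_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"{path}: missing columns {missing}")
        if df["residue"].duplicated().any():
            raise ValueError(f"{path}: duplicate residue assignments")
        shifts = {
            int(r.residue): (float(r.dH), float(r.dN)) for r in df.itertuples()
        }
        conf = {int(r.residue): str(r.confidence) for r in df.itertuples()}
        return cls(label or str(path), shifts, conf)

    def write_tsv(self, path, aa_of: dict[int, str] | None = None) -> None:
        rows = [
            {
                "residue": r,
                "aa": (aa_of or {}).get(r, "X"),
                "dH": h,
                "dN": n,
                "confidence": self.confidence.get(r, "high"),
            }
            for r, (h, n) in sorted(self.shifts.items())
        ]
        pd.DataFrame(rows, columns=PEAKLIST_COLUMNS).to_csv(path, sep="\t", index=False)


def combined_csp(delta_h: float, delta_n: float) -> float:
    """sqrt(ΔδH² + (ΔδN/5)²), in ppm."""
    return sqrt(delta_h ** 2 + (delta_n / N_SCALE) ** 2)


@dataclass
class CspProfile:
    delta_h: dict[int, float]     # reference minus variant, ppm
    delta_n: dict[int, float]
    csp: dict[int, float]
    mean_csp: float               # over high-confidence residues only
    included: set[int]            # residues entering the mean


def csp(wt: PeakList, mut: PeakList) -> CspProfile:
    """Per-residue shift changes and perturbations between two peak lists.

    Only residues assigned in both lists are compared; a residue is excluded
    from the mean if either list flags it low-confidence.
    """
    common = sorted(set(wt.shifts) & set(mut.shifts))
    if not common:
        raise ValueError(
            f"peak lists {wt.label!r} and {mut.label!r} share no assigned residues"
        )
    dh, dn, c = {}, {}, {}
    included = set()
    for r in common:
        wh, wn = wt.shifts[r]
        mh, mn = mut.shifts[r]
        dh[r] = wh - mh
        dn[r] = wn - mn
        c[r] = combined_csp(dh[r], dn[r])
        if wt.confidence.get(r, "high") == "high" and mut.confidence.get(r, "high") == "high":
            included.add(r)
    mean = float(np.mean([c[r] for r in sorted(included)])) if included else float("nan")
    return CspProfile(dh, dn, c, mean, included)


def profile_to_frame(profile: CspProfile) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "residue": r,
            "delta_h": profile.delta_h[r],
            "delta_n": profile.delta_n[r],
            "csp": profile.csp[r],
            "in_mean": r in profile.included,
        }
        for r in sorted(profile.csp)
    )


def call_perturbed(
    profile: CspProfile, k_sd: float = 1.0, gap: int = 1
) -> list[tuple[int, int]]:
    """Residue intervals with CSP above mean + k_sd * SD.

    Flagged residues are merged into maximal runs; gaps of up to ``gap``
    residues are bridged only where the intervening positions are unassigned
    (absent from the profile), accommodating prolines and missing peaks.
    """
    vals = {r: profile.csp[r] for r in profile.included}
    if len(vals) < 5:
        raise ValueError("need >= 5 included residues to call a perturbed region")
    arr = np.array(list(vals.values()))
    cut = arr.mean() + k_sd * arr.std(ddof=0)
    flagged = sorted(r for r, v in profile.csp.items() if v > cut)
    if not flagged:
        return []
    assigned = set(profile.csp)
    intervals = [[flagged[0], flagged[0]]]
    for r in flagged[1:]:
        prev = intervals[-1][1]
        between = range(prev + 1, r)
        bridgeable = (
            len(between) <= gap and all(p not in assigned for p in between)
        )
        if r == prev + 1 or bridgeable:
            intervals[-1][1] = r
        else:
            intervals.append([r, r])
    return [(a, b) for a, b in intervals]
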
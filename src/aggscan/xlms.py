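"""Cross-linking MS post-filters, replicate consensus, and structure checks.

Identifications from a cross-link search engine are post-filtered on spectral
quality (score, mass error, %TIC, peptide length, fragment support), then
collapsed across technical replicates: only residue pairs observed in every
replicate (5 of 5 by default) enter the consensus map, with the mean
identification count per replicate as the pair's frequency.  Consensus pairs
can then be tested for geometric compatibility against conformers of a
multi-model ensemble (Cα–Cα distance below a cutoff, strict inequality), and
the ensemble itself clustered by superposed-region RMSD with k-medoids.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

XLMS_COLUMNS = [
    "replicate", "pep_a", "pep_b", "res_a", "res_b", "score",
    "mass_error", "tic_pct", "frags_a", "frags_b", "contig_a", "contig_b",
]

# Post-search filter bounds
MIN_SCORE = 30.0            # strict >
MASS_ERROR_RANGE = (-2.2, 3.8)   # ppm, inclusive
MIN_TIC_PCT = 10.0          # strict >
MIN_PEPTIDE_LENGTH = 6      # inclusive
MIN_FRAGS = 4               # inclusive, per peptide ...
MIN_CONTIG = 3              # ... or this many contiguous fragments


def read_xlms_tsv(path) -> pd.DataFrame:
    """Strict reader for the cross-link identification table dialect."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in XLMS_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    return df


def write_xlms_tsv(df: pd.DataFrame, path) -> None:
    df[XLMS_COLUMNS].to_csv(path, sep="\t", index=False)


def filter_ids(ids: pd.DataFrame) -> pd.DataFrame:
    """Apply the post-search quality filters.

    Kept: score > 30, mass error in [-2.2, +3.8] ppm, %TIC > 10, both peptide
    lengths >= 6, and each peptide supported by >= 4 assigned fragment ions or
    >= 3 contiguous ones.  Rows with missing fields are dropped.
    """
    df = ids.dropna(subset=[c for c in XLMS_COLUMNS if c in ids.columns])
    lo, hi = MASS_ERROR_RANGE
    keep = (
        (df["score"] > MIN_SCORE)
        & (df["mass_error"] >= lo)
        & (df["mass_error"] <= hi)
        & (df["tic_pct"] > MIN_TIC_PCT)
        & (df["pep_a"].str.len() >= MIN_PEPTIDE_LENGTH)
        & (df["pep_b"].str.len() >= MIN_PEPTIDE_LENGTH)
        & ((df["frags_a"] >= MIN_FRAGS) | (df["contig_a"] >= MIN_CONTIG))
        & ((df["frags_b"] >= MIN_FRAGS) | (df["contig_b"] >= MIN_CONTIG))
    )
    return df[keep].reset_index(drop=True)


def _pair_counts(df: pd.DataFrame) -> dict[tuple[int, int], int]:
    """Identification counts per unordered residue pair (peptide context ignored)."""
    counts: dict[tuple[int, int], int] = {}
    for a, b in zip(df["res_a"].astype(int), df["res_b"].astype(int)):
        pair = (min(a, b), max(a, b))
        counts[pair] = counts.get(pair, 0) + 1
    return counts


@dataclass
class ConsensusLinkMap:
    """Replicate-consensus residue pairs with mean per-replicate counts."""

    pairs: dict[tuple[int, int], float]
    n_replicates: int
    required: int

    def total_frequency(self) -> float:
        return float(sum(self.pairs.values()))

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"res_a": a, "res_b": b, "mean_count": f}
            for (a, b), f in sorted(self.pairs.items())
        ]
        return pd.DataFrame(rows, columns=["res_a", "res_b", "mean_count"])

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def consensus(
    replicate_tables: list[pd.DataFrame], required: int | None = None
) -> ConsensusLinkMap:
    """Pairs present in >= ``required`` replicates (default: all of them).

    A pair's frequency is the arithmetic mean of its identification count
    over *all* replicates (absences count as zero when required < n).
    """
    n = len(replicate_tables)
    if n == 0:
        raise ValueError("no replicate tables given")
    required = n if required is None else required
    if not 1 <= required <= n:
        raise ValueError(f"required={required} outside 1..{n}")
    per_rep = [_pair_counts(df) for df in replicate_tables]
    all_pairs = set().union(*per_rep)
    pairs: dict[tuple[int, int], float] = {}
    for pair in sorted(all_pairs):
        present = sum(1 for c in per_rep if pair in c)
        if present >= required:
            pairs[pair] = sum(c.get(pair, 0) for c in per_rep) / n
    return ConsensusLinkMap(pairs, n, required)


def region_link_count(
    link_map: ConsensusLinkMap,
    region: tuple[int, int] = (1, 35),
    mode: str = "both",
) -> tuple[float, int]:
    """Total mean frequency and distinct-pair count of links in a region.

    ``mode="both"``: both endpoints inside the region (default);
    ``mode="any"``: at least one endpoint inside.
    """
    lo, hi = region
    if hi < lo:
        raise ValueError(f"empty region {region}")
    if mode not in ("both", "any"):
        raise ValueError("mode must be 'both' or 'any'")
    freq = 0.0
    n = 0
    for (a, b), f in link_map.pairs.items():
        in_a, in_b = lo <= a <= hi, lo <= b <= hi
        if (in_a and in_b) if mode == "both" else (in_a or in_b):
            freq += f
            n += 1
    return freq, n


# ---------------------------------------------------------------------------
# Ensemble geometry


@dataclass
class Ensemble:
    """Cα traces of a multi-model conformational ensemble.

    ``coords`` has shape (n_models, n_residues, 3); residue i is 1-based
    index ``i`` into axis 1 (``coords[:, i-1]``).
    """

    coords: np.ndarray
    name: str = "ensemble"

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (n_models, n_residues, 3)")
        if not np.isfinite(self.coords).all():
            raise ValueError("non-finite coordinates in ensemble")

    @property
    def n_models(self) -> int:
        return self.coords.shape[0]

    @property
    def n_residues(self) -> int:
        return self.coords.shape[1]

    @classmethod
    def from_pdb(cls, path, atom: str = "CA") -> "Ensemble":
        """Read a multi-model (PED-style) PDB, one Cα per residue per model."""
        from Bio.PDB import PDBParser

        parser = PDBParser(QUIET=True)
        structure = parser.get_structure("ens", str(path))
        models = []
        for model in structure:
            xyz = {}
            for chain in model:
                for res in chain:
                    if atom in res:
                        xyz[res.id[1]] = res[atom].coord
            models.append(xyz)
        if not models:
            raise ValueError(f"{path}: no models found")
        residues = sorted(models[0])
        for m in models:
            if sorted(m) != residues:
                raise ValueError(f"{path}: models disagree on residue numbering")
        if residues != list(range(1, len(residues) + 1)):
            raise ValueError(f"{path}: residues must be numbered 1..N")
        coords = np.array([[m[r] for r in residues] for m in models])
        return cls(coords, name=str(path))


def compatibility(
    link_map: ConsensusLinkMap,
    model_coords: np.ndarray,
    cutoff: float = 30.0,
) -> tuple[int, int, dict[tuple[int, int], float]]:
    """Count consensus pairs with Cα–Cα distance strictly below ``cutoff`` Å.

    ``model_coords``: (n_residues, 3) Cα coordinates of one conformer.
    Returns (n_compatible, n_total, per-pair distances).
    """
    xyz = np.asarray(model_coords, dtype=float)
    dists: dict[tuple[int, int], float] = {}
    n_compat = 0
    for a, b in link_map.pairs:
        if not (1 <= a <= xyz.shape[0] and 1 <= b <= xyz.shape[0]):
            raise ValueError(f"linked residue pair ({a},{b}) outside model (n={xyz.shape[0]})")
        d = float(np.linalg.norm(xyz[a - 1] - xyz[b - 1]))
        dists[(a, b)] = d
        if d < cutoff:
            n_compat += 1
    return n_compat, len(dists), dists


def superposed_rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """Least-squares Cα RMSD after optimal rigid superposition (Kabsch)."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    ac = a - a.mean(axis=0)
    bc = b - b.mean(axis=0)
    rot, _ = Rotation.align_vectors(ac, bc)
    diff = ac - rot.apply(bc)
    return float(np.sqrt((diff ** 2).sum() / len(a)))


def _kmedoids(dist: np.ndarray, k: int, seed: int, n_restarts: int = 8) -> np.ndarray:
    """PAM-style k-medoids on a precomputed distance matrix; returns medoid idx."""
    n = dist.shape[0]
    rng = np.random.default_rng(seed)
    best_cost = np.inf
    best = None
    for _ in range(n_restarts):
        medoids = rng.choice(n, size=k, replace=False)
        while True:
            assign = np.argmin(dist[:, medoids], axis=1)
            # re-center each cluster on its in-cluster cost minimizer
            new = medoids.copy()
            for c in range(k):
                members = np.where(assign == c)[0]
                if members.size == 0:
                    continue
                sub = dist[np.ix_(members, members)]
                new[c] = members[np.argmin(sub.sum(axis=1))]
            if np.array_equal(np.sort(new), np.sort(medoids)):
                break
            medoids = new
        cost = dist[np.arange(n), medoids[np.argmin(dist[:, medoids], axis=1)]].sum()
        if cost < best_cost:
            best_cost, best = cost, np.sort(medoids)
    return best


@dataclass
class ClusterResult:
    labels: np.ndarray            # cluster index per model, 0..k-1 by occupancy
    occupancies: np.ndarray       # descending fractions, sum to 1
    medoid_models: np.ndarray     # model index of each cluster's medoid
    region: tuple[int, int]


def cluster_region(
    ensemble: Ensemble,
    region: tuple[int, int] = (1, 35),
    k: int = 4,
    seed: int = 0,
) -> ClusterResult:
    """k-medoids clustering of a residue window across ensemble conformers.

    The pairwise metric is the Kabsch-superposed Cα RMSD over ``region``.
    Clusters are reported in decreasing occupancy order.
    """
    if k > ensemble.n_models:
        raise ValueError(f"k={k} exceeds {ensemble.n_models} models")
    lo, hi = region
    if not (1 <= lo <= hi <= ensemble.n_residues):
        raise ValueError(f"region {region} outside 1..{ensemble.n_residues}")
    sub = ensemble.coords[:, lo - 1: hi, :]
    n = ensemble.n_models
    dist = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        dist[i, j] = dist[j, i] = superposed_rmsd(sub[i], sub[j])
    medoids = _kmedoids(dist, k, seed)
    raw = np.argmin(dist[:, medoids], axis=1)
    occ = np.bincount(raw, minlength=k) / n
    order = np.argsort(-occ, kind="stable")
    relabel = np.empty(k, dtype=int)
    relabel[order] = np.arange(k)
    return ClusterResult(
        labels=relabel[raw],
        occupancies=occ[order],
        medoid_models=medoids[order],
        region=region,
    )
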
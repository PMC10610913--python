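"""Synthetic data generation for every pipeline input, with truth tables.

No raw sequencing, MS, or NMR data accompany the study design this pipeline
implements, so each stage ships a seeded generator that emulates its input:

* ``simulate_screen`` — a one-variant-per-cell sort-seq screen.  Each cell
  carries one codon variant; its probability of landing in the FRET-positive
  gate follows a logistic link ``p = expit(alpha + beta * s)`` on a
  ground-truth propensity ``s`` (wild type 0, designated core substitutions
  strongly negative, enhancers positive).  Stop-codon variants truncate the
  protein before the fluorophore and are FRET-incapable (p = 0) — their only
  route into the positive gate is the sorter error ``epsilon``, which flips
  any cell's gate with that probability.  Reads are drawn multinomially per
  pool and corrupted with a uniform per-base substitution error.
* ``simulate_xlms`` — replicate cross-link tables with planted true pairs
  (always present, passing all quality filters) and decoys that either fail a
  filter or drop out of at least one replicate.
* ``simulate_ensemble`` — a multi-model Cα ensemble built from self-avoiding
  random-walk conformers (3.8 Å spacing) replicated at planted occupancies
  with Gaussian coordinate noise.
* ``simulate_peaklists`` — paired HSQC peak lists with localized shift
  offsets in a designated region over a small global jitter.

Every generator is bit-deterministic for a fixed seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .asyn import ASYN_AA, asyn_reference
from .counts import DEFAULT_ANCHOR3, DEFAULT_ANCHOR5
from .library import STOP, CodingSequence, VariantDatabase, enumerate_nns, variant_to_string
from .nmr import PeakList
from .xlms import XLMS_COLUMNS, Ensemble

# Designated inhibitory-core residues of the default screen: contiguous
# aggregation-core windows of aSyn (pre-NAC and NAC segments).
DEFAULT_CORE_RESIDUES = frozenset(
    set(range(36, 43)) | set(range(46, 57)) | set(range(65, 79)) | set(range(88, 96))
)
#: Residues whose substitution enhances seeding in the default truth model.
DEFAULT_ENHANCER_RESIDUES = frozenset({13, 61})

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_BASE_INDEX = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _BASE_INDEX[_b] = _i


@dataclass(frozen=True)
class ScreenSimConfig:
    """Study conditions of the simulated screen (defaults are the conditions
    used throughout the test suite and acceptance run)."""

    mutable_range: tuple[int, int] = (2, 140)
    core_residues: frozenset[int] = DEFAULT_CORE_RESIDUES
    enhancer_residues: frozenset[int] = DEFAULT_ENHANCER_RESIDUES
    s_core: float = -4.0
    s_enhancer: float = 1.5
    baseline_p: float = 0.3          # wild-type FRET+ probability
    beta: float = 1.0                # logistic slope on the propensity score
    sorter_error: float = 0.036      # probability of landing in the wrong gate
    n_cells: int = 200_000
    reads_per_pool: int = 200_000
    per_base_error: float = 1e-3
    dirichlet_concentration: float = 50.0
    seed: int = 0

    def config_hash(self) -> str:
        payload = json.dumps(
            dataclasses.asdict(self), sort_keys=True, default=sorted
        ).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


@dataclass
class ScreenSim:
    """Simulator output: file paths, per-allele truth, and gate bookkeeping."""

    config: ScreenSimConfig
    db: VariantDatabase
    truth: pd.DataFrame            # one row per codon variant
    pos_gate_fraction: float
    fastq_paths: dict[str, Path]
    manifest_path: Path

    def protein_truth(self) -> pd.DataFrame:
        """Truth collapsed to protein variants (stop/synonymous included)."""
        g = self.truth.groupby("variant", sort=True)
        out = g.agg(
            position=("position", "first"),
            substitution=("substitution", "first"),
            true_class=("true_class", "first"),
            s=("s", "first"),
            p=("p", "first"),
            cells=("cells", "sum"),
            pos_cells=("pos_cells", "sum"),
            neg_cells=("neg_cells", "sum"),
            reads_input=("reads_input", "sum"),
            reads_pos=("reads_pos", "sum"),
            reads_neg=("reads_neg", "sum"),
        ).reset_index()
        return out


def _variant_truth_class(position: int, product: str, wt_aa: str, cfg: ScreenSimConfig) -> str:
    if product == STOP:
        return "stop"
    if product == wt_aa:
        return "wt_synonymous"
    if position in cfg.core_residues:
        return "inhibitory"
    if position in cfg.enhancer_residues:
        return "enhancer"
    return "neutral"


_CLASS_S = {"wt_synonymous": 0.0, "neutral": 0.0}


def _write_fastq(
    path: Path,
    gene_idx_matrix: np.ndarray,
    allele_idx: np.ndarray,
    rng: np.random.Generator,
    per_base_error: float,
    pool: str,
) -> None:
    """Emit reads (anchor5 + gene + anchor3) with per-base substitution errors.

    ``gene_idx_matrix``: (n_alleles, L) base indices 0..3.  Error positions
    are drawn with replacement within a read; at the default error rate the
    chance of a duplicated position is negligible.
    """
    order = rng.permutation(len(allele_idx))
    reads = gene_idx_matrix[allele_idx[order]]
    n_reads, L = reads.shape
    n_err = rng.binomial(L, per_base_error, size=n_reads)
    rows = np.repeat(np.nonzero(n_err)[0], n_err[n_err > 0])
    if rows.size:
        cols = rng.integers(0, L, size=rows.size)
        shift = rng.integers(1, 4, size=rows.size).astype(np.uint8)
        reads[rows, cols] = (reads[rows, cols] + shift) % 4
    ascii_reads = _BASES[reads]
    a5 = DEFAULT_ANCHOR5.encode()
    a3 = DEFAULT_ANCHOR3.encode()
    qual = b"I" * (len(a5) + L + len(a3))
    with open(path, "wb") as fh:
        for i in range(n_reads):
            fh.write(b"@%s_%d\n" % (pool.encode(), i))
            fh.write(a5 + ascii_reads[i].tobytes() + a3 + b"\n+\n" + qual + b"\n")


def simulate_screen(
    cfg: ScreenSimConfig = ScreenSimConfig(),
    out_dir: str | Path = "screen_sim",
    wt: CodingSequence | None = None,
) -> ScreenSim:
    """Generate input / FRET+ / FRET− FASTQ pools with a full truth table."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seed)
    wt = wt or asyn_reference()
    db = enumerate_nns(wt, cfg.mutable_range)
    alleles = db.codon_variants
    n = len(alleles)
    if cfg.n_cells < n:
        import warnings

        warnings.warn(f"n_cells={cfg.n_cells} < {n} alleles; dropout expected")

    alpha = float(logit(cfg.baseline_p))
    s = np.empty(n)
    p = np.empty(n)
    classes = []
    for i, cv in enumerate(alleles):
        cls = _variant_truth_class(cv.position, cv.product, wt.aa[cv.position - 1], cfg)
        classes.append(cls)
        if cls == "stop":
            s[i] = -np.inf
            p[i] = 0.0
        else:
            s[i] = {"inhibitory": cfg.s_core, "enhancer": cfg.s_enhancer}.get(cls, 0.0)
            p[i] = expit(alpha + cfg.beta * s[i])

    freqs = rng.dirichlet(np.full(n, cfg.dirichlet_concentration))
    cells = rng.multinomial(cfg.n_cells, freqs)
    eps = cfg.sorter_error
    q = p * (1 - eps) + (1 - p) * eps
    pos_cells = rng.binomial(cells, q)
    neg_cells = cells - pos_cells
    pos_gate_fraction = pos_cells.sum() / cfg.n_cells

    def pool_reads(weights: np.ndarray) -> np.ndarray:
        tot = weights.sum()
        if tot == 0:
            return np.zeros(n, dtype=int)
        return rng.multinomial(cfg.reads_per_pool, weights / tot)

    reads_input = pool_reads(cells.astype(float))
    reads_pos = pool_reads(pos_cells.astype(float))
    reads_neg = pool_reads(neg_cells.astype(float))

    L = len(wt.nt)
    gene_idx = np.empty((n, L), dtype=np.uint8)
    for i, cv in enumerate(alleles):
        gene_idx[i] = _BASE_INDEX[np.frombuffer(cv.gene_nt.encode(), dtype=np.uint8)]

    fastq_paths = {}
    for pool, reads in (
        ("input_library", reads_input),
        ("fret_pos", reads_pos),
        ("fret_neg", reads_neg),
    ):
        path = out / f"{pool}.fastq"
        idx = np.repeat(np.arange(n), reads)
        _write_fastq(path, gene_idx, idx, rng, cfg.per_base_error, pool)
        fastq_paths[pool] = path

    truth = pd.DataFrame(
        {
            "variant": [variant_to_string(db.gene_to_key[cv.gene_nt], wt) for cv in alleles],
            "position": [cv.position for cv in alleles],
            "codon": [cv.codon for cv in alleles],
            "substitution": [cv.product for cv in alleles],
            "true_class": classes,
            "s": s,
            "p": p,
            "freq": freqs,
            "cells": cells,
            "pos_cells": pos_cells,
            "neg_cells": neg_cells,
            "reads_input": reads_input,
            "reads_pos": reads_pos,
            "reads_neg": reads_neg,
        }
    )
    truth_path = out / "truth.tsv"
    truth.to_csv(truth_path, sep="\t", index=False)

    manifest = {
        "config": dataclasses.asdict(cfg) | {
            "core_residues": sorted(cfg.core_residues),
            "enhancer_residues": sorted(cfg.enhancer_residues),
        },
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "wt_name": wt.name,
        "pos_gate_fraction": pos_gate_fraction,
        "outputs": {k: str(v) for k, v in fastq_paths.items()} | {"truth": str(truth_path)},
    }
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return ScreenSim(cfg, db, truth, pos_gate_fraction, fastq_paths, manifest_path)


# ---------------------------------------------------------------------------
# XL-MS replicate tables

DEFAULT_TRUE_PAIRS = (
    (3, 17), (5, 21), (6, 12), (8, 25), (10, 30), (11, 19), (15, 32),
    (16, 27), (20, 34), (22, 29), (24, 33),
    (13, 45), (23, 83), (28, 60), (46, 97),
)

_AA20 = "ACDEFGHIKLMNPQRSTVWY"


def _random_peptide(rng: np.random.Generator, lo: int = 6, hi: int = 12) -> str:
    k = int(rng.integers(lo, hi + 1))
    return "".join(_AA20[i] for i in rng.integers(0, 20, size=k))


def _passing_row(rng, rep, pair) -> dict:
    return {
        "replicate": rep,
        "pep_a": _random_peptide(rng),
        "pep_b": _random_peptide(rng),
        "res_a": pair[0],
        "res_b": pair[1],
        "score": float(rng.uniform(31, 55)),
        "mass_error": float(rng.uniform(-2.0, 3.5)),
        "tic_pct": float(rng.uniform(12, 45)),
        "frags_a": int(rng.integers(4, 9)),
        "frags_b": int(rng.integers(4, 9)),
        "contig_a": int(rng.integers(2, 5)),
        "contig_b": int(rng.integers(2, 5)),
    }


_FAIL_MODES = ("score", "mass_error", "tic", "pep_len", "frags")


def _failing_row(rng, rep, pair, mode: str) -> dict:
    row = _passing_row(rng, rep, pair)
    if mode == "score":
        row["score"] = float(rng.choice([30.0, rng.uniform(5, 30)]))
    elif mode == "mass_error":
        row["mass_error"] = float(rng.choice([-2.3, 3.9, rng.uniform(5, 12)]))
    elif mode == "tic":
        row["tic_pct"] = float(rng.choice([10.0, rng.uniform(0, 10)]))
    elif mode == "pep_len":
        row["pep_a"] = _random_peptide(rng, 3, 5)
    elif mode == "frags":
        row["frags_a"], row["contig_a"] = 3, 2
    return row


def simulate_xlms(
    true_pairs=DEFAULT_TRUE_PAIRS,
    n_decoys: int = 50,
    n_replicates: int = 5,
    seed: int = 0,
    protein_length: int = 140,
    out_dir: str | Path | None = None,
) -> tuple[list[pd.DataFrame], dict[tuple[int, int], float]]:
    """Replicate cross-link tables with planted true pairs and decoys.

    True pairs appear in every replicate with filter-passing fields; each
    decoy pair either fails a quality filter in all its appearances or passes
    but is absent from at least one replicate.  Returns the tables and the
    truth map pair -> mean identification count per replicate.
    """
    rng = np.random.default_rng(seed)
    true_pairs = [tuple(sorted(p)) for p in true_pairs]
    for a, b in true_pairs:
        if not (1 <= a <= protein_length and 1 <= b <= protein_length):
            raise ValueError(f"true pair ({a},{b}) outside protein 1..{protein_length}")
    used = set(true_pairs)
    decoys = []
    while len(decoys) < n_decoys:
        a, b = sorted(rng.integers(1, protein_length + 1, size=2))
        if a == b or (a, b) in used:
            continue
        used.add((a, b))
        decoys.append((a, b))

    tables: list[list[dict]] = [[] for _ in range(n_replicates)]
    truth: dict[tuple[int, int], float] = {}
    for pair in true_pairs:
        lam = rng.uniform(1.5, 5.0)
        counts = np.maximum(1, rng.poisson(lam, size=n_replicates))
        truth[pair] = counts.sum() / n_replicates
        for rep in range(n_replicates):
            for _ in range(counts[rep]):
                tables[rep].append(_passing_row(rng, rep + 1, pair))

    for i, pair in enumerate(decoys):
        if i % 2 == 0:  # filter-failing decoy, may appear in every replicate
            mode = _FAIL_MODES[int(rng.integers(len(_FAIL_MODES)))]
            for rep in range(n_replicates):
                tables[rep].append(_failing_row(rng, rep + 1, pair, mode))
        else:  # clean-looking decoy that drops out of >= 1 replicate
            k = int(rng.integers(0, n_replicates))
            reps = rng.choice(n_replicates, size=k, replace=False)
            for rep in reps:
                tables[rep].append(_passing_row(rng, rep + 1, pair))

    frames = [pd.DataFrame(t, columns=XLMS_COLUMNS) for t in tables]
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for i, df in enumerate(frames, 1):
            df.to_csv(out / f"replicate_{i}.tsv", sep="\t", index=False)
    return frames, truth


# ---------------------------------------------------------------------------
# Conformational ensembles


def make_extended_chain(n_residues: int, spacing: float = 3.8) -> np.ndarray:
    """Fully extended straight Cα trace: residue i at x = (i-1) * spacing."""
    xyz = np.zeros((n_residues, 3))
    xyz[:, 0] = np.arange(n_residues) * spacing
    return xyz


def _self_avoiding_walk(
    rng: np.random.Generator, n_residues: int, spacing: float = 3.8,
    min_dist: float = 3.0, max_tries: int = 200,
) -> np.ndarray:
    xyz = np.zeros((n_residues, 3))
    for i in range(1, n_residues):
        for _ in range(max_tries):
            v = rng.normal(size=3)
            v *= spacing / np.linalg.norm(v)
            cand = xyz[i - 1] + v
            if i < 2 or np.min(np.linalg.norm(xyz[: i - 1] - cand, axis=1)) >= min_dist:
                break
        xyz[i] = cand
    return xyz


def simulate_ensemble(
    n_models: int = 100,
    occupancies=(0.4, 0.3, 0.2, 0.1),
    noise: float = 0.2,
    n_residues: int = 140,
    seed: int = 0,
    out_path: str | Path | None = None,
) -> tuple[Ensemble, np.ndarray]:
    """Multi-model ensemble with planted conformer clusters.

    Base conformers are independent self-avoiding random walks; each is
    replicated to its occupancy share (largest-remainder rounding) with
    isotropic Gaussian coordinate noise of SD ``noise`` Å.  Returns the
    ensemble and the true cluster label per model.
    """
    occ = np.asarray(occupancies, dtype=float)
    if abs(occ.sum() - 1) > 1e-9:
        raise ValueError("occupancies must sum to 1")
    rng = np.random.default_rng(seed)
    base = [_self_avoiding_walk(rng, n_residues) for _ in occ]
    raw = occ * n_models
    counts = np.floor(raw).astype(int)
    for i in np.argsort(-(raw - counts))[: n_models - counts.sum()]:
        counts[i] += 1
    coords = []
    labels = []
    for c, (k, b) in zip(counts, enumerate(base)):
        for _ in range(c):
            coords.append(b + rng.normal(scale=noise, size=b.shape) if noise > 0 else b.copy())
            labels.append(k)
    order = rng.permutation(n_models)
    ensemble = Ensemble(np.asarray(coords)[order], name="synthetic_ensemble")
    labels = np.asarray(labels)[order]
    if out_path is not None:
        write_ensemble_pdb(ensemble, out_path)
    return ensemble, labels


def write_ensemble_pdb(ensemble: Ensemble, path: str | Path) -> None:
    """Write a multi-model Cα-trace PDB (poly-alanine, chain A)."""
    import gemmi

    st = gemmi.Structure()
    st.name = ensemble.name[:20]
    for m, model_xyz in enumerate(ensemble.coords, 1):
        model = gemmi.Model(m)
        chain = gemmi.Chain("A")
        for r, xyz in enumerate(model_xyz, 1):
            res = gemmi.Residue()
            res.name = "ALA"
            res.seqid = gemmi.SeqId(r, " ")
            atom = gemmi.Atom()
            atom.name = "CA"
            atom.element = gemmi.Element("C")
            atom.pos = gemmi.Position(*map(float, xyz))
            res.add_atom(atom)
            chain.add_residue(res)
        model.add_chain(chain)
        st.add_model(model)
    st.write_pdb(str(path))


# ---------------------------------------------------------------------------
# NMR peak lists


def simulate_peaklists(
    aa: str = ASYN_AA,
    perturbed_region: tuple[int, int] = (4, 23),
    magnitude: float = 0.05,
    jitter: float = 0.002,
    n_low_confidence: int = 12,
    seed: int = 0,
) -> tuple[PeakList, PeakList, dict]:
    """Paired peak lists with localized shift changes in ``perturbed_region``.

    Wild-type amide shifts are drawn from typical disordered-protein ranges
    (δH 7.8–8.6, δN 108–130 ppm); the variant list subtracts per-residue
    offsets of scale ``magnitude`` (proton dimension; nitrogen scaled 5x)
    inside the region, plus a global jitter everywhere.  Prolines are absent
    from both lists.  Low-confidence flags are assigned outside the region.
    """
    lo, hi = perturbed_region
    if not (1 <= lo <= hi <= len(aa)):
        raise ValueError(f"region {perturbed_region} outside protein 1..{len(aa)}")
    rng = np.random.default_rng(seed)
    residues = [i for i in range(1, len(aa) + 1) if aa[i - 1] != "P"]
    wt_shifts = {
        r: (float(rng.uniform(7.8, 8.6)), float(rng.uniform(108, 130))) for r in residues
    }
    mut_shifts = {}
    for r in residues:
        h, n = wt_shifts[r]
        dh = float(rng.normal(scale=jitter))
        dn = float(rng.normal(scale=5 * jitter))
        if lo <= r <= hi:
            sign = rng.choice([-1.0, 1.0])
            dh += sign * magnitude * float(rng.uniform(0.8, 1.2))
            dn += rng.choice([-1.0, 1.0]) * 5 * magnitude * float(rng.uniform(0.8, 1.2))
        mut_shifts[r] = (h - dh, n - dn)
    outside = [r for r in residues if not lo <= r <= hi]
    low = set(
        rng.choice(outside, size=min(n_low_confidence, len(outside)), replace=False).tolist()
    )
    conf = {r: ("low" if r in low else "high") for r in residues}
    aa_of = {r: aa[r - 1] for r in residues}
    wt = PeakList("wt", wt_shifts, dict(conf))
    mut = PeakList("mutant", mut_shifts, dict(conf))
    truth = {"perturbed_region": perturbed_region, "magnitude": magnitude,
             "low_confidence": sorted(low), "aa_of": aa_of}
    return wt, mut, truth
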
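# aggscan

Analysis pipeline for **sort-seq saturation-mutagenesis screens of protein
aggregation**, built around the α-synuclein (aSyn, UniProt P37840) FRET
biosensor design: a library of single-point variants is expressed one per
cell, cells are seeded with fibrils, sorted into FRET-positive
(aggregate-containing) and FRET-negative pools, and each pool is deeply
sequenced.  `aggscan` takes the merged reads and turns them into per-variant
aggregation phenotypes, residue-level domain calls, and companion structural
readouts (cross-linking MS consensus maps, NMR chemical shift perturbations).

It is aimed at groups running deep mutational scanning of amyloidogenic
proteins who need a tested, deterministic reference implementation of the
scoring and classification stages, together with a synthetic-data generator
for validating the whole chain against known ground truth.

## What it computes

**Library model.** Every codon of the coding sequence (residues 2–140 by
default; the initiator Met is fixed) is replaced by the 32 NNS degenerate
codons (N = A/C/G/T, S = G/C), which encode all 20 amino acids plus the TAG
stop.  Collapsed to protein level this yields 20 non-wild-type variants per
position — for aSyn, 139 × 20 = **2780 variants** (19 missense + 1 stop
each).  Reads are matched **exactly** against this database; reads carrying
synonymous codons are pooled into the wild-type count, and everything else
(sequencing errors, multi-mutants) is set aside as unmatched.

**Relative enrichment.** For variant *i* with frequencies *f* among matched
reads,

```
RE_i = log10(f_i_sel / f_i_inlib) − log10(f_WT_sel / f_WT_inlib)
```

RE > 0: over-represented in the FRET-positive pool relative to wild type
(aggregation-prone); RE < 0: depleted (inhibitory).  Variants below a
configurable input-count floor are masked, not imputed.  Scores are arranged
in a fixed-order 20-substitution × position matrix (rows R, H, K, D, E, S, T,
N, Q, C, G, P, A, V, I, L, M, F, Y, W), with wild-type cells and missing
cells flagged distinctly; the stop row is kept separately.

**Stop-codon error control.** A stop before the C-terminal fluorophore makes
FRET physically impossible, so stop variants in the positive gate measure
sorter error.  Three estimates are reported: the fraction of scored stops
with RE > 0, the unlogged stop read-enrichment ratio, and a calibrated
estimator of the sorter error itself (fraction of stop-carrying cells sorted
FRET-positive, reconstructed from both sorted pools and the recorded gate
occupancy).

**Residue classification.** Per-residue medians of the scored missense cells
are split by Otsu's between-class-variance threshold into inhibitory vs
tolerant residues, merged into intervals ("29 to 30" style), and each
residue's 20-substitution profile can be embedded in 2-D by t-SNE
(perplexity 30, Euclidean, exact gradient, seeded).

**XL-MS.** Cross-link identifications are post-filtered (score > 30, mass
error −2.2 to +3.8 ppm, %TIC > 10, peptide length ≥ 6, ≥ 4 fragment ions or
≥ 3 contiguous per peptide), collapsed to unordered residue pairs, and
required in 5 of 5 replicates for the consensus map.  Consensus pairs are
checked against multi-model conformational ensembles (Cα–Cα < 30 Å, strict),
and ensembles clustered by superposed-region RMSD with seeded k-medoids.

**NMR CSP.** Between two assigned ¹H-¹⁵N peak lists,
`CSP = sqrt(ΔδH² + (ΔδN/5)²)` per residue, with low-confidence assignments
excluded from the mean and perturbed regions called at mean + k·SD.

## Worked example

Simulate a screen at reduced depth and run the full pipeline:

```
$ aggscan simulate screen --seed 1 --out demo --reads-per-pool 60000 --n-cells 60000
wrote 3 pools to demo (positive gate fraction 0.2351)

$ aggscan run-all --input-library demo/input_library.fastq \
    --fret-pos demo/fret_pos.fastq --fret-neg demo/fret_neg.fastq \
    --min-input-count 5 --out demo_run
{
  "count": {
    "input_library": {"total": 60000, "matched": 39494, "wt": 1914},
    "fret_pos":      {"total": 60000, "matched": 39467, "wt": 2380},
    "fret_neg":      {"total": 60000, "matched": 39431, "wt": 1777}
  },
  "score": {
    "n_scored": 2129,
    "n_missing_cells": 551,
    "stop_fdr_re_positive": 0.0,
    "stop_read_enrichment": 0.15151789441226146
  },
  "classify": {
    "otsu_threshold": -0.3907838803212781,
    "n_inhibitory": 40,
    "intervals": "36 to 42, 46 to 56, 65 to 78, 88 to 95"
  }
}
```

About a third of reads carry at least one sequencing error over the 420-nt
gene and are excluded by exact matching (matched ≈ 39.5k of 60k at the
default 10⁻³ per-base error).  Of the 2780 database variants, 2129 are scored
at this depth; the Otsu split recovers exactly the four inhibitory-core
windows planted by the simulator (residues 36–42, 46–56, 65–78, 88–95).  The
calibrated sorter-error estimate from stop-codon reads on the same run is
0.0352 against an injected sorter error of 0.036:

```python
import json, aggscan as ag
db  = ag.enumerate_nns(ag.asyn_reference())
pos = ag.count_fastq("demo/fret_pos.fastq", db, "fret_pos")
neg = ag.count_fastq("demo/fret_neg.fastq", db, "fret_neg")
w   = json.load(open("demo/manifest.json"))["pos_gate_fraction"]
ag.sorter_error_from_stops(pos, neg, db, w)   # 0.0352
```

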
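# Methods

## Screen model and scoring

The pipeline models a one-variant-per-cell sort-seq screen: a saturation
library of single-codon variants is expressed in a FRET biosensor line,
seeded, sorted into FRET-positive and FRET-negative pools, and each pool is
amplicon-sequenced.  The analysis assumes (i) merged, full-length amplicon
reads (pair merging happens upstream), (ii) a single substituted codon per
construct, and (iii) that read frequencies among recognized alleles are
proportional to cell frequencies within a pool.

**Exact matching.**  Reads are trimmed to the gene region between two
constant anchor strings (the invariant primer tails; reverse-complement
reads are re-oriented via the anchors) and matched exactly against the
enumerated database.  No error-tolerant rescue is attempted: a one-mismatch
rescue would reassign reads between genuine single-codon neighbours, which
is worse than losing depth.  Synonymous codon variants are pooled into the
wild-type count, because at protein level they are the reference.

**Frequencies and RE.**  Frequencies are computed over matched reads only,
so enrichment ratios are invariant to pool-specific junk rates (adapter
read-through, multi-mutants, error-carrying reads).  The relative enrichment
is the log10 ratio-of-ratios against wild type.  RE is antisymmetric in the
choice of reference and invariant to sequencing depth; both properties are
enforced by tests.

**Missing data.**  Variants with fewer than `min_input_count` input-library
reads (default 10) or zero selected-pool reads are masked rather than
pseudocounted.  The default floor keeps the Poisson contribution to the RE
standard error below ~0.15 log10 units at typical depth
(SD ≈ sqrt(2/n)/ln 10).  A `pseudocount` option exists for sensitivity
analysis only.

**Stop-codon error estimates.**  Truncations upstream of the C-terminal
fluorophore cannot FRET, so stop variants calibrate the sorting error.
Three quantities are reported:

1. fraction of scored stop variants with RE > 0 (`stop_codon_fdr`);
2. the unlogged ratio of total stop frequency in the selected pool to the
   input library (`stop_read_enrichment`);
3. a calibrated sorter-error estimate (`sorter_error_from_stops`): with
   read frequencies f⁺, f⁻ of stop alleles in the two sorted pools and the
   recorded positive-gate occupancy w⁺,

   ε̂ = f⁺w⁺ / (f⁺w⁺ + f⁻w⁻),  with w⁻ = 1 − w⁺.

   Because a stop-carrying cell reaches the positive gate only by sorting
   error, ε̂ is an unbiased estimate of the gate-flip probability.  The
   first two definitions are *not* estimates of ε: the RE > 0 fraction
   collapses to ~0 whenever ε is much smaller than the wild-type gate rate,
   and the read-ratio scales with the mean gate rate of the library.  All
   three are computed so the user can compare conventions.

## Residue classification

Per-residue medians are taken over scored missense cells only (stop row and
masked cells excluded; even counts use the mean of the central pair).  The
median distribution of a selective screen is bimodal, and the split uses
Otsu's method: the sample is histogrammed into B = 256 equal-width bins over
its range and the inter-bin edge maximizing between-class variance is the
threshold, reported as that bin edge.  Classification is inclusive
(median ≤ threshold → inhibitory).  B is configurable; with clearly bimodal
data the resulting classification is insensitive to B (tests check
equivalence with an exhaustive, unbinned cut-point search and with an
independent image-processing implementation).  Constant input is rejected.

The covariance embedding feeds each scored residue's 20-substitution RE
vector (masked cells zero-filled; residues with no scored cells dropped)
into t-SNE with perplexity 30, Euclidean metric, exact gradient, and PCA
initialization.  With N ≈ 139 positions the exact solver is cheap and, with
a fixed seed, bit-reproducible.  Early exaggeration and learning rate are
scikit-learn defaults and are recorded in the result object.

## Cross-linking MS

Identifications are filtered exactly as stated by the post-search criteria:
score strictly above 30, mass error within [−2.2, +3.8] ppm inclusive, %TIC
strictly above 10, both peptides at least 6 residues, and each peptide
supported by ≥ 4 assigned fragment ions or ≥ 3 contiguous ones.  Pairs are
keyed by unordered residue positions; peptide context is discarded because
the consensus map is residue-level.  A pair enters the consensus only if
present in `required` replicates (default: all), with the mean count across
all replicates as its frequency.  Region link counts default to requiring
both endpoints inside the window (an "any endpoint" mode is available,
since "within a region" is ambiguous for a pair); both the summed frequency
and the distinct-pair count are returned.

Geometric compatibility uses Cα–Cα Euclidean distance with a strict < 30 Å
default cutoff.  Cα is the conventional choice for zero-length cross-link
restraints at this resolution.  Ensemble clustering computes pairwise
Kabsch-superposed RMSD over the region of interest and runs PAM k-medoids
(k = 4 default, 8 seeded restarts); medoids make cluster representatives
directly inspectable, and occupancies are reported in decreasing order.
k-medoids is implemented in-package because no installed library provides
it.

## NMR chemical shift perturbation

Shift changes are signed reference-minus-variant differences per dimension;
the combined CSP is sqrt(ΔδH² + (ΔδN/5)²), the standard amide-scaling form.
Residues absent from either list are skipped; residues flagged
low-confidence contribute to the per-residue profile but not to the mean.
The perturbed-region call flags residues with CSP above mean + k·SD
(k = 1 default — the data themselves define "substantial", so the cutoff is
a package choice and k is exposed) and merges runs, bridging gaps of one
residue only where the intervening position is unassigned (prolines, missing
peaks).  Fewer than 5 included residues is rejected as unstable.

## Synthetic data generator

The generator defines the study conditions used by the tests and emulates:

- **Screen** (`simulate_screen`): library frequencies ~ Dirichlet
  (concentration 50, mimicking roughly even per-residue coverage); one
  variant per cell; FRET-positive probability p = expit(α + βs) with
  α = logit(0.3) (baseline seeding rate of a wild-type-like cell),
  β = 1, core substitutions s = −4 (strongly protective when mutated
  region is required for aggregation), enhancers s = +1.5, stops p = 0;
  gate flips with sorter error ε = 0.036; pools of 2 × 10⁵ reads drawn
  multinomially from 2 × 10⁵ cells; uniform per-base substitution error
  10⁻³.  Default core windows: residues 36–42, 46–56, 65–78, 88–95
  (contiguous pre-NAC/NAC segments); enhancers at 13 and 61.  The truth
  table records s, p, class, and exact per-pool cell/read counts, and
  error-free runs recount to it exactly.
- **XL-MS** (`simulate_xlms`): 15 true pairs (11 N-terminal, 4 long-range)
  present in all replicates with filter-passing fields; 50 decoys that
  either fail one filter in every appearance or pass but drop out of at
  least one replicate, so filtering + 5-of-5 consensus recovers the truth
  exactly.
- **Ensemble** (`simulate_ensemble`): self-avoiding random-walk Cα traces at
  3.8 Å spacing, replicated at planted occupancies (largest-remainder
  rounding) with Gaussian coordinate noise (0.2 Å default), shuffled, and
  written as multi-model PDB.
- **Peak lists** (`simulate_peaklists`): wild-type shifts uniform in
  δH 7.8–8.6 / δN 108–130 ppm; variant shifts offset by ~0.05 ppm
  (proton; 5× nitrogen) inside the perturbed region (default residues
  4–23) over 0.002 ppm global jitter; prolines omitted; 12 low-confidence
  residues flagged outside the region.

What the generator does **not** emulate: PCR jackpotting and amplification
bias, quality-score structure and indels (errors are uniform substitutions),
multiple lentiviral integrations per cell, library cloning artifacts
(multi-mutants), chromatographic and charge-state effects on cross-link
detectability, and real spectral overlap in HSQC assignment.  Passing
recovery tests therefore demonstrates correctness of the analysis chain
under a faithful idealization of the screen's sampling structure, not
robustness to every real-data pathology.

## Numerical and design choices

- Codons identical to the wild-type codon are excluded from the enumerated
  library (they would reproduce the wild-type gene string); positions whose
  wild-type codon is itself NNS (the three internal Met of aSyn) therefore
  contribute 31 codon variants instead of 32.  Protein-level counts are
  unaffected.
- The bundled aSyn coding sequence is a synthetic reverse translation
  (third-base A/T codons) of the canonical protein sequence; every
  protein-level quantity is codon-choice independent.
- Log base 10 throughout; a natural-log option is deliberately absent since
  it would silently rescale thresholds.
- Otsu ties resolve to the lowest maximizing edge; classification is
  inclusive at the threshold.
- Kabsch superposition via SVD (scipy rotation alignment) after centroid
  removal; RMSD is symmetric and zero iff the regions differ by a rigid
  motion.
- k-medoids restarts and initial medoids derive from a single seeded
  generator; reruns are bit-identical.
- Problem sizes in the test suite: the default-condition end-to-end screen
  runs once at full configured depth (3 × 2 × 10⁵ reads); other tests use
  reduced depths (2–6 × 10⁴ reads) chosen to keep their assertions well
  inside sampling tolerances.

## Known limitations

- Exact matching discards ~1 − (1 − e)^L of reads to sequencing error
  (~34% at e = 10⁻³, L = 420); this costs depth but no bias.
- No replicate-aware variance model for RE (single point estimate per
  variant); shrinkage estimators are out of scope.
- The enrichment matrix display format carries only the 20 missense rows;
  stop-row values live in the records table.
- Ensemble clustering assumes models share residue numbering 1..N and reads
  Cα atoms only.
- The perturbed-region call is a z-score heuristic; for marginal
  perturbations the k_sd sensitivity should be inspected.
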
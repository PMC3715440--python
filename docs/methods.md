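# Methods

## The system

ICEBs1 is a site-specific integrative and conjugative element (ICE) of
*Bacillus subtilis*. It normally resides at a single primary attachment
site, *attB*, inside the tRNA gene *trnS-leu2*. The site is a 17 bp
stem-loop: a 5 bp inverted repeat (the arms) flanking a 7 bp spacer. The
spacer is the crossover region — integrase-mediated strand exchange occurs
there during both integration and excision. When the primary site is
deleted, the element integrates into secondary chromosomal sites that
resemble the stem-loop to varying degrees (2–12 mismatches out of 17).
Integration into a secondary site is costly twice over: excision is reduced
or abolished, and spontaneous activation of element gene expression in a
cell whose element cannot excise triggers rolling-circle replication in the
chromosome and kills the cell. `iceatt` implements the quantitative
analyses built on these observations.

## Attachment-site model (`iceatt.attsite`)

A core is decomposed by the fixed 5+7+5 partition; the perfect-stem check
(right arm equals reverse complement of the left arm) is informational,
never an error, because observed secondary sites violate it freely.
Similarity to a reference core is the Hamming distance over the 17
positions — a metric, property-tested for symmetry, identity, and the
triangle inequality.

**Heteroduplex bookkeeping.** Integration into a target site forms two
junctions: attL (chromosomal left arm + element right arm) and attR
(element left arm + chromosomal right arm). A spacer difference between
target and element initially forms a mismatched duplex that host
replication resolves, leaving the two junctions with different spacers.
Which junction inherits which spacer is not observable from the junction
sequences alone, so it is a configuration switch (`spacer_assignment`);
the default gives attL the chromosomal spacer. All downstream logic —
`predict_heteroduplex`, the excision flag — depends only on spacer
*inequality*, so the convention is isolated. Under the default convention
`excise(integrate(t, e))` returns the target site and the element site
exactly, a round-trip identity the tests exercise.

**Catalog tallying.** Distinct sites are keyed by (locus, orientation):
the same locus hit in opposite orientations presents two different
sequences and counts twice (the observed *yqhG* pair mandates this).
Percentages are rounded to the nearest integer, ties away from zero, so
11/27 reports as 41%. Raw occurrence totals are conserved exactly.

**Genome scanning** is a convenience extension (the catalog itself was
obtained experimentally): every 17-mer on both strands within a Hamming
threshold of the reference, vectorized over sliding windows. Windows
containing non-ACGT characters are skipped rather than raising, since
draft genomes contain N runs. Coordinates are 0-based half-open on the
reference strand (BED convention); a minus-strand hit's core is the
reverse complement of the reference-strand slice. Correctness is checked
against a naive pure-Python sliding-window oracle.

## Sequence logos (`iceatt.motif`)

Site contexts are aligned, ungapped 26 bp windows (the 17 bp core plus
flanks; the flank split is carried explicitly in `SiteContext.core_offset`
because it is a property of window extraction). Per position,
H_i = −Σ f_ib log2 f_ib and R_i = 2 − H_i bits. The small-sample
correction e(n) = 3/(2 ln2 · n) is available behind a flag and off by
default: at the ~15-sequence depth typical here it is visually material
(~0.14 bits), both conventions are in common use among logo tools, and the
uncorrected form keeps R_i = 2 exactly for a conserved column. Letter
heights are f_ib · R_i. Consensus calling takes the per-column argmax,
uppercase at or above a frequency threshold, ties broken alphabetically.

## qPCR quantification (`iceatt.qpcr`)

The chain is standard reference-gene-normalized relative quantification:

- Standard curve: ordinary least squares of Cq on log10(copies); at least
  3 points spanning ≥ 2 logs. Efficiency = 10^(−1/slope) − 1, flagged when
  outside 0.5–1.5.
- Copies = 10^((Cq − intercept)/slope) per replicate, combined by
  geometric mean — equivalent to averaging Cq, where the noise is additive
  under the log-linear model. Dispersion is reported as the geometric SD
  across replicates; no further interval machinery (the underlying assays
  report SDs over biological replicates). Technical replicates are
  combined before normalization; a single-plate design is assumed.
- Excision frequency: (empty site/reference)_sample ÷ the same ratio in a
  cured strain, which by construction represents 100% excision and
  self-normalizes to 1. Circle:empty ratios are normalized to wild type
  the same way. Integration at a secondary site in a transconjugant pool
  is quantified against a control strain carrying that insertion in every
  chromosome. All three ratios are scale-invariant in the copy numbers.
- Limit of detection: a measurement whose mean Cq exceeds the top of the
  dilution series by more than `lod_cycles` (default 2) is flagged below
  LOD; ratios built on such a numerator report a bound, never a number.
- `mating_excision_fold` divides relative excision by relative mating
  efficiency (each as a fraction of the primary-site strain): ~1 means the
  excised circle is stable; 75 for the heteroduplex-forming class means
  the circle is lost between excision and transfer.

## Competition model (`iceatt.popdyn`)

Cells with the element at a secondary site lose a fraction D per
generation (spontaneous activation times death of activated cells);
primary-site cells pay nothing. With discrete doubling generations,
P(G) = P0·2^G·(1−D)^G, the primary:secondary ratio is R = 1/(1−D)^G, and
G(R) = log(1/R)/log(1−D). At R = 10: D = 10⁻⁴ gives G ≈ 23,025 (~23,000
at two significant figures, the headline rounding convention; raw values
always available) and D = 10⁻³ gives G ≈ 2,301 (~2,300). The death
fraction optionally decomposes as D = a·(1−v) — activation frequency
times the dying fraction of activated cells — so measured partial
viabilities can soften the all-activated-cells-die default (v = 0).

The stochastic simulator is the finite-population counterpart: per
generation both subpopulations double, each secondary-site cell dies
independently with probability D (binomial draw; death applied after
doubling — the closed form's algebra is order-independent, the simulator
fixes this order), and when the total exceeds a population cap the
population is down-sampled by a neutral binomial bottleneck. The cap is
pure bookkeeping to keep exponential growth at desk scale; it adds drift
but no bias in expectation, which the stochastic-deterministic agreement
test verifies (mean log ratio within 3 standard errors of −G·log(1−D)).
Replicate r draws from seed + r; identical seeds are bit-identical.

## Synthetic data (`iceatt.synth`)

Generators are pure functions of (spec, seed).

- **Genomes**: i.i.d. background at a configurable GC fraction (default
  0.435, a *B. subtilis*-like composition), with cores planted at exact
  mismatch counts. Mutated positions are drawn uniformly without
  replacement; spacer positions are allowed only for sites flagged
  spacer-divergent, and a divergent site is forced to carry at least one
  spacer mismatch, so heteroduplex truth labels are exact. Note >10
  mismatches cannot fit in the 10 arm positions, so such sites are
  necessarily divergent. After planting, accidental exact copies of the
  reference core are destroyed by point substitution, so 0-mismatch scans
  find planted sites only. The i.i.d. background has no higher-order
  structure, which limits what the scan false-positive rate says about
  real chromosomes.
- **qPCR panels**: Cq = slope·log10(true copies) + intercept +
  N(0, σ_Cq), default σ_Cq = 0.15 per technical replicate, triplicates —
  matched to triplicate assays with sub-cycle replicate spread. Recovery
  tests plant relative excision frequencies {1.0, 0.15, 0.06, 10⁻³},
  the observed primary-site, *mmsA*-class, *yrkM*-class, and
  detection-floor values.
- **Transconjugants**: multinomial draws of isolate counts over a site
  probability vector — a desk-scale stand-in for pooling ~10⁸
  transconjugants; proportions are exact and sampling noise is controlled
  by the isolate count, so pooled experiments are emulated at the ratio
  level, not the colony level.

The shipped reference core (`DEFAULT_REFERENCE_CORE`) is a synthetic
stand-in obeying the structural constraints (perfect 5 bp inverted repeat,
7 bp spacer), not the genomic *attB* sequence; real site sequences are
user-supplied inputs.

## Problem sizes and numerical choices

The test and acceptance workloads use: 50 replicates × 2,301 generations
at a 10⁶ population cap for the simulator; 200 synthetic panels per
planted excision level; ~100 random genomes (mostly 0.5–5 kb, up to
100 kb) for scanner-vs-oracle comparison — sizes chosen so the whole suite
runs in seconds while leaving standard errors well inside the tested
bands. Entropy uses the 0·log 0 = 0 convention; frequency rows sum to 1
within 1e−9; the closed-form/ inversion pair round-trips to 1e−9 relative
error. Division-by-zero states (cured copies, control junctions, D = 1
death) raise rather than propagate infinities; D = 0 with R > 1 is
signaled as having no finite solution.

## Known limitations

- The package quantifies and models; it does not predict which secondary
  sites are used in vivo, nor model integrase biochemistry, DNA bending,
  or supercoiling.
- The competition model has no horizontal-transfer benefit term, host
  population structure, or stress-dependent activation dynamics.
- Single-plate qPCR assumption; no amplification-curve processing
  (inputs start at Cq) and no inter-plate calibration.
- Passing recovery tests on i.i.d. backgrounds and log-linear Cq noise
  demonstrates correctness of the estimators, not robustness to real-data
  pathologies (inhibition, plate effects, repeat-rich genomes).
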
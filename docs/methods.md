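# Methods

## Activity estimation model

Quantification is count-based and per-sample. Reads are reduced to
barcodes (adaptor-anchored extraction, substitution tolerance 2 in the
adaptor, strict Q > 30 on the barcode bases, mean by default, per-base
minimum optionally). Barcodes absent from the assignment map are dropped.
An enhancer enters a sample when it is seen with at least `min_bcs`
**distinct** barcodes there — read counts do not substitute for barcode
diversity. The defaults follow library complexity: 5 for tiling-scale
libraries, 10 for accessibility-peak libraries, 20 for the low-complexity
synthetic-combination library.

Counts are summed over each enhancer's barcodes and CPM-normalised with
the denominator restricted to passing enhancers, so CPMs always total 1e6.
Only enhancers quantified in both input and output survive the merge —
there are no pseudocounts anywhere; an enhancer with no usable signal is
absent, not zero. The fold change FC = CPM_cDNA / CPM_plasmid is divided
by the median control FC and log2-transformed, which pins the control
median at exactly 0 and removes the shared multiplicative bias that
per-barcode noise induces on aggregated ratios (see noise model below).

The null is a Gaussian fitted robustly to the control activities:
location = median, scale = 1.4826·MAD (consistent at the Gaussian).
A Huber joint M-estimate and a classic mean/SD fit are available;
the robust default resists the occasional genuinely active "control"
(e.g. a shuffle that recreates a binding site) — with 10% contamination
at +5 the classic SD more than doubles while the robust scale moves by
a few percent. Constant controls are an error, not a fit.

P-values are upper-tail by default: the screen asks for activation, and a
one-sided test preserves power for it. A two-sided mode exists; nothing
downstream depends on the choice except the calls themselves. BH step-up
runs over **all** tested enhancers (controls included, so the adjusted
p-values are comparable across the table); active means adjusted p < 0.05.

Sample QC keeps the coverage rule (< 450 quantified enhancers fails the
sample) and reports — without gating — the fraction of |z| > 3 activities,
a symptom of an over-dispersed or under-covered sample.

## Library design

Tiling emits `floor((L − offset + 1 − 190)/20) + 1` windows of 190 bp per
region: offsets 1 (sublibrary A) and 11 (sublibrary B) interleave to a
10 bp grid; the knockdown-series variant is the same operator with a
120 bp step and a single sublibrary. A tile is emitted only while its last
base stays inside the region.

Motif-mutant tiles destroy, per tile and per motif, **all** occurrences of
that single motif, so each mutant isolates one factor. "Most important
nucleotides" is operationalised as per-position information content
Σ p·log2(p/q) (ties to the leftmost position); the replacement base is the
lowest-probability base at that position that differs from the observed
base — deterministic and maximally score-destroying. Two positions change
for monomeric models, four for dimeric ones. Palindromic double hits
(same window, both strands) are collapsed to the forward hit before
mutation; overlapping occurrences are mutated left to right, skipping hits
whose window was already edited (recorded per tile). The scan threshold
(default 5 bits, configurable) is the only conservation filter.

Shuffled negatives are Altschul–Erickson Eulerian-path shuffles: the
(k−1)-mers are vertices, k-lets edges; random last-exit edges forming an
arborescence into the terminal vertex guarantee a valid Eulerian walk, so
the dinucleotide count table of the output equals the input's **exactly**
(the tested contract; uniformity over valid permutations is the sampling
goal). Candidates with a homopolymer run of 6+ are discarded, survivors
are re-scanned with all design PWMs, and the requested number (800 for the
tiling library, 100 for the knockdown library) is sampled without
replacement, seeded.

The synthetic-combination design places SOX-dimer (ACAAAGACGGCTTTGT) and
MITF (CACGTG) sites on 259 bp neutral backgrounds. Centring convention:
the central motif's central base sits at position 130 (= ⌈259/2⌉);
flanking sites are spaced edge-to-edge (25/50/75 bp). Sites replace
background bases — synthesis length is fixed — and an explicit layout
spec can override the convention when a bespoke geometry is needed.
Full oligos are 15 + 11 (barcode) + 259 + 15 = 300 bp.

## Barcode assignment

Long reads are processed independently (no circular-consensus step);
per-barcode majority voting replaces consensus: the top enhancer keeps a
barcode iff its read share is ≥ 0.75 (dominance) and its read count is
≥ `min_support`. With noisy reads, `min_support=3` additionally removes
the sequencing-error barcode variants that would otherwise accumulate as
singletons. Insert matching is k-mer-seeded edit-distance alignment
(edlib) against the design; instead of a mapper's MAPQ cutoff, the best
hit must beat the runner-up by an ambiguity margin (default 2 edits), so
inserts equally consistent with two overlapping tiles stay unassigned.
Design-identifying barcodes (8/11 bp) are matched exactly — at those
lengths one substitution can cross designs — and random barcodes are
taken verbatim (no error-correction clustering).

## Synthetic data: what it emulates, what it does not

Per-barcode plasmid abundance is LogNormal(0, 1.0) on the natural-log
scale (cloning bottlenecks and amplification jackpots make barcode
abundances heavy-tailed); cDNA propensity multiplies abundance by
2^(t_e + ε_b) with ε_b ~ Normal(0, 0.75) on the log2 scale (per-barcode
reporter noise); both samples are Multinomial at fixed depth so column
sums are exact and CPM denominators sharp (a negative-binomial mode is
unnecessary for the calibration claims and not provided). Reads carry
constant Phred 37 (a `phred` argument exercises the Q > 30 gate) and
seeded uniform substitution errors.

Defaults define the study conditions: 50 barcodes/enhancer, 800 shuffled
controls, 2×10⁶ reads per sample. Under them the aggregated estimator
achieves MAE ≈ 0.15 log2 units and the BH calls keep the realized FDR
under the nominal level with sensitivity ≈ 1 at an effect of 2.

Passing these benchmarks shows the estimator and null machinery are
correct and calibrated **under the stated noise model**. Real data add
what the simulator deliberately omits: PCR duplication structure,
GC-dependent amplification bias, indel-dominant long-read errors,
cross-sample dispersion, and genuinely active shuffles. The robust null
and the barcode-diversity filter are the defences aimed at those, but the
benchmarks here do not quantify them.

## Numerical choices and degeneracies

- Scanning skips windows containing N rather than scoring them against
  background; sequences shorter than the motif return empty, not errors.
- Zero-probability PWM cells (pseudocount 0) score −inf and can never
  clear a finite threshold.
- Median of an even number of controls is the mean of the central pair
  (NumPy convention).
- All user-facing coordinates are 1-based inclusive; BED/bedGraph export
  converts to 0-based half-open at the boundary.
- All stochastic code takes a seed or Generator; identical seeds give
  byte-identical outputs. Problem sizes in the test-suite benchmarks
  (20 calibration seeds, 10 FDR seeds, 1000-shuffle contract, 60-design
  assignment run) were chosen as the smallest sizes at which the binomial
  noise on the measured rates is well below the margins being asserted.

## Known limitations

- Cluster-level (multi-motif) scoring is out of scope; one PWM is scanned
  at a time.
- The ambiguity margin approximates, but does not reproduce, a mapper's
  MAPQ; reads from heavily truncated inserts may be assigned where a
  mapper would not.
- Replicate meta-analysis and cross-line normalisation are not provided;
  tables are per sample.
- The quantile-regression outlier diagnostic sometimes used for sample
  exclusion is reduced to the coverage rule plus a reported extreme-value
  fraction.
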
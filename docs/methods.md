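# Methods

## Coordinate and score conventions

All internal coordinates are 0-based half-open (BED convention). Gene tables
are read as 1-based inclusive (Ensembl/BioMart style) and converted once, on
input; the exon/UTR feature table uses the same convention. Strand is ±1,
with `.`/absent mapped to unstranded for peaks. The TSS of a +-strand gene
is `body.start`; of a −-strand gene, `body.end − 1`.

Peak significance is carried everywhere as −log₁₀ *p* of the peak call.
Gene-level binding is the sum of these scores over assigned peaks; the
heat-map display transform is ln(−log₁₀ p + 1).

## Peak annotation

Peaks are assigned by **summit-to-TSS distance only** — peak boundaries
never enter the assignment — to the single nearest gene on the same
scaffold, with ties broken by lexicographically smallest gene id (an
arbitrary but deterministic rule). Signed distance is oriented by the gene's
strand: negative means upstream in the transcription direction.

Two anchors deliberately coexist:

- **Region bands** (proximal ≤1 kb, intermediate 1–5 kb, distal >5 kb,
  up/downstream) are measured from the **nearer gene-body edge**. Inside the
  body, the subclass is UTR (taking precedence over plain exon), exon, or
  intron; the intron count equals gene-body peaks minus exonic (incl. UTR)
  peaks — the subtraction rule keeps the partition exact.
- **Occupancy bins and window sums** are **TSS-anchored**: 25 bins of
  400 bp per side covering ±10 kb, plus one overflow bin per side for
  |d| > 10 kb, so the bin total always conserves the summed peak scores.
  Window sums (<1 kb, 1–5 kb, >5 kb per side) are computed from raw signed
  distances rather than by re-summing bins, because 1 kb and 5 kb are not
  multiples of 400 bp and bin re-summation would misallocate band edges.

The distance histogram uses 200-bp breaks over ±20 kb and keeps an explicit
out-of-range counter instead of clipping, so counts always total the number
of assignments.

## Co-binding

Peak-level co-occupancy is the fraction of query summits whose nearest
reference summit lies within a threshold (default 100 bp). The measure is
intentionally asymmetric (denominator = query track); query peaks on
scaffolds absent from the reference count as non-colocalized and are
reported.

Gene-level sharing uses a two-tier rule on Σ(−log₁₀ p): *strong* at ≥25
(p ≤ 10⁻²⁵), *relaxed* at ≥1 (p ≤ 0.1). A gene enters the shared analysis
only if strong for at least one factor, and joins every factor's region for
which it is at least relaxed ("relaxed rescue"). With more than two factors
this generalises the pairwise strong↔relaxed rule by pooling a gene into the
region of all factors where it clears the relaxed bar; the per-factor
bookkeeping (strong + rescued = total) is computed independently of the
region decomposition and cross-checked in tests. Both thresholds are
parameters of `tier_of`.

## Motif scanning

PWMs are additive log₁₀ likelihood-ratio matrices against a background
(uniform by default): w[i,b] = log₁₀(((count+ε)/(rowsum+4ε))/bg_b). A window
score is the sum over positions; any window containing a non-ACGT base (N,
i.e. masked sequence) scores −∞ and can never be reported. Both strands are
scanned; reverse-complement hits are reported at the forward-strand window
start so that one coordinate system feeds BED export. Display scores clamp
raw values into [1.5, 5.0] and scale linearly onto 0–1000; exported motif
features may be widened by ±40 bp purely for browser legibility. Motif
discovery (the upstream step that produces PWMs from over-represented
k-mers) is out of scope; construction from counts, scanning, coverage and
positional statistics are what the downstream analyses consume.

## Expression integration

Replicate expression is handled on the log2 scale internally; the signed
fold convention (magnitude ≥ 1, minus = downregulation) is applied only at
reporting boundaries. The per-gene test is a two-tailed pooled-variance
Student's t on log2 replicates — chosen for fold-change symmetry — followed
by Benjamini–Hochberg step-up adjustment (scipy's implementation) across the
full gene table. Misregulation requires both |fold| ≥ 1.5 and FDR < 0.10.

Gene-set overlap uses the one-sided hypergeometric tail P(X ≥ k) with
expected overlap |A||B|/N. The binding-enrichment comparison is a one-tailed
two-group Mann–Whitney U ("set 1 stochastically greater"), run with and
without zero occupancies since unbound genes (occupancy 0) are a modelling
choice, not a measurement. The exact branch (n₁+n₂ ≤ 20) enumerates all
C(n₁+n₂, n₁) group assignments over the pooled mid-ranks, which handles ties
correctly; above the cutover, scipy's normal approximation with tie
correction is used. The cutover at 20 keeps the exact branch under ~2·10⁵
enumerations.

qPCR utilities invert a least-squares standard curve ct = a·log₁₀q + b
(rejecting non-negative slopes) and compute antibody-vs-IgG ratios or
percent input as 100·q_ab/(q_input/input_fraction).

## Biophysics

Binding follows the 1:1 Langmuir isotherm R = R_max·c/(K_d + c);
equilibrium response is taken as given (kinetic fitting is out of scope).
Fits use `scipy.optimize.curve_fit` with K_d⁰ = median(c), R_max⁰ = max(R)
and positivity bounds; inputs must span at least one decade of
concentration, and degenerate (flat) responses are rejected rather than
fitted. Fractional occupancy is c/(c+K_d). Nuclear concentration treats the
nucleus as a sphere specified by its envelope surface S (r = √(S/4π)),
takes the nuclear protein fraction as an explicit parameter, and keeps the
cell census (total copies / number of expressing cells) in a separate
helper so geometry and census assumptions never mix. The protein's
molecular weight is a required input to `copies_from_mass`, not a constant.

## Synthetic data

The generators define the study conditions for every test:

- **Genome**: genes tiled per scaffold with exponential intergenic gaps
  (mean 6 kb), lengths uniform in 1–8 kb, random strands, 1–8 non-overlapping
  exons whose outer edges coincide with the gene body, and short UTR stubs
  on the terminal exons; background sequence is i.i.d. uniform ACGT.
- **Peaks**: a `target_fraction` of genes receives a summit ~
  Normal(TSS, 100 bp); scores are gamma(1.5, 20) in −log₁₀ p units — a
  long-tailed distribution in which many genes are weakly and few strongly
  bound; background peaks are uniform per scaffold.
- **Cofactor track**: a `cofactor_shared_fraction` (default 0.8) of peaks is
  duplicated with Normal(0, 10 bp) summit jitter and independently resampled
  scores; the rest are uniform.
- **Motifs**: the consensus (or its reverse complement, p = ½) is written
  uniformly within ±100 bp of a peak summit with probability 0.8 per peak.
- **Expression**: genes whose promoter-proximal occupancy exceeds the median
  of the positive occupancies are shifted −2 log2 units in the knockdown;
  10% of the remaining genes are shifted +2 (so the up-vs-down analyses are
  exercised); replicate noise is Normal(0, 0.5) on log2 scale, 3 replicates
  per condition.
- **Isotherms**: responses at 8 log-spaced concentrations over
  3 nM – 3.8 µM with Gaussian noise (1% of R_max in the recovery studies).

A single root seed is paired with a fixed per-generator stream id
(`default_rng([seed, stream])`), so every generator is independently
deterministic and adding one does not perturb the others.

What the generator does **not** emulate: read-level noise, chromatin
accessibility, sequence composition bias, correlated replicate structure,
or any realistic background-binding model (uniform placement is a
stand-in). Passing tests therefore demonstrate the correctness of the
computations and their recovery of planted structure under these idealised
conditions — not performance on real ChIP-seq data.

## Problem sizes and numerical choices

The analysis drivers use 400 genes on 4 scaffolds (~4 Mb); recovery studies
use up to 600 genes / ~650 peaks (cofactor sharing, which needs ≥500 peaks
for the ±0.05 binomial tolerance), 50 noisy isotherms, 20 pipeline seeds for
the linkage detection rate, and 2,000 draws for the Mann–Whitney null
calibration — sizes at which every planted parameter is recoverable at its
stated tolerance while the whole suite runs in a couple of minutes.
Tie-breaks (lexicographic gene id), clamps (summits at scaffold edges,
BED score range), and degenerate-input errors (empty sets after zero
removal, flat isotherms, zero-variance correlations, non-negative
standard-curve slopes) are all explicit rather than silent.

## Known limitations

- Nearest-gene assignment ignores enhancer–promoter loops and k-nearest
  alternatives; a distal peak is attributed to the closest TSS even when
  implausible.
- The two-tier sharing rule reproduces automated calling only; manual
  rescue of peaks missed by a caller (visual inspection of browser tracks)
  is not implementable and therefore excluded.
- The Mann–Whitney asymptotic branch is a normal approximation; far-tail
  p-values (≪10⁻²) are approximate there, though comparisons at usual
  significance levels are accurate.
- The isotherm model is strictly 1:1; cooperative or dimeric binding (which
  palindromic motifs suggest) is not modelled.
- Whether a printed nuclear concentration already includes the nuclear
  fraction is ambiguous in general; `nuclear_concentration` takes the
  fraction as an explicit argument and reports both the geometry and the
  resulting molarity so either interpretation can be computed and labelled.
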
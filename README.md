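# tboxscan

Downstream analysis of multi-transcription-factor embryonic ChIP-seq and
RNA-seq: peak-to-gene annotation, co-occupancy and shared-target calling,
position-weight-matrix scanning, binding-versus-differential-expression
statistics, and equilibrium DNA-binding biophysics — exercised end to end on
synthetic data with planted structure.

## The problem

T-box transcription factors (Brachyury/Xbra, Eomesodermin, VegT) steer
embryonic cells between mesodermal and neural fates. Genome-wide binding maps
of such factors pose a recurring set of downstream questions: which gene does
each binding peak belong to, and where does it sit relative to the gene
(promoter-proximal, intronic, distal)? Do two factors, or two developmental
stages, occupy the same sites and the same target genes? Are the bound
sequences enriched for the factor's recognition motif? Does binding predict
how genes respond when the factor is knocked down? And given a measured
dissociation constant and nuclear concentration, what fraction of recognition
sites should be occupied at equilibrium?

`tboxscan` implements this analysis chain as a tested library, with a
synthetic-data module that generates genomes, peak tracks, motif-bearing
sequences, replicate expression tables and binding-isotherm curves whose
planted parameters the downstream analyses must recover.

## The quantities at the core

- **Peak annotation.** Each peak is assigned to the gene with minimal
  summit-to-TSS distance; peaks are classed as proximal (≤1 kb),
  intermediate (1–5 kb) or distal (>5 kb) up/downstream of the gene body, or
  within it (exon / intron / UTR, introns by subtracting exonic peaks from
  gene-body peaks). Gene-level occupancy is the sum of peak −log₁₀ *p*
  scores, binned at 400 bp over ±10 kb of the TSS with single overflow bins,
  and a gene counts as a target when Σ(−log₁₀ p) ≥ 25.
- **Co-binding.** Tracks are compared by nearest-summit distance; two peaks
  co-localize at ≤100 bp. Shared target genes use a two-tier rule: a gene
  anchors in a factor's target set at p ≤ 10⁻²⁵ and is rescued into sharing
  down to p ≤ 0.1.
- **Motifs.** PWMs are log₁₀ likelihood-ratio matrices; both strands of
  200/400-bp summit flanks are scanned, raw scores in [1.5, 5] are scaled to
  the BED 0–1000 display range, and coverage is the fraction of peaks with a
  hit within 100 bp of the summit.
- **Binding vs. regulation.** Misregulation is called at ≥1.5-fold and
  FDR < 10% (two-tailed Student's t on log2 replicates, Benjamini–Hochberg).
  Overlap of bound and misregulated gene sets is tested with the one-sided
  hypergeometric (Fisher) test with expected overlap |A||B|/N; binding-level
  differences between gene sets use a one-tailed two-group Mann–Whitney U
  (exact, tie-aware enumeration for n₁+n₂ ≤ 20), run with and without zero
  occupancies.
- **Biophysics.** Binding responses follow the 1:1 isotherm
  R = R_max·c/(K_d + c), fitted by nonlinear least squares; fractional
  occupancy is c/(c + K_d); nuclear concentration derives from copies/cell,
  the nuclear fraction, and a spherical envelope of surface S via
  r = √(S/4π), V = 4πr³/3.

## Worked example

The numbered scripts under `analysis/` run the whole chain on a synthetic
study (400 genes, two TF tracks, planted motifs and expression effects):

```
python analysis/01_simulate.py --seed 1
python analysis/02_annotate_peaks.py
python analysis/03_cobinding.py
python analysis/04_motif_scan.py
python analysis/05_expression_integration.py
python analysis/06_biophysics.py
```

Selected output (seed 1):

```
primary track: 317 peaks (197 planted at TSSs, 120 background)
region distribution: 105 proximal, 150 in gene bodies (27 intronic after exon subtraction)
208 of 317 summits lie within 400 bp of a TSS; 0 beyond +/-20 kb
colocalization at 100 bp: 0.792 (317 cofactor peaks vs 317 primary)
misregulated at >=1.5-fold & FDR<10%: 94 down, 26 up of 400 genes
Fisher overlap of bound targets with down set: observed 92 vs expected 36.0 (p = 3.94e-46)
Mann-Whitney down>unaffected proximal binding: p = 6.63e-48
v1: Kd = 1.34e-08 M (true 1.4e-08, 4.6% error); occupancy at 2.9 uM = 0.995
nuclear concentration exceeds the v1 Kd 217-fold
```

Reading this: most planted summits fall within one 400-bp bin of a TSS; the
cofactor track recovers its planted 80% shared-site fraction at the 100-bp
summit-distance threshold; knockdown-downregulated genes overlap bound
targets far beyond the |A||B|/N expectation and carry significantly higher
promoter-proximal binding than unaffected genes; and a 14 nM site is
essentially saturated (occupancy 0.995) at a 2.9 µM nuclear concentration —
some 200-fold above its K_d — while a site with K_d at the nuclear
concentration itself sits at half occupancy.

## Layout

```
src/tboxscan/     library: core_io, simulate, annotate, cobind, motifs,
                  expression, biophys
analysis/         numbered narrative drivers writing under results/
tests/            pytest suite (unit, property, acceptance)
scripts/          acceptance.py
docs/methods.md   models, assumptions, parameter choices, limitations
```
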
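# Methods

## Copy-number model

A translocation allele is modelled purely by the genomic segments whose
copy number it elevates: Cs29 adds one copy of the chromosome-6 *KIT*
segment per allele carried; Cs6 adds one copy of that same segment **and**
one copy of a chromosome-29 segment. A diploid genotype's expected
standardized depth ratio over a region is `(2 + Σ count × copies_added)/2`,
which yields the 1.0 / 1.5 / 2.0 ladder for 2 / 3 / 4 copies. The internal
junction order of the translocated material is deliberately not modelled:
read depth only sees dosage, and the breakpoint assay only sees
junction-adjacent primer sites.

Region coordinates are configuration, not constants. The published
region-of-interest boundaries were obtained by lifting older assembly
coordinates over to ARS-UCD1.2 and are not printed anywhere accessible, so
the shipped defaults are placeholders centred on *KIT* (chr6 ≈ 71.8 Mbp)
and clearly marked as such; every computation joins regions to allele
models by label, so swapping in exact coordinates is a config edit. The
YAML schema is in `cside.io.read_allele_models`.

## Depth genotyping

1. **Binning.** Per-base/interval depth (bedGraph) is averaged into fixed
   windows (default 10 kbp) by length-weighted mean; windows without any
   coverage record are missing, not zero, and are excluded from all
   medians.
2. **Standardization.** Each window is divided by the genome-wide median
   window depth. The median is taken genome-wide by default (a
   region-local alternative is a caller argument away via region
   selection); with the scored regions a small minority of all windows,
   the two coincide. Standardization is scale-invariant and idempotent.
3. **Region summary.** The median (not mean) of windows *fully inside*
   each region — robust to breakpoint-edge windows, which are excluded
   because partial overlap dilutes the copy signal.
4. **Calling.** The fit score of each candidate genotype is
   `Σ_regions (observed − expected)²`; the call is the arg-min over the
   enumerated six-genotype space, ties broken by genotype name for
   determinism. On a single region this reduces to nearest-expected-ratio
   classification with thresholds at 1.25 and 1.75. A call is flagged
   `ambiguous` when the best two scores differ by less than 0.01 or an
   observed ratio lies within ±0.05 of a midpoint between adjacent
   expected levels (both tunable). The published analysis made this
   comparison visually against 1.5× and 2× reference lines; the explicit
   rule makes it reproducible and testable.

## In-silico breakpoint PCR

Primer sites are found by direct scanning with IUPAC base-set matching and
a mismatch budget; the 3′-terminal base must always pair, because
polymerase extension requires a matched 3′ end. Products are every
convergent plus/minus site combination within a maximum product size, with
length measured 5′ end of the forward-facing primer through 5′ end of the
reverse-facing primer inclusive (the convention in which assay product
sizes are reported). Thermodynamics (Tm, dimers) are out of scope.

Band decoding follows the informative multiplex: the junction band
(nominal 318 bp) and wildtype chromosome-29 band (394 bp) read Cs29
codominantly (both → het, 318 only → hom, 394 only → non-carrier); the
Cs6 junction band (525 bp) is dominant presence-only, since the Cs6
haplotype retains a wildtype-configured chromosome 29 and therefore also
yields the 394 band — one or two Cs6 alleles give the same pattern. A
pattern with neither a 318- nor a 394-class band is a failed PCR, not a
genotype. Band-size matching tolerance defaults to ±3% of nominal
(electrophoresis sizing error); the marker map refuses tolerances at which
nominal sizes collide.

The real primer nucleotide sequences are published elsewhere and not
bundled; the shipped primers are synthetic stand-ins (labelled as such)
whose amplicons on the synthetic templates reproduce the 318/394/525 bp
diagnostic sizes, keeping every sequence-level code path exercised.

## Cohort statistics

* Codominant allele frequency: `p̂ = (2·hom + het)/2n` over allele draws.
* Dominant marker: positive-animal fraction `k/n` only; an optional
  Hardy–Weinberg back-calculation `q̂ = 1 − √(1 − f_pos)` is provided but
  labelled as an extension, since it assumes random mating.
* Confidence intervals: exact Clopper–Pearson, computed by incomplete-beta
  inversion (`scipy.stats.beta.ppf/isf`); bounds are 0 at k=0 and 1 at
  k=n. Display rounding is half-away-from-zero to 2 decimals; full
  precision is retained internally.
* Fisher exact test: full enumeration of all margin-fixed r×c tables;
  two-sided p is the sum of hypergeometric probabilities ≤ the observed
  table's (relative tie tolerance 1e-7 absorbs floating-point ties), the
  same convention as the conditional exact test in the standard
  statistical software family. Enumeration above a configurable cap
  (default 2×10⁶ tables) raises with advice to use Monte-Carlo rather
  than silently approximating. Which genotype classes enter a cohort
  comparison (2×3 hom/het/non-carrier vs 2×2 pooled) is an explicit
  argument with the full class set as default; no single choice is
  asserted as canonical.

## Synthetic data

* **Depth tracks**: window counts are Poisson with mean
  `mean_depth × expected ratio` (negative binomial, `var = m + αm²`, when
  overdispersion α > 0 is requested); defaults are 10 kbp windows at 26X —
  the sequenced panel's average coverage — with 2,000 diploid background
  windows anchoring the median. GC and mappability bias are not simulated;
  median standardization removes global scale, and the caller is tested
  for robustness via the overdispersion knob instead. Because the
  simulated "genome" is small, background windows must outnumber region
  windows for the median to stay anchored (in a real genome the scored
  300 windows are a negligible fraction of ~250,000).
* **Haplotypes**: uniform-composition random DNA with primer sites planted
  exactly at spacings that give the configured product sizes; an optional
  mismatch-injection mode perturbs internal (never 3′) bases for matcher
  tests.
* **Populations**: two alleles drawn i.i.d. per animal from the allele
  frequency vector (Hardy–Weinberg sampling); dominance masking collapses
  hom/het to "positive" on the observed record only, never touching the
  true alleles.

Everything is reproducible bit-for-bit under a fixed seed. What passing
simulation tests show is that the decision rules are correct under the
stated noise model; they do not certify performance on real data with
mapping artefacts, GC waves, or segmental duplications beyond the modelled
regions.

## Problem sizes used in tests

Simulation-based tests use 150-window (1.5 Mbp at 10 kbp) scored regions,
2,000 background windows, and cohorts of 30–200 animals; the caller
recovery check runs 200 animals at 26X. The Fisher engine is verified
against an independently written brute-force enumerator on 500 random
2×2/2×3 tables with totals ≤ 40, and interval coverage on a
{10, 25, 60} × {0.1, 0.4, 0.7} grid with 2,000 draws per cell.

## Known limitations

* Depth genotyping assumes the scored regions are the only copy-number
  variable segments in view and that the genome-wide median reflects the
  diploid state; heavily rearranged genomes would need region-local
  standardization.
* The survey frequency table treats the published cohort counts as exact
  inputs; re-deriving the sequenced cohort's genotype counts (5
  homozygotes, 8 heterozygotes of 30) requires the ~26X whole-genome read
  data (ENA accession PRJEB60564), which is deliberately not bundled.
* The Fisher test is exact-conditional only; no mid-P or asymptotic
  alternatives, and no multiple-testing correction (two tests are
  reported raw, matching the survey's practice).
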
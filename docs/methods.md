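# Methods

## Model

Selection leaves a signature in the allele frequency spectrum: deleterious
alleles are held at low frequency, so a variant class under negative
selection is enriched for singletons (alleles seen once in the cohort).
The proportion of singletons is, however, also a strong function of
mutability — highly mutable sites recur and climb in frequency — so the
raw proportion singleton of a variant class is uninterpretable without a
mutability-matched baseline.

The package's core statistic treats each variant's singleton status as a
Bernoulli outcome whose neutral success probability depends only on the
variant's mutability context. The baseline is estimated from intergenic
variants (≥ 25 kb from any annotated feature, trimmed and gap-subtracted),
stratified by context, and the statistic

    iMAPS = (Σᵢ 1[singleton_i] − Σᵢ p̂s(context_i)) / n

is the per-variant rate of excess singletons. Under neutrality it is
centred at zero with variance ≈ Σ ps(1−ps)/n²; positive values indicate
selection. It is additive over cohort unions and invariant to variant
order.

### Contexts

A context combines the base change, flanking sequence at a chosen depth
(1–5 bases per side, "di" through "hexa"), a methylation stratum at CpG
transitions, and two binary chromatin flags (DNase hypersensitivity,
H3K9me3). Reverse-complement descriptions of the same event are collapsed:
of a key and its reverse complement, the lexicographically smaller
serialization (change first, then flanks) is canonical. The pairing is
fixed-point-free because the central ancestral base always differs from
its complement, giving exactly 96 sequence classes at the dinucleotide
level and the parent-context arithmetic 96 → 104 (methylation strata for
the 4 NCG>NTG classes) → 416 (×2 DNase ×2 H3K9me3).

Methylation bins are half-open: high > 60, medium (20, 60], low ≤ 20 mean
methylation (percent). Bins apply only to C>T at CpG on either strand;
other changes at CpG sites carry no bin, which is what makes the
parent-context count 104 rather than larger. Methylation is looked up at
the variant's own annotated position.

### Extended-context selection

Deeper flanks improve mutability matching but fragment the data (65,536
hexanucleotide descendants per parent). Each candidate extended context is
compared with its parent by a two-sided Fisher exact test on the disjoint
2×2 table (child counts vs parent-minus-child counts; the exclusion keeps
the cells independent). p-values are Benjamini–Hochberg corrected within
each level — one family per level, all parents jointly — and accepted at
FDR 0.2. Variants under an accepted context are removed before the next
(shallower) level is tested, so a single deviation cannot be discovered
twice. Queries resolve at the deepest accepted ancestor, else the parent;
a query whose parent context was never observed raises rather than
defaulting to a global mean (calibration totality).

No minimum child count is imposed beyond n ≥ 1: with tiny cells the exact
test's p-values are large and BH simply never selects them, while any
floor would need its own justification.

### Group comparisons

Two variant classes are compared by a one-sided exact test on the 2×2
singleton table. The null is *not* independence: it is the odds ratio
implied by the two groups' expected singleton counts,
ψ₀ = [E_A/(n_A−E_A)] / [E_B/(n_B−E_B)], realized as Fisher's noncentral
hypergeometric distribution with the margins fixed at the observed totals.
The implementation enumerates the support in log space (exact for group
sizes into the 10⁵ range, far beyond what the package ever feeds it; a
continuity-corrected normal tail is used past that and flagged in the
result). ψ₀ = 1 recovers the ordinary one-sided Fisher exact test. Exact
conditional confidence intervals for odds ratios invert the same tails by
Brent root-finding on log-odds.

Cross-mode comparisons rescale a class's iMAPS to the genome-wide scale
with the two-point affine map anchored at synonymous and missense
benchmark values; being affine, midpoints map to midpoints.

## Element classification

* **PSAM scanning.** A k×4 matrix of relative affinities (row maxima 1.0);
  window affinity is the per-position product, scanned 5'→3' on the sense
  strand only (RNA binding; no reverse-complement scan). T and U are
  synonyms. Windows containing an ambiguous base score 0 and are masked.
* **ReP sites.** For each eCLIP-style peak, the highest-affinity window
  whose start lies within ±75 nt of the strand-aware 5' end. Affinity ties
  break to the smallest |offset|, then 5'-most — deterministic and
  strand-symmetric. A permutation test (10,000 draws, uniform offsets,
  add-one estimator (r+1)/(n+1)) checks that observed sites concentrate at
  a modal offset; RBPs with p ≥ 0.01 are flagged for exclusion.
* **Variant effects at ReP sites.** Ancestral and derived affinities sum
  the k windows covering the variant on each allele's sequence; the local
  affinity sums windows fully inside the site ±25 nt (clipped at
  transcript ends, flagged). Focal: ancestral/local > 2/3; non-focal:
  < 1/3 or another same-RBP site within 25 nt. Disrupting:
  derived/ancestral < 1/3; preserving: > 2/3. The gap (1/3, 2/3) is an
  explicit "intermediate" label excluded from both classes; a relaxed
  preset (1/2 both ways) is available for power-limited cohorts.
* **Pumilio-site creation.** Created iff derived/ancestral affinity > 2
  and derived affinity exceeds a sweepable floor (default 0.25).
* **PAS.** A variant in an ancestral AWUAAA hexamer loses the signal iff
  no 6-mer frame overlapping the variant on the derived sequence matches
  the whitelist (canonical AWUAAA plus caller-supplied enriched A-rich
  hexamers — the enriched list is an input, not hardcoded). A PAS is
  "primary" when its hexamer lies wholly 15–30 nt (inclusive) upstream of
  the primary poly(A) site; the window requires full hexamer containment
  since the anchoring base is otherwise ambiguous.
* **miRNA targets.** Site types 8mer / 7mer-m8 / 7mer-A1 with analyzable
  positions derived from the site's mRNA 3' end: seed-pairing positions
  2–7 for all types, the position-1 base for 8mer/7mer-A1, position 8 for
  8mer/7mer-m8 (8/7/7 positions respectively). Multi-family targeting
  counts distinct families covering the variant. The AU flank metric is
  the A/U fraction of the up-to-two bases on each side.
* **3'UTR models.** Each poly(A) site attaches to the closest upstream
  stop codon; the primary site has the highest mean RPM (ties go to the
  most proximal site); core = stop→primary regardless of intervening
  sites, variable = primary→distal. UTRs over 50 kb are dropped; pairs
  whose sites crowd within 100 nt of a downstream UTR start are dropped
  both.
* **CDS benchmark.** Codons are reconstructed across exon junctions from
  annotated phases; variants in frame-conflicted exons, within 3 nt of a
  splice site, or at ancestral stop codons are excluded. Isoform
  collisions resolve by severity (stop-gain > missense > synonymous).

## Variant filtering

Exclusions (pure predicates; retained set independent of order): quality
fail, non-SNV, chromosomes X/Y/M, low-complexity regions, median coverage
outside [25, 42] (the stated bounds govern, though 3/4·32 = 24), the C of
a CpG without methylation data, CpG islands, reference ≠ ancestral allele,
A>G on either strand (transcription-coupled damage/repair asymmetry is
handled by exclusion, not modelling), any N within ±5 bases (checked on
the observed reference window), and — for 3'UTR cohorts — CDS overlap on
either strand. Multi-allelic records are split and treated independently.
Intergenic region lengths are capped at 1.5× their 75th percentile
(linear interpolation by default; the convention is a parameter), trimming
keeps the 5'-most span.

## Synthetic data

The generator emulates every input format the pipeline reads (FASTA
observed/ancestral, GFF-style gene structures with phased CDS, poly(A)
usage tables, methylation TSV, mask BEDs, VCF cohorts, PSAMs and peak
BEDs) at toy scale: a 200 kb annotation-free intergenic contig and a
400 kb contig with three genes. Singleton status is drawn directly as
Bernoulli(baseline(parent context) + planted deviation + class Δ), with
per-parent baselines fixed by the seed in [0.35, 0.65] — the scale of
intergenic proportion-singleton values in large human cohorts. Only the
singleton indicator and allele count enter the statistic, so simulating a
full population would add realism the pipeline cannot see; consequently
the synthetic cohorts do not reproduce linkage, demography,
recurrent-mutation biases, or the true human context-mutability map, and
passing tests demonstrate correctness of the machinery and its statistical
calibration, not real-data effect sizes. Planted-context fixtures embed
one 11-mer many times (a single hexanucleotide context) plus background
windows sharing its inner trinucleotide, giving the parent complement the
weight that genome-scale data provides; the chromatin masks are kept off
the planted stretch so its stratum is fully determined by design.

## Numerical choices

* Two-sided Fisher p-values are computed by a vectorized log-gamma
  enumeration (the scipy scalar routine is the test oracle); tables are
  processed in support-width-sorted blocks so one large table cannot
  inflate the padding of thousands of small ones. The "as extreme"
  comparison uses the customary (1+1e-7) relative tolerance.
* Permutation p-values use the add-one estimator, so p = 0 is impossible.
* Window ties in scanning break to the 5'-most window; region trims keep
  the 5' span; both are documented parameters where configurable.
* Expected-count odds ratios require expectations strictly inside (0, n);
  degenerate margins return p = 1 with a flag rather than an error.
* Validation experiments share one fitted calibration table across
  replicates; the standard error of a mean recovery estimate therefore
  includes the propagated calibration variance Σ_c w_c² ps_c(1−ps_c)/N_c
  in addition to the across-replicate term.

## Problem sizes

Validation experiments run at: calibration cohorts of 1.5×10⁵ variants,
scored cohorts of 2×10⁴ per class over 200 replicates, 100 replicates for
false-discovery behaviour at 5×10³–1.5×10⁴ variants each, 40 peaks with
10,000 permutation draws, and 10⁴ random variants for the PAS oracle.
These sizes give standard errors comfortably below the effects being
measured while keeping a full run around a minute on one CPU.

## Known limitations

* PSAMs are consumed as sequence-only matrices; affinity models trained
  with structural context are accepted but their structure terms are not
  re-derived.
* The calibration requires every query parent context to be observed
  intergenically; at toy calibration sizes rare strata can be missing, and
  the CLI exposes an explicit opt-in to drop such variants.
* The exact clipping of the ±25 nt local-affinity span at UTR ends, the
  PAS hexamer anchoring convention, and the intergenic percentile
  convention are all documented package choices where the field has no
  single standard; each is parameterized.
* No confidence interval is attached to iMAPS itself; group contrasts are
  the supported inferential tool.
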
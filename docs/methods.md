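# Methods

## The enzyme model

FspEI is a Type IIS methylation-dependent restriction enzyme: it binds a
5-methyl- (or 5-hydroxymethyl-) cytosine in one of two sequence contexts
and cuts double-stranded DNA at a fixed distance on the 3′ side of the
modified base. The two recognition contexts are

* **C^mC** — the modified cytosine is the second C of a CC dinucleotide;
* **^mCDS** — the modified cytosine is followed by D = [A/G/T] and then
  S = [C/G].

Both strands are scanned; a cytosine matching both contexts is catalogued
once per context. N bases never participate in a match. The scanner is
regex-based with lookahead, so overlapping occurrences all count, and it
is verified against a per-position IUPAC window oracle in the tests.

### Cut geometry

The double-strand break sits D1 nucleotides 3′ of the mC on its own
strand and D2 = D1 + 4 on the opposite strand (the 4-nt stagger leaves 5′
overhangs). The offsets are calibrated constants: the only geometric
anchor the protocol provides is that a CCGG site methylated on both
strands releases a 32 nt top-strand fragment. With the top-strand mC at
motif offset 1 and the bottom-strand mC at offset 2, the released length
is D1 + D2 + (1 − 2) + 1 = D1 + D2, so **D1 = 14, D2 = 18**. The same
arithmetic gives **31 nt for CCWGG**: its bottom-strand mC sits one base
further 3′, which moves the left-hand cut 1 bp to the right. We
deliberately anchor CCGG = 32 and accept the CCWGG consequence rather
than force both lengths to 32. For length bookkeeping the 4-nt overhangs
are ignored — fragment lengths are top-strand nucleotides, matching how
single integer read lengths are reported.

Fragment prediction places one break per methylated catalogue site
(breaks falling outside the contig are no-ops), takes maximal uncut
intervals, and flags a fragment *symmetric* when its two bounding breaks
are the paired cytosines of one CCGG/CCWGG occurrence methylated on both
strands. Fragment lengths always sum to the contig length.

### Genome context statistics

* Site density: genome length / number of distinct (contig, position,
  strand) recognisable cytosines, truncated to 2 decimals (truncation,
  not rounding, is the reporting convention for these densities).
* CCGG and CCWGG are their own reverse complements, so forward-strand
  occurrence counts cover both strands; motif densities are truncated to
  integer bp.
* Context coverage: the fraction of CG-context cytosines (both strands)
  lying inside a CCGG occurrence, and of CHG-context cytosines inside a
  CCWGG occurrence.

## Site calling

A MethylRAD tag carries the enzyme cut at its 5′ end (at both ends for a
symmetric-length tag, which is a complete double-digestion fragment). A
tag end is *validated* when its coordinate abuts a break that a
catalogued cytosine would produce: for a + strand mC at m the break falls
after m + D1 (tags ending at m + D1 or starting at m + D1 + 1); for a −
strand mC at m, after m − D2 − 1. The read filter keeps a tag iff at
least one end validates — this is the "reads without restriction sites"
filter, and with a decoy fraction f in the simulator the filtering ratio
converges to 1 − f.

Counting convention: **counts are tag-end increments**, not fragment
increments — one symmetric fragment increments both of its flanking
sites, which is also why the front/end orientation dichotomy exists
(front = validating cut at the read's 5′ end, end = at its 3′ end). When
one end validates more than one catalogue cytosine, the candidate whose
cytosine lies on the tag wins, then the nearest offset, and the end is
counted once. The on-tag preference matters: a bare nearest-offset rule
lets a chance cytosine at the shorter offset on the far side of the cut
deterministically outcompete the true site for roughly one minus-strand
site in ten, which would make exact-position recovery impossible. With
the on-tag rule, attribution on noiseless simulations is exact: the count
matrix equals the per-source tally of emitted tags.

The coverage filter (≥ min_reads reads in ≥ min_samples samples, defaults
3 and 3) counts samples over both groups, because it is applied once
before any group comparison. It is monotone in both thresholds.

## The count model and the exact test

Counts are negative binomial: y ~ NB(mean μ, dispersion φ), variance
μ + φμ². Inference is classic qCML for small two-group designs:

1. **Library equalization.** Every sample's counts are mapped to the
   common library size (geometric mean) by quantile mapping between NB
   distributions at the current dispersion; the continuous map averages a
   normal and a gamma approximation, which keeps pseudo-counts smooth.
   Per-site expected proportions are estimated within group. Equalization
   and dispersion estimation alternate (at most 3 iterations, tolerance
   1e-4 on φ; the estimate is insensitive to further iterations).
2. **Common dispersion** maximises the summed conditional log-likelihood
   of within-group splits given group totals: per group with counts
   y₁..y_n, z = Σyᵢ and r = 1/φ,
   ℓ(φ) = Σᵢ lnΓ(yᵢ + r) + lnΓ(n·r) − lnΓ(z + n·r) − n·lnΓ(r),
   maximised over φ ∈ [1e-6, 10] by bounded scalar search. Parameter
   recovery at the default design is within a few percent (tested at
   φ ∈ {0.05, 0.2, 0.5}). Tagwise dispersions (empirical-Bayes shrinkage
   toward the common value with a fixed prior weight) are available as a
   diagnostic but off by default; the exact test always uses the common
   dispersion.
3. **Exact test.** Conditional on the site total z = z₁ + z₂, the group
   sum follows a negative hypergeometric law with shape parameters
   n_g / φ (the group mean cancels); φ = 0 degenerates to
   Binomial(z, n₁/(n₁+n₂)). The two-sided p-value doubles the smaller
   tail with the observed point included in both tails, capped at 1;
   z = 0 gives p = 1. Group sums of the continuous pseudo-counts are
   rounded to integers before testing.
4. **Multiplicity.** Benjamini–Hochberg is the default behind the
   "FDR < 0.05" DMS call; Bonferroni is available by flag. (The two are
   often conflated in protocol descriptions; both are provided so either
   reading is recoverable, and the Bonferroni-significant set is always a
   subset of the BH set.)

`logFC` = log2((mean female CPM + c)/(mean male CPM + c)) with prior
c = 0.5 CPM for stability (configurable); a site more methylated in males
therefore has negative logFC. `logCPM` is the log2 across-sample mean CPM
plus the prior. No TMM-style composition normalization is applied — CPM
uses total site counts.

**Known statistical limitations.** The doubled-tail conditional test is
discrete and conservative: at the default study conditions (3 vs 3,
mean coverage 20, Beta(2,2) methylation baseline, so site totals around
z ≈ 60) its achievable size at nominal 0.05 is ≈ 0.036, not 0.05 — the
same behaviour as the reference qCML implementation, whose p-value
ranking ours matches to Spearman ρ > 0.99 on shared fixtures. Likewise,
the power of a 3 vs 3 exact test for a 4-fold change at these coverages
is modest: BH-corrected recall of planted differential sites is ≈ 20%
(raw p < 0.05 recall ≈ 75%), again indistinguishable from the reference
implementation on identical matrices. Detected sites are reliable —
empirical FDR stays well under the nominal level — but absence of a call
at this design is weak evidence of absence.

## The synthetic-data generator

The generator emulates the statistical structure the analysis assumes,
with the study's shape as defaults: 2 groups × 3 samples, a 100 kb
genome at GC 0.42 (≈ 20,000 catalogue sites), 100 + 100 planted
CCGG/CCWGG motifs, mean coverage μ = 20 tags per fully methylated site,
dispersion φ = 0.15, 5% differential sites at |log2FC| = 2, and library
size factors spread evenly over [0.85, 1.15].

* Methylation level maps **linearly** to expected coverage (MethylRAD
  counts are level proxies); no bisulfite-style per-read conversion is
  modelled.
* Baseline levels are Beta(2, 2) — unimodal around 0.5, giving per-site
  expected coverage ≈ μ/2. The two strand-cytosines of one CCGG/CCWGG
  occurrence share their state, since symmetric methylation is what
  releases their common fragment.
* Differential units keep the baseline in the high group and divide it by
  the fold change in the low group (direction Bernoulli(0.5)); when the
  0.01 floor binds, both levels are lifted so the exact
  |log2(m_f/m_m)| = effect invariant always holds.
* Symmetric units emit NB-distributed copies of their exact 32/31 nt
  fragment; hemi-methylated sites emit 150 nt single-cut tags on the
  methylcytosine side of the break (sites whose tag would run off the
  contig are not sequenced). Decoy tags are rejection-sampled from
  positions with no restriction-site context. Each tag records its source
  site(s), which is what the end-to-end recovery tests compare against;
  "recoverable" sites are defined as those whose *emitted* tag counts
  pass the coverage filter, so recovery measures calling correctness
  rather than NB tail luck.
* Determinism: each operation draws from its own stream derived from the
  master seed by a fixed offset, so regenerating one artifact never
  perturbs another; identical config + seed gives byte-identical outputs.

What the generator does **not** emulate: sequencing errors, adapters,
PCR duplicates, mapping ambiguity (alignments are taken as ground truth),
enzyme star activity or partial digestion. Passing tests therefore show
the pipeline's bookkeeping and statistics are correct under the assumed
NB model, not that real libraries meet those assumptions.

## Gene annotation and integration

A site belongs to gene G when its coordinate lies in
[start − 2000, end + 2000]; zones are strand-aware (upstream = 5′ per the
gene's strand) and the promoter flag marks the 2 kb strictly upstream of
the TSS — gene-body sites are never promoter-flagged, but both zones are
reported so either reading of "promoter" is recoverable. Sites inside
two genes produce two records (no nearest-gene collapse). The indexed
interval lookup is contract-bound to the brute-force all-pairs oracle.

Integration correlates matched per-sample values: gene-level methylation
is the mean CPM of the gene's assigned sites (promoter-only selectable),
expression is whatever per-sample measure the user supplies, and
Pearson's test at α = 0.05 classifies genes as negative/positive/none.
When only group fold changes exist, a sign-concordance mode compares
methylation and expression log2FC directly; it is a fallback, not a
correlation. With n = 6 paired samples the Pearson test only reaches
|r| ≳ 0.81, so the negative class is conservative at this design.

## Numerical conventions

* Coordinates are 1-based inclusive everywhere inside the package;
  BED/pysam conversions happen only at format boundaries.
* Densities are truncated, not rounded.
* All tables are written sorted by (contig, position, strand), so
  re-running any stage with unchanged inputs is byte-identical.
* PCA for QC uses per-site centred log2-CPM (prior 0.5) via SVD; each
  axis's sign is fixed by making the largest-magnitude loading positive.
* Test problem sizes (20 kb tag-level genomes, 2,000–6,000-site count
  matrices, 5–10 simulation replicates) were chosen as the smallest
  scales at which the binomial/recovery bands in the tests are sharp.
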
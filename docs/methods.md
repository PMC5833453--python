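# Methods

`rrbsdiff` implements a reduced-representation bisulfite sequencing (RRBS)
differential-methylation analysis together with a synthetic-data generator
that lets every stage run, and be tested, without external data. This note
describes the models, the defaults and why they were chosen, what the
simulator does and does not emulate, and the numerical conventions.

## Quantification model

A CpG *site* is the 0-based position of the C of a forward-strand CpG
dinucleotide; reads covering the reverse-strand G of the symmetric CpG are
pooled into the same site. Per site and sample the data are a pair
(m, t) of methylated and total read counts; the methylation level is the
exact proportion m/t.

Replicates are pooled by summing counts (Σm, Σt), which weights each
replicate by its coverage. Sites are then gated: only CpGs with **t ≥ 10 in
every sample** enter the analysis, so levels are always defined and the test
below always has positive margins. Levels are classified as
high (≥ 0.8), intermediate (≥ 0.3 and < 0.8) or low (< 0.3); category
assignment compares the rational m/t against the cutoffs by integer cross
multiplication, so boundary counts such as 24/30 = 0.8 are never
misclassified by float rounding. Inter-sample agreement is summarised by
Spearman correlation (Pearson on mid-ranks) over the gated site set — the
only universe on which all samples are defined.

## Differential calls

For two samples A and B at one site, the 2×2 table
(m_A, t_A−m_A; m_B, t_B−m_B) is tested with a **two-sided Fisher's exact
test**: p is the sum of hypergeometric probabilities of all tables with the
observed margins whose point probability is ≤ the observed one (relative
tolerance 1e-7 for floating ties — the convention of standard statistical
packages; the implementation delegates to `scipy.stats.fisher_exact` and is
checked in the test suite against a full enumeration in exact rational
arithmetic). A site is a **strong DMC** when |level_A − level_B| > 1/3
*strictly* and p < 0.05 strictly. The printed form of the effect threshold is
"33.3%"; it is implemented as the exact fraction 1/3 and compared by cross
multiplication, so a difference of exactly one third (e.g. 25/30 vs 15/30)
is not called. Direction is the sign of delta with A (the first-named
sample) minus B; "hyper" means A more methylated.

Benjamini–Hochberg q-values are reported alongside p for transparency but do
not gate calls: the strong-DMC definition is on the raw p-value.

**DMRs.** Strong same-direction DMCs on one chromosome are chained when
consecutive inter-CpG gaps are ≤ 300 bp; chains of ≥ 3 CpGs become DMRs
spanning first to last CpG (half-open, +1). These two parameters are this
package's defaults, exposed in configuration; they follow common RRBS
practice for gap-based DMR construction. A DMR's level per sample is the
unweighted mean of its constituent CpG levels. When DMR sets from two
comparisons are combined, intervals overlapping by ≥ 1 bp are unioned
transitively and the merged region's level is recomputed as the unweighted
mean over *all* gated CpGs inside the merged interval (not an average of the
parents' levels).

## Annotation

Promoters are the symmetric windows [TSS − 1 kb, TSS + 1 kb), clipped at
contig ends; strand is retained but does not change the interval. Promoter
CpG-density classes use sliding 500-bp windows at 5-bp steps with
CpG observed/expected O/E = (N_CpG · L)/(N_C · N_G), 0 when a window lacks C
or G: **HCP** if any window has O/E ≥ 0.75 and GC ≥ 0.55, **LCP** if no
window reaches O/E ≥ 0.48, **ICP** otherwise. All five constants are
arguments. Subsampling offsets at step 5 can only *miss* enrichment, never
invent it, so a step-5 HCP is always a step-1 HCP and a step-1 LCP is always
a step-5 LCP; near-threshold promoters can shift one class, which the tests
bound explicitly.

Genomic-location labels are exclusive with precedence
promoter > exon > intron > intergenic (the field convention when a site lies
in nested annotation); repeat, imprinted-cluster and gDMR overlaps are
reported as separate non-exclusive flags. DMR labels (promoter-DMR,
imprinting-region DMR, gDMR- and repeat-overlapping) require ≥ 1 bp overlap
on half-open, strand-blind intervals.

## Clustering and expression integration

Promoter-DMR methylation matrices (regions × samples, raw levels — the
heatmap quantity is the methylation ratio itself, so rows are deliberately
not re-scaled) are partitioned by K-means with K = 3, k-means++
initialisation, best of 10 restarts by within-cluster sum of squares, with a
fixed seed; rows are re-ordered by identifier within each cluster. DMR and
expression matrices are ordered by agglomerative hierarchical clustering;
average linkage on Euclidean distances is the package default (exposed as
arguments). FPKM expression is converted per gene to
z = (x − mean)/sd with the **n − 1** standard deviation — with three cell
types this choice is material, so it is fixed in the library rather than
left to callers. Genes with zero FPKM in all samples are removed first;
remaining zero-variance genes cannot be standardised and are dropped with a
logged count. "No expression" means FPKM exactly 0; no near-zero threshold
is applied.

## Synthetic data generator

The generator emulates the statistical structure the analysis assumes, not
any real genome:

- **Sequence.** Random contigs (GC ≈ 42%) with CpG dinucleotides depleted to
  O/E ≈ 0.2 (an i.i.d. sequence would sit at O/E ≈ 1, which no vertebrate
  genome does). MspI sites (CCGG) are planted at spacings drawn uniformly
  from 150–330 bp so that a large share of digest fragments falls in the
  170–370 bp size-selected range and CpG coverage concentrates near
  fragments, as in RRBS.
- **Features.** Non-overlapping gene blocks (promoter ±1 kb around the TSS,
  three exons, derived introns), LINE/SINE/LTR repeats, and imprinted
  clusters each containing one gDMR sub-interval. Half of the promoters (by
  default) receive a CpG-island-like core (GC ≈ 60%, a forced CG every 8 bp)
  that guarantees an HCP-qualifying window; the rest stay on the depleted
  background and class as LCP/ICP. Large blocks are placed first, with an
  exact free-gap fallback, so a sizing error means the request truly does
  not fit.
- **Methylation states.** Each CpG's true methylation probability m is drawn
  from a two-component Beta mixture — Beta(1.5, 30) near 0, Beta(30, 1.5)
  near 1 — whose high-component weight depends on the feature class
  containing the CpG (innermost feature wins; gDMR > imprinted cluster >
  promoter > repeats > exon > intron > background). The shipped archetypes
  are generator settings, not measurements:

  | class | ESC-like | C-like | 4F-like |
  |---|---|---|---|
  | background | 0.03 | 0.08 | 0.22 |
  | promoter | 0.01 | 0.05 | 0.10 |
  | exon / intron | 0.03 | 0.10 | 0.30 |
  | repeats (LINE/SINE/LTR) | 0.05 | 0.40 | 0.80 |
  | imprinted cluster | 0.05 | 0.40 | 0.80 |
  | gDMR | 0.08 | 0.40 | 0.80 |

  This produces the intended qualitative contrasts: a strongly bimodal
  4F-like methylome, hypermethylated repeats and imprinted regions in the
  4F-like archetype, an intermediate C-like one, and a globally
  hypomethylated ESC-like one. Cell types share per-CpG uniform variates for
  the mixture component and the Beta quantile (comonotone coupling), so
  their methylomes are highly correlated — as real pluripotent methylomes
  are — while each marginal remains exactly its profile's mixture. A
  consequence of the nested component indicators is that a lower-weight
  archetype is never *truly* more methylated at any CpG than a higher-weight
  one: hypomethylation calls against the 4F-like archetype arise only from
  sampling noise and are therefore rare in simulated data.
- **Counts.** Per covered CpG (inside a retained fragment) and sample,
  t ~ Poisson(30) by default, optionally Gamma-overdispersed across
  replicates (dispersion 0.05), and m_obs ~ Binomial(t, q) with
  q = m + (1 − m)(1 − c): incomplete bisulfite conversion (default
  c = 0.995) leaves unmethylated Cs unconverted and *inflates* apparent
  methylation rather than being ignored.
- **Expression.** A synthetic FPKM table ties each gene to its promoter
  methylation, FPKM = 30 · 2^(−6·m) with log-normal noise, plus a 5% random
  all-zero subset to exercise the zero-expression filter.

What the simulator does **not** emulate: real sequence composition, SNPs,
non-CpG methylation, sequencing error, PCR duplicates, read geometry,
allele-specific (parent-of-origin) methylation — gDMR hypermethylation is
modelled as a bulk shift, not monoallelic 50% — or biological replicate
structure beyond count overdispersion. Passing tests therefore demonstrate
the correctness of the pipeline's arithmetic, gating, testing and
aggregation on data with the assumed structure; they do not validate the
archetype parameters against any real methylome.

One caveat made explicit: the inter-sample reproducibility check
(Spearman R > 0.9 between two samples observing the same states at 30×)
holds for spread-out state distributions (e.g. uniform, R ≈ 0.94). Under the
strongly bimodal default profiles the near-zero mode is dominated by
binomial rank noise at 30× and replicate Spearman sits near 0.75–0.8; real
RRBS reaches R > 0.9 with deeper effective coverage and a much larger site
universe. The reproducibility test uses the uniform-state null.

## Problem sizes and determinism

The default end-to-end conditions are a 2 × 250 kb genome (≈ 8,800 CpGs,
≈ 5,700 gated), three cell types × two replicates at 30× — the full pipeline
runs in seconds. The planted-recovery analysis uses the larger 2 Mb genome
with 50 planted regions (≥ 5 CpGs each, true difference 0.5) at 30×.
Every random draw flows from explicit seeds through
`numpy.random.default_rng` / `SeedSequence.spawn`, and tabular outputs are
written with fixed formatting, so identical configuration and seed reproduce
byte-identical artifacts.

## Known limitations

- No beta-binomial model of biological variance: the Fisher test treats
  replicate-pooled counts as one binomial sample, so with many replicates it
  is anti-conservative relative to dispersion-aware callers. q-values are
  reported but not used for gating, by design.
- Gap-based DMR chaining has no statistical control at the region level;
  region counts depend on the max-gap/min-CpG defaults.
- The promoter classing step size trades exactness for speed; step 1
  reproduces the exhaustive scan exactly and is available everywhere.
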
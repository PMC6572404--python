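# Methods

This note records the statistical model bsmeth implements, the defaults and
why they were chosen, what the synthetic-data generator does and does not
emulate, and the numerical conventions that matter for reproducing results.

## Coordinates and formats

All internal intervals are 0-based half-open. 1-based coordinates exist only
at format boundaries: the `pos` column of the cytosine (CX) report and GFF3
start/end. The CX dialect is fixed to seven tab-separated columns without a
header (chrom, pos, strand, mC count, umC count, context, trinucleotide),
matching the dominant aligner-emitted cytosine-report convention.
Zero-coverage cytosines are kept in memory: they contribute nothing to any
ML denominator, but window site-count filters need to know they exist.

## Context classification

A cytosine's context is read from the next two bases 5'→3' on its own
strand: CG when base+1 is G, CHG when base+2 is G, CHH otherwise (H =
A/C/T). Within 2 bp of a contig end, or when either following base is not
A/C/G/T, the context is Unknown — a CG whose second following base is
ambiguous is deliberately not rescued, so every non-Unknown label is based
on two confirmed bases. Two independent implementations exist (a positional
scan in `core` and a regex scan in `simulate`); the test suite and the
acceptance script verify they agree at every cytosine of random genomes.

## Site-level methylation calling

The methylated read count at a covered site is modelled as
Binomial(coverage, r). A site is called methylated by the one-sided exact
binomial test H₀: r = ε vs H₁: r > ε, where ε is the bisulfite
non-conversion rate (default 0.005 — the order observed for spiked
unmethylated controls in plant WGBS). P-values are Benjamini–Hochberg
corrected across tested sites and called at α = 0.05 by default. Both the
null rate and the correction are explicit configuration, since a binomial
model alone does not fix a decision rule; the chosen rule is the standard
practice for WGBS site calling. Under a simulated null methylome (every
site truly unmethylated at rate ε) the uncorrected false-call rate at α
stays below α + 3 SE, which the acceptance battery re-measures on every
run.

Site ML at zero coverage is undefined (NaN), never 0, to avoid silently
deflating window averages.

## Windows and genome summaries

Genome-scale ML tracks pool counts in non-overlapping bins (default 10 kb)
tiled from coordinate 0; terminal partial windows are kept so that pooled
counts over windows exactly conserve pooled counts over sites. Per-context
summaries report two different quantities that must not be conflated:

- the share of methylated cytosines falling in each context (sums to 100%),
- the within-context ratio of called-methylated to tested sites.

Level histograms use four equal ML bins by default, matching the quartile
bands conventionally used to display per-context level distributions.

## 9-mer motif tables

For every methylated cytosine the 9 bp window with the cytosine in the
fifth position is extracted on the cytosine's strand. The
position-frequency matrix is computed over methylated sites only; the
per-9-mer "percentage of methylation" is (methylated sites / tested
sites)·100 within the motif class. A read-weighted variant (pooled mC over
pooled coverage) is available behind `weighted=True`, since either reading
of "percentage" is defensible; the site-count version is the default
because it matches how per-context ratios are reported. Motifs with fewer
than 10 tested sites are flagged low-confidence — percentages over a
handful of sites are unstable.

## Feature and metagene profiles

Feature classes are promoter (upstream 2 kb of the TSS, strand-aware),
exon, intron (gene span minus exons), and repeat. A site inside overlapping
features counts once per class it touches; genes overlapping other genes'
flanks still contribute, with no masking — the simplest rule that conserves
counts.

Metagene profiles bin the upstream and downstream 2 kb flanks into 20 fixed
100 bp bins each and the gene body into 20 proportional bins (defaults;
curve shape is insensitive to the bin count at these scales). Counts are
pooled across genes per bin and the frame is mirrored for minus-strand
genes; genes shorter than the body bin count are excluded because they
cannot fill the body bins.

Expression classes follow the FPKM convention: *none* below 1, then *low*,
*medium*, *high* splitting expressed genes (FPKM ≥ 1) at the lower/upper
quartiles computed over expressed genes only. Ties at a quartile boundary
go to the lower class, and FPKM exactly 1 is *low* (it cannot be *none*,
whose rule is strict FPKM < 1). For region-level comparisons the classes
pool into L (none + low) and H (medium + high) and are compared per region
with a two-sided Mann–Whitney U on per-gene weighted MLs; per-gene rather
than per-site values are used so deep-covered genes do not dominate the
rank test. When every per-gene ML is identical the test is degenerate and
p is reported as 1.

## DMR calling

Windows of 1000 bp advanced in 100 bp steps cover every base; the terminal
window is clipped. In each window, sites with coverage ≥ 4 in *both*
samples (min 5 such sites) contribute pooled counts to a 2×2 table tested
with a two-sided Fisher exact test. Kept windows need p < α (default 0.01)
and a pooled ML difference ≥ 0.1; same-direction kept windows separated by
at most one step merge into a DMR. Merged regions are re-scored from their
pooled counts — combining window p-values would assume independence that
overlapping windows do not have. The coverage/site/effect-size floors are
recorded in the run manifest; they suppress windows whose Fisher test would
be driven by a handful of reads.

Numerics: the two-sided Fisher p sums the probabilities of all tables with
the observed margins that are no more likely than the observed one. For
tables with grand total ≤ 200 the sum is carried out in integer arithmetic
(hypergeometric probabilities share one denominator, so tables compare by
integer numerators and no floating-point tie tolerance is needed); larger
tables delegate to `scipy.stats.fisher_exact`. The exact path is verified
against an independent factorial-based enumeration of every 2×2 table with
margins ≤ 40, and both paths against scipy on random tables.

DMR-gene association: a gene is DMR-associated when any DMR intersects its
body or ±2 kb flanks. Per link the compartment follows the precedence
promoter > exon > intron > downstream; repeat overlap is reported
independently. The genome-wide compartment distribution instead assigns
each DMR a single primary compartment by maximal bp overlap (ties by the
same precedence, repeat before other) so shares sum to 100%.

DMRs are called per context, not over pooled contexts: the three contexts
are maintained by different methyltransferase pathways and mixing them
would let an abundant context mask a differential sparse one.

## Expression integration

The differential-expression model is not refit: the module consumes a
fold-change/FDR table and applies fold change ≥ 2 and FDR ≤ 0.05, both
inclusive. Enrichment of each (hypo|hyper) × (up|down) pair is a two-sided
Fisher exact test on a 2×2 partition of the gene universe (default: all
annotated genes; configurable, since the appropriate background depends on
what was testable in both assays). The odds ratio is the cross-product,
with a 0.5 continuity correction flagged when a cell is zero. The
2^-ΔΔCt utility implements relative qPCR quantification:
2^-((Ct_target − Ct_reference) − (Ct_cal.target − Ct_cal.reference)).

## Clone bisulfite analysis

Clones are aligned to the untreated amplicon with a global affine-gap
alignment (match +2, mismatch −2, open −6, extend −1) in which reference C
against clone T scores as a match — the expected signature of conversion,
not an error. Clones below 70% identity (bisulfite-aware matches over
amplicon length) are rejected with a report. At each amplicon cytosine the
C/T calls are tallied across clones; percent methylation is
100·C/(C + T) with any other base or unaligned position excluded from the
denominator. Region summaries pool counts per context inside
promoter-relative intervals; the coordinate convention is that −1 is the
base immediately upstream of the TSS and there is no position 0. Clones
are not deduplicated — sequenced clones are presumed independent molecules.
Conversion efficiency, 100·T/(C + T) over non-CG (or user-designated
control) sites, is reported as a QC figure; in heavily CHG/CHH-methylated
plant material it understates the true efficiency and should be read
accordingly.

## The synthetic-data generator

The generator is the package's ground truth and defines the conditions the
test battery runs under:

- **Genome**: random sequence at GC 0.39 (a typical eudicot genome), genes
  of 1.5–4 kb with 1–5 exons placed without overlap, repeats dropped into
  intergenic space.
- **Methylation architecture**: `base_rates` (CG 0.6, CHG 0.4, CHH 0.08)
  give the probability that a site of a context is methylated at all — a
  Bernoulli site state, matching how per-context methylation ratios are
  reported as site fractions in plant methylomes. A methylated site draws
  its true level from a per-context Beta: CG ~ Beta(8, 1.5) (mass in the
  75–100% band), CHG ~ Beta(1.3, 1.3) (broad), CHH ~ Beta(2, 8) (low,
  0–25% band). Unmethylated sites have level 0.
- **Sharing across samples**: baseline states and levels are drawn once per
  seed and shared by all samples, so samples differ only inside planted
  DMRs. This is what makes the no-difference null meaningful; it also means
  the generator does not emulate genome-wide tissue shifts in methylation —
  only localised differential regions.
- **Reads**: coverage ~ Poisson(30); methylated count ~ Binomial(n, r +
  (1 − r)·ε) with ε = 0.005. Conversion error acts only meth-ward (false
  methylation), the dominant artifact class in real bisulfite data; false
  unmethylation is not modelled.
- **Expression**: FPKM ~ lognormal; genes whose promoter overlaps a planted
  hypo-DMR are forced up-regulated with probability `planted_assoc`, others
  receive a 5% background DEG rate independent of methylation. Fold
  changes and FDRs are planted labels, not refit from the FPKM draws — the
  integration module consumes exactly this kind of upstream table.
- **Clones**: each clone converts every unmethylated C to T, retaining C
  per-site with the site's methylation probability and on conversion
  failure with probability ε.

What passing tests therefore show: the pipeline recovers planted
parameters, regions and associations under binomial read sampling at
realistic coverage, with exact agreement between independent
implementations of the deterministic primitives. What they do not show:
robustness to alignment artifacts, coverage biases, strand asymmetries,
biological replicate dispersion (single library per sample, as is common in
organ-level WGBS designs), or genome-wide methylation shifts between
samples.

## Problem sizes and determinism

The verification battery runs at deliberately modest scales chosen as the
smallest sizes at which each property is statistically sharp: 50 × 10 kb
genomes for the classifier cross-check, all 741 321 2×2 tables with margins
≤ 40 for the Fisher enumeration, ~12 000 null sites for type-I calibration,
five seeds × ten planted 2 kb DMRs at coverage 30 for recovery, a 1 Mb
genome for rate recovery, 200 genes for the metagene flat-limit, and ten
seeds per condition for the enrichment contrast. All randomness flows from
`numpy.random.default_rng` seeded from a single integer; reruns of the
pipeline with one seed are byte-identical, which the manifest's SHA-256
checksums make checkable.

## Known limitations

- DMR boundaries inherit the sliding-window resolution: calls extend up to
  about one window beyond a sharp planted boundary.
- The Fisher test treats reads as independent draws; overlapping mates or
  PCR duplicates would violate this upstream of the pipeline.
- Three-way (rather than pairwise) differential models and replicate
  dispersion models are out of scope.
- GO/KEGG enrichment of DMR genes requires external annotation databases
  and is not included.
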
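# Methods

## Scope and data model

The package analyzes CAGE-type 5'-end data: per-sample **CTSS** records
(chromosome, 1-based position, strand, tag count). All interval-valued
entities (clusters, peaks, exons, promoter windows) use 0-based half-open
coordinates (BED convention); single-base TSS positions are 1-based (CTSS
convention). Conversion happens only in `cryptic_tss.core`/`io`, never ad
hoc downstream.

## Normalization and clustering

Counts are normalized to **tags per 10 million** (TP10M):
`tp10m(p) = count(p) / library_size × 10^7`, so per-sample TP10M sums to
10^7 before thresholding. Positions with TP10M ≥ `min_tp10m` (default
0.5) are clustered per (chromosome, strand) by greedy single-linkage over
sorted positions: consecutive surviving CTSSs join one tag cluster iff
their distance is ≤ `max_gap` (default 20 bp). This is the *distclu*
flavor of CAGE clustering; the greedy pass over sorted positions is
provably identical to the transitive closure of the pairwise gap relation,
and the test suite checks that equivalence against an O(n²) brute force on
1,000 random instances. The dominant position is the argmax-count base,
ties resolved to the 5'-most base (strand-aware) for determinism. Cluster
breadth is summarized by the interquantile width (default q = 0.1–0.9):
the distance in bp between the first positions whose 5'→3' cumulative
count reaches each quantile, plus one.

Per-sample tag clusters are merged across samples into **consensus
clusters** when intervals on the same strand are within `merge_gap`
(default 0, i.e. overlap or direct adjacency). Each consensus carries one
TP10M value per sample (sum of that sample's overlapping tag clusters; 0
when absent) and the dominant position of its highest-expressed member.

## Categorization and enhancer filtering

A consensus cluster is categorized by its **dominant base**, not its whole
interval, with priority *annotated promoter > exonic > intronic >
intergenic*. Promoter windows are annotated TSS ± `promoter_halfwidth`
(default 500 bp; the window is a free parameter of such analyses and is
recorded in the run manifest). Gene-linked categories require a
sense-strand match; an antisense hit falls through (CAGE is stranded, and
antisense initiation within a gene body is not initiation *of* that
gene). Introns are gene-body minus the union of exons over transcripts.

Clusters whose interval intersects ≥1 bp of an ATAC **or** H3K27ac peak are
flagged as putative enhancer RNA sources; the sensitive-set construction
removes them, and per-set overlap fractions are reported separately.
CpG-island overlap likewise uses ≥1 bp intersection of the full cluster
interval (whether the original analyses used intervals or dominant bases
is not documented anywhere; the interval rule is the more conservative
enhancer filter and is declared here).

The built-in CpG-island caller uses the Gardiner-Garden–Frommer criteria
(length ≥200 bp, GC ≥0.5, observed/expected CpG ≥0.6 with
obs/exp = #CG·L/(#C·#G)), scanning 200-bp windows at step 1, merging
overlapping qualifying windows, and re-measuring each merged interval —
trimming back to a qualifying core if needed — so that every reported
island satisfies all three criteria under independent re-measurement. An
externally supplied island BED is accepted anywhere the caller's output is.

## Differential classification

With condition means m_WT and m_KO (mean TP10M over replicates) and
presence defined as mean ≥ `presence_min` (default 1 TP10M):

* **On** = absent in WT ∧ present in KO; **Off** = the reverse;
* otherwise **Up** if log2((m_KO+ψ)/(m_WT+ψ)) ≥ log2(f), **Down** if
  ≤ −log2(f), else **Unchanged** (ψ = 0.1, f = 2 by default);
* **Absent** when below presence in both conditions.

This is a deliberately simple thresholded classifier rather than a
count-model test: consensus clusters carry replicate-level TP10M, so users
wanting dispersion-aware calls can feed the expression matrix to a
negative-binomial GLM; the pipeline's own claims (set construction,
ratios, attribution) are robust to the classifier choice at the planted
effect sizes it is validated on, and that validation is exactly what the
acceptance checks measure.

Sensitive sets: the two-clone (HDAC-pathway) set takes intragenic
(exonic/intronic), non-enhancer clusters **Up in both clones** —
concordance across independent clones is the replication guard; the
single-KO (DNA-methylation-pathway) set takes intragenic, non-enhancer
clusters **On or Up**. Each filter step's surviving count is recorded as
provenance and asserted non-increasing.

Set overlap uses connected components of the slack-extended interval
overlap graph: components containing members of both sets count as
shared, which makes the count symmetric even when one interval overlaps
several from the other set. Nearest distances are measured between
dominant positions on the same chromosome; queries with no same-chromosome
reference are reported missing, and the fraction within 100 bp is
summarized. Expression quartiles sort genes by descending wild-type
expression (summed TP10M of their annotated-promoter clusters) and split
them into four `np.array_split` groups (n = 10 → sizes 3,3,2,2), ties
broken by gene id. Chi-square tests are Pearson tests of independence
without continuity correction (margins → expected counts,
df = (r−1)(c−1)). Rank-sum comparisons are two-sided Mann-Whitney U:
exact null distribution when both groups have ≤20 observations and no
ties, tie-corrected normal approximation otherwise (the exact recurrence
assumes no ties).

## Metagene profiles

For each site the signal matrix row holds mean coverage in `bin_size`
(25 bp) bins over oriented offsets o ∈ [−1000, 1000), where offset o maps
to genomic position dom₀+o on plus-strand sites and dom₀−o on minus-strand
sites. This convention makes column profiles exactly invariant under
mirroring the genome (coordinates reversed, strands flipped), which the
tests assert. Out-of-bounds positions are missing and excluded from
column means.

Sites are isolation-filtered first: any site closer than 2 kb (default) to
another candidate is dropped — both members of a close pair — and optional
exclusion sets apply their own distances (e.g. 2 kb from annotated TSSs,
100 bp from the other pathway's sites). The per-site scalar used for group
comparison is the **relative difference** (m_KO − m_WT)/(m_WT + ψ) of mean
coverage over the central ±250 bp, ψ = 1. Sites are ranked by an
upregulation score — mean KO TP10M − mean WT TP10M by default, log2 fold
change optionally — and the Top/Bottom groups are the first/last
⌊0.175·n⌋ (the fraction approximates the 326-of-1,869 grouping used in
this kind of analysis; it is configurable). Top vs Bottom relative
differences are compared per track by the two-sided rank-sum test.

## Synthetic-data generator

The generator is first-class, tested code; its defaults *are* the study
conditions the validation runs under.

* **Genome/annotation**: 2 chromosomes × 100 non-overlapping multi-exon
  genes (4–7 exons of 200–400 bp, introns 1.5–3.2 kb, both strands,
  intergenic gaps 2.5–5.5 kb), background sequence iid at 40% GC (which is
  CpG-depleted relative to the ≥0.5-GC island criterion, so no background
  islands fire). TSS ± 300 bp is rewritten at 60% GC with CG dinucleotides
  injected at rate 0.12, so the island caller fires on >80% of promoters.
* **Expression**: genes split into four equal quartiles with mean expected
  WT tags 2000/400/50/0 per replicate and lognormal within-quartile spread
  (σ = 0.3); the top ~10% by expression get a "high" occupancy label,
  emulating an externally supplied binding classification.
* **Cryptic sites**: 150 primary-pathway sites (85/10/5% in
  High/Intermediate/Low genes by largest-remainder allocation), base mean
  30 tags, width 1–5 bp with geometric tag spread, sense strand of the
  host, ≥800 bp from the host TSS and ≥2.5 kb from any other planted
  site; 90% are Up (KO mean ×4), 10% Down (÷4). A second, disjoint
  pathway of 80 sites (60% On: WT mean 0; 40% Up) is measured in a
  separate single-KO experiment sharing the genome — this provides the
  cross-pathway overlap and nearest-distance analyses with a known-disjoint
  truth.
* **Enhancers**: 30 intergenic sites emitting tags on both strands
  (±75 bp), each covered by an ATAC and an H3K27ac peak; peaks are also
  placed at expressed promoters and nowhere else, so the enhancer filter
  cannot remove planted cryptic sites by construction.
* **Counts**: per site × replicate, totals are negative binomial with
  variance μ + d·μ² (d = 0.1; d = 0 degrades to Poisson), spread over the
  site's shape by a multinomial; a uniform background process adds 0.05
  tags/kb per replicate on random strands. Replicates: 3 WT + 2/3 per KO
  clone, and 2+2 for the single-KO experiment.
* **Tracks**: each expressed site contributes Gaussian bumps at ±150 bp
  (σ = 75 bp) — the ±1-nucleosome acetylation pattern with a trough at the
  site — scaled by expression with per-site lognormal jitter (σ = 0.2);
  KO tracks multiply bump height by 1.5 at KO-sensitive sites (or at an
  explicit site list, used by the planted Top-group experiments).
* **Determinism**: every artifact is a pure function of the config;
  independent `SeedSequence` streams per (artifact, experiment, sample)
  make outputs byte-identical across runs and independent of call order.

What the generator does **not** emulate: promoter sequence motifs, splice
isoform diversity, mappability artifacts, batch effects between
replicates, library-size imbalance, antisense promoter transcription, and
realistic library depth (a desk-scale library of ~10^5 tags makes a single
background tag worth ~80 TP10M, so On calls in the single-KO comparison
absorb background singletons — at realistic 2×10^7-tag depth the same
1-TP10M presence threshold suppresses them). Passing tests therefore
demonstrate correctness of the pipeline's logic and its recovery of
planted structure under the stated noise model, not performance on real
sequencing data.

## Numerical and design choices

* Duplicate CTSS input lines are summed, not rejected.
* Clustering/consensus parameters, thresholds, and pseudocounts are free
  parameters (no canonical published values exist for this kind of
  analysis); every default is in `AnalysisParams`/`SyntheticConfig`, can
  be set in the YAML config, and is echoed into `manifest.json`.
* "Longer than 10 nt" width filtering is strict (> 10). On synthetic data
  the planted 1–5 bp cryptic widths empty the filtered set, so the GC
  summary also reports unfiltered medians.
* The dominant-position tie-break (5'-most), quartile tie-break (gene id)
  and Top/Bottom tie-break (cluster id) exist purely for deterministic
  output.
* The run manifest records parameters and counts but no wall-clock
  timestamps: byte-identical reruns are treated as more valuable than
  embedded timing metadata.
* Degenerate inputs: empty libraries, empty clusters, empty rank-sum
  groups, empty nearest-distance references and zero-margin contingency
  tables raise; unknown chromosomes in metagene computation are skipped
  with a logged count; all-N sequence yields missing GC.

## Validation problem sizes

The default validation study is 2 chromosomes (~1.6 Mb each), 200 genes,
150 + 80 planted cryptic sites, 12 CTSS libraries of ~10^5 tags; repeated
stochastic checks (Up:Down asymmetry, Top/Bottom discrimination) use 20
seeds of a single-chromosome, 60–80-gene layout. These sizes give
binomial error bars comfortably inside the asserted tolerances (e.g.
recovery ≥90% at a true per-site recovery probability of ~96%) while the
full suite runs in well under a minute.

## Known limitations

* The differential classifier ignores replicate dispersion (documented
  above); no multiple-testing correction is applied because the pipeline
  reports classifications, not per-cluster p-values.
* bigWig and BAM are out of scope; bedGraph and CTSS text stand in.
* Motif discovery and GO enrichment are external analyses and are not
  reimplemented.
* Isolation filtering uses dominant positions only; interval-aware
  isolation would differ for very broad clusters.
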
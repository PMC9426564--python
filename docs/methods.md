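# Methods

## Metagenomic distances on k-mer spectra

A sample's profile is the multiset of canonical k-mers over all its reads:
every length-k window over {A, C, G, T} increments the count of the
lexicographic minimum of the window and its reverse complement; windows
containing N are skipped, and both mates of a paired sample pool into one
profile.  Counting is exact — k-mers are packed 2 bits/base into uint64
words (hence k ≤ 31) and tallied in one vectorized pass — rather than
sketched, because the package targets desk-scale inputs; the distance
contracts would hold equally for a sketched backend.

Two dissimilarities are defined on profiles p, q (absent k-mers count 0):

- **abundance-weighted Jaccard** (the default):
  d = 1 − Σ_w min(p_w, q_w) / Σ_w max(p_w, q_w).  This is the Ruzicka
  dissimilarity; it is a true metric, which is the reason it is preferred
  for hierarchical clustering.
- **Bray–Curtis**: d = 1 − 2 Σ_w min(p_w, q_w) / (Σp + Σq).  Bounded and
  symmetric but not triangular; provided for comparison only.

Both return 0 for two empty profiles (identity convention).  Defaults:
k = 21 (the conventional length for comparative metagenomics — long
enough that random collisions are negligible, short enough to tolerate
sequencing error), `min_abundance` = 1 (no solid-k-mer filter is imposed;
filtering is exposed as a parameter because published pipelines differ).

## Coassembly group selection

Ward-criterion agglomerative clustering is applied **directly to the
dissimilarity matrix** — the Lance–Williams recurrence on squared
dissimilarities with square-rooted heights (the "ward.D2" convention, as
implemented by scipy's `linkage(…, method="ward")` on a condensed
distance input).  No Euclidean embedding is performed; with a metric
dissimilarity the update is well behaved and deterministic (scipy breaks
equal-cost merges by index, so runs are reproducible across platforms).

The dendrogram is cut at every k from 2 to n−1 (`cut_tree`, i.e. undoing
the last k−1 merges) and each partition is scored by the unweighted mean
silhouette with the common convention s(i) = 0 for members of singleton
clusters.  `optimal_k` is the argmax, smallest k on ties.  The full curve
is retained and written as two-column plot data.

**Suboptimal k.**  To compare against an a-priori grouping with a given
number of groups, `find_suboptimal_clustering` returns the silhouette
**local maximum** nearest the target count (curve endpoints compare
against their single neighbour; ties break toward the higher silhouette,
then the smaller k).  This rule is a documented policy, not a unique
answer — any cut level can be forced via `--suboptimal-k`.

## Strategy planning

With N samples and G coassembly groups:

| strategy | assembly units | mapping jobs |
|----------|----------------|--------------|
| SASB     | N (one per sample) | N |
| SACB     | N | N² |
| CASB     | G (one per group)  | Σ_g \|g\| = N |
| CACB     | G | N·G |

"Cobinning uses all metagenomes" is read as all samples in the input
manifest.  Unit ids are `single_<sample>` / `coasm_<group>`; job lists are
deduplicated and sorted so emitted plans are byte-stable.

## Coverage, breadth, detection

Alignments reduce to 0-based half-open aligned spans (SAM/BAM
`reference_start..reference_end`; soft clips and insertions fall outside
the span).  Defaults: primary alignments only, no MAPQ floor.  Per-base
coverage is accumulated with difference arrays, so mean and **population**
variance per (contig, sample) are exact.  Contigs shorter than 1500 nt are
excluded from the depth table (the binning floor); the table is written in
the `jgi_summarize_bam_contig_depths` column dialect
(`contigName contigLen totalAvgDepth` then `<sample>.bam`,
`<sample>.bam-var` pairs) so MetaBAT2 can consume it unchanged.

Per genome and sample: breadth = fraction of positions covered ≥ 1×
(overlaps count once); mean depth = coverage sum / length;
`mapped_read_fraction` = distinct mapped query ids / sample read count
(duplicate alignments of one read add depth but count once for
recruitment).  A genome is **detected** at breadth ≥ 0.3 — the boundary is
inclusive, since a "minimum of 30%" reads naturally as ≥ — and the flag is
exposed.  Prevalence counts detecting samples; cumulative abundance is
Σ_samples (100 × mapped_read_fraction) / genome length, i.e. a mapped-read
percentage normalized per base.  The recruitment denominator is per
sample, not pooled over the dataset; with unequal sample sizes the two
normalizations differ.

## Quality classes and dereplication

HQ requires completeness > 90 **and** contamination < 5; MQ requires
> 50 and < 10; all inequalities strict, everything else LQ.  Only HQ and
MQ bins are MAGs and only MAGs may enter dereplication.

**ANI estimator.**  Alignment-free, so the package needs no embedded
aligner: the smaller genome is tiled into non-overlapping 1000-bp windows
(per contig; full tiles, with a whole short contig as its own window);
each window's canonical 16-mer containment j in the other genome's k-mer
set converts to a per-window identity j^(1/k), because under an i.i.d.
substitution model at divergence d a k-mer survives intact with
probability (1−d)^k and the window containment concentrates there.  ANI is
the mean identity over mapped windows and the aligned fraction is the
mapped share of windows, both measured on the smaller genome.  A window is
mapped only when j ≥ 0.01 (≈ 10 of ~985 window k-mers): a lone chance hit
— expected in a few percent of windows against an unrelated 100-kb genome
— is not alignment evidence, while genuine homology keeps j ≥ 0.028 even
at the 20% divergence cap of the mutation model.  On simulated
substitution-only pairs the estimator tracks realized divergence within
about 0.2 percentage points up to 10% divergence; small asymmetry (< 0.01)
arises only from which genome is tiled.  The simple Jaccard-style
log-transform sometimes used with sketch containment is deliberately not
used: applied to a containment index it overestimates identity by ~0.5 pp
at 1% divergence and ~3 pp at 10%, enough to cross the strain threshold.

**Dereplication.**  Two MAGs link when ANI ≥ t and aligned fraction
> 0.6 (strictly); clusters are connected components of that graph (single
linkage — the simplest rule consistent with a pairwise duplicate
criterion; production dereplicators add a pre-clustering stage, which
changes efficiency, not the threshold semantics).  t = 0.95 corresponds to
species-level and t = 0.99 to strain-level collapsing.  Each cluster's
representative maximizes completeness − 5 × contamination (a borrowed
scoring convention, not derived here), ties broken by larger genome then
lexicographic id.

## Synthetic communities

Genomes are i.i.d. base sequences (optionally GC-biased) — distance and
clustering behaviour needs compositional contrast, not biological realism,
and nothing is downloaded.  Abundances are log-normal with μ = 1, σ = 2 on
the natural log (the conventional simulator defaults).  Reads: source
genome ∝ abundance × length, uniform start and strand, i.i.d.
substitutions at `error_rate` (default 0.001, short-read scale), fixed
quality; origins are recorded so recovery tests never re-read FASTQ.
Substitution-only (no indels): indels barely affect k-mer distances at
these rates and would complicate the read-origin oracle.

**Planted structure.**  Groups get disjoint genome pools; each group draws
one base log-normal(μ, σ) profile and each of its samples multiplies that
profile by log-normal(0, `sample_sigma` = 0.5) jitter before
renormalizing.  The hierarchical draw makes within-group samples
correlated resamplings of one community — as related metagenomes are —
while between-group distances sit near 1.  Fully independent per-sample
draws at σ = 2 would let a single genome dominate different samples of the
same group and destroy the very structure being planted.

**Default desk-scale spec** (the `CommunitySpec` defaults): 12 samples in
3 groups, 12 genomes of 100 kb, 2 × 10⁴ reads × 150 bp per sample
(≈ 3 Mb) — a deliberate scale-down from Gbp-sized real metagenomes.
Replicate sweeps in the test-suite and acceptance script use smaller
communities (20-kb genomes, 2500 × 100-bp reads) across 3–8 groups and
12–60 samples so that a hundred full pipeline replicates run in minutes on
one CPU; these sizes keep per-pool coverage above ~4×, which is what the
recovery property actually needs.

What passing tests show — and what they do not: recovery results
demonstrate the distance/clustering machinery under clean compositional
contrast (disjoint pools, substitution-only error, no conserved regions
shared across groups).  Real communities share genes and strains across
habitats, so real between-group distances are < 1 and optimal k is less
clear-cut than in these tests.

## Numerical and degenerate-input conventions

- Distances of two empty profiles are 0; mismatched k is a usage error.
- Silhouette requires ≥ 2 clusters; singletons score 0; equidistant data
  score 0.
- `count_kmers` with k longer than every read warns and returns an empty
  profile (not an error).
- Depth variance is the population variance (divide by L), matching depth
  summarizers.
- Quality percentages outside [0, 100] are clamped with a warning on
  read-in (contamination may legitimately exceed 100 and is kept).
- All generators are pure functions of (spec, seed); gzip writers pin
  mtime = 0 so outputs are byte-reproducible.
- Floats are serialized with `%.10g`, enough for exact round-trips at the
  precisions produced here.

## Known limitations

- Exact in-memory counting bounds input size by RAM; terabyte-scale
  comparisons need the sketched/disk-based tools this package deliberately
  does not replace.
- The ANI estimator assumes substitution-only divergence; real indel-rich
  or rearranged genome pairs will read as lower aligned fraction.
- Connected-component dereplication can chain A–B–C at borderline
  thresholds where a centroid-based scheme would split.
- The suboptimal-k rule is one reasonable policy among several; it is
  exposed and overridable rather than claimed canonical.
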
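# Methods

This note documents the models and conventions behind `symbiomark`: what
the pipeline assumes, what every tunable parameter means, what the
synthetic-data generator does and does not emulate, and where genuinely
open design choices were pinned.

## The analysis model

A library is a mixture of amplicons from three markers sequenced together
(COI via BF3/BR2, 16S V1-V2 via 27F/338R, 16S V4 via 515F/806R) on a
2×300 bp paired-end run. The pipeline treats each marker bin as an
independent amplicon dataset and assumes:

- reads are already demultiplexed per sample; only marker assignment
  remains, and it is decidable from the 5' primer sequences;
- within a marker, true biological templates are a small set of exact
  sequences; observed variation around them is substitution-dominated
  sequencing error, PCR chimeras, or genuine minor variants
  (heteroplasmy, numts, rRNA operon copies);
- negative controls (water carried through extraction, first PCR, and
  indexing) see the same reagent contaminants as specimens, at relative
  abundances at least as high, because they lack template competition.

### Marker binning

A pair is assigned to marker *m* iff the forward mate starts with
*m*'s forward primer and the reverse mate with its reverse primer, each
within `max_mismatch` IUPAC-aware substitutions (default 2 — tolerant of
sequencing error yet far below the distance between these primer sets;
no indels). Mixed-orientation pairs are detected and the mates swapped.
Pairs matching conflicting primers or more than one marker are kept in
an unassigned pool with a reason code, so binning is a partition of the
input.

### Merging and quality filtering

Merging maximizes (matches − mismatches) over all ungapped overlaps in
both geometries: *normal* (insert longer than a read; union contig) and
*staggered* (insert shorter than a read, each mate reading through the
opposite primer; the overlap consensus is emitted, which trims the
read-through). Defaults `min_overlap=20`, overlap mismatch fraction
≤ 0.15. Disagreements resolve to the higher-quality base; the merged
quality is the per-position maximum. Contigs pass iff expected errors
EE = Σ 10^(−Q/10) ≤ `max_ee` (default 1.0, the field-standard value) and
the length falls in the marker's window. Exact seed lookup makes the
error-free case O(1) per pair, with an exhaustive offset scan as
fallback.

### Dereplication, denoising, recruitment

Dereplication is exact and global across samples, with per-sample counts
retained; sequences seen once in the whole run are set aside (the
denoiser cannot distinguish them from error). Denoising is the
UNOISE-style greedy rule — in decreasing abundance order, unique *U* is
absorbed into centroid *C* iff substitution distance d(U,C) ≤ `d_max`
(10) and abundance(U)/abundance(C) ≤ skew(d) = 1/2^(αd+1) — run **per
sample**, with centroids merged across samples by exact sequence. The
per-sample scope matters: a genuine minor haplotype at 10% of an
individual's mitochondrial pool has a within-sample ratio of ~1/9 to the
dominant haplotype, but pooled across a cohort its ratio collapses to
~1/50 and any skew threshold would absorb it. With α = 3.0 (default),
skew(1) = 1/16 < 1/9, so such variants survive in their carriers, while
per-base error uniques (ratio ~1/500 at Q30) are still absorbed. α = 2.0
(the published default of the original denoiser) sits on the wrong side
of the 10%-at-d=1 case and is available as a parameter.

Because singleton removal discards the error-bearing majority of reads
at realistic noise (at Q30, ~1/3 of 418-bp COI reads carry at least one
error), final zOTU counts are rebuilt by **recruitment**: every unique
sequence, singletons included, maps to its exact centroid or to the
closest same-length centroid within `d_max` substitutions; more distant
sequences stay unmapped. At zero error the step is an identity on the
tables.

### Chimera screening

Applied to the 16S markers only (COI chimeras between divergent
mitochondrial templates are not expected to survive the thresholds, and
the screen risks flagging real heteroplasmy). For each abundance-sorted
zOTU, candidate parents are the more abundant non-flagged zOTUs of the
same length with ≥ `min_parent_ratio` (2.0) times its abundance (up to
`max_parents` = 64). For every ordered candidate pair, the best
single-crossover two-segment model is found by prefix/suffix mismatch
cumsums; the query is flagged iff the model beats the best single parent
strictly, by ≥ `score_min` (0.005) mismatches per base, **and** explains
the query to within `max_residual` (0.02) mismatches per base. The
residual guard is what keeps unrelated sequences — where an optimal
crossover can always shave a few mismatches by chance — from being
flagged.

### OTUs and taxonomy

97% clustering is greedy in abundance order against cluster
representatives, with identity pinned as 1 − levenshtein/max(length)
(unique across co-optimal alignments, equal to matches/columns for
equal-length substitution-only pairs). Taxonomy is best-hit against the
reference set, ties to the lexicographically smallest reference id, with
the lineage truncated at the deepest rank whose cutoff the identity
passes: genus 0.95, family 0.90, order 0.85, else domain only. The COI
path adds species at 0.97, the conventional barcoding threshold.

### Decontamination and thresholds

At zOTU level (then propagated to OTUs): a feature is a contaminant iff
mean relative abundance across controls ≥ `contam_ratio` (1.0) × mean
across specimens; features absent from all controls are never flagged.
Controls are pooled across the three roles. Non-target lineages
(mitochondria, chloroplast, Eukaryota, Archaea) are removed from 16S
tables by lineage keyword. Focal zOTUs need ≥100 reads **and** ≥5%
relative abundance in at least one library (both inclusive); the rest
sum into "Others", conserving per-sample totals exactly. Samples need
≥100 reads of their barcode zOTU and ≥1000 16S-V4 reads; the OTU display
view keeps OTUs reaching ≥1% in at least one library.

### Host typing

The barcode is the most abundant host-genus COI zOTU per specimen (ties
to the lower abundance rank). Species identity is the barcode's
species-rank taxonomy; mismatches with the morphological label are
reported and the molecular call wins downstream. Heteroplasmy variants
are non-barcode zOTUs of the barcode's OTU with ≥100 reads and ≥5% of
the OTU's reads in that sample (the whole-library denominator is a
switch); distances are substitutions, and indel-bearing variants are
annotated as possible artifacts. A non-barcode host-genus OTU is
numt-like iff in every library where it occurs the barcode OTU occurs
too and it stays ≤10% of the library; a dominating conspecific OTU is
logged as an anomaly rather than called either way, since read data
alone cannot separate a biological explanation from a laboratory one.
Off-target COI OTUs split into parasitoid candidates (insect lineage
outside the host family), endosymbiont signals (Rickettsiales), and a
logged remainder, with a 100-read tier separating "detected" from
"trace".

### Statistics

Distances are Jaccard (presence/absence) and Bray-Curtis (counts).
dbRDA Gower-centers the squared distance matrix, G = −½ J D² J, projects
onto centered one-hot factor designs, and reports tr(HGH) over the sum
of positive eigenvalues of G (both metrics are non-Euclidean; negative
eigenvalues are excluded from the denominator). Factors are tested
sequentially in the order given, with free permutation of sample labels
and p = (1+#{F* ≥ F})/(1+n_perm); constant factors contribute nothing
rather than erroring, so an intercept-only design cleanly reports zero.
The chi-square on 2×2 tables is the closed-form Pearson statistic
N(ad−bc)²/(r₁r₂c₁c₂) with df = 1, continuity correction off by default.
Operon strain grouping links same-genus features that co-occur in ≥90%
of the samples where either occurs and whose per-sample abundance-ratio
coefficient of variation (sd/mean of the natural-scale ratio — the
log-ratio CV is undefined at 50/50) is ≤0.5; connected components of
size ≥2 are single-strain candidates. Region concordance maps V4 and
V1-V2 features onto full-length 16S references by best infix alignment
and compares genus presence on samples passing a 1000-read floor in both
regions. Prevalence counts a specimen as infected at any retained reads
(floor 0), because trace infections are biologically meaningful here;
the floor is a parameter.

## The synthetic-data generator

The generator is first-class code: it produces per-sample gzipped FASTQ
pairs, a manifest, miniature reference databases, and a truth object
recording every decision, and is the substrate for all pipeline-level
tests.

What it emulates, with defaults chosen to mirror the surveyed system:
library sizes negative binomial per sample and marker (means 3000 for
COI and V4, 600 for V1-V2, dispersion 10; controls 300); within-sample
composition Dirichlet-multinomial (concentration 200) around configured
mean weights; obligate *Sulcia* (0.453) and *Nasuia* (0.266) in every
specimen; *Arsenophonus* at 0.822 prevalence in the main species with
four 16S operon copies at fixed 0.4/0.3/0.2/0.1 within-genome ratios
(multinomial split inside the symbiont's Dirichlet share, so the ratios
are stable the way genomic copy number is); *Phytoplasma* as a low-titer
(0.003) two-operon 50/50 pathogen with a nested-PCR label of imperfect
sensitivity (0.8); rare *Wolbachia*/*Rickettsia* that also appear in the
COI bin; a 1-substitution minor haplotype at 10% of the mitochondrial
pool in 15.9% of individuals; a 15-substitution numt at 1% of the COI
library; host mitochondrial 16S and chloroplast reads; reagent
contaminants shared with water controls; PCR chimeras (rate 0.01) with
uniform interior breakpoints; morphological mislabels at 0.03; *Nasuia*
absent from V1-V2 through a 27F primer-mismatch dropout. The per-base
substitution rate defaults to 0.001 with flat per-read Phred values
drawn around −10·log₁₀(error_rate) (~Q30, the MiSeq average); fixed
seeds give byte-identical output (gzip headers carry a zeroed
timestamp).

What it does **not** emulate — and therefore what passing tests do not
show about real data: indel and homopolymer errors, position-dependent
quality decay along the read, instrument-specific error motifs, index
cross-talk (available as a knob, off by default), variable amplicon
lengths within a marker, primer-site degeneracy in templates, and PCR
amplification bias beyond the Dirichlet noise. Real runs also confront
reference databases far larger and messier than the bundled fixtures.

## Numerical choices and degenerate inputs

Ordering is pinned everywhere randomness or ties could leak in:
dereplication sorts by (−abundance, sequence); zOTU and OTU ids re-rank
by total abundance after each stage; taxonomy ties break to the smallest
reference id; denoise absorption prefers the smallest distance, then the
larger centroid. Empty inputs return empty outputs (a zero-read request
yields valid empty FASTQ; an empty retained-sample set yields an empty
"Others" table); an all-zero sample is an error naming the sample;
decontamination without controls is an error unless explicitly skipped.
Problem sizes in the test suite (20-specimen round-trip runs, a
200-specimen COI-only heteroplasmy cohort, 200 truth-level prevalence
cohorts of 40) were chosen so the full suite exercises every stage at
cohort scale while staying comfortable on a single CPU.

## Known limitations

The chimera model is two-parent, single-crossover, same-length; the
original screening tool's multi-way heuristics are not reproduced.
Recruitment is substitution-only and same-length, consistent with the
generator's error model but not with indel-bearing real data. Taxonomy
is nearest-neighbor without bootstrap confidence. The dbRDA convention
(sequential terms, positive-eigenvalue denominator) is one of several
defensible readings of distance-based redundancy analysis; results are
comparable within this package, not necessarily across tools.
Equivalence with any specific historical tool chain is not claimed —
the rules above are pinned so that this implementation is reproducible
against itself.
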
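# Methods

This note documents the models, conventions and design choices behind
`promcore`, in the order the pipeline runs.

## Coordinates and formats

All internal coordinates are 0-based half-open; GFF3 (1-based inclusive)
and BED are converted at the boundary by inverse bijections. The native
fragments table stores, per deduplicatable read pair: chrom, strand,
`cap_pos` (the first transcribed base — genomic leftmost base on `+`,
rightmost on `−`), `insert_end` (the exclusive right edge on `+`; the
genomic leftmost, i.e. 3′-most, base on `−`), a splice signature
(semicolon-joined `donor-acceptor` genomic intervals) and a library id.
SAM input is an adapter over the same type; soft-clipped alignments are
rejected because clipping shifts the apparent cap site, and the exclusion
count is reported.

PCR duplicates are defined as read pairs identical on (library, chrom,
strand, cap position, insert 3′ end, splice signature). We read
"similar alignment coordinates" as exact equality — the strictest reading
of the three quoted fields; an off-by-k tolerance would need a clustering
of its own and is intentionally not implemented.

## TSS clustering

Per library: OTSSs below 3 TPM are discarded as raw-signal noise, adjacent
OTSSs with positional gap < 20 bp join transitively (so positions 0 and 19
join, 0 and 20 do not), and clusters below 3 TPM total support are
dropped — the TPM floor is applied at both levels. Boundaries are the
inclusive cumulative step function (no interpolation — counts are
discrete): `boundary_start` is the first position whose cumulative read
fraction reaches 0.10 and `boundary_end` one past the first position
reaching 0.90. The dominant TSS is the highest-count position; ties break
to the most upstream position in transcript orientation (deterministic and
strand-symmetric). Cross-library merging joins same-strand clusters whose
boundary intervals are within 100 bp (closest edges, transitive) and
recomputes boundaries and the dominant TSS from the pooled per-position
counts. The TPM denominator defaults to the retained (deduplicated)
fragment pairs per library.

## Artifact filters

**Adapter mis-hybridization (TGAG).** The 5′ adapter's 3′ end can anneal
to internal RNA sites, leaving the genomic TGAG motif (or a 1-bp variant;
13 motifs in all) immediately upstream of the false read start. For each
motif and TSC stratum (genic/intergenic × 1-bp/wider — the width split
matters because most artifact clusters are single-base), we count TSCs
whose 10 bp upstream of the dominant TSS contain the motif, compare with
the motif rate in windows at an equal number of seeded random genomic
positions by a one-sided binomial test, and BH-adjust across all
motif × stratum tests. A cluster is removed iff it carries a motif whose
stratum test has observed > 20 AND q < 1e−10 (both strict). The 10-bp
window, the random-position null and the binomial test are this package's
choices (the filter rule quotes only the thresholds); all are
configurable. The window is kept small deliberately: a 4-mer family hits a
10-bp window by chance in ~3% of genuine promoters, which bounds the
filter's false-removal rate; wider windows degrade specificity quickly.

**Truncated mRNAs.** Reads from 5′-truncated transcripts start at internal
positions, so their insert 3′ ends sit unusually deep into the linked
mRNA. Per cluster we take the mean transcript-coordinate offset (exonic
bases from the annotated mRNA 5′ start, floored at 0) of its fragments' 3′
ends, and remove clusters strictly above the empirical 90% quantile of the
genome-wide distribution. The empirical quantile is used rather than a
fitted lognormal — the fit adds assumptions without changing the decision
rule. Clusters with no linkable fragments keep an undefined statistic and
are retained, flagged. Note the rule's structural property: a quantile
cutoff removes a fixed share of the population, so it is effective exactly
when truncation artifacts are the tail of the distribution, not the bulk.

**rRNA.** Clusters whose boundary interval overlaps an annotated rRNA
locus by ≥ 1 bp (half-open arithmetic) are removed.

## Gene assignment and expression

A TSC is genic iff ≥ 1 fragment has its cap inside the TSC boundaries and
its 3′ end inside an annotated exon of a same-strand gene (strand
agreement is required). Multi-gene candidates resolve to the closest gene;
distance is measured from the annotated start codon to the **dominant
TSS** (configurable to boundary-edge anchoring), with ties broken by gene
id for determinism. Exactly 3,000 bp is classed adjacent (the two strict
inequalities in the definition leave the boundary open; we close it on the
adjacent side). Promoters downstream of the start codon are classed
adjacent and flagged. Expression is the per-library count of fragments
(R1 reads) capping inside the TSC, normalized to the library's total over
genic TSCs only, ×1e6.

## Promoter statistics

* **PSS** uses the probability vector over the qualifying positions L
  (pooled expression ≥ 3 TPM), renormalized over L, and w = (last − first
  + 1) over L, so w ≥ 1 and log2 w ≥ 0; PSS ≤ 0 always, with 0 for a
  single qualifying position. Note the floor's scale-dependence: at small
  total tag counts a single read can fall below 3 TPM and L collapses
  toward the dominant base, biasing PSS upward; shape-class recovery is
  therefore assessed at tag totals where one read clears the floor, the
  regime the threshold was designed for.
* **Shannon diversity** is computed on pooled member-OTSS counts; clusters
  with < 10 reads or < 2 OTSSs are ineligible. The down-sampled variant
  draws exactly 10 reads without replacement (multivariate
  hypergeometric), seeded.
* **τ** is computed on log2(TPM + 1) (the transform base and pseudocount
  are configurable; the definition says only "log TPM"), with negative
  values floored at 0 so x̂ stays in [0, 1].
* **D_s** compares the most-proximal and most-distal promoter of a
  multi-promoter gene (the statistic is binary; genes with > 2 promoters
  use that extreme pair). The chi-squared test on [[Pt, Dt], [Pc, Dc]] is
  uncorrected (Yates' correction is reserved for the TFBS comparison,
  following the source conventions); zero cells make D_s infinite and the
  result is flagged. Calls require all three strict thresholds.

## Sequence features and TFBSs

Windowing is strand-aware everywhere; reverse-strand promoters are read on
the reverse complement. The 25-bp consensus window places the dominant TSS
at index 10 (10 bp upstream, 14 downstream; configurable — the source
says only "surrounding"). CpG o/e uses overlapping dinucleotide counts and
the (#C×#G)/L expected form; windows with no C or no G are masked. The
shipped core-promoter element table carries literature consensus strings
(TATA, Inr, TCT, MTE, DPE) and is overridable.

The PWM scanner scores log2 odds with a 0.01 per-cell pseudocount over the
motif's background. P-values come from the exact null distribution of the
score of a background-distributed sequence, computed by dynamic programming
over integer-discretized columns (granularity 1e−3 log2 units, ~binning
error ≪ the 1e−5 decision threshold); a window position is a hit when its
score's tail probability is below the cut-off. This replaces an external
scanner dependency while keeping the same cut-off semantics; hits are
"putative" binding sites. Abundance between adjacent and distant promoters
is tested per TF on the 2×2 table of promoters with/without a hit by class
(the per-class construction is this package's documented reading),
Yates-corrected, BH-adjusted across TFs. Divergence is the normalized
Shannon entropy SE = (1/L) Σ_columns(−Σ P log2 P) of the gap-free stack of
strand-normalized hit sequences, in [0, 2].

## SNP profiles

Sites pass MAF > 0.005 (strict), from the AF tag when present, else from
genotypes. Density profiles cover ±500 bp of the dominant TSS,
transcript-oriented; clusters whose window overlaps a repeat interval
("flanked by repetitive elements" is read as any overlap of the full 1-kb
window; an edge-only variant is a config option) or a contig edge are
excluded and counted. The conventional GATK-style hard-filter expressions
are exposed as an optional pass for callers that consume raw VCFs.

## Synthetic data generator

The generator emulates an oligo-capping experiment, not a full sequencer:
no base-call errors, qualities, or adapter chemistry (those stages sit
upstream of this pipeline's inputs).

* **Layout.** Genes are placed without overlap on one chromosome with
  random strands. Each gene has a leader (first exon 120–250 bp, optional
  leader intron, second exon) and an 1,800-bp CDS. Distant promoters arise
  from long leader introns (lognormal, median 6 kb, min 3.5 kb); adjacent
  genes have no intron or a short one (median 300 bp, capped at 2 kb).
  40% of genes carry a second, proximal promoter inside the leader's
  second exon. The per-gene distant probability is scaled so the
  promoter-level distant fraction matches the configured 0.45.
* **Shapes.** TSS usage is a point mass at the dominant base mixed with a
  discretized Gaussian: sharp = 85% dominant, σ 1 bp; intermediate = 60%,
  σ 8 bp; broad = 35%, σ 25 bp. These produce PSS values near −2, −17 and
  −35 at depth ≥ 100, i.e. well inside the three classes, while keeping a
  recoverable dominant base even for broad promoters — real broad
  promoters also retain a modal TSS. The [−1, +1] dinucleotide is forced
  to CA (PyPu) with probability 0.8, else GC.
* **Expression.** Gene abundance is lognormal (σ 0.8) with per-library
  lognormal tissue effects (σ 0.5) and a fixed per-promoter share within
  each gene — so promoter usage ratios are constant across libraries and
  the default conditions are an exact null for promoter shifting.
* **Inserts.** Lengths are lognormal with μ = ln 352.3 and σ = 0.66
  (matching the reported median and interquartile range of real insert 3′
  ends), clipped to the transcript; fragments crossing the leader intron
  record the splice signature, which keeps distant-promoter fragments'
  3′ ends inside annotated exons.
* **Artifacts.** Adapter reads start immediately downstream of genomic
  TGAG occurrences (2% at 1-bp variants). The variant share is kept small
  on purpose: the enrichment filter removes any cluster carrying a
  significant motif, so if every variant were strongly injected, all 13
  motifs would reach significance and ~30% of genuine promoters would be
  removed by chance motif content — the filter is only specific when
  mis-hybridization concentrates on the adapter's own motif. Truncated
  reads start at one recurrent internal hotspot (transcript offset
  900–1400) in 18% of genes, with 3′ extensions 300–700 bp drawn outside
  the insert-size law. The hotspot design keeps truncation clusters at
  ~10–12% of the linked population — the regime where the 90%-quantile
  rule removes nearly all of them at near-zero false removal; spreading
  the same read mass as one-read clusters across all transcripts would
  instead swamp the quantile and no threshold could separate them.
* **Determinism.** All randomness flows from one seed through numpy
  `SeedSequence` spawning (separate streams for sequence, layout and
  reads); outputs are byte-identical under a fixed seed.

Default scale: 2,000 genes on 16 Mb, 4 libraries × 90,000 read pairs
(~100 pooled reads per promoter after artifacts), 10% adapter and 10%
truncation reads. These are the package's reference study conditions for
the recovery tests; the unit-test fixtures use smaller instances of the
same model.

## What passing tests do and do not show

The generator's reads land exactly where its promoter model says, with
independent sampling and no mapping error, chimeras, or annotation noise.
Recovery rates measured on it validate the pipeline's logic — thresholds,
coordinate arithmetic, test calibration — not its performance on real
libraries, where cap-trapping efficiency, mappability and incomplete gene
models add failure modes the model does not contain. The artifact models
reproduce the mechanism (motif-anchored starts; deep 3′ ends at recurrent
internal sites) but not the sequence biology that causes them.

## Known limitations

* The enrichment null (random genomic windows) ignores regional base
  composition; a GC-matched null would be stricter in GC-skewed genomes.
* The truncation statistic requires a provisional gene link; clusters of
  genes missing CDS annotation are never filtered by it.
* `tau` treats libraries as tissues; replicate structure is not modelled.
* The PWM null assumes an i.i.d. background; low-complexity regions
  inflate hit rates as they do for any zeroth-order scanner.
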
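"""False-TSC filters: adapter mis-hybridization, truncated mRNAs, rRNA.

Oligo-capping produces three known classes of spurious clusters:

* adapter mis-hybridization leaves the adapter's 3' TGAG motif (or a 1-bp
  variant) in the genome immediately upstream of the read start; clusters
  enriched for those motifs upstream of the dominant TSS are removed when a
  motif reaches observed > 20 clusters AND BH q < 1e-10 in the cluster's
  stratum;
* truncated mRNAs yield capped reads at internal transcript positions whose
  insert 3' ends sit unusually deep into the linked mRNA; clusters whose
  mean transcript-coordinate 3'-end depth exceeds the empirical 90% quantile
  are removed;
* clusters overlapping annotated rRNA loci are removed outright.

Every filter returns (kept, removed, report) with kept + removed = input.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats as sps

from .assignment import ExonIndex, assign_tsc, map_caps_to_tscs, transcript_offset
from .clustering import TSC
from .io import GeneModel, three_prime_end
from .stats import bh_fdr

BASES = "ACGT"
_COMP = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def tgag_variant_set() -> list[str]:
    """TGAG plus every single-base-substitution 4-mer (13 motifs)."""
    motifs = ["TGAG"]
    for i in range(4):
        for b in BASES:
            if b != "TGAG"[i]:
                motifs.append("TGAG"[:i] + b + "TGAG"[i + 1 :])
    return motifs


def upstream_window(
    genome: dict[str, str], chrom: str, strand: str, pos: int, width: int
) -> str:
    """Sequence of the ``width`` bases immediately 5' of ``pos`` in
    transcript orientation (truncated at contig edges)."""
    seq = genome[chrom]
    if strand == "+":
        return seq[max(0, pos - width) : pos]
    return revcomp(seq[pos + 1 : pos + 1 + width])


# ---------------------------------------------------------------------------
# TGAG adapter mis-hybridization filter
# ---------------------------------------------------------------------------


def _stratum_of(tsc: TSC, gene_spans) -> str:
    width = "1bp" if len(tsc.positions) == 1 else "multi"
    if gene_spans is None:
        return width
    tree = gene_spans.get(tsc.chrom)
    region = "genic" if tree is not None and tree.overlaps(tsc.dominant_pos) else "intergenic"
    return f"{region}:{width}"


def tgag_enrichment_filter(
    tscs: list[TSC],
    genome: dict[str, str],
    genes: list[GeneModel] | None = None,
    window_up: int = 10,
    min_observed: int = 20,
    q_max: float = 1e-10,
    seed: int = 0,
) -> tuple[list[TSC], list[TSC], pd.DataFrame]:
    """Remove TSCs carrying a significantly enriched TGAG-family motif.

    TSCs are stratified by genomic region (genic/intergenic, when gene
    models are supplied) and by 1-bp vs wider clusters. For each motif and
    stratum, the observed count of TSCs whose ``window_up`` bases upstream
    of the dominant TSS contain the motif is compared with the motif rate
    in windows at an equal number of seeded random genomic positions, by a
    one-sided binomial test; q-values are BH-adjusted across all motif x
    stratum tests. A TSC is removed iff its window contains a motif whose
    stratum test has observed > ``min_observed`` AND q < ``q_max``.
    """
    motifs = tgag_variant_set()
    rng = np.random.default_rng(seed)

    gene_spans = None
    if genes is not None:
        gene_spans = {}
        for g in genes:
            s, e = g.span()
            gene_spans.setdefault(g.chrom, IntervalTree()).addi(s, e)

    strata = [_stratum_of(t, gene_spans) for t in tscs]
    windows = [
        upstream_window(genome, t.chrom, t.strand, t.dominant_pos, window_up)
        for t in tscs
    ]
    present = [
        frozenset(m for m in motifs if m in w) for w in windows
    ]

    # background: equal number of random positions, both strands
    chroms = sorted(genome)
    lengths = np.array([len(genome[c]) for c in chroms], dtype=float)
    n_bg = max(len(tscs), 1000)
    bg_chrom = rng.choice(len(chroms), size=n_bg, p=lengths / lengths.sum())
    bg_hits = {m: 0 for m in motifs}
    for ci in bg_chrom:
        c = chroms[ci]
        p = int(rng.integers(window_up, len(genome[c]) - window_up))
        s = "+" if rng.integers(2) == 0 else "-"
        w = upstream_window(genome, c, s, p, window_up)
        for m in motifs:
            if m in w:
                bg_hits[m] += 1

    rows = []
    stratum_sizes = pd.Series(strata).value_counts().to_dict()
    for stratum in sorted(stratum_sizes):
        n = stratum_sizes[stratum]
        idx = [i for i, s in enumerate(strata) if s == stratum]
        for m in motifs:
            observed = sum(1 for i in idx if m in present[i])
            p0 = (bg_hits[m] + 1) / (n_bg + 2)  # smoothed background rate
            expected = p0 * n
            p_value = float(sps.binom.sf(observed - 1, n, p0))
            rows.append((stratum, m, n, observed, expected, p_value))
    report = pd.DataFrame(
        rows, columns=["stratum", "motif", "n_tscs", "observed", "expected", "p_value"]
    )
    report["q_value"] = bh_fdr(report["p_value"].to_numpy())
    report["significant"] = (report["observed"] > min_observed) & (
        report["q_value"] < q_max
    )

    sig = {
        (r.stratum, r.motif)
        for r in report.itertuples()
        if r.significant
    }
    kept, removed = [], []
    for t, stratum, pres in zip(tscs, strata, present):
        if any((stratum, m) in sig for m in pres):
            removed.append(t)
        else:
            kept.append(t)
    return kept, removed, report


# ---------------------------------------------------------------------------
# truncated-mRNA filter
# ---------------------------------------------------------------------------


@dataclass
class TruncationStat:
    tsc_id: str
    mean_3prime_distance: float
    quantile_rank: float


def truncation_filter(
    tscs: list[TSC],
    fragments: pd.DataFrame,
    genes: list[GeneModel],
    quantile: float = 0.90,
) -> tuple[list[TSC], list[TSC], pd.DataFrame]:
    """Remove TSCs whose fragments end unusually deep into the linked mRNA.

    Per TSC, the statistic is the mean transcript-coordinate position of
    its fragments' 3' insert ends along the provisionally linked mRNA
    (offset from the annotated 5' start, exonic bases only, floored at 0).
    TSCs whose statistic strictly exceeds the empirical ``quantile`` of the
    genome-wide distribution are removed; TSCs with no linkable fragments
    keep an undefined statistic and are retained (flagged NaN).
    """
    index = ExonIndex(genes)
    prov = assign_tsc(tscs, fragments, genes, exon_index=index)
    gene_of = dict(zip(prov["tsc_id"], prov["gene_id"]))

    tsc_of = map_caps_to_tscs(tscs, fragments)
    ends = three_prime_end(fragments)
    sums: dict[str, float] = {}
    ns: dict[str, int] = {}
    for fi in np.flatnonzero(tsc_of >= 0):
        t = tscs[int(tsc_of[fi])]
        gid = gene_of.get(t.id)
        if gid is None:
            continue
        off = transcript_offset(index.genes[gid], int(ends[fi]))
        if off is None:
            continue
        sums[t.id] = sums.get(t.id, 0.0) + max(off, 0)
        ns[t.id] = ns.get(t.id, 0) + 1

    stat = {tid: sums[tid] / ns[tid] for tid in sums}
    values = np.array(sorted(stat.values()))
    threshold = float(np.quantile(values, quantile)) if len(values) else np.inf

    rows, kept, removed = [], [], []
    for t in tscs:
        s = stat.get(t.id, np.nan)
        if np.isnan(s):
            rank = np.nan
            keep = True
        else:
            rank = float(np.searchsorted(values, s, side="right") / len(values))
            keep = not (s > threshold)
        rows.append((t.id, s, rank))
        (kept if keep else removed).append(t)
    report = pd.DataFrame(
        rows, columns=["tsc_id", "mean_3prime_distance", "quantile_rank"]
    )
    return kept, removed, report


# ---------------------------------------------------------------------------
# rRNA filter
# ---------------------------------------------------------------------------


def rrna_filter(
    tscs: list[TSC], rrna_intervals: pd.DataFrame
) -> tuple[list[TSC], list[TSC]]:
    """Remove TSCs whose boundary interval overlaps an rRNA locus by >= 1 bp
    (half-open arithmetic: intervals sharing only an endpoint do not
    overlap)."""
    trees: dict[str, IntervalTree] = {}
    for _, r in rrna_intervals.iterrows():
        trees.setdefault(r["chrom"], IntervalTree()).addi(int(r["start"]), int(r["end"]))
    kept, removed = [], []
    for t in tscs:
        tree = trees.get(t.chrom)
        if tree is not None and tree.overlap(t.boundary_start, t.boundary_end):
            removed.append(t)
        else:
            kept.append(t)
    return kept, removed
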
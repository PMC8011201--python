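"""Linking TSCs to protein-coding genes via paired-end evidence.

A TSC is linked to a gene when at least one insert fragment has its capped
5' end inside the TSC boundaries and its 3' end inside an annotated exon of
a same-strand gene; a TSC with several candidate genes goes to the closest
one (smallest start-codon-to-dominant-TSS distance, ties broken by gene id).
Expression of genic TSCs is quantified as TPM with a genic-only library
denominator. Promoters are classified adjacent (< 3 kb) or distant (> 3 kb)
by the distance from the annotated start codon to the dominant TSS; the
exactly-3-kb boundary counts as adjacent.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .clustering import TSC
from .io import GeneModel, three_prime_end

ADJACENCY_THRESHOLD = 3000

ASSIGNMENT_COLUMNS = [
    "tsc_id",
    "gene_id",
    "n_supporting_fragments",
    "distance_to_start_codon",
    "downstream",
    "adjacency",
    "rank",
]


# ---------------------------------------------------------------------------
# interval indexes
# ---------------------------------------------------------------------------


class ExonIndex:
    """Per-(chrom, strand) interval tree over exons -> gene ids."""

    def __init__(self, genes: list[GeneModel]):
        self.trees: dict[tuple[str, str], IntervalTree] = {}
        self.genes = {g.gene_id: g for g in genes}
        for g in genes:
            tree = self.trees.setdefault((g.chrom, g.strand), IntervalTree())
            for s, e in g.exons:
                if s < e:
                    tree.addi(s, e, g.gene_id)

    def genes_at(self, chrom: str, strand: str, pos: int) -> set[str]:
        tree = self.trees.get((chrom, strand))
        if tree is None:
            return set()
        return {iv.data for iv in tree.at(pos)}


def map_caps_to_tscs(tscs: list[TSC], fragments: pd.DataFrame) -> np.ndarray:
    """Index of the TSC whose boundary interval contains each fragment's cap.

    Returns -1 for fragments outside every TSC. TSC boundary intervals on
    one (chrom, strand) never overlap, so a sorted binary search suffices.
    """
    by_key: dict[tuple[str, str], tuple[list[int], list[int], list[int]]] = {}
    for i, t in enumerate(tscs):
        starts, ends, idxs = by_key.setdefault((t.chrom, t.strand), ([], [], []))
        starts.append(t.boundary_start)
        ends.append(t.boundary_end)
        idxs.append(i)
    for key, (starts, ends, idxs) in by_key.items():
        order = np.argsort(starts)
        by_key[key] = (
            np.asarray(starts)[order],
            np.asarray(ends)[order],
            np.asarray(idxs)[order],
        )

    out = np.full(len(fragments), -1, dtype=np.int64)
    caps = fragments["cap_pos"].to_numpy()
    for key, grp_idx in fragments.groupby(["chrom", "strand"]).indices.items():
        entry = by_key.get(key)
        if entry is None:
            continue
        starts, ends, idxs = entry
        c = caps[grp_idx]
        j = np.searchsorted(starts, c, side="right") - 1
        ok = (j >= 0) & (c < ends[np.clip(j, 0, None)])
        out[grp_idx[ok]] = idxs[j[ok]]
    return out


# ---------------------------------------------------------------------------
# distances and transcript projection
# ---------------------------------------------------------------------------


def start_codon_distance(gene: GeneModel, dominant_pos: int) -> int:
    """Signed genomic distance from the start codon to the dominant TSS.

    Positive for promoters upstream of the start codon in transcript
    orientation, negative for downstream promoters.
    """
    if gene.strand == "+":
        return gene.start_codon_pos - dominant_pos
    return dominant_pos - gene.start_codon_pos


def transcript_offset(gene: GeneModel, genomic_pos: int) -> int | None:
    """Offset of a genomic position along the mature transcript (0 at the
    annotated mRNA 5' end); None when the position is intronic/outside."""
    off = 0
    if gene.strand == "+":
        for s, e in gene.exons:
            if s <= genomic_pos < e:
                return off + (genomic_pos - s)
            off += e - s
    else:
        for s, e in reversed(gene.exons):
            if s <= genomic_pos < e:
                return off + (e - 1 - genomic_pos)
            off += e - s
    return None


# ---------------------------------------------------------------------------
# assignment
# ---------------------------------------------------------------------------


def assign_tsc(
    tscs: list[TSC],
    fragments: pd.DataFrame,
    genes: list[GeneModel],
    exon_index: ExonIndex | None = None,
) -> pd.DataFrame:
    """Link TSCs to genes using the paired-read rule.

    Candidate genes per TSC are those with >= 1 fragment whose cap lies in
    the TSC boundaries and whose 3' insert end falls in one of the gene's
    exons (same strand); multi-gene candidates resolve to the closest gene
    by |start-codon -> dominant-TSS| distance, ties by gene id. TSCs with
    no candidate are nongenic and omitted from the result.
    """
    index = exon_index or ExonIndex(genes)
    tsc_of = map_caps_to_tscs(tscs, fragments)
    ends = three_prime_end(fragments)
    chroms = fragments["chrom"].to_numpy()
    strands = fragments["strand"].to_numpy()

    support: dict[int, dict[str, int]] = {}
    for fi in np.flatnonzero(tsc_of >= 0):
        ti = int(tsc_of[fi])
        for gid in index.genes_at(chroms[fi], strands[fi], int(ends[fi])):
            support.setdefault(ti, {}).setdefault(gid, 0)
            support[ti][gid] += 1

    rows = []
    for ti, gene_counts in sorted(support.items()):
        t = tscs[ti]
        best = min(
            gene_counts,
            key=lambda gid: (abs(start_codon_distance(index.genes[gid], t.dominant_pos)), gid),
        )
        dist = start_codon_distance(index.genes[best], t.dominant_pos)
        rows.append(
            (t.id, best, gene_counts[best], dist, dist < 0)
        )
    df = pd.DataFrame(
        rows,
        columns=[
            "tsc_id",
            "gene_id",
            "n_supporting_fragments",
            "distance_to_start_codon",
            "downstream",
        ],
    )
    return df


def classify_adjacency(
    assignments: pd.DataFrame, threshold: int = ADJACENCY_THRESHOLD
) -> pd.DataFrame:
    """Add the adjacent/distant class; distance <= threshold (and any
    downstream promoter, flagged via the ``downstream`` column) is adjacent."""
    out = assignments.copy()
    out["adjacency"] = np.where(
        out["distance_to_start_codon"] > threshold, "distant", "adjacent"
    )
    return out


def per_gene_farthest_distance(assignments: pd.DataFrame) -> pd.DataFrame:
    """Per-gene farthest-promoter distance (feeds the bimodal-leader plot)."""
    return (
        assignments.groupby("gene_id")["distance_to_start_codon"]
        .max()
        .rename("farthest_distance")
        .reset_index()
    )


def promoter_multiplicity(assignments: pd.DataFrame) -> pd.DataFrame:
    """Per-gene promoter counts, single/multi class, and proximity ranks.

    Rank 1 is the most proximal promoter (smallest distance to the start
    codon); ranks are deterministic (distance, then tsc_id).
    """
    out = assignments.copy()
    out = out.sort_values(["gene_id", "distance_to_start_codon", "tsc_id"])
    out["rank"] = out.groupby("gene_id").cumcount() + 1
    n = out.groupby("gene_id")["tsc_id"].transform("size")
    out["gene_class"] = np.where(n > 1, "multi", "single")
    return out


def quantify_tsc_expression(
    tscs: list[TSC],
    fragments: pd.DataFrame,
    genic_tsc_ids: set[str],
) -> pd.DataFrame:
    """TPM matrix (genic TSC x library) with the genic-TSC denominator.

    The library size is the number of fragments (R1 reads) whose cap falls
    in any genic TSC; libraries with a zero denominator are dropped.
    """
    tsc_of = map_caps_to_tscs(tscs, fragments)
    ids = np.array([t.id for t in tscs] + ["__none__"])
    tsc_ids = ids[tsc_of]
    genic = np.isin(tsc_ids, list(genic_tsc_ids))
    df = pd.DataFrame(
        {"tsc_id": tsc_ids[genic], "library_id": fragments["library_id"].to_numpy()[genic]}
    )
    counts = df.groupby(["tsc_id", "library_id"]).size().unstack(fill_value=0)
    denom = counts.sum(axis=0)
    counts = counts.loc[:, denom > 0]
    return counts * 1e6 / counts.sum(axis=0)


def te_annotation(
    assignments: pd.DataFrame,
    tscs: list[TSC],
    genes: list[GeneModel],
    repeat_intervals: pd.DataFrame,
) -> pd.DataFrame:
    """Repeat overlap of each genic TSC and upstream TE coverage.

    ``upstream_te_coverage`` is the fraction of the strand-aware span from
    the dominant TSS to the start codon covered by the union of repeat
    intervals.
    """
    trees: dict[str, IntervalTree] = {}
    for _, r in repeat_intervals.iterrows():
        trees.setdefault(r["chrom"], IntervalTree()).addi(
            int(r["start"]), int(r["end"]), r.get("name", ".")
        )
    tsc_by_id = {t.id: t for t in tscs}
    gene_by_id = {g.gene_id: g for g in genes}
    rows = []
    for _, a in assignments.iterrows():
        t = tsc_by_id[a["tsc_id"]]
        g = gene_by_id[a["gene_id"]]
        tree = trees.get(t.chrom, IntervalTree())
        hits = tree.overlap(t.boundary_start, t.boundary_end)
        te_overlap = len(hits) > 0
        family = sorted(h.data for h in hits)[0] if hits else "."
        lo = min(t.dominant_pos, g.start_codon_pos)
        hi = max(t.dominant_pos, g.start_codon_pos) + 1
        covered = 0
        if hi > lo:
            segs = sorted(
                (max(iv.begin, lo), min(iv.end, hi)) for iv in tree.overlap(lo, hi)
            )
            cur_s = cur_e = None
            for s, e in segs:
                if cur_e is None or s > cur_e:
                    if cur_e is not None:
                        covered += cur_e - cur_s
                    cur_s, cur_e = s, e
                else:
                    cur_e = max(cur_e, e)
            if cur_e is not None:
                covered += cur_e - cur_s
        rows.append(
            (a["tsc_id"], te_overlap, family, covered / (hi - lo) if hi > lo else 0.0)
        )
    return pd.DataFrame(
        rows, columns=["tsc_id", "te_overlap", "te_family", "upstream_te_coverage"]
    )
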
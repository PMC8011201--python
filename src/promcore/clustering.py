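"""TSS clustering: deduplicated fragments -> OTSSs -> TSCs -> merged TSCs.

The pipeline follows the thresholds used for oligo-capping promoter calling:
PCR duplicates are collapsed on exact (chrom, strand, cap, 3' end, splice
signature) identity; per-library capped 5' ends become OTSSs with TPM
normalization; OTSSs at >= 3 TPM separated by < 20 bp single-link into a
TSC; TSCs below 3 TPM total support are dropped; per-library TSCs are merged
across libraries with a 100 bp distance threshold and boundaries/dominant
TSS recomputed from the pooled counts. Cluster boundaries are the 10th/90th
percentile interval of the cumulative read distribution.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

DEDUP_KEY = ["library_id", "chrom", "strand", "cap_pos", "insert_end", "splice_signature"]


@dataclass
class TSC:
    """A transcription start site cluster (putative core promoter).

    ``positions`` are the member OTSS genomic positions (ascending) and
    ``counts`` the matching read-count matrix with one column per library in
    ``libraries``. Boundaries are 0-based half-open.
    """

    id: str
    chrom: str
    strand: str
    positions: np.ndarray
    counts: np.ndarray  # (n_positions, n_libraries)
    libraries: list[str]
    boundary_start: int = 0
    boundary_end: int = 0
    dominant_pos: int = 0
    total_tpm: float = 0.0

    @property
    def pooled_counts(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def width(self) -> int:
        return self.boundary_end - self.boundary_start

    @property
    def total_count(self) -> int:
        return int(self.counts.sum())

    def per_library_counts(self) -> dict[str, int]:
        return {
            lib: int(c) for lib, c in zip(self.libraries, self.counts.sum(axis=0))
        }


# ---------------------------------------------------------------------------
# deduplication and OTSS extraction
# ---------------------------------------------------------------------------


def dedup_fragments(fragments: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Collapse PCR duplicates to one representative per equivalence class.

    Two read pairs are duplicates iff they agree exactly on library, chrom,
    strand, cap position, insert 3' end and splice signature. Returns the
    retained fragments and the number removed.
    """
    out = fragments.drop_duplicates(subset=DEDUP_KEY, keep="first")
    return out.reset_index(drop=True), len(fragments) - len(out)


def library_totals(fragments: pd.DataFrame) -> dict[str, int]:
    """Retained fragment pairs per library (the default TPM denominator)."""
    return fragments.groupby("library_id").size().to_dict()


def extract_otss(fragments: pd.DataFrame, library_total: int) -> pd.DataFrame:
    """Collapse one library's fragments into observed TSSs.

    One OTSS per (chrom, strand, cap_pos) with its read count and
    tags-per-million relative to ``library_total``.
    """
    if library_total <= 0:
        raise ValueError("library_total must be positive")
    otss = (
        fragments.groupby(["chrom", "strand", "cap_pos"])
        .size()
        .rename("count")
        .reset_index()
        .rename(columns={"cap_pos": "pos"})
    )
    otss["tpm"] = otss["count"] * 1e6 / library_total
    return otss


# ---------------------------------------------------------------------------
# clustering
# ---------------------------------------------------------------------------


def tsc_boundaries(
    positions: np.ndarray, counts: np.ndarray, strand: str
) -> tuple[int, int, int]:
    """10th/90th percentile boundaries and dominant TSS of one cluster.

    Boundaries use the inclusive cumulative step function over ascending
    genomic positions: boundary_start is the first position whose cumulative
    read fraction reaches 0.10 and boundary_end one past the first position
    reaching 0.90. The dominant TSS is the highest-count position; ties go
    to the most upstream position in transcript orientation.
    """
    positions = np.asarray(positions)
    counts = np.asarray(counts, dtype=float)
    cum = np.cumsum(counts) / counts.sum()
    lo = int(positions[np.searchsorted(cum, 0.10 - 1e-12)])
    hi = int(positions[np.searchsorted(cum, 0.90 - 1e-12)]) + 1
    best = counts == counts.max()
    idx = np.flatnonzero(best)
    dom = int(positions[idx[0]]) if strand == "+" else int(positions[idx[-1]])
    return lo, hi, dom


def cluster_otss(
    otss: pd.DataFrame,
    tpm_threshold: float = 3.0,
    join_dist: int = 20,
    tsc_tpm_threshold: float = 3.0,
    library_id: str = "pooled",
) -> list[TSC]:
    """Single-linkage cluster one library's OTSSs into TSCs.

    OTSSs below ``tpm_threshold`` TPM are discarded as raw-signal noise;
    surviving same-strand OTSSs whose positional gap is < ``join_dist`` bp
    join transitively; clusters whose summed support is below
    ``tsc_tpm_threshold`` TPM are dropped. Output order (and ids) are
    deterministic: sorted by (chrom, strand, start).
    """
    kept = otss[otss["tpm"] >= tpm_threshold]
    tscs: list[TSC] = []
    for (chrom, strand), grp in kept.groupby(["chrom", "strand"], sort=True):
        grp = grp.sort_values("pos")
        pos = grp["pos"].to_numpy()
        cnt = grp["count"].to_numpy()
        tpm = grp["tpm"].to_numpy()
        if len(pos) == 0:
            continue
        breaks = np.flatnonzero(np.diff(pos) >= join_dist) + 1
        for seg_pos, seg_cnt, seg_tpm in zip(
            np.split(pos, breaks), np.split(cnt, breaks), np.split(tpm, breaks)
        ):
            total_tpm = float(seg_tpm.sum())
            if total_tpm < tsc_tpm_threshold:
                continue
            lo, hi, dom = tsc_boundaries(seg_pos, seg_cnt, strand)
            tscs.append(
                TSC(
                    id=f"{library_id}:{chrom}:{strand}:{seg_pos[0]}",
                    chrom=chrom,
                    strand=strand,
                    positions=seg_pos.astype(np.int64),
                    counts=seg_cnt.reshape(-1, 1).astype(np.int64),
                    libraries=[library_id],
                    boundary_start=lo,
                    boundary_end=hi,
                    dominant_pos=dom,
                    total_tpm=total_tpm,
                )
            )
    return tscs


def merge_libraries(
    per_library_tscs: dict[str, list[TSC]],
    library_totals: dict[str, int],
    merge_dist: int = 100,
) -> list[TSC]:
    """Merge per-library TSCs into the combined cluster set.

    Same-strand TSCs whose boundary intervals are within ``merge_dist`` bp
    (closest-edge distance, transitively) merge; member OTSS counts are
    summed per library and boundaries/dominant TSS recomputed from pooled
    counts. Total TPM uses each library's own denominator. The result is
    independent of library iteration order.
    """
    libs = sorted(per_library_tscs)
    groups: dict[tuple[str, str], list[tuple[TSC, str]]] = {}
    for lib in libs:
        for t in per_library_tscs[lib]:
            groups.setdefault((t.chrom, t.strand), []).append((t, lib))

    merged: list[TSC] = []
    for (chrom, strand) in sorted(groups):
        members = sorted(
            groups[(chrom, strand)], key=lambda x: (x[0].boundary_start, x[1])
        )
        blocks: list[list[tuple[TSC, str]]] = []
        cur: list[tuple[TSC, str]] = []
        cur_end = None
        for t, lib in members:
            if cur and t.boundary_start - cur_end > merge_dist:
                blocks.append(cur)
                cur = []
                cur_end = None
            cur.append((t, lib))
            cur_end = t.boundary_end if cur_end is None else max(cur_end, t.boundary_end)
        if cur:
            blocks.append(cur)

        for block in blocks:
            pos_counts: dict[int, dict[str, int]] = {}
            for t, lib in block:
                pooled = t.pooled_counts
                for p, c in zip(t.positions, pooled):
                    pos_counts.setdefault(int(p), {}).setdefault(lib, 0)
                    pos_counts[int(p)][lib] += int(c)
            positions = np.array(sorted(pos_counts), dtype=np.int64)
            counts = np.zeros((len(positions), len(libs)), dtype=np.int64)
            for i, p in enumerate(positions):
                for j, lib in enumerate(libs):
                    counts[i, j] = pos_counts[int(p)].get(lib, 0)
            lo, hi, dom = tsc_boundaries(positions, counts.sum(axis=1), strand)
            tpm = sum(
                counts[:, j].sum() * 1e6 / library_totals[lib]
                for j, lib in enumerate(libs)
                if library_totals.get(lib)
            )
            merged.append(
                TSC(
                    id="",
                    chrom=chrom,
                    strand=strand,
                    positions=positions,
                    counts=counts,
                    libraries=list(libs),
                    boundary_start=lo,
                    boundary_end=hi,
                    dominant_pos=dom,
                    total_tpm=float(tpm),
                )
            )
    merged.sort(key=lambda t: (t.chrom, t.boundary_start, t.strand))
    for i, t in enumerate(merged):
        t.id = f"TSC{i + 1:06d}"
    return merged


def run_clustering(
    fragments: pd.DataFrame,
    tpm_threshold: float = 3.0,
    join_dist: int = 20,
    merge_dist: int = 100,
) -> tuple[list[TSC], dict[str, int]]:
    """Dedup, per-library clustering, and cross-library merge in one call."""
    frags, _ = dedup_fragments(fragments)
    totals = library_totals(frags)
    per_lib = {}
    for lib, grp in frags.groupby("library_id"):
        otss = extract_otss(grp, totals[lib])
        per_lib[lib] = cluster_otss(
            otss, tpm_threshold, join_dist, tpm_threshold, library_id=str(lib)
        )
    return merge_libraries(per_lib, totals, merge_dist), totals


# ---------------------------------------------------------------------------
# metaprofile
# ---------------------------------------------------------------------------


def gene_body_metaprofile(
    tscs: list[TSC],
    genes,
    n_bins: int = 100,
    assignments: pd.DataFrame | None = None,
) -> np.ndarray:
    """Histogram of dominant-TSS positions over normalized gene coordinates.

    Each TSC's dominant TSS is mapped to its fractional position within the
    linked gene's span (transcript orientation: 0 = gene 5' end). When no
    assignment table is given, a TSC contributes to every same-strand gene
    span containing its dominant TSS.
    """
    profile = np.zeros(n_bins, dtype=np.int64)
    gene_by_id = {g.gene_id: g for g in genes}

    def add(gene, dom):
        s, e = gene.span()
        length = e - s
        if length <= 0 or not (s <= dom < e):
            return
        frac = (dom - s) / length if gene.strand == "+" else (e - 1 - dom) / length
        profile[min(int(frac * n_bins), n_bins - 1)] += 1

    if assignments is not None:
        dom_of = {t.id: t.dominant_pos for t in tscs}
        for tsc_id, gene_id in zip(assignments["tsc_id"], assignments["gene_id"]):
            g = gene_by_id.get(gene_id)
            if g is not None and tsc_id in dom_of:
                add(g, dom_of[tsc_id])
    else:
        for t in tscs:
            for g in genes:
                if g.chrom == t.chrom and g.strand == t.strand:
                    add(g, t.dominant_pos)
    return profile
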
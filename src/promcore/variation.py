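"""TSS-centered SNP density profiles from VCF input.

The pipeline consumes a (presumed pre-filtered) VCF; sites pass a strict
minor-allele-frequency filter (MAF > 0.5%) and the per-offset SNP density
is profiled over 1-kb windows centered on dominant TSSs, strand-oriented so
negative offsets are upstream. TSCs whose window overlaps a repeat, or runs
off a contig edge, are excluded. An optional hard-filter pass implementing
the conventional GATK site thresholds is exposed for completeness.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

try:
    from cyvcf2 import VCF
except ImportError:  # pragma: no cover
    VCF = None

# conventional short-variant hard-filter thresholds (site removed when the
# expression is true for any listed annotation present in the record)
HARD_FILTERS = {
    "QD": ("<", 2.0),
    "MQ": ("<", 40.0),
    "FS": (">", 60.0),
    "SOR": (">", 3.0),
    "MQRankSum": ("<", -12.5),
    "ReadPosRankSum": ("<", -8.0),
}
HARD_FILTER_DP = (10, 800)  # DP < 10 or DP > 800 removed


@dataclass
class SnpSite:
    chrom: str
    pos: int  # 0-based
    maf: float


def _maf_from_af(af: float) -> float:
    return min(af, 1.0 - af)


def _maf_from_genotypes(gts: np.ndarray) -> float | None:
    alleles = [a for row in gts for a in row[:2] if a >= 0]
    if not alleles:
        return None
    af = float(np.mean(np.array(alleles) > 0))
    return _maf_from_af(af)


def hard_filter_record(variant) -> bool:
    """True when the record survives the conventional hard filters."""
    for key, (op, thr) in HARD_FILTERS.items():
        val = variant.INFO.get(key)
        if val is None:
            continue
        if (op == "<" and val < thr) or (op == ">" and val > thr):
            return False
    dp = variant.INFO.get("DP")
    if dp is not None and (dp < HARD_FILTER_DP[0] or dp > HARD_FILTER_DP[1]):
        return False
    return True


def maf_filter(
    vcf_path: str, min_maf: float = 0.005, apply_hard_filters: bool = False
) -> tuple[list[SnpSite], int]:
    """SNP sites with MAF strictly greater than ``min_maf``.

    MAF comes from the AF INFO tag when present, else from genotypes; sites
    with neither are skipped and counted (second return value). Only SNPs
    (1-bp ref and alt) are considered.
    """
    sites: list[SnpSite] = []
    skipped = 0
    for variant in VCF(vcf_path):
        if len(variant.REF) != 1 or any(len(a) != 1 for a in variant.ALT):
            continue
        if apply_hard_filters and not hard_filter_record(variant):
            continue
        af = variant.INFO.get("AF")
        if isinstance(af, tuple):
            af = af[0]
        if af is not None:
            maf = _maf_from_af(float(af))
        else:
            maf = _maf_from_genotypes(variant.genotype.array())
            if maf is None:
                skipped += 1
                continue
        if maf > min_maf:
            sites.append(SnpSite(variant.CHROM, variant.POS - 1, maf))
    return sites, skipped


@dataclass
class DensityProfile:
    offsets: np.ndarray  # -span .. span-1 relative to the dominant TSS
    density: np.ndarray  # SNPs per site per included TSC
    n_tscs: int
    n_excluded: int


def snp_density_profile(
    tscs,
    snps: list[SnpSite],
    repeat_intervals: pd.DataFrame | None = None,
    span: int = 500,
    contig_lengths: dict[str, int] | None = None,
) -> DensityProfile:
    """Position-specific SNP density in 1-kb windows centered on TSSs.

    Offsets are transcript-oriented (negative = upstream of the TSS). TSCs
    whose window overlaps any repeat interval, or extends past a contig
    edge (when contig lengths are known), are excluded and counted.
    """
    rep_trees: dict[str, IntervalTree] = {}
    if repeat_intervals is not None:
        for _, r in repeat_intervals.iterrows():
            rep_trees.setdefault(r["chrom"], IntervalTree()).addi(
                int(r["start"]), int(r["end"])
            )
    snp_pos: dict[str, np.ndarray] = {}
    for s in snps:
        snp_pos.setdefault(s.chrom, []).append(s.pos)
    snp_pos = {c: np.array(sorted(v)) for c, v in snp_pos.items()}

    counts = np.zeros(2 * span, dtype=np.int64)
    n_inc = n_exc = 0
    for t in tscs:
        lo, hi = t.dominant_pos - span, t.dominant_pos + span
        if lo < 0 or (
            contig_lengths is not None and hi > contig_lengths.get(t.chrom, np.inf)
        ):
            n_exc += 1
            continue
        tree = rep_trees.get(t.chrom)
        if tree is not None and tree.overlap(lo, hi):
            n_exc += 1
            continue
        n_inc += 1
        pos = snp_pos.get(t.chrom)
        if pos is None:
            continue
        sel = pos[(pos >= lo) & (pos < hi)]
        off = sel - t.dominant_pos
        if t.strand == "-":
            off = -off - 1
        np.add.at(counts, off + span, 1)
    density = counts / n_inc if n_inc else counts.astype(float)
    return DensityProfile(np.arange(-span, span), density, n_inc, n_exc)
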
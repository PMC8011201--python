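"""Synthetic oligo-capping data with known promoter architecture.

The generator builds a random genome, places non-overlapping protein-coding
genes with annotated leaders and start codons, gives each gene one or two
promoters with a configured TSS-usage shape (sharp / intermediate / broad),
and simulates capped read-pair fragments per library, including the two
experimental artifact classes this protocol is known for:

* adapter mis-hybridization reads starting immediately downstream of a
  genomic TGAG occurrence (with a small share at 1-bp variants), and
* truncated-mRNA reads starting at a recurrent internal transcript position
  of a subset of genes, with 3' ends unconstrained by the insert-size law.

Every read carries a ground-truth label (genuine / tgag / truncated), so
downstream clustering, filtering and assignment can be scored exactly.

Shape parameterization: each promoter's TSS-usage distribution is a mixture
of a point mass at the dominant position and a discretized Gaussian spread;
sharp promoters concentrate ~85% of initiation on the dominant base over a
+/-2 bp support, intermediate ~60% with sigma 8 bp, broad ~35% with sigma
25 bp. Insert lengths are log-normal (right-skewed, long-tailed) with the
median and spread of real oligo-capping insert libraries. All randomness
derives from one seed through numpy SeedSequence spawning.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import FRAGMENT_COLUMNS, GeneModel

SHAPE_CLASSES = ("sharp", "intermediate", "broad")


class SizingError(ValueError):
    """Genome too short to place the requested genes without overlap."""


@dataclass
class SimConfig:
    """Study conditions for one synthetic oligo-capping experiment."""

    genome_length: int = 16_000_000
    n_genes: int = 2000
    n_libraries: int = 4
    reads_per_library: int = 90_000
    promoter_shape_mix: tuple[float, float, float] = (0.45, 0.30, 0.25)
    shape_spread: dict = field(
        default_factory=lambda: {"sharp": 1.0, "intermediate": 8.0, "broad": 25.0}
    )
    dominant_weight: dict = field(
        default_factory=lambda: {"sharp": 0.85, "intermediate": 0.60, "broad": 0.35}
    )
    pypu_fraction: float = 0.80
    distant_fraction: float = 0.45
    multi_promoter_fraction: float = 0.40
    # leader introns: log-normal by class; distant introns are what push a
    # promoter past the 3-kb adjacency threshold
    leader_intron_lengths: dict = field(
        default_factory=lambda: {
            "adjacent_prob": 0.5,
            "adjacent_median": 300.0,
            "adjacent_sigma": 0.5,
            "adjacent_max": 2000.0,
            "distant_median": 6000.0,
            "distant_sigma": 0.3,
            "distant_min": 3500.0,
        }
    )
    insert_size: tuple[float, float] = (math.log(352.3), 0.66)  # log-scale loc/scale
    expression_sigma: float = 0.8  # between-gene log-normal abundance spread
    library_effect_sigma: float = 0.5  # per-gene between-library (tissue) spread
    artifact_tgag_rate: float = 0.10
    artifact_truncation_rate: float = 0.10
    tgag_variant_share: float = 0.02
    truncation_hotspot_fraction: float = 0.18
    cds_length: int = 1800
    seed: int = 0

    def validate(self) -> None:
        fracs = {
            "pypu_fraction": self.pypu_fraction,
            "distant_fraction": self.distant_fraction,
            "multi_promoter_fraction": self.multi_promoter_fraction,
            "artifact_tgag_rate": self.artifact_tgag_rate,
            "artifact_truncation_rate": self.artifact_truncation_rate,
            "tgag_variant_share": self.tgag_variant_share,
            "truncation_hotspot_fraction": self.truncation_hotspot_fraction,
        }
        for name, v in fracs.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if abs(sum(self.promoter_shape_mix) - 1.0) > 1e-9:
            raise ValueError("promoter_shape_mix must sum to 1")
        if self.reads_per_library <= 0:
            raise ValueError("reads_per_library must be positive")
        if self.artifact_tgag_rate + self.artifact_truncation_rate > 1.0:
            raise ValueError("artifact rates must sum to at most 1")


@dataclass
class Promoter:
    """Ground-truth promoter: usage distribution plus its transcript path."""

    promoter_id: str
    gene_id: str
    chrom: str
    strand: str
    dominant_pos: int
    shape_class: str
    offsets: np.ndarray  # transcript-orientation offsets from the dominant
    probs: np.ndarray
    donor: int | None  # genomic leader-intron edges on this promoter's path
    acceptor: int | None
    transcript_length: int  # exonic bases from the dominant TSS to gene end
    distance_to_start_codon: int

    @property
    def adjacency(self) -> str:
        return "distant" if self.distance_to_start_codon > 3000 else "adjacent"

    def interval(self) -> tuple[int, int]:
        lo = int(self.offsets.min())
        hi = int(self.offsets.max())
        if self.strand == "+":
            return self.dominant_pos + lo, self.dominant_pos + hi + 1
        return self.dominant_pos - hi, self.dominant_pos - lo + 1


@dataclass
class SyntheticTruth:
    config: SimConfig
    promoters: list[Promoter]
    hotspots: dict[str, int]  # gene_id -> transcript offset of truncation site
    expression: np.ndarray | None = None  # (n_promoters, n_libraries) weights
    read_labels: pd.DataFrame | None = None

    def promoter_table(self) -> pd.DataFrame:
        rows = []
        for p in self.promoters:
            s, e = p.interval()
            rows.append(
                (
                    p.promoter_id, p.gene_id, p.chrom, p.strand, p.dominant_pos,
                    s, e, p.shape_class, p.distance_to_start_codon, p.adjacency,
                )
            )
        return pd.DataFrame(
            rows,
            columns=[
                "promoter_id", "gene_id", "chrom", "strand", "dominant_pos",
                "start", "end", "shape_class", "distance_to_start_codon",
                "adjacency",
            ],
        )


# ---------------------------------------------------------------------------
# usage distributions
# ---------------------------------------------------------------------------


def usage_distribution(
    shape_class: str, spread: float, dominant_weight: float
) -> tuple[np.ndarray, np.ndarray]:
    """Offsets and probabilities of one promoter's TSS usage.

    A point mass of ``dominant_weight`` at offset 0 mixed with a
    discretized Gaussian of scale ``spread`` truncated at +/- 3 sigma.
    """
    half = max(2, int(round(3 * spread)))
    offsets = np.arange(-half, half + 1)
    tail = np.exp(-0.5 * (offsets / max(spread, 0.5)) ** 2)
    tail[offsets == 0] = 0.0
    tail = tail / tail.sum() * (1 - dominant_weight)
    probs = tail.copy()
    probs[offsets == 0] = dominant_weight
    return offsets, probs / probs.sum()


# ---------------------------------------------------------------------------
# reference generation
# ---------------------------------------------------------------------------

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _force_dinucleotide(seq: np.ndarray, strand: str, dom: int, pypu: bool) -> None:
    """Write the [-1, +1] initiator dinucleotide at a dominant TSS."""
    minus1, plus1 = (b"CA" if pypu else b"GC")
    if strand == "+":
        seq[dom - 1] = minus1
        seq[dom] = plus1
    else:
        comp = {65: 84, 67: 71, 71: 67, 84: 65}
        seq[dom + 1] = comp[minus1]
        seq[dom] = comp[plus1]


def generate_reference(
    config: SimConfig,
) -> tuple[dict[str, str], list[GeneModel], SyntheticTruth]:
    """Build the genome, gene models and ground-truth promoters.

    Genes are placed left to right on one chromosome, alternating strands
    at random, each inside a private slot with margins; a
    :class:`SizingError` is raised when the genome cannot hold them.
    """
    config.validate()
    root = np.random.SeedSequence(config.seed)
    ss_seq, ss_layout, ss_reads = root.spawn(3)
    rng_seq = np.random.default_rng(ss_seq)
    rng = np.random.default_rng(ss_layout)

    chrom = "chr1"
    seq = _BASES[rng_seq.integers(0, 4, size=config.genome_length)].copy()

    li = config.leader_intron_lengths
    m = config.multi_promoter_fraction
    # per-gene distant probability chosen so the promoter-level distant
    # fraction matches config.distant_fraction (multi genes contribute two
    # promoters, the proximal one always adjacent)
    q = min(config.distant_fraction * (1 + m), 1.0)

    genes: list[GeneModel] = []
    promoters: list[Promoter] = []
    hotspots: dict[str, int] = {}
    cursor = 600
    margin = 600

    for gi in range(config.n_genes):
        gene_id = f"G{gi + 1:05d}"
        strand = "+" if rng.integers(2) == 0 else "-"
        shape_primary = rng.choice(3, p=np.asarray(config.promoter_shape_mix))
        multi = rng.random() < m
        distant = rng.random() < q

        # transcript-orientation layout, offsets measured from the primary
        # (most upstream) dominant TSS at coordinate 0
        a1 = int(rng.integers(120, 251))  # first leader exon length
        if distant:
            intron = int(
                np.clip(
                    rng.lognormal(math.log(li["distant_median"]), li["distant_sigma"]),
                    li["distant_min"],
                    None,
                )
            )
        elif rng.random() < li["adjacent_prob"]:
            intron = int(
                np.clip(
                    rng.lognormal(math.log(li["adjacent_median"]), li["adjacent_sigma"]),
                    60,
                    li["adjacent_max"],
                )
            )
        else:
            intron = 0
        u = int(rng.integers(80, 151))  # exon2 5' stretch before the 2nd TSS
        d_exonic = int(rng.integers(150, 401))  # proximal TSS -> start codon
        cds = config.cds_length

        # offsets (transcript path of the primary promoter)
        donor_off = a1
        acceptor_off = a1 + intron
        prox_off = acceptor_off + u if multi else None
        atg_off = acceptor_off + u + d_exonic
        end_off = atg_off + cds
        slot = margin + end_off + 400

        if cursor + slot > config.genome_length:
            raise SizingError(
                f"genome_length={config.genome_length} too short: placed {gi} "
                f"of {config.n_genes} genes"
            )

        if strand == "+":
            dom0 = cursor + margin
            to_g = lambda off: dom0 + off
        else:
            dom0 = cursor + margin + end_off
            to_g = lambda off: dom0 - off
        cursor += slot

        # genomic exon structure (ascending)
        g_points = sorted(
            [to_g(0), to_g(donor_off - 1), to_g(acceptor_off), to_g(end_off - 1)]
        )
        if intron > 0:
            exons = [
                (g_points[0], g_points[1] + 1),
                (g_points[2], g_points[3] + 1),
            ]
        else:
            exons = [(g_points[0], g_points[3] + 1)]
        start_codon = to_g(atg_off)
        mrna_start = to_g(0)
        from .io import _leader_structure

        leader_exons, leader_introns = _leader_structure(
            exons, strand, start_codon, mrna_start
        )
        genes.append(
            GeneModel(
                gene_id=gene_id,
                chrom=chrom,
                strand=strand,
                exons=exons,
                start_codon_pos=start_codon,
                mrna_start=mrna_start,
                leader_exons=leader_exons,
                leader_introns=leader_introns,
            )
        )

        def add_promoter(pid, dom_off, shape_idx, donor, acceptor, t_len, dist):
            cls = SHAPE_CLASSES[shape_idx]
            offsets, probs = usage_distribution(
                cls, config.shape_spread[cls], config.dominant_weight[cls]
            )
            dom = to_g(dom_off)
            pypu = rng.random() < config.pypu_fraction
            _force_dinucleotide(seq, strand, dom, pypu)
            promoters.append(
                Promoter(
                    promoter_id=pid,
                    gene_id=gene_id,
                    chrom=chrom,
                    strand=strand,
                    dominant_pos=dom,
                    shape_class=cls,
                    offsets=offsets,
                    probs=probs,
                    donor=donor,
                    acceptor=acceptor,
                    transcript_length=t_len,
                    distance_to_start_codon=dist,
                )
            )

        # primary (most upstream) promoter: spliced path when an intron exists
        add_promoter(
            f"{gene_id}.p1",
            0,
            shape_primary,
            to_g(donor_off) if intron > 0 else None,
            to_g(acceptor_off) if intron > 0 else None,
            a1 + (end_off - acceptor_off),
            atg_off,
        )
        if multi:
            shape2 = rng.choice(3, p=np.asarray(config.promoter_shape_mix))
            add_promoter(
                f"{gene_id}.p2",
                prox_off,
                shape2,
                None,
                None,
                end_off - prox_off,
                atg_off - prox_off,
            )
        if rng.random() < config.truncation_hotspot_fraction:
            lo = min(900, atg_off + cds // 3)
            hi = min(1400, end_off - 800)
            hotspots[gene_id] = int(rng.integers(lo, max(hi, lo + 1)))

    genome = {chrom: seq.tobytes().decode("ascii")}
    truth = SyntheticTruth(config=config, promoters=promoters, hotspots=hotspots)
    truth._read_seed = ss_reads  # reused by simulate_fragments
    return genome, genes, truth


# ---------------------------------------------------------------------------
# fragment simulation
# ---------------------------------------------------------------------------


def _map_transcript(
    strand: str, cap: int, length: int, donor: int | None, acceptor: int | None
) -> tuple[int, str]:
    """Genomic position of the (length-1)-th transcript base after ``cap``
    and the splice signature crossed along the way."""
    last_off = length - 1
    if strand == "+":
        if donor is not None and cap < donor and cap + last_off >= donor:
            return acceptor + (last_off - (donor - cap)), f"{donor}-{acceptor}"
        return cap + last_off, ""
    if donor is not None and cap > donor and cap - last_off <= donor:
        return acceptor - (last_off - (cap - donor)), f"{acceptor + 1}-{donor + 1}"
    return cap - last_off, ""


def _find_tgag_starts(code: np.ndarray, motif: bytes) -> np.ndarray:
    hit = np.ones(len(code) - len(motif) + 1, dtype=bool)
    for i, b in enumerate(motif):
        hit &= code[i : len(code) - len(motif) + 1 + i] == b
    return np.flatnonzero(hit)


def simulate_fragments(
    genome: dict[str, str],
    genes: list[GeneModel],
    truth: SyntheticTruth,
    config: SimConfig,
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Simulate per-library capped fragments with ground-truth labels.

    Genuine reads start within a true promoter following its TSS-usage
    distribution and get log-normal insert lengths (spliced through the
    leader intron when present). Artifact reads follow the two mechanisms
    described in the module docstring. Returns the fragments table and the
    truth object with ``read_labels`` (one row per fragment, same order).
    """
    config.validate()
    rng = np.random.default_rng(getattr(truth, "_read_seed", config.seed))
    chrom = next(iter(genome))
    code = np.frombuffer(genome[chrom].encode(), dtype=np.uint8)

    promoters = truth.promoters
    n_prom = len(promoters)

    # expression model: gene-level abundance x per-library (tissue) effect,
    # with a fixed per-promoter share within each gene -- so a gene's
    # proximal/distal usage ratio is constant across libraries (no promoter
    # shifting under the default conditions)
    gene_ids = sorted({p.gene_id for p in promoters})
    gene_idx = {g: i for i, g in enumerate(gene_ids)}
    base_gene_w = rng.lognormal(0.0, config.expression_sigma, size=len(gene_ids))
    shares = np.ones(n_prom)
    by_gene: dict[str, list[int]] = {}
    for i, p in enumerate(promoters):
        by_gene.setdefault(p.gene_id, []).append(i)
    for gid, idxs in sorted(by_gene.items()):
        if len(idxs) > 1:
            theta = rng.uniform(0.25, 0.75)
            shares[idxs[0]] = theta
            for j in idxs[1:]:
                shares[j] = (1 - theta) / (len(idxs) - 1)

    hot_genes = sorted(truth.hotspots)
    gene_by_id = {g.gene_id: g for g in genes}
    hot_w = rng.lognormal(0.0, 0.8, size=len(hot_genes)) if hot_genes else None

    variants = []
    for i in range(4):
        for b in "ACGT":
            if b != "TGAG"[i]:
                variants.append("TGAG"[:i] + b + "TGAG"[i + 1 :])
    occ_cache: dict[str, tuple[np.ndarray, np.ndarray]] = {}

    def occurrences(motif: str) -> tuple[np.ndarray, np.ndarray]:
        if motif not in occ_cache:
            comp = motif.translate(str.maketrans("ACGT", "TGCA"))[::-1]
            occ_cache[motif] = (
                _find_tgag_starts(code, motif.encode()),
                _find_tgag_starts(code, comp.encode()),
            )
        return occ_cache[motif]

    mu, sigma = config.insert_size
    rows: list[tuple] = []
    labels: list[tuple] = []
    expr = np.zeros((n_prom, config.n_libraries))

    for lib_i in range(config.n_libraries):
        lib = f"lib{lib_i + 1}"
        gene_w = base_gene_w * rng.lognormal(
            0.0, config.library_effect_sigma, size=len(gene_ids)
        )
        lib_w = np.array(
            [gene_w[gene_idx[p.gene_id]] for p in promoters]
        ) * shares
        expr[:, lib_i] = lib_w
        n_reads = config.reads_per_library
        n_tgag, n_trunc, n_gen = rng.multinomial(
            n_reads,
            [
                config.artifact_tgag_rate,
                config.artifact_truncation_rate if hot_genes else 0.0,
                1
                - config.artifact_tgag_rate
                - (config.artifact_truncation_rate if hot_genes else 0.0),
            ],
        )

        # genuine reads
        if n_prom and n_gen:
            counts = rng.multinomial(n_gen, lib_w / lib_w.sum())
            for pi in np.flatnonzero(counts):
                p = promoters[pi]
                k = int(counts[pi])
                offs = rng.choice(p.offsets, size=k, p=p.probs)
                lengths = np.clip(
                    np.rint(rng.lognormal(mu, sigma, size=k)).astype(int),
                    60,
                    None,
                )
                for off, length in zip(offs, lengths):
                    if p.strand == "+":
                        cap = p.dominant_pos + int(off)
                    else:
                        cap = p.dominant_pos - int(off)
                    length = min(int(length), p.transcript_length - int(off) - 1)
                    end3, sig = _map_transcript(
                        p.strand, cap, length, p.donor, p.acceptor
                    )
                    if p.strand == "+":
                        rows.append((chrom, "+", cap, end3 + 1, sig, lib))
                    else:
                        rows.append((chrom, "-", cap, end3, sig, lib))
                    labels.append(("genuine", p.promoter_id, p.gene_id, lib))

        # adapter mis-hybridization reads
        for _ in range(int(n_tgag)):
            if rng.random() < config.tgag_variant_share:
                motif = variants[int(rng.integers(len(variants)))]
            else:
                motif = "TGAG"
            fpos, rpos = occurrences(motif)
            if rng.integers(2) == 0 and len(fpos):
                occ = int(fpos[rng.integers(len(fpos))])
                cap = occ + 4
                length = max(60, int(rng.lognormal(mu, sigma)))
                end3 = min(cap + length - 1, len(code) - 1)
                rows.append((chrom, "+", cap, end3 + 1, "", lib))
            elif len(rpos):
                occ = int(rpos[rng.integers(len(rpos))])
                cap = occ - 1
                if cap < 100:
                    continue
                length = max(60, int(rng.lognormal(mu, sigma)))
                end3 = max(cap - length + 1, 0)
                rows.append((chrom, "-", cap, end3, "", lib))
            else:
                continue
            labels.append(("tgag", "", "", lib))

        # truncated-mRNA internal reads at recurrent hotspots
        if hot_genes and n_trunc:
            counts = rng.multinomial(n_trunc, hot_w / hot_w.sum())
            for hi_i in np.flatnonzero(counts):
                gid = hot_genes[hi_i]
                g = gene_by_id[gid]
                hs = truth.hotspots[gid]
                # hotspot transcript offset -> genomic cap (exonic walk)
                for _ in range(int(counts[hi_i])):
                    jitter = int(rng.integers(-2, 3))
                    cap = _transcript_to_genomic(g, hs + jitter)
                    if cap is None:
                        continue
                    t_total = sum(e - s for s, e in g.exons)
                    room = t_total - (hs + jitter) - 1
                    ext = int(rng.integers(300, 701))
                    ext = min(ext, max(room, 61))
                    end3, sig = _map_transcript_gene(g, hs + jitter, ext)
                    if g.strand == "+":
                        rows.append((chrom, "+", cap, end3 + 1, sig, lib))
                    else:
                        rows.append((chrom, "-", cap, end3, sig, lib))
                    labels.append(("truncated", "", gid, lib))

    fragments = pd.DataFrame(rows, columns=FRAGMENT_COLUMNS)
    truth.read_labels = pd.DataFrame(
        labels, columns=["label", "promoter_id", "gene_id", "library_id"]
    )
    truth.expression = expr
    return fragments, truth


def _transcript_to_genomic(gene: GeneModel, offset: int) -> int | None:
    """Genomic position of transcript ``offset`` (0 = annotated 5' end)."""
    if offset < 0:
        return None
    if gene.strand == "+":
        for s, e in gene.exons:
            if offset < e - s:
                return s + offset
            offset -= e - s
    else:
        for s, e in reversed(gene.exons):
            if offset < e - s:
                return e - 1 - offset
            offset -= e - s
    return None


def _map_transcript_gene(
    gene: GeneModel, start_offset: int, length: int
) -> tuple[int, str]:
    """Genomic 3'-most base of a fragment covering ``length`` transcript
    bases from ``start_offset``, plus the splice signature it crosses."""
    end_off = start_offset + length - 1
    end_g = _transcript_to_genomic(gene, end_off)
    if end_g is None:
        end_g = (
            gene.exons[-1][1] - 1 if gene.strand == "+" else gene.exons[0][0]
        )
    sig_parts = []
    start_g = _transcript_to_genomic(gene, start_offset)
    for s, e in zip(gene.exons, gene.exons[1:]):
        intron = (s[1], e[0])
        lo, hi = sorted((start_g, end_g))
        if lo < intron[0] and hi >= intron[1]:
            sig_parts.append(f"{intron[0]}-{intron[1]}")
    return end_g, ";".join(sig_parts)


def simulate(config: SimConfig):
    """Reference + fragments in one call."""
    genome, genes, truth = generate_reference(config)
    fragments, truth = simulate_fragments(genome, genes, truth, config)
    return genome, genes, truth, fragments
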
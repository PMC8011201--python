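"""Readers and writers for the formats the pipeline touches.

All internal coordinates are 0-based half-open. GFF3 (1-based inclusive) and
BED (0-based half-open) are converted at the boundary; the converters are
inverse bijections and round-trip tested.

The native "fragments" table is a TSV with one row per deduplicatable read
pair: chrom, strand, cap_pos, insert_end, splice_signature (semicolon-joined
"donor-acceptor" genomic coordinate pairs, empty for unspliced inserts) and
library_id.

Coordinate convention (strand-mirrored):

* ``+`` strand: ``cap_pos`` is the genomic leftmost (5') base of the insert
  and ``insert_end`` the exclusive right edge, so the genomic interval is
  ``[cap_pos, insert_end)`` and the 3'-most base is ``insert_end - 1``.
* ``-`` strand: ``cap_pos`` is the genomic rightmost base (the biological
  5' end) and ``insert_end`` the genomic leftmost base, which is the insert's
  3'-most base; the genomic interval is ``[insert_end, cap_pos + 1)``.

Thus ``cap_pos`` is always the first transcribed base and the insert length
in genomic space is ``abs(cap_pos - insert_end) + (1 if '-' else 0)``;
helpers below expose the normalized genomic interval and 3' end.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import gffutils
import numpy as np
import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

FRAGMENT_COLUMNS = [
    "chrom",
    "strand",
    "cap_pos",
    "insert_end",
    "splice_signature",
    "library_id",
]


class FragmentParseError(ValueError):
    """Raised for malformed fragment records; carries the line number."""


# ---------------------------------------------------------------------------
# fragments
# ---------------------------------------------------------------------------


def empty_fragments() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": pd.Series(dtype=str),
            "strand": pd.Series(dtype=str),
            "cap_pos": pd.Series(dtype=np.int64),
            "insert_end": pd.Series(dtype=np.int64),
            "splice_signature": pd.Series(dtype=str),
            "library_id": pd.Series(dtype=str),
        }
    )


def _validate_fragments(df: pd.DataFrame) -> pd.DataFrame:
    if not df["strand"].isin(["+", "-"]).all():
        raise FragmentParseError("strand must be '+' or '-'")
    plus = df["strand"].to_numpy() == "+"
    cap = df["cap_pos"].to_numpy()
    end = df["insert_end"].to_numpy()
    bad = np.where(plus, cap >= end, end > cap)
    if bad.any():
        i = int(np.flatnonzero(bad)[0])
        raise FragmentParseError(
            f"fragment line {i + 2}: cap/insert coordinates out of order "
            "for the record's strand"
        )
    return df


def read_fragments(path: str, fmt: str = "tabular") -> pd.DataFrame:
    """Read read-pair fragments from a tabular TSV or a SAM/BAM file.

    Returns a DataFrame with :data:`FRAGMENT_COLUMNS`. For SAM input, the
    exclusion count of soft-clipped pairs is available via
    :func:`read_fragments_sam`.
    """
    if fmt == "tabular":
        df = pd.read_csv(
            path,
            sep="\t",
            dtype={
                "chrom": str,
                "strand": str,
                "cap_pos": np.int64,
                "insert_end": np.int64,
                "splice_signature": str,
                "library_id": str,
            },
            keep_default_na=False,
        )
        missing = [c for c in FRAGMENT_COLUMNS if c not in df.columns]
        if missing:
            raise FragmentParseError(f"missing columns: {missing}")
        return _validate_fragments(df[FRAGMENT_COLUMNS])
    if fmt == "sam":
        frags, _ = read_fragments_sam(path)
        return frags
    raise ValueError(f"unknown fragments format: {fmt!r}")


def write_fragments(df: pd.DataFrame, path: str) -> None:
    df[FRAGMENT_COLUMNS].to_csv(path, sep="\t", index=False)


def _cigar_has_softclip(read: pysam.AlignedSegment) -> bool:
    return any(op == 4 for op, _ in (read.cigartuples or []))


def _splice_junctions(read: pysam.AlignedSegment) -> list[tuple[int, int]]:
    """Genomic (donor, acceptor) pairs from N operations, 0-based half-open."""
    juncs = []
    pos = read.reference_start
    for op, length in read.cigartuples or []:
        if op in (0, 2, 7, 8):  # M, D, =, X consume reference
            pos += length
        elif op == 3:  # N
            juncs.append((pos, pos + length))
            pos += length
    return juncs


def read_fragments_sam(
    path: str, library_id: str | None = None
) -> tuple[pd.DataFrame, int]:
    """Extract fragments from proper read pairs in a SAM/BAM file.

    The biological 5' end is the 5'-most base of R1 in transcript
    orientation: the leftmost aligned base of R1 on the + strand, the
    rightmost on the - strand. Soft-clipped alignments are rejected (they
    would shift the apparent cap site); the second return value counts the
    pairs excluded for that reason.
    """
    lib = library_id if library_id is not None else os.path.basename(path)
    rows: list[tuple] = []
    n_softclip = 0
    pending: dict[str, pysam.AlignedSegment] = {}
    mode = "rb" if path.endswith(".bam") else "r"
    with pysam.AlignmentFile(path, mode, check_sq=False) as sam:
        for read in sam:
            if (
                read.is_unmapped
                or read.mate_is_unmapped
                or read.is_secondary
                or read.is_supplementary
                or not read.is_proper_pair
            ):
                continue
            mate = pending.pop(read.query_name, None)
            if mate is None:
                pending[read.query_name] = read
                continue
            r1, r2 = (read, mate) if read.is_read1 else (mate, read)
            if _cigar_has_softclip(r1) or _cigar_has_softclip(r2):
                n_softclip += 1
                continue
            left = min(r1.reference_start, r2.reference_start)
            right = max(r1.reference_end, r2.reference_end)
            strand = "-" if r1.is_reverse else "+"
            cap = left if strand == "+" else right - 1
            juncs = sorted(set(_splice_junctions(r1) + _splice_junctions(r2)))
            sig = ";".join(f"{d}-{a}" for d, a in juncs)
            if strand == "+":
                cap_pos, insert_end = left, right
            else:
                cap_pos, insert_end = right - 1, left
            rows.append((r1.reference_name, strand, cap_pos, insert_end, sig, lib))
    df = pd.DataFrame(rows, columns=FRAGMENT_COLUMNS)
    if df.empty:
        df = empty_fragments()
        df["library_id"] = df["library_id"].astype(str)
    return df, n_softclip


def fragment_genomic_interval(df: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Genomic half-open [start, end) of each insert regardless of strand."""
    plus = df["strand"].to_numpy() == "+"
    cap = df["cap_pos"].to_numpy()
    end = df["insert_end"].to_numpy()
    start = np.where(plus, cap, end)
    stop = np.where(plus, end, cap + 1)
    return start, stop


def three_prime_end(df: pd.DataFrame) -> np.ndarray:
    """0-based genomic position of each insert's 3'-most base."""
    plus = df["strand"].to_numpy() == "+"
    return np.where(plus, df["insert_end"].to_numpy() - 1, df["insert_end"].to_numpy())


# ---------------------------------------------------------------------------
# gene models
# ---------------------------------------------------------------------------


@dataclass
class GeneModel:
    """A protein-coding gene reduced to what promoter assignment needs.

    Coordinates are 0-based half-open genomic intervals. ``start_codon_pos``
    is the genomic position of the first base of the start codon (the A of
    ATG on the + strand; on the - strand the genomic rightmost base of the
    codon). The mRNA leader (5' UTR) is the transcript span 5' of the start
    codon, possibly interrupted by leader introns.
    """

    gene_id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]
    start_codon_pos: int
    mrna_start: int
    leader_exons: list[tuple[int, int]] = field(default_factory=list)
    leader_introns: list[tuple[int, int]] = field(default_factory=list)

    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]


def _leader_structure(
    exons: list[tuple[int, int]], strand: str, start_codon_pos: int, mrna_start: int
) -> tuple[list[tuple[int, int]], list[tuple[int, int]]]:
    """Leader exon/intron intervals 5' of the start codon."""
    leader_exons = []
    if strand == "+":
        for s, e in exons:
            if s >= start_codon_pos:
                break
            leader_exons.append((s, min(e, start_codon_pos)))
    else:
        for s, e in reversed(exons):
            if e <= start_codon_pos + 1:
                break
            leader_exons.append((max(s, start_codon_pos + 1), e))
        leader_exons.reverse()
    introns = []
    for (s1, e1), (s2, e2) in zip(leader_exons, leader_exons[1:]):
        introns.append((e1, s2))
    return leader_exons, introns


def read_gene_models(gff3_path: str) -> list[GeneModel]:
    """Parse a GFF3 into :class:`GeneModel` records.

    1-based inclusive GFF coordinates become 0-based half-open. Genes
    without a CDS are skipped (start codon undefined) with a warning count
    left to the caller via the returned list length.
    """
    db = gffutils.create_db(
        gff3_path,
        ":memory:",
        merge_strategy="create_unique",
        keep_order=True,
    )
    genes: list[GeneModel] = []
    for gene in db.features_of_type("gene"):
        mrnas = list(db.children(gene, featuretype="mRNA"))
        if not mrnas:
            continue
        mrna = mrnas[0]  # first (primary) isoform
        exons = sorted(
            (f.start - 1, f.end) for f in db.children(mrna, featuretype="exon")
        )
        cds = sorted(
            (f.start - 1, f.end) for f in db.children(mrna, featuretype="CDS")
        )
        if not cds or not exons:
            continue
        strand = gene.strand
        if strand == "+":
            start_codon = cds[0][0]
            mrna_start = exons[0][0]
        else:
            start_codon = cds[-1][1] - 1
            mrna_start = exons[-1][1] - 1
        leader_exons, leader_introns = _leader_structure(
            exons, strand, start_codon, mrna_start
        )
        genes.append(
            GeneModel(
                gene_id=gene.id,
                chrom=gene.seqid,
                strand=strand,
                exons=exons,
                start_codon_pos=start_codon,
                mrna_start=mrna_start,
                leader_exons=leader_exons,
                leader_introns=leader_introns,
            )
        )
    return genes


def write_gene_models_gff3(genes: list[GeneModel], path: str) -> None:
    """Serialize gene models as minimal GFF3 (gene/mRNA/exon/CDS)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            gs, ge = g.span()
            attrs = f"ID={g.gene_id}"
            fh.write(
                f"{g.chrom}\t.\tgene\t{gs + 1}\t{ge}\t.\t{g.strand}\t.\t{attrs}\n"
            )
            mid = f"{g.gene_id}.t1"
            fh.write(
                f"{g.chrom}\t.\tmRNA\t{gs + 1}\t{ge}\t.\t{g.strand}\t.\t"
                f"ID={mid};Parent={g.gene_id}\n"
            )
            for s, e in g.exons:
                fh.write(
                    f"{g.chrom}\t.\texon\t{s + 1}\t{e}\t.\t{g.strand}\t.\t"
                    f"Parent={mid}\n"
                )
            if g.strand == "+":
                cds_start, cds_end = g.start_codon_pos, g.span()[1]
            else:
                cds_start, cds_end = g.span()[0], g.start_codon_pos + 1
            for s, e in g.exons:
                cs, ce = max(s, cds_start), min(e, cds_end)
                if cs < ce:
                    fh.write(
                        f"{g.chrom}\t.\tCDS\t{cs + 1}\t{ce}\t.\t{g.strand}\t0\t"
                        f"Parent={mid}\n"
                    )


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def read_fasta(path: str) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(path, "fasta")}


def write_fasta(genome: dict[str, str], path: str) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in genome.items()
    ]
    SeqIO.write(records, path, "fasta")


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------


def read_bed_intervals(path: str) -> pd.DataFrame:
    """BED3+ intervals as a DataFrame (chrom, start, end[, name])."""
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            name = parts[3] if len(parts) > 3 else "."
            rows.append((parts[0], int(parts[1]), int(parts[2]), name))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])


TSC_BED_HEADER = (
    "#chrom\tstart\tend\tname\tscore\tstrand\tdominant_pos\tpss\t"
    "shape_class\tgene_id\n"
)


def write_tsc_bed(tscs, path: str, shape=None, assignments=None) -> None:
    """Write TSCs as BED6+ (extra columns: dominant TSS, PSS, shape class,
    linked gene). Score is the rounded total TPM."""
    shape = shape or {}
    gene_of = {}
    if assignments is not None and len(assignments):
        gene_of = dict(zip(assignments["tsc_id"], assignments["gene_id"]))
    with open(path, "w") as fh:
        fh.write(TSC_BED_HEADER)
        for t in tscs:
            sr = shape.get(t.id)
            pss = f"{sr.pss:.6g}" if sr is not None else "."
            cls = sr.shape_class if sr is not None else "."
            fh.write(
                f"{t.chrom}\t{t.boundary_start}\t{t.boundary_end}\t{t.id}\t"
                f"{round(t.total_tpm)}\t{t.strand}\t{t.dominant_pos}\t{pss}\t"
                f"{cls}\t{gene_of.get(t.id, '.')}\n"
            )


def read_tsc_bed(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    df.columns = [c.lstrip("#") for c in df.columns]
    return df
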
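"""Nucleotide composition around dominant TSSs.

All windowing is strand-aware: reverse-strand promoters are analyzed on the
reverse complement, so "upstream" always means 5' of the TSS in transcript
orientation. Profiles are averaged across promoters; windows truncated by a
contig edge are skipped and counted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .filters import revcomp

PYRIMIDINES = set("CT")
PURINES = set("AG")

IUPAC = {
    "A": set("A"), "C": set("C"), "G": set("G"), "T": set("T"),
    "R": set("AG"), "Y": set("CT"), "S": set("CG"), "W": set("AT"),
    "K": set("GT"), "M": set("AC"), "B": set("CGT"), "D": set("AGT"),
    "H": set("ACT"), "V": set("ACG"), "N": set("ACGT"),
}

# Literature consensus core-promoter elements with their canonical search
# windows relative to the dominant TSS (+1 at offset 0). Overridable.
DEFAULT_ELEMENT_TABLE = pd.DataFrame(
    [
        ("TATA", "STATAAA", -40, -20),
        ("Inr", "TCAKTY", -6, 6),
        ("TCT", "YYCTTTYY", -6, 6),
        ("MTE", "CSARCSSAACGS", 18, 38),
        ("DPE", "RGWYVT", 28, 34),
    ],
    columns=["name", "consensus", "window_start", "window_end"],
)


def tss_window(
    genome: dict[str, str], chrom: str, strand: str, pos: int, up: int, down: int
) -> str | None:
    """Transcript-orientation window covering ``up`` bases 5' of the TSS,
    the TSS itself, and ``down`` bases 3'; None if truncated by an edge."""
    seq = genome[chrom]
    if strand == "+":
        s, e = pos - up, pos + down + 1
        if s < 0 or e > len(seq):
            return None
        return seq[s:e]
    s, e = pos - down, pos + up + 1
    if s < 0 or e > len(seq):
        return None
    return revcomp(seq[s:e])


# ---------------------------------------------------------------------------
# initiator dinucleotides and consensus matrix
# ---------------------------------------------------------------------------


def initiator_dinucleotide(tscs, genome: dict[str, str]) -> pd.DataFrame:
    """[-1, +1] dinucleotide and PyPu flag for each promoter.

    PyPu means pyrimidine at -1 and purine at +1, the canonical metazoan
    initiator signature. Promoters at contig edges are skipped.
    """
    rows = []
    for t in tscs:
        w = tss_window(genome, t.chrom, t.strand, t.dominant_pos, 1, 0)
        if w is None or len(w) != 2:
            continue
        pypu = w[0] in PYRIMIDINES and w[1] in PURINES
        rows.append((t.id, w, pypu))
    return pd.DataFrame(rows, columns=["tsc_id", "dinucleotide", "pypu"])


def pypu_fraction(dinucleotides: pd.DataFrame) -> float:
    if len(dinucleotides) == 0:
        return float("nan")
    return float(dinucleotides["pypu"].mean())


@dataclass
class PositionFrequencyMatrix:
    window_start: int  # offset of the first column relative to the TSS
    counts: np.ndarray  # 4 x window_length, rows A, C, G, T
    n_sequences: int


def consensus_matrix(
    tscs, genome: dict[str, str], window: int = 25, tss_index: int = 10
) -> PositionFrequencyMatrix:
    """Base-count matrix of the ``window`` bp surrounding dominant TSSs.

    The dominant TSS sits at column ``tss_index`` (default 10: 10 bp
    upstream, 14 bp downstream). Rows are A, C, G, T; column sums equal the
    number of non-truncated contributing promoters.
    """
    counts = np.zeros((4, window), dtype=np.int64)
    row = {b: i for i, b in enumerate("ACGT")}
    n = 0
    for t in tscs:
        seq = tss_window(
            genome, t.chrom, t.strand, t.dominant_pos, tss_index, window - tss_index - 1
        )
        if seq is None:
            continue
        n += 1
        for j, b in enumerate(seq):
            if b in row:
                counts[row[b], j] += 1
    return PositionFrequencyMatrix(-tss_index, counts, n)


# ---------------------------------------------------------------------------
# composition profiles
# ---------------------------------------------------------------------------


@dataclass
class CompositionProfile:
    offsets: np.ndarray  # window start offsets relative to the TSS
    values: np.ndarray  # per-window mean across promoters (NaN = masked)
    n_sequences: int


def _windowed_stat(tscs, genome, span, window, fn) -> CompositionProfile:
    n_windows = 2 * span // window
    acc = np.zeros(n_windows)
    cnt = np.zeros(n_windows)
    n = 0
    for t in tscs:
        seq = tss_window(genome, t.chrom, t.strand, t.dominant_pos, span, span - 1)
        if seq is None:
            continue
        n += 1
        for i in range(n_windows):
            v = fn(seq[i * window : (i + 1) * window])
            if v is not None:
                acc[i] += v
                cnt[i] += 1
    values = np.where(cnt > 0, acc / np.maximum(cnt, 1), np.nan)
    offsets = np.arange(n_windows) * window - span
    return CompositionProfile(offsets, values, n)


def _gc_fraction(win: str) -> float | None:
    acgt = sum(win.count(b) for b in "ACGT")
    if acgt == 0:
        return None
    return (win.count("G") + win.count("C")) / acgt


def gc_deviation_profile(
    tscs, genome: dict[str, str], span: int = 2000, window: int = 50
) -> CompositionProfile:
    """GC content per 50-bp window across +/- span, normalized to the mean
    GC over the whole profile (flat = 1.0). N bases are excluded from the
    window denominator."""
    prof = _windowed_stat(tscs, genome, span, window, _gc_fraction)
    mean = np.nanmean(prof.values)
    if mean > 0:
        prof.values = prof.values / mean
    return prof


def cpg_oe(win: str) -> float | None:
    """Observed/expected CpG for one window: (#CG x L) / (#C x #G), with
    overlapping dinucleotide counting; undefined when #C x #G = 0."""
    c, g = win.count("C"), win.count("G")
    if c * g == 0:
        return None
    return win.count("CG") * len(win) / (c * g)


def cpg_oe_profile(
    tscs, genome: dict[str, str], span: int = 2000, window: int = 50
) -> CompositionProfile:
    """Normalized CpG content per 50-bp window across +/- span; windows
    with no C or no G are masked (NaN) and propagated as missing."""
    return _windowed_stat(tscs, genome, span, window, cpg_oe)


# ---------------------------------------------------------------------------
# core-promoter element matching
# ---------------------------------------------------------------------------


def iupac_mismatches(seq: str, consensus: str) -> int:
    """Hamming distance where a base already covered by the IUPAC class at
    that position counts as a match."""
    if len(seq) != len(consensus):
        raise ValueError("length mismatch")
    n = 0
    for b, c in zip(seq, consensus):
        allowed = IUPAC.get(c)
        if allowed is None:
            raise ValueError(f"invalid IUPAC code {c!r}")
        if b not in allowed:
            n += 1
    return n


def element_match(
    tscs,
    genome: dict[str, str],
    element_table: pd.DataFrame | None = None,
    max_mismatch: int = 1,
) -> pd.DataFrame:
    """Presence of each core-promoter element per promoter.

    An element is present iff some start position inside its window
    (offsets relative to the dominant TSS, transcript orientation) matches
    the IUPAC consensus with <= ``max_mismatch`` mismatches.
    """
    table = element_table if element_table is not None else DEFAULT_ELEMENT_TABLE
    rows = []
    for t in tscs:
        rec = {"tsc_id": t.id}
        for el in table.itertuples():
            width = len(el.consensus)
            lo, hi = int(el.window_start), int(el.window_end)
            up = max(0, -lo)
            down = max(0, hi + width - 1)
            seq = tss_window(genome, t.chrom, t.strand, t.dominant_pos, up, down)
            found = False
            if seq is not None:
                for off in range(lo, hi + 1):
                    j = off + up
                    sub = seq[j : j + width]
                    if len(sub) == width and iupac_mismatches(sub, el.consensus) <= max_mismatch:
                        found = True
                        break
            rec[el.name] = found
        rows.append(rec)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# random genomic background
# ---------------------------------------------------------------------------


def random_background(
    genome: dict[str, str], n: int, length: int, seed: int = 0
) -> list[tuple[str, str, int]]:
    """``n`` seeded random (chrom, strand, position) anchors with at least
    ``length`` bp of sequence on both sides, for promoter-vs-background
    composition comparisons."""
    rng = np.random.default_rng(seed)
    chroms = sorted(genome)
    lengths = np.array([len(genome[c]) for c in chroms], dtype=float)
    out = []
    for _ in range(n):
        c = chroms[int(rng.choice(len(chroms), p=lengths / lengths.sum()))]
        p = int(rng.integers(length, len(genome[c]) - length))
        s = "+" if rng.integers(2) == 0 else "-"
        out.append((c, s, p))
    return out


def fraction_chi2(k1: int, n1: int, k2: int, n2: int) -> tuple[float, float]:
    """2x2 chi-squared comparing a feature fraction between two sets."""
    table = np.array([[k1, n1 - k1], [k2, n2 - k2]], dtype=float)
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        return 0.0, 1.0
    chi2, p, _, _ = sps.chi2_contingency(table)
    return float(chi2), float(p)
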
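"""PWM scanning around dominant TSSs and TFBS abundance/divergence.

The scanner scores log-odds (probability matrix with a 0.01 per-cell
pseudocount over the background) on both strands of the [-500, +100] window
around the dominant TSS, in transcript orientation. Statistical calibration
comes from the exact null score distribution under the background model,
computed by dynamic programming over integer-discretized columns; a window
is a hit when the p-value of its score is below the cut-off (1e-5 by
default). Results are putative binding sites: no functional evidence is
implied.

Per-TF divergence of the matched sites uses a normalized Shannon entropy:
SE = (1/L) * sum_columns(-sum_bases P log2 P), in [0, 2] for the DNA
alphabet, computed on the gap-free stack of strand-normalized hit
sequences.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio import motifs as bio_motifs
from scipy import stats as sps

from .filters import revcomp
from .stats import bh_fdr

_CODE = {b: i for i, b in enumerate("ACGT")}
UNIFORM_BG = np.full(4, 0.25)


@dataclass
class PWM:
    tf_name: str
    matrix: np.ndarray  # (width, 4) probabilities, columns A C G T
    background: np.ndarray = None

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.background is None:
            self.background = UNIFORM_BG.copy()
        self.background = np.asarray(self.background, dtype=float)
        if not np.allclose(self.matrix.sum(axis=1), 1.0, atol=1e-3):
            raise ValueError(f"PWM {self.tf_name}: rows must sum to 1")

    @property
    def width(self) -> int:
        return self.matrix.shape[0]


def read_jaspar(path: str) -> list[PWM]:
    with open(path) as fh:
        records = bio_motifs.parse(fh, "jaspar")
    out = []
    for m in records:
        counts = np.array([m.counts[b] for b in "ACGT"], dtype=float).T
        out.append(PWM(m.name or m.matrix_id, counts / counts.sum(axis=1, keepdims=True)))
    return out


def read_meme_minimal(path: str) -> list[PWM]:
    with open(path) as fh:
        records = bio_motifs.parse(fh, "minimal")
    out = []
    for m in records:
        pwm = np.array([m.pwm[b] for b in "ACGT"], dtype=float).T
        bg = np.array([m.background[b] for b in "ACGT"], dtype=float)
        out.append(PWM(m.name, pwm, bg))
    return out


# ---------------------------------------------------------------------------
# log-odds and the exact DP null
# ---------------------------------------------------------------------------


@dataclass
class ScoringScheme:
    """Integer-discretized log-odds matrix with its exact null tail.

    ``int_scores`` is the (width, 4) integer matrix (granularity ``eps`` in
    log2-odds units, scores shifted so the minimum per column is 0);
    ``tail[s]`` is P(integer score >= s) under the background model.
    """

    pwm: PWM
    eps: float
    int_scores: np.ndarray
    offset: int  # sum of per-column minimum raw integer scores
    tail: np.ndarray

    def int_score_to_p(self, s: int) -> float:
        s = min(max(s, 0), len(self.tail) - 1)
        return float(self.tail[s])

    def min_int_score_for_p(self, p_threshold: float) -> int:
        idx = np.flatnonzero(self.tail < p_threshold)
        return int(idx[0]) if len(idx) else len(self.tail)


def build_scoring(
    pwm: PWM, pseudocount: float = 0.01, granularity: float = 1e-3
) -> ScoringScheme:
    """Log-odds scoring with the exact integer-DP null distribution.

    Scores are log2((p + pseudocount-normalized) / background), rounded to
    ``granularity`` log2 units. The null distribution of the total score of
    a random background sequence is the exact convolution of the per-column
    score distributions.
    """
    p = (pwm.matrix + pseudocount) / (1 + 4 * pseudocount)
    lo = np.log2(p / pwm.background[None, :])
    ints = np.rint(lo / granularity).astype(np.int64)
    col_min = ints.min(axis=1)
    shifted = ints - col_min[:, None]
    total_range = int(shifted.max(axis=1).sum())
    dist = np.zeros(total_range + 1)
    dist[0] = 1.0
    pos = 0
    for i in range(pwm.width):
        new = np.zeros_like(dist)
        for b in range(4):
            s = int(shifted[i, b])
            new[s : pos + s + 1] += dist[: pos + 1] * pwm.background[b]
        dist = new
        pos += int(shifted[i].max())
    tail = dist[::-1].cumsum()[::-1]
    return ScoringScheme(pwm, granularity, shifted, int(col_min.sum()), tail)


def score_sequence(scheme: ScoringScheme, seq: str) -> int | None:
    """Shifted integer score of one width-length sequence (None if it
    contains a non-ACGT base)."""
    if len(seq) != scheme.pwm.width:
        raise ValueError("sequence length must equal motif width")
    total = 0
    for i, b in enumerate(seq):
        j = _CODE.get(b)
        if j is None:
            return None
        total += int(scheme.int_scores[i, j])
    return total


def sequence_pvalue(scheme: ScoringScheme, seq: str) -> float | None:
    s = score_sequence(scheme, seq)
    return None if s is None else scheme.int_score_to_p(s)


def _scan_strand(scheme: ScoringScheme, codes: np.ndarray) -> np.ndarray:
    """Shifted integer score at every start position of an encoded
    sequence; positions covering a non-ACGT base get -1."""
    w = scheme.pwm.width
    n = len(codes) - w + 1
    if n <= 0:
        return np.zeros(0, dtype=np.int64)
    total = np.zeros(n, dtype=np.int64)
    bad = np.zeros(n, dtype=bool)
    for i in range(w):
        window = codes[i : i + n]
        invalid = window < 0
        bad |= invalid
        total += scheme.int_scores[i, np.where(invalid, 0, window)]
    total[bad] = -1
    return total


def _encode(seq: str) -> np.ndarray:
    return np.array([_CODE.get(b, -1) for b in seq], dtype=np.int64)


def scan_pwm(
    tscs,
    genome: dict[str, str],
    pwms: list[PWM],
    window: tuple[int, int] = (-500, 100),
    p_threshold: float = 1e-5,
    pseudocount: float = 0.01,
) -> pd.DataFrame:
    """Scan each PWM over the window around every dominant TSS.

    The window is [TSS+window[0], TSS+window[1]] in transcript orientation;
    both strands of it are scanned and hits are reported with the offset of
    the site's 5'-most base relative to the TSS, the site strand relative
    to the promoter strand, the log2-odds score, its exact p-value, and the
    strand-normalized matched sequence.
    """
    from .seqfeatures import tss_window

    lo, hi = window
    rows = []
    for pwm in pwms:
        scheme = build_scoring(pwm, pseudocount)
        cutoff = scheme.min_int_score_for_p(p_threshold)
        w = pwm.width
        for t in tscs:
            seq = tss_window(genome, t.chrom, t.strand, t.dominant_pos, -lo, hi)
            if seq is None:
                continue
            fwd = _encode(seq)
            rev = _encode(revcomp(seq))
            for strand, codes in (("+", fwd), ("-", rev)):
                scores = _scan_strand(scheme, codes)
                for j in np.flatnonzero(scores >= cutoff):
                    j = int(j)
                    if strand == "+":
                        offset = j + lo
                        site = seq[j : j + w]
                    else:
                        offset = len(seq) - j - w + lo
                        site = revcomp(seq)[j : j + w]
                    raw = (scores[j] + scheme.offset) * scheme.eps
                    rows.append(
                        (
                            t.id,
                            pwm.tf_name,
                            offset,
                            strand,
                            float(raw),
                            scheme.int_score_to_p(int(scores[j])),
                            site,
                        )
                    )
    return pd.DataFrame(
        rows,
        columns=["tsc_id", "tf_name", "offset", "strand", "score", "p_value", "sequence"],
    )


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------


def positional_distribution(
    hits: pd.DataFrame, window: tuple[int, int] = (-500, 100), bin_size: int = 25
) -> pd.DataFrame:
    """Per-TF histogram of hit offsets within the scan window."""
    lo, hi = window
    edges = np.arange(lo, hi + bin_size + 1, bin_size)
    rows = []
    for tf, grp in hits.groupby("tf_name"):
        counts, _ = np.histogram(grp["offset"], bins=edges)
        for e, c in zip(edges[:-1], counts):
            rows.append((tf, int(e), int(c)))
    return pd.DataFrame(rows, columns=["tf_name", "bin_start", "count"])


def abundance_compare(
    hits: pd.DataFrame, assignments: pd.DataFrame
) -> pd.DataFrame:
    """Per-TF TFBS abundance in adjacent vs distant promoters.

    For each TF a 2x2 table of promoters with vs without a hit, by
    adjacency class, is tested by Yates-corrected chi-squared; p-values are
    BH-adjusted across TFs. ``log2_ratio`` is log2 of the per-promoter hit
    rate (hits per promoter) in adjacent over distant promoters.
    """
    classes = assignments.set_index("tsc_id")["adjacency"]
    n_adj = int((classes == "adjacent").sum())
    n_dist = int((classes == "distant").sum())
    if n_adj == 0 or n_dist == 0:
        raise ValueError("both adjacency classes must be non-empty")
    hits = hits[hits["tsc_id"].isin(classes.index)]
    rows = []
    for tf, grp in hits.groupby("tf_name"):
        cls = classes.loc[grp["tsc_id"]]
        hits_adj = int((cls == "adjacent").sum())
        hits_dist = int((cls == "distant").sum())
        if hits_adj + hits_dist == 0:
            continue
        with_adj = grp.loc[(cls == "adjacent").to_numpy(), "tsc_id"].nunique()
        with_dist = grp.loc[(cls == "distant").to_numpy(), "tsc_id"].nunique()
        table = np.array(
            [[with_adj, n_adj - with_adj], [with_dist, n_dist - with_dist]], dtype=float
        )
        if (table.sum(axis=1) > 0).all() and (table.sum(axis=0) > 0).all():
            chi2, p, _, _ = sps.chi2_contingency(table, correction=True)
        else:
            chi2, p = 0.0, 1.0
        rate_adj = hits_adj / n_adj
        rate_dist = hits_dist / n_dist
        if rate_adj > 0 and rate_dist > 0:
            ratio = math.log2(rate_adj / rate_dist)
        else:
            ratio = math.inf if rate_adj > 0 else -math.inf
        rows.append((tf, hits_adj, hits_dist, rate_adj, rate_dist, ratio, chi2, p))
    df = pd.DataFrame(
        rows,
        columns=[
            "tf_name", "hits_adjacent", "hits_distant", "rate_adjacent",
            "rate_distant", "log2_ratio", "chi2", "p_value",
        ],
    )
    if len(df):
        df["fdr"] = bh_fdr(df["p_value"].to_numpy())
    return df


def yates_chi2(table: np.ndarray) -> float:
    """Yates-corrected chi-squared of a 2x2 table (test oracle helper)."""
    (a, b), (c, d) = np.asarray(table, dtype=float)
    n = a + b + c + d
    num = n * (abs(a * d - b * c) - n / 2) ** 2
    den = (a + b) * (c + d) * (a + c) * (b + d)
    return float(num / den)


def stack_entropy(sequences: list[str]) -> float:
    """Normalized Shannon entropy of a gap-free stack of equal-length
    sequences: per-column -sum P log2 P averaged over columns."""
    if len(sequences) < 2:
        raise ValueError("need >= 2 sequences")
    length = len(sequences[0])
    if any(len(s) != length for s in sequences):
        raise ValueError("sequences must be equal length")
    total = 0.0
    for j in range(length):
        col = [s[j] for s in sequences]
        _, counts = np.unique(col, return_counts=True)
        p = counts / counts.sum()
        total += float(-(p * np.log2(p)).sum())
    return total / length


def tfbs_entropy(hits: pd.DataFrame, assignments: pd.DataFrame) -> pd.DataFrame:
    """Normalized Shannon entropy of hit sequences per TF x adjacency class.

    TFs with fewer than 2 hits in a class are excluded there (entropy
    undefined).
    """
    classes = assignments.set_index("tsc_id")["adjacency"]
    hits = hits[hits["tsc_id"].isin(classes.index)].copy()
    hits["promoter_class"] = classes.loc[hits["tsc_id"]].to_numpy()
    rows = []
    for (tf, cls), grp in hits.groupby(["tf_name", "promoter_class"]):
        seqs = list(grp["sequence"])
        if len(seqs) < 2:
            continue
        rows.append((tf, cls, stack_entropy(seqs), len(seqs), len(seqs[0])))
    return pd.DataFrame(
        rows, columns=["tf_name", "promoter_class", "se", "n_hits", "length"]
    )


def compare_divergence(divergence: pd.DataFrame) -> tuple[float, float]:
    """Wilcoxon rank-sum of per-TF SE between adjacent and distant sites."""
    adj = divergence.loc[divergence["promoter_class"] == "adjacent", "se"]
    dist = divergence.loc[divergence["promoter_class"] == "distant", "se"]
    stat, p = sps.ranksums(adj, dist)
    return float(stat), float(p)
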
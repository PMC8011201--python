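"""Promoter-level statistics: shape, diversity, specificity and shifting.

* Promoter shape score: ``PSS = log2(w) * sum_i p_i log2 p_i`` over the set
  L of member positions with pooled expression >= 3 TPM, where w is the
  positional span of L and p the read-probability vector renormalized over
  L. PSS = 0 means perfectly focused initiation; classes are sharp
  (PSS > -10), intermediate (-20 < PSS <= -10) and broad (PSS <= -20).
* OTSS diversity: Shannon index ``H = -sum p_i ln p_i`` over member OTSSs,
  with clusters of < 10 reads or < 2 OTSSs excluded, plus a 10-read
  down-sampling variant for cross-dataset comparability.
* Tissue specificity: ``tau = sum(1 - x_hat_i) / (n - 1)`` on log TPM.
* Promoter shifting: ``D_s = log2((Pt/Dt) / (Pc/Dc))`` between the proximal
  and distal promoter of a multi-promoter gene in a test vs control tissue,
  with a 2x2 chi-squared test and BH-FDR across genes; a shift is called
  only at |D_s| > 1, P < 0.05 and FDR < 0.1 (all strict).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

SHARP_MIN_PSS = -10.0
BROAD_MAX_PSS = -20.0


@dataclass
class ShapeResult:
    tsc_id: str
    pss: float
    shape_class: str
    w: int
    p: np.ndarray
    positions: np.ndarray


@dataclass
class DiversityResult:
    tsc_id: str
    h: float
    s: int
    eligible: bool
    reason: str = ""
    downsampled_h: float | None = None


@dataclass
class TauResult:
    tsc_id: str
    tau: float | None
    n: int
    x_hat: np.ndarray


@dataclass
class ShiftResult:
    gene_id: str
    tissue: str
    ds: float
    pt: float
    dt: float
    pc: float
    dc: float
    p_value: float
    fdr: float = math.nan
    call: str = "none"


def classify_shape(pss: float) -> str:
    if pss > SHARP_MIN_PSS:
        return "sharp"
    if pss > BROAD_MAX_PSS:
        return "intermediate"
    return "broad"


def pss(
    positions: np.ndarray,
    counts: np.ndarray,
    total_tags: int,
    tpm_floor: float = 3.0,
    tsc_id: str = "",
) -> ShapeResult | None:
    """Promoter shape score for one cluster's per-position read counts.

    ``total_tags`` converts counts to TPM for the qualifying-position floor.
    Positions below ``tpm_floor`` TPM are dropped from L; p is renormalized
    over L and w is the inclusive span (last - first + 1) of L. Returns
    ``None`` when no position qualifies (cluster excluded from shape
    analyses).
    """
    positions = np.asarray(positions)
    counts = np.asarray(counts, dtype=float)
    tpm = counts * 1e6 / total_tags
    keep = tpm >= tpm_floor
    if not keep.any():
        return None
    pos = positions[keep]
    c = counts[keep]
    p = c / c.sum()
    w = int(pos.max() - pos.min() + 1)
    ent = float(np.sum(p * np.log2(p)))
    score = math.log2(w) * ent
    return ShapeResult(
        tsc_id=tsc_id, pss=score, shape_class=classify_shape(score), w=w, p=p,
        positions=pos,
    )


def shape_for_tsc(tsc, library_totals: dict[str, int], tpm_floor: float = 3.0):
    """Shape score of a TSC using pooled counts and the pooled denominator."""
    total = sum(library_totals[lib] for lib in tsc.libraries if lib in library_totals)
    return pss(tsc.positions, tsc.pooled_counts, total, tpm_floor, tsc_id=tsc.id)


# ---------------------------------------------------------------------------
# diversity
# ---------------------------------------------------------------------------


def shannon_diversity(
    counts: np.ndarray,
    min_reads: int = 10,
    min_otss: int = 2,
    tsc_id: str = "",
) -> DiversityResult:
    """Shannon index H = -sum p ln p over member OTSS read counts.

    Clusters with fewer than ``min_reads`` reads or ``min_otss`` member
    OTSSs are marked ineligible (diversity is poorly estimated there).
    """
    counts = np.asarray(counts, dtype=float)
    counts = counts[counts > 0]
    s = len(counts)
    total = counts.sum()
    if total < min_reads:
        return DiversityResult(tsc_id, math.nan, s, False, "min_reads")
    if s < min_otss:
        return DiversityResult(tsc_id, math.nan, s, False, "min_otss")
    p = counts / total
    h = float(-(p * np.log(p)).sum())
    return DiversityResult(tsc_id, h, s, True)


def downsample_diversity(
    counts: np.ndarray,
    k: int = 10,
    seed: int | np.random.Generator = 0,
    tsc_id: str = "",
) -> DiversityResult:
    """H recomputed on ``k`` reads sampled without replacement.

    Sampling is over the read multiset (multivariate hypergeometric), so a
    cluster with exactly ``k`` reads returns its full-data H.
    """
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    counts = np.asarray(counts, dtype=np.int64)
    counts = counts[counts > 0]
    total = int(counts.sum())
    if total < k:
        return DiversityResult(tsc_id, math.nan, len(counts), False, "min_reads")
    sub = rng.multivariate_hypergeometric(counts, k)
    res = shannon_diversity(sub, min_reads=1, min_otss=1, tsc_id=tsc_id)
    res.downsampled_h = res.h
    return res


# ---------------------------------------------------------------------------
# tissue specificity
# ---------------------------------------------------------------------------


def tau(
    expression: np.ndarray,
    log_transform: bool = True,
    log_base: float = 2.0,
    pseudocount: float = 1.0,
    tsc_id: str = "",
) -> TauResult:
    """Tissue-specificity index on a per-tissue expression vector.

    tau = sum(1 - x_hat) / (n - 1) with x_hat = x / max(x), computed on
    log-transformed TPM (log2(TPM + 1) by default). 0 marks ubiquitous and
    1 single-tissue expression; all-zero vectors yield tau = None.
    """
    x = np.asarray(expression, dtype=float)
    n = len(x)
    if n < 2:
        raise ValueError("tau requires at least two tissues")
    if log_transform:
        x = np.log(x + pseudocount) / np.log(log_base)
    x = np.maximum(x, 0.0)
    m = x.max()
    if m <= 0:
        return TauResult(tsc_id, None, n, np.zeros(n))
    x_hat = x / m
    return TauResult(tsc_id, float((1 - x_hat).sum() / (n - 1)), n, x_hat)


# ---------------------------------------------------------------------------
# promoter shifting
# ---------------------------------------------------------------------------


def ds_shift(
    pt: float,
    dt: float,
    pc: float,
    dc: float,
    gene_id: str = "",
    tissue: str = "",
    pseudocount: float = 0.0,
) -> ShiftResult:
    """Degree of promoter shift between proximal (P) and distal (D) usage.

    ``t`` subscripts are the test tissue, ``c`` the control. D_s > 1 marks
    a shift toward the proximal promoter, D_s < -1 toward the distal one.
    The p-value is a 2x2 chi-squared test (no Yates correction) on
    [[Pt, Dt], [Pc, Dc]]; the FDR and call are filled in by
    :func:`call_shifts` across genes.
    """
    a = np.array([[pt, dt], [pc, dc]], dtype=float) + pseudocount
    if (a > 0).all():
        ds = math.log2((a[0, 0] / a[0, 1]) / (a[1, 0] / a[1, 1]))
    else:
        num = a[0, 0] * a[1, 1]
        den = a[0, 1] * a[1, 0]
        ds = math.inf if num > den else (-math.inf if den > num else 0.0)
    if a.sum() > 0 and (a.sum(axis=0) > 0).all() and (a.sum(axis=1) > 0).all():
        _, p, _, _ = sps.chi2_contingency(a, correction=False)
    else:
        p = 1.0
    return ShiftResult(gene_id, tissue, ds, pt, dt, pc, dc, float(p))


def call_shifts(
    results: list[ShiftResult],
    ds_threshold: float = 1.0,
    p_threshold: float = 0.05,
    fdr_threshold: float = 0.1,
) -> list[ShiftResult]:
    """BH-adjust chi-squared p-values across genes and call shifts.

    A gene is called shifted only when |D_s| strictly exceeds
    ``ds_threshold`` AND P < ``p_threshold`` AND FDR < ``fdr_threshold``.
    """
    if not results:
        return results
    q = bh_fdr(np.array([r.p_value for r in results]))
    for r, qi in zip(results, q):
        r.fdr = float(qi)
        if (
            abs(r.ds) > ds_threshold
            and r.p_value < p_threshold
            and r.fdr < fdr_threshold
        ):
            r.call = "proximal_shift" if r.ds > 0 else "distal_shift"
        else:
            r.call = "none"
    return results


def bh_fdr(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (monotone)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# shape vs expression summaries
# ---------------------------------------------------------------------------


def shape_expression_sweep(
    pss_values: np.ndarray,
    tpm: np.ndarray,
    window: int = 200,
    step: int = 40,
) -> pd.DataFrame:
    """Sliding-window mean PSS vs normalized mean TPM along expression rank.

    Promoters are sorted by TPM ascending; windows of ``window`` promoters
    advance by ``step``. Mean TPM per window is normalized by the maximum
    windowed mean so the series tops out at 1. With fewer promoters than
    one window, a single full-set window is emitted.
    """
    order = np.argsort(np.asarray(tpm), kind="stable")
    s_pss = np.asarray(pss_values)[order]
    s_tpm = np.asarray(tpm)[order]
    n = len(s_pss)
    starts = [0] if n < window else list(range(0, n - window + 1, step))
    rows = []
    for st in starts:
        en = min(st + window, n)
        rows.append((st, float(s_pss[st:en].mean()), float(s_tpm[st:en].mean())))
    df = pd.DataFrame(rows, columns=["rank_start", "mean_pss", "mean_tpm"])
    m = df["mean_tpm"].max()
    df["norm_tpm"] = df["mean_tpm"] / m if m > 0 else 0.0
    return df


def expression_diversity_binscatter(
    h_values: np.ndarray,
    tpm: np.ndarray,
    n_bins: int = 10,
) -> tuple[pd.DataFrame, float, float]:
    """Decile binscatter of OTSS diversity against expression.

    Clusters are binned into ``n_bins`` expression-quantile groups; the
    per-bin mean H is returned together with the Pearson correlation of
    TPM vs H over all clusters.
    """
    h = np.asarray(h_values, dtype=float)
    x = np.asarray(tpm, dtype=float)
    bins = pd.qcut(pd.Series(x).rank(method="first"), n_bins, labels=False)
    df = pd.DataFrame({"bin": bins, "h": h, "tpm": x})
    per_bin = df.groupby("bin").agg(mean_h=("h", "mean"), mean_tpm=("tpm", "mean"))
    r, p = sps.pearsonr(x, h)
    return per_bin.reset_index(), float(r), float(p)
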
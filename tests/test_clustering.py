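import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from promcore import (
    cluster_otss,
    dedup_fragments,
    extract_otss,
    gene_body_metaprofile,
    merge_libraries,
    run_clustering,
    tsc_boundaries,
)
from promcore.io import GeneModel

from .conftest import make_fragments


def _otss(rows, total=1_000_000):
    df = pd.DataFrame(rows, columns=["chrom", "strand", "pos", "count"])
    df["tpm"] = df["count"] * 1e6 / total
    return df


# ---------------------------------------------------------------------------
# dedup
# ---------------------------------------------------------------------------


def test_dedup_exact_duplicates_collapse():
    df = make_fragments(
        [
            ("chr1", "+", 100, 450, "", "l"),
            ("chr1", "+", 100, 450, "", "l"),
            ("chr1", "+", 100, 460, "", "l"),  # different 3' end: retained
            ("chr1", "+", 100, 450, "200-300", "l"),  # different splice: retained
        ]
    )
    out, removed = dedup_fragments(df)
    assert len(out) == 3 and removed == 1


def test_dedup_idempotent():
    df = make_fragments(
        [("chr1", "+", i % 5, 400 + i % 3, "", "l") for i in range(30)]
    )
    once, _ = dedup_fragments(df)
    twice, removed = dedup_fragments(once)
    assert removed == 0 and twice.equals(once)


# ---------------------------------------------------------------------------
# OTSS extraction
# ---------------------------------------------------------------------------


def test_extract_otss_counts_and_tpm():
    df = make_fragments(
        [("chr1", "+", 100, 400 + i, "", "l") for i in range(30)]
        + [("chr1", "-", 100, 90, "", "l")]
    )
    otss = extract_otss(df, library_total=1_000_000)
    plus = otss[otss["strand"] == "+"]
    assert len(otss) == 2  # opposite strands never merge
    assert plus.iloc[0]["count"] == 30
    assert plus.iloc[0]["tpm"] == pytest.approx(30.0)
    assert otss["count"].sum() == len(df)


def test_extract_otss_zero_total_rejected():
    with pytest.raises(ValueError):
        extract_otss(make_fragments([]), 0)


# ---------------------------------------------------------------------------
# clustering
# ---------------------------------------------------------------------------


def brute_force_single_linkage(positions, join_dist):
    """Oracle: exhaustive transitive closure of the pairwise gap relation."""
    positions = sorted(positions)
    clusters = [{p} for p in positions]
    changed = True
    while changed:
        changed = False
        for a, b in itertools.combinations(range(len(clusters)), 2):
            if any(
                abs(x - y) < join_dist for x in clusters[a] for y in clusters[b]
            ):
                clusters[a] |= clusters[b]
                del clusters[b]
                changed = True
                break
    return sorted(sorted(c) for c in clusters)


def test_cluster_gap_semantics():
    # gaps 15 (< 20, join) and 25 (>= 20, split)
    otss = _otss(
        [("chr1", "+", 100, 10), ("chr1", "+", 115, 10), ("chr1", "+", 140, 10)]
    )
    tscs = cluster_otss(otss)
    assert [list(t.positions) for t in tscs] == [[100, 115], [140]]


def test_cluster_matches_brute_force_oracle():
    rng = np.random.default_rng(5)
    positions = np.unique(rng.integers(0, 2000, size=150))
    otss = _otss([("chr1", "+", int(p), 10) for p in positions])
    got = [list(t.positions) for t in cluster_otss(otss)]
    assert got == brute_force_single_linkage(positions, 20)


def test_single_otss_forms_1bp_tsc():
    tscs = cluster_otss(_otss([("chr1", "-", 500, 10)]))
    assert len(tscs) == 1
    t = tscs[0]
    assert (t.boundary_start, t.boundary_end, t.width, t.dominant_pos) == (
        500,
        501,
        1,
        500,
    )


def test_cluster_order_invariance():
    rows = [("chr1", "+", p, 5) for p in [140, 100, 115, 300, 310]]
    a = cluster_otss(_otss(rows))
    b = cluster_otss(_otss(rows[::-1]))
    assert [list(t.positions) for t in a] == [list(t.positions) for t in b]


def test_otss_tpm_threshold_and_tsc_tpm_threshold():
    # per-OTSS threshold removes low positions before linkage
    otss = _otss(
        [("chr1", "+", 100, 10), ("chr1", "+", 110, 1), ("chr1", "+", 125, 10)],
        total=1_000_000,
    )
    # position 110 at 1 TPM is dropped, so 100 and 125 are 25 apart -> split
    tscs = cluster_otss(otss, tpm_threshold=3.0)
    assert [list(t.positions) for t in tscs] == [[100], [125]]
    # cluster-level threshold drops weak clusters
    tscs = cluster_otss(
        _otss([("chr1", "+", 100, 1)]), tpm_threshold=0.5, tsc_tpm_threshold=3.0
    )
    assert tscs == []


@settings(max_examples=50, deadline=None)
@given(
    st.lists(
        st.integers(min_value=0, max_value=5000), min_size=1, max_size=60, unique=True
    )
)
def test_cluster_partition_invariants(positions):
    """Every above-threshold OTSS lands in exactly one TSC and no
    intra-cluster neighbour gap reaches the join distance."""
    otss = _otss([("chr1", "+", p, 10) for p in positions])
    tscs = cluster_otss(otss)
    covered = sorted(p for t in tscs for p in t.positions)
    assert covered == sorted(positions)
    for t in tscs:
        gaps = np.diff(t.positions)
        assert (gaps < 20).all()
        assert t.width >= 1
        assert t.pooled_counts.max() == t.pooled_counts[t.positions == t.dominant_pos]


# ---------------------------------------------------------------------------
# boundaries
# ---------------------------------------------------------------------------


def test_boundaries_cumulative_percentile_rule():
    # 10 unit-count positions: cumulative 0.1 at the 1st, 0.9 at the 9th
    pos = np.arange(1, 11)
    lo, hi, dom = tsc_boundaries(pos, np.ones(10), "+")
    assert (lo, hi) == (1, 10)
    assert hi - lo == 9


def test_boundaries_oracle_cumulative_sum():
    rng = np.random.default_rng(3)
    pos = np.sort(rng.choice(5000, size=40, replace=False))
    cnt = rng.integers(1, 50, size=40)
    lo, hi, _ = tsc_boundaries(pos, cnt, "+")
    cum = np.cumsum(cnt) / cnt.sum()
    assert lo == pos[np.argmax(cum >= 0.10 - 1e-12)]
    assert hi == pos[np.argmax(cum >= 0.90 - 1e-12)] + 1


def test_boundaries_single_position():
    lo, hi, dom = tsc_boundaries(np.array([777]), np.array([50]), "+")
    assert (lo, hi, dom) == (777, 778, 777)


def test_dominant_tie_break_most_upstream_in_transcript_orientation():
    pos = np.array([100, 110])
    cnt = np.array([5, 5])
    assert tsc_boundaries(pos, cnt, "+")[2] == 100
    assert tsc_boundaries(pos, cnt, "-")[2] == 110


# ---------------------------------------------------------------------------
# cross-library merge
# ---------------------------------------------------------------------------


def _lib_tscs(lib, rows, total=1_000_000):
    otss = _otss([("chr1", "+", p, c) for p, c in rows], total)
    return cluster_otss(otss, library_id=lib)


def test_merge_identical_tsc_across_libraries():
    per_lib = {
        "lib1": _lib_tscs("lib1", [(100, 10), (105, 5)]),
        "lib2": _lib_tscs("lib2", [(100, 20), (105, 4)]),
    }
    merged = merge_libraries(per_lib, {"lib1": 1_000_000, "lib2": 1_000_000})
    assert len(merged) == 1
    t = merged[0]
    assert t.per_library_counts() == {"lib1": 15, "lib2": 24}
    assert t.dominant_pos == 100


def test_merge_distance_threshold():
    per_lib = {
        "lib1": _lib_tscs("lib1", [(100, 10)]),
        "lib2": _lib_tscs("lib2", [(251, 10)]),  # 150 bp from [100,101): no merge
    }
    merged = merge_libraries(per_lib, {"lib1": 1_000_000, "lib2": 1_000_000})
    assert len(merged) == 2


def test_merge_library_order_independence():
    rows1 = [(100, 10), (160, 5)]
    rows2 = [(130, 7)]
    a = merge_libraries(
        {"lib1": _lib_tscs("lib1", rows1), "lib2": _lib_tscs("lib2", rows2)},
        {"lib1": 1_000_000, "lib2": 1_000_000},
    )
    b = merge_libraries(
        {"lib2": _lib_tscs("lib2", rows2), "lib1": _lib_tscs("lib1", rows1)},
        {"lib1": 1_000_000, "lib2": 1_000_000},
    )
    assert [(list(t.positions), t.dominant_pos) for t in a] == [
        (list(t.positions), t.dominant_pos) for t in b
    ]


def test_run_clustering_dedups_and_merges(small_sim):
    tscs, totals = run_clustering(small_sim["fragments"])
    assert len(totals) == small_sim["config"].n_libraries
    for t in tscs[:200]:
        assert t.boundary_start <= t.dominant_pos < t.boundary_end
        assert t.width >= 1


# ---------------------------------------------------------------------------
# metaprofile
# ---------------------------------------------------------------------------


def _flat_gene(length=100_000):
    return GeneModel(
        gene_id="g1",
        chrom="chr1",
        strand="+",
        exons=[(0, length)],
        start_codon_pos=100,
        mrna_start=0,
    )


def test_metaprofile_gene_five_prime_end_maps_to_bin0():
    from .conftest import make_tsc

    gene = _flat_gene()
    t = make_tsc([0], [10])
    prof = gene_body_metaprofile([t], [gene])
    assert prof[0] == 1 and prof.sum() == 1


def test_metaprofile_uniform_positions_flat():
    """Uniformly placed dominant TSSs give a flat profile (chi-squared GOF
    not rejected at alpha = 0.01)."""
    from scipy import stats as sps

    from .conftest import make_tsc

    gene = _flat_gene()
    rng = np.random.default_rng(0)
    tscs = [
        make_tsc([int(p)], [10], tsc_id=f"T{i}")
        for i, p in enumerate(rng.integers(0, 100_000, size=10_000))
    ]
    prof = gene_body_metaprofile(tscs, [gene])
    assert prof.sum() == 10_000
    _, p = sps.chisquare(prof)
    assert p > 0.01


def test_metaprofile_empty_input_zero_vector():
    prof = gene_body_metaprofile([], [_flat_gene()])
    assert prof.sum() == 0 and len(prof) == 100
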
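import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from promcore import (
    PWM,
    abundance_compare,
    build_scoring,
    positional_distribution,
    read_jaspar,
    scan_pwm,
    sequence_pvalue,
    stack_entropy,
    tfbs_entropy,
    yates_chi2,
)
from promcore.tfbs import _CODE, score_sequence

from .conftest import make_tsc


def _point_mass_pwm(site="TGCA", eps=1e-9):
    m = np.full((len(site), 4), eps / 3)
    for i, b in enumerate(site):
        m[i] = eps / 3
        m[i, _CODE[b]] = 1 - eps
    return PWM("pm", m / m.sum(axis=1, keepdims=True))


def _random_pwm(rng, width):
    m = rng.dirichlet(np.ones(4) * 0.7, size=width)
    return PWM("rand", m)


# ---------------------------------------------------------------------------
# exact null
# ---------------------------------------------------------------------------


@pytest.mark.parametrize("width", [3, 5, 8])
def test_dp_null_matches_exhaustive_enumeration(width):
    """Tail probabilities from the DP convolution equal brute-force
    enumeration over all 4^w background sequences."""
    rng = np.random.default_rng(width)
    pwm = _random_pwm(rng, width)
    scheme = build_scoring(pwm)
    # brute force: P(score >= s) summed over every sequence
    scores = []
    probs = []
    for seq in itertools.product("ACGT", repeat=width):
        s = score_sequence(scheme, "".join(seq))
        scores.append(s)
        probs.append(np.prod([pwm.background[_CODE[b]] for b in seq]))
    scores = np.array(scores)
    probs = np.array(probs)
    for s in np.unique(scores):
        brute = probs[scores >= s].sum()
        assert scheme.int_score_to_p(int(s)) == pytest.approx(brute, rel=1e-9)


def test_pvalue_monotone_in_score():
    scheme = build_scoring(_random_pwm(np.random.default_rng(0), 6))
    ps = [scheme.int_score_to_p(s) for s in range(0, len(scheme.tail), 50)]
    assert all(a >= b for a, b in zip(ps, ps[1:]))


# ---------------------------------------------------------------------------
# scanning
# ---------------------------------------------------------------------------


def test_point_mass_pwm_single_exact_hit():
    seq = list("A" * 1200)
    site = "TGCC"  # non-palindromic so only the forward scan can match
    # plant the site once at offset -50 from the TSS (TSS at 600)
    for i, b in enumerate(site):
        seq[550 + i] = b
    genome = {"chr1": "".join(seq)}
    t = make_tsc([600], [10], tsc_id="T")
    # a width-4 motif's best attainable p is 4^-4 under a uniform
    # background, so the cut-off must sit just above it
    hits = scan_pwm([t], genome, [_point_mass_pwm(site)], p_threshold=0.004)
    fwd = hits[hits["strand"] == "+"]
    assert len(fwd) == 1
    assert fwd.iloc[0]["offset"] == -50
    assert fwd.iloc[0]["sequence"] == site


def test_scan_strand_symmetry():
    """Reverse-complementing the genome and flipping the promoter strand
    yields the same hit sequences."""
    rng = np.random.default_rng(2)
    seq = "".join(rng.choice(list("ACGT"), 2000))
    genome = {"chr1": seq}
    from promcore import revcomp

    genome_rc = {"chr1": revcomp(seq)}
    pwm = _random_pwm(rng, 6)
    t_fwd = make_tsc([1000], [10], strand="+", tsc_id="T")
    t_rev = make_tsc([len(seq) - 1 - 1000], [10], strand="-", tsc_id="T")
    h1 = scan_pwm([t_fwd], genome, [pwm], p_threshold=1e-3)
    h2 = scan_pwm([t_rev], genome_rc, [pwm], p_threshold=1e-3)
    assert sorted(h1["sequence"]) == sorted(h2["sequence"])
    assert sorted(h1["offset"]) == sorted(h2["offset"])


def test_null_hit_rate_matches_nominal_p():
    """On random sequence the empirical hit rate at the 1e-3 cut-off
    matches the nominal p within Poisson error."""
    rng = np.random.default_rng(3)
    p_threshold = 1e-3
    pwm = _random_pwm(rng, 8)
    n_tscs, span = 150, (-500, 100)
    seq = "".join(rng.choice(list("ACGT"), 200_000))
    genome = {"chr1": seq}
    tscs = [
        make_tsc([1000 + 1200 * i], [10], tsc_id=f"T{i}") for i in range(n_tscs)
    ]
    hits = scan_pwm(tscs, genome, [pwm], window=span, p_threshold=p_threshold)
    positions_per_window = span[1] - span[0] + 1 - pwm.width + 1
    n_slots = n_tscs * positions_per_window * 2
    # the DP threshold is conservative: the attained p at the cut-off score
    scheme = build_scoring(pwm)
    attained = scheme.int_score_to_p(scheme.min_int_score_for_p(p_threshold))
    expected = n_slots * attained
    assert abs(len(hits) - expected) < 4 * math.sqrt(expected)


def test_positional_distribution_totals():
    hits = pd.DataFrame(
        {
            "tsc_id": ["a"] * 5,
            "tf_name": ["tf"] * 5,
            "offset": [-400, -100, -50, -50, 0],
            "strand": ["+"] * 5,
            "score": [1.0] * 5,
            "p_value": [1e-6] * 5,
            "sequence": ["AAAA"] * 5,
        }
    )
    hist = positional_distribution(hits)
    assert hist["count"].sum() == 5


# ---------------------------------------------------------------------------
# abundance comparison
# ---------------------------------------------------------------------------


def test_yates_chi2_hand_value():
    # N(|ad - bc| - N/2)^2 / ((a+b)(c+d)(a+c)(b+d)) on [[10,20],[20,10]]
    assert yates_chi2([[10, 20], [20, 10]]) == pytest.approx(5.4)
    chi2, _, _, _ = sps.chi2_contingency(
        np.array([[10, 20], [20, 10]]), correction=True
    )
    assert chi2 == pytest.approx(5.4)


def _assignments(n_adj, n_dist):
    rows = [(f"a{i}", "adjacent") for i in range(n_adj)] + [
        (f"d{i}", "distant") for i in range(n_dist)
    ]
    df = pd.DataFrame(rows, columns=["tsc_id", "adjacency"])
    df["gene_id"] = "g"
    return df


def _hits(tsc_ids, tf="tf1"):
    return pd.DataFrame(
        {
            "tsc_id": tsc_ids,
            "tf_name": tf,
            "offset": 0,
            "strand": "+",
            "score": 1.0,
            "p_value": 1e-6,
            "sequence": "ACGT",
        }
    )


def test_abundance_identical_classes_null():
    asg = _assignments(50, 50)
    hits = _hits([f"a{i}" for i in range(10)] + [f"d{i}" for i in range(10)])
    out = abundance_compare(hits, asg)
    assert out.iloc[0]["log2_ratio"] == pytest.approx(0.0)
    assert out.iloc[0]["p_value"] > 0.5


def test_abundance_detects_synthetic_enrichment():
    """A 2x hit rate in distant promoters is detected at FDR < 0.01 with
    500 promoters per class."""
    rng = np.random.default_rng(4)
    asg = _assignments(500, 500)
    adj_hits = [f"a{i}" for i in range(500) if rng.random() < 0.2]
    dist_hits = [f"d{i}" for i in range(500) if rng.random() < 0.4]
    out = abundance_compare(_hits(adj_hits + dist_hits), asg)
    assert out.iloc[0]["fdr"] < 0.01
    assert out.iloc[0]["log2_ratio"] < 0


# ---------------------------------------------------------------------------
# divergence entropy
# ---------------------------------------------------------------------------


def test_stack_entropy_examples():
    assert stack_entropy(["ACGT", "ACGT"]) == 0.0
    # one binary column of entropy 1 bit over 4 columns
    assert stack_entropy(["ACGT", "ACGA"]) == pytest.approx(0.25)
    # all columns uniform over the 4 bases: maximum 2 bits
    stack = ["AAAA", "CCCC", "GGGG", "TTTT"]
    assert stack_entropy(stack) == pytest.approx(2.0)


def test_stack_entropy_monotone_with_diversity():
    low = stack_entropy(["AAAA"] * 9 + ["AAAC"])
    high = stack_entropy(["AAAA"] * 5 + ["CCCC"] * 5)
    assert low < high


def test_compare_divergence_detects_class_difference():
    from promcore import compare_divergence

    rng = np.random.default_rng(7)
    rows = []
    for i in range(30):
        rows.append((f"tf{i}", "adjacent", 0.2 + 0.05 * rng.random()))
        rows.append((f"tf{i}", "distant", 1.2 + 0.05 * rng.random()))
    div = pd.DataFrame(rows, columns=["tf_name", "promoter_class", "se"])
    _, p = compare_divergence(div)
    assert p < 1e-6


def test_tfbs_entropy_excludes_singletons():
    asg = _assignments(2, 1)
    hits = _hits(["a0", "a1", "d0"])
    out = tfbs_entropy(hits, asg)
    assert set(out["promoter_class"]) == {"adjacent"}  # distant has 1 hit


# ---------------------------------------------------------------------------
# PWM IO
# ---------------------------------------------------------------------------


def test_read_jaspar_matrix(tmp_path):
    text = """>MA0001.1 tf_test
A  [ 10  0  0 10 ]
C  [  0 10  0  0 ]
G  [  0  0 10  0 ]
T  [  0  0  0  0 ]
"""
    p = tmp_path / "m.jaspar"
    p.write_text(text)
    pwms = read_jaspar(str(p))
    assert len(pwms) == 1
    assert pwms[0].width == 4
    assert np.allclose(pwms[0].matrix.sum(axis=1), 1.0)
    assert pwms[0].matrix[0, 0] == pytest.approx(1.0)  # A at position 0
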
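"""Audic-Claverie statistic, BH-FDR, and DE calling."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy.stats import nbinom

import tagdge as t
from tagdge.de import _log_pmf, _two_sided_p


def nb_oracle(x, N1, N2):
    """Independent oracle: conditioned on x, the second count is negative
    binomial with x+1 successes and success probability N1/(N1+N2)."""
    return nbinom(x + 1, N1 / (N1 + N2))


def oracle_two_sided(x, y, N1, N2):
    d = nb_oracle(x, N1, N2)
    lower = d.cdf(y)
    upper = d.sf(y - 1) if y > 0 else 1.0
    return min(1.0, 2.0 * min(lower, upper))


@pytest.mark.parametrize(
    "x,y,expected",
    [
        (0, 0, 0.5),
        (3, 3, 20 / 128),       # C(6,3) / 2^7
        (5, 0, 1 / 2**6),       # 1 / 2^(x+y+1)
    ],
)
def test_pmf_closed_forms_equal_libraries(x, y, expected):
    pair = t.TagCountPair(x, y, 10**6, 10**6)
    assert t.audic_claverie_pmf(pair) == pytest.approx(expected, rel=1e-12)


def test_pmf_matches_negative_binomial_oracle():
    for N1, N2 in [(10**6, 10**6), (10**6, 5 * 10**5), (5 * 10**5, 10**6)]:
        for x in (0, 1, 7, 50, 200):
            y = np.arange(0, 300)
            ours = _log_pmf(y, x, N1, N2)
            theirs = nb_oracle(x, N1, N2).logpmf(y)
            np.testing.assert_allclose(ours, theirs, rtol=1e-10)


def test_pmf_sums_to_one():
    for N1, N2 in [(1000, 1000), (1000, 2000), (2000, 1000)]:
        for x in (0, 3, 40):
            total = math.fsum(np.exp(_log_pmf(np.arange(0, 5000), x, N1, N2)))
            assert total == pytest.approx(1.0, abs=1e-12)


def test_two_sided_centre_is_capped_at_one():
    """x == y with equal totals sits at the distribution's centre."""
    for x in (0, 5, 100):
        p = _two_sided_p(x, x, 10**6, 10**6)
        assert p >= 0.5
        assert p == pytest.approx(oracle_two_sided(x, x, 10**6, 10**6), rel=1e-10)


def test_extreme_tail_matches_bruteforce_to_ten_digits():
    # doubled single-point lower tail: 2 * p(0|100) = 2 / 2^101
    p = t.audic_claverie_test(t.TagCountPair(100, 0, 10**6, 10**6))
    brute = 2.0 * math.exp(_log_pmf(0, 100, 10**6, 10**6))
    assert p == pytest.approx(brute, rel=1e-10)


@given(
    x=st.integers(0, 150),
    y=st.integers(0, 150),
    scale=st.sampled_from([(10**6, 10**6), (10**6, 2 * 10**6), (2 * 10**6, 10**6)]),
)
def test_library_swap_asymmetry_is_bounded(x, y, scale):
    """Swapping (x, N1) <-> (y, N2) conditions the test on the other library.

    The doubled-tail two-sided p is not exactly swap-invariant — at a tail
    boundary one direction sums a single point mass while the other sums a
    geometric tail with term ratio q = max(r, 1/r)/(1 + max(r, 1/r)) — but
    the discrepancy is bounded by that tail sum's factor 1/(1-q), i.e. the
    p-values differ by at most a factor 1 + max(N2/N1, N1/N2).
    """
    N1, N2 = scale
    a = _two_sided_p(x, y, N1, N2)
    b = _two_sided_p(y, x, N2, N1)
    bound = 1 + max(N1 / N2, N2 / N1)
    assert max(a, b) <= bound * min(a, b) * (1 + 1e-9)


def test_equal_counts_and_totals_give_p_one():
    """x = y with N1 = N2: the lower tail is exactly 1/2, so p caps at 1."""
    for x in (0, 1, 5, 40):
        assert _two_sided_p(x, x, 10**6, 10**6) == pytest.approx(1.0, abs=1e-9)


def test_pair_validation():
    with pytest.raises(ValueError, match="non-negative"):
        t.TagCountPair(-1, 0, 100, 100)
    with pytest.raises(ValueError, match="positive"):
        t.TagCountPair(0, 0, 0, 100)
    with pytest.raises(ValueError, match="smaller"):
        t.TagCountPair(200, 0, 100, 100)


def test_bh_hand_computation():
    np.testing.assert_allclose(t.bh_fdr([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])


def test_bh_trivial_cases():
    assert t.bh_fdr([0.2]) == pytest.approx([0.2])
    np.testing.assert_allclose(t.bh_fdr([0.4, 0.4, 0.4]), [0.4, 0.4, 0.4])
    with pytest.raises(ValueError, match="empty"):
        t.bh_fdr([])


def test_bh_is_monotone_on_sorted_input():
    rng = np.random.default_rng(0)
    p = np.sort(rng.uniform(size=100))
    fdr = t.bh_fdr(p)
    assert (np.diff(fdr) >= -1e-15).all()
    assert (fdr >= p - 1e-15).all()


def _expr(counts, total, genes=None):
    genes = genes or [f"g{i}" for i in range(len(counts))]
    return t.tpm_normalize(dict(zip(genes, counts)), total, gene_universe=genes)


def test_zero_tpm_substitution_gives_log2_ratio_ten():
    # TPM2 = 128 * 1e6 / 12.5e6 = 10.24; TPM1 = 0 -> 0.01; log2(1024) = 10
    e1 = _expr([0, 500], 12_500_000)
    e2 = _expr([128, 500], 12_500_000)
    df = t.call_degs(e1, e2)
    row = df[df["gene_id"] == "g0"].iloc[0]
    assert row["TPM2"] == pytest.approx(10.24)
    assert row["log2_ratio"] == pytest.approx(10.0)


def test_identical_libraries_yield_no_calls(sim):
    qc, res = sim["qc"]["A"], sim["mapping"]["A"]
    ev = t.tpm_normalize(res, qc.clean_total, gene_universe=sim["universe"])
    df = t.call_degs(ev, ev)
    assert (df["call"] == "not-DE").all()
    tested = df["p_value"].notna()
    assert df.loc[tested, "p_value"].to_numpy() == pytest.approx(1.0, abs=1e-9)


def test_untestable_genes_are_excluded_from_the_family():
    e1 = _expr([0, 10, 3], 10_000)
    e2 = _expr([0, 12, 0], 10_000)
    df = t.call_degs(e1, e2)
    assert np.isnan(df.loc[df["gene_id"] == "g0", "p_value"]).all()
    assert df["p_value"].notna().sum() == 2


def test_mismatched_universes_rejected():
    e1 = _expr([1, 2], 1000, genes=["a", "b"])
    e2 = _expr([1, 2], 1000, genes=["a", "c"])
    with pytest.raises(ValueError, match="universe"):
        t.call_degs(e1, e2)


def test_recovery_on_the_shared_simulation(sim):
    """Planted |log2FC|=3 genes are found with few false positives."""
    expr = {
        c: t.tpm_normalize(sim["mapping"][c], sim["qc"][c].clean_total,
                           gene_universe=sim["universe"])
        for c in "AB"
    }
    df = t.call_degs(expr["A"], expr["B"])
    called = set(df.loc[df["call"] != "not-DE", "gene_id"])
    truth = sim["truth"]
    de = set(np.array(truth.genes)[truth.is_de])
    assert len(called & de) / len(de) >= 0.9
    assert len(called - de) <= max(1, 0.05 * len(called))
    # direction agrees with the planted sign
    sign = dict(zip(truth.genes, truth.log2fc))
    for g in called & de:
        call = df.loc[df["gene_id"] == g, "call"].iloc[0]
        assert call == ("up" if sign[g] > 0 else "down")
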
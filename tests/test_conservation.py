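"""Pairwise identity, matrices, distributions, column filtering, logos."""

import math

import numpy as np
import pytest

from cpcompare.conservation import (
    MSA, IdentityMatrix, MSAError, column_conservation, distribution_summary,
    filter_columns, identity_matrix, pairwise_identity,
)
from cpcompare.synthetic import evolve_msa


@pytest.mark.parametrize(
    "a,b,expected",
    [
        ("ACDEF", "ACDEF", 1.0),
        ("AC-DE", "AG-DE", 3 / 4),   # gap-gap column removed; denominator 4
        ("ACDEF", "AC-EF", 4 / 5),   # one-sided gap keeps the longer length 5
        ("acdef", "ACDEF", 1.0),     # case-insensitive
        ("AXDEF", "AXDEF", 4 / 5),   # ambiguity codes never count as identity
    ],
)
def test_pairwise_identity_hand_examples(a, b, expected):
    assert pairwise_identity(a, b) == pytest.approx(expected)


def test_pairwise_identity_rejects_length_mismatch():
    with pytest.raises(MSAError, match="length"):
        pairwise_identity("ACD", "AC")


def test_gap_gap_columns_never_change_the_score(rng):
    """Inserting a column gapped in both rows is a no-op for the score."""
    letters = "ACDEFGHIKLMNPQRSTVWY-"
    for _ in range(30):
        n = int(rng.integers(4, 30))
        a = "".join(rng.choice(list(letters), size=n))
        b = "".join(rng.choice(list(letters), size=n))
        if set(a) == {"-"} or set(b) == {"-"}:
            continue
        pos = int(rng.integers(0, n))
        assert pairwise_identity(a[:pos] + "-" + a[pos:], b[:pos] + "-" + b[pos:]) \
            == pytest.approx(pairwise_identity(a, b))


def test_identity_matrix_two_identical_rows():
    m = identity_matrix(MSA(ids=["x", "y"], rows=["ACDE", "ACDE"]))
    np.testing.assert_allclose(m.values, [[1, 1], [1, 1]])


def test_identity_matrix_matches_per_pair_oracle():
    msa = MSA(ids=["a", "b", "c"], rows=["AC-DEF", "AG-DEG", "A--DEF"])
    m = identity_matrix(msa)
    for i in range(3):
        for j in range(3):
            expected = 1.0 if i == j else pairwise_identity(msa.rows[i], msa.rows[j])
            assert m.values[i, j] == pytest.approx(expected)


def test_identity_matrix_invariants_on_evolved_family():
    msa, target = evolve_msa(length=200, n_seqs=30, target_identity=0.6,
                             gap_rate=0.02, seed=5)
    m = identity_matrix(msa)
    np.testing.assert_allclose(m.values, m.values.T, atol=1e-12)
    np.testing.assert_allclose(np.diag(m.values), 1.0)
    assert np.all((m.values >= 0) & (m.values <= 1))


def test_ragged_msa_rejected():
    with pytest.raises(MSAError, match="ragged"):
        MSA(ids=["a", "b"], rows=["ACDE", "ACD"])


def test_duplicate_ids_rejected():
    with pytest.raises(MSAError, match="unique"):
        MSA(ids=["a", "a"], rows=["ACDE", "ACDE"])


def test_distribution_of_constant_pairs():
    msa = MSA(ids=["a", "b", "c"], rows=["AAAA", "AAAB", "AABA"])
    m = identity_matrix(msa)
    # a-b, a-c identical at 0.75; b-c at 0.5
    summary = distribution_summary(m)
    assert summary.n_pairs == 3
    assert sum(summary.histogram.values()) == pytest.approx(100.0, abs=1e-9)
    assert summary.histogram[75] == pytest.approx(200 / 3)


def test_histogram_mass_is_100_percent():
    msa, _ = evolve_msa(length=150, n_seqs=25, target_identity=0.5, seed=9)
    summary = distribution_summary(identity_matrix(msa))
    assert sum(summary.histogram.values()) == pytest.approx(100.0, abs=1e-9)


def test_five_number_summary_matches_sort_oracle(rng):
    vals = rng.uniform(0, 1, size=100)
    n = len(vals)
    m = np.eye(n + 1)
    iu = np.triu_indices(n + 1, k=1)
    # place the 100 values into the first 100 upper-triangle slots, rest = copy
    fill = np.concatenate([vals, rng.choice(vals, size=iu[0].size - n)])
    m[iu] = fill
    m[(iu[1], iu[0])] = fill
    summary = distribution_summary(
        IdentityMatrix(ids=[str(i) for i in range(n + 1)], values=m))
    srt = np.sort(fill)
    def quantile(p):
        h = (len(srt) - 1) * p
        lo = int(math.floor(h))
        return srt[lo] + (h - lo) * (srt[min(lo + 1, len(srt) - 1)] - srt[lo])
    assert summary.five_number[0] == pytest.approx(srt[0])
    assert summary.five_number[1] == pytest.approx(quantile(0.25))
    assert summary.five_number[2] == pytest.approx(quantile(0.5))
    assert summary.five_number[3] == pytest.approx(quantile(0.75))
    assert summary.five_number[4] == pytest.approx(srt[-1])


def test_single_sequence_matrix_rejected():
    with pytest.raises(MSAError):
        identity_matrix(MSA(ids=["a"], rows=["ACDE"]))


def test_filter_columns_identity_at_threshold_one():
    msa = MSA(ids=["a", "b"], rows=["A-CD", "A--D"])
    filtered, kept = filter_columns(msa, 1.0)
    assert filtered.rows == msa.rows
    assert kept == [0, 1, 2, 3]


def test_filter_columns_hand_enumeration():
    msa = MSA(ids=["a", "b", "c", "d"],
              rows=["A-CD-", "A--D-", "AC-D-", "ACCD-"])
    # gap fractions per column: 0, 0.5, 0.5, 0, 1.0
    filtered, kept = filter_columns(msa, 0.5)
    assert kept == [0, 1, 2, 3]
    filtered, kept = filter_columns(msa, 0.25)
    assert kept == [0, 3]
    assert filtered.rows == ["AD", "AD", "AD", "AD"]


def test_column_conservation_limits():
    n = 20
    all_w = MSA(ids=[f"s{i}" for i in range(n)], rows=["W"] * n)
    col = column_conservation(all_w)[0]
    assert col.information == pytest.approx(math.log2(20))
    assert col.frequencies == {"W": 1.0}

    uniform = MSA(ids=[f"s{i}" for i in range(20)],
                  rows=[c for c in "ACDEFGHIKLMNPQRSTVWY"])
    assert column_conservation(uniform)[0].information == pytest.approx(0.0, abs=1e-12)


def test_column_conservation_gap_scaling():
    """Half-gapped all-W column: frequencies sum to 0.5, IC unchanged."""
    msa = MSA(ids=["a", "b", "c", "d"], rows=["W", "W", "-", "-"])
    col = column_conservation(msa)[0]
    assert sum(col.frequencies.values()) == pytest.approx(0.5)
    assert col.information == pytest.approx(math.log2(20))


def test_all_gap_column_is_empty():
    msa = MSA(ids=["a", "b"], rows=["-A", "-A"])
    col = column_conservation(msa)[0]
    assert col.information == 0.0
    assert col.frequencies == {}


def test_median_ordering_of_two_evolved_families():
    """A family evolved at target identity 0.7 has a higher distribution
    median than one at 0.4 — the beta-vs-alpha conservation ordering."""
    low, _ = evolve_msa(length=300, n_seqs=50, target_identity=0.4, gap_rate=0.01, seed=21)
    high, _ = evolve_msa(length=300, n_seqs=50, target_identity=0.7, gap_rate=0.01, seed=22)
    med_low = distribution_summary(identity_matrix(low)).median
    med_high = distribution_summary(identity_matrix(high)).median
    assert med_high > med_low
    assert med_low == pytest.approx(0.4, abs=0.1)
    assert med_high == pytest.approx(0.7, abs=0.1)
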
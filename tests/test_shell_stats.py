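"""Statistical layer: chi-square homogeneity, rank tests, count
reconstruction, fusion index — each cross-checked against an independent
oracle where one exists."""

from itertools import combinations

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from nucshell import (
    chi_square_homogeneity,
    fusion_index,
    mann_whitney_u,
    reconstruct_counts,
    sample_nucleus_params,
    shapiro_wilk,
    SimulationConfig,
)
from nucshell.errors import NucshellError
from nucshell.shell_stats import round_half_up


def pearson_chi2_oracle(a, b):
    """Textbook Pearson statistic, coded independently: sum (O-E)^2/E with
    E from the row/column margins of the 2xK table."""
    table = np.vstack([a, b]).astype(float)
    row = table.sum(1, keepdims=True)
    col = table.sum(0, keepdims=True)
    expected = row @ col / table.sum()
    return float(((table - expected) ** 2 / expected).sum())


def test_identical_rows_give_zero_statistic():
    res = chi_square_homogeneity([10] * 5, [10] * 5)
    assert res.statistic == 0.0
    assert res.p_value == 1.0
    assert res.df == 4


def test_2x2_closed_form():
    res = chi_square_homogeneity([10, 20], [20, 10])
    assert res.statistic == pytest.approx(200.0 / 30.0)
    assert res.df == 1


@given(
    st.lists(st.integers(0, 60), min_size=2, max_size=8).flatmap(
        lambda a: st.tuples(
            st.just(a), st.lists(st.integers(0, 60), min_size=len(a), max_size=len(a))
        )
    )
)
def test_statistic_matches_independent_formula_and_is_symmetric(ab):
    a, b = np.array(ab[0]), np.array(ab[1])
    if a.sum() == 0 or b.sum() == 0 or np.count_nonzero(a + b) < 2:
        return
    keep = (a + b) > 0
    res = chi_square_homogeneity(a, b)
    assert res.statistic == pytest.approx(pearson_chi2_oracle(a[keep], b[keep]))
    swapped = chi_square_homogeneity(b, a)
    assert swapped.statistic == pytest.approx(res.statistic)
    assert swapped.p_value == pytest.approx(res.p_value)
    assert res.df == keep.sum() - 1


def test_zero_total_column_dropped_with_reduced_df():
    res = chi_square_homogeneity([5, 0, 10, 5], [5, 0, 5, 10])
    assert res.dropped_columns == (1,)
    assert res.df == 2


def test_low_expected_count_warns_not_fails():
    res = chi_square_homogeneity([50, 2], [50, 3])
    assert res.warning_low_expected


def test_all_zero_rows_rejected():
    with pytest.raises(NucshellError):
        chi_square_homogeneity([0, 0, 0], [1, 2, 3])


def test_type_one_error_calibration():
    """Counts from a common multinomial reject at about the nominal 5%."""
    rng = np.random.default_rng(2024)
    p = np.array([0.20, 0.35, 0.25, 0.12, 0.08])
    rejections = 0
    n_rep = 10_000
    for _ in range(n_rep):
        a = rng.multinomial(100, p)
        b = rng.multinomial(100, p)
        rejections += chi_square_homogeneity(a, b).p_value < 0.05
    assert 0.04 <= rejections / n_rep <= 0.06


# --- Mann-Whitney --------------------------------------------------------

def mwu_exact_oracle(x, y):
    """Two-sided exact p by enumerating all rank splits (no ties)."""
    pooled = sorted(x + y)
    ranks = {v: i + 1 for i, v in enumerate(pooled)}
    n1 = len(x)

    def u_of(subset):
        r = sum(ranks[v] for v in subset)
        return r - n1 * (n1 + 1) / 2

    u_obs = u_of(x)
    n = len(pooled)
    us = [u_of(list(c)) for c in combinations(pooled, n1)]
    mean_u = n1 * (n - n1) / 2
    extreme = sum(abs(u - mean_u) >= abs(u_obs - mean_u) - 1e-12 for u in us)
    return extreme / len(us)


def test_identical_samples_symmetric():
    res = mann_whitney_u([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
    assert res.u == pytest.approx(4.5)  # n1*n2/2
    assert res.p_value > 0.9


def test_exact_enumeration_separated_samples():
    x, y = [1.0, 2.0, 3.0], [4.0, 5.0, 6.0]
    res = mann_whitney_u(x, y)
    assert res.method == "exact"
    assert res.u == 0.0
    assert res.p_value == pytest.approx(0.1)
    assert res.p_value == pytest.approx(mwu_exact_oracle(x, y))


@given(
    st.lists(st.integers(-50, 50), min_size=3, max_size=5),
    st.lists(st.integers(51, 151), min_size=3, max_size=5),
)
def test_exact_small_sample_p_matches_enumeration(xi, yi):
    x = [float(v) for v in set(xi)]
    y = [float(v) for v in set(yi)]
    if len(x) < 2 or len(y) < 2:
        return
    res = mann_whitney_u(x, y)
    assert res.method == "exact"
    assert res.p_value == pytest.approx(mwu_exact_oracle(x, y))


def test_u_bounds_respected():
    res = mann_whitney_u(np.arange(20.0), np.arange(30.0) + 5.0)
    assert 0 <= res.u <= 20 * 30
    assert res.method == "asymptotic"


def test_morphometry_difference_detected_across_seeds():
    """At n=50/group the generator's condition effect is detected with
    p < 1e-4 in nearly every seed."""
    cfg = SimulationConfig()
    hits_v = hits_f = 0
    n_seeds = 20
    for seed in range(n_seeds):
        rng = np.random.default_rng(seed)
        mb = [sample_nucleus_params(cfg, "myoblast", rng) for _ in range(50)]
        mc = [sample_nucleus_params(cfg, "myocyte", rng) for _ in range(50)]
        hits_v += mann_whitney_u([t.volume for t in mb],
                                 [t.volume for t in mc]).p_value < 1e-4
        hits_f += mann_whitney_u([t.flattening for t in mb],
                                 [t.flattening for t in mc]).p_value < 1e-4
    assert hits_v / n_seeds >= 0.95
    assert hits_f / n_seeds >= 0.95


# --- Shapiro-Wilk --------------------------------------------------------

def test_shapiro_null_rarely_rejects_at_strict_alpha():
    rng = np.random.default_rng(8)
    rejections = sum(
        shapiro_wilk(rng.normal(size=500))[1] < 0.001 for _ in range(200)
    )
    assert rejections <= 4  # ~0.1% expected; allow 2%


def test_shapiro_rejects_lognormal():
    rng = np.random.default_rng(9)
    hits = sum(
        shapiro_wilk(np.exp(rng.normal(size=300)))[1] < 0.001 for _ in range(40)
    )
    assert hits >= 38  # >=95% of seeds


def test_shapiro_input_validation():
    with pytest.raises(ValueError):
        shapiro_wilk([1.0, 2.0])
    with pytest.raises(NucshellError):
        shapiro_wilk([3.0] * 10)


# --- count reconstruction ------------------------------------------------

def test_degenerate_percentage_row():
    rec = reconstruct_counts([100.0, 0.0, 0.0, 0.0, 0.0])
    assert rec.exact and rec.n == 1
    assert rec.counts.tolist() == [1, 0, 0, 0, 0]


@pytest.mark.parametrize(
    "pcts,n,counts",
    [
        ((19.77, 31.40, 30.23, 9.30, 9.30), 86, (17, 27, 26, 8, 8)),
        ((29.41, 48.53, 14.71, 7.35, 0.00), 68, (20, 33, 10, 5, 0)),
    ],
)
def test_published_rows_reconstruct_to_known_totals(pcts, n, counts):
    rec = reconstruct_counts(pcts)
    assert rec.exact
    assert rec.n == n
    assert tuple(rec.counts) == counts
    assert tuple(round_half_up(100 * rec.counts / rec.n, 2)) == pcts


def test_percentages_must_sum_to_100():
    with pytest.raises(ValueError):
        reconstruct_counts([50.0, 30.0, 10.0, 5.0, 4.0])


@given(
    st.lists(st.integers(0, 80), min_size=2, max_size=6).filter(
        lambda c: 0 < sum(c) <= 200
    )
)
def test_reconstruction_inverts_percentage_rounding(counts):
    """From the 2-decimal percentages of any true count vector the search
    finds an n' <= n whose counts reproduce the same percentages."""
    counts = np.array(counts)
    n = counts.sum()
    pcts = round_half_up(100.0 * counts / n, 2)
    if abs(pcts.sum() - 100.0) > 0.05:  # rounding pushed the row sum out
        return
    rec = reconstruct_counts(pcts, n_max=200)
    assert rec.exact
    assert rec.n <= n
    assert np.array_equal(round_half_up(100.0 * rec.counts / rec.n, 2), pcts)


# --- fusion index --------------------------------------------------------

@pytest.mark.parametrize("nd,nud,expected", [(9, 2, 4.5), (0, 5, 0.0), (7, 7, 1.0)])
def test_fusion_index_ratio(nd, nud, expected):
    assert fusion_index(nd, nud) == expected


def test_fusion_index_zero_denominator():
    with pytest.raises(ValueError):
        fusion_index(3, 0)
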
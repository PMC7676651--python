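"""Rank tests vs brute-force enumeration oracles and reference libraries."""

import itertools

import numpy as np
import pytest
from scipy import stats as sps

from vasokin.errors import DegenerateDataError, ValidationError
from vasokin.stats import ks_normality, mann_whitney, wilcoxon_signed_rank


# ---------------------------------------------------------------- oracles
def brute_force_mw_p(x, y, alternative):
    """Exact Mann-Whitney p by enumerating all C(n1+n2, n1) labelings."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    combined = np.concatenate([x, y])
    n1 = len(x)

    def u_stat(xs, ys):
        return sum(1.0 for a in xs for b in ys if a > b)

    u_obs = u_stat(x, y)
    us = [
        u_stat(combined[list(idx)], np.delete(combined, list(idx)))
        for idx in itertools.combinations(range(len(combined)), n1)
    ]
    us = np.array(us)
    p_greater = np.mean(us >= u_obs)
    p_less = np.mean(us <= u_obs)
    if alternative == "greater":
        return p_greater
    if alternative == "less":
        return p_less
    return min(1.0, 2.0 * min(p_greater, p_less))


def brute_force_wilcoxon_p(diffs, alternative):
    """Exact signed-rank p by enumerating all 2^m sign patterns."""
    diffs = np.asarray(diffs, float)
    diffs = diffs[diffs != 0]
    ranks = sps.rankdata(np.abs(diffs))
    w_obs = ranks[diffs > 0].sum()
    ws = [
        np.sum(ranks[np.array(signs) > 0])
        for signs in itertools.product([-1, 1], repeat=len(diffs))
    ]
    ws = np.array(ws)
    p_greater = np.mean(ws >= w_obs - 1e-12)
    p_less = np.mean(ws <= w_obs + 1e-12)
    if alternative == "greater":
        return p_greater
    if alternative == "less":
        return p_less
    return min(1.0, 2.0 * min(p_greater, p_less))


# ----------------------------------------------------------- Mann-Whitney
def test_mw_separated_samples_worked_example():
    res = mann_whitney([1, 2, 3], [4, 5, 6])
    assert res.statistic == 0
    assert res.p_value == pytest.approx(2 / 20)
    assert res.exact


def test_mw_identical_multisets_u_is_half():
    x = [1.0, 2.5, 7.0]
    res = mann_whitney(x, x)
    assert res.statistic == len(x) ** 2 / 2


def test_mw_empty_sample_errors():
    with pytest.raises(ValidationError):
        mann_whitney([], [1.0])


@pytest.mark.parametrize("alternative", ["two-sided", "greater", "less"])
def test_mw_exact_path_matches_enumeration(alternative):
    """DP null distribution equals brute force for every split n1+n2 <= 10."""
    rng = np.random.default_rng(7)
    for n1 in range(1, 9):
        for n2 in range(1, 11 - n1):
            x = rng.normal(0, 1, n1)
            y = rng.normal(0.5, 1, n2)
            res = mann_whitney(x, y, alternative)
            assert res.exact
            assert res.p_value == pytest.approx(
                brute_force_mw_p(x, y, alternative), abs=1e-12
            )


def test_mw_exact_p_is_rational_with_binomial_denominator():
    from math import comb

    rng = np.random.default_rng(3)
    x, y = rng.normal(size=5), rng.normal(size=4)
    res = mann_whitney(x, y)
    total = comb(9, 5)
    assert res.p_value * total == pytest.approx(round(res.p_value * total))


@pytest.mark.parametrize("alternative", ["two-sided", "greater", "less"])
def test_mw_large_n_matches_scipy(alternative):
    rng = np.random.default_rng(11)
    x = rng.normal(0, 1, 40)
    y = rng.normal(0.3, 1.2, 35)
    res = mann_whitney(x, y, alternative)
    assert not res.exact
    ref = sps.mannwhitneyu(x, y, alternative=alternative, method="asymptotic")
    assert res.p_value == pytest.approx(ref.pvalue, abs=1e-8)


def test_mw_ties_fall_back_to_approximation():
    res = mann_whitney([1, 2, 2], [2, 3, 4])
    assert not res.exact


# --------------------------------------------------------------- Wilcoxon
def test_wilcoxon_all_positive_worked_example():
    res = wilcoxon_signed_rank([1.0, 2.0, 3.0], alternative="greater")
    assert res.p_value == pytest.approx(1 / 8)
    assert res.exact


def test_wilcoxon_antisymmetric_two_sided_p_is_one():
    res = wilcoxon_signed_rank([-2.0, 2.0])
    assert res.p_value == 1.0


def test_wilcoxon_paired_form_uses_post_minus_pre():
    pre = [10.0, 12.0, 9.0]
    post = [11.0, 14.0, 12.0]
    res = wilcoxon_signed_rank(pre, post, alternative="greater")
    assert res.p_value == pytest.approx(1 / 8)


def test_wilcoxon_all_zero_differences_error():
    with pytest.raises(DegenerateDataError):
        wilcoxon_signed_rank([0.0, 0.0])


@pytest.mark.parametrize("alternative", ["two-sided", "greater", "less"])
def test_wilcoxon_exact_path_matches_enumeration(alternative):
    """Sign-flip DP equals brute force for every m <= 10, ties included."""
    rng = np.random.default_rng(13)
    for m in range(1, 11):
        d = rng.normal(0.4, 1, m)
        res = wilcoxon_signed_rank(d, alternative=alternative)
        assert res.exact
        assert res.p_value == pytest.approx(
            brute_force_wilcoxon_p(d, alternative), abs=1e-12
        )
    # tied absolute differences keep the sign-flip null exact
    d = np.array([-1.0, 1.0, 2.0, 2.0, 3.0])
    assert wilcoxon_signed_rank(d, alternative=alternative).p_value == pytest.approx(
        brute_force_wilcoxon_p(d, alternative), abs=1e-12
    )


@pytest.mark.parametrize("alternative", ["two-sided", "greater", "less"])
def test_wilcoxon_large_m_matches_scipy(alternative):
    rng = np.random.default_rng(17)
    d = rng.normal(0.3, 1, 20)
    res = wilcoxon_signed_rank(d, alternative=alternative)
    assert not res.exact
    ref = sps.wilcoxon(d, alternative=alternative, correction=True, method="approx")
    assert res.p_value == pytest.approx(ref.pvalue, abs=1e-6)


def test_rank_tests_type_i_error_near_exact_level():
    """Simulated MW type-I error at 8 vs 7 sits near the achievable level."""
    from vasokin.stats import _u_counts

    counts = np.array(_u_counts(8, 7), float)
    total = counts.sum()
    cdf = np.cumsum(counts) / total
    sf = np.cumsum(counts[::-1])[::-1] / total
    p_by_u = np.minimum(1.0, 2.0 * np.minimum(cdf, sf))
    achievable = float(counts[p_by_u <= 0.05].sum() / total)

    rng = np.random.default_rng(19)
    reps = 4000
    x = rng.normal(size=(reps, 8))
    y = rng.normal(size=(reps, 7))
    u = (x[:, :, None] > y[:, None, :]).sum(axis=(1, 2))
    simulated = float(np.mean(p_by_u[u] <= 0.05))
    assert abs(simulated - achievable) < 0.01 + 3 * np.sqrt(achievable * (1 - achievable) / reps)


# ------------------------------------------------------------- normality
def test_ks_normality_requires_n4_and_variation():
    with pytest.raises(ValidationError):
        ks_normality([1.0, 2.0, 3.0])
    with pytest.raises(DegenerateDataError):
        ks_normality([2.0] * 10)


def test_ks_normality_accepts_normal_quantile_sample():
    # points at the fitted normal's own quantiles: tiny distance, large p
    n = 40
    x = sps.norm.ppf((np.arange(1, n + 1) - 0.5) / n)
    res = ks_normality(x)
    assert res.statistic < 0.05
    assert res.p_value > 0.5


def test_ks_normality_rejects_exponential_sample():
    rng = np.random.default_rng(23)
    res = ks_normality(rng.exponential(size=200))
    assert res.p_value < 0.01


def test_ks_normality_calibrated_on_normal_samples():
    """p > 0.05 for at least 95% of large standard-normal samples."""
    rng = np.random.default_rng(29)
    hits = sum(ks_normality(rng.standard_normal(2000)).p_value > 0.05 for _ in range(40))
    assert hits >= 38


def test_ks_normality_agrees_with_statsmodels_lilliefors():
    """Independent cross-check of the Monte-Carlo Lilliefors p-value."""
    from statsmodels.stats.diagnostic import lilliefors

    rng = np.random.default_rng(31)
    for x in (rng.standard_normal(50), rng.exponential(size=50)):
        d_ref, p_ref = lilliefors(x, dist="norm")
        res = ks_normality(x)
        assert res.statistic == pytest.approx(d_ref, abs=1e-12)
        assert res.p_value == pytest.approx(p_ref, abs=0.05)
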
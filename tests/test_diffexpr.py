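"""Unit and property tests for the no-replicate exact DE test."""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cernet.diffexpr import (
    DeParams,
    bh_adjust,
    call_de,
    classify_status,
    log2_fold_change,
    nb_exact_test,
    size_factors,
)

# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------


def _nb_logpmf(k: int, r: float, p: float) -> float:
    return (
        math.lgamma(k + r)
        - math.lgamma(r)
        - math.lgamma(k + 1)
        + r * math.log(p)
        + k * math.log1p(-p)
    )


def oracle_exact_p(count_test: int, count_ref: int, dispersion: float) -> float:
    """Brute-force enumeration of the conditional two-sided p-value for equal
    size factors, written from the pmf definition (independent of the
    implementation's vectorized path)."""
    total = count_test + count_ref
    if total == 0:
        return 1.0
    if dispersion == 0.0:
        weights = [math.comb(total, k) * 0.5**total for k in range(total + 1)]
    else:
        r = 1.0 / dispersion
        mu = total / 2.0
        p = r / (r + mu)
        logw = [
            _nb_logpmf(k, r, p) + _nb_logpmf(total - k, r, p)
            for k in range(total + 1)
        ]
        m = max(logw)
        weights = [math.exp(lw - m) for lw in logw]
        z = sum(weights)
        weights = [w / z for w in weights]
    z = sum(weights)
    weights = [w / z for w in weights]
    obs = weights[count_test]
    return min(1.0, sum(w for w in weights if w <= obs * (1 + 1e-12)))


def oracle_bh(p: np.ndarray) -> np.ndarray:
    """Literal step-up definition: q_(i) = min_{j>=i} min(1, n*p_(j)/j)."""
    n = len(p)
    order = np.argsort(p, kind="mergesort")
    q = np.empty(n)
    running = 1.0
    for rank in range(n, 0, -1):
        idx = order[rank - 1]
        running = min(running, min(1.0, n * p[idx] / rank))
        q[idx] = running
    return q


# ---------------------------------------------------------------------------
# log2 fold change
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "test,ref,pc,expected",
    [(4, 1, 0, 2.0), (7, 7, 0.5, 0.0), (0, 0, 1, 0.0), (1, 4, 0, -2.0)],
)
def test_log2_fold_change_values(test, ref, pc, expected):
    assert log2_fold_change(test, ref, pc) == pytest.approx(expected)


def test_log2_fold_change_rejects_negative():
    with pytest.raises(ValueError):
        log2_fold_change(-1, 2, 1)


# ---------------------------------------------------------------------------
# exact test
# ---------------------------------------------------------------------------


def test_exact_test_symmetric_mode_gives_p_one():
    assert nb_exact_test(5, 5, 1, 1, 0) == pytest.approx(1.0)


def test_exact_test_extreme_split_matches_binomial_enumeration():
    # all 11 outcomes of Binomial(10, 0.5): only 0 and 10 are as unlikely
    assert nb_exact_test(10, 0, 1, 1, 0) == pytest.approx(2 / 1024)
    assert nb_exact_test(10, 0, 1, 1, 0) == pytest.approx(oracle_exact_p(10, 0, 0.0))


@pytest.mark.parametrize("count_test", [0, 7, 15, 20, 33, 40])
def test_exact_test_matches_enumeration_oracle_dispersion(count_test):
    total = 40
    got = nb_exact_test(count_test, total - count_test, 1, 1, 0.1)
    want = oracle_exact_p(count_test, total - count_test, 0.1)
    assert got == pytest.approx(want, rel=1e-9)


def test_exact_test_symmetry_in_samples():
    for a, b in [(3, 9), (0, 5), (12, 12)]:
        assert nb_exact_test(a, b, 1, 1, 0.2) == pytest.approx(
            nb_exact_test(b, a, 1, 1, 0.2)
        )


def test_poisson_limit_of_nb_weights():
    """NB conditional weights converge to binomial as dispersion -> 0."""
    from scipy import stats

    from cernet.diffexpr import _conditional_log_weights

    for total in (10, 57, 100):
        w_nb = np.exp(_conditional_log_weights(total, 1.0, 1.0, 1e-10))
        w_bin = stats.binom.pmf(np.arange(total + 1), total, 0.5)
        assert np.abs(w_nb - w_bin).max() < 1e-8


def test_exact_test_rejects_bad_input():
    with pytest.raises(ValueError):
        nb_exact_test(3, 4, 1, 1, -0.1)
    with pytest.raises(ValueError):
        nb_exact_test(-1, 4)
    with pytest.raises(ValueError):
        nb_exact_test(2, 2, 0, 1)


# ---------------------------------------------------------------------------
# Benjamini-Hochberg
# ---------------------------------------------------------------------------


def test_bh_hand_example():
    assert bh_adjust([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)


def test_bh_single_value_unchanged():
    assert bh_adjust([0.37]) == pytest.approx([0.37])


def test_bh_rejects_out_of_range():
    with pytest.raises(ValueError):
        bh_adjust([0.5, 1.2])


@settings(derandomize=True, deadline=None, max_examples=60)
@given(
    st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=40)
)
def test_bh_matches_stepup_definition_and_statsmodels(pvals):
    p = np.asarray(pvals)
    q = bh_adjust(p)
    assert q == pytest.approx(oracle_bh(p))
    from statsmodels.stats.multitest import multipletests

    _, q_sm, _, _ = multipletests(p, method="fdr_bh")
    assert q == pytest.approx(q_sm)


@settings(derandomize=True, deadline=None, max_examples=30)
@given(
    st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=2, max_size=20),
    st.randoms(use_true_random=False),
)
def test_bh_permutation_equivariance(pvals, rnd):
    p = np.asarray(pvals)
    perm = np.arange(len(p))
    rnd.shuffle(perm)
    assert bh_adjust(p[perm]) == pytest.approx(bh_adjust(p)[perm])


# ---------------------------------------------------------------------------
# call_de
# ---------------------------------------------------------------------------


def test_status_thresholds_are_strict():
    params = DeParams()
    assert classify_status(1.5, 0.01, params)[0] == "up"
    assert classify_status(1.0, 0.001, params)[0] == "ns"  # strict >
    assert classify_status(-1.2, 0.04, params)[0] == "down"
    assert classify_status(2.0, 0.05, params)[0] == "ns"  # strict <
    assert classify_status(2.0, 0.2, params, q=0.01)[0] == "ns"
    assert classify_status(2.0, 0.2, DeParams(use_q=True), q=0.01)[0] == "up"


def _toy_counts() -> pd.DataFrame:
    rng = np.random.default_rng(7)
    base = rng.integers(50, 400, size=30)
    counts = pd.DataFrame(
        {
            "A": base,
            "B": (base * rng.uniform(0.3, 3.0, 30)).astype(int),
        },
        index=[f"g{i}" for i in range(30)],
    )
    return counts


def test_call_de_direction_antisymmetry():
    counts = _toy_counts()
    params = DeParams(dispersion=0.05)
    fwd = call_de(counts, "A", "B", params)
    rev = call_de(counts, "B", "A", params)
    assert fwd.table["log2fc"].to_numpy() == pytest.approx(
        -rev.table["log2fc"].to_numpy()
    )
    swap = {"up": "down", "down": "up", "ns": "ns"}
    assert [swap[s] for s in fwd.table["status"]] == list(rev.table["status"])


def test_call_de_unknown_sample():
    with pytest.raises(KeyError):
        call_de(_toy_counts(), "A", "Z")


def test_size_factors_recover_depth_ratio():
    rng = np.random.default_rng(3)
    base = rng.integers(100, 500, 200)
    counts = pd.DataFrame({"A": base, "B": base * 2})  # B sequenced 2x deeper
    sf = size_factors(counts)
    assert sf["B"] / sf["A"] == pytest.approx(2.0, rel=0.01)
    sf_tot = size_factors(counts, method="total")
    assert sf_tot["B"] / sf_tot["A"] == pytest.approx(2.0, rel=1e-12)


def test_size_factors_resist_composition_bias():
    """A handful of strongly induced genes must not drag the size factor."""
    rng = np.random.default_rng(4)
    base = rng.integers(100, 300, 100)
    b = base.copy()
    b[:10] *= 20  # 10 genes hugely induced in B only
    counts = pd.DataFrame({"A": base, "B": b})
    sf = size_factors(counts)
    assert sf["B"] / sf["A"] == pytest.approx(1.0, rel=0.02)
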
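"""Unit and property tests for the four disproportionality algorithms.

The brute-force oracles here are written scalar-by-scalar with the math
module, independently of the vectorized implementations they check; the
Yates chi-square and the odds-ratio CI are additionally cross-checked
against scipy and statsmodels.
"""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import assume, given, settings
from hypothesis import strategies as st
from scipy.stats import chi2_contingency

from faerspv.signal_stats import (ContingencyTable, bcpnn_ic,
                                  compute_signal_table, evaluate_pair, mhra,
                                  pearson_chi2, prr, ror, yates_chi2)

Z = 1.959963984540054


def oracle_ror(a, b, c, d):
    est = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return est, est * math.exp(-Z * se), est * math.exp(Z * se)


def oracle_prr(a, b, c, d):
    est = (a / (a + b)) / (c / (c + d))
    se = math.sqrt(1 / a - 1 / (a + b) + 1 / c - 1 / (c + d))
    return est, est * math.exp(-Z * se), est * math.exp(Z * se)


def oracle_yates(a, b, c, d):
    n = a + b + c + d
    total = 0.0
    for obs, row, col in ((a, a + b, a + c), (b, a + b, b + d),
                          (c, c + d, a + c), (d, c + d, b + d)):
        e = row * col / n
        total += max(abs(obs - e) - 0.5, 0.0) ** 2 / e
    return total


def oracle_ic(a, b, c, d):
    n = a + b + c + d
    e = (a + b) * (a + c) / n
    ic = math.log2((a + 0.5) / (e + 0.5))
    return ic, ic - 3.3 * (a + 0.5) ** -0.5 - 2.0 * (a + 0.5) ** -1.5


@pytest.mark.parametrize("a,b,c,d,expected_ror", [
    (10, 20, 30, 240, 4.0),   # ad/bc = 2400/600
    (3, 1, 1, 3, 9.0),
    (25, 25, 25, 25, 1.0),
])
def test_ror_point_estimates(a, b, c, d, expected_ror):
    est, lo, hi = ror(a, b, c, d)
    assert est == pytest.approx(expected_ror)
    assert lo <= est <= hi


def test_ror_null_ci_spans_one():
    _, lo, hi = ror(25, 25, 25, 25)
    assert lo < 1.0 < hi


def test_prr_point_estimate():
    est, lo, hi = prr(10, 90, 10, 890)
    assert est == pytest.approx(9.0)  # (10/100)/(10/900)
    assert lo <= est <= hi


def test_prr_null_when_margins_proportional():
    est, _, _ = prr(10, 90, 100, 900)
    assert est == pytest.approx(1.0)


def test_chi2_zero_at_independence():
    assert yates_chi2(25, 25, 25, 25) == pytest.approx(0.0)
    _, chi2, pos = mhra(25, 25, 25, 25)
    assert chi2 == pytest.approx(0.0)
    assert not pos


def test_mhra_large_table():
    est, chi2, pos = mhra(3, 997, 3, 8997)
    assert est == pytest.approx(9.0)  # (3/1000)/(3/9000)
    assert chi2 == pytest.approx(oracle_yates(3, 997, 3, 8997))
    assert bool(pos) == (chi2 >= 4.0)


def test_ic_example():
    # E = 30*40/300 = 4.0; IC = log2(10.5/4.5)
    ic, ic025 = bcpnn_ic(10, 20, 30, 240)
    assert ic == pytest.approx(math.log2(10.5 / 4.5))
    assert ic == pytest.approx(1.2224, abs=1e-3)
    assert ic025 < ic


def test_ic_zero_when_observed_equals_expected():
    # margins chosen so E = (a+b)(a+c)/N equals a exactly
    ic, _ = bcpnn_ic(10, 90, 90, 810)
    assert ic == pytest.approx(0.0)


def test_ic_asymptotic_limit():
    """With a/E fixed at 8 and counts growing, IC -> 3 bits, IC025 -> IC."""
    # p_drug = p_event = 1e-2, joint = 8e-4, so observed/expected = 8
    n = 10_000_000_000
    a = int(8e-4 * n)
    drug_total = event_total = int(1e-2 * n)
    b, c = drug_total - a, event_total - a
    d = n - a - b - c
    ic, ic025 = bcpnn_ic(a, b, c, d)
    assert ic == pytest.approx(3.0, abs=1e-3)
    assert ic025 == pytest.approx(ic, abs=1e-2)


def test_bate_variant_close_to_noren_at_large_counts():
    ic_n, lo_n = bcpnn_ic(800, 7200, 9200, 82800, variant="noren")
    ic_b, lo_b = bcpnn_ic(800, 7200, 9200, 82800, variant="bate")
    assert ic_b == pytest.approx(ic_n, abs=0.05)
    assert lo_b == pytest.approx(lo_n, abs=0.1)
    with pytest.raises(ValueError):
        bcpnn_ic(1, 1, 1, 1, variant="nope")


def _random_tables(n, seed, low=1, high=500):
    rng = np.random.default_rng(seed)
    return rng.integers(low, high, size=(n, 4))


def test_oracle_equivalence_random_tables():
    """All four statistics match independent brute-force implementations
    (and scipy / statsmodels where available) on 1,000 random tables."""
    sm_table = pytest.importorskip("statsmodels.stats.contingency_tables")
    tables = _random_tables(1000, seed=7)
    a, b, c, d = (tables[:, i].astype(float) for i in range(4))
    ror_est, ror_lo, ror_hi = ror(a, b, c, d)
    prr_est, prr_lo, prr_hi = prr(a, b, c, d)
    chi2 = yates_chi2(a, b, c, d)
    ic, ic025 = bcpnn_ic(a, b, c, d)
    for i in range(len(tables)):
        ai, bi, ci, di = (int(x) for x in tables[i])
        o_ror = oracle_ror(ai, bi, ci, di)
        o_prr = oracle_prr(ai, bi, ci, di)
        o_ic = oracle_ic(ai, bi, ci, di)
        assert ror_est[i] == pytest.approx(o_ror[0], rel=1e-9)
        assert ror_lo[i] == pytest.approx(o_ror[1], rel=1e-9)
        assert ror_hi[i] == pytest.approx(o_ror[2], rel=1e-9)
        assert prr_est[i] == pytest.approx(o_prr[0], rel=1e-9)
        assert prr_lo[i] == pytest.approx(o_prr[1], rel=1e-9)
        assert prr_hi[i] == pytest.approx(o_prr[2], rel=1e-9)
        assert chi2[i] == pytest.approx(oracle_yates(ai, bi, ci, di), rel=1e-9)
        assert ic[i] == pytest.approx(o_ic[0], rel=1e-9)
        assert ic025[i] == pytest.approx(o_ic[1], rel=1e-9)
    # independent library cross-checks on a subsample
    for i in range(0, 1000, 97):
        ai, bi, ci, di = (int(x) for x in tables[i])
        sp = chi2_contingency([[ai, bi], [ci, di]], correction=True)
        assert chi2[i] == pytest.approx(sp.statistic, rel=1e-9)
        t22 = sm_table.Table2x2([[ai, bi], [ci, di]])
        assert ror_est[i] == pytest.approx(t22.oddsratio, rel=1e-9)
        lo_sm, hi_sm = t22.oddsratio_confint(0.05)
        assert ror_lo[i] == pytest.approx(lo_sm, rel=1e-6)
        assert ror_hi[i] == pytest.approx(hi_sm, rel=1e-6)


@settings(max_examples=200, deadline=None)
@given(row=st.integers(10, 2000), col=st.integers(10, 2000),
       a1=st.integers(1, 9), delta=st.integers(1, 5))
def test_monotonicity_in_a_with_margins_fixed(row, col, a1, delta):
    """With the margins (drug total, event total, N) fixed, ROR, PRR and IC
    are increasing in the a cell."""
    n = 100_000
    a2 = a1 + delta
    assume(a2 < min(row, col))
    vals = []
    for a in (a1, a2):
        b, c = row - a, col - a
        d = n - row - col + a
        vals.append((ror(a, b, c, d)[0], prr(a, b, c, d)[0],
                     bcpnn_ic(a, b, c, d)[0]))
    (r1, p1, i1), (r2, p2, i2) = vals
    assert r2 > r1 and p2 > p1 and i2 > i1


def test_zero_cell_continuity_policy():
    """A zero cell triggers the Haldane–Anscombe correction and the result
    is finite and marked corrected."""
    df = compute_signal_table(pd.DataFrame(
        {"a": [3], "b": [0], "c": [5], "d": [992]}))
    row = df.iloc[0]
    assert np.isfinite(row["ror"]) and np.isfinite(row["prr"])
    assert row["corrected"]
    # corrected values equal the all-cells +0.5 arithmetic
    assert row["ror"] == pytest.approx((3.5 * 992.5) / (0.5 * 5.5))


def test_degenerate_margin_flagged():
    df = compute_signal_table(pd.DataFrame(
        {"a": [0], "b": [0], "c": [5], "d": [95]}))
    assert df.iloc[0]["degenerate"]
    assert np.isnan(df.iloc[0]["chi2"])
    assert not df.iloc[0]["composite"]


def test_minimum_report_rule_suppresses_flags():
    """A pair with a = 2 is never a signal, whatever the estimates say."""
    res = evaluate_pair(ContingencyTable(2, 1, 1, 10_000))
    assert res.ror > 1000  # wildly disproportionate
    assert not res.composite
    assert not any(res.flags.values())


def test_composite_requires_all_four():
    res = evaluate_pair(ContingencyTable(50, 50, 100, 9800))
    assert res.composite == all(res.flags.values())
    assert res.composite  # strong, well-supported signal
    weak = evaluate_pair(ContingencyTable(50, 5000, 100, 9800))
    assert not weak.composite


def test_null_one_tail_rate():
    """Under independence with all expected cells >= 5, the rate of
    ror_lo > 1 is near the nominal 2.5% one tail (Wald approximation)."""
    rng = np.random.default_rng(11)
    p_drug, p_event, n = 0.1, 0.1, 2000
    probs = [p_drug * p_event, p_drug * (1 - p_event),
             (1 - p_drug) * p_event, (1 - p_drug) * (1 - p_event)]
    t = rng.multinomial(n, probs, size=10_000)
    _, lo, _ = ror(t[:, 0], t[:, 1], t[:, 2], t[:, 3])
    rate = (lo > 1).mean()
    assert 0.015 <= rate <= 0.04


def test_contingency_table_validation():
    with pytest.raises(ValueError):
        ContingencyTable(-1, 1, 1, 1)
    with pytest.raises(ValueError):
        ContingencyTable(0, 0, 0, 0)
    ct = ContingencyTable.from_margins(10, 40, 30, 300)
    assert (ct.a, ct.b, ct.c, ct.d) == (10, 30, 20, 240)
    assert ct.n == 300
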
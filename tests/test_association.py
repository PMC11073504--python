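import numpy as np
import pandas as pd
import pytest
from scipy import stats

import oracles
from hallmarktasks.association import (
    correlate,
    ecdf_compare,
    fixed_effect_model,
    per_hallmark_effects,
)
from hallmarktasks.errors import AnalysisError, ParameterError
from hallmarktasks.io import GrowthTable


def _growth(rates, cells=None):
    cells = cells or [f"c{i}" for i in range(len(rates))]
    return GrowthTable(
        division_rate=pd.Series(rates, index=cells, dtype=float),
        inhibition=pd.DataFrame(index=cells),
    )


def _delta_frame(deltas):
    rows = [
        {"cell_id": cell, "set_name": name, "delta": v}
        for (cell, name), v in deltas.items()
    ]
    return pd.DataFrame(rows)


def test_correlate_perfect_linearity():
    x = np.arange(10, dtype=float)
    rec = correlate(x, 2 * x)
    assert rec.pcc == pytest.approx(1.0)
    assert rec.n == 10


def test_correlate_matches_t_based_formula():
    x = [1.0, 2.0, 4.0, 4.5, 7.0]
    y = [2.0, 1.5, 3.0, 5.0, 6.0]
    rec = correlate(x, y)
    r = oracles.pearson_r(x, y)
    t = r * np.sqrt((5 - 2) / (1 - r**2))
    p = 2 * stats.t.sf(abs(t), 5 - 2)
    assert rec.pcc == pytest.approx(r, abs=1e-12)
    assert rec.p_value == pytest.approx(p, abs=1e-12)


def test_correlate_affine_invariance(rng):
    x = rng.normal(size=15)
    y = rng.normal(size=15)
    base = correlate(x, y)
    scaled = correlate(3 * x + 1, 0.5 * y - 2)
    assert scaled.pcc == pytest.approx(base.pcc, abs=1e-12)


def test_correlate_flags_constant_and_drops_missing():
    rec = correlate([1, 1, 1, 1], [1, 2, 3, 4])
    assert rec.flagged and np.isnan(rec.pcc)
    rec2 = correlate([1, 2, 3, np.nan], [1, 2, 3, 4])
    assert rec2.n == 3
    with pytest.raises(AnalysisError):
        correlate([1, 2], [1, 2])


def test_correlate_null_p_uniform(rng):
    ps = []
    for _ in range(200):
        ps.append(correlate(rng.normal(size=20), rng.normal(size=20)).p_value)
    assert stats.kstest(ps, "uniform").pvalue > 0.01


def test_fixed_effect_recovers_noiseless_slope():
    deltas = {}
    rates = []
    cells = [f"c{i}" for i in range(6)]
    for i, cell in enumerate(cells):
        deltas[(cell, "h1")] = 0.1 * i
        deltas[(cell, "h2")] = 0.1 * i + 0.5  # hallmark offset absorbed by factor
        rates.append(1.0 - 2.0 * 0.1 * i)
    growth = _growth(rates, cells)
    est = fixed_effect_model(_delta_frame(deltas), growth)
    assert est.estimate == pytest.approx(-2.0, abs=1e-8)
    assert est.model == "pooled_fixed_effect"


def test_fixed_effect_rank_deficient_rejected():
    deltas = {}
    cells = [f"c{i}" for i in range(4)]
    for cell in cells:
        deltas[(cell, "h1")] = 0.3  # constant within every hallmark
        deltas[(cell, "h2")] = -0.1
    with pytest.raises(AnalysisError, match="rank"):
        fixed_effect_model(_delta_frame(deltas), _growth([1, 2, 3, 4], cells))


def test_per_hallmark_slopes_equal_pooled_on_exact_data():
    deltas = {}
    cells = [f"c{i}" for i in range(5)]
    rates = []
    for i, cell in enumerate(cells):
        deltas[(cell, "h1")] = 0.2 * i
        deltas[(cell, "h2")] = 0.2 * i + 1.0
        rates.append(3.0 - 1.5 * 0.2 * i)
    growth = _growth(rates, cells)
    pooled = fixed_effect_model(_delta_frame(deltas), growth)
    per = per_hallmark_effects(_delta_frame(deltas), growth)
    assert len(per) == 2
    for est in per:
        assert est.estimate == pytest.approx(pooled.estimate, abs=1e-8)


def test_per_hallmark_matches_ols_formula():
    x = [0.0, 1.0, 2.0, 4.0]
    y = [1.0, 0.5, 0.2, -1.0]
    deltas = {(f"c{i}", "h1"): xv for i, xv in enumerate(x)}
    growth = _growth(y, [f"c{i}" for i in range(4)])
    (est,) = per_hallmark_effects(_delta_frame(deltas), growth)
    assert est.estimate == pytest.approx(oracles.ols_slope(x, y), abs=1e-12)


def test_per_hallmark_skips_small_groups(caplog):
    deltas = {
        ("c0", "big"): 0.0, ("c1", "big"): 1.0, ("c2", "big"): 2.0,
        ("c0", "small"): 0.5, ("c1", "small"): 0.7,
    }
    growth = _growth([1.0, 2.0, 3.0], ["c0", "c1", "c2"])
    with caplog.at_level("WARNING"):
        per = per_hallmark_effects(_delta_frame(deltas), growth)
    assert [e.hallmark for e in per] == ["big"]
    assert "skipped" in caplog.text


def test_ecdf_identity_and_full_separation():
    a = [1.0, 2.0, 3.0]
    assert ecdf_compare(a, a).statistic == pytest.approx(0.0)
    res = ecdf_compare([1, 2, 3], [10, 11, 12], alternative="greater")
    assert res.statistic == pytest.approx(1.0)


def test_ecdf_matches_brute_force_supremum(rng):
    for _ in range(20):
        a = rng.normal(size=5)
        b = rng.normal(0.5, 1.2, size=7)
        for alt in ("two_sided", "greater", "less"):
            d = ecdf_compare(a, b, alternative=alt).statistic
            assert d == pytest.approx(oracles.ks_sup(a, b, alt), abs=1e-12)


def test_ecdf_matches_scipy_two_sided(rng):
    a = rng.normal(size=40)
    b = rng.normal(0.3, 1, size=50)
    mine = ecdf_compare(a, b)
    ref = stats.ks_2samp(a, b, method="asymp")
    assert mine.statistic == pytest.approx(ref.statistic, abs=1e-12)
    # scipy's "asymp" p uses the finite-n kstwo distribution; ours uses the
    # classical Kolmogorov limit -- close but not identical at these sizes
    assert mine.p_value == pytest.approx(ref.pvalue, rel=0.2)


def test_ecdf_reports_scaled_statistic():
    res = ecdf_compare([1, 2, 3, 4], [5, 6, 7], alternative="greater")
    en = np.sqrt(4 * 3 / 7)
    assert res.scaled_statistic == pytest.approx(en * res.statistic)
    with pytest.raises(ParameterError):
        ecdf_compare([1.0], [2.0, 3.0])
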
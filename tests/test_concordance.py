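import numpy as np
import pandas as pd
import pytest
from scipy import stats

import oracles
from conftest import make_collection
from hallmarktasks.concordance import (
    CorrelationMatrix,
    cross_correlation,
    hallmark_vs_random,
    same_vs_other,
    sample_random_set,
    setwise_correlation,
)
from hallmarktasks.errors import AnalysisError, ParameterError
from hallmarktasks.io import AbundanceMatrix


def _matrix(values, modality="mrna", genes=None, cells=None):
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    cells = cells or [f"c{i}" for i in range(values.shape[1])]
    return AbundanceMatrix(modality, pd.DataFrame(values, index=genes, columns=cells))


def test_identical_matrices_give_unit_diagonal(tiny_pair):
    corr = cross_correlation(*tiny_pair)
    np.testing.assert_allclose(corr.same_cell(), 1.0, atol=1e-12)


def test_pearson_affine_invariance(rng):
    x = rng.gamma(2, 2, size=(30, 4))
    mrna = _matrix(x)
    protein = _matrix(2 * x + 3, "protein")
    a = cross_correlation(mrna, _matrix(x, "protein"), log_transform=False)
    b = cross_correlation(mrna, protein, log_transform=False)
    np.testing.assert_allclose(a.values.to_numpy(), b.values.to_numpy(), atol=1e-12)
    np.testing.assert_allclose(np.diag(b.values.to_numpy()), 1.0, atol=1e-12)


def test_single_cell_matches_textbook_formula():
    mrna = _matrix([[1.0], [2.0], [4.0]])
    protein = _matrix([[2.0], [2.0], [5.0]], "protein")
    corr = cross_correlation(mrna, protein, log_transform=False)
    expected = oracles.pearson_r([1, 2, 4], [2, 2, 5])
    assert corr.values.iloc[0, 0] == pytest.approx(expected, abs=1e-12)


def test_spearman_equals_pearson_on_ranks(rng):
    x = rng.gamma(2, 1, size=(40, 3))
    y = rng.gamma(2, 1, size=(40, 3))
    mrna, protein = _matrix(x), _matrix(y, "protein")
    rho = cross_correlation(mrna, protein, method="spearman")
    expected = np.array(
        [
            [stats.spearmanr(x[:, i], y[:, j]).statistic for j in range(3)]
            for i in range(3)
        ]
    )
    np.testing.assert_allclose(rho.values.to_numpy(), expected, atol=1e-12)


def test_invariant_to_joint_gene_permutation(rng):
    x = rng.gamma(2, 1, size=(25, 3))
    y = rng.gamma(2, 1, size=(25, 3))
    genes = [f"g{i}" for i in range(25)]
    perm = rng.permutation(25)
    a = cross_correlation(_matrix(x, genes=genes), _matrix(y, "protein", genes=genes))
    b = cross_correlation(
        _matrix(x[perm], genes=[genes[i] for i in perm]),
        _matrix(y[perm], "protein", genes=[genes[i] for i in perm]),
    )
    np.testing.assert_allclose(a.values.to_numpy(), b.values.to_numpy(), atol=1e-12)


def test_constant_profile_flagged_not_zero():
    x = np.array([[1.0, 1.0], [2.0, 1.0], [3.0, 1.0]])
    corr = cross_correlation(_matrix(x), _matrix(x, "protein"), log_transform=False)
    assert np.isnan(corr.values.iloc[0, 1])  # constant protein profile
    assert corr.values.iloc[0, 0] == pytest.approx(1.0)


def test_fewer_than_three_shared_genes_rejected():
    mrna = _matrix(np.ones((3, 2)) * [[1], [2], [3]], genes=["a", "b", "c"])
    protein = _matrix(np.ones((3, 2)) * [[1], [2], [3]], "protein", genes=["c", "d", "e"])
    with pytest.raises(AnalysisError, match="shared genes"):
        cross_correlation(mrna, protein)


def test_same_vs_other_separated_groups(rng):
    n = 6
    vals = 0.1 + 0.01 * rng.standard_normal((n, n))
    np.fill_diagonal(vals, 0.9 + 0.01 * rng.standard_normal(n))
    cells = [f"c{i}" for i in range(n)]
    corr = CorrelationMatrix(pd.DataFrame(vals, index=cells, columns=cells), "pearson", 100)
    welch, ks = same_vs_other(corr)
    assert welch.statistic > 10
    assert ks.statistic == pytest.approx(1.0)


def test_welch_matches_closed_form():
    vals = np.array(
        [[0.9, 0.2, 0.15], [0.1, 0.7, 0.3], [0.25, 0.05, 0.8]]
    )
    cells = ["c1", "c2", "c3"]
    corr = CorrelationMatrix(pd.DataFrame(vals, index=cells, columns=cells), "pearson", 50)
    welch, _ = same_vs_other(corr)
    t, df = oracles.welch_t(list(np.diag(vals)), [0.2, 0.15, 0.1, 0.3, 0.25, 0.05])
    assert welch.statistic == pytest.approx(t, abs=1e-12)
    assert welch.df == pytest.approx(df, abs=1e-10)


def test_same_vs_other_null_p_uniform(rng):
    """With iid entries the diagonal is exchangeable with the off-diagonal,
    so Welch p-values are approximately uniform."""
    ps = []
    for _ in range(200):
        vals = rng.standard_normal((8, 8))
        cells = [f"c{i}" for i in range(8)]
        corr = CorrelationMatrix(
            pd.DataFrame(vals, index=cells, columns=cells), "pearson", 10
        )
        welch, _ = same_vs_other(corr)
        ps.append(welch.p_value)
    assert stats.kstest(ps, "uniform").pvalue > 0.01


def test_setwise_whole_universe_equals_diagonal(tiny_pair):
    mrna, protein = tiny_pair
    sets = make_collection({"all": list(mrna.gene_ids)})
    table = setwise_correlation(mrna, protein, sets)
    diag = cross_correlation(mrna, protein).same_cell()
    np.testing.assert_allclose(table["r"].to_numpy(), diag, atol=1e-12)


def test_setwise_small_set_flagged_undefined(tiny_pair):
    mrna, protein = tiny_pair
    sets = make_collection({"tiny": ["gA", "gB"]}, universe=list(mrna.gene_ids))
    table = setwise_correlation(mrna, protein, sets)
    assert table["r"].isna().all()
    assert (table["n_genes"] == 2).all()


def test_hallmark_correlations_exceed_background(small_cohort):
    """Hallmark sets are more tightly coupled than a random set by
    construction; the median contrast should hold in a single cohort."""
    mrna, protein, sets, growth, truth = small_cohort
    rand = sample_random_set(mrna.gene_ids, 100, seed=5)
    coll = make_collection({**sets.sets, "random_set": rand}, universe=list(sets.universe))
    table = setwise_correlation(mrna, protein, coll)
    hall = table[table["set_name"] != "random_set"]["r"]
    randr = table[table["set_name"] == "random_set"]["r"]
    assert np.nanmedian(hall) > np.nanmedian(randr)


def test_sample_random_set_determinism_and_bounds():
    universe = [f"g{i}" for i in range(50)]
    assert sample_random_set(universe, 10, seed=1) == sample_random_set(universe, 10, seed=1)
    assert sorted(sample_random_set(universe, 50, seed=2)) == sorted(universe)
    with pytest.raises(ParameterError):
        sample_random_set(universe, 0, seed=1)
    with pytest.raises(ParameterError):
        sample_random_set(universe, 51, seed=1)


def _setwise_frame(values_by_set):
    rows = []
    for name, vals in values_by_set.items():
        for i, v in enumerate(vals):
            rows.append((name, f"c{i}", v, 10))
    return pd.DataFrame(rows, columns=["set_name", "cell_id", "r", "n_genes"])


def test_hallmark_vs_random_no_effect():
    vals = [0.1, 0.3, 0.2, 0.5, 0.4]
    table = _setwise_frame({"h1": vals, "h2": vals})
    per_set, anova = hallmark_vs_random(table, pd.Series(vals), alternative="two-sided")
    assert anova.statistic == pytest.approx(0.0, abs=1e-12)
    for t in per_set.values():
        assert t.p_value > 0.9


def test_anova_matches_sum_of_squares_oracle():
    g1 = [0.1, 0.2, 0.3]
    g2 = [0.4, 0.6, 0.5]
    table = _setwise_frame({"h1": g1})
    _, anova = hallmark_vs_random(table, pd.Series(g2))
    assert anova.statistic == pytest.approx(oracles.anova_f([g1, g2]), abs=1e-10)
    assert anova.df == (1.0, 4.0)


def test_shifted_hallmark_wilcoxon_significant(rng):
    rand = rng.uniform(0, 0.4, size=32)
    table = _setwise_frame({"h1": rand + 0.2})
    per_set, _ = hallmark_vs_random(table, pd.Series(rand))
    assert per_set["h1"].p_value < 0.01
    assert per_set["h1"].direction == "greater"


def test_wilcoxon_matches_exact_enumeration(rng):
    a = list(rng.normal(0.5, 0.3, size=6))
    b = list(rng.normal(0.0, 0.3, size=6))
    table = _setwise_frame({"h1": a})
    per_set, _ = hallmark_vs_random(table, pd.Series(b))
    expected = oracles.ranksum_exact_p_greater(a, b)
    assert per_set["h1"].p_value == pytest.approx(expected, abs=1e-12)
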
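import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import oracles
from conftest import make_collection
from hallmarktasks.enrichment import (
    RankedList,
    enrich_matrix,
    enrichment_score,
    gsea_preranked,
    rank_products,
    records_to_frame,
)
from hallmarktasks.errors import AnalysisError, ParameterError
from hallmarktasks.io import AbundanceMatrix


def _ranked(scores, genes=None, cell="c1", modality="mrna"):
    scores = np.asarray(scores, dtype=float)
    order = np.argsort(-scores, kind="stable")
    genes = np.asarray(
        genes if genes is not None else [f"g{i + 1}" for i in range(len(scores))],
        dtype=object,
    )
    return RankedList(cell, modality, genes[order], scores[order])


def test_rank_products_sorts_descending_with_tie_rule():
    data = pd.DataFrame({"c1": [5.0, 3.0, 9.0, 5.0]}, index=["A", "B", "C", "A2"])
    # rename so the tie pair is (A, A2) with A first lexicographically
    matrix = AbundanceMatrix("mrna", data)
    ranked = rank_products(matrix, "c1")
    assert list(ranked.genes) == ["C", "A", "A2", "B"]
    assert list(ranked.scores) == [9.0, 5.0, 5.0, 3.0]


def test_rank_products_unknown_cell_and_missing_values():
    data = pd.DataFrame({"c1": [1.0, 2.0, 3.0]}, index=["A", "B", "C"])
    matrix = AbundanceMatrix("mrna", data)
    with pytest.raises(ParameterError, match="unknown cell"):
        rank_products(matrix, "nope")
    # all-missing column: injected after construction to bypass validation
    matrix.data.loc[:, "c1"] = np.nan
    with pytest.raises(AnalysisError, match="defined values"):
        rank_products(matrix, "c1")


def test_es_worked_example_two_thirds():
    ranked = _ranked([5, 4, 3, 2, 1])
    es, extreme = enrichment_score(ranked, {"g1", "g3"}, exponent=1.0)
    assert es == pytest.approx(2 / 3, abs=1e-12)
    assert extreme == 2  # the running sum peaks after the hit at rank 3


def test_es_extremes_at_top_and_bottom():
    ranked = _ranked([9, 8, 7, 6, 5, 4])
    assert enrichment_score(ranked, {"g1", "g2"})[0] == pytest.approx(1.0)
    assert enrichment_score(ranked, {"g5", "g6"})[0] == pytest.approx(-1.0)


def test_es_degenerate_sets_rejected():
    ranked = _ranked([3, 2, 1])
    with pytest.raises(AnalysisError):
        enrichment_score(ranked, {"g1", "g2", "g3"})
    with pytest.raises(AnalysisError):
        enrichment_score(ranked, {"absent"})


def test_es_matches_brute_force_on_random_cases(rng):
    """500 random (list <= 20 genes, set) cases against an independent
    enumeration of the running sum."""
    for case in range(500):
        n = int(rng.integers(4, 21))
        scores = np.round(rng.gamma(2, 2, size=n), 3)
        k = int(rng.integers(1, n))
        ranked = _ranked(scores)
        members = set(rng.choice(ranked.genes, size=k, replace=False))
        exponent = float(rng.choice([0.0, 1.0, 2.0]))
        es, _ = enrichment_score(ranked, members, exponent)
        expected = oracles.brute_force_es(ranked.genes, ranked.scores, members, exponent)
        assert es == pytest.approx(expected, abs=1e-12), f"case {case}"


def test_exponent_zero_reduces_to_unweighted_ks(rng):
    scores = rng.gamma(2, 2, size=15)
    ranked = _ranked(scores)
    members = set(ranked.genes[[1, 4, 7]])
    es, _ = enrichment_score(ranked, members, exponent=0.0)
    # classic KS form: hit steps 1/N_hit, miss steps 1/(N - N_hit)
    inside = np.array([g in members for g in ranked.genes])
    path = np.cumsum(np.where(inside, 1 / 3, -1 / 12))
    expected = path[np.abs(path).argmax()]
    assert es == pytest.approx(expected, abs=1e-12)


def test_es_invariant_to_positive_scaling_at_exponent_zero(rng):
    scores = np.sort(rng.gamma(2, 2, size=20))[::-1]
    ranked = _ranked(scores)
    scaled = _ranked(scores * 7.5)
    members = set(ranked.genes[[0, 3, 9]])
    assert enrichment_score(ranked, members, 0.0)[0] == enrichment_score(
        scaled, members, 0.0
    )[0]


@given(
    n=st.integers(5, 18),
    seed=st.integers(0, 10_000),
)
def test_es_bounded_and_matches_oracle(n, seed):
    rng = np.random.default_rng(seed)
    scores = rng.exponential(3, size=n)
    ranked = _ranked(scores)
    k = int(rng.integers(1, n))
    members = set(rng.choice(ranked.genes, size=k, replace=False))
    es, _ = enrichment_score(ranked, members)
    assert -1.0 <= es <= 1.0
    assert es == pytest.approx(
        oracles.brute_force_es(ranked.genes, ranked.scores, members), abs=1e-12
    )


def _random_collection(ranked, sizes, rng):
    sets = {
        f"s{i}": list(rng.choice(ranked.genes, size=size, replace=False))
        for i, size in enumerate(sizes)
    }
    return make_collection(sets, universe=list(ranked.genes))


def test_gsea_deterministic_and_sign_consistent(rng):
    scores = rng.gamma(2, 2, size=120)
    ranked = _ranked(scores)
    coll = _random_collection(ranked, [10, 20, 30], rng)
    a = gsea_preranked(ranked, coll, n_perm=200, seed=9)
    b = gsea_preranked(ranked, coll, n_perm=200, seed=9)
    assert records_to_frame(a).equals(records_to_frame(b))
    for r in a:
        if not r.flagged and r.es != 0:
            assert np.sign(r.nes) == np.sign(r.es)
        assert r.p_value >= 1 / (r.n_perm + 1)  # add-one floor: never zero


def test_gsea_flags_undersized_and_out_of_universe_sets(rng):
    scores = rng.gamma(2, 2, size=50)
    ranked = _ranked(scores)
    coll = make_collection(
        {"ok": list(ranked.genes[:10]), "tiny": list(ranked.genes[:2]), "out": ["zz1", "zz2", "zz3", "zz4", "zz5"]},
        universe=list(ranked.genes),
    )
    records = {r.set_name: r for r in gsea_preranked(ranked, coll, n_perm=150, seed=0)}
    assert not records["ok"].flagged
    assert records["tiny"].flagged and np.isnan(records["tiny"].fdr_q)
    assert records["out"].flagged
    assert records["out"].set_size_effective == 0


def test_gsea_bh_ordering_preserved(rng):
    scores = rng.gamma(2, 2, size=200)
    ranked = _ranked(scores)
    coll = _random_collection(ranked, [8, 12, 16, 24, 40], rng)
    records = [r for r in gsea_preranked(ranked, coll, n_perm=300, seed=3) if not r.flagged]
    by_p = sorted(records, key=lambda r: r.p_value)
    qs = [r.fdr_q for r in by_p]
    assert all(q2 >= q1 - 1e-12 for q1, q2 in zip(qs, qs[1:]))
    assert all(r.fdr_q >= r.p_value - 1e-12 for r in records)


def test_gsea_requires_minimum_permutations(rng):
    ranked = _ranked(rng.gamma(2, 2, size=30))
    coll = _random_collection(ranked, [8], rng)
    with pytest.raises(ParameterError, match="n_perm"):
        gsea_preranked(ranked, coll, n_perm=50, seed=0)


def test_null_mean_positive_nes_close_to_one(rng):
    """Under random rankings the positive-side NES averages 1: the observed
    ES and the null draws share a distribution."""
    genes = np.array([f"g{i:03d}" for i in range(150)], dtype=object)
    pos = []
    for i in range(60):
        scores = np.sort(rng.gamma(2, 2, size=150))[::-1]
        ranked = RankedList("c", "mrna", genes, scores)
        members = list(rng.choice(genes, size=15, replace=False))
        coll = make_collection({"s": members}, universe=list(genes))
        rec = gsea_preranked(ranked, coll, n_perm=500, seed=1000 + i)[0]
        if rec.nes > 0:
            pos.append(rec.nes)
    assert abs(np.mean(pos) - 1.0) < 0.1


def test_enrich_matrix_independent_of_cell_order(rng):
    values = rng.gamma(2, 5, size=(60, 3))
    genes = [f"g{i:02d}" for i in range(60)]
    cells = ["c1", "c2", "c3"]
    m1 = AbundanceMatrix("mrna", pd.DataFrame(values, index=genes, columns=cells))
    coll = make_collection({"s": genes[:12]}, universe=genes)
    records = enrich_matrix(m1, coll, n_perm=150, seed=4)
    # per-cell seeds derive from the column index, so each cell's record is
    # reproducible in isolation
    again = enrich_matrix(m1, coll, n_perm=150, seed=4)
    pd.testing.assert_frame_equal(records, again)
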
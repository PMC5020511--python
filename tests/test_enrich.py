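import math
from fractions import Fraction
from math import comb

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from statsmodels.stats.multitest import multipletests

from geneora import fixtures
from geneora.enrich import (
    CORRECTION_METHODS,
    ContingencyInputs,
    adjust_pvalues,
    fisher_right_tail,
    hypergeom_pmf,
    overlap,
    run_enrichment,
)
from geneora.model import DbName, GeneList, GeneSet, GeneSetDatabase, IdKind

STATSMODELS_NAMES = {
    "BH": "fdr_bh",
    "Bonferroni": "bonferroni",
    "Hochberg": "simes-hochberg",
    "Hommel": "hommel",
    "BY": "fdr_by",
}


def exact_tail(N: int, k: int, d: int, x: int) -> Fraction:
    """Independent oracle: exact-rational hypergeometric right tail."""
    return sum(
        (Fraction(comb(k, j) * comb(N - k, d - j), comb(N, d))
         for j in range(max(x, max(0, k + d - N)), min(d, k) + 1)),
        Fraction(0),
    )


# ---------------------------------------------------------------------------
# Contingency table
# ---------------------------------------------------------------------------


def test_contingency_cells_match_reporting_convention():
    ci = ContingencyInputs(x=3, d=10, k=8, N=100)
    assert (ci.n11, ci.n21, ci.n12) == (3, 7, 8)
    assert ci.n22_reported == 100 - (8 + 10)
    assert ci.n22 == 100 - 8 - 10 + 3


def test_contingency_reported_cell_may_go_negative_but_standard_cell_not():
    ci = ContingencyInputs(x=5, d=8, k=9, N=12)
    assert ci.n22_reported < 0
    assert ci.n22 >= 0


@pytest.mark.parametrize(
    "kwargs",
    [
        dict(x=6, d=5, k=10, N=100),   # x > d
        dict(x=-1, d=5, k=10, N=100),  # negative overlap
        dict(x=0, d=0, k=10, N=100),   # empty list
        dict(x=0, d=101, k=10, N=100),  # d > N
    ],
)
def test_contingency_rejects_invalid_inputs(kwargs):
    with pytest.raises(ValueError):
        ContingencyInputs(**kwargs)


# ---------------------------------------------------------------------------
# Hypergeometric pmf and Fisher right tail
# ---------------------------------------------------------------------------


def test_pmf_single_point_support_is_one():
    assert hypergeom_pmf(5, ContingencyInputs(x=5, d=5, k=5, N=5)) == 1.0


def test_pmf_worked_example_matches_binomial_arithmetic():
    # C(5,5)*C(15,0)/C(20,5) evaluated by integer combinatorics
    expected = Fraction(comb(5, 5) * comb(15, 0), comb(20, 5))
    assert expected == Fraction(1, 15504)
    got = hypergeom_pmf(5, ContingencyInputs(x=5, d=5, k=5, N=20))
    assert got == pytest.approx(float(expected), abs=1e-15)


def test_pmf_zero_outside_support():
    ci = ContingencyInputs(x=0, d=5, k=5, N=20)
    assert hypergeom_pmf(6, ci) == 0.0
    assert hypergeom_pmf(-1, ci) == 0.0


@settings(max_examples=60, derandomize=True)
@given(st.integers(2, 25), st.data())
def test_pmf_sums_to_one_over_support(N, data):
    k = data.draw(st.integers(1, N))
    d = data.draw(st.integers(1, N))
    ci = ContingencyInputs(x=min(d, k), d=d, k=k, N=N)
    total = sum(hypergeom_pmf(j, ci)
                for j in range(max(0, k + d - N), min(d, k) + 1))
    assert total == pytest.approx(1.0, abs=1e-12)


def test_tail_worked_example_76_over_15504():
    got = fisher_right_tail(ContingencyInputs(x=4, d=5, k=5, N=20))
    expected = Fraction(comb(5, 4) * comb(15, 1) + comb(5, 5) * comb(15, 0),
                        comb(20, 5))
    assert expected == Fraction(76, 15504)
    assert got == pytest.approx(float(expected), abs=1e-14)


def test_tail_is_one_at_zero_overlap():
    assert fisher_right_tail(ContingencyInputs(x=0, d=7, k=4, N=30)) == 1.0


@settings(max_examples=60, derandomize=True)
@given(st.integers(2, 28), st.data())
def test_tail_matches_exact_rational_oracle(N, data):
    k = data.draw(st.integers(1, N))
    d = data.draw(st.integers(1, N))
    x = data.draw(st.integers(0, min(d, k)))
    got = fisher_right_tail(ContingencyInputs(x=x, d=d, k=k, N=N))
    assert got == pytest.approx(float(exact_tail(N, k, d, x)), abs=1e-12)


def test_tail_non_increasing_in_x():
    ci = lambda x: ContingencyInputs(x=x, d=8, k=6, N=40)  # noqa: E731
    ps = [fisher_right_tail(ci(x)) for x in range(0, 7)]
    assert all(a >= b for a, b in zip(ps, ps[1:]))


def test_tail_agrees_with_scipy_survival_function():
    from scipy.stats import hypergeom

    for (N, k, d, x) in [(2000, 40, 100, 7), (5000, 25, 120, 3), (50, 10, 10, 4)]:
        got = fisher_right_tail(ContingencyInputs(x=x, d=d, k=k, N=N))
        assert got == pytest.approx(hypergeom.sf(x - 1, N, k, d), rel=1e-10)


# ---------------------------------------------------------------------------
# Multiple-testing corrections
# ---------------------------------------------------------------------------


@pytest.mark.parametrize("method", CORRECTION_METHODS)
def test_single_hypothesis_is_identity(method):
    assert adjust_pvalues([0.037], method) == pytest.approx([0.037])


def test_bonferroni_definitional_product():
    assert adjust_pvalues([0.01, 0.4], "Bonferroni") == pytest.approx([0.02, 0.8])


def test_bh_step_up_hand_evaluation():
    # min over j >= rank of m*p_(j)/j: all three collapse to 0.03
    assert adjust_pvalues([0.01, 0.02, 0.03], "BH") == pytest.approx(
        [0.03, 0.03, 0.03])


def test_adjusted_values_clipped_to_unit_interval():
    out = adjust_pvalues([0.9, 0.95, 0.99], "Bonferroni")
    assert np.all(out <= 1.0)


def test_rejects_pvalues_outside_unit_interval():
    for bad in ([1.2], [-0.1], [np.nan]):
        with pytest.raises(ValueError):
            adjust_pvalues(bad, "BH")


def test_unknown_method_rejected():
    with pytest.raises(ValueError, match="unknown correction"):
        adjust_pvalues([0.5], "holm-sidak")


@pytest.mark.parametrize("method", CORRECTION_METHODS)
@settings(max_examples=40, derandomize=True)
@given(ps=st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=60))
def test_corrections_match_statsmodels_reference(method, ps):
    ours = adjust_pvalues(ps, method)
    ref = multipletests(ps, method=STATSMODELS_NAMES[method])[1]
    assert ours == pytest.approx(ref, abs=1e-12)


@settings(max_examples=40, derandomize=True)
@given(ps=st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=40))
def test_dominance_chain_and_lower_bound(ps):
    raw = np.asarray(ps)
    adj = {m: adjust_pvalues(ps, m) for m in CORRECTION_METHODS}
    eps = 1e-12
    for m in CORRECTION_METHODS:
        assert np.all(adj[m] >= raw - eps)
        assert np.all(adj[m] <= 1.0 + eps)
    assert np.all(adj["Hommel"] <= adj["Hochberg"] + eps)
    assert np.all(adj["Hochberg"] <= adj["Bonferroni"] + eps)
    assert np.all(adj["BH"] <= adj["BY"] + eps)


@pytest.mark.parametrize("method", CORRECTION_METHODS)
@settings(max_examples=25, derandomize=True)
@given(data=st.data())
def test_corrections_are_permutation_equivariant(method, data):
    ps = data.draw(st.lists(st.floats(0, 1, allow_nan=False),
                            min_size=2, max_size=30))
    perm = data.draw(st.permutations(range(len(ps))))
    base = adjust_pvalues(ps, method)
    permuted = adjust_pvalues([ps[i] for i in perm], method)
    assert permuted == pytest.approx([base[i] for i in perm], abs=1e-12)


# ---------------------------------------------------------------------------
# Overlap and the full run
# ---------------------------------------------------------------------------


def _gl(*ids):
    return GeneList(ids=tuple(ids), id_kind=IdKind.SYM)


def test_overlap_is_set_intersection():
    gs = GeneSet("T", "t", frozenset({"B", "C", "D"}))
    x, hits = overlap(_gl("A", "B", "C"), gs)
    assert (x, hits) == (2, {"B", "C"})


def test_overlap_disjoint_and_identical_cases():
    gs = GeneSet("T", "t", frozenset({"X", "Y"}))
    assert overlap(_gl("A", "B"), gs)[0] == 0
    x, _ = overlap(_gl("X", "Y"), gs)
    assert x == gs.k == 2


def test_run_enrichment_rejects_id_kind_mismatch(tiny_db):
    gid_list = GeneList(ids=("7157",), id_kind=IdKind.GID)
    with pytest.raises(ValueError, match="--gtype"):
        run_enrichment(gid_list, tiny_db)


def test_run_enrichment_omits_zero_hit_terms(tiny_db):
    results = run_enrichment(_gl("A", "B"), tiny_db)
    assert {r.term_id for r in results} == {"T1", "T2"}  # T3 has no hit
    m = len(results)
    for r in results:
        # family of corrections is the emitted terms only
        assert r.adjusted["Bonferroni"] == pytest.approx(min(1.0, m * r.p_value))


def test_run_enrichment_disjoint_list_returns_empty_with_warning(tiny_db, caplog):
    with caplog.at_level("WARNING"):
        results = run_enrichment(_gl("Z9", "Z8"), tiny_db)
    assert results == []
    assert any("no gene" in rec.message for rec in caplog.records)


def test_run_enrichment_ranks_by_pvalue_with_deterministic_ties():
    # two identical copies of a term -> identical x and p, adjacent ranks in id order
    db = GeneSetDatabase(
        db_name=DbName.REACTOME, organism="hsa",
        sets=(
            GeneSet("B_copy", "b", frozenset({"A", "B", "C"})),
            GeneSet("A_copy", "a", frozenset({"A", "B", "C"})),
            GeneSet("Weak", "w", frozenset({"A", "X", "Y", "Z", "W", "V"})),
        ),
        id_kind=IdKind.SYM,
    )
    results = run_enrichment(_gl("A", "B", "C"), db)
    assert [r.term_id for r in results] == ["A_copy", "B_copy", "Weak"]
    assert results[0].p_value == results[1].p_value
    assert [r.rank for r in results] == [1, 2, 3]


def test_run_enrichment_invariant_to_list_order(tiny_db):
    a = run_enrichment(_gl("A", "B", "D"), tiny_db)
    b = run_enrichment(_gl("D", "B", "A"), tiny_db)
    assert [(r.term_id, r.p_value, r.rank) for r in a] == \
        [(r.term_id, r.p_value, r.rank) for r in b]


def test_run_enrichment_d_counts_genes_outside_universe(tiny_db):
    inside = run_enrichment(_gl("A", "B"), tiny_db, background=50)
    with_outside = run_enrichment(_gl("A", "B", "NOTINDB"), tiny_db, background=50)
    # same overlaps but larger d -> larger (weaker) p-values
    assert with_outside[0].x == inside[0].x
    assert with_outside[0].p_value > inside[0].p_value


def test_run_enrichment_background_must_cover_d_and_k(tiny_db):
    with pytest.raises(ValueError, match="background"):
        run_enrichment(_gl("A", "B"), tiny_db, background=2)


def test_run_enrichment_default_background_is_universe_size(tiny_db):
    results = run_enrichment(_gl("A", "F"), tiny_db)
    N = len(tiny_db.universe)
    r = next(r for r in results if r.term_id == "T3")
    expected = float(exact_tail(N, 2, 2, 1))
    assert r.p_value == pytest.approx(expected, abs=1e-12)


def test_run_enrichment_percentage_is_term_coverage(tiny_db):
    results = run_enrichment(_gl("A", "B"), tiny_db)
    r = next(r for r in results if r.term_id == "T1")
    assert r.percentage == pytest.approx(100.0 * 2 / 3)


def test_sort_by_hits_orders_by_overlap_first(tiny_db):
    results = run_enrichment(_gl("A", "B", "E"), tiny_db, sort_by="hits")
    xs = [r.x for r in results]
    assert xs == sorted(xs, reverse=True)


def test_planted_fixture_term_attains_rank_one(small_spec, small_db):
    gl = fixtures.make_gene_list(small_spec, small_db)
    results = run_enrichment(gl, small_db)
    planted_id = small_db.sets[small_spec.planted_term_index].term_id
    assert results[0].term_id == planted_id
    # brute-force cross-check: rank-1 has the smallest oracle tail
    N = len(small_db.universe)
    oracle = {}
    for s in small_db.sets:
        x = len(set(gl.ids) & s.members)
        if x >= 1:
            oracle[s.term_id] = exact_tail(N, s.k, gl.d, x)
    assert min(oracle, key=lambda t: (oracle[t], t)) == planted_id


def test_global_null_bh_rejection_rate_is_controlled(default_spec):
    """Random lists from the pool: BH<0.05 rejections stay near/below 5%."""
    db = fixtures.make_database(default_spec)
    rng = np.random.default_rng(2024)
    pool = default_spec.gene_pool
    n_lists = 500
    fracs = []
    for _ in range(n_lists):
        ids = rng.choice(pool, size=default_spec.list_size, replace=False)
        gl = GeneList(ids=tuple(ids), id_kind=IdKind.SYM)
        results = run_enrichment(gl, db)
        if results:
            sig = sum(r.adjusted["BH"] < 0.05 for r in results)
            fracs.append(sig / len(results))
        else:
            fracs.append(0.0)
    mean = float(np.mean(fracs))
    se = float(np.std(fracs, ddof=1) / math.sqrt(n_lists))
    assert mean <= 0.05 + 3 * se
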
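import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ssrpop import (
    GenotypeMatrix,
    MISSING_CODE,
    distance_matrix,
    exhaustive_core,
    objective_value,
    pairwise_distance,
    retained_diversity,
    select_core,
)
from ssrpop.diversity import diversity_table


def test_pairwise_distance_hand_values(toy_matrix):
    assert pairwise_distance(toy_matrix, "acc0", "acc0", "MR") == 0.0
    # acc0 vs acc1 differ at 1 of 4 loci
    assert pairwise_distance(toy_matrix, "acc0", "acc1", "MR") == pytest.approx(0.5)
    # disjoint alleles everywhere
    assert pairwise_distance(toy_matrix, "acc0", "acc5", "CE") == pytest.approx(1.0)


def test_distance_requires_shared_loci():
    calls = np.array([[101, MISSING_CODE], [MISSING_CODE, 103]])
    m = GenotypeMatrix(["a", "b"], ["l1", "l2"], calls)
    with pytest.raises(ValueError, match="share"):
        pairwise_distance(m, "a", "b")


@given(st.integers(0, 10_000))
@settings(max_examples=30)
def test_mr_and_ce_coincide_for_homozygous_lines(seed):
    rng = np.random.default_rng(seed)
    n, L = int(rng.integers(3, 10)), int(rng.integers(2, 8))
    calls = rng.integers(1, 4, size=(n, L)) * 2 + 100
    calls[rng.random((n, L)) < 0.15] = MISSING_CODE
    m = GenotypeMatrix([f"a{i}" for i in range(n)], [f"l{j}" for j in range(L)], calls)
    mr, ce = distance_matrix(m, "MR"), distance_matrix(m, "CE")
    assert np.allclose(mr, ce, equal_nan=True)


def test_objective_full_set_identities(toy_matrix):
    table = diversity_table(toy_matrix)
    body = table[~table["locus"].isin(("mean", "min", "max"))]
    swi = objective_value(toy_matrix, toy_matrix.accession_ids, "SWI")
    assert swi == pytest.approx(body["d_SWI"].mean())
    # uniform k-allele locus contributes NE = k
    calls = np.array([[2], [4], [6], [8]]) + 100
    m = GenotypeMatrix(list("abcd"), ["l"], calls)
    assert objective_value(m, list("abcd"), "NE") == pytest.approx(4.0)


def test_objective_mean_mr_matches_hand_average(toy_matrix):
    ids = ["acc0", "acc1", "acc2"]
    pairs = [
        pairwise_distance(toy_matrix, a, b, "MR")
        for a, b in [("acc0", "acc1"), ("acc0", "acc2"), ("acc1", "acc2")]
    ]
    assert objective_value(toy_matrix, ids, "MR") == pytest.approx(np.mean(pairs))


def test_objective_validation(toy_matrix):
    with pytest.raises(ValueError, match=">= 2"):
        objective_value(toy_matrix, ["acc0"], "MR")
    with pytest.raises(ValueError, match="empty"):
        objective_value(toy_matrix, [], "SWI")
    with pytest.raises(ValueError, match="objective"):
        objective_value(toy_matrix, ["acc0"], "XX")


def test_private_allele_carrier_always_selected():
    # accession X carries the only copies of 3 private alleles
    # only two distinct genotypes besides X, so a size-3 subset can hold a
    # third allele per locus only by including X
    calls = np.array(
        [
            [101, 201, 301],
            [101, 201, 301],
            [101, 201, 301],
            [103, 203, 303],
            [103, 203, 303],
            [999, 997, 995],  # X
        ]
    )
    m = GenotypeMatrix([f"a{i}" for i in range(5)] + ["X"], ["l1", "l2", "l3"], calls)
    ids, best = exhaustive_core(m, 3, "SWI")
    assert "X" in ids
    cs = select_core(m, 3, objective="SWI", restarts=4, seed=0)
    assert "X" in cs.accession_ids
    assert cs.objective_value == pytest.approx(best, abs=1e-12)


@given(st.integers(0, 10_000))
@settings(max_examples=15)
def test_local_search_matches_exhaustive_on_toys(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(6, 12))
    L = int(rng.integers(3, 7))
    calls = rng.integers(1, 5, size=(n, L)) * 2 + 100
    calls[rng.random((n, L)) < 0.1] = MISSING_CODE
    m = GenotypeMatrix([f"a{i}" for i in range(n)], [f"l{j}" for j in range(L)], calls)
    size = int(rng.integers(2, min(6, n - 1) + 1))
    objective = ["SWI", "NE", "MR", "CE"][seed % 4]
    _, best = exhaustive_core(m, size, objective)
    cs = select_core(m, size, objective=objective, restarts=4, seed=seed)
    assert cs.objective_value == pytest.approx(best, abs=1e-9)


def test_select_core_beats_random_subsets():
    rng = np.random.default_rng(7)
    calls = rng.integers(1, 10, size=(50, 20)) * 2 + 100
    m = GenotypeMatrix([f"a{i}" for i in range(50)], [f"l{j}" for j in range(20)], calls)
    cs = select_core(m, 10, objective="SWI", restarts=2, seed=1)
    rand_best = max(
        objective_value(m, list(rng.choice(50, size=10, replace=False)), "SWI")
        for _ in range(100)
    )
    assert cs.objective_value >= rand_best


def test_select_core_full_set_and_initial_subset(toy_matrix):
    cs = select_core(toy_matrix, toy_matrix.n_accessions, objective="SWI", seed=0)
    assert cs.accession_ids == toy_matrix.accession_ids
    init = ["acc0", "acc1", "acc2"]
    cs = select_core(
        toy_matrix, 3, objective="SWI", restarts=0, seed=0, initial_subset=init
    )
    assert cs.objective_value >= objective_value(toy_matrix, init, "SWI")
    with pytest.raises(ValueError, match="infeasible"):
        select_core(toy_matrix, 1, seed=0)


def test_annealing_never_below_plain_search_floor(toy_matrix):
    cs = select_core(toy_matrix, 3, objective="MR", restarts=2, seed=3,
                     anneal=True, anneal_steps=500)
    _, best = exhaustive_core(toy_matrix, 3, "MR")
    assert cs.objective_value <= best + 1e-12
    assert cs.objective_value > 0


def test_retained_diversity_identity_and_degenerate(toy_matrix):
    ret = retained_diversity(toy_matrix, toy_matrix.accession_ids)
    for k in ("retained_d_Nei_pct", "retained_d_SWI_pct", "retained_d_AR_pct"):
        assert ret[k] == pytest.approx(100.0)
    clones = GenotypeMatrix(
        ["c1", "c2", "c3"], ["l1"], np.array([[101], [101], [101]])
    )
    full = GenotypeMatrix(
        ["c1", "c2", "c3"], ["l1"], np.array([[101], [103], [105]])
    )
    ret = retained_diversity(full, ["c1"])
    assert ret["retained_d_Nei_pct"] == 0.0 and ret["retained_d_SWI_pct"] == 0.0


def test_retained_allele_count_monotone_under_superset():
    rng = np.random.default_rng(11)
    calls = rng.integers(1, 8, size=(30, 10)) * 2 + 100
    m = GenotypeMatrix([f"a{i}" for i in range(30)], [f"l{j}" for j in range(10)], calls)
    small = m.accession_ids[:5]
    larger = m.accession_ids[:15]
    r_small = retained_diversity(m, small)
    r_large = retained_diversity(m, larger)
    assert r_large["core_d_AR_total"] >= r_small["core_d_AR_total"]
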
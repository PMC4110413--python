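import itertools
import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from ssrpop import (
    GenotypeMatrix,
    MISSING_CODE,
    allele_frequencies,
    diversity_indices,
    diversity_table,
    genome_partition_diversity,
    phenotype_swi,
    rarefied_richness,
    summarize_diversity_table,
)
from ssrpop.diversity import AlleleFrequencies


def freqs_from_counts(counts):
    counts = np.asarray(counts)
    return AlleleFrequencies("x", np.arange(counts.size), counts, int(counts.sum()))


def column_matrix(calls):
    calls = np.asarray(calls).reshape(-1, 1)
    return GenotypeMatrix([f"a{i}" for i in range(len(calls))], ["loc"], calls)


def test_allele_frequencies_drop_missing_keep_null():
    fr = allele_frequencies(column_matrix([101, 101, 103, MISSING_CODE]), "loc")
    assert fr.n == 3
    assert np.allclose(sorted(fr.freqs), [1 / 3, 2 / 3])

    fr = allele_frequencies(column_matrix([101, 0, 0]), "loc")
    assert set(fr.alleles) == {0, 101}
    assert np.allclose(sorted(fr.freqs), [1 / 3, 2 / 3])

    with pytest.raises(ValueError, match="non-missing"):
        allele_frequencies(column_matrix([MISSING_CODE, MISSING_CODE]), "loc")


@pytest.mark.parametrize(
    "counts,expected",
    [
        # (d_AR, d_RAR, d_Nei, d_PIC, d_SWI)
        ([10], (1, 0, 0.0, 0.0, 0.0)),
        ([5, 5], (2, 0, 0.5, 0.375, math.log(2))),
        ([9, 1], (2, 0, 0.18, 0.1638, 0.3251)),
        ([3, 3, 3, 3], (4, 0, 0.75, 0.7031, math.log(4))),
    ],
)
def test_diversity_indices_hand_values(counts, expected):
    idx = diversity_indices(freqs_from_counts(counts))
    assert idx["d_AR"] == expected[0]
    assert idx["d_RAR"] == expected[1]
    assert idx["d_Nei"] == pytest.approx(expected[2], abs=1e-4)
    assert idx["d_PIC"] == pytest.approx(expected[3], abs=1e-4)
    assert idx["d_SWI"] == pytest.approx(expected[4], abs=1e-4)


def test_rare_allele_threshold():
    idx = diversity_indices(freqs_from_counts([96, 2, 2]), rare_threshold=0.05)
    assert idx["d_RAR"] == 2


@given(
    st.lists(st.floats(0.01, 1.0), min_size=1, max_size=12).map(
        lambda w: np.array(w) / np.sum(w)
    )
)
def test_index_inequalities_on_random_simplex(p):
    counts = np.round(p * 10_000).astype(int)
    counts = counts[counts > 0]
    idx = diversity_indices(freqs_from_counts(counts))
    assert 0.0 <= idx["d_PIC"] <= idx["d_Nei"] + 1e-12 < 1.0
    assert idx["d_SWI"] <= math.log(idx["d_AR"]) + 1e-9


def test_indices_invariant_under_allele_relabeling():
    calls = np.array([101, 101, 103, 105, 105, 105])
    relabeled = np.array([999, 999, 1, 42, 42, 42])
    a = diversity_indices(allele_frequencies(column_matrix(calls), "loc"))
    b = diversity_indices(allele_frequencies(column_matrix(relabeled), "loc"))
    assert a == b


def brute_force_rarefaction(counts, g):
    """Mean distinct-allele count over all C(n, g) subsamples."""
    pool = [a for a, c in enumerate(counts) for _ in range(c)]
    vals = [len(set(combo)) for combo in itertools.combinations(pool, g)]
    return float(np.mean(vals))


def test_rarefaction_matches_brute_force_enumeration():
    assert rarefied_richness([5, 3, 2], 2) == pytest.approx(76 / 45, abs=1e-12)
    rng = np.random.default_rng(0)
    for _ in range(10):
        k = int(rng.integers(1, 5))
        counts = rng.integers(1, 5, size=k)
        n = int(counts.sum())
        if n > 12:
            continue
        for g in range(1, n + 1):
            assert rarefied_richness(counts, g) == pytest.approx(
                brute_force_rarefaction(counts, g), abs=1e-9
            )


def test_rarefaction_edge_cases_and_monotonicity():
    counts = [7, 5, 3, 1]
    n = sum(counts)
    assert rarefied_richness(counts, 1) == pytest.approx(1.0)
    assert rarefied_richness(counts, n) == pytest.approx(4.0)
    vals = [rarefied_richness(counts, g) for g in range(1, n + 1)]
    assert all(b >= a - 1e-12 for a, b in zip(vals, vals[1:]))
    with pytest.raises(ValueError):
        rarefied_richness(counts, 0)
    with pytest.raises(ValueError):
        rarefied_richness(counts, n + 1)


def test_rarefaction_matches_monte_carlo():
    rng = np.random.default_rng(1)
    counts = rng.integers(1, 40, size=8)
    pool = np.repeat(np.arange(8), counts)
    g = 15
    draws = np.array(
        [len(np.unique(rng.choice(pool, size=g, replace=False))) for _ in range(10_000)]
    )
    se = draws.std(ddof=1) / np.sqrt(draws.size)
    assert abs(rarefied_richness(counts, g) - draws.mean()) < 3 * se


def test_diversity_table_rows_and_summary():
    calls = np.array([[101, 101], [101, 101], [103, 103], [MISSING_CODE, MISSING_CODE]])
    m = GenotypeMatrix(["a", "b", "c", "d"], ["l1", "l2"], calls)
    table = diversity_table(m)
    body = table[~table["locus"].isin(("mean", "min", "max"))]
    # identical call columns give identical index rows
    assert body.iloc[0][["d_AR", "d_Nei", "d_SWI"]].equals(
        body.iloc[1][["d_AR", "d_Nei", "d_SWI"]]
    )
    summary = summarize_diversity_table(table)
    mean_row = summary[summary["locus"] == "mean"].iloc[0]
    assert mean_row["d_Nei"] == pytest.approx(body["d_Nei"].mean())
    with pytest.raises(ValueError, match="no loci"):
        summarize_diversity_table(table, subset=["nope"])


def test_phenotype_swi_binning():
    # all values in one class
    res = phenotype_swi({"T1": np.full(10, 3.0), "T2": np.linspace(0, 12, 10)})
    assert res["per_trial"].set_index("trial").loc["T1", "d_SWIp"] == pytest.approx(0.0)

    # equal counts in all 12 classes -> ln 12
    vals = np.repeat(np.arange(12) + 0.5, 5)
    res = phenotype_swi({"T1": vals})
    assert res["per_trial"]["d_SWIp"].iloc[0] == pytest.approx(math.log(12), abs=1e-9)

    # 24 values split equally over two occupied classes -> ln 2
    vals = np.concatenate([np.full(12, 0.25), np.full(12, 6.25)])
    res = phenotype_swi({"T1": vals})
    assert res["per_trial"]["d_SWIp"].iloc[0] == pytest.approx(math.log(2), abs=1e-9)


def test_phenotype_swi_constant_trait_warns_zero():
    with pytest.warns(UserWarning, match="constant"):
        res = phenotype_swi({"T1": np.full(5, 1.0)})
    assert (res["per_trial"]["d_SWIp"] == 0.0).all()


def test_genome_partition_constant_index_and_convergence():
    import pandas as pd
    from ssrpop import marker_info

    # 10 loci per genome, constant index value v per genome
    rows = []
    labels = {}
    for gi, genome in enumerate("ABD"):
        for j in range(10):
            name = f"{genome.lower()}{j}"
            rows.append({"locus": name, "chromosome_label": f"1{genome}",
                         "missing_pct": 0.0, "d_AR": 2, "d_RAR": 0,
                         "d_rarefied": 2.0, "d_Nei": 0.5, "d_PIC": 0.4,
                         "d_SWI": float(gi + 1)})
            labels[name] = f"1{genome}"
    table = pd.DataFrame(rows)
    m = GenotypeMatrix(
        ["x", "y"], list(labels), np.full((2, len(labels)), 101, dtype=int)
    )
    info = marker_info(m, labels)
    res = genome_partition_diversity(
        table, info, index_cols=("d_SWI",), subsample_size=8, reps=50, seed=0
    ).set_index("genome")
    for gi, genome in enumerate("ABD"):
        assert res.loc[genome, "d_SWI_full_mean"] == pytest.approx(gi + 1)
        assert res.loc[genome, "d_SWI_subsample_mean"] == pytest.approx(gi + 1)

    # varying values: subsample mean approaches the full mean with many reps
    rng = np.random.default_rng(2)
    table.loc[table.index[:10], "d_SWI"] = rng.uniform(0.5, 3.0, size=10)
    res = genome_partition_diversity(
        table, info, index_cols=("d_SWI",), subsample_size=8, reps=10_000, seed=3
    ).set_index("genome")
    assert res.loc["A", "d_SWI_subsample_mean"] == pytest.approx(
        res.loc["A", "d_SWI_full_mean"], abs=0.02
    )


def test_genome_partition_too_few_loci():
    import pandas as pd
    from ssrpop import marker_info

    m = GenotypeMatrix(["x", "y"], ["a1"], np.full((2, 1), 101, dtype=int))
    info = marker_info(m, {"a1": "1A"})
    table = pd.DataFrame(
        [{"locus": "a1", "chromosome_label": "1A", "missing_pct": 0.0,
          "d_AR": 2, "d_RAR": 0, "d_rarefied": 2.0, "d_Nei": 0.5,
          "d_PIC": 0.4, "d_SWI": 0.7}]
    )
    with pytest.raises(ValueError, match="genome A"):
        genome_partition_diversity(table, info, subsample_size=8)
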
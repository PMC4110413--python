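"""Diversity-maximizing core-collection selection.

A core set is a subset of accessions chosen to retain as much of a
collection's genetic diversity as possible.  Four objectives are supported,
all oriented to maximize:

* ``SWI`` — mean per-locus Shannon–Weaver index of the subset;
* ``NE``  — mean per-locus number of effective alleles, ``1 / sum p_a^2``;
* ``MR``  — mean pairwise Modified Rogers distance within the subset;
* ``CE``  — mean pairwise Cavalli-Sforza & Edwards distance.

For fully homozygous lines each accession's within-accession allele
frequency is 0/1, so MR and CE coincide:
``sqrt(#differing shared loci / #shared loci)``.

The optimizer is a steepest-ascent single-swap local search with random
restarts; swap deltas are evaluated incrementally (allele-count updates for
frequency objectives, distance-row sums for distance objectives), so a full
neighborhood scan is cheap even for collection-scale inputs.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import xlogy

from .io import GenotypeMatrix, MISSING_CODE
from .diversity import allele_frequencies, diversity_indices

FREQ_OBJECTIVES = ("SWI", "NE")
DIST_OBJECTIVES = ("MR", "CE")
OBJECTIVES = FREQ_OBJECTIVES + DIST_OBJECTIVES


@dataclass
class CoreSet:
    accession_ids: list[str]
    size: int
    objective: str
    objective_value: float
    objective_values: dict[str, float]
    trajectory: list[float]
    retained_percent: dict[str, float] = field(default_factory=dict)


def pairwise_distance(
    matrix: GenotypeMatrix, i: int | str, j: int | str, metric: str = "MR"
) -> float:
    """MR or CE genetic distance between two accessions, in [0, 1].

    Only mutually non-missing loci enter; with one allele copy per
    accession both metrics reduce to the square root of the fraction of
    shared loci at which the alleles differ.
    """
    if metric not in DIST_OBJECTIVES:
        raise ValueError(f"metric must be one of {DIST_OBJECTIVES}")
    if isinstance(i, str):
        i = matrix.accession_index(i)
    if isinstance(j, str):
        j = matrix.accession_index(j)
    a, b = matrix.calls[i], matrix.calls[j]
    shared = (a != MISSING_CODE) & (b != MISSING_CODE)
    L = int(shared.sum())
    if L == 0:
        raise ValueError("accessions share no mutually non-missing locus")
    ndiff = int(((a != b) & shared).sum())
    return float(np.sqrt(ndiff / L))


def distance_matrix(matrix: GenotypeMatrix, metric: str = "MR") -> np.ndarray:
    """Full pairwise MR/CE distance matrix (vectorized)."""
    if metric not in DIST_OBJECTIVES:
        raise ValueError(f"metric must be one of {DIST_OBJECTIVES}")
    calls = matrix.calls
    present = calls != MISSING_CODE
    shared = present.astype(np.int32) @ present.astype(np.int32).T
    same = np.zeros_like(shared)
    # accumulate per locus to keep memory modest
    for l in range(calls.shape[1]):
        col = calls[:, l]
        ok = present[:, l]
        eq = (col[:, None] == col[None, :]) & ok[:, None] & ok[None, :]
        same += eq.astype(np.int32)
    with np.errstate(invalid="ignore", divide="ignore"):
        d = np.sqrt((shared - same) / np.maximum(shared, 1))
    d[shared == 0] = np.nan
    np.fill_diagonal(d, 0.0)
    return d


def _onehot_counts(matrix: GenotypeMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Per-accession allele-index codes and the per-locus allele counts.

    Returns ``codes`` (n, L) with -1 for missing, and ``n_alleles`` (L,).
    """
    n, L = matrix.calls.shape
    codes = np.full((n, L), -1, dtype=np.int64)
    n_alleles = np.zeros(L, dtype=np.int64)
    for l in range(L):
        col = matrix.calls[:, l]
        alleles = sorted(set(col[col != MISSING_CODE].tolist()))
        amap = {a: k for k, a in enumerate(alleles)}
        n_alleles[l] = len(alleles)
        for i in range(n):
            if col[i] != MISSING_CODE:
                codes[i, l] = amap[col[i]]
    return codes, n_alleles


class _FreqState:
    """Incremental SWI/NE evaluation over allele counts of the subset."""

    def __init__(self, codes: np.ndarray, n_alleles: np.ndarray, objective: str):
        self.codes = codes
        self.A = int(n_alleles.max())
        self.L = codes.shape[1]
        self.objective = objective
        self.lrange = np.arange(self.L)

    def set_subset(self, subset: np.ndarray) -> None:
        self.subset = np.asarray(subset, dtype=np.int64)
        C = np.zeros((self.L, self.A), dtype=np.int64)
        for i in self.subset:
            row = self.codes[i]
            ok = row >= 0
            np.add.at(C, (self.lrange[ok], row[ok]), 1)
        self.C = C
        self.N = C.sum(axis=1)

    @staticmethod
    def _swi_from(C: np.ndarray, N: np.ndarray) -> float:
        # -sum (c/N) log(c/N) = log N - (sum c log c)/N, per locus
        S = xlogy(C, C).sum(axis=-1)
        with np.errstate(divide="ignore", invalid="ignore"):
            per_locus = np.where(N > 0, np.log(np.maximum(N, 1)) - S / np.maximum(N, 1), 0.0)
        return float(per_locus.mean())

    @staticmethod
    def _ne_from(C: np.ndarray, N: np.ndarray) -> float:
        sum2 = (C.astype(float) ** 2).sum(axis=-1)
        with np.errstate(divide="ignore", invalid="ignore"):
            per_locus = np.where(N > 0, (N.astype(float) ** 2) / np.maximum(sum2, 1e-300), 1.0)
        return float(per_locus.mean())

    def value(self) -> float:
        fn = self._swi_from if self.objective == "SWI" else self._ne_from
        return fn(self.C, self.N)

    def eval_swaps(self, out_idx: int, cand: np.ndarray) -> np.ndarray:
        """Objective after swapping subset member out_idx for each candidate."""
        i = self.subset[out_idx]
        row_i = self.codes[i]
        ok_i = row_i >= 0
        C_i = self.C.copy()
        C_i[self.lrange[ok_i], row_i[ok_i]] -= 1
        N_i = self.N - ok_i.astype(np.int64)
        rows_j = self.codes[cand]  # (m, L)
        ok_j = rows_j >= 0
        gathered = np.where(
            ok_j, C_i[self.lrange[None, :], np.maximum(rows_j, 0)], 0
        ).astype(float)  # count of candidate's allele before adding it
        N_new = N_i[None, :] + ok_j
        if self.objective == "SWI":
            S_i = xlogy(C_i, C_i).sum(axis=1)  # (L,)
            dS = xlogy(gathered + 1, gathered + 1) - xlogy(gathered, gathered)
            S_new = S_i[None, :] + np.where(ok_j, dS, 0.0)
            with np.errstate(divide="ignore", invalid="ignore"):
                per_locus = np.where(
                    N_new > 0,
                    np.log(np.maximum(N_new, 1)) - S_new / np.maximum(N_new, 1),
                    0.0,
                )
            return per_locus.mean(axis=1)
        else:  # NE
            sum2_i = (C_i.astype(float) ** 2).sum(axis=1)
            d2 = (gathered + 1) ** 2 - gathered**2
            sum2_new = sum2_i[None, :] + np.where(ok_j, d2, 0.0)
            with np.errstate(divide="ignore", invalid="ignore"):
                per_locus = np.where(
                    N_new > 0,
                    (N_new.astype(float) ** 2) / np.maximum(sum2_new, 1e-300),
                    1.0,
                )
            return per_locus.mean(axis=1)

    def apply_swap(self, out_idx: int, j: int) -> None:
        i = self.subset[out_idx]
        row = self.codes[i]
        ok = row >= 0
        self.C[self.lrange[ok], row[ok]] -= 1
        self.N -= ok.astype(np.int64)
        row = self.codes[j]
        ok = row >= 0
        self.C[self.lrange[ok], row[ok]] += 1
        self.N += ok.astype(np.int64)
        self.subset[out_idx] = j


class _DistState:
    """Incremental mean-pairwise-distance evaluation (MR/CE)."""

    def __init__(self, D: np.ndarray):
        self.D = D

    def set_subset(self, subset: np.ndarray) -> None:
        self.subset = np.asarray(subset, dtype=np.int64)
        sub = self.D[np.ix_(self.subset, self.subset)]
        self.total = float(sub.sum()) / 2.0
        self.rowsum = self.D[:, self.subset].sum(axis=1)  # vs all accessions

    def _npairs(self) -> int:
        s = self.subset.size
        return s * (s - 1) // 2

    def value(self) -> float:
        return self.total / self._npairs()

    def eval_swaps(self, out_idx: int, cand: np.ndarray) -> np.ndarray:
        i = self.subset[out_idx]
        base = self.total - self.rowsum[i]
        add = self.rowsum[cand] - self.D[cand, i]
        return (base + add) / self._npairs()

    def apply_swap(self, out_idx: int, j: int) -> None:
        i = self.subset[out_idx]
        self.total += self.rowsum[j] - self.D[j, i] - self.rowsum[i]
        self.rowsum += self.D[:, j] - self.D[:, i]
        self.subset[out_idx] = j


def objective_value(
    matrix: GenotypeMatrix, subset: list[str] | list[int], objective: str
) -> float:
    """Evaluate one objective on an accession subset."""
    if objective not in OBJECTIVES:
        raise ValueError(f"objective must be one of {OBJECTIVES}")
    if len(subset) == 0:
        raise ValueError("subset is empty")
    idx = np.array(
        [matrix.accession_index(a) if isinstance(a, str) else int(a) for a in subset]
    )
    if objective in DIST_OBJECTIVES:
        if idx.size < 2:
            raise ValueError("distance objectives need >= 2 accessions")
        D = distance_matrix(matrix, metric=objective)
        sub = D[np.ix_(idx, idx)]
        return float(sub.sum() / (idx.size * (idx.size - 1)))
    sub = matrix.subset(accessions=[matrix.accession_ids[i] for i in idx])
    vals = []
    for locus in sub.locus_names:
        try:
            fr = allele_frequencies(sub, locus)
        except ValueError:
            # all calls missing within the subset: no diversity observable
            vals.append(0.0 if objective == "SWI" else 1.0)
            continue
        p = fr.freqs
        if objective == "SWI":
            vals.append(float(-xlogy(p, p).sum()))
        else:
            vals.append(float(1.0 / (p**2).sum()))
    return float(np.mean(vals))


def _make_state(matrix: GenotypeMatrix, objective: str):
    if objective in FREQ_OBJECTIVES:
        codes, n_alleles = _onehot_counts(matrix)
        return _FreqState(codes, n_alleles, objective)
    return _DistState(distance_matrix(matrix, metric=objective))


def select_core(
    matrix: GenotypeMatrix,
    size: int,
    objective: str = "SWI",
    restarts: int = 3,
    max_no_improve: int = 1,
    seed: int = 0,
    initial_subset: list[str] | None = None,
    anneal: bool = False,
    anneal_steps: int = 20_000,
    t0: float = 0.05,
) -> CoreSet:
    """Select a diversity-maximizing core subset by local search.

    Steepest-ascent over the single-swap neighborhood from ``restarts``
    random starts (plus ``initial_subset`` as an extra start when given);
    the result never scores below its initialization.  With
    ``anneal=True`` a simulated-annealing pass (geometric cooling from
    ``t0``) precedes the ascent on each restart.  Deterministic given
    ``seed``.
    """
    n = matrix.n_accessions
    if objective not in OBJECTIVES:
        raise ValueError(f"objective must be one of {OBJECTIVES}")
    if not 2 <= size <= n:
        raise ValueError(f"infeasible core size {size} for {n} accessions")
    if size == n:
        ids = list(matrix.accession_ids)
        val = objective_value(matrix, ids, objective)
        return CoreSet(ids, size, objective, val, _all_objectives(matrix, ids), [val])
    rng = np.random.default_rng(seed)
    state = _make_state(matrix, objective)
    all_idx = np.arange(n)

    starts: list[np.ndarray] = []
    if initial_subset is not None:
        starts.append(
            np.array([matrix.accession_index(a) for a in initial_subset])
        )
    for _ in range(max(restarts, 0 if starts else 1)):
        starts.append(rng.choice(n, size=size, replace=False))

    best_subset = None
    best_val = -np.inf
    best_traj: list[float] = []
    for start in starts:
        state.set_subset(start.copy())
        if anneal:
            _anneal(state, all_idx, rng, anneal_steps, t0)
        traj = [state.value()]
        no_improve = 0
        while no_improve < max_no_improve:
            cur = state.value()
            in_set = np.zeros(n, dtype=bool)
            in_set[state.subset] = True
            cand = all_idx[~in_set]
            move = None
            move_val = cur
            for out_idx in range(size):
                vals = state.eval_swaps(out_idx, cand)
                k = int(np.argmax(vals))
                if vals[k] > move_val + 1e-12:
                    move_val = float(vals[k])
                    move = (out_idx, int(cand[k]))
            if move is None:
                no_improve += 1
            else:
                state.apply_swap(*move)
                traj.append(move_val)
                no_improve = 0
        val = state.value()
        if val > best_val:
            best_val = val
            best_subset = state.subset.copy()
            best_traj = traj
    ids = [matrix.accession_ids[i] for i in sorted(best_subset)]
    return CoreSet(
        accession_ids=ids,
        size=size,
        objective=objective,
        objective_value=float(best_val),
        objective_values=_all_objectives(matrix, ids),
        trajectory=best_traj,
    )


def _anneal(state, all_idx, rng, steps: int, t0: float) -> None:
    n = all_idx.size
    size = state.subset.size
    cur = state.value()
    for t in range(steps):
        temp = t0 * (0.999 ** t)
        out_idx = int(rng.integers(size))
        j = int(rng.integers(n))
        if j in state.subset:
            continue
        val = float(state.eval_swaps(out_idx, np.array([j]))[0])
        if val > cur or rng.random() < np.exp((val - cur) / max(temp, 1e-9)):
            state.apply_swap(out_idx, j)
            cur = val


def _all_objectives(matrix: GenotypeMatrix, ids: list[str]) -> dict[str, float]:
    out = {}
    for obj in OBJECTIVES:
        try:
            out[obj] = objective_value(matrix, ids, obj)
        except ValueError:
            out[obj] = float("nan")
    return out


def exhaustive_core(
    matrix: GenotypeMatrix, size: int, objective: str
) -> tuple[list[str], float]:
    """Brute-force optimum over all subsets (small instances only)."""
    n = matrix.n_accessions
    if n > 20:
        raise ValueError("exhaustive search is for toy instances")
    best, best_val = None, -np.inf
    for combo in itertools.combinations(range(n), size):
        val = objective_value(matrix, list(combo), objective)
        if val > best_val:
            best_val, best = val, combo
    return [matrix.accession_ids[i] for i in best], float(best_val)


def retained_diversity(
    matrix: GenotypeMatrix, core_ids: list[str], rare_threshold: float = 0.05
) -> dict[str, float]:
    """Percent of the full collection's diversity retained by a core.

    For d_Nei and d_SWI: 100 x (mean per-locus index on the core) / (mean
    on the full collection).  Allele counts (d_AR, d_RAR) are reported as
    totals for core and full set plus their ratio, since rare alleles are
    what a small core chiefly loses.
    """
    sub = matrix.subset(accessions=core_ids)
    full_vals = {"d_Nei": [], "d_SWI": []}
    core_vals = {"d_Nei": [], "d_SWI": []}
    full_ar = full_rar = core_ar = core_rar = 0
    for locus in matrix.locus_names:
        f_full = allele_frequencies(matrix, locus)
        i_full = diversity_indices(f_full, rare_threshold)
        try:
            f_core = allele_frequencies(sub, locus)
            i_core = diversity_indices(f_core, rare_threshold)
        except ValueError:  # all-missing in the core at this locus
            i_core = {k: 0.0 for k in i_full}
        for k in ("d_Nei", "d_SWI"):
            full_vals[k].append(i_full[k])
            core_vals[k].append(i_core[k])
        full_ar += i_full["d_AR"]
        full_rar += i_full["d_RAR"]
        core_ar += i_core["d_AR"]
        core_rar += i_core["d_RAR"]
    out: dict[str, float] = {}
    for k in ("d_Nei", "d_SWI"):
        denom = float(np.mean(full_vals[k]))
        out[f"retained_{k}_pct"] = (
            100.0 * float(np.mean(core_vals[k])) / denom if denom > 0 else 100.0
        )
    out["full_d_AR_total"] = float(full_ar)
    out["core_d_AR_total"] = float(core_ar)
    out["retained_d_AR_pct"] = 100.0 * core_ar / full_ar if full_ar else 100.0
    out["full_d_RAR_total"] = float(full_rar)
    out["core_d_RAR_total"] = float(core_rar)
    out["retained_d_RAR_pct"] = 100.0 * core_rar / full_rar if full_rar else 100.0
    return out
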
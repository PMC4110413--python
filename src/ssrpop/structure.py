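"""Bayesian admixture clustering of multi-allelic haploid genotypes.

The model is the classic admixture mixture model: accession ``i`` has
ancestry proportions ``q_i`` (Dirichlet(alpha) prior) over ``K`` ancestral
clusters, cluster ``k`` has allele frequencies ``p_kl`` at locus ``l``
(Dirichlet(lambda) prior), and each observed allele is drawn by first
sampling an origin cluster ``Z_il ~ q_i`` and then an allele from
``p_{Z_il, l}``.  Because the lines are inbred single-seed descendants, one
allele copy per locus is modelled (no heterozygotes).  Inference is by
Gibbs sampling over ``(Z, Q, P)``; missing calls are skipped, NULL alleles
are ordinary allele states.

Model order is chosen with the Evanno delta-K statistic: with ``L_K`` the
per-run estimate of ln P(Data | K) (posterior mean log-likelihood minus
half its variance), ``deltaK = mean_r |L''_r(K)| / sd_r(L_K)`` over
replicate runs, where ``L''`` is the second difference of ``L`` in K.
A two-level hierarchical analysis re-runs the whole procedure inside each
top-level group.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .io import GenotypeMatrix, MISSING_CODE


@dataclass
class StructureRun:
    """One Gibbs-sampling run at fixed K."""

    K: int
    accession_ids: list[str]
    Q: np.ndarray  # (n, K) posterior-mean ancestry, rows sum to 1
    P: np.ndarray  # (K, L, A_max) posterior-mean cluster allele freqs
    loglik_trace: np.ndarray  # post-burn-in data log-likelihood per iteration
    L_K: float  # estimated ln P(Data | K)
    seed: int
    burnin: int
    iters: int


def _encode(matrix: GenotypeMatrix) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, int]:
    """Flatten non-missing calls to (i, l, allele-index) triplets."""
    n, L = matrix.calls.shape
    allele_index: list[dict[int, int]] = []
    n_alleles = np.zeros(L, dtype=np.int64)
    cols = []
    for l in range(L):
        col = matrix.calls[:, l]
        codes = sorted(set(col[col != MISSING_CODE].tolist()))
        allele_index.append({c: k for k, c in enumerate(codes)})
        n_alleles[l] = len(codes)
        cols.append(col)
    A = int(n_alleles.max()) if L else 0
    obs_i, obs_l, obs_a = [], [], []
    for l in range(L):
        col = cols[l]
        idx = np.flatnonzero(col != MISSING_CODE)
        obs_i.append(idx)
        obs_l.append(np.full(idx.size, l, dtype=np.int64))
        amap = allele_index[l]
        obs_a.append(np.array([amap[c] for c in col[idx]], dtype=np.int64))
    return (
        np.concatenate(obs_i) if L else np.array([], int),
        np.concatenate(obs_l) if L else np.array([], int),
        np.concatenate(obs_a) if L else np.array([], int),
        n_alleles,
        A,
    )


def run_admixture(
    matrix: GenotypeMatrix,
    K: int,
    burnin: int = 10_000,
    iters: int = 50_000,
    alpha: float = 1.0,
    lam: float = 1.0,
    seed: int = 0,
) -> StructureRun:
    """Gibbs-sample the admixture model at fixed K.

    ``iters`` counts post-burn-in sweeps.  Each sweep samples origins Z
    given (Q, P), then Q given Z (Dirichlet(alpha + counts)) and P given Z
    (Dirichlet(lambda + counts)).  The returned Q and P are posterior means
    over the post-burn-in sweeps; ``L_K`` is the mean log-likelihood minus
    half its variance.  Deterministic given ``seed``.
    """
    n, L = matrix.calls.shape
    if K < 1:
        raise ValueError("K must be >= 1")
    if K > n:
        raise ValueError(f"K={K} exceeds the number of accessions ({n})")
    if n < 2:
        raise ValueError("need at least 2 accessions")
    rng = np.random.default_rng(seed)
    obs_i, obs_l, obs_a, n_alleles, A = _encode(matrix)
    n_obs = obs_i.size

    valid = np.zeros((L, A), dtype=bool)
    for l in range(L):
        valid[l, : n_alleles[l]] = True
    p_prior = np.where(valid, lam, 0.0)[None, :, :] * np.ones((K, 1, 1))

    # initialization: uniform Q, prior draw for P
    Q = np.full((n, K), 1.0 / K)
    P = rng.standard_gamma(p_prior)
    P /= P.sum(axis=2, keepdims=True)

    Q_sum = np.zeros_like(Q)
    P_sum = np.zeros_like(P)
    trace = np.empty(iters)
    flat_la = obs_l * A + obs_a

    for it in range(burnin + iters):
        # P gathered at the observed (locus, allele) cells: (K, n_obs)
        Pobs = P.reshape(K, L * A)[:, flat_la]
        W = Q[obs_i].T * Pobs
        tot = W.sum(axis=0)
        ll = float(np.log(tot).sum())
        # sample origins Z
        cum = np.cumsum(W, axis=0)
        u = rng.random(n_obs) * tot
        Z = (cum <= u[None, :]).sum(axis=0)
        np.minimum(Z, K - 1, out=Z)
        # Q | Z
        cnt_ik = np.bincount(obs_i * K + Z, minlength=n * K).reshape(n, K)
        Q = rng.standard_gamma(alpha + cnt_ik)
        Q /= Q.sum(axis=1, keepdims=True)
        # P | Z
        cnt_kla = np.bincount(Z * (L * A) + flat_la, minlength=K * L * A).reshape(
            K, L, A
        )
        P = rng.standard_gamma(p_prior + cnt_kla)
        P /= np.maximum(P.sum(axis=2, keepdims=True), 1e-300)
        if it >= burnin:
            Q_sum += Q
            P_sum += P
            trace[it - burnin] = ll

    Q_mean = Q_sum / iters
    P_mean = P_sum / iters
    L_K = float(trace.mean() - trace.var() / 2.0)
    return StructureRun(
        K=K,
        accession_ids=list(matrix.accession_ids),
        Q=Q_mean,
        P=P_mean,
        loglik_trace=trace,
        L_K=L_K,
        seed=seed,
        burnin=burnin,
        iters=iters,
    )


def _match_permutation(Q_ref: np.ndarray, Q: np.ndarray) -> np.ndarray:
    """Column permutation of Q minimizing Frobenius distance to Q_ref."""
    K = Q.shape[1]
    cost = np.empty((K, K))
    for a in range(K):
        for b in range(K):
            cost[a, b] = float(((Q_ref[:, a] - Q[:, b]) ** 2).sum())
    _, perm = linear_sum_assignment(cost)
    return perm


def align_runs(runs: list[StructureRun]) -> list[StructureRun]:
    """Permute each run's cluster labels to match the first run.

    Label switching makes cluster indices arbitrary per run; the optimal
    column matching (Hungarian assignment on squared distances of Q
    columns) is applied to both Q and P.
    """
    if not runs:
        return []
    K = runs[0].K
    for r in runs:
        if r.K != K:
            raise ValueError("all runs must share K")
    ref = runs[0].Q
    out = [runs[0]]
    for r in runs[1:]:
        perm = _match_permutation(ref, r.Q)
        out.append(
            StructureRun(
                K=r.K,
                accession_ids=r.accession_ids,
                Q=r.Q[:, perm],
                P=r.P[perm],
                loglik_trace=r.loglik_trace,
                L_K=r.L_K,
                seed=r.seed,
                burnin=r.burnin,
                iters=r.iters,
            )
        )
    return out


def mean_q(runs: list[StructureRun]) -> np.ndarray:
    """Average Q over label-aligned replicate runs."""
    aligned = align_runs(runs)
    return np.mean([r.Q for r in aligned], axis=0)


def evanno_delta_k(L_values: dict[int, list[float]]) -> pd.DataFrame:
    """Evanno delta-K table from replicate L_K values per K.

    Requires >= 3 consecutive K values with >= 2 replicates each.  Per
    replicate r: L'_r(K) = L_r(K) - L_r(K-1) and L''_r(K) =
    |L'_r(K+1) - L'_r(K)|; deltaK = mean_r L''_r(K) / sd_r(L(K)) (sample
    sd).  Endpoints, and interior K with zero replicate sd, have no deltaK
    (NaN, the latter with a warning).
    """
    Ks = sorted(L_values)
    if len(Ks) < 3 or any(b - a != 1 for a, b in zip(Ks, Ks[1:])):
        raise ValueError("need >= 3 consecutive K values")
    reps = {k: len(L_values[k]) for k in Ks}
    if min(reps.values()) < 2:
        raise ValueError("need >= 2 replicates per K")
    r_min = min(reps.values())
    arr = np.array([L_values[k][:r_min] for k in Ks], dtype=float)  # (nK, r)
    rows = []
    for idx, K in enumerate(Ks):
        mean_L = float(arr[idx].mean())
        sd_L = float(arr[idx].std(ddof=1))
        lp = lpp = dk = np.nan
        if idx >= 1:
            lp = float((arr[idx] - arr[idx - 1]).mean())
        if 1 <= idx <= len(Ks) - 2:
            second = np.abs(
                (arr[idx + 1] - arr[idx]) - (arr[idx] - arr[idx - 1])
            )
            lpp = float(second.mean())
            if sd_L > 0:
                dk = lpp / sd_L
            else:
                warnings.warn(
                    f"sd of L(K) is 0 at K={K}; deltaK undefined", stacklevel=2
                )
        rows.append(
            {
                "K": K,
                "mean_L": mean_L,
                "sd_L": sd_L,
                "L_prime": lp,
                "L_doubleprime": lpp,
                "delta_K": dk,
            }
        )
    return pd.DataFrame(rows)


def assign_groups(
    Q: np.ndarray, accession_ids: list[str], level: str = "group"
) -> pd.DataFrame:
    """Label each accession by its argmax ancestry cluster (1-based).

    Ties go to the lowest cluster index with a warning.
    """
    Q = np.asarray(Q, dtype=float)
    labels = np.argmax(Q, axis=1)
    top = Q[np.arange(Q.shape[0]), labels]
    ties = (Q == top[:, None]).sum(axis=1) > 1
    if ties.any():
        warnings.warn(
            f"{int(ties.sum())} accession(s) with tied ancestry; "
            "assigned to the lowest cluster index",
            stacklevel=2,
        )
    return pd.DataFrame(
        {
            "accession_id": accession_ids,
            level: labels + 1,
            "max_ancestry": top,
        }
    )


@dataclass
class StructureLevelResult:
    delta_k: pd.DataFrame
    best_k: int | None
    clear_structure: bool
    mean_Q: np.ndarray
    assignment: pd.DataFrame
    runs_L: dict[int, list[float]]


def analyse_structure_level(
    matrix: GenotypeMatrix,
    k_range: tuple[int, int],
    reps: int = 10,
    burnin: int = 10_000,
    iters: int = 50_000,
    alpha: float = 1.0,
    lam: float = 1.0,
    seed: int = 0,
) -> StructureLevelResult:
    """Run the full model-order selection procedure on one dataset.

    Runs K = 1 .. k_max (K=1 is always included so deltaK is defined at
    K=2 even when the requested range starts there), ``reps`` replicates
    each, picks K* by maximal deltaK, and assigns groups from the aligned
    mean Q at K*.  Structure is reported as "clear" only when the deltaK
    peak is defined and the mean L at K* exceeds the single-population
    L(1) — otherwise a single group is reported rather than forcing a
    split.
    """
    k_lo, k_hi = k_range
    k_hi = min(k_hi, matrix.n_accessions)
    if k_hi < max(2, k_lo):
        raise ValueError("K range too small for this dataset")
    runs_by_k: dict[int, list[StructureRun]] = {}
    ss = np.random.SeedSequence(seed)
    for K in range(1, k_hi + 1):
        child = ss.spawn(1)[0]
        seeds = child.generate_state(reps) % (2**31)
        runs_by_k[K] = [
            run_admixture(
                matrix, K, burnin=burnin, iters=iters, alpha=alpha, lam=lam,
                seed=int(s),
            )
            for s in seeds
        ]
    L_values = {K: [r.L_K for r in rs] for K, rs in runs_by_k.items()}
    dk = evanno_delta_k(L_values)
    interior = dk.dropna(subset=["delta_K"])
    interior = interior[interior["K"] >= 2]
    mean_L = dict(zip(dk["K"], dk["mean_L"]))
    if interior.empty:
        best_k, clear = None, False
    else:
        best_k = int(interior.loc[interior["delta_K"].idxmax(), "K"])
        clear = mean_L[best_k] > mean_L[1]
    if best_k is not None and clear:
        Q = mean_q(runs_by_k[best_k])
    else:
        Q = np.ones((matrix.n_accessions, 1))
    assignment = assign_groups(Q, matrix.accession_ids)
    return StructureLevelResult(
        delta_k=dk,
        best_k=best_k,
        clear_structure=bool(clear),
        mean_Q=Q,
        assignment=assignment,
        runs_L=L_values,
    )


@dataclass
class HierarchicalResult:
    level1: StructureLevelResult
    level2: dict[int, StructureLevelResult]
    assignment: pd.DataFrame  # accession_id, group, subgroup, max_ancestry
    sister_concordance: float | None


def hierarchical_structure(
    matrix: GenotypeMatrix,
    k_range: tuple[int, int] = (2, 25),
    reps: int = 10,
    burnin: int = 10_000,
    iters: int = 50_000,
    alpha: float = 1.0,
    lam: float = 1.0,
    seed: int = 0,
    sister_pairs: list[tuple[str, str]] | None = None,
    min_group_size: int = 10,
) -> HierarchicalResult:
    """Two-level hierarchical admixture analysis.

    Level 1 analyses the full collection (sister lines included), picks K*
    by deltaK and assigns top-level groups.  Level 2 repeats the procedure
    within each level-1 group large enough to analyse (the K range is
    truncated to the group size with a warning if needed).  Also reports
    the fraction of sister pairs whose members share a level-1 group.
    """
    lvl1 = analyse_structure_level(
        matrix, k_range, reps=reps, burnin=burnin, iters=iters,
        alpha=alpha, lam=lam, seed=seed,
    )
    assignment = lvl1.assignment.rename(columns={"group": "group"})
    assignment["subgroup"] = 0
    level2: dict[int, StructureLevelResult] = {}
    for g in sorted(assignment["group"].unique()):
        members = assignment.loc[assignment["group"] == g, "accession_id"].tolist()
        if len(members) < max(min_group_size, 3):
            continue
        sub = matrix.subset(accessions=members)
        k_hi = min(k_range[1], len(members) - 1)
        if k_hi < 2:
            warnings.warn(f"group {g} too small for a level-2 analysis")
            continue
        if k_hi < k_range[1]:
            warnings.warn(f"group {g}: K range truncated to (2, {k_hi})")
        res = analyse_structure_level(
            sub, (2, k_hi), reps=reps, burnin=burnin, iters=iters,
            alpha=alpha, lam=lam, seed=seed + 1000 * int(g),
        )
        level2[int(g)] = res
        sub_map = dict(
            zip(res.assignment["accession_id"], res.assignment["group"])
        )
        mask = assignment["group"] == g
        assignment.loc[mask, "subgroup"] = assignment.loc[
            mask, "accession_id"
        ].map(sub_map)
    concordance = None
    if sister_pairs:
        gmap = dict(zip(assignment["accession_id"], assignment["group"]))
        shared = [gmap[a] == gmap[b] for a, b in sister_pairs if a in gmap and b in gmap]
        concordance = float(np.mean(shared)) if shared else None
    return HierarchicalResult(
        level1=lvl1,
        level2=level2,
        assignment=assignment,
        sister_concordance=concordance,
    )


def q_to_frame(Q: np.ndarray, accession_ids: list[str]) -> pd.DataFrame:
    """Q matrix as a frame (accession, k1..kK) for CSV export."""
    K = Q.shape[1]
    df = pd.DataFrame(Q, columns=[f"k{j + 1}" for j in range(K)])
    df.insert(0, "accession_id", accession_ids)
    return df
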
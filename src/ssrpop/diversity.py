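"""Allele-frequency diversity indices for multi-allelic loci.

Per locus, from allele frequencies ``p_i`` (NULL alleles count as ordinary
alleles; missing calls are dropped from the denominator):

* allele richness ``d_AR`` — number of distinct alleles observed;
* rare alleles ``d_RAR`` — number with ``p_i`` below a threshold
  (default 0.05);
* rarefied richness ``d_r(g)`` — expected distinct alleles in a random
  subsample of ``g`` calls, the hypergeometric rarefaction
  ``sum_i 1 - C(n - n_i, g) / C(n, g)``;
* Nei's gene diversity (expected heterozygosity) ``d_Nei = 1 - sum p_i^2``;
* polymorphic information content
  ``d_PIC = 1 - sum p_i^2 - sum_{i<j} 2 p_i^2 p_j^2``;
* Shannon–Weaver index ``d_SWI = -sum p_i ln p_i`` (natural log).

The same Shannon–Weaver form is applied to phenotype scores after binning
the pooled trait range into equal-width classes (default 12).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln, xlogy

from .io import GenotypeMatrix, MISSING_CODE

SUMMARY_ROWS = ("mean", "min", "max")
INDEX_COLUMNS = ("d_AR", "d_RAR", "d_rarefied", "d_Nei", "d_PIC", "d_SWI")


@dataclass
class AlleleFrequencies:
    locus_name: str
    alleles: np.ndarray  # allele codes (NULL included)
    counts: np.ndarray  # n_i per allele
    n: int  # total non-missing calls

    @property
    def freqs(self) -> np.ndarray:
        return self.counts / self.n


def allele_frequencies(matrix: GenotypeMatrix, locus: str) -> AlleleFrequencies:
    """Observed allele counts/frequencies at a locus (NULL is an allele)."""
    col = matrix.calls[:, matrix.locus_index(locus)]
    observed = col[col != MISSING_CODE]
    if observed.size == 0:
        raise ValueError(f"locus {locus!r} has no non-missing calls")
    alleles, counts = np.unique(observed, return_counts=True)
    return AlleleFrequencies(locus, alleles, counts, int(observed.size))


def diversity_indices(
    freqs: AlleleFrequencies, rare_threshold: float = 0.05
) -> dict[str, float]:
    """d_AR, d_RAR, d_Nei, d_PIC and d_SWI from one locus's frequencies."""
    p = freqs.freqs
    d_ar = int(p.size)
    d_rar = int((p < rare_threshold).sum())
    sum_p2 = float((p**2).sum())
    d_nei = 1.0 - sum_p2
    # sum_{i<j} 2 p_i^2 p_j^2 = (sum p^2)^2 - sum p^4
    d_pic = 1.0 - sum_p2 - (sum_p2**2 - float((p**4).sum()))
    d_swi = float(-xlogy(p, p).sum())
    return {
        "d_AR": d_ar,
        "d_RAR": d_rar,
        "d_Nei": d_nei,
        "d_PIC": d_pic,
        "d_SWI": d_swi,
    }


def rarefied_richness(counts: np.ndarray, g: int) -> float:
    """Expected allele count in a subsample of size g (overflow-safe)."""
    counts = np.asarray(counts, dtype=np.int64)
    n = int(counts.sum())
    if not 1 <= g <= n:
        raise ValueError(f"subsample size g={g} outside [1, {n}]")

    def log_choose(a: np.ndarray, b: int) -> np.ndarray:
        a = np.asarray(a, dtype=float)
        return gammaln(a + 1) - gammaln(b + 1) - gammaln(a - b + 1)

    keep = counts <= n - g  # C(n - n_i, g) = 0 when n - n_i < g
    terms = np.ones(counts.size, dtype=float)
    if keep.any():
        ratio = np.exp(log_choose(n - counts[keep], g) - log_choose(np.array(n), g))
        terms[keep] = 1.0 - ratio
    return float(terms.sum())


def diversity_table(
    matrix: GenotypeMatrix,
    marker_info: pd.DataFrame | None = None,
    g: int | None = None,
    rare_threshold: float = 0.05,
    summary_subset: list[str] | None = None,
) -> pd.DataFrame:
    """Per-locus diversity table plus mean/min/max summary rows.

    ``g`` (rarefaction size) defaults to the smallest non-missing sample
    size over the included loci.  ``summary_subset`` restricts the summary
    rows to a designated locus subset (e.g. SSR loci only); body rows always
    cover every locus.
    """
    ns = [
        int((matrix.calls[:, j] != MISSING_CODE).sum())
        for j in range(matrix.n_loci)
    ]
    if min(ns) == 0:
        bad = matrix.locus_names[int(np.argmin(ns))]
        raise ValueError(f"locus {bad!r} has no non-missing calls")
    if g is None:
        g = min(ns)
    rows = []
    for locus in matrix.locus_names:
        fr = allele_frequencies(matrix, locus)
        idx = diversity_indices(fr, rare_threshold=rare_threshold)
        chrom = ""
        if marker_info is not None and locus in marker_info.index:
            chrom = marker_info.loc[locus, "chromosome_label"]
        rows.append(
            {
                "locus": locus,
                "chromosome_label": chrom,
                "missing_pct": 100.0 * (1.0 - fr.n / matrix.n_accessions),
                "d_AR": idx["d_AR"],
                "d_RAR": idx["d_RAR"],
                "d_rarefied": rarefied_richness(fr.counts, min(g, fr.n)),
                "d_Nei": idx["d_Nei"],
                "d_PIC": idx["d_PIC"],
                "d_SWI": idx["d_SWI"],
            }
        )
    body = pd.DataFrame(rows)
    return pd.concat(
        [body, summarize_diversity_table(body, summary_subset)], ignore_index=True
    )


def summarize_diversity_table(
    body: pd.DataFrame, subset: list[str] | None = None
) -> pd.DataFrame:
    """Mean/min/max rows recomputed from a table's body rows.

    ``subset`` names the loci the summary runs over (default: all body
    rows); an empty subset is an error.
    """
    rows = body[~body["locus"].isin(SUMMARY_ROWS)]
    if subset is not None:
        rows = rows[rows["locus"].isin(subset)]
    if rows.empty:
        raise ValueError("summary subset selects no loci")
    num_cols = ["missing_pct", *INDEX_COLUMNS]
    out = []
    for stat, fn in [("mean", np.mean), ("min", np.min), ("max", np.max)]:
        rec = {"locus": stat, "chromosome_label": ""}
        for c in num_cols:
            rec[c] = float(fn(rows[c].to_numpy(dtype=float)))
        out.append(rec)
    return pd.DataFrame(out)


def phenotype_swi(
    values_by_trial: dict[str, np.ndarray],
    n_classes: int = 12,
    equal_count: bool = False,
) -> dict:
    """Shannon–Weaver diversity of phenotype scores, per trial.

    The pooled (all-trial) range is divided into ``n_classes`` classes —
    equal-width intervals by default, equal-count (quantile) bins with
    ``equal_count=True``.  Per trial, class frequencies over non-missing
    scores give ``d_SWIp = -sum f_c ln f_c`` (non-empty classes only).
    A constant trait yields 0 with a warning.
    """
    pooled = np.concatenate(
        [np.asarray(v, dtype=float) for v in values_by_trial.values()]
    )
    pooled = pooled[~np.isnan(pooled)]
    if pooled.size == 0:
        raise ValueError("no non-missing phenotype values")
    lo, hi = float(pooled.min()), float(pooled.max())
    if lo == hi:
        warnings.warn("constant trait: phenotype diversity is 0", stacklevel=2)
        per_trial = pd.DataFrame(
            {"trial": list(values_by_trial), "d_SWIp": 0.0}
        )
        return {"boundaries": np.array([lo, hi]), "per_trial": per_trial}
    if equal_count:
        boundaries = np.quantile(pooled, np.linspace(0, 1, n_classes + 1))
        boundaries = np.unique(boundaries)
    else:
        boundaries = np.linspace(lo, hi, n_classes + 1)
    recs = []
    for trial, vals in values_by_trial.items():
        v = np.asarray(vals, dtype=float)
        v = v[~np.isnan(v)]
        classes = np.clip(
            np.searchsorted(boundaries, v, side="right") - 1,
            0,
            len(boundaries) - 2,
        )
        counts = np.bincount(classes, minlength=len(boundaries) - 1)
        f = counts[counts > 0] / counts.sum()
        recs.append({"trial": trial, "d_SWIp": float(-xlogy(f, f).sum())})
    return {"boundaries": boundaries, "per_trial": pd.DataFrame(recs)}


def phenotype_diversity(
    phenotypes: pd.DataFrame, n_classes: int = 12, equal_count: bool = False
) -> pd.DataFrame:
    """Per-trait, per-trial d_SWIp from a long-form phenotype table."""
    out = []
    for trait, sub in phenotypes.groupby("trait", sort=False):
        by_trial = {
            str(trial): grp["value"].to_numpy()
            for trial, grp in sub.groupby("trial", sort=False)
        }
        res = phenotype_swi(by_trial, n_classes=n_classes, equal_count=equal_count)
        for _, row in res["per_trial"].iterrows():
            out.append(
                {"trait": trait, "trial": row["trial"], "d_SWIp": row["d_SWIp"]}
            )
    return pd.DataFrame(out)


def single_genome_loci(
    marker_info: pd.DataFrame,
    genome_override: dict[str, str] | None = None,
) -> dict[str, list[str]]:
    """Loci assignable to exactly one genome, optionally with overrides.

    ``genome_override`` maps a locus name to the genome it should count
    toward even if its chromosome label names several genomes (some
    multi-genome markers are conventionally attributed to one genome).
    """
    override = genome_override or {}
    out: dict[str, list[str]] = {"A": [], "B": [], "D": []}
    for locus, row in marker_info.iterrows():
        if locus in override:
            out[override[locus]].append(str(locus))
        elif len(row["genomes"]) == 1:
            (g,) = row["genomes"]
            out[g].append(str(locus))
    return out


def genome_partition_diversity(
    table: pd.DataFrame,
    marker_info: pd.DataFrame,
    index_cols: tuple[str, ...] = ("d_SWI", "d_PIC"),
    subsample_size: int = 8,
    reps: int = 1000,
    seed: int = 0,
    genome_override: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Genome-wise mean diversity, full sets and random marker subsets.

    For each genome: the mean index over all its single-genome loci, and —
    to remove marker-count bias — the average over ``reps`` seeded random
    subsets of ``subsample_size`` loci.
    """
    rng = np.random.default_rng(seed)
    body = table[~table["locus"].isin(SUMMARY_ROWS)].set_index("locus")
    groups = single_genome_loci(marker_info, genome_override)
    recs = []
    for genome, loci in groups.items():
        loci = [l for l in loci if l in body.index]
        if len(loci) < subsample_size:
            raise ValueError(
                f"genome {genome}: {len(loci)} single-genome loci, "
                f"need >= {subsample_size}"
            )
        rec = {"genome": genome, "n_loci": len(loci)}
        vals = body.loc[loci, list(index_cols)]
        for c in index_cols:
            rec[f"{c}_full_mean"] = float(vals[c].mean())
        sub_means = {c: [] for c in index_cols}
        loci_arr = np.array(loci)
        for _ in range(reps):
            pick = rng.choice(loci_arr, size=subsample_size, replace=False)
            for c in index_cols:
                sub_means[c].append(float(body.loc[pick, c].mean()))
        for c in index_cols:
            rec[f"{c}_subsample_mean"] = float(np.mean(sub_means[c]))
        recs.append(rec)
    return pd.DataFrame(recs)
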
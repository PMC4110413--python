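"""Synthetic genotype/phenotype generator for inbred landrace collections.

The generator emulates the statistical structure of a genebank collection of
single-seed-descent bread-wheat landraces genotyped at multi-allelic SSR
loci: several hundred effectively homozygous lines, tens of loci with up to
dozens of alleles each, weak two-level population structure, per-locus
missing data, heritable NULL alleles, and "sister line" pairs (two SSD
streams drawn from one heterogeneous original accession).

Population structure follows the correlated-frequencies F-model used by
Bayesian admixture clustering: ancestral allele frequencies are drawn from a
symmetric Dirichlet, and each population's frequencies from
``Dirichlet(ancestral * (1 - F) / F)``, so ``F`` plays the role of Wright's
FST between populations.  With the optional nested configuration the model
is applied in two stages (top-level split, then subgroup drift within each
top-level group), mirroring a hierarchical structure analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .io import GenotypeMatrix, MISSING_CODE, NULL_CODE, marker_info


@dataclass
class TraitSpec:
    """A simulated trait: baseline + top-level-group shift + Normal noise."""

    name: str
    group_shifts: tuple[float, ...]
    sd: float
    baseline: float = 0.0


@dataclass
class SimConfig:
    n_accessions: int = 826
    n_loci: int = 45
    alleles_per_locus: tuple[int, int] = (3, 40)
    K_true: int = 2
    subgroups: tuple[int, ...] | None = (4, 5)
    drift_F: float = 0.05
    drift_F_sub: float | None = None
    admixture_alpha: float = 0.1
    missing_rate_per_locus: tuple[float, float] = (0.0, 0.23)
    null_allele_rate: float = 0.15
    sister_fraction: float = 0.28
    sister_divergence: float = 0.357
    trait_specs: tuple[TraitSpec, ...] = ()
    n_trials: int = 1
    seed: int = 0

    def validate(self) -> None:
        if self.n_accessions < 1 or self.n_loci < 1:
            raise ValueError("n_accessions and n_loci must be positive")
        if self.K_true < 1:
            raise ValueError("K_true must be >= 1")
        if self.alleles_per_locus[0] < 2:
            raise ValueError("polymorphic loci need >= 2 alleles")
        if self.alleles_per_locus[0] > self.alleles_per_locus[1]:
            raise ValueError("alleles_per_locus range is inverted")
        if self.subgroups is not None and len(self.subgroups) != self.K_true:
            raise ValueError("subgroups must list one count per top-level group")
        for name, v in [
            ("drift_F", self.drift_F),
            ("null_allele_rate", self.null_allele_rate),
            ("sister_fraction", self.sister_fraction),
            ("sister_divergence", self.sister_divergence),
        ]:
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if not 0.0 < self.drift_F < 1.0:
            raise ValueError("drift_F must be in (0, 1)")
        lo, hi = self.missing_rate_per_locus
        if not (0.0 <= lo <= hi <= 1.0):
            raise ValueError("missing_rate_per_locus must be an ordered range in [0,1]")
        if self.admixture_alpha < 0:
            raise ValueError("admixture_alpha must be >= 0")
        if hi + self.null_allele_rate > 1.0:
            raise ValueError("missing + NULL rates exceed 1")


@dataclass
class SimTruth:
    """Ground truth accompanying a simulated dataset."""

    q_true: np.ndarray  # (n_total, K) ancestry fractions, rows sum to 1
    p_true: list[np.ndarray]  # per locus: (K, n_alleles) frequency rows
    group_labels: pd.DataFrame  # accession_id, top_group, subgroup
    sister_pairs: list[tuple[str, str]]
    allele_codes: list[np.ndarray] = field(default_factory=list)


def _dirichlet(rng: np.random.Generator, alpha: np.ndarray, size=None) -> np.ndarray:
    draw = rng.dirichlet(np.asarray(alpha, dtype=float), size=size)
    return draw


def _drift(rng: np.random.Generator, base: np.ndarray, F: float, k: int) -> np.ndarray:
    """k daughter frequency vectors drifted from `base` under the F-model."""
    conc = base * (1.0 - F) / F
    # dirichlet requires strictly positive concentration
    conc = np.clip(conc, 1e-9, None)
    return rng.dirichlet(conc, size=k)


def generate_dataset(
    config: SimConfig,
) -> tuple[GenotypeMatrix, pd.DataFrame, SimTruth]:
    """Simulate a genotype matrix, marker metadata and ground truth.

    Deterministic given ``config.seed``.  Returns ``(matrix, marker_info,
    truth)``; marker metadata carries invented chromosome labels cycling
    through the three genomes so genome-partition analyses are exercisable.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n, L = config.n_accessions, config.n_loci
    F_sub = config.drift_F if config.drift_F_sub is None else config.drift_F_sub

    # --- cluster allele frequencies (one- or two-stage F-model) ---
    if config.subgroups is None:
        K = config.K_true
        top_of_cluster = np.arange(K)  # degenerate: each cluster its own top
    else:
        K = int(sum(config.subgroups))
        top_of_cluster = np.repeat(np.arange(config.K_true), config.subgroups)

    n_alleles = rng.integers(
        config.alleles_per_locus[0], config.alleles_per_locus[1] + 1, size=L
    )
    p_true: list[np.ndarray] = []
    allele_codes: list[np.ndarray] = []
    for l in range(L):
        A = int(n_alleles[l])
        ancestral = rng.dirichlet(np.ones(A))
        if config.subgroups is None:
            if config.K_true == 1:
                pops = ancestral[None, :]
            else:
                pops = _drift(rng, ancestral, config.drift_F, config.K_true)
        else:
            tops = _drift(rng, ancestral, config.drift_F, config.K_true)
            pops = np.vstack(
                [
                    _drift(rng, tops[t], F_sub, g)
                    for t, g in enumerate(config.subgroups)
                ]
            )
        p_true.append(pops)
        base = int(rng.integers(80, 300))
        codes = base + 2 * np.arange(A)
        # NULL allele: with some probability the locus segregates a null
        # (no-product) allele, represented by the reserved code 0
        if rng.random() < config.null_allele_rate:
            codes = codes.copy()
            codes[int(rng.integers(A))] = NULL_CODE
        allele_codes.append(codes)

    # --- ancestry proportions ---
    if config.admixture_alpha == 0.0:
        base_cluster = rng.integers(K, size=n)
        q = np.zeros((n, K))
        q[np.arange(n), base_cluster] = 1.0
    else:
        q = rng.dirichlet(np.full(K, config.admixture_alpha), size=n)

    # --- genotypes: per cell, origin cluster ~ q_i, allele ~ p_origin ---
    calls = np.empty((n, L), dtype=np.int64)
    u = rng.random((n, L))
    origin = (q.cumsum(axis=1)[:, :, None] < u[:, None, :]).sum(axis=1)  # (n, L)
    for l in range(L):
        pops = p_true[l]
        cum = pops.cumsum(axis=1)
        v = rng.random(n)
        idx = (cum[origin[:, l]] < v[:, None]).sum(axis=1)
        idx = np.minimum(idx, pops.shape[1] - 1)
        calls[:, l] = allele_codes[l][idx]

    # --- missingness, completely at random per locus ---
    lo, hi = config.missing_rate_per_locus
    miss_rate = rng.uniform(lo, hi, size=L)
    miss_mask = rng.random((n, L)) < miss_rate[None, :]
    calls[miss_mask] = MISSING_CODE

    ids = [f"W{i + 1:04d}" for i in range(n)]
    top_labels = top_of_cluster[np.argmax(q, axis=1)]
    sub_labels = np.argmax(q, axis=1)

    # --- sister lines: copy an accession, re-draw a fraction of loci ---
    n_sisters = int(round(config.sister_fraction * n))
    sister_parents = rng.choice(n, size=n_sisters, replace=False) if n_sisters else np.array([], int)
    sister_rows = []
    sister_ids = []
    sister_pairs: list[tuple[str, str]] = []
    for i in sister_parents:
        row = calls[i].copy()
        redraw = rng.random(L) < config.sister_divergence
        for l in np.flatnonzero(redraw):
            pops = p_true[l]
            k = int((q[i].cumsum() < rng.random()).sum())
            a = int((pops[k].cumsum() < rng.random()).sum())
            a = min(a, pops.shape[1] - 1)
            row[l] = allele_codes[l][a]
            if rng.random() < miss_rate[l]:
                row[l] = MISSING_CODE
        sid = ids[i] + ".s"
        sister_rows.append(row)
        sister_ids.append(sid)
        sister_pairs.append((ids[i], sid))
    if sister_rows:
        calls = np.vstack([calls, np.array(sister_rows)])
        q = np.vstack([q, q[sister_parents]])
        top_labels = np.concatenate([top_labels, top_labels[sister_parents]])
        sub_labels = np.concatenate([sub_labels, sub_labels[sister_parents]])
        ids = ids + sister_ids

    matrix = GenotypeMatrix(ids, [f"ssr{l + 1:03d}" for l in range(L)], calls)
    chrom_cycle = ["1A", "2B", "3D", "4A", "5B", "6D", "7A", "1B", "2D"]
    labels = {
        name: chrom_cycle[j % len(chrom_cycle)]
        for j, name in enumerate(matrix.locus_names)
    }
    info = marker_info(matrix, labels)
    groups = pd.DataFrame(
        {
            "accession_id": ids,
            "top_group": top_labels,
            "subgroup": sub_labels,
        }
    )
    truth = SimTruth(
        q_true=q,
        p_true=p_true,
        group_labels=groups,
        sister_pairs=sister_pairs,
        allele_codes=allele_codes,
    )
    return matrix, info, truth


def generate_phenotypes(truth: SimTruth, config: SimConfig) -> pd.DataFrame:
    """Simulate a long-form phenotype table from the ground-truth grouping.

    Each trait value is ``baseline + shift[top_group] + Normal(0, sd)``,
    independently per trial.  Deterministic given ``config.seed``.
    """
    if not config.trait_specs:
        raise ValueError("trait_specs is empty")
    rng = np.random.default_rng(config.seed + 10_007)
    ids = truth.group_labels["accession_id"].tolist()
    tops = truth.group_labels["top_group"].to_numpy()
    rows = []
    for spec in config.trait_specs:
        shifts = np.asarray(spec.group_shifts, dtype=float)
        if tops.max() >= len(shifts):
            raise ValueError(
                f"trait {spec.name!r}: {len(shifts)} shifts for "
                f"{tops.max() + 1} top-level groups"
            )
        for trial in range(config.n_trials):
            noise = rng.normal(0.0, spec.sd, size=len(ids)) if spec.sd > 0 else 0.0
            vals = spec.baseline + shifts[tops] + noise
            for aid, v in zip(ids, np.broadcast_to(vals, (len(ids),))):
                rows.append((aid, spec.name, f"T{trial + 1}", float(v)))
    return pd.DataFrame(rows, columns=["accession_id", "trait", "trial", "value"])
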
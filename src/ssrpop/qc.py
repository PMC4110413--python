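"""Marker scoring rules: NULL vs missing calls, locus exclusion, sister lines.

An SSR reaction that repeatedly yields no PCR product is ambiguous: either
the accession carries a NULL allele (a heritable primer-site mutation) or
the data point is simply missing.  The scoring rule used here calls NULL
only when the evidence supports a real allele:

(a) the reaction gave no product;
(b) the accession's DNA is demonstrably good — its success rate over the
    *other* loci is at least ``dna_quality_min``;
(c) the locus itself is well-behaved — its overall no-product fraction is
    below ``locus_missing_threshold``.

Otherwise the cell is scored missing.  Downstream, loci whose missing
fraction exceeds a cutoff (default: strictly more than 20 %) are excluded.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import GenotypeMatrix, MISSING_CODE, NULL_CODE

NO_PRODUCT = -1


@dataclass
class AmplificationTable:
    """Raw per-reaction outcomes: an allele code, or NO_PRODUCT (-1)."""

    accession_ids: list[str]
    locus_names: list[str]
    outcomes: np.ndarray  # (n, L) int; NO_PRODUCT = -1, otherwise allele code

    def __post_init__(self) -> None:
        self.outcomes = np.asarray(self.outcomes, dtype=np.int64)
        if self.outcomes.shape != (len(self.accession_ids), len(self.locus_names)):
            raise ValueError("outcomes shape does not match identifier lists")
        if np.any((self.outcomes < 0) & (self.outcomes != NO_PRODUCT)):
            raise ValueError("negative codes other than NO_PRODUCT (-1) not allowed")

    def success_rate(self) -> np.ndarray:
        """Per-accession fraction of loci with an amplified product."""
        return (self.outcomes != NO_PRODUCT).mean(axis=1)


def call_null_and_missing(
    raw: AmplificationTable,
    locus_missing_threshold: float = 0.05,
    dna_quality_min: float = 0.80,
) -> GenotypeMatrix:
    """Score NO_PRODUCT reactions as NULL alleles or as missing data.

    Applies rules (a)-(c) from the module docstring cell by cell; product
    cells pass through unchanged.  Rule (b) evaluates the accession's
    success rate over all loci *except* the one being scored.
    """
    for name, v in [
        ("locus_missing_threshold", locus_missing_threshold),
        ("dna_quality_min", dna_quality_min),
    ]:
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} must be in [0, 1]")
    out = raw.outcomes.copy()
    n, L = out.shape
    no_prod = out == NO_PRODUCT
    locus_fail_frac = no_prod.mean(axis=0)
    ok = ~no_prod
    if L > 1:
        # success rate over the other loci, per cell
        other_ok = (ok.sum(axis=1, keepdims=True) - ok) / (L - 1)
    else:
        other_ok = np.zeros((n, 1))
    is_null = (
        no_prod
        & (other_ok >= dna_quality_min)
        & (locus_fail_frac[None, :] < locus_missing_threshold)
    )
    out[no_prod] = MISSING_CODE
    out[is_null] = NULL_CODE
    return GenotypeMatrix(list(raw.accession_ids), list(raw.locus_names), out)


def exclude_high_missing_loci(
    matrix: GenotypeMatrix, max_missing: float = 0.20
) -> tuple[GenotypeMatrix, list[str]]:
    """Drop loci whose missing fraction is strictly above ``max_missing``."""
    miss = matrix.missing_fraction()
    excluded = [l for l in matrix.locus_names if miss[l] > max_missing]
    kept = [l for l in matrix.locus_names if miss[l] <= max_missing]
    return matrix.subset(loci=kept), excluded


def sister_line_divergence(
    matrix: GenotypeMatrix, pairs: list[tuple[str, str]]
) -> tuple[pd.DataFrame, dict]:
    """Per-pair count of loci with differing alleles, plus a summary.

    A locus enters a pair's comparison only when both members have a
    non-missing call there (NULL counts as an allele).  The summary reports
    the mean, sample SD and range of the per-pair differing-locus counts
    and fractions.
    """
    rows = []
    for a, b in pairs:
        ia, ib = matrix.accession_index(a), matrix.accession_index(b)
        ra, rb = matrix.calls[ia], matrix.calls[ib]
        comparable = (ra != MISSING_CODE) & (rb != MISSING_CODE)
        n_comp = int(comparable.sum())
        n_diff = int(((ra != rb) & comparable).sum())
        rows.append(
            {
                "pair": f"{a}|{b}",
                "n_loci_compared": n_comp,
                "n_loci_differing": n_diff,
                "fraction_differing": n_diff / n_comp if n_comp else np.nan,
            }
        )
    report = pd.DataFrame(rows)
    diffs = report["n_loci_differing"].to_numpy(dtype=float)
    fracs = report["fraction_differing"].to_numpy(dtype=float)
    summary = {
        "n_pairs": len(pairs),
        "mean_differing": float(np.nanmean(diffs)) if len(diffs) else np.nan,
        "sd_differing": float(np.nanstd(diffs, ddof=1)) if len(diffs) > 1 else np.nan,
        "min_differing": float(np.nanmin(diffs)) if len(diffs) else np.nan,
        "max_differing": float(np.nanmax(diffs)) if len(diffs) else np.nan,
        "mean_fraction": float(np.nanmean(fracs)) if len(fracs) else np.nan,
    }
    return report, summary
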
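"""Genotype, marker and phenotype data model plus readers/writers.

Genotype tables describe collections of inbred (single-seed-descent) lines,
which are effectively homozygous, so each accession carries a single allele
per locus.  Alleles are integer codes mimicking PCR fragment sizes in base
pairs.  Two reserved codes exist:

* ``NULL_CODE`` (0) — a NULL allele: the locus amplified no product although
  the DNA was good; it is a heritable allele state, not missing data.
* ``MISSING_CODE`` (-9) — a genuinely missing call.

The CSV dialect is: UTF-8, comma-separated, first header cell
``accession_id``, remaining header cells locus names; body cells are integer
allele sizes, ``0`` = NULL, ``-9`` = missing.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

NULL_CODE = 0
MISSING_CODE = -9

_CHROM_TOKEN = re.compile(r"\d[ABD]+")
_CHROM_FULL = re.compile(r"(?:\d[ABD]+)+\Z")


@dataclass
class GenotypeMatrix:
    """Accessions x loci table of single allele codes for inbred lines."""

    accession_ids: list[str]
    locus_names: list[str]
    calls: np.ndarray  # shape (n_accessions, n_loci), dtype int

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int64)
        n, L = self.calls.shape
        if n != len(self.accession_ids) or L != len(self.locus_names):
            raise ValueError("calls shape does not match identifier lists")
        if len(set(self.accession_ids)) != n:
            raise ValueError("duplicate accession identifiers")
        if len(set(self.locus_names)) != L:
            raise ValueError("duplicate locus names")

    @property
    def n_accessions(self) -> int:
        return self.calls.shape[0]

    @property
    def n_loci(self) -> int:
        return self.calls.shape[1]

    def missing_fraction(self) -> pd.Series:
        """Per-locus fraction of MISSING calls (NULL is *not* missing)."""
        frac = (self.calls == MISSING_CODE).mean(axis=0)
        return pd.Series(frac, index=self.locus_names, name="missing_fraction")

    def locus_index(self, locus: str) -> int:
        try:
            return self.locus_names.index(locus)
        except ValueError:
            raise KeyError(f"unknown locus {locus!r}") from None

    def accession_index(self, accession: str) -> int:
        try:
            return self.accession_ids.index(accession)
        except ValueError:
            raise KeyError(f"unknown accession {accession!r}") from None

    def subset(
        self,
        accessions: Sequence[str] | None = None,
        loci: Sequence[str] | None = None,
    ) -> "GenotypeMatrix":
        rows = (
            np.arange(self.n_accessions)
            if accessions is None
            else np.array([self.accession_index(a) for a in accessions])
        )
        cols = (
            np.arange(self.n_loci)
            if loci is None
            else np.array([self.locus_index(l) for l in loci])
        )
        return GenotypeMatrix(
            [self.accession_ids[i] for i in rows],
            [self.locus_names[j] for j in cols],
            self.calls[np.ix_(rows, cols)],
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.calls, index=self.accession_ids, columns=self.locus_names
        )


def parse_chromosome_label(label: str) -> frozenset[str]:
    """Return the set of wheat genomes (A/B/D) named in a chromosome label.

    Labels concatenate chromosome tokens of the form digit + genome letters,
    e.g. ``"3A"`` -> {A}, ``"7BD5B"`` -> {B, D}, ``"1AD"`` -> {A, D}.  A
    marker is genome-specific iff the returned set has size 1.
    """
    label = label.strip()
    if not label or not _CHROM_FULL.match(label):
        raise ValueError(f"unparseable chromosome label: {label!r}")
    genomes: set[str] = set()
    for token in _CHROM_TOKEN.findall(label):
        genomes.update(token[1:])
    return frozenset(genomes)


def marker_info(
    matrix: GenotypeMatrix,
    chromosome_labels: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Build the per-locus metadata frame (chromosome, genomes, missingness)."""
    labels = chromosome_labels or {}
    rows = []
    miss = matrix.missing_fraction()
    for locus in matrix.locus_names:
        lab = labels.get(locus, "")
        genomes = parse_chromosome_label(lab) if lab else frozenset()
        rows.append(
            {
                "locus_name": locus,
                "chromosome_label": lab,
                "genomes": genomes,
                "missing_fraction": miss[locus],
            }
        )
    return pd.DataFrame(rows).set_index("locus_name", drop=False)


def read_genotypes(
    path: str | Path, marker_path: str | Path | None = None
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Read the genotype CSV dialect; optionally join marker metadata.

    Returns the matrix and a marker-info frame with per-locus
    ``missing_fraction`` already computed.  Malformed input (ragged rows,
    duplicate identifiers, non-integer cells) raises ``ValueError`` naming
    the offending row/column.
    """
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise ValueError(f"{path}: empty file") from None
        if not header or header[0] != "accession_id":
            raise ValueError(f"{path}: first header cell must be 'accession_id'")
        loci = header[1:]
        ids: list[str] = []
        rows: list[list[int]] = []
        for rnum, row in enumerate(reader, start=2):
            if len(row) != len(header):
                raise ValueError(
                    f"{path}: ragged row {rnum} ({len(row)} cells, "
                    f"expected {len(header)})"
                )
            ids.append(row[0])
            vals = []
            for cell, locus in zip(row[1:], loci):
                try:
                    vals.append(int(cell))
                except ValueError:
                    raise ValueError(
                        f"{path}: non-integer allele {cell!r} at row {rnum}, "
                        f"locus {locus}"
                    ) from None
            rows.append(vals)
    matrix = GenotypeMatrix(ids, list(loci), np.array(rows, dtype=np.int64))
    labels = None
    if marker_path is not None:
        mdf = pd.read_csv(marker_path, dtype=str)
        labels = dict(zip(mdf["locus_name"], mdf["chromosome_label"].fillna("")))
    return matrix, marker_info(matrix, labels)


def write_genotypes(matrix: GenotypeMatrix, path: str | Path) -> None:
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        fh.write("accession_id," + ",".join(matrix.locus_names) + "\n")
        for aid, row in zip(matrix.accession_ids, matrix.calls):
            fh.write(aid + "," + ",".join(str(int(v)) for v in row) + "\n")


def write_structure_input(
    matrix: GenotypeMatrix, path: str | Path, ploidy_rows: int = 1
) -> Path:
    """Export in the classic admixture-clustering program's input layout.

    One whitespace-delimited row per accession (``ploidy_rows=1``, for
    homozygous inbreds) or the same row duplicated (``ploidy_rows=2``).
    Missing is encoded -9.  Alleles are recoded per locus to consecutive
    integers starting at 1; the map is written to a ``<path>.alleles.csv``
    sidecar (columns locus_name, recoded, original) and its path returned.
    """
    if ploidy_rows not in (1, 2):
        raise ValueError("ploidy_rows must be 1 or 2")
    path = Path(path)
    recode: list[dict[int, int]] = []
    map_rows = []
    for j, locus in enumerate(matrix.locus_names):
        col = matrix.calls[:, j]
        observed = sorted(set(col[col != MISSING_CODE].tolist()))
        mapping = {orig: k + 1 for k, orig in enumerate(observed)}
        recode.append(mapping)
        for orig, code in mapping.items():
            map_rows.append((locus, code, orig))
    with path.open("w", encoding="utf-8") as fh:
        for aid, row in zip(matrix.accession_ids, matrix.calls):
            tokens = [
                "-9" if v == MISSING_CODE else str(recode[j][v])
                for j, v in enumerate(row)
            ]
            line = aid + " " + " ".join(tokens) + "\n"
            fh.write(line * ploidy_rows)
    sidecar = path.with_name(path.name + ".alleles.csv")
    with sidecar.open("w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["locus_name", "recoded", "original"])
        w.writerows(map_rows)
    return sidecar


def read_allele_map(sidecar: str | Path) -> dict[str, dict[int, int]]:
    """Read a recode sidecar; returns {locus: {recoded: original}}."""
    df = pd.read_csv(sidecar)
    out: dict[str, dict[int, int]] = {}
    for locus, sub in df.groupby("locus_name", sort=False):
        out[str(locus)] = dict(zip(sub["recoded"].astype(int), sub["original"].astype(int)))
    return out


def read_phenotypes(path: str | Path) -> pd.DataFrame:
    """Long-form phenotype table: accession_id, trait, trial, value."""
    df = pd.read_csv(path, dtype={"accession_id": str, "trait": str, "trial": str})
    required = {"accession_id", "trait", "trial", "value"}
    if not required.issubset(df.columns):
        raise ValueError(f"phenotype table must have columns {sorted(required)}")
    df["value"] = pd.to_numeric(df["value"], errors="coerce")
    return df


def write_phenotypes(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False, columns=["accession_id", "trait", "trial", "value"])
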
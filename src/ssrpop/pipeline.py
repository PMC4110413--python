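"""End-to-end pipeline: simulate/load -> QC -> diversity -> structure -> core.

A pipeline run is fully described by a ``PipelineConfig`` (constructible
from a YAML mapping).  Every stochastic stage carries an explicit seed;
re-running the same config is bit-identical, which the manifest verifies by
recording a SHA-256 checksum per persisted artifact.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .io import GenotypeMatrix, read_genotypes, write_genotypes, marker_info
from .simulate import SimConfig, TraitSpec, generate_dataset, generate_phenotypes
from .qc import exclude_high_missing_loci, sister_line_divergence
from .diversity import diversity_table, genome_partition_diversity, phenotype_diversity
from .structure import hierarchical_structure, q_to_frame
from .core import retained_diversity, select_core

log = logging.getLogger("ssrpop")


@dataclass
class PipelineConfig:
    sim: SimConfig | None = None
    genotype_path: str | None = None
    marker_path: str | None = None
    qc_max_missing: float = 0.20
    rare_threshold: float = 0.05
    rarefaction_g: int | None = None
    genome_reps: int = 1000
    genome_subsample: int = 8
    k_range: tuple[int, int] = (2, 25)
    structure_reps: int = 10
    burnin: int = 10_000
    iters: int = 50_000
    core_size: int | None = None
    core_objective: str = "SWI"
    core_restarts: int = 3
    run_structure: bool = True
    run_core: bool = True
    seed: int | None = None

    def validate(self) -> None:
        if self.sim is None and self.genotype_path is None:
            raise ValueError("config must provide either sim or genotype_path")
        if self.seed is None:
            raise ValueError("pipeline config requires an explicit seed")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim_raw = raw.pop("sim", None)
        cfg = cls(**{k: v for k, v in raw.items() if k in cls.__dataclass_fields__})
        if isinstance(cfg.k_range, list):
            cfg.k_range = tuple(cfg.k_range)
        if sim_raw is not None:
            traits = tuple(
                TraitSpec(
                    name=t["name"],
                    group_shifts=tuple(t["group_shifts"]),
                    sd=float(t["sd"]),
                    baseline=float(t.get("baseline", 0.0)),
                )
                for t in sim_raw.pop("trait_specs", [])
            )
            for key in ("alleles_per_locus", "missing_rate_per_locus", "subgroups"):
                if key in sim_raw and sim_raw[key] is not None:
                    sim_raw[key] = tuple(sim_raw[key])
            cfg.sim = SimConfig(trait_specs=traits, **sim_raw)
        return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> dict[str, Any]:
    """Execute all configured stages; persist artifacts and a manifest.

    Returns the manifest dict (also written to ``manifest.json``).  Any
    stage failure is re-raised annotated with the stage name.
    """
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {
        "version": __version__,
        "seed": config.seed,
        "stages": {},
        "checksums": {},
    }
    artifacts: dict[str, Path] = {}

    def stage(name):
        def deco(fn):
            t0 = time.time()
            log.info("stage %s: start", name)
            try:
                fn()
            except Exception as exc:
                raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
            manifest["stages"][name] = round(time.time() - t0, 3)
            log.info("stage %s: done in %.1fs", name, manifest["stages"][name])

        return deco

    ctx: dict[str, Any] = {}

    @stage("input")
    def _input():
        if config.sim is not None:
            sim = config.sim
            if config.seed is not None:
                sim.seed = config.seed
            matrix, info, truth = generate_dataset(sim)
            ctx["truth"] = truth
            if sim.trait_specs:
                pheno = generate_phenotypes(truth, sim)
                pheno.to_csv(outdir / "phenotypes.csv", index=False)
                artifacts["phenotypes"] = outdir / "phenotypes.csv"
                ctx["phenotypes"] = pheno
        else:
            matrix, info = read_genotypes(config.genotype_path, config.marker_path)
        write_genotypes(matrix, outdir / "genotypes.csv")
        artifacts["genotypes"] = outdir / "genotypes.csv"
        ctx["matrix"], ctx["info"] = matrix, info

    @stage("qc")
    def _qc():
        matrix, excluded = exclude_high_missing_loci(
            ctx["matrix"], config.qc_max_missing
        )
        (outdir / "excluded_loci.json").write_text(json.dumps(excluded))
        artifacts["excluded_loci"] = outdir / "excluded_loci.json"
        ctx["matrix_qc"] = matrix
        truth = ctx.get("truth")
        if truth is not None and truth.sister_pairs:
            report, summary = sister_line_divergence(matrix, truth.sister_pairs)
            report.to_csv(outdir / "sister_divergence.csv", index=False)
            artifacts["sister_divergence"] = outdir / "sister_divergence.csv"
            manifest["sister_summary"] = summary

    @stage("diversity")
    def _diversity():
        table = diversity_table(
            ctx["matrix_qc"],
            ctx["info"],
            g=config.rarefaction_g,
            rare_threshold=config.rare_threshold,
        )
        table.to_csv(outdir / "diversity_table.csv", index=False)
        artifacts["diversity_table"] = outdir / "diversity_table.csv"
        ctx["table"] = table
        try:
            gp = genome_partition_diversity(
                table,
                ctx["info"],
                subsample_size=config.genome_subsample,
                reps=config.genome_reps,
                seed=config.seed,
            )
            gp.to_csv(outdir / "genome_partition.csv", index=False)
            artifacts["genome_partition"] = outdir / "genome_partition.csv"
        except ValueError:
            log.info("genome partition skipped (too few single-genome loci)")
        if "phenotypes" in ctx:
            pd_df = phenotype_diversity(ctx["phenotypes"])
            pd_df.to_csv(outdir / "phenotype_diversity.csv", index=False)
            artifacts["phenotype_diversity"] = outdir / "phenotype_diversity.csv"

    if config.run_structure:

        @stage("structure")
        def _structure():
            truth = ctx.get("truth")
            res = hierarchical_structure(
                ctx["matrix_qc"],
                k_range=config.k_range,
                reps=config.structure_reps,
                burnin=config.burnin,
                iters=config.iters,
                seed=config.seed,
                sister_pairs=truth.sister_pairs if truth else None,
            )
            res.assignment.to_csv(outdir / "group_assignment.csv", index=False)
            artifacts["group_assignment"] = outdir / "group_assignment.csv"
            res.level1.delta_k.to_csv(outdir / "delta_k_level1.csv", index=False)
            artifacts["delta_k_level1"] = outdir / "delta_k_level1.csv"
            for g, lvl in res.level2.items():
                p = outdir / f"delta_k_level2_group{g}.csv"
                lvl.delta_k.to_csv(p, index=False)
                artifacts[f"delta_k_level2_group{g}"] = p
            q_to_frame(
                res.level1.mean_Q, ctx["matrix_qc"].accession_ids
            ).to_csv(outdir / "q_level1.csv", index=False)
            artifacts["q_level1"] = outdir / "q_level1.csv"
            manifest["structure"] = {
                "level1_best_k": res.level1.best_k,
                "clear_structure": res.level1.clear_structure,
                "level2_best_k": {g: r.best_k for g, r in res.level2.items()},
                "sister_concordance": res.sister_concordance,
            }
            ctx["structure"] = res

    if config.run_core:

        @stage("core")
        def _core():
            matrix = ctx["matrix_qc"]
            size = config.core_size or max(2, round(0.15 * matrix.n_accessions))
            core = select_core(
                matrix,
                size,
                objective=config.core_objective,
                restarts=config.core_restarts,
                seed=config.seed,
            )
            flags = pd.DataFrame(
                {
                    "accession_id": matrix.accession_ids,
                    "selected": [
                        int(a in set(core.accession_ids))
                        for a in matrix.accession_ids
                    ],
                }
            )
            flags.to_csv(outdir / "core_set.csv", index=False)
            artifacts["core_set"] = outdir / "core_set.csv"
            retained = retained_diversity(matrix, core.accession_ids)
            pd.DataFrame([retained]).to_csv(
                outdir / "core_retained.csv", index=False
            )
            artifacts["core_retained"] = outdir / "core_retained.csv"
            manifest["core"] = {
                "size": size,
                "objective": core.objective,
                "objective_value": core.objective_value,
                **retained,
            }

    manifest["checksums"] = {k: _sha256(p) for k, p in sorted(artifacts.items())}
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest
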
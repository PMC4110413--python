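"""Select a diversity-maximizing core subset and audit what it retains.

Builds a 400-line synthetic collection, selects a 15% core by maximizing
the mean per-locus Shannon-Weaver index with steepest-ascent swap search,
and reports the diversity retained relative to the full collection.
"""

from ssrpop import (
    SimConfig,
    exclude_high_missing_loci,
    generate_dataset,
    retained_diversity,
    select_core,
)

config = SimConfig(n_accessions=400, seed=4)
matrix, _, _ = generate_dataset(config)
matrix, excluded = exclude_high_missing_loci(matrix)
print(f"collection: {matrix.n_accessions} lines x {matrix.n_loci} loci "
      f"({len(excluded)} high-missing loci excluded)")

size = round(0.15 * matrix.n_accessions)
core = select_core(matrix, size, objective="SWI", restarts=2, seed=1)
print(f"core of {core.size} lines, mean per-locus d_SWI = "
      f"{core.objective_value:.3f}")
print("objective values on the core:",
      {k: round(v, 3) for k, v in core.objective_values.items()})

ret = retained_diversity(matrix, core.accession_ids)
print(f"retained gene diversity (d_Nei): {ret['retained_d_Nei_pct']:.1f}%")
print(f"retained Shannon-Weaver (d_SWI): {ret['retained_d_SWI_pct']:.1f}%")
print(f"retained alleles: {ret['retained_d_AR_pct']:.1f}% "
      f"(rare alleles only {ret['retained_d_RAR_pct']:.1f}%)")
# Frequency-based diversity survives heavy downsizing almost intact, but
# allele counts - rare alleles above all - drop: a small core is a poor
# tool for mining very rare variants.
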
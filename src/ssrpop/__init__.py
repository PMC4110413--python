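"""ssrpop: diversity, structure and core-set analysis of SSR-genotyped inbred collections."""

from importlib import resources

import pandas as pd

from .io import (
    GenotypeMatrix,
    MISSING_CODE,
    NULL_CODE,
    marker_info,
    parse_chromosome_label,
    read_genotypes,
    read_phenotypes,
    write_genotypes,
    write_phenotypes,
    write_structure_input,
)
from .simulate import SimConfig, SimTruth, TraitSpec, generate_dataset, generate_phenotypes
from .qc import (
    AmplificationTable,
    NO_PRODUCT,
    call_null_and_missing,
    exclude_high_missing_loci,
    sister_line_divergence,
)
from .diversity import (
    allele_frequencies,
    diversity_indices,
    diversity_table,
    genome_partition_diversity,
    phenotype_diversity,
    phenotype_swi,
    rarefied_richness,
    single_genome_loci,
    summarize_diversity_table,
)
from .structure import (
    HierarchicalResult,
    StructureRun,
    align_runs,
    analyse_structure_level,
    assign_groups,
    evanno_delta_k,
    hierarchical_structure,
    mean_q,
    run_admixture,
)
from .core import (
    CoreSet,
    distance_matrix,
    exhaustive_core,
    objective_value,
    pairwise_distance,
    retained_diversity,
    select_core,
)

__version__ = "0.1.0"


def load_reference_diversity_table() -> pd.DataFrame:
    """Published per-locus diversity table for an 826-accession bread-wheat
    landrace collection genotyped at 45 SSR loci (allele sizes scored on
    ~1,050 inbred lines).  Columns follow the standard report layout:
    locus, chromosome label, missing %, d_AR, d_RAR, rarefied richness,
    d_Nei, d_PIC, d_SWI."""
    with resources.files("ssrpop.data").joinpath(
        "landrace_ssr_diversity.csv"
    ).open() as fh:
        return pd.read_csv(fh)
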
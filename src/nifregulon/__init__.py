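"""nifregulon: transcriptional analysis of bacterial nitrogen fixation.

Tools for inferring a nitrogen-fixation-inducible regulon from
condition-contrast fold changes, scanning upstream regions for the NifA
upstream activator sequence (TGT-N10-ACA) and the sigma-54 -24/-12
promoter element, predicting NifA-sigma54-dependent operons, detecting
chromosomal expression islands, and simulating synthetic datasets with
planted ground truth.
"""

from importlib import resources

__version__ = "0.1.0"

from .expression import (
    DEConfig,
    ExpressionMatrix,
    FoldChangeTable,
    classify_regulation,
    classify_table,
    compute_fold_changes,
    summarize_contrast,
)
from .io_formats import (
    GeneRecord,
    GenomeAnnotation,
    Table1Fixture,
    read_annotations,
    read_table1,
    write_bed,
)
from .operon_island import (
    IslandConfig,
    OperonConfig,
    detect_islands,
    island_span,
    predict_operons,
)
from .promoter_scan import (
    MotifPattern,
    ScanConfig,
    annotate_promoter,
    compile_pattern,
    extract_upstream,
    scan_sequence,
)
from .regulon import (
    categorize_functions,
    core_genome_overlap,
    core_subset,
    infer_regulon,
    island_partition,
    regulon_members,
)
from .synthetic_data import (
    IslandSpec,
    SimulationSpec,
    evaluate_recovery,
    generate_expression,
    generate_genome,
    generate_orthologs,
)


def data_path(name: str):
    """Path to a packaged data table (e.g. ``table1_nif_island.tsv``)."""
    return resources.files("nifregulon") / "data" / name
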
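"""meltcol: detect snow-to-soil microbial colonisers during snow melt.

A pipeline for longitudinal, multi-compartment 16S ASV count tables:
prevalence-based contaminant removal against negative controls, occupancy-rule
coloniser classification, life-strategy tallies, supporting community
statistics (Shannon diversity, Bray-Curtis/PCoA, phylum composition, linear
time trends), and a source-sink colonisation simulator with known ground
truth.
"""

from importlib import resources

from .table_io import (
    Compartment,
    CountTable,
    RelAbundanceTable,
    filter_min_abundance,
    read_count_table,
    read_metadata,
    read_taxonomy,
    total_sum_scaling,
    write_count_table,
    write_metadata,
)
from .decontam_prevalence import (
    ContaminantReport,
    classify_contaminants,
    presence_absence,
    prevalence_score,
    remove_contaminants,
)
from .coloniser import (
    ColoniserReport,
    ColoniserRules,
    DetectionHistory,
    build_detection_history,
    classify_feature,
    classify_features,
    coloniser_summary,
    potential_colonisers,
    successful_colonisers,
)
from .life_strategy import (
    StrategyTable,
    assign_strategy,
    default_strategy_table,
    load_strategy_table,
    tally_strategies,
)
from .community_stats import (
    TrendFit,
    alpha_diversity,
    bray_curtis,
    fit_time_trend,
    pcoa,
    phylum_composition,
    shannon,
)
from .synthetic_data import (
    SimulationConfig,
    SimulationTruth,
    evaluate_recovery,
    recovery_benchmark_config,
    simulate,
)

__version__ = "0.1.0"


def load_toy_dataset():
    """The 12-feature x 18-sample worked example from the docs.

    Returns (CountTable, metadata DataFrame, taxonomy DataFrame). Designed so
    every coloniser class occurs at least once.
    """
    data = resources.files("meltcol").joinpath("data")
    with resources.as_file(data.joinpath("toy_counts.tsv")) as p:
        table = read_count_table(p)
    with resources.as_file(data.joinpath("toy_metadata.tsv")) as p:
        meta = read_metadata(p)
    with resources.as_file(data.joinpath("toy_taxonomy.tsv")) as p:
        taxonomy = read_taxonomy(p)
    return table, meta, taxonomy
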
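"""Copiotroph/oligotroph life-strategy annotation of features.

Colonisation outcomes are often interpreted through the r/K spectrum:
copiotrophs (r-strategists) grow fast when resources pulse, oligotrophs
(K-strategists) persist under scarcity and stress. The mapping from taxonomy
to strategy comes from the literature, is coarse, and is genuinely contested
(several phyla have been classified both ways), so it is shipped here as
*data*: an editable table of (rank, taxon) -> strategy rules with a provenance
note per rule.

Assignment takes the most specific matching rule (genus beats family beats ...
beats domain); a feature matching no rule is ``unclear``. The bundled default
table is a small partial reconstruction of classifications commonly used for
Arctic soil/snow taxa and is NOT a complete literature survey — users with a
curated mapping should load their own.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import pandas as pd

from .table_io import TAXONOMY_RANKS

__all__ = [
    "STRATEGIES",
    "StrategyTable",
    "load_strategy_table",
    "default_strategy_table",
    "assign_strategy",
    "tally_strategies",
]

STRATEGIES = ("copiotroph", "oligotroph", "unclear")

# most specific last; assignment scans from genus down to domain
_RANK_SPECIFICITY = {rank: i for i, rank in enumerate(TAXONOMY_RANKS)}


@dataclass(frozen=True)
class StrategyTable:
    """Ordered (rank, taxon) -> strategy rules with provenance notes."""

    rules: pd.DataFrame  # columns: rank, taxon, strategy, citation

    def __post_init__(self) -> None:
        required = {"rank", "taxon", "strategy"}
        missing = required - set(self.rules.columns)
        if missing:
            raise ValueError(f"strategy table missing columns: {sorted(missing)}")
        bad_rank = set(self.rules["rank"]) - set(TAXONOMY_RANKS)
        if bad_rank:
            raise ValueError(f"unknown ranks in strategy table: {sorted(bad_rank)}")
        bad_strategy = set(self.rules["strategy"]) - set(STRATEGIES)
        if bad_strategy:
            raise ValueError(f"unknown strategies: {sorted(bad_strategy)}")
        keys = list(zip(self.rules["rank"], self.rules["taxon"]))
        if len(keys) != len(set(keys)):
            dups = sorted({k for k in keys if keys.count(k) > 1})
            raise ValueError(f"duplicate (rank, taxon) rules: {dups[:5]}")

    def lookup(self, rank: str, taxon: str) -> str | None:
        hit = self.rules[(self.rules["rank"] == rank) & (self.rules["taxon"] == taxon)]
        if len(hit):
            return str(hit["strategy"].iloc[0])
        return None


def load_strategy_table(path: str | Path) -> StrategyTable:
    """Load a strategy table from TSV (columns: rank, taxon, strategy, citation)."""
    rules = pd.read_csv(path, sep="\t", dtype=str)
    if "citation" not in rules.columns:
        rules["citation"] = ""
    return StrategyTable(rules=rules)


def default_strategy_table() -> StrategyTable:
    """The bundled partial default mapping (see module docstring caveats)."""
    with resources.as_file(
        resources.files("meltcol").joinpath("data/default_strategies.tsv")
    ) as path:
        return load_strategy_table(path)


def assign_strategy(taxonomy: pd.Series | dict, table: StrategyTable) -> str:
    """Assign a strategy to one feature's (possibly partial) rank labels.

    The most specific matching rule wins; no match -> ``unclear``.
    Deterministic given the table and taxonomy.
    """
    if isinstance(taxonomy, dict):
        taxonomy = pd.Series(taxonomy, dtype=object)
    for rank in reversed(TAXONOMY_RANKS):  # genus first
        if rank not in taxonomy.index:
            continue
        taxon = taxonomy.get(rank)
        if taxon is None or (isinstance(taxon, float) and pd.isna(taxon)) or pd.isna(taxon):
            continue
        hit = table.lookup(rank, str(taxon))
        if hit is not None:
            return hit
    return "unclear"


def tally_strategies(
    features: set | frozenset | list,
    taxonomy: pd.DataFrame,
    table: StrategyTable | None = None,
) -> dict[str, int]:
    """Count strategies over a feature set; counts sum to ``len(features)``.

    Features absent from the taxonomy table are ``unclear``. The tally is
    permutation-invariant and additive over disjoint feature sets.
    """
    table = table or default_strategy_table()
    counts = {s: 0 for s in STRATEGIES}
    for fid in features:
        if fid in taxonomy.index:
            strategy = assign_strategy(taxonomy.loc[fid], table)
        else:
            strategy = "unclear"
        counts[strategy] += 1
    return counts
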
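"""Occupancy-rule classification of snow-to-soil colonisers.

The central procedure of the package. During snow melt, meltwater percolates
into the underlying soil and carries snow microorganisms with it. Given a
longitudinal presence/absence history per feature over two habitats — snow
(surface and bulk layers merged) and soil — across ordered sampling days, each
feature is assigned one of five classes, evaluated in precedence order:

1. ``snow_only``            never detected in soil;
2. ``soil_only``            never detected in snow;
3. ``resident_day1``        detected in soil on the first sampling day
                            (already there before the melt, regardless of any
                            snow history);
4. ``soil_first``           earliest soil detection precedes earliest snow
                            detection (soil, not snow, is the likely source);
                            a same-day tie is resolved by ``tie_policy``
                            (default: excluded as ``soil_first``, the
                            conservative choice);
5. ``potential_coloniser``  everything else: absent from soil on day 1,
                            detected in snow first and in soil at a later day
                            — subject to the ``snow_persistence`` policy; a
                            feature failing that policy is demoted to
                            ``soil_first``.

Among potential colonisers, *successful* colonisers are those detected in at
least ``min_soil_detections`` soil samples (the study design has one soil
sample per day, so this is a count of soil detection days) including, by
default, the final sampling day.

Snow-persistence policies (the occupancy literature does not pin one down):

* ``any``         at least one snow detection (default; "first identified in
                  the snow and subsequently observed in the soil");
* ``all_days``    detected in snow on every sampling day with snow data;
* ``before_soil`` detected in snow on every sampling day strictly before the
                  first soil detection.

Missing compartment-day cells (no sample collected that day) count as "no
evidence": they never count as absence for the snow_only/soil_only rules and
are skipped by the persistence policies.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .table_io import (
    Compartment,
    CountTable,
    RelAbundanceTable,
    check_paired,
    validate_metadata,
)

__all__ = [
    "CLASS_LABELS",
    "ColoniserRules",
    "DetectionHistory",
    "ColoniserReport",
    "build_detection_history",
    "classify_feature",
    "classify_features",
    "potential_colonisers",
    "successful_colonisers",
    "coloniser_summary",
]

CLASS_LABELS = (
    "snow_only",
    "soil_only",
    "resident_day1",
    "soil_first",
    "potential_coloniser",
)

SNOW_PERSISTENCE_POLICIES = ("any", "all_days", "before_soil")
TIE_POLICIES = ("soil_first", "potential")


@dataclass(frozen=True)
class ColoniserRules:
    """Tunable parameters of the coloniser rule set.

    detection_threshold : minimum read count for presence (default 1).
    snow_persistence : how strictly "always identified in the snow" is read.
    tie_policy : class for a same-day first detection in snow and soil.
    min_soil_detections : soil detection days required for "successful".
    require_final_day : successful colonisers must be in soil on the last day.
    """

    detection_threshold: int = 1
    snow_persistence: str = "any"
    tie_policy: str = "soil_first"
    min_soil_detections: int = 2
    require_final_day: bool = True

    def __post_init__(self) -> None:
        if self.detection_threshold < 1:
            raise ValueError("detection_threshold must be >= 1")
        if self.snow_persistence not in SNOW_PERSISTENCE_POLICIES:
            raise ValueError(
                f"snow_persistence must be one of {SNOW_PERSISTENCE_POLICIES}"
            )
        if self.tie_policy not in TIE_POLICIES:
            raise ValueError(f"tie_policy must be one of {TIE_POLICIES}")
        if self.min_soil_detections < 1:
            raise ValueError("min_soil_detections must be >= 1")


@dataclass(frozen=True)
class DetectionHistory:
    """Boolean detection over (habitat, day) for a collection of features.

    ``snow``/``soil`` are features x days boolean matrices where snow is the
    OR over the surface and bulk samples of that day. ``snow_missing`` /
    ``soil_missing`` mark day cells with no underlying sample — "no evidence",
    distinct from an observed absence. ``provenance`` maps (compartment, day)
    to the sample IDs that produced each cell.
    """

    feature_ids: tuple[str, ...]
    days: tuple[int, ...]
    snow: np.ndarray
    soil: np.ndarray
    snow_missing: np.ndarray
    soil_missing: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        days = np.asarray(self.days)
        if len(days) and not (np.diff(days) > 0).all():
            raise ValueError("days must be strictly increasing")
        for name in ("snow", "soil"):
            mat = np.asarray(getattr(self, name), dtype=bool)
            if mat.shape != (len(self.feature_ids), len(self.days)):
                raise ValueError(f"{name} matrix shape mismatch")
            object.__setattr__(self, name, mat)
        object.__setattr__(self, "snow_missing",
                           np.asarray(self.snow_missing, dtype=bool))
        object.__setattr__(self, "soil_missing",
                           np.asarray(self.soil_missing, dtype=bool))

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    def feature(self, fid: str) -> "DetectionHistory":
        i = self.feature_ids.index(fid)
        return DetectionHistory(
            feature_ids=(fid,),
            days=self.days,
            snow=self.snow[i : i + 1],
            soil=self.soil[i : i + 1],
            snow_missing=self.snow_missing,
            soil_missing=self.soil_missing,
            provenance=self.provenance,
        )


@dataclass(frozen=True)
class ColoniserReport:
    """Classification outcome for every feature.

    ``per_feature`` columns: ``class``, ``n_snow_detections``,
    ``n_soil_detections``, ``first_snow_day``, ``first_soil_day``,
    ``final_day_soil``, ``is_potential``, ``is_successful``. Classes partition
    the features; ``successful_set`` is a subset of ``potential_set``.
    """

    per_feature: pd.DataFrame
    potential_set: frozenset
    successful_set: frozenset
    rules: ColoniserRules

    def __post_init__(self) -> None:
        if not self.successful_set <= self.potential_set:
            raise ValueError("successful set must be a subset of potential set")

    def to_tsv(self, path) -> None:
        out = self.per_feature.copy()
        out.insert(0, "feature_id", out.index)
        out.to_csv(path, sep="\t", index=False)


def build_detection_history(
    table: CountTable, meta: pd.DataFrame, detection_threshold: int = 1
) -> DetectionHistory:
    """Collapse a count table to per-feature snow/soil detection by day.

    Control samples are excluded. Surface and bulk snow samples of the same
    day are merged by OR. A day that has neither a snow nor a soil sample is
    dropped with a warning; a day that has only one of the two gets a
    "missing" mark for the other habitat.
    """
    if detection_threshold < 1:
        raise ValueError("detection_threshold must be >= 1")
    validate_metadata(meta)
    check_paired(table, meta)
    sub = meta.loc[list(table.sample_ids)]
    real = sub[~sub["is_control"].astype(bool)]
    days = sorted(int(d) for d in real["day"].dropna().unique())

    counts = pd.DataFrame(table.counts, index=list(table.feature_ids),
                          columns=list(table.sample_ids))
    present = counts >= detection_threshold

    snow_comps = {Compartment.SURFACE_SNOW.value, Compartment.BULK_SNOW.value}
    kept_days, snow_cols, soil_cols = [], [], []
    snow_missing, soil_missing = [], []
    provenance: dict = {}
    n = table.n_features
    for day in days:
        day_rows = real[real["day"] == day]
        snow_ids = [s for s in day_rows.index if day_rows.loc[s, "compartment"] in snow_comps]
        soil_ids = [s for s in day_rows.index if day_rows.loc[s, "compartment"] == Compartment.SOIL.value]
        if not snow_ids and not soil_ids:
            warnings.warn(f"day {day} has no snow or soil sample; dropped", stacklevel=2)
            continue
        kept_days.append(day)
        snow_cols.append(
            present[snow_ids].any(axis=1).to_numpy() if snow_ids else np.zeros(n, bool)
        )
        soil_cols.append(
            present[soil_ids].any(axis=1).to_numpy() if soil_ids else np.zeros(n, bool)
        )
        snow_missing.append(not snow_ids)
        soil_missing.append(not soil_ids)
        provenance[("snow", day)] = tuple(snow_ids)
        provenance[("soil", day)] = tuple(soil_ids)

    shape = (n, len(kept_days))
    return DetectionHistory(
        feature_ids=table.feature_ids,
        days=tuple(kept_days),
        snow=np.column_stack(snow_cols) if kept_days else np.zeros(shape, bool),
        soil=np.column_stack(soil_cols) if kept_days else np.zeros(shape, bool),
        snow_missing=np.asarray(snow_missing, bool),
        soil_missing=np.asarray(soil_missing, bool),
        provenance=provenance,
    )


def _classify_matrix(history: DetectionHistory, rules: ColoniserRules) -> np.ndarray:
    """Vectorised rule walk; returns an array of class labels."""
    snow, soil = history.snow, history.soil
    n, n_days = snow.shape
    labels = np.empty(n, dtype=object)
    if n_days == 0:
        labels[:] = "snow_only"  # no evidence at all; rule 1 fires vacuously
        return labels

    days = np.asarray(history.days)
    any_snow = snow.any(axis=1)
    any_soil = soil.any(axis=1)
    # first detection day per habitat (index into days; n_days when never)
    first_snow_idx = np.where(any_snow, snow.argmax(axis=1), n_days)
    first_soil_idx = np.where(any_soil, soil.argmax(axis=1), n_days)

    # rule 3 applies only if a day-1 soil sample exists
    day1_soil_observed = not history.soil_missing[0]
    resident = day1_soil_observed & soil[:, 0]

    soil_first = first_soil_idx < first_snow_idx
    tie = any_soil & any_snow & (first_soil_idx == first_snow_idx)
    if rules.tie_policy == "soil_first":
        soil_first = soil_first | tie

    # snow-persistence demotion for would-be potential colonisers
    observed_snow_days = ~history.snow_missing
    if rules.snow_persistence == "any":
        persistent = any_snow
    elif rules.snow_persistence == "all_days":
        persistent = (snow | ~observed_snow_days[None, :]).all(axis=1)
    else:  # before_soil
        day_idx = np.arange(n_days)
        before = day_idx[None, :] < first_soil_idx[:, None]
        relevant = before & observed_snow_days[None, :]
        persistent = (snow | ~relevant).all(axis=1)

    labels[:] = "potential_coloniser"
    labels[~persistent] = "soil_first"
    labels[soil_first] = "soil_first"
    labels[resident] = "resident_day1"
    labels[~any_snow] = "soil_only"
    labels[~any_soil] = "snow_only"
    return labels


def classify_feature(history: DetectionHistory, rules: ColoniserRules | None = None) -> str:
    """Classify a single-feature history; returns one of :data:`CLASS_LABELS`."""
    if history.n_features != 1:
        raise ValueError("classify_feature expects a single-feature history")
    rules = rules or ColoniserRules()
    return str(_classify_matrix(history, rules)[0])


def classify_features(
    history: DetectionHistory, rules: ColoniserRules | None = None
) -> ColoniserReport:
    """Classify every feature and extract the potential and successful sets."""
    rules = rules or ColoniserRules()
    labels = _classify_matrix(history, rules)
    n_days = len(history.days)

    n_snow = history.snow.sum(axis=1)
    n_soil = history.soil.sum(axis=1)
    days = np.asarray(history.days) if n_days else np.array([], dtype=int)
    first_snow = [
        int(days[r.argmax()]) if r.any() else None for r in history.snow
    ]
    first_soil = [
        int(days[r.argmax()]) if r.any() else None for r in history.soil
    ]
    final_soil = (
        history.soil[:, -1] if n_days else np.zeros(history.n_features, bool)
    )

    is_potential = labels == "potential_coloniser"
    is_successful = is_potential & (n_soil >= rules.min_soil_detections)
    if rules.require_final_day:
        is_successful &= final_soil

    per_feature = pd.DataFrame(
        {
            "class": labels,
            "n_snow_detections": n_snow,
            "n_soil_detections": n_soil,
            "first_snow_day": first_snow,
            "first_soil_day": first_soil,
            "final_day_soil": final_soil,
            "is_potential": is_potential,
            "is_successful": is_successful,
        },
        index=pd.Index(history.feature_ids, name="feature_id"),
    )
    return ColoniserReport(
        per_feature=per_feature,
        potential_set=frozenset(per_feature.index[is_potential]),
        successful_set=frozenset(per_feature.index[is_successful]),
        rules=rules,
    )


def potential_colonisers(report: ColoniserReport) -> frozenset:
    """Features first detected in snow, absent from day-1 soil, later in soil."""
    return report.potential_set


def successful_colonisers(
    potential: frozenset,
    history: DetectionHistory,
    min_soil_detections: int = 2,
    require_final_day: bool = True,
) -> frozenset:
    """Subset of ``potential`` meeting the soil-occupancy persistence rule.

    A potential coloniser is successful when detected in at least
    ``min_soil_detections`` soil samples (detection days; one soil sample per
    day in this design) and, if ``require_final_day``, in soil on the last
    sampling day.
    """
    if min_soil_detections < 1:
        raise ValueError("min_soil_detections must be >= 1")
    unknown = set(potential) - set(history.feature_ids)
    if unknown:
        raise ValueError(f"potential features missing from history: {sorted(unknown)[:5]}")
    index = {f: i for i, f in enumerate(history.feature_ids)}
    out = set()
    for fid in potential:
        row = history.soil[index[fid]]
        if row.sum() < min_soil_detections:
            continue
        if require_final_day and not (len(row) and row[-1]):
            continue
        out.add(fid)
    return frozenset(out)


def coloniser_summary(
    report: ColoniserReport,
    rel: RelAbundanceTable,
    taxonomy: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Long-format (feature, class, sample, relative_abundance) table for the
    successful colonisers — the data behind a coloniser heatmap.

    Rows appear only for the successful set. When a taxonomy with a ``class``
    rank is supplied, rows are ordered by taxonomic class then feature ID.
    """
    frame = rel.to_frame()
    rows = []
    for fid in sorted(report.successful_set):
        tax_class = None
        if taxonomy is not None and fid in taxonomy.index and "class" in taxonomy.columns:
            tax_class = taxonomy.loc[fid, "class"]
        for sid in rel.sample_ids:
            rows.append(
                {
                    "feature_id": fid,
                    "class": report.per_feature.loc[fid, "class"],
                    "taxonomic_class": tax_class,
                    "sample_id": sid,
                    "relative_abundance": frame.loc[fid, sid],
                }
            )
    out = pd.DataFrame(
        rows,
        columns=["feature_id", "class", "taxonomic_class", "sample_id",
                 "relative_abundance"],
    )
    if taxonomy is not None and len(out):
        out = out.sort_values(
            ["taxonomic_class", "feature_id"], na_position="last", kind="stable"
        ).reset_index(drop=True)
    return out
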
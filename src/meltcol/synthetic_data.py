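"""Synthetic longitudinal source-sink colonisation data with known truth.

Emulates the study design the pipeline targets: three compartments (surface
snow, bulk snow, soil) sampled on six days spanning a melt season, with
negative controls, uneven sequencing depth, and a planted set of snow-origin
features transferred into soil midway through the series.

Generative model (all randomness from one seeded ``numpy`` Generator, so a
given config + seed is bit-reproducible):

* Snow community: relative-abundance profile drawn log-normally over the
  snow-side features (snow-only + shared background + colonisers), with
  day-to-day compositional drift applied as multiplicative log-normal jitter
  on the previous day's profile (a random walk in log-abundance, renormalised;
  rare features drift but are never absorbed at zero, so planted colonisers
  keep a snow presence throughout, as the design requires). Surface and bulk
  share the day profile.
* Soil community: independent log-normal profile over soil-side features
  (residents + shared background) with higher richness and evenness (smaller
  log-sigma) and its own drift.
* Colonisers: present in snow from day 1; from ``transfer_day`` onward each
  coloniser establishes in soil with probability
  ``coloniser_establishment_prob`` per day, contributing relative abundance
  ``transfer_fraction * (snow abundance) * (snow:soil biomass ratio)`` to the
  soil profile, which is then renormalised. Soil is the much larger biomass
  pool, so the default ratio is 1e-2 — transferred cells are rare in soil.
* Contaminants: extra features present in negative controls at
  ``contaminant_control_prevalence`` and in real samples at a low background
  prevalence. Controls also pick up sparse cross-talk from real features.
* Depths: log-normal around ``depth_mean`` (default 27,000 reads/sample, the
  order of a typical MiSeq amplicon run); reads assigned multinomially, so
  column sums equal the drawn depths exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .table_io import CountTable, TAXONOMY_RANKS

__all__ = [
    "SimulationConfig",
    "SimulationTruth",
    "simulate",
    "evaluate_recovery",
    "recovery_benchmark_config",
]

DEFAULT_DAYS = (1, 4, 8, 11, 15, 19)


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the source-sink colonisation simulator (see module docstring)."""

    n_features_snow: int = 300
    n_features_soil: int = 600
    n_shared_background: int = 50
    days: tuple[int, ...] = DEFAULT_DAYS
    depth_mean: float = 27_000.0
    depth_dispersion: float = 0.3  # sigma of log-normal depth model
    n_colonisers: int = 30
    transfer_day: int = 8
    transfer_fraction: float = 0.1
    coloniser_establishment_prob: float = 0.8
    n_contaminants: int = 20
    contaminant_control_prevalence: float = 0.9
    contaminant_sample_prevalence: float = 0.05
    control_crosstalk_rate: float = 0.01
    n_controls: int = 6  # 3 extraction-kit + 3 sequencing negatives, pooled
    snow_soil_biomass_ratio: float = 1e-2
    abundance_lognormal_mu: float = 0.0
    abundance_lognormal_sigma: float = 1.5
    soil_lognormal_sigma: float = 1.0
    drift_lognormal_sigma: float = 0.3  # per-day log-abundance jitter
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_features_snow, self.n_features_soil) < 1:
            raise ValueError("need at least one snow and one soil feature")
        if self.n_shared_background < 0 or self.n_colonisers < 0 or self.n_contaminants < 0:
            raise ValueError("feature counts must be non-negative")
        days = tuple(sorted(int(d) for d in self.days))
        if len(days) < 2 or len(set(days)) != len(days):
            raise ValueError("days must be >= 2 distinct integers")
        object.__setattr__(self, "days", days)
        if self.transfer_day not in days or self.transfer_day <= days[0]:
            raise ValueError("transfer_day must be a sampling day after the first")
        if not 0 < self.transfer_fraction <= 1:
            raise ValueError("transfer_fraction must lie in (0, 1]")
        for name in (
            "coloniser_establishment_prob",
            "contaminant_control_prevalence",
            "contaminant_sample_prevalence",
            "control_crosstalk_rate",
        ):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.depth_mean <= 0 or self.depth_dispersion < 0:
            raise ValueError("invalid depth model")
        if self.n_controls < 1:
            raise ValueError("need at least one negative control")


@dataclass(frozen=True)
class SimulationTruth:
    """Ground truth of one simulation, for recovery scoring.

    The ID sets are pairwise disjoint. ``soil_presence_days`` records, per
    planted coloniser, the days on which it was actually present in the soil
    community (before read sampling); ``established`` marks colonisers with at
    least one such day.
    """

    coloniser_ids: frozenset
    contaminant_ids: frozenset
    resident_soil_ids: frozenset
    snow_only_ids: frozenset
    shared_background_ids: frozenset
    soil_presence_days: dict = field(default_factory=dict)

    @property
    def established(self) -> frozenset:
        return frozenset(
            f for f, days in self.soil_presence_days.items() if len(days) > 0
        )

    def eligible(self, target: str, final_day: int, min_soil_detections: int = 2) -> frozenset:
        """Truth colonisers that the pipeline's rules *should* recover.

        ``potential``: at least one soil-presence day. ``successful``: at
        least ``min_soil_detections`` soil-presence days including the final
        sampling day — the same rule parameters the classifier applies.
        """
        if target == "potential":
            return self.established
        if target == "successful":
            return frozenset(
                f
                for f, days in self.soil_presence_days.items()
                if len(days) >= min_soil_detections and final_day in days
            )
        raise ValueError("target must be 'potential' or 'successful'")


def _lognormal_profile(rng: np.random.Generator, n: int, mu: float, sigma: float) -> np.ndarray:
    raw = rng.lognormal(mean=mu, sigma=sigma, size=n)
    return raw / raw.sum()


def _drift(rng: np.random.Generator, profile: np.ndarray, sigma: float) -> np.ndarray:
    jittered = profile * rng.lognormal(mean=0.0, sigma=sigma, size=profile.shape)
    return jittered / jittered.sum()


def _fake_taxonomy(rng: np.random.Generator, feature_ids, pools: dict) -> pd.DataFrame:
    """Small fake rank hierarchy so taxonomy-dependent stages are exercisable."""
    phyla = ["Proteobacteria", "Bacteroidetes", "Actinobacteria", "Acidobacteria",
             "Chloroflexi", "Verrucomicrobia"]
    classes = {
        "Proteobacteria": ["Betaproteobacteria", "Gammaproteobacteria",
                           "Alphaproteobacteria"],
        "Bacteroidetes": ["Sphingobacteriia", "Cytophagia"],
        "Actinobacteria": ["Actinobacteria_c"],
        "Acidobacteria": ["Acidobacteriia"],
        "Chloroflexi": ["Chloroflexia"],
        "Verrucomicrobia": ["Verrucomicrobiae"],
    }
    genera = {
        "Betaproteobacteria": ["Massilia", "Janthinobacterium"],
        "Gammaproteobacteria": ["Pseudomonas", "Psychrobacter"],
        "Alphaproteobacteria": ["Sphingomonas"],
        "Sphingobacteriia": ["Pedobacter"],
        "Cytophagia": ["Hymenobacter"],
        "Actinobacteria_c": ["Arthrobacter"],
        "Acidobacteriia": ["Granulicella"],
        "Chloroflexia": ["Ktedonobacter"],
        "Verrucomicrobiae": ["Chthoniobacter"],
    }
    rows = []
    for fid in feature_ids:
        phylum = phyla[rng.integers(len(phyla))]
        cls = classes[phylum][rng.integers(len(classes[phylum]))]
        genus = genera[cls][rng.integers(len(genera[cls]))]
        rows.append(
            {
                "feature_id": fid,
                "domain": "Bacteria",
                "phylum": phylum,
                "class": cls,
                "order": f"{cls}_o",
                "family": f"{genus}aceae",
                "genus": genus,
            }
        )
    return pd.DataFrame(rows).set_index("feature_id")[list(TAXONOMY_RANKS)]


def simulate(
    config: SimulationConfig,
) -> tuple[CountTable, pd.DataFrame, pd.DataFrame, SimulationTruth]:
    """Run the source-sink simulation.

    Returns (count table, sample metadata, taxonomy, truth). Deterministic
    given ``config`` (which carries the seed).
    """
    rng = np.random.default_rng(config.seed)
    days = list(config.days)
    final_day = days[-1]

    # --- feature registry -------------------------------------------------
    snow_only = [f"snow{i:04d}" for i in range(config.n_features_snow)]
    colonisers = [f"col{i:04d}" for i in range(config.n_colonisers)]
    residents = [f"soil{i:04d}" for i in range(config.n_features_soil)]
    shared = [f"shared{i:04d}" for i in range(config.n_shared_background)]
    contaminants = [f"contam{i:04d}" for i in range(config.n_contaminants)]
    feature_ids = snow_only + colonisers + shared + residents + contaminants
    index = {f: i for i, f in enumerate(feature_ids)}
    n_total = len(feature_ids)

    snow_side = snow_only + colonisers + shared
    soil_side = residents + shared

    # --- per-day relative-abundance profiles ------------------------------
    snow_profile = _lognormal_profile(
        rng, len(snow_side), config.abundance_lognormal_mu, config.abundance_lognormal_sigma
    )
    soil_profile = _lognormal_profile(
        rng, len(soil_side), config.abundance_lognormal_mu, config.soil_lognormal_sigma
    )

    # establishment outcomes drawn up front so soil composition is consistent
    post_transfer = [d for d in days if d >= config.transfer_day]
    soil_presence_days = {f: [] for f in colonisers}
    establish = {
        f: {d: rng.random() < config.coloniser_establishment_prob for d in post_transfer}
        for f in colonisers
    }

    sample_rows = []
    columns = {}
    snow_day_profiles = {}
    soil_day_profiles = {}
    cur_snow, cur_soil = snow_profile, soil_profile
    for di, day in enumerate(days):
        if di > 0:
            cur_snow = _drift(rng, cur_snow, config.drift_lognormal_sigma)
            cur_soil = _drift(rng, cur_soil, config.drift_lognormal_sigma)
        snow_day_profiles[day] = cur_snow
        soil_full = np.zeros(n_total)
        for f, p in zip(soil_side, cur_soil):
            soil_full[index[f]] = p
        if day >= config.transfer_day:
            for f in colonisers:
                if establish[f][day]:
                    snow_p = cur_snow[snow_side.index(f)]
                    contrib = (
                        config.transfer_fraction * snow_p * config.snow_soil_biomass_ratio
                    )
                    if contrib > 0:
                        soil_full[index[f]] += contrib
                        soil_presence_days[f].append(day)
        total = soil_full.sum()
        soil_full = soil_full / total if total else soil_full
        soil_day_profiles[day] = soil_full

    # --- draw reads --------------------------------------------------------
    def draw_sample(profile_full: np.ndarray) -> np.ndarray:
        depth = max(1, int(round(rng.lognormal(
            mean=np.log(config.depth_mean), sigma=config.depth_dispersion
        ))))
        return rng.multinomial(depth, profile_full)

    for day in days:
        snow_full = np.zeros(n_total)
        for f, p in zip(snow_side, snow_day_profiles[day]):
            snow_full[index[f]] = p
        for comp, sid in (
            ("surface_snow", f"SS_D{day}"),
            ("bulk_snow", f"BS_D{day}"),
        ):
            columns[sid] = draw_sample(snow_full)
            sample_rows.append(
                {"sample_id": sid, "compartment": comp, "day": day, "is_control": False}
            )
        sid = f"SO_D{day}"
        columns[sid] = draw_sample(soil_day_profiles[day])
        sample_rows.append(
            {"sample_id": sid, "compartment": "soil", "day": day, "is_control": False}
        )

    # --- contaminants into real samples (low prevalence, low abundance) ----
    counts = np.column_stack([columns[s["sample_id"]] for s in sample_rows])
    contam_rows = [index[f] for f in contaminants]
    for i in contam_rows:
        for j in range(counts.shape[1]):
            if rng.random() < config.contaminant_sample_prevalence:
                counts[i, j] += rng.integers(1, 20)

    # --- negative controls --------------------------------------------------
    control_cols = []
    for c in range(config.n_controls):
        col = np.zeros(n_total, dtype=np.int64)
        for i in contam_rows:
            if rng.random() < config.contaminant_control_prevalence:
                col[i] = rng.integers(5, 200)
        if config.control_crosstalk_rate > 0:
            real = np.flatnonzero(counts.sum(axis=1) > 0)
            for i in real:
                if rng.random() < config.control_crosstalk_rate:
                    col[i] += rng.integers(1, 5)
        control_cols.append(col)
        sid = f"NC_{c + 1}"
        sample_rows.append(
            {"sample_id": sid, "compartment": "negative_control",
             "day": pd.NA, "is_control": True}
        )
    counts = np.column_stack([counts] + control_cols)

    meta = pd.DataFrame(sample_rows).set_index("sample_id")
    meta["day"] = meta["day"].astype("Int64")
    table = CountTable(
        counts=counts,
        feature_ids=tuple(feature_ids),
        sample_ids=tuple(meta.index),
    )
    taxonomy = _fake_taxonomy(rng, feature_ids, {})
    truth = SimulationTruth(
        coloniser_ids=frozenset(colonisers),
        contaminant_ids=frozenset(contaminants),
        resident_soil_ids=frozenset(residents),
        snow_only_ids=frozenset(snow_only),
        shared_background_ids=frozenset(shared),
        soil_presence_days={f: tuple(d) for f, d in soil_presence_days.items()},
    )
    return table, meta, taxonomy, truth


def recovery_benchmark_config(seed: int = 0) -> SimulationConfig:
    """Idealised noise-free recovery regime: deep sampling, certain
    establishment, undamped transfer, no control cross-talk.

    200 features (100 snow-only, 60 residents, 20 shared, 20 colonisers),
    depth 1e5. Used to check that the occupancy rules recover exactly the
    planted colonisers when detection is not depth-limited.
    """
    return SimulationConfig(
        n_features_snow=100,
        n_features_soil=60,
        n_shared_background=20,
        n_colonisers=20,
        n_contaminants=0,
        depth_mean=1e5,
        depth_dispersion=0.1,
        coloniser_establishment_prob=1.0,
        transfer_fraction=1.0,
        snow_soil_biomass_ratio=1.0,
        control_crosstalk_rate=0.0,
        contaminant_sample_prevalence=0.0,
        seed=seed,
    )


def evaluate_recovery(
    predicted: set | frozenset,
    truth: SimulationTruth,
    target: str = "potential",
    final_day: int = DEFAULT_DAYS[-1],
    min_soil_detections: int = 2,
) -> dict:
    """Score a predicted coloniser set against the simulation truth.

    Sensitivity = |predicted ∩ eligible| / |eligible|, where eligibility
    applies the classifier's own rule parameters to the truth trajectories;
    precision analogously over the predictions. Empty denominators give NaN
    (reported, not raised). Also returns the false-discovery list.
    """
    predicted = frozenset(predicted)
    eligible = truth.eligible(target, final_day, min_soil_detections)
    tp = predicted & eligible
    false_discoveries = sorted(predicted - eligible)
    sensitivity = len(tp) / len(eligible) if eligible else float("nan")
    precision = len(tp) / len(predicted) if predicted else float("nan")
    return {
        "sensitivity": sensitivity,
        "precision": precision,
        "n_eligible": len(eligible),
        "n_predicted": len(predicted),
        "false_discoveries": false_discoveries,
    }
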
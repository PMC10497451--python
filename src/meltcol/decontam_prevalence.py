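"""Prevalence-based contaminant identification against negative controls.

Low-biomass amplicon libraries (melted snow especially) are prone to reagent
and sequencing contamination. The prevalence approach compares, for each
feature, how often it is present in negative controls versus in true samples:
a feature more prevalent in controls than in samples is called a contaminant.

For every feature a 2x2 contingency table (present/absent x control/sample)
is scored with a one-sided significance probability of control enrichment:

* chi-square test (with the usual signed halving of the two-sided p-value)
  when every expected cell count is >= 5;
* exact one-sided hypergeometric (Fisher) test otherwise.

Small scores indicate contaminants; a feature is flagged when its score is
below the threshold (default 0.5, i.e. "more prevalent in controls than in
samples"). Extraction-kit and sequencing negative controls are pooled into a
single control class.

Conventions for degenerate features:

* present only in controls -> score forced to 0 (contaminant by definition);
* absent everywhere -> score undefined (NaN), retained by convention.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .table_io import CountTable, check_paired

__all__ = [
    "ContaminantReport",
    "presence_absence",
    "prevalence_score",
    "classify_contaminants",
    "remove_contaminants",
]


@dataclass(frozen=True)
class ContaminantReport:
    """Per-feature contaminant calls plus the parameters that produced them.

    ``per_feature`` columns: ``prev_samples``, ``prev_controls`` (presence
    fractions), ``score`` (NaN when undefined), ``method`` (``chisq``,
    ``fisher``, ``forced`` or ``undefined``) and ``is_contaminant``.
    """

    per_feature: pd.DataFrame
    threshold: float
    n_controls: int
    n_samples: int

    @property
    def contaminant_ids(self) -> tuple[str, ...]:
        flagged = self.per_feature.index[self.per_feature["is_contaminant"]]
        return tuple(flagged)

    def to_tsv(self, path) -> None:
        out = self.per_feature.copy()
        out.insert(0, "feature_id", out.index)
        out.to_csv(path, sep="\t", index=False)


def presence_absence(table: CountTable, detection_threshold: int = 1) -> np.ndarray:
    """Boolean features x samples matrix: entry true iff count >= threshold."""
    if detection_threshold < 1:
        raise ValueError("detection_threshold must be >= 1")
    return table.counts >= detection_threshold


def prevalence_score(
    feature_presence: np.ndarray, is_control: np.ndarray
) -> tuple[float, str]:
    """One-sided control-enrichment significance for one feature.

    Parameters
    ----------
    feature_presence : boolean vector over samples (presence calls).
    is_control : boolean vector marking negative controls.

    Returns
    -------
    (score, method)
        ``score`` in [0, 1] (NaN if the feature is absent everywhere; 0.0 if
        present only in controls); ``method`` records which branch decided.

    Small scores mean the feature looks control-enriched, i.e. a contaminant.
    """
    feature_presence = np.asarray(feature_presence, dtype=bool)
    is_control = np.asarray(is_control, dtype=bool)
    if feature_presence.shape != is_control.shape:
        raise ValueError("presence and control vectors must have equal length")
    n_controls = int(is_control.sum())
    n_samples = int((~is_control).sum())
    if n_controls == 0 or n_samples == 0:
        raise ValueError("need at least one control and one non-control sample")

    pres_ctrl = int(feature_presence[is_control].sum())
    pres_samp = int(feature_presence[~is_control].sum())

    if pres_ctrl + pres_samp == 0:
        return float("nan"), "undefined"
    if pres_samp == 0:  # present only in controls: contaminant by definition
        return 0.0, "forced"

    # 2x2 table: rows present/absent, columns control/sample
    table22 = np.array(
        [
            [pres_ctrl, pres_samp],
            [n_controls - pres_ctrl, n_samples - pres_samp],
        ]
    )
    total = table22.sum()
    expected = np.outer(table22.sum(axis=1), table22.sum(axis=0)) / total
    prev_ctrl = pres_ctrl / n_controls
    prev_samp = pres_samp / n_samples
    if (expected >= 5).all():
        chi2, p_two, _, _ = stats.chi2_contingency(table22, correction=False)
        score = p_two / 2 if prev_ctrl > prev_samp else 1 - p_two / 2
        return float(score), "chisq"
    # exact one-sided hypergeometric: P(control presences >= observed | margins)
    _, p_one = stats.fisher_exact(table22, alternative="greater")
    return float(p_one), "fisher"


def classify_contaminants(
    table: CountTable,
    meta: pd.DataFrame,
    threshold: float = 0.5,
    detection_threshold: int = 1,
) -> ContaminantReport:
    """Score every feature against the negative controls and flag contaminants.

    ``is_contaminant`` is true when the score is defined and below
    ``threshold``. The flagged set is monotone in the threshold.
    """
    if not 0 < threshold < 1:
        raise ValueError("threshold must lie in (0, 1)")
    check_paired(table, meta)
    is_control = meta.loc[list(table.sample_ids), "is_control"].to_numpy(dtype=bool)
    if not is_control.any():
        raise ValueError("no negative-control samples in metadata")
    if is_control.all():
        raise ValueError("no non-control samples in metadata")

    presence = presence_absence(table, detection_threshold)
    n_controls = int(is_control.sum())
    n_samples = int((~is_control).sum())

    rows = []
    for i, fid in enumerate(table.feature_ids):
        score, method = prevalence_score(presence[i], is_control)
        rows.append(
            {
                "feature_id": fid,
                "prev_samples": presence[i, ~is_control].mean(),
                "prev_controls": presence[i, is_control].mean(),
                "score": score,
                "method": method,
                "is_contaminant": bool(np.isfinite(score) and score < threshold),
            }
        )
    per_feature = pd.DataFrame(rows).set_index("feature_id")
    return ContaminantReport(
        per_feature=per_feature,
        threshold=threshold,
        n_controls=n_controls,
        n_samples=n_samples,
    )


def remove_contaminants(table: CountTable, report: ContaminantReport) -> CountTable:
    """Drop flagged features; counts of survivors are unchanged."""
    flagged = set(report.contaminant_ids)
    unknown = flagged - set(table.feature_ids)
    if unknown:
        raise ValueError(f"report flags features absent from table: {sorted(unknown)[:5]}")
    keep = [f for f in table.feature_ids if f not in flagged]
    if not keep:
        warnings.warn("all features flagged as contaminants; returning empty table",
                      stacklevel=2)
    return table.select_features(keep)
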
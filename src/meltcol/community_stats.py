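"""Supporting community statistics: alpha diversity, Bray-Curtis, PCoA,
phylum composition with rare-phylum lumping, and linear time trends.

Notes on choices:

* Alpha diversity defaults to the Shannon index with natural logarithm
  (H = -sum p_i ln p_i); observed richness is reported alongside. Output
  headers name the index.
* PCoA is classical metric scaling (double-centre -0.5 * D^2, eigendecompose).
  Negative eigenvalues are reported, not corrected (no Lingoes/Cailliez);
  their axes are excluded. Axis signs are arbitrary.
* Trend p-values are raw (no multiple-testing correction) — callers comparing
  many trends should correct downstream.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from skbio import DistanceMatrix
from skbio.stats.ordination import pcoa as _skbio_pcoa

from .table_io import CountTable, RelAbundanceTable

__all__ = [
    "TrendFit",
    "shannon",
    "observed_richness",
    "alpha_diversity",
    "bray_curtis",
    "pcoa",
    "phylum_composition",
    "fit_time_trend",
]


def shannon(counts: np.ndarray) -> float:
    """Shannon diversity H = -sum p_i ln p_i over the positive fractions.

    0 for a single-taxon sample; bounded above by ln(richness), with equality
    iff abundances are uniform. Raises on an all-zero vector.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.size == 0 or (counts < 0).any():
        raise ValueError("counts must be a non-empty non-negative vector")
    total = counts.sum()
    if total == 0:
        raise ValueError("Shannon diversity undefined for an all-zero sample")
    p = counts[counts > 0] / total
    return float(-(p * np.log(p)).sum())


def observed_richness(counts: np.ndarray) -> int:
    """Number of features with a positive count."""
    return int((np.asarray(counts) > 0).sum())


def alpha_diversity(table: CountTable) -> pd.DataFrame:
    """Per-sample diversity: columns ``shannon_ln`` and ``observed_richness``."""
    rows = {}
    for j, sid in enumerate(table.sample_ids):
        col = table.counts[:, j]
        rows[sid] = {
            "shannon_ln": shannon(col) if col.sum() else np.nan,
            "observed_richness": observed_richness(col),
        }
    return pd.DataFrame.from_dict(rows, orient="index").rename_axis("sample_id")


def bray_curtis(table: RelAbundanceTable | CountTable) -> DistanceMatrix:
    """Bray-Curtis dissimilarity between samples.

    d(j,k) = sum_i |x_ij - x_ik| / sum_i (x_ij + x_ik). A semimetric: zero
    diagonal and symmetry hold, the triangle inequality need not. The distance
    between two all-zero samples is defined as 0 (with a warning).
    """
    x = (table.counts if isinstance(table, CountTable) else table.fractions).astype(float)
    if x.shape[1] < 2:
        raise ValueError("need at least two samples")
    n = x.shape[1]
    d = np.zeros((n, n))
    zero_pair = False
    for j in range(n):
        for k in range(j + 1, n):
            denom = (x[:, j] + x[:, k]).sum()
            if denom == 0:
                zero_pair = True
                val = 0.0
            else:
                val = np.abs(x[:, j] - x[:, k]).sum() / denom
            d[j, k] = d[k, j] = val
    if zero_pair:
        warnings.warn("all-zero sample pair: Bray-Curtis defined as 0", stacklevel=2)
    return DistanceMatrix(d, ids=list(table.sample_ids))


@dataclass(frozen=True)
class PCoAResult:
    coordinates: pd.DataFrame  # samples x retained axes
    eigenvalues: np.ndarray  # all eigenvalues, descending (negatives included)
    proportion_explained: np.ndarray  # over retained (positive) axes


def pcoa(d: DistanceMatrix, k: int = 2) -> PCoAResult:
    """Principal coordinates analysis (classical metric scaling).

    Returns the top-``k`` axes ordered by eigenvalue. Negative eigenvalues are
    reported in ``eigenvalues`` but never yield axes; if fewer than ``k``
    positive eigenvalues exist the returned axes are truncated with a warning.
    Axis signs are arbitrary.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    with warnings.catch_warnings():
        # skbio warns when asked for all dimensions; that is what we want
        warnings.filterwarnings("ignore", category=RuntimeWarning, module="skbio")
        res = _skbio_pcoa(d, method="eigh", number_of_dimensions=0)
    eigvals = res.eigvals.to_numpy()
    positive = int((eigvals > 1e-12).sum())
    kept = min(k, positive)
    if kept < k:
        warnings.warn(
            f"only {positive} positive eigenvalues; returning {kept} axes", stacklevel=2
        )
    coords = res.samples.iloc[:, :kept].copy()
    coords.columns = [f"PC{i + 1}" for i in range(kept)]
    coords.index = pd.Index(d.ids, name="sample_id")
    total_positive = eigvals[eigvals > 0].sum()
    prop = (eigvals[:kept] / total_positive) if total_positive > 0 else np.zeros(kept)
    return PCoAResult(
        coordinates=coords,
        eigenvalues=eigvals,
        proportion_explained=np.asarray(prop),
    )


def phylum_composition(
    rel: RelAbundanceTable,
    taxonomy: pd.DataFrame,
    min_fraction: float = 0.01,
    groups: pd.Series | None = None,
    other_label: str = "Other (<1%)",
) -> pd.DataFrame:
    """Per-sample phylum fractions with rare phyla lumped into an "Other" bin.

    A phylum is lumped when its mean fraction within its grouping (by default
    one global group; pass per-sample group labels, e.g. compartments, to lump
    per facet) is below ``min_fraction``. Features without a phylum go to
    ``Unassigned``. Columns are samples, rows phyla; each column sums to 1
    (up to the source table's column sums).
    """
    if not 0 <= min_fraction < 1:
        raise ValueError("min_fraction must lie in [0, 1)")
    frame = rel.to_frame()
    phyla = pd.Series(
        [
            taxonomy.loc[f, "phylum"]
            if f in taxonomy.index and pd.notna(taxonomy.loc[f, "phylum"])
            else "Unassigned"
            for f in frame.index
        ],
        index=frame.index,
    )
    by_phylum = frame.groupby(phyla).sum()

    if groups is None:
        groups = pd.Series("all", index=frame.columns)
    else:
        groups = groups.reindex(frame.columns)

    lumped = by_phylum.copy()
    if min_fraction > 0:
        rare_anywhere = set()
        rare_per_group: dict[str, set] = {}
        for g in groups.unique():
            cols = groups.index[groups == g]
            means = by_phylum[cols].mean(axis=1)
            rare_per_group[g] = set(means.index[means < min_fraction])
        # lump within each group independently
        out = by_phylum.copy()
        for g, rare in rare_per_group.items():
            cols = groups.index[groups == g]
            if not rare:
                continue
            other = out.loc[sorted(rare), cols].sum(axis=0)
            out.loc[sorted(rare), cols] = 0.0
            if other_label not in out.index:
                out.loc[other_label] = 0.0
            out.loc[other_label, cols] += other
        lumped = out[(out != 0).any(axis=1)]
    return lumped


@dataclass(frozen=True)
class TrendFit:
    """Simple linear regression of a response on sampling day."""

    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n: int


def fit_time_trend(values, days) -> TrendFit:
    """Ordinary least squares of ``values`` on ``days``.

    R-squared and the two-sided p-value of the slope from the F(1, n-2) test
    (identical to the two-sided t-test in simple regression). Requires n >= 3
    and at least two distinct days.
    """
    values = np.asarray(values, dtype=float)
    days = np.asarray(days, dtype=float)
    if values.shape != days.shape:
        raise ValueError("values and days must have equal length")
    n = len(values)
    if n < 3:
        raise ValueError("need at least 3 observations to fit a trend")
    if np.ptp(days) == 0:
        raise ValueError("days must not all be equal")
    if np.ptp(values) == 0:  # constant response: flat fit, no explained variance
        return TrendFit(slope=0.0, intercept=float(values[0]), r_squared=0.0,
                        p_value=1.0, n=n)
    res = stats.linregress(days, values)
    return TrendFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        p_value=float(res.pvalue) if np.isfinite(res.pvalue) else 1.0,
        n=n,
    )
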
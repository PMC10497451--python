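"""Shared fixtures and independent oracles for the test suite.

The oracles here are deliberately naive (literal set operations, explicit
combinatorial enumeration, closed-form formulas) and share no code with the
implementation paths they check.
"""

from __future__ import annotations

from math import comb

import numpy as np
import pandas as pd
import pytest

import meltcol as mc


@pytest.fixture(scope="session")
def toy():
    """The bundled 12-feature x 18-sample worked example."""
    return mc.load_toy_dataset()


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def make_table(rng: np.random.Generator, n_features=8, n_samples=5) -> mc.CountTable:
    counts = rng.integers(0, 50, size=(n_features, n_samples))
    return mc.CountTable(
        counts=counts,
        feature_ids=tuple(f"F{i}" for i in range(n_features)),
        sample_ids=tuple(f"S{j}" for j in range(n_samples)),
    )


# ---------------------------------------------------------------------------
# Independent oracles


def hypergeom_tail_oracle(a: int, b: int, c: int, d: int) -> float:
    """P(X >= a) for X hypergeometric, by literal enumeration with binomials.

    2x2 table [[a, b], [c, d]]: a = present controls, b = present samples,
    c = absent controls, d = absent samples. Conditions on both margins.
    """
    n_present = a + b
    n_controls = a + c
    total = a + b + c + d
    denom = comb(total, n_present)
    prob = 0.0
    for x in range(a, min(n_present, n_controls) + 1):
        if n_present - x > total - n_controls:
            continue
        prob += comb(n_controls, x) * comb(total - n_controls, n_present - x) / denom
    return prob


def brute_force_classify(
    snow_days: set,
    soil_days: set,
    days: list,
    snow_missing: set,
    soil_missing: set,
    snow_persistence: str = "any",
    tie_policy: str = "soil_first",
) -> str:
    """Literal set-operation version of the coloniser rule walk."""
    if not soil_days:
        return "snow_only"
    if not snow_days:
        return "soil_only"
    first_day = days[0]
    if first_day not in soil_missing and first_day in soil_days:
        return "resident_day1"
    first_snow = min(snow_days)
    first_soil = min(soil_days)
    if first_soil < first_snow:
        return "soil_first"
    if first_soil == first_snow and tie_policy == "soil_first":
        return "soil_first"
    observed_snow = [d for d in days if d not in snow_missing]
    if snow_persistence == "any":
        persistent = len(snow_days) >= 1
    elif snow_persistence == "all_days":
        persistent = all(d in snow_days for d in observed_snow)
    elif snow_persistence == "before_soil":
        persistent = all(d in snow_days for d in observed_snow if d < first_soil)
    else:  # pragma: no cover
        raise ValueError(snow_persistence)
    return "potential_coloniser" if persistent else "soil_first"


def all_histories(n_days: int) -> mc.DetectionHistory:
    """One feature per possible boolean (snow, soil) history over n_days."""
    n = 2 ** (2 * n_days)
    bits = ((np.arange(n)[:, None] >> np.arange(2 * n_days)[None, :]) & 1).astype(bool)
    return mc.DetectionHistory(
        feature_ids=tuple(f"h{i}" for i in range(n)),
        days=tuple(range(1, n_days + 1)),
        snow=bits[:, :n_days],
        soil=bits[:, n_days:],
        snow_missing=np.zeros(n_days, bool),
        soil_missing=np.zeros(n_days, bool),
    )


def ols_oracle(days, values):
    """Closed-form simple OLS: slope, intercept, R^2 and the F(1, n-2) p-value."""
    from scipy.stats import f as f_dist

    x = np.asarray(days, dtype=float)
    y = np.asarray(values, dtype=float)
    n = len(x)
    xbar, ybar = x.mean(), y.mean()
    sxx = ((x - xbar) ** 2).sum()
    sxy = ((x - xbar) * (y - ybar)).sum()
    slope = sxy / sxx
    intercept = ybar - slope * xbar
    resid = y - (intercept + slope * x)
    ss_res = (resid**2).sum()
    ss_tot = ((y - ybar) ** 2).sum()
    r2 = 1 - ss_res / ss_tot if ss_tot > 0 else 0.0
    if ss_res == 0:
        p = 0.0
    else:
        f_stat = (ss_tot - ss_res) / (ss_res / (n - 2))
        p = float(f_dist.sf(f_stat, 1, n - 2))
    return slope, intercept, r2, p
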
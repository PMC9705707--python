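"""Whole-cell fluorescence readout: vehicle normalization and one-sample tests.

Median reporter fluorescence per sample is normalized to the mean of the
matched vehicle-control replicates, and each compound's normalized values
are tested against a hypothetical mean of 1 with a two-tailed one-sample
t-test. An increase above 1 indicates a net gain in reactive (exposed)
thiols across the cell population.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError
from .features import significance_stars

VEHICLE = "vehicle"


def normalize_medians(table: pd.DataFrame, vehicle_label: str = VEHICLE) -> pd.DataFrame:
    """Divide each treated median by the mean of its batch's vehicle medians.

    A ``batch`` column, when present, pairs treated samples with their own
    vehicle replicates; otherwise the whole table is one batch. Medians must
    be positive; missing vehicle rows are a configuration error.
    """
    if (table["median"] <= 0).any():
        raise ConfigurationError("median fluorescence values must be > 0")
    if "batch" not in table.columns:
        table = table.assign(batch="all")
    out = []
    for batch, group in table.groupby("batch", sort=True):
        vehicle = group.loc[group["condition"] == vehicle_label, "median"]
        if vehicle.empty:
            raise ConfigurationError(f"batch {batch!r} has no {vehicle_label!r} rows")
        reference = float(vehicle.mean())
        treated = group[group["condition"] != vehicle_label].copy()
        treated["normalized"] = treated["median"] / reference
        out.append(treated)
    if not out:
        raise ConfigurationError("no treated rows to normalize")
    return pd.concat(out, ignore_index=True)[
        ["sample_id", "condition", "batch", "replicate", "median", "normalized"]]


@dataclass
class OneSampleResult:
    """Two-tailed one-sample t-test of normalized ratios against 1."""

    n: int
    mean: float
    t: float
    p: float
    stars: str
    degenerate: bool


def one_sample_test(values, popmean: float = 1.0) -> OneSampleResult:
    """Test normalized values against ``popmean`` (default 1)."""
    arr = np.asarray(values, dtype=float)
    arr = arr[~np.isnan(arr)]
    if arr.size < 2:
        raise ConfigurationError("one-sample test requires >= 2 values")
    mean = float(arr.mean())
    if float(arr.std(ddof=1)) == 0.0:
        return OneSampleResult(n=arr.size, mean=mean, t=np.nan, p=np.nan,
                               stars="", degenerate=True)
    res = stats.ttest_1samp(arr, popmean)
    p = float(res.pvalue)
    return OneSampleResult(n=arr.size, mean=mean, t=float(res.statistic), p=p,
                           stars=significance_stars(p), degenerate=False)


def analyze_cytometry(table: pd.DataFrame, vehicle_label: str = VEHICLE) -> pd.DataFrame:
    """Normalize and test every compound; one result row per compound."""
    normalized = normalize_medians(table, vehicle_label=vehicle_label)
    rows = []
    for compound, group in normalized.groupby("condition", sort=True):
        result = one_sample_test(group["normalized"])
        rows.append({"condition": compound, **result.__dict__})
    return pd.DataFrame(rows)
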
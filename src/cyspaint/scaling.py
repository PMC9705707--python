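"""P-value-weighted scaling, control-derived thresholds and classification.

Each peptide's replicate values (corrected cys ratios on the cys axis, plain
log2 ratios on the noncys axis) are collapsed to a single scaled value:

    scaled = mean * (1 - p)

where p is the two-tailed one-sample t-test of the replicates against 0.
The weight shrinks uncertain means toward the null instead of imposing a
hard significance cutoff. Thresholds are then derived from a vehicle-vs-
vehicle control experiment so that they contain a chosen fraction (default
95%) of the control scaled values; peptides above the upper threshold are
called exposed, below the lower threshold protected, otherwise unchanged.

Threshold fitting offers two methods. The default, ``empirical``, takes the
central-coverage quantiles of the control scaled values and therefore
contains the nominal fraction exactly regardless of distributional shape
(the scaled values are noticeably heavier-tailed than Gaussian, because the
weight compresses the middle of the distribution more than the tails). The
``gaussian`` method uses mean ± z·SD with z the two-sided normal quantile
(1.96 at 95% coverage); it matches the classical z-score framing but
under-covers on the scaled scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError, FittingError
from .io import ratio_columns

CLASS_EXPOSED = "exposed"
CLASS_PROTECTED = "protected"
CLASS_UNCHANGED = "unchanged"
CLASS_UNQUANTIFIED = "unquantified"

AXIS_CYS = "cys"
AXIS_NONCYS = "noncys"


def pvalue_weighted_scale(values) -> tuple[float, float, float, int]:
    """Collapse replicate values to (mean, p, scaled, n_quantified).

    ``scaled = mean * (1 - p)`` with p the two-tailed one-sample t-test
    against 0. Conventions for degenerate inputs: identical nonzero values
    (zero SD) take weight 1; all-zero values scale to 0; fewer than two
    quantified values make the peptide unquantifiable (all-NaN result).
    """
    arr = np.asarray(values, dtype=float)
    arr = arr[~np.isnan(arr)]
    n = arr.size
    if n < 2:
        return (np.nan, np.nan, np.nan, n)
    mean = float(arr.mean())
    sd = float(arr.std(ddof=1))
    if sd == 0.0:
        p = 1.0 if mean == 0.0 else 0.0
    else:
        with warnings.catch_warnings():
            # near-identical replicates trigger a benign precision warning
            warnings.simplefilter("ignore", RuntimeWarning)
            p = float(stats.ttest_1samp(arr, 0.0).pvalue)
    return (mean, p, mean * (1.0 - p), n)


def scale_table(table: pd.DataFrame, axis: str, weight=None) -> pd.DataFrame:
    """Vectorized p-value-weighted scaling of every peptide row.

    Returns one row per peptide with columns ``n_quantified``, ``mean``,
    ``p_value``, ``scaled``, ``quantifiable`` and ``axis``. Peptides with
    fewer than two quantified replicates are kept but flagged
    unquantifiable (NaN scaled value). ``weight`` maps the p-value array to
    the shrinkage weights (default ``1 - p``); any replacement must stay
    within [0, 1].
    """
    if axis not in (AXIS_CYS, AXIS_NONCYS):
        raise ConfigurationError(f"axis must be '{AXIS_CYS}' or '{AXIS_NONCYS}'")
    rcols = ratio_columns(table)
    values = table[rcols].to_numpy(dtype=float)
    n_quant = np.sum(~np.isnan(values), axis=1)
    # rows with < 2 values legitimately produce NaN statistics (flagged below)
    with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(np.where(np.isnan(values), np.nan, values), axis=1)
        sd = np.nanstd(values, axis=1, ddof=1)
        res = stats.ttest_1samp(values, 0.0, axis=1, nan_policy="omit")
    p = np.asarray(res.pvalue, dtype=float)
    # zero-SD conventions: identical nonzero -> weight 1; all zero -> scaled 0
    zero_sd = (sd == 0) & (n_quant >= 2)
    p = np.where(zero_sd & (mean != 0), 0.0, p)
    p = np.where(zero_sd & (mean == 0), 1.0, p)
    w = (1.0 - p) if weight is None else np.asarray(weight(p), dtype=float)
    scaled = mean * w
    quantifiable = n_quant >= 2
    mean = np.where(quantifiable, mean, np.nan)
    p = np.where(quantifiable, p, np.nan)
    scaled = np.where(quantifiable, scaled, np.nan)

    meta_cols = [c for c in ("peptide_id", "sequence", "protein", "gene", "stimulus")
                 if c in table.columns]
    out = table[meta_cols].copy()
    out["n_quantified"] = n_quant
    out["mean"] = mean
    out["p_value"] = p
    out["scaled"] = scaled
    out["quantifiable"] = quantifiable
    out["axis"] = axis
    return out


@dataclass(frozen=True)
class ControlThresholds:
    """Classification thresholds derived from a control dataset."""

    axis: str
    lower: float
    upper: float
    mean: float
    sd: float
    coverage: float
    z: float
    method: str
    n: int

    def __post_init__(self):
        if not self.upper > self.lower:
            raise FittingError("upper threshold must exceed lower threshold")


def two_sided_z(coverage: float) -> float:
    """Two-sided standard-normal quantile for a central coverage (1.96 at 0.95)."""
    if not 0 < coverage < 1:
        raise ConfigurationError("coverage must be in (0, 1)")
    return float(stats.norm.ppf(0.5 + coverage / 2.0))


def fit_control_thresholds(
    control_scaled,
    coverage: float = 0.95,
    method: str = "empirical",
    axis: str = AXIS_CYS,
    min_values: int = 30,
) -> ControlThresholds:
    """Fit lower/upper thresholds containing ``coverage`` of the control values.

    ``method="empirical"`` (default) uses the central-coverage sample
    quantiles; ``method="gaussian"`` uses mean ± z·SD. Requires at least
    ``min_values`` finite control values with positive SD.
    """
    values = np.asarray(control_scaled, dtype=float)
    values = values[np.isfinite(values)]
    if values.size < min_values:
        raise FittingError(
            f"need >= {min_values} control values to fit thresholds, got {values.size}")
    mean = float(values.mean())
    sd = float(values.std(ddof=1))
    if sd == 0.0:
        raise FittingError("control values are constant; thresholds undefined")
    z = two_sided_z(coverage)
    if method == "gaussian":
        lower, upper = mean - z * sd, mean + z * sd
    elif method == "empirical":
        alpha = (1.0 - coverage) / 2.0
        lower, upper = (float(q) for q in np.quantile(values, [alpha, 1.0 - alpha]))
    else:
        raise ConfigurationError("method must be 'empirical' or 'gaussian'")
    return ControlThresholds(axis=axis, lower=lower, upper=upper, mean=mean, sd=sd,
                             coverage=coverage, z=z, method=method, n=values.size)


def classify(scaled, thresholds: ControlThresholds, axis: str | None = None):
    """Classify scaled values against control thresholds (strict inequalities).

    Values exactly on a threshold are unchanged; NaN values are
    unquantified. ``axis``, when given, must match the axis the thresholds
    were fitted on.
    """
    if axis is not None and axis != thresholds.axis:
        raise ConfigurationError(
            f"axis mismatch: thresholds fitted on {thresholds.axis!r}, data is {axis!r}")
    arr = np.asarray(scaled, dtype=float)
    out = np.where(arr > thresholds.upper, CLASS_EXPOSED,
                   np.where(arr < thresholds.lower, CLASS_PROTECTED, CLASS_UNCHANGED))
    out = np.where(np.isnan(arr), CLASS_UNQUANTIFIED, out)
    if np.isscalar(scaled):
        return str(out)
    if isinstance(scaled, pd.Series):
        return pd.Series(out, index=scaled.index, name="classification")
    return out


def classify_table(calls: pd.DataFrame, thresholds: ControlThresholds) -> pd.DataFrame:
    """Attach a classification column to a scaled-call table."""
    axes = set(calls["axis"].unique())
    if axes - {thresholds.axis}:
        raise ConfigurationError(
            f"axis mismatch: thresholds fitted on {thresholds.axis!r}, table has {axes}")
    out = calls.copy()
    out["classification"] = classify(out["scaled"], thresholds)
    return out
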
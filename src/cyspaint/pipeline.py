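"""High-level orchestration: peptide table in, classified calls out.

Thin glue over the stage modules, used by the command-line interface and by
end-to-end tests. The canonical flow is::

    control peptide table --quantify--> corrected ratios --scale--> calls
                                                           |
                                       fit thresholds <----+
    stimulus peptide table --quantify--> --scale--> --classify--> calls
    per-stimulus calls --> comparison matrix --> network / features
"""

from __future__ import annotations

import pandas as pd

from . import reactivity, scaling
from .comparison import ComparisonMatrix, build_comparison_matrix


def scale_dataset(result: reactivity.ReactivityResult) -> pd.DataFrame:
    """P-value-weighted scaling of both axes of a quantified dataset.

    Returns the concatenated cys-axis (corrected ratios) and noncys-axis
    (raw log2 ratios) call tables.
    """
    cys_calls = scaling.scale_table(result.corrected, axis=scaling.AXIS_CYS)
    noncys_calls = scaling.scale_table(result.noncys, axis=scaling.AXIS_NONCYS)
    return pd.concat([cys_calls, noncys_calls], ignore_index=True)


def fit_thresholds(
    control_calls: pd.DataFrame,
    coverage: float = 0.95,
    method: str = "empirical",
) -> dict[str, scaling.ControlThresholds]:
    """Fit per-axis control thresholds from a scaled control call table."""
    thresholds = {}
    for axis, group in control_calls.groupby("axis"):
        values = group.loc[group["quantifiable"], "scaled"]
        thresholds[axis] = scaling.fit_control_thresholds(
            values, coverage=coverage, method=method, axis=axis)
    return thresholds


def classify_calls(
    calls: pd.DataFrame,
    thresholds: dict[str, scaling.ControlThresholds],
) -> pd.DataFrame:
    """Classify a scaled call table axis by axis."""
    parts = [scaling.classify_table(group, thresholds[axis])
             for axis, group in calls.groupby("axis")]
    return pd.concat(parts, ignore_index=True)


def run_stimulus(
    table: pd.DataFrame,
    thresholds: dict[str, scaling.ControlThresholds],
    patterns=reactivity.DEFAULT_CONTAMINANT_PATTERNS,
    center: str = "mean",
) -> pd.DataFrame:
    """Quantify, scale and classify one stimulus peptide table."""
    result = reactivity.quantify(table, patterns=patterns, center=center)
    calls = scale_dataset(result)
    return classify_calls(calls, thresholds)


def run_control(
    table: pd.DataFrame,
    coverage: float = 0.95,
    method: str = "empirical",
    patterns=reactivity.DEFAULT_CONTAMINANT_PATTERNS,
    center: str = "mean",
) -> tuple[pd.DataFrame, dict[str, scaling.ControlThresholds]]:
    """Quantify and scale the control table, fit thresholds, classify it."""
    result = reactivity.quantify(table, patterns=patterns, center=center)
    calls = scale_dataset(result)
    thresholds = fit_thresholds(calls, coverage=coverage, method=method)
    return classify_calls(calls, thresholds), thresholds


def compare_stimuli(classified_by_stimulus: list[pd.DataFrame]) -> ComparisonMatrix:
    """Build the comparison matrix from classified cys calls of >= 2 stimuli."""
    cys = [c[c["axis"] == scaling.AXIS_CYS] for c in classified_by_stimulus]
    return build_comparison_matrix(pd.concat(cys, ignore_index=True))
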
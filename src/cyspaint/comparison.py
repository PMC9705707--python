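"""Cross-stimulus comparison set, signed-max summaries and intersections.

Per protein and stimulus, the cys-peptide scaled values are summarized by
the signed maximum — the scaled value of largest absolute magnitude, sign
preserved (ties in magnitude break toward the positive, i.e. toward
exposure). The comparison set keeps proteins quantified (>= 1 quantifiable
cys call, pre-thresholding) in every stimulus and conformationally changed
in at least one. A protein's degree is the number of stimuli in which it
changed; the intersection summary partitions proteins by the exact
combination of stimuli in which they changed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .errors import ConfigurationError, EmptyMatrixError
from .scaling import CLASS_EXPOSED, CLASS_PROTECTED

logger = logging.getLogger(__name__)


def signed_max(values, by_magnitude: bool = True) -> float:
    """The value of largest |magnitude|, sign preserved; ties break positive.

    ``by_magnitude=False`` returns the literal signed maximum instead.
    """
    arr = [float(v) for v in np.asarray(values, dtype=float) if not np.isnan(v)]
    if not arr:
        raise ValueError("signed_max of an empty value list")
    if not by_magnitude:
        return max(arr)
    return max(arr, key=lambda v: (abs(v), v))


def summarize_protein(calls: pd.DataFrame) -> tuple[float, bool]:
    """Summarize one protein's cys calls under one stimulus.

    Returns (signed max scaled ratio, change flag); the flag is true iff any
    cys peptide was classified exposed or protected.
    """
    quantified = calls.loc[calls["quantifiable"], "scaled"]
    if quantified.empty:
        raise ValueError("protein has no quantifiable cys call for this stimulus")
    changed = calls["classification"].isin([CLASS_EXPOSED, CLASS_PROTECTED]).any()
    return signed_max(quantified), bool(changed)


@dataclass
class ComparisonMatrix:
    """Proteins x stimuli signed-max ratios with change flags and degrees."""

    ratios: pd.DataFrame   # float, proteins x stimuli
    changed: pd.DataFrame  # bool, proteins x stimuli
    stimuli: list[str]

    @property
    def proteins(self) -> list[str]:
        return self.ratios.index.tolist()

    @property
    def degree(self) -> pd.Series:
        return self.changed.sum(axis=1).rename("degree")

    def to_frame(self) -> pd.DataFrame:
        """Flat TSV-ready view: ratios, flags and degree per protein."""
        out = self.ratios.add_prefix("ratio_").join(
            self.changed.add_prefix("changed_"))
        out["degree"] = self.degree
        return out.rename_axis("protein").reset_index()

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "ComparisonMatrix":
        """Rebuild a matrix from its :meth:`to_frame` TSV representation."""
        frame = frame.set_index("protein")
        stimuli = sorted(c[len("ratio_"):] for c in frame.columns
                         if c.startswith("ratio_"))
        ratios = frame[[f"ratio_{s}" for s in stimuli]]
        ratios.columns = stimuli
        changed = frame[[f"changed_{s}" for s in stimuli]].astype(bool)
        changed.columns = stimuli
        return cls(ratios=ratios, changed=changed, stimuli=stimuli)


def build_comparison_matrix(classified: pd.DataFrame) -> ComparisonMatrix:
    """Assemble the comparison set from classified cys calls of all stimuli.

    ``classified`` concatenates the per-stimulus classified cys-axis call
    tables (columns ``protein``, ``stimulus``, ``scaled``, ``quantifiable``,
    ``classification``). Proteins must be quantified in every stimulus and
    changed in at least one; both filters are logged with counts.
    """
    stimuli = sorted(classified["stimulus"].unique())
    if len(stimuli) < 2:
        raise ConfigurationError("comparison requires >= 2 stimuli")
    quant = classified[classified["quantifiable"]]
    per_stim = quant.groupby("protein")["stimulus"].nunique()
    in_all = set(per_stim[per_stim == len(stimuli)].index)
    if not in_all:
        raise EmptyMatrixError("no protein is quantified in all stimuli")
    logger.info("%d proteins quantified in all %d stimuli", len(in_all), len(stimuli))

    sub = quant[quant["protein"].isin(in_all)]
    grouped = sub.groupby(["protein", "stimulus"])
    ratios = grouped["scaled"].agg(signed_max).unstack("stimulus")[stimuli]
    changed = (
        sub["classification"].isin([CLASS_EXPOSED, CLASS_PROTECTED])
        .groupby([sub["protein"], sub["stimulus"]]).any().unstack("stimulus")[stimuli]
    )
    keep = changed.any(axis=1)
    logger.info("%d of %d proteins changed in >= 1 stimulus", int(keep.sum()), len(keep))
    if not keep.any():
        raise EmptyMatrixError("no protein changed in any stimulus")
    return ComparisonMatrix(ratios=ratios[keep].sort_index(),
                            changed=changed[keep].sort_index(),
                            stimuli=stimuli)


def intersection_degrees(matrix: ComparisonMatrix) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Partition comparison proteins by the combination of stimuli they changed in.

    Returns (combinations, degrees): per nonempty stimulus combination the
    protein count and proportion, and per degree d in 1..n_stimuli the count
    and proportion. Each protein is counted in exactly one combination, so
    proportions sum to 1 over all proteins.
    """
    n_proteins = len(matrix.changed)
    combo_of = matrix.changed.apply(
        lambda row: "+".join(s for s in matrix.stimuli if row[s]), axis=1)
    combo_counts = combo_of.value_counts()
    combos = pd.DataFrame({
        "combination": combo_counts.index,
        "n_stimuli": [c.count("+") + 1 for c in combo_counts.index],
        "count": combo_counts.to_numpy(),
    })
    combos["proportion"] = combos["count"] / n_proteins
    combos = combos.sort_values(["n_stimuli", "combination"]).reset_index(drop=True)

    degree = matrix.degree
    degrees = pd.DataFrame({
        "degree": range(1, len(matrix.stimuli) + 1),
    })
    degrees["count"] = degrees["degree"].map(degree.value_counts()).fillna(0).astype(int)
    degrees["proportion"] = degrees["count"] / n_proteins
    return combos, degrees


def enumerate_combinations(stimuli: list[str]):
    """All 2^n - 1 nonempty stimulus combinations (brute-force helper)."""
    for k in range(1, len(stimuli) + 1):
        yield from combinations(stimuli, k)


def stimulus_linkage(matrix: ComparisonMatrix):
    """Agglomerative clustering of stimuli (average linkage, Euclidean).

    Presentation helper for heatmap column ordering; returns the scipy
    linkage matrix and the leaf-ordered stimulus list.
    """
    data = matrix.ratios.fillna(0.0).to_numpy().T
    if data.shape[0] < 2:
        raise ConfigurationError("need >= 2 stimuli to cluster")
    link = hierarchy.linkage(pdist(data, metric="euclidean"), method="average")
    order = hierarchy.leaves_list(link)
    return link, [matrix.stimuli[i] for i in order]


def plot_intersections(matrix: ComparisonMatrix, path) -> None:
    """UpSet-style intersection bar chart (optional figure export)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    combos, _ = intersection_degrees(matrix)
    fig, ax = plt.subplots(figsize=(max(6, 0.5 * len(combos)), 4))
    ax.bar(range(len(combos)), combos["count"], color="0.3")
    ax.set_xticks(range(len(combos)))
    ax.set_xticklabels(combos["combination"], rotation=90, fontsize=7)
    ax.set_ylabel("proteins")
    ax.set_title("conformational-change intersections")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
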
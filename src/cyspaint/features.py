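"""Inside/outside pairwise-correlation analysis over functional features.

Comparison proteins are profiled by their signed-max scaled ratio across
stimuli. For every unordered protein pair the Spearman correlation R_s of
those profiles is computed (average ranks for ties); pairs are then binned
per feature: "inside" when both proteins are members, "outside" when exactly
one is, discarded when neither is. For each member protein the mean |R_s| in
each bin is taken, and features with at least three proteins holding both
means are tested with a paired two-tailed t-test of inside minus outside.
For the direct-interaction feature the inside bin is instead the pairs that
share a network edge.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .comparison import ComparisonMatrix
from .errors import ConfigurationError

logger = logging.getLogger(__name__)


def significance_stars(p: float) -> str:
    """Star notation: * p<0.05, ** p<0.01, *** p<0.001."""
    if not np.isfinite(p):
        return ""
    return "***" if p < 0.001 else "**" if p < 0.01 else "*" if p < 0.05 else ""


def pairwise_spearman(matrix: ComparisonMatrix) -> pd.DataFrame:
    """Spearman correlation of stimulus profiles for every unordered protein pair.

    Requires >= 3 stimuli. Profiles with zero rank variance (or missing
    values) give undefined correlations; those pairs are excluded with a
    logged count. Returns columns protein_a, protein_b, rs, abs_rs with
    protein_a < protein_b.
    """
    if len(matrix.stimuli) < 3:
        raise ConfigurationError("pairwise correlation requires >= 3 stimuli")
    data = matrix.ratios.to_numpy(dtype=float)
    proteins = np.array(matrix.proteins)
    ranks = np.apply_along_axis(stats.rankdata, 1, data)
    with np.errstate(invalid="ignore"):
        corr = np.corrcoef(ranks)
    iu = np.triu_indices(len(proteins), k=1)
    pairs = pd.DataFrame({
        "protein_a": proteins[iu[0]],
        "protein_b": proteins[iu[1]],
        "rs": corr[iu],
    })
    n_undefined = int(pairs["rs"].isna().sum())
    if n_undefined:
        logger.info("excluded %d pairs with undefined correlation", n_undefined)
        pairs = pairs.dropna(subset=["rs"]).reset_index(drop=True)
    pairs["abs_rs"] = pairs["rs"].abs()
    return pairs


def inside_outside_means(pairs: pd.DataFrame, feature_members) -> pd.DataFrame:
    """Per-member mean |R_s| with partners inside vs outside a feature.

    A pair is inside when both proteins are feature members, outside when
    exactly one is; pairs with neither member are discarded. Members lacking
    either bin are dropped with a logged count. Returns columns protein,
    inside_mean, outside_mean, n_inside, n_outside.
    """
    members = set(feature_members)
    a_in = pairs["protein_a"].isin(members)
    b_in = pairs["protein_b"].isin(members)
    inside = pairs[a_in & b_in]
    outside = pairs[a_in ^ b_in]

    records = []
    for protein in sorted(members):
        mine_in = inside[(inside["protein_a"] == protein) | (inside["protein_b"] == protein)]
        mine_out = outside[(outside["protein_a"] == protein) | (outside["protein_b"] == protein)]
        records.append((protein, mine_in["abs_rs"].mean(), mine_out["abs_rs"].mean(),
                        len(mine_in), len(mine_out)))
    out = pd.DataFrame(records, columns=["protein", "inside_mean", "outside_mean",
                                         "n_inside", "n_outside"])
    incomplete = out["inside_mean"].isna() | out["outside_mean"].isna()
    if incomplete.any():
        logger.info("dropped %d members lacking an inside or outside bin",
                    int(incomplete.sum()))
    return out[~incomplete].reset_index(drop=True)


def edge_inside_outside_means(pairs: pd.DataFrame, network) -> pd.DataFrame:
    """Inside/outside means for the direct-interaction feature.

    Here the inside bin of a protein is its pairs that share a network edge
    and the outside bin its pairs that do not; proteins with no edge in the
    network (non-members of the feature) are excluded, as are pairs between
    two non-members.
    """
    members = {n for n in network.nodes if network.degree(n) > 0}
    a_in = pairs["protein_a"].isin(members)
    b_in = pairs["protein_b"].isin(members)
    kept = pairs[a_in | b_in].copy()
    kept["has_edge"] = [network.has_edge(a, b)
                        for a, b in zip(kept["protein_a"], kept["protein_b"])]
    records = []
    for protein in sorted(members):
        mine = kept[(kept["protein_a"] == protein) | (kept["protein_b"] == protein)]
        records.append((protein,
                        mine.loc[mine["has_edge"], "abs_rs"].mean(),
                        mine.loc[~mine["has_edge"], "abs_rs"].mean(),
                        int(mine["has_edge"].sum()),
                        int((~mine["has_edge"]).sum())))
    out = pd.DataFrame(records, columns=["protein", "inside_mean", "outside_mean",
                                         "n_inside", "n_outside"])
    incomplete = out["inside_mean"].isna() | out["outside_mean"].isna()
    return out[~incomplete].reset_index(drop=True)


@dataclass
class FeatureCorrelation:
    """Paired inside-vs-outside comparison for one feature."""

    feature: str
    n_proteins: int
    inside_mean: float
    outside_mean: float
    t: float
    p: float
    stars: str
    degenerate: bool = False


def feature_test(per_protein: pd.DataFrame, feature: str = "",
                 min_members: int = 3, mode: str = "paired") -> FeatureCorrelation | None:
    """Two-tailed t-test of per-protein inside vs outside mean |R_s|.

    ``mode="paired"`` (default) tests the per-protein differences;
    ``mode="welch"`` compares the two columns as independent samples.
    Returns None when fewer than ``min_members`` proteins hold both means;
    zero-variance differences set the degenerate flag with undefined p.
    """
    n = len(per_protein)
    if n < min_members:
        return None
    inside = per_protein["inside_mean"].to_numpy(dtype=float)
    outside = per_protein["outside_mean"].to_numpy(dtype=float)
    diffs = inside - outside
    if mode == "paired":
        degenerate = float(np.std(diffs, ddof=1)) == 0.0
        if degenerate:
            t, p = (0.0 if np.allclose(diffs, 0) else np.inf * np.sign(diffs.mean())), np.nan
        else:
            res = stats.ttest_rel(inside, outside)
            t, p = float(res.statistic), float(res.pvalue)
    elif mode == "welch":
        degenerate = np.std(inside, ddof=1) == 0.0 and np.std(outside, ddof=1) == 0.0
        if degenerate:
            t, p = 0.0, np.nan
        else:
            res = stats.ttest_ind(inside, outside, equal_var=False)
            t, p = float(res.statistic), float(res.pvalue)
    else:
        raise ConfigurationError("mode must be 'paired' or 'welch'")
    return FeatureCorrelation(
        feature=feature, n_proteins=n,
        inside_mean=float(inside.mean()), outside_mean=float(outside.mean()),
        t=t, p=p, stars=significance_stars(p), degenerate=degenerate)


def test_features(pairs: pd.DataFrame, annotations: dict,
                  min_members: int = 3, mode: str = "paired") -> pd.DataFrame:
    """Run the inside/outside test for every annotated feature.

    ``annotations`` maps feature id -> member protein set. Emits one row per
    testable feature plus a Benjamini-Hochberg adjusted-p column for
    transparency (the primary readout is the per-feature p and stars).
    """
    rows = []
    for feature in sorted(annotations):
        per_protein = inside_outside_means(pairs, annotations[feature])
        result = feature_test(per_protein, feature, min_members=min_members, mode=mode)
        if result is None:
            logger.info("feature %s skipped (< %d members with both bins)",
                        feature, min_members)
            continue
        rows.append(result.__dict__)
    table = pd.DataFrame(rows, columns=["feature", "n_proteins", "inside_mean",
                                        "outside_mean", "t", "p", "stars", "degenerate"])
    if len(table):
        finite = table["p"].notna()
        table["p_bh"] = np.nan
        if finite.any():
            table.loc[finite, "p_bh"] = multipletests(
                table.loc[finite, "p"], method="fdr_bh")[1]
    return table


def profile_degree_correlation(matrix: ComparisonMatrix) -> tuple[float, int]:
    """Spearman correlation of |signed max ratio| vs protein degree.

    Pooled over all protein x stimulus datapoints. Returns (rs, n); rs is
    NaN (flagged undefined) when either variable has zero variance.
    """
    degree = matrix.degree
    magnitudes = matrix.ratios.abs()
    long = magnitudes.stack().rename("magnitude").reset_index()
    long.columns = ["protein", "stimulus", "magnitude"]
    long["degree"] = long["protein"].map(degree)
    long = long.dropna(subset=["magnitude"])
    n = len(long)
    if long["degree"].nunique() < 2 or long["magnitude"].nunique() < 2:
        logger.warning("degree correlation undefined (zero variance)")
        return float("nan"), n
    rs = stats.spearmanr(long["magnitude"], long["degree"]).statistic
    return float(rs), n
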
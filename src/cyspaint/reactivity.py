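"""Filtering rules and abundance-corrected cysteine ratios.

A cysteine-containing peptide's heavy/light log2 ratio mixes two signals:
the protein's overall abundance change and the change in thiol accessibility
of that peptide. The noncys peptides of the same protein carry only the
abundance signal, so subtracting their per-replicate mean from each cys
peptide's log2 ratio leaves the conformational component — the corrected cys
ratio. Correction is per replicate, so downstream one-sample statistics see
independent replicate-level values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .io import ratio_columns

logger = logging.getLogger(__name__)

#: default contaminant patterns: keratin gene symbols and MaxQuant markers
DEFAULT_CONTAMINANT_PATTERNS = ("^Krt", "^CON__", "^REV__")


def remove_contaminants(
    table: pd.DataFrame,
    patterns: tuple[str, ...] = DEFAULT_CONTAMINANT_PATTERNS,
) -> pd.DataFrame:
    """Drop peptide rows whose protein or gene matches a contaminant pattern."""
    if not patterns:
        raise ConfigurationError("contaminant pattern list must be non-empty")
    mask = pd.Series(False, index=table.index)
    for pattern in patterns:
        mask |= table["protein"].astype(str).str.contains(pattern, regex=True, na=False)
        mask |= table["gene"].astype(str).str.contains(pattern, regex=True, na=False)
    n_removed = int(mask.sum())
    if n_removed:
        logger.info("removed %d contaminant peptide rows", n_removed)
    return table.loc[~mask].reset_index(drop=True)


def filter_proteins(table: pd.DataFrame) -> pd.DataFrame:
    """Keep proteins with >= 2 unique peptides, >= 1 of them cys-containing.

    Uniqueness is at the sequence level (modified forms were already merged at
    ingestion), evaluated per stimulus.
    """
    group = table.groupby(["stimulus", "protein"])
    n_unique = group["sequence"].transform("nunique")
    any_cys = group["contains_cys"].transform("any")
    keep = (n_unique >= 2) & any_cys
    n_proteins_dropped = table.loc[~keep, "protein"].nunique()
    if n_proteins_dropped:
        logger.info("protein filter dropped %d proteins", n_proteins_dropped)
    return table.loc[keep].reset_index(drop=True)


@dataclass
class ReactivityResult:
    """Corrected cys ratios plus the noncys side of each protein.

    Attributes
    ----------
    corrected
        Cys peptide rows whose ratio columns hold corrected values (cys log2
        ratio minus the protein's noncys mean, per replicate).
    noncys
        The noncys peptide rows, unchanged (the abundance axis).
    noncys_means
        Per (stimulus, protein): per-replicate noncys mean, pooled mean and
        unique cys/noncys peptide counts.
    skipped
        Proteins excluded because no noncys peptide was quantified.
    """

    corrected: pd.DataFrame
    noncys: pd.DataFrame
    noncys_means: pd.DataFrame
    skipped: pd.DataFrame = field(default_factory=pd.DataFrame)


def compute_corrected_ratios(table: pd.DataFrame, center: str = "mean") -> ReactivityResult:
    """Compute per-replicate corrected cys ratios for a filtered peptide table.

    ``center`` selects the noncys summary ("mean" is the default reading of
    the protocol; "median" is available). Proteins whose peptides are all
    cys-containing cannot be corrected; they are excluded and reported in
    ``skipped``.
    """
    if center not in ("mean", "median"):
        raise ConfigurationError("center must be 'mean' or 'median'")
    rcols = ratio_columns(table)
    cys = table[table["contains_cys"]].copy()
    noncys = table[~table["contains_cys"]].copy()

    key = ["stimulus", "protein"]
    summary = noncys.groupby(key)[rcols].agg(center)
    counts = (
        table.assign(side=np.where(table["contains_cys"], "n_cys", "n_noncys"))
        .groupby(key + ["side"])["sequence"].nunique().unstack("side", fill_value=0)
        .reindex(columns=["n_cys", "n_noncys"], fill_value=0)
    )
    noncys_means = summary.join(counts).reset_index()
    noncys_means["pooled"] = summary.mean(axis=1).to_numpy()

    idx = pd.MultiIndex.from_frame(cys[key])
    centers = summary.reindex(idx)
    corrected = cys.copy()
    corrected[rcols] = cys[rcols].to_numpy() - centers.to_numpy()

    # proteins with cys peptides but no quantified noncys value at all
    quantified = centers.notna().any(axis=1).to_numpy()
    skipped_rows = corrected.loc[~quantified, key].drop_duplicates()
    if len(skipped_rows):
        logger.info("skipped %d proteins with no quantified noncys peptides",
                    len(skipped_rows))
    corrected = corrected.loc[quantified].reset_index(drop=True)
    return ReactivityResult(
        corrected=corrected,
        noncys=noncys.reset_index(drop=True),
        noncys_means=noncys_means,
        skipped=skipped_rows.reset_index(drop=True),
    )


def quantify(table: pd.DataFrame,
             patterns: tuple[str, ...] = DEFAULT_CONTAMINANT_PATTERNS,
             center: str = "mean") -> ReactivityResult:
    """Full reactivity stage: contaminant removal, protein filter, correction."""
    table = remove_contaminants(table, patterns)
    table = filter_proteins(table)
    return compute_corrected_ratios(table, center=center)
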
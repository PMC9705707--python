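"""Readers and writers for the tabular interchange formats.

Everything on disk is tab-separated UTF-8 text with a header row and '.'
decimals. The in-memory currency is the pandas DataFrame; graphs are
:class:`networkx.Graph` with a ``score`` edge attribute.

Peptide tables come in two dialects:

``simple``
    The package's own normalized layout: one row per (peptide, stimulus) with
    columns ``peptide_id``, ``sequence``, ``protein``, ``gene``, ``stimulus``
    and one ``ratio_<k>`` column per replicate holding log2 heavy/light
    ratios (missing values allowed).

``maxquant``
    A subset of the MaxQuant ``peptides.txt`` columns (``Sequence``,
    ``Proteins``, ``Gene names`` and per-experiment ``Ratio H/L`` columns).
    Raw ratios are log2-transformed on read; nonpositive or unparseable
    ratios become missing.
"""

from __future__ import annotations

import logging
import re
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .errors import FormatError

logger = logging.getLogger(__name__)

#: prefix of replicate log2-ratio columns in the simple dialect
RATIO_PREFIX = "ratio_"

#: identity columns of the simple peptide-table dialect
ID_COLUMNS = ["peptide_id", "sequence", "protein", "gene", "stimulus"]

_MAXQUANT_RATIO_PATTERN = r"^Ratio H/L(?! count| variability| type)(?: (.+))?$"


def ratio_columns(table: pd.DataFrame) -> list[str]:
    """Return the replicate ratio columns of a simple-dialect table, in order."""
    cols = [c for c in table.columns if c.startswith(RATIO_PREFIX)]
    return sorted(cols, key=lambda c: (len(c), c))


def _derive_contains_cys(table: pd.DataFrame) -> pd.DataFrame:
    table = table.copy()
    table["contains_cys"] = table["sequence"].str.contains("C", regex=False)
    return table


def _merge_duplicate_rows(table: pd.DataFrame) -> pd.DataFrame:
    """Collapse rows sharing (sequence, protein, stimulus) by per-replicate median.

    Modified and unmodified forms of one sequence are a single "unique
    peptide" for filtering purposes, so their quantitation is merged here.
    """
    key = ["sequence", "protein", "stimulus"]
    if not table.duplicated(key).any():
        return table
    n_before = len(table)
    rcols = ratio_columns(table)
    agg = {c: "first" for c in table.columns if c not in key + rcols}
    agg.update({c: "median" for c in rcols})
    merged = table.groupby(key, as_index=False, sort=False).agg(agg)
    merged = merged[table.columns.tolist()]
    logger.info("merged %d duplicate peptide rows", n_before - len(merged))
    return merged


def _drop_unquantified(table: pd.DataFrame) -> pd.DataFrame:
    rcols = ratio_columns(table)
    quantified = table[rcols].notna().any(axis=1)
    n_dropped = int((~quantified).sum())
    if n_dropped:
        logger.info("dropped %d peptide rows with no quantified replicate", n_dropped)
    return table.loc[quantified].reset_index(drop=True)


def read_peptide_table(
    path: str | Path,
    dialect: str = "simple",
    stimulus: str | None = None,
    ratio_pattern: str = _MAXQUANT_RATIO_PATTERN,
) -> pd.DataFrame:
    """Read a peptide quantitation table and return a simple-dialect DataFrame.

    Parameters
    ----------
    path
        Tab-separated input file.
    dialect
        ``"simple"`` or ``"maxquant"`` (see module docstring).
    stimulus
        Stimulus label to assign when the file carries none (maxquant
        dialect); defaults to the file stem.
    ratio_pattern
        Regex selecting the MaxQuant per-experiment ratio columns. The
        experiment-naming scheme varies between deposits, so the pattern is
        configurable.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"peptide table not found: {path}")
    raw = pd.read_csv(path, sep="\t", dtype=str)
    if dialect == "simple":
        table = _parse_simple(raw)
    elif dialect == "maxquant":
        table = _parse_maxquant(raw, stimulus or path.stem, ratio_pattern)
    else:
        raise FormatError(f"unknown peptide-table dialect: {dialect!r}")
    table = _derive_contains_cys(table)
    table = _merge_duplicate_rows(table)
    table = _drop_unquantified(table)
    return table


def _parse_simple(raw: pd.DataFrame) -> pd.DataFrame:
    required = ["peptide_id", "sequence", "protein", "stimulus"]
    for col in required:
        if col not in raw.columns:
            raise FormatError(f"missing required column: {col!r}")
    table = raw.copy()
    if "gene" not in table.columns:
        table["gene"] = ""
    table["gene"] = table["gene"].fillna("")
    rcols = [c for c in table.columns if c.startswith(RATIO_PREFIX)]
    if not rcols:
        raise FormatError(f"missing required column: {RATIO_PREFIX!r}*")
    for col in rcols:
        table[col] = _parse_ratio_column(table[col], col, transform=None)
    keep = ID_COLUMNS + sorted(rcols, key=lambda c: (len(c), c))
    return table[keep]


def _parse_maxquant(raw: pd.DataFrame, stimulus: str, ratio_pattern: str) -> pd.DataFrame:
    for col in ("Sequence", "Proteins"):
        if col not in raw.columns:
            raise FormatError(f"missing required column: {col!r}")
    pattern = re.compile(ratio_pattern)
    mq_ratio_cols = [c for c in raw.columns if pattern.match(c)]
    if not mq_ratio_cols:
        raise FormatError(f"no ratio columns match pattern {ratio_pattern!r}")
    table = pd.DataFrame()
    table["sequence"] = raw["Sequence"].str.upper()
    # multi-protein groups are assigned to the first accession
    table["protein"] = raw["Proteins"].fillna("").str.split(";").str[0]
    gene = raw["Gene names"] if "Gene names" in raw.columns else ""
    table["gene"] = pd.Series(gene).fillna("").str.split(";").str[0]
    table["stimulus"] = stimulus
    table["peptide_id"] = table["protein"] + "|" + table["sequence"]
    for k, col in enumerate(mq_ratio_cols, start=1):
        table[f"{RATIO_PREFIX}{k}"] = _parse_ratio_column(raw[col], col, transform="log2")
    return table[ID_COLUMNS + [f"{RATIO_PREFIX}{k}" for k in range(1, len(mq_ratio_cols) + 1)]]


def _float_or_nan(token) -> float:
    try:
        return float(token)
    except (TypeError, ValueError):
        return float("nan")


def _parse_ratio_column(values: pd.Series, name: str, transform: str | None) -> pd.Series:
    # float() is correctly rounded, so written values round-trip bit-exactly
    parsed = values.map(_float_or_nan)
    bad = parsed.isna() & values.notna() & (values.astype(str).str.strip() != "") \
        & (values.astype(str).str.lower() != "nan")
    for idx in values.index[bad]:
        logger.warning("unparseable ratio %r in column %s row %d; set missing",
                       values[idx], name, idx)
    if transform == "log2":
        with np.errstate(divide="ignore", invalid="ignore"):
            parsed = pd.Series(np.where(parsed > 0, np.log2(parsed), np.nan),
                               index=parsed.index)
    return parsed.astype(float)


def write_peptide_table(table: pd.DataFrame, path: str | Path) -> None:
    """Write a simple-dialect peptide table (round-trips quantitative fields)."""
    cols = [c for c in table.columns if c != "contains_cys"]
    # repr round-trips float64 bit-exactly (shortest-repr guarantee)
    table[cols].to_csv(path, sep="\t", index=False,
                       float_format=lambda v: repr(float(v)))


def read_edge_list(path: str | Path, score_cutoff: float = 0.4) -> nx.Graph:
    """Read a 3-column (node_a, node_b, combined_score) TSV into a graph.

    Edges with score strictly greater than ``score_cutoff`` are retained
    (the STRING "medium confidence" convention at the default 0.4).
    Self-loops are dropped with a warning; duplicate (a,b)/(b,a) rows are
    merged keeping the maximum score.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"edge list not found: {path}")
    graph = nx.Graph()
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"line {lineno}: expected 3 tab-separated columns")
            a, b, score_str = fields[0], fields[1], fields[2]
            if lineno == 1 and _looks_like_header(score_str):
                continue
            try:
                score = float(score_str)
            except ValueError:
                raise FormatError(f"line {lineno}: non-numeric score {score_str!r}") from None
            if a == b:
                logger.warning("line %d: self-loop %s dropped", lineno, a)
                continue
            if graph.has_edge(a, b):
                score = max(score, graph.edges[a, b]["score"])
            graph.add_edge(a, b, score=score)
    drop = [(a, b) for a, b, s in graph.edges(data="score") if s <= score_cutoff]
    graph.remove_edges_from(drop)
    graph.remove_nodes_from(list(nx.isolates(graph)))
    return graph


def _looks_like_header(token: str) -> bool:
    try:
        float(token)
    except ValueError:
        return True
    return False


def write_edge_list(graph: nx.Graph, path: str | Path) -> None:
    """Write a graph as a 3-column TSV edge list with header."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("node_a\tnode_b\tcombined_score\n")
        for a, b, score in sorted(graph.edges(data="score", default=1.0)):
            fh.write(f"{a}\t{b}\t{score}\n")


def read_annotations(path: str | Path, namespace: str = "") -> dict[str, set[str]]:
    """Read a 2-column (protein, feature) TSV into feature -> protein-set."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"annotation file not found: {path}")
    table = pd.read_csv(path, sep="\t", dtype=str)
    if table.empty:
        raise FormatError(f"annotation file is empty: {path}")
    if table.shape[1] < 2:
        raise FormatError("annotation file must have two columns (protein, feature)")
    protein_col, feature_col = table.columns[:2]
    table = table.drop_duplicates([protein_col, feature_col])
    mapping: dict[str, set[str]] = {}
    for feature, group in table.groupby(feature_col, sort=True):
        members = set(group[protein_col].dropna())
        if members:
            mapping[str(feature)] = members
    if not mapping:
        raise FormatError(f"annotation file has no usable rows: {path}")
    return mapping


def read_cytometry(path: str | Path) -> pd.DataFrame:
    """Read exported median-fluorescence rows (sample_id, condition, replicate, median)."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"cytometry table not found: {path}")
    table = pd.read_csv(path, sep="\t")
    if table.empty:
        raise FormatError(f"cytometry table is empty: {path}")
    for col in ("condition", "median"):
        if col not in table.columns:
            raise FormatError(f"missing required column: {col!r}")
    table["median"] = pd.to_numeric(table["median"], errors="raise")
    if "replicate" not in table.columns:
        table["replicate"] = table.groupby("condition").cumcount() + 1
    if "sample_id" not in table.columns:
        table["sample_id"] = table["condition"] + "_" + table["replicate"].astype(str)
    return table


def write_table(table: pd.DataFrame, path: str | Path) -> None:
    """Write any result DataFrame as TSV with header."""
    table.to_csv(path, sep="\t", index=False)
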
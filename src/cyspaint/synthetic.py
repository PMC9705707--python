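"""Synthetic SILAC peptide tables, interaction networks and cytometry medians.

Every generator plants a known ground truth so each downstream stage can be
tested for parameter recovery without any external download. The simulated
design mirrors a heavy/light labeling experiment: a control arm in which both
channels received vehicle (all true log2 ratios are 0), and stimulus arms in
which selected proteins carry an abundance shift on all their peptides and
selected cysteine-containing peptides additionally carry a conformation shift.
Both effects are additive in log2 space, with i.i.d. Gaussian per-replicate
noise; interaction networks follow a planted-partition model; cytometry
medians get mean-preserving multiplicative log-normal noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import networkx as nx
import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .io import RATIO_PREFIX

_AMINO_ACIDS_NO_CYS = np.array(list("ADEFGHIKLMNPQRSTVWY"))

#: ground-truth classification labels for cys peptides
LABELS = ("exposed", "protected", "unchanged")


@dataclass
class SimulationConfig:
    """Parameters of one simulated SILAC experiment.

    Attributes
    ----------
    n_proteins
        Number of simulated proteins.
    peptides_per_protein
        Either a fixed count or an inclusive (low, high) range sampled
        uniformly per protein; minimum 1.
    cys_fraction
        Probability that a peptide contains a cysteine.
    n_replicates
        Biological replicates per peptide (the study design uses 3).
    noise_sd
        SD of per-replicate Gaussian noise on log2 ratios. The study does
        not report its empirical ratio scatter; 0.2 is this package's
        default working value.
    frac_changed
        Fraction of (correctable) proteins carrying a planted conformation
        effect on their cys peptides.
    effect_size
        Magnitude of the planted per-cys-peptide log2 shift; the sign is
        drawn per protein.
    frac_abundance_shift
        Fraction of proteins carrying a planted whole-protein abundance
        shift.
    abundance_effect
        Magnitude of the planted per-protein log2 abundance shift (random
        sign per protein).
    dropout
        Probability that any single replicate measurement is missing.
    seed
        Seed for the generator; identical configs are bit-reproducible.
    """

    n_proteins: int = 200
    peptides_per_protein: int | tuple[int, int] = (3, 8)
    cys_fraction: float = 0.4
    n_replicates: int = 3
    noise_sd: float = 0.2
    frac_changed: float = 0.1
    effect_size: float = 0.8
    frac_abundance_shift: float = 0.1
    abundance_effect: float = 1.0
    dropout: float = 0.0
    seed: int = 0
    stimulus: str = "stimulus"

    def validate(self) -> None:
        if self.n_proteins < 1:
            raise ConfigurationError("n_proteins must be >= 1")
        low, high = self._peptide_range()
        if low < 1 or high < low:
            raise ConfigurationError("peptides_per_protein must be >= 1 (low <= high)")
        for name in ("cys_fraction", "frac_changed", "frac_abundance_shift", "dropout"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1]")
        if self.n_replicates < 2:
            raise ConfigurationError("n_replicates must be >= 2")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")
        if self.frac_changed > 0 and self.effect_size == 0:
            raise ConfigurationError(
                "frac_changed > 0 with effect_size = 0: planted changes are unidentifiable")

    def _peptide_range(self) -> tuple[int, int]:
        if isinstance(self.peptides_per_protein, (tuple, list)):
            low, high = self.peptides_per_protein
        else:
            low = high = int(self.peptides_per_protein)
        return int(low), int(high)


class SyntheticDataset(NamedTuple):
    """A generated peptide table plus its per-peptide ground truth."""

    peptides: pd.DataFrame
    truth: pd.DataFrame


def _random_sequence(rng: np.random.Generator, with_cys: bool) -> str:
    length = int(rng.integers(8, 15))
    seq = rng.choice(_AMINO_ACIDS_NO_CYS, size=length)
    if with_cys:
        seq[int(rng.integers(length))] = "C"
    return "".join(seq)


def _skeleton(config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    low, high = config._peptide_range()
    counts = rng.integers(low, high + 1, size=config.n_proteins)
    width = max(4, len(str(config.n_proteins)))
    proteins = [f"P{i + 1:0{width}d}" for i in range(config.n_proteins)]
    rows = []
    for protein, count in zip(proteins, counts):
        gene = "G" + protein[1:]
        for j in range(count):
            has_cys = bool(rng.random() < config.cys_fraction)
            rows.append((f"{protein}_pep{j + 1}", _random_sequence(rng, has_cys),
                         protein, gene, has_cys))
    table = pd.DataFrame(rows, columns=["peptide_id", "sequence", "protein", "gene",
                                        "contains_cys"])
    table["stimulus"] = config.stimulus
    return table


def _finalize(config: SimulationConfig, rng: np.random.Generator,
              table: pd.DataFrame, truth_value: np.ndarray) -> pd.DataFrame:
    n = len(table)
    noise = rng.normal(0.0, config.noise_sd, size=(n, config.n_replicates)) \
        if config.noise_sd > 0 else np.zeros((n, config.n_replicates))
    ratios = truth_value[:, None] + noise
    if config.dropout > 0:
        missing = rng.random(size=ratios.shape) < config.dropout
        ratios = np.where(missing, np.nan, ratios)
    for k in range(config.n_replicates):
        table[f"{RATIO_PREFIX}{k + 1}"] = ratios[:, k]
    cols = ["peptide_id", "sequence", "protein", "gene", "stimulus", "contains_cys"]
    return table[cols + [f"{RATIO_PREFIX}{k + 1}" for k in range(config.n_replicates)]]


def _truth_frame(table: pd.DataFrame, abundance: pd.Series,
                 conformation: np.ndarray) -> pd.DataFrame:
    label = np.where(conformation > 0, "exposed",
                     np.where(conformation < 0, "protected", "unchanged"))
    return pd.DataFrame({
        "peptide_id": table["peptide_id"],
        "protein": table["protein"],
        "contains_cys": table["contains_cys"],
        "abundance_shift": table["protein"].map(abundance).astype(float),
        "conformation_shift": conformation,
        "label": label,
    })


def generate_control_dataset(config: SimulationConfig) -> SyntheticDataset:
    """Simulate the vehicle-vs-vehicle control arm (all true effects zero)."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    table = _skeleton(config, rng)
    truth_value = np.zeros(len(table))
    abundance = pd.Series(0.0, index=sorted(table["protein"].unique()))
    peptides = _finalize(config, rng, table, truth_value)
    truth = _truth_frame(table, abundance, truth_value)
    return SyntheticDataset(peptides, truth)


def generate_stimulus_dataset(config: SimulationConfig) -> SyntheticDataset:
    """Simulate a stimulus arm with planted abundance and conformation effects.

    Abundance shifts apply to every peptide of a selected protein; conformation
    shifts apply to the cys peptides of selected proteins (drawn among proteins
    that have both a cys and a noncys peptide, so the planted effect is
    recoverable after abundance correction). Noncys peptides never carry a
    conformation shift.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    table = _skeleton(config, rng)
    proteins = sorted(table["protein"].unique())

    has_cys = table.groupby("protein")["contains_cys"].any()
    has_noncys = (~table["contains_cys"]).groupby(table["protein"]).any()
    correctable = [p for p in proteins if has_cys[p] and has_noncys[p]]

    abund_mask = rng.random(len(proteins)) < config.frac_abundance_shift
    abund_sign = rng.choice([-1.0, 1.0], size=len(proteins))
    abundance = pd.Series(
        np.where(abund_mask, abund_sign * config.abundance_effect, 0.0), index=proteins)

    changed_mask = rng.random(len(correctable)) < config.frac_changed
    changed_sign = rng.choice([-1.0, 1.0], size=len(correctable))
    conf_by_protein = pd.Series(
        np.where(changed_mask, changed_sign * config.effect_size, 0.0), index=correctable)

    conformation = np.where(
        table["contains_cys"],
        table["protein"].map(conf_by_protein).fillna(0.0), 0.0)
    truth_value = table["protein"].map(abundance).to_numpy() + conformation
    peptides = _finalize(config, rng, table, truth_value)
    truth = _truth_frame(table, abundance, conformation)
    return SyntheticDataset(peptides, truth)


def generate_interaction_network(
    cluster_sizes: list[int],
    p_in: float,
    p_out: float,
    seed: int = 0,
    score_range: tuple[float, float] = (0.41, 1.0),
) -> tuple[nx.Graph, dict[str, int]]:
    """Planted-partition graph with STRING-like combined scores.

    Within-cluster node pairs are joined with probability ``p_in``, between-
    cluster pairs with ``p_out`` (requires ``p_in >= p_out``). Edge scores are
    drawn uniformly from ``score_range``, above the usual 0.4 confidence
    cutoff so the graph survives re-reading. Returns the graph and the true
    node -> cluster-index assignment.
    """
    if not cluster_sizes or any(s < 1 for s in cluster_sizes):
        raise ConfigurationError("cluster_sizes must be positive counts")
    if not (0 <= p_out <= p_in <= 1):
        raise ConfigurationError("require 0 <= p_out <= p_in <= 1")
    rng = np.random.default_rng(seed)
    total = sum(cluster_sizes)
    width = max(4, len(str(total)))
    nodes = [f"N{i + 1:0{width}d}" for i in range(total)]
    membership: dict[str, int] = {}
    start = 0
    for cluster_id, size in enumerate(cluster_sizes):
        for node in nodes[start:start + size]:
            membership[node] = cluster_id
        start += size
    graph = nx.Graph()
    graph.add_nodes_from(nodes)
    lo, hi = score_range
    for i in range(total):
        for j in range(i + 1, total):
            p = p_in if membership[nodes[i]] == membership[nodes[j]] else p_out
            if rng.random() < p:
                graph.add_edge(nodes[i], nodes[j], score=float(rng.uniform(lo, hi)))
    return graph, membership


def generate_cytometry_medians(
    n_treated: int,
    n_vehicle: int,
    fold_effect: float,
    cv: float,
    seed: int = 0,
    compound: str = "compound",
    base: float = 1000.0,
) -> pd.DataFrame:
    """Simulate exported median-fluorescence rows for one compound batch.

    Vehicle medians scatter multiplicatively around ``base``, treated medians
    around ``base * fold_effect``; the log-normal noise is mean-preserving so
    the expected normalized treated value is ``fold_effect``.
    """
    if fold_effect <= 0:
        raise ConfigurationError("fold_effect must be > 0")
    if cv < 0:
        raise ConfigurationError("cv must be >= 0")
    if n_treated < 1 or n_vehicle < 1:
        raise ConfigurationError("n_treated and n_vehicle must be >= 1")
    rng = np.random.default_rng(seed)
    sigma = float(np.sqrt(np.log1p(cv ** 2)))

    def draw(mean: float, n: int) -> np.ndarray:
        if sigma == 0:
            return np.full(n, mean)
        return mean * np.exp(rng.normal(-sigma ** 2 / 2, sigma, size=n))

    rows = []
    for rep, value in enumerate(draw(base, n_vehicle), start=1):
        rows.append((f"vehicle_{rep}", "vehicle", rep, value))
    for rep, value in enumerate(draw(base * fold_effect, n_treated), start=1):
        rows.append((f"{compound}_{rep}", compound, rep, value))
    return pd.DataFrame(rows, columns=["sample_id", "condition", "replicate", "median"])


def write_truth(truth: pd.DataFrame, path) -> None:
    """Write the ground-truth sidecar TSV keyed by peptide id."""
    truth.to_csv(path, sep="\t", index=False)
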
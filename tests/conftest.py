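import numpy as np
import pandas as pd
import pytest

from cyspaint import SimulationConfig, generate_control_dataset, run_control


def make_peptide_table(rows, n_replicates=3, stimulus="stim"):
    """Build a simple-dialect peptide table from terse row tuples.

    Each row is (protein, sequence, ratios) where ``ratios`` is a list of
    per-replicate log2 values (may contain None for missing).
    """
    records = []
    for i, (protein, sequence, ratios) in enumerate(rows):
        record = {
            "peptide_id": f"pep{i + 1}",
            "sequence": sequence,
            "protein": protein,
            "gene": protein.replace("P", "G", 1),
            "stimulus": stimulus,
            "contains_cys": "C" in sequence,
        }
        for k in range(n_replicates):
            value = ratios[k] if k < len(ratios) else None
            record[f"ratio_{k + 1}"] = np.nan if value is None else float(value)
        records.append(record)
    return pd.DataFrame(records)


@pytest.fixture(scope="session")
def large_control():
    """Seeded control arm with >= 10^4 cys peptides (study-scale noise)."""
    config = SimulationConfig(
        n_proteins=4500, peptides_per_protein=5, cys_fraction=0.5,
        n_replicates=3, noise_sd=0.2, seed=2024, stimulus="control")
    return generate_control_dataset(config)


@pytest.fixture(scope="session")
def control_calls_and_thresholds(large_control):
    """The large control set pushed through scaling + threshold fitting."""
    return run_control(large_control.peptides)
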
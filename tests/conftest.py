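import numpy as np
import pandas as pd
import pytest

from ptmquant import simulate


@pytest.fixture
def generic_long_csv(tmp_path):
    """A 4-row generic_long table: 1 protein, 2 features x 2 runs."""
    path = tmp_path / "features.csv"
    pd.DataFrame(
        {
            "ProteinName": ["P1"] * 4,
            "PeptideSequence": ["ABS*CK", "ABS*CK", "DEFK", "DEFK"],
            "PrecursorCharge": [2, 2, 3, 3],
            "Run": ["R1", "R2", "R1", "R2"],
            "Condition": ["C1", "C2", "C1", "C2"],
            "BioReplicate": ["B1", "B2", "B1", "B2"],
            "Intensity": [1024.0, 2048.0, 512.0, 4096.0],
        }
    ).to_csv(path, index=False)
    return path


@pytest.fixture
def fasta_file(tmp_path):
    """FASTA with 'ABSCK' placed so its marked serine sits at position 70,
    plus a protein containing a repeated peptide."""
    seq_p1 = "M" + "A" * 66 + "ABSCK" + "G" * 28  # plain peptide starts at 68
    seq_p2 = "M" + "PEPTIDEK" + "L" * 5 + "PEPTIDEK" + "W" * 5
    path = tmp_path / "db.fasta"
    path.write_text(
        f">sp|P1|TEST1\n{seq_p1}\n>sp|P2|TEST2\n{seq_p2}\n"
    )
    return path


@pytest.fixture(scope="session")
def small_sim():
    """A small clean-design dataset shared across tests."""
    cfg = simulate.sim1_config(n_proteins=40, n_replicates=5, seed=7)
    return simulate.simulate(cfg)


def make_summaries(values_by_condition, target=("site", "P1", "S1"), mixture=None):
    """Run-summary frame for one target from {condition: [values]}."""
    rows = []
    k = 0
    for cond, vals in values_by_condition.items():
        for v in vals:
            rows.append(
                {
                    "target_type": target[0],
                    "protein_id": target[1],
                    "site_id": target[2] if len(target) > 2 else np.nan,
                    "run_id": f"{cond}R{k}",
                    "channel": np.nan,
                    "condition": cond,
                    "mixture_id": mixture[k] if mixture else np.nan,
                    "replicate_id": f"{cond}R{k}",
                    "value": v,
                    "n_features": 1,
                    "method": "median_polish",
                }
            )
            k += 1
    df = pd.DataFrame(rows)
    df["_target"] = [target] * len(df)
    return df
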
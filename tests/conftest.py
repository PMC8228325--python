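import numpy as np
import pandas as pd
import pytest

from synaptomito.quantify import GroupDesign, PeptideTable, ProteinMatrix


@pytest.fixture
def design_2x6() -> GroupDesign:
    samples = [f"WT{i}" for i in range(1, 7)] + [f"KO{i}" for i in range(1, 7)]
    return GroupDesign(group=pd.Series(["WT"] * 6 + ["KO"] * 6, index=samples))


def make_peptide_table(qpass: np.ndarray, samples, proteins=None) -> PeptideTable:
    """Build a PeptideTable from a boolean Q-pass matrix (peptides x samples)."""
    n, m = qpass.shape
    idx = [f"pep{i}" for i in range(n)]
    if proteins is None:
        proteins = [f"prot{i}" for i in range(n)]
    q = np.where(qpass, 1e-4, 0.5)
    inten = np.full((n, m), 100.0)
    return PeptideTable(
        intensity=pd.DataFrame(inten, index=idx, columns=samples),
        qvalue=pd.DataFrame(q, index=idx, columns=samples),
        protein=pd.Series(proteins, index=idx),
    )


@pytest.fixture
def protein_matrix_small() -> ProteinMatrix:
    rng = np.random.default_rng(0)
    samples = [f"WT{i}" for i in range(1, 7)] + [f"KO{i}" for i in range(1, 7)]
    x = rng.normal(20.0, 1.0, size=(50, 12))
    log2 = pd.DataFrame(x, index=[f"P{i:03d}" for i in range(50)], columns=samples)
    return ProteinMatrix(log2=log2, n_peptides=pd.Series(2, index=log2.index))


def morpho_frame(rows) -> pd.DataFrame:
    return pd.DataFrame(
        rows,
        columns=[
            "animal_id", "genotype", "synapse_id", "compartment", "has_mito",
            "area_um2", "perimeter_um", "distance_nm", "synapse_length_nm",
        ],
    )
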
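import numpy as np
import pandas as pd
import pytest

from sclc_subtyping.quantify import AbundanceMatrix, IntensityTable


@pytest.fixture
def small_intensity() -> IntensityTable:
    """4 proteins x 3 samples with one missing entry and easy arithmetic."""
    raw = pd.DataFrame(
        {
            "s1": [100.0, 30.0, 0.0, 70.0],
            "s2": [40.0, 0.0, 50.0, 10.0],
            "s3": [8.0, 12.0, 20.0, 60.0],
        },
        index=["A", "B", "C", "D"],
    )
    pep = pd.Series([4, 3, 5, 7], index=raw.index)
    return IntensityTable(raw_intensity=raw, theoretical_peptides=pep)


def make_abundance(values: np.ndarray, protein_ids=None, sample_ids=None) -> AbundanceMatrix:
    """AbundanceMatrix from a dense array; zeros mean not detected."""
    values = np.asarray(values, dtype=float)
    protein_ids = protein_ids or [f"p{i}" for i in range(values.shape[0])]
    sample_ids = sample_ids or [f"s{j}" for j in range(values.shape[1])]
    fot = pd.DataFrame(values, index=protein_ids, columns=sample_ids)
    return AbundanceMatrix(fot=fot, detected=fot > 0)
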
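import numpy as np
import pandas as pd
import pytest

from dynamaps.io_formats import QuantTable


def make_quant_table(
    intensities: np.ndarray,
    fractions: list[str],
    protein_ids: list[str] | None = None,
    gene_names: list[str] | None = None,
    mol_weights: list[float] | None = None,
    replicate_id: str = "M1",
    quant_method: str = "LFQ",
) -> QuantTable:
    """Assemble a QuantTable directly from an intensity matrix."""
    intensities = np.asarray(intensities, dtype=float)
    n = intensities.shape[0]
    ids = protein_ids or [f"P{i + 1}" for i in range(n)]
    data = pd.DataFrame(index=pd.Index(ids, name="protein_id"))
    data["gene_name"] = gene_names or [f"G{i + 1}" for i in range(n)]
    data["mol_weight"] = mol_weights or [5.0e4] * n
    for j, f in enumerate(fractions):
        data[f] = intensities[:, j]
    return QuantTable(data, list(fractions), replicate_id, quant_method)


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)
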
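import numpy as np
import pandas as pd
import pytest

from panelforge import (
    GenotypeMatrix,
    PopulationModel,
    generate_structured_populations,
)


def make_matrix(dosage, chrom="1", positions=None, **loci_cols):
    """Small helper: wrap a dosage array in a GenotypeMatrix."""
    dosage = np.asarray(dosage, dtype=np.int8)
    n, m = dosage.shape
    pos = positions if positions is not None else np.arange(1, m + 1) * 100
    loci = pd.DataFrame(
        {"chrom": chrom, "pos": pos, "ref": "A", "alt": "G", **loci_cols}
    )
    return GenotypeMatrix(
        dosage=dosage, samples=[f"s{i}" for i in range(n)], loci=loci
    )


@pytest.fixture(scope="session")
def five_pop_sim():
    """5 populations at strong panel-scale differentiation, 12 per pop."""
    model = PopulationModel(n_pops=5, fst_target=0.2, n_loci=600, seed=11)
    gm, meta, truth = generate_structured_populations(model, 12)
    return gm, meta, truth


@pytest.fixture(scope="session")
def two_pop_sim():
    model = PopulationModel(n_pops=2, fst_target=0.05, n_loci=5000, seed=7)
    gm, meta, truth = generate_structured_populations(model, 50)
    return gm, meta, truth
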
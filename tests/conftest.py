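import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from msapbf.bandmatrix_io import BandId, BandMatrix, load_accession_metadata
from msapbf.epigenotyping import classify_matrix, partition_loci, polymorphic_loci

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


def make_band_matrix(hpa_rows, msp_rows, accessions, bands=None, bf_category=None):
    """Build a BandMatrix from per-accession HPA/MSP call lists."""
    n_bands = len(hpa_rows[0])
    if bands is None:
        bands = [BandId("a", i + 1) for i in range(n_bands)]
    rows, index = [], []
    for acc, h, m in zip(accessions, hpa_rows, msp_rows):
        rows.append(h)
        index.append((acc, "HPA"))
        rows.append(m)
        index.append((acc, "MSP"))
    calls = pd.DataFrame(
        np.asarray(rows, dtype="int8"),
        index=pd.MultiIndex.from_tuples(index, names=["accession", "assay"]),
        columns=[b.name for b in bands],
    )
    bf_category = bf_category or {a: "No" for a in accessions}
    return BandMatrix(calls, bf_category, bands)


@pytest.fixture(scope="session")
def accession_meta():
    return load_accession_metadata()


@pytest.fixture
def toy_matrix():
    """2 accessions x 3 bands covering all four isoschizomer patterns."""
    return make_band_matrix(
        hpa_rows=[[1, 1, 0], [0, 1, 1]],
        msp_rows=[[1, 0, 1], [0, 1, 0]],
        accessions=["acc1", "acc2"],
    )


@pytest.fixture
def classified_toy(toy_matrix):
    epi = classify_matrix(toy_matrix)
    partition_loci(epi)
    polymorphic_loci(epi)
    return epi


@pytest.fixture(scope="session")
def small_synthetic():
    """Seeded small synthetic matrix: 22 accessions, 30 bands/primer x 3."""
    from msapbf.synthetic_data import SimulationConfig, generate

    cfg = SimulationConfig(bands_per_primer=(30, 30, 30), seed=42)
    matrix, truth = generate(cfg)
    return matrix, truth
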
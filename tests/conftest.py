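import numpy as np
import pandas as pd
import pytest

from breedtrace.genotype_io import MISSING, GenotypeDataset


def make_dataset(calls, positions=None, chromosomes=None, breeds=None,
                 snp_ids=None, sample_ids=None):
    """Small helper: build a GenotypeDataset from a raw call matrix."""
    calls = np.asarray(calls, dtype=np.int8)
    n, m = calls.shape
    positions = positions if positions is not None else (np.arange(m) + 1) * 100_000
    chromosomes = chromosomes if chromosomes is not None else ["1"] * m
    snp_ids = snp_ids or [f"s{j}" for j in range(m)]
    sample_ids = sample_ids or [f"ind{i}" for i in range(n)]
    breeds = breeds or ["X"] * n
    loci = pd.DataFrame(
        {
            "snp_id": snp_ids,
            "chromosome": chromosomes,
            "position_bp": np.asarray(positions, dtype=np.int64),
            "allele1": "A",
            "allele2": "G",
        }
    )
    samples = pd.DataFrame({"sample_id": sample_ids, "breed": breeds})
    return GenotypeDataset(samples, loci, calls)


@pytest.fixture
def two_snp_text_fixture(tmp_path):
    """The hand-built 2-sample / 2-SNP .ped/.map pair used in decode tests."""
    (tmp_path / "toy.map").write_text("1 s1 0 1000\n1 s2 0 2000\n")
    (tmp_path / "toy.ped").write_text(
        "FAM1 ind1 0 0 0 -9 A A A G\n"
        "FAM2 ind2 0 0 0 -9 G G 0 0\n"
    )
    return tmp_path / "toy"


@pytest.fixture
def random_dataset():
    rng = np.random.default_rng(7)
    calls = rng.choice(
        np.array([0, 1, 2, MISSING], dtype=np.int8),
        size=(12, 40),
        p=[0.35, 0.3, 0.3, 0.05],
    )
    pos = np.sort(rng.choice(np.arange(1, 5_000_000), size=40, replace=False))
    chroms = ["1"] * 25 + ["2"] * 15
    pos[25:] = np.sort(pos[25:])
    breeds = ["X"] * 6 + ["Y"] * 6
    return make_dataset(calls, positions=pos, chromosomes=chroms, breeds=breeds)
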
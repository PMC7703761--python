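import numpy as np
import pytest

from orthonet import simulate, transfer
from orthonet.model import Proteome, SequenceRecord

AA = "ACDEFGHIKLMNPQRSTVWY"


def random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(AA), size=length))


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def tiny_proteome(rng):
    records = [
        SequenceRecord(f"p{i:02d}", random_protein(rng, int(rng.integers(30, 60))))
        for i in range(8)
    ]
    return Proteome(species_code="tiny", records=records)


@pytest.fixture(scope="session")
def small_config():
    """Desk-scale generator config for fast CLI / IO round trips."""
    return simulate.SynthConfig(
        n_source_species=2,
        n_ancestral_genes=40,
        n_modules=3,
        module_size_range=(4, 6),
        isoforms_per_gene_max=2,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_bundle(small_config, tmp_path_factory):
    out = tmp_path_factory.mktemp("small_bundle")
    truth = simulate.make_bundle(small_config, out)
    return truth


@pytest.fixture(scope="session")
def default_bundle(tmp_path_factory):
    """The default synthetic study system, built once per session."""
    out = tmp_path_factory.mktemp("default_bundle")
    truth = simulate.make_bundle(simulate.SynthConfig(), out)
    result = transfer.build_network(
        truth.target_fasta,
        truth.manifest,
        isoform_table_path=truth.isoform_table,
    )
    return truth, result
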
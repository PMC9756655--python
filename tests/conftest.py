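import numpy as np
import pytest

from cdgmap.model import DomainHit, ProteinRecord
from cdgmap.simulate import SyntheticConfig, generate_dataset


def make_protein(protein_id="p1", hits=(), length=500, sequence=None):
    """Convenience builder: hits given as (acc, name) pairs laid out head to
    tail."""
    dh = []
    pos = 10
    for acc, name in hits:
        dh.append(DomainHit(protein_id, acc, name, pos, pos + 99))
        pos += 110
    return ProteinRecord(protein_id=protein_id, length=length,
                         sequence=sequence, hits=dh)


@pytest.fixture(scope="session")
def small_dataset(tmp_path_factory):
    """One small generated dataset shared across tests: 5 genomes on 150 kb
    replicons with sequences, curated ori table, planted structure."""
    cfg = SyntheticConfig(seed=42, n_genomes_per_genus=1,
                          replicon_length_bp=150_000, secondary_length_bp=120_000,
                          secondary_chromosome_prob=0.4)
    out = tmp_path_factory.mktemp("smalldata")
    return generate_dataset(cfg, out)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
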
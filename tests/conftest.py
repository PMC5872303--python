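import pytest

from luxrbgc.records import PipelineConfig
from luxrbgc.synthetic import SynthSpec, generate_dataset


@pytest.fixture(scope="session")
def default_spec():
    return SynthSpec(seed=11)


@pytest.fixture(scope="session")
def default_dataset(default_spec):
    """Records, hits and ground truth for the default synthetic spec."""
    return generate_dataset(default_spec)


@pytest.fixture()
def cfg():
    return PipelineConfig()


@pytest.fixture(scope="session")
def luxr_sequences(default_dataset):
    """Planted LuxR protein_id -> sequence for the default dataset."""
    records, _hits, truth = default_dataset
    seqs = {}
    for rec in records:
        for gene in rec.genes:
            if gene.gene_id in truth.family_of:
                seqs[gene.gene_id] = gene.translation
    return seqs
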
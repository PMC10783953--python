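import string

import pytest
from hypothesis import settings

import pepmhc as pm

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")
from pepmhc.context import ContextConfig, calpha_distance_matrix, mean_distance_matrix


@pytest.fixture(scope="session")
def letters_cfg():
    """Tokenizer config over the full uppercase alphabet, for worked examples
    that use letters outside the 20 amino acids."""
    return pm.TokenizerConfig(alphabet=frozenset(string.ascii_uppercase))


@pytest.fixture(scope="session")
def panel():
    return pm.gen_panel(n_families=2, alleles_per_family=3, n_columns=72, seed=7)


@pytest.fixture(scope="session")
def binding_records(panel):
    return pm.gen_binding_data(panel, n_pos_per_allele=200, decoy_ratio=1.0, seed=7)


@pytest.fixture(scope="session")
def split(binding_records):
    return pm.split_dataset(binding_records, seed=7)


@pytest.fixture(scope="session")
def context_cfg(panel):
    return ContextConfig(residue_lo=1, residue_hi=panel.n_columns)


@pytest.fixture(scope="session")
def mean_dm(panel, context_cfg):
    return mean_distance_matrix(
        [calpha_distance_matrix(a.coords, context_cfg) for a in panel.alleles]
    )


@pytest.fixture(scope="session")
def trained_model(panel, split):
    """A binding model trained briefly on the synthetic panel (shared across
    tests that need a functional but not fully converged model)."""
    positives = [r for r in split.train if r.label == 1]
    sampler = pm.NegativeSampler(
        pm.peptide_length_distribution(positives), panel.names, seed=7
    )
    model = pm.build_model(
        pm.EmbeddingTable(seed=1),
        pm.EmbeddingTable(seed=2),
        panel.aligned,
        pm.NetConfig(max_epochs=120, patience=120),
        seed=7,
    )
    log = pm.train_binding(model, positives, split.validation, sampler, seed=7)
    return model, log
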
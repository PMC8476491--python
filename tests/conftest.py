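import numpy as np
import pytest

from banvep import FamilySpec, Msa, ModelConfig, build_model, sample_family


@pytest.fixture
def tiny_msa() -> Msa:
    rows = [
        "ACDEFG",
        "ACDEFG",
        "ACDQFG",
        "A-DEFG",
    ]
    return Msa(ids=[f"s{i}" for i in range(len(rows))], rows=rows, focus_index=0)


@pytest.fixture
def tiny_model_factory():
    """Small protein-alphabet models for structural tests."""

    def make(seq_length=8, seed=0, **kw):
        defaults = dict(
            seq_length=seq_length,
            embedding_dim=8,
            conv_channels=8,
            dilation_schedule=(1, 2),
            attention_dim=4,
        )
        defaults.update(kw)
        return build_model(ModelConfig(**defaults), rng_seed=seed)

    return make


@pytest.fixture(scope="session")
def small_family():
    """A quick conserved family for pipeline-level tests."""
    spec = FamilySpec(length=12, n_sequences=200, alpha=0.2, seed=5)
    return sample_family(spec)
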
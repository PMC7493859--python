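import numpy as np
import pytest

from corenup import (
    DnaSequence, LabeledDataset, ModelConfig, SimulationConfig,
    simulate_dataset,
)


@pytest.fixture
def tiny_config():
    """A scaled-down architecture that builds and trains in milliseconds."""
    return ModelConfig(input_length=20, conv1_filters=4, conv1_kernel=3,
                       lstm_units=4, conv2_filters=4, conv2_kernel=4,
                       dense_units=8)


@pytest.fixture
def tiny_dataset():
    """60 + 60 length-20 sequences with a strong planted signal."""
    cfg = SimulationConfig(n_per_class=60, length=20, period=10,
                           periodic_strength=1.0, motif="GGGCCC",
                           motif_prob=1.0, seed=7)
    return simulate_dataset(cfg)


@pytest.fixture
def null_dataset():
    """Signal-free dataset: both classes identically distributed."""
    cfg = SimulationConfig(n_per_class=60, length=20, period=10,
                           periodic_strength=0.0, motif_prob=0.0, seed=8)
    return simulate_dataset(cfg)


@pytest.fixture
def fasta_pair(tmp_path, tiny_dataset):
    pos = tmp_path / "pos.fasta"
    neg = tmp_path / "neg.fasta"
    tiny_dataset.to_fasta(str(pos), str(neg))
    return str(pos), str(neg)


def make_dataset(strings, labels):
    return LabeledDataset([
        DnaSequence(f"s{i}", s, label=l)
        for i, (s, l) in enumerate(zip(strings, labels))])
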
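"""Shared fixtures: tiny annotations and a zero-noise planted dataset."""

import pytest

from relaxkit.cli import run_mine
from relaxkit.seqio import GeneFeature, RepliconAnnotation
from relaxkit.synth import SynthConfig, generate_replicons, write_dataset


@pytest.fixture()
def tiny_annotation() -> RepliconAnnotation:
    # 60 bp with a single 9-bp CDS "ATGAAATAA" at 11..19 (+)
    seq = ("GGGGGGGGGG" + "ATGAAATAA" + "C" * 41)
    feat = GeneFeature(gene_id="g1", start=11, end=19, strand="+")
    return RepliconAnnotation("rep1", seq, [feat])


@pytest.fixture(scope="session")
def zero_noise_config() -> SynthConfig:
    """Twenty replicons, every one a full aux1-aux2-relaxase triplet, no noise."""
    return SynthConfig(seed=1, n_replicons=20, p_aux2_upstream=1.0,
                       p_aux1_upstream=1.0, mutation_rate=0.0)


@pytest.fixture(scope="session")
def zero_noise_replicons(zero_noise_config):
    return generate_replicons(zero_noise_config)


@pytest.fixture(scope="session")
def zero_noise_dataset(tmp_path_factory, zero_noise_config):
    out = tmp_path_factory.mktemp("dataset")
    manifest = write_dataset(zero_noise_config, out)
    return out, manifest


@pytest.fixture(scope="session")
def mined_summary(tmp_path_factory, zero_noise_dataset):
    dataset, manifest = zero_noise_dataset
    out = tmp_path_factory.mktemp("mine_out")
    summary = run_mine(dataset, out)
    return summary, out, manifest
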
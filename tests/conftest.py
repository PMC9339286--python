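import dataclasses

import pytest

from pertpred.build import build_feature_matrix, build_labels, load_dataset
from pertpred.io_formats import RunConfig, TssRecord
from pertpred.synthetic_data import YEASTLIKE, simulate_dataset


@pytest.fixture(scope="session")
def tiny_sim(tmp_path_factory):
    """A small yeastlike dataset shared by unit tests (150 genes, 3 TFs)."""
    cfg = dataclasses.replace(YEASTLIKE, n_genes=150, n_tfs=3, seed=7)
    out = tmp_path_factory.mktemp("tiny_sim")
    return simulate_dataset(cfg, out)


@pytest.fixture(scope="session")
def tiny_dataset(tiny_sim):
    return load_dataset(tiny_sim.out_dir, chrom_length=tiny_sim.paths["chrom_length"])


@pytest.fixture(scope="session")
def tiny_config():
    return RunConfig(mode="yeast", fold_count=3, enhancer_scheme="none", seed=7)


@pytest.fixture(scope="session")
def tiny_matrix(tiny_dataset, tiny_config):
    return build_feature_matrix(tiny_dataset, tiny_config)


@pytest.fixture(scope="session")
def tiny_labels(tiny_dataset, tiny_config):
    return build_labels(tiny_dataset, tiny_config)


@pytest.fixture
def plus_tss():
    return TssRecord("geneA", "chr1", 10_000, "+")


@pytest.fixture
def minus_tss():
    return TssRecord("geneB", "chr1", 10_000, "-")
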
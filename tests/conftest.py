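from pathlib import Path

import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import mexplorer as mx
from mexplorer.regdata import BASELINE_CLASS, ProcessResponse

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

DATA = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def data_dir() -> Path:
    return DATA


@pytest.fixture(scope="session")
def toy_matrix():
    return mx.read_matrix(DATA / "toy_matrix.tsv")


@pytest.fixture(scope="session")
def toy_lists():
    return mx.read_gene_lists(DATA / "toy_lists.gmt")


@pytest.fixture(scope="session")
def toy_response(toy_matrix, toy_lists):
    return mx.build_response(toy_lists, toy_matrix.genes)


@pytest.fixture(scope="session")
def toy_gold(toy_matrix, data_dir):
    positives = {
        line.strip()
        for line in open(data_dir / "toy_gold.txt")
        if line.strip()
    }
    return mx.GoldStandard(positives, toy_matrix.tfs)


@pytest.fixture(scope="session")
def default_benchmark():
    """The default planted benchmark: 2000 genes, 100 TFs, 5 planted, odds 8."""
    return mx.gen_benchmark(mx.GeneratorSpec())


def make_response(class_counts: dict[str, int], prefix: str = "g") -> ProcessResponse:
    """Deterministic response with the given per-class gene counts
    (baseline count under the key 'baseline')."""
    genes, labels = [], []
    i = 0
    for cls, n in class_counts.items():
        for _ in range(n):
            genes.append(f"{prefix}{i:05d}")
            labels.append(cls)
            i += 1
    classes = [c for c in class_counts if c != BASELINE_CLASS] + [BASELINE_CLASS]
    return ProcessResponse(classes, pd.Series(labels, index=genes))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
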
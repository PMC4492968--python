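import numpy as np
import pandas as pd
import pytest

from icossy.io import ChipMap, ExpressionMatrix, GeneNetwork, PhenotypeLabels
from icossy.synthdata import SynthConfig, generate


@pytest.fixture
def tiny_gct(tmp_path):
    path = tmp_path / "tiny.gct"
    path.write_text(
        "#1.2\n"
        "2\t3\n"
        "Name\tDescription\ts1\ts2\ts3\n"
        "p1\tGENE1\t1.5\t2.0\t3.25\n"
        "p2\tGENE2\t0.5\t0.25\t4.0\n"
    )
    return path


@pytest.fixture
def tiny_cls(tmp_path):
    path = tmp_path / "tiny.cls"
    path.write_text("4 2 1\n# A B\nA A B B\n")
    return path


@pytest.fixture
def tiny_chip(tmp_path):
    path = tmp_path / "tiny.chip"
    path.write_text(
        "Probe Set ID\tGene Symbol\np1\tGENE1\np2\tGENE1\np3\tGENE2\n"
    )
    return path


@pytest.fixture
def tiny_sif(tmp_path):
    path = tmp_path / "tiny.sif"
    path.write_text("A\tpp\tB\nB\tpp\tC\nA\tpp\tB\n")
    return path


def make_matrix(values, row_ids=None, sample_ids=None, descriptions=None):
    values = np.asarray(values, dtype=float)
    row_ids = row_ids or [f"p{i}" for i in range(values.shape[0])]
    sample_ids = sample_ids or [f"s{j}" for j in range(values.shape[1])]
    desc = pd.Series(descriptions or [""] * len(row_ids), index=row_ids)
    return ExpressionMatrix(pd.DataFrame(values, index=row_ids, columns=sample_ids), desc)


def make_labels(n_per_class=2, class_names=("A", "B")):
    ids = [f"s{j}" for j in range(2 * n_per_class)]
    assignment = {
        s: class_names[0] if j < n_per_class else class_names[1] for j, s in enumerate(ids)
    }
    return PhenotypeLabels(ids, class_names, assignment)


def identity_chip(row_ids):
    return ChipMap({r: r for r in row_ids})


@pytest.fixture(scope="session")
def planted_dataset():
    """Default planted-module dataset: 6 dense 10-gene modules, 20+20 samples,
    a 2-sigma coordinated shift in module 0."""
    return generate(SynthConfig(seed=11))
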
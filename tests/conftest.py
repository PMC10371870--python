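import warnings

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from cardioniche.io_core import Annotation, CountMatrix, NormMatrix, normalize_log
from cardioniche.synthetic_data import (
    SynthSpec,
    gen_drug_table,
    gen_expression,
    gen_lr_tables,
    gen_peaks_snps,
    gen_spots,
)

warnings.filterwarnings("ignore", message="Maximum number of iterations")


@pytest.fixture(scope="session")
def spec():
    return SynthSpec(seed=11)


@pytest.fixture(scope="session")
def expression(spec):
    """(counts, state annotation, log-normalized matrix) planted fixture."""
    counts, ann = gen_expression(spec)
    return counts, ann, normalize_log(counts)


@pytest.fixture(scope="session")
def spots(spec):
    return gen_spots(spec)


@pytest.fixture(scope="session")
def peaks_bundle(spec):
    return gen_peaks_snps(spec)


@pytest.fixture(scope="session")
def drug_table(spec):
    return gen_drug_table(spec)


@pytest.fixture(scope="session")
def lr_tables(spec):
    return gen_lr_tables(spec)


@pytest.fixture()
def tiny_norm():
    """Dense 4x3 log-expression toy with hand-readable values."""
    vals = np.array([
        [1.0, 0.0, 2.0],
        [2.0, 1.0, 0.0],
        [0.0, 3.0, 1.0],
        [1.0, 1.0, 1.0],
    ])
    return NormMatrix(sp.csr_matrix(vals), [f"c{i}" for i in range(4)],
                      ["gA", "gB", "gC"])


def make_counts(array, row_kind="cell", prefix="r"):
    array = np.asarray(array)
    return CountMatrix(
        sp.csr_matrix(array),
        [f"{prefix}{i}" for i in range(array.shape[0])],
        [f"g{j}" for j in range(array.shape[1])],
        row_kind,
    )


def make_annotation(labels, ids=None):
    labels = list(labels)
    if ids is None:
        ids = [f"r{i}" for i in range(len(labels))]
    return Annotation(pd.Series(labels, index=ids))
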
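import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from uvbsrna.preprocess import clean_reads, merge_tag_counts
from uvbsrna.synthetic import (
    ReferenceParams,
    default_design,
    generate_reference,
    simulate_libraries,
)


@pytest.fixture(scope="session")
def small_ref():
    return generate_reference(ReferenceParams(), seed=101)


@pytest.fixture(scope="session")
def small_sim(small_ref):
    """One modest simulated experiment shared by read-level tests."""
    design = default_design(small_ref, depth=12_000, seed=101)
    libs, truth = simulate_libraries(small_ref, design)
    return small_ref, design, libs, truth


@pytest.fixture(scope="session")
def cleaned(small_sim):
    ref, design, libs, truth = small_sim
    per_lib = {}
    qc_rows = {}
    for lib, records in libs.items():
        tags, qc = clean_reads(records, design.adapter, library=lib)
        per_lib[lib] = tags
        qc_rows[lib] = qc
    return merge_tag_counts(per_lib), qc_rows


@pytest.fixture()
def rng():
    return np.random.default_rng(7)
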
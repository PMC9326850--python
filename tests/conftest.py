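"""Shared fixtures: planted-truth bundles and small on-disk fixtures."""

import numpy as np
import pandas as pd
import pytest

from ltscaf import simulate as sim
from ltscaf.cli import preprocess_links


@pytest.fixture(scope="session")
def chain10():
    """50 kb genome, 10 contigs, PE+MP libraries (shared, read-only)."""
    return sim.chain_scenario(seed=11, length=50_000, n_contigs=10)


@pytest.fixture(scope="session")
def chain10_ready(chain10):
    """chain10 after preprocessing: (paired, tgs, insert_models)."""
    return preprocess_links(chain10.paired, chain10.tgs, chain10.insert_obs,
                            None, chain10.contigs, chain10.libraries)


@pytest.fixture
def write_fasta(tmp_path):
    def _write(records, name="test.fasta"):
        path = tmp_path / name
        with open(path, "w") as fh:
            for header, seq in records:
                fh.write(f">{header}\n{seq}\n")
        return path
    return _write
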
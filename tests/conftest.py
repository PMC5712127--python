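import dataclasses

import pytest

from spermevol import simulate
from spermevol.evidence import ReplicateEvidence


def make_evidence(rows):
    """rows: (protein, replicate, unique_peptides, spectral_count, prob)."""
    return [ReplicateEvidence(*r) for r in rows]


@pytest.fixture(scope="session")
def small_config():
    """A fast generator configuration used across tests."""
    return dataclasses.replace(
        simulate.scenario_paper_like(), n_genes=1200, n_sperm=250, resample_iters=500
    )


@pytest.fixture(scope="session")
def small_bundle(small_config):
    return simulate.generate(small_config, seed=20260927)
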
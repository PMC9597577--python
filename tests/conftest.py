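import numpy as np
import pandas as pd
import pytest

from motifshift.config import AnalysisConfig
from motifshift.motifs import PFMotif, build_pwm
from motifshift.pipeline import run_pipeline


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_pfm():
    """Width-3 motif with consensus ACG and soft columns."""
    counts = np.array([[8, 1, 1],
                       [1, 8, 1],
                       [1, 1, 8],
                       [1, 1, 1.0]])
    return PFMotif("M_SMALL", "small test motif", counts)


@pytest.fixture
def small_pwm(small_pfm):
    return build_pwm(small_pfm, pseudocount=0.1)


@pytest.fixture
def consensus_only_pfm():
    """Degenerate motif with a single allowed letter per column (TGCA)."""
    counts = np.zeros((4, 4))
    for j, b in enumerate("TGCA"):
        counts["ACGT".index(b), j] = 10
    return PFMotif("M_CONS", "consensus-only motif", counts)


@pytest.fixture(scope="session")
def default_bundle():
    """One full pipeline run at generator defaults, shared across tests."""
    return run_pipeline(AnalysisConfig(seed=1))
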
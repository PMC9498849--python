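import numpy as np
import pytest

from enrichsim import (
    GenotypePanel,
    apply_qc,
    define_functional_subset,
    simulate_panel,
)


@pytest.fixture(scope="session")
def small_panel():
    """Clean 300 x 800 panel used across unit tests."""
    panel = simulate_panel(300, 800, chrom_length_bp=20_000_000, seed=101)
    clean, _ = apply_qc(panel)
    return clean


@pytest.fixture(scope="session")
def functional_subset(small_panel):
    return define_functional_subset(
        small_panel, target_size=round(0.1 * small_panel.m), seed=7
    )


@pytest.fixture()
def toy_panel():
    """Deterministic 4 x 3 panel with hand-set dosages."""
    dosages = np.array(
        [
            [0, 0, 2],
            [1, 1, 2],
            [2, 1, 0],
            [0, 0, 1],
        ],
        dtype=np.int8,
    )
    freq = dosages.mean(axis=0) / 2.0
    return GenotypePanel(
        dosages=dosages,
        chrom=np.array([1, 1, 1]),
        pos=np.array([100, 5_000, 1_000_000]),
        freq=freq,
        call_rate=np.ones(3),
    )


def make_panel_from_dosages(dosages, pos=None, chrom=None):
    dosages = np.asarray(dosages, dtype=np.int8)
    n, m = dosages.shape
    if pos is None:
        pos = np.arange(1, m + 1) * 1000
    if chrom is None:
        chrom = np.ones(m, dtype=np.int32)
    obs = dosages != -1
    freq = np.where(obs, dosages, 0).sum(axis=0) / (2.0 * obs.sum(axis=0))
    return GenotypePanel(
        dosages=dosages,
        chrom=np.asarray(chrom),
        pos=np.asarray(pos),
        freq=freq,
        call_rate=obs.mean(axis=0),
    )
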
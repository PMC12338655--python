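"""Shared fixtures: small synthetic maps and fast simulation configs."""

from __future__ import annotations

import numpy as np
import pytest

from hicfold import (
    BinaryContactMap,
    GenomicBinning,
    RawContactMatrix,
    SimulationConfig,
)
from hicfold.synthetic import contacts_from_conformation, make_toy_conformation


@pytest.fixture
def binning() -> GenomicBinning:
    return GenomicBinning("chrT", 200_000, 20)


@pytest.fixture
def two_domain_map():
    """Factory: noise-free two-domain contact map at a given size/seed."""

    def make(n_beads: int = 60, seed: int = 1, noise_rate: float = 0.0) -> BinaryContactMap:
        chain = make_toy_conformation("two_domain", n_beads, seed=seed)
        return contacts_from_conformation(chain, noise_rate=noise_rate, seed=seed)

    return make


@pytest.fixture
def fast_cfg():
    """Reduced step budgets for unit tests that only need qualitative folding."""

    def make(seed: int = 1, **kwargs) -> SimulationConfig:
        defaults = dict(
            seed=seed,
            max_steps_formation=4000,
            max_steps_production=3000,
            check_interval=200,
        )
        defaults.update(kwargs)
        return SimulationConfig(**defaults)

    return make


def random_symmetric_matrix(n: int, rng: np.random.Generator, *, positive: bool = True,
                            sparsity: float = 0.0) -> RawContactMatrix:
    """Random symmetric non-negative test matrix (optionally with zeros)."""
    a = rng.uniform(0.5 if positive else 0.0, 5.0, size=(n, n))
    if sparsity > 0:
        a[rng.random((n, n)) < sparsity] = 0.0
    a = np.triu(a) + np.triu(a, 1).T
    binning = GenomicBinning("chrR", 1000, n)
    return RawContactMatrix(binning, a)
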
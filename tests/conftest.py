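from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from rohfst import GenotypeDataset
from rohfst.dataset import MISSING


def make_random_dataset(
    rng: np.random.Generator,
    n_samples: int = 20,
    markers_per_chrom: int = 30,
    chromosomes: tuple[str, ...] = ("1", "2"),
    n_breeds: int = 2,
    missing_rate: float = 0.05,
    ensure_polymorphic: bool = False,
) -> GenotypeDataset:
    """Random dataset built directly (independent of the simulator)."""
    rows = []
    for chrom in chromosomes:
        pos = np.sort(rng.choice(np.arange(1, 10_000_000), markers_per_chrom, replace=False))
        for p in pos:
            rows.append((f"m_{chrom}_{p}", chrom, int(p), "A", "G"))
    markers = pd.DataFrame(
        rows, columns=["marker_id", "chromosome", "position_bp", "allele_a", "allele_b"]
    )
    n_markers = len(markers)
    freqs = rng.uniform(0.1, 0.9, n_markers)
    calls = rng.binomial(1, freqs, (n_samples, n_markers)) + rng.binomial(
        1, freqs, (n_samples, n_markers)
    )
    calls = calls.astype(np.int8)
    if missing_rate > 0:
        calls[rng.random(calls.shape) < missing_rate] = MISSING
    if ensure_polymorphic:
        # force both alleles to be observed at every marker
        for k in range(n_markers):
            col = calls[:, k]
            obs = col[col != MISSING]
            if (obs == 0).all():
                calls[rng.integers(n_samples), k] = 2
            elif (obs == 2).all() or (obs == 1).all():
                calls[rng.integers(n_samples), k] = 0
    breeds = [f"B{i % n_breeds + 1}" for i in range(n_samples)]
    samples = pd.DataFrame(
        {"sample_id": [f"s{i:03d}" for i in range(n_samples)], "breed": breeds}
    )
    return GenotypeDataset(markers=markers, samples=samples, calls=calls)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260929)


@pytest.fixture
def small_dataset(rng) -> GenotypeDataset:
    return make_random_dataset(rng, n_samples=12, markers_per_chrom=25)
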
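from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from methdomain.genomic_io import MethylomeTable


def make_methylome(rows, label="test") -> MethylomeTable:
    """Build a methylome from (chrom, pos, n_meth, n_unmeth) tuples."""
    return MethylomeTable.from_frame(
        pd.DataFrame(rows, columns=["chrom", "pos", "n_meth", "n_unmeth"]),
        label,
    )


def uniform_methylome(
    chrom: str,
    positions,
    meth_pct: float,
    coverage: int = 10,
) -> MethylomeTable:
    """Methylome with identical counts at every position."""
    n_meth = int(round(coverage * meth_pct / 100.0))
    return make_methylome(
        [(chrom, int(p), n_meth, coverage - n_meth) for p in positions]
    )


def random_chromosome(rng: np.random.Generator, n_cpgs: int, span: int = 40_000):
    """Random CpG records for one chromosome, as (pos, n_meth, n_unmeth).

    Bimodal methylation in domain-sized patches with occasional intermediate
    values, and Poisson coverage including CpGs below the scoring depth, so
    every filter in the window/domain rules is exercised.
    """
    pos = np.sort(rng.choice(span, size=min(n_cpgs, span // 2), replace=False))
    records = []
    state = rng.uniform(0, 100)
    for p in pos:
        if rng.random() < 0.05:
            state = rng.choice([5.0, 50.0, 95.0], p=[0.4, 0.2, 0.4])
        cov = int(rng.poisson(7))
        m = int(rng.binomial(cov, np.clip(state / 100 + rng.normal(0, 0.05), 0, 1)))
        records.append((int(p), m, cov - m))
    return records


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20_240_901)
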
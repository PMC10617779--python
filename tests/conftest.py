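"""Shared fixtures: small in-memory genotype matrices and cohorts."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from drmatch.genotype_io import GenotypeMatrix, PairCohort


def make_matrix(
    calls: np.ndarray,
    sample_ids: list[str] | None = None,
    chrom: str | list[str] = "chr1",
    pos: list[int] | None = None,
    info: list[float] | None = None,
) -> GenotypeMatrix:
    """Build a GenotypeMatrix from a (samples x variants) call array."""
    calls = np.asarray(calls, dtype=np.int8)
    n_s, n_v = calls.shape
    sample_ids = sample_ids or [f"S{i}" for i in range(n_s)]
    pos = pos or [1000 * (j + 1) for j in range(n_v)]
    chroms = [chrom] * n_v if isinstance(chrom, str) else list(chrom)
    variants = pd.DataFrame(
        {
            "chrom": chroms,
            "pos": pos,
            "ref": ["A"] * n_v,
            "alt": ["G"] * n_v,
            "variant_id": [f"var{j}" for j in range(n_v)],
            "info_score": info if info is not None else [1.0] * n_v,
        }
    )
    order = variants.sort_values(["chrom", "pos"], kind="mergesort").index.to_numpy()
    return GenotypeMatrix(sample_ids, variants.iloc[order], calls[:, order])


def make_cohort(
    pairs: list[tuple[str, str]],
    follow_time: list[float] | None = None,
    event: list[int] | None = None,
    **overrides,
) -> PairCohort:
    n = len(pairs)
    table = pd.DataFrame(
        {
            "donor_id": [d for d, _ in pairs],
            "recipient_id": [r for _, r in pairs],
            "follow_time": follow_time or [100.0] * n,
            "event": event or [0] * n,
            "hla_mismatch": [2] * n,
            "donor_status": ["living"] * n,
            "induction": ["depleting"] * n,
            "donor_ancestry": ["EUR"] * n,
            "recipient_ancestry": ["EUR"] * n,
        }
    )
    for key, values in overrides.items():
        table[key] = values
    return PairCohort(table)


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
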
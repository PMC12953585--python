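"""Shared fixtures: toy cohort builders and small cached simulations."""

from __future__ import annotations

import numpy as np
import pytest

import lupus_popgen as lp


def make_cohort(
    genotypes: list[list[tuple[int, int]]],
    positions: list[int] | None = None,
    chroms: list[str] | None = None,
    sample_ids: list[str] | None = None,
    quality: list[float] | None = None,
    phased: bool = True,
) -> lp.Cohort:
    """Build a small cohort from per-site lists of (a, b) allele pairs.

    Use (-1, -1) for a missing call. All sites default to chromosome
    "chr1" with positions 0, 1000, 2000, ...
    """
    n_sites = len(genotypes)
    n_samples = len(genotypes[0]) if n_sites else 0
    gt = np.array(genotypes, dtype=np.int8).reshape(n_sites, n_samples, 2)
    if positions is None:
        positions = list(range(0, 1000 * n_sites, 1000))
    if chroms is None:
        chroms = ["chr1"] * n_sites
    chrom_ids: list[str] = []
    for c in chroms:
        if c not in chrom_ids:
            chrom_ids.append(c)
    if sample_ids is None:
        sample_ids = [f"S{i + 1}" for i in range(n_samples)]
    return lp.Cohort(
        chrom_ids=chrom_ids,
        chrom_index=np.array([chrom_ids.index(c) for c in chroms], np.int32),
        positions=np.array(positions, np.int64),
        ref=np.full(n_sites, "A", "U1"),
        alt=np.full(n_sites, "T", "U1"),
        gt=gt,
        phased=np.full((n_sites, n_samples), phased, bool),
        sample_ids=list(sample_ids),
        site_quality=np.array(quality if quality is not None else [100.0] * n_sites, float),
    )


@pytest.fixture(scope="session")
def small_wolf_sim() -> lp.SimResult:
    """A small (2 x 2 Mb) cohort under the default wolf model."""
    model = lp.default_wolf_model(chromosome_count=2, sequence_length=2e6)
    return lp.simulate_cohort(
        model,
        {"Indian": 2, "Central": 3, "SWAsia": 2, "Tibetan": 2, "Outgroup1": 1, "Outgroup2": 1},
        seed=20_240_101,
    )


@pytest.fixture(scope="session")
def panmictic_sim() -> lp.SimResult:
    """A single panmictic population (1 x 10 Mb, N_e 10,000)."""
    model = lp.DemographicModel(
        populations={"Pop": 10_000.0}, chromosome_count=1, sequence_length=1e7
    )
    return lp.simulate_cohort(model, {"Pop": 12}, seed=77)
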
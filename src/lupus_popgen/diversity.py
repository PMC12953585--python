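"""Per-individual genome-wide heterozygosity and inbreeding coefficient."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import Cohort, CohortError, PopulationMap


@dataclass
class DiversityReport:
    sample_id: str
    n_het: int
    n_callable: int
    heterozygosity: float
    inbreeding_f: float | None = None


def heterozygosity(cohort: Cohort, individual: str) -> DiversityReport:
    """H = n_het / n_callable over the individual's non-missing calls."""
    j = cohort.sample_index(individual)
    called = ~(cohort.gt[:, j, :] < 0).any(axis=1)
    n_callable = int(called.sum())
    if n_callable == 0:
        raise CohortError(f"{individual!r} has no callable sites")
    n_het = int((cohort.gt[called, j, 0] != cohort.gt[called, j, 1]).sum())
    return DiversityReport(individual, n_het, n_callable, n_het / n_callable)


def inbreeding_coefficient(cohort: Cohort, popmap: PopulationMap, individual: str) -> float:
    """Moment estimator F = 1 - observed het / expected het under HWE.

    Expected heterozygosity is summed over the individual's callable
    sites using allele frequencies estimated from the *other* members of
    its population (the focal individual is excluded to avoid self-bias
    at small sample sizes).
    """
    j = cohort.sample_index(individual)
    pop = popmap.population_of(individual)
    others = [
        cohort.sample_index(s)
        for s in popmap.samples_of(pop)
        if s != individual and s in cohort.sample_ids
    ]
    if len(others) < 2:
        raise CohortError(
            f"population {pop!r} needs >= 2 members besides {individual!r} "
            "for frequency estimation"
        )
    called = ~(cohort.gt[:, j, :] < 0).any(axis=1)
    alt_n, called_n = cohort.allele_counts(others)
    # only sites segregating among the reference members carry information;
    # sites private to the focal individual would otherwise bias F downward
    ok = called & (alt_n > 0) & (alt_n < called_n)
    if not ok.any():
        raise CohortError("expected heterozygosity is zero; F undefined")
    p = alt_n[ok] / called_n[ok]
    c = called_n[ok].astype(float)
    # per retained site: unbiased 2pq (factor c/(c-1)) times the estimated
    # probability the site was ascertained as segregating in the reference
    # members, so observed and expected condition on the same site set
    p_ret = 1.0 - p**c - (1.0 - p) ** c
    expected = float(np.sum(2.0 * p * (1.0 - p) * c / (c - 1.0) * p_ret))
    if expected == 0:
        raise CohortError("expected heterozygosity is zero; F undefined")
    g = cohort.gt[ok, j, :]
    observed = float((g[:, 0] != g[:, 1]).sum())
    return 1.0 - observed / expected


def diversity_table(cohort: Cohort, popmap: PopulationMap) -> pd.DataFrame:
    """One row per sample: n_het, n_callable, H, and F where estimable."""
    rows = []
    for s in cohort.sample_ids:
        rep = heterozygosity(cohort, s)
        try:
            f = inbreeding_coefficient(cohort, popmap, s)
        except CohortError:
            f = float("nan")
        rows.append(
            {
                "sample": s,
                "population": popmap.population_of(s),
                "n_het": rep.n_het,
                "n_callable": rep.n_callable,
                "heterozygosity": rep.heterozygosity,
                "inbreeding_f": f,
            }
        )
    return pd.DataFrame(rows)
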
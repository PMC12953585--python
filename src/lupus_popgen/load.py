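"""Two-outgroup polarization and derived-allele genetic-load accounting.

Sites are polarized by pseudo-haploidizing two outgroup genomes (one
allele sampled per genotype) and keeping only sites where the two agree;
the agreed allele is taken as ancestral and the derived allele is assumed
deleterious when its impact category is HIGH or MODERATE. Per individual:

* total load   — derived alleles at HIGH+MODERATE sites (2 per
  homozygous-derived site, 1 per het),
* realized load — derived alleles in homozygous state,
* masked load  — derived alleles in heterozygous state,

so total = realized + masked holds exactly. Per-category derived counts
are also normalized per 100,000 MODIFIER (putatively neutral) derived
alleles to compare individuals with different overall derived counts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import Cohort, CohortError, PopulationMap
from .sim import IMPACT_CATEGORIES, AnnotationTable

logger = logging.getLogger(__name__)

DELETERIOUS = ("HIGH", "MODERATE")
NORMALIZATION_SCALE = 100_000


@dataclass
class PolarizedSites:
    """Derived-allele dosages at sites polarized by two-outgroup agreement."""

    site_index: np.ndarray  # indices into the source cohort
    ancestral_is_ref: np.ndarray  # bool per retained site
    impact: np.ndarray  # category per retained site
    dosage: np.ndarray  # (n_sites, n_samples) derived-allele count; -1 missing
    sample_ids: list[str]

    @property
    def n_sites(self) -> int:
        return len(self.site_index)


def _resolve_outgroup(cohort: Cohort, popmap: PopulationMap | None, outgroup: str) -> int:
    """An outgroup is one genome: a sample id or a single-sample population."""
    if outgroup in cohort.sample_ids:
        return cohort.sample_index(outgroup)
    if popmap is not None:
        samples = [s for s in popmap.samples_of(outgroup) if s in cohort.sample_ids]
        if len(samples) == 1:
            return cohort.sample_index(samples[0])
        if len(samples) > 1:
            raise CohortError(
                f"outgroup {outgroup!r} has {len(samples)} samples; pseudo-haploid "
                "polarization needs a single genome (pass a sample id)"
            )
    raise CohortError(f"outgroup {outgroup!r} not found")


def polarize_sites(
    cohort: Cohort,
    outgroup1: str,
    outgroup2: str,
    annotation: AnnotationTable,
    seed: int,
    popmap: PopulationMap | None = None,
) -> PolarizedSites:
    """Polarize cohort sites by agreement of two pseudo-haploid outgroups.

    Each outgroup genotype is reduced to one allele (homozygote: that
    allele; heterozygote: one of the two picked uniformly, seeded; missing:
    site dropped). A site is retained iff both pseudo-haploid alleles agree;
    the agreed allele is ancestral and the cohort's other allele is derived.
    """
    j1 = _resolve_outgroup(cohort, popmap, outgroup1)
    j2 = _resolve_outgroup(cohort, popmap, outgroup2)
    if j1 == j2:
        raise CohortError("the two outgroups must be distinct genomes")
    rng = np.random.default_rng(seed)

    def pseudo_haploid(j: int) -> np.ndarray:
        g = cohort.gt[:, j, :]
        pick = rng.integers(0, 2, size=cohort.n_sites)
        allele = g[np.arange(cohort.n_sites), pick].astype(np.int16)
        allele[(g < 0).any(axis=1)] = -1
        return allele

    h1 = pseudo_haploid(j1)
    h2 = pseudo_haploid(j2)
    keep = (h1 >= 0) & (h2 >= 0) & (h1 == h2)
    n_missing = int(((h1 < 0) | (h2 < 0)).sum())
    n_disagree = int(((h1 >= 0) & (h2 >= 0) & (h1 != h2)).sum())
    logger.info(
        "polarize_sites: kept %d/%d sites (%d outgroup-missing, %d disagreeing)",
        int(keep.sum()), cohort.n_sites, n_missing, n_disagree,
    )
    site_index = np.flatnonzero(keep)
    ancestral_is_ref = h1[keep] == 0
    impact = annotation.lookup(cohort.take_sites(site_index))
    alt_dos = cohort.alt_dosage()[site_index]
    dosage = np.where(ancestral_is_ref[:, None], alt_dos, 2 - alt_dos).astype(np.int8)
    dosage[alt_dos < 0] = -1
    # ingroup dosages only make biological sense without the outgroups, but
    # the matrix keeps all samples so callers can subset however they like
    return PolarizedSites(site_index, ancestral_is_ref, impact, dosage, list(cohort.sample_ids))


@dataclass
class LoadReport:
    sample_id: str
    total_load: int
    realized_load: int
    masked_load: int
    category_counts: dict[str, int]
    normalized_rates: dict[str, float | None]
    unit: str = "allele"


def count_load(
    polarized: PolarizedSites, individual: str, unit: str = "allele"
) -> LoadReport:
    """Derived-allele load accounting for one individual.

    With ``unit='allele'`` (default) a homozygous-derived site contributes
    2 to the realized load, so total = realized + masked holds exactly;
    ``unit='site'`` counts homozygous-derived *sites* instead.
    """
    if unit not in ("allele", "site"):
        raise CohortError("unit must be 'allele' or 'site'")
    j = polarized.sample_ids.index(individual)
    dos = polarized.dosage[:, j]
    deleterious = np.isin(polarized.impact, DELETERIOUS)
    hom_w = 2 if unit == "allele" else 1
    called = dos >= 0
    hom = called & (dos == 2)
    het = called & (dos == 1)
    realized = hom_w * int((hom & deleterious).sum())
    masked = int((het & deleterious).sum())
    total = int(dos[called & deleterious].sum()) if unit == "allele" else realized + masked
    cat_counts = {
        cat: int(dos[called & (polarized.impact == cat)].sum())
        for cat in IMPACT_CATEGORIES
    }
    modifier = cat_counts["MODIFIER"]
    norm: dict[str, float | None] = {}
    for cat in ("HIGH", "MODERATE", "LOW"):
        norm[cat] = (
            cat_counts[cat] / modifier * NORMALIZATION_SCALE if modifier > 0 else None
        )
    norm["mutational_load"] = (
        (cat_counts["HIGH"] + cat_counts["MODERATE"]) / modifier * NORMALIZATION_SCALE
        if modifier > 0
        else None
    )
    if modifier == 0:
        logger.warning("no MODIFIER derived alleles for %s; rates undefined", individual)
    return LoadReport(individual, total, realized, masked, cat_counts, norm, unit)


def load_table(
    polarized: PolarizedSites,
    popmap: PopulationMap,
    individuals: list[str] | None = None,
    unit: str = "allele",
) -> pd.DataFrame:
    """One row of load metrics per (ingroup) individual."""
    if individuals is None:
        individuals = [
            s
            for s in polarized.sample_ids
            if popmap.population_of(s) not in popmap.outgroups
        ]
    rows = []
    for s in individuals:
        rep = count_load(polarized, s, unit=unit)
        rows.append(
            {
                "sample": s,
                "population": popmap.population_of(s),
                "total_load": rep.total_load,
                "realized_load": rep.realized_load,
                "masked_load": rep.masked_load,
                **{f"derived_{c.lower()}": rep.category_counts[c] for c in IMPACT_CATEGORIES},
                **{
                    f"per100k_{k.lower()}": (v if v is not None else float("nan"))
                    for k, v in rep.normalized_rates.items()
                },
            }
        )
    return pd.DataFrame(rows)


def compare_populations(reports: pd.DataFrame) -> pd.DataFrame:
    """Per-population mean/SD of each load metric, with rank orderings.

    Populations with no individuals are simply absent; the ``rank_*``
    columns order populations by descending mean (1 = highest).
    """
    metrics = ["total_load", "realized_load", "masked_load"]
    grouped = reports.groupby("population")[metrics].agg(["mean", "std", "count"])
    grouped.columns = ["_".join(c) for c in grouped.columns]
    for m in metrics:
        grouped[f"rank_{m}"] = (
            grouped[f"{m}_mean"].rank(ascending=False, method="min").astype(int)
        )
    return grouped.reset_index()
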
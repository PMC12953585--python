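"""Coalescent cohort simulation for the three-lineage wolf system.

The generator produces phased diploid biallelic-SNP cohorts under an
explicit demographic model with three deeply diverged wolf lineages
(Indian, Tibetan, Holarctic/Central), a recently admixed southwestern
population, and two long-diverged canid outgroups for allele
polarization. Inbreeding is emulated by planting autozygous tracts and
deleteriousness by annotation only — there is no selection in the
simulator, so downstream load analyses are accounting checks, not
selection tests.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import NamedTuple

import msprime
import numpy as np

from .cohort import Cohort, CohortError, PopulationMap, RecombinationMap

GENERATION_TIME_YEARS = 4.4  # pedigree-calibrated wolf generation time
MUTATION_RATE = 4.5e-9  # de novo rate per bp per generation (wolf pedigree)

IMPACT_CATEGORIES = ("HIGH", "MODERATE", "LOW", "MODIFIER")
#: Rough genome-wide proportions of SnpEff-style impact classes among SNPs.
DEFAULT_IMPACT_PROPORTIONS = (0.001, 0.01, 0.05, 0.939)


class Split(NamedTuple):
    time: float  # generations before present
    derived: str
    ancestral: str


class Admixture(NamedTuple):
    """A pulse: forward in time, ``proportion`` of ``dest`` comes from ``source``."""

    time: float
    source: str
    dest: str
    proportion: float


class HybridOrigin(NamedTuple):
    """``derived`` founded at ``time`` from ``ancestors`` with ``proportions``."""

    time: float
    derived: str
    ancestors: tuple[str, ...]
    proportions: tuple[float, ...]


class SizeChange(NamedTuple):
    """``population`` takes diploid size ``size`` before ``time`` (pastward)."""

    time: float
    population: str
    size: float


@dataclass
class DemographicModel:
    """Populations, sizes, split times, admixture pulses and rates.

    Times are in generations before present; sizes are diploid N_e.
    ``sequence_length`` is per chromosome.
    """

    populations: dict[str, float]
    splits: list[Split] = field(default_factory=list)
    admixture_events: list[Admixture] = field(default_factory=list)
    hybrid_origins: list[HybridOrigin] = field(default_factory=list)
    size_changes: list[SizeChange] = field(default_factory=list)
    mutation_rate: float = MUTATION_RATE
    recombination_rate: float = 1e-8
    generation_time: float = GENERATION_TIME_YEARS
    sequence_length: float = 5e6
    chromosome_count: int = 10
    outgroups: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.validate()

    def origin_time(self, pop: str) -> float:
        """Generations at which ``pop`` originates (inf for root populations)."""
        for s in self.splits:
            if s.derived == pop:
                return s.time
        for h in self.hybrid_origins:
            if h.derived == pop:
                return h.time
        return float("inf")

    def validate(self) -> None:
        if self.mutation_rate <= 0:
            raise CohortError("mutation rate must be positive")
        for s in self.splits:
            if s.time <= 0:
                raise CohortError("split times must be positive")
            for p in (s.derived, s.ancestral):
                if p not in self.populations:
                    raise CohortError(f"unknown population {p!r} in split")
        for a in self.admixture_events:
            if not (0.0 < a.proportion < 1.0):
                raise CohortError("admixture proportion must be in (0, 1)")
            if a.time <= 0:
                raise CohortError("admixture times must be positive")
            for p in (a.source, a.dest):
                if p not in self.populations:
                    raise CohortError(f"unknown population {p!r} in admixture")
                if a.time >= self.origin_time(p):
                    raise CohortError(
                        f"admixture at {a.time} predates origin of {p!r}"
                    )
        for h in self.hybrid_origins:
            if abs(sum(h.proportions) - 1.0) > 1e-9:
                raise CohortError("hybrid-origin proportions must sum to 1")
        for c in self.size_changes:
            if c.time < 0 or c.size <= 0:
                raise CohortError("size changes need non-negative time and positive size")
            if c.population not in self.populations:
                raise CohortError(f"unknown population {c.population!r} in size change")

    def to_msprime(self) -> msprime.Demography:
        dem = msprime.Demography()
        for name, ne in self.populations.items():
            dem.add_population(name=name, initial_size=ne)
        for a in self.admixture_events:
            # Backward in time: lineages in dest trace back to source.
            dem.add_mass_migration(
                time=a.time, source=a.dest, dest=a.source, proportion=a.proportion
            )
        for c in self.size_changes:
            dem.add_population_parameters_change(
                time=c.time, population=c.population, initial_size=c.size
            )
        for h in self.hybrid_origins:
            dem.add_admixture(
                time=h.time,
                derived=h.derived,
                ancestral=list(h.ancestors),
                proportions=list(h.proportions),
            )
        for s in sorted(self.splits, key=lambda s: s.time):
            dem.add_population_split(time=s.time, derived=[s.derived], ancestral=s.ancestral)
        dem.sort_events()
        return dem


def years(y: float, generation_time: float = GENERATION_TIME_YEARS) -> float:
    """Convert years before present to generations."""
    return y / generation_time


def default_wolf_model(**overrides) -> DemographicModel:
    """The study conditions: three wolf lineages, recent admixture, outgroups.

    Indian splits ~100 kya, Tibetan (earliest-diverging lineage) ~120 kya,
    southwestern Asia splits from the Central/Holarctic population ~10.3 kya,
    with an Indian -> SWAsia admixture pulse of 0.11 at ~6 kya. Two canid
    outgroups diverge at 1 and 2 My, emulating dhole/Andean-fox polarization
    anchors. N_e defaults are order-of-magnitude realistic for wolves (small
    for the isolated Indian/Tibetan/SWAsia populations, larger for the
    connected Holarctic population) and are exposed as configuration.
    """
    kw = dict(
        populations={
            "Indian": 5000.0,
            "Tibetan": 5000.0,
            "Central": 15000.0,
            "SWAsia": 5000.0,
            "Outgroup1": 15000.0,
            "Outgroup2": 15000.0,
        },
        splits=[
            Split(years(10_300), "SWAsia", "Central"),
            Split(years(100_000), "Indian", "Central"),
            Split(years(120_000), "Tibetan", "Central"),
            Split(years(1_000_000), "Outgroup1", "Central"),
            Split(years(2_000_000), "Outgroup2", "Central"),
        ],
        admixture_events=[Admixture(years(6_000), "Indian", "SWAsia", 0.11)],
        outgroups=("Outgroup1", "Outgroup2"),
    )
    kw.update(overrides)
    return DemographicModel(**kw)


@dataclass
class TruthRecord:
    """Ground truth of a simulated cohort, for recovery tests."""

    seed: int
    model: DemographicModel
    planted_roh: dict[str, list[tuple[str, int, int]]] = field(default_factory=dict)
    admixture_fractions: dict[str, float] = field(default_factory=dict)

    def to_json(self, path: str) -> None:
        payload = {
            "seed": self.seed,
            "planted_roh": self.planted_roh,
            "admixture_fractions": self.admixture_fractions,
            "model": {
                "populations": self.model.populations,
                "splits": [list(s) for s in self.model.splits],
                "admixture_events": [list(a) for a in self.model.admixture_events],
                "mutation_rate": self.model.mutation_rate,
                "recombination_rate": self.model.recombination_rate,
                "generation_time": self.model.generation_time,
                "sequence_length": self.model.sequence_length,
                "chromosome_count": self.model.chromosome_count,
            },
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)


@dataclass
class AnnotationTable:
    """Per-site impact category, aligned with a cohort's sites."""

    chroms: list[str]
    positions: np.ndarray
    categories: np.ndarray  # of IMPACT_CATEGORIES strings

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.categories = np.asarray(self.categories, dtype="U8")
        bad = set(np.unique(self.categories)) - set(IMPACT_CATEGORIES)
        if bad:
            raise CohortError(f"unknown impact categories: {sorted(bad)}")

    def to_tsv(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write("#chrom\tpos\timpact\n")
            for c, p, cat in zip(self.chroms, self.positions, self.categories):
                fh.write(f"{c}\t{int(p) + 1}\t{cat}\n")

    @classmethod
    def from_tsv(cls, path: str) -> "AnnotationTable":
        chroms, pos, cats = [], [], []
        with open(path) as fh:
            for line in fh:
                if not line.strip() or line.startswith("#"):
                    continue
                c, p, cat = line.rstrip("\n").split("\t")[:3]
                chroms.append(c)
                pos.append(int(p) - 1)
                cats.append(cat)
        return cls(chroms, np.array(pos), np.array(cats))

    def lookup(self, cohort: Cohort) -> np.ndarray:
        """Impact category per cohort site; error if a site is unannotated."""
        table = {
            (c, int(p)): cat
            for c, p, cat in zip(self.chroms, self.positions, self.categories)
        }
        out = np.empty(cohort.n_sites, dtype="U8")
        for i in range(cohort.n_sites):
            key = (cohort.chrom_ids[cohort.chrom_index[i]], int(cohort.positions[i]))
            if key not in table:
                raise CohortError(f"site {key} lacks an impact annotation")
            out[i] = table[key]
        return out


@dataclass
class SimResult:
    cohort: Cohort
    popmap: PopulationMap
    truth: TruthRecord
    recomb_map: RecombinationMap


def _child_seeds(seed: int, n: int) -> np.ndarray:
    return np.random.default_rng(seed).integers(1, 2**31 - 1, size=n)


def simulate_cohort(
    model: DemographicModel,
    samples_per_pop: dict[str, int] | int,
    seed: int,
    missing_fraction: float = 0.0,
) -> SimResult:
    """Simulate a phased diploid cohort under ``model``.

    ``samples_per_pop`` is either one diploid count applied to every model
    population or a mapping population -> count (omitted populations are
    simulated but unsampled). Sites are biallelic SNPs on
    ``chromosome_count`` independent chromosomes; byte-identical given the
    same seed. ``missing_fraction`` plants missing diploid calls uniformly
    at random so that missingness filters are exercisable.
    """
    if model.sequence_length <= 0:
        raise CohortError("zero-length sequence")
    if isinstance(samples_per_pop, int):
        samples = {p: samples_per_pop for p in model.populations}
    else:
        unknown = set(samples_per_pop) - set(model.populations)
        if unknown:
            raise CohortError(f"unknown populations: {sorted(unknown)}")
        samples = {p: n for p, n in samples_per_pop.items() if n > 0}
    if not samples or min(samples.values()) < 1:
        raise CohortError("need at least one sample in some population")

    demography = model.to_msprime()
    sample_ids: list[str] = []
    assignments: dict[str, str] = {}
    for pop, n in samples.items():
        for k in range(n):
            sid = f"{pop}_{k + 1}"
            sample_ids.append(sid)
            assignments[sid] = pop

    rng_seeds = _child_seeds(seed, 2 * model.chromosome_count + 1)
    chrom_ids = [f"chr{i + 1}" for i in range(model.chromosome_count)]
    chrom_index, positions, refs, alts, gts = [], [], [], [], []
    for ci in range(model.chromosome_count):
        ts = msprime.sim_ancestry(
            samples,
            demography=demography,
            sequence_length=model.sequence_length,
            recombination_rate=model.recombination_rate,
            random_seed=int(rng_seeds[2 * ci]),
        )
        mts = msprime.sim_mutations(
            ts, rate=model.mutation_rate, random_seed=int(rng_seeds[2 * ci + 1])
        )
        for v in mts.variants():
            if len(v.alleles) != 2:
                continue  # multi-hit site; cohort holds biallelic SNPs only
            chrom_index.append(ci)
            positions.append(int(v.site.position))
            refs.append(v.alleles[0])
            alts.append(v.alleles[1])
            gts.append(v.genotypes.astype(np.int8))

    n_sites = len(positions)
    gt = (
        np.stack(gts).reshape(n_sites, len(sample_ids), 2)
        if n_sites
        else np.empty((0, len(sample_ids), 2), np.int8)
    )
    cohort = Cohort(
        chrom_ids=chrom_ids,
        chrom_index=np.array(chrom_index, np.int32),
        positions=np.array(positions, np.int64),
        ref=np.array(refs, "U1"),
        alt=np.array(alts, "U1"),
        gt=gt,
        phased=np.ones((n_sites, len(sample_ids)), bool),
        sample_ids=sample_ids,
        site_quality=np.full(n_sites, 100.0),
    )
    if missing_fraction > 0:
        rng = np.random.default_rng(int(rng_seeds[-1]))
        mask = rng.random((n_sites, len(sample_ids))) < missing_fraction
        cohort.gt[mask] = -1
        cohort.phased[mask] = False
    cohort.validate()

    popmap = PopulationMap(assignments, frozenset(model.outgroups))
    alpha_by_pop = {a.dest: a.proportion for a in model.admixture_events}
    truth = TruthRecord(
        seed=seed,
        model=model,
        admixture_fractions={
            s: alpha_by_pop.get(assignments[s], 0.0) for s in sample_ids
        },
    )
    rate_cm_mb = model.recombination_rate * 1e8
    rmap = RecombinationMap(
        chroms=chrom_ids,
        starts=np.zeros(model.chromosome_count, np.int64),
        ends=np.full(model.chromosome_count, int(model.sequence_length), np.int64),
        rates=np.full(model.chromosome_count, rate_cm_mb),
    )
    return SimResult(cohort, popmap, truth, rmap)


def plant_roh(
    cohort: Cohort,
    individual: str,
    tracts: list[tuple[str, int, int]],
    seed: int,
    truth: TruthRecord | None = None,
) -> tuple[Cohort, TruthRecord | None]:
    """Force homozygosity within the given tracts for one individual.

    Inside each half-open tract every heterozygous call of ``individual``
    is set to a homozygote, picking one of its two alleles uniformly at
    random (seeded); other genotypes, other samples, and sites outside the
    tracts are untouched. Returns a new cohort; the input is unchanged.
    """
    j = cohort.sample_index(individual)
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for chrom, start, end in tracts:
        if chrom not in cohort.chrom_ids:
            raise CohortError(f"unknown chromosome {chrom!r}")
        if not (0 <= start < end):
            raise CohortError(f"bad tract bounds {chrom}:{start}-{end}")
        by_chrom.setdefault(chrom, []).append((int(start), int(end)))
    for chrom, spans in by_chrom.items():
        spans.sort()
        for (s0, e0), (s1, _) in zip(spans, spans[1:]):
            if s1 < e0:
                raise CohortError(f"overlapping tracts on {chrom}")

    out = cohort.copy()
    rng = np.random.default_rng(seed)
    for chrom, start, end in tracts:
        ci = cohort.chrom_ids.index(chrom)
        in_tract = (
            (out.chrom_index == ci) & (out.positions >= start) & (out.positions < end)
        )
        rows = np.flatnonzero(in_tract)
        g = out.gt[rows, j, :]
        het = (g[:, 0] != g[:, 1]) & (g >= 0).all(axis=1)
        pick = rng.integers(0, 2, size=int(het.sum()))
        chosen = g[het][np.arange(int(het.sum())), pick]
        g[het] = chosen[:, None]
        out.gt[rows, j, :] = g
    if truth is not None:
        truth.planted_roh.setdefault(individual, []).extend(
            [(c, int(s), int(e)) for c, s, e in tracts]
        )
    return out, truth


def assign_impact_annotations(
    cohort: Cohort,
    proportions: tuple[float, float, float, float] = DEFAULT_IMPACT_PROPORTIONS,
    seed: int = 0,
) -> AnnotationTable:
    """Assign each site one impact category at the given proportions.

    Categories follow the (HIGH, MODERATE, LOW, MODIFIER) order; draws are
    i.i.d. multinomial, seeded, so the table is reproducible.
    """
    props = np.asarray(proportions, float)
    if abs(props.sum() - 1.0) > 1e-9:
        raise CohortError("impact proportions must sum to 1")
    rng = np.random.default_rng(seed)
    cats = rng.choice(np.array(IMPACT_CATEGORIES), size=cohort.n_sites, p=props)
    chroms = [cohort.chrom_ids[i] for i in cohort.chrom_index]
    return AnnotationTable(chroms, cohort.positions.copy(), cats)
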
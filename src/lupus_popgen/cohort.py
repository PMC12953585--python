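"""Shared data model and I/O for genotyped cohorts.

The in-memory substrate of every analysis stage is a :class:`Cohort`: a
sites x samples matrix of diploid genotype calls at biallelic SNPs, with
0-based half-open coordinates internally (VCF I/O converts to/from 1-based).
Alongside it live the sample-to-population map, the recombination map
(cM/Mb per window), and a per-stage site filter specification.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from cyvcf2 import VCF

logger = logging.getLogger(__name__)

MISSING = -1
_BASES = frozenset("ACGT")


class CohortError(ValueError):
    """Raised on malformed cohort data or violated preconditions."""


@dataclass
class Cohort:
    """Biallelic-SNP genotype matrix for a set of diploid samples.

    Attributes
    ----------
    chrom_ids : list of str
        Chromosome names, in order of first appearance.
    chrom_index : (n_sites,) int32 array
        Index into ``chrom_ids`` per site.
    positions : (n_sites,) int64 array
        0-based site coordinates, strictly increasing within a chromosome.
    ref, alt : (n_sites,) single-character arrays
        Reference and alternate alleles; allele code 0 is ref, 1 is alt.
    gt : (n_sites, n_samples, 2) int8 array
        Diploid allele calls in {0, 1}; ``-1`` marks a missing call
        (half-missing VCF calls are treated as fully missing).
    phased : (n_sites, n_samples) bool array
        Per-call phase flags.
    sample_ids : list of str
    site_quality : (n_sites,) float array
        Non-negative site quality; NaN when unknown.
    """

    chrom_ids: list[str]
    chrom_index: np.ndarray
    positions: np.ndarray
    ref: np.ndarray
    alt: np.ndarray
    gt: np.ndarray
    phased: np.ndarray
    sample_ids: list[str]
    site_quality: np.ndarray

    def __post_init__(self) -> None:
        self.chrom_index = np.asarray(self.chrom_index, dtype=np.int32)
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.ref = np.asarray(self.ref, dtype="U1")
        self.alt = np.asarray(self.alt, dtype="U1")
        self.gt = np.asarray(self.gt, dtype=np.int8)
        self.phased = np.asarray(self.phased, dtype=bool)
        self.site_quality = np.asarray(self.site_quality, dtype=float)

    # -- shape ---------------------------------------------------------
    @property
    def n_sites(self) -> int:
        return len(self.positions)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def validate(self) -> None:
        n, m = self.n_sites, self.n_samples
        if self.gt.shape != (n, m, 2):
            raise CohortError(f"genotype matrix shape {self.gt.shape} != ({n}, {m}, 2)")
        if self.phased.shape != (n, m):
            raise CohortError("phase matrix shape mismatch")
        if len(self.chrom_index) != n or len(self.ref) != n or len(self.alt) != n:
            raise CohortError("per-site array length mismatch")
        if n and (self.chrom_index.min() < 0 or self.chrom_index.max() >= len(self.chrom_ids)):
            raise CohortError("chrom_index out of range")
        same = self.ref == self.alt
        if same.any():
            raise CohortError(f"ref == alt at site {int(np.flatnonzero(same)[0])}")
        for c in range(len(self.chrom_ids)):
            pos = self.positions[self.chrom_index == c]
            if len(pos) > 1 and not (np.diff(pos) > 0).all():
                raise CohortError(f"positions not strictly increasing on {self.chrom_ids[c]}")
        with np.errstate(invalid="ignore"):
            if np.any(self.site_quality < 0):
                raise CohortError("negative site quality")

    # -- convenience views ---------------------------------------------
    def sample_index(self, sample_id: str) -> int:
        try:
            return self.sample_ids.index(sample_id)
        except ValueError:
            raise CohortError(f"sample {sample_id!r} not in cohort") from None

    def missing_mask(self) -> np.ndarray:
        """(n_sites, n_samples) bool: True where the diploid call is missing."""
        return (self.gt < 0).any(axis=2)

    def het_mask(self) -> np.ndarray:
        """(n_sites, n_samples) bool: True where the call is heterozygous."""
        called = ~self.missing_mask()
        return called & (self.gt[:, :, 0] != self.gt[:, :, 1])

    def alt_dosage(self) -> np.ndarray:
        """(n_sites, n_samples) int8 count of alt alleles; -1 where missing."""
        dos = self.gt.sum(axis=2, dtype=np.int16)
        dos[self.missing_mask()] = MISSING
        return dos.astype(np.int8)

    def allele_counts(self, sample_idx: np.ndarray | list[int]) -> tuple[np.ndarray, np.ndarray]:
        """Per-site (#alt alleles, #called alleles) over the given samples."""
        sub = self.gt[:, list(sample_idx), :]
        called = sub >= 0
        return (sub == 1).sum(axis=(1, 2)), called.sum(axis=(1, 2))

    def take_sites(self, selector: np.ndarray) -> "Cohort":
        """New cohort restricted to the selected sites (mask or index array)."""
        sel = np.asarray(selector)
        if sel.dtype == bool:
            sel = np.flatnonzero(sel)
        return Cohort(
            chrom_ids=list(self.chrom_ids),
            chrom_index=self.chrom_index[sel],
            positions=self.positions[sel],
            ref=self.ref[sel],
            alt=self.alt[sel],
            gt=self.gt[sel],
            phased=self.phased[sel],
            sample_ids=list(self.sample_ids),
            site_quality=self.site_quality[sel],
        )

    def sites_on(self, chrom: str) -> np.ndarray:
        """Indices of sites on the named chromosome."""
        return np.flatnonzero(self.chrom_index == self.chrom_ids.index(chrom))

    def copy(self) -> "Cohort":
        return Cohort(
            chrom_ids=list(self.chrom_ids),
            chrom_index=self.chrom_index.copy(),
            positions=self.positions.copy(),
            ref=self.ref.copy(),
            alt=self.alt.copy(),
            gt=self.gt.copy(),
            phased=self.phased.copy(),
            sample_ids=list(self.sample_ids),
            site_quality=self.site_quality.copy(),
        )


@dataclass
class PopulationMap:
    """sample id -> population label, with designated outgroup labels."""

    assignments: dict[str, str]
    outgroups: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        self.outgroups = frozenset(self.outgroups)
        ingroups = {p for p in self.assignments.values() if p not in self.outgroups}
        if ingroups & self.outgroups:
            raise CohortError("outgroup labels overlap ingroup labels")

    def population_of(self, sample_id: str) -> str:
        try:
            return self.assignments[sample_id]
        except KeyError:
            raise CohortError(f"sample {sample_id!r} absent from population map") from None

    def samples_of(self, population: str) -> list[str]:
        return [s for s, p in self.assignments.items() if p == population]

    @property
    def populations(self) -> list[str]:
        seen: dict[str, None] = {}
        for p in self.assignments.values():
            seen.setdefault(p)
        return list(seen)

    def validate_against(self, cohort: Cohort) -> None:
        missing = [s for s in cohort.sample_ids if s not in self.assignments]
        if missing:
            raise CohortError(f"samples absent from population map: {missing}")


@dataclass
class RecombinationMap:
    """Non-overlapping half-open windows with local rates in cM/Mb."""

    chroms: list[str]
    starts: np.ndarray
    ends: np.ndarray
    rates: np.ndarray

    def __post_init__(self) -> None:
        self.starts = np.asarray(self.starts, dtype=np.int64)
        self.ends = np.asarray(self.ends, dtype=np.int64)
        self.rates = np.asarray(self.rates, dtype=float)
        if np.any(self.rates < 0):
            raise CohortError("negative recombination rate")
        if np.any(self.ends <= self.starts):
            raise CohortError("empty or inverted recombination-map window")
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for c, s, e in zip(self.chroms, self.starts, self.ends):
            by_chrom.setdefault(c, []).append((int(s), int(e)))
        for c, wins in by_chrom.items():
            wins.sort()
            for (s0, e0), (s1, _) in zip(wins, wins[1:]):
                if s1 < e0:
                    raise CohortError(f"overlapping recombination-map windows on {c}")

    @property
    def genome_mean_rate(self) -> float:
        """Length-weighted mean rate over all windows (cM/Mb)."""
        lengths = (self.ends - self.starts).astype(float)
        return float(np.sum(self.rates * lengths) / np.sum(lengths))

    def mean_rate_in(self, chrom: str, start: int, end: int) -> float:
        """bp-overlap-weighted mean rate over [start, end); uncovered bp get 0."""
        if end <= start:
            raise CohortError("empty interval")
        total = 0.0
        covered = 0
        for c, s, e, r in zip(self.chroms, self.starts, self.ends, self.rates):
            if c != chrom:
                continue
            ov = min(end, int(e)) - max(start, int(s))
            if ov > 0:
                total += r * ov
                covered += ov
        if covered < end - start:
            warnings.warn(
                f"{end - start - covered} bp of {chrom}:{start}-{end} uncovered by the "
                "recombination map; treated as rate 0",
                stacklevel=2,
            )
        return total / (end - start)


@dataclass
class FilterSpec:
    """Per-stage site filter: quality, missingness, minor-allele count.

    Read-depth filters in the original pipelines act on raw reads and have
    no genotype-level analogue; they are represented here by the site
    quality and missingness knobs.
    """

    min_site_quality: float = 0.0
    max_missing_fraction: float = 1.0
    min_minor_allele_count: int = 0
    biallelic_only: bool = True

    def __post_init__(self) -> None:
        if not (0.0 <= self.max_missing_fraction <= 1.0):
            raise CohortError("max_missing_fraction must be in [0, 1]")
        if self.min_minor_allele_count < 0 or self.min_site_quality < 0:
            raise CohortError("filter thresholds must be non-negative")


def filter_sites(cohort: Cohort, spec: FilterSpec) -> tuple[Cohort, dict[str, int]]:
    """Apply all criteria of ``spec``; returns (new cohort, removed-per-criterion).

    A site survives iff it passes every criterion; the counts report, for
    each criterion, how many input sites fail it (a site failing several
    criteria is counted under each). Unknown (NaN) site quality passes the
    quality criterion. The input cohort is not modified.
    """
    n = cohort.n_sites
    quality_ok = ~(cohort.site_quality < spec.min_site_quality)  # NaN passes
    miss_frac = cohort.missing_mask().sum(axis=1) / max(cohort.n_samples, 1)
    missing_ok = miss_frac <= spec.max_missing_fraction
    alt_n, called_n = cohort.allele_counts(np.arange(cohort.n_samples))
    minor = np.minimum(alt_n, called_n - alt_n)
    mac_ok = minor >= spec.min_minor_allele_count
    keep = quality_ok & missing_ok & mac_ok
    removed = {
        "min_site_quality": int(n - quality_ok.sum()),
        "max_missing_fraction": int(n - missing_ok.sum()),
        "min_minor_allele_count": int(n - mac_ok.sum()),
    }
    if not keep.any():
        warnings.warn("all sites removed by filter", stacklevel=2)
    return cohort.take_sites(keep), removed


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def read_popmap(path: str) -> PopulationMap:
    """Read a TSV ``sample<TAB>population[<TAB>{ingroup|outgroup}]``."""
    assignments: dict[str, str] = {}
    outgroups: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise CohortError(f"{path}:{lineno}: expected at least 2 tab-separated fields")
            sample, pop = parts[0], parts[1]
            role = parts[2] if len(parts) > 2 else "ingroup"
            if role not in ("ingroup", "outgroup"):
                raise CohortError(f"{path}:{lineno}: role must be ingroup or outgroup")
            if sample in assignments:
                raise CohortError(f"{path}:{lineno}: duplicate sample {sample!r}")
            assignments[sample] = pop
            if role == "outgroup":
                outgroups.add(pop)
    return PopulationMap(assignments, frozenset(outgroups))


def read_vcf_cohort(
    path: str, popmap_path: str | None = None
) -> tuple[Cohort, PopulationMap | None, dict[str, int]]:
    """Read a VCF into a Cohort, keeping only biallelic SNP records.

    Multi-allelic records, indels and non-ACGT records are dropped and
    counted in the returned drop log. Sample order is the VCF header order.
    When ``popmap_path`` is given, every VCF sample must appear in it.
    """
    vcf = VCF(path, gts012=False)
    samples = list(vcf.samples)
    popmap = None
    if popmap_path is not None:
        popmap = read_popmap(popmap_path)
        absent = [s for s in samples if s not in popmap.assignments]
        if absent:
            raise CohortError(f"samples absent from population map: {absent}")

    chrom_ids: list[str] = []
    chrom_lookup: dict[str, int] = {}
    chrom_idx: list[int] = []
    positions: list[int] = []
    refs: list[str] = []
    alts: list[str] = []
    quals: list[float] = []
    gts: list[np.ndarray] = []
    phases: list[np.ndarray] = []
    drop_log = {"multiallelic": 0, "indel": 0, "non_acgt": 0}

    for v in vcf:
        if len(v.ALT) != 1:
            drop_log["multiallelic"] += 1
            continue
        if len(v.REF) != 1 or len(v.ALT[0]) != 1:
            drop_log["indel"] += 1
            continue
        if v.REF not in _BASES or v.ALT[0] not in _BASES:
            drop_log["non_acgt"] += 1
            continue
        if v.CHROM not in chrom_lookup:
            chrom_lookup[v.CHROM] = len(chrom_ids)
            chrom_ids.append(v.CHROM)
        geno = np.array(v.genotypes, dtype=np.int16)  # (n_samples, ploidy+1)
        if geno.shape[1] != 3:
            raise CohortError(f"non-diploid GT at {v.CHROM}:{v.POS}")
        alleles = geno[:, :2].astype(np.int8)
        alleles[(alleles < 0).any(axis=1)] = MISSING
        chrom_idx.append(chrom_lookup[v.CHROM])
        positions.append(v.POS - 1)  # to 0-based
        refs.append(v.REF)
        alts.append(v.ALT[0])
        quals.append(float(v.QUAL) if v.QUAL is not None else np.nan)
        gts.append(alleles)
        phases.append(geno[:, 2].astype(bool))

    n = len(positions)
    cohort = Cohort(
        chrom_ids=chrom_ids,
        chrom_index=np.array(chrom_idx, dtype=np.int32),
        positions=np.array(positions, dtype=np.int64),
        ref=np.array(refs, dtype="U1"),
        alt=np.array(alts, dtype="U1"),
        gt=np.stack(gts) if n else np.empty((0, len(samples), 2), np.int8),
        phased=np.stack(phases) if n else np.empty((0, len(samples)), bool),
        sample_ids=samples,
        site_quality=np.array(quals, dtype=float),
    )
    cohort.validate()
    if any(drop_log.values()):
        logger.info("read_vcf_cohort dropped records: %s", drop_log)
    return cohort, popmap, drop_log


def write_vcf_cohort(cohort: Cohort, path: str, popmap: PopulationMap | None = None) -> None:
    """Write a VCF 4.2 file (1-based POS); read-write round trips exactly."""
    cohort.validate()
    if popmap is not None:
        popmap.validate_against(cohort)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=lupus_popgen\n")
        for c in cohort.chrom_ids:
            on_c = cohort.positions[cohort.chrom_index == cohort.chrom_ids.index(c)]
            length = int(on_c.max()) + 1 if len(on_c) else 1
            fh.write(f"##contig=<ID={c},length={length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(cohort.sample_ids)
            + "\n"
        )
        for i in range(cohort.n_sites):
            qual = cohort.site_quality[i]
            qual_s = "." if np.isnan(qual) else f"{qual:g}"
            fields = [
                cohort.chrom_ids[cohort.chrom_index[i]],
                str(int(cohort.positions[i]) + 1),
                ".",
                str(cohort.ref[i]),
                str(cohort.alt[i]),
                qual_s,
                "PASS",
                ".",
                "GT",
            ]
            row = cohort.gt[i]
            ph = cohort.phased[i]
            calls = []
            for j in range(cohort.n_samples):
                a, b = int(row[j, 0]), int(row[j, 1])
                sep = "|" if ph[j] else "/"
                if a < 0 or b < 0:
                    calls.append("./.")
                else:
                    calls.append(f"{a}{sep}{b}")
            fh.write("\t".join(fields + calls) + "\n")


def write_popmap(popmap: PopulationMap, path: str) -> None:
    with open(path, "w") as fh:
        for sample, pop in popmap.assignments.items():
            role = "outgroup" if pop in popmap.outgroups else "ingroup"
            fh.write(f"{sample}\t{pop}\t{role}\n")


def read_recomb_map(path: str) -> RecombinationMap:
    """Read a BED4 TSV ``chrom start end cM_per_Mb`` (0-based half-open)."""
    chroms: list[str] = []
    starts: list[int] = []
    ends: list[int] = []
    rates: list[float] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise CohortError(f"{path}:{lineno}: expected 4 columns")
            chroms.append(parts[0])
            starts.append(int(parts[1]))
            ends.append(int(parts[2]))
            rates.append(float(parts[3]))
    return RecombinationMap(chroms, np.array(starts), np.array(ends), np.array(rates))


def write_recomb_map(rmap: RecombinationMap, path: str) -> None:
    with open(path, "w") as fh:
        for c, s, e, r in zip(rmap.chroms, rmap.starts, rmap.ends, rmap.rates):
            fh.write(f"{c}\t{int(s)}\t{int(e)}\t{r:g}\n")
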
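"""ABBA-BABA D-statistics with weighted block-jackknife standard errors.

For a quartet (((P1, P2), P3), P4) with P4 an outgroup, derived-allele
frequencies p_i per population give per-site pattern expectations

    abba = (1 - p1) * p2 * p3 * (1 - p4)
    baba = p1 * (1 - p2) * p3 * (1 - p4)

and D = (sum(baba) - sum(abba)) / (sum(baba) + sum(abba)), so an excess
of derived-allele sharing between P2 and P3 (ABBA) drives D negative.
Standard errors come from a delete-one-block jackknife over contiguous
genomic blocks, weighted by the number of informative sites per block
(Busing-style unequal block sizes); Z = D / SE.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import Cohort, CohortError, PopulationMap

DEFAULT_BLOCK_BP = 5_000_000


@dataclass
class QuartetSpec:
    """Four disjoint taxa, each a population label or explicit sample list."""

    p1: str | list[str]
    p2: str | list[str]
    p3: str | list[str]
    p4: str | list[str]

    def resolve(self, cohort: Cohort, popmap: PopulationMap) -> list[np.ndarray]:
        """Sample index arrays for P1..P4; validates disjointness."""
        groups = []
        for spec in (self.p1, self.p2, self.p3, self.p4):
            samples = [spec] if isinstance(spec, str) and spec in cohort.sample_ids else spec
            if isinstance(samples, str):
                samples = popmap.samples_of(samples)
                samples = [s for s in samples if s in cohort.sample_ids]
            if not samples:
                raise CohortError(f"quartet member {spec!r} resolves to no samples")
            groups.append(np.array([cohort.sample_index(s) for s in samples]))
        flat = np.concatenate(groups)
        if len(np.unique(flat)) != len(flat):
            raise CohortError("quartet sample sets are not disjoint")
        return groups


@dataclass
class PatternSums:
    """Per-block ABBA/BABA sums (jackknife units tiling the genome)."""

    chrom: list[str]
    start: np.ndarray
    end: np.ndarray
    abba: np.ndarray
    baba: np.ndarray
    n_sites_used: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": self.chrom,
                "start": self.start,
                "end": self.end,
                "abba": self.abba,
                "baba": self.baba,
                "n_sites_used": self.n_sites_used,
            }
        )


@dataclass
class DResult:
    d: float
    se: float
    z: float
    abba: float
    baba: float
    n_blocks: int
    n_sites: int


def site_patterns(
    cohort: Cohort, popmap: PopulationMap, quartet: QuartetSpec
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-site (abba, baba, used) arrays over all cohort sites.

    Sites are polarized by the P4 consensus allele (the outgroup's majority
    allele among non-missing calls); sites where P4 is polymorphic, or any
    quartet population has no called allele, are skipped (used = False).
    """
    groups = quartet.resolve(cohort, popmap)
    alt_counts, called = [], []
    for g in groups:
        a, c = cohort.allele_counts(g)
        alt_counts.append(a.astype(float))
        called.append(c.astype(float))
    a4, c4 = alt_counts[3], called[3]
    p4_fixed_alt = (c4 > 0) & (a4 == c4)
    p4_fixed_ref = (c4 > 0) & (a4 == 0)
    usable = p4_fixed_alt | p4_fixed_ref
    for a, c in zip(alt_counts[:3], called[:3]):
        usable &= c > 0
    with np.errstate(invalid="ignore", divide="ignore"):
        freqs = [np.where(c > 0, a / np.maximum(c, 1), np.nan) for a, c in zip(alt_counts, called)]
    # derived = the allele absent from the P4 consensus
    p = [np.where(p4_fixed_ref, f, 1.0 - f) for f in freqs]
    abba = (1 - p[0]) * p[1] * p[2] * (1 - p[3])
    baba = p[0] * (1 - p[1]) * p[2] * (1 - p[3])
    abba = np.where(usable, abba, 0.0)
    baba = np.where(usable, baba, 0.0)
    return abba, baba, usable


def site_pattern_sums(
    cohort: Cohort,
    popmap: PopulationMap,
    quartet: QuartetSpec,
    block_bp: int = DEFAULT_BLOCK_BP,
) -> PatternSums:
    """Accumulate ABBA/BABA site patterns into contiguous genomic blocks."""
    if block_bp <= 0:
        raise CohortError("block_bp must be positive")
    abba, baba, usable = site_patterns(cohort, popmap, quartet)
    chroms, starts, ends, ab, ba, ns = [], [], [], [], [], []
    for ci, chrom in enumerate(cohort.chrom_ids):
        on_c = cohort.chrom_index == ci
        if not on_c.any():
            continue
        pos = cohort.positions[on_c]
        blk = pos // block_bp
        n_blocks = int(blk.max()) + 1
        for b in range(n_blocks):
            in_b = on_c.copy()
            in_b[on_c] = blk == b
            chroms.append(chrom)
            starts.append(b * block_bp)
            ends.append((b + 1) * block_bp)
            ab.append(abba[in_b].sum())
            ba.append(baba[in_b].sum())
            ns.append(int(usable[in_b].sum()))
    return PatternSums(
        chroms,
        np.array(starts, np.int64),
        np.array(ends, np.int64),
        np.array(ab),
        np.array(ba),
        np.array(ns, np.int64),
    )


def _weighted_jackknife_se(theta_hat: float, theta_del: np.ndarray, m: np.ndarray) -> float:
    """Busing et al. delete-one jackknife SE with unequal block weights m_j."""
    g = len(m)
    n = m.sum()
    h = n / m
    theta_j = g * theta_hat - float(np.sum((1.0 - m / n) * theta_del))
    tau = h * theta_hat - (h - 1.0) * theta_del
    # with equal weights this reduces to the classic (g-1)/g * sum((theta_del - mean)^2)
    var = float(np.sum((tau - theta_j) ** 2 / (h - 1.0)) / g)
    return float(np.sqrt(var))


def d_statistic(patterns: PatternSums) -> DResult:
    """D, jackknife SE and Z from per-block pattern sums."""
    keep = patterns.n_sites_used > 0
    abba = patterns.abba[keep]
    baba = patterns.baba[keep]
    m = patterns.n_sites_used[keep].astype(float)
    tot_a, tot_b = float(abba.sum()), float(baba.sum())
    if tot_a + tot_b == 0:
        raise CohortError("no informative sites: D undefined")
    if len(m) < 2:
        raise CohortError("need >= 2 non-empty blocks for a jackknife SE")
    d = (tot_b - tot_a) / (tot_b + tot_a)
    del_a = tot_a - abba
    del_b = tot_b - baba
    theta_del = (del_b - del_a) / (del_b + del_a)
    se = _weighted_jackknife_se(d, theta_del, m)
    z = d / se if se > 0 else float("nan")
    return DResult(
        d=d,
        se=se,
        z=z,
        abba=tot_a,
        baba=tot_b,
        n_blocks=int(keep.sum()),
        n_sites=int(patterns.n_sites_used.sum()),
    )


def d_test(
    cohort: Cohort,
    popmap: PopulationMap,
    quartet: QuartetSpec,
    block_bp: int = DEFAULT_BLOCK_BP,
) -> DResult:
    """Convenience: pattern sums + D in one call."""
    return d_statistic(site_pattern_sums(cohort, popmap, quartet, block_bp))
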
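"""Runs-of-homozygosity detection, length binning and inbreeding timing.

A two-state hidden Markov model walks along one individual's biallelic
calls: state AZ (autozygous) emits heterozygotes only at an error rate,
state HW (Hardy-Weinberg) emits them at 2f(1-f) with a fixed allele
frequency f. Maximal runs of sites whose AZ posterior exceeds 0.5,
extended to the midpoints between flanking sites, become candidate
segments, then length and quality filters are applied.

The expected length of an autozygous tract whose inbreeding loop closed
g generations ago is 100/(2 g r) Mb at recombination rate r cM/Mb, so a
segment of length L Mb dates the inbreeding to g = 100 / (2 r L)
generations before present.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import Cohort, CohortError, RecombinationMap

GENOME_MEAN_RATE_CM_MB = 1.34  # dog genome average recombination rate

#: ROH length bins in Mb: (label, low, high), half-open except the last.
LENGTH_BINS = (
    ("short", 0.1, 1.0),
    ("short_medium", 1.0, 5.0),
    ("medium_long", 5.0, 10.0),
    ("long", 10.0, 100.0),
)


@dataclass
class HmmParams:
    """Emission/transition parameters of the two-state autozygosity HMM."""

    default_alt_freq: float = 0.4
    het_emission_in_roh: float = 1e-4
    # Per-site state-switch probability. The default is set so that the
    # posterior error floor deep inside a clean tract (~ transition^2 / 2)
    # stays well below the phred-80 segment-quality filter.
    transition: float = 1e-5
    min_length: int = 100_000  # bp
    min_quality: float = 80.0  # phred-scaled mean AZ posterior

    def __post_init__(self) -> None:
        for p in (self.default_alt_freq, self.het_emission_in_roh, self.transition):
            if not (0.0 < p < 1.0):
                raise CohortError("HMM probabilities must lie in (0, 1)")


@dataclass
class RohSegment:
    chrom: str
    start: int  # bp, half-open
    end: int
    n_sites: int
    quality: float

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class RohProfile:
    """Per-individual ROH totals and counts in the four length bins."""

    sample_id: str
    bin_totals: dict[str, float]  # bp per bin
    bin_counts: dict[str, int]
    total_length: int  # bp, all segments (incl. any over 100 Mb)
    f_roh: float


def _forward_backward(het: np.ndarray, params: HmmParams, t: np.ndarray) -> np.ndarray:
    """AZ-state posterior per site. ``t`` is the per-step transition prob."""
    p_het_hw = 2.0 * params.default_alt_freq * (1.0 - params.default_alt_freq)
    p_het_az = params.het_emission_in_roh
    # emission[state, site]; state 0 = HW, 1 = AZ
    e = np.empty((2, len(het)))
    e[0] = np.where(het, p_het_hw, 1.0 - p_het_hw)
    e[1] = np.where(het, p_het_az, 1.0 - p_het_az)
    n = len(het)
    fwd = np.empty((2, n))
    bwd = np.empty((2, n))
    fwd[:, 0] = 0.5 * e[:, 0]
    fwd[:, 0] /= fwd[:, 0].sum()
    for i in range(1, n):
        stay = 1.0 - t[i - 1]
        f0 = (fwd[0, i - 1] * stay + fwd[1, i - 1] * t[i - 1]) * e[0, i]
        f1 = (fwd[1, i - 1] * stay + fwd[0, i - 1] * t[i - 1]) * e[1, i]
        s = f0 + f1
        fwd[0, i], fwd[1, i] = f0 / s, f1 / s
    bwd[:, n - 1] = 1.0
    for i in range(n - 2, -1, -1):
        stay = 1.0 - t[i]
        b0 = stay * e[0, i + 1] * bwd[0, i + 1] + t[i] * e[1, i + 1] * bwd[1, i + 1]
        b1 = stay * e[1, i + 1] * bwd[1, i + 1] + t[i] * e[0, i + 1] * bwd[0, i + 1]
        s = b0 + b1
        bwd[0, i], bwd[1, i] = b0 / s, b1 / s
    post = fwd * bwd
    return post[1] / post.sum(axis=0)


def population_informative_sites(cohort: Cohort, popmap, population: str) -> np.ndarray:
    """Mask of sites segregating within ``population`` (minor count >= 1).

    The HW emission model assumes sites where a non-inbred individual
    could plausibly be heterozygous; variants private to distant taxa in
    a multi-species cohort (where the focal population is fixed) carry no
    autozygosity information and would bias the HMM toward AZ everywhere.
    """
    idx = [cohort.sample_index(s) for s in popmap.samples_of(population)
           if s in cohort.sample_ids]
    alt_n, called_n = cohort.allele_counts(idx)
    return (alt_n > 0) & (alt_n < called_n)


def detect_roh(
    cohort: Cohort,
    individual: str,
    params: HmmParams | None = None,
    recomb_map: RecombinationMap | None = None,
) -> list[RohSegment]:
    """Detect autozygous segments for one individual.

    The cohort should be restricted to sites informative for the
    individual's population (see :func:`population_informative_sites`)
    when it contains deeply diverged outgroups. With a recombination map,
    the per-step transition probability is scaled by the local genetic
    distance between consecutive sites relative to the genome-wide mean;
    otherwise it is constant per site.
    """
    params = params or HmmParams()
    j = cohort.sample_index(individual)
    called_all = ~(cohort.gt[:, j, :] < 0).any(axis=1)
    if not called_all.any():
        raise CohortError(f"{individual!r} has no callable sites")
    segments: list[RohSegment] = []
    for ci, chrom in enumerate(cohort.chrom_ids):
        idx = np.flatnonzero((cohort.chrom_index == ci) & called_all)
        if len(idx) < 2:
            continue
        pos = cohort.positions[idx]
        het = cohort.gt[idx, j, 0] != cohort.gt[idx, j, 1]
        gaps = np.diff(pos).astype(float)
        if recomb_map is not None:
            mids = (pos[:-1] + pos[1:]) / 2.0
            rates = np.array(
                [
                    recomb_map.mean_rate_in(chrom, int(p0), max(int(p1), int(p0) + 1))
                    for p0, p1 in zip(pos[:-1], pos[1:])
                ]
            )
            mean_rate = recomb_map.genome_mean_rate
            scale = rates / mean_rate if mean_rate > 0 else np.ones_like(rates)
        else:
            scale = np.ones_like(gaps)
        t = np.clip(params.transition * scale, 1e-12, 0.45)
        post = _forward_backward(het, params, t)
        in_roh = post > 0.5
        if not in_roh.any():
            continue
        # maximal runs of AZ sites
        edges = np.diff(in_roh.astype(np.int8))
        starts = list(np.flatnonzero(edges == 1) + 1)
        ends = list(np.flatnonzero(edges == -1) + 1)
        if in_roh[0]:
            starts.insert(0, 0)
        if in_roh[-1]:
            ends.append(len(in_roh))
        for s, e in zip(starts, ends):
            bp_start = int(pos[s] if s == 0 else (pos[s - 1] + pos[s]) // 2)
            bp_end = int(pos[e - 1] + 1 if e == len(pos) else (pos[e - 1] + pos[e]) // 2)
            err = np.clip(1.0 - post[s:e], 1e-10, 1.0)
            quality = float(np.mean(-10.0 * np.log10(err)))
            seg = RohSegment(chrom, bp_start, bp_end, int(e - s), quality)
            if seg.length >= params.min_length and seg.quality >= params.min_quality:
                segments.append(seg)
    return segments


def bin_roh(segments: list[RohSegment], genome_length: int, sample_id: str = "") -> RohProfile:
    """Assign segment lengths to the four ROH bins and compute F_ROH.

    Segments over 100 Mb are excluded from the bins (with a warning) but
    still count toward the total length and F_ROH.
    """
    import warnings

    totals = {label: 0.0 for label, _, _ in LENGTH_BINS}
    counts = {label: 0 for label, _, _ in LENGTH_BINS}
    total = 0
    for seg in segments:
        total += seg.length
        mb = seg.length / 1e6
        placed = False
        for label, lo, hi in LENGTH_BINS:
            if (lo <= mb < hi) or (label == "long" and mb == hi):
                totals[label] += seg.length
                counts[label] += 1
                placed = True
                break
        if not placed and mb > 100.0:
            warnings.warn(f"segment of {mb:.1f} Mb exceeds the 100 Mb bin", stacklevel=2)
    return RohProfile(
        sample_id=sample_id,
        bin_totals=totals,
        bin_counts=counts,
        total_length=total,
        f_roh=total / genome_length if genome_length > 0 else 0.0,
    )


def inbreeding_time(
    length_mb: float,
    rate_cm_per_mb: float = GENOME_MEAN_RATE_CM_MB,
    generation_time: float | None = None,
) -> tuple[float, float | None]:
    """Generations (and optionally years) since the inbreeding loop closed.

    g = 100 / (2 r L): a 5-Mb segment at the genome-wide mean rate of
    1.34 cM/Mb dates to ~7.46, i.e. about 7 generations ago. Assumes a
    constant recombination rate; results are estimates only.
    """
    if length_mb <= 0 or rate_cm_per_mb <= 0:
        raise CohortError("length and rate must be positive")
    g = 100.0 / (2.0 * rate_cm_per_mb * length_mb)
    return g, (g * generation_time if generation_time is not None else None)


def segments_table(segments: list[RohSegment]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "chrom": s.chrom,
                "start": s.start,
                "end": s.end,
                "length": s.length,
                "n_sites": s.n_sites,
                "quality": s.quality,
            }
            for s in segments
        ],
        columns=["chrom", "start", "end", "length", "n_sites", "quality"],
    )
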
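"""Folded joint SFS, simulated expected spectra, and AIC model comparison.

The observed statistic is a folded (minor-allele) joint site-frequency
spectrum over three populations, built per 2-Mb genome block from a
complete-data subsample of individuals (the block structure keeps linked
sites together so that an unlinked one-SNP-per-block spectrum can be
drawn for likelihood recalculation). Expected spectra under a candidate
demographic model are tabulated from coalescent simulations of unlinked
loci. Fitting maximizes the composite log-likelihood

    lnL = sum_cells m_cell * log p_cell

over the model's free parameters (coarse log-grid search plus
Nelder-Mead refinement with common random numbers), and models are
compared by AIC computed from the likelihood recomputed on the unlinked
spectrum: AIC = 2k - 2 lnL_unlinked, with Akaike weights
exp(-dAIC/2) / sum_j exp(-dAIC_j/2).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Callable

import msprime
import numpy as np
from scipy.optimize import minimize

from .cohort import Cohort, CohortError, PopulationMap
from .sim import MUTATION_RATE, years

DEFAULT_BLOCK_BP = 2_000_000


class InvalidParameters(CohortError):
    """Raised when a parameter combination is demographically impossible."""


# ---------------------------------------------------------------------------
# folded joint SFS
# ---------------------------------------------------------------------------


def fold_cell(cell: tuple[int, ...], sizes: tuple[int, ...]) -> tuple[int, ...]:
    """Canonical (minor-allele) key of a joint frequency cell.

    A cell and its full complement are merged; the side with the smaller
    total derived count keys the merged cell, with exact half-ties going
    to the lexicographically smaller index.
    """
    comp = tuple(n - c for c, n in zip(cell, sizes))
    s, cs = sum(cell), sum(comp)
    if s < cs:
        return cell
    if cs < s:
        return comp
    return min(cell, comp)


def fold_array(raw: np.ndarray) -> tuple[np.ndarray, float]:
    """Fold an unfolded joint spectrum; returns (folded, monomorphic mass).

    The monomorphic mass pools the all-ancestral and all-derived corner
    cells; the zero cell of the folded array is left empty.
    """
    sizes = tuple(d - 1 for d in raw.shape)
    folded = np.zeros_like(raw, dtype=float)
    mono = 0.0
    for cell in itertools.product(*(range(d) for d in raw.shape)):
        v = float(raw[cell])
        if v == 0.0:
            continue
        canon = fold_cell(cell, sizes)
        if sum(canon) == 0:
            mono += v
        else:
            folded[canon] += v
    return folded, mono


def canonical_polymorphic_mask(sizes: tuple[int, ...]) -> np.ndarray:
    """Boolean array flagging the canonical polymorphic folded cells."""
    shape = tuple(n + 1 for n in sizes)
    mask = np.zeros(shape, dtype=bool)
    for cell in itertools.product(*(range(d) for d in shape)):
        if sum(cell) > 0 and fold_cell(cell, sizes) == cell:
            mask[cell] = True
    return mask


@dataclass
class FoldedSFS:
    """Folded joint minor-allele spectrum (any dimensionality >= 1)."""

    sizes: tuple[int, ...]  # haploid sample sizes
    counts: np.ndarray  # mass on canonical cells only
    monomorphic: float = 0.0
    provenance: str = "all_snps"

    def __post_init__(self) -> None:
        self.sizes = tuple(int(n) for n in self.sizes)
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape != tuple(n + 1 for n in self.sizes):
            raise CohortError("SFS array shape inconsistent with sample sizes")

    @property
    def n_polymorphic(self) -> float:
        return float(self.counts.sum())

    def to_text(self, path: str) -> None:
        """dadi/fastsimcoal-style flat table: header then row-major cells."""
        with open(path, "w") as fh:
            fh.write("#" + " ".join(str(n) for n in self.sizes) + "\n")
            fh.write(f"#monomorphic {self.monomorphic:g}\n")
            fh.write(f"#provenance {self.provenance}\n")
            for idx, v in enumerate(self.counts.ravel(order="C")):
                fh.write(f"{idx}\t{v:g}\n")

    @classmethod
    def from_text(cls, path: str) -> "FoldedSFS":
        sizes: tuple[int, ...] = ()
        mono = 0.0
        prov = "all_snps"
        values: list[float] = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line:
                    continue
                if line.startswith("#monomorphic"):
                    mono = float(line.split()[1])
                elif line.startswith("#provenance"):
                    prov = line.split()[1]
                elif line.startswith("#"):
                    sizes = tuple(int(x) for x in line[1:].split())
                else:
                    values.append(float(line.split("\t")[1]))
        shape = tuple(n + 1 for n in sizes)
        return cls(sizes, np.array(values).reshape(shape), mono, prov)


def build_folded_sfs(
    cohort: Cohort,
    popmap: PopulationMap,
    pops: list[str],
    subsample_sizes: list[int],
    block_bp: int = DEFAULT_BLOCK_BP,
    seed: int = 0,
) -> tuple[FoldedSFS, FoldedSFS]:
    """Observed folded joint SFS with per-block complete-data downsampling.

    Per genome block of ``block_bp``, each population contributes the
    ``subsample_sizes[i]`` individuals with the least missingness inside
    the block (ties broken by cohort sample order); only SNPs with
    complete data in that selection are retained. Returns the all-SNP
    spectrum and an unlinked spectrum built from one retained SNP per
    block (uniform, seeded).
    """
    if block_bp <= 0:
        raise CohortError("block_bp must be positive")
    if len(pops) != len(subsample_sizes):
        raise CohortError("pops and subsample_sizes must align")
    pop_samples = []
    for p, k in zip(pops, subsample_sizes):
        members = [s for s in popmap.samples_of(p) if s in cohort.sample_ids]
        if len(members) < k:
            raise CohortError(f"population {p!r} has {len(members)} < {k} samples")
        pop_samples.append(members)
    sizes = tuple(2 * k for k in subsample_sizes)
    shape = tuple(n + 1 for n in sizes)
    counts = np.zeros(shape)
    unlinked = np.zeros(shape)
    mono = 0.0
    rng = np.random.default_rng(seed)
    missing = cohort.missing_mask()

    for ci in range(len(cohort.chrom_ids)):
        on_c = np.flatnonzero(cohort.chrom_index == ci)
        if len(on_c) == 0:
            continue
        blocks = cohort.positions[on_c] // block_bp
        for b in np.unique(blocks):
            rows = on_c[blocks == b]
            chosen: list[list[int]] = []
            for members, k in zip(pop_samples, subsample_sizes):
                idx = np.array([cohort.sample_index(s) for s in members])
                miss_counts = missing[rows][:, idx].sum(axis=0)
                order = np.argsort(miss_counts, kind="stable")
                chosen.append(list(idx[order[:k]]))
            flat = [j for grp in chosen for j in grp]
            complete = ~missing[rows][:, flat].any(axis=1)
            kept = rows[complete]
            block_cells = []
            for r in kept:
                cell = tuple(
                    int((cohort.gt[r, grp, :] == 1).sum()) for grp in chosen
                )
                canon = fold_cell(cell, sizes)
                if sum(canon) == 0:
                    mono += 1.0
                    block_cells.append(None)
                else:
                    counts[canon] += 1.0
                    block_cells.append(canon)
            poly = [c for c in block_cells if c is not None]
            if poly:
                unlinked[poly[rng.integers(0, len(poly))]] += 1.0
    return (
        FoldedSFS(sizes, counts, mono, "all_snps"),
        FoldedSFS(sizes, unlinked, 0.0, "unlinked_one_per_block"),
    )


# ---------------------------------------------------------------------------
# demographic models for the SFS fit
# ---------------------------------------------------------------------------


@dataclass
class ModelSpec:
    """A candidate demography: fixed and free parameters plus a builder."""

    model_id: str
    pops: tuple[str, ...]
    sample_sizes: dict[str, int]  # diploid individuals per population
    fixed: dict[str, float]
    free: dict[str, tuple[float, float]]  # name -> (low, high) search range
    builder: Callable[[dict[str, float]], msprime.Demography]

    @property
    def k(self) -> int:
        return len(self.free)

    def demography(self, free_values: dict[str, float]) -> msprime.Demography:
        params = {**self.fixed, **free_values}
        for name, (lo, hi) in self.free.items():
            v = params[name]
            # tolerate float noise from log-space optimization round trips
            if not (lo * (1 - 1e-9) - 1e-12 <= v <= hi * (1 + 1e-9) + 1e-12):
                raise InvalidParameters(f"{name}={v} outside [{lo}, {hi}]")
            params[name] = min(max(v, lo), hi)
        return self.builder(params)


def _wolf_trio_builder(model_id: str) -> Callable[[dict[str, float]], msprime.Demography]:
    def build(p: dict[str, float]) -> msprime.Demography:
        dem = msprime.Demography()
        dem.add_population(name="Indian", initial_size=p["N_IND"])
        dem.add_population(name="SWAsia", initial_size=p["N_SW"])
        dem.add_population(name="Central", initial_size=p["N_CEN"])
        t_split = p["T_SPLIT_SW"]
        if model_id == "B":
            if not (0 < p["T_INTRO"] < t_split):
                raise InvalidParameters("introgression must postdate the SWAsia split")
            dem.add_mass_migration(
                time=p["T_INTRO"], source="SWAsia", dest="Indian", proportion=p["ALPHA"]
            )
            dem.add_population_split(time=t_split, derived=["SWAsia"], ancestral="Central")
        elif model_id == "C":
            dem.add_admixture(
                time=t_split,
                derived="SWAsia",
                ancestral=["Central", "Indian"],
                proportions=[1.0 - p["H"], p["H"]],
            )
        else:
            dem.add_population_split(time=t_split, derived=["SWAsia"], ancestral="Central")
        if p["T_IND"] <= t_split:
            raise InvalidParameters("Indian split must predate the SWAsia split")
        dem.add_population_split(time=p["T_IND"], derived=["Indian"], ancestral="Central")
        dem.add_population_parameters_change(
            time=p["T_IND"], population="Central", initial_size=p["N_ANC"]
        )
        dem.sort_events()
        return dem

    return build


def wolf_model_spec(
    model_id: str,
    sample_sizes: dict[str, int] | None = None,
    **fixed_overrides: float,
) -> ModelSpec:
    """Candidate origins of the southwestern Asian population.

    A: strict bifurcation (SWAsia splits from Central after the Indian
    lineage diverged). B: the same topology plus an Indian -> SWAsia
    introgression pulse (adds ALPHA and T_INTRO). C: SWAsia founded as a
    hybrid of Indian and Central parental populations (contribution H).
    Sizes and the deep Indian split are fixed at the study conditions;
    times are in generations.
    """
    if model_id not in ("A", "B", "C"):
        raise CohortError("model_id must be one of A, B, C")
    fixed = {
        "N_IND": 5000.0,
        "N_SW": 5000.0,
        "N_CEN": 15000.0,
        "N_ANC": 15000.0,
        "T_IND": years(100_000),
    }
    fixed.update(fixed_overrides)
    free: dict[str, tuple[float, float]] = {"T_SPLIT_SW": (years(2_000), years(60_000))}
    if model_id == "B":
        free["ALPHA"] = (0.01, 0.6)
        free["T_INTRO"] = (years(500), years(40_000))
    elif model_id == "C":
        free["H"] = (0.01, 0.9)
    return ModelSpec(
        model_id=model_id,
        pops=("Indian", "SWAsia", "Central"),
        sample_sizes=sample_sizes or {"Indian": 3, "SWAsia": 6, "Central": 9},
        fixed=fixed,
        free=free,
        builder=_wolf_trio_builder(model_id),
    )


def single_population_spec(ne: float, n_diploid: int, name: str = "Pop") -> ModelSpec:
    """A panmictic constant-size population (neutral-SFS reference case)."""

    def build(p: dict[str, float]) -> msprime.Demography:
        dem = msprime.Demography()
        dem.add_population(name=name, initial_size=p["N"])
        return dem

    return ModelSpec(
        model_id="panmictic",
        pops=(name,),
        sample_sizes={name: n_diploid},
        fixed={"N": ne},
        free={},
        builder=build,
    )


# ---------------------------------------------------------------------------
# expected spectra and composite likelihood
# ---------------------------------------------------------------------------


def simulate_folded_counts(
    model_spec: ModelSpec,
    free_values: dict[str, float],
    n_loci: int,
    seed: int,
    mode: str = "site",
    locus_bp: int = 5_000,
    mutation_rate: float = MUTATION_RATE,
) -> tuple[np.ndarray, float]:
    """Folded joint spectrum of ``n_loci`` simulated unlinked loci.

    ``mode='site'`` drops mutations on each locus and tabulates polymorphic
    sites (a genuine multinomial draw); ``mode='branch'`` tabulates the
    branch-length spectrum of the same genealogies (the same expectation
    with far less Monte-Carlo noise). Returns (folded counts array,
    monomorphic mass); reproducible given the seed.
    """
    if n_loci < 1:
        raise CohortError("n_loci must be positive")
    if mode not in ("site", "branch"):
        raise CohortError("mode must be 'site' or 'branch'")
    demography = model_spec.demography(free_values)
    samples = {p: model_spec.sample_sizes[p] for p in model_spec.pops}
    sizes = tuple(2 * samples[p] for p in model_spec.pops)
    raw = np.zeros(tuple(n + 1 for n in sizes))
    seeds = np.random.default_rng(seed).integers(1, 2**31 - 1, size=n_loci + 1)
    reps = msprime.sim_ancestry(
        samples,
        demography=demography,
        sequence_length=locus_bp,
        num_replicates=n_loci,
        random_seed=int(seeds[-1]),
    )
    sample_sets = None
    for i, ts in enumerate(reps):
        if sample_sets is None:
            name_to_id = {pop.metadata.get("name"): pop.id for pop in ts.populations()}
            sample_sets = [ts.samples(population=name_to_id[p]) for p in model_spec.pops]
        if mode == "site":
            ts = msprime.sim_mutations(ts, rate=mutation_rate, random_seed=int(seeds[i]))
        raw += ts.allele_frequency_spectrum(
            sample_sets=sample_sets, mode=mode, polarised=True, span_normalise=False
        )
    return fold_array(raw)


def expected_sfs(
    model_spec: ModelSpec,
    free_values: dict[str, float],
    n_loci: int,
    seed: int,
    mode: str = "site",
    locus_bp: int = 5_000,
    mutation_rate: float = MUTATION_RATE,
) -> np.ndarray:
    """Folded cell probabilities from coalescent simulation of unlinked loci.

    Empty polymorphic cells receive a pseudocount of 1/(10 n_loci) before
    normalization; the result sums to 1 over canonical polymorphic cells
    and is reproducible given the seed. See :func:`simulate_folded_counts`
    for the underlying tabulation and the site/branch mode distinction.
    """
    folded, _ = simulate_folded_counts(
        model_spec, free_values, n_loci, seed, mode, locus_bp, mutation_rate
    )
    sizes = tuple(2 * model_spec.sample_sizes[p] for p in model_spec.pops)
    poly = canonical_polymorphic_mask(sizes)
    probs = np.zeros_like(folded)
    eps = 1.0 / (10.0 * n_loci)
    vals = folded[poly]
    vals = np.where(vals == 0.0, eps, vals)
    probs[poly] = vals / vals.sum()
    return probs


def composite_loglik(observed: FoldedSFS, expected: np.ndarray) -> float:
    """lnL = sum over polymorphic folded cells of m_cell * log p_cell."""
    if expected.shape != observed.counts.shape:
        raise CohortError("observed and expected cell structures differ")
    m = observed.counts
    occupied = m > 0
    if np.any(occupied & (expected <= 0.0)):
        raise CohortError("expected probability 0 at an occupied cell")
    return float(np.sum(m[occupied] * np.log(expected[occupied])))


# ---------------------------------------------------------------------------
# fitting and model comparison
# ---------------------------------------------------------------------------


@dataclass
class SearchConfig:
    """Budget of the composite-likelihood search."""

    grid_points: int = 4  # per free parameter, log-spaced
    nm_maxfev: int = 40  # Nelder-Mead function-evaluation budget
    n_loci: int = 600
    locus_bp: int = 5_000
    mode: str = "branch"

    def __post_init__(self) -> None:
        if self.grid_points < 1 or self.nm_maxfev < 0:
            raise CohortError("search budget must be positive")


@dataclass
class FitResult:
    model_id: str
    params: dict[str, float]  # best free-parameter values
    lnl_all: float
    lnl_unlinked: float
    k: int
    aic: float
    n_evaluations: int
    data_signature: float
    delta_aic: float | None = None
    akaike_weight: float | None = None


def _signature(observed: FoldedSFS) -> float:
    return float(observed.counts.sum() + 0.5 * observed.monomorphic)


def fit_model(
    observed: FoldedSFS,
    model_spec: ModelSpec,
    search: SearchConfig | None = None,
    seed: int = 0,
    unlinked: FoldedSFS | None = None,
) -> FitResult:
    """Maximize the composite lnL over the model's free parameters.

    A coarse log-spaced grid seeds a Nelder-Mead refinement in log
    parameter space; every evaluation reuses the same simulation seed
    (common random numbers), making the objective deterministic and the
    whole fit reproducible. The likelihood used for AIC is recomputed on
    the unlinked spectrum at the optimum.
    """
    search = search or SearchConfig()
    names = list(model_spec.free)
    n_evals = 0

    def objective(free_values: dict[str, float]) -> float:
        nonlocal n_evals
        n_evals += 1
        try:
            p = expected_sfs(
                model_spec,
                free_values,
                n_loci=search.n_loci,
                seed=seed,
                mode=search.mode,
                locus_bp=search.locus_bp,
            )
            return -composite_loglik(observed, p)
        except InvalidParameters:
            return 1e12

    if names:
        axes = [
            np.exp(np.linspace(np.log(lo), np.log(hi), search.grid_points))
            for lo, hi in (model_spec.free[n] for n in names)
        ]
        best_x, best_v = None, np.inf
        for combo in itertools.product(*axes):
            v = objective(dict(zip(names, combo)))
            if v < best_v:
                best_x, best_v = np.log(np.array(combo)), v
        if search.nm_maxfev > 0:
            res = minimize(
                lambda x: objective(dict(zip(names, np.exp(x)))),
                best_x,
                method="Nelder-Mead",
                options={"maxfev": search.nm_maxfev, "xatol": 1e-3, "fatol": 1e-3},
            )
            if res.fun < best_v:
                best_x, best_v = res.x, res.fun
        best = dict(zip(names, np.exp(best_x)))
        lnl_all = -best_v
    else:
        best = {}
        lnl_all = -objective(best)

    p_best = expected_sfs(
        model_spec, best, n_loci=search.n_loci, seed=seed,
        mode=search.mode, locus_bp=search.locus_bp,
    )
    lnl_unlinked = composite_loglik(unlinked if unlinked is not None else observed, p_best)
    k = model_spec.k
    return FitResult(
        model_id=model_spec.model_id,
        params=best,
        lnl_all=lnl_all,
        lnl_unlinked=lnl_unlinked,
        k=k,
        aic=2.0 * k - 2.0 * lnl_unlinked,
        n_evaluations=n_evals,
        data_signature=_signature(observed),
    )


def compare_models(fits: list[FitResult]) -> list[FitResult]:
    """Fill delta-AIC and Akaike weights; returns fits sorted by AIC.

    dAIC_i = AIC_i - min AIC; w_i = exp(-dAIC_i/2) / sum_j exp(-dAIC_j/2)
    (the best model's w is its relative likelihood). All fits must come
    from the same observed data.
    """
    if len(fits) < 2:
        raise CohortError("need at least two fits to compare")
    sigs = {f.data_signature for f in fits}
    if len(sigs) != 1:
        raise CohortError("fits were made on different observed data")
    aics = np.array([f.aic for f in fits])
    delta = aics - aics.min()
    w = np.exp(-delta / 2.0)
    w = w / w.sum()
    for f, d, wi in zip(fits, delta, w):
        f.delta_aic = float(d)
        f.akaike_weight = float(wi)
    return sorted(fits, key=lambda f: f.aic)
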
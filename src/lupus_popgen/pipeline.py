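"""Configuration-driven orchestration of the full analysis pipeline.

``run_pipeline`` simulates (or loads) a cohort, applies per-stage site
filters, runs the enabled analysis stages in dependency order, and
writes one TSV per stage plus a JSON manifest. Outputs are plain text
with ``#key=value`` comment headers and are byte-identical across reruns
with the same configuration and seed; wall-clock timings go to the run
log only, which is the one non-deterministic output.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
import traceback
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from . import __version__
from .cohort import (
    FilterSpec,
    filter_sites,
    read_recomb_map,
    read_vcf_cohort,
    write_popmap,
    write_recomb_map,
    write_vcf_cohort,
)
from .diversity import diversity_table
from .dstat import QuartetSpec, d_test
from .load import compare_populations, load_table, polarize_sites
from .roh import HmmParams, bin_roh, detect_roh, segments_table
from .sfsfit import SearchConfig, build_folded_sfs, fit_model, wolf_model_spec
from .sim import (
    AnnotationTable,
    assign_impact_annotations,
    default_wolf_model,
    simulate_cohort,
)
from .topoweights import (
    enumerate_topologies,
    make_snp_windows,
    stratify_weights,
    weights_frame,
    window_weights,
)

logger = logging.getLogger(__name__)

ALL_STAGES = ("dstat", "topoweights", "roh", "diversity", "load", "sfsfit")


@dataclass
class SimulationBlock:
    samples_per_pop: dict[str, int] = field(
        default_factory=lambda: {
            "Indian": 3,
            "Tibetan": 2,
            "Central": 3,
            "SWAsia": 3,
            "Outgroup1": 1,
            "Outgroup2": 1,
        }
    )
    chromosome_count: int = 10
    sequence_length: float = 5e6
    missing_fraction: float = 0.0


@dataclass
class PipelineConfig:
    out_dir: str
    seed: int = 1
    simulation: SimulationBlock | None = None
    vcf: str | None = None
    popmap: str | None = None
    recomb_map: str | None = None
    annotations: str | None = None
    stages: tuple[str, ...] = ALL_STAGES
    filter: FilterSpec = field(default_factory=FilterSpec)
    dstat_quartet: tuple[str, str, str, str] = ("Central", "SWAsia", "Indian", "Outgroup1")
    dstat_block_bp: int = 5_000_000
    topo_groups: tuple[str, ...] = ("Indian", "SWAsia", "Central", "Outgroup1")
    topo_samples_per_group: int = 1
    topo_window_snps: int = 100
    roh_params: HmmParams = field(default_factory=HmmParams)
    load_outgroups: tuple[str, str] = ("Outgroup1", "Outgroup2")
    sfs_pops: tuple[str, ...] = ("Indian", "SWAsia", "Central")
    sfs_subsample: tuple[int, ...] = (2, 2, 2)
    sfs_block_bp: int = 1_000_000
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.simulation is None and self.vcf is None:
            raise ValueError("config needs either a simulation block or input paths")
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        data = dict(data)
        if "simulation" in data and data["simulation"] is not None:
            data["simulation"] = SimulationBlock(**data["simulation"])
        if "filter" in data:
            data["filter"] = FilterSpec(**data["filter"])
        if "roh_params" in data:
            data["roh_params"] = HmmParams(**data["roh_params"])
        for key in ("stages", "dstat_quartet", "topo_groups", "load_outgroups",
                    "sfs_pops", "sfs_subsample"):
            if key in data and data[key] is not None:
                data[key] = tuple(data[key])
        return cls(**data)

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_dict(self) -> dict:
        d = asdict(self)
        return d


def _write_tsv(frame, path: Path, header: dict) -> None:
    with open(path, "w") as fh:
        for k, v in header.items():
            fh.write(f"#{k}={v}\n")
        frame.to_csv(fh, sep="\t", index=False, float_format="%.10g")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the enabled stages; returns the manifest dictionary.

    A failing stage is recorded in the manifest (status/error) without
    aborting the remaining stages.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_path = out / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
    root = logging.getLogger("lupus_popgen")
    root.addHandler(handler)
    root.setLevel(getattr(logging, config.log_level.upper(), logging.INFO))

    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "config": config.to_dict(),
        "stages": {},
        "outputs": {},
    }
    header = {"seed": config.seed, "version": __version__}
    try:
        # ------------------------------------------------------ inputs
        annotations: AnnotationTable | None = None
        if config.simulation is not None:
            model = default_wolf_model(
                chromosome_count=config.simulation.chromosome_count,
                sequence_length=config.simulation.sequence_length,
            )
            sim = simulate_cohort(
                model,
                config.simulation.samples_per_pop,
                seed=config.seed,
                missing_fraction=config.simulation.missing_fraction,
            )
            cohort, popmap, rmap = sim.cohort, sim.popmap, sim.recomb_map
            annotations = assign_impact_annotations(cohort, seed=config.seed)
            write_vcf_cohort(cohort, str(out / "cohort.vcf"), popmap)
            write_popmap(popmap, str(out / "popmap.tsv"))
            write_recomb_map(rmap, str(out / "recomb_map.bed"))
            annotations.to_tsv(str(out / "annotations.tsv"))
            sim.truth.to_json(str(out / "truth.json"))
        else:
            cohort, popmap, _ = read_vcf_cohort(config.vcf, config.popmap)
            rmap = read_recomb_map(config.recomb_map) if config.recomb_map else None
            if config.annotations:
                annotations = AnnotationTable.from_tsv(config.annotations)

        cohort, removed = filter_sites(cohort, config.filter)
        manifest["filter_removed"] = removed
        manifest["n_sites"] = cohort.n_sites
        manifest["n_samples"] = cohort.n_samples

        # ------------------------------------------------------ stages
        def run_stage(name, fn):
            t0 = time.perf_counter()
            try:
                fn()
                manifest["stages"][name] = {"status": "ok"}
            except Exception as exc:  # noqa: BLE001 - stage isolation
                logger.error("stage %s failed: %s", name, traceback.format_exc())
                manifest["stages"][name] = {"status": "failed", "error": str(exc)}
            logger.info("stage %s finished in %.2f s", name, time.perf_counter() - t0)

        if "dstat" in config.stages:
            def _dstat():
                q = QuartetSpec(*config.dstat_quartet)
                res = d_test(cohort, popmap, q, config.dstat_block_bp)
                import pandas as pd

                frame = pd.DataFrame(
                    [
                        {
                            "quartet": ",".join(config.dstat_quartet),
                            "D": res.d,
                            "SE": res.se,
                            "Z": res.z,
                            "nABBA": res.abba,
                            "nBABA": res.baba,
                            "n_blocks": res.n_blocks,
                            "n_sites": res.n_sites,
                        }
                    ]
                )
                _write_tsv(frame, out / "dstat.tsv", header)

            run_stage("dstat", _dstat)

        if "topoweights" in config.stages:
            def _topo():
                catalog = enumerate_topologies(config.topo_groups)
                windows = make_snp_windows(cohort, rmap, config.topo_window_snps)
                samples = []
                for g in config.topo_groups:
                    samples.extend(
                        [s for s in popmap.samples_of(g) if s in cohort.sample_ids][
                            : config.topo_samples_per_group
                        ]
                    )
                w = window_weights(cohort, popmap, windows, catalog, samples)
                _write_tsv(weights_frame(w, windows, catalog), out / "topoweights.tsv", header)
                import pandas as pd

                strata = stratify_weights(w, windows)
                rows = []
                for name, s in strata.items():
                    row = {"stratum": name, "n_windows": s.n_windows}
                    for e in catalog.entries:
                        row[f"topo{e.index}"] = (
                            s.mean_weights[e.index] if s.mean_weights is not None else float("nan")
                        )
                    rows.append(row)
                _write_tsv(pd.DataFrame(rows), out / "topoweights_strata.tsv", header)

            run_stage("topoweights", _topo)

        if "roh" in config.stages:
            def _roh():
                import pandas as pd

                genome_length = int(
                    sum(
                        cohort.positions[cohort.chrom_index == ci].max() + 1
                        for ci in range(len(cohort.chrom_ids))
                        if (cohort.chrom_index == ci).any()
                    )
                )
                seg_frames, prof_rows = [], []
                from .roh import population_informative_sites

                for s in cohort.sample_ids:
                    if popmap.population_of(s) in popmap.outgroups:
                        continue
                    informative = population_informative_sites(cohort, popmap, popmap.population_of(s))
                    segs = detect_roh(cohort.take_sites(informative), s, config.roh_params, rmap)
                    f = segments_table(segs)
                    f.insert(0, "sample", s)
                    seg_frames.append(f)
                    prof = bin_roh(segs, genome_length, s)
                    prof_rows.append(
                        {
                            "sample": s,
                            **{f"total_{k}": v for k, v in prof.bin_totals.items()},
                            **{f"count_{k}": v for k, v in prof.bin_counts.items()},
                            "total_length": prof.total_length,
                            "f_roh": prof.f_roh,
                        }
                    )
                nonempty = [f for f in seg_frames if not f.empty]
                seg_out = (
                    pd.concat(nonempty, ignore_index=True)
                    if nonempty
                    else seg_frames[0]
                )
                _write_tsv(seg_out, out / "roh_segments.tsv", header)
                _write_tsv(pd.DataFrame(prof_rows), out / "roh_profiles.tsv", header)

            run_stage("roh", _roh)

        if "diversity" in config.stages:
            run_stage(
                "diversity",
                lambda: _write_tsv(diversity_table(cohort, popmap), out / "diversity.tsv", header),
            )

        if "load" in config.stages:
            def _load():
                og1, og2 = config.load_outgroups
                pol = polarize_sites(cohort, og1, og2, annotations, config.seed, popmap)
                table = load_table(pol, popmap)
                _write_tsv(table, out / "load.tsv", header)
                _write_tsv(compare_populations(table), out / "load_by_population.tsv", header)

            run_stage("load", _load)

        if "sfsfit" in config.stages:
            def _sfs():
                import pandas as pd

                spec = wolf_model_spec(
                    "A",
                    sample_sizes={
                        p: k for p, k in zip(config.sfs_pops, config.sfs_subsample)
                    },
                )
                obs, unlinked = build_folded_sfs(
                    cohort,
                    popmap,
                    list(config.sfs_pops),
                    list(config.sfs_subsample),
                    config.sfs_block_bp,
                    seed=config.seed,
                )
                obs.to_text(str(out / "sfs_observed.txt"))
                unlinked.to_text(str(out / "sfs_unlinked.txt"))
                fit = fit_model(
                    obs,
                    spec,
                    SearchConfig(grid_points=3, nm_maxfev=0, n_loci=300),
                    seed=config.seed,
                    unlinked=unlinked,
                )
                frame = pd.DataFrame(
                    [
                        {
                            "model": fit.model_id,
                            **{f"param_{k}": v for k, v in fit.params.items()},
                            "lnl_all": fit.lnl_all,
                            "lnl_unlinked": fit.lnl_unlinked,
                            "k": fit.k,
                            "aic": fit.aic,
                        }
                    ]
                )
                _write_tsv(frame, out / "sfsfit.tsv", header)

            run_stage("sfsfit", _sfs)

        for f in sorted(out.iterdir()):
            if f.name not in ("manifest.json", "run.log") and f.is_file():
                manifest["outputs"][f.name] = _sha256(f)
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1, sort_keys=True)
        return manifest
    finally:
        root.removeHandler(handler)
        handler.close()
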
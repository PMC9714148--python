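"""End-to-end orchestration with a reproducibility manifest.

``run_pipeline`` executes the synthetic study end to end — simulate →
EME → co-expression screen → replicate-peak merging → metagene profile
→ Escore → interaction screen — writing every stage output as TSV under
an output directory and finishing with a JSON manifest of per-file
SHA-256 checksums.  All stage outputs are pure functions of the config
and the root seed, so re-running with the same config reproduces
identical checksums.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .coexpression import detect_modules, screen_modules_vs_eme, variance_filter
from .cooccurrence import (global_methylation, merge_replicate_peaks,
                           metagene_profile, peak_methylation,
                           stage_correlation)
from .eigengene import compute_eme
from .errors import ConfigError
from .interaction import escore_table, screen_interaction_regions
from .io import (MethylationTable, write_expression_matrix,
                 write_methylation_table, write_peak_counts, write_peaks,
                 write_sample_sheet)
from .simulate import (SimulationConfig, simulate_expression,
                       simulate_interaction_study,
                       simulate_methylome_and_peaks, wgbs_sample_sheet)

logger = logging.getLogger(__name__)

ALL_STAGES = ("simulate", "eme", "coexpress", "merge_peaks", "profile",
              "escore", "interact")


@dataclass
class RunConfig:
    """Flat configuration of a full synthetic run."""

    out_dir: Path
    seed: int = 0
    stages: tuple[str, ...] = ALL_STAGES
    simulation: SimulationConfig | None = None
    hub_threshold: float = 0.7
    hub_mode: str = "absolute"
    variance_quantile: float = 0.25
    power: float = 6.0
    cut_height: float = 0.995
    min_module_size: int = 30
    r_threshold: float = 0.8
    p_threshold: float = 0.05
    flank: int = 5000
    bins: tuple[int, int, int] = (20, 10, 20)
    min_cpgs_per_bin: int = 20
    aggregation: str = "mean_of_instances"
    alpha: float = 0.05
    correction: str = "none"

    def __post_init__(self) -> None:
        self.out_dir = Path(self.out_dir)
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ConfigError(f"unknown stages: {sorted(unknown)}")
        if self.simulation is None:
            self.simulation = SimulationConfig(seed=self.seed)

    @classmethod
    def from_yaml(cls, path, **overrides) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update(overrides)
        sim_raw = raw.pop("simulation", None)
        if "out_dir" not in raw:
            raise ConfigError("config is missing the field 'out_dir'")
        cfg = cls(**raw)
        if sim_raw:
            sim_raw.setdefault("seed", cfg.seed)
            for key in ("stages", "meth_stages", "module_sizes",
                        "peak_len_range", "enrichment_range", "beta",
                        "module_eme_link"):
                if key in sim_raw and sim_raw[key] is not None:
                    sim_raw[key] = tuple(sim_raw[key])
            cfg.simulation = SimulationConfig(**sim_raw)
        return cfg


@dataclass
class RunManifest:
    version: str
    config_hash: str
    checksums: dict[str, str] = field(default_factory=dict)
    timestamps: dict[str, float] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _config_hash(config: RunConfig) -> str:
    payload = dataclasses.asdict(config)
    payload["out_dir"] = None  # the output location must not change the hash
    return hashlib.sha256(
        json.dumps(payload, sort_keys=True, default=str).encode()).hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(map(str, df.columns)) + "\n")
        df.to_csv(fh, sep="\t", header=False, index=False)


def run_pipeline(config: RunConfig) -> RunManifest:
    """Run the selected stages in dependency order; returns the manifest.

    A stage failure aborts the run with the failing stage named; files
    already written are kept.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(version=__version__,
                           config_hash=_config_hash(config))
    sim = config.simulation
    written: list[Path] = []

    def emit(name: str, writer) -> Path:
        path = out / name
        writer(path)
        written.append(path)
        return path

    state: dict[str, object] = {}
    for stage in ALL_STAGES:
        if stage not in config.stages:
            continue
        t0 = time.time()
        try:
            _run_stage(stage, config, sim, state, emit)
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
        manifest.timestamps[stage] = time.time() - t0
        logger.info("stage %s done in %.2fs", stage, manifest.timestamps[stage])

    for path in written:
        manifest.checksums[path.name] = _sha256(path)
    (out / "run_manifest.json").write_text(manifest.to_json())
    return manifest


def _run_stage(stage: str, config: RunConfig, sim: SimulationConfig,
               state: dict, emit) -> None:
    if stage == "simulate":
        expr, expr_truth = simulate_expression(sim)
        meth, reps, meth_truth = simulate_methylome_and_peaks(sim)
        study = simulate_interaction_study(sim)
        state.update(expr=expr, expr_truth=expr_truth, meth=meth,
                     rep_peaks=reps, meth_truth=meth_truth, study=study)
        emit("expression.tsv", lambda p: write_expression_matrix(expr, p))
        emit("sample_sheet.tsv",
             lambda p: write_sample_sheet(
                 expr.samples + wgbs_sample_sheet(sim), p))
        emit("methylation.tsv", lambda p: write_methylation_table(meth, p))
        for rep, ps in reps.items():
            emit(f"peaks_rep{rep}.bed", lambda p, ps=ps: write_peaks(ps, p))
        emit("interaction_peaks.bed",
             lambda p: write_peaks(study.peaks, p))
        emit("interaction_expression.tsv",
             lambda p: write_expression_matrix(study.expression, p))
        emit("interaction_methylation.tsv",
             lambda p: write_methylation_table(study.methylation, p))
        emit("interaction_counts.tsv",
             lambda p: write_peak_counts(study.counts, p,
                                         str(p).replace(".tsv", "_totals.tsv")))
        truth_df = pd.DataFrame(
            [{"gene_id": g, "planted_interaction": g in study.truth.interaction_genes}
             for g in study.expression.gene_ids])
        emit("interaction_truth.tsv", lambda p: _write_tsv(truth_df, p))
    elif stage == "eme":
        expr = state["expr"]
        regulators = state["expr_truth"].regulator_ids
        res = compute_eme(expr, regulators, threshold=config.hub_threshold,
                          mode=config.hub_mode)
        state["eme"] = res
        emit("eme.tsv", lambda p: _write_tsv(pd.DataFrame(
            {"sample_id": res.eme.sample_ids, "eme": res.eme.values}), p))
        emit("membership.tsv", lambda p: _write_tsv(pd.DataFrame(
            sorted(res.membership.items()), columns=["gene_id", "kme"]), p))
        emit("hubs.tsv", lambda p: _write_tsv(
            pd.DataFrame({"gene_id": res.hubs}), p))
    elif stage == "coexpress":
        expr = state["expr"]
        res = state["eme"]
        filtered = variance_filter(expr, quantile=config.variance_quantile)
        assignment = detect_modules(filtered, power=config.power,
                                    cut_height=config.cut_height,
                                    min_module_size=config.min_module_size)
        screen = screen_modules_vs_eme(assignment, filtered, res.eme,
                                       r_threshold=config.r_threshold,
                                       p_threshold=config.p_threshold)
        state["module_screen"] = screen
        emit("module_assignment.tsv", lambda p: _write_tsv(pd.DataFrame(
            sorted(assignment.labels.items()), columns=["gene_id", "module"]), p))
        emit("module_screen.tsv", lambda p: _write_tsv(screen.table, p))
    elif stage == "merge_peaks":
        reps = state["rep_peaks"]
        merged = merge_replicate_peaks(reps[1], reps[2])
        state["merged_peaks"] = merged
        emit("merged_peaks.bed", lambda p: write_peaks(merged, p))
    elif stage == "profile":
        merged = state["merged_peaks"]
        meth: MethylationTable = state["meth"]
        profile = metagene_profile(merged, meth, flank=config.flank,
                                   bins=config.bins,
                                   min_cpgs_per_bin=config.min_cpgs_per_bin,
                                   aggregation=config.aggregation)
        emit("metagene_profile.tsv", lambda p: _write_tsv(profile.table, p))
        # stage-level summary: global 5mC vs per-stage peak count
        stages = sorted({s.stage_days for s in wgbs_sample_sheet(sim)})
        levels = []
        for st in stages:
            sub = meth.records[meth.records["sample_id"].str.contains(
                f"_s{st}_")]
            levels.append(global_methylation(MethylationTable(sub)))
        state["stage_meth_levels"] = (stages, levels)
        emit("stage_methylation.tsv", lambda p: _write_tsv(pd.DataFrame(
            {"stage_days": stages, "global_meth": levels}), p))
    elif stage == "escore":
        study = state["study"]
        esc = escore_table(study.counts, study.sample_sheet,
                           mode=study.escore_mode)
        state["escore"] = esc
        emit("escore.tsv", lambda p: _write_tsv(esc, p))
    elif stage == "interact":
        study = state["study"]
        esc = state["escore"]
        pm = peak_methylation(study.peaks, study.methylation,
                              min_cpgs_per_peak=1)
        screen = screen_interaction_regions(
            study.expression, study.peaks, esc, pm, study.sample_sheet,
            alpha=config.alpha, correction=config.correction)
        state["interaction_screen"] = screen
        emit("interaction_fits.tsv", lambda p: _write_tsv(screen.fits, p))
        emit("interaction_genes.tsv", lambda p: _write_tsv(screen.genes, p))
    else:  # pragma: no cover - guarded by RunConfig validation
        raise ConfigError(f"unknown stage {stage!r}")
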
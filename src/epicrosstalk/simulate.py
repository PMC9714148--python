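"""Synthetic multi-omics data with planted, recoverable structure.

The generators emulate the study design the analysis assumes:

* an expression matrix over 27 developmental stages x 3 replicates
  (81 RNA samples) containing a block of 41 co-expressed 5mC/m6A
  regulator genes plus planted co-expression modules, some of which
  track (or mirror) the regulator block's latent profile;
* per-CpG methylomes for 4 postnatal stages x 2 replicates with
  elevated methylation inside m6A peak intervals, and two replicate
  peak sets with boundary jitter;
* per-peak IP/input read counts with configurable true enrichment;
* a matched postnatal study in which a subset of genes has its
  expression written exactly from the interaction model
  log2(FPKM+1) = b0 + bS*S + bX*X + bY*Y + bXY*X*Y + noise, using the
  realized Escore X and peak methylation Y, so coefficient recovery is
  a closed loop.

Every generator is deterministic under a fixed seed (named substreams
derived from the root seed) and returns the planted truth next to the
data.  All distributional choices here are artifact conventions: the
source study reports no noise model for any quantity.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError
from .io import (ExpressionMatrix, MethylationTable, PeakCountTable, PeakSet,
                 SampleInfo)

# 27 developmental stages on one days-post-conception axis: embryonic days
# 33..105 as-is, postnatal day d mapped to 114 + d (pig gestation ~114 d).
PRENATAL_DAYS = (33, 40, 45, 50, 55, 60, 65, 70, 75, 80, 85, 90, 95, 100, 105)
POSTNATAL_DAYS = (0, 9, 20, 30, 40, 60, 80, 100, 120, 140, 160, 180)
GESTATION_DAYS = 114
DEFAULT_STAGES = tuple(PRENATAL_DAYS) + tuple(GESTATION_DAYS + d
                                              for d in POSTNATAL_DAYS)
POSTNATAL_WGBS_STAGES = (30, 60, 120, 180)


@dataclass
class SimulationConfig:
    """Parameters of every generator; defaults mirror the study design."""

    seed: int = 0
    # expression
    n_genes: int = 2000
    stages: tuple[int, ...] = DEFAULT_STAGES
    reps_per_stage: int = 3
    n_regulators: int = 41
    n_regulators_5mc: int = 21        # remainder are m6A regulators
    regulator_cor: float = 0.9        # target pairwise r within the block
    n_modules: int = 3
    module_sizes: tuple[int, ...] | None = None
    module_cor: float = 0.8           # target within-module correlation
    module_eme_link: tuple[str, ...] = ("pos", "neg", "none")
    module_trend_sd: float = 1.0      # amplitude of module latent trends
    noise_sd: float = 0.5             # sd of unstructured background genes
    baseline_log2: float = 5.0        # mean log2(FPKM+1) level
    # methylome + peaks
    n_peaks: int = 100
    peak_len_range: tuple[int, int] = (200, 2000)
    flank: int = 5000
    flank_meth_mean: float = 0.5
    peak_meth_delta: float = 0.3
    meth_concentration: float = 50.0  # Beta concentration of CpG levels
    cpg_density: float = 0.1          # expected CpGs per bp
    mean_coverage: float = 30.0
    meth_stages: tuple[int, ...] = POSTNATAL_WGBS_STAGES
    meth_reps: int = 2
    replicate_jitter: int = 30        # bp jitter between replicate peak sets
    # MeRIP counts
    mean_input_count: float = 100.0
    background_reads: int = 1_000_000  # off-peak mapped reads per library
    enrichment_range: tuple[float, float] = (2.0, 16.0)
    # interaction study
    n_interaction_genes: int = 5
    n_null_genes: int = 100
    beta: tuple[float, float, float, float, float] = (3.0, 0.01, 0.5, 1.0, 2.0)
    interaction_noise_sd: float = 0.2

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ConfigError("seed is mandatory")
        for name in ("regulator_cor", "module_cor", "flank_meth_mean",
                     "cpg_density"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ConfigError(f"{name} must be in [0, 1], got {v}")
        if not -1 <= self.peak_meth_delta <= 1:
            raise ConfigError("peak_meth_delta must be in [-1, 1]")
        if self.n_regulators_5mc > self.n_regulators:
            raise ConfigError("n_regulators_5mc exceeds n_regulators")
        if self.peak_len_range[0] < 10 or self.peak_len_range[0] > self.peak_len_range[1]:
            raise ConfigError("invalid peak_len_range")
        sizes = self.resolved_module_sizes()
        if self.n_regulators + sum(sizes) > self.n_genes:
            raise ConfigError("module_sizes plus regulators exceed n_genes")

    def resolved_module_sizes(self) -> tuple[int, ...]:
        if self.module_sizes is not None:
            return tuple(self.module_sizes)
        budget = max(self.n_genes - self.n_regulators, 0) // 2
        size = budget // max(self.n_modules, 1)
        return tuple(size for _ in range(self.n_modules))

    def rng(self, stream: str) -> np.random.Generator:
        """Named substream so stages are independently reproducible."""
        digest = sum((i + 1) * b for i, b in enumerate(stream.encode())) % (2**16)
        return np.random.default_rng([self.seed % (2**31), digest])


@dataclass
class SyntheticTruth:
    """Ground-truth labels planted by the generators."""

    regulator_ids: list[str] = field(default_factory=list)
    regulator_classes: dict[str, tuple[str, str]] = field(default_factory=dict)
    module_assignment: dict[str, int] = field(default_factory=dict)
    regulator_latent: np.ndarray | None = None       # per RNA sample
    module_latents: dict[int, np.ndarray] = field(default_factory=dict)
    consensus_peaks: PeakSet | None = None
    peak_enrichment: pd.DataFrame | None = None      # peak_id, stage_days, multiplier
    interaction_genes: list[str] = field(default_factory=list)
    true_beta: dict[str, tuple[float, ...]] = field(default_factory=dict)
    realized_x: pd.DataFrame | None = None
    realized_y: pd.DataFrame | None = None


def _standardized(v: np.ndarray) -> np.ndarray:
    return (v - v.mean()) / v.std()


def _smooth_trend(rng: np.random.Generator, stage_values: np.ndarray,
                  reps: int) -> np.ndarray:
    """A smooth random stage trend replicated across within-stage samples."""
    t = (stage_values - stage_values.min()) / max(np.ptp(stage_values), 1)
    a, b, phase = rng.normal(size=3)
    trend = a * t + b * np.cos(np.pi * t + phase)
    return np.repeat(trend, reps)


# ---------------------------------------------------------------------------
# Expression
# ---------------------------------------------------------------------------

def regulator_gene_ids(config: SimulationConfig) -> tuple[list[str], dict]:
    n5 = config.n_regulators_5mc
    n6 = config.n_regulators - n5
    ids, classes = [], {}
    for i in range(n5):
        g = f"reg5mc_{i + 1:02d}"
        ids.append(g)
        classes[g] = ("5mc", "regulator")
    for i in range(n6):
        g = f"regm6a_{i + 1:02d}"
        ids.append(g)
        classes[g] = ("m6a", "regulator")
    return ids, classes


def simulate_expression(config: SimulationConfig
                        ) -> tuple[ExpressionMatrix, SyntheticTruth]:
    """Expression with a correlated regulator block and planted modules.

    On the log2(FPKM+1) scale each regulator is
    sqrt(rho) * z + sqrt(1-rho) * eps around the baseline, where z is a
    standardized smooth latent stage profile, so the planted pairwise
    correlation is ``regulator_cor``.  Module genes follow the same
    construction around per-module latents; ``module_eme_link`` ties a
    module's latent to +z / -z / an independent profile.  Remaining
    genes are unstructured noise with heterogeneous variances.
    """
    rng = config.rng("expression")
    stages = np.asarray(config.stages)
    reps = config.reps_per_stage
    samples = [SampleInfo(f"rna_s{st}_r{r}", int(st), r, "rna")
               for st in stages for r in range(1, reps + 1)]
    n_samples = len(samples)
    if n_samples < 4:
        raise ConfigError("need at least 4 RNA samples")

    z = _standardized(_smooth_trend(rng, stages, reps)
                      + 0.5 * rng.normal(size=n_samples))

    reg_ids, reg_classes = regulator_gene_ids(config)
    sizes = config.resolved_module_sizes()
    n_structured = config.n_regulators + sum(sizes)
    n_noise = config.n_genes - n_structured

    gene_ids: list[str] = list(reg_ids)
    profiles = []
    rho = config.regulator_cor
    for _ in reg_ids:
        eps = _standardized(rng.normal(size=n_samples)) if rho < 1 else 0.0
        profiles.append(np.sqrt(rho) * z + np.sqrt(1 - rho) * eps)

    truth = SyntheticTruth(regulator_ids=reg_ids,
                           regulator_classes=reg_classes,
                           regulator_latent=z.copy())
    module_of: dict[str, int] = {g: 0 for g in reg_ids}
    links = tuple(config.module_eme_link) + ("none",) * max(
        0, len(sizes) - len(config.module_eme_link))
    rho_m = config.module_cor
    used_latents = [z]  # unlinked module latents are orthogonalized to these
    g_counter = 0
    for m, size in enumerate(sizes, start=1):
        link = links[m - 1]
        if link == "pos":
            u = z.copy()
        elif link == "neg":
            u = -z
        elif link == "none":
            raw = (config.module_trend_sd * _smooth_trend(rng, stages, reps)
                   + 0.5 * rng.normal(size=n_samples))
            raw = raw - raw.mean()
            for v in used_latents:  # keep planted between-module r at ~0
                vc = v - v.mean()
                raw = raw - (raw @ vc) / (vc @ vc) * vc
            u = _standardized(raw)
            used_latents.append(u)
        else:
            raise ConfigError(f"unknown module_eme_link entry {link!r}")
        truth.module_latents[m] = u.copy()
        for _ in range(size):
            g_counter += 1
            g = f"gene_{g_counter:05d}"
            gene_ids.append(g)
            module_of[g] = m
            eps = _standardized(rng.normal(size=n_samples)) if rho_m < 1 else 0.0
            profiles.append(np.sqrt(rho_m) * u + np.sqrt(1 - rho_m) * eps)
    for _ in range(n_noise):
        g_counter += 1
        g = f"gene_{g_counter:05d}"
        gene_ids.append(g)
        module_of[g] = 0
        sd = rng.uniform(0.05, config.noise_sd) if config.noise_sd > 0 else 0.0
        profiles.append(sd * rng.normal(size=n_samples))

    truth.module_assignment = module_of
    log2v = config.baseline_log2 + np.vstack(profiles)
    fpkm = np.maximum(np.exp2(np.maximum(log2v, 0.0)) - 1.0, 0.0)
    return ExpressionMatrix(gene_ids, samples, fpkm), truth


# ---------------------------------------------------------------------------
# Methylome + peaks
# ---------------------------------------------------------------------------

def _beta_levels(rng: np.random.Generator, mu: np.ndarray,
                 concentration: float) -> np.ndarray:
    mu = np.clip(mu, 0.01, 0.99)
    return rng.beta(mu * concentration, (1 - mu) * concentration)


def _layout_peaks(config: SimulationConfig, rng: np.random.Generator
                  ) -> tuple[pd.DataFrame, int]:
    """Consensus peaks spaced so that flanks never touch a neighbor."""
    gap = 2 * config.flank + 200
    lo, hi = config.peak_len_range
    lengths = rng.integers(lo, hi + 1, size=config.n_peaks)
    starts = np.empty(config.n_peaks, dtype=np.int64)
    cursor = config.flank + 100
    for i, ln in enumerate(lengths):
        starts[i] = cursor
        cursor += ln + gap
    chrom_len = int(cursor)
    df = pd.DataFrame({
        "chrom": "chrS1",
        "start": starts,
        "end": starts + lengths,
        "strand": "+",
        "gene_id": None,
        "peak_id": [f"peak_{i + 1:04d}" for i in range(config.n_peaks)],
    })
    return df, chrom_len


def simulate_methylome_and_peaks(config: SimulationConfig
                                 ) -> tuple[MethylationTable,
                                            dict[int, PeakSet],
                                            SyntheticTruth]:
    """Methylomes with planted in-peak elevation plus jittered replicate peaks.

    CpG positions come from a seeded uniform point process shared across
    samples (as in a real methylome).  Per-CpG levels are Beta-distributed
    around ``flank_meth_mean`` outside consensus peaks and around
    ``flank_meth_mean + peak_meth_delta`` inside, identically across the
    4 stages x 2 replicates.  The two replicate PeakSets jitter the
    consensus boundaries by up to ``replicate_jitter`` bp.
    """
    rng = config.rng("methylome")
    peaks_df, chrom_len = _layout_peaks(config, rng)
    if (peaks_df["end"] + config.flank > chrom_len).any():
        raise ConfigError("peak layout exceeds the simulated chromosome")

    n_cpg = rng.binomial(chrom_len, config.cpg_density)
    pos = np.sort(rng.choice(chrom_len, size=n_cpg, replace=False))
    inside = np.zeros(n_cpg, dtype=bool)
    for r in peaks_df.itertuples():
        lo = np.searchsorted(pos, r.start, side="left")
        hi = np.searchsorted(pos, r.end, side="left")
        inside[lo:hi] = True
    mu = np.where(inside, config.flank_meth_mean + config.peak_meth_delta,
                  config.flank_meth_mean)

    frames = []
    for st in config.meth_stages:
        for rep in range(1, config.meth_reps + 1):
            sid = f"wgbs_s{st}_r{rep}"
            levels = _beta_levels(rng, mu, config.meth_concentration)
            cov = rng.poisson(config.mean_coverage, size=n_cpg) + 1
            frames.append(pd.DataFrame({
                "sample_id": sid, "chrom": "chrS1", "pos": pos,
                "meth_level": levels, "coverage": cov}))
    meth = MethylationTable(pd.concat(frames, ignore_index=True))

    replicate_sets: dict[int, PeakSet] = {}
    for rep in (1, 2):
        df = peaks_df.copy()
        if config.replicate_jitter > 0:
            j = config.replicate_jitter
            df["start"] = df["start"] + rng.integers(-j, j + 1, len(df))
            df["end"] = df["end"] + rng.integers(-j, j + 1, len(df))
            df["end"] = np.maximum(df["end"], df["start"] + 1)
        df["peak_id"] = [f"rep{rep}_{pid}" for pid in peaks_df["peak_id"]]
        replicate_sets[rep] = PeakSet(df)

    truth = SyntheticTruth(consensus_peaks=PeakSet(peaks_df))
    return meth, replicate_sets, truth


# ---------------------------------------------------------------------------
# MeRIP counts
# ---------------------------------------------------------------------------

def simulate_merip_counts(config: SimulationConfig, peaks: PeakSet,
                          multipliers: np.ndarray | None = None
                          ) -> tuple[PeakCountTable, SyntheticTruth]:
    """IP/input read counts with planted per-peak true enrichment.

    Input counts are Poisson around a per-peak abundance; IP counts are
    Poisson around abundance x multiplier.  ``multipliers`` may be
    (n_peaks,), (n_peaks, n_stages) or (n_peaks, n_stages, n_reps); by
    default one multiplier per (peak, stage) is drawn log-uniformly from
    ``enrichment_range``.  Library totals are the per-sample peak-count
    sums plus ``background_reads`` off-peak mapped reads, as in a real
    library where most reads fall outside called peaks.
    """
    if len(peaks) == 0:
        raise ConfigError("peaks must be nonempty")
    rng = config.rng("merip")
    n_peaks = len(peaks)
    stages = config.meth_stages
    n_stages = len(stages)
    n_reps = config.meth_reps
    if multipliers is None:
        lo, hi = config.enrichment_range
        mult = np.exp(rng.uniform(np.log(lo), np.log(hi),
                                  size=(n_peaks, n_stages)))
    else:
        mult = np.asarray(multipliers, dtype=float)
    if mult.ndim == 1:
        mult = np.repeat(mult[:, None], n_stages, axis=1)
    if mult.ndim == 2:
        mult = np.repeat(mult[:, :, None], n_reps, axis=2)
    if mult.shape != (n_peaks, n_stages, n_reps):
        raise ConfigError("multipliers shape mismatch")
    abundance = rng.lognormal(mean=np.log(config.mean_input_count),
                              sigma=0.5, size=n_peaks)
    rows = []
    totals: dict[str, int] = {}
    for si, st in enumerate(stages):
        for ri, rep in enumerate(range(1, n_reps + 1)):
            ip_sid = f"merip_ip_s{st}_r{rep}"
            in_sid = f"merip_input_s{st}_r{rep}"
            input_counts = rng.poisson(abundance)
            ip_counts = rng.poisson(abundance * mult[:, si, ri])
            for pid, c_in, c_ip in zip(peaks.peaks["peak_id"],
                                       input_counts, ip_counts):
                rows.append({"peak_id": pid, "sample_id": in_sid,
                             "count": int(c_in)})
                rows.append({"peak_id": pid, "sample_id": ip_sid,
                             "count": int(c_ip)})
            totals[in_sid] = int(input_counts.sum()) + config.background_reads
            totals[ip_sid] = int(ip_counts.sum()) + config.background_reads
    counts = PeakCountTable(pd.DataFrame(rows), totals)
    enr = pd.DataFrame(
        [{"peak_id": pid, "stage_days": st, "replicate": rep,
          "multiplier": mult[pi, si, ri]}
         for pi, pid in enumerate(peaks.peaks["peak_id"])
         for si, st in enumerate(stages)
         for ri, rep in enumerate(range(1, n_reps + 1))])
    return counts, SyntheticTruth(peak_enrichment=enr)


def merip_sample_sheet(config: SimulationConfig) -> list[SampleInfo]:
    sheet = []
    for st in config.meth_stages:
        for rep in range(1, config.meth_reps + 1):
            sheet.append(SampleInfo(f"merip_ip_s{st}_r{rep}", int(st), rep,
                                    "merip_ip"))
            sheet.append(SampleInfo(f"merip_input_s{st}_r{rep}", int(st), rep,
                                    "merip_input"))
    return sheet


def wgbs_sample_sheet(config: SimulationConfig) -> list[SampleInfo]:
    return [SampleInfo(f"wgbs_s{st}_r{rep}", int(st), rep, "wgbs")
            for st in config.meth_stages
            for rep in range(1, config.meth_reps + 1)]


# ---------------------------------------------------------------------------
# Interaction study (closed-loop GLM recovery)
# ---------------------------------------------------------------------------

@dataclass
class InteractionStudy:
    """A matched postnatal multi-omics study with planted interactions."""

    expression: ExpressionMatrix
    peaks: PeakSet
    counts: PeakCountTable
    methylation: MethylationTable
    sample_sheet: list[SampleInfo]
    truth: SyntheticTruth
    escore_mode: str = "replicate"


def simulate_interaction_study(config: SimulationConfig) -> InteractionStudy:
    """One region per gene; planted genes obey the interaction model exactly.

    RNA, WGBS and MeRIP samples share the (stage, replicate) grid
    (4 postnatal stages x 2 biological replicates by default, 8 matched
    observations per region).  Enrichment multipliers and target peak
    methylation are drawn per (peak, stage, replicate) — replicates are
    different animals, so both marks vary between them.  X is realized
    as the replicate-level Escore of the generated counts and Y as the
    per-(peak, sample) mean CpG level of the generated methylome; the
    response of every gene is then drawn from
    b0 + bS*S + bX*X + bY*Y + bXY*X*Y + N(0, sd), with bXY = beta[4]
    for the ``n_interaction_genes`` planted genes and bXY = 0 for the
    nulls.  With only four stages a stage-pooled X is constant within
    stage and the interaction is barely identifiable at n = 8, so this
    study is generated — and should be screened — in replicate mode.
    """
    from .cooccurrence import peak_methylation
    from .interaction import escore_table

    rng = config.rng("interaction")
    n_genes = config.n_interaction_genes + config.n_null_genes
    stages = config.meth_stages
    reps = config.meth_reps
    if len(stages) * reps < 6:
        raise ConfigError("interaction study needs >= 6 (stage, replicate) "
                          "observations")

    # geometry: one compact peak per gene, no flanks needed here
    peak_len, gap = 1000, 500
    starts = np.arange(n_genes, dtype=np.int64) * (peak_len + gap) + gap
    gene_ids = [f"gene_{i + 1:04d}" for i in range(n_genes)]
    peaks = PeakSet(pd.DataFrame({
        "chrom": "chrS1", "start": starts, "end": starts + peak_len,
        "strand": "+", "gene_id": gene_ids,
        "peak_id": [f"region_{i + 1:04d}" for i in range(n_genes)]}))

    # methylome: per (peak, stage, rep) target level drawn uniformly
    n_cpg_per_peak = max(int(peak_len * config.cpg_density), 5)
    frames = []
    for st in stages:
        for rep in range(1, reps + 1):
            sid = f"wgbs_s{st}_r{rep}"
            mu = rng.uniform(0.1, 0.9, size=n_genes)
            pos_list, lv_list = [], []
            for i in range(n_genes):
                offs = np.sort(rng.choice(peak_len, size=n_cpg_per_peak,
                                          replace=False))
                pos_list.append(starts[i] + offs)
                lv_list.append(_beta_levels(
                    rng, np.full(n_cpg_per_peak, mu[i]),
                    config.meth_concentration))
            frames.append(pd.DataFrame({
                "sample_id": sid, "chrom": "chrS1",
                "pos": np.concatenate(pos_list),
                "meth_level": np.concatenate(lv_list),
                "coverage": rng.poisson(config.mean_coverage,
                                        size=n_genes * n_cpg_per_peak) + 1}))
    meth = MethylationTable(pd.concat(frames, ignore_index=True))

    lo, hi = config.enrichment_range
    mult = np.exp(rng.uniform(np.log(lo), np.log(hi),
                              size=(n_genes, len(stages), reps)))
    counts, enr_truth = simulate_merip_counts(config, peaks, multipliers=mult)
    sheet = merip_sample_sheet(config) + wgbs_sample_sheet(config)

    # realized covariates, computed exactly as the screen computes them
    esc = escore_table(counts, sheet, mode="replicate")
    x_lut = {(r.peak_id, r.stage_days, r.replicate): r.escore
             for r in esc.itertuples()}
    pm = peak_methylation(peaks, meth, min_cpgs_per_peak=1)
    y_lut = {(r.peak_id, r.sample_id): r.level for r in pm.itertuples()}

    rna_samples = [SampleInfo(f"rna_s{st}_r{rep}", int(st), rep, "rna")
                   for st in stages for rep in range(1, reps + 1)]
    b0, b_s, b_x, b_y, b_xy = config.beta
    planted = gene_ids[:config.n_interaction_genes]
    values = np.zeros((n_genes, len(rna_samples)))
    for gi, (gene, pid) in enumerate(zip(gene_ids, peaks.peaks["peak_id"])):
        bxy = b_xy if gene in planted else 0.0
        for si, smp in enumerate(rna_samples):
            x = x_lut[(pid, smp.stage_days, smp.replicate)]
            y = y_lut[(pid, f"wgbs_s{smp.stage_days}_r{smp.replicate}")]
            v = (b0 + b_s * smp.stage_days + b_x * x + b_y * y + bxy * x * y
                 + rng.normal(0.0, config.interaction_noise_sd))
            values[gi, si] = max(v, 0.0)
    fpkm = np.exp2(values) - 1.0
    expression = ExpressionMatrix(gene_ids, rna_samples, fpkm)

    truth = SyntheticTruth(
        interaction_genes=planted,
        true_beta={g: (b0, b_s, b_x, b_y, b_xy if g in planted else 0.0)
                   for g in gene_ids},
        peak_enrichment=enr_truth.peak_enrichment,
        realized_x=esc, realized_y=pm, consensus_peaks=peaks)
    return InteractionStudy(expression, peaks, counts, meth,
                            sheet + rna_samples, truth)
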
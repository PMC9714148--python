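"""CpG methylation around m6A peaks: merging, per-peak 5mC, metagene profile.

Replicate peak merging keeps only intervals supported by both biological
replicates (>= 1 bp overlap) and unions overlapping survivors — the
"reproducible peak" rule.  The metagene profile splits the upstream
flank, the peak body and the downstream flank into 20, 10 and 20 bins
respectively and averages CpG methylation per bin, keeping only
(peak, bin) instances covered by at least ``min_cpgs_per_bin`` CpG
sites (default 20).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigError, DataError
from .eigengene import CorrelationResult, pearson_with_p
from .io import MethylationTable, PeakSet

logger = logging.getLogger(__name__)

REGION_LABELS = ("upstream", "peak", "downstream")


# ---------------------------------------------------------------------------
# Replicate peak merging
# ---------------------------------------------------------------------------

def _overlaps_any(starts: np.ndarray, ends: np.ndarray,
                  other_starts: np.ndarray, other_ends: np.ndarray) -> np.ndarray:
    """Boolean mask: does [starts, ends) overlap any [other_starts, other_ends)?

    Half-open semantics: overlap iff start < other_end and other_start < end.
    """
    if other_starts.size == 0:
        return np.zeros(starts.size, dtype=bool)
    order = np.argsort(other_starts, kind="mergesort")
    os = other_starts[order]
    oe = other_ends[order]
    # running max of ends lets us answer "any interval starting at or before x
    # that is still open at x" with one scan
    out = np.zeros(starts.size, dtype=bool)
    for i, (s, e) in enumerate(zip(starts, ends)):
        j = np.searchsorted(os, e, side="left")  # candidates with os < e
        out[i] = bool((oe[:j] > s).any())
    return out


def merge_replicate_peaks(rep1: PeakSet, rep2: PeakSet) -> PeakSet:
    """Keep peaks reproduced in both replicates and union the survivors.

    A peak survives iff it overlaps (>= 1 bp) at least one peak of the
    other replicate; surviving intervals covering a contiguous run of
    bases (overlapping or book-ended) are unioned into a single merged
    peak.  The merged strand/gene_id is kept only when all
    contributing peaks agree; merged ids are ``merged_<n>`` in
    (chrom, start) order.
    """
    chroms = sorted(set(rep1.peaks["chrom"]) | set(rep2.peaks["chrom"]))
    survivors = []
    for chrom in chroms:
        p1 = rep1.peaks[rep1.peaks["chrom"] == chrom]
        p2 = rep2.peaks[rep2.peaks["chrom"] == chrom]
        s1, e1 = p1["start"].to_numpy(int), p1["end"].to_numpy(int)
        s2, e2 = p2["start"].to_numpy(int), p2["end"].to_numpy(int)
        keep1 = _overlaps_any(s1, e1, s2, e2)
        keep2 = _overlaps_any(s2, e2, s1, e1)
        sub = pd.concat([p1[keep1], p2[keep2]])
        if len(sub):
            survivors.append(sub)
    if not survivors:
        warnings.warn("no reproducible peaks between replicates")
        empty = pd.DataFrame(columns=list(PeakSet.COLUMNS))
        return PeakSet(empty)
    surv = pd.concat(survivors).sort_values(["chrom", "start", "end"],
                                            kind="mergesort")
    rows = []
    for chrom, grp in surv.groupby("chrom", sort=True):
        cur_start = cur_end = None
        members: list[pd.Series] = []
        for r in grp.itertuples():
            if cur_start is None:
                cur_start, cur_end, members = r.start, r.end, [r]
            elif r.start <= cur_end:  # overlapping or book-ended run
                cur_end = max(cur_end, r.end)
                members.append(r)
            else:
                rows.append(_merged_row(chrom, cur_start, cur_end, members))
                cur_start, cur_end, members = r.start, r.end, [r]
        if cur_start is not None:
            rows.append(_merged_row(chrom, cur_start, cur_end, members))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "strand",
                                     "gene_id"])
    df["peak_id"] = [f"merged_{i + 1}" for i in range(len(df))]
    return PeakSet(df)


def _merged_row(chrom, start, end, members):
    strands = {m.strand for m in members}
    genes = {m.gene_id for m in members if isinstance(m.gene_id, str)}
    return {"chrom": chrom, "start": int(start), "end": int(end),
            "strand": strands.pop() if len(strands) == 1 else ".",
            "gene_id": genes.pop() if len(genes) == 1 else None}


# ---------------------------------------------------------------------------
# Per-peak methylation (the GLM's Y)
# ---------------------------------------------------------------------------

def peak_methylation(peaks: PeakSet, meth: MethylationTable,
                     min_cpgs_per_peak: int = 1,
                     weighting: str = "unweighted") -> pd.DataFrame:
    """Mean CpG methylation inside each peak, per sample.

    Returns a DataFrame (peak_id, sample_id, level, n_cpgs); ``level``
    is NaN when fewer than ``min_cpgs_per_peak`` CpGs fall inside the
    peak.  ``weighting='coverage'`` weights each CpG by its read
    coverage instead of the default unweighted mean.
    """
    if weighting not in ("unweighted", "coverage"):
        raise ConfigError(f"unknown weighting {weighting!r}")
    rows = []
    n_undefined = 0
    for sid in meth.sample_ids:
        sub = meth.for_sample(sid)
        by_chrom = {c: g.sort_values("pos") for c, g in sub.groupby("chrom")}
        for pk in peaks.peaks.itertuples():
            grp = by_chrom.get(pk.chrom)
            if grp is None:
                level, n = np.nan, 0
            else:
                pos = grp["pos"].to_numpy()
                lo = np.searchsorted(pos, pk.start, side="left")
                hi = np.searchsorted(pos, pk.end, side="left")
                n = int(hi - lo)
                if n < min_cpgs_per_peak or n == 0:
                    level = np.nan
                else:
                    lv = grp["meth_level"].to_numpy()[lo:hi]
                    if weighting == "coverage":
                        w = grp["coverage"].to_numpy()[lo:hi].astype(float)
                        level = float((lv * w).sum() / w.sum())
                    else:
                        level = float(lv.mean())
            if np.isnan(level):
                n_undefined += 1
            rows.append({"peak_id": pk.peak_id, "sample_id": sid,
                         "level": level, "n_cpgs": n})
    if n_undefined:
        logger.info("peak_methylation: %d (peak, sample) pairs below the "
                    "%d-CpG threshold", n_undefined, min_cpgs_per_peak)
    return pd.DataFrame(rows, columns=["peak_id", "sample_id", "level",
                                       "n_cpgs"])


# ---------------------------------------------------------------------------
# Metagene profile
# ---------------------------------------------------------------------------

@dataclass
class MetageneProfile:
    """Binned methylation around peaks: 20 upstream, 10 body, 20 downstream.

    ``table`` rows are ordered 5'→3' in transcript orientation; bins with
    no contributing instance have NaN mean and n_instances = 0.
    """

    table: pd.DataFrame  # bin, region, mean_meth, n_instances, n_cpgs
    bins: tuple[int, int, int]
    flank: int

    def region_means(self, region: str) -> np.ndarray:
        return self.table.loc[self.table["region"] == region,
                              "mean_meth"].to_numpy()


def bin_edges(region_start: int, region_end: int, n_bins: int) -> np.ndarray:
    """Floor-based equal split; the last bin absorbs the remainder.

    Edges partition [region_start, region_end) exactly: length n_bins+1,
    strictly increasing when the region has >= n_bins positions.
    """
    length = region_end - region_start
    if length < n_bins:
        raise DataError(f"region of length {length} cannot be split "
                        f"into {n_bins} bins")
    width = length // n_bins
    edges = region_start + width * np.arange(n_bins + 1, dtype=np.int64)
    edges[-1] = region_end
    return edges


def _bin_counts(pos: np.ndarray, lv: np.ndarray, edges: np.ndarray
                ) -> tuple[np.ndarray, np.ndarray]:
    """Per-bin CpG count and methylation sum for sorted positions."""
    idx = np.searchsorted(pos, edges)
    n_bins = len(edges) - 1
    counts = np.diff(idx)
    sums = np.zeros(n_bins)
    for b in range(n_bins):
        sums[b] = lv[idx[b]:idx[b + 1]].sum()
    return counts, sums


def metagene_profile(peaks: PeakSet, meth: MethylationTable,
                     flank: int = 5000, bins: tuple[int, int, int] = (20, 10, 20),
                     min_cpgs_per_bin: int = 20,
                     aggregation: str = "mean_of_instances") -> MetageneProfile:
    """CpG methylation profile across aligned peak neighborhoods.

    For each peak the upstream flank, the peak body and the downstream
    flank are split into ``bins`` equal-length bins (250 bp flank bins at
    the defaults).  Minus-strand peaks are flipped so bin 0 is always
    transcript-upstream; '.' strands are treated as '+'.  A (peak, bin)
    instance contributes only when it contains at least
    ``min_cpgs_per_bin`` CpGs ("no less than 20" at the default).  The
    bin summary is the mean over contributing instance means
    (``mean_of_instances``) or the mean over all pooled CpGs
    (``pooled``).  Peaks shorter than the body bin count are skipped and
    logged.  Tables with several samples contribute one instance per
    (peak, sample, bin).
    """
    if flank <= 0:
        raise ConfigError("flank must be positive")
    if any(b <= 0 for b in bins):
        raise ConfigError("bin counts must be positive")
    if aggregation not in ("mean_of_instances", "pooled"):
        raise ConfigError(f"unknown aggregation {aggregation!r}")
    n_up, n_body, n_down = bins
    total_bins = n_up + n_body + n_down

    inst_sum = np.zeros(total_bins)    # sum of instance means
    inst_n = np.zeros(total_bins, dtype=int)
    cpg_sum = np.zeros(total_bins)     # pooled methylation sum
    cpg_n = np.zeros(total_bins, dtype=int)
    skipped: list[str] = []

    for sid in meth.sample_ids:
        sub = meth.for_sample(sid)
        by_chrom = {c: g.sort_values("pos") for c, g in sub.groupby("chrom")}
        for pk in peaks.peaks.itertuples():
            if pk.end - pk.start < n_body:
                if pk.peak_id not in skipped:
                    skipped.append(pk.peak_id)
                continue
            grp = by_chrom.get(pk.chrom)
            if grp is None:
                continue
            pos = grp["pos"].to_numpy()
            lv = grp["meth_level"].to_numpy()
            edges_list = [
                bin_edges(pk.start - flank, pk.start, n_up),
                bin_edges(pk.start, pk.end, n_body),
                bin_edges(pk.end, pk.end + flank, n_down),
            ]
            per_region = [_bin_counts(pos, lv, e) for e in edges_list]
            counts = np.concatenate([c for c, _ in per_region])
            sums = np.concatenate([s for _, s in per_region])
            if pk.strand == "-":
                counts = counts[::-1]
                sums = sums[::-1]
            ok = counts >= min_cpgs_per_bin
            with np.errstate(invalid="ignore", divide="ignore"):
                means = np.where(ok & (counts > 0), sums / np.where(counts, counts, 1), 0.0)
            inst_sum[ok] += means[ok]
            inst_n[ok] += 1
            cpg_sum[ok] += sums[ok]
            cpg_n[ok] += counts[ok]
    if skipped:
        logger.info("metagene_profile skipped %d peaks shorter than %d bp: %s%s",
                    len(skipped), n_body, skipped[:5],
                    "..." if len(skipped) > 5 else "")
    with np.errstate(invalid="ignore", divide="ignore"):
        if aggregation == "mean_of_instances":
            mean = np.where(inst_n > 0, inst_sum / np.where(inst_n, inst_n, 1),
                            np.nan)
        else:
            mean = np.where(cpg_n > 0, cpg_sum / np.where(cpg_n, cpg_n, 1),
                            np.nan)
    region = ([REGION_LABELS[0]] * n_up + [REGION_LABELS[1]] * n_body
              + [REGION_LABELS[2]] * n_down)
    table = pd.DataFrame({
        "bin": np.arange(total_bins),
        "region": region,
        "mean_meth": mean,
        "n_instances": inst_n,
        "n_cpgs": cpg_n,
    })
    return MetageneProfile(table, bins, flank)


# ---------------------------------------------------------------------------
# Stage-level summaries (global methylation vs peak number)
# ---------------------------------------------------------------------------

def global_methylation(meth: MethylationTable) -> float:
    """Mean CpG methylation of a table: mean over per-sample means.

    With one sample this is the plain unweighted record mean; with
    replicate samples, replicate means are averaged so that unequal CpG
    counts per replicate do not bias the stage summary.
    """
    if len(meth.records) == 0:
        raise DataError("empty methylation table")
    per_sample = meth.records.groupby("sample_id")["meth_level"].mean()
    return float(per_sample.mean())


def stage_correlation(x, y) -> CorrelationResult:
    """Pearson correlation of two per-stage summaries (e.g. global 5mC
    level vs m6A peak number across postnatal stages)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ConfigError("stage vectors of unequal length")
    if x.size < 3:
        raise ConfigError("need >= 3 stages")
    return pearson_with_p(x, y)
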
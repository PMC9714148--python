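"""Domain containers and tab-separated file formats.

All genomic intervals are 0-based half-open internally; BED input is
consumed natively, per-CpG methylation tables are assumed 1-based
(CX-report style) and converted on read.  Every writer emits a header
line starting with ``#`` and every reader accepts (and ignores) such
lines, so write→read round-trips are the identity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import AlignmentError, DataError, FormatError

logger = logging.getLogger(__name__)

ASSAYS = ("rna", "wgbs", "merip_ip", "merip_input")
STRANDS = ("+", "-", ".")


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SampleInfo:
    """One sequencing library.

    ``stage_days`` is the developmental stage in days (postnatal days for
    the WGBS/MeRIP assays, e.g. 30/60/120/180).  ``replicate`` numbers
    biological replicates within a stage, starting at 1.
    """

    sample_id: str
    stage_days: int
    replicate: int
    assay: str

    def __post_init__(self) -> None:
        if self.stage_days <= 0:
            raise DataError(f"stage_days must be > 0, got {self.stage_days} "
                            f"for sample {self.sample_id!r}")
        if self.replicate < 1:
            raise DataError(f"replicate must be >= 1, got {self.replicate}")
        if self.assay not in ASSAYS:
            raise DataError(f"unknown assay {self.assay!r}; expected one of {ASSAYS}")


def _check_unique_sheet(samples: Sequence[SampleInfo]) -> None:
    keys = [(s.stage_days, s.replicate, s.assay) for s in samples]
    if len(set(keys)) != len(keys):
        raise FormatError("duplicate (stage_days, replicate, assay) in sample sheet")
    ids = [s.sample_id for s in samples]
    if len(set(ids)) != len(ids):
        raise FormatError("duplicate sample_id in sample sheet")


@dataclass
class ExpressionMatrix:
    """Dense genes × samples matrix of FPKM values with sample metadata."""

    gene_ids: list[str]
    samples: list[SampleInfo]
    values: np.ndarray  # shape (n_genes, n_samples), FPKM >= 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.samples)):
            raise DataError(
                f"value matrix shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.samples)} samples")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise DataError("gene_ids are not unique")
        if np.isnan(self.values).any():
            raise DataError("expression matrix contains missing values")
        if (self.values < 0).any():
            g, s = np.argwhere(self.values < 0)[0]
            raise DataError(f"negative FPKM at gene {self.gene_ids[g]!r}, "
                            f"sample {self.samples[s].sample_id!r}")

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def row(self, gene_id: str) -> np.ndarray:
        return self.values[self.gene_ids.index(gene_id)]

    def subset_genes(self, gene_ids: Sequence[str]) -> "ExpressionMatrix":
        index = {g: i for i, g in enumerate(self.gene_ids)}
        missing = [g for g in gene_ids if g not in index]
        if missing:
            raise DataError(f"genes absent from matrix: {missing[:5]}")
        rows = [index[g] for g in gene_ids]
        return ExpressionMatrix(list(gene_ids), list(self.samples),
                                self.values[rows].copy())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids,
                            columns=self.sample_ids)


@dataclass
class MethylationTable:
    """Per-CpG methylation records, one row per (sample, chrom, pos).

    Positions are 0-based internally.  ``meth_level`` is a fraction in
    [0, 1]; ``coverage`` the number of reads informing it.
    """

    records: pd.DataFrame  # columns: sample_id, chrom, pos, meth_level, coverage

    REQUIRED = ("sample_id", "chrom", "pos", "meth_level", "coverage")

    def __post_init__(self) -> None:
        df = self.records
        for col in self.REQUIRED:
            if col not in df.columns:
                raise FormatError(f"methylation table missing column {col!r}")
        lv = df["meth_level"].to_numpy()
        if ((lv < 0) | (lv > 1)).any():
            bad = df.iloc[int(np.argmax((lv < 0) | (lv > 1)))]
            raise DataError(f"meth_level outside [0,1] at "
                            f"{bad['chrom']}:{bad['pos']} ({bad['meth_level']})")
        if (df["coverage"].to_numpy() < 1).any():
            raise DataError("coverage < 1 in methylation table")
        if df.duplicated(["sample_id", "chrom", "pos"]).any():
            raise FormatError("duplicate (sample, chrom, pos) in methylation table")

    @property
    def sample_ids(self) -> list[str]:
        return list(pd.unique(self.records["sample_id"]))

    def for_sample(self, sample_id: str) -> pd.DataFrame:
        return self.records[self.records["sample_id"] == sample_id]


@dataclass
class PeakSet:
    """Genomic intervals (0-based half-open) with optional gene assignment."""

    peaks: pd.DataFrame  # columns: chrom, start, end, strand, gene_id, peak_id

    COLUMNS = ("chrom", "start", "end", "strand", "gene_id", "peak_id")

    def __post_init__(self) -> None:
        df = self.peaks
        for col in self.COLUMNS:
            if col not in df.columns:
                raise FormatError(f"peak table missing column {col!r}")
        if len(df) and (df["start"].to_numpy() >= df["end"].to_numpy()).any():
            bad = df[df["start"] >= df["end"]].iloc[0]
            raise DataError(f"peak {bad['peak_id']!r} has start >= end "
                            f"({bad['start']} >= {bad['end']})")
        if df["peak_id"].duplicated().any():
            raise DataError("peak_ids are not unique")
        if len(df) and (~df["strand"].isin(STRANDS)).any():
            raise DataError("strand must be one of +, -, .")

    def __len__(self) -> int:
        return len(self.peaks)

    def sorted(self) -> "PeakSet":
        df = self.peaks.sort_values(["chrom", "start", "end"],
                                    kind="mergesort").reset_index(drop=True)
        return PeakSet(df)


@dataclass
class PeakCountTable:
    """Per-peak read counts keyed by (peak_id, sample_id) plus library totals."""

    counts: pd.DataFrame           # columns: peak_id, sample_id, count
    library_totals: dict[str, int]  # sample_id -> total mapped reads

    def __post_init__(self) -> None:
        for col in ("peak_id", "sample_id", "count"):
            if col not in self.counts.columns:
                raise FormatError(f"count table missing column {col!r}")
        if (self.counts["count"].to_numpy() < 0).any():
            raise DataError("negative read count")
        for sid, grp in self.counts.groupby("sample_id"):
            if sid not in self.library_totals:
                raise DataError(f"sample {sid!r} has counts but no library total")
            total = self.library_totals[sid]
            if total <= 0:
                raise DataError(f"library total for {sid!r} must be > 0")
            if total < grp["count"].max():
                raise DataError(f"library total for {sid!r} smaller than a peak count")

    def count(self, peak_id: str, sample_id: str) -> int:
        sel = self.counts[(self.counts["peak_id"] == peak_id)
                          & (self.counts["sample_id"] == sample_id)]
        if len(sel) != 1:
            raise DataError(f"expected one count for ({peak_id}, {sample_id}), "
                            f"found {len(sel)}")
        return int(sel["count"].iloc[0])


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def _read_tsv(path, **kwargs) -> pd.DataFrame:
    """Read a TSV whose header line may be prefixed with '#'."""
    with open(path) as fh:
        first = fh.readline()
    header = first.lstrip("#").strip().split("\t")
    df = pd.read_csv(path, sep="\t", skiprows=1, names=header,
                     dtype=str, **kwargs)
    return df


def read_sample_sheet(path) -> list[SampleInfo]:
    df = _read_tsv(path)
    for col in ("sample_id", "stage_days", "replicate", "assay"):
        if col not in df.columns:
            raise FormatError(f"sample sheet missing column {col!r}")
    samples = [SampleInfo(r.sample_id, int(r.stage_days), int(r.replicate), r.assay)
               for r in df.itertuples()]
    _check_unique_sheet(samples)
    return samples


def write_sample_sheet(samples: Sequence[SampleInfo], path) -> None:
    with open(path, "w") as fh:
        fh.write("#sample_id\tstage_days\treplicate\tassay\n")
        for s in samples:
            fh.write(f"{s.sample_id}\t{s.stage_days}\t{s.replicate}\t{s.assay}\n")


def read_expression_matrix(path, sample_sheet: Sequence[SampleInfo]) -> ExpressionMatrix:
    """Read a gene × sample FPKM matrix; columns resolved in the sheet.

    Row and column order of the file are preserved.
    """
    df = _read_tsv(path)
    gene_col = df.columns[0]
    sample_ids = list(df.columns[1:])
    by_id = {s.sample_id: s for s in sample_sheet if s.assay == "rna"}
    unknown = [sid for sid in sample_ids if sid not in by_id]
    if unknown:
        raise FormatError(f"expression columns not in sample sheet (assay=rna): "
                          f"{unknown[:5]}")
    genes = df[gene_col].tolist()
    try:
        values = df[sample_ids].astype(float).to_numpy()
    except ValueError as exc:
        raise DataError(f"non-numeric FPKM value: {exc}") from exc
    if np.isnan(values).any() or (values < 0).any():
        bad = np.argwhere(np.isnan(values) | (values < 0))[0]
        raise DataError(f"invalid FPKM at gene {genes[bad[0]]!r}, "
                        f"column {sample_ids[bad[1]]!r}")
    return ExpressionMatrix(genes, [by_id[sid] for sid in sample_ids], values)


def write_expression_matrix(matrix: ExpressionMatrix, path) -> None:
    with open(path, "w") as fh:
        fh.write("#gene_id\t" + "\t".join(matrix.sample_ids) + "\n")
        for g, row in zip(matrix.gene_ids, matrix.values):
            fh.write(g + "\t" + "\t".join(repr(float(v)) for v in row) + "\n")


def read_methylation_table(path, position_base: int = 1) -> MethylationTable:
    """Read per-CpG methylation records.

    Accepts either a ``meth_level`` column or ``methylated_count`` +
    ``coverage`` (level computed as the ratio).  Input positions are
    ``position_base``-based (default 1, CX-report style) and shifted to the
    internal 0-based convention.  Zero-coverage records are dropped with a
    logged count.
    """
    if position_base not in (0, 1):
        raise FormatError("position_base must be 0 or 1")
    df = _read_tsv(path)
    for col in ("sample_id", "chrom", "pos"):
        if col not in df.columns:
            raise FormatError(f"methylation table missing column {col!r}")
    if "coverage" not in df.columns:
        raise FormatError("methylation table missing column 'coverage'")
    df = df.copy()
    df["pos"] = df["pos"].astype(int) - position_base
    df["coverage"] = df["coverage"].astype(int)
    n_zero = int((df["coverage"] == 0).sum())
    if n_zero:
        logger.info("dropping %d zero-coverage methylation records", n_zero)
        df = df[df["coverage"] > 0]
    if "meth_level" in df.columns:
        df["meth_level"] = df["meth_level"].astype(float)
    elif "methylated_count" in df.columns:
        mc = df["methylated_count"].astype(int)
        if (mc > df["coverage"]).any():
            raise DataError("methylated_count exceeds coverage")
        df["meth_level"] = mc / df["coverage"]
    else:
        raise FormatError("need either 'meth_level' or 'methylated_count' column")
    out = df[["sample_id", "chrom", "pos", "meth_level", "coverage"]]
    return MethylationTable(out.reset_index(drop=True))


def write_methylation_table(table: MethylationTable, path,
                            position_base: int = 1) -> None:
    df = table.records.copy()
    df["pos"] = df["pos"] + position_base
    with open(path, "w") as fh:
        fh.write("#sample_id\tchrom\tpos\tmeth_level\tcoverage\n")
        df.to_csv(fh, sep="\t", header=False, index=False)


def read_peaks(path) -> PeakSet:
    """Read a BED6+ peak file (0-based half-open, native).

    Column 4 (name) becomes ``peak_id``; missing names are auto-assigned
    ``peak_<n>`` in file order.  Column 6 is the strand ('.' when absent)
    and an optional column 7 the gene assignment.
    """
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"line {ln}: fewer than 3 BED columns")
            chrom = parts[0]
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise FormatError(f"line {ln}: non-integer coordinates") from exc
            if start >= end:
                raise FormatError(f"line {ln}: start >= end ({start} >= {end})")
            name = parts[3] if len(parts) > 3 and parts[3] not in ("", ".") else None
            strand = parts[5] if len(parts) > 5 and parts[5] in STRANDS else "."
            gene = parts[6] if len(parts) > 6 and parts[6] not in ("", ".") else None
            rows.append((chrom, start, end, strand, gene, name))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "strand",
                                     "gene_id", "peak_id"])
    auto = df["peak_id"].isna()
    df.loc[auto, "peak_id"] = [f"peak_{i + 1}" for i in np.flatnonzero(auto)]
    return PeakSet(df)


def write_peaks(peaks: PeakSet, path) -> None:
    with open(path, "w") as fh:
        fh.write("#chrom\tstart\tend\tname\tscore\tstrand\tgene_id\n")
        for r in peaks.peaks.itertuples():
            gene = r.gene_id if isinstance(r.gene_id, str) else "."
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.peak_id}\t0\t"
                     f"{r.strand}\t{gene}\n")


def read_peak_counts(counts_path, totals_path,
                     sample_sheet: Sequence[SampleInfo] | None = None) -> PeakCountTable:
    df = _read_tsv(counts_path)
    for col in ("peak_id", "sample_id", "count"):
        if col not in df.columns:
            raise FormatError(f"count table missing column {col!r}")
    df = df.copy()
    df["count"] = df["count"].astype(int)
    tdf = _read_tsv(totals_path)
    for col in ("sample_id", "total"):
        if col not in tdf.columns:
            raise FormatError(f"library-total table missing column {col!r}")
    totals = {r.sample_id: int(r.total) for r in tdf.itertuples()}
    if sample_sheet is not None:
        known = {s.sample_id for s in sample_sheet}
        unknown = sorted(set(df["sample_id"]) - known)
        if unknown:
            raise FormatError(f"count samples not in sheet: {unknown[:5]}")
    return PeakCountTable(df[["peak_id", "sample_id", "count"]], totals)


def write_peak_counts(table: PeakCountTable, counts_path, totals_path) -> None:
    with open(counts_path, "w") as fh:
        fh.write("#peak_id\tsample_id\tcount\n")
        table.counts.to_csv(fh, sep="\t", header=False, index=False)
    with open(totals_path, "w") as fh:
        fh.write("#sample_id\ttotal\n")
        for sid, total in table.library_totals.items():
            fh.write(f"{sid}\t{total}\n")
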
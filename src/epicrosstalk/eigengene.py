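"""Module eigengenes, module membership (kME), hub selection and the EME.

A module eigengene is the first right-singular vector (sample space) of
the standardized expression submatrix of a gene set — the unit-norm
summary profile explaining the largest share of the module's variance.
Module membership (kME) of a gene is the Pearson correlation between its
expression profile and the eigengene.  The epigenetic module eigengene
(EME) treats a curated list of 41 DNA-5mC and RNA-m6A regulators (21 and
20 genes: writers, readers and erasers of each mark) as one module,
keeps the hub regulators with |kME| > 0.7 and recomputes the eigengene
from the hubs only.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import AlignmentError, ConfigError, DegenerateModuleError
from .io import ExpressionMatrix

logger = logging.getLogger(__name__)

_NEAR_TIE_REL_GAP = 1e-6


@dataclass(frozen=True)
class CorrelationResult:
    """Pearson correlation with a two-sided t-based p-value."""

    r: float
    p: float
    n: int


@dataclass
class Eigengene:
    sample_ids: list[str]
    values: np.ndarray      # unit Euclidean norm, one entry per sample
    source_genes: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        norm = float(np.linalg.norm(self.values))
        if abs(norm - 1.0) > 1e-10:
            raise ValueError(f"eigengene norm {norm} != 1")


@dataclass
class EMEResult:
    """All artifacts of the EME construction."""

    module_eigengene: Eigengene      # eigengene of the full regulator set
    membership: dict[str, float]     # kME of every regulator vs that eigengene
    hubs: list[str]                  # regulators with |kME| > threshold
    eme: Eigengene                   # eigengene recomputed from the hubs


def pearson_with_p(x: np.ndarray, y: np.ndarray) -> CorrelationResult:
    """Pearson r with the classical two-sided t test.

    t = r * sqrt((n-2) / (1-r^2)) on n-2 degrees of freedom.  For |r| = 1
    (within floating point) the p-value is reported as 0.0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n != y.size:
        raise AlignmentError("vectors of unequal length")
    if n < 3:
        raise ConfigError("need at least 3 observations for a correlation test")
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc * xc).sum() * (yc * yc).sum())
    if denom == 0:
        warnings.warn("constant vector: correlation undefined")
        return CorrelationResult(float("nan"), float("nan"), n)
    r = float(np.clip((xc * yc).sum() / denom, -1.0, 1.0))
    one_minus_r2 = max(1.0 - r * r, 0.0)
    if one_minus_r2 < 1e-300:
        return CorrelationResult(r, 0.0, n)
    t = r * np.sqrt((n - 2) / one_minus_r2)
    p = float(2.0 * stats.t.sf(abs(t), df=n - 2))
    return CorrelationResult(r, p, n)


def default_regulators() -> pd.DataFrame:
    """The packaged 41-gene regulator table (21 5mC + 20 m6A).

    Curated from the literature on 5mC/m6A writer, reader and eraser
    enzymes; fully overridable by passing any other gene list.
    Columns: symbol, mark ('5mc'|'m6a'), role ('writer'|'reader'|'eraser').
    """
    ref = resources.files("epicrosstalk.data") / "regulators_5mc_m6a.tsv"
    with resources.as_file(ref) as path:
        df = pd.read_csv(path, sep="\t")
    df.columns = [c.lstrip("#") for c in df.columns]
    return df


def log2_fpkm(matrix: ExpressionMatrix) -> np.ndarray:
    return np.log2(matrix.values + 1.0)


def standardize_expression(matrix: ExpressionMatrix, log_transform: bool = True
                           ) -> tuple[np.ndarray, list[str], list[str]]:
    """Row-standardize expression to mean 0, sd 1 (n-1 denominator).

    Returns ``(z, kept_gene_ids, dropped_gene_ids)``; zero-variance genes
    are dropped and logged.  Raises if every gene is constant.
    """
    if matrix.n_samples < 3:
        raise ConfigError("standardization requires at least 3 samples")
    x = log2_fpkm(matrix) if log_transform else matrix.values.astype(float)
    sd = x.std(axis=1, ddof=1)
    keep = sd > 0
    dropped = [g for g, k in zip(matrix.gene_ids, keep) if not k]
    if dropped:
        logger.info("dropping %d zero-variance genes: %s%s", len(dropped),
                    dropped[:5], "..." if len(dropped) > 5 else "")
    if not keep.any():
        raise DegenerateModuleError("all genes have zero variance")
    xk = x[keep]
    z = (xk - xk.mean(axis=1, keepdims=True)) / sd[keep][:, None]
    kept = [g for g, k in zip(matrix.gene_ids, keep) if k]
    return z, kept, dropped


def module_eigengene(matrix: ExpressionMatrix, gene_set: Sequence[str],
                     log_transform: bool = True) -> Eigengene:
    """First right-singular vector of the standardized submatrix.

    Orientation: the sign is fixed so that the mean membership of the
    source genes is >= 0; an exact tie is broken toward a positive first
    component.  A near-degenerate leading singular pair (relative gap
    < 1e-6) triggers a warning, not an error.
    """
    sub = matrix.subset_genes(gene_set)
    z, kept, _ = standardize_expression(sub, log_transform=log_transform)
    if len(kept) < 2:
        raise DegenerateModuleError(
            f"module needs >= 2 genes with nonzero variance, got {len(kept)}")
    _, s, vt = np.linalg.svd(z, full_matrices=False)
    if len(s) > 1 and s[0] > 0 and (s[0] - s[1]) / s[0] < _NEAR_TIE_REL_GAP:
        warnings.warn("leading singular values nearly tied; "
                      "eigengene orientation may be unstable")
    e = vt[0]
    # orient: mean correlation of source genes with e must be >= 0
    zc = z - z.mean(axis=1, keepdims=True)
    ec = e - e.mean()
    ec_norm = np.linalg.norm(ec)
    if ec_norm > 0:
        mm = (zc @ ec) / (np.linalg.norm(zc, axis=1) * ec_norm)
        mean_mm = mm.mean()
    else:
        mean_mm = 0.0
    if mean_mm < 0 or (mean_mm == 0 and _first_nonzero_sign(e) < 0):
        e = -e
    e = e / np.linalg.norm(e)
    return Eigengene(sub.sample_ids, e, kept)


def _first_nonzero_sign(v: np.ndarray) -> float:
    nz = v[v != 0]
    return float(np.sign(nz[0])) if nz.size else 1.0


def module_membership(matrix: ExpressionMatrix, eig: Eigengene,
                      log_transform: bool = True) -> dict[str, float]:
    """kME: Pearson correlation of each gene's profile with the eigengene.

    Zero-variance genes map to NaN.  Sample ids must match in order.
    """
    if matrix.sample_ids != eig.sample_ids:
        raise AlignmentError("sample ids of matrix and eigengene differ")
    x = log2_fpkm(matrix) if log_transform else matrix.values.astype(float)
    xc = x - x.mean(axis=1, keepdims=True)
    xn = np.linalg.norm(xc, axis=1)
    ec = eig.values - eig.values.mean()
    en = np.linalg.norm(ec)
    mm = np.full(matrix.n_genes, np.nan)
    ok = (xn > 0) & (en > 0)
    mm[ok] = np.clip((xc[ok] @ ec) / (xn[ok] * en), -1.0, 1.0)
    return dict(zip(matrix.gene_ids, mm.tolist()))


def select_hubs(mm: Mapping[str, float], threshold: float = 0.7,
                mode: str = "absolute") -> list[str]:
    """Genes whose membership exceeds the threshold (strict inequality).

    ``mode='absolute'`` (default) applies the cut to |kME| so that
    strongly anticorrelated regulators (e.g. erasers) are retained;
    ``mode='signed'`` applies it to signed kME.  Sorted by descending
    |kME|.
    """
    if mode not in ("absolute", "signed"):
        raise ConfigError(f"unknown hub-selection mode {mode!r}")
    if not mm:
        raise ConfigError("empty membership table")
    stat = {g: (abs(v) if mode == "absolute" else v)
            for g, v in mm.items() if not np.isnan(v)}
    hubs = [g for g, v in stat.items() if v > threshold]
    if not hubs:
        warnings.warn(f"no gene passes membership threshold {threshold}")
    return sorted(hubs, key=lambda g: (-abs(mm[g]), g))


def compute_eme(matrix: ExpressionMatrix, regulators: Sequence[str],
                threshold: float = 0.7, mode: str = "absolute",
                log_transform: bool = True) -> EMEResult:
    """Regulator eigengene → membership → hubs → EME from hubs only."""
    eig = module_eigengene(matrix, regulators, log_transform=log_transform)
    sub = matrix.subset_genes(regulators)
    mm = module_membership(sub, eig, log_transform=log_transform)
    hubs = select_hubs(mm, threshold=threshold, mode=mode)
    if len(hubs) < 2:
        raise DegenerateModuleError(
            f"hub selection left {len(hubs)} gene(s); cannot recompute the EME")
    eme = module_eigengene(matrix, hubs, log_transform=log_transform)
    return EMEResult(eig, mm, hubs, eme)


def pairwise_regulator_correlation(matrix: ExpressionMatrix,
                                   regulators: Sequence[str],
                                   log_transform: bool = True
                                   ) -> tuple[pd.DataFrame, pd.DataFrame, int]:
    """All-vs-all Pearson correlation of regulator expression profiles.

    Returns (r, p, n): symmetric DataFrames with unit diagonal on r and
    NaN rows/columns for zero-variance genes.
    """
    sub = matrix.subset_genes(regulators)
    if sub.n_samples < 3:
        raise ConfigError("need at least 3 samples")
    x = log2_fpkm(sub) if log_transform else sub.values.astype(float)
    n = sub.n_samples
    k = sub.n_genes
    r = np.full((k, k), np.nan)
    p = np.full((k, k), np.nan)
    sd = x.std(axis=1, ddof=1)
    ok = np.flatnonzero(sd > 0)
    if ok.size:
        c = np.corrcoef(x[ok])
        c = np.clip(np.atleast_2d(c), -1.0, 1.0)
        one_minus = np.clip(1.0 - c * c, 0.0, None)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = c * np.sqrt((n - 2) / one_minus)
        pv = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
        pv[one_minus < 1e-300] = 0.0
        r[np.ix_(ok, ok)] = c
        p[np.ix_(ok, ok)] = pv
        r[ok, ok] = 1.0
        p[ok, ok] = 0.0
    genes = sub.gene_ids
    return (pd.DataFrame(r, index=genes, columns=genes),
            pd.DataFrame(p, index=genes, columns=genes), n)
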
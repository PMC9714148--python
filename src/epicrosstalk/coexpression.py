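"""Co-expression module detection and EME correlation screening.

The detector is a compact weighted-correlation-network pipeline: an
unsigned adjacency |cor|^power on log2(FPKM+1) profiles, the unsigned
topological overlap matrix (TOM), average-linkage hierarchical
clustering on 1 - TOM with a static cut, and a minimum module size.
Detected modules are summarized by their eigengenes and screened
against the EME with |r| > 0.8 and p < 0.05 (Pearson, two-sided).

The static cut is a deliberate simplification of dynamic tree cutting:
module recovery on data with planted block structure is the supported
contract, not bit-for-bit agreement with any particular reference
implementation, and the detector is pluggable.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .errors import ConfigError, DegenerateModuleError
from .eigengene import (CorrelationResult, Eigengene, log2_fpkm,
                        module_eigengene, pearson_with_p)
from .io import ExpressionMatrix

logger = logging.getLogger(__name__)


@dataclass
class ModuleAssignment:
    """Per-gene module labels; 0 marks unassigned genes.

    Labels 1..K are assigned in order of decreasing module size.
    """

    labels: dict[str, int]
    sizes: dict[int, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.sizes:
            counts: dict[int, int] = {}
            for lab in self.labels.values():
                counts[lab] = counts.get(lab, 0) + 1
            self.sizes = counts

    def genes_in(self, label: int) -> list[str]:
        return [g for g, lab in self.labels.items() if lab == label]

    @property
    def module_labels(self) -> list[int]:
        return sorted(lab for lab in self.sizes if lab != 0)


def variance_filter(matrix: ExpressionMatrix, quantile: float = 0.25,
                    log_transform: bool = True) -> ExpressionMatrix:
    """Keep genes in the top ``quantile`` fraction by expression variance.

    Variance is computed on log2(FPKM+1) by default.  Genes whose
    variance ties the (1 - quantile) boundary are included.
    """
    if not 0 < quantile <= 1:
        raise ConfigError(f"quantile must be in (0, 1], got {quantile}")
    if matrix.n_samples < 2:
        raise ConfigError("variance filter needs >= 2 samples")
    x = log2_fpkm(matrix) if log_transform else matrix.values.astype(float)
    variances = x.var(axis=1, ddof=1)
    cutoff = float(np.quantile(variances, 1.0 - quantile))
    keep = variances >= cutoff
    kept = [g for g, k in zip(matrix.gene_ids, keep) if k]
    logger.info("variance filter kept %d/%d genes (cutoff %.4g)",
                len(kept), matrix.n_genes, cutoff)
    return matrix.subset_genes(kept)


def adjacency_matrix(z: np.ndarray, power: float = 6.0) -> np.ndarray:
    """Unsigned soft-thresholded adjacency a_ij = |cor(g_i, g_j)|^power."""
    if power < 1:
        raise ConfigError(f"soft-threshold power must be >= 1, got {power}")
    c = np.corrcoef(z)
    a = np.abs(np.clip(c, -1.0, 1.0)) ** power
    np.fill_diagonal(a, 0.0)
    return a


def topological_overlap(a: np.ndarray) -> np.ndarray:
    """Unsigned TOM from an adjacency with zero diagonal.

    TOM_ij = (L_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij) with
    L_ij = sum_u a_iu * a_uj and k_i the connectivity; TOM_ii = 1.
    """
    k = a.sum(axis=1)
    l = a @ a
    kmin = np.minimum.outer(k, k)
    tom = (l + a) / (kmin + 1.0 - a)
    np.fill_diagonal(tom, 1.0)
    return np.clip((tom + tom.T) / 2.0, 0.0, 1.0)


def detect_modules(matrix: ExpressionMatrix, power: float = 6.0,
                   cut_height: float = 0.995, min_module_size: int = 30,
                   log_transform: bool = True) -> ModuleAssignment:
    """Cluster genes into co-expression modules on TOM dissimilarity.

    ``cut_height`` is a fraction of the maximum merge height of the
    average-linkage dendrogram (static cut).  Clusters smaller than
    ``min_module_size`` are relabeled 0 (unassigned); surviving modules
    are labeled 1..K by decreasing size.
    """
    if matrix.n_genes < 3:
        raise ConfigError("module detection needs >= 3 genes")
    if matrix.n_samples < 4:
        raise ConfigError("module detection needs >= 4 samples")
    x = log2_fpkm(matrix) if log_transform else matrix.values.astype(float)
    sd = x.std(axis=1, ddof=1)
    if (sd == 0).any():
        raise DegenerateModuleError("zero-variance genes present; filter first")
    a = adjacency_matrix(x, power=power)
    tom = topological_overlap(a)
    dist = 1.0 - tom
    np.fill_diagonal(dist, 0.0)
    condensed = squareform(np.clip(dist, 0.0, None), checks=False)
    link = hierarchy.linkage(condensed, method="average")
    max_height = link[:, 2].max() if len(link) else 0.0
    raw = hierarchy.fcluster(link, t=cut_height * max_height,
                             criterion="distance")
    labels = _relabel_by_size(raw, min_module_size)
    return ModuleAssignment(dict(zip(matrix.gene_ids, labels)))


def _relabel_by_size(raw: np.ndarray, min_size: int) -> list[int]:
    sizes = pd.Series(raw).value_counts()
    keep = sizes[sizes >= min_size]
    # decreasing size; ties broken by first appearance for determinism
    order = sorted(keep.index, key=lambda lab: (-keep[lab],
                                                int(np.argmax(raw == lab))))
    remap = {lab: i + 1 for i, lab in enumerate(order)}
    return [remap.get(lab, 0) for lab in raw]


@dataclass
class ModuleScreenResult:
    """Per-module EME correlation screen (the Fig-4A-style table)."""

    table: pd.DataFrame  # module, n_genes, r, p, n, selected, direction
    r_threshold: float
    p_threshold: float

    @property
    def selected_modules(self) -> list[int]:
        return self.table.loc[self.table["selected"], "module"].tolist()


def screen_modules_vs_eme(assignment: ModuleAssignment,
                          matrix: ExpressionMatrix, eme: Eigengene,
                          r_threshold: float = 0.8,
                          p_threshold: float = 0.05,
                          log_transform: bool = True) -> ModuleScreenResult:
    """Correlate each module eigengene with the EME and screen.

    A module is selected iff |r| > r_threshold and p < p_threshold;
    the direction (positive/negative) is reported so anticorrelated
    modules remain visible.  Modules with < 2 genes are skipped with a
    warning.
    """
    if matrix.sample_ids != eme.sample_ids:
        raise ConfigError("matrix and EME sample ids differ")
    rows = []
    for label in assignment.module_labels:
        genes = assignment.genes_in(label)
        if len(genes) < 2:
            warnings.warn(f"module {label} has < 2 genes; skipped")
            continue
        me = module_eigengene(matrix, genes, log_transform=log_transform)
        res = pearson_with_p(me.values, eme.values)
        selected = (not np.isnan(res.r) and abs(res.r) > r_threshold
                    and res.p < p_threshold)
        rows.append({"module": label, "n_genes": len(genes), "r": res.r,
                     "p": res.p, "n": res.n, "selected": selected,
                     "direction": "positive" if res.r >= 0 else "negative"})
    table = pd.DataFrame(rows, columns=["module", "n_genes", "r", "p", "n",
                                        "selected", "direction"])
    return ModuleScreenResult(table, r_threshold, p_threshold)
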
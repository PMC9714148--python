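"""m6A enrichment scores and the 5mC × m6A interaction linear model.

Per-peak enrichment is Escore = RPM_IP / RPM_Input with
RPM = count * 1e6 / library_total.  For each m6A region on a gene the
model

    log2(FPKM + 1) = b0 + bS*S + bX*X + bY*Y + bXY*(X*Y) + e

is fitted by ordinary least squares, where S is the postnatal stage in
days, X the region's Escore, Y its CpG methylation level and X*Y the
interaction term.  Regions (and genes, by an any-region rule) are
called significant when the two-sided t-test p-value of bXY falls below
alpha (raw by default; Benjamini-Hochberg optional).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import linalg, stats

from .errors import (ConfigError, DataError, InsufficientDataError)
from .io import ExpressionMatrix, PeakCountTable, PeakSet, SampleInfo

logger = logging.getLogger(__name__)

TERMS = ("intercept", "stage", "escore", "meth", "interaction")


# ---------------------------------------------------------------------------
# RPM / Escore
# ---------------------------------------------------------------------------

def rpm(count: float, library_total: float) -> float:
    """Reads per million: count * 1e6 / library_total."""
    if library_total <= 0:
        raise DataError(f"library total must be > 0, got {library_total}")
    if count < 0:
        raise DataError("count must be >= 0")
    return count * 1e6 / library_total


def escore(ip_count: float, ip_total: float,
           input_count: float, input_total: float) -> float:
    """Per-peak m6A enrichment: RPM_IP / RPM_Input.

    Returns NaN (undefined enrichment) when the input RPM is zero; this
    is a flag, not an exception, so screening can skip such regions.
    """
    r_ip = rpm(ip_count, ip_total)
    r_in = rpm(input_count, input_total)
    if r_in == 0:
        return float("nan")
    return r_ip / r_in


def escore_table(counts: PeakCountTable, samples: Sequence[SampleInfo],
                 mode: str = "stage_pooled") -> pd.DataFrame:
    """Escore per peak and stage (or per replicate).

    ``stage_pooled`` (default) sums IP counts and totals over the
    replicates of each stage, and likewise for input, before forming the
    ratio; ``replicate`` matches IP replicate i with input replicate i.
    Returns columns peak_id, stage_days, [replicate,] escore, rpm_ip,
    rpm_input.
    """
    if mode not in ("stage_pooled", "replicate"):
        raise ConfigError(f"unknown escore mode {mode!r}")
    by_id = {s.sample_id: s for s in samples}
    df = counts.counts.copy()
    missing = sorted(set(df["sample_id"]) - set(by_id))
    if missing:
        raise DataError(f"count samples not in sheet: {missing[:5]}")
    df["stage_days"] = [by_id[s].stage_days for s in df["sample_id"]]
    df["replicate"] = [by_id[s].replicate for s in df["sample_id"]]
    df["assay"] = [by_id[s].assay for s in df["sample_id"]]
    df["total"] = [counts.library_totals[s] for s in df["sample_id"]]
    ip = df[df["assay"] == "merip_ip"]
    inp = df[df["assay"] == "merip_input"]
    if ip.empty or inp.empty:
        raise DataError("count table needs both merip_ip and merip_input samples")

    keys = ["peak_id", "stage_days"] if mode == "stage_pooled" else \
           ["peak_id", "stage_days", "replicate"]
    rows = []
    ip_g = ip.groupby(keys)
    inp_g = inp.groupby(keys)
    # totals must be pooled per (stage[, replicate]) over distinct samples,
    # not summed per peak row
    def _pooled_totals(sub: pd.DataFrame, keys_no_peak):
        t = sub.drop_duplicates("sample_id")
        return t.groupby(keys_no_peak)["total"].sum()

    keys_np = keys[1:]
    ip_tot = _pooled_totals(ip, keys_np)
    inp_tot = _pooled_totals(inp, keys_np)
    ip_cnt = ip_g["count"].sum()
    inp_cnt = inp_g["count"].sum()
    for key in ip_cnt.index:
        if key not in inp_cnt.index:
            continue
        group_key = key[1] if len(keys_np) == 1 else key[1:]
        r_ip = rpm(ip_cnt[key], ip_tot[group_key])
        r_in = rpm(inp_cnt[key], inp_tot[group_key])
        row = {"peak_id": key[0], "stage_days": key[1],
               "rpm_ip": r_ip, "rpm_input": r_in,
               "escore": (r_ip / r_in) if r_in > 0 else float("nan")}
        if mode == "replicate":
            row["replicate"] = key[2]
        rows.append(row)
    out = pd.DataFrame(rows)
    n_undef = int(out["escore"].isna().sum()) if len(out) else 0
    if n_undef:
        logger.info("escore undefined (zero input RPM) for %d rows", n_undef)
    return out


# ---------------------------------------------------------------------------
# Interaction GLM
# ---------------------------------------------------------------------------

@dataclass
class InteractionFit:
    """OLS fit of log2(FPKM+1) ~ S + X + Y + X*Y for one region."""

    region_id: str
    gene_id: str
    coef: dict[str, float]
    se: dict[str, float]
    tstat: dict[str, float]
    pvalue: dict[str, float]
    df_resid: int
    r2: float
    dropped: list[str] = field(default_factory=list)
    perfect_fit: bool = False

    @property
    def p_interaction(self) -> float:
        return self.pvalue.get("interaction", float("nan"))


def fit_interaction_glm(response: np.ndarray, stage_days: np.ndarray,
                        x_escore: np.ndarray, y_meth: np.ndarray,
                        region_id: str = "", gene_id: str = "") -> InteractionFit:
    """OLS via pivoted QR; rank-deficient columns are dropped and flagged.

    ``response`` is log2(FPKM+1).  Standard errors come from the residual
    variance on n - rank degrees of freedom; p-values are two-sided t.
    A residual variance below 1e-12 is reported as a perfect fit with
    undefined p-values (NaN) and a warning.
    """
    y = np.asarray(response, dtype=float)
    s = np.asarray(stage_days, dtype=float)
    x = np.asarray(x_escore, dtype=float)
    m = np.asarray(y_meth, dtype=float)
    n = y.size
    if not (s.size == x.size == m.size == n):
        raise ConfigError("response and covariates must have equal length")
    if np.isnan(np.concatenate([y, s, x, m])).any():
        raise DataError("NaN in model inputs; filter undefined X/Y first")
    design = np.column_stack([np.ones(n), s, x, m, x * m])
    if n < design.shape[1] + 1:
        raise InsufficientDataError(
            f"need at least {design.shape[1] + 1} observations, got {n}")

    q, r, piv = linalg.qr(design, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = max(design.shape) * np.finfo(float).eps * (diag[0] if diag.size else 0)
    rank = int((diag > tol).sum())
    kept_idx = np.sort(piv[:rank])
    dropped = [TERMS[i] for i in piv[rank:]]
    if dropped:
        warnings.warn(f"rank-deficient design; dropped terms: {dropped}")
    xk = design[:, kept_idx]
    q2, r2m = np.linalg.qr(xk)
    beta = linalg.solve_triangular(r2m, q2.T @ y)
    fitted = xk @ beta
    resid = y - fitted
    df_resid = n - rank
    if df_resid < 1:
        raise InsufficientDataError("no residual degrees of freedom")
    rss = float(resid @ resid)
    sigma2 = rss / df_resid
    rinv = linalg.solve_triangular(r2m, np.eye(rank))
    xtx_inv_diag = (rinv * rinv).sum(axis=1)
    tss = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - rss / tss if tss > 0 else float("nan")

    perfect = sigma2 < 1e-12
    if perfect:
        warnings.warn(f"perfect fit for region {region_id!r}; "
                      "p-values undefined")
    coef = {t: float("nan") for t in TERMS}
    se = dict(coef)
    tstat = dict(coef)
    pval = dict(coef)
    for j, idx in enumerate(kept_idx):
        term = TERMS[idx]
        coef[term] = float(beta[j])
        if perfect:
            continue
        se_j = float(np.sqrt(sigma2 * xtx_inv_diag[j]))
        se[term] = se_j
        t_j = beta[j] / se_j if se_j > 0 else float("inf")
        tstat[term] = float(t_j)
        pval[term] = float(2.0 * stats.t.sf(abs(t_j), df=df_resid))
    for term in dropped:
        coef[term] = float("nan")
    return InteractionFit(region_id, gene_id, coef, se, tstat, pval,
                          df_resid, r2, dropped, perfect)


# ---------------------------------------------------------------------------
# Region screening
# ---------------------------------------------------------------------------

@dataclass
class InteractionScreen:
    """Region-level fits plus the gene-level any-region rollup."""

    fits: pd.DataFrame        # region_id, gene_id, coefficients, p_interaction, significant
    genes: pd.DataFrame       # gene_id, n_regions, n_significant, significant
    n_significant_regions: int
    n_significant_genes: int
    skipped: pd.DataFrame     # region_id, reason
    alpha: float
    correction: str


def benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    """Step-up BH adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p)
    ranked = p[order] * m / (np.arange(m) + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out


def screen_interaction_regions(expression: ExpressionMatrix,
                               peaks: PeakSet,
                               enrichment: pd.DataFrame,
                               peak_meth: pd.DataFrame,
                               sample_sheet: Sequence[SampleInfo],
                               alpha: float = 0.05,
                               correction: str = "none") -> InteractionScreen:
    """Fit the interaction GLM for every gene-assigned region and screen.

    Observations are (stage, replicate) pairs present in the RNA samples
    and matched to a WGBS sample of the same stage and replicate; X is
    joined per stage (stage-pooled Escore) or per (stage, replicate) when
    the enrichment table carries a ``replicate`` column.  Regions with
    undefined X or Y in any observation are skipped and logged with a
    reason.  A gene is significant when any of its regions is.
    """
    if correction not in ("none", "benjamini_hochberg"):
        raise ConfigError(f"unknown correction {correction!r}")
    if not 0 < alpha < 1:
        raise ConfigError("alpha must be in (0, 1)")
    wgbs = {(s.stage_days, s.replicate): s.sample_id
            for s in sample_sheet if s.assay == "wgbs"}
    rna = [(s.stage_days, s.replicate, s.sample_id) for s in expression.samples]
    obs = [(st, rep, sid, wgbs[(st, rep)]) for st, rep, sid in rna
           if (st, rep) in wgbs]
    if len(obs) < 6:
        raise InsufficientDataError(
            f"only {len(obs)} RNA observations match a WGBS sample by "
            "(stage, replicate); need >= 6")
    rna_cols = {sid: j for j, sid in enumerate(expression.sample_ids)}
    meth_lut = {(r.peak_id, r.sample_id): (r.level, r.n_cpgs)
                for r in peak_meth.itertuples()}
    per_rep = "replicate" in enrichment.columns
    if per_rep:
        esc_lut = {(r.peak_id, r.stage_days, r.replicate): r.escore
                   for r in enrichment.itertuples()}
    else:
        esc_lut = {(r.peak_id, r.stage_days): r.escore
                   for r in enrichment.itertuples()}
    gene_index = set(expression.gene_ids)

    fit_rows, skipped = [], []
    for pk in peaks.peaks.itertuples():
        gene = pk.gene_id
        if not isinstance(gene, str) or gene not in gene_index:
            skipped.append({"region_id": pk.peak_id, "reason": "no_gene_expression"})
            continue
        yv, sv, xv, mv = [], [], [], []
        bad = None
        for st, rep, rna_sid, wgbs_sid in obs:
            key = (pk.peak_id, st, rep) if per_rep else (pk.peak_id, st)
            x = esc_lut.get(key, float("nan"))
            lvl, _ = meth_lut.get((pk.peak_id, wgbs_sid), (float("nan"), 0))
            if np.isnan(x):
                bad = "undefined_escore"
                break
            if np.isnan(lvl):
                bad = "undefined_methylation"
                break
            yv.append(np.log2(expression.values[
                expression.gene_ids.index(gene), rna_cols[rna_sid]] + 1.0))
            sv.append(st)
            xv.append(x)
            mv.append(lvl)
        if bad:
            skipped.append({"region_id": pk.peak_id, "reason": bad})
            continue
        try:
            fit = fit_interaction_glm(np.array(yv), np.array(sv),
                                      np.array(xv), np.array(mv),
                                      region_id=pk.peak_id, gene_id=gene)
        except InsufficientDataError:
            skipped.append({"region_id": pk.peak_id, "reason": "insufficient_data"})
            continue
        if fit.perfect_fit or "interaction" in fit.dropped \
                or np.isnan(fit.p_interaction):
            reason = "perfect_fit" if fit.perfect_fit else "interaction_dropped"
            skipped.append({"region_id": pk.peak_id, "reason": reason})
            continue
        row = {"region_id": pk.peak_id, "gene_id": gene,
               "df_resid": fit.df_resid, "r2": fit.r2}
        for term in TERMS:
            row[f"coef_{term}"] = fit.coef[term]
            row[f"p_{term}"] = fit.pvalue[term]
        fit_rows.append(row)

    fits = pd.DataFrame(fit_rows)
    if fits.empty:
        warnings.warn("no fittable region; empty interaction screen")
        genes = pd.DataFrame(columns=["gene_id", "n_regions", "n_significant",
                                      "significant"])
        return InteractionScreen(fits, genes, 0, 0,
                                 pd.DataFrame(skipped), alpha, correction)
    p = fits["p_interaction"].to_numpy()
    if correction == "benjamini_hochberg":
        fits["p_interaction_adj"] = benjamini_hochberg(p)
        fits["significant"] = fits["p_interaction_adj"] < alpha
    else:
        fits["significant"] = p < alpha
    genes = (fits.groupby("gene_id")
             .agg(n_regions=("region_id", "size"),
                  n_significant=("significant", "sum"))
             .reset_index())
    genes["significant"] = genes["n_significant"] > 0
    n_sig_regions = int(fits["significant"].sum())
    n_sig_genes = int(genes["significant"].sum())
    logger.info("interaction screen: %d/%d regions significant in %d genes",
                n_sig_regions, len(fits), n_sig_genes)
    return InteractionScreen(fits, genes, n_sig_regions, n_sig_genes,
                             pd.DataFrame(skipped, columns=["region_id", "reason"]),
                             alpha, correction)
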
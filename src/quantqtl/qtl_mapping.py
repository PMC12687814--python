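"""cis-window construction, the four QTL scans, and the two-stage
hierarchical multiple-testing correction.

Scans
-----
xQTL
    standard linear regression of the phenotype on each dosage column with
    covariates adjusted (two-sided slope t-test).
qQTL
    quantile rank-score test at each level of a 19-point grid, fitted
    against per-level covariate-only null models shared across variants,
    with per-variant Cauchy combination across levels.
vQTL
    a QUAIL-inspired variance contrast built from the same rank scores:
    V = sum over paired levels (S_{1-tau} - S_tau) for tau < 0.5, with its
    exact null variance from the joint score covariance
    Cov(S_a, S_b) = (min(a,b) - ab) ||G*||^2 / n.
iQTL
    ordinary least squares of the rank-inverse-normal-transformed
    phenotype on genotype, an interacting factor, and their product
    (MAF > 0.05 filter applied), with amplifying / counteracting /
    uncertain directionality classes.

Hierarchical correction: Benjamini-Hochberg on per-gene lead Bonferroni
p-values, then a data-driven variant threshold t* = max lead Bonferroni p
among significant genes; pairs from significant genes with within-gene
Bonferroni p <= t* are declared significant.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import DosageMatrix, normalize_chrom
from .quantile_core import (
    QuantileGrid,
    RankScoreResult,
    cauchy_combine,
    fit_quantile_null,
    projection_basis,
    project_out,
    rank_score_scan,
)

logger = logging.getLogger(__name__)

__all__ = [
    "CisWindow",
    "PairResult",
    "HierarchicalCall",
    "InteractionFit",
    "VarianceTestResult",
    "build_cis_windows",
    "map_xqtl",
    "map_qqtl",
    "map_vqtl",
    "map_iqtl",
    "classify_iqtl_direction",
    "hierarchical_correct",
    "rank_inverse_normal",
]


@dataclass(frozen=True)
class CisWindow:
    gene_id: str
    chrom: str
    start: int
    end: int

    def contains(self, chrom: str, pos: int) -> bool:
        """Variant positions are 1-based; the window is 0-based half-open."""
        return normalize_chrom(chrom) == normalize_chrom(self.chrom) and (
            self.start <= pos - 1 < self.end
        )


@dataclass
class PairResult:
    gene_id: str
    variant_id: str
    method: str  # xqtl | qqtl | vqtl | iqtl
    statistic: float
    p_nominal: float
    beta: float = float("nan")
    p_bonf_within_gene: float = float("nan")
    per_tau_p: np.ndarray | None = None
    per_tau_score: np.ndarray | None = None
    testable: bool = True


@dataclass
class VarianceTestResult:
    gene_id: str
    variant_id: str
    V: float
    var_V: float
    z: float
    p: float
    testable: bool = True


@dataclass
class InteractionFit:
    gene_id: str
    variant_id: str
    beta0: float
    betaG: float
    betaF: float
    betaI: float
    pG: float
    pF: float
    pI: float
    direction: str = "uncertain"
    testable: bool = True


@dataclass
class HierarchicalCall:
    gene_q: dict[str, float]
    significant_genes: list[str]
    t_star: float | None
    significant_pairs: list[tuple[str, str]]
    pair_table: pd.DataFrame

    def is_significant_pair(self, gene_id: str, variant_id: str) -> bool:
        return (gene_id, variant_id) in set(self.significant_pairs)


# ---------------------------------------------------------------------------
# cis-windows
# ---------------------------------------------------------------------------


def build_cis_windows(
    genes: list[tuple[str, str, int, int]],
    tadb: pd.DataFrame | None = None,
    span: int = 2_000_000,
    chrom_lengths: dict[str, int] | None = None,
) -> list[CisWindow]:
    """TSS-centered ``span`` windows, replaced by the enclosing TAD interval
    when that interval is longer; always extended to contain the gene body;
    clipped at chromosome bounds when lengths are provided."""
    windows = []
    for gid, chrom, start, end in genes:
        tss = int(start)
        half = span // 2
        lo, hi = tss - half, tss + half
        if tadb is not None:
            sub = tadb[tadb["chrom"] == normalize_chrom(chrom)]
            if sub.empty:
                logger.info("gene %s: chromosome %s absent from TADB; "
                            "falling back to %d bp span", gid, chrom, span)
            else:
                enclosing = sub[(sub["start"] <= tss) & (tss < sub["end"])]
                if not enclosing.empty:
                    iv = enclosing.iloc[0]
                    if iv["end"] - iv["start"] > span:
                        lo, hi = int(iv["start"]), int(iv["end"])
        lo = min(lo, int(start))
        hi = max(hi, int(end))
        lo = max(lo, 0)
        if chrom_lengths:
            L = chrom_lengths.get(normalize_chrom(chrom))
            if L is not None:
                hi = min(hi, int(L))
        windows.append(CisWindow(gid, chrom, lo, hi))
    return windows


def variants_in_window(dm: DosageMatrix, window: CisWindow) -> np.ndarray:
    return np.array(
        [j for j, v in enumerate(dm.variants) if window.contains(v.chrom, v.pos)],
        dtype=int,
    )


# ---------------------------------------------------------------------------
# xQTL: OLS scan
# ---------------------------------------------------------------------------


def _ols_scan(Y: np.ndarray, G: np.ndarray, C: np.ndarray | None):
    """Per-column OLS slope and two-sided t-test with covariates projected
    out (Frisch-Waugh); returns (beta, t, p, testable)."""
    Y = np.asarray(Y, dtype=float)
    G = np.atleast_2d(np.asarray(G, dtype=float))
    n = Y.size
    if G.shape[0] != n:
        G = G.T
    Q = projection_basis(C, n)
    y_star = project_out(Y[:, None], Q)[:, 0]
    G_star = project_out(G, Q)
    gg = np.einsum("ij,ij->j", G_star, G_star)
    testable = gg > 1e-10 * np.maximum(np.einsum("ij,ij->j", G, G), 1.0)
    gg_safe = np.where(testable, gg, 1.0)
    beta = (G_star.T @ y_star) / gg_safe
    df = n - Q.shape[1] - 1
    rss = float(y_star @ y_star) - beta**2 * gg_safe
    rss = np.maximum(rss, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(rss / df / gg_safe)
        t = np.where(se > 0, beta / np.where(se > 0, se, 1.0), np.inf * np.sign(beta))
    p = 2.0 * stats.t.sf(np.abs(t), df)
    p = np.where(np.isfinite(t), p, np.where(testable, np.finfo(float).tiny, np.nan))
    beta = np.where(testable, beta, np.nan)
    t = np.where(testable, t, np.nan)
    p = np.where(testable, p, np.nan)
    return beta, t, p, testable


def map_xqtl(
    gene_id: str,
    Y: np.ndarray,
    G_window: DosageMatrix,
    C: np.ndarray | None,
) -> list[PairResult]:
    beta, t, p, testable = _ols_scan(Y, G_window.dosages, C)
    return [
        PairResult(
            gene_id=gene_id,
            variant_id=v.id,
            method="xqtl",
            statistic=float(t[j]) if testable[j] else float("nan"),
            p_nominal=float(p[j]) if testable[j] else float("nan"),
            beta=float(beta[j]) if testable[j] else float("nan"),
            testable=bool(testable[j]),
        )
        for j, v in enumerate(G_window.variants)
    ]


# ---------------------------------------------------------------------------
# qQTL: rank-score scan
# ---------------------------------------------------------------------------


def fit_null_models(
    Y: np.ndarray,
    C: np.ndarray | None,
    grid: QuantileGrid | None = None,
    solver: str = "fn",
):
    grid = grid or QuantileGrid.mapping()
    return [fit_quantile_null(Y, C, float(tau), solver=solver) for tau in grid]


def map_qqtl(
    gene_id: str,
    Y: np.ndarray,
    G_window: DosageMatrix,
    C: np.ndarray | None,
    grid: QuantileGrid | None = None,
    null_fits=None,
    solver: str = "fn",
) -> tuple[list[PairResult], RankScoreResult]:
    """Rank-score scan over the grid with Cauchy combination per variant.

    The covariate-only null model is fitted once per quantile level and
    reused across all variants in the window. The returned
    :class:`RankScoreResult` is shared with :func:`map_vqtl`.
    """
    grid = grid or QuantileGrid.mapping()
    if null_fits is None:
        null_fits = fit_null_models(Y, C, grid, solver=solver)
    scan = rank_score_scan(G_window.dosages, null_fits, C)
    results = []
    for j, v in enumerate(G_window.variants):
        ok = bool(scan.testable[j])
        results.append(
            PairResult(
                gene_id=gene_id,
                variant_id=v.id,
                method="qqtl",
                statistic=float("nan"),
                p_nominal=float(scan.combined_p[j]) if ok else float("nan"),
                per_tau_p=scan.pvalues[:, j].copy() if ok else None,
                per_tau_score=scan.score[:, j].copy() if ok else None,
                testable=ok,
            )
        )
    return results, scan


# ---------------------------------------------------------------------------
# vQTL: variance contrast from rank scores
# ---------------------------------------------------------------------------


def variance_contrast_vector(taus: np.ndarray) -> np.ndarray:
    """Contrast c with V = c'S = sum_{tau<0.5} (S_{1-tau} - S_tau); levels
    without a mirrored partner (and tau = 0.5) get weight 0."""
    taus = np.asarray(taus, dtype=float)
    c = np.zeros(taus.size)
    for i, tau in enumerate(taus):
        if tau < 0.5:
            j = np.argmin(np.abs(taus - (1 - tau)))
            if abs(taus[j] - (1 - tau)) < 1e-9:
                c[i] -= 1.0
                c[j] += 1.0
    return c


def map_vqtl(
    gene_id: str,
    Y: np.ndarray,
    G_window: DosageMatrix,
    C: np.ndarray | None,
    grid: QuantileGrid | None = None,
    scan: RankScoreResult | None = None,
    null_fits=None,
    solver: str = "fn",
) -> list[VarianceTestResult]:
    """QUAIL-inspired variance-QTL test.

    Aggregates the upper-minus-lower tail rank-score contrast; under the
    null Cov(S_a, S_b) = (min(a,b) - a b) ||G*||^2 / n exactly, so the
    contrast variance is closed-form. Shares per-tau scores with the qQTL
    scan bit-for-bit when ``scan`` is passed.
    """
    grid = grid or QuantileGrid.mapping()
    if null_fits is None:
        if scan is not None:
            raise ValueError("map_vqtl needs the null fits, not just the scan")
        null_fits = fit_null_models(Y, C, grid, solver=solver)
    if scan is None:
        scan = rank_score_scan(G_window.dosages, null_fits, C)
    taus = scan.taus
    c = variance_contrast_vector(taus)
    K = np.minimum.outer(taus, taus) - np.outer(taus, taus)
    quad = float(c @ K @ c)  # multiplies ||G*||^2 / n
    n = Y.size
    G = np.asarray(G_window.dosages, dtype=float)
    Q = projection_basis(C, n)
    G_star = project_out(G, Q)
    y_star = project_out(np.asarray(Y, float)[:, None], Q)[:, 0]
    norm2 = np.einsum("ij,ij->j", G_star, G_star)
    norm2_safe = np.where(norm2 > 0, norm2, 1.0)
    bhat = (G_star.T @ y_star) / norm2_safe  # per-variant OLS mean effect
    # mean-recentered rank-score contrast: the indicator threshold absorbs
    # each variant's fitted location effect, so strong mean effects do not
    # leak into the variance statistic (the raw contrast only cancels them
    # to first order when the genotype distribution is skewed)
    shift = G_star * bhat[None, :]  # (n, m)
    V = np.zeros(G.shape[1])
    for k, f in enumerate(null_fits):
        if c[k] == 0.0:
            continue
        phi = f.tau - (f.residuals[:, None] < shift)
        V += c[k] * np.einsum("ij,ij->j", G_star, phi)
    V /= math.sqrt(n)
    var_V = quad * norm2 / n
    out = []
    for j, v in enumerate(G_window.variants):
        if not scan.testable[j] or var_V[j] <= 0:
            out.append(VarianceTestResult(gene_id, v.id, math.nan, math.nan,
                                          math.nan, math.nan, testable=False))
            continue
        z = float(V[j]) / math.sqrt(var_V[j])
        p = 2.0 * stats.norm.sf(abs(z))
        out.append(VarianceTestResult(gene_id, v.id, float(V[j]),
                                      float(var_V[j]), z, float(p)))
    return out


# ---------------------------------------------------------------------------
# iQTL: interaction scan
# ---------------------------------------------------------------------------


def rank_inverse_normal(y: np.ndarray, offset: float = 3.0 / 8.0) -> np.ndarray:
    """Rank-based inverse-normal transform with the Blom offset (c = 3/8).

    Ties receive average ranks; deterministic.
    """
    y = np.asarray(y, dtype=float)
    n = y.size
    ranks = stats.rankdata(y, method="average")
    return stats.norm.ppf((ranks - offset) / (n - 2 * offset + 1))


def classify_iqtl_direction(fit: InteractionFit, alpha_main: float = 0.05) -> str:
    """Amplifying when main and interaction effects share sign, counteracting
    when they oppose; uncertain when the main effect is not nominally
    significant (pG > alpha_main)."""
    if not np.isfinite(fit.pG) or fit.pG > alpha_main:
        return "uncertain"
    return "amplifying" if np.sign(fit.betaG) == np.sign(fit.betaI) else "counteracting"


def map_iqtl(
    gene_id: str,
    Y: np.ndarray,
    G_window: DosageMatrix,
    F: np.ndarray,
    C: np.ndarray | None,
    maf_min: float = 0.05,
    transform: bool = True,
) -> list[InteractionFit]:
    """OLS interaction scan Y ~ G + F + GxF + C on the rank-inverse-normal
    transformed phenotype, restricted to variants with MAF > ``maf_min``."""
    F = np.asarray(F, dtype=float)
    if np.all(F == F[0]):
        raise ValueError("interaction factor is constant")
    Yt = rank_inverse_normal(Y) if transform else np.asarray(Y, dtype=float)
    n = Yt.size
    if C is None or np.size(C) == 0:
        Cmat = np.empty((n, 0))
    else:
        Cmat = np.atleast_2d(np.asarray(C, dtype=float))
        if Cmat.shape[0] != n:
            Cmat = Cmat.T
    out = []
    for j, v in enumerate(G_window.variants):
        if not (v.maf > maf_min):
            continue
        g = G_window.dosages[:, j]
        X = np.column_stack([np.ones(n), g, F, g * F, Cmat])
        if np.linalg.matrix_rank(X) < X.shape[1]:
            out.append(InteractionFit(gene_id, v.id, *([math.nan] * 7),
                                      testable=False))
            continue
        XtX = X.T @ X
        coef = np.linalg.solve(XtX, X.T @ Yt)
        resid = Yt - X @ coef
        df = n - X.shape[1]
        s2 = float(resid @ resid) / df
        se = np.sqrt(np.diag(np.linalg.inv(XtX)) * s2)
        with np.errstate(divide="ignore", invalid="ignore"):
            tvals = coef / se
        pvals = 2.0 * stats.t.sf(np.abs(tvals), df)
        fit = InteractionFit(
            gene_id=gene_id,
            variant_id=v.id,
            beta0=float(coef[0]),
            betaG=float(coef[1]),
            betaF=float(coef[2]),
            betaI=float(coef[3]),
            pG=float(pvals[1]),
            pF=float(pvals[2]),
            pI=float(pvals[3]),
        )
        fit.direction = classify_iqtl_direction(fit)
        out.append(fit)
    return out


# ---------------------------------------------------------------------------
# Hierarchical multiple-testing correction
# ---------------------------------------------------------------------------


def _bh_qvalues(p: np.ndarray) -> np.ndarray:
    from statsmodels.stats.multitest import multipletests

    return multipletests(p, method="fdr_bh")[1]


def flat_bh_correct(
    pairs_by_gene: dict[str, list[tuple[str, float]]],
    fdr: float = 0.05,
) -> HierarchicalCall:
    """Flat Benjamini-Hochberg across all pairs, as an alternative to the
    two-stage procedure (no gene stage; t_star reported as None)."""
    rows = [
        {"gene_id": gid, "variant_id": vid, "p_nominal": p}
        for gid, pairs in pairs_by_gene.items()
        for vid, p in pairs
        if np.isfinite(p)
    ]
    table = pd.DataFrame(rows, columns=["gene_id", "variant_id", "p_nominal"])
    if table.empty:
        table["significant"] = []
        return HierarchicalCall({}, [], None, [], table)
    q = _bh_qvalues(table["p_nominal"].to_numpy())
    table["q_value"] = q
    table["significant"] = q <= fdr
    sig_pairs = [(r.gene_id, r.variant_id) for r in table.itertuples()
                 if r.significant]
    sig_genes = sorted({g for g, _ in sig_pairs})
    return HierarchicalCall({}, sig_genes, None, sig_pairs, table)


def hierarchical_correct(
    pairs_by_gene: dict[str, list[tuple[str, float]]],
    fdr: float = 0.05,
) -> HierarchicalCall:
    """Two-stage hierarchical FDR control.

    ``pairs_by_gene`` maps gene id -> list of (variant_id, p_nominal) for
    all testable variants of that gene. Stage 1 applies BH across genes to
    the per-gene lead Bonferroni p-values at level ``fdr``. Stage 2 sets
    t* = max lead Bonferroni p among significant genes and declares a pair
    significant iff its gene is significant and its within-gene Bonferroni
    p-value is <= t* (the boundary gene's own lead variant thus passes).
    """
    genes, leads, rows = [], [], []
    for gid, pairs in pairs_by_gene.items():
        ps = [(vid, p) for vid, p in pairs if np.isfinite(p)]
        if not ps:
            continue
        m_g = len(ps)
        bonf = [(vid, min(1.0, p * m_g), p) for vid, p in ps]
        lead = min(b[1] for b in bonf)
        genes.append(gid)
        leads.append(lead)
        rows.extend(
            {"gene_id": gid, "variant_id": vid, "p_nominal": p,
             "p_bonf_within_gene": pb}
            for vid, pb, p in bonf
        )
    table = pd.DataFrame(rows, columns=["gene_id", "variant_id", "p_nominal",
                                        "p_bonf_within_gene"])
    if not genes:
        return HierarchicalCall({}, [], None, [], table)
    q = _bh_qvalues(np.array(leads))
    gene_q = dict(zip(genes, (float(x) for x in q)))
    sig_genes = [g for g, qq in gene_q.items() if qq <= fdr]
    if not sig_genes:
        table["significant"] = False
        return HierarchicalCall(gene_q, [], None, [], table)
    lead_by_gene = dict(zip(genes, leads))
    t_star = max(lead_by_gene[g] for g in sig_genes)
    sig_set = set(sig_genes)
    table["significant"] = table["gene_id"].isin(sig_set) & (
        table["p_bonf_within_gene"] <= t_star
    )
    sig_pairs = [
        (r.gene_id, r.variant_id)
        for r in table.itertuples()
        if r.significant
    ]
    return HierarchicalCall(gene_q, sig_genes, float(t_star), sig_pairs, table)
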
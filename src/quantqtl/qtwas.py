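"""Quantile TWAS: quantile-specific weight training, quantile-region
integration, and LD-aware association against GWAS summary statistics.

Per gene, significant quantile-QTL variants are LD-pruned (greedy,
r^2 < 0.8), and a joint quantile regression of expression on the pruned
variant set plus covariates is fitted on a fine 99-level grid, giving a
p x 99 weight matrix. Weights are summed within quantile regions — three
fixed thirds of the grid, or data-driven contiguous regions found by
modularity-guided agglomerative clustering of the weight correlation
structure. For each region k with integrated weight w_k, the association
statistic against a GWAS with z-scores z and LD matrix Sigma is

    Z_k = w_k' z / sqrt(w_k' Sigma w_k)  ~  N(0, 1) under the null,

and region p-values are Cauchy-combined into one gene-level p-value.

Genotypes are standardized (mean 0, variance 1) before weight training, and
the LD matrix is a correlation matrix of the same standardized dosages, so
the two scales are self-consistent in Z_k.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .io_formats import DosageMatrix, LdMatrix
from .quantile_core import QuantileGrid, cauchy_combine, fit_quantile_joint

logger = logging.getLogger(__name__)

__all__ = [
    "WeightMatrix",
    "QuantileRegionSet",
    "QtwasResult",
    "select_and_prune",
    "estimate_weights",
    "make_fixed_regions",
    "make_dynamic_regions",
    "integrate_weights",
    "region_assoc",
    "gene_assoc",
]


@dataclass
class WeightMatrix:
    gene_id: str
    variant_ids: list[str]
    taus: np.ndarray  # (99,)
    weights: np.ndarray  # (p, n_tau)

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.shape != (len(self.variant_ids), self.taus.size):
            raise ValueError("weight matrix shape mismatch")
        if np.any(~np.isfinite(self.weights)):
            raise ValueError("non-finite weights")


@dataclass
class QuantileRegionSet:
    """Disjoint contiguous index regions covering the whole tau grid."""

    regions: list[np.ndarray]  # index arrays into the tau grid
    method: str  # fixed | dynamic
    n_levels: int = 99

    def __post_init__(self):
        idx = np.concatenate(self.regions) if self.regions else np.array([], int)
        if sorted(idx.tolist()) != list(range(self.n_levels)):
            raise ValueError("regions must partition all quantile levels")
        for r in self.regions:
            r = np.sort(np.asarray(r))
            if r.size and not np.array_equal(np.diff(r), np.ones(r.size - 1, int)):
                raise ValueError("regions must be contiguous in tau")

    @property
    def K(self) -> int:
        return len(self.regions)


@dataclass
class QtwasResult:
    gene_id: str
    region_Z: np.ndarray
    region_p: np.ndarray
    combined_p: float
    significant: bool = False


def select_and_prune(
    sig_variant_pairs: list[tuple[str, float]],
    ld: LdMatrix,
    r2: float = 0.8,
) -> list[str]:
    """Greedy prune of significant qQTL variants against the LD panel.

    Variants absent from the panel are dropped (logged) — qTWAS needs the
    panel LD for every retained variant.
    """
    panel = set(ld.ids)
    present = [(v, p) for v, p in sig_variant_pairs if v in panel]
    dropped = [v for v, _ in sig_variant_pairs if v not in panel]
    if dropped:
        logger.info("dropped %d variant(s) absent from LD panel: %s",
                    len(dropped), dropped[:5])
    if not present:
        return []
    from .qtl_classify import ld_clump

    return ld_clump(present, ld, r2=r2)


def estimate_weights(
    gene_id: str,
    Y: np.ndarray,
    G_final: DosageMatrix,
    C: np.ndarray | None,
    grid: QuantileGrid | None = None,
    standardize: bool = True,
    solver: str = "fn",
) -> WeightMatrix:
    """Joint quantile regression weights over the 99-level grid.

    Rank-deficient variant blocks are resolved by deterministically
    dropping offending columns in variant-id order (logged).
    """
    grid = grid or QuantileGrid.weights()
    D = G_final.dosages.copy()
    ids = G_final.variant_ids()
    if standardize:
        D = (D - D.mean(axis=0)) / D.std(axis=0)
    n = D.shape[0]
    if C is None or np.size(C) == 0:
        Cmat = np.empty((n, 0))
    else:
        Cmat = np.atleast_2d(np.asarray(C, dtype=float))
        if Cmat.shape[0] != n:
            Cmat = Cmat.T
    # deterministic greedy rank filter (by id order)
    base = np.column_stack([np.ones(n), Cmat])
    keep: list[int] = []
    cur = base
    for j in range(D.shape[1]):
        cand = np.column_stack([cur, D[:, j]])
        if np.linalg.matrix_rank(cand) == cand.shape[1]:
            keep.append(j)
            cur = cand
        else:
            logger.info("gene %s: dropping collinear variant %s", gene_id, ids[j])
    if not keep:
        raise ValueError(f"gene {gene_id}: no linearly independent variants")
    D = D[:, keep]
    ids = [ids[j] for j in keep]
    W = fit_quantile_joint(Y, D, Cmat if Cmat.size else None, grid, solver=solver)
    return WeightMatrix(gene_id, ids, grid.taus.copy(), W)


def make_fixed_regions(n_levels: int = 99) -> QuantileRegionSet:
    """Three fixed thirds of the grid: lower tau in [0.01, 0.33], middle
    [0.34, 0.66], upper [0.67, 0.99] (33 levels each on the default grid)."""
    k = n_levels // 3
    regions = [
        np.arange(0, k),
        np.arange(k, 2 * k),
        np.arange(2 * k, n_levels),
    ]
    return QuantileRegionSet(regions, "fixed", n_levels)


def _column_similarity(W: np.ndarray) -> np.ndarray:
    """Pearson correlation between per-tau weight columns; for a single
    variant (p = 1) columns are scalars, so similarity falls back to sign
    agreement (+1 same sign, -1 opposite)."""
    p, T = W.shape
    if p >= 2:
        sd = W.std(axis=0)
        const = sd < 1e-14
        with np.errstate(invalid="ignore", divide="ignore"):
            R = np.corrcoef(W, rowvar=False)
        R = np.where(np.isfinite(R), R, 0.0)
        R = np.clip((R + R.T) / 2, -1, 1)
        # constant columns: similar to each other, neutral to the rest
        R[const, :] = 0.0
        R[:, const] = 0.0
        R[np.ix_(const, const)] = 1.0
        np.fill_diagonal(R, 1.0)
        return R
    w = W[0]
    s = np.sign(w)
    s[s == 0] = 1.0
    return np.outer(s, s)


def make_dynamic_regions(
    W: WeightMatrix,
    k_max: int = 10,
    min_width: int = 3,
    graph_threshold: float = 0.0,
) -> QuantileRegionSet:
    """Data-driven contiguous quantile regions.

    Agglomerative clustering restricted to merges of adjacent regions, with
    average inter-region similarity (Pearson correlation of per-tau weight
    vectors) as the linkage; the partition (K between 1 and ``k_max``, every
    region at least ``min_width`` levels wide) maximizing Newman modularity
    of the thresholded similarity graph is returned. Degenerate weight
    matrices (all columns identical) collapse to K = 1.
    """
    import networkx as nx

    T = W.taus.size
    R = _column_similarity(W.weights)
    if np.allclose(W.weights, W.weights[:, [0]], atol=1e-14):
        return QuantileRegionSet([np.arange(T)], "dynamic", T)
    # similarity graph for modularity scoring (edges above threshold)
    G = nx.Graph()
    G.add_nodes_from(range(T))
    for i in range(T):
        for j in range(i + 1, T):
            if R[i, j] > graph_threshold:
                G.add_edge(i, j, weight=float(R[i, j]))
    # agglomerative merging of adjacent blocks
    blocks = [np.array([i]) for i in range(T)]
    candidates: list[list[np.ndarray]] = []

    def record(bs):
        if len(bs) <= k_max and all(b.size >= min_width for b in bs):
            candidates.append([b.copy() for b in bs])

    record(blocks)
    while len(blocks) > 1:
        best, best_sim = None, -np.inf
        for i in range(len(blocks) - 1):
            sim = float(R[np.ix_(blocks[i], blocks[i + 1])].mean())
            if sim > best_sim:
                best_sim, best = sim, i
        i = best
        blocks = blocks[:i] + [np.concatenate([blocks[i], blocks[i + 1]])] + blocks[i + 2:]
        record(blocks)
    if not candidates:
        return QuantileRegionSet([np.arange(T)], "dynamic", T)
    if G.number_of_edges() == 0:
        return QuantileRegionSet([np.arange(T)], "dynamic", T)

    def modularity(bs):
        return nx.algorithms.community.modularity(
            G, [set(b.tolist()) for b in bs], weight="weight"
        )

    best = max(candidates, key=modularity)
    return QuantileRegionSet(best, "dynamic", T)


def integrate_weights(W: WeightMatrix, regions: QuantileRegionSet) -> list[np.ndarray]:
    """Per-region integrated weights: elementwise sums over region members."""
    return [W.weights[:, r].sum(axis=1) for r in regions.regions]


def region_assoc(
    omega_k: np.ndarray,
    z_gwas: np.ndarray,
    sigma: LdMatrix | np.ndarray,
    ridge: float = 1e-6,
) -> tuple[float, float]:
    """Region association statistic Z_k = w'z / sqrt(w' Sigma w), two-sided p.

    A near-singular denominator (w' Sigma w <= 1e-10) falls back to
    Sigma + ridge*I (logged).
    """
    w = np.asarray(omega_k, dtype=float).ravel()
    z = np.asarray(z_gwas, dtype=float).ravel()
    S = sigma.sigma if isinstance(sigma, LdMatrix) else np.asarray(sigma, dtype=float)
    if w.size != z.size or S.shape != (w.size, w.size):
        raise ValueError("dimension mismatch in region association")
    denom = float(w @ S @ w)
    if denom <= 1e-10:
        logger.info("near-singular quadratic form; applying ridge %.1e", ridge)
        denom = float(w @ (S + ridge * np.eye(w.size)) @ w)
        if denom <= 0:
            return (float("nan"), float("nan"))
    Z = float(w @ z) / math.sqrt(denom)
    p = 2.0 * stats.norm.sf(abs(Z))
    return (Z, float(p))


def gene_assoc(
    gene_id: str,
    region_results: list[tuple[float, float]],
    n_tests_in_family: int = 1,
    alpha: float = 0.05,
) -> QtwasResult:
    """Cauchy-combine region p-values into a gene-level p-value.

    ``significant`` applies the Bonferroni threshold alpha / family size
    (family = number of gene-context tests in the configured analysis).
    """
    if not region_results:
        raise ValueError("no region results to combine")
    Z = np.array([r[0] for r in region_results])
    p = np.array([r[1] for r in region_results])
    ok = np.isfinite(p)
    if not ok.any():
        raise ValueError("all region p-values undefined")
    combined = cauchy_combine(p[ok])
    return QtwasResult(
        gene_id=gene_id,
        region_Z=Z,
        region_p=p,
        combined_p=combined,
        significant=bool(combined < alpha / max(n_tests_in_family, 1)),
    )
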
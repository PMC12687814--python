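"""Characterization of quantile-QTL discoveries relative to linear QTLs.

Variant-gene pairs significant in at least one scan are partitioned into
qQTL-only, xQTL-only, and shared categories; shared pairs are split into
homogeneous and heterogeneous by a Chatterjee correlation test of the
per-quantile slope estimates against the quantile level. A heterogeneity
index log|sd(beta)/mean(beta)| summarizes how much the quantile-specific
effects vary, and tail labels flag pairs whose significance is confined to
the lower (tau < 0.3) or upper (tau > 0.7) part of the distribution.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .io_formats import LdMatrix
from .qtl_mapping import HierarchicalCall
from .quantile_core import chatterjee_xi

logger = logging.getLogger(__name__)

__all__ = [
    "QtlCategory",
    "HET_GRID",
    "categorize_pairs",
    "categorize_genes",
    "ld_clump",
    "test_heterogeneity",
    "heterogeneity_index",
    "label_tail_specific",
]

#: default grid for the per-pair heterogeneity characterization
HET_GRID = np.round(np.arange(1, 10) * 0.10, 2)  # 0.10 ... 0.90


@dataclass
class QtlCategory:
    gene_id: str
    variant_id: str
    category: str  # qqtl_only | xqtl_only | shared_homogeneous | shared_heterogeneous
    xi: float = float("nan")
    p_xi: float = float("nan")
    het_index: float = float("nan")
    tail_label: str = "none"


def test_heterogeneity(
    betas_by_tau: np.ndarray,
    taus: np.ndarray | None = None,
    alpha: float = 0.05,
) -> tuple[float, float, bool]:
    """Chatterjee test of dependence of quantile-specific slopes on tau.

    Returns ``(xi, p_xi, flag)`` with ``flag = p_xi < alpha``. Any number
    of slope estimates >= 3 is accepted; the default characterization grid
    is tau = 0.10 ... 0.90.
    """
    betas = np.asarray(betas_by_tau, dtype=float).ravel()
    if np.any(~np.isfinite(betas)):
        return (float("nan"), float("nan"), False)
    if taus is None:
        if betas.size != HET_GRID.size:
            taus = np.linspace(0.1, 0.9, betas.size)
        else:
            taus = HET_GRID
    xi, p = chatterjee_xi(np.asarray(taus, dtype=float), betas)
    return (xi, p, bool(p < alpha))


def heterogeneity_index(betas_by_tau: np.ndarray) -> float:
    """Natural log of |sd / mean| of the per-quantile slopes.

    sd uses the sample convention (ddof=1). A mean within 1e-12 of zero
    yields +inf (maximal heterogeneity); sd = 0 yields -inf (perfectly
    homogeneous).
    """
    betas = np.asarray(betas_by_tau, dtype=float).ravel()
    if betas.size < 2:
        raise ValueError("need at least 2 slope estimates")
    sd = float(np.std(betas, ddof=1))
    mean = float(np.mean(betas))
    if sd == 0.0:
        return float("-inf")
    if abs(mean) <= 1e-12:
        return float("inf")
    return math.log(abs(sd / mean))


def label_tail_specific(
    per_tau_p: np.ndarray,
    taus: np.ndarray,
    threshold: float,
    lower: float = 0.3,
    upper: float = 0.7,
) -> str:
    """'lower_only' when every significant level lies at tau < 0.3 (and at
    least one is significant); 'upper_only' symmetric; otherwise 'none'."""
    p = np.asarray(per_tau_p, dtype=float)
    taus = np.asarray(taus, dtype=float)
    sig = np.isfinite(p) & (p < threshold)
    if not sig.any():
        return "none"
    st = taus[sig]
    if np.all(st < lower):
        return "lower_only"
    if np.all(st > upper):
        return "upper_only"
    return "none"


def ld_clump(
    pairs: list[tuple[str, float]],
    ld: LdMatrix,
    r2: float = 0.8,
) -> list[str]:
    """Greedy LD clumping: sort variants by p ascending, keep a variant
    unless its r^2 with an already-kept variant is >= ``r2``. Variants
    absent from the LD matrix are kept with a warning."""
    order = sorted(pairs, key=lambda t: (t[1], t[0]))
    pos = {v: i for i, v in enumerate(ld.ids)}
    kept: list[str] = []
    kept_idx: list[int] = []
    for vid, _ in order:
        i = pos.get(vid)
        if i is None:
            logger.warning("variant %s absent from LD matrix; kept", vid)
            kept.append(vid)
            continue
        if any(ld.sigma[i, j] ** 2 >= r2 for j in kept_idx):
            continue
        kept.append(vid)
        kept_idx.append(i)
    return kept


def categorize_pairs(
    qqtl_call: HierarchicalCall,
    xqtl_call: HierarchicalCall,
    betas_by_pair: dict[tuple[str, str], np.ndarray] | None = None,
    het_taus: np.ndarray | None = None,
    het_alpha: float = 0.05,
) -> list[QtlCategory]:
    """Assign each pair significant in >= 1 scan to exactly one category.

    Both calls must have been computed on the same pair universe. When
    per-quantile slope estimates are supplied (``betas_by_pair``), shared
    pairs are split into shared_heterogeneous / shared_homogeneous by the
    Chatterjee test at ``het_alpha``; without slopes shared pairs default
    to shared_homogeneous with NaN statistics.
    """
    uni_q = set(map(tuple, qqtl_call.pair_table[["gene_id", "variant_id"]]
                    .itertuples(index=False, name=None)))
    uni_x = set(map(tuple, xqtl_call.pair_table[["gene_id", "variant_id"]]
                    .itertuples(index=False, name=None)))
    if uni_q != uni_x:
        bad = sorted(uni_q.symmetric_difference(uni_x))[:20]
        raise ValueError(f"pair universes differ between scans, e.g. {bad}")
    sig_q = set(qqtl_call.significant_pairs)
    sig_x = set(xqtl_call.significant_pairs)
    out = []
    for pair in sorted(sig_q | sig_x):
        gid, vid = pair
        betas = None if betas_by_pair is None else betas_by_pair.get(pair)
        xi = p_xi = het = float("nan")
        if betas is not None:
            xi, p_xi, _ = test_heterogeneity(betas, het_taus, het_alpha)
            het = heterogeneity_index(betas)
        if pair in sig_q and pair in sig_x:
            heterogeneous = np.isfinite(p_xi) and p_xi < het_alpha
            cat = "shared_heterogeneous" if heterogeneous else "shared_homogeneous"
        elif pair in sig_q:
            cat = "qqtl_only"
        else:
            cat = "xqtl_only"
        out.append(QtlCategory(gid, vid, cat, xi=xi, p_xi=p_xi, het_index=het))
    return out


def categorize_genes(
    qqtl_call: HierarchicalCall,
    xqtl_call: HierarchicalCall,
) -> dict[str, str]:
    """Gene-level categories: a gene is a qQTL (xQTL) gene when it harbors
    at least one significant pair in the corresponding scan."""
    q_genes = {g for g, _ in qqtl_call.significant_pairs}
    x_genes = {g for g, _ in xqtl_call.significant_pairs}
    out = {}
    for g in sorted(q_genes | x_genes):
        if g in q_genes and g in x_genes:
            out[g] = "shared"
        elif g in q_genes:
            out[g] = "qqtl_only"
        else:
            out[g] = "xqtl_only"
    return out
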
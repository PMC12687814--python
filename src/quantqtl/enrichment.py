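"""Excess-of-overlap (EOO) enrichment of variant-gene link sets, with
leave-one-chromosome-out jackknife errors and difference z-tests, and
hypergeometric gene-set over-representation (ORA).

EOO compares two sets of significant variant-gene (VG) links against the
overlap expected if the two selection processes were independent:

    EOO = (|VG1 n VG2| / T12) / ((|VG1|/T1) * (|VG2|/T2))

where T1, T2 are the pair universes tested by each method and T12 the
pairs tested by both. EOO > 1 means more overlap than expected under
independence. An annotation is treated as a pseudo-method whose
"significant" pairs are the tested pairs overlapping the annotation.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

from .io_formats import normalize_chrom

logger = logging.getLogger(__name__)

__all__ = [
    "EooResult",
    "OraResult",
    "overlap_annotation",
    "eoo",
    "eoo_loco_se",
    "eoo_diff_test",
    "ora",
]


@dataclass
class EooResult:
    eoo: float
    overlap: int
    n1: int
    n2: int
    t1: int
    t2: int
    t12: int
    se_loco: float = float("nan")
    defined: bool = True
    reason: str = ""


@dataclass
class OraResult:
    a: int  # |G n T|
    b: int  # |G \ T|
    c: int  # |T \ G|
    d: int  # |U \ (G u T)|
    enrichment: float
    p: float
    defined: bool = True


def overlap_annotation(
    pairs: pd.DataFrame,
    annotation: pd.DataFrame,
) -> np.ndarray:
    """Boolean mask of pairs whose variant position falls in an annotation
    interval.

    ``pairs`` needs columns chrom and pos (1-based); ``annotation`` is a
    BED-style frame (chrom, start, end; 0-based half-open). A variant at
    1-based position P overlaps an interval iff P-1 in [start, end).
    Chromosome names are normalized ('chr1' == '1').
    """
    trees: dict[str, IntervalTree] = {}
    for _, r in annotation.iterrows():
        trees.setdefault(normalize_chrom(r["chrom"]), IntervalTree()).addi(
            int(r["start"]), int(r["end"])
        )
    mask = np.zeros(len(pairs), dtype=bool)
    for i, (chrom, pos) in enumerate(zip(pairs["chrom"], pairs["pos"])):
        tree = trees.get(normalize_chrom(chrom))
        if tree is not None and tree.overlaps_point(int(pos) - 1):
            mask[i] = True
    return mask


def _eoo_from_counts(overlap, n1, n2, t1, t2, t12) -> tuple[float, bool, str]:
    if t1 <= 0 or t2 <= 0 or t12 <= 0:
        return (float("nan"), False, "empty tested universe")
    if n1 <= 0 or n2 <= 0:
        return (float("nan"), False, "empty significant set")
    return ((overlap / t12) / ((n1 / t1) * (n2 / t2)), True, "")


def eoo(
    sig1: np.ndarray,
    sig2: np.ndarray,
    tested1: np.ndarray | None = None,
    tested2: np.ndarray | None = None,
) -> EooResult:
    """Excess of overlap between two flag vectors over a shared pair index.

    ``sig1``/``sig2`` mark pairs significant by each method; ``tested1``/
    ``tested2`` mark pairs tested by each (default: all). Significant pairs
    are restricted to their tested universe.
    """
    sig1 = np.asarray(sig1, dtype=bool)
    sig2 = np.asarray(sig2, dtype=bool)
    N = sig1.size
    tested1 = np.ones(N, bool) if tested1 is None else np.asarray(tested1, bool)
    tested2 = np.ones(N, bool) if tested2 is None else np.asarray(tested2, bool)
    sig1 = sig1 & tested1
    sig2 = sig2 & tested2
    t12 = int((tested1 & tested2).sum())
    overlap = int((sig1 & sig2).sum())
    n1, n2 = int(sig1.sum()), int(sig2.sum())
    t1, t2 = int(tested1.sum()), int(tested2.sum())
    value, defined, reason = _eoo_from_counts(overlap, n1, n2, t1, t2, t12)
    return EooResult(value, overlap, n1, n2, t1, t2, t12,
                     defined=defined, reason=reason)


def eoo_loco_se(
    sig1: np.ndarray,
    sig2: np.ndarray,
    chroms: np.ndarray,
    tested1: np.ndarray | None = None,
    tested2: np.ndarray | None = None,
) -> float:
    """Leave-one-chromosome-out delete-one jackknife standard error of EOO:

        se^2 = (K-1)/K * sum_c (theta_{-c} - mean(theta_{-.}))^2
    """
    chroms = np.asarray([normalize_chrom(c) for c in np.asarray(chroms)])
    levels = sorted(set(chroms.tolist()))
    if len(levels) < 2:
        raise ValueError("LOCO jackknife needs >= 2 chromosomes")
    N = sig1.size if hasattr(sig1, "size") else len(sig1)
    tested1 = np.ones(N, bool) if tested1 is None else np.asarray(tested1, bool)
    tested2 = np.ones(N, bool) if tested2 is None else np.asarray(tested2, bool)
    thetas = []
    for c in levels:
        keep = chroms != c
        r = eoo(np.asarray(sig1)[keep], np.asarray(sig2)[keep],
                tested1[keep], tested2[keep])
        if not r.defined:
            raise ValueError(f"EOO undefined when dropping chromosome {c}")
        thetas.append(r.eoo)
    thetas = np.asarray(thetas)
    K = thetas.size
    return float(math.sqrt((K - 1) / K * np.sum((thetas - thetas.mean()) ** 2)))


def eoo_diff_test(
    e1: np.ndarray,
    se1: np.ndarray,
    e2: np.ndarray,
    se2: np.ndarray,
) -> pd.DataFrame:
    """Two-sided z-test of enrichment differences across annotations with
    Benjamini-Hochberg correction.

    Equal estimates give z = 0, p = 1; zero joint standard error with a
    non-zero difference gives an infinite-z sentinel (p = 0).
    """
    from statsmodels.stats.multitest import multipletests

    e1 = np.atleast_1d(np.asarray(e1, float))
    se1 = np.atleast_1d(np.asarray(se1, float))
    e2 = np.atleast_1d(np.asarray(e2, float))
    se2 = np.atleast_1d(np.asarray(se2, float))
    diff = e1 - e2
    denom = np.sqrt(se1**2 + se2**2)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(denom > 0, diff / np.where(denom > 0, denom, 1.0),
                     np.where(diff == 0, 0.0, np.sign(diff) * np.inf))
    p = np.where(np.isinf(z), 0.0, 2.0 * stats.norm.sf(np.abs(z)))
    p = np.where((denom == 0) & (diff == 0), 1.0, p)
    q = multipletests(p, method="fdr_bh")[1]
    return pd.DataFrame({"z": z, "p": p, "bh_q": q})


def ora(gene_set, term_set, universe) -> OraResult:
    """Hypergeometric over-representation of a gene set in a term.

    Enrichment is the 2x2 odds ratio a*d / (b*c) with
    a = |G n T|, b = |G \\ T|, c = |T \\ G|, d = |U \\ (G u T)|;
    the p-value is the upper-tail hypergeometric probability of >= a
    successes. A zero margin yields an undefined sentinel with p = 1.
    """
    U = set(universe)
    G = set(gene_set) & U
    T = set(term_set) & U
    if set(gene_set) - U or set(term_set) - U:
        raise ValueError("gene set and term must be subsets of the universe")
    a = len(G & T)
    b = len(G - T)
    c = len(T - G)
    d = len(U - (G | T))
    if len(G) == 0 or len(T) == 0 or len(G) == len(U) or len(T) == len(U):
        return OraResult(a, b, c, d, float("nan"), 1.0, defined=False)
    if b == 0 or c == 0:
        enr = float("inf") if a > 0 else 0.0
    else:
        enr = (a * d) / (b * c)
    if a == 0:
        enr = 0.0
    # P(X >= a), X ~ Hypergeom(|U|, |T|, |G|)
    p = float(stats.hypergeom.sf(a - 1, len(U), len(T), len(G)))
    return OraResult(a, b, c, d, enr, p)
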
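"""Monte-Carlo comparison of interaction-QTL, quantile-QTL, and linear-QTL
detection under a genotype-by-factor interaction model.

Data model, per individual i:

    Y_i = bG * G_i + bF * F_i + bI * G_i F_i + C_i' bC + eps_i

with genotype G and factor F drawn as Hardy-Weinberg dosages in {0,1,2}
(MAFs p_G = 0.1 and p_F = 0.15), 45 independent N(0,1) covariates, and
Gaussian residuals with variance 0.2667. The default grid crosses main
effects bG in {0, 0.15, 0.3} with interaction effects bI in
{0, +-0.1, ..., +-0.8}; bF = 0. Each replicate is analyzed three ways:

* iQTL: OLS interaction test on the rank-inverse-normal phenotype;
* qQTL: 19-level quantile rank-score test with Cauchy combination;
* xQTL: OLS slope t-test;

and, when the quantile test detects the variant, per-quantile slopes on
the tau = 0.10 ... 0.90 grid (17 levels, step 0.05) feed a Chatterjee
heterogeneity test. Detection and heterogeneity are evaluated at
alpha = 0.05 and the genome-wide 1e-6.

Every replicate is a pure function of (cell parameters, replicate seed);
seeds are derived from a master seed with numpy SeedSequence spawning.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .qtl_mapping import _ols_scan, rank_inverse_normal
from .quantile_core import (
    QuantileGrid,
    cauchy_combine,
    chatterjee_xi,
    fit_quantile_joint,
    fit_quantile_null,
    rank_score_scan,
)
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "SimConfig",
    "SimSummary",
    "run_replicate",
    "run_cell",
    "run_grid",
    "summarize_cells",
    "amplifying_cells",
    "strong_amplifying_both_rate",
    "amplifying_het_fraction",
]

#: Chatterjee slope grid: the 19-level mapping grid restricted to [0.10, 0.90]
HET_GRID_17 = np.round(np.arange(2, 19) * 0.05, 2)


@dataclass(frozen=True)
class SimConfig:
    """One cell (or the full grid) of the Monte-Carlo design."""

    n: int = 400
    p_g: float = 0.1
    p_f: float = 0.15
    beta_g: tuple = (0.0, 0.15, 0.3)
    beta_f: float = 0.0
    beta_i: tuple = tuple(
        np.round(np.concatenate([[0.0], np.arange(0.1, 0.81, 0.1),
                                 -np.arange(0.1, 0.81, 0.1)]), 2)
    )
    n_cov: int = 45
    resid_var: float = 0.2667
    resid_is_sd: bool = False  # sensitivity flag: treat resid_var as an SD
    beta_c_mode: str = "zero"  # 'zero' | 'random' (drawn once, N(0, 0.1^2))
    n_reps: int = 1000
    alphas: tuple = (0.05, 1e-6)
    seed: int = 0

    @property
    def sigma(self) -> float:
        return float(self.resid_var if self.resid_is_sd
                     else np.sqrt(self.resid_var))

    def beta_c(self) -> np.ndarray:
        if self.beta_c_mode == "zero":
            return np.zeros(self.n_cov)
        rng = np.random.default_rng(np.random.SeedSequence([self.seed, 977]))
        return rng.normal(scale=0.1, size=self.n_cov)


@dataclass
class SimSummary:
    """Aggregated proportions for a grid of cells."""

    cells: pd.DataFrame  # one row per (beta_g, beta_i, alpha)
    records: pd.DataFrame  # one row per replicate


def run_replicate(
    config: SimConfig,
    beta_g: float,
    beta_i: float,
    rep_seed,
    mapping_grid: QuantileGrid | None = None,
    het_grid: np.ndarray = HET_GRID_17,
    het_if_below: float = 0.05,
) -> dict:
    """Simulate one dataset and analyze it as iQTL, qQTL, and xQTL.

    The Chatterjee heterogeneity p-value is computed only when the
    Cauchy-combined quantile p-value falls below ``het_if_below`` (the
    loosest detection threshold in use); otherwise it is NaN.
    """
    grid = mapping_grid or QuantileGrid.mapping()
    rng = np.random.default_rng(rep_seed)
    n = config.n
    redraws = 0
    G = rng.binomial(2, config.p_g, size=n).astype(float)
    while G.std() == 0:
        redraws += 1
        G = rng.binomial(2, config.p_g, size=n).astype(float)
    F = rng.binomial(2, config.p_f, size=n).astype(float)
    while F.std() == 0:
        F = rng.binomial(2, config.p_f, size=n).astype(float)
    C = rng.normal(size=(n, config.n_cov))
    eps = rng.normal(scale=config.sigma, size=n)
    Y = (beta_g * G + config.beta_f * F + beta_i * G * F
         + C @ config.beta_c() + eps)

    # xQTL: OLS slope test
    _, _, p_x, _ = _ols_scan(Y, G[:, None], C)
    p_x = float(p_x[0])

    # qQTL: rank-score scan over the grid, Cauchy combined
    null_fits = [fit_quantile_null(Y, C, float(t)) for t in grid]
    scan = rank_score_scan(G[:, None], null_fits, C)
    p_q = float(scan.combined_p[0])

    # iQTL: interaction OLS on the rank-inverse-normal phenotype
    maf = min(G.mean() / 2, 1 - G.mean() / 2)
    Yt = rank_inverse_normal(Y)
    X = np.column_stack([np.ones(n), G, F, G * F, C])
    XtX = X.T @ X
    coef = np.linalg.solve(XtX, X.T @ Yt)
    resid = Yt - X @ coef
    df = n - X.shape[1]
    s2 = float(resid @ resid) / df
    se = np.sqrt(np.diag(np.linalg.inv(XtX)) * s2)
    tv = coef / se
    pv = 2.0 * stats.t.sf(np.abs(tv), df)
    p_i, p_gmain = float(pv[3]), float(pv[1])
    if p_gmain > 0.05:
        direction = "uncertain"
    elif np.sign(coef[1]) == np.sign(coef[3]):
        direction = "amplifying"
    else:
        direction = "counteracting"

    p_xi = float("nan")
    if np.isfinite(p_q) and p_q < het_if_below:
        betas = fit_quantile_joint(Y, G[:, None], C, het_grid)[0]
        _, p_xi = chatterjee_xi(het_grid, betas)

    return {
        "beta_g": beta_g,
        "beta_i": beta_i,
        "p_x": p_x,
        "p_q": p_q,
        "p_i": p_i if maf > 0.05 else float("nan"),
        "p_g_main": p_gmain,
        "direction": direction,
        "p_xi": p_xi,
        "redraws": redraws,
    }


def run_cell(
    config: SimConfig,
    beta_g: float,
    beta_i: float,
    n_reps: int | None = None,
    seed_seq: np.random.SeedSequence | None = None,
    het_if_below: float | None = None,
) -> pd.DataFrame:
    """Run all replicates of one (beta_g, beta_i) cell."""
    n_reps = n_reps or config.n_reps
    if seed_seq is None:
        seed_seq = np.random.SeedSequence(
            [config.seed, int(round(beta_g * 100)), int(round(beta_i * 100)) % 2**16]
        )
    het_below = max(config.alphas) if het_if_below is None else het_if_below
    children = seed_seq.spawn(n_reps)
    rows = [
        run_replicate(config, beta_g, beta_i, child, het_if_below=het_below)
        for child in children
    ]
    df = pd.DataFrame(rows)
    df["rep"] = np.arange(n_reps)
    return df


def run_grid(
    config: SimConfig,
    cells: list[tuple[float, float]] | None = None,
    n_reps: int | None = None,
    min_detections: int = 0,
    top_up_reps: int = 0,
) -> SimSummary:
    """Run the full beta_g x beta_i grid and aggregate.

    When ``min_detections`` > 0, cells with fewer quantile-test detections
    than that at the strictest alpha receive up to ``top_up_reps``
    additional replicates (seeded independently of the base run).
    """
    if cells is None:
        cells = [(g, i) for g in config.beta_g for i in config.beta_i]
    frames = []
    alpha_strict = min(config.alphas)
    for beta_g, beta_i in cells:
        df = run_cell(config, beta_g, beta_i, n_reps=n_reps)
        if min_detections > 0 and top_up_reps > 0:
            det = int((df["p_q"] < alpha_strict).sum())
            if det < min_detections:
                extra_seq = np.random.SeedSequence(
                    [config.seed, 7001, int(round(beta_g * 100)),
                     int(round(beta_i * 100)) % 2**16]
                )
                extra = run_cell(config, beta_g, beta_i, n_reps=top_up_reps,
                                 seed_seq=extra_seq)
                extra["rep"] += len(df)
                df = pd.concat([df, extra], ignore_index=True)
        frames.append(df)
    records = pd.concat(frames, ignore_index=True)
    return SimSummary(cells=summarize_cells(records, config.alphas),
                      records=records)


def summarize_cells(records: pd.DataFrame, alphas) -> pd.DataFrame:
    """Per-cell, per-alpha detection and classification proportions."""
    rows = []
    for (bg, bi), sub in records.groupby(["beta_g", "beta_i"], sort=True):
        nreps = len(sub)
        for alpha in alphas:
            det_q = sub["p_q"] < alpha
            det_x = sub["p_x"] < alpha
            det_i = sub["p_i"] < alpha
            shared = det_q & det_x
            n_qdet = int(det_q.sum())
            het = sub["p_xi"] < alpha
            rows.append(
                {
                    "beta_g": bg,
                    "beta_i": bi,
                    "alpha": alpha,
                    "n_reps": nreps,
                    "rate_iqtl": float(det_i.mean()),
                    "rate_qqtl": float(det_q.mean()),
                    "rate_xqtl": float(det_x.mean()),
                    "prop_shared": float(shared.mean()),
                    "prop_qqtl_only": float((det_q & ~det_x).mean()),
                    "prop_xqtl_only": float((det_x & ~det_q).mean()),
                    "prop_neither": float((~det_q & ~det_x).mean()),
                    "n_qqtl_detected": n_qdet,
                    "het_frac_given_qqtl": (
                        float((het & det_q).sum() / n_qdet) if n_qdet else float("nan")
                    ),
                }
            )
    return pd.DataFrame(rows)


def amplifying_cells(config: SimConfig) -> list[tuple[float, float]]:
    """Same-sign (beta_g, beta_i) cells with both effects non-zero."""
    return [
        (g, i)
        for g in config.beta_g
        for i in config.beta_i
        if g != 0 and i != 0 and np.sign(g) == np.sign(i)
    ]


def strong_amplifying_both_rate(
    cells: pd.DataFrame,
    alpha: float = 0.05,
    beta_g: float = 0.3,
    beta_i_set=(0.6, 0.7, 0.8),
) -> float:
    """Pooled proportion of replicates significant by BOTH the quantile and
    the linear test across the strong amplifying cells."""
    sel = cells[
        (cells["alpha"] == alpha)
        & (cells["beta_g"] == beta_g)
        & (cells["beta_i"].isin(list(beta_i_set)))
    ]
    if sel.empty:
        raise ValueError("strong amplifying cells missing from summary")
    w = sel["n_reps"].to_numpy(float)
    return float(np.average(sel["prop_shared"].to_numpy(float), weights=w))


def amplifying_het_fraction(
    cells: pd.DataFrame,
    alpha: float,
    config: SimConfig | None = None,
) -> float:
    """Average across amplifying cells of the fraction of quantile-test
    detections showing Chatterjee heterogeneity at the same threshold.

    Cells with zero detections at ``alpha`` carry no conditional fraction
    and are excluded from the average.
    """
    config = config or SimConfig()
    amp = set(amplifying_cells(config))
    sel = cells[cells["alpha"] == alpha]
    sel = sel[[(g, i) in amp for g, i in zip(sel["beta_g"], sel["beta_i"])]]
    fracs = sel["het_frac_given_qqtl"].to_numpy(float)
    fracs = fracs[np.isfinite(fracs)]
    if fracs.size == 0:
        return float("nan")
    return float(fracs.mean())
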
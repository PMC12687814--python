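"""Synthetic-data generation for every pipeline stage.

Generators cover Hardy-Weinberg genotype dosages, Gaussian covariates,
phenotypes under five generative models (null, location shift, scale /
variance, tail-specific, and genotype-by-factor interaction), RSS-style
GWAS z-scores consistent with an LD panel, and a complete miniature study
bundle written in the package's file dialects.

Every generator is a pure function of its parameters and a seed.

Phenotype models
----------------
null            Y = C'g + eps
location        Y = beta * G + C'g + eps
scale           Y = (1 + s * G) * eps + C'g ; the per-quantile genotype
                slope has the closed form s * Phi^{-1}(tau) * sigma_eps,
                antisymmetric about tau = 0.5 (a pure variance signal)
tail_specific   a latent binary context B (P(B) = pi) gates the genotype
                effect: Y = beta * G * B + C'g + eps, emulating an effect
                present only in a carrier subgroup
interaction     Y = b0 + bG*G + bF*F + bI*G*F + C'bC + eps with F itself a
                Hardy-Weinberg dosage
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import (
    CovariateMatrix,
    DosageMatrix,
    GwasSummary,
    LdMatrix,
    PhenotypeTable,
    VariantRecord,
    ld_from_panel,
    write_covariates,
    write_genotypes_tsv,
    write_gwas,
    write_ld,
    write_phenotypes,
)

logger = logging.getLogger(__name__)

__all__ = [
    "PhenoModelSpec",
    "gen_genotypes",
    "gen_covariates",
    "gen_phenotype",
    "gen_gwas_and_ld",
    "make_fixture_bundle",
]


@dataclass(frozen=True)
class PhenoModelSpec:
    """Parameters of one phenotype generative model.

    ``kind`` is one of null / location / scale / tail_specific /
    interaction. ``noise_sd`` is the residual standard deviation.
    """

    kind: str = "null"
    beta: float = 0.0  # location & tail effect size; interaction betaG
    scale_s: float = 0.0  # s in Y = (1 + s G) eps; requires s > -1/2
    tail_pi: float = 0.3  # P(latent context B = 1)
    beta_f: float = 0.0  # interaction: factor main effect
    beta_i: float = 0.0  # interaction: G x F effect
    f_maf: float = 0.15  # interaction: factor allele frequency
    noise_sd: float = 1.0
    beta_c: np.ndarray | None = None  # covariate effects (default zero)

    def __post_init__(self):
        kinds = {"null", "location", "scale", "tail_specific", "interaction"}
        if self.kind not in kinds:
            raise ValueError(f"unknown phenotype model {self.kind!r}")
        if self.kind == "scale" and not self.scale_s > -0.5:
            raise ValueError("scale parameter must satisfy s > -1/2")
        if not 0.0 < self.tail_pi < 1.0:
            raise ValueError("tail_pi must lie in (0, 1)")


def gen_genotypes(
    n: int,
    m: int,
    maf_range=(0.05, 0.5),
    seed: int | np.random.Generator = 0,
    chrom: str = "1",
    pos_start: int = 1_000_000,
    pos_step: int = 1_000,
) -> DosageMatrix:
    """Hardy-Weinberg genotype dosages: per-variant trinomial draws with
    probabilities {(1-p)^2, 2p(1-p), p^2} (a Binomial(2, p) per sample)."""
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    lo, hi = (maf_range, maf_range) if np.isscalar(maf_range) else maf_range
    if not (0.0 < lo <= hi <= 0.5):
        raise ValueError("MAF range must lie in (0, 0.5]")
    mafs = rng.uniform(lo, hi, size=m) if lo < hi else np.full(m, lo)
    D = rng.binomial(2, mafs[None, :], size=(n, m)).astype(float)
    variants = [
        VariantRecord(
            id=f"chr{chrom}:{pos_start + j * pos_step}:A:G",
            chrom=str(chrom),
            pos=pos_start + j * pos_step,
            ref="A",
            alt="G",
            maf=float(min(D[:, j].mean() / 2, 1 - D[:, j].mean() / 2)),
            mac=int(round(min(D[:, j].sum(), 2 * n - D[:, j].sum()))),
        )
        for j in range(m)
    ]
    samples = [f"S{i:04d}" for i in range(n)]
    return DosageMatrix(samples, variants, D)


def gen_covariates(n: int, q: int, seed=0, samples=None) -> CovariateMatrix:
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    return CovariateMatrix(
        names=[f"cov{k}" for k in range(q)],
        samples=samples or [f"S{i:04d}" for i in range(n)],
        values=rng.normal(size=(n, q)),
    )


def gen_phenotype(
    G: np.ndarray,
    C: np.ndarray | None,
    spec: PhenoModelSpec,
    seed: int | np.random.Generator = 0,
) -> np.ndarray | tuple[np.ndarray, np.ndarray]:
    """Draw one phenotype vector given a dosage column and covariates.

    For ``interaction`` the sampled factor F is returned alongside Y; for
    ``tail_specific`` the latent context B is returned alongside Y.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    G = np.asarray(G, dtype=float).ravel()
    n = G.size
    if C is None or np.size(C) == 0:
        cov_part = np.zeros(n)
        q = 0
    else:
        C = np.atleast_2d(np.asarray(C, dtype=float))
        if C.shape[0] != n:
            C = C.T
        q = C.shape[1]
        bc = np.zeros(q) if spec.beta_c is None else np.asarray(spec.beta_c, float)
        cov_part = C @ bc
    eps = rng.normal(scale=spec.noise_sd, size=n)
    if spec.kind == "null":
        return cov_part + eps
    if spec.kind == "location":
        return spec.beta * G + cov_part + eps
    if spec.kind == "scale":
        return (1.0 + spec.scale_s * G) * eps + cov_part
    if spec.kind == "tail_specific":
        B = rng.binomial(1, spec.tail_pi, size=n).astype(float)
        return spec.beta * G * B + cov_part + eps, B
    # interaction
    F = rng.binomial(2, spec.f_maf, size=n).astype(float)
    Y = spec.beta * G + spec.beta_f * F + spec.beta_i * G * F + cov_part + eps
    return Y, F


def gen_gwas_and_ld(
    p: int = 20,
    n_panel: int = 500,
    rho: float = 0.6,
    lam: float = 0.0,
    direction: np.ndarray | None = None,
    maf_range=(0.1, 0.5),
    seed: int | np.random.Generator = 0,
    chrom: str = "1",
    pos_start: int = 5_000_000,
) -> tuple[GwasSummary, LdMatrix, DosageMatrix]:
    """RSS-style GWAS generator consistent with an LD panel.

    An AR(1)-correlated latent Gaussian panel (parameter ``rho``) is
    thresholded to Hardy-Weinberg dosages, giving a panel and its Pearson
    LD matrix Sigma. GWAS z-scores are drawn from MVN(Sigma mu, Sigma)
    with mu = lam * d / ||d|| along ``direction`` d (default: equal
    loading); lam = 0 is an exact null.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    if not -1.0 < rho < 1.0:
        raise ValueError("AR(1) parameter must lie in (-1, 1)")
    lo, hi = (maf_range, maf_range) if np.isscalar(maf_range) else maf_range
    mafs = rng.uniform(lo, hi, size=p)
    # two latent haplotype layers -> dosage in {0,1,2}
    def latent(nn):
        Z = np.empty((nn, p))
        Z[:, 0] = rng.normal(size=nn)
        for j in range(1, p):
            Z[:, j] = rho * Z[:, j - 1] + np.sqrt(1 - rho**2) * rng.normal(size=nn)
        return Z
    thr = stats.norm.ppf(mafs)
    H1 = (latent(n_panel) < thr).astype(float)
    H2 = (latent(n_panel) < thr).astype(float)
    D = H1 + H2
    # guard monomorphic columns (redraw those columns deterministically)
    for j in range(p):
        tries = 0
        while D[:, j].std() == 0 and tries < 20:
            col = (rng.normal(size=n_panel) < thr[j]).astype(float)
            col += (rng.normal(size=n_panel) < thr[j]).astype(float)
            D[:, j] = col
            tries += 1
    variants = [
        VariantRecord(
            id=f"chr{chrom}:{pos_start + j * 500}:A:G",
            chrom=str(chrom),
            pos=pos_start + j * 500,
            ref="A",
            alt="G",
            maf=float(min(D[:, j].mean() / 2, 1 - D[:, j].mean() / 2)),
            mac=int(round(min(D[:, j].sum(), 2 * n_panel - D[:, j].sum()))),
        )
        for j in range(p)
    ]
    panel = DosageMatrix([f"P{i:04d}" for i in range(n_panel)], variants, D)
    ld = ld_from_panel(panel)
    if direction is None:
        d = np.ones(p)
    else:
        d = np.asarray(direction, dtype=float).ravel()
        if d.size != p or not np.any(d != 0):
            raise ValueError("invalid direction vector")
    mu = lam * d / np.linalg.norm(d)
    L = np.linalg.cholesky(ld.sigma + 1e-10 * np.eye(p))
    z = ld.sigma @ mu + L @ rng.normal(size=p)
    gwas = GwasSummary(
        pd.DataFrame(
            {
                "id": [v.id for v in variants],
                "chrom": [v.chrom for v in variants],
                "pos": [v.pos for v in variants],
                "a1": [v.alt for v in variants],
                "a2": [v.ref for v in variants],
                "z": z,
            }
        )
    )
    return gwas, ld, panel


# ---------------------------------------------------------------------------
# Fixture bundle
# ---------------------------------------------------------------------------


def make_fixture_bundle(
    outdir,
    seed: int = 0,
    n: int = 400,
    n_genes: int = 50,
    n_variants: int = 5000,
    q: int = 10,
    n_location: int = 10,
    n_scale: int = 5,
    n_interaction: int = 5,
    location_beta: float = 0.6,
    scale_s: float = 1.0,
    interaction_beta_i: float = 0.8,
) -> dict:
    """Write a complete miniature study to ``outdir``.

    Two chromosomes, ``n_genes`` genes with cis-windows tiling them,
    ``n_variants`` variants, ``q`` covariates, a TAD BED, three annotation
    BEDs, a gene-set GMT, a GWAS + LD panel, and a truth table recording
    the planted causal genes (location / scale / interaction) with their
    causal variant ids. Returns the path manifest.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    half = n_variants // 2
    g1 = gen_genotypes(n, half, (0.05, 0.5), rng, chrom="1",
                       pos_start=1_000_000, pos_step=2_000)
    g2 = gen_genotypes(n, n_variants - half, (0.05, 0.5), rng, chrom="2",
                       pos_start=1_000_000, pos_step=2_000)
    g2 = DosageMatrix(g1.samples, g2.variants, g2.dosages)
    dm = DosageMatrix(
        g1.samples, g1.variants + g2.variants,
        np.hstack([g1.dosages, g2.dosages]),
    )
    cov = gen_covariates(n, q, rng, samples=g1.samples)

    genes = []
    per_chrom = n_genes // 2
    gene_span = (half * 2_000) // per_chrom
    for k in range(n_genes):
        chrom = "1" if k < per_chrom else "2"
        i = k if k < per_chrom else k - per_chrom
        start = 1_000_000 + i * gene_span + gene_span // 2
        genes.append((f"GENE{k:03d}", chrom, start, start + 10_000))

    kinds = (["location"] * n_location + ["scale"] * n_scale
             + ["interaction"] * n_interaction)
    kinds += ["null"] * (n_genes - len(kinds))
    perm = rng.permutation(n_genes)
    truth_rows = []
    values = np.empty((n_genes, n))
    var_by_chrom = {
        "1": [j for j, v in enumerate(dm.variants) if v.chrom == "1"],
        "2": [j for j, v in enumerate(dm.variants) if v.chrom == "2"],
    }
    for k, kind in zip(perm, kinds):
        gid, chrom, start, end = genes[k]
        # causal variant: nearest to the gene start
        cand = var_by_chrom[chrom]
        jc = min(cand, key=lambda j: abs(dm.variants[j].pos - start))
        Gc = dm.dosages[:, jc]
        if kind == "null":
            spec = PhenoModelSpec(kind="null")
            Y = gen_phenotype(Gc, cov.values, spec, rng)
            extra = ""
        elif kind == "location":
            spec = PhenoModelSpec(kind="location", beta=location_beta)
            Y = gen_phenotype(Gc, cov.values, spec, rng)
            extra = f"beta={location_beta}"
        elif kind == "scale":
            spec = PhenoModelSpec(kind="scale", scale_s=scale_s)
            Y = gen_phenotype(Gc, cov.values, spec, rng)
            extra = f"s={scale_s}"
        else:
            spec = PhenoModelSpec(kind="interaction", beta=0.2,
                                  beta_i=interaction_beta_i)
            Y, F = gen_phenotype(Gc, cov.values, spec, rng)
            extra = f"beta_i={interaction_beta_i}"
        values[k] = Y
        truth_rows.append(
            {"gene_id": gid, "kind": kind,
             "causal_variant": dm.variants[jc].id if kind != "null" else "",
             "params": extra}
        )
    pheno = PhenotypeTable(genes, g1.samples, values)

    # TADs: alternate 1.5 Mb / 3 Mb blocks on each chromosome
    tad_rows = []
    for chrom in ("1", "2"):
        pos, toggle = 0, True
        end_pos = 1_000_000 + half * 2_000 + 1_000_000
        while pos < end_pos:
            width = 1_500_000 if toggle else 3_000_000
            tad_rows.append((chrom, pos, pos + width))
            pos += width
            toggle = not toggle
    tadb = pd.DataFrame(tad_rows, columns=["chrom", "start", "end"])

    # annotations: three interval tracks of varying density
    ann_paths = {}
    for name, width, step in (("promoterlike", 2_000, 50_000),
                              ("enhancerlike", 5_000, 120_000),
                              ("broadmark", 50_000, 400_000)):
        rows = []
        for chrom in ("1", "2"):
            start = int(rng.integers(0, step))
            for s in range(start, 1_000_000 + half * 2_000, step):
                rows.append((chrom, s, s + width))
        path = outdir / f"annotation_{name}.bed"
        pd.DataFrame(rows).to_csv(path, sep="\t", header=False, index=False)
        ann_paths[name] = str(path)

    # gene sets: one set enriched in planted causal genes, one random
    causal = [r["gene_id"] for r in truth_rows if r["kind"] != "null"]
    null_genes = [r["gene_id"] for r in truth_rows if r["kind"] == "null"]
    set1 = causal[: len(causal) // 2] + list(
        rng.choice(null_genes, size=min(3, len(null_genes)), replace=False)
    )
    set2 = list(rng.choice([g[0] for g in genes],
                           size=min(10, n_genes), replace=False))
    gmt = outdir / "genesets.gmt"
    with open(gmt, "w") as fh:
        fh.write("PLANTED_SET\tsynthetic\t" + "\t".join(sorted(set1)) + "\n")
        fh.write("RANDOM_SET\tsynthetic\t" + "\t".join(sorted(set2)) + "\n")

    gwas, ld, panel = gen_gwas_and_ld(p=30, n_panel=400, rho=0.6, lam=0.0,
                                      seed=rng, chrom="1")

    paths = {
        "genotypes": str(outdir / "genotypes.tsv"),
        "phenotypes": str(outdir / "phenotypes.bed.tsv"),
        "covariates": str(outdir / "covariates.tsv"),
        "tadb": str(outdir / "tadb.bed"),
        "gwas": str(outdir / "gwas.tsv"),
        "ld": str(outdir / "ld.tsv"),
        "ld_panel": str(outdir / "ld_panel.tsv"),
        "truth": str(outdir / "truth.tsv"),
        "genesets": str(gmt),
        **{f"annotation_{k}": v for k, v in ann_paths.items()},
    }
    write_genotypes_tsv(dm, paths["genotypes"])
    write_phenotypes(pheno, paths["phenotypes"])
    write_covariates(cov, paths["covariates"])
    tadb.to_csv(paths["tadb"], sep="\t", header=False, index=False)
    write_gwas(gwas, paths["gwas"])
    write_ld(ld, paths["ld"])
    write_genotypes_tsv(panel, paths["ld_panel"])
    pd.DataFrame(truth_rows).to_csv(paths["truth"], sep="\t", index=False)
    with open(outdir / "manifest.json", "w") as fh:
        json.dump({"seed": seed, "n": n, "paths": paths}, fh, indent=1)
    return paths
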
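"""Readers, writers and container types for every external format the
pipeline touches.

Conventions (centralized here):

* variant positions are 1-based (VCF convention);
* genomic intervals (phenotype gene bodies, TAD boundaries, annotations)
  are 0-based half-open (BED convention);
* dosages are minor-allele counts in [0, 2]; missing entries are imputed
  to the per-variant column mean; zero-variance columns are dropped;
* sample order is identical across genotype / phenotype / covariate
  objects after :func:`align`.

Dialects: VCF 4.x (DS preferred over GT; multi-allelic sites rejected);
TSV dosage matrix (rows = variants, columns = samples) with a sidecar
variant table (id, chrom, pos, ref, alt); phenotype BED-like TSV
(#chr, start, end, gene_id, then one column per sample); covariate TSV
(covariates x samples); GWAS TSV (id, chrom, pos, a1, a2, z); LD square
TSV with an id header row/column.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "VariantRecord",
    "DosageMatrix",
    "PhenotypeTable",
    "CovariateMatrix",
    "GwasSummary",
    "LdMatrix",
    "read_genotypes",
    "write_genotypes_tsv",
    "read_phenotypes",
    "write_phenotypes",
    "read_covariates",
    "write_covariates",
    "read_gwas",
    "write_gwas",
    "read_ld",
    "write_ld",
    "ld_from_panel",
    "read_bed_intervals",
    "align",
    "harmonize_gwas",
    "normalize_chrom",
]


def normalize_chrom(chrom: str) -> str:
    """Strip a 'chr' prefix so 'chr1' and '1' compare equal."""
    c = str(chrom)
    return c[3:] if c.lower().startswith("chr") else c


@dataclass(frozen=True)
class VariantRecord:
    id: str
    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    maf: float = float("nan")
    mac: int = 0


@dataclass
class DosageMatrix:
    """Per-sample variant dosages (n samples x m variants) with metadata.

    Dosages are in [0, 2] with no NaN after load + imputation; every
    retained column has positive variance; ``maf``/``mac`` on each
    :class:`VariantRecord` are recomputed from the imputed dosages.
    """

    samples: list[str]
    variants: list[VariantRecord]
    dosages: np.ndarray

    def __post_init__(self):
        self.dosages = np.asarray(self.dosages, dtype=float)
        n, m = self.dosages.shape
        if n != len(self.samples) or m != len(self.variants):
            raise ValueError("dosage shape does not match samples/variants")
        if len(set(self.samples)) != n:
            raise ValueError("duplicate sample identifiers")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def variant_ids(self) -> list[str]:
        return [v.id for v in self.variants]

    def subset_variants(self, indices) -> "DosageMatrix":
        idx = np.asarray(indices)
        return DosageMatrix(
            samples=list(self.samples),
            variants=[self.variants[i] for i in idx],
            dosages=self.dosages[:, idx],
        )

    def subset_samples(self, sample_ids: list[str]) -> "DosageMatrix":
        pos = {s: i for i, s in enumerate(self.samples)}
        idx = [pos[s] for s in sample_ids]
        return DosageMatrix(
            samples=list(sample_ids),
            variants=list(self.variants),
            dosages=self.dosages[idx, :],
        )


@dataclass
class PhenotypeTable:
    """Molecular phenotypes: one row per gene, one column per sample.

    Gene coordinates follow the BED convention (0-based half-open).
    """

    genes: list[tuple[str, str, int, int]]  # (gene_id, chrom, start, end)
    samples: list[str]
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        ids = [g[0] for g in self.genes]
        if len(set(ids)) != len(ids):
            dups = sorted({g for g in ids if ids.count(g) > 1})
            raise ValueError(f"duplicate gene identifiers: {dups}")
        if self.values.shape != (len(self.genes), len(self.samples)):
            raise ValueError("phenotype value shape mismatch")

    def gene_ids(self) -> list[str]:
        return [g[0] for g in self.genes]

    def row(self, gene_id: str) -> np.ndarray:
        return self.values[self.gene_ids().index(gene_id)]

    def subset_samples(self, sample_ids: list[str]) -> "PhenotypeTable":
        pos = {s: i for i, s in enumerate(self.samples)}
        idx = [pos[s] for s in sample_ids]
        return PhenotypeTable(list(self.genes), list(sample_ids), self.values[:, idx])


@dataclass
class CovariateMatrix:
    """q covariates for n samples (n x q); full column rank with intercept."""

    names: list[str]
    samples: list[str]
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        n, q = self.values.shape
        if n != len(self.samples) or q != len(self.names):
            raise ValueError("covariate shape mismatch")
        X = np.column_stack([np.ones(n), self.values])
        if n > q and np.linalg.matrix_rank(X) < q + 1:
            raise ValueError("covariate matrix is rank-deficient with intercept")

    def subset_samples(self, sample_ids: list[str]) -> "CovariateMatrix":
        pos = {s: i for i, s in enumerate(self.samples)}
        idx = [pos[s] for s in sample_ids]
        return CovariateMatrix(list(self.names), list(sample_ids), self.values[idx, :])


@dataclass
class GwasSummary:
    """GWAS summary statistics: per variant id, position, alleles, z-score."""

    table: pd.DataFrame  # columns: id, chrom, pos, a1, a2, z

    def __post_init__(self):
        req = ["id", "chrom", "pos", "a1", "a2", "z"]
        missing = [c for c in req if c not in self.table.columns]
        if missing:
            raise ValueError(f"GWAS table missing columns: {missing}")
        t = self.table
        if not np.all(np.isfinite(t["z"].to_numpy(dtype=float))):
            raise ValueError("non-finite GWAS z-scores")
        same = t["a1"].astype(str) == t["a2"].astype(str)
        if same.any():
            raise ValueError(
                f"identical alleles at rows {list(np.nonzero(same.to_numpy())[0])}"
            )
        if t["id"].duplicated().any():
            dups = sorted(t.loc[t["id"].duplicated(), "id"].unique())
            raise ValueError(f"duplicate GWAS variant ids: {dups}")


@dataclass
class LdMatrix:
    """Pearson LD correlation matrix with ordered variant ids."""

    ids: list[str]
    sigma: np.ndarray

    def __post_init__(self):
        self.sigma = np.asarray(self.sigma, dtype=float)
        p = len(self.ids)
        if self.sigma.shape != (p, p):
            raise ValueError("LD matrix shape mismatch")
        if not np.allclose(self.sigma, self.sigma.T, atol=1e-8):
            raise ValueError("LD matrix is not symmetric")
        if not np.allclose(np.diag(self.sigma), 1.0, atol=1e-8):
            raise ValueError("LD matrix diagonal is not unit")
        w = np.linalg.eigvalsh(self.sigma)
        if w.min() < -1e-8:
            raise ValueError(f"LD matrix has negative eigenvalue {w.min():.3e}")

    def subset(self, ids: list[str]) -> "LdMatrix":
        pos = {s: i for i, s in enumerate(self.ids)}
        idx = [pos[s] for s in ids]
        return LdMatrix(list(ids), self.sigma[np.ix_(idx, idx)])


# ---------------------------------------------------------------------------
# Genotypes
# ---------------------------------------------------------------------------


def _impute_and_qc(samples, variants, dosages) -> DosageMatrix:
    """Impute missing entries to the column mean, drop zero-variance
    columns (logged), recompute MAF/MAC."""
    D = np.asarray(dosages, dtype=float)
    col_mean = np.nanmean(np.where(np.isnan(D), np.nan, D), axis=0)
    nan_cols = np.all(np.isnan(D), axis=0)
    col_mean = np.where(nan_cols, 0.0, col_mean)
    idx = np.where(np.isnan(D))
    D[idx] = col_mean[idx[1]]
    var = D.var(axis=0)
    keep = var > 0
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("dropped %d zero-variance variant(s)", n_dropped)
    D = D[:, keep]
    kept_variants = []
    n = D.shape[0]
    for j, v in enumerate(np.nonzero(keep)[0]):
        alt_freq = D[:, j].sum() / (2 * n)
        maf = min(alt_freq, 1 - alt_freq)
        mac = int(round(min(D[:, j].sum(), 2 * n - D[:, j].sum())))
        kept_variants.append(replace(variants[v], maf=float(maf), mac=mac))
    return DosageMatrix(list(samples), kept_variants, D)


def _read_vcf(path: Path) -> tuple[list, list, np.ndarray]:
    """Minimal-but-strict plain-text VCF 4.x parser.

    DS FORMAT field is preferred; otherwise GT allele counts are used.
    Multi-allelic sites are rejected with a pointer to the offending line
    (the pipeline operates on biallelic dosages).
    """
    samples: list[str] = []
    variants: list[VariantRecord] = []
    rows: list[np.ndarray] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("##"):
                continue
            if line.startswith("#CHROM"):
                parts = line.split("\t")
                if len(parts) < 10 or parts[:9] != [
                    "#CHROM", "POS", "ID", "REF", "ALT",
                    "QUAL", "FILTER", "INFO", "FORMAT",
                ]:
                    raise ValueError(f"malformed VCF header at line {lineno}")
                samples = parts[9:]
                continue
            if not samples:
                raise ValueError(f"VCF data before #CHROM header at line {lineno}")
            parts = line.split("\t")
            if len(parts) != 9 + len(samples):
                raise ValueError(f"malformed VCF record at line {lineno}")
            chrom, pos, vid, ref, alt = parts[0], parts[1], parts[2], parts[3], parts[4]
            if "," in alt:
                raise ValueError(
                    f"multi-allelic site at line {lineno} ({chrom}:{pos}); "
                    "split or filter to biallelic records first"
                )
            fmt = parts[8].split(":")
            if "DS" in fmt:
                k = fmt.index("DS")
                vals = []
                for s in parts[9:]:
                    f = s.split(":")
                    v = f[k] if k < len(f) else "."
                    vals.append(float("nan") if v in (".", "") else float(v))
            elif "GT" in fmt:
                k = fmt.index("GT")
                vals = []
                for s in parts[9:]:
                    f = s.split(":")
                    gt = f[k] if k < len(f) else "."
                    alleles = gt.replace("|", "/").split("/")
                    if "." in alleles or gt in (".", ""):
                        vals.append(float("nan"))
                    else:
                        vals.append(float(sum(int(a) for a in alleles)))
            else:
                raise ValueError(f"VCF record without GT or DS at line {lineno}")
            vid = vid if vid not in (".", "") else f"{chrom}:{pos}:{ref}:{alt}"
            variants.append(VariantRecord(vid, chrom, int(pos), ref, alt))
            rows.append(np.array(vals))
    if not samples:
        raise ValueError("no #CHROM header found; not a VCF file")
    D = np.array(rows).T if rows else np.empty((len(samples), 0))
    return samples, variants, D


def _read_dosage_tsv(path: Path) -> tuple[list, list, np.ndarray]:
    """TSV dosage matrix (rows = variants, cols = samples) plus sidecar
    ``<path>.variants.tsv`` with columns id, chrom, pos, ref, alt."""
    mat = pd.read_csv(path, sep="\t", index_col=0)
    sidecar = Path(str(path) + ".variants.tsv")
    if not sidecar.exists():
        raise FileNotFoundError(f"missing variant sidecar table {sidecar}")
    meta = pd.read_csv(sidecar, sep="\t", dtype={"chrom": str})
    if list(meta["id"]) != list(mat.index):
        raise ValueError(
            "variant ids in sidecar do not align with dosage matrix rows"
        )
    if meta["id"].duplicated().any():
        dups = sorted(meta.loc[meta["id"].duplicated(), "id"].unique())
        raise ValueError(f"duplicate variant ids: {dups}")
    variants = [
        VariantRecord(str(r.id), str(r.chrom), int(r.pos), str(r.ref), str(r.alt))
        for r in meta.itertuples()
    ]
    return list(mat.columns), variants, mat.to_numpy(dtype=float).T


def read_genotypes(path, dialect: str = "auto") -> DosageMatrix:
    """Read genotype dosages from a VCF or a TSV dosage matrix.

    Dosages come from DS when present, else GT allele counts. Missing
    entries are imputed to the column mean; zero-variance columns are
    dropped with a logged count; MAF/MAC are computed from the imputed
    dosages.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "auto":
        dialect = "vcf" if path.suffix == ".vcf" or str(path).endswith(".vcf.gz") else "tsv"
    if dialect == "vcf":
        samples, variants, D = _read_vcf(path)
    elif dialect == "tsv":
        samples, variants, D = _read_dosage_tsv(path)
    else:
        raise ValueError(f"unknown genotype dialect {dialect!r}")
    if np.nanmin(D, initial=0.0) < -1e-9 or np.nanmax(D, initial=0.0) > 2 + 1e-9:
        raise ValueError("dosages outside [0, 2]")
    return _impute_and_qc(samples, variants, np.clip(D, 0.0, 2.0))


def write_genotypes_tsv(dm: DosageMatrix, path) -> None:
    path = Path(path)
    df = pd.DataFrame(
        dm.dosages.T, index=dm.variant_ids(), columns=dm.samples
    )
    df.index.name = "id"
    df.to_csv(path, sep="\t", float_format="%.10g")
    meta = pd.DataFrame(
        [(v.id, v.chrom, v.pos, v.ref, v.alt) for v in dm.variants],
        columns=["id", "chrom", "pos", "ref", "alt"],
    )
    meta.to_csv(str(path) + ".variants.tsv", sep="\t", index=False)


# ---------------------------------------------------------------------------
# Phenotypes / covariates
# ---------------------------------------------------------------------------


def read_phenotypes(path) -> PhenotypeTable:
    """BED-like phenotype TSV: #chr, start, end, gene_id, then samples."""
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    cols = list(df.columns)
    if len(cols) < 5:
        raise ValueError("phenotype table needs #chr,start,end,gene_id + samples")
    samples = cols[4:]
    genes = [
        (str(r[cols[3]]), str(r[cols[0]]), int(r[cols[1]]), int(r[cols[2]]))
        for _, r in df.iterrows()
    ]
    return PhenotypeTable(genes, samples, df[samples].to_numpy(dtype=float))


def write_phenotypes(pt: PhenotypeTable, path) -> None:
    rows = []
    for (gid, chrom, start, end), vals in zip(pt.genes, pt.values):
        rows.append([chrom, start, end, gid, *vals])
    df = pd.DataFrame(rows, columns=["#chr", "start", "end", "gene_id", *pt.samples])
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_covariates(path) -> CovariateMatrix:
    """Covariate TSV: rows = covariates, columns = samples."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.duplicated().any():
        dups = sorted(df.index[df.index.duplicated()].unique())
        raise ValueError(f"duplicate covariate names: {dups}")
    return CovariateMatrix(
        names=[str(i) for i in df.index],
        samples=[str(c) for c in df.columns],
        values=df.to_numpy(dtype=float).T,
    )


def write_covariates(cm: CovariateMatrix, path) -> None:
    df = pd.DataFrame(cm.values.T, index=cm.names, columns=cm.samples)
    df.index.name = "covariate"
    df.to_csv(path, sep="\t", float_format="%.10g")


# ---------------------------------------------------------------------------
# GWAS / LD
# ---------------------------------------------------------------------------


def read_gwas(path) -> GwasSummary:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    return GwasSummary(df[["id", "chrom", "pos", "a1", "a2", "z"]].copy())


def write_gwas(g: GwasSummary, path) -> None:
    g.table.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_ld(path) -> LdMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    ids = [str(i) for i in df.index]
    if list(df.columns) != ids:
        raise ValueError("LD matrix row/column ids disagree")
    return LdMatrix(ids, df.to_numpy(dtype=float))


def write_ld(ld: LdMatrix, path) -> None:
    df = pd.DataFrame(ld.sigma, index=ld.ids, columns=ld.ids)
    df.index.name = "id"
    df.to_csv(path, sep="\t", float_format="%.12g")


def ld_from_panel(panel: DosageMatrix) -> LdMatrix:
    """Pearson correlation of dosage columns of a genotype panel."""
    D = panel.dosages
    sd = D.std(axis=0)
    if np.any(sd == 0):
        bad = [panel.variants[i].id for i in np.nonzero(sd == 0)[0]]
        raise ValueError(f"zero-variance panel variants: {bad}")
    R = np.corrcoef(D, rowvar=False)
    R = np.clip((R + R.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(R, 1.0)
    # project tiny negative eigenvalues up so the invariant holds exactly
    w = np.linalg.eigvalsh(R)
    if w.min() < -1e-8:
        wv, V = np.linalg.eigh(R)
        R = (V * np.maximum(wv, 0)) @ V.T
        d = np.sqrt(np.diag(R))
        R = R / np.outer(d, d)
        np.fill_diagonal(R, 1.0)
    return LdMatrix(panel.variant_ids(), R)


def qc_filter(
    dm: DosageMatrix,
    maf_min: float = 0.01,
    mac_min: int = 5,
    mode: str = "either",
) -> DosageMatrix:
    """Variant QC: retain variants passing the MAF and/or MAC criteria.

    ``mode='either'`` (the default) keeps a
    variant when MAF >= maf_min OR MAC >= mac_min; ``mode='both'``
    requires both.
    """
    if mode not in ("either", "both"):
        raise ValueError("mode must be 'either' or 'both'")
    keep = []
    for j, v in enumerate(dm.variants):
        ok_maf = v.maf >= maf_min
        ok_mac = v.mac >= mac_min
        keep.append((ok_maf or ok_mac) if mode == "either"
                    else (ok_maf and ok_mac))
    idx = np.nonzero(keep)[0]
    dropped = dm.n_variants - idx.size
    if dropped:
        logger.info("QC dropped %d variant(s) (mode=%s)", dropped, mode)
    return dm.subset_variants(idx)


def read_bed_intervals(path) -> pd.DataFrame:
    """BED intervals (0-based half-open): chrom, start, end [, name]."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype={0: str})
    df = df.iloc[:, :4] if df.shape[1] >= 4 else df.iloc[:, :3]
    df.columns = ["chrom", "start", "end", "name"][: df.shape[1]]
    if "name" not in df.columns:
        df["name"] = [f"iv{i}" for i in range(len(df))]
    df["chrom"] = df["chrom"].map(normalize_chrom)
    if (df["end"] <= df["start"]).any():
        raise ValueError("BED intervals with end <= start")
    return df


# ---------------------------------------------------------------------------
# Alignment / harmonization
# ---------------------------------------------------------------------------


def align(
    genotypes: DosageMatrix,
    phenotypes: PhenotypeTable,
    covariates: CovariateMatrix | None = None,
):
    """Subset all objects to the common samples, in genotype order.

    After alignment the i-th sample is the same individual in every matrix.
    """
    common = [s for s in genotypes.samples if s in set(phenotypes.samples)]
    if covariates is not None:
        cset = set(covariates.samples)
        common = [s for s in common if s in cset]
    if not common:
        raise ValueError("no samples shared across genotype/phenotype/covariates")
    g = genotypes.subset_samples(common)
    p = phenotypes.subset_samples(common)
    if covariates is None:
        return g, p, None
    return g, p, covariates.subset_samples(common)


_AMBIGUOUS = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}
_COMP = {"A": "T", "T": "A", "C": "G", "G": "C"}


def harmonize_gwas(
    gwas: GwasSummary,
    variants: list[VariantRecord],
    drop_ambiguous: bool = True,
) -> pd.DataFrame:
    """Match GWAS rows to a variant list on (chrom, pos, alleles).

    Swapped alleles flip the z sign; strand-ambiguous A/T and C/G pairs are
    dropped by default; indels are excluded. Returns a frame with one row
    per matched variant (columns: id, z), in the order of ``variants``.
    """
    key = {}
    for _, r in gwas.table.iterrows():
        key[(normalize_chrom(r["chrom"]), int(r["pos"]))] = (
            str(r["a1"]).upper(),
            str(r["a2"]).upper(),
            float(r["z"]),
        )
    out = []
    for v in variants:
        hit = key.get((normalize_chrom(v.chrom), v.pos))
        if hit is None:
            continue
        a1, a2, z = hit
        ref, alt = v.ref.upper(), v.alt.upper()
        if len(ref) != 1 or len(alt) != 1 or len(a1) != 1 or len(a2) != 1:
            continue  # indels excluded
        if drop_ambiguous and (a1, a2) in _AMBIGUOUS:
            continue
        if (a1, a2) == (alt, ref):
            out.append((v.id, z))
        elif (a1, a2) == (ref, alt):
            out.append((v.id, -z))
        elif not drop_ambiguous and (
            (_COMP.get(a1), _COMP.get(a2)) == (alt, ref)
        ):
            out.append((v.id, z))
        elif not drop_ambiguous and (
            (_COMP.get(a1), _COMP.get(a2)) == (ref, alt)
        ):
            out.append((v.id, -z))
    return pd.DataFrame(out, columns=["id", "z"])
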
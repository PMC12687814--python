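"""End-to-end orchestration: scan a study, apply hierarchical correction,
classify, train/associate qTWAS, and run enrichments, with a manifest
recording versions, seeds, and input checksums.

The heavy lifting lives in the per-module functions; this module wires
them together over aligned study objects and writes documented TSVs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .io_formats import (
    CovariateMatrix,
    DosageMatrix,
    GwasSummary,
    LdMatrix,
    PhenotypeTable,
    align,
    harmonize_gwas,
)
from .qtl_mapping import (
    HierarchicalCall,
    build_cis_windows,
    fit_null_models,
    hierarchical_correct,
    map_iqtl,
    map_qqtl,
    map_vqtl,
    map_xqtl,
    variants_in_window,
)
from .quantile_core import QuantileGrid, fit_quantile_joint
from .qtl_classify import HET_GRID, categorize_pairs
from .qtwas import (
    estimate_weights,
    gene_assoc,
    integrate_weights,
    make_dynamic_regions,
    make_fixed_regions,
    region_assoc,
    select_and_prune,
)

logger = logging.getLogger(__name__)

__all__ = ["StudyScan", "scan_study", "qtwas_train", "qtwas_assoc",
           "run_full_pipeline"]


@dataclass
class StudyScan:
    """All per-method scan results for one study."""

    windows: dict
    pair_tables: dict[str, pd.DataFrame]
    calls: dict[str, HierarchicalCall]
    qqtl_scans: dict[str, object] = field(default_factory=dict)


def _pairs_by_gene(df: pd.DataFrame) -> dict:
    out: dict[str, list] = {}
    for r in df.itertuples():
        if np.isfinite(r.p_nominal):
            out.setdefault(r.gene_id, []).append((r.variant_id, r.p_nominal))
    return out


def scan_study(
    genotypes: DosageMatrix,
    phenotypes: PhenotypeTable,
    covariates: CovariateMatrix | None,
    tadb: pd.DataFrame | None = None,
    methods: tuple = ("xqtl", "qqtl", "vqtl"),
    factor: np.ndarray | None = None,
    grid: QuantileGrid | None = None,
    fdr: float = 0.05,
    span: int = 2_000_000,
) -> StudyScan:
    """Run the requested cis scans for every gene and apply the two-stage
    hierarchical correction per method."""
    grid = grid or QuantileGrid.mapping()
    g, p, c = align(genotypes, phenotypes, covariates)
    C = None if c is None else c.values
    windows = {w.gene_id: w for w in build_cis_windows(p.genes, tadb, span=span)}
    rows: dict[str, list] = {m: [] for m in methods}
    for gi, (gid, chrom, start, end) in enumerate(p.genes):
        w = windows[gid]
        idx = variants_in_window(g, w)
        if idx.size == 0:
            logger.info("gene %s: no cis variants", gid)
            continue
        sub = g.subset_variants(idx)
        Y = p.values[gi]
        null_fits = None
        scan = None
        if "qqtl" in methods or "vqtl" in methods:
            null_fits = fit_null_models(Y, C, grid)
        if "xqtl" in methods:
            for r in map_xqtl(gid, Y, sub, C):
                rows["xqtl"].append(
                    (r.gene_id, r.variant_id, r.beta, r.statistic, r.p_nominal)
                )
        if "qqtl" in methods:
            qres, scan = map_qqtl(gid, Y, sub, C, grid, null_fits=null_fits)
            for r in qres:
                rows["qqtl"].append(
                    (r.gene_id, r.variant_id, np.nan, np.nan, r.p_nominal)
                )
        if "vqtl" in methods:
            for r in map_vqtl(gid, Y, sub, C, grid, scan=scan,
                              null_fits=null_fits):
                rows["vqtl"].append((r.gene_id, r.variant_id, r.V, r.z, r.p))
        if "iqtl" in methods:
            if factor is None:
                raise ValueError("iqtl scan requires an interaction factor")
            for r in map_iqtl(gid, Y, sub, factor, C):
                rows["iqtl"].append(
                    (r.gene_id, r.variant_id, r.betaI, r.direction, r.pI)
                )
    tables, calls = {}, {}
    for m in methods:
        cols = ["gene_id", "variant_id", "beta", "statistic", "p_nominal"]
        if m == "iqtl":
            cols = ["gene_id", "variant_id", "beta", "direction", "p_nominal"]
        df = pd.DataFrame(rows[m], columns=cols)
        tables[m] = df
        calls[m] = hierarchical_correct(_pairs_by_gene(df), fdr=fdr)
    return StudyScan(windows=windows, pair_tables=tables, calls=calls)


def per_tau_slopes(
    genotypes: DosageMatrix,
    phenotypes: PhenotypeTable,
    covariates: CovariateMatrix | None,
    pairs: list[tuple[str, str]],
    taus: np.ndarray = HET_GRID,
) -> dict:
    """Per-quantile slope refits for selected (gene, variant) pairs."""
    g, p, c = align(genotypes, phenotypes, covariates)
    C = None if c is None else c.values
    vid_index = {v.id: j for j, v in enumerate(g.variants)}
    gid_index = {gene[0]: i for i, gene in enumerate(p.genes)}
    out = {}
    for gid, vid in pairs:
        Y = p.values[gid_index[gid]]
        G = g.dosages[:, vid_index[vid]]
        out[(gid, vid)] = fit_quantile_joint(Y, G[:, None], C,
                                             QuantileGrid(taus))[0]
    return out


def qtwas_train(
    genotypes: DosageMatrix,
    phenotypes: PhenotypeTable,
    covariates: CovariateMatrix | None,
    qqtl_call: HierarchicalCall,
    ld: LdMatrix,
    r2: float = 0.8,
) -> dict:
    """Train quantile weights for every gene with significant qQTL."""
    g, p, c = align(genotypes, phenotypes, covariates)
    C = None if c is None else c.values
    vid_index = {v.id: j for j, v in enumerate(g.variants)}
    gid_index = {gene[0]: i for i, gene in enumerate(p.genes)}
    pair_p = {
        (r.gene_id, r.variant_id): r.p_nominal
        for r in qqtl_call.pair_table.itertuples()
    }
    weights = {}
    for gid in qqtl_call.significant_genes:
        sig = [(vid, pair_p[(g2, vid)])
               for g2, vid in qqtl_call.significant_pairs if g2 == gid]
        kept = select_and_prune(sig, ld, r2=r2)
        kept = [v for v in kept if v in vid_index]
        if not kept:
            logger.info("gene %s: no variants survive pruning/harmonization", gid)
            continue
        sub = g.subset_variants([vid_index[v] for v in kept])
        Y = p.values[gid_index[gid]]
        weights[gid] = estimate_weights(gid, Y, sub, C)
    return weights


def qtwas_assoc(
    weights: dict,
    gwas: GwasSummary,
    ld: LdMatrix,
    panel_variants=None,
    regions: str = "fixed",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Associate trained weights with a GWAS through the LD panel."""
    results = []
    n_family = max(len(weights), 1)
    for gid, W in weights.items():
        if panel_variants is not None:
            matched = harmonize_gwas(gwas, [panel_variants[v] for v in W.variant_ids
                                            if v in panel_variants])
            zmap = dict(zip(matched["id"], matched["z"]))
        else:
            zmap = dict(zip(gwas.table["id"], gwas.table["z"]))
        ids = [v for v in W.variant_ids if v in zmap and v in set(ld.ids)]
        if not ids:
            logger.info("gene %s: no GWAS overlap", gid)
            continue
        keep = [W.variant_ids.index(v) for v in ids]
        Wsub = W.weights[keep, :]
        z = np.array([zmap[v] for v in ids])
        sig = ld.subset(ids)
        from .qtwas import WeightMatrix

        Wm = WeightMatrix(gid, ids, W.taus, Wsub)
        rset = (make_fixed_regions(W.taus.size) if regions == "fixed"
                else make_dynamic_regions(Wm))
        omegas = integrate_weights(Wm, rset)
        rres = [region_assoc(w, z, sig) for w in omegas]
        res = gene_assoc(gid, rres, n_tests_in_family=n_family, alpha=alpha)
        results.append(
            {"gene_id": gid, "K": rset.K, "combined_p": res.combined_p,
             "significant": res.significant,
             "region_Z": ";".join(f"{v:.4g}" for v in res.region_Z),
             "region_p": ";".join(f"{v:.4g}" for v in res.region_p)}
        )
    return pd.DataFrame(
        results, columns=["gene_id", "K", "combined_p", "significant",
                          "region_Z", "region_p"]
    )


def _checksum(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


def run_full_pipeline(config: dict, outdir) -> dict:
    """Execute map -> correct -> classify -> qtwas -> enrichment from a
    configuration dict of file paths and options; returns the manifest.

    Any stage failure is recorded in the manifest and downstream stages
    are skipped; earlier outputs stay intact.
    """
    from . import io_formats as io
    from .enrichment import eoo, eoo_loco_se, overlap_annotation
    from .qtl_classify import categorize_pairs

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {"version": __version__, "seed": config.get("seed", 0),
                "stages": [], "inputs": {}}
    for key in ("genotypes", "phenotypes", "covariates", "tadb", "gwas", "ld"):
        if config.get(key):
            manifest["inputs"][key] = {"path": str(config[key]),
                                       "sha256_16": _checksum(config[key])}

    def stage(name, fn):
        try:
            result = fn()
            manifest["stages"].append({"name": name, "status": "ok"})
            return result
        except Exception as exc:  # noqa: BLE001 - manifest records the reason
            logger.error("stage %s failed: %s", name, exc)
            manifest["stages"].append(
                {"name": name, "status": "failed", "reason": str(exc)}
            )
            return None

    state: dict = {}

    def _load():
        g = io.read_genotypes(config["genotypes"])
        p = io.read_phenotypes(config["phenotypes"])
        c = (io.read_covariates(config["covariates"])
             if config.get("covariates") else None)
        tadb = (io.read_bed_intervals(config["tadb"])
                if config.get("tadb") else None)
        return g, p, c, tadb

    loaded = stage("load", _load)
    if loaded is not None:
        state["data"] = loaded

        def _scan():
            g, p, c, tadb = state["data"]
            scan = scan_study(g, p, c, tadb, fdr=config.get("fdr", 0.05))
            for m, df in scan.pair_tables.items():
                df.to_csv(outdir / f"pairs_{m}.tsv", sep="\t", index=False)
                scan.calls[m].pair_table.to_csv(
                    outdir / f"call_{m}.tsv", sep="\t", index=False
                )
            return scan

        scan = stage("map", _scan)
        if scan is not None:
            state["scan"] = scan

            def _classify():
                g, p, c, tadb = state["data"]
                pairs = sorted(
                    set(scan.calls["qqtl"].significant_pairs)
                    | set(scan.calls["xqtl"].significant_pairs)
                )
                betas = per_tau_slopes(g, p, c, pairs)
                cats = categorize_pairs(scan.calls["qqtl"], scan.calls["xqtl"],
                                        betas_by_pair=betas)
                df = pd.DataFrame(
                    [(x.gene_id, x.variant_id, x.category, x.xi, x.p_xi,
                      x.het_index) for x in cats],
                    columns=["gene_id", "variant_id", "category", "xi",
                             "p_xi", "het_index"],
                )
                df.to_csv(outdir / "categories.tsv", sep="\t", index=False)
                return df

            stage("classify", _classify)

            if config.get("gwas") and config.get("ld"):

                def _qtwas():
                    g, p, c, tadb = state["data"]
                    ld = io.read_ld(config["ld"])
                    gwas = io.read_gwas(config["gwas"])
                    weights = qtwas_train(g, p, c, scan.calls["qqtl"], ld)
                    rows = []
                    for gid, W in weights.items():
                        for j, vid in enumerate(W.variant_ids):
                            for k, tau in enumerate(W.taus):
                                rows.append((gid, vid, tau, W.weights[j, k]))
                    pd.DataFrame(
                        rows, columns=["gene_id", "variant_id", "tau", "weight"]
                    ).to_csv(outdir / "qtwas_weights.tsv", sep="\t", index=False)
                    assoc = qtwas_assoc(
                        weights, gwas, ld,
                        regions=config.get("regions", "fixed"),
                    )
                    assoc.to_csv(outdir / "qtwas_assoc.tsv", sep="\t", index=False)
                    return assoc

                stage("qtwas", _qtwas)

            if config.get("annotations"):

                def _enrich():
                    qcall, xcall = scan.calls["qqtl"], scan.calls["xqtl"]
                    qt = qcall.pair_table
                    vmeta = {v.id: v for v in state["data"][0].variants}
                    pairs = qt[["gene_id", "variant_id"]].copy()
                    pairs["chrom"] = [vmeta[v].chrom for v in qt["variant_id"]]
                    pairs["pos"] = [vmeta[v].pos for v in qt["variant_id"]]
                    sig_q = np.array(
                        [(g2, v) in set(qcall.significant_pairs)
                         for g2, v in zip(qt["gene_id"], qt["variant_id"])]
                    )
                    rows = []
                    for path in config["annotations"]:
                        ann = io.read_bed_intervals(path)
                        in_ann = overlap_annotation(pairs, ann)
                        r = eoo(sig_q, in_ann)
                        se = (eoo_loco_se(sig_q, in_ann, pairs["chrom"].to_numpy())
                              if pairs["chrom"].nunique() > 1 else float("nan"))
                        rows.append({"annotation": Path(path).stem,
                                     "eoo": r.eoo, "se_loco": se,
                                     "overlap": r.overlap, "n_sig": r.n1,
                                     "n_in_annotation": r.n2, "tested": r.t12})
                    df = pd.DataFrame(rows)
                    df.to_csv(outdir / "eoo.tsv", sep="\t", index=False)
                    return df

                stage("enrichment", _enrich)

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest
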
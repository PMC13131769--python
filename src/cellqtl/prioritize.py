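"""Four-tier risk-gene integration, multiple-testing utilities, and the
end-to-end pipeline driver.

A gene is prioritized in a cell type when it clears all four tiers:

1. cell-type meta-eQTL RE2 p at the Bonferroni level for the realized
   number of unique eSNP-eGene pairs,
2. colocalization with a GWAS LD chunk at PP4 >= 0.8,
3. SMR association (single- or multi-SNP) at the Bonferroni level for the
   number of forwarded eGenes,
4. a non-significant HEIDI test (p >= 0.01), i.e. no evidence the eQTL
   and GWAS signals come from distinct linked variants.

Orthogonal evidence layers (allelic imbalance, bulk replication, dynamic
genotype x pathology effects) annotate but never gate the list.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple

import numpy as np
import pandas as pd

from . import __version__
from .ase import ase_scan, pseudobulk_ase
from .cis import dynamic_interaction, map_cis, select_candidate_variants
from .coloc import pair_and_run
from .io import SummaryStatsTable
from .ld import clump, ld_r, pi1
from .meta import meta_analyze
from .pseudobulk import adjust_covariates, normalize_and_pseudobulk, zscale
from .simulate import (SimConfig, build_truth, gene_annotation, simulate_ase,
                       simulate_bulk, simulate_cells, simulate_covariates,
                       simulate_genotypes, simulate_gwas)
from .smr import run_smr

logger = logging.getLogger(__name__)

__all__ = ["bonferroni_threshold", "bh_fdr", "apply_four_tiers",
           "annotate_evidence", "PipelineConfig", "Pipeline",
           "PipelineResult", "run_pipeline", "BonferroniThreshold"]


class BonferroniThreshold(NamedTuple):
    exact: float
    rounded: float


def _round_sig(x: float, digits: int) -> float:
    if x == 0:
        return 0.0
    return float(f"{x:.{digits - 1}e}")


def bonferroni_threshold(alpha: float, m: int,
                         digits: int = 3) -> BonferroniThreshold:
    """Family-wise threshold alpha/m, exact and at ``digits`` significant
    figures."""
    if m < 1:
        raise ValueError("m must be >= 1")
    exact = alpha / m
    return BonferroniThreshold(exact, _round_sig(exact, digits))


def bh_fdr(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, returned in input order."""
    p = np.asarray(pvalues, dtype=float)
    m = len(p)
    if m == 0:
        return p.copy()
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


# ---------------------------------------------------------------------------
# tier integration
# ---------------------------------------------------------------------------

DETAIL_COLUMNS = ["gene_id", "cell_type", "best_esnp", "best_p",
                  "eqtl_significant", "coloc_pass", "smr_pass", "heidi_pass",
                  "prioritized"]

RISK_COLUMNS = ["gene_id", "cell_types", "best_esnp", "chunk_id",
                "eqtl_significant", "coloc_pass", "smr_pass", "heidi_pass",
                "prioritized", "ase_tested", "ase_support",
                "bulk_tested", "bulk_replicated", "dynamic_eqtl"]


def apply_four_tiers(meta_records: pd.DataFrame, coloc_results: pd.DataFrame,
                     smr_results: pd.DataFrame, alpha: float = 0.05,
                     pp4_threshold: float = 0.8, heidi_alpha: float = 0.01,
                     heidi_missing: str = "fail",
                     ) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Combine the four tiers into per-gene records.

    Returns (per-gene table, per gene x cell-type detail table, thresholds
    dict).  Tier thresholds are computed from the realized test counts:
    tier 1 at alpha / n unique eSNP-eGene pairs, tier 3 at alpha / n
    forwarded eGenes.  ``heidi_missing`` decides genes whose HEIDI test
    could not be computed: "fail" (default) excludes them, "pass" lets
    them through.
    """
    for name, frame in [("meta", meta_records)]:
        if frame is None:
            raise ValueError(f"missing upstream table: {name}")
    if heidi_missing not in ("fail", "pass"):
        raise ValueError("heidi_missing must be 'fail' or 'pass'")

    n_pairs = int(meta_records[["gene_id", "variant_id"]].drop_duplicates()
                  .shape[0]) if len(meta_records) else 0
    tier1 = bonferroni_threshold(alpha, max(n_pairs, 1))

    detail_rows = []
    if len(meta_records):
        grouped = meta_records.groupby(["gene_id", "cell_type"])
        for (gene, ctype), grp in grouped:
            i = grp["p_re2"].idxmin()
            detail_rows.append((gene, ctype, grp.loc[i, "variant_id"],
                                float(grp.loc[i, "p_re2"]),
                                bool(grp.loc[i, "p_re2"] <= tier1.exact)))
    detail = pd.DataFrame(detail_rows, columns=["gene_id", "cell_type",
                                                "best_esnp", "best_p",
                                                "eqtl_significant"])
    forwarded = sorted(detail.loc[detail["eqtl_significant"], "gene_id"]
                       .unique()) if len(detail) else []
    tier3 = bonferroni_threshold(alpha, max(len(forwarded), 1))

    coloc_pass = set()
    if coloc_results is not None and len(coloc_results):
        ok = coloc_results[coloc_results["pp4"] >= pp4_threshold]
        coloc_pass = set(zip(ok["gene_id"], ok["cell_type"]))

    smr_pass, heidi_pass = set(), set()
    if smr_results is not None and len(smr_results):
        for row in smr_results.itertuples(index=False):
            key = (row.gene_id, row.cell_type)
            ps = [p for p in (row.p_smr, row.p_smr_multi)
                  if p is not None and np.isfinite(p)]
            if ps and min(ps) <= tier3.exact:
                smr_pass.add(key)
            if row.p_heidi is None or not np.isfinite(row.p_heidi):
                if heidi_missing == "pass":
                    heidi_pass.add(key)
            elif row.p_heidi >= heidi_alpha:
                heidi_pass.add(key)

    if len(detail):
        keys = list(zip(detail["gene_id"], detail["cell_type"]))
        detail["coloc_pass"] = [k in coloc_pass for k in keys]
        detail["smr_pass"] = [k in smr_pass for k in keys]
        detail["heidi_pass"] = [k in heidi_pass for k in keys]
        detail["prioritized"] = (detail["eqtl_significant"]
                                 & detail["coloc_pass"] & detail["smr_pass"]
                                 & detail["heidi_pass"])
    else:
        detail = pd.DataFrame(columns=DETAIL_COLUMNS)

    gene_rows = []
    for gene, grp in detail.groupby("gene_id"):
        sig = grp[grp["eqtl_significant"]]
        best = grp.loc[grp["best_p"].idxmin()]
        gene_rows.append({
            "gene_id": gene,
            "cell_types": ",".join(sorted(sig["cell_type"])),
            "best_esnp": best["best_esnp"],
            "chunk_id": None,
            "eqtl_significant": bool(grp["eqtl_significant"].any()),
            "coloc_pass": bool(grp["coloc_pass"].any()),
            "smr_pass": bool(grp["smr_pass"].any()),
            "heidi_pass": bool(grp["heidi_pass"].any()),
            "prioritized": bool(grp["prioritized"].any()),
            "ase_tested": False, "ase_support": False,
            "bulk_tested": False, "bulk_replicated": False,
            "dynamic_eqtl": False,
        })
    risk = pd.DataFrame(gene_rows, columns=RISK_COLUMNS)
    thresholds = {"tier1_threshold": tier1.exact, "tier1_n_pairs": n_pairs,
                  "tier3_threshold": tier3.exact,
                  "tier3_n_forwarded": len(forwarded),
                  "pp4_threshold": pp4_threshold, "heidi_alpha": heidi_alpha}
    return risk, detail, thresholds


def annotate_evidence(risk: pd.DataFrame, ase_results: pd.DataFrame | None,
                      bulk_meta: pd.DataFrame | None,
                      dynamic_records: pd.DataFrame | None,
                      ase_alpha: float = 0.05, bulk_fdr: float = 0.05,
                      dynamic_alpha: float = 0.01) -> pd.DataFrame:
    """Set the orthogonal-evidence flags on the risk-gene table.

    A gene absent from an evidence input keeps the corresponding
    ``*_tested`` flag False (insufficient data, not a negative).
    Bulk q-values are Benjamini-Hochberg over the supplied bulk records.
    """
    out = risk.copy()
    if ase_results is not None and len(ase_results):
        tested = set(ase_results["gene_id"])
        support = set(ase_results.loc[ase_results["p"] <= ase_alpha, "gene_id"])
        out["ase_tested"] = out["gene_id"].isin(tested)
        out["ase_support"] = out["gene_id"].isin(support)
    if bulk_meta is not None and len(bulk_meta):
        bulk = bulk_meta.copy()
        bulk["q"] = bh_fdr(bulk["p_re2"].to_numpy())
        tested = set(bulk["gene_id"])
        passed = set(bulk.loc[bulk["q"] <= bulk_fdr, "gene_id"])
        out["bulk_tested"] = out["gene_id"].isin(tested)
        out["bulk_replicated"] = out["gene_id"].isin(passed)
    if dynamic_records is not None and len(dynamic_records):
        dyn = set(dynamic_records.loc[
            dynamic_records["p_interaction"] <= dynamic_alpha, "gene_id"])
        out["dynamic_eqtl"] = out["gene_id"].isin(dyn)
    return out


# ---------------------------------------------------------------------------
# pipeline driver
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """End-to-end run settings: simulation conditions plus thresholds."""

    sim: SimConfig = field(default_factory=SimConfig)
    n_datasets: int = 3
    window_bp: int = 1_000_000
    min_cells: int = 10
    n_hidden: int = 30
    batch_mode: str = "meanvar"
    min_n: int = 20
    alpha: float = 0.05
    clump_r2: float = 0.1
    clump_kb: float = 500.0
    gwas_p1: float = 5e-8
    gwas_p2: float = 1e-6
    pp4_threshold: float = 0.8
    coloc_p1: float = 1e-4
    coloc_p2: float = 1e-4
    coloc_p12: float = 1e-5
    heidi_alpha: float = 0.01
    heidi_missing: str = "fail"
    ase_min_umis: int = 20
    ase_alpha: float = 0.05
    bulk_fdr: float = 0.05
    dynamic_alpha: float = 0.01
    n_bulk_cohorts: int = 2
    run_ase: bool = True
    run_dynamic: bool = True
    run_bulk: bool = True

    @property
    def seed(self) -> int:
        return self.sim.seed


@dataclass
class PipelineResult:
    """All stage outputs of one pipeline run."""

    config: PipelineConfig
    truth: object
    selection: object
    meta: pd.DataFrame
    gwas_chunks: list
    eqtl_chunk_stats: dict
    coloc: pd.DataFrame
    smr: pd.DataFrame
    ase: pd.DataFrame
    dynamic: pd.DataFrame
    bulk_meta: pd.DataFrame
    risk: pd.DataFrame
    detail: pd.DataFrame
    thresholds: dict
    manifest: dict

    def prioritized_genes(self) -> list[str]:
        if not len(self.risk):
            return []
        return sorted(self.risk.loc[self.risk["prioritized"], "gene_id"])

    def summary(self) -> str:
        m = self.manifest
        lines = [
            "cell-type eQTL prioritization run",
            f"  seed: {m['seed']}   datasets: {m['n_datasets']}   "
            f"subjects/dataset: {m['n_subjects']}",
            f"  candidate variants: {m['n_candidate_variants']} "
            f"(classes {m['variant_class_counts']})",
            f"  meta-eQTL tests: {m['n_meta_tests']} "
            f"({m['tier1_n_pairs']} unique eSNP-eGene pairs; "
            f"tier-1 threshold {self.thresholds['tier1_threshold']:.3g})",
            f"  significant eGenes forwarded: {m['tier3_n_forwarded']} "
            f"(tier-3 threshold {self.thresholds['tier3_threshold']:.3g})",
            f"  independent eQTL chunks: {m['n_eqtl_chunks']} "
            f"({m['n_egenes']} primary + {m['n_additional_eqtls']} additional)",
            f"  GWAS chunks: {m['n_gwas_chunks']}",
            f"  prioritized genes: {len(self.prioritized_genes())} "
            f"{self.prioritized_genes()}",
        ]
        return "\n".join(lines)

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.risk.to_csv(out / "risk_genes.tsv", sep="\t", index=False,
                         float_format="%.6g")
        self.detail.to_csv(out / "tier_detail.tsv", sep="\t", index=False,
                           float_format="%.6g")
        self.meta.to_csv(out / "meta_eqtl.tsv", sep="\t", index=False,
                         float_format="%.6g")
        for name, frame in [("coloc", self.coloc), ("smr", self.smr),
                            ("ase", self.ase), ("dynamic", self.dynamic),
                            ("bulk_meta", self.bulk_meta)]:
            frame.to_csv(out / f"{name}.tsv", sep="\t", index=False,
                         float_format="%.6g")
        with open(out / "manifest.json", "w") as fh:
            json.dump(self.manifest, fh, indent=2, sort_keys=True)
            fh.write("\n")


class Pipeline:
    """Driver: simulate (or accept) inputs and run every stage in order."""

    def __init__(self, config: PipelineConfig | None = None):
        self.config = config or PipelineConfig()

    # -- stages ------------------------------------------------------------
    def run(self) -> PipelineResult:
        cfg = self.config
        sim = cfg.sim
        panel = simulate_genotypes(sim, stream=1)
        truth = build_truth(sim, panel)
        annotation = gene_annotation(sim)
        gwas = simulate_gwas(sim, panel, truth, stream=90)
        panel_ld = ld_r(panel)

        loci = _gwas_leads(gwas, cfg.gwas_p1)
        selection = select_candidate_variants(
            gwas, panel, loci, p_significant=cfg.gwas_p1,
            p_subthreshold=cfg.gwas_p2)
        candidate_ids = set(selection.variant_ids())

        # surrogate-variable count must stay well below the gene-panel size;
        # surrogates are estimated from the background (variant-free) genes
        # so they cannot absorb the cis signal under test
        n_hidden = min(cfg.n_hidden, max(1, sim.n_genes // 10))
        locus_genes = {f"gene{i}" for i in range(sim.n_loci)}

        per_dataset: dict[str, pd.DataFrame] = {}
        d1_state = {}
        for d in range(1, cfg.n_datasets + 1):
            name = f"d{d}"
            geno = panel if d == 1 else simulate_genotypes(sim, stream=d)
            cov = simulate_covariates(sim, geno, stream=d)
            cells = simulate_cells(sim, geno, cov, truth, stream=d)
            pbs = normalize_and_pseudobulk(cells, min_cells=cfg.min_cells)
            tables = []
            zscaled = {}
            for ctype, pb in pbs.items():
                sv_mask = np.array([g not in locus_genes for g in pb.genes])
                if not sv_mask.any():
                    sv_mask = None
                adj = adjust_covariates(pb, cov, n_hidden=n_hidden,
                                        batch_mode=cfg.batch_mode,
                                        sv_gene_mask=sv_mask)
                z = zscale(adj)
                zscaled[ctype] = z
                if candidate_ids:
                    tables.append(map_cis(z, geno, annotation,
                                          window_bp=cfg.window_bp,
                                          candidate_ids=candidate_ids,
                                          min_n=cfg.min_n, dataset=name))
            per_dataset[name] = (pd.concat(tables, ignore_index=True)
                                 if tables else pd.DataFrame())
            if d == 1:
                d1_state = {"geno": geno, "cov": cov, "zscaled": zscaled}

        nonempty = {k: v for k, v in per_dataset.items() if len(v)}
        meta = (meta_analyze(nonempty) if nonempty
                else pd.DataFrame(columns=["gene_id", "variant_id",
                                           "cell_type", "p_re2", "beta_re",
                                           "se_re", "n_subjects"]))

        risk, detail, thresholds = apply_four_tiers(
            meta, None, None, alpha=cfg.alpha,
            pp4_threshold=cfg.pp4_threshold, heidi_alpha=cfg.heidi_alpha,
            heidi_missing=cfg.heidi_missing)
        tier1 = thresholds["tier1_threshold"]

        sig = detail[detail["eqtl_significant"]] if len(detail) else detail
        forwarded = sorted(sig["gene_id"].unique()) if len(sig) else []

        eqtl_chunk_stats = _eqtl_chunks(meta, panel_ld, gwas, tier1)
        gwas_chunks = clump(gwas, panel_ld, cfg.gwas_p1, cfg.gwas_p2,
                            cfg.clump_r2, cfg.clump_kb)

        coloc_df, smr_df = self._coloc_and_smr(
            meta, gwas, gwas_chunks, panel, panel_ld, annotation, sig)

        risk, detail, thresholds = apply_four_tiers(
            meta, coloc_df, smr_df, alpha=cfg.alpha,
            pp4_threshold=cfg.pp4_threshold, heidi_alpha=cfg.heidi_alpha,
            heidi_missing=cfg.heidi_missing)

        ase_df = pd.DataFrame(columns=["gene_id", "variant_id", "cell_type",
                                       "log_odds", "p"])
        if cfg.run_ase and len(forwarded):
            raw = simulate_ase(sim, d1_state["geno"], truth, stream=1)
            if len(raw):
                pseudo = pseudobulk_ase(raw, min_umis=cfg.ase_min_umis)
                scan = ase_scan(pseudo, alpha=cfg.ase_alpha)
                ase_df = scan[scan["gene_id"].isin(forwarded)].reset_index(
                    drop=True)

        dynamic_df = pd.DataFrame(columns=["gene_id", "variant_id",
                                           "cell_type", "p_interaction"])
        if cfg.run_dynamic and len(sig):
            parts = []
            for ctype, grp in sig.groupby("cell_type"):
                if ctype not in d1_state["zscaled"]:
                    continue
                pairs = grp.rename(columns={"best_esnp": "variant_id"})
                parts.append(dynamic_interaction(
                    d1_state["zscaled"][ctype], d1_state["geno"],
                    d1_state["cov"], pairs[["gene_id", "variant_id"]],
                    min_n=cfg.min_n, flag_p=cfg.dynamic_alpha))
            if parts:
                dynamic_df = pd.concat(parts, ignore_index=True)

        bulk_meta = pd.DataFrame(columns=["gene_id", "variant_id", "p_re2"])
        if cfg.run_bulk and len(sig):
            bulk_meta = self._bulk_replication(annotation, truth, sig,
                                               candidate_ids)

        risk = annotate_evidence(risk, ase_df, bulk_meta, dynamic_df,
                                 ase_alpha=cfg.ase_alpha,
                                 bulk_fdr=cfg.bulk_fdr,
                                 dynamic_alpha=cfg.dynamic_alpha)
        chunk_map = eqtl_chunk_stats.get("gene_chunk", {})
        if len(risk):
            risk["chunk_id"] = risk["gene_id"].map(
                lambda g: chunk_map.get(g))

        manifest = {
            "package": "cellqtl", "version": __version__,
            "seed": sim.seed, "n_datasets": cfg.n_datasets,
            "n_subjects": sim.n_subjects,
            "n_candidate_variants": selection.total,
            "variant_class_counts": selection.counts,
            "n_meta_tests": int(len(meta)),
            "n_gwas_chunks": len(gwas_chunks),
            "n_eqtl_chunks": eqtl_chunk_stats["n_chunks"],
            "n_egenes": eqtl_chunk_stats["n_egenes"],
            "n_additional_eqtls": eqtl_chunk_stats["n_additional"],
            "pi1_cross_cell_type": eqtl_chunk_stats["pi1"],
            "n_prioritized": int(risk["prioritized"].sum()) if len(risk) else 0,
            **{k: v for k, v in thresholds.items()},
        }
        return PipelineResult(
            config=cfg, truth=truth, selection=selection, meta=meta,
            gwas_chunks=gwas_chunks, eqtl_chunk_stats=eqtl_chunk_stats,
            coloc=coloc_df, smr=smr_df, ase=ase_df, dynamic=dynamic_df,
            bulk_meta=bulk_meta, risk=risk, detail=detail,
            thresholds=thresholds, manifest=manifest)

    # -- helpers -----------------------------------------------------------
    def _coloc_and_smr(self, meta, gwas, gwas_chunks, panel, panel_ld,
                       annotation, sig):
        cfg = self.config
        from .coloc import COLOC_COLUMNS
        from .smr import SMR_COLUMNS
        coloc_rows = pd.DataFrame(columns=COLOC_COLUMNS)
        smr_rows = pd.DataFrame(columns=SMR_COLUMNS)
        if not len(sig):
            return coloc_rows, smr_rows
        ann = {g.gene_id: g for g in annotation}
        cis_ranges = {g: (ann[g].chrom, ann[g].start - cfg.window_bp,
                          ann[g].end + cfg.window_bp)
                      for g in sig["gene_id"].unique()}
        panel_vars = {v.id: v for v in panel.variants}
        eaf = dict(zip(panel.variant_ids, panel.eaf()))
        n_total = cfg.sim.n_subjects * cfg.n_datasets

        eqtl_stats: dict[tuple[str, str], SummaryStatsTable] = {}
        gwas_idx = gwas.table.set_index("snp")
        smr_list = []
        for row in sig.itertuples(index=False):
            grp = meta[(meta["gene_id"] == row.gene_id)
                       & (meta["cell_type"] == row.cell_type)]
            recs = []
            for r in grp.itertuples(index=False):
                v = panel_vars[r.variant_id]
                recs.append((v.id, v.chrom, v.pos, v.a1, v.a2,
                             eaf[v.id], r.beta_re, r.se_re,
                             max(r.p_re2, 1e-300), n_total))
            table = pd.DataFrame(recs, columns=["snp", "chrom", "pos", "a1",
                                                "a2", "eaf", "beta", "se",
                                                "p", "n"])
            stats_t = SummaryStatsTable(
                trait=f"{row.gene_id}:{row.cell_type}", table=table)
            eqtl_stats[(row.gene_id, row.cell_type)] = stats_t

            et = table.set_index("snp")[["beta", "se", "p"]]
            shared = [s for s in et.index if s in gwas_idx.index]
            gt = gwas_idx.loc[shared, ["beta", "se", "p"]]
            res = run_smr(row.gene_id, row.cell_type, et.loc[shared], gt,
                          panel_ld)
            if res is not None:
                smr_list.append(res.row())
        if smr_list:
            smr_rows = pd.DataFrame(smr_list, columns=SMR_COLUMNS)
        coloc_rows = pair_and_run(
            eqtl_stats, gwas, gwas_chunks, cis_ranges,
            threshold=cfg.pp4_threshold, p1=cfg.coloc_p1, p2=cfg.coloc_p2,
            p12=cfg.coloc_p12)
        return coloc_rows, smr_rows

    def _bulk_replication(self, annotation, truth, sig, candidate_ids):
        """RE2 meta of the forwarded pairs across simulated bulk cohorts."""
        cfg = self.config
        tables = {}
        for c in range(cfg.n_bulk_cohorts):
            stream = 50 + c
            geno = simulate_genotypes(cfg.sim, stream=stream,
                                      subject_prefix="B")
            cov = simulate_covariates(cfg.sim, geno, stream=stream)
            pb = simulate_bulk(cfg.sim, geno, cov, truth, stream=stream)
            locus_genes = {f"gene{i}" for i in range(cfg.sim.n_loci)}
            sv_mask = np.array([g not in locus_genes for g in pb.genes])
            adj = adjust_covariates(
                pb, cov, batch_mode=cfg.batch_mode,
                n_hidden=min(cfg.n_hidden, max(1, cfg.sim.n_genes // 10)),
                sv_gene_mask=sv_mask if sv_mask.any() else None)
            z = zscale(adj)
            tables[f"bulk{c}"] = map_cis(z, geno, annotation,
                                         window_bp=cfg.window_bp,
                                         candidate_ids=candidate_ids,
                                         min_n=cfg.min_n, dataset=f"bulk{c}")
        nonempty = {k: v for k, v in tables.items() if len(v)}
        if not nonempty:
            return pd.DataFrame(columns=["gene_id", "variant_id", "p_re2"])
        bulk = meta_analyze(nonempty)
        pairs = set(zip(sig["gene_id"], sig["best_esnp"]))
        keep = [(g, v) in pairs for g, v in
                zip(bulk["gene_id"], bulk["variant_id"])]
        return bulk[keep].reset_index(drop=True)


def _gwas_leads(gwas: SummaryStatsTable, p1: float,
                min_gap_bp: int = 2_000_000) -> list[tuple[str, int]]:
    """Distance-pruned GWAS lead positions (smallest p first)."""
    t = gwas.table[gwas.table["p"] <= p1].sort_values(
        ["p", "pos", "snp"], kind="mergesort")
    leads: list[tuple[str, int]] = []
    for row in t.itertuples(index=False):
        if all(row.chrom != c or abs(row.pos - p) > min_gap_bp
               for c, p in leads):
            leads.append((row.chrom, int(row.pos)))
    return leads


def _eqtl_chunks(meta: pd.DataFrame, panel_ld, gwas, tier1: float) -> dict:
    """Per-gene LD chunking of significant eSNPs; sharing diagnostics.

    Primary eQTL = first (smallest-p) chunk per eGene; additional =
    further independent chunks of the same gene.  The pi1 statistic
    estimates cross-cell-type sharing from the p-values that significant
    eSNPs attain in the other cell types.
    """
    out = {"n_chunks": 0, "n_egenes": 0, "n_additional": 0, "pi1": None,
           "gene_chunk": {}}
    if not len(meta):
        return out
    sig = meta[meta["p_re2"] <= tier1]
    if not len(sig):
        return out
    pos = dict(zip(gwas.table["snp"], gwas.table["pos"]))
    n_chunks = 0
    for gene, grp in sig.groupby("gene_id"):
        best = grp.groupby("variant_id")["p_re2"].min().reset_index()
        table = pd.DataFrame({
            "snp": best["variant_id"],
            "chrom": "1", "pos": [pos.get(v, 0) for v in best["variant_id"]],
            "a1": "A", "a2": "G", "eaf": 0.5,
            "beta": 1.0, "se": 1.0, "p": best["p_re2"].clip(lower=1e-300),
            "n": 1})
        stats_t = SummaryStatsTable(trait=gene, table=table)
        chunks = clump(stats_t, panel_ld, p1=tier1, p2=tier1,
                       r2_thresh=0.1, kb=500.0)
        if chunks:
            out["gene_chunk"][gene] = chunks[0].chunk_id
        n_chunks += len(chunks)
        out["n_egenes"] += 1 if chunks else 0
    out["n_chunks"] = n_chunks
    out["n_additional"] = n_chunks - out["n_egenes"]
    # cross-cell-type sharing: p-values of significant eSNPs in other cells
    sig_keys = set(zip(sig["gene_id"], sig["variant_id"], sig["cell_type"]))
    sig_pairs = set(zip(sig["gene_id"], sig["variant_id"]))
    others = meta[[(g, v) in sig_pairs and (g, v, c) not in sig_keys
                   for g, v, c in zip(meta["gene_id"], meta["variant_id"],
                                      meta["cell_type"])]]
    if len(others) >= 10:
        out["pi1"] = float(pi1(others["p_re2"].clip(1e-300, 1.0).to_numpy()))
    return out


def run_pipeline(config: PipelineConfig | None = None,
                 out_dir: str | Path | None = None) -> PipelineResult:
    """Execute the full pipeline; optionally write the output directory."""
    result = Pipeline(config).run()
    if out_dir is not None:
        result.write(out_dir)
    return result
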
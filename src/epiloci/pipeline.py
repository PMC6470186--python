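"""End-to-end orchestration: config validation and the full analysis run.

Stages: indirect comparison -> suggestive selection + locus assembly ->
enhancer overlap -> cell-type enrichment (+ binned fold change) -> optional
LD-cluster sensitivity analysis -> per-locus gene prioritization with drug
annotation -> moderated-t differential expression -> the combined locus
report. Each stage consumes and produces plain TSV files, so stages are
independently runnable; a structured run log records seed, thresholds and
per-stage row counts. Outputs carry no timestamps, so a rerun with the same
inputs and seed is byte-identical.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, fields as dc_fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import degx, enrich, genes as genes_mod, ldclust, loci as loci_mod, overlap, sumstats

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Invalid pipeline configuration (unknown key, bad type or bound)."""


@dataclass
class PipelineConfig:
    """All pipeline inputs and thresholds; defaults are the study constants."""

    sumstats_a: str = ""
    sumstats_b: str = ""
    enhancers: str = ""                 # combined BED with cell type in column 4
    eqtls: str = ""
    genes: str = ""
    drugs: str = ""
    expression: str = ""
    expression_groups: dict = field(default_factory=dict)
    genotype_panel: str | None = None   # optional: enables the LD-cluster stage
    outdir: str = "results"

    p_thresh: float = 1e-4
    mhc_mask: tuple = ("6", 26_000_000, 34_000_000)
    max_gap: int = 500_000
    fisher_alternative: str = "two-sided"
    baseline_mode: str = "any"
    bin_width: float = 1.0
    r2_threshold: float = 0.9
    n_perm: int = 999
    fdr_threshold: float = 0.05
    indication_filter: tuple = ("arthritis",)
    seed: int = 0

    def validate(self) -> "PipelineConfig":
        if not (0.0 < self.p_thresh < 1.0):
            raise ConfigError(f"p_thresh: must be in (0, 1), got {self.p_thresh}")
        if self.max_gap <= 0:
            raise ConfigError(f"max_gap: must be > 0, got {self.max_gap}")
        if not (0.0 < self.r2_threshold < 1.0):
            raise ConfigError(f"r2_threshold: must be in (0, 1), got {self.r2_threshold}")
        if not (0.0 < self.fdr_threshold < 1.0):
            raise ConfigError(f"fdr_threshold: must be in (0, 1), got {self.fdr_threshold}")
        if self.fisher_alternative not in ("two-sided", "greater"):
            raise ConfigError(f"fisher_alternative: got {self.fisher_alternative!r}")
        if self.baseline_mode not in ("any", "any_other"):
            raise ConfigError(f"baseline_mode: got {self.baseline_mode!r}")
        if self.n_perm < 100:
            raise ConfigError(f"n_perm: must be >= 100, got {self.n_perm}")
        if not (0.0 < self.bin_width):
            raise ConfigError(f"bin_width: must be > 0, got {self.bin_width}")
        mask = tuple(self.mhc_mask)
        if len(mask) != 3 or not all(isinstance(x, (int, np.integer)) for x in mask[1:]):
            raise ConfigError(f"mhc_mask: expected (chrom, start, end), got {self.mhc_mask!r}")
        self.mhc_mask = (str(mask[0]), int(mask[1]), int(mask[2]))
        self.indication_filter = tuple(self.indication_filter)
        return self


def validate_config(path) -> PipelineConfig:
    """Load and normalize a YAML pipeline config; unknown keys are rejected."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: config must be a mapping")
    known = {f.name for f in dc_fields(PipelineConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"{path}: unknown config key(s): {sorted(unknown)}")
    numeric = {"p_thresh": float, "bin_width": float, "r2_threshold": float,
               "fdr_threshold": float, "max_gap": int, "n_perm": int, "seed": int}
    for key, typ in numeric.items():
        if key in raw:
            try:
                raw[key] = typ(raw[key])
            except (TypeError, ValueError):
                raise ConfigError(f"{path}: {key}: expected {typ.__name__}, "
                                  f"got {raw[key]!r}") from None
    cfg = PipelineConfig(**raw).validate()
    logger.info("config: %s", cfg)
    return cfg


def _fmt_p(p: float) -> str:
    return f"{p:.3g}"


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute every stage and write the report bundle under ``cfg.outdir``.

    Returns the in-memory results (DataFrames keyed by stage). Raises on any
    stage failure after logging the stage name.
    """
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    log_lines = [
        f"epiloci {__version__}",
        f"seed={cfg.seed} p_thresh={cfg.p_thresh} max_gap={cfg.max_gap} "
        f"mhc_mask={cfg.mhc_mask[0]}:{cfg.mhc_mask[1]}-{cfg.mhc_mask[2]} "
        f"fisher_alternative={cfg.fisher_alternative} baseline={cfg.baseline_mode} "
        f"bin_width={cfg.bin_width} r2_threshold={cfg.r2_threshold} "
        f"n_perm={cfg.n_perm} fdr_threshold={cfg.fdr_threshold}",
    ]
    results: dict = {}

    def stage(name):
        def deco(fn):
            try:
                fn()
            except Exception:
                log_lines.append(f"stage {name}: FAILED")
                (out / "run_log.txt").write_text("\n".join(log_lines) + "\n")
                logger.exception("stage %s failed", name)
                raise
            return fn
        return deco

    @stage("sumstats")
    def _sumstats():
        df_a = sumstats.read_sumstats(cfg.sumstats_a)
        df_b = sumstats.read_sumstats(cfg.sumstats_b)
        indirect = sumstats.compare_sumstats(df_a, df_b)
        sumstats.write_indirect(indirect, out / "indirect.tsv")
        results["indirect"] = indirect
        log_lines.append(
            f"stage sumstats: {len(df_a)}+{len(df_b)} markers in -> "
            f"{len(indirect)} compared"
        )

    @stage("loci")
    def _loci():
        indirect = results["indirect"]
        sugg = loci_mod.select_suggestive(indirect, cfg.p_thresh, cfg.mhc_mask)
        assembled = loci_mod.assemble_loci(sugg, cfg.max_gap)
        loci_mod.loci_to_frame(assembled).to_csv(out / "loci.tsv", sep="\t", index=False)
        results["suggestive"] = sugg
        results["loci"] = assembled
        log_lines.append(
            f"stage loci: {len(indirect)} markers in -> {len(sugg)} suggestive "
            f"kept -> {len(assembled)} loci formed"
        )

    @stage("overlap")
    def _overlap():
        tracks = overlap.read_bed_multi(cfg.enhancers)
        markers = results["indirect"][["id", "chrom", "pos", "p"]]
        om = overlap.build_overlap_matrix(markers, tracks)
        overlap.write_overlap_matrix(om, out / "overlap_matrix.tsv")
        results["om"] = om
        log_lines.append(
            f"stage overlap: {len(tracks)} tracks x {len(markers)} markers -> "
            f"{int(om.any_overlap.sum())} any-overlap markers"
        )

    @stage("enrich")
    def _enrich():
        om = results["om"]
        sugg_ids = set(results["suggestive"]["id"])
        suggestive = pd.Series(
            [i in sugg_ids for i in om.incidence.index], index=om.incidence.index
        )
        enr = enrich.celltype_enrichment(
            om, suggestive, loci=results["loci"],
            alternative=cfg.fisher_alternative, baseline=cfg.baseline_mode,
        )
        enr.to_csv(out / "enrichment.tsv", sep="\t", index=False)
        p_series = results["indirect"].set_index("id")["p"]
        fc = enrich.binned_fold_change(p_series, om, bin_width=cfg.bin_width)
        fc.to_csv(out / "binned_fc.tsv", sep="\t", index=False)
        results["enrichment"] = enr
        results["binned_fc"] = fc
        results["suggestive_flags"] = suggestive
        enriched = enr.loc[enr["p_bonf"] < 0.05, "cell_type"].tolist()
        results["enriched_celltypes"] = enriched
        log_lines.append(
            f"stage enrich: {len(enr)} cell types tested -> "
            f"{len(enriched)} Bonferroni-significant: {','.join(enriched) or '-'}"
        )

    @stage("ldclust")
    def _ldclust():
        if not cfg.genotype_panel:
            log_lines.append("stage ldclust: skipped (no genotype panel)")
            return
        panel = ldclust.read_panel_tsv(cfg.genotype_panel)
        sugg = results["suggestive"]
        keep = sugg[sugg["id"].isin(panel.marker_ids)]
        idx = [panel.marker_ids.index(i) for i in keep["id"]]
        sub = ldclust.GenotypePanel(
            marker_ids=tuple(keep["id"]),
            sample_ids=panel.sample_ids,
            dosages=panel.dosages[idx],
        )
        r2 = ldclust.r2_matrix(sub)
        labels, heights = ldclust.ward_cluster(1.0 - r2, cut_height=1.0 - cfg.r2_threshold)
        reps = ldclust.cluster_representatives(labels, keep)
        ldclust.cluster_table(labels, keep, reps).to_csv(
            out / "ld_clusters.tsv", sep="\t", index=False
        )
        om = results["om"]
        pool = [i for i in om.incidence.index if i not in set(sugg["id"])]
        perm_p = ldclust.cluster_enrichment_null(
            reps, om, pool, n_perm=cfg.n_perm, seed=cfg.seed
        )
        perm_df = perm_p.rename_axis("cell_type").reset_index()
        perm_df.to_csv(out / "cluster_enrichment.tsv", sep="\t", index=False)
        results["ld_clusters"] = labels
        results["cluster_perm_p"] = perm_p
        log_lines.append(
            f"stage ldclust: {len(keep)} markers -> {labels.max()} clusters "
            f"(cut {1.0 - cfg.r2_threshold:g}) -> {cfg.n_perm} permutations"
        )

    @stage("genes")
    def _genes():
        om = results["om"]
        eqtls = genes_mod.read_eqtls(cfg.eqtls)
        gene_ann = genes_mod.read_gene_annotation(cfg.genes)
        drugs = genes_mod.read_drug_targets(cfg.drugs)
        enriched = results["enriched_celltypes"]
        inc = om.incidence
        p_of = results["indirect"].set_index("id")["p"]
        pos_of = results["indirect"].set_index("id")["pos"]
        candidates, cand_rows = {}, []
        for locus in results["loci"]:
            member_inc = inc.loc[list(locus.marker_ids), enriched] if enriched else None
            if member_inc is None or not member_inc.to_numpy().any():
                continue
            over_ids = member_inc.index[member_inc.any(axis=1)]
            over = pd.DataFrame(
                {"id": over_ids, "pos": pos_of.loc[over_ids].to_numpy(),
                 "p": p_of.loc[over_ids].to_numpy()}
            )
            cand = genes_mod.prioritize_gene(locus, over, eqtls, gene_ann)
            ann = (genes_mod.annotate_drugs(cand.gene, drugs, set(cfg.indication_filter))
                   if cand.gene else genes_mod.DrugAnnotation(gene="", drugs=()))
            candidates[locus.label] = (locus, over, cand, ann)
        results["candidates"] = candidates
        log_lines.append(
            f"stage genes: {len(results['loci'])} loci -> "
            f"{len(candidates)} overlapping enriched-cell-type enhancers"
        )

    @stage("degx")
    def _degx():
        expr = degx.read_expression(cfg.expression, dict(cfg.expression_groups))
        per_probe, hp = degx.fit_moderated_t(expr)
        per_gene = degx.collapse_probesets(per_probe, expr.probe_to_gene)
        called = degx.call_degs(per_gene, cfg.fdr_threshold)
        degx.write_degs(called, out / "degs.tsv")
        results["degs"] = called
        results["eb_hyperparams"] = hp
        log_lines.append(
            f"stage degx: {len(per_probe)} probesets -> {len(per_gene)} genes -> "
            f"{int(called['is_deg'].sum())} DEGs at FDR<{cfg.fdr_threshold} "
            f"(d0={hp.d0:.4g}, s0_sq={hp.s0_sq:.4g})"
        )

    @stage("report")
    def _report():
        deg_of = results["degs"].set_index("gene")["is_deg"]
        p_of = results["indirect"].set_index("id")["p"]
        inc = results["om"].incidence
        enriched = results["enriched_celltypes"]
        rows = []
        for label, (locus, over, cand, ann) in results["candidates"].items():
            row = {"locus": label}
            for ct in enriched:
                hit = over["id"][inc.loc[over["id"], ct].to_numpy(bool)]
                row[f"min_p_{ct}"] = _fmt_p(p_of.loc[hit].min()) if len(hit) else "NA"
            row["candidate"] = cand.evidence_string
            row["drugs"] = ",".join(ann.drugs) if ann.drugs else "-"
            row["is_deg"] = (
                int(bool(deg_of.get(cand.gene, False))) if cand.gene else 0
            )
            rows.append(row)
        report = pd.DataFrame(rows)
        if report.empty:
            log_lines.append("stage report: WARNING no locus overlaps an enriched "
                             "cell type; empty report")
            report = pd.DataFrame(columns=["locus", "candidate", "drugs", "is_deg"])
        report.to_csv(out / "locus_report.tsv", sep="\t", index=False)
        results["report"] = report
        log_lines.append(f"stage report: {len(report)} locus rows written")

    (out / "run_log.txt").write_text("\n".join(log_lines) + "\n")
    return results
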
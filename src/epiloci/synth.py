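"""Seeded synthetic inputs with the statistical structure the pipeline assumes.

The default scenario mirrors the study design the pipeline targets: two
case-vs-control summary-statistic sets whose indirect comparison yields
~165 suggestive markers in ~49 loci outside the MHC, ~20 enhancer tracks of
which two are planted with odds ratio 3 for suggestive-marker overlap, an
LD reference panel with block structure over the planted loci, an eQTL
table where each planted locus's causal gene carries the strongest signal,
a drug-target table tagging a subset of causal genes with arthritis drugs,
and a 3-vs-3 log2 expression matrix drawn from the scaled inverse-chi-square
variance hierarchy (d0 = 4, s0^2 = 0.05) with planted fold changes.

Every generator is a pure function of (config, seed): generators derive
independent deterministic streams from ``cfg.seed`` so each stage is
reproducible in isolation.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, asdict, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from . import loci as loci_mod
from . import sumstats as sumstats_mod
from .ldclust import GenotypePanel
from .overlap import EnhancerTrack, merge_intervals, incidence_to_matrix
from .degx import ExpressionMatrix

logger = logging.getLogger(__name__)

_CHROM_LEN = 200_000_000          # null markers live in [1, _CHROM_LEN]
_PLANTED_BASE = 205_000_000       # planted loci in reserved bands above this
_PLANTED_SLOT = 2_000_000         # one band per planted locus

_ARTHRITIS_DRUGS = (
    "celecoxib", "diclofenac", "indomethacin", "piroxicam", "azathioprine",
    "cyclosporine", "methotrexate", "dexamethasone", "prednisone",
)
_OTHER_INDICATIONS = ("hypertension", "diabetes", "asthma")

# substream tags so each generator draws independently of the others
_STREAMS = {"sumstats": 1, "tracks": 2, "panel": 3, "tables": 4}


@dataclass(frozen=True)
class SynthConfig:
    """Scenario parameters; defaults encode the target study's conditions."""

    seed: int = 0
    # association scan
    n_markers: int = 20_000
    n_chroms: int = 22
    se: float = 0.05
    beta_sd: float = 0.1
    n_planted_loci: int = 49
    markers_per_locus_mean: float = 165 / 49
    planted_z: float = 8.0
    allele_swap_rate: float = 0.1
    # enhancer tracks
    n_celltypes: int = 20
    n_planted_celltypes: int = 2
    planted_or: float = 3.0
    base_overlap_rate: float = 0.3
    interval_len_range: tuple[int, int] = (200, 2000)
    # genotype panel
    n_samples: int = 200
    block_r2: float = 0.95
    maf_range: tuple[float, float] = (0.1, 0.5)
    missing_rate: float = 0.0
    # gene / eQTL / drug tables
    decoy_genes_per_locus: int = 2
    drug_fraction: float = 0.8
    # expression
    n_genes: int = 2000
    probes_per_gene: int = 2
    d0: float = 4.0
    s0_sq: float = 0.05
    pi_de: float = 0.1
    log_fc_loc: float = 1.2
    log_fc_scale: float = 0.2
    n_per_group: int = 3

    def __post_init__(self) -> None:
        for name in ("base_overlap_rate", "drug_fraction", "block_r2"):
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise ValueError(f"{name} must be in (0, 1), got {v}")
        if not (0.0 <= self.pi_de < 1.0):
            raise ValueError(f"pi_de must be in [0, 1), got {self.pi_de}")
        if not self.planted_or > 0:
            raise ValueError(f"planted_or must be > 0, got {self.planted_or}")
        if self.n_planted_celltypes > self.n_celltypes:
            raise ValueError("more planted cell types than cell types")

    def rng(self, stream: str) -> np.random.Generator:
        return np.random.default_rng([int(self.seed), _STREAMS[stream]])


def celltype_labels(cfg: SynthConfig) -> list[str]:
    return [f"CT{i:02d}" for i in range(cfg.n_celltypes)]


def planted_celltypes(cfg: SynthConfig) -> list[str]:
    return celltype_labels(cfg)[: cfg.n_planted_celltypes]


# ---------------------------------------------------------------- sumstats

def gen_sumstats(cfg: SynthConfig):
    """Two summary-statistic tables plus ground truth.

    Null markers share a true effect between comparisons (indirect chi2
    central); planted-locus markers differ by delta = planted_z*sqrt(2)*se
    (noncentral). Planted loci sit in reserved coordinate bands disjoint
    from null positions, so they are recoverable exactly. A fraction of
    table-b rows have ref/alt swapped (beta negated) to exercise allele
    harmonization.

    Returns ``(df_a, df_b, truth)`` where ``truth`` has keys
    ``markers`` (DataFrame with is_planted, planted_locus) and ``loci``
    (DataFrame with chrom, start, end, marker_ids).
    """
    rng = cfg.rng("sumstats")
    chroms, positions, planted_locus = [], [], []

    per_chrom = np.full(cfg.n_chroms, cfg.n_markers // cfg.n_chroms)
    per_chrom[: cfg.n_markers % cfg.n_chroms] += 1
    for c in range(cfg.n_chroms):
        pos = np.sort(rng.choice(_CHROM_LEN - 1, size=per_chrom[c], replace=False) + 1)
        chroms.extend([str(c + 1)] * per_chrom[c])
        positions.extend(pos.tolist())
        planted_locus.extend([-1] * per_chrom[c])

    n_members = rng.poisson(max(cfg.markers_per_locus_mean - 1.0, 0.0),
                            size=cfg.n_planted_loci) + 1
    slots_per_chrom = np.zeros(cfg.n_chroms, dtype=int)
    for li in range(cfg.n_planted_loci):
        c = li % cfg.n_chroms
        base = _PLANTED_BASE + slots_per_chrom[c] * _PLANTED_SLOT
        slots_per_chrom[c] += 1
        gaps = rng.integers(10_000, 150_000, size=n_members[li])
        pos = base + np.cumsum(gaps)
        chroms.extend([str(c + 1)] * n_members[li])
        positions.extend(pos.tolist())
        planted_locus.extend([li] * n_members[li])

    df = pd.DataFrame({"chrom": chroms, "pos": positions, "planted_locus": planted_locus})
    df = df.sort_values(["planted_locus", "chrom", "pos"]).reset_index(drop=True)
    df = df.sort_values(
        by=["chrom", "pos"],
        key=lambda s: s.astype(int) if s.name == "chrom" else s,
        kind="mergesort",
    ).reset_index(drop=True)
    n = len(df)
    df["id"] = [f"rs{i:07d}" for i in range(n)]

    bases = np.array(list("ACGT"))
    ref_i = rng.integers(0, 4, size=n)
    alt_i = (ref_i + rng.integers(1, 4, size=n)) % 4
    df["ref"], df["alt"] = bases[ref_i], bases[alt_i]

    shared = rng.normal(0.0, cfg.beta_sd, size=n)
    delta = np.where(df["planted_locus"] >= 0, cfg.planted_z * np.sqrt(2.0) * cfg.se, 0.0)
    beta_a = shared + delta / 2.0 + rng.normal(0.0, cfg.se, size=n)
    beta_b = shared - delta / 2.0 + rng.normal(0.0, cfg.se, size=n)

    def table(beta: np.ndarray, ref, alt) -> pd.DataFrame:
        z = beta / cfg.se
        p = np.clip(2.0 * stats.norm.sf(np.abs(z)), np.nextafter(0, 1), 1.0)
        return pd.DataFrame(
            {
                "chrom": df["chrom"], "pos": df["pos"], "id": df["id"],
                "ref": ref, "alt": alt,
                "beta": beta, "se": cfg.se, "p": p,
            }
        )

    df_a = table(beta_a, df["ref"], df["alt"])
    swap = rng.random(n) < cfg.allele_swap_rate
    ref_b = np.where(swap, df["alt"], df["ref"])
    alt_b = np.where(swap, df["ref"], df["alt"])
    df_b = table(np.where(swap, -beta_b, beta_b), ref_b, alt_b)

    truth_markers = df[["id", "chrom", "pos", "planted_locus"]].copy()
    truth_markers["is_planted"] = truth_markers["planted_locus"] >= 0
    planted = truth_markers[truth_markers["is_planted"]]
    truth_loci = (
        planted.groupby("planted_locus")
        .agg(chrom=("chrom", "first"), start=("pos", "min"), end=("pos", "max"),
             marker_ids=("id", tuple))
        .reset_index()
    )
    return df_a, df_b, {"markers": truth_markers, "loci": truth_loci}


# ------------------------------------------------------------------ tracks

def planted_overlap_rate(cfg: SynthConfig) -> float:
    """Suggestive-marker overlap rate q' solving q'/(1-q') = OR * q/(1-q)."""
    odds = cfg.planted_or * cfg.base_overlap_rate / (1.0 - cfg.base_overlap_rate)
    return odds / (1.0 + odds)


def gen_overlap_incidence(
    cfg: SynthConfig,
    marker_ids,
    suggestive: np.ndarray,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Marker x cell-type Bernoulli incidence with planted odds ratios.

    Non-planted cell types (and non-suggestive markers everywhere) overlap
    with probability ``base_overlap_rate``; suggestive markers of planted
    cell types use the elevated rate from :func:`planted_overlap_rate`.
    """
    if rng is None:
        rng = cfg.rng("tracks")
    suggestive = np.asarray(suggestive, dtype=bool)
    n = len(marker_ids)
    q, qp = cfg.base_overlap_rate, planted_overlap_rate(cfg)
    prob = np.full((n, cfg.n_celltypes), q)
    prob[suggestive, : cfg.n_planted_celltypes] = qp
    draws = rng.random((n, cfg.n_celltypes)) < prob
    return pd.DataFrame(draws, index=pd.Index(marker_ids, name="id"),
                        columns=celltype_labels(cfg))


def gen_enhancer_tracks(
    cfg: SynthConfig, markers: pd.DataFrame, suggestive: np.ndarray
) -> tuple[list[EnhancerTrack], pd.DataFrame]:
    """Materialize BED-style tracks realizing a drawn incidence exactly.

    Each (marker, cell type) success places a 200-2,000 bp interval covering
    the marker point, clipped so it cannot reach a neighboring marker's
    point; misses place nothing. Returns ``(tracks, incidence)`` where the
    incidence is the exact ground truth the tracks encode.
    """
    rng = cfg.rng("tracks")
    incidence = gen_overlap_incidence(cfg, markers["id"], suggestive, rng=rng)
    lo, hi = cfg.interval_len_range

    order = markers.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
    inc_np = incidence.loc[order["id"]].to_numpy(bool)
    pos0 = order["pos"].to_numpy(np.int64) - 1
    chrom_arr = order["chrom"].astype(str).to_numpy()

    lengths = rng.integers(lo, hi + 1, size=inc_np.shape)
    offsets = (rng.random(inc_np.shape) * lengths).astype(np.int64)

    prev_pos = np.empty_like(pos0)
    next_pos = np.empty_like(pos0)
    prev_pos[0], next_pos[-1] = -1, np.iinfo(np.int64).max
    same_prev = chrom_arr[1:] == chrom_arr[:-1]
    prev_pos[1:] = np.where(same_prev, pos0[:-1], -1)
    next_pos[:-1] = np.where(same_prev, pos0[1:], np.iinfo(np.int64).max)

    tracks = []
    for j, ct in enumerate(incidence.columns):
        hit = inc_np[:, j]
        s = np.maximum(pos0[hit] - offsets[hit, j], prev_pos[hit] + 1)
        s = np.maximum(s, 0)
        e = np.minimum(s + lengths[hit, j], next_pos[hit])
        intervals = {}
        for chrom in pd.unique(chrom_arr[hit]):
            sel = chrom_arr[hit] == chrom
            intervals[str(chrom)] = merge_intervals(s[sel], e[sel])
        tracks.append(EnhancerTrack(cell_type=str(ct), intervals=intervals))
    return tracks, incidence


# ------------------------------------------------------------------- panel

def gen_genotype_panel(
    cfg: SynthConfig, marker_ids, block_ids
) -> GenotypePanel:
    """Block-LD dosage panel: within a block markers copy a latent haplotype.

    Per block, two latent gamete vectors are drawn at a random MAF; each
    marker flips each gamete allele independently with probability
    eps = (1 - block_r2**(1/4)) / 2, which calibrates the expected pairwise
    r^2 within a block to ``block_r2`` (eps = 0 gives r^2 = 1). Blocks are
    independent.
    """
    rng = cfg.rng("panel")
    marker_ids = list(marker_ids)
    block_ids = np.asarray(block_ids)
    eps = (1.0 - cfg.block_r2 ** 0.25) / 2.0
    dosages = np.empty((len(marker_ids), cfg.n_samples))
    for block in pd.unique(block_ids):
        rows = np.flatnonzero(block_ids == block)
        maf = rng.uniform(*cfg.maf_range)
        latent = rng.random((cfg.n_samples, 2)) < maf
        for i in rows:
            flips = rng.random((cfg.n_samples, 2)) < eps
            dosages[i] = (latent ^ flips).sum(axis=1)
    if cfg.missing_rate > 0:
        dosages[rng.random(dosages.shape) < cfg.missing_rate] = np.nan
    return GenotypePanel(
        marker_ids=tuple(marker_ids),
        sample_ids=tuple(f"S{i:04d}" for i in range(cfg.n_samples)),
        dosages=dosages,
    )


# ------------------------------------------------- gene tables + expression

def gen_tables_and_expression(cfg: SynthConfig, loci_truth: pd.DataFrame):
    """eQTL, drug-target and gene-annotation tables plus an expression matrix.

    Each planted locus gets a causal gene spanning its center whose eQTL p
    (1e-20..1e-8 scale) beats every decoy record (1e-4..1e-1); a
    ``drug_fraction`` subset of causal genes is linked to arthritis-tagged
    drugs. Expression follows the inverse-chi-square variance hierarchy with
    all causal genes differentially expressed plus a ``pi_de`` fraction of
    filler genes.

    Returns ``(eqtl_df, drug_df, gene_df, expression, truth)``.
    """
    rng = cfg.rng("tables")
    gene_rows, eqtl_rows, drug_rows = [], [], []
    causal_genes: dict[int, str] = {}

    for row in loci_truth.itertuples(index=False):
        li = int(row.planted_locus)
        gene = f"GENE{li:03d}"
        causal_genes[li] = gene
        center = (int(row.start) + int(row.end)) // 2
        gene_rows.append((str(row.chrom), center - 10_000, center + 10_000, "+", gene))
        for j in range(cfg.decoy_genes_per_locus):
            off = 150_000 * (j + 1) * (1 if j % 2 == 0 else -1)
            gene_rows.append(
                (str(row.chrom), center + off, center + off + 20_000, "-", f"{gene}D{j}")
            )
        for mid in row.marker_ids:
            eqtl_rows.append((mid, gene, 10.0 ** -rng.uniform(8, 20)))
            if cfg.decoy_genes_per_locus and rng.random() < 0.5:
                dj = int(rng.integers(cfg.decoy_genes_per_locus))
                eqtl_rows.append((mid, f"{gene}D{dj}", 10.0 ** -rng.uniform(1, 4)))

    with_drug = [li for li in causal_genes if rng.random() < cfg.drug_fraction]
    for li in with_drug:
        n_drugs = int(rng.integers(1, 4))
        picks = rng.choice(len(_ARTHRITIS_DRUGS), size=n_drugs, replace=False)
        for k in picks:
            drug_rows.append((_ARTHRITIS_DRUGS[k], causal_genes[li], "arthritis"))
    # distractors: wrong-indication rows for causal genes and unrelated genes
    for li in causal_genes:
        if rng.random() < 0.3:
            drug_rows.append(
                (f"drug_x{li}", causal_genes[li],
                 _OTHER_INDICATIONS[int(rng.integers(len(_OTHER_INDICATIONS)))])
            )

    gene_df = pd.DataFrame(gene_rows, columns=["chrom", "start", "end", "strand", "symbol"])
    eqtl_df = pd.DataFrame(eqtl_rows, columns=["marker_id", "gene", "p"])
    drug_df = pd.DataFrame(drug_rows, columns=["drug", "gene", "indication"])

    # ---- expression -------------------------------------------------------
    genes = list(causal_genes.values())
    genes += [f"FILL{i:04d}" for i in range(cfg.n_genes - len(genes))]
    n_genes = len(genes)
    is_causal = np.zeros(n_genes, dtype=bool)
    is_causal[: len(causal_genes)] = True
    de = is_causal | (rng.random(n_genes) < cfg.pi_de)
    sign = np.where(rng.random(n_genes) < 0.5, 1.0, -1.0)
    lfc = np.where(de, sign * rng.normal(cfg.log_fc_loc, cfg.log_fc_scale, n_genes), 0.0)

    n1 = n2 = cfg.n_per_group
    samples = [f"pre_{i+1}" for i in range(n1)] + [f"post_{i+1}" for i in range(n2)]
    group = pd.Series(["pre"] * n1 + ["post"] * n2, index=samples, name="group")

    probe_ids, rows, probe_to_gene = [], [], {}
    baseline = rng.normal(7.0, 1.0, size=n_genes)
    for gi, gene in enumerate(genes):
        for pj in range(cfg.probes_per_gene):
            sigma_sq = cfg.s0_sq * cfg.d0 / rng.chisquare(cfg.d0)
            mu = np.concatenate(
                [np.full(n1, baseline[gi] - lfc[gi] / 2.0),
                 np.full(n2, baseline[gi] + lfc[gi] / 2.0)]
            )
            rows.append(mu + rng.normal(0.0, np.sqrt(sigma_sq), size=n1 + n2))
            pid = f"{gene}_at{pj}"
            probe_ids.append(pid)
            probe_to_gene[pid] = gene
    expr = ExpressionMatrix(
        values=pd.DataFrame(rows, index=pd.Index(probe_ids, name="probeset"), columns=samples),
        group=group,
        probe_to_gene=probe_to_gene,
    )
    truth = {
        "causal_genes": causal_genes,
        "drug_genes": {li: causal_genes[li] for li in with_drug},
        "deg_genes": [g for g, flag in zip(genes, de) if flag],
        "log_fc": dict(zip(genes, lfc)),
    }
    return eqtl_df, drug_df, gene_df, expr, truth


# ------------------------------------------------------------------ bundle

def gen_scenario(cfg: SynthConfig) -> dict:
    """Generate the full in-memory scenario (all inputs plus ground truth)."""
    df_a, df_b, assoc_truth = gen_sumstats(cfg)
    indirect = sumstats_mod.compare_sumstats(df_a, df_b)
    suggestive_df = loci_mod.select_suggestive(indirect)
    suggestive_ids = set(suggestive_df["id"])
    markers = indirect[["id", "chrom", "pos", "p"]]
    sugg_mask = markers["id"].isin(suggestive_ids).to_numpy()

    tracks, incidence = gen_enhancer_tracks(cfg, markers, sugg_mask)

    assembled = loci_mod.assemble_loci(suggestive_df)
    block_of = loci_mod.marker_locus_map(assembled)
    sugg = suggestive_df.sort_values(["chrom", "pos"], kind="mergesort")
    panel = gen_genotype_panel(cfg, sugg["id"], [block_of[i] for i in sugg["id"]])

    eqtl_df, drug_df, gene_df, expr, expr_truth = gen_tables_and_expression(
        cfg, assoc_truth["loci"]
    )
    return {
        "config": cfg,
        "sumstats_a": df_a,
        "sumstats_b": df_b,
        "indirect": indirect,
        "markers": markers,
        "suggestive_mask": sugg_mask,
        "tracks": tracks,
        "incidence": incidence,
        "panel": panel,
        "eqtls": eqtl_df,
        "drugs": drug_df,
        "genes": gene_df,
        "expression": expr,
        "truth": {**assoc_truth, **expr_truth,
                  "planted_celltypes": planted_celltypes(cfg)},
    }


def write_bundle(cfg: SynthConfig, outdir) -> Path:
    """Emit a complete input bundle plus ground-truth manifest and a ready
    pipeline config (``config.yaml``) into ``outdir``."""
    import yaml

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    sc = gen_scenario(cfg)

    sumstats_mod.write_sumstats(sc["sumstats_a"], out / "sumstats_a.tsv")
    sumstats_mod.write_sumstats(sc["sumstats_b"], out / "sumstats_b.tsv")

    with open(out / "enhancers.bed", "w") as fh:
        for t in sc["tracks"]:
            for chrom in sorted(t.intervals):
                starts, ends = t.intervals[chrom]
                for s, e in zip(starts, ends):
                    fh.write(f"{chrom}\t{s}\t{e}\t{t.cell_type}\n")

    panel = sc["panel"]
    pd.DataFrame(panel.dosages, index=list(panel.marker_ids),
                 columns=list(panel.sample_ids)).to_csv(
        out / "panel.tsv", sep="\t", na_rep="NA")

    sc["eqtls"].to_csv(out / "eqtls.tsv", sep="\t", index=False)
    sc["drugs"].to_csv(out / "drugs.tsv", sep="\t", index=False)
    sc["genes"].to_csv(out / "genes.tsv", sep="\t", index=False)

    expr = sc["expression"]
    expr_out = expr.values.copy()
    expr_out.insert(0, "gene", [expr.probe_to_gene[p] for p in expr_out.index])
    expr_out.to_csv(out / "expression.tsv", sep="\t")

    truth = sc["truth"]
    manifest = {
        "seed": cfg.seed,
        "planted_celltypes": truth["planted_celltypes"],
        "planted_loci": [
            {"locus": int(r.planted_locus), "chrom": str(r.chrom),
             "start": int(r.start), "end": int(r.end),
             "marker_ids": list(r.marker_ids),
             "causal_gene": truth["causal_genes"][int(r.planted_locus)]}
            for r in truth["loci"].itertuples(index=False)
        ],
        "deg_genes": truth["deg_genes"],
        "drug_genes": {str(k): v for k, v in truth["drug_genes"].items()},
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)

    pipe_cfg = {
        "sumstats_a": str(out / "sumstats_a.tsv"),
        "sumstats_b": str(out / "sumstats_b.tsv"),
        "enhancers": str(out / "enhancers.bed"),
        "genotype_panel": str(out / "panel.tsv"),
        "eqtls": str(out / "eqtls.tsv"),
        "genes": str(out / "genes.tsv"),
        "drugs": str(out / "drugs.tsv"),
        "expression": str(out / "expression.tsv"),
        "expression_groups": {s: g for s, g in expr.group.items()},
        "seed": int(cfg.seed),
        "outdir": str(out / "results"),
    }
    with open(out / "config.yaml", "w") as fh:
        yaml.safe_dump(pipe_cfg, fh, sort_keys=True)
    return out
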
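"""Candidate-gene prioritization per locus and drug-target annotation.

For each locus whose markers overlap enhancers of an enriched cell type,
the candidate gene is the strongest eQTL target among those overlapping
markers (smallest eQTL p; ties broken by marker-to-gene distance, then gene
symbol). Loci without any eQTL record fall back to the gene nearest the
lead overlapping marker. Candidates are then annotated with drugs whose
recorded indication matches a filter (e.g. "arthritis").
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .loci import Locus

logger = logging.getLogger(__name__)

DEFAULT_PROXIMITY_WINDOW = 1_000_000


@dataclass(frozen=True)
class GeneCandidate:
    """One locus's prioritized gene with its evidence trail.

    Exactly one of ``eqtl_p`` (evidence="eqtl") or ``distance_bp``
    (evidence="proximity") is populated; ``gene`` is None when neither an
    eQTL nor a gene within the proximity window exists.
    """

    locus_label: str
    gene: str | None
    evidence: str | None           # "eqtl" | "proximity" | None
    eqtl_p: float | None
    distance_bp: int | None
    source_marker: str | None

    @property
    def evidence_string(self) -> str:
        """Render Table-style evidence: 'GENE (eQTL: p = ...; marker)' etc."""
        if self.gene is None:
            return "none"
        if self.evidence == "eqtl":
            return f"{self.gene} (eQTL: p = {self.eqtl_p:.3g}; {self.source_marker})"
        if self.distance_bp == 0:
            return f"{self.gene} (proximity: intragenic; {self.source_marker})"
        return f"{self.gene} (proximity: {self.distance_bp / 1000:g} kb; {self.source_marker})"


@dataclass(frozen=True)
class DrugAnnotation:
    """Drugs (with indication tags) targeting one gene, deduplicated."""

    gene: str
    drugs: tuple[str, ...]


def read_gene_annotation(path) -> pd.DataFrame:
    """Gene spans TSV: chrom, start, end, strand, symbol (1-based inclusive)."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"chrom": str})
    need = {"chrom", "start", "end", "strand", "symbol"}
    missing = need - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing column(s): {sorted(missing)}")
    return df


def read_eqtls(path) -> pd.DataFrame:
    """eQTL table TSV: marker_id, gene, p."""
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = {"marker_id", "gene", "p"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing column(s): {sorted(missing)}")
    return df


def read_drug_targets(path) -> pd.DataFrame:
    """Drug-target table TSV: drug, gene, indication."""
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = {"drug", "gene", "indication"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing column(s): {sorted(missing)}")
    return df


def _span_distance(pos: int, start: int, end: int) -> int:
    """Gap from a 1-based position to a 1-based inclusive span (0 if inside)."""
    if pos < start:
        return start - pos
    if pos > end:
        return pos - end
    return 0


def prioritize_gene(
    locus: Locus,
    overlapping_markers: pd.DataFrame,
    eqtls: pd.DataFrame,
    genes: pd.DataFrame,
    window: int = DEFAULT_PROXIMITY_WINDOW,
    cis_window: int | None = None,
) -> GeneCandidate:
    """Pick the locus's candidate gene: best eQTL first, nearest gene second.

    ``overlapping_markers`` are the locus members overlapping enriched-cell-
    type enhancers (columns ``id pos p``); they must be a subset of the
    locus's marker ids. ``cis_window``, if given, drops eQTL records whose
    marker-to-gene distance exceeds it (records for genes without an
    annotated span are kept — the eQTL table is trusted as given).
    """
    if overlapping_markers.empty:
        raise ValueError(f"locus {locus.label}: no overlapping markers")
    extra = set(overlapping_markers["id"]) - set(locus.marker_ids)
    if extra:
        raise ValueError(f"locus {locus.label}: markers not in locus: {sorted(extra)}")

    pos_of = dict(zip(overlapping_markers["id"], overlapping_markers["pos"].astype(int)))
    spans = genes[genes["chrom"].astype(str) == str(locus.chrom)]

    def gene_distance(marker_id: str, gene: str) -> float:
        rows = spans[spans["symbol"] == gene]
        if rows.empty:
            return math.inf
        return min(
            _span_distance(pos_of[marker_id], int(r.start), int(r.end))
            for r in rows.itertuples(index=False)
        )

    hits = eqtls[eqtls["marker_id"].isin(pos_of)].copy()
    if not hits.empty and cis_window is not None:
        dist = [gene_distance(r.marker_id, r.gene) for r in hits.itertuples(index=False)]
        hits = hits[[d <= cis_window or math.isinf(d) for d in dist]]
    if not hits.empty:
        hits["_dist"] = [gene_distance(r.marker_id, r.gene) for r in hits.itertuples(index=False)]
        hits = hits.sort_values(["p", "_dist", "gene"], kind="mergesort")
        best = hits.iloc[0]
        return GeneCandidate(
            locus_label=locus.label,
            gene=str(best["gene"]),
            evidence="eqtl",
            eqtl_p=float(best["p"]),
            distance_bp=None,
            source_marker=str(best["marker_id"]),
        )

    # proximity fallback: gene nearest the lead overlapping marker
    lead = overlapping_markers.sort_values(["p", "pos"], kind="mergesort").iloc[0]
    lead_pos = int(lead["pos"])
    if spans.empty:
        logger.warning("locus %s: no genes annotated on chromosome %s", locus.label, locus.chrom)
        return GeneCandidate(locus.label, None, None, None, None, None)
    d = np.minimum(
        np.abs(spans["start"].to_numpy(int) - lead_pos),
        np.abs(spans["end"].to_numpy(int) - lead_pos),
    )
    inside = (spans["start"].to_numpy(int) <= lead_pos) & (lead_pos <= spans["end"].to_numpy(int))
    d = np.where(inside, 0, d)
    order = np.lexsort((spans["symbol"].to_numpy(), d))
    best_i = order[0]
    if d[best_i] > window:
        logger.warning(
            "locus %s: no gene within %d bp of lead marker and no eQTL", locus.label, window
        )
        return GeneCandidate(locus.label, None, None, None, None, None)
    return GeneCandidate(
        locus_label=locus.label,
        gene=str(spans["symbol"].iloc[best_i]),
        evidence="proximity",
        eqtl_p=None,
        distance_bp=int(d[best_i]),
        source_marker=str(lead["id"]),
    )


def annotate_drugs(
    gene: str,
    drug_targets: pd.DataFrame,
    indication_filter: set[str] = frozenset({"arthritis"}),
) -> DrugAnnotation:
    """Drugs targeting ``gene`` whose indication is in the filter.

    Drug names are deduplicated case-insensitively (first spelling wins)
    and returned sorted case-insensitively. An empty annotation is allowed.
    """
    if not indication_filter:
        raise ValueError("indication_filter must be non-empty")
    filt = {s.lower() for s in indication_filter}
    rows = drug_targets[
        (drug_targets["gene"] == gene)
        & (drug_targets["indication"].astype(str).str.lower().isin(filt))
    ]
    seen: dict[str, str] = {}
    for name in sorted(rows["drug"].astype(str), key=str.lower):
        seen.setdefault(name.lower(), name)
    return DrugAnnotation(gene=gene, drugs=tuple(seen.values()))
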
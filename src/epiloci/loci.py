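"""Suggestive-marker selection and locus assembly.

Markers with association p below the suggestive threshold (default 1e-4,
strict) and outside the MHC mask (default chr6:26,000,000-34,000,000,
inclusive) are grouped into loci: contiguous runs where consecutive sorted
positions on a chromosome differ by less than ``max_gap`` (default 500 kb,
strict). This greedy sweep equals the transitive closure of the pairwise
"< max_gap" relation on a line.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DEFAULT_P_THRESH = 1e-4
DEFAULT_MAX_GAP = 500_000
#: MHC mask: chromosome, start, end (1-based, both bounds inclusive)
DEFAULT_MHC_MASK = ("6", 26_000_000, 34_000_000)


@dataclass(frozen=True)
class Locus:
    """A contiguous group of suggestive markers on one chromosome.

    ``start``/``end`` are the min/max member positions (1-based inclusive);
    ``lead_id`` is the member with the smallest p.
    """

    chrom: str
    start: int
    end: int
    marker_ids: tuple[str, ...]
    lead_id: str
    min_p: float

    @property
    def label(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"

    @property
    def n_markers(self) -> int:
        return len(self.marker_ids)


def _norm_chrom(c) -> str:
    c = str(c)
    return c[3:] if c.lower().startswith("chr") else c


def select_suggestive(
    markers: pd.DataFrame,
    p_thresh: float = DEFAULT_P_THRESH,
    mask: tuple[str, int, int] | None = DEFAULT_MHC_MASK,
) -> pd.DataFrame:
    """Markers with p strictly below ``p_thresh`` and outside the mask.

    ``markers`` needs columns ``id chrom pos p``. The mask test is inclusive
    on both bounds; chromosome labels are compared with any "chr" prefix
    stripped. An empty result is allowed.
    """
    if not (0.0 < p_thresh < 1.0):
        raise ValueError(f"p_thresh must be in (0, 1), got {p_thresh}")
    keep = markers["p"].to_numpy(float) < p_thresh
    if mask is not None:
        mchrom, mstart, mend = mask
        chroms = markers["chrom"].map(_norm_chrom)
        pos = markers["pos"].to_numpy(np.int64)
        in_mask = (chroms == _norm_chrom(mchrom)).to_numpy() & (pos >= mstart) & (pos <= mend)
        keep &= ~in_mask
    return markers.loc[keep].copy()


def _dedupe(markers: pd.DataFrame) -> pd.DataFrame:
    # duplicate (chrom,pos): keep smaller p, then lexicographically smaller id
    dup = markers.duplicated(subset=["chrom", "pos"], keep=False)
    if not dup.any():
        return markers
    n0 = len(markers)
    markers = (
        markers.sort_values(["chrom", "pos", "p", "id"], kind="mergesort")
        .drop_duplicates(subset=["chrom", "pos"], keep="first")
    )
    logger.warning("collapsed %d duplicate-position markers", n0 - len(markers))
    return markers


def assemble_loci(markers: pd.DataFrame, max_gap: int = DEFAULT_MAX_GAP) -> list[Locus]:
    """Group selected markers into loci by the strict ``< max_gap`` rule.

    Returns loci sorted by (chrom, start); members within a locus are in
    position order. Input order is irrelevant. Duplicate (chrom, pos)
    markers collapse to the one with the smaller p (logged).
    """
    if max_gap <= 0:
        raise ValueError(f"max_gap must be > 0, got {max_gap}")
    if markers.empty:
        return []
    markers = _dedupe(markers)
    out: list[Locus] = []
    ordered = markers.sort_values(["chrom", "pos"], kind="mergesort")
    for chrom, grp in ordered.groupby("chrom", sort=True):
        pos = grp["pos"].to_numpy(np.int64)
        breaks = np.flatnonzero(np.diff(pos) >= max_gap) + 1
        for block in np.split(np.arange(len(grp)), breaks):
            sub = grp.iloc[block]
            lead = sub.sort_values(["p", "id"], kind="mergesort").iloc[0]
            out.append(
                Locus(
                    chrom=str(chrom),
                    start=int(sub["pos"].min()),
                    end=int(sub["pos"].max()),
                    marker_ids=tuple(sub["id"]),
                    lead_id=str(lead["id"]),
                    min_p=float(lead["p"]),
                )
            )
    out.sort(key=lambda l: (l.chrom, l.start))
    return out


def loci_to_frame(loci: list[Locus]) -> pd.DataFrame:
    """Tabulate loci: locus_label, chrom, start, end, n_markers, lead_id, min_p."""
    return pd.DataFrame(
        {
            "locus_label": [l.label for l in loci],
            "chrom": [l.chrom for l in loci],
            "start": [l.start for l in loci],
            "end": [l.end for l in loci],
            "n_markers": [l.n_markers for l in loci],
            "lead_id": [l.lead_id for l in loci],
            "min_p": [l.min_p for l in loci],
        }
    )


def lead_windows(loci: list[Locus], markers: pd.DataFrame, half_width: int = 500_000) -> pd.DataFrame:
    """Alternative report: fixed window of ±half_width around each lead marker.

    Some published locus tables are exactly ``2*half_width`` wide, suggesting
    lead-marker windows rather than marker-span hulls; this view is offered
    alongside :func:`loci_to_frame` without preferring either.
    """
    pos_of = dict(zip(markers["id"], markers["pos"].astype(int)))
    rows = []
    for l in loci:
        center = pos_of[l.lead_id]
        rows.append(
            {
                "locus_label": l.label,
                "chrom": l.chrom,
                "window_start": max(1, center - half_width),
                "window_end": center + half_width,
                "lead_id": l.lead_id,
                "min_p": l.min_p,
            }
        )
    return pd.DataFrame(rows)


def marker_locus_map(loci: list[Locus]) -> dict[str, str]:
    """Map member marker id -> locus label."""
    return {mid: l.label for l in loci for mid in l.marker_ids}
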
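"""Enhancer-track loading and marker x cell-type overlap incidence.

Tracks are BED3+ interval sets (0-based, half-open), one per cell type,
marking H3K27ac active enhancers. Markers are points at their 1-based
variant position (indels: leftmost base): a marker at position p overlaps
[s, e) iff s <= p-1 < e, so BED interval [10, 20) covers 1-based positions
11..20. Lookup is a binary search over per-chromosome merged intervals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


class BedFormatError(ValueError):
    """Malformed BED line (non-integer coordinates, start >= end)."""


@dataclass(frozen=True)
class EnhancerTrack:
    """Sorted, merged, non-overlapping intervals of one cell type's enhancers.

    ``intervals`` maps chromosome -> (starts, ends) int64 arrays, 0-based
    half-open, sorted by start with no two intervals overlapping or abutting.
    """

    cell_type: str
    intervals: dict[str, tuple[np.ndarray, np.ndarray]]

    @property
    def n_intervals(self) -> int:
        return sum(len(s) for s, _ in self.intervals.values())


@dataclass(frozen=True)
class OverlapMatrix:
    """Boolean markers x cell-types incidence with the any-cell-type column.

    ``incidence`` is indexed by marker id with one column per cell type;
    ``any_overlap`` is the row-wise OR (the enrichment baseline indicator).
    """

    incidence: pd.DataFrame
    any_overlap: pd.Series

    @property
    def marker_ids(self) -> list[str]:
        return list(self.incidence.index)

    @property
    def cell_types(self) -> list[str]:
        return list(self.incidence.columns)


def merge_intervals(starts, ends) -> tuple[np.ndarray, np.ndarray]:
    """Sort and merge intervals; abutting intervals merge (half-open adjacency)."""
    starts = np.asarray(starts, dtype=np.int64)
    ends = np.asarray(ends, dtype=np.int64)
    if starts.size == 0:
        return starts, ends
    order = np.argsort(starts, kind="stable")
    starts, ends = starts[order], ends[order]
    ms, me = [starts[0]], [ends[0]]
    for s, e in zip(starts[1:], ends[1:]):
        if s <= me[-1]:  # overlap or abut
            me[-1] = max(me[-1], e)
        else:
            ms.append(s)
            me.append(e)
    return np.array(ms, dtype=np.int64), np.array(me, dtype=np.int64)


def _track_from_frame(df: pd.DataFrame, cell_type: str) -> EnhancerTrack:
    intervals = {}
    for chrom, grp in df.groupby("chrom", sort=True):
        intervals[str(chrom)] = merge_intervals(grp["start"], grp["end"])
    return EnhancerTrack(cell_type=cell_type, intervals=intervals)


def _parse_bed_lines(path, n_fields: int):
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < n_fields:
                raise BedFormatError(f"{path}, line {lineno}: expected >= {n_fields} fields")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError:
                raise BedFormatError(
                    f"{path}, line {lineno}: non-integer coordinates {parts[1]!r}/{parts[2]!r}"
                ) from None
            if start >= end:
                raise BedFormatError(f"{path}, line {lineno}: start {start} >= end {end}")
            rows.append((parts[0], start, end) + tuple(parts[3:n_fields]))
    return rows


def read_bed(path, cell_type: str) -> EnhancerTrack:
    """Read one cell type's BED3+ file; intervals are merged per chromosome.

    Columns beyond the first three are ignored. An empty file yields a track
    with zero intervals.
    """
    rows = _parse_bed_lines(path, 3)
    df = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    return _track_from_frame(df, cell_type)


def read_bed_multi(path) -> list[EnhancerTrack]:
    """Read a combined BED file with the cell type in column 4.

    Returns one merged track per cell type, in order of first appearance.
    """
    rows = _parse_bed_lines(path, 4)
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "cell_type"])
    tracks = []
    for ct in dict.fromkeys(df["cell_type"]):
        tracks.append(_track_from_frame(df[df["cell_type"] == ct], str(ct)))
    return tracks


def marker_overlaps(markers: pd.DataFrame, track: EnhancerTrack) -> np.ndarray:
    """Boolean per marker: does the marker point fall in a track interval?

    ``markers`` needs columns ``chrom pos`` (1-based positions). Chromosomes
    absent from the track yield False (logged once per chromosome).
    """
    out = np.zeros(len(markers), dtype=bool)
    pos0 = markers["pos"].to_numpy(np.int64) - 1  # to 0-based point
    chroms = markers["chrom"].astype(str).to_numpy()
    for chrom in pd.unique(chroms):
        sel = chroms == chrom
        if chrom not in track.intervals:
            logger.debug("track %s: no intervals on chromosome %s", track.cell_type, chrom)
            continue
        starts, ends = track.intervals[chrom]
        if starts.size == 0:
            continue
        idx = np.searchsorted(starts, pos0[sel], side="right") - 1
        hit = (idx >= 0) & (pos0[sel] < ends[np.clip(idx, 0, None)])
        out[sel] = hit
    return out


def build_overlap_matrix(markers: pd.DataFrame, tracks: list[EnhancerTrack]) -> OverlapMatrix:
    """Assemble the incidence matrix; column order follows input track order."""
    if not tracks:
        raise ValueError("at least one enhancer track is required")
    labels = [t.cell_type for t in tracks]
    if len(set(labels)) != len(labels):
        seen, dups = set(), set()
        for l in labels:
            (dups if l in seen else seen).add(l)
        raise ValueError(f"duplicate cell_type label(s): {sorted(dups)}")
    data = {t.cell_type: marker_overlaps(markers, t) for t in tracks}
    incidence = pd.DataFrame(data, index=pd.Index(markers["id"], name="id"))
    return OverlapMatrix(incidence=incidence, any_overlap=incidence.any(axis=1))


def incidence_to_matrix(incidence: pd.DataFrame) -> OverlapMatrix:
    """Wrap a precomputed boolean incidence frame (rows: marker ids)."""
    return OverlapMatrix(incidence=incidence.astype(bool), any_overlap=incidence.any(axis=1))


def write_overlap_matrix(om: OverlapMatrix, path) -> None:
    df = om.incidence.astype(int).copy()
    df["any_overlap"] = om.any_overlap.astype(int)
    df.to_csv(path, sep="\t")
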
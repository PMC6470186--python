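"""LD-based clustering of suggestive markers and the permutation sensitivity test.

Marker-level enrichment can double-count markers in strong linkage
disequilibrium. As a sensitivity analysis, suggestive markers are clustered
by 1 - r^2 distance with Ward's criterion (the squared-distance ward.D2
variant), the tree is cut at d = 1 - r2_threshold (default r^2 = 0.9), one
representative per cluster is kept (smallest association p), and each cell
type's overlap count among representatives is compared with draws of
equally many markers from a pool of non-suggestive markers:

    perm_p = (1 + #{perm stat >= observed}) / (1 + n_perm).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

logger = logging.getLogger(__name__)

MAX_MISSING_FRACTION = 0.2


@dataclass(frozen=True)
class GenotypePanel:
    """Reference genotypes: markers x samples allele-count dosages.

    ``dosages`` is float with values in {0, 1, 2} or NaN for missing.
    """

    marker_ids: tuple[str, ...]
    sample_ids: tuple[str, ...]
    dosages: np.ndarray

    def __post_init__(self) -> None:
        d = self.dosages
        if d.shape != (len(self.marker_ids), len(self.sample_ids)):
            raise ValueError("dosage matrix shape does not match id lists")
        if len(self.sample_ids) < 2:
            raise ValueError("a genotype panel needs >= 2 samples")
        ok = np.isnan(d) | np.isin(d, (0.0, 1.0, 2.0))
        if not ok.all():
            raise ValueError("dosages must be 0/1/2 or missing")


@dataclass(frozen=True)
class LDClusterResult:
    """Cluster assignments, merge heights and the permutation p-values."""

    assignments: pd.Series          # marker id -> cluster id (1-based)
    merge_heights: np.ndarray
    representatives: tuple[str, ...]
    perm_p: pd.Series               # cell type -> empirical p
    n_perm: int
    seed: int | None


def read_panel_tsv(path) -> GenotypePanel:
    """Read a dosage matrix TSV: rows markers, columns samples, values 0/1/2/NA."""
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA", "na", ""])
    return GenotypePanel(
        marker_ids=tuple(str(i) for i in df.index),
        sample_ids=tuple(str(c) for c in df.columns),
        dosages=df.to_numpy(float),
    )


def read_panel_vcf(path) -> GenotypePanel:
    """Read hard-called dosages from the GT fields of an uncompressed VCF."""
    marker_ids, rows = [], []
    samples: list[str] = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("##"):
                continue
            fields = line.rstrip("\n").split("\t")
            if line.startswith("#CHROM"):
                samples = fields[9:]
                continue
            fmt = fields[8].split(":")
            gt_i = fmt.index("GT")
            dosage_row = []
            for cell in fields[9:]:
                gt = cell.split(":")[gt_i].replace("|", "/")
                if "." in gt:
                    dosage_row.append(np.nan)
                else:
                    dosage_row.append(float(sum(int(x) > 0 for x in gt.split("/"))))
            vid = fields[2] if fields[2] != "." else f"{fields[0]}:{fields[1]}"
            marker_ids.append(vid)
            rows.append(dosage_row)
    return GenotypePanel(tuple(marker_ids), tuple(samples), np.array(rows, dtype=float))


def r2_matrix(panel: GenotypePanel) -> np.ndarray:
    """Pairwise-complete squared Pearson correlation of dosage vectors.

    Missing dosages are handled pairwise-complete (composite LD on hard
    calls). Markers with >20% missingness are rejected; monomorphic markers
    (no variance among non-missing samples) raise with the marker names.
    """
    X = panel.dosages
    miss = np.isnan(X)
    frac = miss.mean(axis=1)
    bad = frac > MAX_MISSING_FRACTION
    if bad.any():
        names = [panel.marker_ids[i] for i in np.flatnonzero(bad)]
        raise ValueError(f"markers with >{MAX_MISSING_FRACTION:.0%} missing dosages: {names}")
    with np.errstate(invalid="ignore"):
        mono = np.nanstd(X, axis=1) == 0
    if mono.any():
        names = [panel.marker_ids[i] for i in np.flatnonzero(mono)]
        raise ValueError(f"monomorphic markers: {names}")
    # pairwise-complete moments via zero-filled products and mask counts
    M = (~miss).astype(float)
    X0 = np.where(miss, 0.0, X)
    n = M @ M.T
    sx = X0 @ M.T
    sxx = (X0 * X0) @ M.T
    sxy = X0 @ X0.T
    cov = n * sxy - sx * sx.T
    var = n * sxx - sx**2
    denom = var * var.T
    if np.any(n < 2) or np.any(denom <= 0):
        i = np.flatnonzero((n < 2).any(axis=1) | (denom <= 0).any(axis=1))
        names = [panel.marker_ids[j] for j in i[:5]]
        raise ValueError(f"insufficient pairwise-complete variation (markers {names})")
    r2 = cov**2 / denom
    np.fill_diagonal(r2, 1.0)
    return np.clip(r2, 0.0, 1.0)


def ward_cluster(
    dist: np.ndarray,
    cut_height: float = 0.1,
    method: str = "ward",
) -> tuple[np.ndarray, np.ndarray]:
    """Agglomerative clustering of a distance matrix, cut at ``cut_height``.

    ``method="ward"`` applies the squared-distance Lance-Williams update
    d(ij,k) = sqrt(((n_i+n_k) d_ik^2 + (n_j+n_k) d_jk^2 - n_k d_ij^2) /
    (n_i+n_j+n_k)) (ward.D2). ``method="complete"`` instead guarantees every
    within-cluster pair is within the cut (the constrained-r^2 alternative).

    Returns ``(assignments, merge_heights)``: 1-based cluster labels and the
    linkage heights; clusters are maximal subtrees merged at height <=
    ``cut_height``. A 1x1 matrix yields one singleton.
    """
    dist = np.asarray(dist, dtype=float)
    if dist.ndim != 2 or dist.shape[0] != dist.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(dist, dist.T, atol=1e-12):
        raise ValueError("distance matrix must be symmetric")
    if dist.shape[0] == 1:
        return np.array([1]), np.array([])
    Z = hierarchy.linkage(squareform(dist, checks=False), method=method)
    labels = hierarchy.fcluster(Z, t=cut_height, criterion="distance")
    return labels, Z[:, 2].copy()


def cluster_representatives(
    assignments: np.ndarray, markers: pd.DataFrame
) -> tuple[str, ...]:
    """One representative marker per cluster: smallest p, ties by position.

    ``markers`` rows align with ``assignments`` and need columns ``id pos p``.
    Representatives are returned ordered by cluster id.
    """
    df = markers.reset_index(drop=True).copy()
    df["cluster"] = np.asarray(assignments)
    reps = (
        df.sort_values(["cluster", "p", "pos"], kind="mergesort")
        .groupby("cluster", sort=True)
        .head(1)
    )
    return tuple(reps["id"])


def cluster_enrichment_null(
    representatives,
    om,
    candidate_pool,
    n_perm: int = 999,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> pd.Series:
    """Empirical per-cell-type enrichment p against randomly sampled markers.

    The observed statistic per cell type is the count of representatives
    overlapping that cell type's track; each permutation draws
    ``len(representatives)`` markers uniformly without replacement from
    ``candidate_pool`` (marker ids disjoint from the representatives) and
    recomputes the count. Add-one smoothing keeps p in
    [1/(n_perm+1), 1].
    """
    reps = list(representatives)
    pool = list(candidate_pool)
    if n_perm < 100:
        raise ValueError(f"n_perm must be >= 100, got {n_perm}")
    if set(reps) & set(pool):
        raise ValueError("candidate pool must be disjoint from representatives")
    if len(pool) < len(reps):
        raise ValueError(f"pool of {len(pool)} markers cannot supply {len(reps)} draws")
    inc = om.incidence
    obs = inc.loc[reps].to_numpy(bool).sum(axis=0)
    pool_inc = inc.loc[pool].to_numpy(bool)
    if rng is None:
        rng = np.random.default_rng(seed)
    k, m = len(reps), len(pool)
    # vectorized draws without replacement: k smallest random keys per row
    keys = rng.random((n_perm, m))
    idx = np.argpartition(keys, k - 1, axis=1)[:, :k]
    perm_stats = pool_inc[idx].sum(axis=1)  # n_perm x n_celltypes
    exceed = (perm_stats >= obs[None, :]).sum(axis=0)
    p = (1.0 + exceed) / (1.0 + n_perm)
    return pd.Series(p, index=inc.columns, name="perm_p")


def cluster_table(assignments: np.ndarray, markers: pd.DataFrame,
                  representatives) -> pd.DataFrame:
    """Tabulate marker_id, cluster_id, representative_flag."""
    reps = set(representatives)
    return pd.DataFrame(
        {
            "marker_id": markers["id"].to_numpy(),
            "cluster_id": np.asarray(assignments),
            "representative_flag": [int(i in reps) for i in markers["id"]],
        }
    )
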
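"""GWAS summary statistics I/O and the indirect meta-analysis comparison.

Two case-vs-control GWAS (e.g. PsA vs control and PsC vs control) can be
contrasted without individual-level data by the indirect (Wald difference)
statistic: for a marker typed in both,

    z = (beta_1 - beta_2) / sqrt(se_1^2 + se_2^2),   chi2 = z^2  (1 df).

Correlation between the two comparisons (e.g. shared controls) is ignored by
default; an optional covariance term is exposed for sensitivity analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

#: required columns of a summary-statistics table, in canonical order
SUMSTAT_COLUMNS = ("chrom", "pos", "id", "ref", "alt", "beta", "se", "p")


class SumstatsFormatError(ValueError):
    """Malformed summary-statistics file (missing column, bad row)."""


class AlleleMismatchError(ValueError):
    """Two records for one marker whose alleles cannot be reconciled."""


@dataclass(frozen=True)
class MarkerAssoc:
    """One marker's association record for one case-vs-control comparison.

    Positions are 1-based; ``beta`` is on the log-odds scale with standard
    error ``se``; ``p`` is the association p-value.
    """

    chrom: str
    pos: int
    id: str
    ref: str
    alt: str
    beta: float
    se: float
    p: float

    def __post_init__(self) -> None:
        if not (0.0 < self.p <= 1.0):
            raise ValueError(f"marker {self.id}: p must be in (0, 1], got {self.p}")
        if not self.se > 0:
            raise ValueError(f"marker {self.id}: se must be > 0, got {self.se}")
        if self.pos < 1:
            raise ValueError(f"marker {self.id}: pos must be >= 1, got {self.pos}")


@dataclass(frozen=True)
class IndirectComparison:
    """Indirect meta-analysis result for one marker: 1-df chi-square and p."""

    id: str
    chi2: float
    p: float


def _validate_frame(df: pd.DataFrame, path: str, header_offset: int) -> pd.DataFrame:
    for col in ("pos", "beta", "se", "p"):
        numeric = pd.to_numeric(df[col], errors="coerce")
        bad = numeric.isna() & df[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise SumstatsFormatError(
                f"{path}, line {row + header_offset + 2}: non-numeric value "
                f"{df[col].iloc[row]!r} in column '{col}'"
            )
        df[col] = numeric
    checks = [
        ("p", (df["p"] <= 0) | (df["p"] > 1), "p must be in (0, 1]"),
        ("se", df["se"] <= 0, "se must be > 0"),
        ("pos", df["pos"] < 1, "pos must be >= 1"),
    ]
    for col, bad, msg in checks:
        bad = bad | df[col].isna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise SumstatsFormatError(
                f"{path}, line {row + header_offset + 2}: {msg} "
                f"(got {df[col].iloc[row]!r})"
            )
    df["pos"] = df["pos"].astype(np.int64)
    dup = df.duplicated(subset=["chrom", "pos", "ref", "alt"])
    if dup.any():
        row = int(np.flatnonzero(dup.to_numpy())[0])
        raise SumstatsFormatError(
            f"{path}, line {row + header_offset + 2}: duplicate (chrom, pos, ref, alt)"
        )
    return df


def read_sumstats(path) -> pd.DataFrame:
    """Read a tab-separated summary-statistics table.

    The header must name at least ``chrom pos id ref alt beta se p``
    (case-insensitive); ``#`` lines are ignored. Rows are returned in file
    order with numeric fields validated (p in (0,1], se>0, pos>=1).
    """
    path = str(path)
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    df.columns = [c.lower() for c in df.columns]
    missing = [c for c in SUMSTAT_COLUMNS if c not in df.columns]
    if missing:
        raise SumstatsFormatError(f"{path}: missing required column(s): {', '.join(missing)}")
    # line numbers reported below assume '#' lines (if any) precede the header
    with open(path) as fh:
        header_offset = 0
        for line in fh:
            if line.startswith("#"):
                header_offset += 1
            else:
                break
    df = df[list(SUMSTAT_COLUMNS)].copy()
    return _validate_frame(df, path, header_offset)


def write_sumstats(df: pd.DataFrame, path) -> None:
    """Write a summary-statistics table as TSV with the canonical header."""
    df[list(SUMSTAT_COLUMNS)].to_csv(path, sep="\t", index=False)


def records(df: pd.DataFrame) -> list[MarkerAssoc]:
    """Materialize a validated table as a list of :class:`MarkerAssoc`."""
    return [MarkerAssoc(str(r.chrom), int(r.pos), str(r.id), str(r.ref), str(r.alt),
                        float(r.beta), float(r.se), float(r.p))
            for r in df.itertuples(index=False)]


def _harmonized_beta(a: MarkerAssoc, b: MarkerAssoc) -> float:
    """Return b.beta on a's allele orientation.

    Ref/alt swaps are resolved by negating b.beta; strand flips are NOT
    auto-resolved (silent strand guessing is a known error source).
    """
    if (a.ref, a.alt) == (b.ref, b.alt):
        return b.beta
    if (a.ref, a.alt) == (b.alt, b.ref):
        return -b.beta
    raise AlleleMismatchError(
        f"marker {a.id}: irreconcilable alleles {a.ref}/{a.alt} vs {b.ref}/{b.alt}"
    )


def indirect_meta_chi2(a: MarkerAssoc, b: MarkerAssoc, cov: float = 0.0) -> IndirectComparison:
    """Indirect meta-analysis chi-square for one marker typed in two comparisons.

    chi2 = (beta_a - beta_b)^2 / (se_a^2 + se_b^2 - 2*cov), 1 df; symmetric
    in (a, b). ``cov`` is an optional covariance between the two estimates
    (shared controls), default 0.
    """
    if a.id != b.id:
        raise ValueError(f"marker id mismatch: {a.id!r} vs {b.id!r}")
    beta_b = _harmonized_beta(a, b)
    var = a.se**2 + b.se**2 - 2.0 * cov
    if var <= 0:
        raise ValueError(f"marker {a.id}: non-positive variance of the difference ({var})")
    chi2 = (a.beta - beta_b) ** 2 / var
    p = float(stats.chi2.sf(chi2, df=1)) if chi2 > 0 else 1.0
    return IndirectComparison(id=a.id, chi2=float(chi2), p=p)


def compare_sumstats(df_a: pd.DataFrame, df_b: pd.DataFrame, cov: float = 0.0) -> pd.DataFrame:
    """Vectorized indirect comparison of two summary-statistic tables.

    Markers are joined on ``id``; b's beta is flipped where its ref/alt are
    swapped relative to a's. Markers private to one table are dropped;
    markers with irreconcilable alleles raise.

    Returns a DataFrame with columns ``id chrom pos chi2 p`` in a's order.
    """
    m = df_a.merge(df_b, on="id", suffixes=("_a", "_b"), validate="one_to_one")
    same = (m["ref_a"] == m["ref_b"]) & (m["alt_a"] == m["alt_b"])
    swap = (m["ref_a"] == m["alt_b"]) & (m["alt_a"] == m["ref_b"])
    bad = ~(same | swap)
    if bad.any():
        ids = m.loc[bad, "id"].head(5).tolist()
        raise AlleleMismatchError(f"irreconcilable alleles for marker(s): {ids}")
    beta_b = np.where(swap & ~same, -m["beta_b"].to_numpy(float), m["beta_b"].to_numpy(float))
    var = m["se_a"].to_numpy(float) ** 2 + m["se_b"].to_numpy(float) ** 2 - 2.0 * cov
    if np.any(var <= 0):
        raise ValueError("non-positive variance of the difference for some markers")
    chi2 = (m["beta_a"].to_numpy(float) - beta_b) ** 2 / var
    out = pd.DataFrame(
        {
            "id": m["id"],
            "chrom": m["chrom_a"],
            "pos": m["pos_a"],
            "chi2": chi2,
            "p": stats.chi2.sf(chi2, df=1),
        }
    )
    out.loc[out["chi2"] == 0, "p"] = 1.0
    return out


def write_indirect(df: pd.DataFrame, path) -> None:
    """Write an indirect-comparison table (id, chrom, pos, chi2, p) as TSV."""
    df[["id", "chrom", "pos", "chi2", "p"]].to_csv(path, sep="\t", index=False)
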
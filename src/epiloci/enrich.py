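"""Cell-type enrichment of suggestive markers among enhancer-overlapping markers.

The baseline reference is the set of markers overlapping an active enhancer
of ANY cell type. For each cell type k the 2x2 table over baseline markers is

                     overlap k   no overlap k
    suggestive           a            b
    non-suggestive       c            d

tested by Fisher's exact test, Bonferroni-corrected over the number of cell
types with at least one overlapping baseline marker. Binned fold-change
profiles report, per -log10(p) bin, each cell type's overlap proportion
relative to the [0,1) reference bin.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.stats.contingency import odds_ratio as _cond_odds_ratio

from .loci import Locus, marker_locus_map

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class EnrichmentResult:
    """Per-cell-type 2x2 counts, odds ratios and exact-test p-values."""

    cell_type: str
    a: int
    b: int
    c: int
    d: int
    odds_ratio: float        # sample cross-product a*d/(b*c)
    odds_ratio_cmle: float   # conditional MLE, for reference
    p: float
    p_bonf: float
    n_suggestive_markers: int
    n_loci: int


def fisher_exact(a: int, b: int, c: int, d: int, alternative: str = "two-sided"):
    """Fisher's exact test on the 2x2 table [[a, b], [c, d]].

    Returns ``(odds_ratio, p)`` where the odds ratio is the sample
    cross-product a*d/(b*c) (inf if b*c == 0 with a*d > 0, 0 in the opposite
    corner case, NaN if both products are 0). The p-value is the exact
    conditional (hypergeometric) tail; the two-sided p sums probabilities of
    tables no more likely than the observed one (relative tolerance 1e-7).

    Both margins of the table must be positive.
    """
    if alternative not in ("two-sided", "greater"):
        raise ValueError(f"alternative must be 'two-sided' or 'greater', got {alternative!r}")
    for name, v in (("a", a), ("b", b), ("c", c), ("d", d)):
        if v < 0:
            raise ValueError(f"count {name} must be >= 0, got {v}")
    if a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0:
        raise ValueError(f"zero margin in 2x2 table ({a}, {b}; {c}, {d})")
    ad, bc = a * d, b * c
    if ad == 0 and bc == 0:
        or_ = math.nan
    elif bc == 0:
        or_ = math.inf
    else:
        or_ = ad / bc
    res = stats.fisher_exact([[a, b], [c, d]], alternative=alternative)
    return or_, float(res.pvalue)


def conditional_odds_ratio(a: int, b: int, c: int, d: int) -> float:
    """Conditional maximum-likelihood odds ratio of the 2x2 table."""
    return float(_cond_odds_ratio([[a, b], [c, d]], kind="conditional").statistic)


def celltype_enrichment(
    om,
    suggestive: pd.Series,
    loci: list[Locus] | None = None,
    alternative: str = "two-sided",
    baseline: str = "any",
    cmle: bool = True,
) -> pd.DataFrame:
    """Fisher enrichment of every cell type among baseline markers.

    Parameters
    ----------
    om : OverlapMatrix
        Incidence over ALL markers (suggestive and non-suggestive).
    suggestive : boolean Series indexed like ``om.incidence``.
    loci : optional list of loci; if given, ``n_loci`` counts loci
        contributing at least one marker to cell ``a``.
    baseline : "any" (default) counts baseline membership over all cell
        types including the tested one; "any_other" restricts, per tested
        cell type k, to markers overlapping some cell type other than k.
    cmle : also compute the conditional-MLE odds ratio (slower on large
        tables; disable in simulation loops).

    Rows are sorted by p. Bonferroni correction is over the number of cell
    types with >= 1 overlapping baseline marker.
    """
    if baseline not in ("any", "any_other"):
        raise ValueError(f"baseline must be 'any' or 'any_other', got {baseline!r}")
    inc = om.incidence
    suggestive = suggestive.reindex(inc.index).astype(bool)
    any_mask = om.any_overlap.to_numpy()
    if not any_mask.any():
        raise ValueError("empty baseline: no marker overlaps any cell type")
    sug = suggestive.to_numpy()
    inc_np = inc.to_numpy(bool)
    locus_of = marker_locus_map(loci) if loci is not None else {}
    ids = np.asarray(inc.index)

    tables = []
    for j, ct in enumerate(inc.columns):
        if baseline == "any":
            base = any_mask
        else:
            base = (inc_np[:, np.arange(inc_np.shape[1]) != j]).any(axis=1)
        k = inc_np[:, j] & base
        a = int(np.sum(sug & base & inc_np[:, j]))
        b = int(np.sum(sug & base & ~inc_np[:, j]))
        c = int(np.sum(~sug & base & inc_np[:, j]))
        d = int(np.sum(~sug & base & ~inc_np[:, j]))
        tables.append((ct, a, b, c, d, int(k.sum()), base))

    n_tested = sum(1 for _, a, _, c, *_ in tables if a + c > 0)
    if n_tested == 0:
        raise ValueError("no cell type has an overlapping baseline marker")
    rows = []
    for ct, a, b, c, d, n_overlap_base, base in tables:
        if a + c == 0:
            logger.info("cell type %s has no overlapping baseline marker; not tested", ct)
            continue
        if a + b == 0 or c + d == 0 or b + d == 0:
            # degenerate margin (e.g. the tested cell type covers the whole
            # baseline): no information against the null, p = 1
            or_, p = math.nan, 1.0
        else:
            or_, p = fisher_exact(a, b, c, d, alternative=alternative)
        j = list(inc.columns).index(ct)
        a_ids = ids[sug & base & inc_np[:, j]]
        n_loci = len({locus_of[i] for i in a_ids if i in locus_of}) if locus_of else 0
        rows.append(
            EnrichmentResult(
                cell_type=ct,
                a=a, b=b, c=c, d=d,
                odds_ratio=or_,
                odds_ratio_cmle=(
                    conditional_odds_ratio(a, b, c, d)
                    if cmle and min(a + b, c + d, b + d) > 0 else math.nan
                ),
                p=p,
                p_bonf=min(1.0, p * n_tested),
                n_suggestive_markers=a + b,
                n_loci=n_loci,
            )
        )
    df = pd.DataFrame([r.__dict__ for r in rows]).sort_values(
        ["p", "cell_type"], kind="mergesort"
    )
    return df.reset_index(drop=True)


def binned_fold_change(
    p: pd.Series,
    om,
    bin_width: float = 1.0,
    ref_bin: tuple[float, float] = (0.0, 1.0),
    denominator: str = "any_overlap",
) -> pd.DataFrame:
    """Per -log10(p) bin and cell type: overlap proportion and fold change.

    Bins are [0,1), [1,2), ... on -log10(p), the last bin open-ended. The
    proportion for cell type k in a bin is, by default, the fraction of that
    bin's any-overlap markers that overlap k (consistent with the Fisher
    baseline); ``denominator="all"`` divides by all markers in the bin.
    Fold change divides by the reference-bin proportion.
    """
    if denominator not in ("any_overlap", "all"):
        raise ValueError(f"denominator must be 'any_overlap' or 'all', got {denominator!r}")
    inc = om.incidence
    p = p.reindex(inc.index).astype(float)
    nlp = -np.log10(p.to_numpy())
    max_bin = max(int(np.floor(np.nanmax(nlp) / bin_width)), int(ref_bin[1] / bin_width) - 1)
    edges = [(i * bin_width, (i + 1) * bin_width) for i in range(max_bin + 1)]
    edges[-1] = (edges[-1][0], math.inf)

    any_np = om.any_overlap.to_numpy()
    inc_np = inc.to_numpy(bool)

    def props(lo, hi):
        in_bin = (nlp >= lo) & (nlp < hi)
        denom = int(np.sum(in_bin & any_np)) if denominator == "any_overlap" else int(np.sum(in_bin))
        counts = inc_np[in_bin].sum(axis=0)
        return in_bin.sum(), denom, counts

    _, ref_denom, ref_counts = props(*ref_bin)
    if ref_denom == 0:
        raise ValueError(f"reference bin {ref_bin} is empty")
    ref_prop = ref_counts / ref_denom

    rows = []
    for lo, hi in edges:
        n_in_bin, denom, counts = props(lo, hi)
        for j, ct in enumerate(inc.columns):
            defined = denom > 0
            prop = counts[j] / denom if defined else math.nan
            if defined and ref_prop[j] > 0:
                fc = prop / ref_prop[j]
            else:
                fc = math.nan
            rows.append(
                {
                    "cell_type": ct,
                    "bin_lo": lo,
                    "bin_hi": hi,
                    "n_markers_in_bin": int(n_in_bin),
                    "n_denominator": denom,
                    "proportion": prop,
                    "fold_change": fc,
                    "defined": bool(defined),
                }
            )
    return pd.DataFrame(rows)
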
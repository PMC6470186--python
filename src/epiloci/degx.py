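"""Two-group differential expression with empirical-Bayes moderated t-statistics.

Per probeset g with pooled residual variance s_g^2 on d_g = n - 2 degrees of
freedom, variances are shrunk toward a prior through the scaled
inverse-chi-square hierarchical model

    s_g^2 | sigma_g^2 ~ sigma_g^2 * chi2_{d_g} / d_g,
    1 / sigma_g^2 ~ chi2_{d0} / (d0 * s0^2),

giving the posterior variance

    s~_g^2 = (d0 * s0^2 + d_g * s_g^2) / (d0 + d_g)

and the moderated t = logFC / (s~_g * sqrt(1/n1 + 1/n2)) referred to a t
distribution with d0 + d_g degrees of freedom. The hyperparameters (d0,
s0^2) are estimated by moment matching on z_g = log s_g^2: under the model
Var(z) = trigamma(d_g/2) + trigamma(d0/2) and
E[z] = log s0^2 + log(d0/2) - digamma(d0/2) + digamma(d_g/2) - log(d_g/2),
so trigamma(d0/2) is set to the (unbiased) sample variance of z minus
trigamma(d_g/2) and inverted monotonically; a non-positive estimate means no
excess variance dispersion and collapses to d0 = +inf, s~^2 = s0^2.

DEG calls use Benjamini-Hochberg FDR with a strict <5% default threshold,
after collapsing multiple probesets per gene to the most significant one.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

DEFAULT_FDR_THRESHOLD = 0.05


@dataclass(frozen=True)
class ExpressionMatrix:
    """Log2-scale expression: probesets x samples with a two-level design.

    ``group`` assigns each sample to one of exactly two levels (>=2 samples
    each); ``probe_to_gene`` maps probeset id -> gene symbol.
    """

    values: pd.DataFrame
    group: pd.Series
    probe_to_gene: dict[str, str]

    def __post_init__(self) -> None:
        if not np.isfinite(self.values.to_numpy(float)).all():
            raise ValueError("expression values must be finite")
        levels = pd.unique(self.group.reindex(self.values.columns))
        if len(levels) != 2:
            raise ValueError(f"exactly two groups required, got {list(levels)}")
        counts = self.group.reindex(self.values.columns).value_counts()
        if (counts < 2).any():
            raise ValueError("each group needs >= 2 samples")

    @property
    def levels(self) -> tuple[str, str]:
        seen = pd.unique(self.group.reindex(self.values.columns))
        return str(seen[0]), str(seen[1])


@dataclass(frozen=True)
class EBHyperparams:
    """Variance-shrinkage prior: d0 degrees of freedom, s0^2 scale."""

    d0: float
    s0_sq: float

    def __post_init__(self) -> None:
        if not self.d0 > 0:
            raise ValueError(f"d0 must be > 0, got {self.d0}")
        if not self.s0_sq > 0:
            raise ValueError(f"s0_sq must be > 0, got {self.s0_sq}")


def read_expression(path, group_map: dict[str, str]) -> ExpressionMatrix:
    """Read an expression TSV: probeset, gene, then one column per sample."""
    df = pd.read_csv(path, sep="\t", comment="#")
    cols = list(df.columns)
    if cols[0].lower() != "probeset":
        raise ValueError(f"{path}: first column must be 'probeset', got {cols[0]!r}")
    if len(cols) > 1 and cols[1].lower() == "gene":
        probe_to_gene = dict(zip(df[cols[0]].astype(str), df[cols[1]].astype(str)))
        values = df.set_index(cols[0])[cols[2:]]
    else:
        probe_to_gene = {}
        values = df.set_index(cols[0])[cols[1:]]
    values.index = values.index.astype(str)
    group = pd.Series(group_map, name="group").reindex(values.columns)
    if group.isna().any():
        missing = list(values.columns[group.isna()])
        raise ValueError(f"{path}: samples without group assignment: {missing}")
    return ExpressionMatrix(values=values.astype(float), group=group, probe_to_gene=probe_to_gene)


def _invert_trigamma(y: float, lo: float = 1e-6, hi: float = 1e6, tol: float = 1e-10) -> float:
    """Solve trigamma(x) = y for x by monotone bisection on (lo, hi)."""
    if y <= float(special.polygamma(1, hi)):
        return math.inf
    if y >= float(special.polygamma(1, lo)):
        return lo
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if float(special.polygamma(1, mid)) > y:
            lo = mid
        else:
            hi = mid
        if hi - lo < tol:
            break
    return 0.5 * (lo + hi)


def estimate_hyperparams(s_sq: np.ndarray, d_resid: float) -> EBHyperparams:
    """Moment-matching fit of (d0, s0^2) from sample variances.

    Probesets with zero or non-finite log variance are excluded from the
    fit (they are still shrunk downstream). A non-positive trigamma target
    yields d0 = +inf.
    """
    s_sq = np.asarray(s_sq, dtype=float)
    with np.errstate(divide="ignore"):
        z = np.log(s_sq)
    z = z[np.isfinite(z)]
    n = z.size
    if n < 2:
        raise ValueError("hyperparameter estimation needs >= 2 probesets with positive variance")
    if z.size < s_sq.size:
        logger.warning("excluded %d zero-variance probesets from the prior fit",
                       s_sq.size - z.size)
    zbar = float(np.mean(z))
    var_z = float(np.sum((z - zbar) ** 2) / (n - 1))
    target = var_z - float(special.polygamma(1, d_resid / 2.0))
    d0 = 2.0 * _invert_trigamma(target) if target > 0 else math.inf
    log_s0 = zbar - float(special.digamma(d_resid / 2.0)) + math.log(d_resid / 2.0)
    if math.isfinite(d0):
        log_s0 += float(special.digamma(d0 / 2.0)) - math.log(d0 / 2.0)
    return EBHyperparams(d0=d0, s0_sq=float(np.exp(log_s0)))


def fit_moderated_t(
    expr: ExpressionMatrix,
    hyperparams: EBHyperparams | None = None,
    prior_df: float | None = None,
) -> tuple[pd.DataFrame, EBHyperparams]:
    """Per-probeset moderated t-statistics for a two-group design.

    logFC = mean(group2) - mean(group1) (groups in order of first
    appearance among the sample columns). ``hyperparams`` overrides the
    moment-matching estimate; ``prior_df=0`` recovers the classical pooled
    two-sample t exactly.

    Returns (per-probeset DataFrame, hyperparameters used). The frame has
    columns ``probeset log_fc s_sq t_mod df_total p zero_var``.
    """
    g1, g2 = expr.levels
    grp = expr.group.reindex(expr.values.columns)
    X1 = expr.values.loc[:, (grp == g1).to_numpy()].to_numpy(float)
    X2 = expr.values.loc[:, (grp == g2).to_numpy()].to_numpy(float)
    n1, n2 = X1.shape[1], X2.shape[1]
    d_resid = n1 + n2 - 2
    log_fc = X2.mean(axis=1) - X1.mean(axis=1)
    rss = ((X1 - X1.mean(axis=1, keepdims=True)) ** 2).sum(axis=1) + (
        (X2 - X2.mean(axis=1, keepdims=True)) ** 2
    ).sum(axis=1)
    s_sq = rss / d_resid

    if prior_df is not None and prior_df == 0:
        hp = EBHyperparams(d0=np.finfo(float).tiny, s0_sq=1.0)
        d0, s0_sq = 0.0, 1.0  # prior carries zero weight
    elif hyperparams is not None:
        hp = hyperparams
        d0, s0_sq = hp.d0, hp.s0_sq
    else:
        if len(s_sq) < 2:
            raise ValueError("hyperparameter estimation needs >= 2 probesets")
        hp = estimate_hyperparams(s_sq, d_resid)
        d0, s0_sq = hp.d0, hp.s0_sq

    zero_var = s_sq == 0.0
    if zero_var.any():
        logger.warning("%d probesets have zero residual variance (shrunk toward s0^2)",
                       int(zero_var.sum()))
    if math.isinf(d0):
        s_tilde_sq = np.full_like(s_sq, s0_sq)
        df_total = np.inf
    else:
        s_tilde_sq = (d0 * s0_sq + d_resid * s_sq) / (d0 + d_resid)
        df_total = d0 + d_resid
    scale = np.sqrt(s_tilde_sq * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t_mod = np.where(scale > 0, log_fc / scale, np.where(log_fc == 0, 0.0, np.inf * np.sign(log_fc)))
    p = 2.0 * stats.t.sf(np.abs(t_mod), df=df_total)
    out = pd.DataFrame(
        {
            "probeset": expr.values.index.astype(str),
            "log_fc": log_fc,
            "s_sq": s_sq,
            "t_mod": t_mod,
            "df_total": df_total,
            "p": np.clip(p, np.nextafter(0, 1), 1.0),
            "zero_var": zero_var,
        }
    )
    return out, hp


def collapse_probesets(results: pd.DataFrame, probe_to_gene: dict[str, str]) -> pd.DataFrame:
    """Per gene, keep the most significant probeset.

    Ties on p go to the larger |t_mod|, then the lexicographically smaller
    probeset id. Unmapped probesets are dropped with a log entry.
    """
    df = results.copy()
    df["gene"] = df["probeset"].map(probe_to_gene)
    unmapped = df["gene"].isna()
    if unmapped.any():
        logger.warning("dropping %d probesets without a gene mapping", int(unmapped.sum()))
        df = df[~unmapped]
    df["_abs_t"] = -df["t_mod"].abs()
    df = (
        df.sort_values(["gene", "p", "_abs_t", "probeset"], kind="mergesort")
        .groupby("gene", sort=True)
        .head(1)
        .drop(columns="_abs_t")
    )
    cols = ["gene"] + [c for c in df.columns if c != "gene"]
    return df[cols].reset_index(drop=True)


def bh_fdr(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted values, in input order.

    q_(i) = min_{j >= i} p_(j) * m / j, capped at 1.
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p <= 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def call_degs(per_gene: pd.DataFrame, fdr_threshold: float = DEFAULT_FDR_THRESHOLD) -> pd.DataFrame:
    """Attach fdr, fc_ratio and the strict ``fdr < threshold`` DEG flag.

    ``fc_ratio = 2**log_fc`` reports fold change on the ratio scale
    (values < 1 mean down-regulation).
    """
    out = per_gene.copy()
    out["fdr"] = bh_fdr(out["p"].to_numpy())
    out["fc_ratio"] = np.exp2(out["log_fc"].to_numpy(float))
    out["is_deg"] = out["fdr"] < fdr_threshold
    return out


def write_degs(df: pd.DataFrame, path) -> None:
    cols = ["gene", "probeset", "fc_ratio", "log_fc", "t_mod", "p", "fdr", "is_deg"]
    df[cols].to_csv(path, sep="\t", index=False)
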
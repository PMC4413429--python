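"""Two-group array-style differential expression.

Chain: variance-stabilizing transform -> robust spline normalization ->
empirical-Bayes moderated t -> fold-change / P filtering -> hypergeometric
gene-set over-representation.

The moderation hyperparameters (d0, s0sq) are fit by the standard
method-of-moments on log residual variances:

    e_g = log s2_g - psi(d_g / 2) + log(d_g / 2)
    trigamma(d0 / 2) = var(e) - trigamma(d_g / 2)
    s0sq = exp(mean(e) + psi(d0 / 2) - log(d0 / 2))

with var(e) <= trigamma(d_g / 2) collapsing to the d0 = inf limit (prior is
a point mass; s0sq is the geometric mean of the s2_g).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Optional, Set, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from scipy.interpolate import PchipInterpolator
from scipy.optimize import nnls
from scipy.special import digamma, polygamma
from statsmodels.stats.multitest import multipletests

from .model import (
    RAW_SCALE,
    TRANSFORMED_SCALE,
    ExpressionMatrix,
    GeneSetCollection,
    ValidationError,
)

logger = logging.getLogger(__name__)

__all__ = [
    "ModerationFit",
    "DEResult",
    "EnrichmentResult",
    "vst_transform",
    "rsn_normalize",
    "fit_moderation",
    "moderated_t_test",
    "filter_de",
    "enrichment_test",
    "collapse_probes",
]

MIN_GENES_FOR_FIT = 8


@dataclass
class ModerationFit:
    d0: float  # prior degrees of freedom; math.inf = no-residual-variation limit
    s0sq: float  # prior variance scale
    d_g: int  # per-gene residual df (constant: n_WT + n_KO - 2)
    converged: bool = True

    def __post_init__(self):
        # fitted d0 is always > 0; d0 = 0 is accepted as the explicit
        # no-moderation limit (reduces to the ordinary pooled t)
        if not (self.d0 >= 0):
            raise ValidationError("d0 must be nonnegative (inf permitted)")
        if not (self.s0sq > 0):
            raise ValidationError("s0sq must be positive")


@dataclass
class DEResult:
    table: pd.DataFrame  # index gene_id: log2fc, mean_expr, s2, s2_post, t, p, p_adj[, call]
    fit: ModerationFit
    fc_threshold: Optional[float] = None
    p_threshold: Optional[float] = None
    p_mode: Optional[str] = None

    @property
    def calls(self) -> pd.Series:
        if "call" not in self.table.columns:
            raise ValidationError("no calls yet; run filter_de first")
        return self.table["call"]

    def gene_ids(self, call: str) -> Set[str]:
        return set(self.calls.index[self.calls == call])


@dataclass
class EnrichmentResult:
    table: pd.DataFrame  # index term: description, k, K, n, N, p, p_adj


# ---------------------------------------------------------------------------
# transforms


def vst_transform(matrix: ExpressionMatrix, mode: str = "vst") -> ExpressionMatrix:
    """Variance-stabilizing transform of a raw intensity matrix.

    Models per-gene variance as quadratic in the mean, v ~ a*m^2 + b, and
    applies the generalized log g(x) = log2(x + sqrt(x^2 + lam)) - 1 with
    lam = b / a. Falls back to plain log2 when the trend fit degenerates
    (or with ``mode='log2'``).
    """
    if matrix.scale != RAW_SCALE:
        raise ValidationError("vst_transform expects a raw-intensity matrix")
    if np.any(matrix.values <= 0):
        raise ValidationError("raw intensities must be strictly positive")
    if mode not in ("vst", "log2"):
        raise ValueError(f"unknown transform mode {mode!r}")
    if mode == "log2":
        return matrix.with_values(np.log2(matrix.values), scale=TRANSFORMED_SCALE)
    if len(matrix.feature_ids) < MIN_GENES_FOR_FIT:
        raise ValidationError(
            f"need >= {MIN_GENES_FOR_FIT} genes to fit the mean-variance trend"
        )
    lam = _fit_glog_lambda(matrix.values)
    if lam is None:
        logger.warning("mean-variance trend fit degenerate; falling back to log2")
        return matrix.with_values(np.log2(matrix.values), scale=TRANSFORMED_SCALE)
    x = matrix.values
    out = np.log2(x + np.sqrt(x * x + lam)) - 1.0
    return matrix.with_values(out, scale=TRANSFORMED_SCALE)


def _fit_glog_lambda(values: np.ndarray) -> Optional[float]:
    """Nonnegative LS fit of var ~ a * mean^2 + b; returns lam = b / a.

    Rows are weighted by 1 / mean^2 so every gene contributes relative
    rather than absolute error; an unweighted fit is dominated by the
    brightest genes and badly overestimates the additive component.
    """
    m = values.mean(axis=1)
    v = values.var(axis=1, ddof=1)
    design = np.column_stack([np.ones_like(m), 1.0 / (m * m)])
    try:
        coef, _ = nnls(design, v / (m * m))
    except Exception:  # pragma: no cover - nnls is robust in practice
        return None
    a, b = coef
    if a <= 0 or not np.isfinite(a) or not np.isfinite(b):
        return None
    return max(b, 0.0) / a


def rsn_normalize(matrix: ExpressionMatrix, n_knots: int = 100) -> ExpressionMatrix:
    """Robust spline normalization of a transformed matrix.

    Each sample is mapped through a monotone smooth (PCHIP) function fitted
    on quantile knots onto the quantiles of the reference pseudo-sample
    (the per-gene mean array). Within-sample ranks are preserved.
    """
    if len(matrix.samples) < 2:
        raise ValidationError("rsn_normalize needs >= 2 samples")
    values = matrix.values
    for j, s in enumerate(matrix.samples):
        if np.ptp(values[:, j]) == 0:
            raise ValidationError(f"sample {s.sample_id!r} is constant (zero variance)")
    reference = values.mean(axis=1)
    q = np.linspace(0.0, 1.0, min(n_knots, len(matrix.feature_ids)))
    ref_q = np.quantile(reference, q)
    out = np.empty_like(values)
    for j in range(values.shape[1]):
        x = values[:, j]
        xq = np.quantile(x, q)
        keep = np.concatenate([[True], np.diff(xq) > 0])
        f = PchipInterpolator(xq[keep], ref_q[keep], extrapolate=True)
        out[:, j] = f(x)
    return matrix.with_values(out, scale=TRANSFORMED_SCALE)


# ---------------------------------------------------------------------------
# moderated t


def _group_stats(matrix: ExpressionMatrix) -> Tuple[np.ndarray, np.ndarray, np.ndarray, int, int]:
    wt_cols = matrix.genotype_columns("WT")
    ko_cols = matrix.genotype_columns("KO")
    n1, n2 = len(wt_cols), len(ko_cols)
    if n1 < 2 or n2 < 2:
        raise ValidationError("need >= 2 samples per genotype")
    wt = matrix.values[:, wt_cols]
    ko = matrix.values[:, ko_cols]
    mean_wt = wt.mean(axis=1)
    mean_ko = ko.mean(axis=1)
    ss = ((wt - mean_wt[:, None]) ** 2).sum(axis=1) + ((ko - mean_ko[:, None]) ** 2).sum(axis=1)
    s2 = ss / (n1 + n2 - 2)
    return mean_wt, mean_ko, s2, n1, n2


def _trigamma_inverse(y: float, tol: float = 1e-10, max_iter: int = 200) -> float:
    """Solve trigamma(x) = y for x > 0 by bisection on a geometrically
    widened bracket; trigamma is strictly decreasing on (0, inf)."""
    if y <= 0:
        return math.inf
    lo, hi = 1e-3, 1.0
    while polygamma(1, lo) < y:
        lo /= 2.0
        if lo < 1e-300:
            return math.inf
    while polygamma(1, hi) > y:
        hi *= 2.0
        if hi > 1e12:
            return math.inf
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        if polygamma(1, mid) > y:
            lo = mid
        else:
            hi = mid
        if hi - lo < tol * max(1.0, lo):
            break
    return 0.5 * (lo + hi)


def fit_moderation(matrix: ExpressionMatrix, min_genes: int = MIN_GENES_FOR_FIT) -> ModerationFit:
    """Method-of-moments fit of the variance prior (d0, s0sq)."""
    if len(matrix.feature_ids) < min_genes:
        raise ValidationError(f"need >= {min_genes} genes for a stable moment fit")
    _, _, s2, n1, n2 = _group_stats(matrix)
    d = n1 + n2 - 2
    # quantile-style normalization pins extreme-rank genes to the reference,
    # which can leave residual variances of exactly (or nearly) zero; a
    # relative floor keeps their exclusion stable under reordering noise
    floor = 1e-10 * float(np.median(s2))
    positive = s2 > floor
    if not np.all(positive):
        logger.warning(
            "%d genes with (near-)zero residual variance excluded from moment fit",
            int(np.sum(~positive)),
        )
    s2p = s2[positive]
    if s2p.size < min_genes:
        raise ValidationError("too few genes with positive residual variance")
    e = np.log(s2p) - digamma(d / 2.0) + np.log(d / 2.0)
    evar = float(np.var(e, ddof=1)) - float(polygamma(1, d / 2.0))
    if evar <= 0:
        # no excess spread: point-mass prior
        return ModerationFit(
            d0=math.inf, s0sq=float(np.exp(np.mean(np.log(s2p)))), d_g=d, converged=True
        )
    x = _trigamma_inverse(evar)
    if not np.isfinite(x):
        return ModerationFit(
            d0=math.inf, s0sq=float(np.exp(np.mean(np.log(s2p)))), d_g=d, converged=False
        )
    d0 = 2.0 * x
    s0sq = float(np.exp(np.mean(e) + digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return ModerationFit(d0=d0, s0sq=s0sq, d_g=d, converged=True)


def moderated_t_test(matrix: ExpressionMatrix, fit: ModerationFit) -> DEResult:
    """Moderated two-group comparison (KO minus WT) with BH adjustment.

    Posterior variance s2_post = (d0*s0sq + d_g*s2) / (d0 + d_g); the
    statistic is log2FC / (s_post * sqrt(1/n1 + 1/n2)) referred to a t
    distribution with d0 + d_g df (normal in the d0 = inf limit).
    """
    if matrix.scale != TRANSFORMED_SCALE:
        raise ValidationError("moderated_t_test expects a transformed matrix")
    mean_wt, mean_ko, s2, n1, n2 = _group_stats(matrix)
    d = n1 + n2 - 2
    if d != fit.d_g:
        raise ValidationError(f"fit.d_g={fit.d_g} does not match design df {d}")
    log2fc = mean_ko - mean_wt
    if math.isinf(fit.d0):
        s2_post = np.full_like(s2, fit.s0sq)
    else:
        s2_post = (fit.d0 * fit.s0sq + d * s2) / (fit.d0 + d)
    v = 1.0 / n1 + 1.0 / n2
    se = np.sqrt(s2_post * v)
    flagged = se == 0
    t = np.zeros_like(log2fc)
    np.divide(log2fc, se, out=t, where=~flagged)
    if math.isinf(fit.d0):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df=fit.d0 + d)
    p = np.where(flagged, 1.0, p)
    p_adj = multipletests(p, method="fdr_bh")[1]
    table = pd.DataFrame(
        {
            "log2fc": log2fc,
            "mean_expr": matrix.values.mean(axis=1),
            "s2": s2,
            "s2_post": s2_post,
            "t": t,
            "p": p,
            "p_adj": p_adj,
            "zero_variance": flagged,
        },
        index=pd.Index(matrix.feature_ids, name="gene_id"),
    )
    return DEResult(table=table, fit=fit)


def filter_de(
    result: DEResult,
    fc_threshold: float = 2.0,
    p_threshold: float = 0.05,
    p_mode: str = "raw",
) -> DEResult:
    """Attach down/up/unchanged calls.

    down <=> log2FC <= -log2(fc_threshold) and p < p_threshold (fold-change
    boundary inclusive, p boundary exclusive); up symmetric.
    """
    if fc_threshold <= 0 or p_threshold <= 0:
        raise ValidationError("thresholds must be positive")
    if p_mode not in ("raw", "adjusted"):
        raise ValueError(f"p_mode must be 'raw' or 'adjusted', got {p_mode!r}")
    table = result.table.copy()
    lfc_cut = math.log2(fc_threshold)
    p = table["p"] if p_mode == "raw" else table["p_adj"]
    sig = p < p_threshold
    call = np.where(
        sig & (table["log2fc"] <= -lfc_cut),
        "down",
        np.where(sig & (table["log2fc"] >= lfc_cut), "up", "unchanged"),
    )
    table["call"] = call
    return DEResult(
        table=table,
        fit=result.fit,
        fc_threshold=fc_threshold,
        p_threshold=p_threshold,
        p_mode=p_mode,
    )


# ---------------------------------------------------------------------------
# enrichment


def enrichment_test(
    query: Iterable[str],
    universe: Iterable[str],
    collection: GeneSetCollection,
) -> EnrichmentResult:
    """Upper-tail hypergeometric over-representation of each term in the query.

    Terms are intersected with the universe first; empty intersections are
    skipped. p = P(X >= k) for X ~ Hypergeom(N, K, n).
    """
    query = set(query)
    universe = set(universe)
    offenders = sorted(query - universe)
    if offenders:
        raise ValidationError(
            f"query genes not in universe: {', '.join(offenders[:10])}"
            + ("..." if len(offenders) > 10 else "")
        )
    N = len(universe)
    n = len(query)
    rows = []
    for term in collection.terms:
        members = set(collection.members(term)) & universe
        K = len(members)
        if K == 0:
            continue
        k = len(members & query)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append((term, collection.description(term), k, K, n, N, min(p, 1.0)))
    if rows:
        df = pd.DataFrame(
            rows, columns=["term", "description", "k", "K", "n", "N", "p"]
        ).set_index("term")
        df["p_adj"] = multipletests(df["p"].to_numpy(), method="fdr_bh")[1]
        df = df.sort_values(["p", "term"], kind="stable")
    else:
        df = pd.DataFrame(
            columns=["description", "k", "K", "n", "N", "p", "p_adj"],
            index=pd.Index([], name="term"),
        )
    return EnrichmentResult(table=df)


# ---------------------------------------------------------------------------
# probe handling for real array data


def collapse_probes(matrix: ExpressionMatrix, probe_to_gene: dict) -> ExpressionMatrix:
    """Collapse probes to genes keeping the probe with the highest mean
    intensity per gene. Probes without a mapping are dropped."""
    means = matrix.values.mean(axis=1)
    best: dict = {}
    for i, pid in enumerate(matrix.feature_ids):
        gene = probe_to_gene.get(pid)
        if gene is None:
            continue
        if gene not in best or means[i] > means[best[gene]]:
            best[gene] = i
    genes = sorted(best)
    idx = [best[g] for g in genes]
    return ExpressionMatrix(
        feature_ids=genes,
        samples=list(matrix.samples),
        values=matrix.values[idx],
        scale=matrix.scale,
    )
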
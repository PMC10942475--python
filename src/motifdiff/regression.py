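"""GC-aware normalization and regression-based motif activity scores.

Contents:

* smooth quantile normalization within GC bins (qsmooth): within each
  equal-occupancy GC bin, each quantile is shrunk toward the overall reference
  quantile with a weight ``w = 1 - SSB/SST`` (between-group over total sum of
  squares of the order statistics), smoothed by a running median — so shared
  technical GC effects are removed while genuine group differences survive;
* a per-sample multivariate linear model (MLM) regressing each sample's
  normalized accessibility on all motif-match columns jointly, returning
  per-motif t-values as activity scores;
* per-motif univariate models of the peak log fold-changes (binary match,
  match score, or binary plus GC covariate);
* binned motif enrichment: peaks binned by logFC, one-sided Fisher tests of
  motif over-representation per bin against the zero bin (``vsZero``) or all
  other bins (``vsOthers``), aggregated per motif with Simes' method.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import hypergeom, rankdata
from scipy.stats import t as t_dist

from .chromvar import ActivityMatrix
from .stats import simes_aggregate

log = logging.getLogger(__name__)

DEFAULT_JITTER_FACTOR = 1e-3
DEFAULT_NBINS_ENRICH = 9


def log_cpm(counts: np.ndarray) -> np.ndarray:
    """log2(counts-per-million + 0.5), the input transform ahead of qsmooth."""
    X = np.asarray(counts, dtype=float)
    colsum = X.sum(axis=0, keepdims=True)
    if (colsum <= 0).any():
        raise ValueError("every sample needs a positive library size")
    return np.log2(X / colsum * 1e6 + 0.5)


@dataclass
class NormalizedMatrix:
    """Peaks x samples normalized log-accessibility with bin/group labels."""

    values: np.ndarray
    gc_bin: np.ndarray
    groups: np.ndarray
    sample_ids: list[str] | None = None


def _running_median(x: np.ndarray, window: int) -> np.ndarray:
    from scipy.ndimage import median_filter

    window = max(3, int(window))
    if window % 2 == 0:
        window += 1
    return median_filter(x, size=min(window, len(x) | 1), mode="nearest")


def _gc_bins(gc: np.ndarray, nbins: int) -> np.ndarray:
    """Equal-occupancy GC bins; bins with < 2 peaks merge into a neighbor."""
    n = len(gc)
    nbins = max(1, min(nbins, n // 2 if n >= 4 else 1))
    ranks = rankdata(gc, method="average")
    bins = np.minimum((ranks - 1) * nbins // n, nbins - 1).astype(int)
    # merge undersized bins (possible with heavy ties) into the lower neighbor
    for b in range(nbins):
        if 0 < (bins == b).sum() < 2:
            warnings.warn(f"GC bin {b} has < 2 peaks; merging into neighbor")
            bins[bins == b] = b - 1 if b > 0 else b + 1
    return bins


def gc_smooth_quantile_normalize(
    logcpm: np.ndarray,
    gc: np.ndarray,
    groups,
    nbins: int = 10,
    window_frac: float = 0.05,
) -> NormalizedMatrix:
    """Smooth quantile normalization within equal-occupancy GC bins.

    Within each bin and at each quantile rank k, the normalized value for a
    sample of group g is ``w_k * q_k + (1 - w_k) * q_gk`` where ``q_k`` is the
    across-sample mean order statistic, ``q_gk`` the group-specific one, and
    ``w_k = 1 - SSB_k / SST_k`` (clipped to [0, 1], smoothed by a running
    median over ``window_frac`` of the ranks). One group, or identical group
    distributions, gives w = 1: exact within-bin quantile normalization.
    Values are mapped back through each sample's average ranks.
    """
    X = np.asarray(logcpm, dtype=float)
    groups = np.asarray(groups)
    if X.shape[1] != len(groups):
        raise ValueError("groups must label every sample column")
    levels = np.unique(groups)
    gc = np.asarray(gc, dtype=float)
    bins = _gc_bins(gc, nbins)
    out = np.empty_like(X)
    for b in np.unique(bins):
        rows = np.flatnonzero(bins == b)
        Y = X[rows]
        n = len(rows)
        Q = np.sort(Y, axis=0)
        qk = Q.mean(axis=1)
        sst = ((Q - qk[:, None]) ** 2).sum(axis=1)
        group_means = {}
        ssb = np.zeros(n)
        for g in levels:
            cols = groups == g
            qgk = Q[:, cols].mean(axis=1)
            group_means[g] = qgk
            ssb += cols.sum() * (qgk - qk) ** 2
        with np.errstate(divide="ignore", invalid="ignore"):
            w = 1.0 - ssb / sst
        w[sst == 0] = 1.0
        w = np.clip(_running_median(np.clip(w, 0.0, 1.0), window_frac * n), 0.0, 1.0)
        grid = np.arange(n, dtype=float)
        for j in range(X.shape[1]):
            target = w * qk + (1.0 - w) * group_means[groups[j]]
            r = rankdata(Y[:, j], method="average") - 1.0
            out[rows, j] = np.interp(r, grid, target)
    return NormalizedMatrix(out, bins, groups)


@dataclass
class LogFCVector:
    values: np.ndarray
    jitter_applied: bool = False


def peak_logfc(
    norm: NormalizedMatrix,
    jitter_factor: float = DEFAULT_JITTER_FACTOR,
    jitter_seed: int = 0,
) -> LogFCVector:
    """Per-peak log2 fold-change: mean(group B) - mean(group A) of normalized values.

    If the vector contains ties and ``jitter_factor`` > 0, uniform noise of
    amplitude ``jitter_factor * max|logFC|`` is added (fixed seed) — binned
    enrichment needs strictly orderable values.
    """
    levels = np.unique(norm.groups)
    if len(levels) != 2:
        raise ValueError("exactly two groups are required for a log fold-change")
    a = norm.values[:, norm.groups == levels[0]].mean(axis=1)
    b = norm.values[:, norm.groups == levels[1]].mean(axis=1)
    lfc = b - a
    jittered = False
    if jitter_factor and len(np.unique(lfc)) < len(lfc):
        rng = np.random.default_rng(jitter_seed)
        amp = jitter_factor * max(np.abs(lfc).max(), 1e-12)
        lfc = lfc + rng.uniform(-amp, amp, size=len(lfc))
        jittered = True
    return LogFCVector(lfc, jitter_applied=jittered)


def mlm_sample_activities(
    norm: NormalizedMatrix, matches, sample_ids=None
) -> ActivityMatrix:
    """Per-sample multivariate linear model on all motifs jointly.

    Each sample's (column-centered) normalized accessibility is regressed by
    OLS on the column-standardized motif-match matrix plus an intercept;
    the per-motif t-values (coefficient / SE) are the activity scores.
    All-zero or duplicated match columns are dropped (logged) and reported as
    NaN; highly similar motifs are better handled as archetypes upstream.
    """
    M = matches.indicator if hasattr(matches, "indicator") else np.asarray(matches)
    motif_ids = (
        list(matches.motif_ids)
        if hasattr(matches, "motif_ids")
        else [f"m{i}" for i in range(M.shape[1])]
    )
    M = np.asarray(M, dtype=float)
    n_peaks, n_motifs = M.shape
    if n_motifs >= n_peaks:
        raise ValueError("need fewer motifs than peaks for the multivariate fit")
    keep = np.ones(n_motifs, dtype=bool)
    sd = M.std(axis=0)
    keep &= sd > 0
    uniq, first = np.unique(M.T, axis=0, return_index=True)
    dup_mask = np.zeros(n_motifs, dtype=bool)
    dup_mask[first] = True
    dropped_dup = keep & ~dup_mask
    if dropped_dup.any():
        log.warning(
            "dropping duplicated match columns: %s",
            [motif_ids[i] for i in np.flatnonzero(dropped_dup)],
        )
    keep &= dup_mask
    Z = (M[:, keep] - M[:, keep].mean(axis=0)) / M[:, keep].std(axis=0)
    D = np.column_stack([np.ones(n_peaks), Z])
    # rank check; drop collinear columns if necessary
    q, r = np.linalg.qr(D)
    diag = np.abs(np.diag(r))
    if (diag < 1e-10 * diag.max()).any():
        bad = np.flatnonzero(diag < 1e-10 * diag.max())
        keep_idx = np.flatnonzero(keep)
        for col in bad:
            if col > 0:
                keep[keep_idx[col - 1]] = False
        log.warning("dropping %d collinear match column(s)", len(bad))
        Z = (M[:, keep] - M[:, keep].mean(axis=0)) / M[:, keep].std(axis=0)
        D = np.column_stack([np.ones(n_peaks), Z])
        q, r = np.linalg.qr(D)
    Y = norm.values - norm.values.mean(axis=0, keepdims=True)
    coef = np.linalg.solve(r, q.T @ Y)  # p x samples
    resid = Y - D @ coef
    dof = n_peaks - D.shape[1]
    sigma2 = (resid**2).sum(axis=0) / dof
    xtx_inv_diag = np.sum(np.linalg.inv(r) ** 2, axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        tvals = coef / np.sqrt(np.outer(xtx_inv_diag, sigma2))
    out = np.full((n_motifs, Y.shape[1]), np.nan)
    out[keep] = tvals[1:]  # drop intercept row
    if sample_ids is None:
        sample_ids = [f"s{j}" for j in range(Y.shape[1])]
    return ActivityMatrix(
        out,
        motif_ids,
        list(sample_ids),
        kind="mlm_t",
        flags={"dropped": [motif_ids[i] for i in np.flatnonzero(~keep)]},
    )


def ulm_motif_test(
    logfc: LogFCVector,
    matches,
    variant: str = "binary",
    gc: np.ndarray | None = None,
) -> pd.DataFrame:
    """Simple per-motif linear regression of peak logFCs on motif presence.

    ``binary`` uses the 0/1 indicator, ``scores`` the match score, and
    ``binary+GC`` adds peak GC as a covariate. Two-sided t-test on the motif
    slope. Constant predictors yield NA (flagged in the table).
    """
    y = np.asarray(logfc.values, dtype=float)
    n = len(y)
    if n < 3:
        raise ValueError("need at least three peaks")
    if hasattr(matches, "indicator"):
        motif_ids = list(matches.motif_ids)
        X = matches.score if variant == "scores" else matches.indicator.astype(float)
    else:
        X = np.asarray(matches, dtype=float)
        motif_ids = [f"m{i}" for i in range(X.shape[1])]
    X = np.asarray(X, dtype=float)
    if variant not in ("binary", "scores", "binary+GC"):
        raise ValueError(f"unknown variant: {variant!r}")
    if variant == "binary+GC":
        if gc is None:
            raise ValueError("binary+GC requires the per-peak GC vector")
        C = np.column_stack([np.ones(n), np.asarray(gc, float)])
        # residualize y and every predictor on [1, gc]
        y_res = y - C @ np.linalg.lstsq(C, y, rcond=None)[0]
        X_res = X - C @ np.linalg.lstsq(C, X, rcond=None)[0]
        dof = n - 3
    else:
        y_res = y - y.mean()
        X_res = X - X.mean(axis=0)
        dof = n - 2
    sxx = (X_res**2).sum(axis=0)
    constant = sxx <= 1e-12
    with np.errstate(divide="ignore", invalid="ignore"):
        slope = (X_res * y_res[:, None]).sum(axis=0) / sxx
        rss = (y_res**2).sum() - slope**2 * sxx
        sigma2 = rss / dof
        se = np.sqrt(sigma2 / sxx)
        tstat = slope / se
    p = 2.0 * t_dist.sf(np.abs(tstat), dof)
    slope[constant] = np.nan
    tstat[constant] = np.nan
    p[constant] = np.nan
    return pd.DataFrame(
        {
            "motif": motif_ids,
            "effect": slope,
            "t": tstat,
            "p": p,
            "constant_predictor": constant,
        }
    )


@dataclass
class BinnedEnrichment:
    """Per-motif, per-bin enrichment plus Simes-aggregated p-values."""

    motif_ids: list[str]
    bin_edges: np.ndarray
    zero_bin: int
    log2_enrichment: np.ndarray  # motifs x bins
    pvalues: np.ndarray  # motifs x bins (NaN for the zero bin)
    simes_p: np.ndarray
    table: pd.DataFrame = field(default=None)


def binned_enrichment(
    logfc: LogFCVector,
    matches,
    mode: str = "vsOthers",
    nbins: int = DEFAULT_NBINS_ENRICH,
) -> BinnedEnrichment:
    """Binned motif over-representation along the logFC axis.

    Peaks are sorted into ``nbins`` (odd, >= 3) equal-count bins of logFC; the
    bin whose range contains zero is the reference. For every motif and
    non-zero bin a one-sided Fisher exact test (hypergeometric tail) compares
    motif presence in the bin against the comparison set — the zero bin
    (``vsZero``) or all other bins (``vsOthers``). log2 enrichments use +0.5
    pseudocounts on all four table cells. Per-motif p-values are aggregated
    with Simes' rule over the non-zero bins.
    """
    if mode not in ("vsZero", "vsOthers"):
        raise ValueError(f"unknown mode: {mode!r}")
    if nbins < 3 or nbins % 2 == 0:
        raise ValueError("nbins must be odd and >= 3")
    y = np.asarray(logfc.values, dtype=float)
    n = len(y)
    M = matches.indicator if hasattr(matches, "indicator") else np.asarray(matches, bool)
    motif_ids = (
        list(matches.motif_ids)
        if hasattr(matches, "motif_ids")
        else [f"m{i}" for i in range(M.shape[1])]
    )
    order = np.argsort(y, kind="stable")
    bin_of_sorted = np.minimum(np.arange(n) * nbins // n, nbins - 1)
    bins = np.empty(n, dtype=int)
    bins[order] = bin_of_sorted
    edges = np.empty(nbins + 1)
    edges[0], edges[-1] = -np.inf, np.inf
    for b in range(1, nbins):
        edges[b] = (y[order][bin_of_sorted == b - 1][-1] + y[order][bin_of_sorted == b][0]) / 2
    lo = y[order][np.searchsorted(bin_of_sorted, np.arange(nbins), side="left")]
    hi = y[order][np.searchsorted(bin_of_sorted, np.arange(nbins), side="right") - 1]
    contains_zero = (lo <= 0) & (hi >= 0)
    if contains_zero.any():
        zero_bin = int(np.flatnonzero(contains_zero)[0])
    else:  # all-positive or all-negative logFCs: closest bin to zero
        zero_bin = int(np.argmin(np.minimum(np.abs(lo), np.abs(hi))))

    n_motifs = M.shape[1]
    matched_per_bin = np.vstack(
        [M[bins == b].sum(axis=0) for b in range(nbins)]
    )  # bins x motifs
    size_per_bin = np.bincount(bins, minlength=nbins)
    log2_enr = np.full((n_motifs, nbins), np.nan)
    pvals = np.full((n_motifs, nbins), np.nan)
    for b in range(nbins):
        if b == zero_bin:
            continue
        a = matched_per_bin[b]
        bb = size_per_bin[b] - a
        if mode == "vsZero":
            c = matched_per_bin[zero_bin]
            dd = size_per_bin[zero_bin] - c
        else:
            c = matched_per_bin.sum(axis=0) - a
            dd = (size_per_bin.sum() - size_per_bin[b]) - c
        total = a + bb + c + dd
        # one-sided Fisher (enrichment): P(X >= a) hypergeometric
        pvals[:, b] = hypergeom.sf(a - 1, total, a + c, a + bb)
        absent = (a + c) == 0
        pvals[absent, b] = 1.0
        log2_enr[:, b] = np.log2(((a + 0.5) * (dd + 0.5)) / ((bb + 0.5) * (c + 0.5)))
        log2_enr[absent, b] = 0.0
    simes = np.array(
        [simes_aggregate(pvals[m, np.arange(nbins) != zero_bin]) for m in range(n_motifs)]
    )
    best_bin = np.nanargmin(np.where(np.isnan(pvals), np.inf, pvals), axis=1)
    table = pd.DataFrame(
        {
            "motif": motif_ids,
            "p": simes,
            "effect": log2_enr[np.arange(n_motifs), best_bin],
        }
    )
    return BinnedEnrichment(
        motif_ids, edges, zero_bin, log2_enr, pvals, simes, table=table
    )
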
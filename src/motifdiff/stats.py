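"""Shared inferential machinery for motif-activity matrices.

The central tool is an empirical-Bayes moderated two-group comparison in the
style of limma's ``lmFit``/``eBayes``: per-motif pooled-variance linear models
whose residual variances are shrunk toward a global prior estimated by matching
the moments of the log residual variances (scaled-F model, digamma/trigamma
closed forms). Also provided: Simes and Fisher p-value aggregation,
Benjamini-Hochberg adjustment, and the deterministic result-ranking rule
(ascending p, ties by descending absolute effect, then motif id).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import digamma, polygamma
from scipy.stats import t as t_dist

__all__ = [
    "ModeratedFit",
    "moderated_t_test",
    "simes_aggregate",
    "fisher_combine",
    "bh_adjust",
    "rank_results",
]


def _trigamma(x):
    return polygamma(1, x)


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x for y > 0 (Newton iteration on 1/trigamma)."""
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = _trigamma(y)
        dif = tri * (1.0 - tri / x) / polygamma(2, y)
        y += dif
        if abs(dif) / y < 1e-8:
            break
    return float(y)


def fit_f_dist(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Moment-match a scaled F prior (d0, s0^2) to observed variances.

    Works on ``e = log s2 - digamma(df/2) + log(df/2)``; the mean identifies
    ``s0^2`` and the excess variance over ``trigamma(df/2)`` identifies ``d0``
    through the trigamma inverse. ``d0 = inf`` when the observed variances are
    no more dispersed than sampling noise allows.
    """
    s2 = np.asarray(s2, dtype=float)
    ok = np.isfinite(s2) & (s2 > 0)
    if ok.sum() < 2:
        raise ValueError("need at least two positive variances to fit a prior")
    z = np.log(s2[ok])
    e = z - digamma(df / 2.0) + np.log(df / 2.0)
    emean = e.mean()
    evar = e.var(ddof=1) - _trigamma(df / 2.0)
    if evar > 0:
        d0 = 2.0 * _trigamma_inverse(evar)
        s02 = float(np.exp(emean + digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    else:
        d0 = np.inf
        s02 = float(np.exp(emean))
    return d0, s02


@dataclass
class ModeratedFit:
    """Per-motif moderated two-group comparison results."""

    table: pd.DataFrame  # motif, effect, s2, df, s2_post, t, p, fdr
    d0: float
    s02: float

    def __len__(self):
        return len(self.table)


def moderated_t_test(
    scores: np.ndarray,
    groups,
    motif_ids=None,
    d0: float | None = None,
) -> ModeratedFit:
    """Empirical-Bayes moderated two-group t-tests, one per motif (row).

    Parameters
    ----------
    scores:
        motifs x samples activity matrix.
    groups:
        length-n_samples labels with exactly two levels; effect = mean(second
        level) - mean(first level), levels in sorted order ('A' then 'B').
    d0:
        Force the prior degrees of freedom (``0`` disables moderation and
        reproduces ordinary pooled-variance t-tests; default: estimate).

    Pooled-variance design only; motifs with non-finite scores yield NA.
    """
    X = np.asarray(scores, dtype=float)
    if X.ndim != 2:
        raise ValueError("scores must be 2-D (motifs x samples)")
    groups = np.asarray(groups)
    levels = np.unique(groups)
    if len(levels) != 2:
        raise ValueError("exactly two group levels are required")
    a = groups == levels[0]
    b = groups == levels[1]
    na, nb = int(a.sum()), int(b.sum())
    if na < 1 or nb < 1:
        raise ValueError("both groups must be non-empty")
    df_res = na + nb - 2
    if df_res < 1:
        raise ValueError("at least one residual degree of freedom is required")

    ok = np.isfinite(X).all(axis=1)
    effect = np.full(X.shape[0], np.nan)
    s2 = np.full(X.shape[0], np.nan)
    effect[ok] = X[ok][:, b].mean(axis=1) - X[ok][:, a].mean(axis=1)
    ssa = ((X[ok][:, a] - X[ok][:, a].mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    ssb = ((X[ok][:, b] - X[ok][:, b].mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    s2[ok] = (ssa + ssb) / df_res

    fit_ok = ok & (s2 > 0)
    if not fit_ok.any():
        raise ValueError("all residual variances are zero: degenerate input")
    if d0 is None:
        if fit_ok.sum() < 2:
            warnings.warn("single testable motif: no moderation possible, ordinary t used")
            d0, s02 = 0.0, float(np.nanmean(s2[fit_ok]))
        else:
            d0, s02 = fit_f_dist(s2[fit_ok], df_res)
    else:
        s02 = float(np.nanmean(s2[fit_ok]))

    if np.isinf(d0):
        s2_post = np.where(ok, s02, np.nan)
        df_total = np.inf
    elif d0 == 0:
        s2_post = s2
        df_total = df_res
    else:
        s2_post = (d0 * s02 + df_res * s2) / (d0 + df_res)
        df_total = d0 + df_res

    se = np.sqrt(s2_post * (1.0 / na + 1.0 / nb))
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = effect / se
    if np.isinf(df_total):
        from scipy.stats import norm

        p = 2.0 * norm.sf(np.abs(tstat))
    else:
        p = 2.0 * t_dist.sf(np.abs(tstat), df_total)
    if motif_ids is None:
        motif_ids = [f"m{i}" for i in range(X.shape[0])]
    table = pd.DataFrame(
        {
            "motif": list(motif_ids),
            "effect": effect,
            "s2": s2,
            "df": float(df_res),
            "s2_post": s2_post,
            "t": tstat,
            "p": p,
            "fdr": bh_adjust(p),
        }
    )
    return ModeratedFit(table, d0=float(d0), s02=s02)


def simes_aggregate(pvals) -> float:
    """Simes' combined p-value: min over i of n * p_(i) / i, capped at 1.

    NaN entries are dropped with a warning; all-NaN input returns NaN.
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    nan = np.isnan(p)
    if nan.any():
        warnings.warn(f"dropping {int(nan.sum())} NaN p-value(s) from Simes aggregation")
        p = p[~nan]
        if p.size == 0:
            return np.nan
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    ps = np.sort(p)
    n = len(ps)
    return float(min(1.0, (n * ps / np.arange(1, n + 1)).min()))


def fisher_combine(p1: float, p2: float) -> float:
    """Fisher's combination of two p-values via the chi-square(4) tail."""
    from scipy.stats import chi2

    tiny = np.finfo(float).tiny
    vals = []
    for p in (p1, p2):
        if not (0 <= p <= 1):
            raise ValueError("p-values must lie in [0, 1]")
        if p == 0:
            warnings.warn("p-value of 0 clamped to the smallest positive float")
            p = tiny
        vals.append(p)
    x = -2.0 * (np.log(vals[0]) + np.log(vals[1]))
    return float(chi2.sf(x, df=4))


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values; NaNs are passed through."""
    from statsmodels.stats.multitest import multipletests

    p = np.asarray(pvals, dtype=float)
    out = np.full(p.shape, np.nan)
    ok = np.isfinite(p)
    if ok.any():
        out[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return out


def rank_results(table: pd.DataFrame) -> pd.DataFrame:
    """Rank motifs: ascending p, ties by descending |effect|, then motif id.

    NA p-values are ranked last (among themselves by motif id). Adds ``rank``
    (1-based) and returns the table sorted by it.
    """
    need = {"motif", "p", "effect"}
    missing = need - set(table.columns)
    if missing:
        raise ValueError(f"result table missing columns: {sorted(missing)}")
    df = table.copy()
    df["_absfx"] = -df["effect"].abs().fillna(0.0)
    df["_pna"] = df["p"].isna()
    df = df.sort_values(
        ["_pna", "p", "_absfx", "motif"], kind="stable", na_position="last"
    ).drop(columns=["_absfx", "_pna"])
    df["rank"] = np.arange(1, len(df) + 1)
    return df.reset_index(drop=True)
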
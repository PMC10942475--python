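"""Insertion-profile scores around motif matches.

Two footprint-flavoured methods operate on Tn5 insertion events accumulated in
a +/- 200 bp window around motif match sites (strand-flipped for minus-strand
sites, summed over sites):

* the *insertion model*: each motif's global (across-sample) profile, smoothed
  and symmetrized, becomes a position weight vector; the weighted insertion
  counts per sample are summed into a motif x sample activity score;
* a BagFoot-like two-part test: per motif and sample, a footprint depth
  (near-flank vs in-motif insertion rate, log2) and a flanking accessibility
  (far-flank rate, log2) are computed; group differences in the two are tested
  with the moderated t machinery and combined with Fisher's method.

Sequence (Tn5 preference) bias correction is deliberately omitted: it is
shared across samples and cancels in relative comparisons.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .chromvar import ActivityMatrix
from .core_io import FragmentSet, tn5_insertions
from .stats import bh_adjust, fisher_combine, moderated_t_test

log = logging.getLogger(__name__)

DEFAULT_WINDOW = 200
DEFAULT_SMOOTH_WINDOW = 11
NEAR_FLANK = 20
FAR_FLANK = 200


@dataclass
class InsertionProfile:
    """Per-motif, per-sample insertion counts over relative positions.

    ``counts[k]`` holds insertions at relative position ``k - window`` from the
    site start; the vector spans ``-window .. site_length + window - 1``.
    """

    motif_id: str
    sample_id: str
    counts: np.ndarray
    window: int
    site_length: int
    n_sites: int


def motif_insertion_profiles(
    fragment_sets: list[FragmentSet],
    sites: pd.DataFrame,
    window: int = DEFAULT_WINDOW,
    shift_plus: int = 0,
    shift_minus: int = 0,
) -> list[InsertionProfile]:
    """Accumulate insertion events around motif match sites.

    ``sites`` needs columns ``chrom/start/end/motif`` and optionally ``strand``;
    all sites of one motif must share a length (fixed-width matches). Events in
    ``[site.start - window, site.end + window)`` are binned by position
    relative to the site start and flipped for minus-strand sites. Motifs with
    zero sites yield empty (all-zero) profiles and a warning.
    """
    if "motif" not in sites.columns:
        raise ValueError("sites need a 'motif' column")
    sites = sites.reset_index(drop=True)
    if "strand" not in sites.columns:
        sites = sites.assign(strand="+")
    profiles: list[InsertionProfile] = []
    for fs in fragment_sets:
        ins = tn5_insertions(fs, shift_plus, shift_minus)
        by_chrom = {}
        for chrom, sub in ins.groupby("chrom", observed=True):
            pos = sub["pos"].to_numpy()
            w = sub["weight"].to_numpy(np.int64)
            order = np.argsort(pos, kind="stable")
            by_chrom[chrom] = (pos[order], w[order])
        for motif, msites in sites.groupby("motif", sort=True, observed=True):
            lengths = (msites["end"] - msites["start"]).to_numpy()
            if len(msites) == 0:
                continue
            if len(np.unique(lengths)) > 1:
                raise ValueError(f"motif {motif}: sites must share one length")
            L = int(lengths[0])
            span = 2 * window + L
            acc = np.zeros(span, dtype=np.int64)
            for row in msites.itertuples(index=False):
                data = by_chrom.get(row.chrom)
                if data is None:
                    continue
                pos, w = data
                lo = row.start - window
                hi = row.end + window
                i0, i1 = np.searchsorted(pos, [lo, hi])
                if i1 <= i0:
                    continue
                rel = pos[i0:i1] - lo
                if row.strand == "-":
                    rel = span - 1 - rel
                np.add.at(acc, rel, w[i0:i1])
            profiles.append(
                InsertionProfile(str(motif), fs.sample_id, acc, window, L, len(msites))
            )
    empty = [p.motif_id for p in profiles if p.n_sites == 0]
    if empty:
        log.warning("motifs with zero sites: %s", sorted(set(empty)))
    return profiles


def _smooth(x: np.ndarray, window: int) -> np.ndarray:
    """Centered running mean with edge renormalization."""
    if window <= 1:
        return x.astype(float)
    kernel = np.ones(window)
    num = np.convolve(x, kernel, mode="same")
    den = np.convolve(np.ones_like(x, dtype=float), kernel, mode="same")
    return num / den


def insertion_model_scores(
    profiles: list[InsertionProfile],
    smooth_window: int = DEFAULT_SMOOTH_WINDOW,
) -> ActivityMatrix:
    """Position-weighted insertion scores per motif and sample.

    Per motif: the global profile (summed over samples) is smoothed by a
    centered running mean, symmetrized by averaging mirrored positions about
    the match center, and normalized to sum 1; the score of each sample is the
    weighted sum of its insertion counts. All-zero global profiles fall back to
    uniform weights (flagged).
    """
    motif_ids = sorted({p.motif_id for p in profiles})
    sample_ids = []
    for p in profiles:
        if p.sample_id not in sample_ids:
            sample_ids.append(p.sample_id)
    values = np.full((len(motif_ids), len(sample_ids)), np.nan)
    flat = {}
    for p in profiles:
        flat.setdefault(p.motif_id, []).append(p)
    uniform_flagged = []
    for i, m in enumerate(motif_ids):
        plist = flat[m]
        span = len(plist[0].counts)
        global_profile = np.sum([p.counts for p in plist], axis=0).astype(float)
        smoothed = _smooth(global_profile, smooth_window)
        sym = (smoothed + smoothed[::-1]) / 2.0
        total = sym.sum()
        if total == 0:
            uniform_flagged.append(m)
            weights = np.full(span, 1.0 / span)
        else:
            weights = sym / total
        for p in plist:
            j = sample_ids.index(p.sample_id)
            values[i, j] = float(weights @ p.counts)
    return ActivityMatrix(
        values,
        motif_ids,
        sample_ids,
        kind="insertion_model",
        flags={"uniform_weights": uniform_flagged},
    )


def symmetrize(profile: np.ndarray) -> np.ndarray:
    """Average mirrored positions about the window center."""
    x = np.asarray(profile, dtype=float)
    return (x + x[::-1]) / 2.0


@dataclass
class FootprintSummary:
    """Motif x sample footprint depth and flanking accessibility (log2)."""

    motif_ids: list[str]
    sample_ids: list[str]
    depth: np.ndarray
    flank: np.ndarray


def footprint_summaries(
    profiles: list[InsertionProfile],
    pseudocount: float = 0.5,
) -> FootprintSummary:
    """Footprint depth and flanking accessibility per motif and sample.

    With per-bp insertion rates, depth = log2((F20/40 + c) / (M/L + c)) where
    F20 counts the 20 bp on each side of the match, M the in-motif insertions
    over match length L; flanking accessibility = log2(F200/400 + c) over the
    200 bp on each side. ``c`` is a per-bp pseudocount (default 0.5). Positive
    depth marks a protected footprint (flanks more accessible than the match).
    """
    motif_ids = sorted({p.motif_id for p in profiles})
    sample_ids = []
    for p in profiles:
        if p.sample_id not in sample_ids:
            sample_ids.append(p.sample_id)
    depth = np.full((len(motif_ids), len(sample_ids)), np.nan)
    flank = np.full_like(depth, np.nan)
    for p in profiles:
        if p.window < FAR_FLANK:
            raise ValueError("profiles need a window of at least 200 bp")
        if p.site_length <= 0:
            raise ValueError("motif length must be positive")
        i = motif_ids.index(p.motif_id)
        j = sample_ids.index(p.sample_id)
        W, L = p.window, p.site_length
        c = p.counts
        m_count = c[W : W + L].sum()
        near = c[W - NEAR_FLANK : W].sum() + c[W + L : W + L + NEAR_FLANK].sum()
        far = c[W - FAR_FLANK : W].sum() + c[W + L : W + L + FAR_FLANK].sum()
        depth[i, j] = np.log2((near / (2 * NEAR_FLANK) + pseudocount) / (m_count / L + pseudocount))
        flank[i, j] = np.log2(far / (2 * FAR_FLANK) + pseudocount)
    return FootprintSummary(motif_ids, sample_ids, depth, flank)


def bagfootlike_test(summary: FootprintSummary, groups) -> pd.DataFrame:
    """Two-part BagFoot-style test: depth and flank tested separately with the
    moderated-t machinery, combined per motif with Fisher's method (chi-square,
    4 df) and BH-adjusted."""
    fit_depth = moderated_t_test(summary.depth, groups, motif_ids=summary.motif_ids)
    fit_flank = moderated_t_test(summary.flank, groups, motif_ids=summary.motif_ids)
    td = fit_depth.table.set_index("motif")
    tf = fit_flank.table.set_index("motif")
    combined = []
    for m in summary.motif_ids:
        pd_, pf_ = td.loc[m, "p"], tf.loc[m, "p"]
        if np.isnan(pd_) or np.isnan(pf_):
            combined.append(np.nan)
        else:
            combined.append(fisher_combine(pd_, pf_))
    out = pd.DataFrame(
        {
            "motif": summary.motif_ids,
            "effect": td["effect"].to_numpy() + tf["effect"].to_numpy(),
            "p_depth": td["p"].to_numpy(),
            "p_flank": tf["p"].to_numpy(),
            "p": combined,
        }
    )
    out["fdr"] = bh_adjust(out["p"].to_numpy())
    return out
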
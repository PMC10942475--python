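"""Evaluation layer: motif archetypes, truth-based metrics and method ranking.

A method run produces a ranked motif list (see ``stats.rank_results``); this
module scores such rankings against a truth set:

* *true-motif rank*: best (minimum) rank of any true motif;
* *member AUC scores*: for k = 1..kmax, the proportion of the top k motifs
  that belong to a member set (known interactors -> "network score"; motifs
  clustering with the true motif -> "archetype score"); the mean of the curve
  is divided by its best attainable value, giving a score in [0, 1];
* *precision / recall* at an adjusted-p threshold, with positives expanded to
  whole archetype clusters containing a member;
* the *rank transform* ``2 e^(-x) / (1 + e^(-x))`` with ``x = sqrt(rank)``,
  used to place ranks on a bounded, decaying scale before averaging metrics
  across datasets, plus worst-of-median/mean imputation of missing cells;
* a rank-sum permutation aggregation of several methods' motif rankings.

Motif similarity is the Pearson correlation of aligned PPM columns weighted by
information content, over all ungapped offsets and both orientations;
archetypes are complete-linkage clusters of 1 - similarity cut at a fixed
height (defaults: 0.45 human, 0.35 mouse).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_io import MotifPPM

log = logging.getLogger(__name__)

CUT_HEIGHT_HUMAN = 0.45
CUT_HEIGHT_MOUSE = 0.35
MIN_ALIGN_OVERLAP = 5
DEFAULT_KMAX = 100


@dataclass
class TruthSet:
    """Ground truth for one dataset: true motifs, network members, archetypes."""

    true_motifs: set
    network_members: set
    archetypes: dict = field(default_factory=dict)  # motif id -> cluster label

    def __post_init__(self):
        self.true_motifs = set(self.true_motifs)
        self.network_members = set(self.network_members) | self.true_motifs


def _weighted_pearson(x: np.ndarray, y: np.ndarray, w: np.ndarray) -> float:
    sw = w.sum()
    if sw <= 0:
        return np.nan
    mx = (w * x).sum() / sw
    my = (w * y).sum() / sw
    cov = (w * (x - mx) * (y - my)).sum()
    vx = (w * (x - mx) ** 2).sum()
    vy = (w * (y - my) ** 2).sum()
    if vx <= 0 or vy <= 0:
        return np.nan
    return float(cov / np.sqrt(vx * vy))


def motif_similarity(a: MotifPPM, b: MotifPPM) -> tuple[float, int, bool]:
    """Best IC-weighted Pearson similarity over ungapped offsets/orientations.

    Columns are compared flattened (4 values each), every column weighted by
    the mean information content of the two aligned columns. Overlaps shorter
    than ``min(5, shorter motif)`` are skipped; if no offset satisfies the
    constraint the similarity is -1 (flagged by the offset = 0 convention).
    Returns ``(similarity, offset of b relative to a, reverse-complement?)``.
    """
    best = (-1.0, 0, False)
    found = False
    ica = a.information_content()
    for rc in (False, True):
        bb = b.reverse_complement() if rc else b
        icb = bb.information_content()
        la, lb = a.length, bb.length
        min_ov = min(MIN_ALIGN_OVERLAP, la, lb)
        for offset in range(-(lb - min_ov), la - min_ov + 1):
            a0, a1 = max(0, offset), min(la, offset + lb)
            if a1 - a0 < min_ov:
                continue
            cols_a = a.matrix[:, a0:a1]
            cols_b = bb.matrix[:, a0 - offset : a1 - offset]
            w_cols = (ica[a0:a1] + icb[a0 - offset : a1 - offset]) / 2.0
            w = np.repeat(w_cols, 4)
            r = _weighted_pearson(
                cols_a.T.ravel(), cols_b.T.ravel(), w
            )
            if np.isnan(r):  # zero information everywhere: undefined -> 0
                r = 0.0
            found = True
            if r > best[0]:
                best = (r, offset, rc)
    if not found:
        log.warning("motifs %s/%s: no alignment satisfies the overlap constraint",
                    a.motif_id, b.motif_id)
        return -1.0, 0, False
    return best


def similarity_matrix(ppms: list[MotifPPM]) -> pd.DataFrame:
    """Symmetric pairwise similarity matrix (diagonal 1)."""
    n = len(ppms)
    S = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            s, _, _ = motif_similarity(ppms[i], ppms[j])
            S[i, j] = S[j, i] = s
    ids = [p.motif_id for p in ppms]
    return pd.DataFrame(S, index=ids, columns=ids)


def cluster_archetypes(sim: pd.DataFrame, cut_height: float = CUT_HEIGHT_HUMAN) -> dict:
    """Complete-linkage clusters of distance 1 - similarity, cut at a height.

    Returns motif id -> integer cluster label.
    """
    if not (0 < cut_height < 2):
        raise ValueError("cut_height must lie in (0, 2)")
    ids = list(sim.index)
    if len(ids) == 1:
        return {ids[0]: 1}
    from scipy.cluster.hierarchy import fcluster, linkage
    from scipy.spatial.distance import squareform

    D = 1.0 - sim.to_numpy()
    np.fill_diagonal(D, 0.0)
    D = np.clip((D + D.T) / 2.0, 0.0, None)
    Z = linkage(squareform(D, checks=False), method="complete")
    labels = fcluster(Z, t=cut_height, criterion="distance")
    return dict(zip(ids, (int(v) for v in labels)))


def true_motif_rank(ranked: pd.DataFrame, truth: TruthSet) -> int:
    """Best rank of any true motif in a ranked result table."""
    hits = ranked[ranked["motif"].isin(truth.true_motifs)]
    if not len(hits):
        raise ValueError("no true motif present in the result table")
    return int(hits["rank"].min())


def member_auc_score(
    ranked: pd.DataFrame, members: set, kmax: int = DEFAULT_KMAX
) -> float:
    """Normalized AUC of the top-k member proportion curve.

    prop_k = |top-k intersect members| / k for k = 1..kmax (capped at the
    number of motifs); the mean of the curve is divided by the best value
    attainable with ``|members|`` members ranked first.
    """
    if kmax < 1:
        raise ValueError("kmax must be >= 1")
    if not members:
        raise ValueError("member set must be non-empty")
    ordered = ranked.sort_values("rank")["motif"].tolist()
    kmax = min(kmax, len(ordered))
    is_member = np.array([m in members for m in ordered[:kmax]], dtype=float)
    k = np.arange(1, kmax + 1)
    prop = np.cumsum(is_member) / k
    auc = prop.mean()
    n_members = len(members)
    best = (np.minimum(k, n_members) / k).mean()
    return float(auc / best)


def precision_recall(
    ranked: pd.DataFrame,
    truth: TruthSet,
    alpha: float = 0.05,
    expand_archetypes: bool = True,
    adjusted_col: str = "fdr",
) -> tuple[float, float]:
    """Precision and recall of the significant set at adjusted p <= alpha.

    Positives are motifs whose archetype cluster contains a network member or
    true motif (or the raw member set when ``expand_archetypes`` is off).
    Precision is NaN when nothing is significant; recall counts only true
    motifs.
    """
    if not (0 < alpha < 1):
        raise ValueError("alpha must lie in (0, 1)")
    sig = set(ranked.loc[ranked[adjusted_col] <= alpha, "motif"])
    positives = set(truth.network_members)
    if expand_archetypes and truth.archetypes:
        member_clusters = {
            truth.archetypes[m] for m in truth.network_members if m in truth.archetypes
        }
        positives |= {m for m, c in truth.archetypes.items() if c in member_clusters}
    precision = len(sig & positives) / len(sig) if sig else np.nan
    recall = (
        len(sig & truth.true_motifs) / len(truth.true_motifs) if truth.true_motifs else np.nan
    )
    return precision, recall


def rank_transform(rank) -> float:
    """Map a rank r to 2 e^(-sqrt(r)) / (1 + e^(-sqrt(r))) in (0, ~0.538]."""
    r = np.asarray(rank, dtype=float)
    if np.any(r < 1):
        raise ValueError("ranks must be >= 1")
    x = np.sqrt(r)
    out = 2.0 / (np.exp(x) + 1.0)
    return float(out) if out.ndim == 0 else out


def rank_methods(
    metrics: dict[str, pd.DataFrame],
    rank_metrics: tuple = ("true_motif_rank",),
) -> pd.DataFrame:
    """Order methods by the mean of all scores across datasets.

    ``metrics`` maps metric name -> (methods x datasets) frame. Metrics listed
    in ``rank_metrics`` are ranks (lower better) and are passed through the
    rank transform first; everything else is treated as a benefit score in
    [0, 1]. Missing cells are imputed per dataset column with the worse of the
    column median and mean (after transformation, all metrics are
    higher-is-better, so "worse" = smaller). Ties in the final ordering break
    by method name. Returns a frame with the mean score and ordering.
    """
    if not metrics:
        raise ValueError("at least one metric table is required")
    transformed = []
    for name, frame in metrics.items():
        tf = frame.astype(float).copy()
        if name in rank_metrics:
            arr = tf.to_numpy(dtype=float)
            if np.nanmin(arr) < 1:
                raise ValueError(f"{name}: ranks must be >= 1")
            with np.errstate(invalid="ignore"):
                arr = 2.0 / (np.exp(np.sqrt(arr)) + 1.0)
            tf = pd.DataFrame(arr, index=tf.index, columns=tf.columns)
        for col in tf.columns:
            vals = tf[col]
            if vals.isna().all():
                continue
            impute = min(vals.median(skipna=True), vals.mean(skipna=True))
            tf[col] = vals.fillna(impute)
        transformed.append(tf)
    all_scores = pd.concat(transformed, axis=1)
    never_observed = all_scores.isna().all(axis=1)
    if never_observed.any():
        log.warning("methods with no observed metric: %s",
                    list(all_scores.index[never_observed]))
    mean_score = all_scores.mean(axis=1)
    mean_score[never_observed] = -np.inf
    out = pd.DataFrame({"mean_score": mean_score})
    out = out.loc[sorted(out.index, key=lambda m: (-out.loc[m, "mean_score"], str(m)))]
    out["order"] = np.arange(1, len(out) + 1)
    return out


def aggregate_method_ranks(
    rank_matrix: np.ndarray,
    n_mc: int = 100_000,
    seed: int | None = 0,
) -> np.ndarray:
    """Rank-sum aggregation across methods: per motif, the probability that a
    sum of independent uniform ranks is <= the observed rank sum.

    ``rank_matrix`` is motifs x methods, each column a permutation of 1..n.
    Exact convolution is used when ``n * methods <= 10^4``; otherwise a seeded
    Monte-Carlo estimate with ``n_mc`` draws.
    """
    R = np.asarray(rank_matrix)
    n, m = R.shape
    if m < 2:
        raise ValueError("need at least two methods to aggregate")
    for j in range(m):
        if sorted(R[:, j]) != list(range(1, n + 1)):
            raise ValueError(f"column {j} is not a permutation of 1..{n}")
    T = R.sum(axis=1)
    if n * m <= 10_000:
        # exact: convolve m uniform{1..n} pmfs
        pmf = np.full(n, 1.0 / n)
        dist = pmf.copy()
        for _ in range(m - 1):
            dist = np.convolve(dist, pmf)
        # dist[k] = P(sum = k + m)
        cdf = np.cumsum(dist)
        return cdf[T - m]
    rng = np.random.default_rng(seed)
    draws = rng.integers(1, n + 1, size=(n_mc, m)).sum(axis=1)
    return np.searchsorted(np.sort(draws), T, side="right") / n_mc
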
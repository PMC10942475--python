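"""Semi-simulation engine: plant TF-specific accessibility perturbations.

Starting from real (or synthetic) baseline fragment sets, a perturbation on a
single TF is introduced by downsampling the fragments overlapping that TF's
ChIP-seq peaks in one of the two sample groups. The per-peak effect size is
borrowed from a reference differential-binding scenario: ChIP enrichment scores
are quantile-mapped onto the reference enrichment distribution and each peak
inherits the log2 fold-change of its closest-matching reference peak. A global
perturbation strength ``p`` scales all planted effects; ``p = 0`` reproduces the
input exactly. For a peak/sample with ``n0`` overlapping fragments the retained
count is

    n_s = min(ceil(n0 * 2**(-p * |log2FC|)), n0)

i.e. the printed fold-change is applied on the log scale, so that ``p = 0``
gives a fraction of 1 (the unperturbed dataset). Which group loses fragments at
a peak is set by the sign of its log2FC: negative fold-changes downsample group
B ("treatment"), positive ones group A, so the realized B-vs-A log-ratio carries
the sign of the planted log2FC.

Optional sample-wise technical biases re-sample fragments according to GC
content or fragment-length class, mimicking reference composition
distributions.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_io import (
    LENGTH_CLASSES,
    FragmentSet,
    classify_fragments,
)

log = logging.getLogger(__name__)

PERTURBATION_STRENGTH_GRID = (0.0, 0.25, 0.5, 1.0, 3.0)


@dataclass
class BindingScenario:
    """Reference (enrichment, log2FC) pairs defining a differential-binding shape."""

    name: str
    enrichment: np.ndarray
    log2fc: np.ndarray

    def __post_init__(self):
        self.enrichment = np.asarray(self.enrichment, dtype=float)
        self.log2fc = np.asarray(self.log2fc, dtype=float)
        if self.enrichment.shape != self.log2fc.shape or self.enrichment.ndim != 1:
            raise ValueError("enrichment and log2fc must be matching 1-D arrays")
        if len(self.enrichment) < 1:
            raise ValueError("scenario needs at least one reference peak")
        if not np.isfinite(self.enrichment).all():
            raise ValueError("enrichment scores must be finite")


def builtin_scenario(name: str, n_ref: int = 500) -> BindingScenario:
    """Bundled synthetic reference scenarios.

    ``activation`` emulates ligand-induced activation: effects grow with peak
    occupancy, reaching ~3 log2 units at the most enriched peaks.
    ``haploinsufficiency`` emulates halved TF dosage where the remaining protein
    preferentially retains high-occupancy sites: effects are mild overall and
    largest at *low*-occupancy peaks. Both are deterministic curves over a
    log-normal-shaped enrichment grid; they stand in for real reference ChIP
    experiments and are labelled synthetic.
    """
    q = (np.arange(n_ref) + 0.5) / n_ref
    from scipy.stats import norm

    enrichment = np.exp(norm.ppf(q) * 0.8 + 2.0)
    if name == "activation":
        log2fc = -(0.15 + 2.85 * q**1.7)
    elif name == "haploinsufficiency":
        log2fc = -(0.05 + 1.15 * (1.0 - q) ** 1.3)
    else:
        raise ValueError(f"unknown scenario: {name!r}")
    return BindingScenario(name, enrichment, log2fc)


def read_scenario_tsv(path, name: str | None = None) -> BindingScenario:
    df = pd.read_csv(path, sep="\t")
    return BindingScenario(name or str(path), df["enrichment"].to_numpy(), df["log2fc"].to_numpy())


def write_scenario_tsv(scenario: BindingScenario, path) -> None:
    pd.DataFrame({"enrichment": scenario.enrichment, "log2fc": scenario.log2fc}).to_csv(
        path, sep="\t", index=False
    )


def quantile_match_fold_changes(
    target_enrich: np.ndarray, scenario: BindingScenario
) -> np.ndarray:
    """Assign each target peak the log2FC of its closest-matching reference peak.

    Target enrichments are quantile-mapped (rank-based, linear interpolation
    between order statistics — type-7 quantiles) onto the reference enrichment
    distribution; each mapped value then picks the reference peak with the
    nearest enrichment (equidistant ties go to the lower reference index).
    """
    target_enrich = np.asarray(target_enrich, dtype=float)
    n = len(target_enrich)
    if n == 0:
        return np.empty(0)
    if not np.isfinite(target_enrich).all():
        raise ValueError("target enrichments must be finite")
    from scipy.stats import rankdata

    if n == 1:
        q = np.array([0.5])
    else:
        q = (rankdata(target_enrich, method="average") - 1.0) / (n - 1.0)
    mapped = np.quantile(scenario.enrichment, q)  # linear interpolation (type 7)

    # nearest reference enrichment, equidistant/equal ties -> lowest original index
    order = np.lexsort((np.arange(len(scenario.enrichment)), scenario.enrichment))
    ref_sorted = scenario.enrichment[order]
    pos = np.searchsorted(ref_sorted, mapped)
    lo = np.clip(pos - 1, 0, len(ref_sorted) - 1)
    hi = np.clip(pos, 0, len(ref_sorted) - 1)
    d_lo = np.abs(mapped - ref_sorted[lo])
    d_hi = np.abs(mapped - ref_sorted[hi])
    idx_lo, idx_hi = order[lo], order[hi]
    pick_lo = (d_lo < d_hi) | ((d_lo == d_hi) & (idx_lo <= idx_hi))
    chosen = np.where(pick_lo, idx_lo, idx_hi)
    return scenario.log2fc[chosen]


def effective_fraction(log2fc, p: float):
    """Retention fraction 2**(-p*|log2fc|) and the group to downsample.

    Vectorized over ``log2fc``. Group 'B' when log2fc < 0, else 'A'; ``p = 0``
    yields fraction 1 (no downsampling).
    """
    if p < 0:
        raise ValueError("perturbation strength must be non-negative")
    lfc = np.asarray(log2fc, dtype=float)
    fraction = 2.0 ** (-p * np.abs(lfc))
    group = np.where(lfc < 0, "B", "A")
    if lfc.ndim == 0:
        return float(fraction), str(group)
    return fraction, group


@dataclass
class PerturbationPlan:
    """Per-ChIP-peak planted effects and realized per-sample counts."""

    peaks: pd.DataFrame  # chrom start end enrichment log2fc fraction group
    p: float
    realized: dict = field(default_factory=dict)  # sample_id -> {"n0": arr, "ns": arr}

    def __post_init__(self):
        need = {"chrom", "start", "end", "log2fc", "fraction", "group"}
        missing = need - set(self.peaks.columns)
        if missing:
            raise ValueError(f"plan peaks missing columns: {sorted(missing)}")


def build_plan(
    chip_peaks: pd.DataFrame, scenario: BindingScenario, p: float
) -> PerturbationPlan:
    """Quantile-match fold-changes to ChIP enrichments and compute fractions."""
    df = chip_peaks.reset_index(drop=True).copy()
    if "enrichment" not in df.columns:
        if "score" in df.columns:
            df = df.rename(columns={"score": "enrichment"})
        else:
            raise ValueError("chip peaks need an 'enrichment' (or 'score') column")
    lfc = quantile_match_fold_changes(df["enrichment"].to_numpy(), scenario)
    fraction, group = effective_fraction(lfc, p)
    df["log2fc"], df["fraction"], df["group"] = lfc, fraction, group
    return PerturbationPlan(df, p)


def _assign_to_peaks(frag_df: pd.DataFrame, peaks: pd.DataFrame) -> np.ndarray:
    """Assign each fragment to at most one peak: largest overlap, tie -> lower index.

    Returns -1 for fragments overlapping no peak. Disjoint peaks take a sorted
    two-pointer fast path; overlapping/nested peak sets fall back to an interval
    tree.
    """
    assignment = np.full(len(frag_df), -1, dtype=np.int64)
    if not len(peaks) or not len(frag_df):
        return assignment
    pk = peaks.reset_index(drop=True)
    frag_pos = np.arange(len(frag_df))
    for chrom, sub in frag_df.reset_index(drop=True).groupby("chrom", observed=True):
        rows = np.flatnonzero((pk["chrom"] == chrom).to_numpy())
        if not len(rows):
            continue
        ps = pk["start"].to_numpy()[rows]
        pe = pk["end"].to_numpy()[rows]
        order = np.argsort(ps, kind="stable")
        ps_s, pe_s, rows_s = ps[order], pe[order], rows[order]
        fs = sub["start"].to_numpy()
        fe = sub["end"].to_numpy()
        fidx = sub.index.to_numpy()
        disjoint = len(ps_s) < 2 or np.all(ps_s[1:] >= pe_s[:-1])
        if disjoint:
            i0 = np.searchsorted(pe_s, fs, side="right")
            i1 = np.searchsorted(ps_s, fe, side="left")
            ncand = i1 - i0
            one = ncand == 1
            assignment[fidx[one]] = rows_s[i0[one]]
            multi = np.flatnonzero(ncand > 1)
            for k in multi:
                cand = np.arange(i0[k], i1[k])
                ov = np.minimum(pe_s[cand], fe[k]) - np.maximum(ps_s[cand], fs[k])
                keyed = sorted(zip(-ov, rows_s[cand]))
                assignment[fidx[k]] = keyed[0][1]
        else:
            from intervaltree import IntervalTree

            tree = IntervalTree()
            for s, e, r in zip(ps_s, pe_s, rows_s):
                tree.addi(int(s), int(e), int(r))
            for k in range(len(fs)):
                hits = tree.overlap(int(fs[k]), int(fe[k]))
                if not hits:
                    continue
                best = min(
                    hits,
                    key=lambda iv: (
                        -(min(iv.end, fe[k]) - max(iv.begin, fs[k])),
                        iv.data,
                    ),
                )
                assignment[fidx[k]] = best.data
    return assignment


def downsample_fragments(
    frags: FragmentSet,
    plan: PerturbationPlan,
    group: str,
    seed: int | None,
) -> FragmentSet:
    """Downsample fragments overlapping perturbed peaks for a sample of ``group``.

    For each plan peak whose downsampled group equals ``group``, retain
    ``min(ceil(n0 * fraction), n0)`` of the overlapping fragments, chosen
    uniformly at random without replacement. Fragments outside all such peaks
    (or assigned to peaks targeting the other group) pass through unchanged;
    original row order is preserved. A fragment overlapping several perturbed
    peaks is resolved once (largest overlap, tie -> lower peak index).

    Records the realized per-peak counts in ``plan.realized[frags.sample_id]``.
    """
    if seed is None:
        raise ValueError("a seed is required for reproducible downsampling")
    rng = np.random.default_rng(seed)
    pk = plan.peaks
    df = frags.df
    # expand weighted rows inside perturbed regions so the formula counts fragments
    if (df["weight"].to_numpy() > 1).any():
        df = df.loc[df.index.repeat(df["weight"].to_numpy())].assign(weight=np.int64(1))
        df = df.reset_index(drop=True)
    assignment = _assign_to_peaks(df, pk)
    active = (pk["group"].to_numpy() == group)
    frac = pk["fraction"].to_numpy()
    n_peaks = len(pk)
    n0 = np.bincount(assignment[assignment >= 0], minlength=n_peaks)

    target = np.where(
        active, np.minimum(np.ceil(n0 * frac), n0), n0
    ).astype(np.int64)
    plan.realized[frags.sample_id] = {"n0": n0.copy(), "ns": np.where(active, target, n0)}

    if not active.any() or np.all(target == n0):
        return FragmentSet(frags.sample_id, df.reset_index(drop=True), frags.n_rejected)

    keep = np.ones(len(df), dtype=bool)
    keys = rng.random(len(df))
    in_peak = assignment >= 0
    idx = np.flatnonzero(in_peak)
    a = assignment[idx]
    order = np.lexsort((keys[idx], a))
    a_sorted = a[order]
    # rank of each fragment within its peak group (0-based, random order)
    starts = np.flatnonzero(np.concatenate([[True], a_sorted[1:] != a_sorted[:-1]]))
    group_start = np.repeat(starts, np.diff(np.concatenate([starts, [len(a_sorted)]])))
    rank_in_group = np.arange(len(a_sorted)) - group_start
    drop = rank_in_group >= target[a_sorted]
    keep[idx[order[drop]]] = False
    out = df[keep].reset_index(drop=True)
    return FragmentSet(frags.sample_id, out, frags.n_rejected)


@dataclass
class BiasSpec:
    """Target composition for technical-bias injection.

    ``kind='gc'``: ``bin_edges`` over [0,1] plus target probabilities per bin.
    ``kind='fragment_length'``: target probabilities over the four length
    classes (NF, mono, di, multi).
    """

    kind: str
    target: np.ndarray
    bin_edges: np.ndarray | None = None

    def __post_init__(self):
        self.target = np.asarray(self.target, dtype=float)
        if self.kind not in ("gc", "fragment_length"):
            raise ValueError("kind must be 'gc' or 'fragment_length'")
        if not np.isclose(self.target.sum(), 1.0):
            raise ValueError("target probabilities must sum to 1")
        if self.kind == "gc":
            if self.bin_edges is None:
                self.bin_edges = np.linspace(0, 1, len(self.target) + 1)
            self.bin_edges = np.asarray(self.bin_edges, dtype=float)
            if len(self.bin_edges) != len(self.target) + 1:
                raise ValueError("need len(target)+1 bin edges")
        elif len(self.target) != len(LENGTH_CLASSES):
            raise ValueError("fragment_length target needs 4 class probabilities")


def apply_composition_bias(
    frags: FragmentSet, bias: BiasSpec, seed: int | None
) -> FragmentSet:
    """Subsample fragments toward a target GC or fragment-length composition.

    Acceptance probability per fragment is proportional to
    ``target density / empirical density`` of its attribute bin, normalized so
    the largest acceptance is 1 (importance resampling without replacement).
    Target mass on empirically empty bins is unreachable and triggers a warning.
    Weighted rows are binomially thinned.
    """
    if seed is None:
        raise ValueError("a seed is required for reproducible bias injection")
    rng = np.random.default_rng(seed)
    df = frags.df
    if not len(df):
        return frags.copy()
    if bias.kind == "gc":
        if "gc" not in df.columns:
            raise ValueError("gc bias requires a per-fragment 'gc' column")
        bin_idx = np.clip(
            np.searchsorted(bias.bin_edges, df["gc"].to_numpy(), side="right") - 1,
            0,
            len(bias.target) - 1,
        )
    else:
        labels = classify_fragments(frags, "length_class")
        lut = {c: i for i, c in enumerate(LENGTH_CLASSES)}
        bin_idx = np.array([lut[c] for c in labels])
    w = df["weight"].to_numpy(np.int64)
    empirical = np.bincount(bin_idx, weights=w, minlength=len(bias.target)).astype(float)
    empirical /= empirical.sum()
    unreachable = (bias.target > 0) & (empirical == 0)
    if unreachable.any():
        warnings.warn(
            f"{unreachable.sum()} target bin(s) have no empirical mass; "
            "that mass is unreachable"
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(empirical > 0, bias.target / empirical, 0.0)
    mx = ratio.max()
    if mx == 0:
        raise ValueError("target assigns no mass to any non-empty bin")
    accept = ratio / mx
    new_w = rng.binomial(w, accept[bin_idx])
    keep = new_w > 0
    out = df[keep].reset_index(drop=True).assign(weight=new_w[keep])
    return FragmentSet(frags.sample_id, out, frags.n_rejected)


@dataclass
class SimulationResult:
    group_a: list[FragmentSet]
    group_b: list[FragmentSet]
    plan: PerturbationPlan
    manifest: dict


def simulate_two_group_dataset(
    baseline: list[FragmentSet],
    chip_peaks: pd.DataFrame,
    scenario: BindingScenario,
    p: float,
    seed: int,
    biases: list[BiasSpec | None] | None = None,
    groups: list[str] | None = None,
) -> SimulationResult:
    """Plant a single-TF perturbation into baseline samples.

    Samples are split into two groups (first half A, second half B, or an
    explicit per-sample 'A'/'B' assignment). Fold-changes are quantile-matched
    to the scenario, converted to retention fractions at strength ``p``, and
    fragments over each ChIP peak are downsampled in the peak's target group.
    Per-sample composition biases (``biases[j]``, optional) are applied last.
    The truth manifest records the planted effects, the groups, all fractions
    and the seed.
    """
    if len(baseline) < 2:
        raise ValueError("need at least two baseline samples")
    n = len(baseline)
    if groups is None:
        groups = ["A"] * (n // 2) + ["B"] * (n - n // 2)
    if biases is None:
        biases = [None] * n
    if len(groups) != n or len(biases) != n:
        raise ValueError("groups and biases must match the number of samples")
    plan = build_plan(chip_peaks, scenario, p)
    rng = np.random.default_rng(seed)
    sample_seeds = rng.integers(0, 2**31 - 1, size=2 * n)
    out_a, out_b = [], []
    total_perturbed = 0
    for j, (fs, grp) in enumerate(zip(baseline, groups)):
        sim = downsample_fragments(fs, plan, grp, int(sample_seeds[2 * j]))
        rec = plan.realized[fs.sample_id]
        total_perturbed += int((rec["n0"] - rec["ns"]).sum())
        if biases[j] is not None:
            sim = apply_composition_bias(sim, biases[j], int(sample_seeds[2 * j + 1]))
        (out_a if grp == "A" else out_b).append(sim)
    if total_perturbed == 0 and p > 0:
        log.warning("no fragments were removed by the perturbation")
    manifest = {
        "scenario": scenario.name,
        "perturbation_strength": p,
        "seed": int(seed),
        "groups": list(groups),
        "n_chip_peaks": int(len(plan.peaks)),
        "zero_perturbed_fragments": bool(total_perturbed == 0),
        "peaks": plan.peaks[["chrom", "start", "end", "log2fc", "fraction", "group"]]
        .to_dict(orient="list"),
        "biases": [
            None if b is None else {"kind": b.kind, "target": b.target.tolist()}
            for b in biases
        ],
    }
    return SimulationResult(out_a, out_b, plan, manifest)
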
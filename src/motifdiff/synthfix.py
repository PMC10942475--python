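"""Fully synthetic fixtures with the statistical structure the methods assume.

The generator lays fixed-width peaks on two synthetic contigs, draws per-peak
GC from a Beta distribution, negative-binomial baseline counts (peak-specific
log-normal means, common dispersion, per-sample depth factors), realizes each
count as a fragment whose length comes from the ATAC four-class mixture
(nucleosome-free / mono / di / multi) and whose midpoint falls inside the peak,
and plants motif matches as Bernoulli draws whose logit is linear in peak GC
(GC-motif association) plus a shared latent peak factor that induces motif
co-occurrence. PPMs are sampled from concentrated Dirichlet columns, with a few
near-duplicate pairs so archetype clustering has structure.

The ChIP peak set of the perturbed motif covers a configurable fraction of its
matched peaks (default 0.7) plus a small off-motif contingent (default 10% of
the ChIP set), reflecting that experimental binding and motif matches overlap
imperfectly. Motifs loading on the same latent factor as the perturbed motif
are recorded as its network members in the truth manifest. The perturbation
itself is delegated to the semi-simulation engine.

GC is an annotation, not derived from generated sequence: no method in scope
consumes raw sequence beyond per-peak GC and precomputed matches.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .core_io import (
    FragmentSet,
    MotifMatchMatrix,
    MotifPPM,
    PeakTable,
    count_overlaps,
    write_fragments,
    write_jaspar,
    write_matches_mtx,
    write_peaks_bed,
)
from .semisim import BiasSpec, builtin_scenario, simulate_two_group_dataset

#: per-class fragment length ranges (inclusive), consistent with the
#: (0,120], (120,300], (300,500], (500,inf) classification thresholds
LENGTH_RANGES = ((30, 120), (121, 300), (301, 500), (501, 800))
DEFAULT_LENGTH_WEIGHTS = (0.55, 0.30, 0.10, 0.05)


@dataclass
class FixtureSpec:
    """Parameters of a synthetic two-group ATAC fixture."""

    n_peaks: int = 2000
    n_motifs: int = 100
    n_samples_per_group: int = 3
    peak_width: int = 300
    gc_beta: tuple = (10.0, 10.0)
    nb_mean_log: tuple = (3.3, 0.6)  # log-normal (mu, sigma) of per-peak NB mean
    nb_size: float = 10.0  # NB dispersion: var = mu + mu^2 / size
    depth_sigma: float = 0.15  # per-sample log-normal depth factor
    length_weights: tuple = DEFAULT_LENGTH_WEIGHTS
    motif_prevalence: tuple = (0.03, 0.20)  # uniform range of base match rates
    gc_association: float = 0.5  # sd of per-motif GC coefficients (logit scale)
    cooccurrence: float = 0.8  # latent-factor loading scale for network motifs
    n_network: int = 10
    n_archetype_twins: int = 6  # near-duplicate PPM pairs (archetype structure)
    perturbed_motif: int = 0
    scenario: str = "activation"
    chip_match_fraction: float = 0.7
    chip_offmotif_fraction: float = 0.1
    strength: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.n_samples_per_group < 2:
            raise ValueError("need >= 2 samples per group for moderated tests")
        if not np.isclose(sum(self.length_weights), 1.0):
            raise ValueError("length-class weights must sum to 1")


@dataclass
class FixtureBundle:
    peak_table: PeakTable
    matches: MotifMatchMatrix
    ppms: list[MotifPPM]
    fragments: list[FragmentSet]  # post-perturbation, groups A then B
    baseline_fragments: list[FragmentSet]
    chip_peaks: pd.DataFrame
    groups: list[str]
    manifest: dict


def _sample_fragments(rng, peaks, counts_col, length_weights, gc):
    """Vectorized realization of one sample's fragments."""
    reps = counts_col
    peak_idx = np.repeat(np.arange(len(peaks)), reps)
    n = len(peak_idx)
    cls = rng.choice(4, size=n, p=np.asarray(length_weights))
    lows = np.array([r[0] for r in LENGTH_RANGES])
    highs = np.array([r[1] for r in LENGTH_RANGES])
    lengths = rng.integers(lows[cls], highs[cls] + 1)
    starts = peaks["start"].to_numpy()[peak_idx]
    ends = peaks["end"].to_numpy()[peak_idx]
    centers = rng.integers(starts, ends)
    fstart = np.maximum(centers - lengths // 2, 0)
    fend = fstart + lengths
    frag_gc = np.clip(gc[peak_idx] + rng.normal(0, 0.04, size=n), 0.0, 1.0)
    df = pd.DataFrame(
        {
            "chrom": peaks["chrom"].to_numpy()[peak_idx],
            "start": fstart,
            "end": fend,
            "weight": np.ones(n, dtype=np.int64),
            "gc": frag_gc,
        }
    )
    return df.sort_values(["chrom", "start", "end"], kind="stable").reset_index(drop=True)


def _sample_ppms(rng, n_motifs, n_twins):
    ppms = []
    for m in range(n_motifs):
        L = int(rng.integers(6, 13))
        mat = rng.dirichlet(np.full(4, 0.3), size=L).T
        ppms.append(MotifPPM(f"M{m:03d}", mat))
    # overwrite some motifs with jittered copies of others -> archetype pairs
    # (never touching the perturbed motif, index 0)
    n_twins = min(n_twins, (n_motifs - 1) // 2)
    donors = rng.choice(np.arange(1, n_motifs), size=2 * n_twins, replace=False)
    for d, t in zip(donors[:n_twins], donors[n_twins:]):
        mat = ppms[d].matrix + rng.uniform(0, 0.03, size=ppms[d].matrix.shape)
        ppms[t] = MotifPPM(ppms[t].motif_id, mat / mat.sum(axis=0))
    return ppms


def generate_fixture(spec: FixtureSpec) -> FixtureBundle:
    """Generate a complete two-group fixture with a planted perturbation.

    Counts in the returned peak table are recomputed from the realized
    (post-perturbation) fragments via interval overlap, so the bundle is
    self-consistent under ``core_io.count_overlaps``.
    """
    rng = np.random.default_rng(spec.seed)
    n_total = 2 * spec.n_samples_per_group

    # --- peaks on two synthetic contigs, gaps large enough to keep them disjoint
    gaps = rng.integers(900, 2200, size=spec.n_peaks)
    starts = 1000 + np.cumsum(gaps + spec.peak_width) - spec.peak_width
    half = spec.n_peaks // 2
    chrom = np.where(np.arange(spec.n_peaks) < half, "chrS1", "chrS2")
    starts = np.where(np.arange(spec.n_peaks) < half, starts, starts - starts[half] + 1000)
    peaks = pd.DataFrame(
        {"chrom": chrom, "start": starts, "end": starts + spec.peak_width}
    )
    gc = rng.beta(*spec.gc_beta, size=spec.n_peaks)
    peaks["gc"] = gc

    # --- motif matches: GC association + latent co-occurrence factor
    zgc = (gc - gc.mean()) / gc.std()
    u = rng.normal(size=spec.n_peaks)  # latent peak factor
    base = rng.uniform(*spec.motif_prevalence, size=spec.n_motifs)
    gc_coef = rng.normal(0, spec.gc_association, size=spec.n_motifs)
    loading = np.zeros(spec.n_motifs)
    loading[spec.perturbed_motif] = spec.cooccurrence
    candidates = [m for m in range(spec.n_motifs) if m != spec.perturbed_motif]
    network = rng.choice(candidates, size=min(spec.n_network, len(candidates)),
                         replace=False)
    loading[network] = spec.cooccurrence * rng.uniform(0.5, 1.0, size=len(network))
    logit = (
        np.log(base / (1 - base))[None, :]
        + gc_coef[None, :] * zgc[:, None]
        + loading[None, :] * u[:, None]
    )
    prob = 1.0 / (1.0 + np.exp(-logit))
    indicator = rng.random((spec.n_peaks, spec.n_motifs)) < prob
    score = np.where(indicator, rng.uniform(5.0, 15.0, size=indicator.shape), 0.0)
    ppms = _sample_ppms(rng, spec.n_motifs, spec.n_archetype_twins)
    matches = MotifMatchMatrix(indicator, score, [p.motif_id for p in ppms])

    # --- baseline fragments: NB counts realized per sample
    mu_peak = rng.lognormal(*spec.nb_mean_log, size=spec.n_peaks)
    depth = rng.lognormal(0.0, spec.depth_sigma, size=n_total)
    baseline = []
    for j in range(n_total):
        mu = mu_peak * depth[j]
        nb_p = spec.nb_size / (spec.nb_size + mu)
        counts_j = rng.negative_binomial(spec.nb_size, nb_p)
        df = _sample_fragments(rng, peaks, counts_j, spec.length_weights, gc)
        baseline.append(FragmentSet(f"sample{j}", df))

    # --- ChIP peaks of the perturbed motif: mostly matched, some off-motif
    matched = np.flatnonzero(indicator[:, spec.perturbed_motif])
    unmatched = np.flatnonzero(~indicator[:, spec.perturbed_motif])
    n_on = max(2, int(round(spec.chip_match_fraction * len(matched))))
    on = rng.choice(matched, size=min(n_on, len(matched)), replace=False)
    n_off = int(round(spec.chip_offmotif_fraction * len(on) / (1 - spec.chip_offmotif_fraction)))
    off = rng.choice(unmatched, size=min(n_off, len(unmatched)), replace=False)
    chip_idx = np.sort(np.concatenate([on, off]))
    chip = peaks.iloc[chip_idx][["chrom", "start", "end"]].reset_index(drop=True)
    # occupancy correlates with accessibility: enrichment tied to the peak mean
    chip["enrichment"] = mu_peak[chip_idx] * rng.lognormal(0.0, 0.4, size=len(chip_idx))

    # --- perturbation
    scenario = builtin_scenario(spec.scenario)
    sim_seed = int(rng.integers(0, 2**31 - 1))
    result = simulate_two_group_dataset(
        baseline, chip, scenario, spec.strength, seed=sim_seed
    )
    fragments = result.group_a + result.group_b
    groups = ["A"] * spec.n_samples_per_group + ["B"] * spec.n_samples_per_group

    counts = count_overlaps(fragments, peaks)
    peak_table = PeakTable(peaks, counts, [fs.sample_id for fs in fragments])
    manifest = {
        "spec": asdict(spec),
        "true_motif": ppms[spec.perturbed_motif].motif_id,
        "network_members": sorted(ppms[m].motif_id for m in network),
        "chip_peak_indices": chip_idx.tolist(),
        "null": spec.strength == 0,
        "simulation": result.manifest,
    }
    return FixtureBundle(
        peak_table, matches, ppms, fragments, baseline, chip, groups, manifest
    )


def generate_null_resample(bundle: FixtureBundle, seed: int) -> FixtureBundle:
    """Permute sample group labels (sizes preserved); data untouched."""
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(bundle.groups))
    groups = [bundle.groups[i] for i in perm]
    manifest = dict(bundle.manifest)
    manifest["null"] = True
    manifest["label_permutation"] = perm.tolist()
    return FixtureBundle(
        bundle.peak_table,
        bundle.matches,
        bundle.ppms,
        bundle.fragments,
        bundle.baseline_fragments,
        bundle.chip_peaks,
        groups,
        manifest,
    )


def write_fixture(bundle: FixtureBundle, directory) -> dict:
    """Emit the fixture in the formats the CLIs consume; returns the paths."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    paths = {}
    for fs in bundle.fragments:
        p = d / f"fragments_{fs.sample_id}.tsv"
        write_fragments(fs, p)
        paths[f"fragments_{fs.sample_id}"] = str(p)
    write_peaks_bed(bundle.peak_table.peaks, d / "peaks.bed")
    bundle.peak_table.peaks.to_csv(d / "peaks_gc.tsv", sep="\t", index=False)
    from .core_io import write_counts_tsv

    write_counts_tsv(
        bundle.peak_table.peaks,
        bundle.peak_table.counts,
        bundle.peak_table.sample_ids,
        d / "counts.tsv",
    )
    write_matches_mtx(bundle.matches, d / "matches")
    write_jaspar(bundle.ppms, d / "motifs.jaspar")
    chip = bundle.chip_peaks.copy()
    chip.to_csv(d / "chip_peaks.bed", sep="\t", header=False, index=False)
    pd.DataFrame({"sample": [fs.sample_id for fs in bundle.fragments], "group": bundle.groups}).to_csv(
        d / "design.tsv", sep="\t", index=False
    )
    with open(d / "manifest.json", "w") as fh:
        json.dump(bundle.manifest, fh, indent=1, sort_keys=True)
    paths.update(
        peaks=str(d / "peaks.bed"),
        counts=str(d / "counts.tsv"),
        matches=str(d / "matches.mtx"),
        motifs=str(d / "motifs.jaspar"),
        chip=str(d / "chip_peaks.bed"),
        design=str(d / "design.tsv"),
        manifest=str(d / "manifest.json"),
    )
    return paths
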
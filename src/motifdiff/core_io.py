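"""Fragment, peak and motif I/O for bulk ATAC-seq differential TF-activity analyses.

Conventions
-----------
All coordinates are BED-style: 0-based, half-open ``[start, end)``. A fragment of
length L spans ``end - start = L`` base pairs and marks two Tn5 insertion events,
one at each end. Fragment files are assumed to be Tn5-pre-shifted (10x-style);
``tn5_insertions`` exposes shift arguments for unshifted input.

Fragment duplicate counts (optional 5th column) are carried as integer weights by
default; every counting operation in the package is weight-aware.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

#: fragment-length class boundaries: (0,120] NF, (120,300] mono, (300,500] di, >500 multi
LENGTH_CLASS_BREAKS = (120, 300, 500)
LENGTH_CLASSES = ("NF", "mono", "di", "multi")
#: nucleosome-free filter bounds (inclusive)
NF_MIN, NF_MAX = 30, 120

FRAGMENT_COLUMNS = ["chrom", "start", "end", "sample", "weight"]


class FragmentParseError(ValueError):
    """Raised for malformed fragment records; carries the 1-based line number."""

    def __init__(self, message: str, line: int | None = None):
        super().__init__(message)
        self.line = line


@dataclass
class FragmentSet:
    """Per-sample genomic fragments.

    Parameters
    ----------
    sample_id:
        Sample label.
    df:
        DataFrame with columns ``chrom`` (str), ``start``, ``end`` (int, half-open)
        and ``weight`` (int multiplicity). An optional ``gc`` column (per-fragment
        GC fraction) is used by composition-bias operations.
    n_rejected:
        Number of malformed/inverted records dropped while reading.
    """

    sample_id: str
    df: pd.DataFrame
    n_rejected: int = 0

    def __post_init__(self):
        required = {"chrom", "start", "end"}
        missing = required - set(self.df.columns)
        if missing:
            raise ValueError(f"fragment frame missing columns: {sorted(missing)}")
        if "weight" not in self.df.columns:
            self.df = self.df.assign(weight=np.ones(len(self.df), dtype=np.int64))
        if len(self.df) and not (self.df["end"].to_numpy() > self.df["start"].to_numpy()).all():
            raise ValueError("fragment ends must exceed starts")

    def __len__(self) -> int:
        return len(self.df)

    @property
    def lengths(self) -> np.ndarray:
        return (self.df["end"] - self.df["start"]).to_numpy()

    @property
    def total_weight(self) -> int:
        return int(self.df["weight"].sum())

    def copy(self) -> "FragmentSet":
        return FragmentSet(self.sample_id, self.df.copy(deep=True), self.n_rejected)


def read_fragments(
    path,
    sample_id: str | None = None,
    expand_duplicates: bool = False,
) -> FragmentSet:
    """Read a fragments TSV/BED (``chrom  start  end  [sample]  [count]``).

    If the file has a sample column and ``sample_id`` is given, only that
    sample's records are returned; otherwise all records are kept. The optional
    duplicate-count column becomes the fragment weight, or — when
    ``expand_duplicates`` — each record is expanded to that many identical rows.
    Records with ``start >= end`` are rejected and counted, not fatal.
    """
    try:
        raw = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    except pd.errors.EmptyDataError:
        empty = pd.DataFrame({"chrom": [], "start": [], "end": [], "weight": []}).astype(
            {"start": np.int64, "end": np.int64, "weight": np.int64}
        )
        return FragmentSet(sample_id or "all", empty)
    if raw.shape[1] < 3:
        raise FragmentParseError(f"{path}: expected >= 3 tab-separated columns")
    ncol = raw.shape[1]
    df = raw.iloc[:, :3].copy()
    df.columns = ["chrom", "start", "end"]
    for col in ("start", "end"):
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna()
        if bad.any():
            line = int(np.flatnonzero(bad.to_numpy())[0]) + 1
            raise FragmentParseError(
                f"{path}: malformed {col} field at line {line}", line=line
            )
        df[col] = converted.astype(np.int64)
    if ncol >= 4:
        df["sample"] = raw.iloc[:, 3]
    if ncol >= 5:
        weight = pd.to_numeric(raw.iloc[:, 4], errors="coerce")
        bad = weight.isna()
        if bad.any():
            line = int(np.flatnonzero(bad.to_numpy())[0]) + 1
            raise FragmentParseError(f"{path}: malformed count at line {line}", line=line)
        df["weight"] = weight.astype(np.int64)
    else:
        df["weight"] = np.int64(1)

    if sample_id is not None and "sample" in df.columns:
        df = df[df["sample"] == sample_id]
    valid = df["end"].to_numpy() > df["start"].to_numpy()
    n_rejected = int((~valid).sum())
    if n_rejected:
        log.warning("%s: rejected %d records with start >= end", path, n_rejected)
        df = df[valid]
    if expand_duplicates:
        df = df.loc[df.index.repeat(df["weight"].to_numpy())].assign(weight=np.int64(1))
    df = df.drop(columns=[c for c in ("sample",) if c in df.columns]).reset_index(drop=True)
    return FragmentSet(sample_id or "all", df, n_rejected=n_rejected)


def write_fragments(frags: FragmentSet, path) -> None:
    """Write a FragmentSet as ``chrom  start  end  sample  weight`` TSV."""
    out = frags.df[["chrom", "start", "end"]].copy()
    out["sample"] = frags.sample_id
    out["weight"] = frags.df["weight"].to_numpy()
    out.to_csv(path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# peaks


@dataclass
class PeakTable:
    """Consensus peaks with optional GC annotation and per-sample counts.

    ``peaks`` holds ``chrom/start/end`` (and optionally ``gc``); ``counts`` is a
    peaks x samples integer matrix aligned to ``sample_ids``.
    """

    peaks: pd.DataFrame
    counts: np.ndarray | None = None
    sample_ids: list[str] | None = None

    def __post_init__(self):
        if "gc" in self.peaks.columns:
            gc = self.peaks["gc"].to_numpy(float)
            if len(gc) and ((gc < 0) | (gc > 1)).any():
                raise ValueError("peak GC fractions must lie in [0, 1]")
        if self.counts is not None and self.counts.shape[0] != len(self.peaks):
            raise ValueError("counts rows must match number of peaks")

    @property
    def n_peaks(self) -> int:
        return len(self.peaks)

    @property
    def gc(self) -> np.ndarray:
        return self.peaks["gc"].to_numpy(float)

    @property
    def widths(self) -> np.ndarray:
        return (self.peaks["end"] - self.peaks["start"]).to_numpy()


def read_peaks_bed(path) -> pd.DataFrame:
    """Read BED3+ peaks; extra columns (name/score) are preserved."""
    try:
        df = pd.read_csv(path, sep="\t", header=None, comment="#")
    except pd.errors.EmptyDataError:
        return pd.DataFrame({"chrom": [], "start": [], "end": []})
    names = ["chrom", "start", "end", "name", "score", "strand"][: df.shape[1]]
    names += [f"extra{i}" for i in range(df.shape[1] - len(names))]
    df.columns = names
    return df


def write_peaks_bed(peaks: pd.DataFrame, path) -> None:
    cols = [c for c in ("chrom", "start", "end", "name", "score", "strand") if c in peaks.columns]
    peaks[cols].to_csv(path, sep="\t", header=False, index=False)


def merge_intervals(df: pd.DataFrame) -> pd.DataFrame:
    """Union-merge overlapping or book-ended intervals (per chromosome)."""
    if not len(df):
        return df[["chrom", "start", "end"]].copy()
    d = df.sort_values(["chrom", "start", "end"], kind="stable").reset_index(drop=True)
    out = []
    for chrom, sub in d.groupby("chrom", sort=True, observed=True):
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        run_end = np.maximum.accumulate(ends)
        new_block = np.ones(len(sub), dtype=bool)
        new_block[1:] = starts[1:] > run_end[:-1]
        block = np.cumsum(new_block) - 1
        for b in range(block[-1] + 1):
            mask = block == b
            out.append((chrom, int(starts[mask][0]), int(run_end[mask][-1])))
    return pd.DataFrame(out, columns=["chrom", "start", "end"])


def resize_and_merge_peaks(
    peak_sets: list[pd.DataFrame],
    width: int,
    chrom_sizes: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Union-merge peak calls across inputs, then resize each merged interval.

    Every merged interval is re-anchored at its (floored) midpoint and set to
    ``width`` bp: ``[mid - width//2, mid - width//2 + width)``. Resized peaks
    that newly overlap are *not* re-merged (fixed-width convention). Intervals
    are truncated at 0 and, when ``chrom_sizes`` is given, at the contig end, so
    edge peaks may be narrower than ``width``.
    """
    if not peak_sets:
        raise ValueError("at least one peak set is required")
    if width <= 0:
        raise ValueError("width must be positive")
    merged = merge_intervals(pd.concat(peak_sets, ignore_index=True))
    mid = (merged["start"].to_numpy() + merged["end"].to_numpy()) // 2
    start = mid - width // 2
    end = start + width
    start = np.maximum(start, 0)
    if chrom_sizes is not None:
        limits = merged["chrom"].map(chrom_sizes).to_numpy()
        end = np.minimum(end, limits)
    out = merged.copy()
    out["start"], out["end"] = start, np.maximum(end, start + 1)
    return out.reset_index(drop=True)


def count_overlaps(
    fragment_sets: list[FragmentSet],
    peaks: pd.DataFrame,
) -> np.ndarray:
    """Count fragments overlapping each peak by >= 1 bp, per sample.

    A fragment overlapping k peaks increments each of the k rows. Weights
    (duplicate counts) are summed. Chromosomes present in the fragments but not
    the peaks contribute nothing (logged at debug level).
    """
    n_peaks = len(peaks)
    counts = np.zeros((n_peaks, len(fragment_sets)), dtype=np.int64)
    if n_peaks == 0:
        return counts
    peak_rows_by_chrom = {
        chrom: sub for chrom, sub in peaks.reset_index().groupby("chrom", observed=True)
    }
    for j, fs in enumerate(fragment_sets):
        if not len(fs.df):
            continue
        for chrom, sub in fs.df.groupby("chrom", observed=True):
            prows = peak_rows_by_chrom.get(chrom)
            if prows is None:
                log.debug("chromosome %s has fragments but no peaks", chrom)
                continue
            fstart = sub["start"].to_numpy()
            fend = sub["end"].to_numpy()
            w = sub["weight"].to_numpy(np.int64)
            order_s = np.argsort(fstart, kind="stable")
            starts_sorted = fstart[order_s]
            cw_start = np.concatenate([[0], np.cumsum(w[order_s])])
            order_e = np.argsort(fend, kind="stable")
            ends_sorted = fend[order_e]
            cw_end = np.concatenate([[0], np.cumsum(w[order_e])])
            ps = prows["start"].to_numpy()
            pe = prows["end"].to_numpy()
            # overlap iff frag.start < peak.end and frag.end > peak.start
            a = cw_start[np.searchsorted(starts_sorted, pe, side="left")]
            b = cw_end[np.searchsorted(ends_sorted, ps, side="right")]
            counts[prows["index"].to_numpy(), j] = a - b
    return counts


def classify_fragments(frags: FragmentSet, mode: str = "length_class"):
    """Classify fragments by length, or filter to nucleosome-free fragments.

    ``length_class`` returns one label per fragment using the fixed thresholds
    (0,120] -> NF, (120,300] -> mono, (300,500] -> di, (500,inf) -> multi.
    ``nucleosome_free`` returns a filtered FragmentSet with 30 <= length <= 120.
    """
    lengths = frags.lengths
    if mode == "length_class":
        idx = np.searchsorted(np.asarray(LENGTH_CLASS_BREAKS), lengths, side="left")
        return np.asarray(LENGTH_CLASSES, dtype=object)[idx]
    if mode == "nucleosome_free":
        keep = (lengths >= NF_MIN) & (lengths <= NF_MAX)
        return FragmentSet(frags.sample_id, frags.df[keep].reset_index(drop=True))
    raise ValueError(f"unknown mode: {mode!r}")


def tn5_insertions(
    frags: FragmentSet, shift_plus: int = 0, shift_minus: int = 0
) -> pd.DataFrame:
    """Expand fragments into per-base insertion events.

    Each fragment contributes two 0-based point positions: ``start + shift_plus``
    and ``end - 1 - shift_minus``. Default shifts (0, 0) assume pre-shifted
    fragment files; pass (4, 5) for the usual Tn5 correction of unshifted input.
    Shifted positions below zero are dropped (logged). Returns a DataFrame with
    columns ``chrom``, ``pos``, ``weight``.
    """
    df = frags.df
    chroms = np.concatenate([df["chrom"].to_numpy()] * 2)
    pos = np.concatenate(
        [df["start"].to_numpy() + shift_plus, df["end"].to_numpy() - 1 - shift_minus]
    )
    weight = np.concatenate([df["weight"].to_numpy()] * 2)
    keep = pos >= 0
    if not keep.all():
        log.warning("dropped %d insertion events shifted below position 0", int((~keep).sum()))
    return pd.DataFrame({"chrom": chroms[keep], "pos": pos[keep], "weight": weight[keep]})


# ---------------------------------------------------------------------------
# motif matches


@dataclass
class MotifMatchMatrix:
    """Peaks x motifs match indicators and (optionally scaled) match scores."""

    indicator: np.ndarray
    score: np.ndarray
    motif_ids: list[str]
    scaled: bool = False

    def __post_init__(self):
        self.indicator = np.asarray(self.indicator, dtype=bool)
        self.score = np.asarray(self.score, dtype=float)
        if self.indicator.shape != self.score.shape:
            raise ValueError("indicator and score shapes differ")
        if self.indicator.shape[1] != len(self.motif_ids):
            raise ValueError("motif_ids length must match number of columns")
        if np.any(self.score[~self.indicator] != 0):
            raise ValueError("scores must be 0 where indicator is 0")

    @property
    def n_motifs(self) -> int:
        return len(self.motif_ids)

    def scale_scores(self) -> "MotifMatchMatrix":
        """Scale each motif's scores by its maximum observed match score."""
        mx = self.score.max(axis=0)
        mx[mx == 0] = 1.0
        return MotifMatchMatrix(self.indicator, self.score / mx, list(self.motif_ids), scaled=True)


def write_matches_mtx(matches: MotifMatchMatrix, prefix) -> None:
    """Write indicator matrix as MatrixMarket plus sidecar row/column names."""
    from scipy.io import mmwrite
    from scipy.sparse import csr_matrix

    mmwrite(f"{prefix}.mtx", csr_matrix(matches.score))
    with open(f"{prefix}.cols", "w") as fh:
        fh.write("\n".join(matches.motif_ids) + "\n")


def read_matches_mtx(prefix) -> MotifMatchMatrix:
    from scipy.io import mmread

    score = np.asarray(mmread(f"{prefix}.mtx").todense())
    with open(f"{prefix}.cols") as fh:
        motif_ids = [line.strip() for line in fh if line.strip()]
    return MotifMatchMatrix(score > 0, score, motif_ids)


def write_counts_tsv(peaks: pd.DataFrame, counts: np.ndarray, sample_ids, path) -> None:
    cols = ["chrom", "start", "end"] + (["gc"] if "gc" in peaks.columns else [])
    out = peaks[cols].copy()
    for j, sid in enumerate(sample_ids):
        out[sid] = counts[:, j]
    out.to_csv(path, sep="\t", index=False)


def read_counts_tsv(path) -> tuple[pd.DataFrame, np.ndarray, list[str]]:
    df = pd.read_csv(path, sep="\t")
    sample_ids = [c for c in df.columns if c not in ("chrom", "start", "end", "gc")]
    return df[[c for c in ("chrom", "start", "end", "gc") if c in df.columns]], df[
        sample_ids
    ].to_numpy(np.int64), sample_ids


# ---------------------------------------------------------------------------
# motif PPMs


@dataclass
class MotifPPM:
    """Position probability matrix: rows A, C, G, T; columns positions."""

    motif_id: str
    matrix: np.ndarray

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape[0] != 4 or self.matrix.shape[1] < 1:
            raise ValueError("PPM must be 4 x L with L >= 1")
        sums = self.matrix.sum(axis=0)
        if not np.allclose(sums, 1.0, atol=1e-6):
            raise ValueError("PPM columns must sum to 1")

    @property
    def length(self) -> int:
        return self.matrix.shape[1]

    def reverse_complement(self) -> "MotifPPM":
        return MotifPPM(self.motif_id, self.matrix[::-1, ::-1])

    def information_content(self) -> np.ndarray:
        """Per-column IC in bits: 2 + sum_b p log2 p (0 log 0 := 0)."""
        with np.errstate(divide="ignore", invalid="ignore"):
            plogp = np.where(self.matrix > 0, self.matrix * np.log2(self.matrix), 0.0)
        return 2.0 + plogp.sum(axis=0)


def _normalize_counts(motif_id: str, counts: np.ndarray) -> MotifPPM:
    counts = np.asarray(counts, dtype=float)
    sums = counts.sum(axis=0)
    zero = sums == 0
    if zero.any():
        warnings.warn(f"motif {motif_id}: zero-count column(s) set to uniform 0.25")
        counts[:, zero] = 0.25
        sums = counts.sum(axis=0)
    return MotifPPM(motif_id, counts / sums)


def read_ppm(path, fmt: str = "jaspar") -> list[MotifPPM]:
    """Read JASPAR raw-count/probability or MEME minimal motif files.

    Counts are normalized per column; zero-count columns become uniform 0.25
    with a warning.
    """
    from Bio import motifs as bio_motifs

    fmt_map = {"jaspar": "jaspar", "meme": "minimal"}
    if fmt not in fmt_map:
        raise ValueError(f"unknown motif format: {fmt!r}")
    with open(path) as fh:
        parsed = bio_motifs.parse(fh, fmt_map[fmt])
    out = []
    for m in parsed:
        if fmt == "jaspar":
            mat = np.array([m.counts[b] for b in "ACGT"], dtype=float)
        else:
            mat = np.array([m.pwm[b] for b in "ACGT"], dtype=float)
        if mat.shape[0] != 4:
            raise ValueError(f"motif {m.name}: expected 4 base rows")
        name = m.name or getattr(m, "matrix_id", None) or f"motif{len(out)}"
        out.append(_normalize_counts(name, mat))
    return out


def write_jaspar(ppms: list[MotifPPM], path, scale: int = 1000) -> None:
    """Write PPMs in JASPAR format (probabilities scaled to pseudo-counts)."""
    with open(path, "w") as fh:
        for ppm in ppms:
            fh.write(f">{ppm.motif_id} {ppm.motif_id}\n")
            for base, row in zip("ACGT", np.round(ppm.matrix * scale).astype(int)):
                fh.write(f"{base}  [ " + " ".join(str(v) for v in row) + " ]\n")
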
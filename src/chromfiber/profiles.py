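"""Aggregate and single-molecule profile views.

Covers 5'-aligned meta-accessibility, motif-centered single-molecule
matrices with Leiden clustering and CpG-methylation overlays, transposase
insertion-preference statistics (the fraction of fragment ends near TSS or
CTCF sites and their fold enrichment over a uniform background), CpG
density/methylation binning of fibers, aggregated track correlation, and
rank-based AUC for methylation-call classification.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import pearsonr, rankdata

from .errors import CapacityError
from .fibertypes import FILTERED, filter_small_clusters, leiden_knn
from .io import Fiber, GenomicInterval


# ---------------------------------------------------------------------------
# 5'-aligned meta profile
# ---------------------------------------------------------------------------


def five_prime_meta(tracks: list[np.ndarray | None], span: int = 1000) -> np.ndarray:
    """Mean accessibility per offset over the first ``span`` nt of each
    molecule, 5'-anchored; shorter molecules contribute as missing beyond
    their length.  Empty input yields an empty profile."""
    total = np.zeros(span)
    count = np.zeros(span)
    any_track = False
    for track in tracks:
        if track is None:
            continue
        any_track = True
        m = min(len(track), span)
        total[:m] += track[:m]
        count[:m] += 1
    if not any_track:
        return np.empty(0)
    with np.errstate(invalid="ignore"):
        return np.where(count > 0, total / count, np.nan)


PERIODICITY_MIN_PROMINENCE = 0.25  # same regularity scale as NRL estimation
PERIODICITY_MIN_AMPLITUDE = 0.5  # oscillation RMS relative to the profile mean


def profile_periodicity(
    profile: np.ndarray,
    band: tuple[int, int] = (120, 250),
    min_prominence: float = PERIODICITY_MIN_PROMINENCE,
    min_amplitude: float = PERIODICITY_MIN_AMPLITUDE,
) -> tuple[float | None, float]:
    """Detect a dominant periodic component in a meta-profile.

    The profile is detrended by subtracting a broad running mean.  Two
    criteria must both hold for a period to be reported: the detrended
    profile's autocorrelation has a peak of prominence at least
    ``min_prominence`` at a lag inside ``band`` (regular structure), and
    the oscillation is large in absolute terms -- its RMS is at least
    ``min_amplitude`` times the profile mean.  The second condition rejects
    the vanishing-amplitude residue that finitely many phase-randomized
    molecules leave in an otherwise flat profile.  Returns ``(period,
    amplitude)`` with ``period=None`` when no dominant component exists.
    """
    from scipy.signal import find_peaks

    x = np.asarray(profile, dtype=np.float64)
    x = x[np.isfinite(x)]
    if len(x) < 2 * band[0] or x.mean() <= 0:
        return None, 0.0
    kernel = np.ones(201) / 201
    detrended = x - np.convolve(x, kernel, mode="same")
    core = detrended[100:-100] if len(detrended) > 400 else detrended
    amplitude = float(np.sqrt(np.mean(core**2)) / x.mean())
    d = detrended - detrended.mean()
    var = np.dot(d, d)
    if var <= 0:
        return None, amplitude
    max_lag = min(len(d) - 2, band[1] + 50)
    nfft = int(2 ** np.ceil(np.log2(2 * len(d))))
    fx = np.fft.rfft(d, nfft)
    acf = np.fft.irfft(fx * np.conj(fx), nfft)[: max_lag + 1] / var
    peaks, props = find_peaks(acf, prominence=min_prominence)
    in_band = [
        (int(p), float(pr)) for p, pr in zip(peaks, props["prominences"]) if band[0] <= p <= band[1]
    ]
    if not in_band or amplitude < min_amplitude:
        return None, amplitude
    period = max(in_band, key=lambda t: t[1])[0]
    return float(period), amplitude


# ---------------------------------------------------------------------------
# Motif-centered matrices
# ---------------------------------------------------------------------------


@dataclass
class MotifMatrix:
    """Single-molecule accessibility around stranded anchors.

    One row per (molecule, anchor) pair whose fiber fully spans the window;
    columns run -W/2..W/2-1 nt from the anchor center, oriented along the
    anchor strand (minus-strand anchors are column-reversed).
    """

    data: np.ndarray  # (n_rows, window) float, 1 accessible / 0 inaccessible / nan missing
    molecule_ids: list[str]
    anchor_ids: list[str]
    anchor_centers: list[int]
    anchor_strands: list[str]

    @property
    def window(self) -> int:
        return self.data.shape[1]


def motif_matrix(
    fibers: list[Fiber],
    tracks: list[np.ndarray | None],
    anchors: list[GenomicInterval],
    window: int = 750,
) -> MotifMatrix:
    half = window // 2
    rows, mols, aids, centers, strands = [], [], [], [], []
    anchors_by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in anchors:
        anchors_by_chrom.setdefault(iv.chrom, []).append(iv)
    for fiber, track in zip(fibers, tracks):
        if track is None:
            continue
        for iv in anchors_by_chrom.get(fiber.chrom, []):
            lo, hi = iv.center - half, iv.center - half + window
            if fiber.start <= lo and fiber.end >= hi:
                row = track[lo - fiber.start : hi - fiber.start].astype(np.float64)
                if iv.strand == "-":
                    row = row[::-1]
                rows.append(row)
                mols.append(fiber.molecule_id)
                aids.append(iv.name)
                centers.append(iv.center)
                strands.append(iv.strand)
    data = np.vstack(rows) if rows else np.empty((0, window))
    return MotifMatrix(data, mols, aids, centers, strands)


def cluster_motif_matrix(
    matrix: MotifMatrix,
    k_neighbors: int = 15,
    resolution: float = 0.1,
    seed: int = 0,
    min_frac: float = 0.10,
    max_missing_frac: float = 0.20,
) -> np.ndarray:
    """Leiden row labels on the motif matrix; clusters below ``min_frac`` of
    rows are removed (label FILTERED).  Rows with more than
    ``max_missing_frac`` missing cells are dropped (FILTERED); remaining
    missing cells are mean-imputed per column."""
    X = matrix.data.copy()
    if X.shape[0] < 100:
        raise CapacityError("motif-matrix clustering needs at least 100 rows")
    missing = ~np.isfinite(X)
    usable = missing.mean(axis=1) <= max_missing_frac
    labels = np.full(X.shape[0], FILTERED, dtype=np.int64)
    Xu = X[usable]
    col_mean = np.nanmean(np.where(np.isfinite(Xu), Xu, np.nan), axis=0)
    col_mean = np.where(np.isfinite(col_mean), col_mean, 0.0)
    Xu = np.where(np.isfinite(Xu), Xu, col_mean[None, :])
    raw = leiden_knn(Xu, k_neighbors, resolution, seed)
    labels[usable] = filter_small_clusters(raw, min_frac)
    return labels


def cluster_cpg_overlay(
    matrix: MotifMatrix,
    labels: np.ndarray,
    fibers_by_id: dict[str, Fiber],
) -> dict[int, np.ndarray]:
    """Per-cluster mean CpG methylation profile across the motif window.

    Positions where a cluster has no CpG observations are missing (nan).
    """
    window = matrix.window
    half = window // 2
    sums: dict[int, np.ndarray] = {}
    counts: dict[int, np.ndarray] = {}
    for row in range(matrix.data.shape[0]):
        label = int(labels[row])
        if label == FILTERED:
            continue
        fiber = fibers_by_id[matrix.molecule_ids[row]]
        center = matrix.anchor_centers[row]
        lo = center - half
        rel = fiber.cpg_positions + fiber.start - lo
        sel = (rel >= 0) & (rel < window)
        cols = rel[sel]
        probs = fiber.m5dc_prob[sel]
        if matrix.anchor_strands[row] == "-":
            cols = window - 1 - cols
        if label not in sums:
            sums[label] = np.zeros(window)
            counts[label] = np.zeros(window)
        np.add.at(sums[label], cols, probs)
        np.add.at(counts[label], cols, 1.0)
    out = {}
    for label, s in sums.items():
        with np.errstate(invalid="ignore"):
            out[label] = np.where(counts[label] > 0, s / counts[label], np.nan)
    return out


# ---------------------------------------------------------------------------
# Insertion preference (FRITSS / FRICBS)
# ---------------------------------------------------------------------------


@dataclass
class InsertionProfile:
    anchor_set_id: str
    window: int
    profile: np.ndarray  # smoothed per-position end counts, anchor-centered
    frit_score: float  # fraction of ends within the window of any anchor
    fold_enrichment: float


def fragment_ends(fibers: list[Fiber]) -> pd.DataFrame:
    """Both genomic end coordinates of every fragment (the insertion sites)."""
    chroms, pos = [], []
    for f in fibers:
        chroms.extend([f.chrom, f.chrom])
        pos.extend([f.start, f.end - 1])
    return pd.DataFrame({"chrom": chroms, "pos": pos})


def _merge_windows(anchors: list[GenomicInterval], half: int) -> dict[str, np.ndarray]:
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for iv in anchors:
        by_chrom.setdefault(iv.chrom, []).append((max(0, iv.center - half), iv.center + half))
    merged = {}
    for chrom, spans in by_chrom.items():
        spans.sort()
        out = [list(spans[0])]
        for s, e in spans[1:]:
            if s <= out[-1][1]:
                out[-1][1] = max(out[-1][1], e)
            else:
                out.append([s, e])
        merged[chrom] = np.array(out)
    return merged


def insertion_preference(
    ends: pd.DataFrame,
    anchors: list[GenomicInterval],
    mappable_span_nt: int,
    window: int = 5000,
    smooth: int = 100,
    anchor_set_id: str = "anchors",
) -> InsertionProfile:
    """Tabulate fragment ends around anchors.

    ``frit_score`` is the fraction of all ends falling within the
    ``window``-nt span centered on any anchor; ``fold_enrichment`` compares
    it against the fraction expected if ends were uniform over the mappable
    span.  The meta-profile is a ``smooth``-nt running mean of the
    anchor-centered end counts.
    """
    if not anchors:
        raise ValueError("insertion_preference requires a non-empty anchor set")
    if len(ends) == 0:
        raise ValueError("insertion_preference requires at least one fragment end")
    half = window // 2
    counts = np.zeros(window)
    pos_by_chrom = {c: np.sort(g["pos"].to_numpy()) for c, g in ends.groupby("chrom")}
    for iv in anchors:
        pos = pos_by_chrom.get(iv.chrom)
        if pos is None:
            continue
        lo, hi = iv.center - half, iv.center + half
        sel = pos[np.searchsorted(pos, lo) : np.searchsorted(pos, hi)]
        rel = sel - lo
        if iv.strand == "-":
            rel = window - 1 - rel
        np.add.at(counts, rel, 1.0)
    kernel = np.ones(smooth) / smooth
    profile = np.convolve(counts, kernel, mode="same")

    merged = _merge_windows(anchors, half)
    n_in = 0
    for chrom, spans in merged.items():
        pos = pos_by_chrom.get(chrom)
        if pos is None:
            continue
        for s, e in spans:
            n_in += np.searchsorted(pos, e) - np.searchsorted(pos, s)
    frit = n_in / len(ends)
    windows_total = sum(int((spans[:, 1] - spans[:, 0]).sum()) for spans in merged.values())
    expected = min(1.0, windows_total / mappable_span_nt)
    fold = frit / expected if expected > 0 else float("nan")
    return InsertionProfile(anchor_set_id, window, profile, float(frit), float(fold))


# ---------------------------------------------------------------------------
# CpG density / methylation binning
# ---------------------------------------------------------------------------

CPG_DENSITY_THRESHOLD = 10.0  # CpGs per kb; strictly greater is "high"
CPG_METH_THRESHOLD = 0.5  # mean score; strictly greater is "high"


@dataclass
class CpGClass:
    molecule_id: str
    cpg_per_kb: float
    mean_score: float
    label: str  # e.g. "high-CpG/low-meth"


def classify_cpg(fiber: Fiber) -> CpGClass | None:
    """Bin a fiber by CpG density (>10/kb high) and mean methylation score
    (>0.5 high); fibers without CpGs are excluded (None)."""
    n = len(fiber.cpg_positions)
    if n == 0:
        return None
    density = n / (fiber.length_nt / 1000.0)
    mean_score = float(fiber.m5dc_prob.mean())
    dens_label = "high" if density > CPG_DENSITY_THRESHOLD else "low"
    meth_label = "high" if mean_score > CPG_METH_THRESHOLD else "low"
    return CpGClass(
        fiber.molecule_id, density, mean_score, f"{dens_label}-CpG/{meth_label}-meth"
    )


# ---------------------------------------------------------------------------
# Track correlation and methylation-call AUC
# ---------------------------------------------------------------------------


def correlate_tracks(
    track_a: np.ndarray, track_b: np.ndarray, pseudocount: float = 1.0
) -> float:
    """Pearson r between log-transformed per-region aggregates."""
    a = np.asarray(track_a, dtype=np.float64)
    b = np.asarray(track_b, dtype=np.float64)
    if len(a) != len(b):
        raise ValueError("tracks must aggregate the same regions")
    if len(a) < 3:
        raise ValueError("correlate_tracks needs at least 3 regions")
    return float(pearsonr(np.log(a + pseudocount), np.log(b + pseudocount))[0])


def cpg_call_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Rank-based AUC (Mann-Whitney normalization, ties averaged)."""
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels).astype(bool)
    n_pos = int(labels.sum())
    n_neg = int(len(labels) - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC requires at least one positive and one negative")
    ranks = rankdata(scores)
    return float((ranks[labels].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))
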
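"""Fiber typing: per-molecule accessibility autocorrelation, Leiden
clustering and nucleosome repeat length (NRL) estimation.

Each molecule at least 1 kb long contributes the autocorrelation of its
per-nt binary accessibility track over lags 1..``max_lag``; the lag axis is
therefore in nucleotides, so a regular array with repeat length L shows an
autocorrelation peak at lag L.  Molecules are clustered on their ACF
vectors with Leiden community detection on a k-nearest-neighbor graph,
small clusters are filtered, and each retained cluster's mean ACF yields
either a repeat-length estimate (the dominant peak in a plausible NRL band)
or "irregular" when no sufficiently prominent peak exists.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .errors import CapacityError

MIN_FIBER_LEN = 1000  # molecules shorter than 1 kb are excluded from typing
FILTERED = -1


@dataclass
class AcfVector:
    molecule_id: str
    values: np.ndarray  # autocorrelation at lags 1..max_lag
    valid: bool


@dataclass
class FiberTypeAssignment:
    molecule_id: str
    cluster_label: int  # FILTERED (-1) when the cluster was removed
    nrl_estimate: float | None


def accessibility_autocorrelation(
    track: np.ndarray | None, max_lag: int = 500, molecule_id: str = ""
) -> AcfVector:
    """Autocorrelation of one binary accessibility track at lags 1..max_lag.

    Computed FFT-style with the global mean/variance normalization; tracks
    with zero variance (or too short to cover ``max_lag``) come back with
    ``valid=False`` and are excluded from clustering.
    """
    if track is None:
        return AcfVector(molecule_id, np.zeros(max_lag), False)
    x = np.asarray(track, dtype=np.float64)
    n = len(x)
    if n <= max_lag + 1:
        return AcfVector(molecule_id, np.zeros(max_lag), False)
    x = x - x.mean()
    var = np.dot(x, x)
    if var <= 0:
        return AcfVector(molecule_id, np.zeros(max_lag), False)
    nfft = int(2 ** np.ceil(np.log2(2 * n)))
    fx = np.fft.rfft(x, nfft)
    acov = np.fft.irfft(fx * np.conj(fx), nfft)[: max_lag + 1]
    values = acov[1:] / var
    return AcfVector(molecule_id, np.clip(values, -1.0, 1.0), True)


def leiden_knn(
    X: np.ndarray, k_neighbors: int = 15, resolution: float = 0.1, seed: int = 0
) -> np.ndarray:
    """Leiden community detection on a symmetrized kNN graph (Euclidean)."""
    import igraph
    import leidenalg
    from sklearn.neighbors import kneighbors_graph

    adj = kneighbors_graph(X, n_neighbors=k_neighbors, mode="connectivity")
    adj = adj.maximum(adj.T).tocoo()
    mask = adj.row < adj.col
    edges = list(zip(adj.row[mask].tolist(), adj.col[mask].tolist()))
    graph = igraph.Graph(n=X.shape[0], edges=edges)
    part = leidenalg.find_partition(
        graph,
        leidenalg.RBConfigurationVertexPartition,
        resolution_parameter=resolution,
        seed=seed,
        n_iterations=-1,
    )
    return np.asarray(part.membership, dtype=np.int64)


def cluster_acf(
    acf_matrix: np.ndarray, k_neighbors: int = 15, resolution: float = 0.1, seed: int = 0
) -> np.ndarray:
    """Cluster molecules on their ACF vectors; deterministic given the seed."""
    X = np.asarray(acf_matrix, dtype=np.float64)
    if X.shape[0] < max(50, k_neighbors + 1):
        raise CapacityError(
            f"clustering needs at least {max(50, k_neighbors + 1)} valid ACF vectors, got {X.shape[0]}"
        )
    return leiden_knn(X, k_neighbors, resolution, seed)


def filter_small_clusters(labels: np.ndarray, min_frac: float = 0.10) -> np.ndarray:
    """Mark clusters holding strictly less than ``min_frac`` of clustered
    fibers as FILTERED; survivors are relabeled contiguously by decreasing
    size (clusters at exactly the threshold are retained)."""
    labels = np.asarray(labels)
    out = np.full(len(labels), FILTERED, dtype=np.int64)
    uniq, counts = np.unique(labels, return_counts=True)
    total = len(labels)
    keep = [(int(c), int(u)) for u, c in zip(uniq, counts) if c / total >= min_frac]
    keep.sort(key=lambda t: (-t[0], t[1]))
    for new_label, (_, old_label) in enumerate(keep):
        out[labels == old_label] = new_label
    return out


def _running_mean(x: np.ndarray, window: int) -> np.ndarray:
    kernel = np.ones(window) / window
    return np.convolve(x, kernel, mode="same")


def estimate_nrl(
    cluster_mean_acf: np.ndarray,
    band: tuple[int, int] = (120, 250),
    smooth_window: int = 10,
    min_prominence: float = 0.25,
) -> float | None:
    """Repeat length from a cluster's mean ACF: the lag of the highest
    sufficiently prominent local maximum inside ``band`` after running-mean
    smoothing; None (irregular) when no such peak exists."""
    acf = np.asarray(cluster_mean_acf, dtype=np.float64)
    smooth = _running_mean(acf, smooth_window)
    peaks, _ = find_peaks(smooth, prominence=min_prominence)
    lags = peaks + 1  # index i holds lag i+1
    in_band = [(int(l), smooth[l - 1]) for l in lags if band[0] <= l <= band[1]]
    if not in_band:
        return None
    return float(max(in_band, key=lambda t: t[1])[0])


def assign_fiber_types(
    acf_vectors: list[AcfVector],
    k_neighbors: int = 15,
    resolution: float = 0.1,
    seed: int = 0,
    min_frac: float = 0.10,
    nrl_band: tuple[int, int] = (120, 250),
) -> tuple[pd.DataFrame, dict[int, np.ndarray]]:
    """Full typing pass over ACF vectors.

    Invalid (zero-variance or short) vectors are dropped as artifactual;
    the rest are canonically sorted by molecule_id, clustered, small-cluster
    filtered, and annotated with their cluster's NRL estimate.  Returns a
    per-molecule table and the retained clusters' mean ACF vectors.
    """
    valid = sorted((v for v in acf_vectors if v.valid), key=lambda v: v.molecule_id)
    if not valid:
        raise CapacityError("no valid ACF vectors to cluster")
    X = np.vstack([v.values for v in valid])
    labels = filter_small_clusters(cluster_acf(X, k_neighbors, resolution, seed), min_frac)
    mean_acfs: dict[int, np.ndarray] = {}
    nrl_by_label: dict[int, float | None] = {}
    for label in np.unique(labels):
        if label == FILTERED:
            continue
        mean_acf = X[labels == label].mean(axis=0)
        mean_acfs[int(label)] = mean_acf
        nrl_by_label[int(label)] = estimate_nrl(mean_acf, band=nrl_band)
    table = pd.DataFrame(
        {
            "molecule_id": [v.molecule_id for v in valid],
            "cluster_label": labels,
            "nrl_estimate": [nrl_by_label.get(int(l), np.nan) for l in labels],
        }
    )
    return table, mean_acfs
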
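"""EEG microstate analysis: GFP peaks, polarity-invariant clustering,
segmentation, and the classical per-state parameters.

The scalp potential at moments of high global field power (GFP) is treated
as a draw from a small set of quasi-stable template topographies.  Because
a dipolar generator reverses sign within a state, all comparisons use the
absolute spatial correlation: the clustering is the "modified k-means" in
which a prototype is the dominant eigenvector of its members' outer-product
sum (the sign-invariant analogue of the mean), and assignment maximizes
|r|.  Segmentation backfits prototypes at GFP peaks and spreads labels to
neighbouring samples by nearest peak.

Per-state parameters follow the standard definitions: mean dwell duration
(ms), occurrence (runs per second), coverage (fraction of samples), GEV
(fraction of GFP-weighted variance explained), and the switch matrix
(fraction of all inter-state transitions per ordered pair).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.signal import argrelextrema

from .containers import EEGRecording, Montage

__all__ = [
    "TopographySet",
    "MicrostateModel",
    "Segmentation",
    "MicrostateStats",
    "TransitionMatrix",
    "gfp",
    "gfp_series",
    "extract_gfp_peaks",
    "spatial_correlation_abs",
    "kmeans_polarity_invariant",
    "group_maps_two_stage",
    "backfit",
    "compute_parameters",
    "transition_probabilities",
    "canonical_maps",
    "order_by_canonical",
]

STATE_NAMES = "ABCDEFGHIJ"


# ---------------------------------------------------------------------------
# containers


@dataclass
class TopographySet:
    """Instantaneous maps sampled at GFP peaks (rows mean-removed)."""

    maps: np.ndarray  # (n_maps, channels)
    gfp_at_peak: np.ndarray  # (n_maps,)
    source_times: np.ndarray  # (n_maps,) sample indices

    def __post_init__(self):
        self.maps = np.asarray(self.maps, dtype=float)
        self.maps = self.maps - self.maps.mean(axis=1, keepdims=True)

    @property
    def n_maps(self) -> int:
        return self.maps.shape[0]


@dataclass
class MicrostateModel:
    """K prototype topographies (zero-mean, unit-norm rows)."""

    prototypes: np.ndarray  # (k, channels)
    gev_total: float
    labels_by_class: tuple[str, ...] = ()

    def __post_init__(self):
        p = np.asarray(self.prototypes, dtype=float)
        p = p - p.mean(axis=1, keepdims=True)
        norms = np.linalg.norm(p, axis=1, keepdims=True)
        if np.any(norms == 0):
            raise ValueError("zero prototype")
        self.prototypes = p / norms
        if not self.labels_by_class:
            self.labels_by_class = tuple(STATE_NAMES[: self.k])

    @property
    def k(self) -> int:
        return self.prototypes.shape[0]


@dataclass
class Segmentation:
    """Per-sample state labels plus |r| to the assigned prototype."""

    labels: np.ndarray  # (n_samples,) int
    fs_hz: float
    corr_series: np.ndarray  # (n_samples,) in [0, 1]


@dataclass
class MicrostateStats:
    """Per-state temporal parameters; ``duration_ms`` is NaN for a state
    that never occurs."""

    duration_ms: np.ndarray
    occurrence_per_s: np.ndarray
    coverage: np.ndarray
    gev: np.ndarray
    state_names: tuple[str, ...] = ()


@dataclass
class TransitionMatrix:
    """Ordered-pair switch counts and their fractions of all switches."""

    counts: np.ndarray  # (k, k) int, zero diagonal
    probs: np.ndarray  # counts / total switches


# ---------------------------------------------------------------------------
# elementary operations


def gfp(sample: np.ndarray) -> float:
    """Global field power: spatial standard deviation of one map."""
    sample = np.asarray(sample, dtype=float)
    if sample.size < 2:
        raise ValueError("GFP needs >= 2 channels")
    return float(np.sqrt(np.mean((sample - sample.mean()) ** 2)))


def gfp_series(data: np.ndarray) -> np.ndarray:
    """GFP at every sample of a channels x samples matrix."""
    return np.sqrt(np.mean((data - data.mean(axis=0, keepdims=True)) ** 2, axis=0))


def spatial_correlation_abs(a: np.ndarray, b: np.ndarray) -> float:
    """|Pearson correlation| of two maps across channels (polarity-blind)."""
    a = np.asarray(a, dtype=float) - np.mean(a)
    b = np.asarray(b, dtype=float) - np.mean(b)
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("zero-variance map has undefined spatial correlation")
    return float(abs(a @ b) / (na * nb))


def extract_gfp_peaks(rec: EEGRecording) -> TopographySet:
    """Maps at strict local maxima of the GFP time series.

    Callers are expected to pass 2-20 Hz filtered, average-referenced data;
    the function itself only mean-removes each extracted map.
    """
    g = gfp_series(rec.data)
    idx = argrelextrema(g, np.greater)[0]  # strict: g[t] > g[t-1] and > g[t+1]
    return TopographySet(maps=rec.data[:, idx].T.copy(), gfp_at_peak=g[idx], source_times=idx)


def _normalize_rows(x: np.ndarray) -> np.ndarray:
    x = x - x.mean(axis=1, keepdims=True)
    n = np.linalg.norm(x, axis=1, keepdims=True)
    n[n == 0] = 1.0
    return x / n


# ---------------------------------------------------------------------------
# clustering


def _gev_of_assignment(z: np.ndarray, w2: np.ndarray, protos: np.ndarray,
                       labels: np.ndarray) -> float:
    """GEV for unit maps ``z`` with squared GFP weights ``w2``."""
    c = np.abs(np.einsum("nc,nc->n", z, protos[labels]))
    return float(np.sum(w2 * c**2) / np.sum(w2))


def kmeans_polarity_invariant(
    tset: TopographySet,
    k: int,
    n_restarts: int = 50,
    seed: int | np.random.Generator = 0,
    max_iter: int = 200,
    tol: float = 1e-9,
) -> MicrostateModel:
    """Modified (polarity-invariant) k-means on GFP-peak maps.

    Assignment maximizes |r| to the prototypes; the update replaces each
    prototype by the dominant eigenvector of its members' scatter matrix.
    The best of ``n_restarts`` random initializations by GEV is returned.
    An emptied cluster is re-seeded from the currently worst-fit map.
    """
    if tset.n_maps < k:
        raise ValueError(f"need at least k={k} maps, got {tset.n_maps}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    z = _normalize_rows(tset.maps.copy())
    w2 = np.asarray(tset.gfp_at_peak, dtype=float) ** 2
    n = z.shape[0]

    best: tuple[float, np.ndarray] | None = None
    for _ in range(max(1, n_restarts)):
        protos = z[rng.choice(n, size=k, replace=False)].copy()
        prev_gev = -1.0
        for _ in range(max_iter):
            corr = np.abs(z @ protos.T)  # (n, k)
            labels = np.argmax(corr, axis=1)  # ties -> lowest class index
            # re-seed empty clusters from the worst-fit map
            for j in range(k):
                if not np.any(labels == j):
                    worst = int(np.argmin(corr[np.arange(n), labels]))
                    protos[j] = z[worst]
                    labels[worst] = j
            for j in range(k):
                members = z[labels == j]
                s = members.T @ members
                vals, vecs = np.linalg.eigh(s)
                v = vecs[:, -1]
                v = v - v.mean()
                nv = np.linalg.norm(v)
                if nv > 0:
                    v = v / nv
                    protos[j] = v * np.sign(v[np.argmax(np.abs(v))])  # fixed sign
            cur = _gev_of_assignment(z, w2, protos, labels)
            if cur - prev_gev < tol:
                break
            prev_gev = cur
        gev = _gev_of_assignment(z, w2, protos, np.argmax(np.abs(z @ protos.T), axis=1))
        if best is None or gev > best[0]:
            best = (gev, protos.copy())
    return MicrostateModel(prototypes=best[1], gev_total=best[0])


def group_maps_two_stage(
    models: list[MicrostateModel],
    k_group: int,
    n_restarts: int = 50,
    seed: int | np.random.Generator = 0,
    canonical: np.ndarray | None = None,
    montage: Montage | None = None,
) -> MicrostateModel:
    """Group-level maps: pool subject prototypes and re-cluster.

    The pooled prototypes are treated as equal-weight maps in a second
    polarity-invariant k-means; output classes are renamed A, B, ... by
    best |r| match to the canonical reference maps when available.
    """
    if not models:
        raise ValueError("no subject models")
    pooled = np.vstack([m.prototypes for m in models])
    if pooled.shape[0] < k_group:
        raise ValueError(f"k_group={k_group} exceeds pooled prototypes ({pooled.shape[0]})")
    tset = TopographySet(
        maps=pooled, gfp_at_peak=np.ones(pooled.shape[0]),
        source_times=np.arange(pooled.shape[0]),
    )
    model = kmeans_polarity_invariant(tset, k_group, n_restarts=n_restarts, seed=seed)
    if canonical is None and montage is not None:
        canonical = canonical_maps(montage)
    if canonical is not None:
        model = order_by_canonical(model, canonical)
    return model


def canonical_maps(montage: Montage) -> np.ndarray:
    """Reference topographies fixing the A-D naming convention.

    These are synthetic idealizations of the four classical map shapes --
    A: left-posterior/right-anterior diagonal, B: the mirrored diagonal,
    C: anterior-posterior, D: fronto-central maximum -- built from the
    electrode coordinates.  They are a naming fixture, not data.
    """
    x, y, z = montage.positions.T  # x right, y anterior, z superior
    maps = np.stack([
        -x - y,          # A
        x - y,           # B
        -y,              # C
        z - 0.5 * y,     # D
    ])
    return _normalize_rows(maps)


def order_by_canonical(model: MicrostateModel, canonical: np.ndarray) -> MicrostateModel:
    """Reorder classes to best match the canonical maps (optimal one-to-one
    assignment on |r|); extra classes keep their relative order."""
    k = model.k
    kc = canonical.shape[0]
    cano = _normalize_rows(canonical.copy())
    corr = np.abs(model.prototypes @ cano.T)  # (k, kc)
    n_assign = min(k, kc)
    rows, cols = linear_sum_assignment(-corr)
    order = [-1] * n_assign
    for r, c in zip(rows, cols):
        if c < n_assign:
            order[c] = r
    rest = [i for i in range(k) if i not in order]
    order = [i for i in order if i >= 0] + rest
    return MicrostateModel(
        prototypes=model.prototypes[order],
        gev_total=model.gev_total,
        labels_by_class=tuple(STATE_NAMES[: k]),
    )


# ---------------------------------------------------------------------------
# segmentation and parameters


def backfit(rec: EEGRecording, model: MicrostateModel) -> Segmentation:
    """Label every sample by the prototype best matching the nearest GFP peak.

    Peak samples take argmax |r|; samples between two peaks split at the
    midpoint (an exactly equidistant sample goes with the later peak);
    samples before the first or after the last peak inherit that peak's
    label.  ``corr_series`` is |r| of every sample to its assigned
    prototype.
    """
    if rec.n_channels != model.prototypes.shape[1]:
        raise ValueError("channel count mismatch between recording and model")
    tset = extract_gfp_peaks(rec)
    if tset.n_maps == 0:
        raise ValueError("recording has no GFP peaks; cannot segment")
    z = _normalize_rows(tset.maps.copy())
    peak_labels = np.argmax(np.abs(z @ model.prototypes.T), axis=1)

    peaks = tset.source_times
    n = rec.n_samples
    labels = np.empty(n, dtype=np.int64)
    cuts = (peaks[:-1] + peaks[1:] + 1) // 2  # first index owned by the later peak
    bounds = np.concatenate([[0], cuts, [n]])
    for i in range(len(peaks)):
        labels[bounds[i] : bounds[i + 1]] = peak_labels[i]

    maps = _normalize_rows(rec.data.T.copy())
    corr = np.abs(np.einsum("nc,nc->n", maps, model.prototypes[labels]))
    return Segmentation(labels=labels, fs_hz=rec.fs_hz, corr_series=corr)


def _runs(labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(state, length) of each maximal same-label run."""
    change = np.flatnonzero(np.diff(labels)) + 1
    starts = np.concatenate([[0], change])
    lengths = np.diff(np.concatenate([starts, [len(labels)]]))
    return labels[starts], lengths


def compute_parameters(
    seg: Segmentation, rec: EEGRecording, model: MicrostateModel
) -> MicrostateStats:
    """Duration, occurrence, coverage and GEV per state."""
    if len(seg.labels) == 0:
        raise ValueError("empty segmentation")
    k = model.k
    states, lengths = _runs(seg.labels)
    total_s = len(seg.labels) / seg.fs_hz

    duration = np.full(k, np.nan)
    occurrence = np.zeros(k)
    coverage = np.zeros(k)
    for j in range(k):
        lj = lengths[states == j]
        if lj.size:
            duration[j] = lj.mean() * 1000.0 / seg.fs_hz
            occurrence[j] = lj.size / total_s
            coverage[j] = lj.sum() / len(seg.labels)

    g = gfp_series(rec.data)
    g2 = g**2
    denom = float(g2.sum())
    gev = np.zeros(k)
    for j in range(k):
        sel = seg.labels == j
        gev[j] = float(np.sum(g2[sel] * seg.corr_series[sel] ** 2) / denom)
    return MicrostateStats(
        duration_ms=duration,
        occurrence_per_s=occurrence,
        coverage=coverage,
        gev=gev,
        state_names=model.labels_by_class,
    )


def transition_probabilities(seg_or_labels, k: int | None = None) -> TransitionMatrix:
    """Ordered-pair switch fractions from a segmentation or label array."""
    labels = seg_or_labels.labels if isinstance(seg_or_labels, Segmentation) else np.asarray(seg_or_labels)
    states, _ = _runs(labels)
    if k is None:
        k = int(labels.max()) + 1
    counts = np.zeros((k, k), dtype=np.int64)
    if len(states) < 2:
        raise ValueError("single run: no transitions to count")
    np.add.at(counts, (states[:-1], states[1:]), 1)
    total = counts.sum()
    return TransitionMatrix(counts=counts, probs=counts / total)
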
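"""Choosing the number of microstate classes by a battery of
cluster-validity criteria.

Every criterion is evaluated under the polarity-invariant dissimilarity
``d = 1 - |r|`` (r = spatial correlation), each criterion casts one vote
for a k in the candidate range, and the meta-criterion returns the median
vote (ties broken toward the smaller k).  The default battery holds seven
criteria: Krzanowski-Lai, Silhouette, inverted Davies-Bouldin,
Point-Biserial, Dunn, Calinski-Harabasz, and the cross-validation
criterion of the microstate literature (residual noise variance inflated
by the model's degrees of freedom).  The battery is configurable; a robust
median over heterogeneous criteria is less brittle than any single one.
"""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np
from sklearn.metrics import silhouette_score

from .microstate import MicrostateModel, TopographySet, kmeans_polarity_invariant, _normalize_rows

__all__ = ["optimal_k_metacriterion", "criterion_votes", "DEFAULT_CRITERIA"]

#: Separations below this (on the 1 - |r| dissimilarity scale) mean two
#: clusters are numerically indistinct: the criterion then reports its
#: degenerate (worst) value instead of amplified round-off, so that on
#: structureless data the parsimony tie rule prevails.
EPS_INDISTINCT = 1e-2


def _fit_range(tset, k_range, n_restarts, seed):
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    return {
        k: kmeans_polarity_invariant(tset, k, n_restarts=n_restarts, seed=rng)
        for k in k_range
    }


def _labels_and_dist(z: np.ndarray, model: MicrostateModel):
    corr = np.abs(z @ model.prototypes.T)
    labels = np.argmax(corr, axis=1)
    dist_to_proto = 1.0 - corr[np.arange(len(z)), labels]
    return labels, dist_to_proto


def _within_dispersion(z, model) -> float:
    _, d = _labels_and_dist(z, model)
    return float(np.sum(d**2))


# --- individual criteria: each maps k -> score; direction says which end wins


def _crit_silhouette(z, dmat, models):
    out = {}
    for k, m in models.items():
        labels, _ = _labels_and_dist(z, m)
        if len(np.unique(labels)) < 2:
            out[k] = -1.0
        else:
            out[k] = float(silhouette_score(dmat, labels, metric="precomputed"))
    return out, "max"


def _crit_davies_bouldin_inv(z, dmat, models):
    out = {}
    for k, m in models.items():
        labels, d = _labels_and_dist(z, m)
        s = np.array([d[labels == j].mean() if np.any(labels == j) else 0.0 for j in range(k)])
        pc = 1.0 - np.abs(m.prototypes @ m.prototypes.T)
        iu = np.triu_indices(k, 1)
        if pc[iu].max() < EPS_INDISTINCT:  # all prototypes coincide
            out[k] = 0.0
            continue
        db = []
        for i in range(k):
            ratios = [(s[i] + s[j]) / max(pc[i, j], 1e-12) for j in range(k) if j != i]
            db.append(max(ratios))
        out[k] = float(1.0 / max(np.mean(db), 1e-12))
    return out, "max"


def _crit_calinski_harabasz(z, dmat, models):
    n = len(z)
    # polarity-invariant "grand centroid": dominant eigenvector of the scatter
    s = z.T @ z
    _, vecs = np.linalg.eigh(s)
    g = vecs[:, -1]
    g = g - g.mean()
    g /= np.linalg.norm(g)
    out = {}
    for k, m in models.items():
        labels, d = _labels_and_dist(z, m)
        w = np.sum(d**2)
        sizes = np.bincount(labels, minlength=k)
        proto_dist = 1.0 - np.abs(m.prototypes @ g)
        if proto_dist.max() < EPS_INDISTINCT:  # no dispersion between clusters
            out[k] = 0.0
            continue
        b = float(np.sum(sizes * proto_dist**2))
        out[k] = float((b / max(k - 1, 1)) / max(w / max(n - k, 1), 1e-12))
    return out, "max"


def _crit_dunn(z, dmat, models):
    out = {}
    for k, m in models.items():
        labels, _ = _labels_and_dist(z, m)
        diam = 0.0
        inter = np.inf
        for i in range(k):
            di = dmat[np.ix_(labels == i, labels == i)]
            if di.size:
                diam = max(diam, float(di.max()))
            for j in range(i + 1, k):
                dij = dmat[np.ix_(labels == i, labels == j)]
                if dij.size:
                    inter = min(inter, float(dij.min()))
        if not np.isfinite(inter) or inter < EPS_INDISTINCT:
            out[k] = 0.0  # some pair of clusters touches: no real separation
        else:
            out[k] = float(inter / max(diam, 1e-12))
    return out, "max"


def _crit_point_biserial(z, dmat, models):
    iu = np.triu_indices(len(z), k=1)
    dv = dmat[iu]
    out = {}
    for k, m in models.items():
        labels, _ = _labels_and_dist(z, m)
        same = (labels[:, None] == labels[None, :])[iu]
        if same.all() or (~same).all():
            out[k] = -1.0
            continue
        gap = dv[~same].mean() - dv[same].mean()
        if abs(gap) < EPS_INDISTINCT * max(dv.mean(), EPS_INDISTINCT):
            out[k] = 0.0  # between/within separation below numeric floor
            continue
        sd = dv.std()
        nw, nb = same.sum(), (~same).sum()
        out[k] = float(gap * np.sqrt(nw * nb) / (len(dv) * max(sd, 1e-12)))
    return out, "max"


def _crit_krzanowski_lai(z, dmat, models):
    ks = sorted(models)
    p = z.shape[1] - 1  # zero-mean maps live in a (C-1)-dim subspace
    w = {k: _within_dispersion(z, models[k]) for k in ks}

    def diff(k, k_prev):
        return (k_prev) ** (2.0 / p) * w[k_prev] - k ** (2.0 / p) * w[k]

    out = {}
    for k in ks:
        if k - 1 in w and k + 1 in w:
            num = abs(diff(k, k - 1))
            den = abs(diff(k + 1, k))
            out[k] = float(num / max(den, 1e-12))
        else:
            out[k] = -np.inf  # edge k cannot be scored; never wins the vote
    return out, "max"


def _crit_cross_validation(z, dmat, models):
    n, c = z.shape
    out = {}
    for k, m in models.items():
        _, d = _labels_and_dist(z, m)
        # residual variance of unit maps after removing the assigned
        # prototype component, inflated by the dof the model consumes
        sigma2 = np.sum(d * (2.0 - d)) / (n * (c - 1))  # 1 - r^2 summed
        out[k] = float(sigma2 * ((c - 1) / max(c - 1 - k, 1)) ** 2)
    return out, "min"


DEFAULT_CRITERIA: dict[str, Callable] = {
    "krzanowski_lai": _crit_krzanowski_lai,
    "silhouette": _crit_silhouette,
    "davies_bouldin_inv": _crit_davies_bouldin_inv,
    "point_biserial": _crit_point_biserial,
    "dunn": _crit_dunn,
    "calinski_harabasz": _crit_calinski_harabasz,
    "cross_validation": _crit_cross_validation,
}


def criterion_votes(
    tset: TopographySet,
    k_range: Sequence[int],
    n_restarts: int = 20,
    seed: int | np.random.Generator = 0,
    criteria: dict[str, Callable] | None = None,
    max_maps: int = 1000,
) -> dict[str, int]:
    """One vote (a k from ``k_range``) per criterion.

    For speed on long recordings the peak maps may be subsampled evenly to
    ``max_maps`` before computing pairwise dissimilarities.
    """
    k_range = sorted(set(int(k) for k in k_range))
    if min(k_range) < 2 or max(k_range) > tset.n_maps:
        raise ValueError("k_range must lie within [2, n_maps]")
    criteria = DEFAULT_CRITERIA if criteria is None else criteria

    maps = tset.maps
    gfpv = tset.gfp_at_peak
    if tset.n_maps > max_maps:
        sel = np.linspace(0, tset.n_maps - 1, max_maps).astype(int)
        maps, gfpv = maps[sel], gfpv[sel]
    sub = TopographySet(maps=maps, gfp_at_peak=gfpv, source_times=np.arange(len(maps)))
    z = _normalize_rows(sub.maps.copy())
    dmat = np.clip(1.0 - np.abs(z @ z.T), 0.0, None)
    np.fill_diagonal(dmat, 0.0)

    models = _fit_range(sub, k_range, n_restarts, seed)
    votes: dict[str, int] = {}
    for name, crit in criteria.items():
        scores, direction = crit(z, dmat, models)
        vals = np.array([scores[k] for k in k_range], dtype=float)
        if not np.any(np.isfinite(vals)):
            continue
        if direction == "min":
            vals = -vals
        votes[name] = int(k_range[int(np.nanargmax(vals))])
    if not votes:
        raise ValueError("all cluster-validity criteria degenerate")
    return votes


def optimal_k_metacriterion(
    tset: TopographySet,
    k_range: Sequence[int],
    n_restarts: int = 20,
    seed: int | np.random.Generator = 0,
    criteria: dict[str, Callable] | None = None,
    max_maps: int = 1000,
) -> int:
    """Median of the criterion votes; an even split resolves to the
    smaller candidate."""
    votes = criterion_votes(tset, k_range, n_restarts, seed, criteria, max_maps)
    v = np.sort(np.array(list(votes.values())))
    return int(v[(len(v) - 1) // 2])  # lower median
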
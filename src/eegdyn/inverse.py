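"""Empirical-Bayes source inversion with network covariance priors, and
per-network band energies.

The sensor covariance is modelled as a weighted sum of components,

    C = exp(l0) I + sum_i exp(l_i) L V_i L^T,

where L is the lead field and V_i the covariance prior of network i: the
Green function (matrix exponential) of the scaled mesh adjacency,
restricted to that network's vertices.  The log-weights are estimated by
restricted maximum likelihood (Fisher scoring on the free energy), and the
posterior mean of the source current density is the linear operator

    M = (sum_i exp(l_i) V_i) L^T C^{-1}.

Band energies follow the two-step recipe: invert once from the broadband
epoch-averaged covariance, then apply the operator to band-filtered
epochs, square, average over time, over each network's vertices, and over
epochs.  Energies are in arbitrary (relative) units.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy.linalg import expm

from .containers import EpochSet
from .forward import LeadField
from .mesh import CorticalMesh, NetworkAtlas

__all__ = [
    "CovariancePriorSet",
    "BandDefinition",
    "DEFAULT_BANDS",
    "RemlResult",
    "NetworkBandEnergyTable",
    "mesh_green_prior",
    "reml_estimate",
    "band_energies",
    "epoch_covariance",
]


#: Conventional resting-EEG band edges within a 0.5-45 Hz analysis band.
DEFAULT_BANDS: tuple[tuple[str, float, float], ...] = (
    ("delta", 0.5, 4.0),
    ("theta", 4.0, 8.0),
    ("alpha1", 8.0, 10.5),
    ("alpha2", 10.5, 13.0),
    ("beta1", 13.0, 20.0),
    ("beta2", 20.0, 30.0),
    ("gamma", 30.0, 45.0),
)


@dataclass(frozen=True)
class BandDefinition:
    """Ordered, non-overlapping frequency bands."""

    bands: tuple[tuple[str, float, float], ...] = DEFAULT_BANDS

    def __post_init__(self):
        prev = 0.0
        for name, low, high in self.bands:
            if not (prev <= low < high):
                raise ValueError(f"band {name} [{low},{high}] overlaps or is inverted")
            prev = high

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(b[0] for b in self.bands)

    def __len__(self) -> int:
        return len(self.bands)


@dataclass
class CovariancePriorSet:
    """Per-network source covariance priors, stored as dense blocks.

    ``blocks[i]`` is the PSD prior over the vertices ``indices[i]`` of
    network i+1; entries outside the network are implicitly zero.  ``q``
    holds the sensor-space projections L V_i L^T, each scaled so that
    trace(Q_i) equals the electrode count (putting hyperparameters on a
    common scale); ``scale[i]`` is that scaling, applied consistently to
    the source-space block when the posterior operator is assembled.
    """

    indices: list[np.ndarray]
    blocks: list[np.ndarray]
    q: list[np.ndarray]
    scale: np.ndarray
    n_vertices: int

    @property
    def n_networks(self) -> int:
        return len(self.blocks)

    def dense_prior(self, i: int) -> np.ndarray:
        """Full V x V prior of network i (0-based), including the scaling
        used for the sensor components."""
        v = np.zeros((self.n_vertices, self.n_vertices))
        v[np.ix_(self.indices[i], self.indices[i])] = self.scale[i] * self.blocks[i]
        return v

    def source_covariance(self, weights: np.ndarray) -> np.ndarray:
        """Weighted sum of the (scaled) priors as a dense V x V matrix."""
        r = np.zeros((self.n_vertices, self.n_vertices))
        for i, (idx, blk) in enumerate(zip(self.indices, self.blocks)):
            r[np.ix_(idx, idx)] += weights[i] * self.scale[i] * blk
        return r


def mesh_green_prior(
    mesh: CorticalMesh,
    atlas: NetworkAtlas,
    lead: LeadField,
    sigma: float = 0.6,
) -> CovariancePriorSet:
    """Network priors from the Green function of the mesh adjacency.

    G = expm(sigma * A_row-normalized) encodes smooth local coherence of
    sources along the mesh; each network prior takes G's rows and columns
    restricted to that network's vertices (zero elsewhere), symmetrized
    and eigenvalue-floored at zero so it is a valid covariance.
    """
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    a = mesh.adjacency.toarray().astype(float)
    deg = a.sum(axis=1)
    deg[deg == 0] = 1.0
    g = expm(sigma * (a / deg[:, None]))

    indices, blocks, qs, scales = [], [], [], []
    n_elec = lead.n_electrodes
    for net in range(1, atlas.n_networks + 1):
        idx = atlas.vertices_of(net)
        blk = g[np.ix_(idx, idx)]
        blk = 0.5 * (blk + blk.T)
        vals, vecs = np.linalg.eigh(blk)
        blk = (vecs * np.clip(vals, 0.0, None)) @ vecs.T
        lq = lead.gain[:, idx]
        q = lq @ blk @ lq.T
        tr = np.trace(q)
        if tr <= 0:
            raise ValueError(f"network {net} prior projects to zero at the sensors")
        scale = n_elec / tr
        indices.append(idx)
        blocks.append(blk)
        qs.append(scale * q)
        scales.append(scale)
    return CovariancePriorSet(
        indices=indices,
        blocks=blocks,
        q=qs,
        scale=np.array(scales),
        n_vertices=mesh.n_vertices,
    )


@dataclass
class RemlResult:
    """ReML hyperparameters and the posterior source operator."""

    lambdas: np.ndarray  # log-weights; [0] is sensor noise
    free_energy: np.ndarray  # per accepted iteration
    posterior_operator: np.ndarray | None  # (V, E)
    model_cov: np.ndarray  # (E, E)
    converged: bool
    flags: list[str] = field(default_factory=list)

    @property
    def network_weights(self) -> np.ndarray:
        return np.exp(self.lambdas[1:])


def epoch_covariance(ep: EpochSet) -> np.ndarray:
    """Average per-epoch second-moment sensor matrix over kept epochs."""
    kept = ep.kept()
    if kept.shape[0] == 0:
        raise ValueError("no kept epochs")
    n = kept.shape[2]
    return np.mean([e @ e.T / n for e in kept], axis=0)


def reml_estimate(
    sensor_cov: np.ndarray,
    lead: LeadField,
    priors: CovariancePriorSet,
    n_samples: int = 1000,
    max_iter: int = 128,
    tol: float = 1e-4,
    lambda_floor: float = -32.0,
    compute_operator: bool = True,
) -> RemlResult:
    """Fisher-scoring ReML over log component weights.

    ``n_samples`` is the effective number of samples behind ``sensor_cov``
    (it scales the curvature but not the optimum).  The free energy is
    guaranteed non-increasing-free by step halving; iteration stops when
    its relative change falls below ``tol``.
    """
    cy = np.asarray(sensor_cov, dtype=float)
    e = cy.shape[0]
    if cy.shape != (e, e) or lead.n_electrodes != e:
        raise ValueError("shape mismatch between covariance and lead field")
    cy = 0.5 * (cy + cy.T)
    comps = [np.eye(e)] + list(priors.q)
    m = len(comps)
    # start from equal small weights scaled to the data power
    power = max(np.trace(cy) / e, 1e-12)
    lam = np.full(m, np.log(power / m))
    flags: list[str] = []

    def free_energy(lam_v):
        c = sum(np.exp(l) * q for l, q in zip(lam_v, comps))
        sign, logdet = np.linalg.slogdet(c)
        if sign <= 0:
            return -np.inf, None
        try:
            cinv = np.linalg.inv(c)
        except np.linalg.LinAlgError:
            return -np.inf, None
        f = -0.5 * n_samples * (logdet + float(np.sum(cinv * cy)))
        return f, cinv

    f_cur, cinv = free_energy(lam)
    if not np.isfinite(f_cur):
        raise ValueError("initial covariance model is singular")
    path = [f_cur]
    converged = False
    for _ in range(max_iter):
        h = np.exp(lam)
        pq = [cinv @ (h[k] * comps[k]) for k in range(m)]
        a = cinv @ cy
        grad = np.array(
            [-0.5 * n_samples * (np.trace(pq[k]) - np.sum(pq[k] * a.T)) for k in range(m)]
        )
        fisher = np.empty((m, m))
        for j in range(m):
            for k in range(j, m):
                fisher[j, k] = fisher[k, j] = 0.5 * n_samples * np.sum(pq[j] * pq[k].T)
        step = np.linalg.solve(fisher + 1e-8 * np.eye(m) * np.trace(fisher) / m, grad)

        accepted = False
        for _ in range(12):
            lam_new = np.clip(lam + step, lambda_floor, 32.0)
            f_new, cinv_new = free_energy(lam_new)
            if f_new >= f_cur - 1e-8 * abs(f_cur):
                accepted = True
                break
            step = step / 2.0
        if not accepted:
            flags.append("no ascent step found")
            break
        rel = abs(f_new - f_cur) / max(abs(f_cur), 1.0)
        lam, f_cur, cinv = lam_new, f_new, cinv_new
        path.append(f_cur)
        if rel < tol:
            converged = True
            break
    if not converged and "no ascent step found" not in flags:
        flags.append("max_iter reached")

    c = sum(np.exp(l) * q for l, q in zip(lam, comps))
    operator = None
    if compute_operator:
        # source prior weights include the trace normalization of Q
        r = priors.source_covariance(np.exp(lam[1:]))
        operator = r @ lead.gain.T @ np.linalg.inv(c)
    return RemlResult(
        lambdas=lam,
        free_energy=np.array(path),
        posterior_operator=operator,
        model_cov=c,
        converged=converged,
        flags=flags,
    )


@dataclass
class NetworkBandEnergyTable:
    """Mean squared current density per vertex: networks x bands."""

    energy: np.ndarray  # (n_networks, n_bands)
    networks: tuple[str, ...]
    bands: tuple[str, ...]
    epochs_used: int

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.energy, index=list(self.networks), columns=list(self.bands))


def band_energies(
    ep: EpochSet,
    lead: LeadField,
    priors: CovariancePriorSet,
    atlas: NetworkAtlas,
    bands: BandDefinition = BandDefinition(),
    n_samples: int | None = None,
    operator: np.ndarray | None = None,
    reml_kwargs: dict | None = None,
) -> NetworkBandEnergyTable:
    """Per-network, per-band mean squared current density.

    One posterior operator is estimated from the broadband epoch-average
    covariance and applied to each band-filtered epoch (the operator is
    linear, so filtering and inversion commute).  A precomputed
    ``operator`` (e.g. shared across the conditions being contrasted)
    bypasses the ReML step.
    """
    kept = ep.kept()
    if kept.shape[0] == 0:
        raise ValueError("no kept epochs")
    nyq = ep.fs_hz / 2
    for name, low, high in bands.bands:
        if high >= nyq:
            raise ValueError(f"band {name} exceeds Nyquist ({nyq} Hz)")
    if operator is None:
        cov = epoch_covariance(ep)
        if n_samples is None:
            n_samples = int(kept.shape[0] * kept.shape[2])
        res = reml_estimate(cov, lead, priors, n_samples=n_samples, **(reml_kwargs or {}))
        m = res.posterior_operator
    else:
        m = operator

    net_idx = [atlas.vertices_of(i) for i in range(1, atlas.n_networks + 1)]
    energy = np.zeros((atlas.n_networks, len(bands)))
    for bi, (name, low, high) in enumerate(bands.bands):
        sos = sps.butter(4, (low, high), btype="bandpass", fs=ep.fs_hz, output="sos")
        filt = sps.sosfiltfilt(sos, kept, axis=2)
        acc = np.zeros(atlas.n_networks)
        for epoch in filt:
            j = m @ epoch  # (V, T)
            ms = np.mean(j**2, axis=1)
            for ni, idx in enumerate(net_idx):
                acc[ni] += ms[idx].mean()
        energy[:, bi] = acc / kept.shape[0]
    return NetworkBandEnergyTable(
        energy=energy,
        networks=atlas.names,
        bands=bands.names,
        epochs_used=int(kept.shape[0]),
    )
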
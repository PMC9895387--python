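"""Synthetic resting-EEG cohorts with planted ground truth.

Two signal families are generated, separately or summed into one recording:

* piecewise-stable scalp topographies with semi-Markov dwell structure --
  the data model the microstate pipeline assumes: at any time one of K
  zero-mean template maps is active, modulated by a smooth positive
  envelope (giving realistic GFP peaks) and a per-dwell random sign
  (polarity carries no information);
* band-limited oscillations confined to the vertices of one labelled
  cortical network, projected to the sensors through a lead field -- the
  ground truth for the network-rhythm source inversion.

A cohort wraps both per subject and per condition (pre/post), applies named
effect multipliers in the post condition, and keeps a ledger of every
planted value together with the analytically expected dwell/coverage/
transition statistics, so downstream recovery can be scored exactly.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy import signal as sps
from scipy.ndimage import gaussian_filter1d

from .containers import EEGRecording, Montage

__all__ = [
    "MicrostateGenSpec",
    "NetworkGenSpec",
    "CohortSpec",
    "Cohort",
    "DEFAULT_EFFECTS",
    "make_template_maps",
    "class_template_maps",
    "null_effects",
    "sensor_rms_per_unit_amp",
    "simulate_state_sequence",
    "render_eeg",
    "simulate_network_eeg",
    "simulate_cohort",
    "expected_state_statistics",
    "pair_fractions",
    "chain_from_pair_fractions",
]


# ---------------------------------------------------------------------------
# specs


def _uniform_offdiag(k: int) -> np.ndarray:
    p = np.full((k, k), 1.0 / max(k - 1, 1))
    np.fill_diagonal(p, 0.0)
    return p if k > 1 else np.zeros((1, 1))


@dataclass
class MicrostateGenSpec:
    """Parameters of the piecewise-stable topography generator.

    ``noise_sd`` defaults to ``gfp_scale / (sqrt(n_channels) * 5)``, i.e. a
    GFP signal-to-noise ratio of 5 on a 32-channel montage, the regime used
    throughout the recovery suites.
    """

    n_states: int = 4
    templates: np.ndarray | None = None  # (k, channels), zero-mean unit-norm rows
    mean_duration_ms: np.ndarray | float = 80.0
    transition_bias: np.ndarray | None = None  # embedded chain, zero diagonal
    gfp_scale: float = 10.0  # microvolts
    noise_sd: float | None = None  # microvolts per channel; None -> SNR 5
    fs_hz: float = 250.0
    length_s: float = 180.0
    dwell: str = "gamma"  # or "geometric"
    gamma_shape: float = 3.0
    sign_flip_prob: float = 0.5
    #: "rectified": positive smoothed-noise envelope with per-dwell random
    #: signs -- densest GFP peaks, best temporal resolution for recovery
    #: studies on broadband data.  "oscillatory": a narrowband (alpha-range)
    #: carrier whose content lies inside the 2-20 Hz analysis band, so the
    #: standard filtering chain passes the signal undistorted.
    envelope: str = "rectified"
    envelope_smooth_ms: float = 10.0
    envelope_floor: float = 0.25
    carrier_band_hz: tuple[float, float] = (8.0, 18.0)
    amp_mod_smooth_ms: float = 300.0
    boundary_dip: float = 0.5  # fractional GFP drop at state transitions
    boundary_dip_tau_ms: float = 8.0
    seed: int = 0

    def __post_init__(self):
        k = self.n_states
        if k < 1:
            raise ValueError("n_states must be >= 1")
        self.mean_duration_ms = np.broadcast_to(
            np.asarray(self.mean_duration_ms, dtype=float), (k,)
        ).copy()
        if np.any(self.mean_duration_ms <= 0):
            raise ValueError("mean durations must be positive")
        if self.transition_bias is None:
            self.transition_bias = _uniform_offdiag(k)
        self.transition_bias = np.asarray(self.transition_bias, dtype=float)
        if k > 1:
            if self.transition_bias.shape != (k, k):
                raise ValueError("transition_bias must be K x K")
            if np.any(np.abs(np.diag(self.transition_bias)) > 0):
                raise ValueError("transition_bias diagonal must be zero")
            rows = self.transition_bias.sum(axis=1)
            if np.any(self.transition_bias < 0) or not np.allclose(rows, 1.0, atol=1e-8):
                raise ValueError("transition_bias rows must be stochastic")
        if self.fs_hz * self.length_s < 1:
            raise ValueError("empty recording")
        if self.templates is not None:
            t = np.asarray(self.templates, dtype=float)
            if t.shape[0] != k:
                raise ValueError("templates rows != n_states")
            self.templates = _normalize_maps(t)

    def resolved_noise_sd(self, n_channels: int) -> float:
        if self.noise_sd is not None:
            return float(self.noise_sd)
        return self.gfp_scale / (np.sqrt(n_channels) * 5.0)


@dataclass
class NetworkGenSpec:
    """Parameters of the network-localized oscillation generator."""

    active_network: int = 1  # 1-based network id
    band_hz: tuple[float, float] = (20.0, 30.0)
    source_amp: float = 1.0  # per-vertex RMS dipole moment (arbitrary units)
    background_amp: float = 0.0  # broadband moment on all vertices
    noise_sd: float = 0.1  # sensor noise, microvolts
    fs_hz: float = 250.0
    length_s: float = 60.0
    seed: int = 0

    def __post_init__(self):
        low, high = self.band_hz
        if not (0 < low < high < self.fs_hz / 2):
            raise ValueError(f"band {self.band_hz} invalid for fs={self.fs_hz}")
        if self.source_amp < 0 or self.background_amp < 0 or self.noise_sd < 0:
            raise ValueError("amplitudes must be nonnegative")


#: Post-condition multipliers mirroring the pre/post findings the pipeline
#: is meant to detect: longer microstate-C dwells, reduced microstate-D
#: coverage, more A<->C and fewer B<->D switches, stronger high-beta
#: oscillation on the visual network.
DEFAULT_EFFECTS: dict[str, float] = {
    "state_C_duration": 1.5,
    "state_D_coverage": 0.8,
    "AC_transition": 1.5,
    "BD_transition": 0.7,
    "visual_beta2": 1.4,
}


def null_effects() -> dict[str, float]:
    return {k: 1.0 for k in DEFAULT_EFFECTS}


@dataclass
class CohortSpec:
    """A pre/post within-subject cohort with named planted effects."""

    n_subjects: int = 20
    effects: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_EFFECTS))
    base_micro: MicrostateGenSpec = field(
        default_factory=lambda: MicrostateGenSpec(envelope="oscillatory")
    )
    base_net: NetworkGenSpec | None = None
    include_network: bool = True
    subject_duration_jitter: float = 0.10  # lognormal sd on dwell means
    subject_amp_jitter: float = 0.15  # lognormal sd on source amplitude (trait)
    session_amp_jitter: float = 0.15  # lognormal sd per recording (state)
    session_duration_jitter: float = 0.08  # per-recording dwell-mean fluctuation
    session_transition_jitter: float = 0.15  # per-recording chain fluctuation
    seed: int = 0

    def __post_init__(self):
        if self.n_subjects < 2:
            raise ValueError("n_subjects must be >= 2")
        bad = {k: v for k, v in self.effects.items() if not v > 0}
        if bad:
            raise ValueError(f"effect multipliers must be positive: {bad}")
        unknown = set(self.effects) - set(DEFAULT_EFFECTS)
        if unknown:
            raise ValueError(f"unknown effects: {sorted(unknown)}")


# ---------------------------------------------------------------------------
# template maps


def _normalize_maps(maps: np.ndarray) -> np.ndarray:
    maps = maps - maps.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(maps, axis=1, keepdims=True)
    if np.any(norms == 0):
        raise ValueError("degenerate (constant) template map")
    return maps / norms


def _abs_corr_matrix(maps: np.ndarray) -> np.ndarray:
    z = _normalize_maps(maps)
    return np.abs(z @ z.T)


def make_template_maps(
    n_states: int,
    montage: Montage,
    seed: int | np.random.Generator = 0,
    max_abs_corr: float = 0.9,
    lengthscale: float = 0.8,
    max_attempts: int = 500,
) -> np.ndarray:
    """Draw ``n_states`` smooth, mutually dissimilar scalp maps.

    Maps are Gaussian random fields over the electrode positions (squared-
    exponential kernel in chord distance), mean-removed and unit-normed.
    Candidates too correlated (``|r| >= max_abs_corr``) with an accepted map
    are resampled; exhausting ``max_attempts`` signals an infeasible spec.
    """
    if n_states < 1:
        raise ValueError("n_states must be >= 1")
    if len(montage) < 2:
        raise ValueError("montage must have >= 2 electrodes")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    pos = montage.positions
    d2 = np.sum((pos[:, None, :] - pos[None, :, :]) ** 2, axis=-1)
    kern = np.exp(-d2 / (2.0 * lengthscale**2))
    chol = np.linalg.cholesky(kern + 1e-8 * np.eye(len(montage)))

    accepted: list[np.ndarray] = []
    attempts = 0
    while len(accepted) < n_states:
        if attempts >= max_attempts:
            raise RuntimeError(
                f"could not draw {n_states} maps with pairwise |r| < {max_abs_corr} "
                f"in {max_attempts} attempts"
            )
        attempts += 1
        cand = _normalize_maps((chol @ rng.standard_normal(len(montage)))[None, :])[0]
        if all(abs(float(cand @ m)) < max_abs_corr for m in accepted):
            accepted.append(cand)
    return np.array(accepted)


def class_template_maps(
    montage: Montage,
    rng: np.random.Generator | None = None,
    jitter: float = 0.3,
    orthogonalize: bool = True,
) -> np.ndarray:
    """Four class templates shaped like the conventional A-D topographies.

    Each canonical reference map gets an additive smooth random-field
    perturbation (relative weight ``jitter``), so different cohorts carry
    different maps that nevertheless classify unambiguously as A, B, C, D.
    By default the set is symmetrically (Loewdin) orthogonalized: mutually
    orthogonal generators keep boundary-mixture maps from resembling a
    third class, so segmentation errors stay local to the two states
    actually switching.
    """
    from .microstate import canonical_maps

    rng = np.random.default_rng(0) if rng is None else rng
    base = canonical_maps(montage)
    maps = _normalize_maps(base + jitter * make_template_maps(base.shape[0], montage, rng))
    if orthogonalize:
        u, _, vt = np.linalg.svd(maps, full_matrices=False)
        maps = _normalize_maps(u @ vt)
    return maps


# ---------------------------------------------------------------------------
# state sequence


def simulate_state_sequence(
    spec: MicrostateGenSpec, rng: np.random.Generator | None = None
) -> np.ndarray:
    """Semi-Markov per-sample state labels.

    Dwell lengths are geometric (default, mean ``fs * mean_duration_ms/1000``
    samples) or gamma-distributed; the successor state is drawn from the
    embedded chain ``transition_bias``.
    """
    rng = np.random.default_rng(spec.seed) if rng is None else rng
    n = int(round(spec.fs_hz * spec.length_s))
    k = spec.n_states
    if k == 1:
        return np.zeros(n, dtype=np.int64)
    mean_samples = spec.mean_duration_ms * spec.fs_hz / 1000.0
    labels = np.empty(n, dtype=np.int64)
    # start from the stationary state distribution of the embedded chain,
    # weighted by dwell length (time-stationary start)
    pi = _stationary(spec.transition_bias)
    w = pi * mean_samples
    state = int(rng.choice(k, p=w / w.sum()))
    t = 0
    while t < n:
        if spec.dwell == "geometric":
            dur = int(rng.geometric(min(1.0, 1.0 / mean_samples[state])))
        elif spec.dwell == "gamma":
            dur = max(1, int(round(rng.gamma(spec.gamma_shape, mean_samples[state] / spec.gamma_shape))))
        else:
            raise ValueError(f"unknown dwell law {spec.dwell!r}")
        labels[t : t + dur] = state
        t += dur
        state = int(rng.choice(k, p=spec.transition_bias[state]))
    return labels


def _stationary(p: np.ndarray) -> np.ndarray:
    """Stationary distribution of a stochastic matrix (left eigenvector)."""
    vals, vecs = np.linalg.eig(p.T)
    i = int(np.argmin(np.abs(vals - 1.0)))
    pi = np.real(vecs[:, i])
    pi = np.abs(pi)
    return pi / pi.sum()


def pair_fractions(p: np.ndarray) -> np.ndarray:
    """Long-run fraction of all switches going i -> j: ``pi_i * P_ij``."""
    pi = _stationary(p)
    return pi[:, None] * p


def chain_from_pair_fractions(t: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Embedded chain and its stationary vector from a pair-fraction matrix.

    ``t`` must have zero diagonal and (for consistency) equal row and
    column sums; symmetric matrices always qualify.
    """
    t = np.asarray(t, dtype=float)
    t = t / t.sum()
    pi = t.sum(axis=1)
    if not np.allclose(pi, t.sum(axis=0), atol=1e-8):
        raise ValueError("pair-fraction matrix is not stationary (row sums != col sums)")
    p = t / pi[:, None]
    return p, pi


def expected_state_statistics(
    mean_duration_ms: np.ndarray, transition: np.ndarray
) -> dict[str, np.ndarray]:
    """Analytic long-run duration/occurrence/coverage/pair-fraction values
    for a semi-Markov generator (independent of the dwell law, which only
    fixes the dwell mean)."""
    d = np.asarray(mean_duration_ms, dtype=float)
    pi = _stationary(transition)
    tot = float(pi @ d)  # mean dwell per run, ms
    coverage = pi * d / tot
    occurrence = pi * 1000.0 / tot  # runs of each state per second
    return {
        "duration_ms": d.copy(),
        "occurrence_per_s": occurrence,
        "coverage": coverage,
        "pair_fractions": pair_fractions(transition),
    }


# ---------------------------------------------------------------------------
# rendering


def _gfp_envelope(
    n: int, fs: float, rng: np.random.Generator,
    smooth_ms: float = 10.0, floor: float = 0.25,
) -> np.ndarray:
    """Rectified smoothed Gaussian noise, unit RMS: a strictly positive
    envelope whose local maxima play the role of GFP peaks.

    ``floor`` keeps the field signal-dominated between envelope bumps, so
    GFP peaks inside a dwell carry the dwell's topography rather than
    sensor noise.
    """
    env = gaussian_filter1d(rng.standard_normal(n), sigma=smooth_ms * fs / 1000.0)
    env = np.abs(env) + floor * np.sqrt(np.mean(env**2))
    return env / np.sqrt(np.mean(env**2))


def _oscillatory_scalar(
    n: int,
    fs: float,
    rng: np.random.Generator,
    band_hz: tuple[float, float] = (8.0, 18.0),
    mod_smooth_ms: float = 300.0,
    floor: float = 0.3,
) -> np.ndarray:
    """Zero-mean narrowband carrier with slow amplitude waxing/waning.

    Emulates the alpha-dominated scalar that rides a quasi-stable
    topography in resting EEG: GFP peaks fall on carrier extrema (two per
    cycle) and polarity alternates every half cycle, so nothing below the
    carrier band is lost to the analysis band-pass.
    """
    sos = sps.butter(4, band_hz, btype="bandpass", fs=fs, output="sos")
    c = sps.sosfiltfilt(sos, rng.standard_normal(n))
    c /= np.sqrt(np.mean(c**2))
    mod = np.abs(gaussian_filter1d(rng.standard_normal(n), sigma=mod_smooth_ms * fs / 1000.0))
    mod = mod / np.sqrt(np.mean(mod**2)) + floor
    s = c * mod
    return s / np.sqrt(np.mean(s**2))


def _boundary_dip(labels: np.ndarray, fs: float, depth: float, tau_ms: float) -> np.ndarray:
    """Multiplicative envelope factor dipping at dwell boundaries.

    Field strength wanes while one topography hands over to the next, so
    transitions happen through low-GFP troughs; ``depth`` in [0, 1) sets
    how far the envelope drops at the boundary itself.
    """
    n = len(labels)
    if depth <= 0:
        return np.ones(n)
    tau = max(tau_ms * fs / 1000.0, 1e-9)
    reach = int(np.ceil(5 * tau))
    dist = np.full(n, np.inf)
    for b in np.flatnonzero(np.diff(labels)) + 1:
        lo, hi = max(0, b - reach), min(n, b + reach)
        idx = np.arange(lo, hi)
        dist[idx] = np.minimum(dist[idx], np.abs(idx - b))
    return 1.0 - depth * np.exp(-(dist**2) / (2.0 * tau**2))


def render_eeg(
    labels: np.ndarray,
    spec: MicrostateGenSpec,
    montage: Montage,
    rng: np.random.Generator | None = None,
) -> EEGRecording:
    """Render a label sequence into sensor space.

    Sample t is ``gfp_scale * s(t) * sign(dwell) * template[label(t)]`` plus
    white sensor noise; ``s`` is the positive envelope (dipping at dwell
    boundaries) and the per-dwell random sign exercises polarity
    invariance downstream.
    """
    rng = np.random.default_rng(spec.seed) if rng is None else rng
    n = int(round(spec.fs_hz * spec.length_s))
    if len(labels) != n:
        raise ValueError(f"labels length {len(labels)} != fs*length={n}")
    templates = spec.templates
    if templates is None:
        templates = make_template_maps(spec.n_states, montage, rng)
    if templates.shape[1] != len(montage):
        raise ValueError("template channel count != montage size")

    if spec.envelope == "rectified":
        env = _gfp_envelope(n, spec.fs_hz, rng, spec.envelope_smooth_ms, spec.envelope_floor)
    elif spec.envelope == "oscillatory":
        env = _oscillatory_scalar(
            n, spec.fs_hz, rng, spec.carrier_band_hz, spec.amp_mod_smooth_ms
        )
    else:
        raise ValueError(f"unknown envelope mode {spec.envelope!r}")
    env = env * _boundary_dip(labels, spec.fs_hz, spec.boundary_dip, spec.boundary_dip_tau_ms)
    env = env / np.sqrt(np.mean(env**2))
    # one sign per dwell (for the oscillatory carrier the signs are a
    # no-op statistically, but keep the draw for stream compatibility)
    boundaries = np.flatnonzero(np.diff(labels)) + 1
    starts = np.concatenate([[0], boundaries])
    signs_per_run = np.where(rng.random(len(starts)) < spec.sign_flip_prob, -1.0, 1.0)
    signs = np.repeat(signs_per_run, np.diff(np.concatenate([starts, [n]])))

    scalar = spec.gfp_scale * env * signs
    data = templates[labels].T * scalar[None, :]
    noise_sd = spec.resolved_noise_sd(len(montage))
    if noise_sd > 0:
        data = data + noise_sd * rng.standard_normal(data.shape)
    return EEGRecording(
        data=data,
        fs_hz=spec.fs_hz,
        channel_names=montage.names,
        montage=montage,
        reference="recorded",
    )


def simulate_network_eeg(
    spec: NetworkGenSpec,
    leadfield,
    atlas,
    rng: np.random.Generator | None = None,
) -> tuple[EEGRecording, dict]:
    """Band-limited sources on one network's vertices, seen at the sensors.

    Each active vertex carries an independent unit-RMS time course filtered
    to ``band_hz`` and scaled by ``source_amp``; optional broadband
    background activity covers every vertex.  Returns the recording and a
    truth dict with the per-network mean squared current density.
    """
    from .forward import LeadField  # local import avoids cycle at module load

    rng = np.random.default_rng(spec.seed) if rng is None else rng
    gain = leadfield.gain if isinstance(leadfield, LeadField) else np.asarray(leadfield)
    n_elec, n_vert = gain.shape
    if len(atlas.labels) != n_vert:
        raise ValueError("lead field and atlas disagree on vertex count")
    active = np.flatnonzero(atlas.labels == spec.active_network)
    if active.size == 0:
        raise ValueError(f"network {spec.active_network} has no vertices")

    n = int(round(spec.fs_hz * spec.length_s))
    sos = sps.butter(4, spec.band_hz, btype="bandpass", fs=spec.fs_hz, output="sos")

    data = np.zeros((n_elec, n))
    energy = np.zeros(atlas.n_networks)

    if spec.source_amp > 0:
        src = sps.sosfiltfilt(sos, rng.standard_normal((active.size, n)), axis=1)
        src /= np.sqrt(np.mean(src**2, axis=1, keepdims=True))
        src *= spec.source_amp
        data += gain[:, active] @ src
        idx = spec.active_network - 1
        energy[idx] += np.mean(np.mean(src**2, axis=1))

    if spec.background_amp > 0:
        bg_sos = sps.butter(4, (1.0, min(45.0, 0.45 * spec.fs_hz)), btype="bandpass",
                            fs=spec.fs_hz, output="sos")
        bg = sps.sosfiltfilt(bg_sos, rng.standard_normal((n_vert, n)), axis=1)
        bg /= np.sqrt(np.mean(bg**2, axis=1, keepdims=True))
        bg *= spec.background_amp
        data += gain @ bg
        for net in range(1, atlas.n_networks + 1):
            sel = atlas.labels == net
            energy[net - 1] += np.mean(np.mean(bg[sel] ** 2, axis=1))

    if spec.noise_sd > 0:
        data = data + spec.noise_sd * rng.standard_normal(data.shape)

    montage = getattr(leadfield, "montage", None)
    if montage is None:
        raise ValueError("lead field must carry its montage")
    rec = EEGRecording(
        data=data,
        fs_hz=spec.fs_hz,
        channel_names=montage.names,
        montage=montage,
        reference="average",
    )
    truth = {
        "network_energy": energy,
        "active_network": spec.active_network,
        "band_hz": spec.band_hz,
        "source_amp": spec.source_amp,
    }
    return rec, truth


def sensor_rms_per_unit_amp(leadfield, atlas, network: int) -> float:
    """Sensor-level RMS produced by unit-RMS independent sources on one
    network (for calibrating ``source_amp`` to a target scalp amplitude)."""
    idx = np.flatnonzero(atlas.labels == network)
    g = leadfield.gain[:, idx]
    return float(np.sqrt(np.mean(np.sum(g**2, axis=1))))


# ---------------------------------------------------------------------------
# cohorts


@dataclass
class Cohort:
    """Synthetic pre/post cohort plus its ground-truth ledger.

    ``recordings[(subject, condition)]`` are the rendered EEGs; the ledger
    stores, per subject and condition, the planted dwell means, embedded
    transition chain, analytic expected microstate statistics, and network
    source amplitudes.
    """

    recordings: dict[tuple[int, str], EEGRecording]
    ledger: dict
    templates: np.ndarray
    montage: Montage
    leadfield: object | None = None
    atlas: object | None = None

    @property
    def n_subjects(self) -> int:
        return len({s for s, _ in self.recordings})

    @property
    def conditions(self) -> tuple[str, ...]:
        return tuple(sorted({c for _, c in self.recordings}))


def _apply_effects(
    base_dur: np.ndarray,
    base_chain: np.ndarray,
    effects: Mapping[str, float],
) -> tuple[np.ndarray, np.ndarray]:
    """Post-condition dwell means and embedded chain from the named
    multipliers.  States are indexed A=0, B=1, C=2, D=3."""
    eff = null_effects() | dict(effects)
    dur = base_dur.copy()
    dur[2] *= eff["state_C_duration"]

    t = pair_fractions(base_chain)
    t = 0.5 * (t + t.T)  # symmetrize so the edited matrix stays stationary
    t[0, 2] *= eff["AC_transition"]
    t[2, 0] *= eff["AC_transition"]
    t[1, 3] *= eff["BD_transition"]
    t[3, 1] *= eff["BD_transition"]
    chain, pi = chain_from_pair_fractions(t)

    # deflate/inflate state-D dwell so its long-run coverage equals the
    # multiplier times the *pre* coverage (coverage is emergent, so the
    # dwell mean is solved for exactly)
    m = eff["state_D_coverage"]
    if m != 1.0:
        pre = expected_state_statistics(base_dur, base_chain)["coverage"][3]
        target = m * pre
        if not 0 < target < 1:
            raise ValueError("state-D coverage target out of (0,1)")
        a = pi[3] * dur[3]
        s = float(pi @ dur)
        dur[3] *= target * (s - a) / (a * (1.0 - target))
    return dur, chain


def simulate_cohort(
    spec: CohortSpec,
    leadfield=None,
    atlas=None,
) -> Cohort:
    """Generate a full pre/post cohort.

    Microstate and (optionally) network signals are summed into a single
    recording per subject and condition; the microstate content lives below
    20 Hz while the planted network oscillation sits in its own band, so
    the two analyses see their respective ground truths.
    """
    if spec.include_network and (leadfield is None or atlas is None):
        raise ValueError("include_network=True requires a lead field and atlas")
    root = np.random.SeedSequence(spec.seed)
    mont_rng = np.random.default_rng(root.spawn(1)[0])
    base = spec.base_micro
    montage = Montage.standard_32()
    templates = base.templates
    if templates is None:
        if base.n_states == 4:
            templates = class_template_maps(montage, mont_rng)
        else:
            templates = make_template_maps(base.n_states, montage, mont_rng)

    post_dur, post_chain = _apply_effects(
        base.mean_duration_ms, base.transition_bias, spec.effects
    )
    amp_mult = (null_effects() | dict(spec.effects))["visual_beta2"]

    recordings: dict[tuple[int, str], EEGRecording] = {}
    ledger: dict = {"subjects": {}, "effects": dict(spec.effects), "seed": spec.seed}
    subject_seeds = root.spawn(spec.n_subjects)
    for s, ss in enumerate(subject_seeds):
        trait_rng = np.random.default_rng(ss.spawn(1)[0])
        dur_jit = np.exp(spec.subject_duration_jitter * trait_rng.standard_normal(base.n_states))
        amp_jit = float(np.exp(spec.subject_amp_jitter * trait_rng.standard_normal()))
        subj_ledger = {}
        for cond, cond_seed in zip(("pre", "post"), ss.spawn(2)):
            rng = np.random.default_rng(cond_seed)
            dur = (base.mean_duration_ms if cond == "pre" else post_dur) * dur_jit
            chain = base.transition_bias if cond == "pre" else post_chain
            # session-to-session fluctuation of the dynamics themselves:
            # recordings of the same subject never share identical dwell
            # means or switching structure
            if spec.session_duration_jitter > 0:
                dur = dur * np.exp(
                    spec.session_duration_jitter * rng.standard_normal(base.n_states)
                )
            if spec.session_transition_jitter > 0 and base.n_states > 1:
                pert = chain * np.exp(
                    spec.session_transition_jitter
                    * rng.standard_normal(chain.shape)
                )
                np.fill_diagonal(pert, 0.0)
                chain = pert / pert.sum(axis=1, keepdims=True)
            mspec = dataclasses.replace(
                base, templates=templates, mean_duration_ms=dur, transition_bias=chain
            )
            labels = simulate_state_sequence(mspec, rng)
            rec = render_eeg(labels, mspec, montage, rng)
            entry = {
                "mean_duration_ms": dur.tolist(),
                "transition": chain.tolist(),
                "expected": {
                    k: v.tolist()
                    for k, v in expected_state_statistics(dur, chain).items()
                },
            }
            if spec.include_network:
                nbase = spec.base_net or NetworkGenSpec(
                    fs_hz=base.fs_hz, length_s=base.length_s
                )
                # session-level amplitude fluctuation: independent across
                # recordings, so condition contrasts face realistic
                # between-session variance rather than epoch noise alone
                sess = float(np.exp(spec.session_amp_jitter * rng.standard_normal()))
                amp = nbase.source_amp * amp_jit * sess * (amp_mult if cond == "post" else 1.0)
                nspec = dataclasses.replace(
                    nbase,
                    source_amp=amp,
                    noise_sd=0.0,
                    fs_hz=base.fs_hz,
                    length_s=base.length_s,
                )
                net_rec, truth = simulate_network_eeg(nspec, leadfield, atlas, rng)
                rec = rec.with_data(rec.data + net_rec.data)
                entry["network"] = {
                    "source_amp": amp,
                    "network_energy": truth["network_energy"].tolist(),
                    "band_hz": list(nspec.band_hz),
                    "active_network": nspec.active_network,
                }
            recordings[(s, cond)] = rec
            subj_ledger[cond] = entry
        ledger["subjects"][s] = subj_ledger

    return Cohort(
        recordings=recordings,
        ledger=ledger,
        templates=templates,
        montage=montage,
        leadfield=leadfield,
        atlas=atlas,
    )
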
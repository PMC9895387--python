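"""Network priors, ReML hyperparameter estimation, band energies."""

import dataclasses

import numpy as np
import pytest
from scipy.linalg import expm

from eegdyn.containers import EpochSet
from eegdyn.inverse import (
    BandDefinition,
    band_energies,
    epoch_covariance,
    mesh_green_prior,
    reml_estimate,
)
from eegdyn.mesh import CorticalMesh, NetworkAtlas, make_icosphere_mesh, make_synthetic_atlas
from eegdyn.preproc import epoch_fixed_length
from eegdyn.synth import NetworkGenSpec, simulate_network_eeg


@pytest.fixture(scope="module")
def priors(small_mesh, atlas, leadfield):
    return mesh_green_prior(small_mesh, atlas, leadfield, sigma=0.6)


# --- priors


def test_sigma_zero_gives_identity_blocks(small_mesh, atlas, leadfield):
    ps = mesh_green_prior(small_mesh, atlas, leadfield, sigma=0.0)
    for idx, blk in zip(ps.indices, ps.blocks):
        assert np.allclose(blk, np.eye(len(idx)))


def test_green_function_against_dense_expm_oracle(montage, leadfield):
    """On a tiny mesh the network blocks must equal the rows/columns of the
    dense matrix exponential of the row-normalized adjacency."""
    import scipy.sparse as sp

    rng = np.random.default_rng(0)
    v = rng.standard_normal((20, 3))
    v = 0.5 * v / np.linalg.norm(v, axis=1, keepdims=True)
    a = (rng.random((20, 20)) < 0.25).astype(float)
    a = np.triu(a, 1)
    a = a + a.T
    mesh = CorticalMesh(vertices=v, normals=v / np.linalg.norm(v, axis=1, keepdims=True),
                        adjacency=sp.csr_matrix(a))
    labels = np.repeat(np.arange(1, 9), [3, 3, 3, 3, 2, 2, 2, 2])
    atlas = NetworkAtlas(labels=labels)
    from eegdyn.forward import LeadField

    lead = LeadField(gain=rng.standard_normal((8, 20)), montage=None)
    sigma = 0.7
    ps = mesh_green_prior(mesh, atlas, lead, sigma=sigma)
    deg = a.sum(axis=1)
    deg[deg == 0] = 1.0
    g = expm(sigma * a / deg[:, None])
    assert np.all(g >= -1e-12)  # nonneg entries of the Green function
    for net in range(8):
        idx = ps.indices[net]
        blk_ref = g[np.ix_(idx, idx)]
        blk_ref = 0.5 * (blk_ref + blk_ref.T)
        assert np.allclose(ps.blocks[net], blk_ref, atol=1e-8)
        # support: dense prior vanishes off the network's vertices
        dense = ps.dense_prior(net)
        mask = np.zeros(20, dtype=bool)
        mask[idx] = True
        assert np.allclose(dense[~mask][:, :], 0.0)
        assert np.allclose(dense[:, ~mask], 0.0)


def test_priors_are_psd(priors):
    for blk in priors.blocks:
        assert np.linalg.eigvalsh(blk).min() > -1e-10


# --- ReML


def test_single_identity_prior_matches_ridge_oracle(leadfield, small_mesh, atlas):
    """With one identity source prior the posterior operator must equal the
    closed-form regularized minimum-norm inverse."""
    ps = mesh_green_prior(small_mesh, atlas, leadfield, sigma=0.0)
    # collapse to a single whole-cortex identity prior
    single = dataclasses.replace(
        ps,
        indices=[np.arange(small_mesh.n_vertices)],
        blocks=[np.eye(small_mesh.n_vertices)],
        q=[leadfield.gain @ leadfield.gain.T
           * (leadfield.n_electrodes / np.trace(leadfield.gain @ leadfield.gain.T))],
        scale=np.array([leadfield.n_electrodes / np.trace(leadfield.gain @ leadfield.gain.T)]),
    )
    rng = np.random.default_rng(1)
    y = leadfield.gain @ rng.standard_normal((small_mesh.n_vertices, 4000)) * 0.3
    y += 0.5 * rng.standard_normal(y.shape)
    cov = y @ y.T / y.shape[1]
    res = reml_estimate(cov, leadfield, single, n_samples=y.shape[1])
    tau = np.exp(res.lambdas[1]) * single.scale[0]
    sig = np.exp(res.lambdas[0])
    l = leadfield.gain
    ridge = tau * l.T @ np.linalg.inv(tau * l @ l.T + sig * np.eye(l.shape[0]))
    assert np.linalg.norm(res.posterior_operator - ridge) / np.linalg.norm(ridge) < 1e-6


def test_evidence_nondecreasing_and_convergence(leadfield, atlas, priors):
    spec = NetworkGenSpec(active_network=4, source_amp=0.5, noise_sd=0.2, length_s=8, seed=2)
    rec, _ = simulate_network_eeg(spec, leadfield, atlas)
    cov = rec.data @ rec.data.T / rec.n_samples
    res = reml_estimate(cov, leadfield, priors, n_samples=rec.n_samples)
    f = res.free_energy
    assert np.all(np.diff(f) >= -1e-8 * np.maximum(np.abs(f[:-1]), 1.0))
    assert res.converged
    assert np.all(np.isfinite(res.lambdas))


def test_planted_network_hyperparameter_recovery(leadfield, atlas, priors):
    from eegdyn.synth import sensor_rms_per_unit_amp

    hits = 0
    for seed in range(8):
        net = seed % 8 + 1
        amp = 1.0 / sensor_rms_per_unit_amp(leadfield, atlas, net)
        spec = NetworkGenSpec(active_network=net, source_amp=amp, noise_sd=0.1,
                              length_s=8, seed=seed)
        rec, _ = simulate_network_eeg(spec, leadfield, atlas)
        cov = rec.data @ rec.data.T / rec.n_samples
        res = reml_estimate(cov, leadfield, priors, n_samples=rec.n_samples,
                            compute_operator=False)
        hits += int(np.argmax(res.lambdas[1:]) + 1 == net)
    assert hits >= 7


def test_zero_covariance_posterior_sources_vanish(leadfield, priors):
    cov = np.zeros((leadfield.n_electrodes, leadfield.n_electrodes))
    res = reml_estimate(cov + 1e-12 * np.eye(32), leadfield, priors, n_samples=100)
    y = np.zeros((leadfield.n_electrodes, 10))
    assert np.allclose(res.posterior_operator @ y, 0.0)
    # with no data power, all weights collapse toward the floor
    assert res.lambdas.max() < -20


# --- band energies


def _epochs_from(rec, length_s=2.0):
    return epoch_fixed_length(rec, length_s)


def test_zero_input_zero_energy(leadfield, atlas, priors):
    ep = EpochSet(epochs=np.zeros((3, 32, 500)), fs_hz=250.0, epoch_length_s=2.0)
    operator = np.zeros((leadfield.n_vertices, 32))
    tab = band_energies(ep, leadfield, priors, atlas, operator=operator)
    assert np.allclose(tab.energy, 0.0)


def test_planted_band_energy_tops_its_row(leadfield, atlas, priors):
    from eegdyn.synth import sensor_rms_per_unit_amp

    amp = 1.0 / sensor_rms_per_unit_amp(leadfield, atlas, 1)
    spec = NetworkGenSpec(active_network=1, band_hz=(20.0, 30.0), source_amp=amp,
                          noise_sd=0.1, length_s=20, seed=3)
    rec, _ = simulate_network_eeg(spec, leadfield, atlas)
    tab = band_energies(_epochs_from(rec), leadfield, priors, atlas)
    beta2 = tab.to_dataframe()["beta2"]
    assert beta2.idxmax() == "visual"
    assert tab.energy.min() >= 0.0


def test_energy_scales_quadratically_with_sensor_gain(leadfield, atlas, priors):
    """Scaling the sensor data by c scales every energy cell by c^2 (the
    ReML optimum shifts by 2 ln c, leaving the operator scale-free)."""
    from eegdyn.synth import sensor_rms_per_unit_amp

    amp = 1.0 / sensor_rms_per_unit_amp(leadfield, atlas, 5)
    spec = NetworkGenSpec(active_network=5, band_hz=(8.0, 12.0), source_amp=amp,
                          noise_sd=0.1, length_s=8, seed=4)
    rec, _ = simulate_network_eeg(spec, leadfield, atlas)
    ep = _epochs_from(rec)
    ep2 = EpochSet(epochs=3.0 * ep.epochs, fs_hz=ep.fs_hz, epoch_length_s=ep.epoch_length_s)
    t1 = band_energies(ep, leadfield, priors, atlas)
    t2 = band_energies(ep2, leadfield, priors, atlas)
    assert np.allclose(t2.energy, 9.0 * t1.energy, rtol=0.05)


def test_band_definition_validation():
    with pytest.raises(ValueError):
        BandDefinition((("a", 1.0, 5.0), ("b", 4.0, 8.0)))
    bands = BandDefinition()
    assert bands.names == ("delta", "theta", "alpha1", "alpha2", "beta1", "beta2", "gamma")


def test_epoch_covariance_rejects_empty():
    ep = EpochSet(epochs=np.zeros((2, 4, 100)), fs_hz=50.0, epoch_length_s=2.0,
                  kept_mask=np.array([False, False]))
    with pytest.raises(ValueError, match="no kept epochs"):
        epoch_covariance(ep)
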
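"""Ground-truth generator: templates, dwell structure, rendering, cohorts."""

import dataclasses

import numpy as np
import pytest

from eegdyn.synth import (
    DEFAULT_EFFECTS,
    CohortSpec,
    MicrostateGenSpec,
    NetworkGenSpec,
    chain_from_pair_fractions,
    expected_state_statistics,
    make_template_maps,
    class_template_maps,
    null_effects,
    pair_fractions,
    render_eeg,
    sensor_rms_per_unit_amp,
    simulate_cohort,
    simulate_network_eeg,
    simulate_state_sequence,
)
from eegdyn.synth import _apply_effects


# --- template maps


def test_single_template_normalized(montage):
    maps = make_template_maps(1, montage, seed=3)
    assert maps.shape == (1, 32)
    assert abs(maps[0].mean()) < 1e-12
    assert abs(np.linalg.norm(maps[0]) - 1.0) < 1e-12


def test_templates_pairwise_dissimilar(montage):
    maps = make_template_maps(4, montage, seed=0)
    corr = np.abs(maps @ maps.T)
    np.fill_diagonal(corr, 0.0)
    assert corr.max() < 0.9


def test_templates_deterministic(montage):
    a = make_template_maps(4, montage, seed=11)
    b = make_template_maps(4, montage, seed=11)
    assert np.array_equal(a, b)


def test_templates_infeasible_spec_fails(montage):
    with pytest.raises(RuntimeError, match="could not draw"):
        make_template_maps(6, montage, seed=0, max_abs_corr=1e-4, max_attempts=20)


def test_class_templates_named_and_orthogonal(montage):
    from eegdyn.microstate import canonical_maps

    maps = class_template_maps(montage, np.random.default_rng(2))
    gram = np.abs(maps @ maps.T)
    assert np.allclose(gram, np.eye(4), atol=1e-8)
    match = np.abs(maps @ canonical_maps(montage).T)
    assert (np.argmax(match, axis=1) == np.arange(4)).all()


# --- state sequences


def test_single_state_sequence_constant():
    spec = MicrostateGenSpec(n_states=1, fs_hz=100, length_s=2.0)
    labels = simulate_state_sequence(spec)
    assert np.array_equal(labels, np.zeros(200, dtype=np.int64))


@pytest.mark.parametrize("dwell", ["geometric", "gamma"])
def test_mean_dwell_converges(dwell):
    spec = MicrostateGenSpec(
        n_states=2, mean_duration_ms=100.0, fs_hz=250, length_s=600, dwell=dwell, seed=4
    )
    labels = simulate_state_sequence(spec)
    change = np.flatnonzero(np.diff(labels)) + 1
    lengths = np.diff(np.concatenate([[0], change, [len(labels)]]))
    mean_ms = lengths.mean() * 1000 / 250
    assert abs(mean_ms - 100.0) / 100.0 < 0.05


def test_forced_cycle_support():
    bias = np.array([[0, 1, 0], [0, 0, 1], [1, 0, 0]], dtype=float)
    spec = MicrostateGenSpec(
        n_states=3, transition_bias=bias, mean_duration_ms=40.0, fs_hz=250, length_s=60
    )
    labels = simulate_state_sequence(spec)
    runs = labels[np.concatenate([[0], np.flatnonzero(np.diff(labels)) + 1])]
    pairs = set(zip(runs[:-1], runs[1:]))
    assert pairs <= {(0, 1), (1, 2), (2, 0)}


def test_non_stochastic_bias_rejected():
    bad = np.array([[0.0, 0.5], [0.5, 0.0]])
    with pytest.raises(ValueError, match="stochastic"):
        MicrostateGenSpec(n_states=2, transition_bias=bad)


# --- rendering


@pytest.mark.parametrize("flip_prob", [0.0, 0.5])
def test_noiseless_samples_proportional_to_template(montage, flip_prob):
    """Without sensor noise every sample correlates perfectly (in absolute
    value) with the active template, sign flips included."""
    spec = MicrostateGenSpec(
        n_states=3, noise_sd=0.0, sign_flip_prob=flip_prob, fs_hz=250, length_s=4, seed=2
    )
    rng = np.random.default_rng(2)
    tpl = make_template_maps(3, montage, rng)
    spec = dataclasses.replace(spec, templates=tpl)
    labels = simulate_state_sequence(spec, rng)
    rec = render_eeg(labels, spec, montage, rng)
    z = rec.data / np.linalg.norm(rec.data, axis=0, keepdims=True)
    corr = np.abs(np.einsum("ct,tc->t", z, tpl[labels]))
    assert np.all(corr > 1 - 1e-9)
    # average-reference compatibility: zero-mean templates render zero-mean
    assert np.abs(rec.data.mean(axis=0)).max() < 1e-9


def test_render_deterministic(montage):
    spec = MicrostateGenSpec(fs_hz=250, length_s=2, seed=9)
    a = render_eeg(simulate_state_sequence(spec), spec, montage)
    b = render_eeg(simulate_state_sequence(spec), spec, montage)
    assert np.array_equal(a.data, b.data)


# --- network recordings


def test_zero_source_pure_noise(leadfield, atlas):
    spec = NetworkGenSpec(active_network=1, source_amp=0.0, noise_sd=1.0, length_s=4, seed=0)
    rec, truth = simulate_network_eeg(spec, leadfield, atlas)
    assert np.allclose(truth["network_energy"], 0.0)
    assert rec.data.std() > 0  # noise only


def test_noiseless_network_in_leadfield_column_space(leadfield, atlas):
    spec = NetworkGenSpec(active_network=1, source_amp=1.0, noise_sd=0.0, length_s=4, seed=1)
    rec, _ = simulate_network_eeg(spec, leadfield, atlas)
    cols = leadfield.gain[:, atlas.vertices_of(1)]
    proj, *_ = np.linalg.lstsq(cols, rec.data, rcond=None)
    resid = rec.data - cols @ proj
    assert np.linalg.norm(resid) < 1e-8 * np.linalg.norm(rec.data)


def test_energy_scales_quadratically(leadfield, atlas):
    s1 = NetworkGenSpec(active_network=2, source_amp=1.0, length_s=2, seed=3)
    s2 = dataclasses.replace(s1, source_amp=2.0)
    _, t1 = simulate_network_eeg(s1, leadfield, atlas)
    _, t2 = simulate_network_eeg(s2, leadfield, atlas)
    assert np.allclose(t2["network_energy"], 4.0 * t1["network_energy"])


def test_empty_network_rejected(leadfield, atlas):
    labels = np.where(atlas.labels == 3, 1, atlas.labels)  # empty network 3
    bad = dataclasses.replace(atlas)
    bad.labels = labels
    spec = NetworkGenSpec(active_network=3, length_s=2)
    with pytest.raises(ValueError):
        simulate_network_eeg(spec, leadfield, bad)


# --- effects arithmetic and cohorts


def test_null_effects_leave_parameters_unchanged():
    base = MicrostateGenSpec()
    dur, chain = _apply_effects(base.mean_duration_ms, base.transition_bias, null_effects())
    assert np.allclose(dur, base.mean_duration_ms)
    assert np.allclose(chain, base.transition_bias)


def test_planted_effect_arithmetic():
    base = MicrostateGenSpec()
    dur, chain = _apply_effects(base.mean_duration_ms, base.transition_bias, DEFAULT_EFFECTS)
    # C dwell multiplied exactly
    assert np.isclose(dur[2], 1.5 * base.mean_duration_ms[2])
    # D coverage lands exactly on 0.8x the pre coverage
    pre = expected_state_statistics(base.mean_duration_ms, base.transition_bias)
    post = expected_state_statistics(dur, chain)
    assert np.isclose(post["coverage"][3], 0.8 * pre["coverage"][3])
    # pair fractions move in the planted directions
    t_pre = pair_fractions(base.transition_bias)
    t_post = post["pair_fractions"]
    assert t_post[0, 2] > t_pre[0, 2] and t_post[2, 0] > t_pre[2, 0]
    assert t_post[1, 3] < t_pre[1, 3] and t_post[3, 1] < t_pre[3, 1]


def test_pair_fraction_round_trip():
    rng = np.random.default_rng(7)
    t = rng.random((4, 4))
    t = 0.5 * (t + t.T)
    np.fill_diagonal(t, 0.0)
    t /= t.sum()
    chain, pi = chain_from_pair_fractions(t)
    assert np.allclose(chain.sum(axis=1), 1.0)
    assert np.allclose(pair_fractions(chain), t, atol=1e-12)


def test_cohort_determinism_and_ledger(leadfield, atlas):
    spec = CohortSpec(
        n_subjects=2,
        base_micro=MicrostateGenSpec(envelope="oscillatory", length_s=4),
        base_net=NetworkGenSpec(
            source_amp=1.0 / sensor_rms_per_unit_amp(leadfield, atlas, 1), length_s=4
        ),
        seed=5,
    )
    a = simulate_cohort(spec, leadfield=leadfield, atlas=atlas)
    b = simulate_cohort(spec, leadfield=leadfield, atlas=atlas)
    assert sorted(a.recordings) == [(0, "post"), (0, "pre"), (1, "post"), (1, "pre")]
    for key in a.recordings:
        assert np.array_equal(a.recordings[key].data, b.recordings[key].data)
    # ledger carries planted values and the post beta-2 amplitude ratio
    for s in range(2):
        led = a.ledger["subjects"][s]
        ratio = led["post"]["network"]["source_amp"] / led["pre"]["network"]["source_amp"]
        # session jitter perturbs the ratio around the planted 1.4
        assert 0.7 < ratio / 1.4 < 1.4
        assert len(led["pre"]["expected"]["coverage"]) == 4


def test_cohort_validation():
    with pytest.raises(ValueError, match="n_subjects"):
        CohortSpec(n_subjects=1)
    with pytest.raises(ValueError, match="unknown effects"):
        CohortSpec(effects={"bogus": 2.0})
    with pytest.raises(ValueError, match="positive"):
        CohortSpec(effects={"state_C_duration": 0.0})
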
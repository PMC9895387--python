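"""Microstate operations: GFP, clustering, backfitting, parameters."""

import itertools

import numpy as np
import pytest
from scipy import stats as ss

from eegdyn.containers import EEGRecording, Montage
from eegdyn.microstate import (
    MicrostateModel,
    TopographySet,
    backfit,
    canonical_maps,
    compute_parameters,
    extract_gfp_peaks,
    gfp,
    gfp_series,
    group_maps_two_stage,
    kmeans_polarity_invariant,
    order_by_canonical,
    spatial_correlation_abs,
    transition_probabilities,
)
from eegdyn.preproc import rereference_average
from eegdyn.synth import MicrostateGenSpec, make_template_maps, render_eeg, simulate_state_sequence


# --- elementary operations


def test_gfp_closed_forms(rng):
    assert gfp(np.array([5.0, 5.0, 5.0])) == 0.0
    assert gfp(np.array([1.0, -1.0])) == 1.0
    x = rng.standard_normal(32)
    brute = np.sqrt(np.mean((x - x.mean()) ** 2))
    assert np.isclose(gfp(x), brute)
    with pytest.raises(ValueError):
        gfp(np.array([1.0]))


def test_spatial_correlation_polarity_and_oracle(rng):
    a = rng.standard_normal(32)
    assert np.isclose(spatial_correlation_abs(a, a), 1.0)
    assert np.isclose(spatial_correlation_abs(a, -a), 1.0)
    u = np.array([1.0, -1.0, 0.0, 0.0])
    v = np.array([0.0, 0.0, 1.0, -1.0])
    assert np.isclose(spatial_correlation_abs(u, v), 0.0)
    b = rng.standard_normal(32)
    assert np.isclose(spatial_correlation_abs(a, b), abs(ss.pearsonr(a, b).statistic))
    with pytest.raises(ValueError):
        spatial_correlation_abs(a, np.zeros(32))


def _recording_with_gfp(profile, montage):
    """Two-channel-pattern recording whose GFP equals ``profile``."""
    n = len(profile)
    data = np.zeros((len(montage), n))
    data[0] = profile
    data[1] = -np.asarray(profile)
    # gfp of (g, -g, 0...0) on 32 channels = g * sqrt(2/32)
    return EEGRecording(data, 100.0, montage.names, montage)


def test_gfp_peak_extraction_strict_maxima(montage):
    rec = _recording_with_gfp([1.0, 3.0, 2.0, 4.0, 1.0], montage)
    tset = extract_gfp_peaks(rec)
    assert list(tset.source_times) == [1, 3]

    mono = _recording_with_gfp([1.0, 2.0, 3.0, 4.0, 5.0], montage)
    assert extract_gfp_peaks(mono).n_maps == 0


# --- clustering


def test_kmeans_exact_two_template_mixture(montage, rng):
    tpl = make_template_maps(2, montage, rng)
    signs = rng.choice([-1.0, 1.0], size=60)
    maps = np.repeat(tpl, 30, axis=0) * signs[:, None]
    tset = TopographySet(maps=maps, gfp_at_peak=np.ones(60), source_times=np.arange(60))
    model = kmeans_polarity_invariant(tset, 2, n_restarts=5, seed=0)
    corr = np.abs(model.prototypes @ tpl.T)
    assert corr.max(axis=1).min() > 1 - 1e-9
    assert model.gev_total > 1 - 1e-9


def test_kmeans_k_equals_n_maps_explains_everything(montage, rng):
    maps = make_template_maps(5, montage, rng)
    tset = TopographySet(maps=maps, gfp_at_peak=np.ones(5), source_times=np.arange(5))
    model = kmeans_polarity_invariant(tset, 5, n_restarts=10, seed=1)
    assert model.gev_total > 1 - 1e-9


def _partition_gev(z, w2, parts):
    """GEV of an explicit 2-partition with eigenvector prototypes."""
    gev = 0.0
    for part in parts:
        members = z[list(part)]
        s = members.T @ members
        _, vecs = np.linalg.eigh(s)
        v = vecs[:, -1]
        v = v - v.mean()
        v /= np.linalg.norm(v)
        c = np.abs(members @ v)
        gev += np.sum(w2[list(part)] * c**2)
    return gev / np.sum(w2)


def test_kmeans_matches_exhaustive_partition_search(montage, rng):
    """For <= 8 maps and k = 2 the restarted k-means attains the optimum of
    brute-force enumeration over all bipartitions (within 1e-9)."""
    maps = make_template_maps(4, montage, rng)
    noisy = np.vstack([maps + 0.3 * rng.standard_normal(maps.shape) for _ in range(2)])
    noisy = noisy - noisy.mean(axis=1, keepdims=True)
    noisy /= np.linalg.norm(noisy, axis=1, keepdims=True)
    w2 = np.ones(len(noisy))
    best = 0.0
    idx = range(len(noisy))
    for r in range(1, len(noisy) // 2 + 1):
        for left in itertools.combinations(idx, r):
            right = tuple(i for i in idx if i not in left)
            best = max(best, _partition_gev(noisy, w2, [left, right]))
    tset = TopographySet(maps=noisy, gfp_at_peak=w2, source_times=np.arange(len(noisy)))
    model = kmeans_polarity_invariant(tset, 2, n_restarts=30, seed=0)
    assert model.gev_total <= best + 1e-9
    assert model.gev_total >= best - 1e-6  # restarts find the optimum here


# --- backfitting and parameters


def test_backfit_single_template(montage, rng):
    tpl = make_template_maps(1, montage, rng)
    spec = MicrostateGenSpec(n_states=1, templates=tpl, noise_sd=0.0,
                             sign_flip_prob=0.0, fs_hz=250, length_s=2)
    labels = simulate_state_sequence(spec, rng)
    rec = render_eeg(labels, spec, montage, rng)
    model = MicrostateModel(prototypes=tpl, gev_total=1.0)
    seg = backfit(rec, model)
    assert (seg.labels == 0).all()
    assert np.all(seg.corr_series > 1 - 1e-9)


def test_backfit_midpoint_rule(montage):
    """Peaks labelled A at t=10 and B at t=20: samples 10..14 -> A,
    15..20 -> B; leading/trailing samples inherit the nearest peak."""
    tpl = canonical_maps(montage)[:2]
    n = 25
    data = np.zeros((len(montage), n))  # flat GFP except at the two peaks
    data[:, 10] = 5.0 * tpl[0]
    data[:, 20] = 5.0 * tpl[1]
    rec = EEGRecording(data, 100.0, montage.names, montage)
    model = MicrostateModel(prototypes=tpl, gev_total=1.0)
    seg = backfit(rec, model)
    assert (seg.labels[:15] == 0).sum() >= 14  # t < 15 follows peak 10 (A)
    assert (seg.labels[10:15] == 0).all()
    assert (seg.labels[15:21] == 1).all()
    assert (seg.labels[21:] == 1).all()


def test_parameters_closed_form(montage):
    labels = np.array([0, 0, 1, 1])
    tpl = canonical_maps(montage)[:2]
    data = tpl[labels].T.copy()
    rec = EEGRecording(data, 2.0, montage.names, montage)
    model = MicrostateModel(prototypes=tpl, gev_total=1.0)
    from eegdyn.microstate import Segmentation

    seg = Segmentation(labels=labels, fs_hz=2.0, corr_series=np.ones(4))
    stats = compute_parameters(seg, rec, model)
    assert np.isclose(stats.duration_ms[0], 1000.0)
    assert np.isclose(stats.occurrence_per_s[0], 0.5)
    assert np.isclose(stats.coverage[0], 0.5)
    assert np.isclose(stats.gev.sum(), 1.0)
    assert np.isclose(stats.coverage.sum(), 1.0)


def test_parameters_missing_state(montage):
    labels = np.zeros(10, dtype=int)
    tpl = canonical_maps(montage)[:2]
    rec = EEGRecording(tpl[labels].T.copy(), 10.0, montage.names, montage)
    from eegdyn.microstate import Segmentation

    seg = Segmentation(labels=labels, fs_hz=10.0, corr_series=np.ones(10))
    stats = compute_parameters(seg, rec, MicrostateModel(prototypes=tpl, gev_total=1.0))
    assert np.isnan(stats.duration_ms[1])
    assert stats.occurrence_per_s[1] == 0.0 and stats.coverage[1] == 0.0


def test_transition_probabilities_closed_form():
    labels = np.array([0, 0, 1, 1, 1, 2])
    tm = transition_probabilities(labels, k=3)
    assert tm.counts[0, 1] == 1 and tm.counts[1, 2] == 1
    assert np.isclose(tm.probs.sum(), 1.0)
    assert np.isclose(tm.probs[0, 1], 0.5) and np.isclose(tm.probs[1, 2], 0.5)
    with pytest.raises(ValueError, match="single run"):
        transition_probabilities(np.zeros(5, dtype=int), k=2)


def test_polarity_invariance_end_to_end(montage, rng):
    """Flipping the sign of an arbitrary subset of samples changes neither
    the GFP peaks nor the segmentation."""
    spec = MicrostateGenSpec(fs_hz=250, length_s=8, seed=3)
    tpl = make_template_maps(4, montage, np.random.default_rng(3))
    spec.templates = tpl
    labels = simulate_state_sequence(spec, np.random.default_rng(3))
    rec = rereference_average(render_eeg(labels, spec, montage, np.random.default_rng(3)))
    flip = rng.random(rec.n_samples) < 0.5
    flipped = rec.with_data(rec.data * np.where(flip, -1.0, 1.0)[None, :])

    assert np.array_equal(
        extract_gfp_peaks(rec).source_times, extract_gfp_peaks(flipped).source_times
    )
    model = MicrostateModel(prototypes=tpl, gev_total=1.0)
    sa, sb = backfit(rec, model), backfit(flipped, model)
    assert np.array_equal(sa.labels, sb.labels)
    assert np.allclose(sa.corr_series, sb.corr_series)


# --- group maps and naming


def test_group_maps_degenerate_pooling(montage, rng):
    tpl = make_template_maps(4, montage, rng)
    model = MicrostateModel(prototypes=tpl, gev_total=0.9)
    group = group_maps_two_stage([model] * 5, 4, n_restarts=5, seed=0)
    corr = np.abs(group.prototypes @ tpl.T)
    assert corr.max(axis=1).min() > 1 - 1e-9


def test_group_maps_single_subject_passthrough(montage, rng):
    tpl = make_template_maps(3, montage, rng)
    model = MicrostateModel(prototypes=tpl, gev_total=0.8)
    group = group_maps_two_stage([model], 3, n_restarts=5, seed=0)
    corr = np.abs(group.prototypes @ tpl.T)
    assert corr.max(axis=1).min() > 1 - 1e-9


def test_group_maps_k_too_large(montage, rng):
    model = MicrostateModel(prototypes=make_template_maps(2, montage, rng), gev_total=0.5)
    with pytest.raises(ValueError, match="pooled"):
        group_maps_two_stage([model], 5)


def test_order_by_canonical_recovers_permutation(montage):
    cano = canonical_maps(montage)
    perm = [2, 0, 3, 1]
    model = MicrostateModel(prototypes=cano[perm], gev_total=1.0)
    ordered = order_by_canonical(model, cano)
    corr = np.abs(ordered.prototypes @ cano.T)
    assert (np.argmax(corr, axis=1) == np.arange(4)).all()
    assert ordered.labels_by_class == ("A", "B", "C", "D")


def test_gfp_series_matches_per_sample(rng):
    data = rng.standard_normal((32, 17))
    per_sample = [gfp(data[:, t]) for t in range(17)]
    assert np.allclose(gfp_series(data), per_sample)
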
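"""Plant four microstate templates in synthetic EEG and recover them.

Generates three minutes of 32-channel EEG whose topography switches among
four planted maps with ~70-85 ms dwells (GFP signal-to-noise 5), then runs
the full microstate chain: GFP peaks -> polarity-invariant k-means ->
backfitting -> temporal parameters, and compares against the generator's
ground truth.
"""

import numpy as np
from scipy.optimize import linear_sum_assignment

from eegdyn import (
    Montage,
    MicrostateGenSpec,
    backfit,
    compute_parameters,
    extract_gfp_peaks,
    kmeans_polarity_invariant,
    make_template_maps,
    render_eeg,
    rereference_average,
    simulate_state_sequence,
    transition_probabilities,
)
from eegdyn.microstate import MicrostateModel
from eegdyn.synth import expected_state_statistics

montage = Montage.standard_32()
rng = np.random.default_rng(1)
templates = make_template_maps(4, montage, rng)
spec = MicrostateGenSpec(
    templates=templates, mean_duration_ms=[70, 75, 85, 80], fs_hz=250, length_s=180, seed=1
)
labels = simulate_state_sequence(spec, rng)
rec = rereference_average(render_eeg(labels, spec, montage, rng))

peaks = extract_gfp_peaks(rec)
model = kmeans_polarity_invariant(peaks, k=4, n_restarts=20, seed=0)

# align recovered classes to the planted templates for reporting
corr = np.abs(model.prototypes @ templates.T)
rows, cols = linear_sum_assignment(-corr)
order = np.empty(4, dtype=int)
order[cols] = rows
model = MicrostateModel(prototypes=model.prototypes[order], gev_total=model.gev_total)

seg = backfit(rec, model)
stats = compute_parameters(seg, rec, model)
planted = expected_state_statistics(spec.mean_duration_ms, spec.transition_bias)
tm = transition_probabilities(seg, k=4)

print(f"{peaks.n_maps} GFP peaks, total GEV {model.gev_total:.3f}")
print(f"template |r| per class: {np.round(corr[rows, cols], 4)}")
print(f"label agreement with planted sequence: {np.mean(seg.labels == labels):.3f}")
print("state  duration(est/planted)  occurrence(est/planted)  coverage(est/planted)")
for j, name in enumerate("ABCD"):
    print(
        f"  {name}   {stats.duration_ms[j]:6.1f} / {planted['duration_ms'][j]:5.1f} ms   "
        f"{stats.occurrence_per_s[j]:5.2f} / {planted['occurrence_per_s'][j]:4.2f} per s   "
        f"{stats.coverage[j]:5.3f} / {planted['coverage'][j]:5.3f}"
    )
print(f"max |switch-fraction error|: {np.abs(tm.probs - planted['pair_fractions']).max():.4f}")
# |r| near 1 and parameters within ~10% of the planted values show the
# pipeline resolves both the maps and the dwell dynamics at this SNR.
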
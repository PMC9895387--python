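"""Source-localized band energy on eight large-scale networks.

Builds the three-shell spherical forward model on an icosphere source
space with a synthetic eight-network atlas, plants a high-beta (20-30 Hz)
oscillation on the visual network, and runs the empirical-Bayes inversion
with network covariance priors.  Prints the networks x bands energy table;
the planted cell should dominate its band column.
"""

import numpy as np

from eegdyn import (
    Montage,
    NetworkGenSpec,
    SphereHeadModel,
    band_energies,
    build_sphere_leadfield,
    make_icosphere_mesh,
    make_synthetic_atlas,
    mesh_green_prior,
)
from eegdyn.preproc import epoch_fixed_length
from eegdyn.synth import sensor_rms_per_unit_amp, simulate_network_eeg

montage = Montage.standard_32()
mesh = make_icosphere_mesh(subdivisions=2, radius=0.8)  # 162 vertices
atlas = make_synthetic_atlas(mesh)
lead = build_sphere_leadfield(SphereHeadModel(), montage, mesh)
priors = mesh_green_prior(mesh, atlas, lead, sigma=0.6)

amp = 1.0 / sensor_rms_per_unit_amp(lead, atlas, network=1)  # 1 uV at the scalp
spec = NetworkGenSpec(
    active_network=1, band_hz=(20.0, 30.0), source_amp=amp, noise_sd=0.1,
    fs_hz=250, length_s=60, seed=0,
)
rec, truth = simulate_network_eeg(spec, lead, atlas)
epochs = epoch_fixed_length(rec, 2.0)
table = band_energies(epochs, lead, priors, atlas, n_samples=rec.n_samples)

df = table.to_dataframe()
print(df.round(4).to_string())
beta2 = df["beta2"]
print(
    f"\nplanted: visual network, 20-30 Hz;   "
    f"largest beta2 energy: {beta2.idxmax()} "
    f"({beta2.max():.4f}, runner-up {beta2.drop(beta2.idxmax()).max():.4f})"
)
# Energies are relative (arbitrary units); what matters is the contrast:
# the planted network tops its band while other bands stay near the
# noise floor spread over all eight networks.
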
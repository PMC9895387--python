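import numpy as np
import pytest

from eegdyn.containers import EEGRecording, Montage
from eegdyn.forward import SphereHeadModel, build_sphere_leadfield
from eegdyn.mesh import make_icosphere_mesh, make_synthetic_atlas


@pytest.fixture(scope="session")
def montage():
    return Montage.standard_32()


@pytest.fixture(scope="session")
def small_mesh():
    return make_icosphere_mesh(subdivisions=2, radius=0.8)  # 162 vertices


@pytest.fixture(scope="session")
def atlas(small_mesh):
    return make_synthetic_atlas(small_mesh)


@pytest.fixture(scope="session")
def head_model():
    return SphereHeadModel()


@pytest.fixture(scope="session")
def leadfield(head_model, montage, small_mesh):
    return build_sphere_leadfield(head_model, montage, small_mesh)


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def make_recording(data, fs, montage):
    return EEGRecording(
        data=np.asarray(data, dtype=float),
        fs_hz=fs,
        channel_names=montage.names[: len(data)],
        montage=Montage(montage.names[: len(data)], montage.positions[: len(data)]),
    )


@pytest.fixture
def sine_recording(montage):
    def _make(freq_hz, fs=250.0, length_s=40.0, amp=1.0):
        t = np.arange(int(fs * length_s)) / fs
        data = np.tile(amp * np.sin(2 * np.pi * freq_hz * t), (len(montage), 1))
        return EEGRecording(data, fs, montage.names, montage)

    return _make
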
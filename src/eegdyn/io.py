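"""Readers and writers for recordings and result bundles.

Standard formats go through mne (EDF, BrainVision readers).  The portable
container for synthetic data is a small HDF5 layout (data, sampling rate,
montage, optional ledger JSON).  A minimal EDF writer is included for
interoperability: EDF is a fixed-layout 16-bit format and the writer
covers the plain continuous-signal case (equal rates, one data record per
second), which is all the synthetic recordings need.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np

from .containers import EEGRecording, Montage

__all__ = [
    "write_hdf5",
    "read_hdf5",
    "write_edf",
    "read_edf",
    "read_brainvision",
]


# ---------------------------------------------------------------------------
# HDF5 container


def write_hdf5(path, rec: EEGRecording, ledger: dict | None = None) -> None:
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=rec.data, compression="gzip")
        f.attrs["fs_hz"] = rec.fs_hz
        f.attrs["reference"] = rec.reference
        f.create_dataset("channel_names", data=np.array(rec.channel_names, dtype="S16"))
        f.create_dataset("montage_positions", data=rec.montage.positions)
        if ledger is not None:
            f.attrs["ledger_json"] = json.dumps(ledger)


def read_hdf5(path) -> tuple[EEGRecording, dict | None]:
    with h5py.File(path, "r") as f:
        names = tuple(n.decode() for n in f["channel_names"][()])
        rec = EEGRecording(
            data=f["data"][()],
            fs_hz=float(f.attrs["fs_hz"]),
            channel_names=names,
            montage=Montage(names, f["montage_positions"][()]),
            reference=str(f.attrs.get("reference", "recorded")),
        )
        ledger = json.loads(f.attrs["ledger_json"]) if "ledger_json" in f.attrs else None
    return rec, ledger


# ---------------------------------------------------------------------------
# EDF


def _edf_str(value: str, width: int) -> bytes:
    s = value[:width]
    return s.ljust(width).encode("ascii")


def write_edf(path, rec: EEGRecording) -> None:
    """Write a continuous EDF file (16-bit, 1-s data records).

    The sampling rate must be an integer; the trailing partial second is
    dropped.  Physical ranges are set per channel from the data.
    """
    fs = rec.fs_hz
    if abs(fs - round(fs)) > 1e-9:
        raise ValueError("EDF export requires an integer sampling rate")
    fs = int(round(fs))
    n_rec = rec.n_samples // fs
    if n_rec < 1:
        raise ValueError("recording shorter than one EDF data record (1 s)")
    data = rec.data[:, : n_rec * fs]
    nch = rec.n_channels

    pmin = data.min(axis=1)
    pmax = data.max(axis=1)
    span = pmax - pmin
    pmin = np.where(span > 0, pmin, pmin - 1.0)
    pmax = np.where(span > 0, pmax, pmax + 1.0)
    dmin, dmax = -32768, 32767
    gain = (dmax - dmin) / (pmax - pmin)
    digital = np.clip(
        np.round((data - pmin[:, None]) * gain[:, None]) + dmin, dmin, dmax
    ).astype("<i2")

    header = b"".join(
        [
            _edf_str("0", 8),
            _edf_str("X X X X", 80),
            _edf_str("synthetic", 80),
            _edf_str("01.01.00", 8),
            _edf_str("00.00.00", 8),
            _edf_str(str(256 * (nch + 1)), 8),
            _edf_str("", 44),
            _edf_str(str(n_rec), 8),
            _edf_str("1", 8),
            _edf_str(str(nch), 4),
        ]
    )
    fields = [
        (16, list(rec.channel_names)),
        (80, ["EEG"] * nch),
        (8, ["uV"] * nch),
        (8, [f"{v:.6g}"[:8] for v in pmin]),
        (8, [f"{v:.6g}"[:8] for v in pmax]),
        (8, [str(dmin)] * nch),
        (8, [str(dmax)] * nch),
        (80, [""] * nch),
        (8, [str(fs)] * nch),
        (32, [""] * nch),
    ]
    sig_header = b"".join(
        b"".join(_edf_str(v, width) for v in values) for width, values in fields
    )
    with open(path, "wb") as f:
        f.write(header + sig_header)
        for r in range(n_rec):
            f.write(digital[:, r * fs : (r + 1) * fs].tobytes())


def _recording_from_raw(raw, montage: Montage | None) -> EEGRecording:
    data = raw.get_data() * 1e6  # mne returns volts
    names = tuple(raw.ch_names)
    if montage is None:
        pos = np.array([raw.info["chs"][i]["loc"][:3] for i in range(len(names))])
        if not np.all(np.isfinite(pos)) or np.allclose(pos, 0):
            raise ValueError("file carries no electrode positions; pass a montage")
        montage = Montage(names, pos)
    return EEGRecording(
        data=data,
        fs_hz=float(raw.info["sfreq"]),
        channel_names=names,
        montage=montage,
        reference="recorded",
    )


def read_edf(path, montage: Montage | None = None) -> EEGRecording:
    import mne

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    return _recording_from_raw(raw, montage)


def read_brainvision(path, montage: Montage | None = None) -> EEGRecording:
    """Read a BrainVision triplet via its .vhdr header file."""
    import mne

    raw = mne.io.read_raw_brainvision(path, preload=True, verbose="error")
    return _recording_from_raw(raw, montage)
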
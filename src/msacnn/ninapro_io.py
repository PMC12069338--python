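"""Reader for Ninapro-style MATLAB recordings.

Ninapro releases store each acquisition as a .mat file with an ``emg``
matrix (samples x channels) and a per-sample gesture label vector, usually
``restimulus`` (movement-onset-refined labels) with ``stimulus`` as the
raw fallback. Files do not reliably carry the sampling rate, so ``fs`` must
be supplied by the caller (2000 Hz for the Delsys/Cometa acquisitions,
DB2/DB4 style; DB1's MyoBock rate must be known to the user).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .preprocess import SignalRecording


@dataclass
class NinaproLayout:
    emg_key: str = "emg"
    label_key: str = "restimulus"
    label_fallback: str = "stimulus"
    fs_override: float | None = None

    def __post_init__(self):
        if not self.emg_key or not self.label_key:
            raise ValueError("emg_key and label_key must be nonempty")


def _load_mat(path: str | Path) -> dict:
    from scipy.io import loadmat
    try:
        raw = loadmat(path)
        return {k: v for k, v in raw.items() if not k.startswith("__")}
    except NotImplementedError:
        # MATLAB v7.3 files are HDF5 containers
        import h5py
        out = {}
        with h5py.File(path, "r") as f:
            for k in f.keys():
                out[k] = np.array(f[k]).T  # HDF5 stores column-major
        return out


def read_ninapro_mat(path: str | Path,
                     layout: NinaproLayout | None = None) -> SignalRecording:
    """Map a Ninapro-style .mat file onto a SignalRecording.

    The emg matrix is transposed to channels x samples; labels come from
    ``label_key`` with ``label_fallback`` engaged when it is absent.
    """
    layout = layout or NinaproLayout()
    if layout.fs_override is None:
        raise ValueError(
            "fs_override is required: Ninapro files do not carry the sampling "
            "rate (use 2000.0 for DB2/DB4-style acquisitions)")
    data = _load_mat(path)
    if layout.emg_key not in data:
        raise KeyError(
            f"variable {layout.emg_key!r} not found; available: {sorted(data)}")
    label_key = layout.label_key
    if label_key not in data:
        if layout.label_fallback in data:
            label_key = layout.label_fallback
        else:
            raise KeyError(
                f"neither {layout.label_key!r} nor {layout.label_fallback!r} "
                f"found; available: {sorted(data)}")
    emg = np.asarray(data[layout.emg_key], dtype=float)
    labels = np.asarray(data[label_key]).ravel().astype(int)
    signal = emg.T  # samples x channels -> channels x samples
    if signal.shape[1] != labels.shape[0]:
        raise ValueError(
            f"emg has {signal.shape[1]} samples but {label_key!r} has "
            f"{labels.shape[0]}")
    return SignalRecording(
        signal=signal, fs=float(layout.fs_override), labels=labels,
        subject_id=Path(path).stem,
        source=f"{path} (emg={layout.emg_key!r}, labels={label_key!r})")
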
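"""Surrogate multi-channel sEMG generator with controllable separability.

Real surface EMG is well approximated, for classification purposes, by
band-limited zero-mean Gaussian noise whose per-channel amplitude envelope
reflects which muscles are active. The generator emulates exactly that
structure: each gesture class g is assigned a fixed nonnegative unit
activation vector v_g over the C channels (seeded), and during each 5-s
activity bout of class g the per-channel noise amplitude is raised from the
rest floor of 1 to ``1 + r * v_g[c]`` with ``r = 10**(snr_db / 20)``. Bouts
are separated by 3-s rest periods labelled 0, mirroring the repetition
protocol of standard sEMG acquisition sessions.

What this deliberately does NOT model: motor-unit action-potential shapes,
electrode shift, cross-talk, sweat artefacts, or any temporal waveform
structure beyond the band limit — classes are separable purely by their
channel amplitude patterns.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .preprocess import (
    SignalRecording, WindowSpec, WindowedDataset, segment_windows,
)


@dataclass
class SynthSpec:
    n_classes: int = 4
    channels: int = 10
    fs: float = 2000.0
    bout_s: float = 5.0
    rest_s: float = 3.0
    reps: int = 1
    snr_db: float = 20.0
    seed: int = 0
    band: tuple = (20.0, 450.0)

    def __post_init__(self):
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        if self.reps < 1:
            raise ValueError("reps must be >= 1")
        if not np.isfinite(self.snr_db):
            raise ValueError("snr_db must be finite")
        if self.band[1] >= self.fs / 2:
            raise ValueError(
                f"band edge {self.band[1]} Hz requires fs > {2 * self.band[1]} Hz "
                f"(got fs={self.fs}); lower the band or raise fs")


def class_activation_vectors(spec: SynthSpec) -> np.ndarray:
    """Fixed nonnegative unit activation vector per class, (G, C), seeded."""
    rng = np.random.default_rng(spec.seed + 1)
    v = np.abs(rng.standard_normal((spec.n_classes, spec.channels)))
    return v / np.linalg.norm(v, axis=1, keepdims=True)


def generate_recording(spec: SynthSpec) -> SignalRecording:
    """Band-limited Gaussian recording with class-patterned amplitude bouts.

    Each repetition cycles once through every class; every bout is preceded
    AND followed by a rest period (the session starts and ends at rest), so
    all bouts see identical rest neighbourhoods and the sliding windower
    yields exactly equal window counts per class. Total length is
    reps * n_classes * (bout_s + rest_s) * fs + rest_s * fs samples.
    """
    rng = np.random.default_rng(spec.seed)
    bout_n = int(round(spec.bout_s * spec.fs))
    rest_n = int(round(spec.rest_s * spec.fs))
    total = spec.reps * spec.n_classes * (bout_n + rest_n) + rest_n

    white = rng.standard_normal((spec.channels, total))
    sos = sps.butter(4, spec.band, btype="bandpass", fs=spec.fs, output="sos")
    noise = sps.sosfiltfilt(sos, white, axis=1)
    noise /= noise.std(axis=1, keepdims=True)  # unit rest floor per channel

    v = class_activation_vectors(spec)
    r = 10.0 ** (spec.snr_db / 20.0)
    labels = np.zeros(total, dtype=int)
    envelope = np.ones((spec.channels, total))
    pos = rest_n
    for _ in range(spec.reps):
        for g in range(1, spec.n_classes + 1):
            labels[pos:pos + bout_n] = g
            envelope[:, pos:pos + bout_n] = (1.0 + r * v[g - 1])[:, None]
            pos += bout_n + rest_n
    return SignalRecording(
        signal=noise * envelope, fs=spec.fs, labels=labels,
        subject_id="synthetic", source=f"synth(seed={spec.seed})")


def make_separable_windows(spec: SynthSpec, wspec: WindowSpec | None = None,
                           min_per_class: int = 10) -> WindowedDataset:
    """Generate a recording and window it with rest excluded.

    Raises if any class yields fewer than ``min_per_class`` windows, stating
    the recording duration that would be required.
    """
    wspec = wspec or WindowSpec(include_rest=False)
    if wspec.include_rest:
        raise ValueError("make_separable_windows requires include_rest=False")
    rec = generate_recording(spec)
    ds = segment_windows(rec, wspec)
    counts = np.bincount(ds.class_ids, minlength=spec.n_classes)
    if ds.n_classes < spec.n_classes or counts.min() < min_per_class:
        per_bout = max(counts.min() // max(spec.reps, 1), 1)
        need_reps = int(np.ceil(min_per_class / per_bout))
        need_s = need_reps * spec.n_classes * (spec.bout_s + spec.rest_s)
        raise ValueError(
            f"only {counts.min()} windows in the rarest class; need "
            f">= {min_per_class}. Increase reps to ~{need_reps} "
            f"(~{need_s:.0f} s of recording) or lengthen bout_s.")
    return ds
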
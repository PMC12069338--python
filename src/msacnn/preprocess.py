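"""Segmentation of labelled sEMG recordings into model-ready window datasets.

A continuous recording (channels x samples, with one gesture label per
sample, 0 = rest) is cut into fixed-duration sliding windows, each window is
assigned a single class, rest windows are optionally dropped, classes are
re-indexed densely, labels are one-hot encoded, and the window stack is
shuffled and split 70/15/15 into train/validation/test. Windows are finally
triplicated so that each of the model's three streams receives an identical
copy of the input.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

_LABEL_RULES = ("majority", "center", "last")


@dataclass
class SignalRecording:
    """Raw multi-channel recording with a per-sample label stream.

    signal : (channels, samples) float array, arbitrary units
    fs     : sampling rate in Hz
    labels : (samples,) nonnegative int array; 0 = rest, 1..G = gesture id
    """

    signal: np.ndarray
    fs: float
    labels: np.ndarray
    subject_id: str = "unknown"
    source: str = ""

    def __post_init__(self):
        self.signal = np.asarray(self.signal, dtype=float)
        self.labels = np.asarray(self.labels)
        if self.signal.ndim != 2 or self.signal.shape[0] < 1:
            raise ValueError("signal must be a (channels, samples) matrix")
        if self.signal.shape[1] != self.labels.shape[0]:
            raise ValueError(
                f"signal has {self.signal.shape[1]} samples but labels has "
                f"{self.labels.shape[0]}")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if np.any(self.labels < 0) or not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("labels must be nonnegative integers")

    @property
    def n_channels(self) -> int:
        return self.signal.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]


@dataclass
class WindowSpec:
    """Sliding-window geometry: 256 ms windows advanced by 100 ms by default."""

    window_ms: float = 256.0
    step_ms: float = 100.0
    label_rule: str = "majority"
    include_rest: bool = False

    def __post_init__(self):
        if not (self.window_ms >= self.step_ms > 0):
            raise ValueError("require window_ms >= step_ms > 0")
        if self.label_rule not in _LABEL_RULES:
            raise ValueError(f"label_rule must be one of {_LABEL_RULES}")

    def window_samples(self, fs: float) -> int:
        return int(round(fs * self.window_ms / 1000.0))

    def step_samples(self, fs: float) -> int:
        return int(round(fs * self.step_ms / 1000.0))


@dataclass
class WindowedDataset:
    """Stack of (T, C, 1) windows with one-hot labels.

    class_map maps dense class index (0..G-1) back to the original label id.
    """

    windows: np.ndarray
    onehot_labels: np.ndarray
    class_ids: np.ndarray
    fs: float
    spec: WindowSpec
    class_map: dict = field(default_factory=dict)

    @property
    def n(self) -> int:
        return self.windows.shape[0]

    @property
    def n_classes(self) -> int:
        return self.onehot_labels.shape[1]

    def subset(self, idx) -> "WindowedDataset":
        return WindowedDataset(
            windows=self.windows[idx],
            onehot_labels=self.onehot_labels[idx],
            class_ids=self.class_ids[idx],
            fs=self.fs, spec=self.spec, class_map=dict(self.class_map))


@dataclass
class SplitPlan:
    train_idx: np.ndarray
    val_idx: np.ndarray
    test_idx: np.ndarray
    fractions: tuple
    seed: int


def _window_label(labels: np.ndarray, rule: str) -> int:
    if rule == "majority":
        counts = np.bincount(labels)
        return int(counts.argmax())  # argmax ties break toward the lower id
    if rule == "center":
        return int(labels[len(labels) // 2])
    return int(labels[-1])


def segment_windows(rec: SignalRecording, spec: WindowSpec) -> WindowedDataset:
    """Cut a recording into sliding windows and resolve one class per window.

    Window i covers samples [i*S, i*S + T); there are floor((L - T)/S) + 1
    windows. When ``include_rest`` is false, windows resolving to class 0 are
    dropped and the remaining gesture ids are re-indexed densely to 0..G-1.
    """
    t = spec.window_samples(rec.fs)
    s = spec.step_samples(rec.fs)
    if t < 2:
        raise ValueError(
            f"window of {spec.window_ms} ms at fs={rec.fs} Hz gives only {t} "
            "samples; need at least 2")
    length = rec.n_samples
    if length < t:
        raise ValueError(
            f"input too short: {length} samples < one window of {t} samples")
    n = (length - t) // s + 1
    starts = np.arange(n) * s
    # (n, T, C): gather windows then add the trailing depth axis
    win = np.stack([rec.signal[:, a:a + t].T for a in starts])
    raw_labels = np.array(
        [_window_label(rec.labels[a:a + t], spec.label_rule) for a in starts])

    if not spec.include_rest:
        keep = raw_labels != 0
        win, raw_labels = win[keep], raw_labels[keep]
    present = np.unique(raw_labels)
    remap = {int(old): new for new, old in enumerate(present)}
    class_ids = np.array([remap[int(l)] for l in raw_labels], dtype=int)
    class_map = {new: int(old) for old, new in remap.items()}
    g = len(present)
    return WindowedDataset(
        windows=win[..., None],
        onehot_labels=one_hot(class_ids, g) if g else np.zeros((0, 0)),
        class_ids=class_ids,
        fs=rec.fs, spec=spec, class_map=class_map)


def one_hot(class_ids, G: int) -> np.ndarray:
    """Encode integer class ids as an (n, G) 0/1 matrix."""
    ids = np.asarray(class_ids, dtype=int)
    bad = (ids < 0) | (ids >= G)
    if bad.any():
        raise IndexError(
            f"class id {ids[bad][0]} out of range for G={G}")
    out = np.zeros((ids.shape[0], G))
    out[np.arange(ids.shape[0]), ids] = 1.0
    return out


def largest_remainder_sizes(n: int, fractions) -> list[int]:
    """Allocate n items to fractions by floor + largest fractional remainder."""
    exact = np.asarray(fractions, dtype=float) * n
    base = np.floor(exact).astype(int)
    rem = exact - base
    shortfall = n - base.sum()
    # ties broken by position: stable sort on descending remainder
    order = np.argsort(-rem, kind="stable")
    for i in order[:shortfall]:
        base[i] += 1
    return base.tolist()


def shuffle_and_split(ds: WindowedDataset, fractions=(0.70, 0.15, 0.15),
                      seed: int = 0) -> SplitPlan:
    """Seeded shuffle followed by a 3-way split with largest-remainder sizes."""
    fractions = tuple(float(f) for f in fractions)
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError(f"fractions must sum to 1, got {fractions}")
    n = ds.n
    if n < 3:
        raise ValueError(f"need n >= 3 windows to split, got {n}")
    sizes = largest_remainder_sizes(n, fractions)
    for frac, size in zip(fractions, sizes):
        if frac > 0 and size == 0:
            raise ValueError(
                f"n={n} too small to give fraction {frac} at least one element")
    perm = np.random.default_rng(seed).permutation(n)
    a, b = sizes[0], sizes[0] + sizes[1]
    return SplitPlan(
        train_idx=perm[:a], val_idx=perm[a:b], test_idx=perm[b:],
        fractions=fractions, seed=seed)


def triplicate_inputs(ds: WindowedDataset):
    """Three independent copies of the window stack, one per model stream."""
    return (ds.windows.copy(), ds.windows.copy(), ds.windows.copy())


def save_windowed(path, ds: WindowedDataset) -> None:
    """Persist a windowed dataset as a compressed .npz archive."""
    meta = {
        "fs": ds.fs,
        "window_ms": ds.spec.window_ms,
        "step_ms": ds.spec.step_ms,
        "label_rule": ds.spec.label_rule,
        "include_rest": ds.spec.include_rest,
        "class_map": {str(k): v for k, v in ds.class_map.items()},
    }
    np.savez_compressed(
        path, windows=ds.windows, labels=ds.onehot_labels,
        classes=ds.class_ids, meta=json.dumps(meta))


def load_windowed(path) -> WindowedDataset:
    with np.load(path, allow_pickle=False) as arc:
        meta = json.loads(str(arc["meta"]))
        spec = WindowSpec(
            window_ms=meta["window_ms"], step_ms=meta["step_ms"],
            label_rule=meta["label_rule"], include_rest=meta["include_rest"])
        return WindowedDataset(
            windows=arc["windows"], onehot_labels=arc["labels"],
            class_ids=arc["classes"], fs=meta["fs"], spec=spec,
            class_map={int(k): v for k, v in meta["class_map"].items()})
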
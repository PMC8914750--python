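"""Filtering, normalization and windowing of raw sensor streams.

The acquisition chain applies a causal moving-average filter (window 6)
to every channel; the three Hall channels are cut into non-overlapping
200 ms windows, stitched channel-by-channel into one 1-D vector per
window, and min-max normalized to [0, 1] per stitched row.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.model_selection import train_test_split

__all__ = [
    "HallWindow", "moving_average_filter", "minmax_normalize",
    "stitch_windows", "split_dataset", "windows_to_matrix",
    "windows_to_csv", "read_windows_csv",
]

_HALL_COLS = ["h1", "h2", "h3"]


@dataclass
class HallWindow:
    """One stitched Hall window: [h1 block | h2 block | h3 block]."""

    values: np.ndarray
    label: int | None
    t_start: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or len(self.values) % 3 != 0:
            raise ValueError("window vector length must be divisible by 3")

    def __len__(self) -> int:
        return len(self.values)


def moving_average_filter(series, w: int = 6):
    """Causal moving average: element i averages the last min(i+1, w) samples.

    The warm-up edge uses a growing window, so the output has the same
    length as the input and no future samples leak.  Works column-wise on
    2-D input.
    """
    if w < 1:
        raise ValueError("window length must be >= 1")
    x = np.asarray(series, dtype=float)
    if x.size == 0:
        raise ValueError("series must be non-empty")
    one_d = x.ndim == 1
    if one_d:
        x = x[:, None]
    c = np.cumsum(x, axis=0)
    out = np.empty_like(x)
    out[:w] = c[:w] / np.arange(1, min(w, len(x)) + 1)[:, None]
    if len(x) > w:
        out[w:] = (c[w:] - c[:-w]) / w
    return out[:, 0] if one_d else out


def minmax_normalize(row):
    """Min-max scale one row of data to [0, 1]: M = (m - m_min)/(m_max - m_min).

    A constant row (m_max = m_min) maps to all zeros.
    """
    x = np.asarray(row, dtype=float)
    if x.size == 0:
        raise ValueError("row must be non-empty")
    if not np.all(np.isfinite(x)):
        raise ValueError("row contains non-finite entries")
    lo, hi = x.min(), x.max()
    if hi == lo:
        return np.zeros_like(x)
    return (x - lo) / (hi - lo)


def _window_label(labels: np.ndarray) -> int | None:
    """Majority label of one window; exact ties -> None (window discarded)."""
    valid = labels[~pd.isna(labels)]
    if len(valid) == 0:
        return None
    counts = Counter(int(v) for v in valid)
    ranked = counts.most_common()
    if len(ranked) > 1 and ranked[0][1] == ranked[1][1]:
        return None
    return ranked[0][0]


def stitch_windows(stream: pd.DataFrame, window_s: float = 0.2,
                   sampling_rate: float | None = None,
                   normalize: bool = True,
                   scheme: str = "row") -> list[HallWindow]:
    """Cut a stream into non-overlapping Hall windows and stitch channels.

    Each window's vector is [h1 samples | h2 samples | h3 samples] in time
    order, min-max normalized (default per stitched row; ``scheme=
    "channel"`` normalizes each channel block separately).  The trailing
    partial window is discarded; a mixed-label window takes the majority
    label, exact ties are dropped.
    """
    if len(stream) == 0:
        raise ValueError("empty stream")
    t = np.asarray(stream["t"], dtype=float)
    if sampling_rate is None:
        if len(t) < 2:
            raise ValueError("cannot infer sampling rate from one sample")
        sampling_rate = 1.0 / float(np.median(np.diff(t)))
    w = int(round(window_s * sampling_rate))
    if len(stream) < w:
        raise ValueError("stream shorter than one window")

    hall = stream[_HALL_COLS].to_numpy(dtype=float)
    has_labels = "angle" in stream.columns
    labels = stream["angle"].to_numpy() if has_labels else None

    windows = []
    for k in range(len(stream) // w):
        lo = k * w
        block = hall[lo:lo + w]  # (w, 3)
        vec = block.T.reshape(-1)  # channel blocks concatenated in sensor order
        if normalize:
            if scheme == "row":
                vec = minmax_normalize(vec)
            elif scheme == "channel":
                vec = np.concatenate([minmax_normalize(vec[i * w:(i + 1) * w])
                                      for i in range(3)])
            else:
                raise ValueError(f"unknown normalization scheme {scheme!r}")
        label = _window_label(labels[lo:lo + w]) if has_labels else None
        if has_labels and label is None and not np.all(pd.isna(labels[lo:lo + w])):
            continue  # tied transition window discarded
        windows.append(HallWindow(values=vec, label=label, t_start=float(t[lo])))
    return windows


def split_dataset(windows: list[HallWindow], test_fraction: float = 0.2,
                  rng_seed: int = 0):
    """Stratified train/test partition (default 4:1) of labeled windows."""
    if len(windows) < 5:
        raise ValueError("need at least 5 windows to split 4:1")
    labels = [w.label for w in windows]
    if any(lbl is None for lbl in labels):
        raise ValueError("all windows must be labeled to split")
    counts = Counter(labels)
    rare = [lbl for lbl, c in counts.items() if c < 2]
    if rare:
        raise ValueError(f"cannot stratify: labels {rare} have < 2 windows")
    train, test = train_test_split(windows, test_size=test_fraction,
                                   stratify=labels, random_state=rng_seed)
    return train, test


def windows_to_matrix(windows: list[HallWindow]):
    """Stack windows into (X, y) arrays for the classifier."""
    X = np.vstack([w.values for w in windows])
    y = np.array([-1 if w.label is None else w.label for w in windows])
    return X, y


def windows_to_csv(windows: list[HallWindow], path) -> None:
    """One window per row: t_start, label, v_1..v_3W."""
    width = len(windows[0].values)
    cols = ["t_start", "label"] + [f"v{i + 1}" for i in range(width)]
    rows = [[w.t_start, "" if w.label is None else w.label, *w.values]
            for w in windows]
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False)


def read_windows_csv(path) -> list[HallWindow]:
    df = pd.read_csv(path)
    vcols = [c for c in df.columns if c.startswith("v")]
    out = []
    for _, row in df.iterrows():
        label = None if pd.isna(row["label"]) else int(row["label"])
        out.append(HallWindow(values=row[vcols].to_numpy(dtype=float),
                              label=label, t_start=float(row["t_start"])))
    return out
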
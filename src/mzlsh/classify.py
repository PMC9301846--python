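"""Collision-table construction and signal/noise classification.

A window is called *signal* when at least one of its band keys occurs more
than once over the whole processed unit (all windows by default, or one
frame at a time) — i.e. when some other window hashed into the same bucket
of the same band.  A peak is signal when any window containing it is signal;
with the two staggered grids a peak sits in up to two windows.

The intensity-threshold baseline (one global cutoff) is included for
comparison; unlike the LSH calls it is *not* invariant under rescaling of
the data.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from joblib import Parallel, delayed

from .lsh import HashFamily, Signature, bin_windows_matrix
from .peaks import Peak, Window, WindowGridConfig

__all__ = [
    "CollisionTable",
    "build_collision_table",
    "classify_windows",
    "classify_peaks",
    "snr_threshold_classifier",
    "compute_signatures",
    "classify_dataset",
]


@dataclass
class CollisionTable:
    """Per-band maps from band key to occurrence count."""

    band_counts: list[Counter] = field(default_factory=list)
    n_windows: int = 0

    def collided(self, band: int, key: int) -> bool:
        return self.band_counts[band].get(int(key), 0) >= 2

    @property
    def n_collided_keys(self) -> int:
        return sum(1 for c in self.band_counts for v in c.values() if v >= 2)


def _as_key_matrix(signatures) -> np.ndarray:
    if isinstance(signatures, np.ndarray):
        return np.atleast_2d(signatures)
    keys = np.stack([s.bands for s in signatures])
    ns = {s.n for s in signatures}
    if len(ns) > 1:
        raise ValueError("signatures stem from different (m, n) families")
    return keys


def build_collision_table(signatures) -> CollisionTable:
    """Count band-key occurrences over a set of signatures.

    Accepts a list of :class:`~mzlsh.lsh.Signature` or a ``(W, m)`` key
    matrix.  The collided set is all ``(band, key)`` with count >= 2.
    """
    if (isinstance(signatures, (list, tuple)) and len(signatures) == 0) or (
        isinstance(signatures, np.ndarray) and signatures.size == 0
    ):
        return CollisionTable([], 0)
    keys = _as_key_matrix(signatures)
    counts = [Counter(keys[:, j].tolist()) for j in range(keys.shape[1])]
    return CollisionTable(counts, n_windows=keys.shape[0])


def classify_windows(signatures, table: CollisionTable) -> np.ndarray:
    """Boolean signal call per window: any band key found in the collided set."""
    keys = _as_key_matrix(signatures)
    calls = np.zeros(keys.shape[0], dtype=bool)
    for j in range(keys.shape[1]):
        col = keys[:, j]
        cnt = table.band_counts[j]
        calls |= np.fromiter((cnt.get(int(k), 0) >= 2 for k in col),
                             dtype=bool, count=len(col))
    return calls


def classify_peaks(windows: Sequence[Window], window_calls: np.ndarray) -> dict[int, bool]:
    """Propagate window calls to peaks: signal iff any containing window is signal.

    Peaks are addressed by their ``pid``; every peak must carry one.
    """
    peak_calls: dict[int, bool] = {}
    for w, call in zip(windows, window_calls):
        for p in w.peaks:
            if p.pid is None:
                raise ValueError("peak without pid cannot be classified")
            peak_calls[p.pid] = peak_calls.get(p.pid, False) or bool(call)
    return peak_calls


def snr_threshold_classifier(peaks: Iterable[Peak], threshold: float) -> dict[int, bool]:
    """Baseline: a peak is signal iff its intensity >= ``threshold``.

    Assumes a single global noise estimate, reducing signal-to-noise
    filtering to one scalar intensity cutoff.
    """
    if threshold < 0:
        raise ValueError("threshold must be non-negative")
    calls = {}
    for p in peaks:
        if p.pid is None:
            raise ValueError("peak without pid cannot be classified")
        calls[p.pid] = bool(p.intensity >= threshold)
    return calls


# ---------------------------------------------------------------------------
# Pipeline conveniences
# ---------------------------------------------------------------------------

def compute_signatures(
    windows: Sequence[Window],
    family: HashFamily,
    config: WindowGridConfig | None = None,
    n_jobs: int = 1,
    chunk_size: int = 2048,
) -> np.ndarray:
    """Band-key matrix for a window list; optionally computed by a worker pool.

    Windows are processed in fixed chunks and the results concatenated in
    order, so parallel output is identical to serial output.
    """
    config = config or WindowGridConfig()
    chunks = [windows[i:i + chunk_size] for i in range(0, len(windows), chunk_size)]
    if not chunks:
        return np.empty((0, family.m), dtype=np.uint64)

    def one(chunk):
        return family.signature_matrix(bin_windows_matrix(chunk, config))

    if n_jobs == 1:
        parts = [one(c) for c in chunks]
    else:
        parts = Parallel(n_jobs=n_jobs)(delayed(one)(c) for c in chunks)
    return np.concatenate(parts, axis=0)


def classify_dataset(
    windows: Sequence[Window],
    family: HashFamily,
    config: WindowGridConfig | None = None,
    per_frame: bool = False,
    n_jobs: int = 1,
) -> tuple[np.ndarray, dict[int, bool]]:
    """Full LSH classification: signatures -> collision table -> calls.

    With ``per_frame=True`` the collision table is restricted to one frame at
    a time (frame-wise self-similarity); otherwise all windows share one
    table.
    """
    keys = compute_signatures(windows, family, config, n_jobs=n_jobs)
    window_calls = np.zeros(len(windows), dtype=bool)
    if per_frame:
        frames = np.array([w.frame for w in windows])
        for f in np.unique(frames):
            idx = np.nonzero(frames == f)[0]
            table = build_collision_table(keys[idx])
            window_calls[idx] = classify_windows(keys[idx], table)
    else:
        table = build_collision_table(keys)
        window_calls = classify_windows(keys, table)
    return window_calls, classify_peaks(windows, window_calls)
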
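"""ROC analysis, precursor matching and reduction-rate metrics.

ROC rates on synthetic data deliberately exclude peaks labelled ``noise_2``
(noise sharing a window with a pattern): window-level classification assigns
them the window's call by construction, and downstream feature finding — not
this prefilter — is responsible for removing them.  TPR and FPR are computed
over ``signal`` and ``noise_1`` peaks only.

Real-data style evaluation represents signal windows as 2-d points (window
centre m/z, scan) and counts a precursor as kept when its nearest such point
is closer than a Manhattan-distance radius; data reduction is reported as
one minus the kept fraction of windows (and of peaks).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .classify import build_collision_table, classify_peaks, classify_windows, \
    compute_signatures, snr_threshold_classifier
from .lsh import HashFamily
from .peaks import Peak, Window, WindowGridConfig, make_windows

__all__ = [
    "RocPoint",
    "PrecursorRecord",
    "roc_point",
    "roc_points",
    "snr_threshold_sweep",
    "match_precursors_2d",
    "match_precursors_3d",
    "reduction_rates",
    "frame_sweep",
]


@dataclass(frozen=True)
class RocPoint:
    fpr: float
    tpr: float
    setting: object = None


@dataclass
class PrecursorRecord:
    """One vendor-selected precursor: frame, mono m/z, mobility apex, charge."""

    frame: int
    mono_mz: float
    scan_apex: int
    charge: int | None = None


def roc_point(peak_calls: Mapping[int, bool], labels: Mapping[int, str],
              setting: object = None) -> RocPoint:
    """TPR/FPR of per-peak calls against ground-truth labels.

    ``noise_2`` peaks are excluded from both rates.
    """
    n_sig = n_sig_called = n_noise = n_noise_called = 0
    for pid, call in peak_calls.items():
        label = labels.get(pid)
        if label is None:
            raise ValueError(f"peak {pid} has no ground-truth label")
        if label == "signal":
            n_sig += 1
            n_sig_called += bool(call)
        elif label == "noise_1":
            n_noise += 1
            n_noise_called += bool(call)
    if n_sig == 0 or n_noise == 0:
        raise ValueError("labels must contain both signal and noise_1 peaks")
    return RocPoint(fpr=n_noise_called / n_noise, tpr=n_sig_called / n_sig,
                    setting=setting)


def roc_points(calls_by_setting: Mapping[object, Mapping[int, bool]],
               labels: Mapping[int, str]) -> list[RocPoint]:
    """One ROC point per classifier setting (one per (m, n), or per threshold)."""
    return [roc_point(calls, labels, setting)
            for setting, calls in calls_by_setting.items()]


def snr_threshold_sweep(peaks: Sequence[Peak], labels: Mapping[int, str],
                        n_thresholds: int = 101) -> list[RocPoint]:
    """ROC of the global intensity-threshold baseline over its full range.

    Thresholds sweep the quantiles of the observed intensities, plus the
    degenerate keep-everything (0) and keep-nothing (inf) cutoffs.
    """
    intensities = np.array([p.intensity for p in peaks])
    qs = np.unique(np.quantile(intensities, np.linspace(0.0, 1.0, n_thresholds)))
    thresholds = np.concatenate(([0.0], qs, [np.inf]))
    points = []
    for t in thresholds:
        calls = snr_threshold_classifier(peaks, float(min(t, np.finfo(float).max)))
        if np.isinf(t):
            calls = {pid: False for pid in calls}
        points.append(roc_point(calls, labels, setting=float(t)))
    return points


def match_precursors_2d(signal_points: np.ndarray,
                        precursors: Sequence[PrecursorRecord],
                        radius: float = 5.0,
                        mz_scale: float = 1.0,
                        scan_scale: float = 1.0) -> float:
    """Fraction of precursors whose nearest signal window is within ``radius``.

    ``signal_points`` is an ``(N, 2)`` array of (window-centre m/z, scan);
    distance is Manhattan, with optional per-axis unit scaling (default 1, 1:
    the literal unscaled mix of m/z and scan units).
    """
    if len(precursors) == 0:
        raise ValueError("precursor list is empty")
    pts = np.asarray(signal_points, dtype=float).reshape(-1, 2)
    if pts.shape[0] == 0:
        return 0.0
    matched = 0
    for prec in precursors:
        d = (mz_scale * np.abs(pts[:, 0] - prec.mono_mz)
             + scan_scale * np.abs(pts[:, 1] - prec.scan_apex))
        matched += bool(d.min() < radius)
    return matched / len(precursors)


def match_precursors_3d(matches: Sequence[tuple[float, int, int]],
                        precursors: Sequence[PrecursorRecord],
                        radius: float = 10.0,
                        mz_tol: float = 0.01) -> tuple[int, int, int]:
    """Nested tallies (k1, k2, k3) of precursors recovered by reference search.

    ``matches`` are found patterns as ``(mono_mz, scan, charge)`` triples.
    For each precursor the nearest neighbour in Manhattan distance over
    (m/z, scan, charge) is taken; ``k1`` counts precursors with that
    neighbour within ``radius``, ``k2`` the subset whose matched charge is
    exact, and ``k3`` the subset of ``k2`` whose monoisotopic m/z agrees
    within ``mz_tol``.
    """
    if len(precursors) == 0:
        raise ValueError("precursor list is empty")
    for prec in precursors:
        if prec.charge is None:
            raise ValueError("3d matching requires precursor charge states")
    k1 = k2 = k3 = 0
    if len(matches) == 0:
        return 0, 0, 0
    arr = np.array([[m[0], m[1], m[2]] for m in matches], dtype=float)
    for prec in precursors:
        d = (np.abs(arr[:, 0] - prec.mono_mz)
             + np.abs(arr[:, 1] - prec.scan_apex)
             + np.abs(arr[:, 2] - prec.charge))
        j = int(np.argmin(d))
        if d[j] < radius:
            k1 += 1
            if int(arr[j, 2]) == int(prec.charge):
                k2 += 1
                if abs(arr[j, 0] - prec.mono_mz) <= mz_tol:
                    k3 += 1
    return k1, k2, k3


def reduction_rates(window_calls: np.ndarray,
                    peak_calls: Mapping[int, bool]) -> tuple[float, float]:
    """Data reduction achieved by keeping only signal windows/peaks.

    ``window_rate = 1 - |signal windows| / |windows|`` and likewise for
    peaks, where every peak in a signal window counts as signal.
    """
    window_calls = np.asarray(window_calls, dtype=bool)
    if window_calls.size == 0 or len(peak_calls) == 0:
        raise ValueError("reduction rates undefined for an empty frame")
    window_rate = 1.0 - window_calls.sum() / window_calls.size
    kept_peaks = sum(bool(v) for v in peak_calls.values())
    peak_rate = 1.0 - kept_peaks / len(peak_calls)
    return float(window_rate), float(peak_rate)


def frame_sweep(peaks: Iterable[Peak],
                precursors: Sequence[PrecursorRecord],
                settings: Sequence[tuple[int, int]],
                n_frames: int = 50,
                skip_first: int = 1500,
                seed: int = 0,
                config: WindowGridConfig | None = None,
                radius: float = 5.0,
                hash_seed: int = 0) -> list[dict]:
    """Average kept-precursor fraction and reduction rates over sampled frames.

    Frames are sampled without replacement (seeded) after dropping the first
    ``skip_first``; each sampled frame is windowed, hashed and classified
    independently (frame-wise collision tables) for every ``(m, n)`` setting.
    Returns one metrics row per setting.
    """
    config = config or WindowGridConfig()
    by_frame: dict[int, list[Peak]] = {}
    for p in peaks:
        by_frame.setdefault(p.frame, []).append(p)
    frames = sorted(by_frame)
    eligible = [f for f in frames if f >= skip_first]
    if len(eligible) < n_frames:
        warnings.warn(
            f"only {len(eligible)} eligible frames (requested {n_frames}); using all",
            stacklevel=2)
        sampled = eligible
    else:
        rng = np.random.default_rng(seed)
        sampled = sorted(rng.choice(eligible, size=n_frames, replace=False).tolist())
    if not sampled:
        raise ValueError("no frames to evaluate")

    prec_by_frame: dict[int, list[PrecursorRecord]] = {}
    for prec in precursors:
        prec_by_frame.setdefault(prec.frame, []).append(prec)

    rows = []
    for m, n in settings:
        family = HashFamily(m=m, n=n, d=config.n_bins, seed=hash_seed)
        kept, wred, pred = [], [], []
        for f in sampled:
            windows = make_windows(by_frame[f], config)
            keys = compute_signatures(windows, family, config)
            table = build_collision_table(keys)
            window_calls = classify_windows(keys, table)
            peak_calls = classify_peaks(windows, window_calls)
            wr, pr = reduction_rates(window_calls, peak_calls)
            wred.append(wr)
            pred.append(pr)
            frame_precs = prec_by_frame.get(f, [])
            if frame_precs:
                pts = np.array([[w.start + w.length / 2.0, w.scan]
                                for w, c in zip(windows, window_calls) if c])
                kept.append(match_precursors_2d(pts.reshape(-1, 2), frame_precs,
                                                radius=radius))
        rows.append({
            "m": m, "n": n,
            "kept_fraction": float(np.mean(kept)) if kept else float("nan"),
            "window_reduction": float(np.mean(wred)),
            "peak_reduction": float(np.mean(pred)),
            "n_frames": len(sampled),
        })
    return rows
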
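"""Sign-random-projection LSH for cosine similarity, with AND/OR amplification.

A binned window is a fixed-length non-negative intensity vector ``I``.  Two
windows are compared by cosine similarity, which is invariant under positive
rescaling of either vector — the property that makes the classifier blind to
absolute intensities.  Each window is summarised by a *signature* of ``m``
band keys; every key packs ``n`` sign bits ``[<I, r> >= 0]`` for independent
standard-normal directions ``r``.  Two windows collide when at least one band
key coincides, which happens with probability

    P_{m,n}(s) = 1 - (1 - p^n)^m,    p = 1 - arccos(s) / pi,

a sigmoid in the cosine similarity ``s`` whose slope and midpoint are tuned
by the AND-depth ``n`` and OR-width ``m``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .peaks import Window, WindowGridConfig

__all__ = [
    "BinnedWindow",
    "HashFamily",
    "Signature",
    "bin_window",
    "bin_windows_matrix",
    "cosine_similarity",
    "collision_probability",
    "collide",
]


@dataclass
class BinnedWindow:
    """Fixed-resolution intensity vector of one window."""

    intensities: np.ndarray
    source: Window | None = None

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensities.ndim != 1:
            raise ValueError("binned window must be a 1-d vector")
        if not np.any(self.intensities > 0):
            raise ValueError("binned window must have at least one positive bin")


def bin_window(window: Window, config: WindowGridConfig | None = None) -> BinnedWindow:
    """Accumulate a window's peak intensities on the equally spaced bin grid.

    The bin of a peak is ``floor((mz - start) / bin_resolution)``; peaks
    sharing a bin are summed.
    """
    config = config or WindowGridConfig()
    d = config.n_bins
    vec = np.zeros(d)
    res = config.bin_resolution
    for p in window.peaks:
        idx = int(np.floor((p.mz - window.start) / res))
        if idx < 0 or idx >= d:
            raise ValueError(
                f"peak at m/z {p.mz} outside window [{window.start}, {window.end})"
            )
        vec[idx] += p.intensity
    return BinnedWindow(vec, source=window)


def bin_windows_matrix(windows, config: WindowGridConfig | None = None) -> np.ndarray:
    """Stack the binned vectors of many windows into a ``(W, d)`` matrix."""
    config = config or WindowGridConfig()
    X = np.zeros((len(windows), config.n_bins))
    res = config.bin_resolution
    d = config.n_bins
    for i, w in enumerate(windows):
        for p in w.peaks:
            idx = int(np.floor((p.mz - w.start) / res))
            if idx < 0 or idx >= d:
                raise ValueError(
                    f"peak at m/z {p.mz} outside window [{w.start}, {w.end})"
                )
            X[i, idx] += p.intensity
    return X


def cosine_similarity(a, b) -> float:
    """Cosine similarity of two intensity vectors; in [0, 1] for non-negative input."""
    va = a.intensities if isinstance(a, BinnedWindow) else np.asarray(a, dtype=float)
    vb = b.intensities if isinstance(b, BinnedWindow) else np.asarray(b, dtype=float)
    if va.shape != vb.shape:
        raise ValueError(f"dimension mismatch: {va.shape} vs {vb.shape}")
    na = np.linalg.norm(va)
    nb = np.linalg.norm(vb)
    if na == 0 or nb == 0:
        raise ValueError("cosine similarity undefined for zero-norm input")
    return float(np.dot(va, vb) / (na * nb))


@dataclass(frozen=True)
class Signature:
    """``m`` band keys of ``n`` packed sign bits each."""

    bands: np.ndarray  # shape (m,), uint64
    n: int

    @property
    def m(self) -> int:
        return int(self.bands.shape[0])


def collide(a: Signature, b: Signature) -> bool:
    """True iff at least one band key coincides (same band index)."""
    if a.m != b.m or a.n != b.n:
        raise ValueError("signatures stem from different (m, n) families")
    return bool(np.any(a.bands == b.bands))


class HashFamily:
    """A reproducible family of ``m * n`` sign-random-projection hashes.

    Direction vectors are drawn band-major from a single seeded generator, so
    families with the same ``(d, seed)`` share the first ``min(m1*n1, m2*n2)``
    directions — convenient for sweeps over ``(m, n)``.

    Parameters
    ----------
    m : int
        Number of OR bands.
    n : int
        Number of AND hashes per band (sign bits per key); at most 64.
    d : int
        Dimension of the binned windows to be hashed.
    seed : int
        Seed of the direction-vector generator.
    """

    def __init__(self, m: int, n: int, d: int, seed: int = 0):
        if m < 1 or n < 1:
            raise ValueError("m and n must be >= 1")
        if n > 64:
            raise ValueError("band keys are packed into 64-bit integers; n <= 64")
        self.m = int(m)
        self.n = int(n)
        self.d = int(d)
        self.seed = int(seed)
        rng = np.random.default_rng(seed)
        # band-major: row j*n + k is AND-hash k of band j
        self.directions = rng.standard_normal((self.m * self.n, self.d))
        self._weights = (np.uint64(1) << np.arange(self.n, dtype=np.uint64))

    def __repr__(self) -> str:  # pragma: no cover
        return f"HashFamily(m={self.m}, n={self.n}, d={self.d}, seed={self.seed})"

    def signature_matrix(self, X: np.ndarray) -> np.ndarray:
        """Band keys for many vectors at once; returns ``(W, m)`` uint64.

        Bit ``k`` of band ``j`` is ``[<I, r_{j,k}> >= 0]`` (sign(0) := +1),
        packed little-endian into the band key.
        """
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.d:
            raise ValueError(f"expected dimension {self.d}, got {X.shape[1]}")
        bits = (X @ self.directions.T) >= 0.0  # (W, m*n)
        bits = bits.reshape(X.shape[0], self.m, self.n)
        return (bits.astype(np.uint64) * self._weights[None, None, :]).sum(axis=2)

    def signature(self, x) -> Signature:
        """Signature of a single binned window."""
        vec = x.intensities if isinstance(x, BinnedWindow) else np.asarray(x, dtype=float)
        keys = self.signature_matrix(vec[None, :])[0]
        return Signature(bands=keys, n=self.n)


def collision_probability(s, m: int, n: int):
    """Probability that two vectors with cosine ``s`` collide under (m, n).

    Closed form of the AND/OR-amplified sign-random-projection scheme:
    ``1 - (1 - p**n)**m`` with single-bit agreement ``p = 1 - arccos(s)/pi``.
    Accepts scalars or arrays of ``s`` in [-1, 1].
    """
    if m < 1 or n < 1:
        raise ValueError("m and n must be >= 1")
    s_arr = np.asarray(s, dtype=float)
    if np.any(s_arr < -1 - 1e-12) or np.any(s_arr > 1 + 1e-12):
        raise ValueError("similarity must lie in [-1, 1]")
    p = 1.0 - np.arccos(np.clip(s_arr, -1.0, 1.0)) / np.pi
    out = 1.0 - (1.0 - p ** n) ** m
    return float(out) if np.isscalar(s) else out
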
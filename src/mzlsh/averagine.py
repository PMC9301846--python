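"""Averagine isotope-pattern synthesis and LSH-indexed reference search.

Peptide isotope envelopes are predicted from mass alone with the *averagine*
model: a fictitious average residue of composition
C 4.9384, H 7.7583, N 1.3577, O 1.4773, S 0.0417 and mass 111.1254 Da.  A
neutral mass is converted to a (fractional) elemental composition, the
aggregated isotopologue distribution is obtained by convolving the natural
per-element isotope distributions, and the charged pattern places peak ``k``
at ``(M + z*m_p + k*delta)/z`` with ``delta = 1.003355`` Da (the 13C-12C
spacing that dominates peptide isotopologues).

A reference database renders such patterns for a mass/charge grid on a fine
(1e-5 Da) grid re-binned to 1e-2 Da over [-1, +9] Da around the monoisotopic
peak, hashes them with a shared sign-random-projection family, and answers
queries by explicit cosine scoring of the hash-collision candidate set —
returning monoisotopic m/z and charge of the best match above a similarity
threshold (deisotoping).
"""

from __future__ import annotations

from dataclasses import dataclass
from math import floor
from typing import Sequence

import numpy as np

from .lsh import HashFamily
from .peaks import Window

__all__ = [
    "PROTON_MASS",
    "DELTA_ISO",
    "AVERAGINE_RESIDUE",
    "AVERAGINE_RESIDUE_MASS",
    "ElementalComposition",
    "ReferencePattern",
    "ReferenceMatch",
    "ReferenceDB",
    "averagine_composition",
    "isotope_distribution",
    "theoretical_pattern",
    "build_reference_db",
    "reference_search",
    "render_pattern_vector",
    "bin_window_reference",
    "isotope_shift",
]

PROTON_MASS = 1.007276
DELTA_ISO = 1.003355  # Da between adjacent isotopologues (13C - 12C)

#: Senko averagine residue: element counts and residue mass.
AVERAGINE_RESIDUE = {"C": 4.9384, "H": 7.7583, "N": 1.3577, "O": 1.4773, "S": 0.0417}
AVERAGINE_RESIDUE_MASS = 111.1254

#: Natural isotope abundances, aggregated by nucleon-count shift.
ISOTOPE_ABUNDANCES: dict[str, list[tuple[int, float]]] = {
    "C": [(0, 0.9893), (1, 0.0107)],
    "H": [(0, 0.999885), (1, 0.000115)],
    "N": [(0, 0.99636), (1, 0.00364)],
    "O": [(0, 0.99757), (1, 0.00038), (2, 0.00205)],
    "S": [(0, 0.9499), (1, 0.0075), (2, 0.0425), (4, 0.0001)],
}

#: Reference-grid geometry: [-1, +9] Da around the monoisotopic peak,
#: sampled at 1e-5 Da and binned to 1e-2 Da -> 1000 coarse bins,
#: monoisotopic peak in coarse bin 100.
FINE_STEP = 1e-5
COARSE_STEP = 1e-2
REF_SPAN_LOW = -1.0
REF_SPAN_HIGH = 9.0
REF_N_BINS = int(round((REF_SPAN_HIGH - REF_SPAN_LOW) / COARSE_STEP))
MONO_BIN = int(round(-REF_SPAN_LOW / COARSE_STEP))
CANONICAL_ANCHOR = 500  # canonical position of the base peak after alignment


@dataclass
class ElementalComposition:
    """Counts per element {C, H, N, O, S}; fractional counts allowed."""

    counts: dict[str, float]

    def __post_init__(self) -> None:
        for el, c in self.counts.items():
            if el not in ISOTOPE_ABUNDANCES:
                raise ValueError(f"unsupported element {el!r}")
            if c < 0:
                raise ValueError(f"negative count for element {el!r}")


def averagine_composition(mass: float) -> ElementalComposition:
    """Averagine elemental composition for a neutral mass (Da)."""
    if mass <= 0:
        raise ValueError("mass must be positive")
    scale = mass / AVERAGINE_RESIDUE_MASS
    return ElementalComposition({el: scale * c for el, c in AVERAGINE_RESIDUE.items()})


# -- truncated power-series helpers (exact for the leading coefficients) ----

def _series_log(a: np.ndarray) -> np.ndarray:
    k_max = len(a)
    l = np.zeros(k_max)
    l[0] = np.log(a[0])
    for k in range(1, k_max):
        acc = k * a[k]
        for j in range(1, k):
            acc -= j * l[j] * a[k - j]
        l[k] = acc / (k * a[0])
    return l


def _series_exp(l: np.ndarray) -> np.ndarray:
    k_max = len(l)
    b = np.zeros(k_max)
    b[0] = np.exp(l[0])
    for k in range(1, k_max):
        acc = 0.0
        for j in range(1, k + 1):
            acc += j * l[j] * b[k - j]
        b[k] = acc / k
    return b


def _element_power(element: str, count: float, k_max: int) -> np.ndarray:
    """Coefficients of (isotope distribution of one atom) ** count.

    For fractional ``count`` the power is defined through the truncated
    series ``exp(count * log p)``, which coincides with repeated
    convolution for integer counts.
    """
    p = np.zeros(k_max)
    for shift, ab in ISOTOPE_ABUNDANCES[element]:
        if shift < k_max:
            p[shift] = ab
    p /= p.sum() if p.sum() > 0 else 1.0
    if count == 0:
        out = np.zeros(k_max)
        out[0] = 1.0
        return out
    return _series_exp(count * _series_log(p))


def isotope_distribution(comp: ElementalComposition, n_peaks: int = 6) -> np.ndarray:
    """Relative abundances of the first ``n_peaks`` isotopologues, max-normalised.

    Aggregates isotopologues by nucleon-count shift and convolves the
    per-element distributions; fractional element counts enter directly via
    fractional series powers.  For sub-unity counts the truncated fractional
    power can produce tiny negative tail coefficients (|a| < 1e-4 relative);
    these are clipped to zero.
    """
    if n_peaks < 1:
        raise ValueError("n_peaks must be >= 1")
    acc = np.zeros(n_peaks)
    acc[0] = 1.0
    for el, count in comp.counts.items():
        if count == 0:
            continue
        acc = np.convolve(acc, _element_power(el, count, n_peaks))[:n_peaks]
    acc = np.clip(acc, 0.0, None)
    return acc / acc.max()


def theoretical_pattern(mono_mass: float, charge: int,
                        n_peaks: int = 6) -> list[tuple[float, float]]:
    """Averagine stick pattern ``[(mz, relative intensity), ...]``.

    Peak ``k`` sits at ``(mono_mass + charge*m_p + k*delta)/charge``; the
    spacing of adjacent peaks is ``delta/charge`` (~1 m/z at z=1, ~0.5 at
    z=2).  Intensities are max-normalised.
    """
    if not 1 <= int(charge) <= 5:
        raise ValueError(f"charge must be in [1, 5], got {charge}")
    abund = isotope_distribution(averagine_composition(mono_mass), n_peaks)
    z = int(charge)
    return [((mono_mass + z * PROTON_MASS + k * DELTA_ISO) / z, float(abund[k]))
            for k in range(n_peaks)]


# ---------------------------------------------------------------------------
# Reference database
# ---------------------------------------------------------------------------

@dataclass
class ReferencePattern:
    """A rendered theoretical pattern with its coarse vector and band keys."""

    pattern_id: int
    mono_mass: float
    charge: int
    mono_mz: float
    vector: np.ndarray        # (REF_N_BINS,) max-normalised
    base_bin: int             # argmax of ``vector`` (position of the base peak)
    keys: np.ndarray          # (m,) uint64 band keys of the canonical vector


@dataclass
class ReferenceMatch:
    """Best-scoring reference pattern for a query window."""

    mono_mz: float            # theoretical mono m/z of the matched pattern
    charge: int
    score: float
    pattern_id: int
    shift_bins: int           # extra +-delta/z roll applied to the query
    query_mono_offset: float  # estimated mono position in Da from query start


def render_pattern_vector(mono_mass: float, charge: int,
                          n_peaks: int = 6) -> np.ndarray:
    """Render a stick pattern on the [-1, +9] Da reference grid.

    Sticks are placed on the 1e-5 Da fine grid and accumulated by summation
    into 1e-2 Da coarse bins; the result is max-normalised.
    """
    vec = np.zeros(REF_N_BINS)
    for mz, h in theoretical_pattern(mono_mass, charge, n_peaks):
        offset = mz - (mono_mass + charge * PROTON_MASS) / charge  # k*delta/z
        fine = int(round((offset - REF_SPAN_LOW) / FINE_STEP))
        coarse = fine // int(round(COARSE_STEP / FINE_STEP))
        if 0 <= coarse < REF_N_BINS:
            vec[coarse] += h
    return vec / vec.max()


def _canonicalise(vec: np.ndarray) -> tuple[np.ndarray, int]:
    """Roll the vector so its base (most intense) bin sits at the anchor."""
    base = int(np.argmax(vec))
    return np.roll(vec, CANONICAL_ANCHOR - base), base


class ReferenceDB:
    """LSH-indexed database of averagine reference patterns.

    Patterns are compared in a *base-peak-anchored* frame: every vector
    (reference or query) is cyclically rolled so that its most intense bin
    sits at a fixed anchor before hashing and scoring.  This removes the
    unknown alignment between an acquisition window and the reference grid.
    """

    def __init__(self, patterns: Sequence[ReferencePattern], family: HashFamily,
                 params: dict | None = None):
        self.patterns = list(patterns)
        self.family = family
        self.params = dict(params or {})
        self._canon = np.stack([_canonicalise(p.vector)[0] for p in self.patterns]) \
            if self.patterns else np.empty((0, REF_N_BINS))
        self._norms = np.linalg.norm(self._canon, axis=1)
        self.index: list[dict[int, list[int]]] = [dict() for _ in range(family.m)]
        for p in self.patterns:
            for j, key in enumerate(p.keys):
                self.index[j].setdefault(int(key), []).append(p.pattern_id)

    def __len__(self) -> int:
        return len(self.patterns)

    def candidates(self, keys: np.ndarray) -> list[int]:
        """Pattern ids sharing at least one band key with the query."""
        found: set[int] = set()
        for j, key in enumerate(keys):
            found.update(self.index[j].get(int(key), ()))
        return sorted(found)

    # -- persistence --------------------------------------------------------

    def save(self, path) -> None:
        """Persist as a TSV of (pattern id, mono_mass, charge, band keys).

        Construction parameters go into ``#`` header lines so that vectors
        can be re-rendered deterministically on load.
        """
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            for k, v in self.params.items():
                fh.write(f"# {k}={v}\n")
            fh.write(f"# m={self.family.m}\n# n={self.family.n}\n")
            fh.write(f"# d={self.family.d}\n# seed={self.family.seed}\n")
            fh.write("pattern_id\tmono_mass\tcharge\tkeys\n")
            for p in self.patterns:
                keys = ",".join(str(int(k)) for k in p.keys)
                fh.write(f"{p.pattern_id}\t{p.mono_mass!r}\t{p.charge}\t{keys}\n")

    @classmethod
    def load(cls, path) -> "ReferenceDB":
        params: dict[str, str] = {}
        rows = []
        with open(path, encoding="utf-8") as fh:
            for line in fh:
                line = line.rstrip("\n")
                if line.startswith("#"):
                    k, _, v = line[1:].strip().partition("=")
                    params[k.strip()] = v.strip()
                elif line and not line.startswith("pattern_id"):
                    rows.append(line.split("\t"))
        family = HashFamily(m=int(params["m"]), n=int(params["n"]),
                            d=int(params["d"]), seed=int(params["seed"]))
        patterns = []
        for pid_s, mass_s, z_s, _keys in rows:
            vec = render_pattern_vector(float(mass_s), int(z_s))
            canon, base = _canonicalise(vec)
            keys = family.signature_matrix(canon[None, :])[0]
            z = int(z_s)
            mass = float(mass_s)
            patterns.append(ReferencePattern(
                pattern_id=int(pid_s), mono_mass=mass, charge=z,
                mono_mz=(mass + z * PROTON_MASS) / z, vector=vec,
                base_bin=base, keys=keys))
        return cls(patterns, family, params)


def build_reference_db(
    mass_min: float = 150.0,
    mass_max: float = 1800.0,
    mass_step: float = 10.0,
    charges: Sequence[int] = (1, 2, 3, 4, 5),
    family: HashFamily | None = None,
    seed: int = 0,
) -> ReferenceDB:
    """Render, hash and index reference patterns for a mass/charge grid."""
    family = family or HashFamily(m=64, n=32, d=REF_N_BINS, seed=seed)
    if family.d != REF_N_BINS:
        raise ValueError(f"reference hash family must have d={REF_N_BINS}")
    patterns: list[ReferencePattern] = []
    pid = 0
    masses = np.arange(mass_min, mass_max + mass_step / 2, mass_step) \
        if mass_max >= mass_min else np.empty(0)
    for mass in masses:
        for z in charges:
            vec = render_pattern_vector(float(mass), int(z))
            canon, base = _canonicalise(vec)
            keys = family.signature_matrix(canon[None, :])[0]
            patterns.append(ReferencePattern(
                pattern_id=pid, mono_mass=float(mass), charge=int(z),
                mono_mz=(float(mass) + z * PROTON_MASS) / z,
                vector=vec, base_bin=base, keys=keys))
            pid += 1
    params = dict(mass_min=mass_min, mass_max=mass_max, mass_step=mass_step,
                  charges=",".join(str(int(z)) for z in charges))
    return ReferenceDB(patterns, family, params)


def bin_window_reference(window: Window) -> np.ndarray:
    """Re-bin a window's peaks to the 1e-2 Da reference resolution.

    The vector spans ``[start, start + length)``; peak positions are snapped
    to the 1e-5 Da fine grid first, mirroring the reference rendering.
    """
    n = int(round(window.length / COARSE_STEP))
    vec = np.zeros(n)
    per = int(round(COARSE_STEP / FINE_STEP))
    for p in window.peaks:
        fine = int(round((p.mz - window.start) / FINE_STEP))
        coarse = fine // per
        if 0 <= coarse < n:
            vec[coarse] += p.intensity
    return vec


def reference_search(query: np.ndarray, db: ReferenceDB,
                     threshold: float = 0.6,
                     try_shifts: bool = True) -> ReferenceMatch | None:
    """Best-matching reference pattern for a query vector, or ``None``.

    The query (at 1e-2 Da resolution, same length as the reference grid) is
    anchored at its most intense bin, hashed, and scored by explicit cosine
    against all hash-collision candidates.  Because a noisy base peak can
    mis-anchor the query by one isotopologue, the ``+-delta/z`` rolls of the
    query are also scored when ``try_shifts`` is set, and the best variant
    is reported together with the shift applied.  Ties go to the lowest
    charge, then the lowest mass.
    """
    q = np.asarray(query, dtype=float)
    if q.shape != (REF_N_BINS,):
        raise ValueError(f"query must have {REF_N_BINS} bins, got {q.shape}")
    if not np.any(q > 0):
        return None
    canon_q, qbase = _canonicalise(q)
    keys = db.family.signature_matrix(canon_q[None, :])[0]
    cand = db.candidates(keys)
    if not cand:
        return None
    qnorm = np.linalg.norm(canon_q)
    best: tuple | None = None
    for pid in cand:
        pat = db.patterns[pid]
        ref = db._canon[pid]
        rnorm = db._norms[pid]
        shifts = [0]
        if try_shifts:
            dz = int(round(DELTA_ISO / pat.charge / COARSE_STEP))
            shifts += [-dz, dz]
        for s in shifts:
            qv = canon_q if s == 0 else np.roll(canon_q, s)
            score = float(qv @ ref / (qnorm * rnorm))
            rank = (-score, pat.charge, pat.mono_mass, abs(s))
            if best is None or rank < best[0]:
                best = (rank, pat, score, s)
    _, pat, score, s = best
    if score < threshold:
        return None
    mono_offset = COARSE_STEP * ((qbase - s) - (pat.base_bin - MONO_BIN))
    return ReferenceMatch(mono_mz=pat.mono_mz, charge=pat.charge, score=score,
                          pattern_id=pat.pattern_id, shift_bins=s,
                          query_mono_offset=mono_offset)


def isotope_shift(found_mz: float, true_mz: float, charge: int,
                  tol: float = 0.05) -> int | None:
    """Nearest integer isotopologue shift ``k`` with ``found = true + k*delta/z``.

    Returns ``k`` when the residual is within ``tol`` m/z, else ``None``
    (the match is not an isotope-shifted version of the truth at all).
    """
    step = DELTA_ISO / charge
    k = round((found_mz - true_mz) / step)
    if abs(found_mz - true_mz - k * step) <= tol:
        return int(k)
    return None
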
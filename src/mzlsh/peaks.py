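"""Peak data model, TSV/mzML readers, and overlapping mass-axis window generation.

The unit datum of the whole pipeline is a *window*: a short, compact m/z
interval of a single mass axis (one ``(frame, scan)`` pair, i.e. one
retention-time / ion-mobility coordinate).  Two staggered grids of windows —
one anchored at multiples of the window length, one offset by half a length —
guarantee that any isotopic pattern no wider than half a window is contained
whole in at least one window.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from math import floor
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Peak",
    "Window",
    "WindowGridConfig",
    "VALID_LABELS",
    "read_peak_table",
    "read_peak_dataframe",
    "write_peak_table",
    "read_mzml_ms1",
    "make_windows",
    "write_window_summary",
]

VALID_LABELS = frozenset({"signal", "noise_1", "noise_2", "unlabeled"})

#: Columns of the peak-table TSV dialect (label is optional).
PEAK_COLUMNS = ("frame", "scan", "mz", "intensity")


@dataclass
class Peak:
    """One centroided detection on a mass axis.

    Parameters
    ----------
    mz : float
        Mass-to-charge ratio, must be positive.
    intensity : float
        Non-negative abundance in arbitrary counts.
    frame, scan : int
        Retention-time index and ion-mobility index (``scan`` is fixed to 0
        for plain LC-MS data).
    label : str
        Ground-truth class for synthetic data, one of ``signal``,
        ``noise_1``, ``noise_2`` or ``unlabeled``.
    pid : int or None
        Sequential peak id assigned by readers/generators; used to address
        per-peak classification calls.
    """

    mz: float
    intensity: float
    frame: int = 0
    scan: int = 0
    label: str = "unlabeled"
    pid: int | None = None

    def __post_init__(self) -> None:
        if self.mz <= 0:
            raise ValueError(f"peak m/z must be positive, got {self.mz}")
        if self.intensity < 0:
            raise ValueError(f"peak intensity must be non-negative, got {self.intensity}")
        if self.label not in VALID_LABELS:
            raise ValueError(f"unknown peak label {self.label!r}")


@dataclass
class WindowGridConfig:
    """Geometry of the two staggered window grids and of the binning.

    ``window_length`` must be an exact integer multiple of ``bin_resolution``
    (default 10 m/z at 0.1 m/z resolution, i.e. 100 bins per window).
    """

    window_length: float = 10.0
    bin_resolution: float = 0.1
    anchor: float = 0.0

    def __post_init__(self) -> None:
        if self.window_length <= 0 or self.bin_resolution <= 0:
            raise ValueError("window_length and bin_resolution must be positive")
        ratio = self.window_length / self.bin_resolution
        if abs(ratio - round(ratio)) > 1e-9:
            raise ValueError(
                "window_length must be an integer multiple of bin_resolution, "
                f"got {self.window_length} / {self.bin_resolution}"
            )

    @property
    def n_bins(self) -> int:
        return int(round(self.window_length / self.bin_resolution))


@dataclass
class Window:
    """A compact m/z interval ``[start, start + length)`` of one mass axis.

    Contained peaks are sorted by m/z and all share the window's
    ``(frame, scan)`` coordinate.  ``offset_grid`` marks whether the window
    belongs to the half-length-shifted grid.
    """

    start: float
    length: float
    frame: int
    scan: int
    offset_grid: bool = False
    peaks: list[Peak] = field(default_factory=list)

    @property
    def end(self) -> float:
        return self.start + self.length

    def __len__(self) -> int:
        return len(self.peaks)


# ---------------------------------------------------------------------------
# TSV dialect
# ---------------------------------------------------------------------------

def read_peak_dataframe(path) -> pd.DataFrame:
    """Read the tab-separated peak table into a DataFrame.

    Expected header columns: ``frame  scan  mz  intensity  [label]``.
    Raises ``ValueError`` naming the first offending line for malformed
    numeric fields or negative intensities.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, comment=None)
    missing = [c for c in PEAK_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    out = pd.DataFrame(index=df.index)
    for col in ("frame", "scan"):
        converted = pd.to_numeric(df[col], errors="coerce")
        _raise_on_bad(df, converted, col, path)
        if (converted % 1 != 0).any():
            line = int(df.index[converted % 1 != 0][0]) + 2
            raise ValueError(f"{path}: non-integer {col!r} on line {line}")
        out[col] = converted.astype(np.int64)
    for col in ("mz", "intensity"):
        converted = pd.to_numeric(df[col], errors="coerce")
        _raise_on_bad(df, converted, col, path)
        out[col] = converted.astype(float)
    if (out["intensity"] < 0).any():
        line = int(out.index[out["intensity"] < 0][0]) + 2  # header is line 1
        raise ValueError(f"{path}: negative intensity on line {line}")
    if (out["mz"] <= 0).any():
        line = int(out.index[out["mz"] <= 0][0]) + 2
        raise ValueError(f"{path}: non-positive m/z on line {line}")
    if "label" in df.columns:
        labels = df["label"].fillna("unlabeled")
        bad = ~labels.isin(sorted(VALID_LABELS))
        if bad.any():
            line = int(df.index[bad][0]) + 2
            raise ValueError(f"{path}: unknown label {labels[bad].iloc[0]!r} on line {line}")
        out["label"] = labels
    else:
        out["label"] = "unlabeled"
    return out


def _raise_on_bad(raw: pd.DataFrame, converted: pd.Series, col: str, path) -> None:
    bad = converted.isna()
    if bad.any():
        line = int(raw.index[bad][0]) + 2
        raise ValueError(
            f"{path}: malformed value {raw[col][bad].iloc[0]!r} in column "
            f"{col!r} on line {line}"
        )


def read_peak_table(path) -> Iterator[Peak]:
    """Stream :class:`Peak` records from a peak-table TSV, in file order.

    Peaks receive sequential ``pid`` values starting at 0.
    """
    df = read_peak_dataframe(path)
    for pid, row in enumerate(df.itertuples(index=False)):
        yield Peak(mz=row.mz, intensity=row.intensity, frame=int(row.frame),
                   scan=int(row.scan), label=row.label, pid=pid)


def write_peak_table(peaks: Iterable[Peak], path, with_label: bool = True) -> None:
    """Write peaks to the TSV dialect ('.' decimal separator, UTF-8)."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        cols = ["frame", "scan", "mz", "intensity"] + (["label"] if with_label else [])
        fh.write("\t".join(cols) + "\n")
        for p in peaks:
            row = [str(p.frame), str(p.scan), repr(float(p.mz)), repr(float(p.intensity))]
            if with_label:
                row.append(p.label)
            fh.write("\t".join(row) + "\n")


# ---------------------------------------------------------------------------
# mzML
# ---------------------------------------------------------------------------

#: mzML controlled-vocabulary accessions used by the reader.
_CV_MS_LEVEL = "MS:1000511"
_CV_F64 = "MS:1000523"
_CV_F32 = "MS:1000521"
_CV_ZLIB = "MS:1000574"
_CV_MZ_ARRAY = "MS:1000514"
_CV_INTENSITY_ARRAY = "MS:1000515"


def _decode_binary_array(elem, ns: str) -> tuple[str | None, np.ndarray]:
    """Decode one <binaryDataArray>: returns (array accession, values)."""
    import base64
    import zlib

    dtype: np.dtype = np.dtype("<f8")
    compressed = False
    kind: str | None = None
    for cv in elem.iter(f"{ns}cvParam"):
        acc = cv.get("accession")
        if acc == _CV_F64:
            dtype = np.dtype("<f8")
        elif acc == _CV_F32:
            dtype = np.dtype("<f4")
        elif acc == _CV_ZLIB:
            compressed = True
        elif acc in (_CV_MZ_ARRAY, _CV_INTENSITY_ARRAY):
            kind = acc
    binary = elem.find(f"{ns}binary")
    raw = base64.b64decode((binary.text or "").strip()) if binary is not None else b""
    if compressed:
        raw = zlib.decompress(raw)
    return kind, np.frombuffer(raw, dtype=dtype).astype(float)


def _spectrum_mobility_index(elem, ns: str) -> int:
    for cv in elem.iter(f"{ns}cvParam"):
        name = (cv.get("name") or "").lower()
        if "ion mobility" in name or "drift time" in name:
            try:
                return int(float(cv.get("value", "0")))
            except ValueError:  # pragma: no cover - malformed mobility value
                return 0
    return 0


def read_mzml_ms1(path) -> Iterator[Peak]:
    """Stream peaks of all MS1 spectra of an mzML file.

    ``frame`` is the 0-based index of the MS1 spectrum in acquisition order;
    ``scan`` is the ion-mobility bin index when the spectrum carries one,
    else 0.  MS2 (and higher) spectra are skipped.

    The reader handles centroided spectra with base64-encoded 32/64-bit
    float arrays, zlib-compressed or plain.
    """
    import xml.etree.ElementTree as ET

    n_ms1 = 0
    pid = 0
    ns = ""
    for event, elem in ET.iterparse(str(path), events=("start", "end")):
        if event == "start":
            if elem.tag.startswith("{") and not ns:
                ns = elem.tag.split("}")[0] + "}"
            continue
        if elem.tag != f"{ns}spectrum":
            continue
        level = None
        for cv in elem.iter(f"{ns}cvParam"):
            if cv.get("accession") == _CV_MS_LEVEL:
                level = int(cv.get("value", "0"))
                break
        if level == 1:
            frame = n_ms1
            n_ms1 += 1
            scan = _spectrum_mobility_index(elem, ns)
            arrays: dict[str, np.ndarray] = {}
            for bda in elem.iter(f"{ns}binaryDataArray"):
                kind, values = _decode_binary_array(bda, ns)
                if kind is not None:
                    arrays[kind] = values
            mzs = arrays.get(_CV_MZ_ARRAY, np.empty(0))
            intens = arrays.get(_CV_INTENSITY_ARRAY, np.empty(0))
            for mz, inten in zip(mzs, intens):
                yield Peak(mz=float(mz), intensity=float(inten), frame=frame,
                           scan=scan, pid=pid)
                pid += 1
        elem.clear()
    if n_ms1 == 0:
        warnings.warn(f"{path}: no MS1 spectra found", stacklevel=2)


# ---------------------------------------------------------------------------
# Window generation
# ---------------------------------------------------------------------------

def make_windows(peaks: Iterable[Peak], config: WindowGridConfig | None = None) -> list[Window]:
    """Cut every mass axis into two staggered grids of windows.

    Each ``(frame, scan)`` group of peaks is covered twice: by the primary
    grid with starts at ``anchor + k*L`` and by the offset grid with starts
    at ``anchor + k*L + L/2``.  Only windows that contain at least one peak
    are materialised; every peak belongs to exactly one window per grid.
    """
    config = config or WindowGridConfig()
    L = config.window_length
    half = L / 2.0
    axes: dict[tuple[int, int], list[Peak]] = {}
    for p in peaks:
        axes.setdefault((p.frame, p.scan), []).append(p)

    windows: list[Window] = []
    for (frame, scan), axis_peaks in sorted(axes.items()):
        axis_peaks = sorted(axis_peaks, key=lambda p: p.mz)
        for offset_grid, shift in ((False, 0.0), (True, half)):
            buckets: dict[int, list[Peak]] = {}
            for p in axis_peaks:
                k = floor((p.mz - config.anchor - shift) / L)
                buckets.setdefault(k, []).append(p)
            for k in sorted(buckets):
                start = config.anchor + shift + k * L
                windows.append(Window(start=start, length=L, frame=frame,
                                      scan=scan, offset_grid=offset_grid,
                                      peaks=buckets[k]))
    return windows


def write_window_summary(windows: Sequence[Window], path) -> None:
    """Dump a per-window summary TSV (debugging / evaluation aid)."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("start\tframe\tscan\toffset_grid\tn_peaks\n")
        for w in windows:
            fh.write(f"{w.start!r}\t{w.frame}\t{w.scan}\t{int(w.offset_grid)}\t{len(w)}\n")
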
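"""Shared fixtures and fixture builders for the test suite."""

from __future__ import annotations

import base64
import struct
import zlib

import numpy as np
import pytest

from mzlsh import Peak


def _encode_array(values, compress: bool) -> str:
    raw = struct.pack(f"<{len(values)}d", *values)
    if compress:
        raw = zlib.compress(raw)
    return base64.b64encode(raw).decode("ascii")


def write_mzml(path, spectra, compress: bool = False) -> None:
    """Write a minimal centroided mzML file.

    ``spectra`` is a list of ``(ms_level, mz_array, intensity_array)``.
    Arrays are encoded as little-endian 64-bit floats, optionally
    zlib-compressed.
    """
    parts = [
        '<?xml version="1.0" encoding="utf-8"?>',
        '<mzML xmlns="http://psi.hupo.org/ms/mzml" version="1.1.0">',
        '<run id="run1">',
        f'<spectrumList count="{len(spectra)}">',
    ]
    for i, (level, mzs, intens) in enumerate(spectra):
        parts += [
            f'<spectrum index="{i}" id="scan={i + 1}" defaultArrayLength="{len(mzs)}">',
            f'<cvParam cvRef="MS" accession="MS:1000511" name="ms level" value="{level}"/>',
            '<binaryDataArrayList count="2">',
        ]
        comp = ('<cvParam cvRef="MS" accession="MS:1000574" name="zlib compression" value=""/>'
                if compress else
                '<cvParam cvRef="MS" accession="MS:1000576" name="no compression" value=""/>')
        for accession, name, values in (
            ("MS:1000514", "m/z array", mzs),
            ("MS:1000515", "intensity array", intens),
        ):
            encoded = _encode_array(values, compress)
            parts += [
                f'<binaryDataArray encodedLength="{len(encoded)}">',
                '<cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>',
                comp,
                f'<cvParam cvRef="MS" accession="{accession}" name="{name}" value=""/>',
                f'<binary>{encoded}</binary>',
                '</binaryDataArray>',
            ]
        parts += ['</binaryDataArrayList>', '</spectrum>']
    parts += ['</spectrumList>', '</run>', '</mzML>']
    path.write_text("\n".join(parts), encoding="utf-8")


def random_peaks(rng: np.random.Generator, n: int, mz_low=100.0, mz_high=900.0,
                 n_frames=3, n_scans=2) -> list[Peak]:
    peaks = []
    for pid in range(n):
        peaks.append(Peak(
            mz=float(rng.uniform(mz_low, mz_high)),
            intensity=float(rng.exponential(10.0)),
            frame=int(rng.integers(n_frames)),
            scan=int(rng.integers(n_scans)),
            pid=pid,
        ))
    return peaks


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
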
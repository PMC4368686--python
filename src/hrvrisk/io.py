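"""Reading and writing beat-interval data.

Two on-disk forms are supported: plain text (one interval per line, the
lingua franca of HRV toolboxes) and MIT/WFDB-style annotation records as
deposited on PhysioNet. The annotation codec here is deliberately small:
it handles the interval words and the SKIP escape of the MIT format,
which is all that beat-time extraction needs; auxiliary fields are
ignored on read and never written.
"""

from __future__ import annotations

import struct
from pathlib import Path

import numpy as np

from .series import ECTOPIC, NORMAL, RRSeries

# MIT annotation type codes. Codes 1..13 and 34/35/38 mark beats; of
# those, premature/ectopic forms get the "ectopic" label.
_BEAT_CODES = {1, 2, 3, 4, 5, 6, 7, 8, 9, 10, 11, 12, 13, 34, 35, 38}
_ECTOPIC_CODES = {4, 5, 7, 8, 9, 10, 11, 35}
_SKIP, _NUM, _SUB, _CHN, _AUX = 59, 60, 61, 62, 63


def read_rr_text(path: str | Path, record_id: str | None = None) -> RRSeries:
    """Read a one-interval-per-line text file into an :class:`RRSeries`.

    Blank lines and ``#`` comments are ignored. Values are auto-detected
    as milliseconds (median > 10) or seconds and converted to seconds;
    beat times are accumulated from zero.
    """
    path = Path(path)
    values: list[float] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            try:
                values.append(float(line))
            except ValueError:
                raise ValueError(
                    f"{path}: non-numeric interval on line {lineno}: {line!r}"
                ) from None
    if not values:
        raise ValueError(f"{path}: no intervals found")
    arr = np.asarray(values, dtype=float)
    if np.median(arr) > 10.0:  # millisecond dialect
        arr = arr / 1000.0
    return RRSeries(intervals=arr, record_id=record_id or path.stem)


def write_rr_text(rr: RRSeries, path: str | Path) -> None:
    """Write intervals as plain text, one value in seconds per line."""
    with open(path, "w") as fh:
        for v in rr.intervals:
            fh.write(f"{v:.6f}\n")


def read_wfdb_annotations(record_path: str | Path, annotator: str = "atr") -> RRSeries:
    """Read beat annotations of a WFDB record into an :class:`RRSeries`.

    ``record_path`` is the record name without extension; the sampling
    frequency is taken from ``<record>.hea`` and annotation times from
    ``<record>.<annotator>``. Non-beat annotations are dropped.
    """
    record_path = Path(record_path)
    hea = record_path.with_suffix(".hea")
    ann = record_path.with_suffix(f".{annotator}")
    if not hea.exists():
        raise FileNotFoundError(f"missing header file {hea}")
    if not ann.exists():
        raise FileNotFoundError(f"missing annotation file {ann}")
    fs = _read_header_fs(hea)
    samples, codes = _read_annotation_words(ann.read_bytes())
    beat = np.isin(codes, list(_BEAT_CODES))
    samples, codes = samples[beat], codes[beat]
    if samples.size < 2:
        raise ValueError(f"{ann}: fewer than two beat annotations")
    times = samples / fs
    labels = np.where(np.isin(codes[1:], list(_ECTOPIC_CODES)), ECTOPIC, NORMAL)
    return RRSeries(
        intervals=np.diff(times),
        beat_times=times - times[0],
        beat_labels=labels.astype(object),
        record_id=record_path.name,
    )


def write_wfdb_annotations(
    rr: RRSeries, record_path: str | Path, fs: float = 360.0, annotator: str = "atr"
) -> None:
    """Write an :class:`RRSeries` as a minimal WFDB header + annotation pair."""
    record_path = Path(record_path)
    n_samples = int(round(rr.beat_times[-1] * fs)) + 1
    record_path.with_suffix(".hea").write_text(
        f"{record_path.name} 1 {fs:g} {n_samples}\n"
        f"{record_path.name}.dat 16 200 11 1024 0 0 0 ECG\n"
    )
    samples = np.round(rr.beat_times * fs).astype(np.int64)
    codes = np.concatenate(
        [[1], [5 if lab == ECTOPIC else 1 for lab in rr.beat_labels]]
    )
    out = bytearray()
    prev = 0
    for samp, code in zip(samples, codes):
        delta = int(samp - prev)
        if delta >= 1024:  # SKIP escape: 4-byte absolute interval follows
            out += struct.pack("<H", _SKIP << 10)
            out += struct.pack("<H", (delta >> 16) & 0xFFFF)
            out += struct.pack("<H", delta & 0xFFFF)
            out += struct.pack("<H", int(code) << 10)
        else:
            out += struct.pack("<H", (int(code) << 10) | delta)
        prev = samp
    out += struct.pack("<H", 0)  # EOF word
    record_path.with_suffix(f".{annotator}").write_bytes(bytes(out))


def _read_header_fs(hea: Path) -> float:
    first = hea.read_text().splitlines()[0].split()
    if len(first) < 3:
        raise ValueError(f"{hea}: malformed header line")
    return float(first[2])


def _read_annotation_words(data: bytes) -> tuple[np.ndarray, np.ndarray]:
    samples: list[int] = []
    codes: list[int] = []
    t = 0
    i = 0
    pending_skip = 0
    while i + 1 < len(data) or (i + 1 == len(data) and False):
        if i + 2 > len(data):
            break
        (word,) = struct.unpack_from("<H", data, i)
        i += 2
        code = word >> 10
        delta = word & 0x3FF
        if word == 0:  # EOF
            break
        if code == _SKIP:
            if i + 4 > len(data):
                raise ValueError("truncated SKIP annotation")
            (hi,) = struct.unpack_from("<H", data, i)
            (lo,) = struct.unpack_from("<H", data, i + 2)
            i += 4
            pending_skip = (hi << 16) | lo
            continue
        if code in (_NUM, _SUB, _CHN):
            continue
        if code == _AUX:
            n = delta + (delta % 2)  # aux string is null-padded to even length
            i += n
            continue
        t += delta + pending_skip
        pending_skip = 0
        samples.append(t)
        codes.append(code)
    return np.asarray(samples, dtype=np.int64), np.asarray(codes, dtype=np.int64)
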
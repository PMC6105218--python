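"""Peak-list I/O and pipeline configuration.

The native exchange format is a flat centroid peak-list CSV with header
``scan_id,rt_min,mz,intensity,polarity`` — one row per centroid peak.
Centroided mzML is accepted read-only through a minimal built-in reader;
profile-mode spectra are rejected.
"""
from __future__ import annotations

import base64
import csv
import dataclasses
import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = ["Scan", "PeaklistError", "read_peaklist", "write_peaklist",
           "read_mzml", "PipelineConfig"]

PEAKLIST_HEADER = ["scan_id", "rt_min", "mz", "intensity", "polarity"]
_POLARITIES = ("positive", "negative")


class PeaklistError(ValueError):
    """Malformed peak-list input; carries the offending line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


@dataclass
class Scan:
    """One centroided mass spectrum: RT plus parallel m/z / intensity arrays."""

    scan_id: int
    rt_min: float
    mz: np.ndarray
    intensity: np.ndarray
    polarity: str

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.shape != self.intensity.shape:
            raise ValueError("mz and intensity must have equal length")
        if self.polarity not in _POLARITIES:
            raise ValueError(f"polarity must be one of {_POLARITIES}")

    @property
    def n_peaks(self) -> int:
        return int(self.mz.size)


def read_peaklist(path: str | Path) -> list[Scan]:
    """Read a peak-list CSV (or centroided mzML) into RT-ordered scans.

    An empty file (header only, or zero bytes) yields an empty list.
    """
    path = Path(path)
    if path.suffix.lower() == ".mzml":
        return read_mzml(path)
    rows: dict[tuple[int, str], list[tuple[float, float, float]]] = {}
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            return []
        if [h.strip() for h in header] != PEAKLIST_HEADER:
            raise PeaklistError(f"expected header {','.join(PEAKLIST_HEADER)}", line=1)
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != 5:
                raise PeaklistError(f"expected 5 fields, got {len(row)}", line=lineno)
            try:
                scan_id = int(row[0])
                rt = float(row[1])
                mz = float(row[2])
                inten = float(row[3])
            except ValueError as exc:
                raise PeaklistError(str(exc), line=lineno) from None
            pol = row[4].strip()
            if pol not in _POLARITIES:
                raise PeaklistError(f"bad polarity {pol!r}", line=lineno)
            if inten <= 0:
                raise PeaklistError(f"non-positive intensity {inten}", line=lineno)
            if mz <= 0:
                raise PeaklistError(f"non-positive m/z {mz}", line=lineno)
            rows.setdefault((scan_id, pol), []).append((rt, mz, inten))
    scans = []
    for (scan_id, pol), peaks in rows.items():
        rts = {p[0] for p in peaks}
        if len(rts) != 1:
            raise PeaklistError(f"scan {scan_id} ({pol}) has inconsistent rt_min values")
        peaks.sort(key=lambda p: p[1])
        scans.append(Scan(scan_id=scan_id, rt_min=peaks[0][0],
                          mz=np.array([p[1] for p in peaks]),
                          intensity=np.array([p[2] for p in peaks]),
                          polarity=pol))
    scans.sort(key=lambda s: (s.rt_min, s.scan_id, s.polarity))
    return scans


def write_peaklist(scans: Iterable[Scan], path: str | Path) -> None:
    """Write scans to the peak-list CSV dialect (m/z at 6 decimals)."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(PEAKLIST_HEADER)
        for scan in scans:
            for mz, inten in zip(scan.mz, scan.intensity):
                writer.writerow([scan.scan_id, f"{scan.rt_min:.4f}",
                                 f"{mz:.6f}", f"{inten:.2f}", scan.polarity])


_MZML_NS = "{http://psi.hupo.org/ms/mzml}"
# PSI-MS controlled-vocabulary accessions used by the reader
_CV_MS_LEVEL = "MS:1000511"
_CV_CENTROID = "MS:1000127"
_CV_PROFILE = "MS:1000128"
_CV_POSITIVE = "MS:1000130"
_CV_NEGATIVE = "MS:1000129"
_CV_SCAN_START = "MS:1000016"
_CV_MZ_ARRAY = "MS:1000514"
_CV_INT_ARRAY = "MS:1000515"
_CV_F64 = "MS:1000523"
_CV_F32 = "MS:1000521"
_CV_ZLIB = "MS:1000574"
_CV_NOCOMP = "MS:1000576"


def _decode_binary_array(node) -> np.ndarray:
    accs = {cv.get("accession") for cv in node.iter(f"{_MZML_NS}cvParam")}
    binary = node.find(f"{_MZML_NS}binary")
    raw = base64.b64decode((binary.text or "").strip())
    if _CV_ZLIB in accs:
        raw = zlib.decompress(raw)
    dtype = "<f4" if _CV_F32 in accs else "<f8"
    return np.frombuffer(raw, dtype=dtype).astype(float)


def read_mzml(path: str | Path) -> list[Scan]:
    """Read a centroided mzML file into scans (read-only support).

    A deliberately minimal reader for the common instrument-export subset:
    MS1 spectra with uncompressed or zlib-compressed 32/64-bit float
    arrays.  Raises :class:`PeaklistError` for profile-mode spectra
    ("centroided input required") and for spectra without an ESI polarity
    annotation.  Scan start times must be in minutes (the package's RT
    unit) or seconds (converted).
    """
    import xml.etree.ElementTree as ET

    scans: list[Scan] = []
    for i, (_, spec) in enumerate(
            e for e in ET.iterparse(str(path), events=("end",))
            if e[1].tag == f"{_MZML_NS}spectrum"):
        params = {cv.get("accession"): cv for cv in spec.iter(f"{_MZML_NS}cvParam")}
        level = params.get(_CV_MS_LEVEL)
        if level is not None and level.get("value") not in ("", "1"):
            spec.clear()
            continue
        if _CV_PROFILE in params or _CV_CENTROID not in params:
            raise PeaklistError("centroided input required")
        if _CV_POSITIVE in params:
            pol = "positive"
        elif _CV_NEGATIVE in params:
            pol = "negative"
        else:
            raise PeaklistError(f"spectrum {i} lacks a scan polarity")
        rt_param = params.get(_CV_SCAN_START)
        if rt_param is None:
            raise PeaklistError(f"spectrum {i} lacks a scan start time")
        rt = float(rt_param.get("value"))
        if rt_param.get("unitName", "minute") == "second":
            rt /= 60.0
        mz = inten = None
        for arr in spec.iter(f"{_MZML_NS}binaryDataArray"):
            accs = {cv.get("accession") for cv in arr.iter(f"{_MZML_NS}cvParam")}
            if _CV_MZ_ARRAY in accs:
                mz = _decode_binary_array(arr)
            elif _CV_INT_ARRAY in accs:
                inten = _decode_binary_array(arr)
        if mz is None or inten is None:
            raise PeaklistError(f"spectrum {i} lacks m/z or intensity arrays")
        keep = inten > 0
        scans.append(Scan(scan_id=i, rt_min=rt, mz=mz[keep],
                          intensity=inten[keep], polarity=pol))
        spec.clear()
    scans.sort(key=lambda s: (s.rt_min, s.scan_id))
    return scans


@dataclass
class PipelineConfig:
    """Effective configuration of a pipeline run, echoed to the output
    directory as JSON so every run is reproducible from its artifacts.

    Instrument metadata mirrors the acquisition settings the synthetic runs
    emulate (Q-TOF full-scan m/z 100-1700, fragmentor 100 V); it is carried
    as provenance, not consumed by the algorithms.
    """

    seed: int = 0
    preset: str = "study"
    out_dir: str = "."
    log_level: str = "INFO"
    extraction: dict = field(default_factory=dict)
    identification: dict = field(default_factory=dict)
    screening: dict = field(default_factory=dict)
    simulation: dict = field(default_factory=dict)
    instrument: dict = field(default_factory=lambda: {
        "mass_range_mz": [100, 1700],
        "fragmentor_voltage_v": 100,
        "ion_source": "dual ESI",
        "analyzer": "Q-TOF",
    })

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            payload = json.load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        return cls(**{k: v for k, v in payload.items() if k in known})
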
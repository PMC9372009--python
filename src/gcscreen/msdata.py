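"""Data model and I/O for GC-HRMS runs.

A :class:`Run` is a retention-time-ordered sequence of scans, either profile
mode (continuum m/z sampling) or centroid mode (discrete sticks).  This module
also provides profile->centroid conversion and extracted-ion-chromatogram
(EIC) construction, the two steps every downstream deconvolution consumes.

Units: retention time in seconds, m/z in Da, intensity in detector counts.
"""

from __future__ import annotations

import base64
from bisect import bisect_left
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal
import xml.etree.ElementTree as ET

import numpy as np

from .errors import ParseError, ValidationError

__all__ = [
    "ProfileSpectrum",
    "CentroidSpectrum",
    "Run",
    "EIC",
    "read_run",
    "write_run",
    "centroid_profile",
    "centroid_run",
    "extract_eics",
]


def _as_float_array(x) -> np.ndarray:
    return np.asarray(x, dtype=np.float64)


@dataclass(frozen=True)
class ProfileSpectrum:
    """One profile-mode scan: m/z sample points with intensities.

    ``mz`` must be strictly increasing; intensities are non-negative and the
    two arrays have equal length.  Empty scans are allowed.
    """

    rt: float
    mz: np.ndarray
    intensity: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "mz", _as_float_array(self.mz))
        object.__setattr__(self, "intensity", _as_float_array(self.intensity))
        if self.mz.shape != self.intensity.shape or self.mz.ndim != 1:
            raise ValidationError("mz and intensity must be 1-D arrays of equal length")
        if self.mz.size and np.any(np.diff(self.mz) <= 0):
            raise ValidationError("profile m/z values must be strictly increasing")
        if np.any(self.intensity < 0):
            raise ValidationError("profile intensities must be non-negative")

    def __len__(self) -> int:
        return self.mz.size


@dataclass(frozen=True)
class CentroidSpectrum:
    """One centroided scan: unique ascending m/z sticks with intensities > 0."""

    rt: float
    mz: np.ndarray
    intensity: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "mz", _as_float_array(self.mz))
        object.__setattr__(self, "intensity", _as_float_array(self.intensity))
        if self.mz.shape != self.intensity.shape or self.mz.ndim != 1:
            raise ValidationError("mz and intensity must be 1-D arrays of equal length")
        if self.mz.size and np.any(np.diff(self.mz) <= 0):
            raise ValidationError("centroid m/z values must be unique and ascending")
        if np.any(self.intensity <= 0):
            raise ValidationError("centroid intensities must be positive")

    @property
    def peaks(self) -> list[tuple[float, float]]:
        return list(zip(self.mz.tolist(), self.intensity.tolist()))

    def __len__(self) -> int:
        return self.mz.size


Spectrum = ProfileSpectrum | CentroidSpectrum


@dataclass
class Run:
    """A time-ordered acquisition: scans plus acquisition metadata.

    ``scan_period`` defaults to the median inter-scan interval; up to ~10%
    jitter in scan spacing is tolerated without complaint because the
    downstream grouping windows are expressed in seconds, not scan indices.
    """

    scans: list[Spectrum]
    mz_range: tuple[float, float] = (40.0, 1000.0)
    metadata: dict = field(default_factory=dict)
    _scan_period: float | None = None

    def __post_init__(self):
        rts = self.rts
        if rts.size > 1 and np.any(np.diff(rts) <= 0):
            raise ValidationError("scan retention times must be strictly increasing")
        lo, hi = self.mz_range
        for s in self.scans:
            if s.mz.size and (s.mz[0] < lo - 1e-9 or s.mz[-1] > hi + 1e-9):
                raise ValidationError(
                    f"scan at rt={s.rt:.3f}s has m/z outside the declared range {self.mz_range}"
                )

    @property
    def rts(self) -> np.ndarray:
        return np.array([s.rt for s in self.scans], dtype=np.float64)

    @property
    def scan_period(self) -> float:
        if self._scan_period is not None:
            return self._scan_period
        rts = self.rts
        if rts.size < 2:
            return 0.2
        return float(np.median(np.diff(rts)))

    @property
    def is_profile(self) -> bool:
        return any(isinstance(s, ProfileSpectrum) for s in self.scans)

    def __len__(self) -> int:
        return len(self.scans)


@dataclass
class EIC:
    """Extracted-ion chromatogram: one mass trace over the run's scan grid.

    ``mz_trace`` carries the intensity-weighted member m/z per scan (nan on
    scans with no member) so downstream peak detection can measure each
    chromatographic peak's m/z from its own scans rather than from the whole
    trace — one trace may legitimately collect near-isobaric ions of
    different compounds at different retention times.
    """

    target_mz: float
    mz_delta: float
    rts: np.ndarray
    intensities: np.ndarray
    mz_trace: np.ndarray | None = None

    @property
    def trace(self) -> list[tuple[float, float]]:
        return list(zip(self.rts.tolist(), self.intensities.tolist()))

    def __len__(self) -> int:
        return self.rts.size


# ---------------------------------------------------------------------------
# profile -> centroid


def centroid_profile(
    spec: ProfileSpectrum, min_points: int = 2, snr_floor: float = 0.0
) -> CentroidSpectrum:
    """Convert one profile scan to centroids.

    Contiguous profile points above ``snr_floor`` are segmented into
    local-maximum regions (split at interior valleys, and at m/z gaps much
    wider than the local sampling step, so sparse profile data without an
    explicit zero baseline segments correctly); each region with at least
    ``min_points`` points yields one centroid whose m/z is the
    intensity-weighted mean of the region and whose intensity is the region's
    apex intensity.
    """
    mz, inten = spec.mz, spec.intensity
    out_mz: list[float] = []
    out_int: list[float] = []
    above = inten > snr_floor
    n = mz.size
    gap = np.inf
    if n > 1:
        step = float(np.median(np.diff(mz)))
        gap = 5.0 * step if step > 0 else np.inf
    i = 0
    while i < n:
        if not above[i]:
            i += 1
            continue
        j = i
        while j < n and above[j] and (j == i or mz[j] - mz[j - 1] <= gap):
            j += 1
        _centroid_region(mz[i:j], inten[i:j], min_points, out_mz, out_int)
        i = j
    order = np.argsort(out_mz, kind="stable")
    cm = np.array(out_mz)[order] if out_mz else np.empty(0)
    ci = np.array(out_int)[order] if out_int else np.empty(0)
    # merge pathological exact duplicates to preserve the ascending invariant
    if cm.size > 1:
        keep_mz, keep_int = [cm[0]], [ci[0]]
        for k in range(1, cm.size):
            if cm[k] - keep_mz[-1] <= 0:
                keep_int[-1] = max(keep_int[-1], ci[k])
            else:
                keep_mz.append(cm[k])
                keep_int.append(ci[k])
        cm, ci = np.array(keep_mz), np.array(keep_int)
    return CentroidSpectrum(rt=spec.rt, mz=cm, intensity=ci)


def _centroid_region(mz, inten, min_points, out_mz, out_int):
    """Split one above-floor segment at interior valleys, emit one centroid
    per local-maximum sub-region."""
    n = mz.size
    if n == 0:
        return
    # interior valley indices: strictly lower than both neighbours
    splits = [0]
    for k in range(1, n - 1):
        if inten[k] < inten[k - 1] and inten[k] < inten[k + 1]:
            splits.append(k)
    splits.append(n)
    for a, b in zip(splits[:-1], splits[1:]):
        seg_mz, seg_int = mz[a:b], inten[a:b]
        if seg_mz.size < min_points:
            continue
        total = float(seg_int.sum())
        if total <= 0:
            continue
        out_mz.append(float((seg_mz * seg_int).sum() / total))
        out_int.append(float(seg_int.max()))


def centroid_run(run: Run, min_points: int = 2, snr_floor: float = 0.0) -> Run:
    """Centroid every profile scan of a run (centroid scans pass through)."""
    scans: list[Spectrum] = []
    for s in run.scans:
        if isinstance(s, ProfileSpectrum):
            scans.append(centroid_profile(s, min_points=min_points, snr_floor=snr_floor))
        else:
            scans.append(s)
    meta = dict(run.metadata)
    meta["acquisition_mode"] = "centroid"
    return Run(scans=scans, mz_range=run.mz_range, metadata=meta)


# ---------------------------------------------------------------------------
# EIC extraction


def extract_eics(run: Run, mz_delta: float = 0.05) -> list[EIC]:
    """Cluster centroid peaks across scans into mass traces.

    ``mz_delta`` is the FULL trace window: any two member peaks of one EIC
    differ by at most ``mz_delta``.  Membership is greedy in decreasing
    intensity order: each centroid joins the nearest existing trace whose
    intensity-weighted mean m/z is within ``mz_delta / 2``, ties broken toward
    lower m/z; otherwise it seeds a new trace.  Every centroid is assigned to
    exactly one trace, so total ion current is conserved scan by scan.
    """
    if run.is_profile:
        raise TypeError("extract_eics requires a centroided run; call centroid_run first")
    half = mz_delta / 2.0
    rts = run.rts
    n_scans = len(run.scans)

    # flatten all centroids, sort by decreasing intensity (deterministic ties)
    recs: list[tuple[float, float, int]] = []  # (mz, intensity, scan_idx)
    for si, s in enumerate(run.scans):
        for m, i in zip(s.mz, s.intensity):
            recs.append((float(m), float(i), si))
    recs.sort(key=lambda r: (-r[1], r[0], r[2]))

    keys: list[float] = []  # sorted current means
    key_ids: list[int] = []
    wsum: list[float] = []
    wmzsum: list[float] = []
    members: list[list[tuple[int, float, float]]] = []  # per trace: (scan_idx, mz, intensity)

    for m, i, si in recs:
        pos = bisect_left(keys, m)
        best = -1
        best_d = half + 1.0
        for cand in (pos - 1, pos):
            if 0 <= cand < len(keys):
                d = abs(keys[cand] - m)
                if d <= half + 1e-12 and (
                    d < best_d - 1e-15
                    or (abs(d - best_d) <= 1e-15 and best >= 0 and keys[cand] < keys[best])
                ):
                    best, best_d = cand, d
        if best < 0:
            tid = len(wsum)
            wsum.append(i)
            wmzsum.append(m * i)
            members.append([(si, m, i)])
            ins = bisect_left(keys, m)
            keys.insert(ins, m)
            key_ids.insert(ins, tid)
        else:
            tid = key_ids[best]
            wsum[tid] += i
            wmzsum[tid] += m * i
            members[tid].append((si, m, i))
            new_mean = wmzsum[tid] / wsum[tid]
            keys.pop(best)
            key_ids.pop(best)
            ins = bisect_left(keys, new_mean)
            keys.insert(ins, new_mean)
            key_ids.insert(ins, tid)

    eics: list[EIC] = []
    for tid in range(len(wsum)):
        trace = np.zeros(n_scans)
        wmz = np.zeros(n_scans)
        for si, m, i in members[tid]:
            trace[si] += i
            wmz[si] += m * i
        with np.errstate(invalid="ignore"):
            mz_trace = np.where(trace > 0, wmz / np.where(trace > 0, trace, 1.0), np.nan)
        eics.append(
            EIC(
                target_mz=wmzsum[tid] / wsum[tid],
                mz_delta=mz_delta,
                rts=rts,
                intensities=trace,
                mz_trace=mz_trace,
            )
        )
    eics.sort(key=lambda e: e.target_mz)
    return eics


# ---------------------------------------------------------------------------
# internal run format (plain text, fixture friendly)

_INTERNAL_MAGIC = "#gcscreen-run 1"


def _write_internal(run: Run, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write(_INTERNAL_MAGIC + "\n")
        fh.write(f"#mode {'profile' if run.is_profile else 'centroid'}\n")
        fh.write(f"#mz_range {run.mz_range[0]:.6f} {run.mz_range[1]:.6f}\n")
        for k, v in run.metadata.items():
            fh.write(f"#meta {k}={v}\n")
        for s in run.scans:
            fh.write(f"S {s.rt:.12g} {len(s)}\n")
            for m, i in zip(s.mz, s.intensity):
                fh.write(f"{m:.10g} {i:.10g}\n")


def _read_internal(path: Path) -> Run:
    scans: list[Spectrum] = []
    mode = "profile"
    mz_range = (40.0, 1000.0)
    metadata: dict = {}
    with open(path) as fh:
        lines = fh.readlines()
    if not lines or lines[0].strip() != _INTERNAL_MAGIC:
        raise ParseError(f"not a gcscreen internal run file: {path}", line=1)
    i = 1
    while i < len(lines):
        line = lines[i].strip()
        i += 1
        if not line:
            continue
        if line.startswith("#mode"):
            mode = line.split()[1]
        elif line.startswith("#mz_range"):
            _, lo, hi = line.split()
            mz_range = (float(lo), float(hi))
        elif line.startswith("#meta"):
            k, _, v = line[len("#meta "):].partition("=")
            metadata[k] = v
        elif line.startswith("S "):
            _, rt_s, n_s = line.split()
            rt, n = float(rt_s), int(n_s)
            mzs = np.empty(n)
            ints = np.empty(n)
            for k in range(n):
                if i + k >= len(lines):
                    raise ParseError("truncated scan block", line=i + k + 1)
                parts = lines[i + k].split()
                if len(parts) != 2:
                    raise ParseError("expected 'mz intensity' pair", line=i + k + 1)
                mzs[k], ints[k] = float(parts[0]), float(parts[1])
            i += n
            cls = ProfileSpectrum if mode == "profile" else CentroidSpectrum
            scans.append(cls(rt=rt, mz=mzs, intensity=ints))
        else:
            raise ParseError(f"unrecognized line: {line!r}", line=i)
    metadata.setdefault("acquisition_mode", mode)
    return Run(scans=scans, mz_range=mz_range, metadata=metadata)


# ---------------------------------------------------------------------------
# mzML

_NS = "http://psi.hupo.org/ms/mzml"


def _b64(arr: np.ndarray) -> str:
    return base64.b64encode(np.asarray(arr, dtype="<f8").tobytes()).decode()


def _cv(parent, accession, name, value=None, unit=None):
    el = ET.SubElement(parent, "cvParam", cvRef="MS", accession=accession, name=name)
    if value is not None:
        el.set("value", str(value))
    if unit is not None:
        acc, uname = unit
        el.set("unitCvRef", "UO")
        el.set("unitAccession", acc)
        el.set("unitName", uname)
    return el


def _write_mzml(run: Run, path: Path) -> None:
    ET.register_namespace("", _NS)
    root = ET.Element(f"{{{_NS}}}mzML", version="1.1.0")
    cvl = ET.SubElement(root, "cvList", count="2")
    ET.SubElement(cvl, "cv", id="MS", fullName="Proteomics Standards Initiative Mass Spectrometry Ontology",
                  URI="https://raw.githubusercontent.com/HUPO-PSI/psi-ms-CV/master/psi-ms.obo")
    ET.SubElement(cvl, "cv", id="UO", fullName="Unit Ontology",
                  URI="http://ontologies.berkeleybop.org/uo.obo")
    fd = ET.SubElement(root, "fileDescription")
    fc = ET.SubElement(fd, "fileContent")
    _cv(fc, "MS:1000579", "MS1 spectrum")
    sample_id = str(run.metadata.get("sample_id", "run1"))
    runel = ET.SubElement(root, "run", id=sample_id)
    slist = ET.SubElement(runel, "spectrumList", count=str(len(run.scans)))
    for idx, s in enumerate(run.scans):
        sp = ET.SubElement(
            slist, "spectrum", index=str(idx), id=f"scan={idx + 1}",
            defaultArrayLength=str(len(s)),
        )
        _cv(sp, "MS:1000511", "ms level", 1)
        if isinstance(s, ProfileSpectrum):
            _cv(sp, "MS:1000128", "profile spectrum")
        else:
            _cv(sp, "MS:1000127", "centroid spectrum")
        scl = ET.SubElement(sp, "scanList", count="1")
        _cv(scl, "MS:1000795", "no combination")
        scan = ET.SubElement(scl, "scan")
        _cv(scan, "MS:1000016", "scan start time", repr(float(s.rt)),
            unit=("UO:0000010", "second"))
        bdal = ET.SubElement(sp, "binaryDataArrayList", count="2")
        for arr, acc, name, unit in (
            (s.mz, "MS:1000514", "m/z array", ("MS:1000040", "m/z")),
            (s.intensity, "MS:1000515", "intensity array", ("MS:1000131", "number of detector counts")),
        ):
            data = _b64(arr)
            bda = ET.SubElement(bdal, "binaryDataArray", encodedLength=str(len(data)))
            _cv(bda, "MS:1000523", "64-bit float")
            _cv(bda, "MS:1000576", "no compression")
            el = ET.SubElement(bda, "cvParam", cvRef="MS", accession=acc, name=name, value="")
            el.set("unitCvRef", "MS" if unit[0].startswith("MS") else "UO")
            el.set("unitAccession", unit[0])
            el.set("unitName", unit[1])
            ET.SubElement(bda, "binary").text = data
    tree = ET.ElementTree(root)
    ET.indent(tree)
    tree.write(path, xml_declaration=True, encoding="utf-8")


def _decode_binary(bda_el) -> np.ndarray:
    """Decode one <binaryDataArray>: 32/64-bit float, plain or zlib."""
    import zlib

    dtype = "<f8"
    compressed = False
    for cv in bda_el.iter(f"{{{_NS}}}cvParam"):
        acc = cv.get("accession")
        if acc == "MS:1000521":
            dtype = "<f4"
        elif acc == "MS:1000523":
            dtype = "<f8"
        elif acc == "MS:1000574":
            compressed = True
    bin_el = bda_el.find(f"{{{_NS}}}binary")
    raw = base64.b64decode(bin_el.text or "")
    if compressed:
        raw = zlib.decompress(raw)
    return np.frombuffer(raw, dtype=dtype).astype(np.float64)


def _read_mzml(path: Path) -> Run:
    """Minimal mzML 1.1.0 reader (profile/centroid flags, scan start time,
    uncompressed or zlib 32/64-bit float arrays)."""
    tree = ET.parse(path)
    root = tree.getroot()
    scans: list[Spectrum] = []
    any_profile = False
    for sp in root.iter(f"{{{_NS}}}spectrum"):
        profile = False
        rt = None
        for cv in sp.iter(f"{{{_NS}}}cvParam"):
            acc = cv.get("accession")
            if acc == "MS:1000128":
                profile = True
            elif acc == "MS:1000016":
                rt = float(cv.get("value"))
                unit = (cv.get("unitName") or "second").lower()
                if "min" in unit:
                    rt *= 60.0
        if rt is None:
            raise ParseError(f"spectrum {sp.get('id')!r} lacks a scan start time")
        mz = inten = None
        for bda in sp.iter(f"{{{_NS}}}binaryDataArray"):
            accs = {cv.get("accession") for cv in bda.iter(f"{{{_NS}}}cvParam")}
            if "MS:1000514" in accs:
                mz = _decode_binary(bda)
            elif "MS:1000515" in accs:
                inten = _decode_binary(bda)
        if mz is None or inten is None:
            raise ParseError(f"spectrum {sp.get('id')!r} lacks m/z or intensity arrays")
        if profile:
            any_profile = True
            scans.append(ProfileSpectrum(rt=rt, mz=mz, intensity=inten))
        else:
            keep = inten > 0
            scans.append(CentroidSpectrum(rt=rt, mz=mz[keep], intensity=inten[keep]))
    scans.sort(key=lambda s: s.rt)
    lo = min((float(s.mz[0]) for s in scans if len(s)), default=40.0)
    hi = max((float(s.mz[-1]) for s in scans if len(s)), default=1000.0)
    return Run(
        scans=scans,
        mz_range=(min(lo, 40.0), max(hi, 1000.0)),
        metadata={"acquisition_mode": "profile" if any_profile else "centroid",
                  "source": str(path)},
    )


RunFormat = Literal["mzml", "internal"]


def _infer_format(path: Path, fmt: str | None) -> str:
    if fmt is not None:
        return fmt
    return "mzml" if path.suffix.lower() == ".mzml" else "internal"


def read_run(path, format: RunFormat | None = None) -> Run:
    """Read a run from mzML or the internal text format (auto by extension)."""
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such file: {path}")
    fmt = _infer_format(path, format)
    if fmt == "mzml":
        return _read_mzml(path)
    if fmt == "internal":
        return _read_internal(path)
    raise ValueError(f"unknown run format: {fmt}")


def write_run(run: Run, path, format: RunFormat | None = None) -> None:
    """Write a run to mzML or the internal text format (auto by extension)."""
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "mzml":
        _write_mzml(run, path)
    elif fmt == "internal":
        _write_internal(run, path)
    else:
        raise ValueError(f"unknown run format: {fmt}")
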
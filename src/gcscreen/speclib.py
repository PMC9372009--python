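"""Accurate-mass EI spectral library: MSP I/O, entry building, RT->RI migration.

The interchange format is an MSP dialect (NIST-compatible superset): each
entry has ``Name:``, optional ``CASNO:``, ``RI:``, ``RT:``, ``MW:``,
``Comments:`` (space-separated key=value pairs, e.g. ``derivatized=TMS``),
``Num Peaks:`` and then one ``mz intensity`` pair per line.  m/z is written
with 4 decimals and intensities as integers 1-999 with the base peak at 999.

Derivatized (TMS) variants are independent searchable entries whose names are
conventionally suffixed ", TMS".
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

from .errors import AmbiguityError, NotFoundError, ParseError, ValidationError
from .rical import AlkaneCalibration, rt_to_ri

__all__ = [
    "LibraryEntry",
    "SpectralLibrary",
    "read_msp",
    "write_msp",
    "build_entry_from_run",
    "migrate_rt_library",
    "MigrationFit",
    "load_anchor_table",
]


@dataclass
class LibraryEntry:
    """One named accurate-mass EI spectrum with retention metadata."""

    name: str
    mz: np.ndarray                  # ascending, >= 4-decimal accurate masses
    rel_intensity: np.ndarray       # 0-999, base peak == 999
    cas: str = ""
    ri: float | None = None
    rt: float | None = None         # seconds
    derivatized: bool = False       # TMS flag
    compound_class: str = ""
    mw: float | None = None
    logkow: float | None = None

    def __post_init__(self):
        self.mz = np.asarray(self.mz, dtype=np.float64)
        self.rel_intensity = np.asarray(self.rel_intensity, dtype=np.float64)
        if self.mz.size == 0:
            raise ValidationError(f"entry {self.name!r}: spectrum must be non-empty")
        if self.mz.shape != self.rel_intensity.shape:
            raise ValidationError(f"entry {self.name!r}: mz/intensity length mismatch")
        if np.any(np.diff(self.mz) <= 0):
            raise ValidationError(f"entry {self.name!r}: m/z must be strictly ascending")
        if np.any(self.rel_intensity <= 0):
            raise ValidationError(f"entry {self.name!r}: intensities must be positive")
        if abs(self.rel_intensity.max() - 999.0) > 1e-6:
            raise ValidationError(f"entry {self.name!r}: base peak must be normalized to 999")

    @property
    def searchable(self) -> bool:
        return self.ri is not None or self.rt is not None

    def __eq__(self, other):
        if not isinstance(other, LibraryEntry):
            return NotImplemented
        return (
            self.name == other.name
            and self.cas == other.cas
            and _opt_eq(self.ri, other.ri)
            and _opt_eq(self.rt, other.rt)
            and self.derivatized == other.derivatized
            and self.compound_class == other.compound_class
            and _opt_eq(self.mw, other.mw)
            and _opt_eq(self.logkow, other.logkow)
            and np.array_equal(self.mz, other.mz)
            and np.array_equal(self.rel_intensity, other.rel_intensity)
        )


def _opt_eq(a, b, tol=1e-9):
    if a is None or b is None:
        return a is b
    return abs(a - b) <= tol


def normalize_spectrum(mz, intensity) -> tuple[np.ndarray, np.ndarray]:
    """Sort by m/z and scale to base peak 999."""
    mz = np.asarray(mz, dtype=np.float64)
    intensity = np.asarray(intensity, dtype=np.float64)
    order = np.argsort(mz, kind="stable")
    mz, intensity = mz[order], intensity[order]
    return mz, intensity * (999.0 / intensity.max())


@dataclass
class SpectralLibrary:
    """A set of library entries with unique names."""

    entries: list[LibraryEntry]
    source: str = ""

    def __post_init__(self):
        names = [e.name for e in self.entries]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ValidationError(f"duplicate entry names in library: {dupes}")

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def get(self, name: str) -> LibraryEntry:
        for e in self.entries:
            if e.name == name:
                return e
        raise KeyError(name)

    @property
    def names(self) -> list[str]:
        return [e.name for e in self.entries]


# ---------------------------------------------------------------------------
# MSP I/O

_HEADER_KEYS = {"name", "casno", "ri", "rt", "mw", "comments", "num peaks",
                "compound_class", "logkow"}


def read_msp(path) -> SpectralLibrary:
    """Parse an MSP-dialect library file."""
    path = Path(path)
    with open(path) as fh:
        lines = fh.readlines()
    entries: list[LibraryEntry] = []
    i = 0
    n = len(lines)
    while i < n:
        if not lines[i].strip():
            i += 1
            continue
        fields: dict[str, str] = {}
        start_line = i + 1
        while i < n and lines[i].strip():
            line = lines[i].rstrip("\n")
            key, sep, value = line.partition(":")
            if not sep or key.strip().lower() not in _HEADER_KEYS:
                break
            fields[key.strip().lower()] = value.strip()
            i += 1
            if key.strip().lower() == "num peaks":
                break
        if "name" not in fields:
            raise ParseError("entry without Name: field", line=start_line)
        if "num peaks" not in fields:
            raise ParseError(f"entry {fields['name']!r} lacks 'Num Peaks:'", line=start_line)
        try:
            npk = int(fields["num peaks"])
        except ValueError:
            raise ParseError(f"bad Num Peaks value {fields['num peaks']!r}", line=i)
        if npk < 1:
            raise ParseError(f"entry {fields['name']!r} declares {npk} peaks", line=i)
        toks: list[str] = []
        while i < n and lines[i].strip() and len(toks) < 2 * npk:
            toks.extend(lines[i].replace(";", " ").split())
            i += 1
        if len(toks) % 2 != 0 or len(toks) // 2 != npk:
            raise ParseError(
                f"entry {fields['name']!r}: Num Peaks={npk} but found {len(toks) // 2} pairs",
                line=i,
            )
        try:
            vals = [float(v) for v in toks]
        except ValueError:
            raise ParseError(f"entry {fields['name']!r}: non-numeric peak data", line=i)
        mz = np.array(vals[0::2])
        inten = np.array(vals[1::2])
        order = np.argsort(mz, kind="stable")
        mz, inten = mz[order], inten[order]
        import shlex

        comments = dict(
            kv.partition("=")[::2]
            for kv in shlex.split(fields.get("comments", ""))
            if "=" in kv
        )
        entries.append(
            LibraryEntry(
                name=fields["name"],
                cas=fields.get("casno", ""),
                ri=float(fields["ri"]) if "ri" in fields else None,
                rt=float(fields["rt"]) if "rt" in fields else None,
                mw=float(fields["mw"]) if "mw" in fields else None,
                derivatized=comments.get("derivatized", "").upper() == "TMS",
                compound_class=comments.get("class", fields.get("compound_class", "")),
                logkow=float(comments["logkow"]) if "logkow" in comments else None,
                mz=mz,
                rel_intensity=inten,
            )
        )
    return SpectralLibrary(entries=entries, source=str(path))


def write_msp(lib: SpectralLibrary, path) -> None:
    """Write a library in the MSP dialect (normalizing intensities to 1-999)."""
    with open(Path(path), "w") as fh:
        for e in lib.entries:
            fh.write(f"Name: {e.name}\n")
            if e.cas:
                fh.write(f"CASNO: {e.cas}\n")
            if e.ri is not None:
                fh.write(f"RI: {e.ri:g}\n")
            if e.rt is not None:
                fh.write(f"RT: {e.rt:g}\n")
            if e.mw is not None:
                fh.write(f"MW: {e.mw:g}\n")
            comments = []
            if e.derivatized:
                comments.append("derivatized=TMS")
            if e.compound_class:
                cc = e.compound_class
                comments.append(f'class="{cc}"' if " " in cc else f"class={cc}")
            if e.logkow is not None:
                comments.append(f"logkow={e.logkow:g}")
            if comments:
                fh.write("Comments: " + " ".join(comments) + "\n")
            mz, rel = normalize_spectrum(e.mz, e.rel_intensity)
            ints = np.maximum(1, np.rint(rel).astype(int))
            fh.write(f"Num Peaks: {mz.size}\n")
            for m, v in zip(mz, ints):
                fh.write(f"{m:.4f} {v}\n")
            fh.write("\n")


# ---------------------------------------------------------------------------
# entry building from standard runs


def build_entry_from_run(
    run,
    expected_rt: float,
    calib: AlkaneCalibration,
    name: str,
    deconv_params=None,
    rt_tolerance: float = 15.0,
    ambiguity_ratio: float = 0.5,
    cas: str = "",
    derivatized: bool = False,
    centroid_min_points: int = 2,
    centroid_snr_floor: float = 0.0,
) -> LibraryEntry:
    """Build a library entry from a single-standard injection.

    The run is deconvoluted; the dominant component within ``rt_tolerance``
    seconds of ``expected_rt`` becomes the entry's spectrum, its apex RT the
    entry RT and its Kovats index the entry RI.  A second component whose base
    area is within ``ambiguity_ratio`` of the dominant one raises
    :class:`AmbiguityError`.
    """
    from .deconv import DeconvParams, component_spectrum, deconvolute
    from .msdata import centroid_run, extract_eics

    params = deconv_params or DeconvParams()
    crun = centroid_run(run, min_points=centroid_min_points, snr_floor=centroid_snr_floor)
    eics = extract_eics(crun, mz_delta=params.mz_delta)
    comps = deconvolute(eics, crun.scan_period, params)
    near = [c for c in comps if abs(c.apex_rt - expected_rt) <= rt_tolerance]
    if not near:
        raise NotFoundError(
            f"no component within +/-{rt_tolerance:g}s of rt={expected_rt:g}s for {name!r}"
        )
    near.sort(key=lambda c: -c.base_area)
    if len(near) > 1 and near[1].base_area >= ambiguity_ratio * near[0].base_area:
        raise AmbiguityError(
            f"{len(near)} comparable components near rt={expected_rt:g}s for {name!r}",
            candidates=[(c.apex_rt, c.base_area) for c in near],
        )
    best = near[0]
    spec = component_spectrum(best)
    return LibraryEntry(
        name=name,
        cas=cas,
        mz=spec.mz,
        rel_intensity=spec.intensity,
        rt=best.apex_rt,
        ri=float(rt_to_ri(best.apex_rt, calib)),
        derivatized=derivatized,
    )


# ---------------------------------------------------------------------------
# RT-library migration (linear correction + RI conversion)


@dataclass
class MigrationFit:
    """Diagnostics of the anchor regression rt_exp = a * rt_lib + b."""

    a: float
    b: float
    r_squared: float
    residuals: np.ndarray
    anchor_names: list[str]
    anchor_rt_lib: np.ndarray

    @property
    def se_a(self) -> float:
        """Standard error of the slope (0 when the fit is exact or n == 2)."""
        x = self.anchor_rt_lib
        n = x.size
        if n <= 2:
            return 0.0
        s2 = float((self.residuals ** 2).sum() / (n - 2))
        sxx = float(((x - x.mean()) ** 2).sum())
        return float(np.sqrt(s2 / sxx)) if sxx > 0 else 0.0

    @property
    def se_b(self) -> float:
        x = self.anchor_rt_lib
        n = x.size
        if n <= 2:
            return 0.0
        s2 = float((self.residuals ** 2).sum() / (n - 2))
        sxx = float(((x - x.mean()) ** 2).sum())
        return float(np.sqrt(s2 * (1.0 / n + x.mean() ** 2 / sxx))) if sxx > 0 else 0.0


def migrate_rt_library(
    lib: SpectralLibrary,
    anchors: list[tuple[str, float, float]],
    calib: AlkaneCalibration,
) -> tuple[SpectralLibrary, MigrationFit]:
    """Update an RT-annotated library onto the local RT scale and convert to RI.

    ``anchors`` are (name, rt_lib, rt_exp) triples for compounds present in
    the library; an ordinary least-squares line rt_exp = a*rt_lib + b is
    fitted, every entry's RT is corrected through it, and the corrected RT is
    converted to a Kovats RI through ``calib``.  The correction is exact
    (zero residuals) whenever the anchors are exactly affine.
    """
    if len(anchors) < 2:
        raise ValidationError("RT-library migration needs at least 2 anchors")
    names = [a[0] for a in anchors]
    missing = [nm for nm in names if nm not in lib.names]
    if missing:
        raise ValidationError(f"anchor names not in library: {missing}")
    x = np.array([a[1] for a in anchors], dtype=np.float64)
    y = np.array([a[2] for a in anchors], dtype=np.float64)
    a_fit, b_fit = np.polyfit(x, y, 1)
    pred = a_fit * x + b_fit
    resid = y - pred
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - float((resid ** 2).sum()) / ss_tot if ss_tot > 0 else 1.0
    fit = MigrationFit(a=float(a_fit), b=float(b_fit), r_squared=r2,
                       residuals=resid, anchor_names=names, anchor_rt_lib=x)

    migrated = []
    for e in lib.entries:
        if e.rt is None:
            migrated.append(replace(e))
            continue
        rt_corr = float(a_fit * e.rt + b_fit)
        migrated.append(replace(e, rt=rt_corr, ri=float(rt_to_ri(rt_corr, calib))))
    return SpectralLibrary(entries=migrated, source=lib.source), fit


def load_anchor_table(path) -> list[tuple[str, float, float]]:
    """Read an anchor CSV with header ``name,rt_lib,rt_exp`` (seconds)."""
    import pandas as pd

    df = pd.read_csv(path)
    for col in ("name", "rt_lib", "rt_exp"):
        if col not in df.columns:
            raise ValidationError(f"anchor table {path} must have columns name,rt_lib,rt_exp")
    return [(str(r["name"]), float(r["rt_lib"]), float(r["rt_exp"])) for _, r in df.iterrows()]
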
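"""Synthetic GC-EI-HRMS data with known ground truth.

The generator emulates a GC-QTOF acquisition: 5 spectra/s over m/z 40-1000,
profile peaks whose width follows a resolution model interpolated between
(68 Da, R 5700) and (502 Da, R 8400), Gaussian or exponentially-modified
(tailing) chromatographic peaks of ~3 s FWHM, systematic plus random ppm
mass errors, spectrally rich and poor compounds, co-elution and a
matrix background.  Every generator is deterministic under its seed.

The matrix background has two deliberately adversarial ingredients:

* "analog" components — isomer-like features that carry a (non-spiked)
  library entry's full fragment set with perturbed intensities plus extra
  ions of their own.  A reverse search, which ignores query-only ions, scores
  them like the real compound; a forward search penalizes the extra ions.
  These drive the false-positive side of the pure-weight-factor trade-off.
* co-eluting contaminants — small random-ion features riding on top of
  analyte peaks at fixed absolute intensity.  At low spike levels they
  contaminate the deconvoluted spectra and depress forward scores, driving
  the false-negative side.

Neither claims to replicate mussel-extract chemistry; they reproduce the
mechanisms that make forward/reverse weighting a real trade-off.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy.stats import exponnorm, norm

from .errors import ValidationError
from .evalopt import TruthTable
from .msdata import ProfileSpectrum, Run
from .rical import AlkaneCalibration, ri_to_rt
from .speclib import LibraryEntry, SpectralLibrary

__all__ = [
    "SimConfig",
    "MatrixProfile",
    "PlantedCompound",
    "GroundTruth",
    "Experiment",
    "default_calibration",
    "simulate_library",
    "simulate_run",
    "simulate_alkane_run",
    "make_screening_experiment",
]

_FWHM_TO_SIGMA = 1.0 / (2.0 * math.sqrt(2.0 * math.log(2.0)))
BLEED_IONS = ((207.0323, 1.0), (281.0511, 0.6))  # siloxane-like column bleed


@dataclass(frozen=True)
class SimConfig:
    """Acquisition and error model for the simulator.

    seed            master seed; fixes all randomness of a call.
    scan_rate       spectra per second (5 Hz).
    mz_range        acquisition range in Da.
    resolution_points  (m/z, FWHM resolution) anchors; R(m) is linear between
                    them and flat outside.
    peak_fwhm_s     chromatographic peak FWHM in seconds.
    tailing_tau_s   exponential tail time constant (0 = pure Gaussian).
    ppm_bias        systematic mass error applied to every ion.
    ppm_sigma       per-scan random mass error (1 sigma, ppm).
    noise_floor     per-profile-point additive noise sigma in counts.
    base_area       area (counts*s) of a level-1.0 base ion.
    bleed_level     constant column-bleed ion intensity in counts (0 = off).
    profile_spacing profile grid spacing as a fraction of the profile FWHM.
    profile_extent_fwhm  half-extent of each profile peak in FWHM units.
    rt_margin_s     quiet time simulated before/after the outermost peaks.
    """

    seed: int = 0
    scan_rate: float = 5.0
    mz_range: tuple[float, float] = (40.0, 1000.0)
    resolution_points: tuple[tuple[float, float], ...] = ((68.0, 5700.0), (502.0, 8400.0))
    peak_fwhm_s: float = 3.0
    tailing_tau_s: float = 0.0
    ppm_bias: float = 0.0
    ppm_sigma: float = 0.0
    noise_floor: float = 0.0
    base_area: float = 2.0e5
    bleed_level: float = 0.0
    profile_spacing: float = 0.25
    profile_extent_fwhm: float = 1.5
    rt_margin_s: float = 25.0

    def resolution(self, mz: float) -> float:
        pts = self.resolution_points
        ms = np.array([p[0] for p in pts])
        rs = np.array([p[1] for p in pts])
        return float(np.interp(mz, ms, rs))

    def profile_fwhm(self, mz: float) -> float:
        return mz / self.resolution(mz)


@dataclass
class PlantedCompound:
    """One compound (analyte or matrix feature) planted into a run."""

    name: str
    rt: float
    mz: np.ndarray
    rel: np.ndarray            # per-ion relative abundance, base ion largest
    base_area: float           # area (counts*s) of the base ion at level 1
    level: float = 1.0
    is_matrix: bool = False
    tailing_tau_s: float = 0.0

    def ion_areas(self) -> np.ndarray:
        return self.base_area * self.level * self.rel / self.rel.max()


@dataclass
class GroundTruth:
    """Everything a planted run contains, for evaluation."""

    planted: list[PlantedCompound]
    seed: int
    sample_id: str = ""

    @property
    def analytes(self) -> list[PlantedCompound]:
        return [p for p in self.planted if not p.is_matrix]


def default_calibration(
    carbon_range: tuple[int, int] = (7, 40),
    t0: float = 60.0,
    seconds_per_carbon: float = 36.0,
) -> AlkaneCalibration:
    """A linear alkane elution schedule (affine RT<->RI map)."""
    lo, hi = carbon_range
    carbon = np.arange(lo, hi + 1)
    return AlkaneCalibration(carbon=carbon, rt=t0 + seconds_per_carbon * (carbon - lo))


# ---------------------------------------------------------------------------
# library simulation

_CLASSES = ("plasticizer", "PAH", "fragrance", "pesticide", "UV filter",
            "organophosphate", "industrial", "pharmaceutical")


def simulate_library(
    n_compounds: int,
    seed: int,
    richness_range: tuple[int, int] = (3, 25),
    ri_range: tuple[float, float] = (1000.0, 2600.0),
    rel_range: tuple[int, int] = (10, 999),
    mz_span: tuple[float, float] = (45.0, 480.0),
    derivatized_fraction: float = 0.2,
) -> SpectralLibrary:
    """Draw a deterministic accurate-mass EI library.

    Entries carry 3-40 ions with base peak 999, fragment masses with
    CHNOClBrS-plausible mass defects, and Kovats RIs laid out on a jittered
    grid across ``ri_range`` so that compounds do not accidentally co-elute.
    """
    if n_compounds < 1:
        raise ValidationError("n_compounds must be >= 1")
    rng = np.random.default_rng(seed)
    lo_r, hi_r = richness_range
    ri_grid = np.linspace(ri_range[0], ri_range[1], n_compounds)
    if n_compounds > 1:
        step = (ri_range[1] - ri_range[0]) / (n_compounds - 1)
        ri_grid = ri_grid + rng.uniform(-0.25, 0.25, n_compounds) * step
    entries = []
    for k in range(n_compounds):
        n_ions = int(rng.integers(lo_r, hi_r + 1))
        nominal = rng.choice(
            np.arange(int(mz_span[0]), int(mz_span[1])), size=n_ions, replace=False
        )
        defect = nominal * rng.uniform(-0.0002, 0.0008, n_ions)
        mz = np.round(np.sort(nominal + defect), 4)
        rel = rng.integers(rel_range[0], min(rel_range[1], 998) + 1, n_ions).astype(float)
        rel[int(rng.integers(0, n_ions))] = 999.0
        derivatized = bool(rng.random() < derivatized_fraction)
        name = f"Simulated compound {k + 1:03d}" + (", TMS" if derivatized else "")
        entries.append(
            LibraryEntry(
                name=name,
                cas=f"{100000 + k}-00-{k % 10}",
                mz=mz,
                rel_intensity=rel,
                ri=float(np.round(ri_grid[k], 1)),
                derivatized=derivatized,
                compound_class=_CLASSES[int(rng.integers(0, len(_CLASSES)))],
                mw=float(np.round(mz[-1] + rng.integers(0, 80), 1)),
            )
        )
    return SpectralLibrary(entries=entries, source=f"simulated(seed={seed})")


# ---------------------------------------------------------------------------
# run simulation


def _chromatogram(times: np.ndarray, rt: float, area: float, sigma: float,
                  tau: float) -> np.ndarray:
    if tau > 0:
        return area * exponnorm.pdf(times, tau / sigma, loc=rt, scale=sigma)
    return area * norm.pdf(times, loc=rt, scale=sigma)


def simulate_run(
    planted: list[PlantedCompound],
    config: SimConfig,
    seed: int | None = None,
    run_window: tuple[float, float] | None = None,
    sample_id: str = "sim",
) -> tuple[Run, GroundTruth]:
    """Render planted compounds into a profile-mode run.

    Each ion of each compound contributes a chromatographic peak (Gaussian,
    or exponentially modified when the compound's ``tailing_tau_s`` > 0)
    sampled on the scan grid; each scan's sticks are rendered as profile
    peaks with resolution-model widths and per-scan mass errors
    ``ppm_bias + N(0, ppm_sigma)``.
    """
    if not planted:
        raise ValidationError("nothing to simulate")
    seed = config.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    sigma_chrom = config.peak_fwhm_s * _FWHM_TO_SIGMA

    if run_window is None:
        rts = [p.rt for p in planted]
        run_window = (min(rts) - config.rt_margin_s, max(rts) + config.rt_margin_s)
    t_lo, t_hi = run_window
    if any(not (t_lo <= p.rt <= t_hi) for p in planted):
        raise ValidationError("planted retention time outside the run window")
    period = 1.0 / config.scan_rate
    n_scans = int(math.floor((t_hi - t_lo) / period)) + 1
    times = t_lo + period * np.arange(n_scans)

    sticks_mz: list[list[float]] = [[] for _ in range(n_scans)]
    sticks_int: list[list[float]] = [[] for _ in range(n_scans)]
    for comp in planted:
        tau = comp.tailing_tau_s
        extent = 4.0 * sigma_chrom + 8.0 * tau
        i0 = max(0, int(math.ceil((comp.rt - extent - t_lo) / period)))
        i1 = min(n_scans, int(math.floor((comp.rt + extent - t_lo) / period)) + 1)
        if i1 <= i0:
            continue
        tt = times[i0:i1]
        areas = comp.ion_areas()
        for mz, area in zip(comp.mz, areas):
            c = _chromatogram(tt, comp.rt, area, sigma_chrom, tau)
            ppm = config.ppm_bias + (
                rng.normal(0.0, config.ppm_sigma, c.size) if config.ppm_sigma > 0 else 0.0
            )
            mz_obs = mz * (1.0 + ppm * 1e-6)
            for k in range(c.size):
                if c[k] > 1e-6:
                    sticks_mz[i0 + k].append(float(mz_obs[k]) if np.ndim(mz_obs) else float(mz_obs))
                    sticks_int[i0 + k].append(float(c[k]))

    if config.bleed_level > 0:
        for si in range(n_scans):
            for bmz, brel in BLEED_IONS:
                lvl = config.bleed_level * brel * (1.0 + 0.02 * rng.standard_normal())
                if lvl > 0:
                    sticks_mz[si].append(bmz)
                    sticks_int[si].append(float(lvl))

    scans = []
    for si in range(n_scans):
        mz_arr, int_arr = _render_profile(
            np.array(sticks_mz[si]), np.array(sticks_int[si]), config, rng
        )
        scans.append(ProfileSpectrum(rt=float(times[si]), mz=mz_arr, intensity=int_arr))
    run = Run(
        scans=scans,
        mz_range=config.mz_range,
        metadata={"sample_id": sample_id, "acquisition_mode": "profile",
                  "sim_seed": str(seed)},
    )
    return run, GroundTruth(planted=list(planted), seed=seed, sample_id=sample_id)


def _render_profile(mzs: np.ndarray, intens: np.ndarray, config: SimConfig,
                    rng: np.random.Generator):
    """Render stick ions of one scan as continuum profile points.

    Nearby sticks share one uniform m/z grid so overlapping profiles sum
    instead of interleaving.
    """
    if mzs.size == 0:
        return np.empty(0), np.empty(0)
    order = np.argsort(mzs, kind="stable")
    mzs, intens = mzs[order], intens[order]
    fw = np.array([config.profile_fwhm(m) for m in mzs])
    half = config.profile_extent_fwhm * fw
    out_mz: list[np.ndarray] = []
    out_int: list[np.ndarray] = []
    i = 0
    n = mzs.size
    while i < n:
        j = i
        while j + 1 < n and mzs[j + 1] - half[j + 1] <= mzs[j] + half[j]:
            j += 1
        lo = mzs[i] - half[i]
        hi = mzs[j] + half[j]
        spacing = fw[i:j + 1].min() * config.profile_spacing
        grid = lo + spacing * np.arange(int(math.ceil((hi - lo) / spacing)) + 1)
        y = np.zeros_like(grid)
        for k in range(i, j + 1):
            y += intens[k] * np.exp(-4.0 * math.log(2.0) * ((grid - mzs[k]) / fw[k]) ** 2)
        if config.noise_floor > 0:
            y = y + rng.normal(0.0, config.noise_floor, y.size)
            np.clip(y, 0.0, None, out=y)
        keep = y > 0
        out_mz.append(grid[keep])
        out_int.append(y[keep])
        i = j + 1
    mz_all = np.concatenate(out_mz)
    int_all = np.concatenate(out_int)
    # grids of distinct clusters never overlap, but guard the invariant anyway
    d = np.diff(mz_all)
    if np.any(d <= 0):
        keep = np.concatenate(([True], d > 0))
        mz_all, int_all = mz_all[keep], int_all[keep]
    lo, hi = config.mz_range
    keep = (mz_all >= lo) & (mz_all <= hi)
    return mz_all[keep], int_all[keep]


# ---------------------------------------------------------------------------
# alkane calibration runs

ALKANE_IONS = np.array([57.0699, 71.0855, 85.1012, 99.1168])
ALKANE_REL = np.array([999.0, 650.0, 350.0, 180.0])


def simulate_alkane_run(
    carbon_range: tuple[int, int] = (7, 40),
    rt_schedule=None,
    config: SimConfig | None = None,
    base_area: float = 5.0e5,
) -> tuple[Run, AlkaneCalibration, GroundTruth]:
    """Simulate an n-alkane standard injection and its CRT calibration.

    ``rt_schedule`` maps carbon number -> seconds (callable or dict); the
    default is the linear schedule of :func:`default_calibration`.  The
    emitted calibration is the schedule itself; re-deriving it by running the
    detection pipeline on the returned run recovers each alkane retention
    time to within one scan period.
    """
    config = config or SimConfig()
    lo, hi = carbon_range
    carbons = list(range(lo, hi + 1))
    if rt_schedule is None:
        cal = default_calibration((lo, hi))
        rts = {int(c): float(t) for c, t in zip(cal.carbon, cal.rt)}
    elif callable(rt_schedule):
        rts = {c: float(rt_schedule(c)) for c in carbons}
    else:
        rts = {int(c): float(t) for c, t in dict(rt_schedule).items()}
        carbons = sorted(rts)
    rt_list = [rts[c] for c in carbons]
    if any(b <= a for a, b in zip(rt_list, rt_list[1:])):
        raise ValidationError("alkane rt schedule must be strictly increasing in carbon number")
    planted = [
        PlantedCompound(
            name=f"C{c}", rt=rts[c], mz=ALKANE_IONS.copy(), rel=ALKANE_REL.copy(),
            base_area=base_area,
        )
        for c in carbons
    ]
    run, gt = simulate_run(planted, config, sample_id=f"alkanes-C{lo}-C{hi}")
    calib = AlkaneCalibration(carbon=np.array(carbons), rt=np.array(rt_list))
    return run, calib, gt


# ---------------------------------------------------------------------------
# spiked-replicate screening experiments


@dataclass(frozen=True)
class MatrixProfile:
    """Composition of the shared matrix background of an experiment.

    n_analogs           isomer-like matrix features derived from non-spiked
                        library entries (reverse-search FP drivers).
    analog_perturb_sigma    lognormal sigma perturbing the parent intensities.
    analog_extra_ions   (lo, hi) count of extra own ions per analog.
    analog_extra_rel    (lo, hi) relative abundance of the extra ions.
    analog_base_area    base-ion area of an analog (level-independent).
    coelute_prob        probability that an analyte carries a co-eluting
                        contaminant (forward-search FN drivers at low level).
    coelute_ions        (lo, hi) ion count of a contaminant.
    coelute_area        per-ion area scale of a contaminant (counts*s,
                        level-independent).
    intensity_jitter    per-replicate lognormal sigma on every ion area.
    bleed_level         column-bleed intensity passed to the run config.
    """

    n_analogs: int = 12
    analog_perturb_sigma: float = 0.15
    analog_extra_ions: tuple[int, int] = (4, 8)
    analog_extra_rel: tuple[float, float] = (300.0, 900.0)
    analog_base_area: float = 3.0e5
    coelute_prob: float = 0.6
    coelute_ions: tuple[int, int] = (3, 6)
    coelute_area: float = 5.0e4
    intensity_jitter: float = 0.35
    bleed_level: float = 2000.0


@dataclass
class Experiment:
    """A full spiked-replicate screening experiment with ground truth."""

    runs: dict[str, Run]
    truth: TruthTable
    ground_truth: dict[str, GroundTruth]
    calib: AlkaneCalibration
    library: SpectralLibrary
    levels: list[tuple[str, float]]      # (label, multiplier), low -> high
    replicates: int

    @property
    def sample_ids(self) -> list[str]:
        return sorted(self.runs)

    def samples_at_level(self, label: str) -> list[str]:
        return [s for s in self.sample_ids if self.truth.levels.get(s) == label]


def standard_benchmark(seed: int = 42, replicates: int = 5) -> Experiment:
    """The package's standard synthetic screening benchmark.

    26 spiked compounds out of a 60-entry library, two concentration levels
    (50 and 500 ng/mL-equivalent, 1x and 10x), five replicates each, shared
    mussel-extract-style matrix background (analog features, co-eluting
    contaminants, column bleed), 5 ppm per-scan mass error and 30-count
    profile noise.
    """
    lib = simulate_library(60, seed=seed)
    calib = default_calibration()
    return make_screening_experiment(
        lib, lib.names[:26], calib, replicates=replicates, seed=seed
    )


def make_screening_experiment(
    library: SpectralLibrary,
    spiked_names: list[str],
    calib: AlkaneCalibration,
    levels: list[tuple[str, float]] = (("50ngml", 1.0), ("500ngml", 10.0)),
    replicates: int = 5,
    matrix: MatrixProfile | None = None,
    config: SimConfig | None = None,
    seed: int = 0,
) -> Experiment:
    """Build a levels x replicates spiked experiment over a shared matrix.

    The matrix profile (analog features, co-eluting contaminants, bleed) is
    drawn once and shared by every run; per-replicate draws cover intensity
    jitter and mass errors.  Deterministic under ``seed``.
    """
    levels = list(levels)
    if not levels:
        raise ValidationError("levels must be non-empty")
    matrix = matrix or MatrixProfile()
    config = config or SimConfig(ppm_sigma=5.0, noise_floor=30.0)
    config = replace(config, bleed_level=matrix.bleed_level)
    rng = np.random.default_rng(seed)

    spiked = [library.get(n) for n in spiked_names]
    spiked_rts = {e.name: float(ri_to_rt(e.ri, calib)) for e in spiked}
    rt_values = sorted(spiked_rts.values())
    t_lo, t_hi = rt_values[0], rt_values[-1]

    # --- shared matrix profile ----------------------------------------
    non_spiked = [e for e in library.entries if e.name not in set(spiked_names)]
    n_analogs = min(matrix.n_analogs, len(non_spiked))
    parents = list(rng.choice(len(non_spiked), size=n_analogs, replace=False))
    analogs: list[PlantedCompound] = []
    matrix_rts: list[float] = []
    # matrix features live anywhere in the run, >= 4 s from every analyte
    # (so they deconvolute as their own components) and >= 2 s apart
    place_lo = t_lo - config.rt_margin_s + 6.0
    place_hi = t_hi + config.rt_margin_s - 6.0

    def _free_rt() -> float:
        for _ in range(500):
            rt = float(rng.uniform(place_lo, place_hi))
            if all(abs(rt - t) > 4.0 for t in rt_values) and all(
                abs(rt - t) > 2.0 for t in matrix_rts
            ):
                matrix_rts.append(rt)
                return rt
        raise ValidationError("could not place a matrix feature away from the analytes")

    for ai in parents:
        parent = non_spiked[ai]
        rel = parent.rel_intensity * np.exp(
            rng.normal(0.0, matrix.analog_perturb_sigma, parent.mz.size)
        )
        n_extra = int(rng.integers(*matrix.analog_extra_ions, endpoint=True))
        extra_mz = []
        while len(extra_mz) < n_extra:
            m = float(rng.uniform(45.0, 480.0))
            if np.min(np.abs(parent.mz - m)) > 0.2:
                extra_mz.append(round(m, 4))
        extra_rel = rng.uniform(*matrix.analog_extra_rel, n_extra)
        mz = np.concatenate([parent.mz, extra_mz])
        rel = np.concatenate([rel, extra_rel])
        order = np.argsort(mz)
        analogs.append(
            PlantedCompound(
                name=f"matrix analog of {parent.name}",
                rt=_free_rt(),
                mz=mz[order],
                rel=rel[order],
                base_area=matrix.analog_base_area,
                is_matrix=True,
            )
        )

    coelutes: list[PlantedCompound] = []
    for e in spiked:
        if rng.random() >= matrix.coelute_prob:
            continue
        n_ions = int(rng.integers(*matrix.coelute_ions, endpoint=True))
        mz = np.sort(np.round(rng.uniform(45.0, 480.0, n_ions), 4))
        rel = rng.uniform(0.4, 1.0, n_ions)
        coelutes.append(
            PlantedCompound(
                name=f"matrix co-eluting with {e.name}",
                rt=spiked_rts[e.name] + float(rng.uniform(-0.08, 0.08)),
                mz=mz,
                rel=rel,
                base_area=matrix.coelute_area,
                is_matrix=True,
            )
        )

    # --- per-run rendering --------------------------------------------
    runs: dict[str, Run] = {}
    gts: dict[str, GroundTruth] = {}
    truth = TruthTable()
    run_window = (t_lo - config.rt_margin_s, t_hi + config.rt_margin_s)
    for label, mult in levels:
        for rep in range(1, replicates + 1):
            sid = f"{label}-r{rep}"
            rep_seed = int(rng.integers(0, 2**31 - 1))
            rep_rng = np.random.default_rng(rep_seed)
            planted: list[PlantedCompound] = []
            for e in spiked:
                jitter = np.exp(rep_rng.normal(0.0, matrix.intensity_jitter, e.mz.size))
                planted.append(
                    PlantedCompound(
                        name=e.name,
                        rt=spiked_rts[e.name],
                        mz=e.mz.copy(),
                        rel=e.rel_intensity * jitter,
                        base_area=config.base_area * (e.rel_intensity * jitter).max() / 999.0,
                        level=mult,
                    )
                )
            for m in analogs + coelutes:
                jitter = np.exp(rep_rng.normal(0.0, matrix.intensity_jitter, m.mz.size))
                planted.append(
                    replace(m, rel=m.rel * jitter,
                            base_area=m.base_area * (m.rel * jitter).max() / m.rel.max())
                )
            run, gt = simulate_run(
                planted, config, seed=rep_seed, run_window=run_window, sample_id=sid
            )
            runs[sid] = run
            gts[sid] = gt
            for e in spiked:
                truth.add(sid, e.name, label)
    return Experiment(
        runs=runs, truth=truth, ground_truth=gts, calib=calib, library=library,
        levels=levels, replicates=replicates,
    )
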
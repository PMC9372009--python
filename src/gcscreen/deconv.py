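"""Chromatographic peak detection and spectral deconvolution.

EIC traces are smoothed, local maxima are integrated valley-to-valley, and
peaks from different mass traces that co-maximize with the same shape are
grouped into deconvoluted components.  The component's ion list, normalized
to the classic EI base-peak convention (base ion = 999), is what gets scored
against the spectral library.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks, savgol_filter

from .errors import ValidationError
from .msdata import EIC, CentroidSpectrum

__all__ = [
    "DeconvParams",
    "ChromPeak",
    "Component",
    "detect_peaks",
    "build_components",
    "filter_components",
    "component_spectrum",
    "deconvolute",
    "components_to_csv",
]

_SHAPE_LEN = 25  # fixed-length shape vector: apex +/- 12 scans


@dataclass(frozen=True)
class DeconvParams:
    """Deconvolution settings.

    mz_delta
        Full EIC trace window in Da (two member peaks of one trace differ by
        at most this much).
    min_area
        Absolute-area threshold in counts*s; chromatographic peaks below it
        are discarded.
    rt_window_size_factor
        Component grouping window as a percentage of the scan period:
        dt = factor * scan_period / 100 (factor 100 at 5 Hz is 0.2 s).
    min_ion_peaks
        Minimum number of ions a component must retain to survive filtering.
    max_shapes_stored
        Cap on per-component peak shapes kept for correlation bookkeeping.
    shape_corr_min
        Minimum Pearson correlation between a candidate peak's shape and the
        component seed's model shape.
    smooth_window
        Savitzky-Golay window (scans, odd) used before local-maximum search.
    """

    mz_delta: float = 0.05
    min_area: float = 10_000.0
    rt_window_size_factor: float = 100.0
    min_ion_peaks: int = 3
    max_shapes_stored: int = 10
    shape_corr_min: float = 0.9
    smooth_window: int = 7

    def __post_init__(self):
        if self.mz_delta <= 0 or self.min_area <= 0 or self.rt_window_size_factor <= 0:
            raise ValidationError("mz_delta, min_area and rt_window_size_factor must be positive")
        if self.min_ion_peaks < 1 or self.max_shapes_stored < 1:
            raise ValidationError("min_ion_peaks and max_shapes_stored must be >= 1")
        if not (0.0 <= self.shape_corr_min <= 1.0):
            raise ValidationError("shape_corr_min must lie in [0, 1]")


@dataclass(frozen=True)
class ChromPeak:
    """A single integrated chromatographic peak on one EIC."""

    eic_mz: float
    apex_rt: float
    start_rt: float
    end_rt: float
    height: float
    area: float
    shape: np.ndarray  # length _SHAPE_LEN, max == 1


@dataclass
class Component:
    """A deconvoluted feature: co-maximizing ions sharing one peak shape."""

    apex_rt: float
    ions: list[tuple[float, float]]  # (mz, abundance) sorted by mz
    base_area: float
    model_shape: np.ndarray
    shapes: list[np.ndarray] = field(default_factory=list)

    @property
    def n_ions(self) -> int:
        return len(self.ions)


def detect_peaks(eic: EIC, params: DeconvParams) -> list[ChromPeak]:
    """Find and integrate peaks on one EIC (valley-to-valley, trapezoidal)."""
    y = np.asarray(eic.intensities, dtype=np.float64)
    t = np.asarray(eic.rts, dtype=np.float64)
    if y.size < 5:
        raise ValidationError("detect_peaks needs an EIC with at least 5 points")
    win = min(params.smooth_window | 1, (y.size - 1) | 1)
    ys = savgol_filter(y, win, polyorder=min(2, win - 1)) if win >= 3 else y.copy()
    np.clip(ys, 0.0, None, out=ys)

    # local maxima on the smoothed trace; flat tops resolved at the plateau midpoint
    idx, props = find_peaks(ys, height=0.0, plateau_size=1)
    if idx.size == 0:
        return []
    apexes = ((props["left_edges"] + props["right_edges"]) // 2).astype(int)

    peaks: list[ChromPeak] = []
    for k, apex in enumerate(apexes):
        left_bound = apexes[k - 1] if k > 0 else 0
        right_bound = apexes[k + 1] if k + 1 < len(apexes) else y.size - 1
        start = left_bound + int(np.argmin(ys[left_bound:apex + 1])) if apex > left_bound else apex
        end = apex + int(np.argmin(ys[apex:right_bound + 1])) if right_bound > apex else apex
        # trim flat zero tails so start/end hug the peak
        while start < apex - 1 and y[start] <= 0 and y[start + 1] <= 0:
            start += 1
        while end > apex + 1 and y[end] <= 0 and y[end - 1] <= 0:
            end -= 1
        if not (start < apex < end):
            continue
        area = float(np.trapezoid(y[start:end + 1], t[start:end + 1]))
        if area < params.min_area:
            continue
        height = float(y[start:end + 1].max())
        if height <= 0:
            continue
        half = _SHAPE_LEN // 2
        shape = np.zeros(_SHAPE_LEN)
        lo = max(0, apex - half)
        hi = min(y.size, apex + half + 1)
        shape[half - (apex - lo):half + (hi - apex)] = y[lo:hi]
        m = shape.max()
        if m <= 0:
            continue
        shape = shape / m
        # measure the peak's own m/z from its scans (one trace can hold
        # near-isobaric ions of different compounds at different rts)
        peak_mz = eic.target_mz
        if eic.mz_trace is not None:
            seg_i = y[start:end + 1]
            seg_m = eic.mz_trace[start:end + 1]
            ok = np.isfinite(seg_m) & (seg_i > 0)
            if ok.any():
                peak_mz = float((seg_m[ok] * seg_i[ok]).sum() / seg_i[ok].sum())
        peaks.append(
            ChromPeak(
                eic_mz=peak_mz,
                apex_rt=float(t[apex]),
                start_rt=float(t[start]),
                end_rt=float(t[end]),
                height=height,
                area=area,
                shape=shape,
            )
        )
    return peaks


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    da = a - a.mean()
    db = b - b.mean()
    na = float(np.sqrt((da * da).sum()))
    nb = float(np.sqrt((db * db).sum()))
    if na == 0.0 or nb == 0.0:
        return 1.0 if np.array_equal(a, b) else 0.0
    return float((da * db).sum() / (na * nb))


def build_components(
    peaks: list[ChromPeak], scan_period: float, params: DeconvParams
) -> list[Component]:
    """Group co-maximizing peaks into components.

    Seeds are processed in decreasing height order; an unclustered peak joins
    the seed's component when its apex lies within
    dt = rt_window_size_factor * scan_period / 100 of the seed apex AND its
    shape correlates with the seed's model shape at >= shape_corr_min.
    Each peak joins at most one component.  Deterministic for fixed input.
    """
    dt = params.rt_window_size_factor * scan_period / 100.0
    order = sorted(peaks, key=lambda p: (-p.height, p.eic_mz, p.apex_rt))
    used = [False] * len(order)
    components: list[Component] = []
    for si, seed in enumerate(order):
        if used[si]:
            continue
        used[si] = True
        members = [seed]
        shapes = [seed.shape]
        for pi in range(si + 1, len(order)):
            if used[pi]:
                continue
            p = order[pi]
            if abs(p.apex_rt - seed.apex_rt) > dt + 1e-9:
                continue
            if _pearson(p.shape, seed.shape) < params.shape_corr_min:
                continue
            used[pi] = True
            members.append(p)
            if len(shapes) < params.max_shapes_stored:
                shapes.append(p.shape)
        ions = sorted((p.eic_mz, p.area) for p in members)
        components.append(
            Component(
                apex_rt=seed.apex_rt,
                ions=ions,
                base_area=max(p.area for p in members),
                model_shape=seed.shape,
                shapes=shapes,
            )
        )
    components.sort(key=lambda c: (c.apex_rt, -c.base_area))
    return components


def filter_components(components: list[Component], params: DeconvParams) -> list[Component]:
    """Drop components with fewer than ``min_ion_peaks`` ions."""
    return [c for c in components if c.n_ions >= params.min_ion_peaks]


def component_spectrum(c: Component) -> CentroidSpectrum:
    """Component ion list as an EI spectrum, base ion scaled to 999."""
    mz = np.array([m for m, _ in c.ions])
    ab = np.array([a for _, a in c.ions])
    scale = 999.0 / ab.max()
    return CentroidSpectrum(rt=c.apex_rt, mz=mz, intensity=ab * scale)


def deconvolute(eics: list[EIC], scan_period: float, params: DeconvParams) -> list[Component]:
    """detect_peaks -> build_components -> filter_components over all EICs."""
    peaks: list[ChromPeak] = []
    for eic in eics:
        if len(eic) < 5:
            continue
        peaks.extend(detect_peaks(eic, params))
    comps = build_components(peaks, scan_period, params)
    return filter_components(comps, params)


def components_to_csv(components: list[Component], path) -> None:
    """Serialize a component list (one row per ion)."""
    import pandas as pd

    rows = []
    for cid, c in enumerate(components):
        for mz, ab in c.ions:
            rows.append(
                {"component_id": cid, "apex_rt": c.apex_rt, "mz": mz,
                 "abundance": ab, "area": ab}
            )
    pd.DataFrame(rows, columns=["component_id", "apex_rt", "mz", "abundance", "area"]).to_csv(
        path, index=False
    )
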
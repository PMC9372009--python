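"""Kovats retention-index calibration from an n-alkane series.

Under a linear temperature program the retention index of an n-alkane with
carbon number n is defined as 100*n, and intermediate retention times map to
indices by linear interpolation between the bracketing alkanes (the van den
Dool-Kratz convention):

    RI(t) = 100*n + 100 * (t - t_n) / (t_{n+1} - t_n),   t_n <= t <= t_{n+1}

Outside the calibrated range the nearest bracket's slope is extrapolated and
the result is flagged.  The isothermal logarithmic form is available behind
``log_form=True`` for isothermal data.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ValidationError

__all__ = ["AlkaneCalibration", "load_crt", "write_crt", "rt_to_ri", "ri_to_rt"]


@dataclass(frozen=True)
class AlkaneCalibration:
    """Monotone (carbon number, retention time) table, C7-C40 in practice."""

    carbon: np.ndarray  # integer carbon numbers, strictly increasing
    rt: np.ndarray      # seconds, strictly increasing

    def __post_init__(self):
        carbon = np.asarray(self.carbon, dtype=np.int64)
        rt = np.asarray(self.rt, dtype=np.float64)
        object.__setattr__(self, "carbon", carbon)
        object.__setattr__(self, "rt", rt)
        if carbon.size != rt.size or carbon.size < 2:
            raise ValidationError("calibration needs >= 2 (carbon, rt) points of equal length")
        if np.any(np.diff(carbon) <= 0):
            raise ValidationError("carbon numbers must be strictly increasing (no duplicates)")
        if np.any(np.diff(rt) <= 0):
            raise ValidationError("alkane retention times must be strictly increasing")

    @property
    def ri(self) -> np.ndarray:
        return 100.0 * self.carbon

    def covers_rt(self, rt: float) -> bool:
        return self.rt[0] <= rt <= self.rt[-1]

    def covers_ri(self, ri: float) -> bool:
        return self.ri[0] <= ri <= self.ri[-1]


def _interp_extrap(x, xp, fp):
    """Piecewise-linear interpolation with end-segment extrapolation."""
    x = np.asarray(x, dtype=np.float64)
    scalar = x.ndim == 0
    x = np.atleast_1d(x)
    y = np.interp(x, xp, fp)
    lo = x < xp[0]
    hi = x > xp[-1]
    if lo.any():
        slope = (fp[1] - fp[0]) / (xp[1] - xp[0])
        y[lo] = fp[0] + slope * (x[lo] - xp[0])
    if hi.any():
        slope = (fp[-1] - fp[-2]) / (xp[-1] - xp[-2])
        y[hi] = fp[-1] + slope * (x[hi] - xp[-1])
    return float(y[0]) if scalar else y


def rt_to_ri(rt, calib: AlkaneCalibration, log_form: bool = False):
    """Retention time (s) -> retention index.  Accepts scalars or arrays.

    Queries outside [rt(C_first), rt(C_last)] are linearly extrapolated from
    the nearest bracket; use :meth:`AlkaneCalibration.covers_rt` to flag them.
    """
    if log_form:
        return _interp_extrap(np.log(rt), np.log(calib.rt), calib.ri)
    return _interp_extrap(rt, calib.rt, calib.ri)


def ri_to_rt(ri, calib: AlkaneCalibration, log_form: bool = False):
    """Retention index -> retention time (s); exact inverse of rt_to_ri on the
    calibrated range."""
    if log_form:
        return np.exp(_interp_extrap(ri, calib.ri, np.log(calib.rt)))
    return _interp_extrap(ri, calib.ri, calib.rt)


def load_crt(path, rt_unit: str | None = None) -> AlkaneCalibration:
    """Load a calibration retention time (CRT) table.

    CSV with header ``name,rt,ri`` (``rt_min`` accepted for minutes, or pass
    ``rt_unit='min'``).  RI values must be multiples of 100; the alkane carbon
    number is inferred as ri / 100.  Rows may appear in any order.
    """
    df = pd.read_csv(path)
    cols = {c.strip().lower(): c for c in df.columns}
    if "ri" not in cols or ("rt" not in cols and "rt_min" not in cols):
        raise ValidationError(f"CRT file {path} must have columns name,rt[,rt_min],ri")
    if "rt_min" in cols:
        rt = df[cols["rt_min"]].to_numpy(dtype=np.float64) * 60.0
    else:
        rt = df[cols["rt"]].to_numpy(dtype=np.float64)
        if rt_unit in ("min", "minute", "minutes"):
            rt = rt * 60.0
    ri = df[cols["ri"]].to_numpy(dtype=np.float64)
    if df.shape[0] < 2:
        raise ValidationError("CRT file needs at least 2 alkane rows")
    carbon_f = ri / 100.0
    carbon = np.rint(carbon_f).astype(np.int64)
    if np.any(np.abs(carbon_f - carbon) > 1e-9):
        raise ValidationError("CRT RI values must be multiples of 100 (Kovats alkane indices)")
    order = np.argsort(carbon, kind="stable")
    carbon, rt = carbon[order], rt[order]
    if np.any(np.diff(carbon) == 0):
        raise ValidationError("duplicate alkane carbon number in CRT file")
    return AlkaneCalibration(carbon=carbon, rt=rt)


def write_crt(calib: AlkaneCalibration, path) -> None:
    """Write a CRT table (rt in seconds)."""
    pd.DataFrame(
        {"name": [f"C{int(n)}" for n in calib.carbon],
         "rt": calib.rt,
         "ri": (100 * calib.carbon).astype(int)}
    ).to_csv(Path(path), index=False)
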
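"""Accurate-mass EI library search with weighted forward/reverse match factors.

Scoring model
-------------
Query (deconvoluted component) and library ions are first paired one-to-one
within an accurate mass tolerance (AMT, ppm relative to the library mass).
Both spectra are weighted in the Stein-Scott fashion,

    w = intensity^0.5 * mz^1.3,

and two weighted-cosine similarities are computed:

* reverse score R: over the library's ions only — library ions with no query
  partner count against the score, query ions absent from the library are
  ignored (appropriate for matrix-contaminated spectra);
* forward score F: over the union — unmatched ions on either side count
  against the score.

The reported match factor is the convex combination

    score = 100 * (pwf * F + (1 - pwf) * R),

so the pure weight factor pwf = 0 is a purely reverse search and pwf = 1 a
purely forward search.

Retention evidence enters as a multiplicative trapezoidal penalty on the
RT difference between the component apex and the RT expected from the
entry's Kovats RI through the batch alkane calibration: no penalty within
the penalty-free window, a linear ramp up to the maximum penalty at the edge
of the RT search range, and rejection beyond it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError, ValidationError
from .msdata import CentroidSpectrum
from .rical import AlkaneCalibration, ri_to_rt
from .speclib import LibraryEntry, SpectralLibrary

__all__ = [
    "MatchParams",
    "IonPairing",
    "Identification",
    "match_ions",
    "match_factor",
    "forward_reverse_scores",
    "rt_penalty",
    "identify",
    "identifications_to_csv",
]


@dataclass(frozen=True)
class MatchParams:
    """Library search and identification settings.

    amt_ppm
        Accurate mass tolerance in ppm (relative to the library mass).
    pwf
        Pure weight factor in [0, 1]: 0 = reverse search, 1 = forward search.
    min_mz
        Ions below this m/z are excluded from pairing and scoring.
    min_match_factor
        Identification cutoff (0-100) applied to the final score.
    rt_range_s / penalty_free_s / max_rt_penalty
        Trapezoidal retention penalty: free window, search range and penalty
        ceiling (in score points).
    max_hits
        Best hits retained per component.
    weight_int_power / weight_mz_power
        Exponents of the intensity/mass weighting (0.5 / 1.3 by default).
    use_rt_penalty
        Disable to score on spectra alone (the optimization-stage protocol).
    hard_reject
        When True a |dRT| beyond rt_range_s excludes the hit; when False the
        maximum penalty is applied instead.
    threshold_on_final
        Apply min_match_factor to the post-penalty score (default) or to the
        raw spectral match.
    """

    amt_ppm: float = 50.0
    pwf: float = 0.1
    min_mz: float = 30.0
    min_match_factor: float = 75.0
    rt_range_s: float = 20.0
    penalty_free_s: float = 20.0
    max_rt_penalty: float = 20.0
    max_hits: int = 1
    weight_int_power: float = 0.5
    weight_mz_power: float = 1.3
    use_rt_penalty: bool = True
    hard_reject: bool = True
    threshold_on_final: bool = True

    def __post_init__(self):
        if not (0.0 <= self.pwf <= 1.0):
            raise ValidationError("pwf must lie in [0, 1]")
        if self.penalty_free_s > self.rt_range_s:
            raise ValidationError("penalty_free_s must not exceed rt_range_s")
        if min(self.amt_ppm, self.min_mz, self.min_match_factor,
               self.rt_range_s, self.penalty_free_s, self.max_rt_penalty) < 0:
            raise ValidationError("match parameters must be non-negative")


@dataclass
class IonPairing:
    """One-to-one assignment between query and library ions.

    ``pairs`` holds (query_index, library_index, ppm_error) with indices into
    the min_mz-filtered views returned alongside.
    """

    pairs: list[tuple[int, int, float]]
    query_mz: np.ndarray
    query_intensity: np.ndarray
    lib_mz: np.ndarray
    lib_intensity: np.ndarray

    @property
    def matched_query(self) -> set[int]:
        return {q for q, _, _ in self.pairs}

    @property
    def matched_library(self) -> set[int]:
        return {l for _, l, _ in self.pairs}

    @property
    def unmatched_query(self) -> list[int]:
        m = self.matched_query
        return [i for i in range(self.query_mz.size) if i not in m]

    @property
    def unmatched_library(self) -> list[int]:
        m = self.matched_library
        return [i for i in range(self.lib_mz.size) if i not in m]

    @property
    def mean_abs_ppm(self) -> float:
        if not self.pairs:
            return float("nan")
        return float(np.mean([abs(p) for _, _, p in self.pairs]))


@dataclass
class Identification:
    """One component x library-entry hit."""

    component_id: int
    entry_name: str
    library: str
    raw_match: float
    penalty_multiplier: float
    final_score: float
    matched_ions: int
    mean_abs_mass_error_ppm: float
    delta_rt_s: float  # observed - expected; nan when no RT evidence
    rt_evidence: bool = True
    component_rt: float = float("nan")
    component_ri: float = float("nan")


def match_ions(
    query: CentroidSpectrum,
    entry: LibraryEntry,
    amt_ppm: float = 50.0,
    min_mz: float = 30.0,
) -> IonPairing:
    """Pair library ions with query ions within the accurate mass tolerance.

    Ions below ``min_mz`` are dropped from both sides.  Candidate pairs are
    accepted greedily by smallest ppm error (ties toward higher query
    intensity, then lower m/z); each ion participates in at most one pair.
    """
    qkeep = query.mz >= min_mz
    lkeep = entry.mz >= min_mz
    qmz, qint = query.mz[qkeep], query.intensity[qkeep]
    lmz, lint = entry.mz[lkeep], entry.rel_intensity[lkeep]

    candidates: list[tuple[float, float, float, int, int]] = []
    for li, lm in enumerate(lmz):
        tol = lm * amt_ppm * 1e-6
        lo = np.searchsorted(qmz, lm - tol, side="left")
        hi = np.searchsorted(qmz, lm + tol, side="right")
        for qi in range(lo, hi):
            ppm = (qmz[qi] - lm) / lm * 1e6
            candidates.append((abs(ppm), -qint[qi], qmz[qi], qi, li))
    candidates.sort()
    used_q: set[int] = set()
    used_l: set[int] = set()
    pairs: list[tuple[int, int, float]] = []
    for app, negint, _, qi, li in candidates:
        if qi in used_q or li in used_l:
            continue
        used_q.add(qi)
        used_l.add(li)
        ppm = (qmz[qi] - lmz[li]) / lmz[li] * 1e6
        pairs.append((qi, li, float(ppm)))
    pairs.sort(key=lambda p: p[1])
    return IonPairing(pairs=pairs, query_mz=qmz, query_intensity=qint,
                      lib_mz=lmz, lib_intensity=lint)


def _weights(intensity: np.ndarray, mz: np.ndarray, ip: float, mp: float) -> np.ndarray:
    return np.power(intensity, ip) * np.power(mz, mp)


def forward_reverse_scores(
    pairing: IonPairing,
    int_power: float = 0.5,
    mz_power: float = 1.3,
) -> tuple[float, float]:
    """(forward, reverse) weighted-cosine similarities in [0, 1].

    For matched pairs both sides are weighted at the library m/z (the aligned
    coordinate); unmatched ions are weighted at their own m/z.
    """
    if not pairing.pairs:
        return 0.0, 0.0
    qi = np.array([p[0] for p in pairing.pairs], dtype=int)
    li = np.array([p[1] for p in pairing.pairs], dtype=int)
    m_pair = pairing.lib_mz[li]
    wq = _weights(pairing.query_intensity[qi], m_pair, int_power, mz_power)
    wl = _weights(pairing.lib_intensity[li], m_pair, int_power, mz_power)
    dot = float((wq * wl).sum())
    q2_matched = float((wq * wq).sum())
    l2_matched = float((wl * wl).sum())

    ul = pairing.unmatched_library
    l2_unmatched = 0.0
    if ul:
        w = _weights(pairing.lib_intensity[ul], pairing.lib_mz[ul], int_power, mz_power)
        l2_unmatched = float((w * w).sum())
    uq = pairing.unmatched_query
    q2_unmatched = 0.0
    if uq:
        w = _weights(pairing.query_intensity[uq], pairing.query_mz[uq], int_power, mz_power)
        q2_unmatched = float((w * w).sum())

    l2_all = l2_matched + l2_unmatched
    reverse = dot / np.sqrt(q2_matched * l2_all) if q2_matched > 0 and l2_all > 0 else 0.0
    q2_all = q2_matched + q2_unmatched
    forward = dot / np.sqrt(q2_all * l2_all) if q2_all > 0 and l2_all > 0 else 0.0
    return float(forward), float(reverse)


def match_factor(
    query: CentroidSpectrum,
    entry: LibraryEntry,
    pairing: IonPairing | None = None,
    pwf: float = 0.1,
    amt_ppm: float = 50.0,
    min_mz: float = 30.0,
    int_power: float = 0.5,
    mz_power: float = 1.3,
) -> float:
    """Composite match factor 100 * (pwf * F + (1 - pwf) * R), 0-100."""
    if pairing is None:
        pairing = match_ions(query, entry, amt_ppm=amt_ppm, min_mz=min_mz)
    f, r = forward_reverse_scores(pairing, int_power, mz_power)
    return 100.0 * (pwf * f + (1.0 - pwf) * r)


def rt_penalty(delta_rt_s: float, params: MatchParams) -> float | None:
    """Trapezoidal retention penalty multiplier; None means REJECT.

    |dRT| <= penalty_free_s: multiplier 1.  Between penalty_free_s and
    rt_range_s the penalty ramps linearly from 0 to max_rt_penalty score
    points, i.e. multiplier = (100 - penalty)/100.  Beyond rt_range_s the hit
    is rejected (or given the full penalty when ``hard_reject`` is off).
    """
    d = abs(delta_rt_s)
    if d <= params.penalty_free_s:
        return 1.0
    if d > params.rt_range_s:
        if params.hard_reject:
            return None
        return (100.0 - params.max_rt_penalty) / 100.0
    ramp = params.rt_range_s - params.penalty_free_s
    penalty = (d - params.penalty_free_s) / ramp * params.max_rt_penalty
    return (100.0 - penalty) / 100.0


def _score_entry(
    query: CentroidSpectrum,
    apex_rt: float,
    entry: LibraryEntry,
    params: MatchParams,
    calib: AlkaneCalibration | None,
):
    pairing = match_ions(query, entry, amt_ppm=params.amt_ppm, min_mz=params.min_mz)
    raw = match_factor(query, entry, pairing, pwf=params.pwf,
                       int_power=params.weight_int_power, mz_power=params.weight_mz_power)
    rt_evidence = True
    delta = float("nan")
    mult = 1.0
    if params.use_rt_penalty:
        if entry.ri is not None:
            if calib is None:
                raise ConfigurationError(
                    f"library entry {entry.name!r} carries an RI but no alkane calibration "
                    "was supplied"
                )
            expected = float(ri_to_rt(entry.ri, calib))
        elif entry.rt is not None:
            expected = float(entry.rt)
        else:
            expected = None
            rt_evidence = False
        if expected is not None:
            delta = apex_rt - expected
            m = rt_penalty(delta, params)
            if m is None:
                return None, pairing, raw
            mult = m
    return mult, pairing, raw, delta, rt_evidence


def identify(
    components,
    libraries: list[tuple[SpectralLibrary, MatchParams]] | SpectralLibrary,
    calib: AlkaneCalibration | None = None,
    params: MatchParams | None = None,
) -> list[Identification]:
    """Score every component against one or more libraries and keep the best hits.

    ``libraries`` is either a single library (with ``params``) or a list of
    (library, params) pairs so the in-house and pesticide libraries can use
    different retention windows.  Per component, hits below the cutoff are
    dropped and at most ``max_hits`` survive (ties: higher raw match, then
    smaller |dRT|, then name).
    """
    from .deconv import component_spectrum
    from .rical import rt_to_ri

    if isinstance(libraries, SpectralLibrary):
        libraries = [(libraries, params or MatchParams())]

    # fail fast on missing calibration with RI-only libraries
    for lib, p in libraries:
        if p.use_rt_penalty and calib is None:
            if any(e.ri is not None for e in lib.entries):
                raise ConfigurationError(
                    f"library {lib.source or '<unnamed>'} is RI-annotated but no alkane "
                    "calibration was supplied"
                )

    results: list[Identification] = []
    for cid, comp in enumerate(components):
        query = component_spectrum(comp)
        hits: list[Identification] = []
        for lib, p in libraries:
            for entry in lib.entries:
                scored = _score_entry(query, comp.apex_rt, entry, p, calib)
                if scored[0] is None:
                    continue  # rejected by RT range
                mult, pairing, raw, delta, rt_evidence = scored
                final = raw * mult
                gate = final if p.threshold_on_final else raw
                if gate < p.min_match_factor:
                    continue
                hits.append(
                    Identification(
                        component_id=cid,
                        entry_name=entry.name,
                        library=lib.source or "library",
                        raw_match=raw,
                        penalty_multiplier=mult,
                        final_score=final,
                        matched_ions=len(pairing.pairs),
                        mean_abs_mass_error_ppm=pairing.mean_abs_ppm,
                        delta_rt_s=delta,
                        rt_evidence=rt_evidence,
                        component_rt=comp.apex_rt,
                        component_ri=float(rt_to_ri(comp.apex_rt, calib)) if calib else float("nan"),
                    )
                )
        hits.sort(
            key=lambda h: (
                -h.final_score,
                -h.raw_match,
                abs(h.delta_rt_s) if np.isfinite(h.delta_rt_s) else np.inf,
                h.entry_name,
            )
        )
        max_hits = max(p.max_hits for _, p in libraries)
        results.extend(hits[:max_hits])
    return results


def identifications_to_csv(ids: list[Identification], path) -> None:
    """Write the screening report CSV."""
    import pandas as pd

    rows = [
        {
            "component_id": h.component_id,
            "rt": h.component_rt,
            "ri": h.component_ri,
            "name": h.entry_name,
            "library": h.library,
            "raw_match": h.raw_match,
            "penalty": h.penalty_multiplier,
            "final_score": h.final_score,
            "matched_ions": h.matched_ions,
            "mean_ppm_error": h.mean_abs_mass_error_ppm,
        }
        for h in ids
    ]
    pd.DataFrame(
        rows,
        columns=["component_id", "rt", "ri", "name", "library", "raw_match",
                 "penalty", "final_score", "matched_ions", "mean_ppm_error"],
    ).to_csv(path, index=False)
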
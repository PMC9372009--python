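"""Screening evaluation and parameter optimization.

Given identifications for spiked samples with a known truth table, this
module scores true/false positives and negatives, calibrates match-factor
cutoffs that admit a target false-negative rate, sweeps accurate-mass
tolerance (AMT) and pure-weight-factor (PWF) grids, and estimates the
screening detection limit (SDL): the lowest concentration level at which a
compound is detected in at least 95% of replicate samples.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError
from .matching import Identification

__all__ = [
    "TruthTable",
    "EvalResult",
    "DetectionMatrix",
    "score_detections",
    "cutoff_for_fn_rate",
    "sweep_parameters",
    "compute_sdl",
]

NOT_DETERMINED = "not determined"


@dataclass
class TruthTable:
    """Per-sample spiked-compound truth.

    ``samples`` maps a sample id to the set of spiked compound names;
    ``levels`` maps a sample id to its concentration-level label.
    """

    samples: dict[str, set[str]] = field(default_factory=dict)
    levels: dict[str, str] = field(default_factory=dict)

    def add(self, sample: str, compound: str, level: str = "") -> None:
        self.samples.setdefault(sample, set()).add(compound)
        if level:
            self.levels[sample] = level

    def compounds(self, sample: str) -> set[str]:
        return self.samples.get(sample, set())

    def to_csv(self, path) -> None:
        rows = [
            {"sample": s, "compound": c, "level": self.levels.get(s, "")}
            for s in sorted(self.samples)
            for c in sorted(self.samples[s])
        ]
        pd.DataFrame(rows, columns=["sample", "compound", "level"]).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "TruthTable":
        df = pd.read_csv(path)
        tt = cls()
        for _, r in df.iterrows():
            tt.add(str(r["sample"]), str(r["compound"]), str(r.get("level", "")))
        return tt


@dataclass
class EvalResult:
    """TP/FP/FN counts for one sample (or an aggregate)."""

    tp: int
    fp: int
    fn: int
    detected: dict[str, bool]  # per truth compound

    @property
    def fn_rate(self) -> float:
        n = self.tp + self.fn
        return self.fn / n if n else 0.0

    @property
    def n_truth(self) -> int:
        return self.tp + self.fn


def score_detections(
    ids: list[Identification],
    truth: TruthTable | set[str],
    sample: str = "",
    library_names: set[str] | None = None,
) -> EvalResult:
    """Score identifications against the spiked truth for one sample.

    A truth compound with at least one identification of the same name is a
    true positive; truth compounds with none are false negatives; every
    identification whose name is not in the truth set is a false positive
    (matrix/background hits count as FP).  Truth names absent from the active
    library are warned about and excluded from the denominator.
    """
    truth_names = truth.compounds(sample) if isinstance(truth, TruthTable) else set(truth)
    if library_names is not None:
        unresolvable = truth_names - set(library_names)
        if unresolvable:
            warnings.warn(
                f"truth compounds not in the active libraries, excluded: {sorted(unresolvable)}"
            )
            truth_names = truth_names - unresolvable
    hit_names = [h.entry_name for h in ids]
    hit_set = set(hit_names)
    detected = {name: (name in hit_set) for name in sorted(truth_names)}
    tp = sum(detected.values())
    fn = len(detected) - tp
    fp = sum(1 for n in hit_names if n not in truth_names)
    return EvalResult(tp=tp, fp=fp, fn=fn, detected=detected)


def cutoff_for_fn_rate(scores, target_fn_rate: float) -> int:
    """Largest integer cutoff c with fraction(scores < c) <= target_fn_rate.

    ``scores`` are the best final match factors of the truth compounds over
    all replicates, with missed compounds entered as 0.  Detection is defined
    as score >= c, so scores below c are the false negatives the cutoff
    admits.  The result is integer (floored) following the reporting
    convention of screening-cutoff tables.
    """
    scores = np.asarray(list(scores), dtype=np.float64)
    if scores.size == 0:
        raise ValidationError("cutoff_for_fn_rate needs a non-empty score list")
    if not (0.0 <= target_fn_rate < 1.0):
        raise ValidationError("target_fn_rate must lie in [0, 1)")
    best = 0
    for c in range(0, int(math.floor(scores.max())) + 2):
        if np.mean(scores < c) <= target_fn_rate + 1e-12:
            best = c
    return best


# ---------------------------------------------------------------------------
# parameter sweeps


def sweep_parameters(
    samples: dict[str, list],
    truth: TruthTable,
    library,
    calib,
    base_params,
    amt_grid,
    pwf_grid,
    cutoff_policy: float | str = 50.0,
    calibration_samples: list[str] | None = None,
    target_fn_rate: float = 0.05,
) -> pd.DataFrame:
    """Full-factorial AMT x PWF evaluation.

    ``samples`` maps sample id -> deconvoluted component list (deconvolution
    is AMT/PWF independent, so components are computed once upstream).
    ``cutoff_policy`` is a fixed match-factor cutoff, or ``"calibrate"`` to
    derive, per grid cell, the cutoff admitting ``target_fn_rate`` false
    negatives on ``calibration_samples`` (two-stage protocol).  Returns one
    row per (amt, pwf) with aggregate tp/fp/fn over the evaluated samples.
    """
    from dataclasses import replace

    from .matching import identify

    amt_grid = list(amt_grid)
    pwf_grid = list(pwf_grid)
    if not amt_grid or not pwf_grid:
        raise ValidationError("AMT and PWF grids must be non-empty")
    eval_samples = [s for s in samples if calibration_samples is None or s not in calibration_samples]
    rows = []
    for amt in amt_grid:
        for pwf in pwf_grid:
            p = replace(base_params, amt_ppm=amt, pwf=pwf)
            if cutoff_policy == "calibrate":
                if not calibration_samples:
                    raise ValidationError("cutoff_policy='calibrate' needs calibration_samples")
                cut = _calibrated_cutoff(
                    samples, truth, library, calib, p, calibration_samples, target_fn_rate
                )
            else:
                cut = float(cutoff_policy)
            p_cut = replace(p, min_match_factor=cut)
            tp = fp = fn = 0
            for sid in eval_samples:
                ids = identify(samples[sid], library, calib, p_cut)
                r = score_detections(ids, truth, sid)
                tp, fp, fn = tp + r.tp, fp + r.fp, fn + r.fn
            n_samples = max(len(eval_samples), 1)
            rows.append(
                {
                    "amt_ppm": amt,
                    "pwf": pwf,
                    "cutoff": cut,
                    "tp": tp,
                    "fp": fp,
                    "fn": fn,
                    "fn_rate": fn / (tp + fn) if tp + fn else 0.0,
                    "fp_per_sample": fp / n_samples,
                }
            )
    return pd.DataFrame(rows)


def best_scores_per_truth(
    samples: dict[str, list], truth: TruthTable, library, calib, params,
    sample_ids: list[str],
) -> list[float]:
    """Best final score of every (truth compound, sample); 0 when missed.

    Identification runs with the cutoff disabled so the full score
    distribution is visible to the calibration.
    """
    from dataclasses import replace

    from .matching import identify

    p0 = replace(params, min_match_factor=0.0)
    scores: list[float] = []
    for sid in sample_ids:
        ids = identify(samples[sid], library, calib, p0)
        best: dict[str, float] = {}
        for h in ids:
            best[h.entry_name] = max(best.get(h.entry_name, 0.0), h.final_score)
        for name in truth.compounds(sid):
            scores.append(best.get(name, 0.0))
    return scores


def _calibrated_cutoff(samples, truth, library, calib, params, calibration_samples,
                       target_fn_rate):
    scores = best_scores_per_truth(samples, truth, library, calib, params,
                                   calibration_samples)
    return float(cutoff_for_fn_rate(scores, target_fn_rate))


# ---------------------------------------------------------------------------
# screening detection limit


@dataclass
class DetectionMatrix:
    """level -> replicate -> compound -> detected flag.

    ``level_order`` lists level labels from lowest to highest concentration.
    """

    level_order: list[str]
    detected: dict[str, dict[int, dict[str, bool]]] = field(default_factory=dict)
    unevaluable: set[str] = field(default_factory=set)

    def set(self, level: str, replicate: int, compound: str, flag: bool) -> None:
        self.detected.setdefault(level, {}).setdefault(replicate, {})[compound] = flag

    def detection_fraction(self, level: str, compound: str) -> float | None:
        reps = self.detected.get(level, {})
        flags = [r[compound] for r in reps.values() if compound in r]
        if not flags:
            return None
        return sum(flags) / len(flags)

    def compounds(self) -> list[str]:
        names: set[str] = set()
        for reps in self.detected.values():
            for r in reps.values():
                names.update(r)
        return sorted(names)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"level": lvl, "replicate": rep, "compound": c, "detected": flag}
            for lvl, reps in self.detected.items()
            for rep, d in reps.items()
            for c, flag in d.items()
        ]
        return pd.DataFrame(rows, columns=["level", "replicate", "compound", "detected"])


def compute_sdl(matrix: DetectionMatrix, min_rate: float = 0.95) -> dict[str, str]:
    """Per-compound screening detection limit.

    The SDL is the lowest tested level whose detection fraction is at least
    ``min_rate`` AND whose every higher tested level also reaches
    ``min_rate``; compounds with no qualifying level (or flagged unevaluable)
    map to ``"not determined"``.
    """
    out: dict[str, str] = {}
    for compound in matrix.compounds():
        if compound in matrix.unevaluable:
            out[compound] = NOT_DETERMINED
            continue
        fractions = []
        for lvl in matrix.level_order:
            f = matrix.detection_fraction(lvl, compound)
            if f is not None:
                fractions.append((lvl, f))
        sdl = NOT_DETERMINED
        # walk from the highest level down while the >= min_rate rule holds
        for lvl, f in reversed(fractions):
            if f >= min_rate - 1e-12:
                sdl = lvl
            else:
                break
        out[compound] = sdl
    return out
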
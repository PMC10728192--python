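"""Behavioral and imaging statistics for knockout screens.

Implements the population chemotaxis indices (quadrant and distal-spot plate
layouts), the single-worm sector score, pathogen-lawn avoidance/occupancy,
relative changes versus wild type, strict-threshold and quantile hit calling,
interval mean responses for locomotion traces, photobleaching correction of
fluorescence recordings by an exponential fit to pre- and post-stimulus
windows, the dF/F0 transform with a 5-second pre-onset baseline, and
cross-condition response-profile correlations used to relate ligand and
receptor mutants.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "PlateCounts",
    "ScreenRecord",
    "Trace",
    "SECTOR_VALUES",
    "chemotaxis_index_quadrant",
    "chemotaxis_index_distal",
    "single_worm_score",
    "lawn_indices",
    "relative_change",
    "call_hits",
    "interval_mean_response",
    "bleach_correct",
    "delta_f_over_f0",
    "response_correlation",
]

SECTOR_VALUES = {"A": 3, "B": 2, "C": 1, "D": -1, "E": -2, "F": -3}


@dataclass
class PlateCounts:
    """Raw animal counts from one assay plate."""

    assay: str  # quadrant | distal | lawn
    n_odor: int = 0
    n_control: int = 0
    n_total_on_plate: int = 0
    n_on_lawn: int = 0
    n_off_lawn: int = 0

    def __post_init__(self):
        for name in ("n_odor", "n_control", "n_total_on_plate", "n_on_lawn", "n_off_lawn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class ScreenRecord:
    """Per-strain, per-condition screen summary."""

    strain_id: str
    condition: str
    ci: float | None = None
    avoidance: float | None = None
    occupancy: float | None = None
    relative_change: float | None = None
    mean_survival_days: float | None = None
    survival_change: float | None = None
    replicates: list[str] = field(default_factory=list)


@dataclass
class Trace:
    """A per-frame time series (locomotion speed or fluorescence)."""

    kind: str  # speed | fluorescence
    t: np.ndarray
    y: np.ndarray
    stimulus_windows: list[tuple[float, float]] = field(default_factory=list)
    f0: float | None = None
    corrected: bool = False
    warning: str = ""

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.t.shape != self.y.shape:
            raise ValueError("t and y must have equal length")
        if len(self.t) > 1 and not np.all(np.diff(self.t) > 0):
            raise ValueError("t must be strictly increasing")
        if not np.all(np.isfinite(self.y)):
            raise ValueError("y must be finite")


def chemotaxis_index_quadrant(n_odor: int, n_control: int) -> float:
    """CI = (animals on the odorant side - animals on the control side) /
    total animals on both sides; NaN when no animal scored."""
    total = n_odor + n_control
    if total == 0:
        warnings.warn("no animals on either side; CI undefined")
        return math.nan
    return (n_odor - n_control) / total


def chemotaxis_index_distal(
    n_odor_circle: int, n_control_circle: int, n_total_on_plate: int
) -> float:
    """CI = (animals in odorant circle - animals in control circle) / total
    animals on the plate (animals outside both circles still count)."""
    if n_total_on_plate == 0:
        warnings.warn("empty plate; CI undefined")
        return math.nan
    return (n_odor_circle - n_control_circle) / n_total_on_plate


def single_worm_score(sectors_visited) -> int:
    """Sum of sector values (A..F -> 3,2,1,-1,-2,-3) over visited sectors."""
    score = 0
    for sector in sectors_visited:
        if sector not in SECTOR_VALUES:
            raise ValueError(f"unknown sector label {sector!r}")
        score += SECTOR_VALUES[sector]
    return score


def lawn_indices(n_off_lawn: int, n_total: int) -> tuple[float, float]:
    """(avoidance, occupancy): fraction of animals off / on the pathogen lawn."""
    if n_total <= 0:
        raise ValueError("n_total must be > 0")
    if n_off_lawn > n_total:
        raise ValueError("n_off_lawn exceeds n_total")
    avoidance = n_off_lawn / n_total
    return avoidance, 1.0 - avoidance


def relative_change(mutant_value: float, wt_value: float) -> float:
    """(mutant - wild type) / wild type; NaN when the wild-type value is 0."""
    if wt_value == 0:
        warnings.warn("wild-type value is 0; relative change undefined")
        return math.nan
    return (mutant_value - wt_value) / wt_value


def call_hits(
    records: list[ScreenRecord],
    rule: str = "repellent_threshold",
    threshold: float = -0.5,
    quantile: float = 0.05,
) -> list[ScreenRecord]:
    """Deterministic hit flagging.

    ``repellent_threshold``: flag records with CI strictly above ``threshold``
    (animals failing to avoid a repellent; ties at the threshold excluded).
    ``low_tail`` / ``high_tail``: flag records whose relative_change lies
    strictly beyond the ``quantile`` empirical quantile of the batch.
    """
    if not records:
        return []
    if rule == "repellent_threshold":
        return [r for r in records if r.ci is not None and r.ci > threshold]
    values = np.array(
        [r.relative_change for r in records if r.relative_change is not None]
    )
    if values.size == 0:
        return []
    if rule == "low_tail":
        cutoff = np.quantile(values, quantile)
        return [
            r for r in records
            if r.relative_change is not None and r.relative_change < cutoff
        ]
    if rule == "high_tail":
        cutoff = np.quantile(values, 1 - quantile)
        return [
            r for r in records
            if r.relative_change is not None and r.relative_change > cutoff
        ]
    raise ValueError(f"unknown hit rule {rule!r}")


def _window_mask(t: np.ndarray, window: tuple[float, float]) -> np.ndarray:
    lo, hi = window
    return (t >= lo) & (t < hi)


def interval_mean_response(
    trace: Trace,
    baseline_window: tuple[float, float],
    stimulus_window: tuple[float, float],
) -> tuple[float, float, float]:
    """Means over frames in two half-open time windows and their difference
    (stimulus - baseline); NaN for an empty window."""
    out = []
    for window in (baseline_window, stimulus_window):
        mask = _window_mask(trace.t, window)
        out.append(float(np.mean(trace.y[mask])) if mask.any() else math.nan)
    return out[0], out[1], out[1] - out[0]


def bleach_correct(
    trace: Trace,
    fit_windows: tuple[tuple[float, float], tuple[float, float]] | None = None,
) -> Trace:
    """Correct photobleaching by dividing out an exponential decay.

    An exponential y = a*exp(-b*t) is fit by ordinary least squares on
    log-transformed values over the pre- and post-stimulus windows only
    (default: the first 30 s and the last 20 s of the recording), with b
    constrained to be non-negative. The corrected trace is y divided by the
    fitted curve, so a response-free recording becomes constant 1. On fit
    failure the input is returned with a warning flag set.
    """
    t, y = trace.t, trace.y
    if fit_windows is None:
        t0, t1 = float(t[0]), float(t[-1])
        fit_windows = ((t0, t0 + 30.0), (t1 - 20.0, t1 + np.spacing(t1)))
    mask = _window_mask(t, fit_windows[0]) | _window_mask(t, fit_windows[1])
    tf, yf = t[mask], y[mask]
    if tf.size < 2 or np.any(yf <= 0):
        return Trace(trace.kind, t, y, trace.stimulus_windows,
                     warning="bleach_fit_failed: non-positive values or empty windows")
    slope, intercept = np.polyfit(tf, np.log(yf), 1)
    b = max(0.0, -slope)
    a = float(np.exp(intercept)) if b > 0 else float(np.mean(yf))
    if not np.isfinite(a) or a <= 0:
        return Trace(trace.kind, t, y, trace.stimulus_windows,
                     warning="bleach_fit_failed: non-positive amplitude")
    fitted = a * np.exp(-b * t)
    return Trace(trace.kind, t, y / fitted, trace.stimulus_windows, corrected=True)


def delta_f_over_f0(trace: Trace, odor_onset_t: float) -> Trace:
    """dF/F0 with F0 = mean over the 5 s immediately before odor onset."""
    mask = _window_mask(trace.t, (odor_onset_t - 5.0, odor_onset_t))
    if not mask.any():
        raise ValueError("no samples in the 5 s pre-onset baseline window")
    f0 = float(np.mean(trace.y[mask]))
    if f0 == 0:
        warnings.warn("F0 is zero; dF/F0 undefined")
        out = np.full_like(trace.y, math.nan)
    else:
        out = (trace.y - f0) / f0
    result = Trace(trace.kind, trace.t, out, trace.stimulus_windows,
                   corrected=trace.corrected)
    result.f0 = f0
    return result


def response_correlation(
    profiles: pd.DataFrame, method: str = "pearson"
) -> pd.DataFrame:
    """Strain-by-strain correlation of response profiles across conditions.

    ``profiles`` is a strain x condition table (NaN allowed); correlations
    are pairwise-complete and require at least two shared conditions per
    pair. ``method`` is ``pearson`` (default) or ``spearman``.
    """
    if method not in ("pearson", "spearman"):
        raise ValueError("method must be 'pearson' or 'spearman'")
    if profiles.shape[1] < 2:
        raise ValueError("need at least 2 conditions per strain")
    corr = profiles.T.corr(method=method, min_periods=2)
    np.fill_diagonal(corr.values, 1.0)
    return corr
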
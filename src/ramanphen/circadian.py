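"""Circadian time-course analysis of spectral distances.

A culture sampled every 2 h over a 24 h light/dark cycle yields one TSD
value per time point (distance of the current phenotype from the 0 h
reference).  The series is cleaned in two stages — the median method
(points beyond 3 scaled median absolute deviations from the series
median) and a hard TSD > 0.15 exclusion — then summarised by a
least-squares fourth-order polynomial, whose interior extrema expose a
bimodal excursion, and classified for bimodality and return to the
initial phenotype at 24 h.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

__all__ = ["TimeCourse", "QuarticFit", "filter_outliers", "fit_quartic", "classify_rhythm"]

MAD_SCALE = 1.4826  # consistent with a Gaussian standard deviation


@dataclasses.dataclass
class TimeCourse:
    """TSD values over time for one culture condition.

    ``points`` has columns time_h, tsd, kept, reason; filtering flags
    points instead of deleting them, and ``reason`` is one of
    ``median_outlier`` / ``threshold_exceeded`` / "".
    """

    points: pd.DataFrame
    condition: str = ""

    def __post_init__(self) -> None:
        required = {"time_h", "tsd"}
        if not required.issubset(self.points.columns):
            raise ValueError("time course needs time_h and tsd columns")
        pts = self.points.copy()
        if "kept" not in pts.columns:
            pts["kept"] = True
        if "reason" not in pts.columns:
            pts["reason"] = ""
        if np.any(np.diff(pts["time_h"].to_numpy(dtype=float)) < 0):
            raise ValueError("time points must be nondecreasing")
        if (pts["tsd"] < 0).any():
            raise ValueError("TSD values must be nonnegative")
        bad = pts.loc[~pts["kept"], "reason"]
        if (~bad.isin(["median_outlier", "threshold_exceeded"])).any():
            raise ValueError("rejected points must carry a recorded reason")
        self.points = pts.reset_index(drop=True)

    @property
    def kept(self) -> pd.DataFrame:
        return self.points[self.points["kept"]]


@dataclasses.dataclass
class QuarticFit:
    """Degree-4 least-squares fit of a TSD time course.

    ``coefficients`` are in descending power order (numpy polyval
    convention).  Interior extrema come from the real roots of the cubic
    derivative inside the fitted time window; a quartic admits at most
    two interior local maxima.
    """

    coefficients: np.ndarray
    interior_maxima: list[tuple[float, float]]
    interior_minima: list[tuple[float, float]]
    endpoint_values: tuple[float, float]
    t_span: tuple[float, float] = (0.0, 24.0)

    def __post_init__(self) -> None:
        if len(self.interior_maxima) > 2:
            raise ValueError("a quartic cannot have more than 2 interior local maxima")

    def __call__(self, t) -> np.ndarray:
        return np.polyval(self.coefficients, t)


def filter_outliers(
    tc: TimeCourse, mad_multiplier: float = 3.0, tsd_threshold: float = 0.15
) -> TimeCourse:
    """Two-stage outlier flagging: median method, then the TSD ceiling.

    Stage 1 marks points more than ``mad_multiplier`` scaled MADs
    (scale 1.4826) from the series median; stage 2 marks remaining
    points with TSD above ``tsd_threshold``.  Statistics are computed on
    the full series, so the operation is idempotent and non-destructive.
    """
    pts = tc.points.copy()
    values = pts["tsd"].to_numpy(dtype=float)
    med = np.median(values)
    mad = MAD_SCALE * np.median(np.abs(values - med))
    kept = np.ones(len(pts), dtype=bool)
    reason = np.array([""] * len(pts), dtype=object)
    if mad > 0:
        stage1 = np.abs(values - med) > mad_multiplier * mad
        kept[stage1] = False
        reason[stage1] = "median_outlier"
    stage2 = kept & (values > tsd_threshold)
    kept[stage2] = False
    reason[stage2] = "threshold_exceeded"
    if kept.sum() < 5:
        raise ValueError("fewer than 5 points survive outlier filtering")
    pts["kept"] = kept
    pts["reason"] = reason
    return TimeCourse(points=pts, condition=tc.condition)


def fit_quartic(tc: TimeCourse) -> QuarticFit:
    """Least-squares fourth-order polynomial through the kept points.

    High-order polynomials are used precisely because they can express a
    bimodal excursion (two humps) over a single cycle.
    """
    kept = tc.kept
    t = kept["time_h"].to_numpy(dtype=float)
    y = kept["tsd"].to_numpy(dtype=float)
    if t.size < 5 or np.unique(t).size < 5:
        raise ValueError("quartic fit needs at least 5 kept points at 5 distinct times")
    coeffs = np.polyfit(t, y, 4)
    t_lo, t_hi = float(t.min()), float(t.max())
    deriv = np.polyder(coeffs)
    curv = np.polyder(deriv)
    roots = np.roots(deriv)
    real = np.sort(roots[np.abs(roots.imag) < 1e-9].real)
    maxima, minima = [], []
    for r in real:
        if t_lo < r < t_hi:
            val = float(np.polyval(coeffs, r))
            if np.polyval(curv, r) < 0:
                maxima.append((float(r), val))
            elif np.polyval(curv, r) > 0:
                minima.append((float(r), val))
    return QuarticFit(
        coefficients=coeffs,
        interior_maxima=maxima,
        interior_minima=minima,
        endpoint_values=(float(np.polyval(coeffs, t_lo)), float(np.polyval(coeffs, t_hi))),
        t_span=(t_lo, t_hi),
    )


def classify_rhythm(fit: QuarticFit, tolerance: float = 0.10) -> dict:
    """Assess return-to-initial and bimodality of a fitted time course.

    ``returns_to_initial`` holds when the fitted values at the window
    endpoints differ by at most ``tolerance`` of the fitted range;
    ``bimodal`` requires exactly two interior local maxima separated by
    an interior local minimum.  A flat fit trivially returns to its
    initial value and is not bimodal.
    """
    t = np.linspace(fit.t_span[0], fit.t_span[1], 481)
    values = fit(t)
    rng = float(values.max() - values.min())
    start, end = fit.endpoint_values
    if rng <= 1e-9 * max(1.0, float(np.abs(values).max())):  # flat fit
        return {"returns_to_initial": True, "bimodal": False}
    returns = abs(end - start) <= tolerance * rng
    bimodal = False
    if len(fit.interior_maxima) == 2:
        (t1, _), (t2, _) = sorted(fit.interior_maxima)
        bimodal = any(t1 < tm < t2 for tm, _ in fit.interior_minima)
    return {"returns_to_initial": bool(returns), "bimodal": bool(bimodal)}
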
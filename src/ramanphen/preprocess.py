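"""Spectral preprocessing: replicate averaging, truncation, Goldindec
polynomial baseline correction, and vector normalization.

The four steps are applied in that fixed order by
:func:`process_pipeline`; whole-cell Raman spectra are averaged over
their acquisition replicates, truncated to the biological fingerprint
window (400-1,800 cm^-1), stripped of the smooth fluorescence background,
and scaled to unit Euclidean norm so only spectral *shape* enters the
downstream chemometrics.

The baseline estimator follows the Goldindec scheme: a low-order
polynomial is fitted by iteratively reweighted least squares under an
asymmetric truncated-quadratic cost (points rising above the current fit
— peak candidates — stop contributing once their residual exceeds a scale
threshold), and the threshold itself is selected by golden-section search
so that the fraction of points classified as peak region matches the
user-supplied estimated peak ratio.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy.signal import savgol_filter

from .spectra_io import Spectrum, SpectrumSet

__all__ = [
    "ProcessingParams",
    "average_replicates",
    "truncate",
    "goldindec_baseline",
    "vector_normalize",
    "process_pipeline",
]


@dataclasses.dataclass
class ProcessingParams:
    """Tunable preprocessing parameters.

    Defaults are the standard whole-cell settings: truncation to
    400-1,800 cm^-1, cubic baseline, estimated peak ratio 0.5, 5-point
    smoothing window.
    """

    truncation_low: float = 400.0
    truncation_high: float = 1800.0
    poly_order: int = 3
    peak_ratio: float = 0.5
    smoothing_window: int = 5
    max_iter: int = 100
    rel_tol: float = 1e-6

    def __post_init__(self) -> None:
        if not self.truncation_low < self.truncation_high:
            raise ValueError("truncation_low must be < truncation_high")
        if self.poly_order < 1:
            raise ValueError("poly_order must be >= 1")
        if not 0.0 < self.peak_ratio < 1.0:
            raise ValueError("peak_ratio must be in (0, 1)")
        if self.smoothing_window < 3 or self.smoothing_window % 2 == 0:
            raise ValueError("smoothing_window must be odd and >= 3")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")


def average_replicates(sset: SpectrumSet, group_key: str = "sample_id") -> SpectrumSet:
    """Pointwise mean per group; the group size is recorded as ``n_averaged``.

    ``group_key = "sample_id"`` averages acquisition replicates per
    sample; any other metadata column pools samples sharing that factor
    level.
    """
    grid = sset.grid  # raises on mismatched grids
    if group_key == "sample_id":
        groups = np.asarray([str(s.sample_id) for s in sset.spectra], dtype=object)
    else:
        groups = np.asarray([str(v) for v in sset.factor_values(group_key)], dtype=object)
    out: list[Spectrum] = []
    meta_rows = []
    for g in _ordered_unique(groups):
        idx = np.flatnonzero(groups == g)
        X = np.vstack([sset.spectra[i].intensities for i in idx])
        out.append(Spectrum(grid, X.mean(axis=0), sample_id=g, replicate_index=0))
        row = _collapse_metadata(sset, [sset.spectra[i].sample_id for i in idx])
        row["sample_id"] = g
        row["n_averaged"] = len(idx)
        meta_rows.append(row)
    meta = pd.DataFrame(meta_rows)
    return SpectrumSet(out, meta, sset.provenance).with_provenance(
        {"step": "average_replicates", "group_key": group_key}
    )


def _ordered_unique(values: np.ndarray) -> list:
    seen: dict = {}
    for v in values:
        seen.setdefault(v, None)
    return list(seen)


def _collapse_metadata(sset: SpectrumSet, sample_ids: list[str]) -> dict:
    """Keep metadata columns that are constant within the averaged group."""
    sub = sset.metadata[sset.metadata["sample_id"].astype(str).isin({str(s) for s in sample_ids})]
    row: dict = {}
    for col in sub.columns:
        if col == "sample_id":
            continue
        vals = sub[col].drop_duplicates()
        if len(vals) == 1:
            row[col] = vals.iloc[0]
    return row


def truncate(s: Spectrum, low: float = 400.0, high: float = 1800.0) -> Spectrum:
    """Retain points with ``low <= shift <= high`` (inclusive bounds)."""
    if not low < high:
        raise ValueError("low must be < high")
    mask = (s.shifts >= low) & (s.shifts <= high)
    if mask.sum() < 2:
        raise ValueError(f"fewer than 2 points survive truncation to [{low}, {high}]")
    return s.copy_with(shifts=s.shifts[mask], intensities=s.intensities[mask])


def _smooth(y: np.ndarray, window: int, order: int) -> np.ndarray:
    """Savitzky-Golay window smoothing; exact on polynomials up to ``order``."""
    window = min(window, y.size if y.size % 2 == 1 else y.size - 1)
    polyorder = min(order, window - 1)
    return savgol_filter(y, window_length=window, polyorder=polyorder, mode="interp")


def _fit_truncated(
    x: np.ndarray, y: np.ndarray, order: int, s: float, max_iter: int, rel_tol: float
) -> tuple[np.ndarray, np.ndarray, bool]:
    """IRLS polynomial fit under the asymmetric truncated-quadratic cost.

    Points whose residual above the current fit exceeds ``s`` are dropped
    from the next refit (zero weight); points below the fit always keep
    full weight.  Returns (baseline values, peak mask, converged flag).
    """
    w = np.ones_like(y)
    base = np.polyval(np.polyfit(x, y, order, w=np.sqrt(w)), x)
    scale = max(np.ptp(y), 1e-300)
    converged = False
    for _ in range(max_iter):
        resid = y - base
        peak = resid > s
        w_new = np.where(peak, 0.0, 1.0)
        if w_new.sum() <= order:  # keep enough points to fit
            w_new = np.ones_like(y)
        new_base = np.polyval(np.polyfit(x, y, order, w=np.sqrt(w_new)), x)
        delta = np.max(np.abs(new_base - base)) / scale
        base = new_base
        if delta < rel_tol:
            converged = True
            break
    peak = (y - base) > s
    return base, peak, converged


def goldindec_baseline(
    s: Spectrum, p: ProcessingParams | None = None
) -> tuple[Spectrum, Spectrum]:
    """Estimate and subtract a polynomial fluorescence background.

    Returns ``(corrected, baseline)``.  The shift axis is rescaled to
    [0, 1] before polynomial fitting for conditioning, the signal is
    pre-smoothed with a Savitzky-Golay window of ``smoothing_window``
    points, and the peak/background threshold is tuned by golden-section
    search so the implied peak fraction matches ``peak_ratio``.

    A flat (constant) input is degenerate: the baseline is the input and
    the corrected spectrum is identically zero.
    """
    p = p or ProcessingParams()
    y = s.intensities
    rng_y = np.ptp(y)
    if rng_y == 0.0:
        return (
            s.copy_with(intensities=np.zeros_like(y)),
            s.copy_with(intensities=y.copy()),
        )
    x = (s.shifts - s.shifts[0]) / (s.shifts[-1] - s.shifts[0])
    ys = _smooth(y, p.smoothing_window, p.poly_order)
    yn = (ys - ys.min()) / rng_y  # unit-range working copy

    def peak_fraction(thresh: float) -> float:
        _, peak, _ = _fit_truncated(x, yn, p.poly_order, thresh, p.max_iter, p.rel_tol)
        return peak.mean()

    # golden-section search of the threshold: peak fraction decreases with
    # the threshold, so minimise the squared mismatch with peak_ratio
    lo, hi = 1e-6, 1.0
    invphi = (np.sqrt(5.0) - 1.0) / 2.0
    a, b = lo, hi
    c = b - invphi * (b - a)
    d = a + invphi * (b - a)
    fc = (peak_fraction(c) - p.peak_ratio) ** 2
    fd = (peak_fraction(d) - p.peak_ratio) ** 2
    for _ in range(40):
        if b - a < 1e-4:
            break
        if fc < fd:
            b, d, fd = d, c, fc
            c = b - invphi * (b - a)
            fc = (peak_fraction(c) - p.peak_ratio) ** 2
        else:
            a, c, fc = c, d, fd
            d = a + invphi * (b - a)
            fd = (peak_fraction(d) - p.peak_ratio) ** 2
    thresh = (a + b) / 2.0
    base_n, _, converged = _fit_truncated(x, yn, p.poly_order, thresh, p.max_iter, p.rel_tol)
    if not converged:
        import warnings

        warnings.warn(
            f"Goldindec baseline did not converge within {p.max_iter} iterations "
            f"for sample {s.sample_id!r}",
            RuntimeWarning,
            stacklevel=2,
        )
    baseline = base_n * rng_y + ys.min()
    corrected = y - baseline
    return s.copy_with(intensities=corrected), s.copy_with(intensities=baseline)


def vector_normalize(s: Spectrum) -> Spectrum:
    """Scale the intensity vector to unit Euclidean (L2) norm."""
    norm = float(np.linalg.norm(s.intensities))
    if norm == 0.0:
        raise ValueError("cannot normalize an all-zero spectrum")
    return s.copy_with(intensities=s.intensities / norm)


def process_pipeline(sset: SpectrumSet, p: ProcessingParams | None = None) -> SpectrumSet:
    """Averaging -> truncation -> baselining -> vector normalization.

    The step order matters (normalization after baselining, truncation
    before both) and is fixed.  Per-step provenance is recorded on the
    returned set.
    """
    p = p or ProcessingParams()
    averaged = average_replicates(sset, group_key="sample_id")
    out: list[Spectrum] = []
    for spec in averaged.spectra:
        t = truncate(spec, p.truncation_low, p.truncation_high)
        corrected, _ = goldindec_baseline(t, p)
        out.append(vector_normalize(corrected))
    result = SpectrumSet(out, averaged.metadata, averaged.provenance)
    return result.with_provenance(
        {
            "step": "process_pipeline",
            "order": ["average_replicates", "truncate", "goldindec_baseline", "vector_normalize"],
            "params": dataclasses.asdict(p),
        }
    )

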
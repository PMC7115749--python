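"""Spectral distance statistics against a control reference.

Hundreds of intensity channels per spectrum are reduced to a single
number per spectrum by summing absolute coordinate differences against a
reference (control-condition) spectrum:

* TSD — total spectral distance, over the truncated shift grid;
* TPD — total principal-component distance, over the first five PCs;
* TCD — total canonical distance, over the top five DAPC canonicals
  (all of them when the model has fewer than five).

The summand is written sqrt((x_i - ref_i)^2), which is exactly |x_i -
ref_i|, so the default distance is L1; an L2 (Euclidean) variant is
offered as an option.  Distances then feed ANOVA with Tukey HSD pairwise
comparisons (99% confidence), regression against a numeric covariate
(e.g. nitrate percentage), and single-band/analyte Pearson correlation.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .chemometrics import DAPCModel, PCAModel
from .spectra_io import Spectrum, SpectrumSet

__all__ = [
    "DistanceTable",
    "StatsReport",
    "compute_reference",
    "tsd",
    "tpd",
    "tcd",
    "distance_table",
    "anova_distances",
    "regress_distance_vs_covariate",
    "correlate_band",
]


@dataclasses.dataclass
class DistanceTable:
    """Long-form distance values: one row per (sample, metric).

    ``table`` has columns sample_id, metric (TSD/TPD/TCD), value,
    reference_id; ``reference_definition`` documents how the reference
    spectrum was built.
    """

    table: pd.DataFrame
    reference_definition: str

    def __post_init__(self) -> None:
        required = {"sample_id", "metric", "value", "reference_id"}
        if not required.issubset(self.table.columns):
            raise ValueError(f"distance table needs columns {sorted(required)}")
        if (self.table["value"] < 0).any():
            raise ValueError("distances must be nonnegative")

    def values_for(self, metric: str) -> pd.Series:
        sub = self.table[self.table["metric"] == metric]
        return sub.set_index("sample_id")["value"]


@dataclasses.dataclass
class StatsReport:
    """ANOVA p-values per factor plus Tukey HSD pairwise comparisons."""

    anova: dict[str, float]
    pairwise: pd.DataFrame
    alpha: float = 0.01


def _check_grid(a: Spectrum | np.ndarray, b: Spectrum | np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    xa = a.intensities if isinstance(a, Spectrum) else np.asarray(a, dtype=float)
    xb = b.intensities if isinstance(b, Spectrum) else np.asarray(b, dtype=float)
    if isinstance(a, Spectrum) and isinstance(b, Spectrum):
        if a.shifts.size != b.shifts.size or not np.array_equal(a.shifts, b.shifts):
            raise ValueError("spectra are not on the same grid")
    elif xa.size != xb.size:
        raise ValueError("coordinate vectors differ in length")
    return xa, xb


def compute_reference(
    sset: SpectrumSet, control_group: str, group_column: str = "condition"
) -> Spectrum:
    """Pointwise mean of the control group's processed spectra."""
    groups = sset.factor_values(group_column)
    idx = [i for i, g in enumerate(groups) if str(g) == str(control_group)]
    if not idx:
        raise ValueError(f"no spectra with {group_column} == {control_group!r}")
    grid = sset.grid
    X = np.vstack([sset.spectra[i].intensities for i in idx])
    return Spectrum(grid, X.mean(axis=0), sample_id=f"reference:{control_group}")


def tsd(s: Spectrum | np.ndarray, ref: Spectrum | np.ndarray, kind: str = "l1") -> float:
    """Total spectral distance between a spectrum and the reference.

    ``l1`` (default) sums |S_x,i - S_ref,i| over the grid; ``l2`` is the
    Euclidean alternative.
    """
    x, r = _check_grid(s, ref)
    d = x - r
    if kind == "l1":
        return float(np.sum(np.abs(d)))
    if kind == "l2":
        return float(np.linalg.norm(d))
    raise ValueError(f"unknown distance kind {kind!r}")


def tpd(p_x: np.ndarray, p_ref: np.ndarray, n_components: int = 5, kind: str = "l1") -> float:
    """Total principal-component distance over the first five PC scores."""
    p_x = np.asarray(p_x, dtype=float)
    p_ref = np.asarray(p_ref, dtype=float)
    if p_x.size < n_components or p_ref.size < n_components:
        raise ValueError(f"need at least {n_components} PC scores")
    d = p_x[:n_components] - p_ref[:n_components]
    return float(np.sum(np.abs(d))) if kind == "l1" else float(np.linalg.norm(d))


def tcd(c_x: np.ndarray, c_ref: np.ndarray, n_components: int = 5, kind: str = "l1") -> float:
    """Total canonical distance over the top ``min(5, available)`` canonicals.

    A 2-class DAPC has a single canonical axis, so the sum runs over all
    available coordinates when fewer than five exist.
    """
    c_x = np.asarray(c_x, dtype=float)
    c_ref = np.asarray(c_ref, dtype=float)
    if c_x.size < 1 or c_x.size != c_ref.size:
        raise ValueError("need matching nonempty canonical score vectors")
    m = min(n_components, c_x.size)
    d = c_x[:m] - c_ref[:m]
    return float(np.sum(np.abs(d))) if kind == "l1" else float(np.linalg.norm(d))


def distance_table(
    sset: SpectrumSet,
    control_group: str,
    *,
    group_column: str = "condition",
    metrics: Sequence[str] = ("TSD", "TPD", "TCD"),
    pca: PCAModel | None = None,
    dapc: DAPCModel | None = None,
    kind: str = "l1",
) -> DistanceTable:
    """Build the per-spectrum distance table against the control mean.

    TPD requires a fitted PCA (reference scores are the projection of
    the reference spectrum); TCD additionally requires the DAPC model.
    """
    metrics = [m.upper() for m in metrics]
    ref = compute_reference(sset, control_group, group_column)
    ref_id = ref.sample_id
    rows = []
    if "TPD" in metrics or "TCD" in metrics:
        if pca is None:
            raise ValueError("TPD/TCD need a fitted PCA model")
        ref_pc = pca.transform(ref.intensities)
    if "TCD" in metrics:
        if dapc is None:
            raise ValueError("TCD needs a fitted DAPC model")
        ref_canon = dapc.transform(ref_pc)
    for s in sset.spectra:
        if "TSD" in metrics:
            rows.append((s.sample_id, "TSD", tsd(s, ref, kind), ref_id))
        if "TPD" in metrics:
            rows.append((s.sample_id, "TPD", tpd(pca.transform(s.intensities), ref_pc, kind=kind), ref_id))
        if "TCD" in metrics:
            canon = dapc.transform(pca.transform(s.intensities))
            rows.append((s.sample_id, "TCD", tcd(canon, ref_canon, kind=kind), ref_id))
    table = pd.DataFrame(rows, columns=["sample_id", "metric", "value", "reference_id"])
    return DistanceTable(
        table=table,
        reference_definition=(
            f"pointwise mean of processed spectra with {group_column} == {control_group!r}"
        ),
    )


def anova_distances(
    dtable: DistanceTable,
    metadata: pd.DataFrame,
    factors: Sequence[str],
    metric: str = "TSD",
    alpha: float = 0.01,
    tukey_factor: str | None = None,
) -> StatsReport:
    """Multi-way ANOVA of distances on the factors, plus Tukey HSD pairs.

    Type II sums of squares accommodate unbalanced designs; pairwise
    comparisons run on ``tukey_factor`` (default: the first factor) at
    the 99% confidence level by default.
    """
    factors = list(factors)
    if not factors:
        raise ValueError("at least one factor required")
    sub = dtable.table[dtable.table["metric"] == metric.upper()]
    if sub.empty:
        raise ValueError(f"no {metric} rows in the distance table")
    df = sub.merge(metadata, on="sample_id", how="left")
    for f in factors:
        if f not in df.columns:
            raise ValueError(f"factor {f!r} not found in metadata")
        levels = df[f].dropna().unique()
        if len(levels) < 2:
            raise ValueError(f"factor {f!r} has fewer than 2 levels")
        if df.groupby(f)["value"].count().min() < 2:
            raise ValueError(f"factor {f!r} has a level with fewer than 2 observations")
    formula = "value ~ " + " + ".join(f"C(Q('{f}'))" for f in factors)
    model = smf.ols(formula, data=df).fit()
    table = sm.stats.anova_lm(model, typ=2)
    anova_p = {
        f: float(table.loc[f"C(Q('{f}'))", "PR(>F)"]) for f in factors
    }
    tf = tukey_factor or factors[0]
    hsd = pairwise_tukeyhsd(df["value"].to_numpy(), df[tf].astype(str).to_numpy(), alpha=alpha)
    pairwise = pd.DataFrame(
        hsd.summary().data[1:], columns=[str(c) for c in hsd.summary().data[0]]
    ).rename(
        columns={
            "group1": "group_a",
            "group2": "group_b",
            "p-adj": "p_value",
            "reject": "significant",
        }
    )[["group_a", "group_b", "p_value", "significant"]]
    return StatsReport(anova=anova_p, pairwise=pairwise, alpha=alpha)


def regress_distance_vs_covariate(
    dtable: DistanceTable,
    metadata: pd.DataFrame,
    covariate: str,
    metric: str = "TSD",
) -> tuple[float, float, float]:
    """Ordinary least squares of distance on a numeric covariate.

    Returns ``(slope, intercept, R)`` with R the signed Pearson
    correlation coefficient.
    """
    sub = dtable.table[dtable.table["metric"] == metric.upper()]
    df = sub.merge(metadata, on="sample_id", how="left")
    if covariate not in df.columns:
        raise ValueError(f"covariate {covariate!r} not found in metadata")
    x = pd.to_numeric(df[covariate], errors="raise").to_numpy(dtype=float)
    y = df["value"].to_numpy(dtype=float)
    if np.unique(x).size < 3:
        raise ValueError("covariate must take at least 3 distinct values")
    res = scipy.stats.linregress(x, y)
    return float(res.slope), float(res.intercept), float(res.rvalue)


def correlate_band(
    sset: SpectrumSet,
    band: float,
    measurements: Mapping[str, float] | pd.Series,
    half_window: float = 0.0,
) -> float:
    """Pearson correlation of a single band's intensity with an analyte.

    The band intensity is read from each processed spectrum at the grid
    point nearest ``band`` (or averaged over ``band +- half_window`` when
    a half-window is given) and correlated against the external
    measurement keyed by sample id.
    """
    grid = sset.grid
    if band < grid[0] or band > grid[-1]:
        raise ValueError(f"band {band} cm^-1 outside the grid [{grid[0]}, {grid[-1]}]")
    meas = pd.Series(measurements)
    xs, ys = [], []
    for s in sset.spectra:
        if s.sample_id not in meas.index:
            continue
        if half_window > 0:
            mask = np.abs(grid - band) <= half_window
            xs.append(float(s.intensities[mask].mean()))
        else:
            xs.append(float(s.intensities[np.argmin(np.abs(grid - band))]))
        ys.append(float(meas[s.sample_id]))
    if len(xs) < 3:
        raise ValueError("need at least 3 paired observations")
    if np.ptp(xs) == 0 or np.ptp(ys) == 0:
        raise ValueError("constant vector; correlation undefined")
    r, _ = scipy.stats.pearsonr(xs, ys)
    return float(r)
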
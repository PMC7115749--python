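"""Study orchestration: preprocess -> model -> validate -> distances -> stats.

One :class:`StudyConfig` (usually loaded from YAML) drives a full replay:
raw spectra and metadata in, processed matrix, model JSON, validation
report, distance table and statistics out, every artifact stamped with
the config hash and seed for provenance.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import circadian as circ
from .chemometrics import contributions, fit_dapc, fit_pca
from .distance_stats import anova_distances, distance_table
from .preprocess import ProcessingParams, process_pipeline
from .spectra_io import SpectrumSet, read_metadata, read_spectrum_dir, read_spectrum_table, write_wide_matrix
from .validation import pc_sweep

logger = logging.getLogger("ramanphen")

__all__ = ["StudyConfig", "load_config", "run_study", "run_circadian", "circadian_time_course"]


@dataclasses.dataclass
class StudyConfig:
    """Everything needed to replay one study."""

    spectra_path: str
    metadata_path: str | None
    factor: str
    control_group: str
    output_dir: str
    dialect: str = "wide_matrix"
    group_column: str | None = None  # defaults to factor
    processing: ProcessingParams = dataclasses.field(default_factory=ProcessingParams)
    pc_grid: list[int] = dataclasses.field(default_factory=lambda: [2, 5, 10, 20])
    metrics: list[str] = dataclasses.field(default_factory=lambda: ["TSD", "TPD", "TCD"])
    distance_kind: str = "l1"
    tsd_threshold: float = 0.15
    seed: int = 0

    def content_hash(self) -> str:
        payload = dataclasses.asdict(self)
        payload["processing"] = dataclasses.asdict(self.processing)
        return hashlib.sha256(json.dumps(payload, sort_keys=True, default=str).encode()).hexdigest()[:16]


def load_config(path) -> StudyConfig:
    raw = yaml.safe_load(Path(path).read_text())
    proc = ProcessingParams(**raw.pop("processing", {}))
    return StudyConfig(processing=proc, **raw)


def _stamp(cfg: StudyConfig) -> dict:
    return {"config_hash": cfg.content_hash(), "seed": cfg.seed}


def _load_inputs(cfg: StudyConfig) -> SpectrumSet:
    p = Path(cfg.spectra_path)
    sset = read_spectrum_dir(p) if p.is_dir() else read_spectrum_table(p, dialect=cfg.dialect)
    if cfg.metadata_path:
        meta = read_metadata(cfg.metadata_path)
        sset = sset.with_metadata(meta)
    return sset


def _timed(stage: str):
    class _Timer:
        def __enter__(self):
            self.t0 = time.perf_counter()
            logger.info("stage %s: start", stage)
            return self

        def __exit__(self, exc_type, exc, tb):
            dt = time.perf_counter() - self.t0
            if exc is None:
                logger.info("stage %s: done in %.2fs", stage, dt)
            else:
                logger.error("stage %s: failed after %.2fs: %s", stage, dt, exc)
            return False

    return _Timer()


def run_study(cfg: StudyConfig, sset: SpectrumSet | None = None) -> dict:
    """Replay one classification study end to end.

    Emits processed.csv, model.json, validation.json, distances.csv,
    stats.json and summary.txt under the output directory and returns the
    in-memory bundle.
    """
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    stamp = _stamp(cfg)
    if sset is None:
        with _timed("load"):
            sset = _load_inputs(cfg)
    if cfg.factor not in sset.metadata.columns:
        raise ValueError(f"factor column {cfg.factor!r} not found in metadata")
    with _timed("preprocess"):
        processed = process_pipeline(sset, cfg.processing)
        write_wide_matrix(processed, out / "processed.csv")
    labels = [str(v) for v in processed.factor_values(cfg.factor)]
    with _timed("model"):
        pca = fit_pca(processed)
        best_pcs = min(max(cfg.pc_grid), pca.n_components)
        dapc = fit_dapc(pca, labels, best_pcs)
        model_json = {
            **stamp,
            "n_pcs": best_pcs,
            "explained_variance_ratio": pca.explained_variance_ratio.tolist(),
            "class_labels": [str(c) for c in dapc.class_labels],
            "group_centroids": dapc.group_centroids.tolist(),
            "canonical_axes": dapc.canonical_axes.tolist(),
            "pca_loadings": pca.loadings[:best_pcs].tolist(),
            "mean_spectrum": pca.mean_spectrum.tolist(),
            "contributions": contributions(dapc, 15, pca=pca).to_dict(orient="records"),
        }
        (out / "model.json").write_text(json.dumps(model_json))
    with _timed("validate"):
        feasible = [k for k in cfg.pc_grid if k <= len(processed) - 2]
        if not feasible:
            raise ValueError("no feasible n_pcs in pc_grid for this sample count")
        reports, best = pc_sweep(processed, labels, feasible)
        validation_json = {
            **stamp,
            "pc_grid": feasible,
            "best_index": best,
            "reports": [r.to_dict() for r in reports],
        }
        (out / "validation.json").write_text(json.dumps(validation_json))
    with _timed("distances"):
        dt = distance_table(
            processed,
            cfg.control_group,
            group_column=cfg.group_column or cfg.factor,
            metrics=cfg.metrics,
            pca=pca,
            dapc=dapc,
            kind=cfg.distance_kind,
        )
        dt.table.to_csv(out / "distances.csv", index=False)
    with _timed("stats"):
        stats = anova_distances(
            dt, processed.metadata, [cfg.factor],
            metric=cfg.metrics[0], alpha=0.01,
        )
        stats_json = {
            **stamp,
            "anova": stats.anova,
            "alpha": stats.alpha,
            "pairwise": stats.pairwise.to_dict(orient="records"),
        }
        (out / "stats.json").write_text(json.dumps(stats_json, default=str))
    best_report = reports[best]
    summary = (
        f"study replay  (config {stamp['config_hash']}, seed {cfg.seed})\n"
        + best_report.summary()
        + "\nANOVA p-values: "
        + ", ".join(f"{k}={v:.3g}" for k, v in stats.anova.items())
        + "\n"
    )
    (out / "summary.txt").write_text(summary)
    return {
        "processed": processed,
        "pca": pca,
        "dapc": dapc,
        "reports": reports,
        "best_index": best,
        "distances": dt,
        "stats": stats,
        **stamp,
    }


def circadian_time_course(
    sset: SpectrumSet,
    condition: str,
    params: ProcessingParams | None = None,
    kind: str = "l1",
) -> circ.TimeCourse:
    """Build the TSD time course of one condition from raw acquisitions.

    The initial phenotype reference is held out of the series: the
    earliest time point's replicate acquisitions are split in half, one
    half averaged into the reference spectrum and the other half standing
    in as the 0 h observation.  Without the split, the 0 h distance would
    be identically zero by construction (a spectrum compared to itself)
    while every later point carries the acquisition-noise floor, which
    would distort the fitted time course near its endpoints.
    """
    idx = [i for i, c in enumerate(sset.factor_values("condition")) if str(c) == str(condition)]
    if not idx:
        raise ValueError(f"no spectra with condition == {condition!r}")
    sub = sset.subset(idx)
    times = np.asarray([float(v) for v in sub.factor_values("time_h")])
    if np.unique(times).size < 2:
        raise ValueError(f"condition {condition!r} has a single time point")
    t0_sid = str(sub.spectra[int(np.argmin(times))].sample_id)
    t0_reps = sorted(s.replicate_index for s in sub.spectra if str(s.sample_id) == t0_sid)
    ref_sid = f"{t0_sid}__ref"
    ref_reps = set(t0_reps[: max(1, len(t0_reps) // 2)])
    spectra = [
        s.copy_with(sample_id=ref_sid)
        if str(s.sample_id) == t0_sid and s.replicate_index in ref_reps and len(t0_reps) > 1
        else s
        for s in sub.spectra
    ]
    meta = sub.metadata.copy()
    ref_row = meta[meta["sample_id"].astype(str) == t0_sid].iloc[0].to_dict()
    ref_row["sample_id"] = ref_sid
    meta = pd.concat([meta, pd.DataFrame([ref_row])], ignore_index=True)
    processed = process_pipeline(SpectrumSet(spectra, meta), params)
    from .distance_stats import tsd as _tsd

    ref = next(s for s in processed.spectra if str(s.sample_id) == ref_sid)
    rows = [
        (float(processed.meta_for(s.sample_id)["time_h"]), _tsd(s, ref, kind))
        for s in processed.spectra
        if str(s.sample_id) != ref_sid
    ]
    points = pd.DataFrame(sorted(rows), columns=["time_h", "tsd"])
    return circ.TimeCourse(points=points, condition=str(condition))


def run_circadian(cfg: StudyConfig, sset: SpectrumSet | None = None) -> dict:
    """TSD time-course replay: filter, quartic fit, rhythm classification.

    The reference phenotype is the held-out half of each condition's
    earliest sample (see :func:`circadian_time_course`); outputs
    circadian.json plus a plot-ready CSV.
    """
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    stamp = _stamp(cfg)
    if sset is None:
        with _timed("load"):
            sset = _load_inputs(cfg)
    if "time_h" not in sset.metadata.columns:
        raise ValueError("circadian analysis needs a time_h metadata column")
    results = {}
    tables = []
    for cond in pd.unique(sset.metadata["condition"].astype(str)):
        tc = circadian_time_course(sset, cond, cfg.processing, cfg.distance_kind)
        tc = circ.filter_outliers(tc, tsd_threshold=cfg.tsd_threshold)
        fit = circ.fit_quartic(tc)
        verdict = circ.classify_rhythm(fit)
        results[cond] = {
            "points": tc.points.to_dict(orient="records"),
            "coefficients": fit.coefficients.tolist(),
            "interior_maxima": fit.interior_maxima,
            "interior_minima": fit.interior_minima,
            "endpoint_values": fit.endpoint_values,
            **verdict,
        }
        tbl = tc.points.copy()
        tbl["condition"] = cond
        tbl["fitted"] = fit(tbl["time_h"].to_numpy(dtype=float))
        tables.append(tbl)
    (out / "circadian.json").write_text(json.dumps({**stamp, "conditions": results}))
    pd.concat(tables, ignore_index=True).to_csv(out / "circadian_points.csv", index=False)
    return {**stamp, "conditions": results}
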
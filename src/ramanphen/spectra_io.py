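"""Reading, writing and grid alignment of Raman spectra.

A :class:`Spectrum` is one acquisition: a strictly increasing Raman-shift
axis (cm^-1) with one intensity value per shift.  A :class:`SpectrumSet`
bundles many acquisitions with a sample-metadata table (condition factors,
replicate structure, time points).  Two plain-text dialects are supported:

* ``two_column`` — one file per acquisition, rows of ``shift,intensity``;
* ``wide_matrix`` — first column the shared shift axis, every further
  column one acquisition, header cell = sample id (optionally
  ``sample#replicate``).
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Spectrum",
    "SpectrumSet",
    "read_spectrum_table",
    "read_spectrum_dir",
    "read_metadata",
    "write_wide_matrix",
    "align_to_grid",
    "default_grid",
]


def default_grid(low: float = 400.0, high: float = 1800.0, step: float = 1.0) -> np.ndarray:
    """Common shift grid: 1 cm^-1 steps over the biological window by default."""
    return np.arange(low, high + step / 2, step, dtype=float)


@dataclasses.dataclass
class Spectrum:
    """One Raman acquisition on a strictly increasing shift axis."""

    shifts: np.ndarray
    intensities: np.ndarray
    sample_id: str = "sample"
    replicate_index: int = 0

    def __post_init__(self) -> None:
        self.shifts = np.asarray(self.shifts, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.shifts.ndim != 1 or self.intensities.ndim != 1:
            raise ValueError("shifts and intensities must be 1-D")
        if self.shifts.size != self.intensities.size:
            raise ValueError("shifts and intensities must have equal length")
        if self.shifts.size < 2:
            raise ValueError("a spectrum needs at least 2 points")
        if not np.all(np.isfinite(self.shifts)) or not np.all(np.isfinite(self.intensities)):
            raise ValueError("non-finite values in spectrum")
        if np.any(np.diff(self.shifts) <= 0):
            raise ValueError("axis not increasing")
        if self.replicate_index < 0:
            raise ValueError("replicate_index must be >= 0")

    def __len__(self) -> int:
        return self.shifts.size

    def copy_with(self, **kwargs) -> "Spectrum":
        fields = dict(
            shifts=self.shifts.copy(),
            intensities=self.intensities.copy(),
            sample_id=self.sample_id,
            replicate_index=self.replicate_index,
        )
        fields.update(kwargs)
        return Spectrum(**fields)


class SpectrumSet:
    """Ordered collection of spectra plus a sample-metadata table.

    The metadata table has exactly one row per distinct ``sample_id``;
    replicate acquisitions of a sample share that row.  ``provenance``
    accumulates a record per processing step applied to the set.
    """

    def __init__(
        self,
        spectra: Sequence[Spectrum],
        metadata: pd.DataFrame | None = None,
        provenance: list[dict] | None = None,
    ):
        self.spectra = list(spectra)
        if not self.spectra:
            raise ValueError("empty SpectrumSet")
        ids = [s.sample_id for s in self.spectra]
        if metadata is None:
            metadata = pd.DataFrame({"sample_id": pd.unique(np.asarray(ids, dtype=object))})
        if "sample_id" not in metadata.columns:
            raise ValueError("metadata must contain a sample_id column")
        if metadata["sample_id"].duplicated().any():
            dup = metadata.loc[metadata["sample_id"].duplicated(), "sample_id"].iloc[0]
            raise ValueError(f"duplicated sample_id in metadata: {dup!r}")
        known = set(metadata["sample_id"].astype(str))
        missing = [i for i in ids if str(i) not in known]
        if missing:
            raise ValueError(f"sample_id {missing[0]!r} missing from metadata")
        self.metadata = metadata.reset_index(drop=True)
        self.provenance = list(provenance or [])

    def __len__(self) -> int:
        return len(self.spectra)

    def __iter__(self):
        return iter(self.spectra)

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.spectra]

    @property
    def grid(self) -> np.ndarray:
        """Shared shift axis; raises if the spectra are not aligned."""
        g = self.spectra[0].shifts
        for s in self.spectra[1:]:
            if s.shifts.shape != g.shape or not np.array_equal(s.shifts, g):
                raise ValueError("spectra are not on a shared grid; call align_to_grid first")
        return g

    def on_shared_grid(self) -> bool:
        g = self.spectra[0].shifts
        return all(
            s.shifts.shape == g.shape and np.array_equal(s.shifts, g) for s in self.spectra
        )

    def to_matrix(self) -> tuple[np.ndarray, np.ndarray, list[str]]:
        """Return (grid, n_spectra x n_points intensity matrix, sample ids)."""
        g = self.grid
        X = np.vstack([s.intensities for s in self.spectra])
        return g, X, self.sample_ids

    def meta_for(self, sample_id: str) -> pd.Series:
        rows = self.metadata[self.metadata["sample_id"].astype(str) == str(sample_id)]
        if rows.empty:
            raise KeyError(sample_id)
        return rows.iloc[0]

    def factor_values(self, column: str) -> np.ndarray:
        """Metadata column broadcast to one value per spectrum, in order."""
        if column not in self.metadata.columns:
            raise KeyError(f"metadata column {column!r} not found")
        lut = self.metadata.set_index(self.metadata["sample_id"].astype(str))[column]
        return np.asarray([lut[str(s.sample_id)] for s in self.spectra])

    def with_metadata(self, metadata: pd.DataFrame) -> "SpectrumSet":
        return SpectrumSet(self.spectra, metadata, self.provenance)

    def with_provenance(self, record: dict) -> "SpectrumSet":
        return SpectrumSet(self.spectra, self.metadata, self.provenance + [record])

    def subset(self, indices: Iterable[int]) -> "SpectrumSet":
        spectra = [self.spectra[i] for i in indices]
        keep = {str(s.sample_id) for s in spectra}
        meta = self.metadata[self.metadata["sample_id"].astype(str).isin(keep)]
        return SpectrumSet(spectra, meta, self.provenance)


def _read_numeric_table(path: Path) -> pd.DataFrame:
    sep = "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","
    kwargs = dict(sep=sep, float_precision="round_trip")
    df = pd.read_csv(path, **kwargs)
    # headerless two-column files: first row is data, re-read without header
    try:
        float(df.columns[0])
    except (TypeError, ValueError):
        pass
    else:
        df = pd.read_csv(path, header=None, **kwargs)
    return df


def read_spectrum_table(path, dialect: str = "two_column") -> SpectrumSet:
    """Read a plain-text spectral table; values are taken as-is (no resampling).

    Parameters
    ----------
    path:
        CSV/TSV file. ``two_column``: rows of shift,intensity for a single
        acquisition (sample id = file stem). ``wide_matrix``: first column
        shifts, remaining columns one acquisition each; headers are sample
        ids, optionally ``sample#replicate``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = _read_numeric_table(path)
    numeric = df.apply(pd.to_numeric, errors="coerce")
    if numeric.isna().any().any():
        r, c = np.argwhere(numeric.isna().to_numpy())[0]
        raise ValueError(f"non-numeric cell at row {r}, column {df.columns[c]!r} in {path.name}")
    if dialect == "two_column":
        if numeric.shape[1] != 2:
            raise ValueError(f"two_column file must have 2 columns, got {numeric.shape[1]}")
        spec = Spectrum(
            numeric.iloc[:, 0].to_numpy(),
            numeric.iloc[:, 1].to_numpy(),
            sample_id=path.stem,
        )
        return SpectrumSet([spec])
    if dialect == "wide_matrix":
        shifts = numeric.iloc[:, 0].to_numpy()
        # read the raw header: pandas silently renames duplicate columns
        sep = "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","
        with open(path) as fh:
            header = [t.strip() for t in fh.readline().rstrip("\n").split(sep)]
        spectra = []
        seen: set[str] = set()
        next_rep: dict[str, int] = {}
        for j, name in enumerate(header[1:], start=1):
            if "#" in name:
                sid, _, rep = name.rpartition("#")
                rep_idx = int(rep)
            else:
                sid = name
                rep_idx = next_rep.get(name, 0)
                next_rep[name] = rep_idx + 1
            key = f"{sid}#{rep_idx}"
            if key in seen:
                raise ValueError(f"duplicate sample id {key!r} in {path.name}")
            seen.add(key)
            spectra.append(
                Spectrum(
                    shifts, numeric.iloc[:, j].to_numpy(), sample_id=sid, replicate_index=rep_idx
                )
            )
        return SpectrumSet(spectra)
    raise ValueError(f"unknown dialect {dialect!r}")


def read_spectrum_dir(directory, pattern: str = "*.csv") -> SpectrumSet:
    """Read every two-column file in a directory as one acquisition each."""
    directory = Path(directory)
    paths = sorted(directory.glob(pattern))
    if not paths:
        raise FileNotFoundError(f"no files matching {pattern!r} under {directory}")
    spectra: list[Spectrum] = []
    for p in paths:
        sub = read_spectrum_table(p, dialect="two_column")
        spec = sub.spectra[0]
        # filename convention sample#replicate.csv carries replicate structure
        if "#" in spec.sample_id:
            sid, _, rep = spec.sample_id.rpartition("#")
            spec = spec.copy_with(sample_id=sid, replicate_index=int(rep))
        spectra.append(spec)
    return SpectrumSet(spectra)


def write_wide_matrix(sset: SpectrumSet, path) -> None:
    """Write an aligned SpectrumSet as a wide-matrix CSV (full precision)."""
    g, X, ids = sset.to_matrix()
    cols = {"shift": g}
    for spec, row in zip(sset.spectra, X):
        cols[f"{spec.sample_id}#{spec.replicate_index}"] = row
    pd.DataFrame(cols).to_csv(path, index=False)  # repr precision round-trips


def read_metadata(path) -> pd.DataFrame:
    """Read the sample metadata CSV; unknown columns pass through untouched."""
    df = pd.read_csv(path)
    if "sample_id" not in df.columns:
        raise ValueError("metadata file lacks a sample_id column")
    if df["sample_id"].duplicated().any():
        dup = df.loc[df["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise ValueError(f"duplicated sample_id {dup!r} in metadata")
    return df


def align_to_grid(sset: SpectrumSet, grid: np.ndarray) -> SpectrumSet:
    """Linearly interpolate every spectrum onto ``grid`` (no extrapolation)."""
    grid = np.asarray(grid, dtype=float)
    if grid.ndim != 1 or grid.size < 2 or np.any(np.diff(grid) <= 0):
        raise ValueError("grid must be 1-D and strictly increasing")
    out = []
    for s in sset.spectra:
        if grid[0] < s.shifts[0] or grid[-1] > s.shifts[-1]:
            raise ValueError(
                f"grid [{grid[0]}, {grid[-1]}] extends beyond spectrum "
                f"{s.sample_id!r} range [{s.shifts[0]}, {s.shifts[-1]}]"
            )
        out.append(s.copy_with(shifts=grid, intensities=np.interp(grid, s.shifts, s.intensities)))
    return SpectrumSet(out, sset.metadata, sset.provenance).with_provenance(
        {"step": "align_to_grid", "low": float(grid[0]), "high": float(grid[-1]), "n": int(grid.size)}
    )
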
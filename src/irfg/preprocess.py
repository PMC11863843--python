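"""Standardization of raw spectra onto the fixed analysis grid.

Every spectrum is resampled by linear interpolation onto a common wavenumber
grid (default 600-4000 cm^-1 at 1 cm^-1, 3401 points), negative absorbance
is clipped to zero, and intensities are min-max normalized per spectrum to
[0, 1]. Grid cells outside the measured range are filled with 0, the
post-normalization baseline. Records are deduplicated per molecule by
keeping the most recently measured spectrum.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import datetime
from pathlib import Path

import numpy as np
import pandas as pd

from .catalog import DEFAULT_CATALOG, GROUP_NAMES, N_GROUPS, FunctionalGroupCatalog
from .fg_labeling import canonicalize_smiles, label_functional_groups
from .spectra_io import RawSpectrum, read_jcampdx, to_absorbance

__all__ = [
    "GRID_MIN",
    "GRID_MAX",
    "GRID_STEP",
    "default_grid",
    "Spectrum",
    "DatasetRecord",
    "interpolate_to_grid",
    "normalize_minmax",
    "preprocess_record",
    "dedup_latest",
    "slice_subset",
    "quality_screen",
    "load_manifest",
    "preprocess_manifest",
    "records_to_frame",
    "frame_to_records",
]

GRID_MIN = 600.0
GRID_MAX = 4000.0
GRID_STEP = 1.0


def default_grid(
    grid_min: float = GRID_MIN, grid_max: float = GRID_MAX, step: float = GRID_STEP
) -> np.ndarray:
    """Inclusive wavenumber grid; defaults give 3401 points."""
    n = int(round((grid_max - grid_min) / step)) + 1
    return np.linspace(grid_min, grid_max, n)


@dataclass(eq=False)
class Spectrum:
    """A preprocessed spectrum: intensities in [0, 1] on a fixed grid."""

    grid: np.ndarray
    intensities: np.ndarray

    def __post_init__(self):
        self.grid = np.asarray(self.grid, dtype=np.float64)
        self.intensities = np.asarray(self.intensities, dtype=np.float64)
        if self.grid.shape != self.intensities.shape:
            raise ValueError("grid/intensity length mismatch")
        if self.intensities.size and (
            self.intensities.min() < -1e-9 or self.intensities.max() > 1 + 1e-9
        ):
            raise ValueError("intensities must lie in [0, 1]")


@dataclass(eq=False)
class DatasetRecord:
    """One sample: spectrum + canonical SMILES + 17-bit label vector."""

    id: str
    smiles: str | None
    spectrum: Spectrum
    labels: np.ndarray
    timestamp: str = ""

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=np.int8)
        if self.labels.shape != (N_GROUPS,):
            raise ValueError(f"labels must have length {N_GROUPS}")


def interpolate_to_grid(raw: RawSpectrum, grid: np.ndarray) -> np.ndarray:
    """Piecewise-linear resampling; points outside the measured range are 0."""
    grid = np.asarray(grid, dtype=np.float64)
    if grid.size == 0:
        raise ValueError("empty interpolation grid")
    return np.interp(grid, raw.wavenumbers, raw.intensities, left=0.0, right=0.0)


def normalize_minmax(v: np.ndarray) -> np.ndarray:
    """(v - min) / (max - min); a constant vector maps to all zeros."""
    v = np.asarray(v, dtype=np.float64)
    lo, hi = v.min(), v.max()
    if hi == lo:
        return np.zeros_like(v)
    return (v - lo) / (hi - lo)


def preprocess_record(
    jcamp_path: str | Path,
    smiles: str,
    record_id: str,
    timestamp: str = "",
    grid: np.ndarray | None = None,
    catalog: FunctionalGroupCatalog = DEFAULT_CATALOG,
) -> DatasetRecord:
    """Full per-sample pipeline: read, absorbance, resample, normalize, label.

    Steps run in this fixed order: parse JCAMP -> convert to absorbance ->
    linear interpolation onto the grid -> clip negatives to 0 -> per-spectrum
    min-max normalization -> SMARTS labeling of the SMILES. Any error is
    re-raised with the record id prefixed to its message.
    """
    if grid is None:
        grid = default_grid()
    try:
        raw = to_absorbance(read_jcampdx(jcamp_path))
        x = interpolate_to_grid(raw, grid)
        x = normalize_minmax(np.clip(x, 0.0, None))
        canon = canonicalize_smiles(smiles)
        labels = label_functional_groups(canon, catalog)
    except Exception as e:
        raise type(e)(f"[record {record_id}] {e}") from e
    return DatasetRecord(record_id, canon, Spectrum(grid, x), labels, timestamp)


def _parse_ts(ts: str) -> datetime:
    return datetime.fromisoformat(ts)


def dedup_latest(records: list[DatasetRecord]) -> list[DatasetRecord]:
    """Keep one record per canonical SMILES: the latest timestamp.

    Ties on the timestamp are broken by lexicographically larger record id,
    so the result is deterministic. Records without a SMILES are kept as-is.
    Input order of the survivors is preserved; the operation is idempotent.
    """
    best: dict[str, DatasetRecord] = {}
    for rec in records:
        if rec.smiles is None:
            continue
        cur = best.get(rec.smiles)
        if cur is None:
            best[rec.smiles] = rec
            continue
        key_new = (_parse_ts(rec.timestamp), rec.id)
        key_cur = (_parse_ts(cur.timestamp), cur.id)
        if key_new > key_cur:
            best[rec.smiles] = rec
    kept = {id(r) for r in best.values()}
    return [r for r in records if r.smiles is None or id(r) in kept]


def slice_subset(
    records: list[DatasetRecord],
    groups: set[str],
    catalog: FunctionalGroupCatalog = DEFAULT_CATALOG,
) -> list[DatasetRecord]:
    """Records whose label vector is positive for at least one named group."""
    idx = [catalog.index(g) for g in groups]  # raises KeyError on unknown name
    return [r for r in records if any(r.labels[i] for i in idx)]


def quality_screen(
    records: list[DatasetRecord], median_threshold: float = 0.5
) -> list[DatasetRecord]:
    """Drop spectra whose median normalized intensity exceeds the threshold.

    A crude automated screen for high-baseline / saturated spectra, meant as
    a reproducible stand-in for manual visual curation. Disabled by default
    in the pipeline.
    """
    return [
        r for r in records if float(np.median(r.spectrum.intensities)) <= median_threshold
    ]


# ---------------------------------------------------------------------------
# manifest / table I/O

MANIFEST_COLUMNS = ("id", "smiles", "jcamp_path", "timestamp")


def load_manifest(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    missing = set(MANIFEST_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"manifest {path} missing columns: {sorted(missing)}")
    return df


def preprocess_manifest(
    manifest_path: str | Path,
    grid: np.ndarray | None = None,
    dedup: bool = True,
    screen: bool = False,
    catalog: FunctionalGroupCatalog = DEFAULT_CATALOG,
) -> list[DatasetRecord]:
    """Run :func:`preprocess_record` over every manifest row."""
    df = load_manifest(manifest_path)
    base = Path(manifest_path).parent
    records = []
    for row in df.itertuples(index=False):
        p = Path(row.jcamp_path)
        if not p.is_absolute():
            p = base / p
        records.append(
            preprocess_record(p, row.smiles, row.id, row.timestamp, grid, catalog)
        )
    if screen:
        records = quality_screen(records)
    if dedup:
        records = dedup_latest(records)
    return records


def records_to_frame(records: list[DatasetRecord]) -> pd.DataFrame:
    """Flat table: id, smiles, timestamp, 17 label columns, grid columns."""
    if not records:
        raise ValueError("no records")
    grid = records[0].spectrum.grid
    for r in records:
        if not np.array_equal(r.spectrum.grid, grid):
            raise ValueError("records are on inconsistent grids")
    data = {
        "id": [r.id for r in records],
        "smiles": [r.smiles or "" for r in records],
        "timestamp": [r.timestamp for r in records],
    }
    labels = np.stack([r.labels for r in records])
    for j, name in enumerate(GROUP_NAMES):
        data[f"label:{name}"] = labels[:, j]
    intens = np.stack([r.spectrum.intensities for r in records])
    frame = pd.DataFrame(data)
    spec = pd.DataFrame(
        intens, columns=[f"{w:.6g}" for w in grid], index=frame.index
    )
    return pd.concat([frame, spec], axis=1)


def frame_to_records(df: pd.DataFrame) -> list[DatasetRecord]:
    label_cols = [f"label:{n}" for n in GROUP_NAMES]
    meta_cols = ["id", "smiles", "timestamp"] + label_cols
    grid_cols = [c for c in df.columns if c not in meta_cols]
    grid = np.array([float(c) for c in grid_cols])
    records = []
    for _, row in df.iterrows():
        spec = Spectrum(grid, row[grid_cols].to_numpy(dtype=np.float64))
        labels = row[label_cols].to_numpy(dtype=np.int8)
        records.append(
            DatasetRecord(
                str(row["id"]), str(row["smiles"]) or None, spec, labels,
                str(row["timestamp"]) if not pd.isna(row["timestamp"]) else "",
            )
        )
    return records
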
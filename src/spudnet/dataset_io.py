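"""Reading/writing spectral tables and grouped, stratified data splits.

The on-disk dialect is a plain CSV: a header ``tuber_id,grade,replicate``
followed by one column per wavelength (name = wavelength in nm, two
decimals), one row per spectrum. Splits follow the 80/10/10
calibration/validation/test protocol; by default they are stratified by
grade and grouped by tuber so noisy replicates never leak across sets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .synthetic import GRADES, GradeLabel, SpectralDataset, WavelengthGrid

__all__ = [
    "SplitSpec",
    "DatasetSplit",
    "write_spectra_table",
    "read_spectra_table",
    "stratified_split",
]

_META_COLS = ("tuber_id", "grade", "replicate")


def write_spectra_table(ds: SpectralDataset, path) -> None:
    """Write a dataset as a CSV table (one row per spectrum)."""
    frame = pd.DataFrame(
        {
            "tuber_id": ds.tuber_ids.astype(str),
            "grade": [GradeLabel(int(g)).name for g in ds.grades],
            "replicate": ds.replicate_index,
        }
    )
    wl_cols = [f"{w:.2f}" for w in ds.grid.values]
    spectra = pd.DataFrame(ds.intensities, columns=wl_cols, index=frame.index)
    try:
        pd.concat([frame, spectra], axis=1).to_csv(
            path, index=False, float_format="%.12g"
        )
    except OSError as exc:  # pragma: no cover - passthrough with context
        raise OSError(f"failed to write spectra table to {path}: {exc}") from exc


def read_spectra_table(path) -> SpectralDataset:
    """Read a dataset written by :func:`write_spectra_table`."""
    try:
        df = pd.read_csv(path)
    except OSError as exc:
        raise OSError(f"failed to read spectra table from {path}: {exc}") from exc
    for col in _META_COLS:
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column '{col}'")
    wl_cols = [c for c in df.columns if c not in _META_COLS]
    if len(wl_cols) < 2:
        raise ValueError(f"{path}: needs at least two wavelength columns")
    try:
        wl = np.array([float(c) for c in wl_cols])
    except ValueError as exc:
        raise ValueError(f"{path}: non-numeric wavelength column name: {exc}") from exc
    if not np.all(np.diff(wl) > 0):
        raise ValueError(f"{path}: wavelength columns are not strictly increasing")
    grades = np.empty(len(df), dtype=int)
    for i, token in enumerate(df["grade"].astype(str)):
        try:
            grades[i] = GradeLabel[token]
        except KeyError:
            raise ValueError(
                f"{path}: line {i + 2}: unknown grade token '{token}'"
            ) from None
    values = df[wl_cols].to_numpy(dtype=float)
    if not np.all(np.isfinite(values)):
        bad = int(np.where(~np.isfinite(values).all(axis=1))[0][0])
        raise ValueError(f"{path}: line {bad + 2}: non-finite intensity values")
    return SpectralDataset(
        grid=WavelengthGrid(wl),
        intensities=values,
        grades=grades,
        tuber_ids=df["tuber_id"].astype(str).to_numpy(dtype=object),
        replicate_index=df["replicate"].to_numpy(dtype=int),
    )


@dataclass(frozen=True)
class SplitSpec:
    """Calibration/validation/test fractions plus split policy."""

    fractions: tuple[float, float, float] = (0.8, 0.1, 0.1)
    seed: int = 0
    stratify_by_grade: bool = True
    group_by_tuber: bool = True

    def __post_init__(self) -> None:
        f = self.fractions
        if len(f) != 3 or any(x <= 0 for x in f):
            raise ValueError("three positive fractions are required")
        if abs(sum(f) - 1.0) > 1e-9:
            raise ValueError("fractions must sum to 1")


@dataclass
class DatasetSplit:
    """Disjoint, exhaustive index sets over a dataset."""

    calibration: np.ndarray
    validation: np.ndarray
    test: np.ndarray

    SET_NAMES = ("calibration", "validation", "test")

    def indices(self, name: str) -> np.ndarray:
        if name not in self.SET_NAMES:
            raise KeyError(f"unknown set '{name}'; expected one of {self.SET_NAMES}")
        return getattr(self, name)

    def __iter__(self):
        return iter((self.calibration, self.validation, self.test))


def _allocate(n: int, fractions) -> list[int]:
    """Largest-remainder apportionment of n items over the fractions."""
    raw = [f * n for f in fractions]
    base = [int(np.floor(r)) for r in raw]
    short = n - sum(base)
    order = np.argsort([-(r - b) for r, b in zip(raw, base)], kind="stable")
    for j in range(short):
        base[order[j]] += 1
    return base


def stratified_split(ds: SpectralDataset, spec: SplitSpec) -> DatasetSplit:
    """Partition a dataset into calibration/validation/test sets.

    With ``group_by_tuber`` the unit of assignment is the tuber, so every
    replicate of a spectrum lands in the same set as its original; with
    ``stratify_by_grade`` the fractions are honoured within each grade.
    """
    if len(ds) == 0:
        raise ValueError("cannot split an empty dataset")
    rng = np.random.default_rng(spec.seed)

    if spec.group_by_tuber:
        units, first_idx = np.unique(ds.tuber_ids.astype(str), return_index=True)
        unit_grades = ds.grades[first_idx]
    else:
        units = np.arange(len(ds))
        unit_grades = ds.grades

    strata = (
        [int(g) for g in GRADES if (unit_grades == int(g)).any()]
        if spec.stratify_by_grade
        else [None]
    )
    assign: dict = {}
    for g in strata:
        mask = np.ones(len(units), bool) if g is None else unit_grades == g
        members = np.where(mask)[0]
        if spec.stratify_by_grade and len(members) < 3:
            raise ValueError(
                f"grade {GradeLabel(g).name} has {len(members)} tubers; "
                "stratified splitting needs at least 3 per grade"
            )
        perm = rng.permutation(members)
        n_cal, n_val, n_test = _allocate(len(perm), spec.fractions)
        for k, u in enumerate(perm):
            assign[units[u]] = 0 if k < n_cal else (1 if k < n_cal + n_val else 2)

    if spec.group_by_tuber:
        row_sets = np.array([assign[str(t)] for t in ds.tuber_ids])
    else:
        row_sets = np.array([assign[i] for i in range(len(ds))])
    return DatasetSplit(
        calibration=np.where(row_sets == 0)[0],
        validation=np.where(row_sets == 1)[0],
        test=np.where(row_sets == 2)[0],
    )
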
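"""Synthetic Vis/NIR transmission spectra of potato tubers.

The generator emulates the empirical structure of transmittance spectra of
healthy and blackheart-affected tubers measured on a 350-1000 nm instrument:

* a smooth, positive instrument/tissue baseline peaking in the red region;
* a grade-dependent attenuation band over roughly 650-850 nm whose depth
  increases with blackheart severity and is deepest near 703 nm, so the
  healthy-minus-severe difference curve peaks there;
* a second, weaker attenuation bump over 500-650 nm that affects only the
  two severe grades, leaving the healthy and grade-2 mean curves nearly
  coincident in that window;
* a per-tuber multiplicative size factor (log-normal) standing in for the
  optical path-length variation of tubers of different diameter, plus small
  additive sensor noise.

Gaussian-noise augmentation expands a measured set by adding, per original
spectrum, a configurable number of noisy replicates whose noise scale is a
fraction of the per-wavelength standard deviation of the dataset.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from enum import IntEnum

import numpy as np

__all__ = [
    "GradeLabel",
    "WavelengthGrid",
    "Spectrum",
    "SpectralDataset",
    "SimulationConfig",
    "NoiseModel",
    "make_grid",
    "simulate_spectrum",
    "simulate_dataset",
    "augment_gaussian",
    "mean_spectrum_by_grade",
]

INSTRUMENT_LO_NM = 350.0
INSTRUMENT_HI_NM = 1000.0


class GradeLabel(IntEnum):
    """Blackheart severity grade, ordered by affected cut-face area.

    HEALTHY absorbs everything below 10% affected area (the visual grading
    scheme assigns grade 1 both to a 0% and to a <10% black-center area).
    """

    HEALTHY = 1
    GRADE2 = 2
    GRADE3 = 3
    GRADE4 = 4

    @property
    def area_interval(self) -> tuple[float, float]:
        """Blackheart-area fraction interval (lo inclusive, hi exclusive)."""
        return {
            GradeLabel.HEALTHY: (0.0, 0.10),
            GradeLabel.GRADE2: (0.10, 0.25),
            GradeLabel.GRADE3: (0.25, 0.50),
            GradeLabel.GRADE4: (0.50, 1.0),
        }[self]


GRADES: tuple[GradeLabel, ...] = tuple(GradeLabel)


@dataclass(frozen=True)
class WavelengthGrid:
    """Strictly increasing wavelengths (nm) inside the instrument range."""

    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.ndim != 1 or v.size < 2:
            raise ValueError("wavelength grid needs at least two points")
        if not np.all(np.diff(v) > 0):
            raise ValueError("wavelengths must be strictly increasing")
        if v[0] < INSTRUMENT_LO_NM or v[-1] > INSTRUMENT_HI_NM:
            raise ValueError(
                f"grid must lie within the instrument range "
                f"[{INSTRUMENT_LO_NM}, {INSTRUMENT_HI_NM}] nm"
            )

    def __len__(self) -> int:
        return int(self.values.size)

    def __eq__(self, other) -> bool:  # value equality, not identity
        return isinstance(other, WavelengthGrid) and np.array_equal(
            self.values, other.values
        )


@dataclass
class Spectrum:
    """One transmission scan: intensity counts on a wavelength grid."""

    tuber_id: str
    grade: GradeLabel
    intensities: np.ndarray
    replicate_index: int = 0

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        if not np.all(np.isfinite(self.intensities)):
            raise ValueError("spectrum intensities must be finite")
        if self.replicate_index < 0:
            raise ValueError("replicate_index must be >= 0")


@dataclass
class SpectralDataset:
    """Spectra stored as a dense (n_spectra, n_wavelengths) matrix."""

    grid: WavelengthGrid
    intensities: np.ndarray
    grades: np.ndarray
    tuber_ids: np.ndarray
    replicate_index: np.ndarray

    def __post_init__(self) -> None:
        self.intensities = np.atleast_2d(np.asarray(self.intensities, float))
        if self.intensities.size == 0:
            self.intensities = self.intensities.reshape(0, len(self.grid))
        self.grades = np.asarray(self.grades, dtype=int)
        self.tuber_ids = np.asarray(self.tuber_ids, dtype=object)
        self.replicate_index = np.asarray(self.replicate_index, dtype=int)
        n = self.intensities.shape[0]
        if self.intensities.shape[1] != len(self.grid):
            raise ValueError("spectra length does not match the grid")
        if not (len(self.grades) == len(self.tuber_ids) == len(self.replicate_index) == n):
            raise ValueError("inconsistent dataset field lengths")

    def __len__(self) -> int:
        return self.intensities.shape[0]

    @property
    def composition(self) -> dict[GradeLabel, int]:
        c = Counter(self.grades.tolist())
        return {g: c.get(int(g), 0) for g in GRADES}

    def spectra(self):
        for i in range(len(self)):
            yield Spectrum(
                tuber_id=str(self.tuber_ids[i]),
                grade=GradeLabel(int(self.grades[i])),
                intensities=self.intensities[i],
                replicate_index=int(self.replicate_index[i]),
            )

    def subset(self, idx) -> "SpectralDataset":
        idx = np.asarray(idx, dtype=int)
        return SpectralDataset(
            grid=self.grid,
            intensities=self.intensities[idx],
            grades=self.grades[idx],
            tuber_ids=self.tuber_ids[idx],
            replicate_index=self.replicate_index[idx],
        )


DEFAULT_COMPOSITION = {
    GradeLabel.HEALTHY: 265,
    GradeLabel.GRADE2: 150,
    GradeLabel.GRADE3: 78,
    GradeLabel.GRADE4: 150,
}


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic tuber-spectrum generator.

    Attenuation depths are dimensionless optical depths: transmittance is
    multiplied by exp(-depth * profile(lambda)). ``band_depths`` act on the
    650-850 nm band profile (peak at ``peak_nm``) and must increase strictly
    with severity; ``low_band_depths`` act on the 500-650 nm bump and are
    equal (zero) for the healthy and grade-2 classes so those mean curves
    coincide there.
    """

    n_points: int = 2048
    lo_nm: float = INSTRUMENT_LO_NM
    hi_nm: float = INSTRUMENT_HI_NM
    composition: tuple[int, int, int, int] = (265, 150, 78, 150)
    peak_nm: float = 703.0
    peak_sigma: tuple[float, float] = (18.0, 60.0)
    band: tuple[float, float] = (650.0, 850.0)
    band_shelf: float = 0.30
    band_depths: tuple[float, float, float, float] = (0.0, 0.45, 0.85, 1.30)
    low_band: tuple[float, float] = (500.0, 650.0)
    low_band_depths: tuple[float, float, float, float] = (0.0, 0.0, 0.10, 0.18)
    baseline_amplitude: float = 30000.0
    size_sigma: float = 0.05
    sensor_noise: float = 0.003
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_points < 2:
            raise ValueError("n_points must be >= 2")
        if any(c < 0 for c in self.composition):
            raise ValueError("composition counts must be >= 0")
        if not np.all(np.diff(self.band_depths) > 0):
            raise ValueError("band attenuation depths must increase with severity")
        if self.low_band_depths[0] != self.low_band_depths[1]:
            raise ValueError("healthy and grade-2 low-band depths must be equal")

    @property
    def grid(self) -> WavelengthGrid:
        return make_grid(self.n_points, self.lo_nm, self.hi_nm)


@dataclass(frozen=True)
class NoiseModel:
    """Gaussian augmentation noise.

    ``sigma`` is a fraction of the dataset's per-wavelength standard
    deviation (the measured spread at each wavelength sets the scale of a
    plausible perturbation there).
    """

    sigma: float = 0.01
    replicates_per_original: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")
        if self.replicates_per_original < 0:
            raise ValueError("replicates_per_original must be >= 0")


def make_grid(n_points: int, lo_nm: float, hi_nm: float) -> WavelengthGrid:
    """Evenly spaced wavelength grid from ``lo_nm`` to ``hi_nm`` inclusive."""
    if n_points < 2:
        raise ValueError("n_points must be >= 2")
    if not (INSTRUMENT_LO_NM <= lo_nm < hi_nm <= INSTRUMENT_HI_NM):
        raise ValueError(
            f"bounds must satisfy {INSTRUMENT_LO_NM} <= lo < hi <= {INSTRUMENT_HI_NM}"
        )
    return WavelengthGrid(np.linspace(lo_nm, hi_nm, n_points))


def _smoothstep(x: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """C1 ramp from 0 at ``lo`` to 1 at ``hi``."""
    t = np.clip((x - lo) / (hi - lo), 0.0, 1.0)
    return t * t * (3.0 - 2.0 * t)


def _baseline(lam: np.ndarray, amplitude: float) -> np.ndarray:
    # Broad bell over ~500-900 nm on a small positive pedestal.
    bell = np.exp(-0.5 * ((lam - 700.0) / 120.0) ** 2)
    return amplitude * (0.05 + 0.95 * bell)


def _band_profile(lam: np.ndarray, cfg: SimulationConfig) -> np.ndarray:
    """Severity band: sharp asymmetric peak at ``peak_nm`` on a broad shelf.

    The left flank is steep so the profile is negligible below 650 nm (the
    healthy/grade-2 coincidence window must stay clean); the shelf keeps the
    profile strictly positive across the whole 650-850 nm band so the mean
    curves stay severity-ordered pointwise there.
    """
    lo, hi = cfg.band
    sigma = np.where(lam < cfg.peak_nm, cfg.peak_sigma[0], cfg.peak_sigma[1])
    peak = np.exp(-0.5 * ((lam - cfg.peak_nm) / sigma) ** 2)
    shelf = _smoothstep(lam, lo - 4.0, lo + 26.0) * (
        1.0 - _smoothstep(lam, hi - 35.0, hi + 35.0)
    )
    return peak + cfg.band_shelf * shelf


def _low_band_profile(lam: np.ndarray, cfg: SimulationConfig) -> np.ndarray:
    lo, hi = cfg.low_band
    return _smoothstep(lam, lo - 5.0, lo + 15.0) * (
        1.0 - _smoothstep(lam, hi - 20.0, hi + 5.0)
    )


def grade_transmittance(grade: GradeLabel, cfg: SimulationConfig) -> np.ndarray:
    """Noise-free attenuation curve of a grade on the config's grid."""
    lam = cfg.grid.values
    gi = int(grade) - 1
    depth = cfg.band_depths[gi] * _band_profile(lam, cfg)
    depth = depth + cfg.low_band_depths[gi] * _low_band_profile(lam, cfg)
    return np.exp(-depth)


def simulate_spectrum(
    grade: GradeLabel, config: SimulationConfig, seed: int
) -> Spectrum:
    """One tuber scan: baseline x grade attenuation x size factor + noise.

    Deterministic for a fixed (grade, config, seed) triple.
    """
    grade = GradeLabel(grade)
    rng = np.random.default_rng([int(seed), int(config.seed), int(grade)])
    lam = config.grid.values
    base = _baseline(lam, config.baseline_amplitude)
    size_factor = float(np.exp(rng.normal(0.0, config.size_sigma)))
    clean = base * grade_transmittance(grade, config) * size_factor
    noise = rng.normal(0.0, config.sensor_noise * (base + 50.0))
    intensities = np.maximum(clean + noise, 0.0)
    return Spectrum(
        tuber_id=f"T{int(grade)}-{int(seed):05d}",
        grade=grade,
        intensities=intensities,
        replicate_index=0,
    )


def simulate_dataset(config: SimulationConfig | None = None) -> SpectralDataset:
    """Dataset with exactly the configured per-grade composition.

    Default composition mirrors the study cohort: 265 healthy, 150 grade-2,
    78 grade-3 and 150 grade-4 tubers (643 spectra, one per tuber).
    """
    config = config or SimulationConfig()
    rows, grades, ids = [], [], []
    counter = 0
    for grade, count in zip(GRADES, config.composition):
        for _ in range(count):
            spec = simulate_spectrum(grade, config, seed=counter)
            rows.append(spec.intensities)
            grades.append(int(grade))
            ids.append(spec.tuber_id)
            counter += 1
    n = len(rows)
    return SpectralDataset(
        grid=config.grid,
        intensities=np.array(rows) if rows else np.empty((0, config.n_points)),
        grades=np.array(grades, dtype=int),
        tuber_ids=np.array(ids, dtype=object),
        replicate_index=np.zeros(n, dtype=int),
    )


def augment_gaussian(ds: SpectralDataset, noise: NoiseModel) -> SpectralDataset:
    """Originals plus ``replicates_per_original`` noisy copies of each.

    Copies inherit the parent tuber id and grade and carry replicate_index
    >= 1; the output size is len(ds) * (1 + replicates_per_original).
    """
    if len(ds) == 0:
        raise ValueError("cannot augment an empty dataset")
    m = noise.replicates_per_original
    if m == 0:
        return ds.subset(np.arange(len(ds)))
    rng = np.random.default_rng(noise.seed)
    scale = ds.intensities.std(axis=0, ddof=0)
    blocks = [ds.intensities]
    for _ in range(m):
        blocks.append(
            ds.intensities + rng.normal(0.0, 1.0, ds.intensities.shape) * (noise.sigma * scale)
        )
    reps = [ds.replicate_index] + [
        np.full(len(ds), r, dtype=int) for r in range(1, m + 1)
    ]
    return SpectralDataset(
        grid=ds.grid,
        intensities=np.vstack(blocks),
        grades=np.tile(ds.grades, m + 1),
        tuber_ids=np.tile(ds.tuber_ids, m + 1),
        replicate_index=np.concatenate(reps),
    )


def mean_spectrum_by_grade(ds: SpectralDataset) -> dict[GradeLabel, np.ndarray]:
    """Arithmetic mean intensity per wavelength for each grade present."""
    if len(ds) == 0:
        raise ValueError("cannot average an empty dataset")
    out: dict[GradeLabel, np.ndarray] = {}
    for g in GRADES:
        mask = ds.grades == int(g)
        if mask.any():
            out[g] = ds.intensities[mask].mean(axis=0)
    return out
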
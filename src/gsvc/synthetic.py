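"""Artificial two-subject activation datasets with controlled inter-subject variability.

The generator emulates a rectangular region of interest of 20 x 100 pixels
containing three horizontal bands stacked along the 100-pixel axis.  The outer
bands are inactive (baseline 0) while the middle band is active, at level
``a(y) = 1`` or ``2`` depending on the experimental condition ``y``.  Two kinds
of inter-subject variability are injected parametrically:

* geometric — the middle band of the second subject is shifted so that it
  overlaps the first subject's middle band by 100 / 67 / 33 / 0 %;
* activation — a per-(parcel, condition, subject) Gaussian perturbation
  ``eta ~ N(0, sigma_eta**2)`` is added to the band levels, drawn once per
  dataset and held fixed across its trials.

Each trial additionally receives spatially smoothed pixel noise: i.i.d.
``N(0, sigma_pix**2)`` values smoothed by a 2-D Gaussian filter of FWHM 2.35
pixels.  The underlying band pattern itself is piecewise constant and is *not*
smoothed, so band edges are hard when ``sigma_pix = 0``.

Internally images are arrays of shape ``(100, 100-axis rows, 20 columns)``:
row index runs along the axis on which the bands are stacked, and the point
coordinate system is 0-based ``(row, col)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

#: Conversion factor between the full width at half maximum of a Gaussian and
#: its standard deviation: sigma = FWHM / (2 * sqrt(2 * ln 2)).
FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))

#: Default grid: 100 rows (the band-stacking axis) by 20 columns.
DEFAULT_GRID_SHAPE = (100, 20)

#: Default baseline activation level per condition, a(y).
DEFAULT_ACTIVE_LEVELS = {1: 1.0, 2: 2.0}


class InvalidGeometryError(ValueError):
    """The requested band layout does not fit inside the grid."""


def overlap_to_offset(overlap_fraction: float, middle_height: int = 30, b_s1: int = 20,
                      n_rows: int = 100) -> int:
    """Starting row of the second subject's middle band for a given overlap.

    The first subject's middle band starts at row ``b_s1``; shifting the second
    subject's band down by ``(1 - overlap_fraction) * middle_height`` rows
    produces exactly the requested fractional overlap.  With the defaults
    (``b_s1 = 20``, ``middle_height = 30``) the canonical overlap levels
    1.0 / 0.67 / 0.33 / 0.0 map to offsets 20 / 30 / 40 / 50.
    """
    if not 0.0 <= overlap_fraction <= 1.0:
        raise ValueError(f"overlap_fraction must be in [0, 1], got {overlap_fraction}")
    if middle_height <= 0:
        raise ValueError("middle_height must be positive")
    offset = int(b_s1 + round((1.0 - overlap_fraction) * middle_height))
    if offset < 0 or offset + middle_height > n_rows:
        raise InvalidGeometryError(
            f"middle band [{offset}, {offset + middle_height}) does not fit in {n_rows} rows"
        )
    return offset


@dataclass(frozen=True)
class SubjectPatternSpec:
    """Layout and activation levels of one subject's true underlying pattern.

    ``eta`` maps ``(parcel_index, condition)`` to the activation perturbation of
    that parcel under that condition; parcel indices are 0 (top band), 1
    (middle band), 2 (bottom band).
    """

    middle_offset: int
    middle_height: int = 30
    active_levels: Mapping[int, float] = field(default_factory=lambda: dict(DEFAULT_ACTIVE_LEVELS))
    eta: Mapping[tuple[int, int], float] = field(default_factory=dict)
    grid_shape: tuple[int, int] = DEFAULT_GRID_SHAPE

    def __post_init__(self) -> None:
        n_rows = self.grid_shape[0]
        if self.middle_offset < 0 or self.middle_offset + self.middle_height > n_rows:
            raise InvalidGeometryError(
                f"middle band [{self.middle_offset}, "
                f"{self.middle_offset + self.middle_height}) outside grid of {n_rows} rows"
            )

    def band_assignment(self) -> np.ndarray:
        """True parcel index (0/1/2) of every grid point, flattened in C order."""
        rows = np.arange(self.grid_shape[0])
        band = np.where(rows < self.middle_offset, 0,
                        np.where(rows < self.middle_offset + self.middle_height, 1, 2))
        return np.repeat(band, self.grid_shape[1])


def true_pattern(spec: SubjectPatternSpec, condition: int) -> np.ndarray:
    """Noise-free piecewise-constant pattern of one subject for one condition.

    The outer bands take value ``0 + eta(band, condition)`` and the middle band
    ``a(condition) + eta(1, condition)``.
    """
    if condition not in spec.active_levels:
        raise ValueError(f"unknown condition {condition!r}; known: {sorted(spec.active_levels)}")
    n_rows, n_cols = spec.grid_shape
    image = np.zeros((n_rows, n_cols), dtype=float)
    b, h = spec.middle_offset, spec.middle_height
    image[:b] = 0.0 + spec.eta.get((0, condition), 0.0)
    image[b:b + h] = spec.active_levels[condition] + spec.eta.get((1, condition), 0.0)
    image[b + h:] = 0.0 + spec.eta.get((2, condition), 0.0)
    return image


def smooth_gaussian(image: np.ndarray, fwhm_pix: float) -> np.ndarray:
    """Isotropic 2-D Gaussian smoothing parameterized by FWHM in pixels.

    Uses reflective boundary handling so constants are preserved exactly and
    edges are not darkened on small grids.  ``fwhm_pix = 0`` is the identity.
    """
    if fwhm_pix < 0:
        raise ValueError("fwhm_pix must be >= 0")
    if fwhm_pix == 0:
        return image.copy()
    return gaussian_filter(image, sigma=fwhm_pix * FWHM_TO_SIGMA, mode="reflect")


@dataclass
class ROIData:
    """One subject's region-of-interest data.

    Attributes
    ----------
    subject_id : str
    coords : (n_points, 2) float array, 0-based (row, col) point coordinates.
    activations : (n_points, n_trials) float array, one column per trial.
    labels : (n_trials,) integer array of condition labels.
    """

    subject_id: str
    coords: np.ndarray
    activations: np.ndarray
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.activations = np.asarray(self.activations, dtype=float)
        self.labels = np.asarray(self.labels)
        if self.coords.ndim != 2 or self.coords.shape[1] != 2:
            raise ValueError("coords must be (n_points, 2)")
        if self.activations.shape[0] != self.coords.shape[0]:
            raise ValueError("activations rows must match coords rows")
        if self.activations.shape[1] != len(self.labels):
            raise ValueError("one label per activation column required")
        if not (np.isfinite(self.coords).all() and np.isfinite(self.activations).all()):
            raise ValueError("coords and activations must be finite")
        if len(np.unique(self.coords, axis=0)) != len(self.coords):
            raise ValueError("coords rows must be unique")

    @property
    def n_points(self) -> int:
        return self.coords.shape[0]

    @property
    def n_trials(self) -> int:
        return self.activations.shape[1]


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of one artificial two-subject dataset.

    Defaults reproduce the canonical design: a (100, 20) grid, three bands with
    the middle one 30 rows high starting at row 20 for subject 1, two
    conditions at levels 1 and 2, ten trials per condition per subject, pixel
    noise of std 0.5 smoothed at FWHM 2.35 pixels.
    """

    grid_shape: tuple[int, int] = DEFAULT_GRID_SHAPE
    overlap_fraction: float = 1.0
    sigma_eta: float = 0.0
    sigma_pix: float = 0.5
    fwhm_pix: float = 2.35
    n_trials_per_condition: int = 10
    n_conditions: int = 2
    n_subjects: int = 2
    b_s1: int = 20
    middle_height: int = 30
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.overlap_fraction <= 1.0:
            raise ValueError("overlap_fraction must be in [0, 1]")
        if self.sigma_eta < 0 or self.sigma_pix < 0:
            raise ValueError("noise scales must be >= 0")
        if self.n_conditions < 2:
            raise ValueError("need at least two conditions")

    @property
    def conditions(self) -> list[int]:
        return list(range(1, self.n_conditions + 1))

    @property
    def active_levels(self) -> dict[int, float]:
        return {y: float(y) for y in self.conditions}


def _subject_offsets(config: SyntheticConfig) -> list[int]:
    """Middle-band starting rows per subject; subject 1 is fixed at b_s1."""
    offsets = [config.b_s1]
    shifted = overlap_to_offset(config.overlap_fraction, config.middle_height,
                                config.b_s1, config.grid_shape[0])
    for _ in range(1, config.n_subjects):
        offsets.append(shifted)
    return offsets


def generate_dataset(config: SyntheticConfig) -> list[ROIData]:
    """Draw one dataset: a list of per-subject ROIData with balanced labels.

    Per subject, eta is drawn once per (band, condition); each trial adds a
    fresh realization of smoothed pixel noise to the subject's true pattern for
    that trial's condition.  Identical seeds give bit-identical output.
    """
    rng = np.random.default_rng(config.seed)
    n_rows, n_cols = config.grid_shape
    rr, cc = np.meshgrid(np.arange(n_rows), np.arange(n_cols), indexing="ij")
    coords = np.column_stack([rr.ravel(), cc.ravel()]).astype(float)

    subjects = []
    for s, offset in enumerate(_subject_offsets(config)):
        eta_draw = rng.normal(0.0, 1.0, size=(3, config.n_conditions)) * config.sigma_eta
        eta = {(p, y): eta_draw[p, y - 1] for p in range(3) for y in config.conditions}
        spec = SubjectPatternSpec(middle_offset=offset, middle_height=config.middle_height,
                                  active_levels=config.active_levels, eta=eta,
                                  grid_shape=config.grid_shape)
        columns, labels = [], []
        for y in config.conditions:
            base = true_pattern(spec, y)
            for _ in range(config.n_trials_per_condition):
                noise = rng.normal(0.0, 1.0, size=config.grid_shape) * config.sigma_pix
                observed = base + smooth_gaussian(noise, config.fwhm_pix)
                columns.append(observed.ravel())
                labels.append(y)
        subjects.append(ROIData(subject_id=f"s{s + 1}", coords=coords,
                                activations=np.column_stack(columns),
                                labels=np.asarray(labels)))
    return subjects


def true_band_assignment(config: SyntheticConfig, subject_index: int) -> np.ndarray:
    """Ground-truth band index of every point for one subject (0-based index)."""
    offset = _subject_offsets(config)[subject_index]
    spec = SubjectPatternSpec(middle_offset=offset, middle_height=config.middle_height,
                              active_levels=config.active_levels, grid_shape=config.grid_shape)
    return spec.band_assignment()


def derive_seed(seed: int, *key: int) -> int:
    """Deterministic sub-seed below 2**31 for a (seed, key...) combination."""
    return int(np.random.SeedSequence((seed,) + key).generate_state(1)[0] % (2 ** 31))


def variability_grid(overlaps: Sequence[float], sigma_etas: Sequence[float],
                     n_datasets: int, seed: int = 0,
                     **config_kwargs) -> Iterator[tuple[dict, list[ROIData]]]:
    """Iterate datasets over the (overlap x sigma_eta) variability grid.

    Yields ``(case, dataset)`` pairs where ``case`` records the cell, replicate
    index and the derived seed.  Four overlaps x four sigmas x twenty replicates
    reproduce the canonical sixteen-cell design.
    """
    if not overlaps or not sigma_etas:
        raise ValueError("overlaps and sigma_etas must be nonempty")
    for i, overlap in enumerate(overlaps):
        for j, sigma_eta in enumerate(sigma_etas):
            for d in range(n_datasets):
                ds_seed = derive_seed(seed, i, j, d)
                config = SyntheticConfig(overlap_fraction=overlap, sigma_eta=sigma_eta,
                                         seed=ds_seed, **config_kwargs)
                case = {"overlap": overlap, "sigma_eta": sigma_eta,
                        "dataset": d, "seed": ds_seed}
                yield case, generate_dataset(config)


# ---------------------------------------------------------------------------
# dataset persistence: one directory per dataset, plain CSV per subject, plus a
# single-file compressed-array container for speed


def write_dataset(directory: str | Path, subjects: Sequence[ROIData]) -> None:
    """Write a dataset as per-subject CSV files under ``directory``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    label_rows = []
    for roi in subjects:
        pd.DataFrame({"point_id": np.arange(roi.n_points),
                      "x": roi.coords[:, 0], "y": roi.coords[:, 1]}
                     ).to_csv(directory / f"coords_{roi.subject_id}.csv", index=False)
        pd.DataFrame(roi.activations).to_csv(
            directory / f"activations_{roi.subject_id}.csv", index=False)
        for t, y in enumerate(roi.labels):
            label_rows.append({"trial_id": t, "subject_id": roi.subject_id, "condition": y})
    pd.DataFrame(label_rows).to_csv(directory / "labels.csv", index=False)


def read_dataset(directory: str | Path) -> list[ROIData]:
    """Read a dataset written by :func:`write_dataset`."""
    directory = Path(directory)
    labels = pd.read_csv(directory / "labels.csv")
    subjects = []
    for subject_id, group in labels.groupby("subject_id", sort=True):
        coords = pd.read_csv(directory / f"coords_{subject_id}.csv")[["x", "y"]].to_numpy()
        acts = pd.read_csv(directory / f"activations_{subject_id}.csv").to_numpy()
        ordered = group.sort_values("trial_id")
        subjects.append(ROIData(subject_id=str(subject_id), coords=coords,
                                activations=acts, labels=ordered["condition"].to_numpy()))
    return subjects


def save_npz(path: str | Path, subjects: Sequence[ROIData]) -> None:
    """Save a dataset into a single compressed ``.npz`` container."""
    arrays: dict[str, np.ndarray] = {"subject_ids": np.array([r.subject_id for r in subjects])}
    for roi in subjects:
        arrays[f"coords_{roi.subject_id}"] = roi.coords
        arrays[f"activations_{roi.subject_id}"] = roi.activations
        arrays[f"labels_{roi.subject_id}"] = roi.labels
    np.savez_compressed(path, **arrays)


def load_npz(path: str | Path) -> list[ROIData]:
    """Load a dataset saved by :func:`save_npz`."""
    with np.load(path, allow_pickle=False) as data:
        return [ROIData(subject_id=str(sid), coords=data[f"coords_{sid}"],
                        activations=data[f"activations_{sid}"], labels=data[f"labels_{sid}"])
                for sid in data["subject_ids"]]
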
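"""Synthetic N-dimensional sphere benchmarks with known per-sample radius.

Controls are points of the unit N-ball with radius in a low band (default
[0.01, 0.5]), cases in a high band (default [0.5, 1.0]), so class membership
is exactly the radius threshold.  Three variants emulate progressively less
perfect data:

* ``ideal``  — the raw N-ball coordinates;
* ``noisy``  — the ideal coordinates plus extra Uniform(-1, 1) noise columns;
* ``broken`` — half of the coordinates replaced by Uniform(-1, 1) noise.

The stored radius is always the one computed on the ideal coordinates and is
never recalculated after noise injection or breaking: in the degraded models
it is a deliberately imperfect description of each point's true position.
"""

from __future__ import annotations

import dataclasses
import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InvalidSpecError
from .table import TEST, TRAIN, FeatureTable

#: The benchmark design grid: every combination of these dimensions and
#: per-class TRAIN sample counts (8 x 6 x 6 = 288 datasets per model kind).
GRID_DIMENSIONS = (2, 3, 10, 30, 60, 90, 120, 150)
GRID_TRAIN_COUNTS = (15, 65, 115, 165, 215, 265)

#: Fraction of the TRAIN count used for the TEST fold of the same class.
TEST_FRACTION = 0.25

MODEL_KINDS = ("ideal", "noisy", "broken")


def round_half_up(x: float) -> int:
    """Round to the nearest integer, halves away from zero upward."""
    return int(math.floor(x + 0.5))


@dataclass(frozen=True)
class SphereSpec:
    """Full description of one sphere dataset (geometry, counts, seed)."""

    model_kind: str
    dim: int
    n_case_train: int
    n_control_train: int
    n_case_test: int
    n_control_test: int
    r_control: tuple[float, float] = (0.01, 0.5)
    r_case: tuple[float, float] = (0.5, 1.0)
    seed: int = 0
    radial_law: str = "uniform_radius"  # or "uniform_volume"

    def __post_init__(self) -> None:
        if self.model_kind not in MODEL_KINDS:
            raise InvalidSpecError(f"unknown model_kind {self.model_kind!r}")
        if self.dim < 2:
            raise InvalidSpecError("sphere dimension must be at least 2")
        if self.n_case_train <= 0 or self.n_control_train <= 0:
            raise InvalidSpecError("TRAIN sample counts must be positive")
        if self.n_case_test < 0 or self.n_control_test < 0:
            raise InvalidSpecError("TEST sample counts must be non-negative")
        for lo, hi in (self.r_control, self.r_case):
            if not (0.0 <= lo < hi <= 1.0):
                raise InvalidSpecError("radius bands must be non-degenerate within [0, 1]")
        if self.r_control[1] != self.r_case[0]:
            raise InvalidSpecError("control and case radius bands must share a boundary")
        if self.radial_law not in ("uniform_radius", "uniform_volume"):
            raise InvalidSpecError(f"unknown radial_law {self.radial_law!r}")


@dataclass
class SphereDataset:
    """A generated sphere benchmark: table plus ground-truth radii."""

    table: FeatureTable
    radius: np.ndarray
    signal_columns: list[str]
    noise_columns: list[str]
    spec: SphereSpec

    def to_csv(self, path) -> None:
        self.table.to_csv(path, radius=self.radius)


def _draw_radii(rng: np.random.Generator, n: int, band: tuple[float, float],
                dim: int, law: str) -> np.ndarray:
    lo, hi = band
    if law == "uniform_radius":
        return rng.uniform(lo, hi, size=n)
    # uniform in volume: P(R <= r) proportional to r^dim on the band
    u = rng.uniform(size=n)
    return (lo**dim + u * (hi**dim - lo**dim)) ** (1.0 / dim)


def sample_ideal_sphere(spec: SphereSpec) -> SphereDataset:
    """Draw an ideal sphere dataset: R*u with u uniform on the unit sphere.

    Directions come from normalized i.i.d. Gaussians; the radius R is drawn
    per sample from the class's band (uniformly by default).  The stored
    radius of every row equals its Euclidean norm exactly.
    """
    if spec.model_kind != "ideal":
        raise InvalidSpecError("sample_ideal_sphere requires model_kind='ideal'")
    rng = np.random.default_rng(spec.seed)

    blocks = [  # (n, label, fold, band) — TRAIN controls, TRAIN cases, then TEST
        (spec.n_control_train, 0, TRAIN, spec.r_control),
        (spec.n_case_train, 1, TRAIN, spec.r_case),
        (spec.n_control_test, 0, TEST, spec.r_control),
        (spec.n_case_test, 1, TEST, spec.r_case),
    ]
    rows, radii, labels, folds = [], [], [], []
    for n, label, fold, band in blocks:
        if n == 0:
            continue
        u = rng.normal(size=(n, spec.dim))
        u /= np.linalg.norm(u, axis=1, keepdims=True)
        r = _draw_radii(rng, n, band, spec.dim, spec.radial_law)
        rows.append(u * r[:, None])
        radii.append(r)
        labels += [label] * n
        folds += [fold] * n
    X = np.vstack(rows)
    columns = [f"X{i + 1}" for i in range(spec.dim)]
    table = FeatureTable(
        features=pd.DataFrame(X, columns=columns),
        labels=np.array(labels),
        folds=np.array(folds, dtype=object),
    )
    return SphereDataset(
        table=table,
        radius=np.concatenate(radii),
        signal_columns=columns,
        noise_columns=[],
        spec=spec,
    )


def add_noise_features(ds: SphereDataset, k: int = 50,
                       seed: int | None = None) -> SphereDataset:
    """Append ``k`` Uniform(-1, 1) noise columns ("noisy spheres").

    Radii, labels and the original coordinates are untouched; the radius is
    NOT recalculated for the widened vectors.
    """
    if ds.spec.model_kind != "ideal":
        raise InvalidSpecError("noise is added to an ideal sphere dataset")
    if k <= 0:
        raise InvalidSpecError("number of noise features must be positive")
    rng = np.random.default_rng(ds.spec.seed + 1 if seed is None else seed)
    noise = rng.uniform(-1.0, 1.0, size=(len(ds.table), k))
    noise_names = [f"N{i + 1}" for i in range(k)]
    features = pd.concat(
        [ds.table.features, pd.DataFrame(noise, columns=noise_names)], axis=1)
    table = FeatureTable(features, ds.table.labels, ds.table.folds,
                         ds.table.sample_ids)
    return SphereDataset(
        table=table,
        radius=ds.radius.copy(),
        signal_columns=list(ds.signal_columns),
        noise_columns=noise_names,
        spec=dataclasses.replace(ds.spec, model_kind="noisy"),
    )


def break_sphere(ds: SphereDataset, seed: int | None = None) -> SphereDataset:
    """Replace the last floor(N/2) coordinates with Uniform(-1, 1) noise.

    The first ceil(N/2) sphere coordinates are kept, so at least half of the
    signal survives for odd N.  The total column count stays N and the radius
    (computed from the intact ideal coordinates) is NOT recalculated.
    """
    if ds.spec.model_kind != "ideal":
        raise InvalidSpecError("breaking applies to an ideal sphere dataset")
    n_dim = ds.spec.dim
    n_keep = math.ceil(n_dim / 2)
    n_replace = n_dim - n_keep
    rng = np.random.default_rng(ds.spec.seed + 2 if seed is None else seed)
    kept = ds.table.features.iloc[:, :n_keep]
    noise_names = [f"N{i + 1}" for i in range(n_replace)]
    noise = pd.DataFrame(rng.uniform(-1.0, 1.0, size=(len(ds.table), n_replace)),
                         columns=noise_names)
    features = pd.concat([kept.reset_index(drop=True), noise], axis=1)
    table = FeatureTable(features, ds.table.labels, ds.table.folds,
                         ds.table.sample_ids)
    return SphereDataset(
        table=table,
        radius=ds.radius.copy(),
        signal_columns=list(kept.columns),
        noise_columns=noise_names,
        spec=dataclasses.replace(ds.spec, model_kind="broken"),
    )


def generate_sphere(spec: SphereSpec) -> SphereDataset:
    """Generate a dataset of any model kind from a single spec."""
    ideal = sample_ideal_sphere(dataclasses.replace(spec, model_kind="ideal"))
    if spec.model_kind == "ideal":
        return ideal
    if spec.model_kind == "noisy":
        return add_noise_features(ideal)
    return break_sphere(ideal)


def generate_grid(model_kind: str, base_seed: int = 0) -> list[SphereSpec]:
    """The full benchmark design grid for one sphere model (288 specs).

    Ordering is dimension-major, then case TRAIN count, then control TRAIN
    count.  TEST counts are round-half-up of 25% of the TRAIN counts.  Each
    spec's seed is ``(base_seed * 1009 + index) mod 2**31`` where ``index``
    is its position in the grid — distinct within a grid, reproducible from
    the base seed alone.
    """
    if model_kind not in MODEL_KINDS:
        raise InvalidSpecError(f"unknown model_kind {model_kind!r}")
    specs = []
    combos = itertools.product(GRID_DIMENSIONS, GRID_TRAIN_COUNTS, GRID_TRAIN_COUNTS)
    for index, (dim, n_case, n_control) in enumerate(combos):
        specs.append(SphereSpec(
            model_kind=model_kind,
            dim=dim,
            n_case_train=n_case,
            n_control_train=n_control,
            n_case_test=round_half_up(TEST_FRACTION * n_case),
            n_control_test=round_half_up(TEST_FRACTION * n_control),
            seed=(base_seed * 1009 + index) % 2**31,
        ))
    return specs
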
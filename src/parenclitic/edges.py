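"""Pairwise edge-weight models: the computational core of the package.

Each model is fitted in the plane of one feature pair on TRAIN data and maps
any sample's (x, y) values there to a non-negative edge weight:

* :class:`LinearEdgeModel` (wLRPA) — OLS regression of y on x over controls;
  weight = |z-score| of the sample's residual against the control residual
  distribution.  Unbounded above.
* :class:`KdeEdgeModel` (wKDEPA) — 2-D Gaussian kernel density estimate of
  the controls; weight = mass of the highest-density region strictly denser
  than the query point (0 at the mode, -> 1 far away).  Bounded in [0, 1].
* :class:`SvmEdgeModel` (wSA, "synolytic") — RBF-kernel SVM separating
  controls from cases; weight = calibrated probability of case membership.
  Bounded in [0, 1].

All three expose a vectorized ``weight(x, y)`` used by the network builder.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.svm import SVC

from .errors import (
    DegeneracyWarning,
    DegenerateFitError,
    InsufficientDataError,
    InvalidLabelsError,
)

#: Spread below this is treated as exactly degenerate.
DEGENERACY_EPS = 1e-12


def _as_xy(points) -> tuple[np.ndarray, np.ndarray]:
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be an (n, 2) array of (x, y) pairs")
    return pts[:, 0], pts[:, 1]


# ---------------------------------------------------------------------------
# wLRPA: linear-regression residual z-score
# ---------------------------------------------------------------------------

@dataclass
class LinearEdgeModel:
    """OLS line fitted on controls plus their residual distribution."""

    slope: float
    intercept: float
    resid_mean: float
    resid_sd: float
    n_fit: int

    def weight(self, x, y):
        """|z-score| of the residual of (x, y) against the control residuals.

        A degenerate model (zero residual spread) yields weight 0 so that the
        edge still exists for every sample.
        """
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        resid = y - (self.slope * x + self.intercept)
        if self.resid_sd < DEGENERACY_EPS:
            warnings.warn("zero residual spread: edge weight forced to 0",
                          DegeneracyWarning, stacklevel=2)
            return np.zeros_like(resid) if resid.ndim else 0.0
        out = np.abs(resid - self.resid_mean) / self.resid_sd
        return out if out.ndim else float(out)


def fit_linear_edge(control_points) -> LinearEdgeModel:
    """Fit y-on-x OLS over control points only (>= 3 required)."""
    x, y = _as_xy(control_points)
    if len(x) < 3:
        raise InsufficientDataError("need at least 3 control points")
    if np.ptp(x) < DEGENERACY_EPS:
        raise DegenerateFitError("all x values identical: regression undefined")
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    return LinearEdgeModel(
        slope=float(slope),
        intercept=float(intercept),
        resid_mean=float(resid.mean()),
        resid_sd=float(resid.std(ddof=1)),
        n_fit=len(x),
    )


def linear_edge_weight(model: LinearEdgeModel, x: float, y: float) -> float:
    return model.weight(x, y)


# ---------------------------------------------------------------------------
# wKDEPA: highest-density-region mass under a 2-D KDE
# ---------------------------------------------------------------------------

@dataclass
class KdeEdgeModel:
    """Gaussian-product-kernel density of the controls on a rectangular grid.

    The weight of a query is the normalised mass of all grid cells strictly
    denser than the query's (bilinearly interpolated) density — the
    highest-density-region mass, 0 at the mode and saturating at 1 outside
    the grid.
    """

    grid_x: np.ndarray
    grid_y: np.ndarray
    density: np.ndarray            # shape (len(grid_x), len(grid_y))
    bandwidths: tuple[float, float]
    cell_area: float
    total_mass: float
    train_points: np.ndarray = field(repr=False)
    # sorted cell densities and suffix masses, precomputed for O(log m) queries
    _sorted_density: np.ndarray = field(repr=False, default=None)
    _suffix_mass: np.ndarray = field(repr=False, default=None)

    def __post_init__(self) -> None:
        flat = np.sort(self.density, axis=None)
        suffix = np.concatenate([np.cumsum(flat[::-1])[::-1], [0.0]])
        self._sorted_density = flat
        self._suffix_mass = suffix * self.cell_area

    def density_at(self, x, y) -> np.ndarray:
        """Exact product-kernel density at arbitrary points."""
        x = np.atleast_1d(np.asarray(x, dtype=float))
        y = np.atleast_1d(np.asarray(y, dtype=float))
        hx, hy = self.bandwidths
        px, py = self.train_points[:, 0], self.train_points[:, 1]
        zx = (x[:, None] - px[None, :]) / hx
        zy = (y[:, None] - py[None, :]) / hy
        norm = len(px) * 2.0 * np.pi * hx * hy
        return np.exp(-0.5 * (zx**2 + zy**2)).sum(axis=1) / norm

    def _interp_density(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Bilinear interpolation of the gridded density (callers clip)."""
        ix = np.clip(np.searchsorted(self.grid_x, x) - 1, 0, len(self.grid_x) - 2)
        iy = np.clip(np.searchsorted(self.grid_y, y) - 1, 0, len(self.grid_y) - 2)
        x0, x1 = self.grid_x[ix], self.grid_x[ix + 1]
        y0, y1 = self.grid_y[iy], self.grid_y[iy + 1]
        tx = (x - x0) / (x1 - x0)
        ty = (y - y0) / (y1 - y0)
        d = self.density
        return ((1 - tx) * (1 - ty) * d[ix, iy] + tx * (1 - ty) * d[ix + 1, iy]
                + (1 - tx) * ty * d[ix, iy + 1] + tx * ty * d[ix + 1, iy + 1])

    def weight(self, x, y):
        x_arr = np.atleast_1d(np.asarray(x, dtype=float))
        y_arr = np.atleast_1d(np.asarray(y, dtype=float))
        out = np.ones_like(x_arr)
        inside = ((x_arr >= self.grid_x[0]) & (x_arr <= self.grid_x[-1])
                  & (y_arr >= self.grid_y[0]) & (y_arr <= self.grid_y[-1]))
        if inside.any():
            fq = self._interp_density(x_arr[inside], y_arr[inside])
            # strictly denser cells only: the argmax cell itself maps to 0
            k = np.searchsorted(self._sorted_density, fq, side="right")
            out[inside] = self._suffix_mass[k] / self.total_mass
        return out if np.ndim(x) else float(out[0])

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Draw n points from the fitted density (the Gaussian mixture)."""
        idx = rng.integers(0, len(self.train_points), size=n)
        jitter = rng.normal(size=(n, 2)) * np.asarray(self.bandwidths)
        return self.train_points[idx] + jitter


def fit_kde_edge(control_points, grid_size: int = 101, pad: float = 3.0,
                 ) -> KdeEdgeModel:
    """Fit the control KDE on a padded rectangular grid.

    Bandwidths follow Scott's rule per axis (sd * n^(-1/6) for d = 2); the
    grid spans the control range extended by ``pad`` bandwidths so the
    captured mass is within ~0.3% of unity.
    """
    x, y = _as_xy(control_points)
    n = len(x)
    if n < 5:
        raise InsufficientDataError("need at least 5 control points for a KDE")
    sx, sy = x.std(ddof=1), y.std(ddof=1)
    if sx < DEGENERACY_EPS or sy < DEGENERACY_EPS:
        raise DegenerateFitError("zero spread in a coordinate: KDE undefined")
    hx = sx * n ** (-1.0 / 6.0)
    hy = sy * n ** (-1.0 / 6.0)
    grid_x = np.linspace(x.min() - pad * hx, x.max() + pad * hx, grid_size)
    grid_y = np.linspace(y.min() - pad * hy, y.max() + pad * hy, grid_size)
    cell_area = (grid_x[1] - grid_x[0]) * (grid_y[1] - grid_y[0])
    zx = (grid_x[:, None] - x[None, :]) / hx
    zy = (grid_y[:, None] - y[None, :]) / hy
    kx = np.exp(-0.5 * zx**2)                      # (grid, n)
    ky = np.exp(-0.5 * zy**2)
    density = kx @ ky.T / (n * 2.0 * np.pi * hx * hy)
    return KdeEdgeModel(
        grid_x=grid_x,
        grid_y=grid_y,
        density=density,
        bandwidths=(float(hx), float(hy)),
        cell_area=float(cell_area),
        total_mass=float(density.sum() * cell_area),
        train_points=np.column_stack([x, y]),
    )


def kde_edge_weight(model: KdeEdgeModel, x: float, y: float) -> float:
    return model.weight(x, y)


# ---------------------------------------------------------------------------
# wSA: calibrated RBF-SVM case probability
# ---------------------------------------------------------------------------

@dataclass
class SvmEdgeModel:
    """Standardization parameters plus a Platt-calibrated RBF-kernel SVM."""

    svc: SVC
    mean: np.ndarray
    sd: np.ndarray
    n_controls: int
    n_cases: int

    def weight(self, x, y):
        x_arr = np.atleast_1d(np.asarray(x, dtype=float))
        y_arr = np.atleast_1d(np.asarray(y, dtype=float))
        Z = (np.column_stack([x_arr, y_arr]) - self.mean) / self.sd
        case_col = int(np.flatnonzero(self.svc.classes_ == 1)[0])
        p = self.svc.predict_proba(Z)[:, case_col]
        return p if np.ndim(x) else float(p[0])


def fit_svm_edge(points, labels, C: float = 1.0, gamma: str | float = "scale",
                 seed: int = 0) -> SvmEdgeModel:
    """Fit a radial SVM with probability calibration on both classes.

    Inputs are standardized with TRAIN mean/sd per axis.  Platt scaling uses
    the classifier's built-in 5-fold internal cross-validation, seeded for
    determinism.
    """
    x, y = _as_xy(points)
    labels = np.asarray(labels, dtype=int)
    if labels.shape != x.shape:
        raise InvalidLabelsError("labels must align with points")
    n0, n1 = int((labels == 0).sum()), int((labels == 1).sum())
    if n0 < 3 or n1 < 3:
        raise InvalidLabelsError("need at least 3 points per class")
    X = np.column_stack([x, y])
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    sd[sd < DEGENERACY_EPS] = 1.0
    Z = (X - mean) / sd
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", FutureWarning)
        svc = SVC(kernel="rbf", C=C, gamma=gamma, probability=True,
                  random_state=seed)
        svc.fit(Z, labels)
    return SvmEdgeModel(svc=svc, mean=mean, sd=sd, n_controls=n0, n_cases=n1)


def svm_edge_weight(model: SvmEdgeModel, x: float, y: float) -> float:
    return model.weight(x, y)


# ---------------------------------------------------------------------------
# legacy binarization
# ---------------------------------------------------------------------------

def binarize_weight(weight: float, threshold: float,
                    mode: str = "less_than_keeps_edge") -> int:
    """Threshold a weight into edge presence (strict inequality).

    Retained for compatibility with binarized parenclitic pipelines (e.g.
    "edge present iff |z| < 3"); the weighted pipeline never calls it.
    """
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    if mode == "less_than_keeps_edge":
        return int(weight < threshold)
    if mode == "greater_than_keeps_edge":
        return int(weight > threshold)
    raise ValueError(f"unknown mode {mode!r}")
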
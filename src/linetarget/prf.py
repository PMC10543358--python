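"""Gaussian population-receptive-field (pRF) modelling.

The pRF of a voxel/vertex is modelled as an isotropic 2-D Gaussian in the
visual field with center (x0, y0) and spread sigma (all in degrees of
visual angle). The predicted BOLD response to a stimulus aperture movie is

    p(t) = baseline + beta * (HRF ⊛ d)(t),
    d(t) = sum_{x,y} exp(-((x-x0)^2 + (y-y0)^2) / (2 sigma^2)) * aperture(t,x,y),

i.e. the frame-wise dot product between the pRF and the binary stimulus
aperture, convolved with a hemodynamic response function (HRF). Fitting is
two-stage: an exhaustive coarse grid over (x0, y0, sigma) with closed-form
(beta, baseline) per candidate, followed by bounded trust-region refinement
of the spatial parameters, minimising the residual sum of squares.

:class:`GaussianPRFModel` wraps this in a model/results interface: build
the model from a time series and a design, call :meth:`~GaussianPRFModel.fit`,
and inspect the returned :class:`PRFResults` (estimates, standard errors,
diagnostics, ``summary()``).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize, signal, stats

__all__ = [
    "PRFParams",
    "StimulusDesign",
    "HRFModel",
    "PRFGridSpec",
    "CandidateGrid",
    "GaussianPRFModel",
    "PRFResults",
    "build_bar_design",
    "prf_prediction",
    "fit_prf",
    "block_null_prediction",
    "crossval_r2",
    "ecc_polar",
    "polar_to_cartesian",
    "depth_profile",
]


@dataclass(frozen=True)
class PRFParams:
    """Gaussian pRF parameters.

    x0, y0 : visual-field center (degrees); sigma : Gaussian spread
    (degrees, > 0); beta : response amplitude (%BOLD per unit overlap);
    baseline : %BOLD offset; r2 : in-sample variance explained (<= 1).
    ``reliable`` is False when spatial parameters could not be estimated
    (e.g. constant input data).
    """

    x0: float
    y0: float
    sigma: float
    beta: float = 1.0
    baseline: float = 0.0
    r2: float = np.nan
    reliable: bool = True

    def __post_init__(self) -> None:
        if not self.sigma > 0:
            raise ValueError(f"sigma must be > 0, got {self.sigma}")
        if np.isfinite(self.r2) and self.r2 > 1 + 1e-12:
            raise ValueError(f"r2 cannot exceed 1, got {self.r2}")


def ecc_polar(params) -> tuple[float, float]:
    """(eccentricity deg, polar angle rad in (-pi, pi]) of a pRF center.

    Accepts a :class:`PRFParams` or an (x0, y0) pair. (0, 0) maps to
    (0, 0) by convention (atan2(0, 0) = 0).
    """
    if isinstance(params, PRFParams):
        x0, y0 = params.x0, params.y0
    else:
        x0, y0 = params
    if not (np.isfinite(x0) and np.isfinite(y0)):
        raise ValueError("pRF center must be finite for ecc/polar conversion")
    return float(np.hypot(x0, y0)), float(np.arctan2(y0, x0))


def polar_to_cartesian(ecc: float, polar: float) -> tuple[float, float]:
    return float(ecc * np.cos(polar)), float(ecc * np.sin(polar))


# ---------------------------------------------------------------------------
# stimulus design


@dataclass
class StimulusDesign:
    """Binary aperture movie of a visual stimulus.

    apertures : (T, H, W) array with values in {0, 1}; grid_extent :
    degrees spanned per axis (the pixel grid is centered on fixation);
    tr : seconds per frame; blank_frames : indices of empty-screen frames.
    """

    apertures: np.ndarray
    grid_extent: float
    tr: float
    blank_frames: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    n_configurations: int | None = None

    def __post_init__(self) -> None:
        ap = np.asarray(self.apertures)
        if ap.ndim != 3 or ap.shape[0] < 1:
            raise ValueError(f"apertures must be (T, H, W) with T >= 1, got {ap.shape}")
        vals = np.unique(ap)
        if not np.all(np.isin(vals, [0, 1])):
            raise ValueError("aperture values must be binary {0, 1}")
        self.apertures = ap.astype(np.float32)
        self.blank_frames = np.asarray(self.blank_frames, dtype=int)
        if self.blank_frames.size and (
            self.blank_frames.min() < 0 or self.blank_frames.max() >= ap.shape[0]
        ):
            raise ValueError("blank_frames outside [0, T)")
        if self.tr <= 0 or self.grid_extent <= 0:
            raise ValueError("tr and grid_extent must be positive")

    @property
    def n_frames(self) -> int:
        return self.apertures.shape[0]

    def pixel_grid(self) -> tuple[np.ndarray, np.ndarray]:
        """(X, Y) pixel-center coordinates in degrees, fixation at (0, 0)."""
        h, w = self.apertures.shape[1:]
        xs = np.linspace(-self.grid_extent / 2, self.grid_extent / 2, w)
        ys = np.linspace(-self.grid_extent / 2, self.grid_extent / 2, h)
        return np.meshgrid(xs, ys)


def build_bar_design(
    orientations,
    directions=(1, -1),
    bar_widths=(1.25,),
    grid_extent: float = 10.0,
    step: float = 0.25,
    tr: float = 1.5,
    blank_s: float = 15.0,
    circular_mask_radius: float | None = None,
    n_pix: int = 40,
) -> StimulusDesign:
    """Build a sweeping-bar aperture design.

    One traversal per (orientation x direction x width) combination; a
    blank (mean-luminance) block of ``blank_s`` seconds is inserted after
    every two bar passes; all frames are clipped to a circular aperture.

    Parameters
    ----------
    orientations
        Bar-motion axis angles in degrees (0 = bar sweeping along the
        horizontal axis). Must be nonempty.
    directions
        Motion directions (+1/-1) applied to every orientation.
    bar_widths
        Bar widths in degrees; each must be positive and no wider than the
        grid.
    step
        Bar displacement in degrees per frame.
    """
    orientations = list(orientations)
    if not orientations:
        raise ValueError("orientations must be nonempty")
    directions = list(directions)
    bar_widths = list(bar_widths)
    for wdt in bar_widths:
        if wdt <= 0:
            raise ValueError(f"bar width must be positive, got {wdt}")
        if wdt > grid_extent:
            raise ValueError(f"bar width {wdt} deg exceeds grid extent {grid_extent} deg")
    radius = grid_extent / 2 if circular_mask_radius is None else circular_mask_radius

    xs = np.linspace(-grid_extent / 2, grid_extent / 2, n_pix)
    X, Y = np.meshgrid(xs, xs)
    circle = (X**2 + Y**2) <= radius**2

    configs = [(o, d, w) for o in orientations for d in directions for w in bar_widths]
    n_blank = int(round(blank_s / tr))
    positions = np.arange(-grid_extent / 2, grid_extent / 2 + step / 2, step)

    frames: list[np.ndarray] = []
    blank_idx: list[int] = []
    for i, (ori, direc, width) in enumerate(configs):
        u = np.array([np.cos(np.deg2rad(ori)), np.sin(np.deg2rad(ori))])
        proj = X * u[0] + Y * u[1]
        pos = positions if direc > 0 else positions[::-1]
        for s in pos:
            frames.append(((np.abs(proj - s) <= width / 2) & circle).astype(np.uint8))
        if (i + 1) % 2 == 0:
            start = len(frames)
            frames.extend(np.zeros_like(frames[0]) for _ in range(n_blank))
            blank_idx.extend(range(start, len(frames)))

    apertures = np.stack(frames)
    # frames where the bar left the circular aperture entirely also count blank
    empty = np.flatnonzero(apertures.reshape(len(frames), -1).sum(axis=1) == 0)
    blanks = np.unique(np.concatenate([np.asarray(blank_idx, int), empty]))
    return StimulusDesign(
        apertures=apertures,
        grid_extent=grid_extent,
        tr=tr,
        blank_frames=blanks,
        n_configurations=len(configs),
    )


# ---------------------------------------------------------------------------
# HRF


@dataclass(frozen=True)
class HRFModel:
    """A sampled hemodynamic impulse response at a given frame interval."""

    kernel: np.ndarray
    tr: float
    definition: str = "custom"

    def __post_init__(self) -> None:
        k = np.asarray(self.kernel, dtype=float)
        if not np.all(np.isfinite(k)):
            raise ValueError("HRF kernel must be finite")
        object.__setattr__(self, "kernel", k)
        peak = np.argmax(k) * self.tr
        if not (3.0 <= peak <= 8.0):
            warnings.warn(f"HRF kernel peaks at {peak:.2f} s, outside the typical 3-8 s")

    @classmethod
    def double_gamma(
        cls,
        tr: float,
        peak_delay: float = 6.0,
        undershoot_delay: float = 16.0,
        ratio: float = 1.0 / 6.0,
        duration: float = 32.0,
    ) -> "HRFModel":
        """Canonical double-gamma HRF (peak ~6 s, undershoot ~16 s, 1/6 ratio).

        The kernel is normalised to unit peak so that `beta` is in %BOLD.
        """
        t = np.arange(0, duration + tr / 2, tr)
        h = stats.gamma.pdf(t, peak_delay, scale=1.0) - ratio * stats.gamma.pdf(
            t, undershoot_delay, scale=1.0
        )
        h = h / h.max()
        return cls(kernel=h, tr=tr, definition="double_gamma")


def _convolve_hrf(neural: np.ndarray, hrf: HRFModel) -> np.ndarray:
    """Causal zero-padded convolution truncated at the series end.

    Works on a 1-D series or column-wise on a (T, K) array.
    """
    T = neural.shape[0]
    if neural.ndim == 1:
        return np.convolve(neural, hrf.kernel)[:T]
    out = signal.fftconvolve(neural, hrf.kernel[:, None], axes=0)[:T]
    return out


def _gaussian_field(x0: float, y0: float, sigma: float, X: np.ndarray, Y: np.ndarray):
    return np.exp(-((X - x0) ** 2 + (Y - y0) ** 2) / (2.0 * sigma**2))


def prf_prediction(params: PRFParams, design: StimulusDesign, hrf: HRFModel) -> np.ndarray:
    """Predicted %BOLD time series of a Gaussian pRF under a design."""
    if params.sigma <= 0:
        raise ValueError("sigma must be positive")
    X, Y = design.pixel_grid()
    g = _gaussian_field(params.x0, params.y0, params.sigma, X, Y)
    neural = design.apertures.reshape(design.n_frames, -1) @ g.ravel()
    return params.baseline + params.beta * _convolve_hrf(neural, hrf)


def block_null_prediction(design: StimulusDesign, hrf: HRFModel) -> np.ndarray:
    """Spatially non-selective null prediction: on whenever any stimulus is on.

    Amplitude and baseline are left to the GLM in :func:`crossval_r2`.
    """
    on = (design.apertures.reshape(design.n_frames, -1).sum(axis=1) > 0).astype(float)
    return _convolve_hrf(on, hrf)


# ---------------------------------------------------------------------------
# fitting


@dataclass(frozen=True)
class PRFGridSpec:
    """Coarse-search grid over (x0, y0, sigma)."""

    x0: np.ndarray
    y0: np.ndarray
    sigma: np.ndarray

    @classmethod
    def from_design(cls, design: StimulusDesign, n_pos: int = 21, n_sigma: int = 12,
                    sigma_min: float = 0.1) -> "PRFGridSpec":
        half = design.grid_extent / 2
        return cls(
            x0=np.linspace(-half, half, n_pos),
            y0=np.linspace(-half, half, n_pos),
            sigma=np.geomspace(sigma_min, half, n_sigma),
        )


class CandidateGrid:
    """Precomputed convolved predictions for every grid candidate.

    Building this once and reusing it across many fits of the same design
    (e.g. per seed, per depth voxel) amortises the dominant cost of the
    coarse search.
    """

    def __init__(self, design: StimulusDesign, hrf: HRFModel, spec: PRFGridSpec):
        self.design = design
        self.hrf = hrf
        self.spec = spec
        X, Y = design.pixel_grid()
        xs, ys, ss = np.meshgrid(spec.x0, spec.y0, spec.sigma, indexing="ij")
        self.params = np.column_stack([xs.ravel(), ys.ravel(), ss.ravel()])
        px = X.ravel()[:, None]
        py = Y.ravel()[:, None]
        G = np.exp(
            -((px - self.params[:, 0]) ** 2 + (py - self.params[:, 1]) ** 2)
            / (2.0 * self.params[:, 2] ** 2)
        ).astype(np.float32)
        A = design.apertures.reshape(design.n_frames, -1)
        neural = (A @ G).astype(np.float64)
        self.predictions = _convolve_hrf(neural, hrf)  # (T, K)
        self._pred_mean = self.predictions.mean(axis=0)
        centered = self.predictions - self._pred_mean
        self._pred_centered = centered
        self._pred_var = np.einsum("tk,tk->k", centered, centered)

    def best(self, ts: np.ndarray):
        """Closed-form (beta, baseline) least squares for every candidate;
        return the winning (x0, y0, sigma, beta, baseline, ssr, sstot)."""
        tsc = ts - ts.mean()
        sstot = float(tsc @ tsc)
        cov = tsc @ self._pred_centered
        var = self._pred_var
        with np.errstate(divide="ignore", invalid="ignore"):
            beta = np.where(var > 0, cov / np.maximum(var, 1e-300), 0.0)
        ssr = sstot - beta * cov  # residual SS after fitting [pred, 1]
        # tie-break: lowest ssr, then smallest sigma, then lexicographic (x0, y0)
        tol = 1e-9 * max(sstot, 1.0)
        tied = np.flatnonzero(ssr <= ssr.min() + tol)
        p = self.params[tied]
        order = np.lexsort((p[:, 1], p[:, 0], p[:, 2]))
        k = tied[order[0]]
        x0, y0, sig = self.params[k]
        b = beta[k]
        base = ts.mean() - b * self._pred_mean[k]
        return float(x0), float(y0), float(sig), float(b), float(base), float(ssr[k]), sstot


def _ssr_for_spatial(theta, ts, A, X, Y, hrf):
    x0, y0, sigma = theta
    g = _gaussian_field(x0, y0, sigma, X, Y).ravel().astype(np.float32)
    pred = _convolve_hrf((A @ g).astype(float), hrf)
    pc = pred - pred.mean()
    tsc = ts - ts.mean()
    var = pc @ pc
    if var <= 0:
        return float(tsc @ tsc)
    beta = (tsc @ pc) / var
    return float(tsc @ tsc - beta * (tsc @ pc))


def fit_prf(
    ts: np.ndarray,
    design: StimulusDesign,
    hrf: HRFModel | None = None,
    grid=None,
    bounds=None,
    refine: bool = True,
) -> PRFParams:
    """Fit a Gaussian pRF to a time series.

    Stage 1 is an exhaustive coarse grid search with per-candidate
    closed-form (beta, baseline); stage 2 refines (x0, y0, sigma) from the
    grid optimum with bounded trust-region optimisation of the residual
    sum of squares.

    Parameters
    ----------
    grid
        A :class:`PRFGridSpec`, a prebuilt :class:`CandidateGrid`, or None
        for the default grid derived from the design.
    bounds
        Optional ((x0_lo, x0_hi), (y0_lo, y0_hi), (sigma_lo, sigma_hi));
        defaults to the grid ranges.
    """
    ts = np.asarray(ts, dtype=float)
    if ts.shape[0] != design.n_frames:
        raise ValueError(f"ts length {ts.shape[0]} != design frames {design.n_frames}")
    if not np.all(np.isfinite(ts)):
        raise ValueError("time series contains non-finite values")
    if hrf is None:
        hrf = HRFModel.double_gamma(design.tr)

    sstot = float(np.sum((ts - ts.mean()) ** 2))
    if sstot <= 0:
        warnings.warn("all-constant time series: spatial pRF parameters are unreliable")
        half = design.grid_extent / 2
        return PRFParams(0.0, 0.0, half / 2, beta=0.0, baseline=float(ts.mean()),
                         r2=0.0, reliable=False)

    if isinstance(grid, CandidateGrid):
        cand = grid
    else:
        spec = grid if isinstance(grid, PRFGridSpec) else PRFGridSpec.from_design(design)
        cand = CandidateGrid(design, hrf, spec)
    x0, y0, sig, beta, base, ssr, _ = cand.best(ts)

    if refine:
        spec = cand.spec
        if bounds is None:
            bounds = (
                (spec.x0.min(), spec.x0.max()),
                (spec.y0.min(), spec.y0.max()),
                (spec.sigma.min(), spec.sigma.max()),
            )
        X, Y = design.pixel_grid()
        A = design.apertures.reshape(design.n_frames, -1)
        with warnings.catch_warnings():
            # near-flat SSR surfaces trigger a benign quasi-Newton warning
            warnings.filterwarnings("ignore", message="delta_grad == 0.0")
            res = optimize.minimize(
                _ssr_for_spatial,
                x0=[x0, y0, sig],
                args=(ts, A, X, Y, hrf),
                method="trust-constr",
                bounds=optimize.Bounds(*(np.array(b) for b in zip(*bounds))),
                options={"xtol": 1e-6, "gtol": 1e-6, "maxiter": 200},
            )
        if res.fun <= ssr:
            x0, y0, sig = res.x
            ssr = float(res.fun)
            # recover beta/baseline at the refined optimum
            g = _gaussian_field(x0, y0, sig, X, Y)
            pred = _convolve_hrf(A @ g.ravel(), hrf)
            pc = pred - pred.mean()
            var = pc @ pc
            beta = float(((ts - ts.mean()) @ pc) / var) if var > 0 else 0.0
            base = float(ts.mean() - beta * pred.mean())

    r2 = 1.0 - ssr / sstot
    return PRFParams(float(x0), float(y0), float(sig), beta=float(beta),
                     baseline=float(base), r2=float(min(r2, 1.0)))


def crossval_r2(reference, ts: np.ndarray, design: StimulusDesign,
                hrf: HRFModel | None = None) -> float:
    """Cross-validated variance explained of a fixed-shape prediction.

    The reference (a :class:`PRFParams`, or a precomputed regressor array)
    provides the prediction *shape*; amplitude and intercept are refit to
    ``ts`` by ordinary least squares. With a free-sign amplitude the
    result equals the squared Pearson correlation between prediction and
    data, hence cvR^2 >= 0.
    """
    ts = np.asarray(ts, dtype=float)
    if hrf is None:
        hrf = HRFModel.double_gamma(design.tr)
    if isinstance(reference, PRFParams):
        pred = prf_prediction(reference, design, hrf)
    else:
        pred = np.asarray(reference, dtype=float)
    if pred.shape != ts.shape:
        raise ValueError("prediction and data shapes differ")
    tsc = ts - ts.mean()
    sstot = float(tsc @ tsc)
    if sstot <= 0:
        warnings.warn("zero-variance time series: cvR^2 undefined (NaN)")
        return float("nan")
    pc = pred - pred.mean()
    var = float(pc @ pc)
    if var <= 0:
        return 0.0
    cov = float(tsc @ pc)
    return cov * cov / (var * sstot)


def depth_profile(fits, depths) -> pd.DataFrame:
    """Tabulate per-depth pRF fits, ordered superficial (depth 0) to deep.

    Voxels are modelled independently; no smoothing is applied across
    depth.
    """
    depths = np.asarray(depths, dtype=float)
    fits = list(fits)
    if len(fits) != depths.size:
        raise ValueError("fits and depths must have equal length")
    if depths.size < 2:
        raise ValueError("depth profile needs at least 2 depths")
    tab = pd.DataFrame(
        {
            "depth": depths,
            "beta": [f.beta for f in fits],
            "r2": [f.r2 for f in fits],
            "x0": [f.x0 for f in fits],
            "y0": [f.y0 for f in fits],
        }
    )
    return tab.sort_values("depth", kind="stable").reset_index(drop=True)


# ---------------------------------------------------------------------------
# model / results interface


class GaussianPRFModel:
    """Gaussian pRF model bound to one BOLD time series and one design.

    Examples
    --------
    >>> model = GaussianPRFModel(ts, design)
    >>> res = model.fit()
    >>> res.params.x0, res.params.sigma
    >>> print(res.summary())
    """

    def __init__(self, endog: np.ndarray, design: StimulusDesign,
                 hrf: HRFModel | None = None):
        self.endog = np.asarray(endog, dtype=float)
        self.design = design
        self.hrf = hrf if hrf is not None else HRFModel.double_gamma(design.tr)
        if self.endog.shape[0] != design.n_frames:
            raise ValueError("endog length must equal the design frame count")

    @classmethod
    def from_dataframe(cls, frame: pd.DataFrame, column: str, design: StimulusDesign,
                       hrf: HRFModel | None = None) -> "GaussianPRFModel":
        return cls(frame[column].to_numpy(), design, hrf=hrf)

    def predict(self, params: PRFParams) -> np.ndarray:
        return prf_prediction(params, self.design, self.hrf)

    def fit(self, grid=None, bounds=None, refine: bool = True) -> "PRFResults":
        params = fit_prf(self.endog, self.design, self.hrf, grid=grid,
                         bounds=bounds, refine=refine)
        return PRFResults(self, params)


class PRFResults:
    """Fit results: estimates, standard errors, diagnostics, summary table."""

    PARAM_NAMES = ("x0", "y0", "sigma", "beta", "baseline")

    def __init__(self, model: GaussianPRFModel, params: PRFParams):
        self.model = model
        self.params = params
        self._bse = None

    @property
    def fittedvalues(self) -> np.ndarray:
        return self.model.predict(self.params)

    @property
    def resid(self) -> np.ndarray:
        return self.model.endog - self.fittedvalues

    @property
    def rsquared(self) -> float:
        return self.params.r2

    @property
    def nobs(self) -> int:
        return self.model.endog.shape[0]

    def _param_vector(self) -> np.ndarray:
        p = self.params
        return np.array([p.x0, p.y0, p.sigma, p.beta, p.baseline])

    @property
    def bse(self) -> pd.Series:
        """Linearised (Gauss–Newton) standard errors of the five parameters."""
        if self._bse is None:
            theta = self._param_vector()
            eps = np.maximum(1e-4, 1e-4 * np.abs(theta))
            J = np.empty((self.nobs, theta.size))
            for i in range(theta.size):
                hi, lo = theta.copy(), theta.copy()
                hi[i] += eps[i]
                lo[i] -= eps[i]
                J[:, i] = (self._predict_vector(hi) - self._predict_vector(lo)) / (2 * eps[i])
            dof = max(self.nobs - theta.size, 1)
            s2 = float(self.resid @ self.resid) / dof
            cov = s2 * np.linalg.pinv(J.T @ J)
            self._bse = pd.Series(np.sqrt(np.maximum(np.diag(cov), 0.0)),
                                  index=self.PARAM_NAMES)
        return self._bse

    def _predict_vector(self, theta: np.ndarray) -> np.ndarray:
        p = PRFParams(theta[0], theta[1], max(theta[2], 1e-6), beta=theta[3],
                      baseline=theta[4])
        return self.model.predict(p)

    def eccentricity(self) -> float:
        return ecc_polar(self.params)[0]

    def polar_angle(self) -> float:
        return ecc_polar(self.params)[1]

    def crossval_r2(self, ts: np.ndarray, design: StimulusDesign | None = None) -> float:
        """cvR^2 of this fit's prediction shape against held-out data."""
        design = design if design is not None else self.model.design
        return crossval_r2(self.params, np.asarray(ts, float), design, self.model.hrf)

    def plot_fit(self, ax=None):
        """Data and fitted prediction over time (matplotlib axes)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(8, 3))
        t = np.arange(self.nobs) * self.model.design.tr
        ax.plot(t, self.model.endog, lw=0.6, alpha=0.6, label="data")
        ax.plot(t, self.fittedvalues, lw=1.5, label="pRF prediction")
        ax.set_xlabel("time (s)")
        ax.set_ylabel("%BOLD")
        ax.legend(frameon=False)
        return ax

    def plot_prf(self, ax=None):
        """The fitted Gaussian pRF in visual space."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(4, 4))
        X, Y = self.model.design.pixel_grid()
        p = self.params
        ax.contourf(X, Y, _gaussian_field(p.x0, p.y0, p.sigma, X, Y), levels=20)
        ax.plot(p.x0, p.y0, "r+", ms=10)
        ax.set_xlabel("x (deg)")
        ax.set_ylabel("y (deg)")
        ax.set_aspect("equal")
        return ax

    def summary(self) -> str:
        p = self.params
        bse = self.bse
        ecc, pol = ecc_polar(p)
        lines = [
            "Gaussian pRF model fit",
            "=" * 54,
            f"No. observations: {self.nobs:>8d}    R-squared: {p.r2:8.4f}",
            f"TR: {self.model.design.tr:.4f} s    HRF: {self.model.hrf.definition}",
            f"Eccentricity: {ecc:.3f} deg    Polar angle: {np.rad2deg(pol):.1f} deg",
            "-" * 54,
            f"{'param':>10s} {'estimate':>12s} {'std err':>12s}",
        ]
        for name, val in zip(self.PARAM_NAMES, self._param_vector()):
            lines.append(f"{name:>10s} {val:12.4f} {bse[name]:12.4f}")
        if not p.reliable:
            lines.append("warning: spatial parameters flagged unreliable")
        lines.append("=" * 54)
        return "\n".join(lines)
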
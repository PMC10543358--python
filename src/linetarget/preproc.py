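"""The line-scanning signal chain.

Raw multi-coil multi-echo line data go through a fixed sequence of steps:

1. SVD (scree-elbow) thermal-noise suppression per coil and echo
2. tSNR- and sensitivity-weighted sum-of-squares coil combination per echo
3. sum-of-squares echo combination
4. discrete-cosine-transform (DCT) high-pass drift removal (< 0.01 Hz)
5. line-tailored aCompCor: PCA on white-matter/CSF positions inside the
   nominal line, components high-passed above ~0.18 Hz, regressed out
6. conversion to percent signal change
7. Savitzky-Golay low-pass smoothing (window 11, order 3)
8. averaging of stimulus iterations

:class:`PreprocChain` records and enforces this order; the individual
steps are plain functions usable on their own.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import savgol_filter
from sklearn.decomposition import PCA

__all__ = [
    "MultiCoilLineSeries",
    "LineSeries",
    "NuisanceSet",
    "PreprocChain",
    "CHAIN_ORDER",
    "svd_denoise",
    "detect_elbow",
    "temporal_snr",
    "combine_coils",
    "combine_echoes",
    "dct_highpass",
    "line_acompcor",
    "savgol_smooth",
    "percent_signal_change",
    "average_iterations",
]

#: Fixed processing order of the chain.
CHAIN_ORDER = (
    "svd_denoise",
    "combine_coils",
    "combine_echoes",
    "dct_highpass",
    "line_acompcor",
    "percent_signal_change",
    "savgol_smooth",
    "average_iterations",
)


@dataclass
class MultiCoilLineSeries:
    """Raw line data: (coil C, echo E, position P, time T), complex or real.

    dt : seconds per sample (the line TR); echo_times : seconds, length E;
    position_res : mm per voxel along the line (laminar direction).
    """

    data: np.ndarray
    dt: float
    echo_times: tuple
    position_res: float = 0.25

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 4:
            raise ValueError(f"data must be (C, E, P, T), got shape {self.data.shape}")
        self.echo_times = tuple(float(t) for t in self.echo_times)
        if self.data.shape[1] != len(self.echo_times):
            raise ValueError(
                f"{self.data.shape[1]} echoes in data but {len(self.echo_times)} echo times"
            )
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("line data contains NaN/Inf")

    @property
    def n_coils(self) -> int:
        return self.data.shape[0]

    @property
    def n_positions(self) -> int:
        return self.data.shape[2]

    @property
    def n_frames(self) -> int:
        return self.data.shape[3]


@dataclass
class LineSeries:
    """Processed line time courses: (position P, time T), real valued."""

    data: np.ndarray
    dt: float
    position_res: float = 0.25
    depth_labels: np.ndarray | None = None  # per-position tissue/depth annotation

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError(f"data must be (P, T), got {self.data.shape}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("line series contains non-finite values")


@dataclass
class NuisanceSet:
    """Zero-mean nuisance regressors (T x K) with their provenance."""

    regressors: np.ndarray
    source: str  # 'dct' or 'acompcor'
    cutoff_hz: float

    def __post_init__(self) -> None:
        r = np.asarray(self.regressors, dtype=float)
        if r.ndim != 2:
            raise ValueError("regressors must be (T, K)")
        if r.shape[1] and np.max(np.abs(r.mean(axis=0))) > 1e-8 * max(np.abs(r).max(), 1.0):
            raise ValueError("nuisance regressor columns must be zero-mean")
        self.regressors = r


# ---------------------------------------------------------------------------
# SVD denoising


def detect_elbow(singular_values) -> int:
    """Scree-plot elbow of a non-increasing spectrum.

    Returns the index of maximal perpendicular distance from the
    (index, value) curve to the chord joining its first and last points;
    components strictly before that index are retained. Ties break toward
    the larger index (retaining more components). A constant spectrum has
    no elbow: all components are retained (with a warning).
    """
    s = np.asarray(singular_values, dtype=float)
    n = s.size
    if n < 2:
        return n
    if np.any(np.diff(s) > 1e-12 * max(s.max(), 1.0)):
        raise ValueError("singular values must be non-increasing")
    if np.allclose(s, s[0]):
        warnings.warn("constant singular spectrum: elbow undefined, retaining all")
        return n
    x = np.arange(n, dtype=float)
    p0 = np.array([0.0, s[0]])
    p1 = np.array([n - 1.0, s[-1]])
    chord = p1 - p0
    chord = chord / np.linalg.norm(chord)
    rel = np.column_stack([x, s]) - p0
    # perpendicular distance = |component of rel orthogonal to the chord|
    dist = np.abs(rel[:, 0] * chord[1] - rel[:, 1] * chord[0])
    best = np.flatnonzero(dist >= dist.max() - 1e-12 * max(dist.max(), 1.0)).max()
    return int(best)


def svd_denoise(matrix: np.ndarray) -> tuple[np.ndarray, int]:
    """Suppress thermal noise by zeroing singular values past the scree elbow.

    Operates on one position x time (Casorati) matrix of a single coil and
    echo, complex or real. Returns (denoised matrix, retained rank).
    """
    m = np.asarray(matrix)
    if m.ndim != 2:
        raise ValueError("svd_denoise expects a 2-D position x time matrix")
    if not np.any(m):
        return m.copy(), 0
    u, s, vt = np.linalg.svd(m, full_matrices=False)
    keep = detect_elbow(s)
    if keep >= s.size:
        return m.copy(), int(s.size)
    s_thr = s.copy()
    s_thr[keep:] = 0.0
    return (u * s_thr) @ vt, int(keep)


def temporal_snr(data: np.ndarray, axis: int = -1) -> np.ndarray:
    """tSNR = |mean| / std along the time axis (0 where std is 0)."""
    mu = np.abs(np.mean(data, axis=axis))
    sd = np.std(np.abs(data), axis=axis)
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(sd > 0, mu / np.where(sd > 0, sd, 1.0), 0.0)


# ---------------------------------------------------------------------------
# coil / echo combination


def combine_coils(series: MultiCoilLineSeries, sensitivities: np.ndarray,
                  tsnr: np.ndarray | None = None,
                  denoise: bool = True) -> tuple[np.ndarray, np.ndarray]:
    """tSNR- and sensitivity-weighted sum-of-squares coil combination per echo.

    Per echo and position, combined(t) = sqrt( sum_c w_c |x_c(t)|^2 ) with
    w_c = (tsnr_c * |s_c|)^2 / sum_c (tsnr_c * |s_c|)^2. The normalised
    weights make the equal-weight case reduce to the root mean square over
    coils. When ``tsnr`` is None it is computed from the (denoised) data.

    Returns (per-echo combined array (E, P, T), retained SVD ranks (C, E))
    — ranks are -1 when denoising is disabled.
    """
    C, E, P, T = series.data.shape
    sens = np.abs(np.asarray(sensitivities, dtype=float))
    if sens.shape != (C, P):
        raise ValueError(f"sensitivities must be (C, P) = {(C, P)}, got {sens.shape}")
    data = series.data
    ranks = -np.ones((C, E), dtype=int)
    if denoise:
        den = np.empty_like(data)
        for c in range(C):
            for e in range(E):
                den[c, e], ranks[c, e] = svd_denoise(data[c, e])
        data = den
    if tsnr is None:
        tsnr = temporal_snr(np.abs(data).mean(axis=1))  # (C, P), averaged over echoes
    tsnr = np.asarray(tsnr, dtype=float)
    if tsnr.shape != (C, P):
        raise ValueError(f"tsnr must be (C, P) = {(C, P)}, got {tsnr.shape}")
    if np.any(tsnr < 0) or np.any(sens < 0):
        raise ValueError("weights must be non-negative")

    w = (tsnr * sens) ** 2  # (C, P)
    norm = w.sum(axis=0)  # (P,)
    zero = norm <= 0
    if np.any(zero):
        warnings.warn(
            f"{int(zero.sum())} positions have all-zero coil weights; "
            "falling back to unweighted root-sum-of-squares there"
        )
        w[:, zero] = 1.0
        norm = w.sum(axis=0)
    w = w / norm  # normalized weights, sum_c w_c = 1 per position
    combined = np.sqrt(np.einsum("cp,cept->ept", w, np.abs(data) ** 2))
    return combined, ranks


def combine_echoes(per_echo: np.ndarray) -> np.ndarray:
    """Sum-of-squares combination over the echo axis: (E, P, T) -> (P, T)."""
    arr = np.asarray(per_echo, dtype=float)
    if arr.ndim != 3 or arr.shape[0] < 1:
        raise ValueError(f"expected (E, P, T) with E >= 1, got {arr.shape}")
    return np.sqrt(np.sum(arr**2, axis=0))


# ---------------------------------------------------------------------------
# temporal filtering / nuisance regression


def _dct_basis(T: int, dt: float, cutoff_hz: float) -> np.ndarray:
    """Zero-mean DCT-II columns with frequency < cutoff (constant excluded).

    Basis k has frequency k / (2 T dt); the standard drift model.
    """
    kmax = int(np.floor(2.0 * T * dt * cutoff_hz))
    n = np.arange(T)
    cols = [np.cos(np.pi * (2 * n + 1) * k / (2.0 * T)) for k in range(1, kmax + 1)]
    if not cols:
        return np.empty((T, 0))
    B = np.column_stack(cols)
    return B - B.mean(axis=0)


def _regress_out(ts: np.ndarray, regressors: np.ndarray) -> np.ndarray:
    """Residualize rows of (P, T) ts against zero-mean (T, K) regressors.

    The temporal mean of each row is preserved (regressors are zero-mean
    and the projection is taken on demeaned data).
    """
    if regressors.shape[1] == 0:
        return ts.copy()
    mu = ts.mean(axis=1, keepdims=True)
    centered = ts - mu
    coef, *_ = np.linalg.lstsq(regressors, centered.T, rcond=None)
    return centered - (regressors @ coef).T + mu


def dct_highpass(ts: np.ndarray, dt: float, cutoff_hz: float = 0.01
                 ) -> tuple[np.ndarray, NuisanceSet]:
    """Remove slow drifts by regressing out DCT basis functions < cutoff.

    The constant term is excluded, so the temporal mean of each position
    is preserved. With too short a series for even one basis function the
    data pass through unchanged (with a warning).
    """
    ts = np.atleast_2d(np.asarray(ts, dtype=float))
    T = ts.shape[1]
    B = _dct_basis(T, dt, cutoff_hz)
    if B.shape[1] == 0:
        warnings.warn(
            f"series too short for a DCT drift regressor below {cutoff_hz} Hz; "
            "returning data unchanged"
        )
        return ts.copy(), NuisanceSet(np.empty((T, 0)), source="dct", cutoff_hz=cutoff_hz)
    return _regress_out(ts, B), NuisanceSet(B, source="dct", cutoff_hz=cutoff_hz)


def line_acompcor(ts: np.ndarray, seg: np.ndarray, line_mask: np.ndarray,
                  dt: float, n_components: int = 5,
                  resp_cutoff_hz: float = 0.18) -> tuple[np.ndarray, NuisanceSet]:
    """Line-tailored aCompCor physiological-noise regression.

    White-matter and CSF positions inside the nominal line mask provide
    the noise pool; the first ``n_components`` principal-component scores
    of their standardized time courses are high-pass filtered above
    ``resp_cutoff_hz`` (slightly below the respiratory frequency, so slow
    task-band fluctuations are never regressed out) and removed from every
    position's time course.

    Parameters
    ----------
    seg : per-position tissue labels, strings from {'GM','WM','CSF'} or
        ints {1: GM, 2: WM, 3: CSF}.
    line_mask : per-position boolean inclusion in the nominal line.
    """
    ts = np.asarray(ts, dtype=float)
    P, T = ts.shape
    if dt <= 0 or 1.0 / (2 * dt) <= resp_cutoff_hz:
        raise ValueError("sampling rate must exceed twice the high-pass cutoff")
    seg = np.asarray(seg)
    mask = np.asarray(line_mask, dtype=bool)
    if seg.shape[0] != P or mask.shape[0] != P:
        raise ValueError("seg and line_mask must have one entry per position")
    if seg.dtype.kind in "US":
        noise_pool = np.isin(np.char.upper(seg.astype(str)), ["WM", "CSF"]) & mask
        available = sorted(set(seg.astype(str)))
    else:
        noise_pool = np.isin(seg, [2, 3]) & mask
        available = sorted(int(v) for v in np.unique(seg))
    if n_components == 0:
        return ts.copy(), NuisanceSet(np.empty((T, 0)), "acompcor", resp_cutoff_hz)
    if not noise_pool.any():
        raise ValueError(
            f"no WM/CSF positions inside the line mask; labels present: {available}"
        )

    pool = ts[noise_pool]
    sd = pool.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    z = (pool - pool.mean(axis=1, keepdims=True)) / sd
    k = min(n_components, z.shape[0], T)
    scores = PCA(n_components=k, svd_solver="full").fit_transform(z.T)  # (T, k)

    # high-pass each score: remove DCT content below the respiratory cutoff
    low = _dct_basis(T, dt, resp_cutoff_hz)
    scores = _regress_out(scores.T, low).T if low.shape[1] else scores
    scores = scores - scores.mean(axis=0)
    cleaned = _regress_out(ts, scores)
    return cleaned, NuisanceSet(scores, source="acompcor", cutoff_hz=resp_cutoff_hz)


def savgol_smooth(ts: np.ndarray, window: int = 11, polyorder: int = 3) -> np.ndarray:
    """Savitzky-Golay least-squares polynomial smoothing along time.

    Edges are handled by polynomial extrapolation of the terminal windows,
    matching the filter's interior behaviour.
    """
    ts = np.asarray(ts, dtype=float)
    if window % 2 == 0 or window <= polyorder:
        raise ValueError("window must be odd and larger than polyorder")
    if ts.shape[-1] < window:
        raise ValueError(f"series length {ts.shape[-1]} shorter than window {window}")
    return savgol_filter(ts, window_length=window, polyorder=polyorder,
                         axis=-1, mode="interp")


def percent_signal_change(ts: np.ndarray, baseline_frames=None) -> np.ndarray:
    """Convert to %change about a baseline: 100 * (x - mu) / mu per position.

    ``baseline_frames`` indexes the empty-screen frames; None uses the
    full-series mean of each position.
    """
    ts = np.atleast_2d(np.asarray(ts, dtype=float))
    if baseline_frames is None:
        mu = ts.mean(axis=1)
    else:
        idx = np.asarray(baseline_frames, dtype=int)
        if idx.size == 0:
            raise ValueError("baseline frame set is empty")
        mu = ts[:, idx].mean(axis=1)
    bad = np.abs(mu) < 1e-300
    if np.any(bad):
        raise ValueError(
            f"zero baseline at position(s) {np.flatnonzero(bad).tolist()}; "
            "%change undefined"
        )
    return 100.0 * (ts - mu[:, None]) / mu[:, None]


def average_iterations(ts: np.ndarray, iteration_boundaries) -> np.ndarray:
    """Element-wise mean over equal-length segments of the time axis.

    ``iteration_boundaries`` are the segment start indices (the first
    segment must start at 0); segments must tile the series exactly. Also
    used for run- and voxel-averaging by stacking along a leading axis.
    """
    ts = np.atleast_2d(np.asarray(ts, dtype=float))
    T = ts.shape[-1]
    bounds = list(iteration_boundaries) + [T]
    if bounds[0] != 0:
        raise ValueError("first iteration must start at index 0")
    lengths = np.diff(bounds)
    if len(set(lengths.tolist())) != 1:
        raise ValueError(f"ragged iteration segments of lengths {lengths.tolist()}")
    L = int(lengths[0])
    segs = [ts[..., b:b + L] for b in bounds[:-1]]
    return np.mean(segs, axis=0)


# ---------------------------------------------------------------------------
# the chain


@dataclass
class PreprocChain:
    """Descriptor and executor of the fixed line-scanning chain.

    Records parameters for every step and refuses out-of-order execution;
    :meth:`run` pushes a :class:`MultiCoilLineSeries` through the whole
    chain and returns the cleaned :class:`LineSeries` plus a step log.
    """

    dct_cutoff_hz: float = 0.01
    acompcor_cutoff_hz: float = 0.18
    n_acompcor: int = 5
    savgol_window: int = 11
    savgol_polyorder: int = 3
    denoise: bool = True
    order: tuple = CHAIN_ORDER
    log: list = field(default_factory=list)

    def _advance(self, step: str) -> None:
        done = [entry["step"] for entry in self.log]
        expected = [s for s in self.order if s not in done]
        if not expected or expected[0] != step:
            raise RuntimeError(
                f"chain order violation: got {step!r}, expected {expected[0] if expected else 'nothing'}"
            )
        self.log.append({"step": step})

    def run(self, series: MultiCoilLineSeries, sensitivities: np.ndarray,
            seg: np.ndarray, line_mask: np.ndarray,
            baseline_frames=None, iteration_boundaries=None,
            tsnr: np.ndarray | None = None) -> LineSeries:
        self.log = []
        self._advance("svd_denoise")  # folded into combine_coils (per coil/echo)
        self._advance("combine_coils")
        per_echo, ranks = combine_coils(series, sensitivities, tsnr=tsnr,
                                        denoise=self.denoise)
        self.log[-2]["retained_ranks"] = ranks.tolist()
        self._advance("combine_echoes")
        pt = combine_echoes(per_echo)
        self._advance("dct_highpass")
        pt, dct_set = dct_highpass(pt, series.dt, self.dct_cutoff_hz)
        self.log[-1]["n_regressors"] = dct_set.regressors.shape[1]
        self._advance("line_acompcor")
        pt, comp_set = line_acompcor(pt, seg, line_mask, series.dt,
                                     n_components=self.n_acompcor,
                                     resp_cutoff_hz=self.acompcor_cutoff_hz)
        self.log[-1]["n_components"] = comp_set.regressors.shape[1]
        self._advance("percent_signal_change")
        pt = percent_signal_change(pt, baseline_frames)
        self._advance("savgol_smooth")
        pt = savgol_smooth(pt, self.savgol_window, self.savgol_polyorder)
        self._advance("average_iterations")
        if iteration_boundaries is not None:
            pt = average_iterations(pt, iteration_boundaries)
        return LineSeries(data=pt, dt=series.dt, position_res=series.position_res,
                          depth_labels=np.asarray(seg))
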
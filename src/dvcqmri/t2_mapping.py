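"""Pixel-wise T2 mapping from a multi-echo spin-echo series.

The decay model is a mono-exponential with a fixed noise-floor offset,

    S(t) = S0 * exp(-t / T2) + 2 * L * sigma**2,

with L the number of receive-coil elements and sigma the per-channel noise
std. The offset is held fixed during fitting (sigma comes from a background
ROI via the chi-mean relation, see :mod:`dvcqmri.quant`); only (S0, T2) are
free, with S0 >= 0 and T2 in [0.5, 2000] ms. Initialization is a weighted
log-linear regression on the offset-subtracted signal. Voxels without a
decaying component, voxels whose fit does not converge, fits pinned at the
T2 bounds, and fits whose amplitude stays below 5 sigma (noise-only voxels
can mimic a shallow decay) are flagged invalid rather than clamped, so ROI
means are not contaminated by degenerate fits.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .phantom import DEFAULT_ECHO_TIMES_MS, EchoSeries

__all__ = [
    "T2_BOUNDS_MS",
    "MSMEParams",
    "T2FitResult",
    "T2Map",
    "fit_t2_decay",
    "fit_t2_map",
]

#: Fit bounds for T2 (ms).
T2_BOUNDS_MS = (0.5, 2000.0)


@dataclass(frozen=True)
class MSMEParams:
    """Echo grid and repetition time of the multi-echo spin-echo acquisition."""

    echo_times_ms: np.ndarray = field(default_factory=lambda: DEFAULT_ECHO_TIMES_MS.copy())
    tr_ms: float = 8000.0

    def __post_init__(self) -> None:
        t = np.asarray(self.echo_times_ms, dtype=float)
        if t.ndim != 1 or len(t) < 4:
            raise ValueError("at least 4 echoes are required for fitting")
        if t[0] <= 0 or np.any(np.diff(t) <= 0):
            raise ValueError("echo times must be strictly increasing and positive")
        if self.tr_ms <= 0:
            raise ValueError("tr_ms must be positive")
        object.__setattr__(self, "echo_times_ms", t)


@dataclass(frozen=True)
class T2FitResult:
    """Result of one voxel fit. ``offset`` is the fixed value 2*L*sigma**2."""

    s0: float
    t2_ms: float
    offset: float
    rss: float
    converged: bool


@dataclass(frozen=True)
class T2Map:
    """Voxel-wise T2 (ms) with validity mask and fit provenance."""

    values_ms: np.ndarray
    valid: np.ndarray
    provenance: dict = field(default_factory=dict)


def _loglinear_init(t: np.ndarray, w: np.ndarray) -> tuple[float, float] | None:
    """(S0, T2) from a weighted linear fit of log(w) vs t; None if impossible."""
    pos = w > 0
    if pos.sum() < 2:
        return None
    tp, wp = t[pos], w[pos]
    # weight by the signal so the (noisier) log of small values counts less
    coef = np.polyfit(tp, np.log(wp), 1, w=wp)
    slope, intercept = coef[0], coef[1]
    if slope >= 0:
        # no apparent decay; start from the geometric middle of the bounds
        return float(np.exp(intercept)), float(np.sqrt(T2_BOUNDS_MS[0] * T2_BOUNDS_MS[1]))
    t2 = float(np.clip(-1.0 / slope, *T2_BOUNDS_MS))
    return float(np.exp(intercept)), t2


def fit_t2_decay(
    signal: np.ndarray,
    params: MSMEParams,
    sigma: float,
    L: int = 4,
) -> T2FitResult:
    """Fit (S0, T2) of the noise-floor decay model to one voxel's echo train.

    Minimizes ``sum_t [signal(t) - (S0*exp(-t/T2) + 2*L*sigma**2)]**2`` with
    the offset held fixed. ``converged=False`` when the decaying component is
    absent (all offset-subtracted values <= eps), when the solver fails, or
    when T2 is pinned at a bound.
    """
    y = np.asarray(signal, dtype=float)
    t = params.echo_times_ms
    if y.shape != t.shape:
        raise ValueError(f"signal length {y.shape} does not match echo grid {t.shape}")
    if not np.all(np.isfinite(y)):
        raise ValueError("signal contains non-finite values")
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    offset = 2.0 * L * sigma * sigma

    w = y - offset
    eps = 1e-12 * max(1.0, float(np.max(np.abs(y))))
    if np.all(w <= eps):
        return T2FitResult(s0=0.0, t2_ms=np.nan, offset=offset,
                           rss=float(np.sum(w * w)), converged=False)

    init = _loglinear_init(t, w)
    if init is None:
        return T2FitResult(s0=0.0, t2_ms=np.nan, offset=offset,
                           rss=float(np.sum(w * w)), converged=False)
    s0_0, t2_0 = max(init[0], eps), init[1]

    def resid(x):
        return x[0] * np.exp(-t / x[1]) - w

    def jac(x):
        e = np.exp(-t / x[1])
        return np.stack([e, x[0] * t / (x[1] * x[1]) * e], axis=1)

    res = least_squares(
        resid, x0=[s0_0, t2_0], jac=jac,
        bounds=([0.0, T2_BOUNDS_MS[0]], [np.inf, T2_BOUNDS_MS[1]]),
        xtol=1e-8, ftol=1e-8, gtol=1e-8, max_nfev=200,
    )
    s0, t2 = float(res.x[0]), float(res.x[1])
    pinned = t2 <= T2_BOUNDS_MS[0] * (1 + 1e-6) or t2 >= T2_BOUNDS_MS[1] * (1 - 1e-6)
    # amplitude gate: chi-noise fluctuations in signal-free voxels can mimic
    # a shallow decay, so an amplitude below 5 sigma is not a credible tissue
    # signal and the voxel is flagged invalid
    converged = bool(res.success) and not pinned and s0 > max(eps, 5.0 * sigma)
    return T2FitResult(s0=s0, t2_ms=t2 if converged else np.nan, offset=offset,
                       rss=float(2.0 * res.cost), converged=converged)


def fit_t2_map(
    series: EchoSeries,
    mask: np.ndarray,
    sigma: float | None = None,
    L: int = 4,
) -> T2Map:
    """Apply :func:`fit_t2_decay` to every masked voxel of an echo series.

    ``sigma`` must be supplied (estimate it from a background ROI with
    :func:`dvcqmri.quant.estimate_sigma_from_background` first). Non-converged
    voxels carry NaN and are excluded via the validity mask.
    """
    if sigma is None:
        raise ValueError(
            "sigma is required: estimate it from the background ROI with "
            "dvcqmri.quant.estimate_sigma_from_background(series values, L)")
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != series.data.shape[:-1]:
        raise ValueError("mask shape must match the spatial grid of the series")
    params = MSMEParams(echo_times_ms=series.echo_times_ms)

    values = np.full(mask.shape, np.nan)
    valid = np.zeros(mask.shape, dtype=bool)
    idx = np.argwhere(mask)
    curves = series.data[mask]
    for (i, j, k), y in zip(idx, curves):
        fit = fit_t2_decay(y, params, sigma=sigma, L=L)
        if fit.converged:
            values[i, j, k] = fit.t2_ms
            valid[i, j, k] = True
    return T2Map(
        values_ms=values,
        valid=valid,
        provenance={
            "sigma": float(sigma),
            "L": int(L),
            "n_echoes": int(len(series.echo_times_ms)),
            "te_first_ms": float(series.echo_times_ms[0]),
            "te_last_ms": float(series.echo_times_ms[-1]),
            "n_fitted": int(mask.sum()),
            "n_invalid": int(mask.sum() - valid.sum()),
        },
    )
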
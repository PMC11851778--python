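"""MP2RAGE T1 mapping: signal model, lookup table, ratio combination, inversion.

MP2RAGE acquires two gradient-echo (GRE) readout blocks at inversion times
TI1 and TI2 inside one inversion-prepared cycle of length TR_seq. The
bias-free combination

    ratio = GRE1 * GRE2 / (GRE1**2 + GRE2**2)   in [-0.5, 0.5]

is a monotone function of T1 for suitable sequence parameters, so a lookup
table (LUT) simulated from the sequence parameters inverts it voxel-wise.

The longitudinal magnetization obeys an affine map over one cycle
(inversion -> relax TA -> GRE block 1 -> relax TB -> GRE block 2 -> relax TC);
each GRE pulse scales Mz by cos(alpha) and each inter-pulse gap relaxes it
toward M0. The periodic steady state is the closed-form fixed point of that
affine map (|slope| < 1 always holds for positive timings and flips below
90 degrees). Signals are read at the center echo of each block, which fixes
the timing convention: TI is measured to the center of the GRE block
(linear phase encoding), so TA = TI1 - (n/2)*TR_gre, etc.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "MP2RAGEParams",
    "LookupTable",
    "T1Map",
    "derived_timings",
    "simulate_mp2rage_signals",
    "build_lookup_table",
    "mp2rage_combine",
    "invert_ratio_to_t1",
]


@dataclass(frozen=True)
class MP2RAGEParams:
    """Sequence parameters of the 3D MP2RAGE acquisition.

    Defaults are the study protocol at 4.7 T: TI1/TI2/TR = 800/2200/6250 ms,
    160 echoes per GRE readout at TR_gre = 6 ms, 7-degree excitation flips,
    ideal adiabatic inversion.
    """

    ti1_ms: float = 800.0
    ti2_ms: float = 2200.0
    tr_seq_ms: float = 6250.0
    n_gre: int = 160
    tr_gre_ms: float = 6.0
    flip1_deg: float = 7.0
    flip2_deg: float = 7.0
    inversion_efficiency: float = 1.0
    scaling_R: float = 1.0

    def __post_init__(self) -> None:
        if not (0 < self.flip1_deg < 90 and 0 < self.flip2_deg < 90):
            raise ValueError("flip angles must lie in (0, 90) degrees")
        if not (0 < self.inversion_efficiency <= 1):
            raise ValueError("inversion_efficiency must lie in (0, 1]")
        if self.n_gre < 0 or self.n_gre % 2:
            raise ValueError("n_gre must be a nonnegative even integer")
        derived_timings(self)  # validates TA/TB/TC > 0


def derived_timings(params: MP2RAGEParams) -> tuple[float, float, float]:
    """Relaxation gaps (TA, TB, TC) between inversion and the two GRE blocks.

    With TI measured to the center of each block:
    ``TA = TI1 - (n/2)*TR_gre``, ``TB = TI2 - TI1 - n*TR_gre``,
    ``TC = TR_seq - TI2 - (n/2)*TR_gre``. All three must be positive.
    """
    half = params.n_gre / 2.0 * params.tr_gre_ms
    ta = params.ti1_ms - half
    tb = params.ti2_ms - params.ti1_ms - params.n_gre * params.tr_gre_ms
    tc = params.tr_seq_ms - params.ti2_ms - half
    if min(ta, tb, tc) <= 0:
        raise ValueError(
            f"inconsistent sequence parameters: TA={ta:g}, TB={tb:g}, TC={tc:g} ms "
            "(all must be positive)")
    return ta, tb, tc


def _compose(a2: np.ndarray, b2: np.ndarray, a1: np.ndarray, b1: np.ndarray):
    """Compose affine maps: apply (a1,b1) first, then (a2,b2)."""
    return a2 * a1, a2 * b1 + b2


def _relax(dt: float, t1: np.ndarray):
    e = np.exp(-dt / t1)
    return e, 1.0 - e


def _block(n: int, cosa: float, e: np.ndarray):
    """n repetitions of (pulse: *cosa, relax tr_gre): closed-form affine map."""
    k = cosa * e
    a = k ** n
    with np.errstate(invalid="ignore", divide="ignore"):
        b = np.where(np.isclose(k, 1.0), n * (1.0 - e), (1.0 - e) * (1.0 - k ** n) / (1.0 - k))
    return a, b


def simulate_mp2rage_signals(t1_ms, params: MP2RAGEParams | None = None):
    """Steady-state MP2RAGE signals ``(s1, s2, ratio)`` at the given T1.

    ``t1_ms`` may be a scalar or array (ms, > 0). Signals are signed and
    normalized to M0 = 1: ``s_i = sin(alpha_i) * Mz`` at the center echo of
    block i. ``ratio = s1*s2 / (s1**2 + s2**2)`` lies in [-0.5, 0.5].
    """
    params = params or MP2RAGEParams()
    t1 = np.asarray(t1_ms, dtype=float)
    if np.any(t1 <= 0):
        raise ValueError("t1_ms must be positive")
    ta, tb, tc = derived_timings(params)
    cos1, sin1 = np.cos(np.radians(params.flip1_deg)), np.sin(np.radians(params.flip1_deg))
    cos2, sin2 = np.cos(np.radians(params.flip2_deg)), np.sin(np.radians(params.flip2_deg))
    eff = params.inversion_efficiency
    n, half = params.n_gre, params.n_gre // 2

    e_gre, _ = _relax(params.tr_gre_ms, t1) if n else (np.ones_like(t1), None)

    # One full cycle as an affine map Mz -> a*Mz + b, starting just before
    # the inversion pulse.
    a, b = -eff * np.ones_like(t1), np.zeros_like(t1)          # inversion
    a, b = _compose(*_relax(ta, t1), a, b)                     # relax TA
    a, b = _compose(*_block(n, cos1, e_gre), a, b)             # GRE block 1
    a, b = _compose(*_relax(tb, t1), a, b)                     # relax TB
    a, b = _compose(*_block(n, cos2, e_gre), a, b)             # GRE block 2
    a, b = _compose(*_relax(tc, t1), a, b)                     # relax TC
    if np.any(np.abs(a) >= 1.0):
        raise AssertionError("cycle map slope must satisfy |slope| < 1")
    m0 = b / (1.0 - a)  # periodic steady state just before inversion

    # Propagate the steady state to the center echo of each block.
    m = -eff * m0
    ea, fb = _relax(ta, t1)
    m = ea * m + fb
    ah, bh = _block(half, cos1, e_gre)
    s1 = sin1 * (ah * m + bh)
    ah2, bh2 = _block(n - half, cos1, e_gre)
    m = ah2 * (ah * m + bh) + bh2
    eb, fbb = _relax(tb, t1)
    m = eb * m + fbb
    ah, bh = _block(half, cos2, e_gre)
    s2 = sin2 * (ah * m + bh)

    denom = s1 * s1 + s2 * s2
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.where(denom > 0, s1 * s2 / denom, 0.0)
    if np.ndim(t1_ms) == 0:
        return float(s1), float(s2), float(ratio)
    return s1, s2, ratio


@dataclass(frozen=True)
class LookupTable:
    """Tabulated ratio-vs-T1 curve, strictly monotone over its grid."""

    t1_grid_ms: np.ndarray
    ratio_values: np.ndarray
    params: MP2RAGEParams = field(default_factory=MP2RAGEParams)

    @property
    def increasing(self) -> bool:
        """True when ratio increases with T1 (direction is recorded, not assumed)."""
        return bool(self.ratio_values[-1] > self.ratio_values[0])


def build_lookup_table(
    params: MP2RAGEParams | None = None,
    t1_grid_ms: np.ndarray | None = None,
) -> LookupTable:
    """Simulate the ratio over a T1 grid and verify strict monotonicity."""
    params = params or MP2RAGEParams()
    # Default grid covers the monotone branch of the ratio at the default
    # sequence parameters: the curve folds back where |S1| = |S2| (~3400 ms
    # with ideal inversion), so the table stops at 3300 ms — well beyond any
    # tissue T1 in the phantom.
    grid = np.arange(100.0, 3301.0, 1.0) if t1_grid_ms is None else np.asarray(t1_grid_ms, float)
    if grid.ndim != 1 or len(grid) < 2:
        raise ValueError("t1 grid must contain at least two points")
    if np.any(np.diff(grid) <= 0) or grid[0] <= 0 or grid[-1] > 10000:
        raise ValueError("t1 grid must be increasing and within (0, 10000] ms")
    _, _, ratio = simulate_mp2rage_signals(grid, params)
    d = np.diff(ratio)
    if not (np.all(d > 0) or np.all(d < 0)):
        raise ValueError(
            "MP2RAGE ratio is not strictly monotone over the requested T1 grid; "
            "restrict the grid to the monotone branch")
    return LookupTable(t1_grid_ms=grid, ratio_values=ratio, params=params)


def mp2rage_combine(
    gre1: np.ndarray,
    gre2: np.ndarray,
    scaling_R: float = 1.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Voxel-wise ``R * g1 * g2 / (g1**2 + g2**2)``.

    Returns ``(ratio, degenerate)`` where ``degenerate`` flags 0/0 voxels
    (set to 0 in the ratio). With R = 1 the output lies in [-0.5, 0.5].
    """
    g1 = np.asarray(gre1, dtype=float)
    g2 = np.asarray(gre2, dtype=float)
    if g1.shape != g2.shape:
        raise ValueError(f"shape mismatch: {g1.shape} vs {g2.shape}")
    denom = g1 * g1 + g2 * g2
    degenerate = denom == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.where(degenerate, 0.0, scaling_R * g1 * g2 / np.where(degenerate, 1.0, denom))
    return ratio, degenerate


@dataclass(frozen=True)
class T1Map:
    """Voxel-wise T1 (ms) with validity mask and reconstruction provenance."""

    values_ms: np.ndarray
    valid: np.ndarray
    provenance: dict = field(default_factory=dict)


def invert_ratio_to_t1(
    ratio_volume: np.ndarray,
    lut: LookupTable,
    extra_invalid: np.ndarray | None = None,
) -> T1Map:
    """Invert a ratio volume through the LUT by linear interpolation.

    Ratios strictly outside the table range are flagged invalid (NaN), never
    clamped; a boundary-equal ratio maps to the corresponding grid endpoint.
    ``extra_invalid`` marks voxels already known to be degenerate.
    """
    ratio = np.asarray(ratio_volume, dtype=float)
    xp, fp = lut.ratio_values, lut.t1_grid_ms
    if not lut.increasing:
        xp, fp = xp[::-1], fp[::-1]
    lo, hi = xp[0], xp[-1]
    valid = np.isfinite(ratio) & (ratio >= lo) & (ratio <= hi)
    if extra_invalid is not None:
        valid &= ~extra_invalid
    values = np.full(ratio.shape, np.nan)
    values[valid] = np.interp(ratio[valid], xp, fp)
    return T1Map(
        values_ms=values,
        valid=valid,
        provenance={
            "t1_grid_ms": [float(lut.t1_grid_ms[0]), float(lut.t1_grid_ms[-1])],
            "n_grid": int(len(lut.t1_grid_ms)),
            "ti1_ms": lut.params.ti1_ms,
            "ti2_ms": lut.params.ti2_ms,
            "tr_seq_ms": lut.params.tr_seq_ms,
        },
    )
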
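"""Synthetic rat-tail phantom: labeled geometry and acquisition simulators.

The phantom is a stylized cylinder stack, not an anatomical atlas. Axis 2 of
every array is the tail (cranio-caudal) axis; indices are 0-based voxels. One
vertebral unit along the tail axis reads

    disc (NP core + AF ring) -> CEP -> GP -> SB -> vertebral body
                                -> SB -> GP -> CEP (mirrored endplate)

and the pattern repeats ``n_vertebrae`` times. Immature animals have thicker
CEP and GP slabs than mature ones.

Three acquisitions are simulated on top of the label map:

* a multi-slice multi-echo spin-echo (MSME) series for T2 mapping — pure
  mono-exponential ``PD * exp(-TE/T2)`` per voxel (TR = 8000 ms is several
  times the longest T1, so T1 saturation is neglected);
* an MP2RAGE pair of inversion-prepared gradient-echo volumes for T1 mapping
  (signed signals from :mod:`dvcqmri.t1_mapping`);
* a 3D ultrashort-echo-time (UTE) volume — piecewise-constant amplitudes
  calibrated to the per-structure SNR targets (no T2* decay at TE = 31 us).

Magnitude noise follows a 4-element phased-array sum-of-squares model: each
channel receives ``A/sqrt(L)`` plus independent complex Gaussian noise of
std ``sigma`` per real/imaginary component, and the root sum of squares over
channels is the stored magnitude (chi distribution with 2L degrees of
freedom; noise-only mean ``sqrt(2)*gamma(L+1/2)/gamma(L)*sigma``).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .tissues import LABEL_LEGEND, STRUCTURES, TissueParamTable
from .t1_mapping import MP2RAGEParams, simulate_mp2rage_signals

__all__ = [
    "GeometrySpec",
    "LabelVolume",
    "CoilNoiseModel",
    "ROISet",
    "EchoSeries",
    "GeometryOverflowError",
    "EmptyROIError",
    "DEFAULT_SIGMA",
    "DEFAULT_ECHO_TIMES_MS",
    "build_label_map",
    "make_roi_set",
    "add_multicoil_magnitude_noise",
    "simulate_msme_series",
    "simulate_mp2rage_pair",
    "simulate_ute_volume",
]

#: Default per-channel noise std (a.u.). The magnitude-domain noise-floor
#: T2 model is only self-consistent when the fixed offset 2*L*sigma**2 is a
#: small fraction of the signal scale; sigma = 0.2 keeps the offset at
#: 0.32 a.u. (~0.5% of the weakest compartment's proton density) while
#: leaving a visible background floor. UTE amplitudes are calibrated to the
#: per-structure SNR targets at whatever sigma is used, so the UTE contrast
#: matches the in-vivo values by construction.
DEFAULT_SIGMA = 0.2

#: Default MSME echo grid: 100 echoes, uniform 3.8 -> 378.6 ms.
DEFAULT_ECHO_TIMES_MS = np.linspace(3.8, 378.6, 100)


class GeometryOverflowError(ValueError):
    """The requested vertebral units do not fit the matrix."""


class EmptyROIError(ValueError):
    """Erosion (or geometry) left a structure without voxels."""


@dataclass(frozen=True)
class GeometrySpec:
    """Voxel-level geometry of the synthetic tail.

    Thicknesses are along the tail axis (axis 2); ``np_radius_vox`` and
    ``af_ring_thickness_vox`` set the in-plane disc cross-section. The
    ``for_maturity`` constructor encodes the maturity contrast: immature
    animals get CEP/GP slabs twice as thick as mature ones.
    """

    matrix_size: tuple[int, int, int] = (64, 64, 32)
    voxel_size_mm: tuple[float, float, float] = (0.15, 0.15, 0.15)
    n_vertebrae: int = 2
    disc_height_vox: int = 4
    af_ring_thickness_vox: int = 2
    cep_thickness_vox: int = 1
    gp_thickness_vox: int = 1
    sb_thickness_vox: int = 2
    body_height_vox: int = 4
    np_radius_vox: int = 12
    maturity: str = "mature"

    def __post_init__(self) -> None:
        if self.n_vertebrae < 2:
            raise ValueError("n_vertebrae must be >= 2")
        for name in ("disc_height_vox", "af_ring_thickness_vox", "cep_thickness_vox",
                     "gp_thickness_vox", "sb_thickness_vox", "body_height_vox",
                     "np_radius_vox"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1 voxel")
        if any(v <= 0 for v in self.voxel_size_mm):
            raise ValueError("voxel sizes must be positive")

    @property
    def unit_length_vox(self) -> int:
        """Tail-axis extent of one vertebral unit."""
        endplate = self.cep_thickness_vox + self.gp_thickness_vox + self.sb_thickness_vox
        return self.disc_height_vox + 2 * endplate + self.body_height_vox

    @property
    def column_radius_vox(self) -> int:
        return self.np_radius_vox + self.af_ring_thickness_vox

    @classmethod
    def for_maturity(cls, maturity: str, **overrides) -> "GeometrySpec":
        if maturity == "mature":
            base = dict(cep_thickness_vox=1, gp_thickness_vox=1,
                        matrix_size=(64, 64, 32))
        elif maturity == "immature":
            base = dict(cep_thickness_vox=2, gp_thickness_vox=2,
                        matrix_size=(64, 64, 40))
        else:
            raise ValueError(f"unknown maturity {maturity!r}")
        base.update(overrides)
        return cls(maturity=maturity, **base)


@dataclass(frozen=True)
class LabelVolume:
    """3D integer compartment map with the shared label legend."""

    labels: np.ndarray
    voxel_size_mm: tuple[float, float, float]
    legend: dict[int, str] = field(default_factory=lambda: dict(LABEL_LEGEND))

    @property
    def shape(self) -> tuple[int, ...]:
        return self.labels.shape

    def mask(self, structure: str) -> np.ndarray:
        lab = {v: k for k, v in self.legend.items()}[structure]
        return self.labels == lab


@dataclass(frozen=True)
class CoilNoiseModel:
    """Multi-channel magnitude noise: per-channel complex Gaussian std
    ``sigma``, ``n_channels`` coil elements, deterministic under ``seed``."""

    sigma: float = DEFAULT_SIGMA
    n_channels: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if self.n_channels < 1:
            raise ValueError("n_channels must be >= 1")

    def rng(self, stream: int = 0) -> np.random.Generator:
        """Independent generator for a named sub-stream of this model."""
        return np.random.default_rng(np.random.SeedSequence([int(self.seed), int(stream)]))

    def with_seed(self, seed: int) -> "CoilNoiseModel":
        return replace(self, seed=seed)


@dataclass(frozen=True)
class ROISet:
    """Named binary masks, one per DVC structure, plus a background mask."""

    masks: dict[str, np.ndarray]
    background: np.ndarray
    erosion_vox: int = 0

    def __iter__(self):
        return iter(self.masks.items())

    def __getitem__(self, structure: str) -> np.ndarray:
        return self.masks[structure]


@dataclass(frozen=True)
class EchoSeries:
    """4D magnitude volume indexed by echo time (axis 3)."""

    data: np.ndarray
    echo_times_ms: np.ndarray
    voxel_size_mm: tuple[float, float, float]

    def __post_init__(self) -> None:
        if self.data.shape[-1] != len(self.echo_times_ms):
            raise ValueError("last axis must match the number of echo times")


def build_label_map(geom: GeometrySpec) -> LabelVolume:
    """Rasterize the cylinder-stack tail into an integer label map.

    Deterministic for a given geometry. Raises
    :class:`GeometryOverflowError` when the stacked vertebral units exceed the
    tail-axis extent or the column radius exceeds the in-plane field of view.
    """
    nx, ny, nz = geom.matrix_size
    total = geom.n_vertebrae * geom.unit_length_vox
    if total > nz:
        raise GeometryOverflowError(
            f"{geom.n_vertebrae} units of {geom.unit_length_vox} voxels need "
            f"{total} slices but the matrix has {nz}")
    r_col = geom.column_radius_vox
    if 2 * r_col + 1 > min(nx, ny):
        raise GeometryOverflowError(
            f"column diameter {2 * r_col + 1} exceeds in-plane matrix {min(nx, ny)}")

    yy, xx = np.meshgrid(np.arange(ny), np.arange(nx))
    r = np.hypot(xx - (nx - 1) / 2.0, yy - (ny - 1) / 2.0)
    in_np = r <= geom.np_radius_vox
    in_af = (r > geom.np_radius_vox) & (r <= r_col)
    in_col = r <= r_col

    labels = np.zeros((nx, ny, nz), dtype=np.int16)
    # slab sequence of one unit: (label, thickness)
    slabs = [
        ("disc", geom.disc_height_vox),
        (3, geom.cep_thickness_vox),
        (4, geom.gp_thickness_vox),
        (5, geom.sb_thickness_vox),
        (6, geom.body_height_vox),
        (5, geom.sb_thickness_vox),
        (4, geom.gp_thickness_vox),
        (3, geom.cep_thickness_vox),
    ]
    z0 = (nz - total) // 2
    z = z0
    for _ in range(geom.n_vertebrae):
        for lab, thick in slabs:
            sl = slice(z, z + thick)
            if lab == "disc":
                labels[:, :, sl][in_np] = 1
                labels[:, :, sl][in_af] = 2
            else:
                labels[:, :, sl][in_col] = lab
            z += thick
    return LabelVolume(labels=labels, voxel_size_mm=geom.voxel_size_mm)


def make_roi_set(label: LabelVolume, erosion_vox: int = 0) -> ROISet:
    """Binary ROI per DVC structure (eroded), plus a corner background ROI.

    Structure masks are the label regions eroded ``erosion_vox`` times with a
    6-connected structuring element; the background ROI is drawn from the
    volume corners (label 0 only), mirroring a noise ROI placed away from the
    object.
    """
    if erosion_vox < 0:
        raise ValueError("erosion_vox must be >= 0")
    name_to_label = {v: k for k, v in label.legend.items()}
    masks: dict[str, np.ndarray] = {}
    for structure in STRUCTURES:
        m = label.labels == name_to_label[structure]
        if erosion_vox > 0:
            m = ndimage.binary_erosion(m, iterations=erosion_vox)
        if not m.any():
            raise EmptyROIError(
                f"erosion by {erosion_vox} voxel(s) left the {structure} ROI empty")
        masks[structure] = m

    nx, ny, nz = label.labels.shape
    c = max(2, min(8, nx // 4, ny // 4, nz // 4))
    bg = np.zeros_like(label.labels, dtype=bool)
    for sx in (slice(0, c), slice(nx - c, nx)):
        for sy in (slice(0, c), slice(ny - c, ny)):
            bg[sx, sy, :] = True
    bg &= label.labels == 0
    if not bg.any():
        raise EmptyROIError("no background voxels available in the corner regions")
    return ROISet(masks=masks, background=bg, erosion_vox=erosion_vox)


def add_multicoil_magnitude_noise(
    clean: np.ndarray,
    noise: CoilNoiseModel,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Sum-of-squares magnitude of a noiseless amplitude image.

    Each voxel with clean amplitude ``A`` becomes
    ``sqrt(sum_l |A/sqrt(L) + n_l|^2)`` with ``n_l`` i.i.d. complex Gaussian
    (std ``sigma`` per real/imaginary part). Equal coil sensitivities
    ``A/sqrt(L)`` make the noiseless magnitude equal ``A`` exactly and the
    second moment ``A**2 + 2*L*sigma**2``. ``sigma = 0`` returns the input
    unchanged.
    """
    clean = np.asarray(clean, dtype=float)
    if np.any(clean < 0):
        raise ValueError("clean amplitudes must be >= 0")
    if noise.sigma == 0:
        return clean.copy()
    if rng is None:
        rng = noise.rng(stream=0)
    L = noise.n_channels
    a = clean / np.sqrt(L)
    acc = np.zeros_like(clean)
    for _ in range(L):
        acc += (a + rng.normal(0.0, noise.sigma, size=clean.shape)) ** 2
        acc += rng.normal(0.0, noise.sigma, size=clean.shape) ** 2
    return np.sqrt(acc)


def _jitter(values: np.ndarray, cv: float, rng: np.random.Generator) -> np.ndarray:
    """Multiplicative lognormal jitter with unit mean and coefficient of
    variation ``cv`` (emulates inter-animal / intra-tissue spread)."""
    if cv <= 0:
        return values
    s2 = np.log1p(cv * cv)
    factor = rng.lognormal(mean=-0.5 * s2, sigma=np.sqrt(s2), size=values.shape)
    return values * factor


def simulate_msme_series(
    label: LabelVolume,
    params: TissueParamTable,
    echo_times_ms: np.ndarray | None = None,
    noise: CoilNoiseModel | None = None,
    jitter_cv: float = 0.0,
) -> EchoSeries:
    """Simulate the multi-echo spin-echo magnitude series.

    Clean signal at echo time t is ``PD * exp(-t / T2)`` of the voxel's
    compartment; chi noise is applied independently per echo.
    """
    echo_times = np.asarray(DEFAULT_ECHO_TIMES_MS if echo_times_ms is None else echo_times_ms,
                            dtype=float)
    if echo_times.ndim != 1 or len(echo_times) < 1:
        raise ValueError("echo_times_ms must be a 1D sequence")
    if np.any(echo_times <= 0) or np.any(np.diff(echo_times) <= 0):
        raise ValueError("echo times must be strictly increasing and positive")
    noise = noise or CoilNoiseModel(sigma=0.0)
    _check_labels_covered(label, params)

    max_label = int(label.labels.max())
    pd_of = params.param_array("proton_density", max_label)
    t2_of = params.param_array("t2_ms", max_label)
    pd_map = pd_of[label.labels]
    t2_map = t2_of[label.labels]
    if jitter_cv > 0:
        t2_map = _jitter(t2_map, jitter_cv, noise.rng(stream=101))

    clean = pd_map[..., None] * np.exp(-echo_times[None, None, None, :] / t2_map[..., None])
    if noise.sigma > 0:
        rng = noise.rng(stream=1)
        out = np.empty_like(clean)
        for k in range(clean.shape[-1]):
            out[..., k] = add_multicoil_magnitude_noise(clean[..., k], noise, rng=rng)
    else:
        out = clean
    return EchoSeries(data=out, echo_times_ms=echo_times, voxel_size_mm=label.voxel_size_mm)


def simulate_mp2rage_pair(
    label: LabelVolume,
    params: TissueParamTable,
    seq: MP2RAGEParams | None = None,
    noise: CoilNoiseModel | None = None,
    gain: float = 20.0,
    jitter_cv: float = 0.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Simulate the signed GRE1/GRE2 volumes of the MP2RAGE acquisition.

    Per-voxel clean signals are the steady-state inversion-recovery readouts
    at the voxel's T1, scaled by ``gain * PD`` (receiver gain; amplitudes are
    defined only relative to sigma). Real Gaussian noise of std ``sigma`` is
    added to the signed, coil-combined signal — the matched-filter
    combination of L channels each seeing ``A/sqrt(L)`` plus noise ``sigma``.
    """
    seq = seq or MP2RAGEParams()
    noise = noise or CoilNoiseModel(sigma=0.0)
    _check_labels_covered(label, params)

    max_label = int(label.labels.max())
    pd_map = params.param_array("proton_density", max_label)[label.labels]
    t1_map = params.param_array("t1_ms", max_label)[label.labels]
    if jitter_cv > 0:
        t1_map = _jitter(t1_map, jitter_cv, noise.rng(stream=102))

    s1, s2, _ = simulate_mp2rage_signals(t1_map, seq)
    gre1 = gain * pd_map * s1
    gre2 = gain * pd_map * s2
    if noise.sigma > 0:
        rng = noise.rng(stream=2)
        gre1 = gre1 + rng.normal(0.0, noise.sigma, size=gre1.shape)
        gre2 = gre2 + rng.normal(0.0, noise.sigma, size=gre2.shape)
    return gre1, gre2


def simulate_ute_volume(
    label: LabelVolume,
    params: TissueParamTable,
    noise: CoilNoiseModel | None = None,
    sigma_ref: float | None = None,
) -> np.ndarray:
    """Simulate the UTE magnitude volume.

    At TE = 31 us no transverse decay is modelled; each compartment gets a
    constant amplitude ``ute_snr * sigma`` so the measured SNR matches the
    calibration target by construction. With ``sigma = 0`` (and no explicit
    ``sigma_ref``) the reference sigma falls back to 1 a.u. so the noiseless
    output is still the amplitude map.
    """
    noise = noise or CoilNoiseModel(sigma=0.0)
    _check_labels_covered(label, params)
    sref = sigma_ref if sigma_ref is not None else (noise.sigma if noise.sigma > 0 else 1.0)
    max_label = int(label.labels.max())
    amp = (params.param_array("ute_snr", max_label) * sref)[label.labels]
    return add_multicoil_magnitude_noise(amp, noise, rng=noise.rng(stream=3))


def _check_labels_covered(label: LabelVolume, params: TissueParamTable) -> None:
    present = set(np.unique(label.labels).tolist()) - {0}
    missing = present - set(int(i) for i in params.frame.index)
    if missing:
        raise ValueError(f"labels without tissue parameters: {sorted(missing)}")
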
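"""Noise statistics, SNR/CNR, and assembly of the study quantification table.

The background of a sum-of-squares magnitude image from an L-element coil is
chi-distributed with 2L degrees of freedom; its mean is
``sqrt(2) * gamma(L + 1/2) / gamma(L) * sigma`` (2.7416 sigma for L = 4, the
"2.74" divisor). SNR of a structure is its ROI mean divided by sigma; CNR is
the signed SNR difference of two neighboring structures. The quantification
table holds one value per (arm, timepoint, structure, metric, replicate) and
is summarized to mean +/- SD across replicates (simulated animals).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .phantom import ROISet
from .t1_mapping import T1Map
from .t2_mapping import T2Map
from .tissues import STRUCTURES

__all__ = [
    "CNR_PAIRS",
    "NOT_QUANTIFIABLE",
    "NoiseEstimate",
    "QuantRecord",
    "StudyRun",
    "chi_mean_factor",
    "estimate_sigma_from_background",
    "compute_snr",
    "compute_cnr",
    "quantify_study",
    "summarize_records",
]

#: Neighboring-structure pairs used for CNR.
CNR_PAIRS: tuple[tuple[str, str], ...] = (
    ("AF", "NP"), ("AF", "CEP"), ("CEP", "GP"), ("GP", "SB"),
)

#: (structure, metric) cells that cannot be measured on the parametric maps
#: in vivo (GP invisible on T2 maps; CEP and GP indistinguishable on T1 maps).
#: Mirrored here as an explicit exclusion ("XX" cells).
NOT_QUANTIFIABLE: frozenset[tuple[str, str]] = frozenset(
    {("GP", "T2_ms"), ("GP", "T1_ms"), ("CEP", "T1_ms")}
)

METRICS = ("UTE_SNR", "UTE_CNR", "T2_ms", "T1_ms")


class MissingInputError(ValueError):
    """A requested study cell lacks the input it needs."""


@dataclass(frozen=True)
class NoiseEstimate:
    sigma: float
    method: str  # "chi_mean_background" or "known"
    L: int
    n_voxels: int = 0

    def __post_init__(self) -> None:
        if not np.isfinite(self.sigma) or self.sigma < 0:
            raise ValueError("sigma must be finite and >= 0")


@dataclass(frozen=True)
class QuantRecord:
    """One summarized row of the study table (mean +/- SD over replicates)."""

    maturity: str
    state: str
    timepoint: str
    structure: str
    metric: str
    mean: float
    sd: float
    n: int
    quantifiable: bool = True


def chi_mean_factor(L: int) -> float:
    """Mean of the noise-only sum-of-squares magnitude, in units of sigma.

    ``sqrt(2) * gamma(L + 1/2) / gamma(L)``; 1.2533 (Rayleigh) for L = 1 and
    2.7416 for a four-element array (printed as 2.74).
    """
    if L < 1:
        raise ValueError("L must be >= 1")
    return float(np.sqrt(2.0) * np.exp(gammaln(L + 0.5) - gammaln(L)))


def estimate_sigma_from_background(bg_values: np.ndarray, L: int) -> NoiseEstimate:
    """Per-channel sigma from a background-noise ROI of a magnitude image.

    ``sigma = mean(background) / chi_mean_factor(L)``. Requires at least 30
    finite, nonnegative background voxels.
    """
    v = np.asarray(bg_values, dtype=float).ravel()
    if len(v) < 30:
        raise ValueError(f"need >= 30 background voxels, got {len(v)}")
    if not np.all(np.isfinite(v)) or np.any(v < 0):
        raise ValueError("background values must be finite and >= 0")
    sigma = float(np.mean(v)) / chi_mean_factor(L)
    return NoiseEstimate(sigma=sigma, method="chi_mean_background", L=int(L), n_voxels=len(v))


def compute_snr(volume: np.ndarray, roi_mask: np.ndarray, noise: NoiseEstimate) -> float:
    """ROI-mean signal divided by the background-derived sigma."""
    roi_mask = np.asarray(roi_mask, dtype=bool)
    if not roi_mask.any():
        raise ValueError("ROI mask is empty")
    if noise.sigma == 0:
        raise ValueError("sigma must be > 0 to compute SNR")
    return float(np.mean(np.asarray(volume, float)[roi_mask])) / noise.sigma


def compute_cnr(snr_a: float, snr_b: float) -> float:
    """Signed SNR difference of two neighboring structures."""
    if not (np.isfinite(snr_a) and np.isfinite(snr_b)):
        raise ValueError("SNR inputs must be finite")
    return float(snr_a - snr_b)


@dataclass(frozen=True)
class StudyRun:
    """Products of one simulated animal (arm x timepoint x seed)."""

    maturity: str
    state: str
    timepoint: str
    seed: int
    rois: ROISet
    ute: np.ndarray | None = None
    ute_noise: NoiseEstimate | None = None
    t2map: T2Map | None = None
    t1map: T1Map | None = None


def _map_roi_mean(map_values: np.ndarray, valid: np.ndarray, roi: np.ndarray) -> tuple[float, int]:
    sel = roi & valid
    n_excluded = int(roi.sum() - sel.sum())
    if not sel.any():
        return np.nan, n_excluded
    return float(np.mean(map_values[sel])), n_excluded


def quantify_study(
    runs: Iterable[StudyRun],
    metrics: Iterable[str] = METRICS,
    structures: Iterable[str] = STRUCTURES,
    not_quantifiable: frozenset[tuple[str, str]] = NOT_QUANTIFIABLE,
) -> pd.DataFrame:
    """Long-form quantification table, one row per cell and replicate.

    Columns: maturity, state, timepoint, structure, metric, seed, value,
    quantifiable, n_excluded (invalid map voxels dropped from the ROI mean).
    CNR rows use the four neighboring pairs with structure ``"A-B"``.

    Raises :class:`MissingInputError` when a requested metric has no input
    for some run.
    """
    metrics = tuple(metrics)
    structures = tuple(structures)
    unknown = set(metrics) - set(METRICS)
    if unknown:
        raise ValueError(f"unknown metrics: {sorted(unknown)}")
    rows = []
    for run in runs:
        cell = f"{run.maturity}:{run.state}:{run.timepoint} (seed {run.seed})"
        base = dict(maturity=run.maturity, state=run.state,
                    timepoint=run.timepoint, seed=run.seed)
        if "UTE_SNR" in metrics or "UTE_CNR" in metrics:
            if run.ute is None or run.ute_noise is None:
                raise MissingInputError(f"UTE volume/noise missing for cell {cell}")
            snr = {s: compute_snr(run.ute, run.rois[s], run.ute_noise) for s in STRUCTURES}
            if "UTE_SNR" in metrics:
                for s in structures:
                    rows.append(base | dict(structure=s, metric="UTE_SNR",
                                            value=snr[s], quantifiable=True, n_excluded=0))
            if "UTE_CNR" in metrics:
                for a, b in CNR_PAIRS:
                    rows.append(base | dict(structure=f"{a}-{b}", metric="UTE_CNR",
                                            value=compute_cnr(snr[a], snr[b]),
                                            quantifiable=True, n_excluded=0))
        for metric, attr in (("T2_ms", "t2map"), ("T1_ms", "t1map")):
            if metric not in metrics:
                continue
            qmap = getattr(run, attr)
            if qmap is None:
                raise MissingInputError(f"{metric} map missing for cell {cell}")
            for s in structures:
                if (s, metric) in not_quantifiable:
                    rows.append(base | dict(structure=s, metric=metric, value=np.nan,
                                            quantifiable=False, n_excluded=0))
                    continue
                mean, nexc = _map_roi_mean(qmap.values_ms, qmap.valid, run.rois[s])
                rows.append(base | dict(structure=s, metric=metric, value=mean,
                                        quantifiable=True, n_excluded=nexc))
    return pd.DataFrame(
        rows, columns=["maturity", "state", "timepoint", "structure", "metric",
                       "seed", "value", "quantifiable", "n_excluded"])


def summarize_records(table: pd.DataFrame) -> list[QuantRecord]:
    """Aggregate the long table to mean +/- SD across replicates."""
    records = []
    keys = ["maturity", "state", "timepoint", "structure", "metric"]
    for key, grp in table.groupby(keys, sort=False):
        quantifiable = bool(grp["quantifiable"].all())
        vals = grp["value"].to_numpy(dtype=float)
        finite = vals[np.isfinite(vals)]
        records.append(QuantRecord(
            *key,
            mean=float(np.mean(finite)) if quantifiable and len(finite) else np.nan,
            sd=float(np.std(finite, ddof=1)) if quantifiable and len(finite) > 1 else 0.0,
            n=int(len(grp)),
            quantifiable=quantifiable,
        ))
    return records
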
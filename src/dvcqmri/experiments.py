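"""Parameter-recovery experiments on the synthetic phantom.

These functions run the full simulate -> reconstruct -> quantify chain for a
study cell and report ROI means per replicate ("animal" = seed). They are the
basis of the package's validation: the fitted relaxation times of the
phantom should recover the tissue-table ground truth.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .phantom import (
    CoilNoiseModel,
    DEFAULT_SIGMA,
    GeometrySpec,
    build_label_map,
    make_roi_set,
    simulate_mp2rage_pair,
    simulate_msme_series,
    simulate_ute_volume,
)
from .quant import StudyRun, estimate_sigma_from_background, quantify_study
from .t1_mapping import MP2RAGEParams, build_lookup_table, invert_ratio_to_t1, mp2rage_combine
from .t2_mapping import fit_t2_map
from .tissues import tissue_params_for

__all__ = [
    "derive_seeds",
    "t2_recovery_experiment",
    "t1_recovery_experiment",
    "ddd_t2_cohort",
]


def derive_seeds(base_seed: int, n: int) -> list[int]:
    """n reproducible, distinct 31-bit seeds derived from one base seed."""
    state = np.random.SeedSequence(int(base_seed)).generate_state(n, dtype=np.uint64)
    return [int(s % (2**31)) for s in state]


def _phantom_for(maturity: str, geometry: GeometrySpec | None):
    geom = geometry or GeometrySpec.for_maturity(maturity)
    label = build_label_map(geom)
    rois = make_roi_set(label, erosion_vox=0)
    return label, rois


def t2_recovery_experiment(
    maturity: str = "mature",
    state: str = "healthy",
    timepoint: str = "D0",
    n_seeds: int = 10,
    base_seed: int = 0,
    sigma: float = DEFAULT_SIGMA,
    L: int = 4,
    structures: tuple[str, ...] = ("NP", "AF", "CEP", "SB"),
    geometry: GeometrySpec | None = None,
    echo_times_ms: np.ndarray | None = None,
    jitter_cv: float = 0.0,
) -> pd.DataFrame:
    """MSME simulation + noise-floor T2 fitting for one study cell.

    sigma is re-estimated per replicate from the background ROI of the
    simulated series via the chi-mean relation, exactly as the real pipeline
    would. Returns one row per (seed, structure) with the fitted ROI-mean T2
    and the ground truth.
    """
    label, rois = _phantom_for(maturity, geometry)
    table = tissue_params_for(maturity, state, timepoint)
    fit_mask = np.zeros(label.shape, dtype=bool)
    for s in structures:
        fit_mask |= rois[s]

    rows = []
    for seed in derive_seeds(base_seed, n_seeds):
        noise = CoilNoiseModel(sigma=sigma, n_channels=L, seed=seed)
        series = simulate_msme_series(label, table, echo_times_ms, noise, jitter_cv=jitter_cv)
        bg = series.data[rois.background, :].ravel()
        est = estimate_sigma_from_background(bg, L)
        t2map = fit_t2_map(series, fit_mask, sigma=est.sigma, L=L)
        for s in structures:
            sel = rois[s] & t2map.valid
            rows.append({
                "seed": seed, "structure": s,
                "value": float(np.mean(t2map.values_ms[sel])) if sel.any() else np.nan,
                "truth": table.value(s, "t2_ms"),
                "sigma_est": est.sigma,
                "n_valid": int(sel.sum()), "n_roi": int(rois[s].sum()),
            })
    return pd.DataFrame(rows)


def t1_recovery_experiment(
    maturity: str = "mature",
    state: str = "healthy",
    timepoint: str = "D0",
    n_seeds: int = 10,
    base_seed: int = 0,
    sigma: float = DEFAULT_SIGMA,
    L: int = 4,
    structures: tuple[str, ...] = ("NP", "AF", "SB"),
    geometry: GeometrySpec | None = None,
    seq: MP2RAGEParams | None = None,
    gain: float = 20.0,
    jitter_cv: float = 0.0,
) -> pd.DataFrame:
    """MP2RAGE simulation + ratio combination + LUT inversion for one cell."""
    label, rois = _phantom_for(maturity, geometry)
    table = tissue_params_for(maturity, state, timepoint)
    seq = seq or MP2RAGEParams()
    lut = build_lookup_table(seq)

    rows = []
    for seed in derive_seeds(base_seed, n_seeds):
        noise = CoilNoiseModel(sigma=sigma, n_channels=L, seed=seed)
        gre1, gre2 = simulate_mp2rage_pair(label, table, seq, noise, gain=gain,
                                           jitter_cv=jitter_cv)
        ratio, degenerate = mp2rage_combine(gre1, gre2, seq.scaling_R)
        t1map = invert_ratio_to_t1(ratio, lut, extra_invalid=degenerate)
        for s in structures:
            sel = rois[s] & t1map.valid
            rows.append({
                "seed": seed, "structure": s,
                "value": float(np.mean(t1map.values_ms[sel])) if sel.any() else np.nan,
                "truth": table.value(s, "t1_ms"),
                "n_valid": int(sel.sum()), "n_roi": int(rois[s].sum()),
            })
    return pd.DataFrame(rows)


def ddd_t2_cohort(
    maturity: str = "mature",
    n_seeds: int = 8,
    base_seed: int = 0,
    sigma: float = DEFAULT_SIGMA,
    L: int = 4,
    states: tuple[str, ...] = ("ddd",),
    timepoints: tuple[str, ...] = ("D0", "W1"),
    structures: tuple[str, ...] = ("NP", "AF"),
    geometry: GeometrySpec | None = None,
    jitter_cv: float = 0.0,
) -> pd.DataFrame:
    """Longitudinal T2 cohort: one simulated animal per seed per cell.

    Returns the long quantification table (T2_ms rows only) ready for
    :func:`dvcqmri.stats.longitudinal_analysis`.
    """
    label, rois = _phantom_for(maturity, geometry)
    fit_mask = np.zeros(label.shape, dtype=bool)
    for s in structures:
        fit_mask |= rois[s]

    runs = []
    for state in states:
        for timepoint in timepoints:
            table = tissue_params_for(maturity, state, timepoint)
            for k, seed in enumerate(derive_seeds(base_seed, n_seeds)):
                # decorrelate noise across cells while keeping animals paired
                noise = CoilNoiseModel(
                    sigma=sigma, n_channels=L,
                    seed=(seed + 10007 * timepoints.index(timepoint)
                          + 20011 * states.index(state)) % (2**31))
                series = simulate_msme_series(label, table, None, noise, jitter_cv=jitter_cv)
                est = estimate_sigma_from_background(series.data[rois.background, :].ravel(), L)
                t2map = fit_t2_map(series, fit_mask, sigma=est.sigma, L=L)
                runs.append(StudyRun(maturity=maturity, state=state, timepoint=timepoint,
                                     seed=seed, rois=rois, t2map=t2map))
    return quantify_study(runs, metrics=("T2_ms",), structures=structures)
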
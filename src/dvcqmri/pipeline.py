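"""End-to-end pipeline: phantom -> simulate -> fit maps -> quantify -> stats.

A :class:`RunConfig` describes the study (arms, seeds, noise, sequence
blocks); :func:`run_pipeline` executes the stages, writes every product as
NIfTI/JSON/CSV under the output directory and records a manifest with the
config hash so a rerun with the same config is bit-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .experiments import derive_seeds
from .io import write_json, write_volume
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
from .quant import StudyRun, estimate_sigma_from_background, quantify_study, summarize_records
from .stats import longitudinal_analysis
from .t1_mapping import MP2RAGEParams, build_lookup_table, invert_ratio_to_t1, mp2rage_combine
from .t2_mapping import fit_t2_map
from .tissues import STRUCTURES, tissue_params_for

__all__ = ["RunConfig", "PipelineError", "run_pipeline"]

log = logging.getLogger("dvcqmri.pipeline")

STRUCTURE_CODES = {s: i + 1 for i, s in enumerate(STRUCTURES)}


class PipelineError(RuntimeError):
    """A pipeline stage failed; the stage name is recorded."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class RunConfig:
    """Study description consumed by :func:`run_pipeline`."""

    arms: list[str] = field(default_factory=lambda: ["mature:healthy:D0"])
    seeds: list[int] = field(default_factory=lambda: [0, 1])
    sigma: float = DEFAULT_SIGMA
    L: int = 4
    geometry: dict = field(default_factory=dict)      # GeometrySpec overrides
    msme: dict = field(default_factory=dict)          # n_echoes / te_first_ms / te_last_ms
    mp2rage: dict | None = field(default_factory=dict)  # MP2RAGEParams overrides
    gain: float = 20.0
    erosion_vox: int = 0
    metrics: list[str] = field(default_factory=lambda: ["UTE_SNR", "UTE_CNR", "T2_ms", "T1_ms"])
    jitter_cv: float = 0.0

    def __post_init__(self) -> None:
        if self.L < 1:
            raise ValueError("L must be >= 1")
        if len(set(self.seeds)) != len(self.seeds):
            raise ValueError("seeds must be unique")
        for arm in self.arms:
            self.parse_arm(arm)  # validates
        if "T1_ms" in self.metrics and self.mp2rage is None:
            raise ValueError("config requests T1 maps but has no mp2rage block")

    @staticmethod
    def parse_arm(arm: str) -> tuple[str, str, str]:
        parts = arm.split(":")
        if len(parts) != 3:
            raise ValueError(f"arm {arm!r} must be 'maturity:state:timepoint'")
        tissue_params_for(*parts)  # raises on unknown enums
        return tuple(parts)  # type: ignore[return-value]

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)

    def echo_times_ms(self) -> np.ndarray:
        n = int(self.msme.get("n_echoes", 100))
        return np.linspace(float(self.msme.get("te_first_ms", 3.8)),
                           float(self.msme.get("te_last_ms", 378.6)), n)

    def mp2rage_params(self) -> MP2RAGEParams:
        return MP2RAGEParams(**(self.mp2rage or {}))

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _roi_volume(rois, shape) -> np.ndarray:
    vol = np.zeros(shape, dtype=np.int16)
    for s, mask in rois:
        vol[mask] = STRUCTURE_CODES[s]
    return vol


def run_pipeline(config: RunConfig, out_dir) -> Path:
    """Execute the full study and write all products under ``out_dir``.

    Stage failures abort with :class:`PipelineError` naming the stage; files
    written by earlier stages persist. Returns the output directory.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config_hash": config.config_hash(),
        "version": __version__,
        "seeds": list(config.seeds),
        "arms": list(config.arms),
        "files": [],
        "stages": {},
        "notes": [],
    }

    def record(path: Path) -> Path:
        manifest["files"].append(str(path.relative_to(out)))
        return path

    def stage(name: str):
        log.info("stage %s [config %s]", name, manifest["config_hash"])
        manifest["stages"][name] = "done"

    echo_times = config.echo_times_ms()
    seq = config.mp2rage_params() if "T1_ms" in config.metrics else None
    lut = build_lookup_table(seq) if seq is not None else None
    runs: list[StudyRun] = []

    try:
        stage("phantom")
        phantoms = {}
        for arm in config.arms:
            maturity, _, _ = RunConfig.parse_arm(arm)
            if maturity not in phantoms:
                geom = GeometrySpec.for_maturity(maturity, **config.geometry)
                label = build_label_map(geom)
                rois = make_roi_set(label, erosion_vox=config.erosion_vox)
                adir = out / maturity
                record(write_volume(label.labels, label.voxel_size_mm,
                                    adir / "phantom_labels.nii.gz"))
                record(write_volume(_roi_volume(rois, label.shape), label.voxel_size_mm,
                                    adir / "rois.nii.gz"))
                record(write_json({"codes": STRUCTURE_CODES,
                                   "erosion_vox": config.erosion_vox},
                                  adir / "roi_legend.json"))
                phantoms[maturity] = (label, rois)
    except Exception as exc:
        _fail(out, manifest, "phantom", exc)

    for arm in config.arms:
        maturity, state, timepoint = RunConfig.parse_arm(arm)
        label, rois = phantoms[maturity]
        table = tissue_params_for(maturity, state, timepoint)
        arm_dir = out / arm.replace(":", "_")
        record(write_json(table.to_dict(), arm_dir / "tissue_params.json"))
        fit_mask = np.zeros(label.shape, dtype=bool)
        for s in STRUCTURES:
            fit_mask |= rois[s]

        for seed in config.seeds:
            sdir = arm_dir / f"seed{seed}"
            noise = CoilNoiseModel(sigma=config.sigma, n_channels=config.L, seed=seed)
            run_kw: dict = dict(maturity=maturity, state=state, timepoint=timepoint,
                                seed=seed, rois=rois)
            try:
                stage("simulate")
                if "UTE_SNR" in config.metrics or "UTE_CNR" in config.metrics:
                    ute = simulate_ute_volume(label, table, noise)
                    record(write_volume(ute, label.voxel_size_mm, sdir / "ute.nii.gz"))
                    run_kw["ute"] = ute
                    run_kw["ute_noise"] = estimate_sigma_from_background(
                        ute[rois.background], config.L)
                if "T2_ms" in config.metrics:
                    series = simulate_msme_series(label, table, echo_times, noise,
                                                  jitter_cv=config.jitter_cv)
                    record(write_volume(series.data, label.voxel_size_mm, sdir / "msme.nii.gz"))
                    record(write_json({"echo_times_ms": echo_times}, sdir / "msme_echoes.json"))
                if seq is not None:
                    gre1, gre2 = simulate_mp2rage_pair(label, table, seq, noise,
                                                       gain=config.gain,
                                                       jitter_cv=config.jitter_cv)
                    record(write_volume(gre1, label.voxel_size_mm, sdir / "gre1.nii.gz"))
                    record(write_volume(gre2, label.voxel_size_mm, sdir / "gre2.nii.gz"))
            except Exception as exc:
                _fail(out, manifest, "simulate", exc)

            try:
                if "T2_ms" in config.metrics:
                    stage("fit-t2")
                    est = estimate_sigma_from_background(
                        series.data[rois.background, :].ravel(), config.L)
                    t2map = fit_t2_map(series, fit_mask, sigma=est.sigma, L=config.L)
                    record(write_volume(t2map.values_ms, label.voxel_size_mm,
                                        sdir / "t2map.nii.gz"))
                    record(write_volume(t2map.valid.astype(np.int16), label.voxel_size_mm,
                                        sdir / "t2_validity.nii.gz"))
                    record(write_json(t2map.provenance, sdir / "t2_provenance.json"))
                    run_kw["t2map"] = t2map
            except Exception as exc:
                _fail(out, manifest, "fit-t2", exc)

            try:
                if seq is not None:
                    stage("fit-t1")
                    ratio, degenerate = mp2rage_combine(gre1, gre2, seq.scaling_R)
                    t1map = invert_ratio_to_t1(ratio, lut, extra_invalid=degenerate)
                    record(write_volume(ratio, label.voxel_size_mm,
                                        sdir / "mp2rage_ratio.nii.gz"))
                    record(write_volume(t1map.values_ms, label.voxel_size_mm,
                                        sdir / "t1map.nii.gz"))
                    record(write_volume(t1map.valid.astype(np.int16), label.voxel_size_mm,
                                        sdir / "t1_validity.nii.gz"))
                    run_kw["t1map"] = t1map
            except Exception as exc:
                _fail(out, manifest, "fit-t1", exc)

            runs.append(StudyRun(**run_kw))

    try:
        stage("quantify")
        quant = quantify_study(runs, metrics=config.metrics)
        quant.to_csv(record_path := out / "quant_table.csv", index=False)
        record(record_path)
        summary = pd.DataFrame([r.__dict__ for r in summarize_records(quant)])
        summary.to_csv(out / "quant_summary.csv", index=False)
        record(out / "quant_summary.csv")
    except Exception as exc:
        _fail(out, manifest, "quantify", exc)

    try:
        if len(config.seeds) >= 3:
            stage("stats")
            results = longitudinal_analysis(quant)
            results.to_csv(out / "stats_results.csv", index=False)
            record(out / "stats_results.csv")
        else:
            manifest["stages"]["stats"] = "skipped"
            manifest["notes"].append(
                "stats skipped: fewer than 3 seeds (tests need n >= 3 per group)")
            log.warning("stats stage skipped: fewer than 3 seeds")
    except Exception as exc:
        _fail(out, manifest, "stats", exc)

    write_json(manifest, out / "manifest.json")
    return out


def _fail(out: Path, manifest: dict, stage: str, exc: Exception):
    manifest["stages"][stage] = f"failed: {exc}"
    write_json(manifest, out / "manifest.json")
    raise PipelineError(stage, exc) from exc
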
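"""End-to-end orchestration: phantom -> relaxometry -> ROI -> statistics.

One YAML config drives the full chain with a single master seed.  Each
stage draws from a named substream derived from the master seed, so
stages can be re-run independently yet reproducibly, and adding a
subject or stage never reshuffles the draws of another.

The imaging arm runs per subject: the cohort simulator provides each
subject's ground-truth regional R2* means, a phantom is built with
those means, multi-echo volumes are simulated with the configured noise,
fitted, and summarised to trimmed means.  The statistics stage then
operates on the *measured* regional values joined with the simulated
covariates — the same join a real study performs between image-derived
and clinical data.
"""

from __future__ import annotations

import hashlib
import json
import time
import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .cohort import (
    CohortSpec,
    ROI_VARS,
    default_cohort_spec,
    simulate_cohort,
)
from .cohort import spec_from_yaml as cohort_spec_from_yaml
from .phantom import (
    EchoTrain,
    NoiseSpec,
    build_phantom,
    default_nigrostriatal_spec,
    simulate_multi_echo,
)
from .relaxometry import fit_map, make_mask
from .roi import summarize_rois
from .stats import build_correlation_table, build_group_table

__all__ = ["PipelineConfig", "validate_config", "run_pipeline", "derive_seed"]


def derive_seed(master: int, *names: str | int) -> np.random.SeedSequence:
    """Named substream: master seed + CRC32 of each path component."""
    words = [int(master)]
    for n in names:
        words.append(zlib.crc32(str(n).encode()) if isinstance(n, str) else int(n))
    return np.random.SeedSequence(words)


@dataclass
class PipelineConfig:
    seed: int = 0
    out_dir: str = "results/run"
    n_pd: int = 40
    n_control: int = 29
    grid_shape: tuple[int, int, int] = (24, 24, 12)
    echo_times: tuple[float, ...] = tuple(range(7, 48, 8))
    tr: float = 54.0
    flip_angle: float = 20.0
    noise_model: str = "rician"
    snr: float = 40.0
    fit_method: str = "loglinear"
    trim: tuple[float, float] = (5.0, 95.0)
    roi_sd_within: float = 1.0  # voxel-to-voxel R2* spread inside one ROI, s^-1
    mask_fraction: float = 0.1
    cohort_spec: str | None = None  # optional YAML path
    alpha: float = 0.05

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(doc)

    @classmethod
    def from_dict(cls, doc: dict) -> "PipelineConfig":
        kw = {}
        for key in cls.__dataclass_fields__:
            if key in doc:
                v = doc[key]
                kw[key] = tuple(v) if isinstance(v, list) else v
        noise = doc.get("noise")
        if isinstance(noise, dict):
            kw["noise_model"] = noise.get("model", "rician")
            kw["snr"] = noise.get("snr", 40.0)
        return cls(**kw)


def validate_config(config: PipelineConfig | str | Path | dict) -> list[str]:
    """Return every violation at once (empty list = valid)."""
    if isinstance(config, (str, Path)):
        try:
            config = PipelineConfig.from_yaml(config)
        except yaml.YAMLError as e:
            mark = getattr(e, "problem_mark", None)
            line = f" at line {mark.line + 1}" if mark else ""
            return [f"unparseable config{line}: {e}"]
        except TypeError as e:
            return [f"unknown config field: {e}"]
    elif isinstance(config, dict):
        try:
            config = PipelineConfig.from_dict(config)
        except TypeError as e:
            return [f"unknown config field: {e}"]
    v: list[str] = []
    if config.n_pd + config.n_control <= 0:
        v.append("n_pd + n_control: cohort has no subjects")
    if config.n_pd < 0:
        v.append("n_pd: must be non-negative")
    if config.n_control < 0:
        v.append("n_control: must be non-negative")
    te = list(config.echo_times)
    if len(te) < 2:
        v.append("echo_times: need at least 2 echoes")
    if any(t <= 0 for t in te):
        v.append("echo_times: all must be positive")
    if any(b <= a for a, b in zip(te, te[1:])):
        v.append("echo_times: must be strictly increasing")
    if config.noise_model not in ("none", "gaussian", "rician"):
        v.append(f"noise_model: unknown model {config.noise_model!r}")
    if config.noise_model != "none" and not config.snr > 0:
        v.append("snr: must be positive when noise is on")
    if config.fit_method not in ("loglinear", "nonlinear_offset"):
        v.append(f"fit_method: unknown method {config.fit_method!r}")
    lo, hi = config.trim
    if not (0 <= lo < hi <= 100):
        v.append("trim: need 0 <= lo < hi <= 100")
    if not (0 < config.mask_fraction < 1):
        v.append("mask_fraction: must be in (0, 1)")
    if config.roi_sd_within < 0:
        v.append("roi_sd_within: must be non-negative")
    if config.cohort_spec is not None and not Path(config.cohort_spec).exists():
        v.append(f"cohort_spec: path {config.cohort_spec!r} does not exist")
    if any(g < 2 for g in config.grid_shape) or len(config.grid_shape) != 3:
        v.append("grid_shape: need three dimensions >= 2")
    return v


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _image_stage(config: PipelineConfig, cohort: pd.DataFrame) -> pd.DataFrame:
    """Per-subject phantom imaging + fitting + ROI summaries."""
    echoes = EchoTrain(config.echo_times, config.tr, config.flip_angle)
    rows = []
    base = default_nigrostriatal_spec(grid_shape=config.grid_shape)
    for _, subj in cohort.iterrows():
        sid = subj["subject_id"]
        rois = tuple(
            replace(r, r2star_mean=float(subj[f"r2star_{r.name}"]),
                    r2star_sd=config.roi_sd_within)
            for r in base.rois
        )
        spec = replace(base, rois=rois)
        ph_seed = derive_seed(config.seed, "phantom", sid)
        labels, truth, s0 = build_phantom(
            spec, seed=int(ph_seed.generate_state(1)[0] >> 1)
        )
        noise_seed = derive_seed(config.seed, "noise", sid)
        noise = NoiseSpec(model=config.noise_model, snr=config.snr,
                          seed=int(noise_seed.generate_state(1)[0] >> 1))
        vol = simulate_multi_echo(truth, s0, echoes, noise)
        mask = make_mask(vol, config.mask_fraction)
        r2map = fit_map(vol, mask, method=config.fit_method)
        names = {r.label: r.name for r in spec.rois}
        lo, hi = config.trim
        rows.append(summarize_rois(r2map, labels, names, subject_id=sid,
                                   lo_pct=lo, hi_pct=hi))
    return pd.concat(rows, ignore_index=True)


def merge_measured_rois(cohort: pd.DataFrame, roi_table: pd.DataFrame
                        ) -> pd.DataFrame:
    """Replace the cohort's regional R2* columns with measured trimmed means."""
    wide = roi_table.pivot(index="subject_id", columns="roi",
                           values="trimmed_mean_r2star")
    missing = set(cohort["subject_id"]) - set(wide.index)
    if missing:
        raise ValueError(f"missing ROI summaries for subjects: {sorted(missing)}")
    out = cohort.copy()
    for roi in ROI_VARS:
        out[f"r2star_{roi}"] = out["subject_id"].map(wide[roi])
    return out


def analyze_tables(cohort: pd.DataFrame, out_dir: Path, alpha: float = 0.05
                   ) -> dict:
    """Statistics stage: group table + correlation tables + exclusion log."""
    out_dir.mkdir(parents=True, exist_ok=True)
    table1 = build_group_table(cohort)
    corr, log = build_correlation_table(cohort, alpha=alpha)
    clinical = corr[corr["variable"].isin(("updrs3", "duration", "ledd"))
                    & (corr["covariate_set"] == "basic")]
    lipids = corr[corr["variable"].isin(("total_chol", "ldl_chol"))]
    table1.to_csv(out_dir / "table1.csv", index=False, float_format="%.6g")
    clinical.to_csv(out_dir / "table2.csv", index=False, float_format="%.6g")
    lipids.to_csv(out_dir / "table3.csv", index=False, float_format="%.6g")
    (out_dir / "analysis_log.json").write_text(json.dumps(log, indent=1))
    return log


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute simulate -> fit -> summarize -> analyze; return the manifest."""
    violations = validate_config(config)
    if violations:
        raise ValueError("invalid pipeline config: " + "; ".join(violations))
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    stages: dict[str, float] = {}

    def run_stage(name, fn):
        t = time.time()
        try:
            result = fn()
        except Exception as e:
            raise RuntimeError(
                f"pipeline stage {name!r} failed: {e}"
            ) from e
        stages[name] = round(time.time() - t, 3)
        return result

    def _cohort():
        spec = (cohort_spec_from_yaml(config.cohort_spec)
                if config.cohort_spec else default_cohort_spec())
        seed = int(derive_seed(config.seed, "cohort").generate_state(1)[0] >> 1)
        spec = replace(spec, n_pd=config.n_pd, n_control=config.n_control,
                       seed=seed)
        df = simulate_cohort(spec)
        df.to_csv(out_dir / "cohort.csv", index=False)
        return df

    cohort = run_stage("simulate", _cohort)

    def _fit():
        roi_table = _image_stage(config, cohort)
        roi_table.to_csv(out_dir / "roi.csv", index=False)
        return roi_table

    roi_table = run_stage("fit+summarize", _fit)
    measured = run_stage(
        "join", lambda: merge_measured_rois(cohort, roi_table)
    )
    run_stage("analyze", lambda: analyze_tables(measured, out_dir,
                                                config.alpha))
    from importlib.metadata import version as _dist_version

    try:
        pkg_version = _dist_version("nigrastar")
    except Exception:
        pkg_version = "unknown"
    outputs = ["cohort.csv", "roi.csv", "table1.csv", "table2.csv",
               "table3.csv", "analysis_log.json"]
    manifest = {
        "package_version": pkg_version,
        "seed": config.seed,
        "stages_wall_clock_s": stages,
        "total_wall_clock_s": round(time.time() - t0, 3),
        "checksums": {f: _sha256(out_dir / f) for f in outputs},
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
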
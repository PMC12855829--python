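"""End-to-end orchestration: simulate → render → segment → assemble → fit.

A run is driven by one :class:`RunConfig` and a single root seed fanned out
to named per-stage substreams, so stages can be re-run independently and
reproducibly. Every run writes a manifest echoing the fully resolved
configuration; all artifacts are plain CSV/PNG under the run directory.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field
from datetime import date as date_cls
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import assembly, glmm, imaging
from . import io as mio
from . import synthetic
from .lightfield import LightProfile, make_bin_edges
from .synthetic import EnvironmentProfile, GeneratorConfig, Optics

__all__ = ["RunConfig", "run_pipeline", "STAGES"]

log = logging.getLogger("moondvm")

STAGES = ("simulate", "render", "segment", "assemble", "fit")

# per-stage seed substream codes (root seed is fanned out as SeedSequence([seed, code]))
_STAGE_CODES = {"simulate": 11, "render": 23, "segment": 31, "assemble": 41, "fit": 53}


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), _STAGE_CODES[stage]]))


@dataclass
class RunConfig:
    """Resolved configuration of one pipeline run."""

    seed: int = 0
    outdir: str = "runs/demo"
    stages: tuple[str, ...] = STAGES
    design: str = "night"
    taxon: str = "cladoceran"
    dates: tuple[str, ...] = ("2022-08-25", "2022-09-13")
    n_profiles_per_date: tuple[int, ...] = (1, 1)
    scale_factor: int = 4
    gamma_shape: float = 2.0
    sigma_date: float = 0.2
    sigma_profile: float = 0.14
    kd_per_m: float = 0.25
    n_bootstrap: int = 50
    zero_policy: str = "drop"
    noise_sd: float = 2.0
    illumination_gradient: float = 0.2
    lake_depth_m: float = 16.7
    log_level: str = "INFO"
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)

    def __post_init__(self) -> None:
        unknown = [s for s in self.stages if s not in STAGES]
        if unknown:
            raise ValueError(f"unknown stage(s) {unknown}; valid stages are {STAGES}")
        if len(self.dates) != len(self.n_profiles_per_date):
            raise ValueError("dates and n_profiles_per_date must have equal length")
        object.__setattr__(
            self,
            "generator",
            GeneratorConfig(
                taxon=self.taxon,
                design=self.design,
                sigma_date=self.sigma_date,
                sigma_profile=self.sigma_profile,
                gamma_shape=self.gamma_shape,
                kd_per_m=self.kd_per_m,
                lake_depth_m=self.lake_depth_m,
                seed=self.seed,
            ),
        )

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update(overrides)
        valid = set(cls.__dataclass_fields__) - {"generator"}
        unknown = set(raw) - valid
        if unknown:
            raise ValueError(f"unknown config key(s) {sorted(unknown)}; valid keys are {sorted(valid)}")
        for key in ("stages", "dates", "n_profiles_per_date"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def parsed_dates(self) -> tuple[date_cls, ...]:
        return tuple(date_cls.fromisoformat(d) for d in self.dates)

    def paths(self) -> dict[str, Path]:
        out = Path(self.outdir)
        return {
            "manifest": out / "run_manifest.yaml",
            "log": out / "run.log",
            "bins_true": out / "bins_true.csv",
            "truth": out / "truth.csv",
            "environment": out / "environment.csv",
            "light": out / "light.csv",
            "frames": out / "frames",
            "detections": out / "detections.csv",
            "bins": out / "bins.csv",
            "summary": out / "summary.csv",
            "audit": out / "audit.csv",
            "model_report": out / "model_report.csv",
            "fit": out / "fit.yaml",
        }


def _require(path: Path, stage: str) -> Path:
    if not path.exists():
        raise FileNotFoundError(
            f"stage '{stage}' needs {path}, which has not been produced; "
            "run the upstream stage first"
        )
    return path


def _setup_logging(cfg: RunConfig) -> None:
    Path(cfg.outdir).mkdir(parents=True, exist_ok=True)
    log.setLevel(getattr(logging, cfg.log_level.upper(), logging.INFO))
    have = {getattr(h, "baseFilename", None) for h in log.handlers}
    logfile = str(Path(cfg.outdir) / "run.log")
    if logfile not in have:
        fh = logging.FileHandler(logfile)
        fh.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
        log.addHandler(fh)


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------

def _stage_simulate(cfg: RunConfig, paths: dict[str, Path]) -> None:
    rng = stage_rng(cfg.seed, "simulate")
    builder = (
        synthetic.make_night_design if cfg.design == "night" else synthetic.make_daynight_design
    )
    design, envs, lights = builder(
        cfg.generator,
        n_profiles_per_date=cfg.n_profiles_per_date,
        dates=cfg.parsed_dates(),
        seed=int(rng.integers(2**31)),
        return_artifacts=True,
    )
    beta = cfg.generator.beta()
    spec = glmm.GlmmSpec(design=cfg.design)
    table = synthetic.simulate_bin_densities(
        design, beta, cfg.sigma_date, cfg.sigma_profile, cfg.gamma_shape, rng=rng, spec=spec
    )
    table = table.assign(taxon=cfg.taxon)
    table.to_csv(paths["bins_true"], index=False, float_format="%.12g")

    env_rows = []
    for day, env in envs.items():
        env_rows.append(
            pd.DataFrame(
                {
                    "date": day,
                    "depth_m": env.depth_grid,
                    "temperature_C": env.temperature,
                    "chl_a_ugL": env.chl_a,
                    "phycoerythrin": env.phycoerythrin,
                    "oxygen_mgL": env.oxygen,
                }
            )
        )
    pd.concat(env_rows, ignore_index=True).to_csv(
        paths["environment"], index=False, float_format="%.12g"
    )
    for i, (pid, light) in enumerate(lights.items()):
        mio.write_light_profile(light, pid, paths["light"], append=i > 0)

    ind = synthetic.place_individuals(
        table.rename(columns={"bin_mid_depth": "bin_mid_depth"}),
        cfg.generator.optics,
        rng=rng,
        bin_height_m=cfg.generator.bin_height_m,
    )
    mio.write_table(ind, paths["truth"], mio.TRUTH_SCHEMA)
    log.info("simulate: %d design rows, %d individuals", len(table), len(ind))


def _stage_render(cfg: RunConfig, paths: dict[str, Path]) -> None:
    truth = mio.read_table(_require(paths["truth"], "render"), mio.TRUTH_SCHEMA)
    rng = stage_rng(cfg.seed, "render")
    for pid in sorted(truth["profile_id"].unique()):
        frames = synthetic.render_profile_frames(
            truth.loc[truth["profile_id"] == pid],
            cfg.generator.optics,
            lake_depth_m=cfg.lake_depth_m,
            profile_id=pid,
            scale_factor=cfg.scale_factor,
            illumination_gradient=cfg.illumination_gradient,
            noise_sd=cfg.noise_sd,
            rng=rng,
        )
        mio.write_frames(frames, paths["frames"])
        log.info("render: profile %s, %d frames", pid, len(frames))


def _stage_segment(cfg: RunConfig, paths: dict[str, Path]) -> None:
    frames_dir = _require(paths["frames"], "segment")
    sidecars = sorted(frames_dir.glob("*_frames.csv"))
    if not sidecars:
        raise FileNotFoundError(f"stage 'segment' found no frame sidecars in {frames_dir}")
    tables = []
    for sc in sidecars:
        pid = sc.name.removesuffix("_frames.csv")
        frames = mio.read_frames(frames_dir, pid)
        det = imaging.detect_profile(frames, scale_factor=cfg.scale_factor)
        tables.append(det)
        log.info("segment: profile %s, %d raw detections", pid, len(det))
    det = pd.concat([t for t in tables if len(t)], ignore_index=True)
    mio.write_table(det, paths["detections"], mio.DETECTION_SCHEMA)


def _stage_assemble(cfg: RunConfig, paths: dict[str, Path]) -> None:
    det = mio.read_table(_require(paths["detections"], "assemble"), mio.DETECTION_SCHEMA)
    env_df = pd.read_csv(_require(paths["environment"], "assemble"))
    light_df = mio.read_table(_require(paths["light"], "assemble"), mio.LIGHT_SCHEMA)
    frames_dir = _require(paths["frames"], "assemble")

    envs = {}
    for day, grp in env_df.groupby("date"):
        envs[day] = EnvironmentProfile(
            depth_grid=grp["depth_m"].to_numpy(),
            temperature=grp["temperature_C"].to_numpy(),
            chl_a=grp["chl_a_ugL"].to_numpy(),
            phycoerythrin=grp["phycoerythrin"].to_numpy(),
            oxygen=grp["oxygen_mgL"].to_numpy(),
        )
    edges = make_bin_edges(cfg.lake_depth_m)
    bins_all, audits = [], []
    optics: Optics = cfg.generator.optics
    for pid in sorted(light_df["profile_id"].unique()):
        sidecar = frames_dir / f"{pid}_frames.csv"
        meta = pd.read_csv(_require(sidecar, "assemble"))
        height_m = optics.frame_shape(cfg.scale_factor)[0] * float(meta["pixel_pitch_mm"].iloc[0]) / 1000.0
        strips = assembly.deoverlap(meta, height_m)
        pdet = det.loc[det["profile_id"] == pid]
        pdet = assembly.drop_duplicate_detections(pdet, strips)
        pdet = imaging.filter_detections(pdet)
        bins, audit = assembly.bin_densities(
            pdet,
            strips,
            frame_breadth_mm=optics.frame_breadth_mm,
            path_mm=optics.path_mm,
            lake_depth_m=cfg.lake_depth_m,
            profile_id=pid,
        )
        lg = light_df.loc[light_df["profile_id"] == pid].sort_values("bin_index")
        light = LightProfile(
            bin_edges=edges,
            illuminance_lx=lg["illuminance_lx"].to_numpy(),
            surface_lx=float(lg["illuminance_lx"].iloc[0]),
            kd_per_m=cfg.kd_per_m,
        )
        day = pid.split("_")[0]
        bins = assembly.attach_covariates(bins, envs[day], light)
        bins["date"] = day
        bins_all.append(bins)
        audits.append(audit)
    out = pd.concat(bins_all, ignore_index=True)
    out.to_csv(paths["bins"], index=False, float_format="%.12g")
    pd.concat(audits, ignore_index=True).to_csv(paths["audit"], index=False)
    summary = assembly.profile_mean_depth(det)
    summary.to_csv(paths["summary"], index=False, float_format="%.12g")
    log.info("assemble: %d bin rows, %d summary rows", len(out), len(summary))


def _stage_fit(cfg: RunConfig, paths: dict[str, Path]) -> None:
    bins = pd.read_csv(_require(paths["bins"], "fit"))
    bins = bins.loc[bins["taxon"] == cfg.taxon]
    spec = glmm.GlmmSpec(design=cfg.design, zero_policy=cfg.zero_policy)
    data = glmm.build_design(bins, spec)
    fit = glmm.fit_gamma_glmm(data)
    log.info(
        "fit: n=%d (dropped %d zero rows), converged=%s, shape=%.3f",
        fit.n_obs, fit.n_dropped_zero, fit.converged, fit.gamma_shape,
    )
    rng = stage_rng(cfg.seed, "fit")
    ci = glmm.parametric_bootstrap_hpd(fit, n_iter=cfg.n_bootstrap, seed=int(rng.integers(2**31)))
    report = glmm.model_report(fit, ci)
    report.to_csv(paths["model_report"], index=False, float_format="%.12g")
    payload = {
        "design": cfg.design,
        "taxon": cfg.taxon,
        "seed": cfg.seed,
        "n_obs": fit.n_obs,
        "n_dropped_zero": fit.n_dropped_zero,
        "gamma_shape": fit.gamma_shape,
        "sigma2_date": fit.sigma2_date,
        "sigma2_profile": fit.sigma2_profile,
        "loglik": fit.loglik,
        "converged": fit.converged,
        "beta": {k: float(v) for k, v in fit.beta.items()},
        "scaling": fit.scaling,
        "n_bootstrap": cfg.n_bootstrap,
    }
    with open(paths["fit"], "w") as fh:
        yaml.safe_dump(mio._jsonable(payload), fh, sort_keys=False)


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "render": _stage_render,
    "segment": _stage_segment,
    "assemble": _stage_assemble,
    "fit": _stage_fit,
}


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Execute the configured stages in order; returns the artifact paths."""
    _setup_logging(config)
    paths = config.paths()
    mio.write_manifest({"config": asdict(config)}, paths["manifest"])
    for stage in STAGES:
        if stage in config.stages:
            log.info("=== stage %s ===", stage)
            _STAGE_FUNCS[stage](config, paths)
    return paths
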
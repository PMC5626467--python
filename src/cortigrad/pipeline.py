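"""End-to-end orchestration: configuration, seeding, I/O, and run manifests.

A run is described by one flat :class:`RunConfig` (loadable from YAML) whose
parameter blocks are validated before any computation.  The master seed fans
out deterministically per embryo/stage, so identical config + seed reproduces
identical outputs; every run writes a JSON manifest recording the config
hash, seed, package versions and all output files.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from . import extraction, models, stats, synthetic

__all__ = [
    "RunConfig",
    "ConfigError",
    "run_pipeline",
    "read_profile_csv",
    "write_profile_csv",
]

log = logging.getLogger("cortigrad")

_MODES = ("synth", "simulate", "extract", "stats", "end_to_end")


class ConfigError(ValueError):
    """Configuration invalid; raised before any computation starts."""


@dataclass
class RunConfig:
    """Declarative description of one pipeline run."""

    mode: str = "end_to_end"
    input_path: str | None = None
    output_dir: str = "cortigrad_out"
    preset: str = "hypoxia"
    model: str = "sdd"
    n_embryos: int = 12
    n_planes: int = 7
    t_end_s: float = 3600.0
    master_seed: int = 0
    log_level: str = "INFO"
    synth: dict = field(default_factory=dict)      # SyntheticSpec overrides
    simulate: dict = field(default_factory=dict)   # SDDParams/ARTSParams overrides
    roi: dict = field(default_factory=dict)        # ROISpec overrides
    stats: dict = field(default_factory=dict)      # q, shell_width_frac, ...

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def validated(self) -> "RunConfig":
        if self.mode not in _MODES:
            raise ConfigError(f"mode must be one of {_MODES}, got {self.mode!r}")
        if self.mode in ("extract", "stats") and not self.input_path:
            raise ConfigError(f"mode {self.mode!r} requires input_path")
        if self.input_path and not Path(self.input_path).exists():
            raise ConfigError(f"input_path does not exist: {self.input_path}")
        if self.preset not in models.CONDITION_PRESETS:
            raise ConfigError(f"unknown preset {self.preset!r}")
        if self.model not in ("sdd", "arts"):
            raise ConfigError(f"model must be 'sdd' or 'arts', got {self.model!r}")
        if self.n_embryos < 1:
            raise ConfigError("n_embryos must be >= 1")
        # parameter blocks must construct valid objects before any work
        try:
            self._spec(seed=0)
        except (ValueError, TypeError) as exc:
            raise ConfigError(f"synth block invalid: {exc}") from exc
        try:
            self._sim_params()
        except (ValueError, TypeError) as exc:
            raise ConfigError(f"simulate block invalid: {exc}") from exc
        try:
            extraction.ROISpec(**self.roi)
        except (ValueError, TypeError) as exc:
            raise ConfigError(f"roi block invalid: {exc}") from exc
        return self

    # -- parameter-block constructors -------------------------------------
    def _spec(self, seed: int) -> synthetic.SyntheticSpec:
        kw = dict(self.synth)
        tp = kw.pop("truth_profile", None)
        if isinstance(tp, dict):
            kw["truth_profile"] = synthetic.TruthProfile(**tp)
        preset = models.CONDITION_PRESETS[self.preset]
        if preset.interior_mode_override and "interior_mode" not in kw:
            kw["interior_mode"] = preset.interior_mode_override
        return synthetic.SyntheticSpec(rng_seed=seed, **kw)

    def _sim_params(self):
        if self.model == "sdd":
            return models.SDDParams(**self.simulate)
        return models.ARTSParams(**self.simulate)

    def config_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# Profile CSV round trip
# ---------------------------------------------------------------------------

def write_profile_csv(profiles, path: str | Path) -> Path:
    """Write profiles as CSV (embryo_id, position_pct_el, value[, sd, n])."""
    path = Path(path)
    rows = []
    for i, p in enumerate(profiles):
        eid = p.metadata.get("embryo_id", f"embryo_{i:03d}") if p.metadata else f"embryo_{i:03d}"
        for k in range(len(p.positions)):
            rows.append({
                "embryo_id": eid,
                "position_pct_el": repr(float(p.positions[k])),
                "value": repr(float(p.values[k])),
            })
    pd.DataFrame(rows, columns=["embryo_id", "position_pct_el", "value"]).to_csv(path, index=False)
    return path


def read_profile_csv(path: str | Path):
    """Read profiles back from CSV; exact round trip of positions and values.

    Malformed rows are reported with their line numbers; non-monotone
    positions are rejected naming the embryo id; an empty file yields an
    empty list with a warning.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        warnings.warn(f"{path} is empty: no profiles read", stacklevel=2)
        return []
    if df.empty:
        warnings.warn(f"{path} has no data rows: no profiles read", stacklevel=2)
        return []
    required = {"embryo_id", "position_pct_el", "value"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    bad = df[df[["position_pct_el", "value"]].isna().any(axis=1)]
    if len(bad):
        lines = (bad.index + 2).tolist()  # +2: header + 1-based
        raise ValueError(f"{path}: malformed rows at lines {lines}")
    out = []
    for eid, grp in df.groupby("embryo_id", sort=False):
        pos = grp["position_pct_el"].to_numpy(dtype=float)
        if np.any(np.diff(pos) <= 0):
            raise ValueError(f"{path}: non-monotone positions for embryo_id {eid!r}")
        out.append(extraction.IntensityProfile(
            positions=pos,
            values=grp["value"].to_numpy(dtype=float),
            metadata={"embryo_id": eid},
        ))
    return out


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------

def _child_seed(master: int, k: int) -> int:
    return int(np.random.SeedSequence(master, spawn_key=(k,)).generate_state(1)[0] % (2 ** 31))


def _stage_synth(cfg: RunConfig, out: Path) -> list[Path]:
    outputs = []
    for i in range(cfg.n_embryos):
        spec = cfg._spec(seed=_child_seed(cfg.master_seed, i))
        stack, records = synthetic.generate_stack(spec, n_planes=cfg.n_planes)
        tif = out / f"embryo_{i:03d}.tif"
        tifffile.imwrite(tif, stack)
        sidecar = out / f"embryo_{i:03d}.truth.json"
        sidecar.write_text(json.dumps(records[len(records) // 2].to_json_dict(), indent=1))
        outputs += [tif, sidecar]
    return outputs


def _stage_simulate(cfg: RunConfig, out: Path) -> list[Path]:
    params = models.apply_condition_preset(cfg._sim_params(), cfg.preset)
    geometry = "midsagittal_2d"
    if cfg.model == "sdd":
        params = dataclasses.replace(params, geometry=geometry)
        result = models.simulate_sdd(params, t_end=cfg.t_end_s, n_snapshots=6)
    else:
        result = models.simulate_arts(params, geometry=geometry, t_end=cfg.t_end_s, n_snapshots=6)
    rows = []
    for snap in result.snapshots:
        prof = models.field_to_profile(snap, sampling="axial_total")
        for x, v in zip(prof.positions, prof.values):
            rows.append({"time_s": snap.time_s, "position_pct_el": x, "value": v})
    csv = out / f"{cfg.model}_{cfg.preset}_profiles.csv"
    pd.DataFrame(rows).to_csv(csv, index=False)
    tif = out / f"{cfg.model}_{cfg.preset}_final_field.tif"
    tifffile.imwrite(tif, result.final.protein.astype(np.float32))
    return [csv, tif]


def _extract_one(stack: np.ndarray, cfg: RunConfig, embryo_id: str):
    idx = extraction.select_midsagittal(stack)
    plane = stack[idx]
    geom = extraction.segment_embryo(plane)
    path = extraction.trace_dorsal_cortex(geom)
    roi = extraction.ROISpec(**cfg.roi)
    return plane, geom, extraction.sample_profile(
        plane, geom, path, roi=roi, metadata={"embryo_id": embryo_id, "plane": idx})


def _stage_extract(cfg: RunConfig, out: Path, input_dir: Path) -> list[Path]:
    tifs = sorted(input_dir.glob("*.tif"))
    if not tifs:
        raise ConfigError(f"no TIFF stacks found in {input_dir}")
    profiles = []
    for tif in tifs:
        stack = tifffile.imread(tif)
        if stack.ndim == 2:
            stack = stack[None]
        t0 = time.perf_counter()
        _, _, prof = _extract_one(stack, cfg, embryo_id=tif.stem)
        log.info("extracted %s in %.2f s (%d ROIs)", tif.stem,
                 time.perf_counter() - t0, len(prof.positions))
        profiles.append(prof)
    per_embryo = write_profile_csv(profiles, out / "profiles.csv")
    outputs = [per_embryo]
    if len(profiles) >= 2:
        lo = max(p.positions[0] for p in profiles)
        hi = min(p.positions[-1] for p in profiles)
        grid = np.arange(np.ceil(lo), np.floor(hi) + 0.5, 1.0)
        mean = extraction.batch_mean_profile(profiles, grid)
        df = pd.DataFrame({
            "position_pct_el": mean.positions, "mean": mean.mean,
            "sd": mean.sd, "n": mean.n,
        })
        mean_csv = out / "batch_mean_profile.csv"
        df.to_csv(mean_csv, index=False)
        outputs.append(mean_csv)
    return outputs


def _stage_stats(cfg: RunConfig, out: Path, profile_csv: Path) -> list[Path]:
    profiles = read_profile_csv(profile_csv)
    q = float(cfg.stats.get("q", 0.8))
    per_embryo = {}
    for p in profiles:
        m = stats.compute_gradient_metrics(p, q=q)
        per_embryo[p.metadata["embryo_id"]] = {
            "x_q_pct_el": m.x_q_pct_el,
            "lambda_pct_el": m.lambda_pct_el,
            "front_pct_el": m.front_pct_el,
        }
        log.info("metrics %s: x_%.2f = %.2f %%EL", p.metadata["embryo_id"], q, m.x_q_pct_el)
    payload = {"q": q, "per_embryo": per_embryo}
    if len(profiles) >= 2:
        lo = max(p.positions[0] for p in profiles)
        hi = min(p.positions[-1] for p in profiles)
        grid = np.arange(np.ceil(lo), np.floor(hi) + 0.5, 1.0)
        mean = extraction.batch_mean_profile(profiles, grid)
        payload["mean_profile_x_q"] = stats.quantile_position(
            extraction.to_percent_of_total(mean.as_profile()), q)
    js = out / "gradient_metrics.json"
    js.write_text(json.dumps(payload, indent=1))
    return [js]


def run_pipeline(config: RunConfig) -> dict:
    """Validate the config, execute the requested stages, write a manifest."""
    cfg = config.validated()
    logging.basicConfig(level=getattr(logging, cfg.log_level.upper(), logging.INFO))
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "config_hash": cfg.config_hash(),
        "master_seed": cfg.master_seed,
        "mode": cfg.mode,
        "versions": {"numpy": np.__version__, "cortigrad": _version()},
        "outputs": [],
        "status": "ok",
    }
    try:
        if cfg.mode == "synth":
            outputs = _stage_synth(cfg, out)
        elif cfg.mode == "simulate":
            outputs = _stage_simulate(cfg, out)
        elif cfg.mode == "extract":
            outputs = _stage_extract(cfg, out, Path(cfg.input_path))
        elif cfg.mode == "stats":
            outputs = _stage_stats(cfg, out, Path(cfg.input_path))
        else:  # end_to_end
            outputs = _stage_synth(cfg, out)
            outputs += _stage_extract(cfg, out, out)
            outputs += _stage_stats(cfg, out, out / "profiles.csv")
    except Exception as exc:
        manifest["status"] = f"failed: {exc}"
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
        raise
    manifest["outputs"] = [
        {"path": str(p), "sha256": hashlib.sha256(Path(p).read_bytes()).hexdigest()[:16]}
        for p in outputs
    ]
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest


def _version() -> str:
    from importlib.metadata import version
    try:
        return version("cortigrad")
    except Exception:
        return "unknown"
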
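"""End-to-end orchestration: seeded configs, pipeline stages, run artifacts.

A run is fully described by a :class:`RunConfig` (serialisable to YAML) and
proceeds through the same stages as a field analysis: simulate (landscape +
collars), prep (screening, availability, extraction), fit (AICc stepwise on
the ML model, then the Bayesian top-model fit with diagnostics and the
publication-shaped summary tables), and the post-mortality contrast model.
Every stage writes plain-text artifacts plus a manifest of SHA-256
checksums, so a rerun from the same config is byte-identical.

The numbered scripts under ``analysis/`` are thin drivers over the
functions here.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import bayes, model, movement, prep
from .grids import Landscape, generate_landscape, read_ascii_grid, write_ascii_grid
from .movement import TrueParams

__all__ = ["RunConfig", "default_config", "run_simulate", "run_prep", "run_fit",
           "run_fit_mortality", "run_all"]

log = logging.getLogger("reprorsf")

REQUIRED_BLOCKS = ("landscape", "movement", "true_params", "prep", "model", "mcmc")


@dataclass
class RunConfig:
    """Complete, serialisable description of one pipeline run."""

    seed: int
    landscape: dict
    movement: dict
    true_params: dict
    prep: dict
    model: dict
    mcmc: dict
    priors: dict = field(default_factory=dict)

    def validate(self) -> None:
        for name in REQUIRED_BLOCKS:
            if not getattr(self, name):
                raise ValueError(f"config is missing required block: {name!r}")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        fields = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - fields
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        missing = [b for b in ("seed", *REQUIRED_BLOCKS) if b not in d]
        if missing:
            raise ValueError(f"config is missing required block: {missing[0]!r}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def default_config(seed: int = 1) -> RunConfig:
    """Reduced default scenario: 12 females, one 150-day season, a 128x128
    10-m landscape and 3x4000 MCMC draws — a scaled-down stand-in for a
    multi-year deployment (22 collars, 6 fixes/day Jan-Sep, 3x20,000 MCMC)."""
    return RunConfig(
        seed=seed,
        landscape={
            "shape": [128, 128],
            "cell_size": 10.0,
            "relief_range": [1400.0, 2800.0],
            "roughness": 0.7,
            "n_water": 4,
        },
        movement={
            "n_females": 12,
            "start_doy": 32,
            "n_days": 150,
            "step_sd_m": 100.0,
            "p_miss": 0.05,
            "p_2d": 0.05,
            "n_candidates": 50,
            "part_mean_doy": 102.0,
            "part_sd_days": 15.0,
            "daily_hazard": 0.006,
        },
        true_params={
            "beta0": 0.0,
            "beta_base": {"elevation": 0.5, "slope": -0.5},
            "gamma": {"elevation": 1.0},
            "sigma": {"elevation": 20.0},
            "decay_mode": "baseline_return",
        },
        prep={
            "ratio": 10,
            "min_rate": 0.90,
            "wean_cap": 120,
            "mortality_window": 30,
            "correlation_threshold": 0.7,
            "use_landscape_scalers": True,
        },
        model={"stepwise_delta": 2.0, "decay_mode": "baseline_return"},
        mcmc={"iters": 4000, "burnin": 1000, "chains": 3, "rhat_threshold": 1.1,
              "rhat_action": "warn"},
        priors={"beta_mean": 0.0, "beta_spread": 0.1, "beta_spread_kind": "precision",
                "sigma_lower": 1.0, "sigma_upper": 60.0},
    )


# ---------------------------------------------------------------------------
# artifact helpers


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def _write_manifest(outdir: Path, files: list[Path], name="manifest.json") -> dict:
    manifest = {f.name: _sha256(f) for f in sorted(files)}
    (outdir / name).write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def _prepare_outdir(outdir, force: bool) -> Path:
    outdir = Path(outdir)
    if outdir.exists() and any(outdir.iterdir()) and not force:
        raise FileExistsError(
            f"output directory {outdir} is not empty; pass force=True to overwrite"
        )
    outdir.mkdir(parents=True, exist_ok=True)
    return outdir


def _spawn_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(c.generate_state(1)[0] % 2**31) for c in ss.spawn(n)]


# ---------------------------------------------------------------------------
# stages


def run_simulate(config: RunConfig, outdir, force: bool = False) -> dict:
    """Generate landscape rasters, timelines and the fix table; write all
    synthetic artifacts plus a checksum manifest."""
    config.validate()
    outdir = _prepare_outdir(outdir, force)
    s_land, s_tl, s_fix, _ = _spawn_seeds(config.seed, 4)
    lc = config.landscape
    landscape = generate_landscape(
        shape=tuple(lc["shape"]),
        cell_size=lc.get("cell_size", 10.0),
        relief_range=tuple(lc.get("relief_range", (1400.0, 2800.0))),
        roughness=lc.get("roughness", 0.7),
        n_water=lc.get("n_water", 4),
        seed=s_land,
    )
    mv = config.movement
    timelines = movement.simulate_timelines(
        mv["n_females"],
        part_mean_doy=mv.get("part_mean_doy", 102.0),
        part_sd_days=mv.get("part_sd_days", 15.0),
        daily_hazard=mv.get("daily_hazard", 0.006),
        seed=s_tl,
    )
    tp = TrueParams.from_dict(config.true_params)
    fixes = movement.simulate_fixes(
        timelines,
        landscape,
        tp,
        start_doy=mv.get("start_doy", 32),
        n_days=mv["n_days"],
        step_sd_m=mv.get("step_sd_m", 300.0),
        p_miss=mv.get("p_miss", 0.05),
        p_2d=mv.get("p_2d", 0.05),
        n_candidates=mv.get("n_candidates", 50),
        seed=s_fix,
    )
    files = []
    for name, grid in landscape.layers.items():
        path = outdir / f"{name}.asc"
        write_ascii_grid(grid, path)
        files.append(path)
    tl_path = outdir / "timelines.csv"
    timelines.to_csv(tl_path, index=False)
    fx_path = outdir / "fixes.csv"
    fixes.assign(timestamp=fixes["timestamp"].dt.strftime("%Y-%m-%dT%H:%M:%S")).to_csv(
        fx_path, index=False
    )
    tp_path = outdir / "true_params.json"
    tp_path.write_text(json.dumps(tp.to_dict(), indent=2, sort_keys=True))
    cfg_path = outdir / "config.yaml"
    config.to_yaml(cfg_path)
    meta = {
        "scheduled_per_animal": fixes.attrs["scheduled_per_animal"],
        "n_fixes": len(fixes),
    }
    meta_path = outdir / "simulate_meta.json"
    meta_path.write_text(json.dumps(meta, indent=2, sort_keys=True))
    files += [tl_path, fx_path, tp_path, cfg_path, meta_path]
    manifest = _write_manifest(outdir, files)
    log.info("simulate: %d fixes for %d females", len(fixes), len(timelines))
    return {"manifest": manifest, "landscape": landscape, "timelines": timelines,
            "fixes": fixes, "outdir": outdir}


def load_landscape(outdir) -> Landscape:
    outdir = Path(outdir)
    layers = {p.stem: read_ascii_grid(p) for p in sorted(outdir.glob("*.asc"))}
    if not layers:
        raise FileNotFoundError(f"no .asc layers under {outdir}")
    return Landscape(layers)


def run_prep(config: RunConfig, simdir, outdir=None, force: bool = False) -> dict:
    """Screen fixes, label reproduction, build the use-availability tables."""
    config.validate()
    simdir = Path(simdir)
    outdir = _prepare_outdir(outdir, force) if outdir is not None else None
    landscape = load_landscape(simdir)
    timelines = pd.read_csv(simdir / "timelines.csv", dtype={"part_doy": "Int64",
                                                             "death_day": "Int64"})
    fixes = pd.read_csv(simdir / "fixes.csv", parse_dates=["timestamp"])
    meta = json.loads((simdir / "simulate_meta.json").read_text())
    tp = TrueParams.from_dict(config.true_params)
    covs = list(tp.covariates)
    pc = config.prep
    scalers = landscape.scalers(covs) if pc.get("use_landscape_scalers") else None
    _, _, s_prep, _ = _spawn_seeds(config.seed, 4)
    prepared = prep.prepare_datasets(
        fixes,
        timelines,
        landscape,
        covariates=covs,
        scheduled=meta["scheduled_per_animal"],
        ratio=pc.get("ratio", 10),
        min_rate=pc.get("min_rate", 0.90),
        wean_cap=pc.get("wean_cap", 120),
        mortality_window=pc.get("mortality_window", 30),
        scalers=scalers,
        seed=s_prep,
    )
    if len(prepared["dataset1"]) == 0:
        raise RuntimeError("preparation produced an empty dataset1 (check filters)")
    if outdir is not None:
        files = []
        for name in ("dataset1", "dataset2"):
            path = outdir / f"{name}.csv"
            prepared[name].to_csv(path, index=False)
            files.append(path)
        rep = dict(prepared["report"])
        rep["radius_m"] = prepared["radius"]
        rep["scalers"] = {k: list(v) for k, v in prepared.get("dataset1_scalers", {}).items()}
        rep_path = outdir / "screen_report.json"
        rep_path.write_text(json.dumps(rep, indent=2, sort_keys=True, default=str))
        files.append(rep_path)
        _write_manifest(outdir, files)
    for stage, r in prepared["report"].items():
        if isinstance(r, dict) and "n_in" in r:
            log.info("prep %s: %s -> %s rows", stage, r.get("n_in"), r.get("n_out"))
    return prepared


def run_fit(config: RunConfig, prepared: dict, outdir=None, force: bool = False) -> dict:
    """ML + AICc stepwise, then the Bayesian fit of the selected model."""
    config.validate()
    outdir = _prepare_outdir(outdir, force) if outdir is not None else None
    table = prepared["dataset1"]
    tp = TrueParams.from_dict(config.true_params)
    covs = list(tp.covariates)
    spec_full = model.ModelSpec(
        covariates=tuple(covs),
        time_varying=tuple(c for c in covs if c in config.true_params.get("gamma", {})),
        decay_mode=config.model.get("decay_mode", "baseline_return"),
    )
    if spec_full.n_params + 1 >= len(table):
        raise RuntimeError("dataset too small for the requested model")
    if len(covs) >= 2:
        retained, screen = prep.correlation_screen(
            table, covs, config.prep.get("correlation_threshold", 0.7)
        )
        spec_full = model.ModelSpec(
            covariates=tuple(retained),
            time_varying=tuple(c for c in spec_full.time_varying if c in retained),
            decay_mode=spec_full.decay_mode,
        )
    else:
        screen = {"retained": covs, "dropped": []}
    top_spec, top_fit, trace = model.backward_stepwise(
        table, spec_full, delta=config.model.get("stepwise_delta", 2.0)
    )
    priors = bayes.PriorSpec(**config.priors) if config.priors else bayes.PriorSpec()
    mc = config.mcmc
    post = bayes.run_mcmc(
        table,
        top_spec,
        priors,
        iters=mc.get("iters", 20_000),
        burnin=mc.get("burnin", 1_000),
        chains=mc.get("chains", 3),
        seed=config.seed,
        ml_init=top_fit,
    )
    rhats = post.rhat()
    worst = max(rhats.values())
    threshold = mc.get("rhat_threshold", 1.1)
    if worst > threshold:
        msg = f"Rhat {worst:.3f} exceeds threshold {threshold}"
        if mc.get("rhat_action", "warn") == "error":
            raise RuntimeError(msg)
        log.warning(msg)
    table1 = bayes.summary_table(post, top_spec)
    table2 = bayes.return_rate_table(post, top_spec)
    traj = bayes.coefficient_trajectory(post, top_spec)
    out = {
        "screen": screen,
        "top_spec": top_spec,
        "top_fit": top_fit,
        "trace": trace,
        "posterior": post,
        "rhat": rhats,
        "table1": table1,
        "table2": table2,
        "trajectory": traj,
    }
    if outdir is not None:
        files = []

        def _save_df(df, name):
            p = outdir / name
            df.to_csv(p, index=False)
            files.append(p)

        _save_df(trace, "stepwise_trace.csv")
        _save_df(table1, "table1.csv")
        _save_df(table2, "table2.csv")
        _save_df(traj, "trajectory.csv")
        _save_df(post.to_dataframe(), "posterior_draws.csv")
        p = outdir / "top_model.json"
        p.write_text(json.dumps(top_fit.to_dict(), indent=2, sort_keys=True))
        files.append(p)
        p = outdir / "rhat.json"
        p.write_text(json.dumps(rhats, indent=2, sort_keys=True))
        files.append(p)
        _write_manifest(outdir, files)
    log.info("fit: top model %s, worst Rhat %.3f", top_spec.covariates, worst)
    return out


def run_fit_mortality(config: RunConfig, prepared: dict, outdir=None,
                      force: bool = False, min_rows: int = 200) -> dict:
    """Time-constant pre vs post-mortality selection contrast."""
    config.validate()
    outdir = _prepare_outdir(outdir, force) if outdir is not None else None
    d1, d2 = prepared["dataset1"], prepared["dataset2"]
    if len(d2) == 0:
        raise RuntimeError("no post-mortality rows; cannot fit the mortality model")
    both = pd.concat([d1[d1["state"] == "pre"], d2], ignore_index=True)
    tp = TrueParams.from_dict(config.true_params)
    priors = bayes.PriorSpec(**config.priors) if config.priors else bayes.PriorSpec()
    mc = config.mcmc
    res = bayes.fit_mortality_model(
        both,
        list(tp.covariates),
        priors,
        iters=mc.get("iters", 20_000),
        burnin=mc.get("burnin", 1_000),
        chains=mc.get("chains", 3),
        seed=config.seed + 1,
        min_rows=min_rows,
    )
    if outdir is not None:
        files = []
        p = outdir / "table1_mortality.csv"
        res["summary"].to_csv(p, index=False)
        files.append(p)
        p = outdir / "posterior_mortality.csv"
        res["posterior"].to_dataframe().to_csv(p, index=False)
        files.append(p)
        _write_manifest(outdir, files, name="manifest_mortality.json")
    return res


def run_all(config: RunConfig, outdir, force: bool = False,
            mortality_min_rows: int = 200) -> dict:
    """simulate -> prep -> fit (-> mortality model when data allow)."""
    outdir = Path(outdir)
    sim = run_simulate(config, outdir / "sim", force=force)
    prepared = run_prep(config, outdir / "sim", outdir / "prep", force=force)
    fit = run_fit(config, prepared, outdir / "fit", force=force)
    out = {"sim": sim, "prepared": prepared, "fit": fit}
    try:
        out["mortality"] = run_fit_mortality(
            config, prepared, outdir / "fit", force=True, min_rows=mortality_min_rows
        )
    except (RuntimeError, ValueError) as exc:
        log.warning("mortality model skipped: %s", exc)
        out["mortality"] = None
    return out
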
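"""Configuration, provenance, file I/O and the command-line interface.

A single structured YAML config drives every run; command-line flags only
override config values.  All series outputs are NetCDF (classic format,
via xarray's scipy backend) with CF-style global attributes carrying the
config hash, seed and software version, so any output file can be re-run
exactly; tables are tidy CSV.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import click
import numpy as np
import pandas as pd
import xarray as xr
import yaml

from . import __version__
from .column_model import (
    BudgetTracker,
    ModelParams,
    Scenario,
    build_scenario,
    run as run_column,
    spinup as spinup_column,
)
from .experiments import (
    ExperimentSpec,
    anthro_impact,
    attribute_delta,
    attribution_frame,
    build_suite,
    run_suite,
)
from .forcing_synth import SOURCES, ConfigError, ScenarioParams, grid_physics
from .isotope_algebra import FractionationFactors
from .regimes import RegimeThresholds, classify_regime, regime_response_summary

__all__ = ["RunConfig", "load_config", "save_config", "write_outputs",
           "read_run", "cli", "cli_main"]

log = logging.getLogger("isofe")


@dataclass
class RunConfig:
    """Validated run configuration with all defaults materialized."""

    seed: int = 0
    outdir: str = "isofe-out"
    spinup_start: int = 1780
    year_start: int = 1980
    year_end: int = 2014
    scenario: ScenarioParams = field(default_factory=ScenarioParams)
    model: ModelParams = field(default_factory=ModelParams)
    suite: list | None = None   # experiment names; None = full default suite

    def content_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(_config_dict(self), sort_keys=True).encode()).hexdigest()[:16]

    def build(self) -> Scenario:
        return build_scenario(self.scenario, self.model, seed=self.seed)

    def specs(self) -> list:
        specs = build_suite(self.year_start, self.year_end, self.spinup_start)
        if self.suite is None:
            return specs
        known = {s.name: s for s in specs}
        bad = [n for n in self.suite if n not in known]
        if bad:
            raise ConfigError(f"unknown experiment names in suite: {bad}")
        return [known[n] for n in self.suite]


def _update_dataclass(obj, data: dict, section: str):
    names = {f.name for f in dataclasses.fields(obj)}
    unknown = set(data) - names
    if unknown:
        raise ConfigError(f"unknown keys in config section {section!r}: {sorted(unknown)}")
    coerced = {}
    for k, v in data.items():
        if isinstance(v, list):
            v = tuple(v)
        coerced[k] = v
    return dataclasses.replace(obj, **coerced)


def _load_fractionation(data: dict) -> FractionationFactors:
    known = {"alpha_uptake", "alpha_ligand"}
    unknown = set(data) - known
    if unknown:
        raise ConfigError(f"unknown keys in config section 'model.fractionation': {sorted(unknown)}")
    try:
        return FractionationFactors(**data)
    except (ValueError, TypeError) as exc:
        raise ConfigError(f"invalid fractionation factors: {exc}") from exc


def load_config(path) -> RunConfig:
    """Load and validate a YAML run configuration.

    Unknown keys anywhere are rejected with a descriptive error; all
    defaults are materialized on the returned object.
    """
    path = Path(path)
    try:
        raw = yaml.safe_load(path.read_text()) or {}
    except yaml.YAMLError as exc:
        raise ConfigError(f"malformed config file {path}: {exc}") from exc
    if not isinstance(raw, dict):
        raise ConfigError(f"config root must be a mapping, got {type(raw).__name__}")

    cfg = RunConfig()
    top = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - top
    if unknown:
        raise ConfigError(f"unknown top-level config keys: {sorted(unknown)}")

    scenario = _update_dataclass(cfg.scenario, raw.get("scenario", {}) or {}, "scenario")
    model_raw = dict(raw.get("model", {}) or {})
    frac = _load_fractionation(model_raw.pop("fractionation", {}) or {})
    model = _update_dataclass(cfg.model, model_raw, "model")
    model = dataclasses.replace(model, fractionation=frac)
    scenario.validate()
    model.validate()

    cfg = dataclasses.replace(
        cfg,
        seed=int(raw.get("seed", cfg.seed)),
        outdir=str(raw.get("outdir", cfg.outdir)),
        spinup_start=int(raw.get("spinup_start", cfg.spinup_start)),
        year_start=int(raw.get("year_start", cfg.year_start)),
        year_end=int(raw.get("year_end", cfg.year_end)),
        scenario=scenario, model=model,
        suite=list(raw["suite"]) if raw.get("suite") is not None else None,
    )
    if not (cfg.spinup_start <= cfg.year_start <= cfg.year_end <= cfg.scenario.year_end):
        raise ConfigError("require spinup_start <= year_start <= year_end <= scenario.year_end")
    return cfg


def _config_dict(cfg: RunConfig) -> dict:
    d = dataclasses.asdict(cfg)
    d["model"]["fractionation"] = dataclasses.asdict(cfg.model.fractionation)
    return d


def save_config(cfg: RunConfig, path) -> None:
    """Serialize a config back to YAML (round-trips through load_config)."""
    d = _config_dict(cfg)
    for sect in ("scenario", "model"):
        d[sect] = {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in d[sect].items()}
    d["model"]["fractionation"] = dict(d["model"]["fractionation"])
    Path(path).write_text(yaml.safe_dump(d, sort_keys=True))


# ---------------------------------------------------------------------------
# file output


def _netcdf_safe(ds: xr.Dataset) -> xr.Dataset:
    """Cast to types the classic NetCDF format can hold."""
    ds = ds.copy()
    for name in list(ds.coords) + list(ds.data_vars):
        v = ds[name]
        if v.dtype == object:
            ds[name] = v.astype(str)
        elif v.dtype == bool:
            ds[name] = v.astype("i1")
    ds.attrs = {k: (int(v) if isinstance(v, (bool, np.bool_)) else v)
                for k, v in ds.attrs.items() if v is not None}
    return ds


def write_outputs(outputs: dict, outdir, cfg: RunConfig | None = None) -> list:
    """Write run datasets (NetCDF) and DataFrames (CSV) under ``outdir``.

    Returns the list of written paths.  Global attributes record seed,
    config hash and software version; a missing output directory is
    created (with a log notice).  NetCDF round trips are bitwise for
    float64 variables.
    """
    outdir = Path(outdir)
    if not outdir.exists():
        log.info("creating output directory %s", outdir)
        outdir.mkdir(parents=True)
    written = []
    for name, obj in outputs.items():
        if isinstance(obj, xr.Dataset):
            ds = _netcdf_safe(obj)
            ds.attrs.setdefault("software", f"isofe {__version__}")
            if cfg is not None:
                ds.attrs["config_hash"] = cfg.content_hash()
                ds.attrs["seed"] = cfg.seed
            path = outdir / f"{name}.nc"
            ds.to_netcdf(path, engine="scipy")
        elif isinstance(obj, pd.DataFrame):
            path = outdir / f"{name}.csv"
            obj.to_csv(path)
        else:
            raise TypeError(f"cannot write output {name!r} of type {type(obj).__name__}")
        written.append(path)
    return written


def read_run(path) -> xr.Dataset:
    """Read a run output file back (values bitwise-identical to written)."""
    with xr.open_dataset(path, engine="scipy") as ds:
        return ds.load()


# ---------------------------------------------------------------------------
# CLI


def _load(ctx_config) -> RunConfig:
    return load_config(ctx_config) if ctx_config else RunConfig()


@click.group()
@click.option("--config", "config_path", type=click.Path(exists=True, dir_okay=False),
              default=None, help="YAML run configuration.")
@click.option("--seed", type=int, default=None, help="Override the config seed.")
@click.option("--outdir", type=click.Path(file_okay=False), default=None,
              help="Override the output directory.")
@click.option("-v", "--verbose", is_flag=True, help="Chatty logging.")
@click.pass_context
def cli(ctx, config_path, seed, outdir, verbose):
    """isofe: seasonal mixed-layer iron-isotope column model."""
    logging.basicConfig(level=logging.INFO if verbose else logging.WARNING,
                        format="[%(name)s] %(message)s")
    cfg = _load(config_path)
    if seed is not None:
        cfg = dataclasses.replace(cfg, seed=seed)
    if outdir is not None:
        cfg = dataclasses.replace(cfg, outdir=outdir)
    ctx.obj = cfg


@cli.command("synth-forcing")
@click.pass_obj
def cli_synth_forcing(cfg: RunConfig):
    """Generate and write the synthetic deposition + physics forcing."""
    sc = cfg.build()
    dep = sc.deposition.to_dataset()
    phys = grid_physics(sc.grid)
    phys_ds = xr.Dataset(
        {"mld": (("month", "column"), phys.mld),
         "light": (("month", "column"), phys.light)},
        coords={"month": np.arange(1, 13), "column": np.arange(sc.n_columns)})
    paths = write_outputs({"deposition": dep, "physics": phys_ds},
                          cfg.outdir, cfg)
    click.echo("\n".join(str(p) for p in paths))


@cli.command("spinup")
@click.pass_obj
def cli_spinup(cfg: RunConfig):
    """Spin the standard configuration up to the analysis period."""
    sc = cfg.build()
    state, diag = spinup_column(sc, year_end=cfg.year_start,
                                year_start=cfg.spinup_start)
    click.echo(f"spin-up {cfg.spinup_start}-{cfg.year_start}: "
               f"final-decade yoy change {diag['yoy_change']:.3e} "
               f"({'converged' if diag['converged'] else 'NOT converged'})")
    click.echo(f"mean dFe at {cfg.year_start}: {float(np.mean(state.dfe.total)):.4f} umol m-3")


@cli.command("run")
@click.pass_obj
def cli_run(cfg: RunConfig):
    """Spin up and run the standard experiment; write NetCDF + CSV."""
    sc = cfg.build()
    state, _ = spinup_column(sc, year_end=cfg.year_start,
                             year_start=cfg.spinup_start)
    budget = BudgetTracker(state)
    ds, final = run_column(sc, state=state, year_start=cfg.year_start,
                           year_end=cfg.year_end, budget=budget)
    closure = budget.closure(final)
    log.info("per-pool isotope budget closure over the run: %.3e (relative)", closure)
    ds.attrs["budget_closure"] = closure
    summary = ds[["dfe", "delta_dfe", "pp", "fe_uptake"]].mean("time").to_pandas()
    paths = write_outputs({"standard": ds, "standard_summary": summary}, cfg.outdir, cfg)
    click.echo("\n".join(str(p) for p in paths))


def _run_full_suite(cfg: RunConfig) -> dict:
    sc = cfg.build()
    return run_suite(sc, cfg.specs(), progress=True)


@cli.group("suite", invoke_without_command=True)
@click.pass_context
def cli_suite(ctx):
    """Run/analyze the counterfactual experiment suite."""
    if ctx.invoked_subcommand is None:
        ctx.invoke(cli_suite_run)


@cli_suite.command("run")
@click.pass_obj
def cli_suite_run(cfg: RunConfig):
    """Run every configured experiment; one NetCDF per run."""
    runs = _run_full_suite(cfg)
    paths = write_outputs(runs, cfg.outdir, cfg)
    click.echo("\n".join(str(p) for p in paths))


def _read_or_run(cfg: RunConfig, names: list) -> dict:
    out = {}
    missing = []
    for n in names:
        p = Path(cfg.outdir) / f"{n}.nc"
        if p.exists():
            out[n] = read_run(p)
        else:
            missing.append(n)
    if missing:
        sc = cfg.build()
        known = {s.name: s for s in build_suite(cfg.year_start, cfg.year_end,
                                                cfg.spinup_start)}
        out.update(run_suite(sc, [known[n] for n in missing], progress=True))
    return out


@cli_suite.command("diff")
@click.pass_obj
def cli_suite_diff(cfg: RunConfig):
    """Difference standard vs no-anthro into the anthropogenic impact fields."""
    runs = _read_or_run(cfg, ["standard", "no-anthro"])
    delta = anthro_impact(runs["standard"], runs["no-anthro"])
    tidy = delta.mean("time").to_pandas()
    paths = write_outputs({"anthro_impact": delta, "anthro_impact_summary": tidy},
                          cfg.outdir, cfg)
    click.echo("\n".join(str(p) for p in paths))


@cli_suite.command("attribute")
@click.pass_obj
def cli_suite_attribute(cfg: RunConfig):
    """Source/process attribution of delta56Fe_diss from the muted runs."""
    names = ["standard", "no-uptake-frac", "no-ligand-frac"] + \
            [f"mute-{s}" for s in SOURCES]
    runs = _read_or_run(cfg, names)
    att = attribute_delta(runs["standard"],
                          {s: runs[f"mute-{s}"] for s in SOURCES},
                          {"uptake": runs["no-uptake-frac"],
                           "complexation": runs["no-ligand-frac"]})
    paths = write_outputs({"attribution": att,
                           "attribution_table": attribution_frame(att)},
                          cfg.outdir, cfg)
    click.echo("\n".join(str(p) for p in paths))


@cli.command("attribute")
@click.pass_context
def cli_attribute(ctx):
    """Alias for `suite attribute`."""
    ctx.invoke(cli_suite_attribute)


@cli.group("regimes")
def cli_regimes():
    """Regime classification of the biogeochemical response."""


@cli_regimes.command("classify")
@click.pass_obj
def cli_regimes_classify(cfg: RunConfig):
    """Classify columns into the four response cases and summarize."""
    runs = _read_or_run(cfg, ["standard", "no-anthro"])
    labels = classify_regime(runs["standard"])
    delta = anthro_impact(runs["standard"], runs["no-anthro"])
    summary = regime_response_summary(delta, labels, standard=runs["standard"])
    paths = write_outputs({"regime_labels": labels, "regime_summary": summary},
                          cfg.outdir, cfg)
    click.echo(summary.to_string())
    click.echo("\n".join(str(p) for p in paths))


@cli.command("report")
@click.pass_obj
def cli_report(cfg: RunConfig):
    """Render summary tables: deposition, seasonal contrast, attribution, regimes."""
    names = ["standard", "no-anthro", "no-uptake-frac", "no-ligand-frac"] + \
            [f"mute-{s}" for s in SOURCES]
    runs = _read_or_run(cfg, names)
    std = runs["standard"]
    last = int(std.year.max())
    yr = std.where(std.year == last, drop=True)

    click.echo(f"== Annual means, {last} (standard run) ==")
    click.echo(yr[["dfe", "delta_dfe", "pp", "fe_uptake"]].mean("time")
               .to_pandas().to_string())

    delta = anthro_impact(std, runs["no-anthro"])
    click.echo("\n== Anthropogenic impact (standard - no-anthro, period mean) ==")
    click.echo(delta.mean("time").to_pandas()
               .drop(columns=["light"], errors="ignore").to_string())

    att = attribute_delta(std, {s: runs[f"mute-{s}"] for s in SOURCES},
                          {"uptake": runs["no-uptake-frac"],
                           "complexation": runs["no-ligand-frac"]})
    click.echo("\n== delta56Fe_diss attribution (period mean, permil) ==")
    click.echo(attribution_frame(att).to_string())

    labels = classify_regime(std)
    summary = regime_response_summary(delta, labels, standard=std)
    click.echo("\n== Regime response summary ==")
    click.echo(summary.to_string())


def cli_main(argv=None) -> int:
    """Entry point returning an exit code: 0 success, 1 runtime, 2 config."""
    try:
        cli.main(args=argv, standalone_mode=False)
        return 0
    except click.exceptions.UsageError as exc:
        exc.show()
        return 2
    except click.exceptions.Exit as exc:  # --help etc.
        return exc.exit_code
    except ConfigError as exc:
        click.echo(f"configuration error: {exc}", err=True)
        return 2
    except Exception as exc:  # noqa: BLE001 - CLI boundary
        click.echo(f"error: {exc}", err=True)
        return 1


if __name__ == "__main__":  # pragma: no cover
    sys.exit(cli_main())
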
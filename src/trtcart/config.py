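"""Run configuration, validation and result serialization.

A run configuration is a YAML mapping with optional blocks —
``parameters``, ``regimen``, ``schedule``, ``metrics``, ``sweep``,
``sensitivity``, ``calibration``, ``output`` — whose defaults are the
reference experimental protocol: 5e6 tumor cells inoculated at t = 0,
first therapy at day 7, 100 nCi TRT, 1e6 CAR-T cells, lethal-burden
threshold 1e11 cells.  Unknown keys are rejected so a typo cannot
silently fall back to a default.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .dynamics import ModelParameters, TreatmentSchedule
from .outcomes import OS_THRESHOLD_CELLS
from .regimens import DEFAULT_HORIZON, RegimenSpec

__all__ = ["RunConfig", "ConfigError", "load_config", "write_results"]


class ConfigError(ValueError):
    """A configuration file violated the schema."""


_PARAM_KEYS = {"rho", "k1", "k2", "theta", "k_cl", "lam", "gamma",
               "alpha_T", "alpha_C", "beta", "eta"}
_REGIMEN_KEYS = {"kind", "first_therapy_day", "interval_days",
                 "trt_activity_nci", "cart_cells", "initial_burden"}
_METRICS_KEYS = {"os_threshold", "horizon_days", "report_from_first_therapy"}
_SWEEP_KEYS = {"start", "stop", "step"}
_SENSITIVITY_KEYS = {"fraction"}
_CALIBRATION_KEYS = {"known_inoculum", "inoculum_day", "ratio_weight",
                     "n_starts", "seed"}
_TOP_KEYS = {"parameters", "regimen", "schedule", "metrics", "sweep",
             "sensitivity", "calibration", "output_dir", "seed"}


def _check_keys(block: dict, allowed: set, where: str) -> None:
    unknown = set(block) - allowed
    if unknown:
        raise ConfigError(f"unknown key(s) {sorted(unknown)} in {where!r} "
                          f"(allowed: {sorted(allowed)})")


@dataclass
class RunConfig:
    """Fully resolved configuration for one command-line run."""

    params: ModelParameters = field(default_factory=ModelParameters)
    regimen: RegimenSpec = field(default_factory=RegimenSpec)
    schedule: TreatmentSchedule | None = None  # explicit, overrides regimen
    os_threshold: float = OS_THRESHOLD_CELLS
    horizon_days: float = DEFAULT_HORIZON
    report_from_first_therapy: bool = False
    sweep_grid: tuple[float, float, float] = (14.0, 80.0, 1.0)
    sensitivity_fraction: float = 0.5
    calibration: dict = field(default_factory=lambda: {
        "known_inoculum": 5e6, "inoculum_day": 0.0,
        "ratio_weight": 1.0, "n_starts": 16, "seed": 0})
    output_dir: str = "trtcart-results"
    seed: int = 0

    def to_dict(self) -> dict:
        d = {
            "parameters": dataclasses.asdict(self.params),
            "regimen": {
                "kind": self.regimen.kind,
                "first_therapy_day": self.regimen.first_therapy_day,
                "interval_days": self.regimen.interval_days,
                "trt_activity_nci": self.regimen.trt_activity_nci,
                "cart_cells": self.regimen.cart_cells,
                "initial_burden": self.regimen.initial_burden,
            },
            "metrics": {"os_threshold": self.os_threshold,
                        "horizon_days": self.horizon_days,
                        "report_from_first_therapy": self.report_from_first_therapy},
            "sweep": dict(zip(("start", "stop", "step"), self.sweep_grid)),
            "sensitivity": {"fraction": self.sensitivity_fraction},
            "calibration": dict(self.calibration),
            "output_dir": self.output_dir,
            "seed": self.seed,
        }
        if self.schedule is not None:
            d["schedule"] = [
                *({"type": "trt", "day": t, "activity_nCi": a * 1000.0}
                  for t, a in self.schedule.trt_administrations),
                *({"type": "cart", "day": t, "cells": n}
                  for t, n in self.schedule.cart_administrations),
            ]
        return d

    def resolved_regimen(self) -> RegimenSpec:
        r = self.regimen
        return RegimenSpec(kind=r.kind,
                           first_therapy_day=r.first_therapy_day,
                           interval_days=r.interval_days,
                           trt_activity_nci=r.trt_activity_nci,
                           cart_cells=r.cart_cells,
                           initial_burden=r.initial_burden,
                           horizon_days=self.horizon_days,
                           os_threshold=self.os_threshold)


def _parse_schedule(entries: list) -> TreatmentSchedule:
    trt, cart = [], []
    for i, e in enumerate(entries):
        if not isinstance(e, dict) or "type" not in e or "day" not in e:
            raise ConfigError(f"schedule entry {i} must map 'type' and 'day'")
        kind = e["type"]
        if kind == "trt":
            _check_keys(e, {"type", "day", "activity_nCi"}, f"schedule[{i}]")
            trt.append((float(e["day"]), float(e.get("activity_nCi", 0.0))))
        elif kind == "cart":
            _check_keys(e, {"type", "day", "cells"}, f"schedule[{i}]")
            cart.append((float(e["day"]), float(e.get("cells", 0.0))))
        else:
            raise ConfigError(f"schedule entry {i}: unknown type {kind!r}")
    return TreatmentSchedule.build(trt=trt, cart=cart, trt_unit="nCi")


def parse_config(raw: dict | None) -> RunConfig:
    """Validate a raw mapping and resolve defaults."""
    raw = raw or {}
    if not isinstance(raw, dict):
        raise ConfigError("configuration root must be a mapping")
    _check_keys(raw, _TOP_KEYS, "config")

    pblock = raw.get("parameters", {}) or {}
    _check_keys(pblock, _PARAM_KEYS, "parameters")
    try:
        params = ModelParameters(**pblock)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"parameters: {exc}") from exc

    rblock = raw.get("regimen", {}) or {}
    _check_keys(rblock, _REGIMEN_KEYS, "regimen")
    mblock = raw.get("metrics", {}) or {}
    _check_keys(mblock, _METRICS_KEYS, "metrics")
    sblock = raw.get("sweep", {}) or {}
    _check_keys(sblock, _SWEEP_KEYS, "sweep")
    seblock = raw.get("sensitivity", {}) or {}
    _check_keys(seblock, _SENSITIVITY_KEYS, "sensitivity")
    cblock = raw.get("calibration", {}) or {}
    _check_keys(cblock, _CALIBRATION_KEYS, "calibration")

    cfg = RunConfig(params=params)
    try:
        cfg.regimen = RegimenSpec(**rblock)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"regimen: {exc}") from exc
    if "schedule" in raw:
        cfg.schedule = _parse_schedule(raw["schedule"] or [])
    cfg.os_threshold = float(mblock.get("os_threshold", OS_THRESHOLD_CELLS))
    cfg.horizon_days = float(mblock.get("horizon_days", DEFAULT_HORIZON))
    cfg.report_from_first_therapy = bool(
        mblock.get("report_from_first_therapy", False))
    cfg.sweep_grid = (float(sblock.get("start", 14.0)),
                      float(sblock.get("stop", 80.0)),
                      float(sblock.get("step", 1.0)))
    cfg.sensitivity_fraction = float(seblock.get("fraction", 0.5))
    cfg.calibration.update(cblock)
    cfg.output_dir = str(raw.get("output_dir", cfg.output_dir))
    cfg.seed = int(raw.get("seed", 0))
    return cfg


def load_config(path: str | Path | None) -> RunConfig:
    """Load and validate a YAML configuration file.

    ``None`` (no file) yields the pure protocol defaults.
    """
    if path is None:
        return parse_config({})
    p = Path(path)
    if not p.exists():
        raise ConfigError(f"configuration file not found: {p}")
    with open(p) as fh:
        try:
            raw = yaml.safe_load(fh)
        except yaml.YAMLError as exc:
            raise ConfigError(f"cannot parse {p}: {exc}") from exc
    return parse_config(raw)


def write_results(results: dict, outdir: str | Path,
                  config: RunConfig | None = None) -> dict:
    """Write analysis results deterministically and return a manifest.

    ``results`` maps artifact names to DataFrames (written as TSV) or
    JSON-serializable objects (written as JSON).  The resolved config is
    echoed alongside for provenance; the manifest lists every file with
    its sha256 content hash.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, str] = {}

    def _write(name: str, text: str) -> None:
        path = out / name
        path.write_text(text)
        manifest[name] = hashlib.sha256(text.encode()).hexdigest()

    for name, obj in sorted(results.items()):
        if isinstance(obj, pd.DataFrame):
            _write(f"{name}.tsv", obj.to_csv(sep="\t", index=False))
        else:
            _write(f"{name}.json", json.dumps(obj, indent=2, sort_keys=True,
                                              default=str) + "\n")
    if config is not None:
        _write("config.echo.yaml", yaml.safe_dump(config.to_dict(),
                                                  sort_keys=True))
    _write("manifest.json", json.dumps(
        {k: v for k, v in sorted(manifest.items())}, indent=2) + "\n")
    return manifest
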
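"""End-to-end orchestration: simulate/ingest -> accumulate/merge -> GPR ->
surfaces -> states -> reduction -> discrimination gap."""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import io as pio
from . import landscape as ls
from . import synthetic_data as syn
from .errors import ConfigurationError, PairscapeError
from .free_energy import (GridSpec, accumulate, fit_gpr, integrate_gpr,
                          merge_walkers, residual_inefficiency)

log = logging.getLogger("pairscape")

_KNOWN_KEYS = {"seed", "outdir", "temperature", "grid", "systems", "sampler",
               "gpr", "reduce", "gap", "states", "log_level"}


@dataclass
class RunConfig:
    """Validated pipeline configuration (unknown keys rejected)."""

    seed: int = 1
    outdir: str = "pairscape_out"
    temperature: float = 300.0
    grid: dict = field(default_factory=lambda: {
        "mins": [-100.0, -5.0], "maxs": [100.0, 5.0],
        "nbins": [40, 20], "periodic": [False, False]})
    systems: dict = field(default_factory=lambda: {
        "canonical": {"surface": "canonical_like", "params": {}},
        "mismatch": {"surface": "mismatch_like", "params": {}}})
    sampler: dict = field(default_factory=lambda: {
        "n_steps": 300_000, "n_walkers": 4, "step_size": 0.02,
        "bias": "abf_like", "friction": [0.0025, 1.0],
        "force_noise_sd": 1.0, "force_noise_rho": 0.0})
    gpr: dict = field(default_factory=lambda: {
        "maxiter": 40, "n_restarts": 1, "mask_threshold": 10.0})
    reduce: dict = field(default_factory=lambda: {"axis": 0})
    gap: dict = field(default_factory=lambda: {"delta_sigma": -60.0})
    states: dict = field(default_factory=lambda: {"min_depth": 0.5})
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        unknown = set(raw) - _KNOWN_KEYS
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        base = cls()
        for k, v in raw.items():
            if isinstance(getattr(base, k), dict) and isinstance(v, dict):
                merged = dict(getattr(base, k))
                merged.update(v)
                setattr(base, k, merged)
            else:
                setattr(base, k, v)
        return base

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in sorted(_KNOWN_KEYS)}

    def grid_spec(self) -> GridSpec:
        g = self.grid
        return GridSpec(tuple(g["mins"]), tuple(g["maxs"]),
                        tuple(g["nbins"]), tuple(g["periodic"]))


def _stage(name):
    def deco(fn):
        def wrapper(*args, **kwargs):
            t0 = time.perf_counter()
            log.info("stage %s: start", name)
            try:
                out = fn(*args, **kwargs)
            except PairscapeError as exc:
                raise PairscapeError(f"stage {name!r} failed: {exc}") from exc
            log.info("stage %s: done in %.1fs", name, time.perf_counter() - t0)
            return out
        return wrapper
    return deco


@_stage("simulate")
def _simulate_system(name, sysconf, config, grid, outdir, meta):
    surface = syn.make_surface(sysconf["surface"], **sysconf.get("params", {}))
    import zlib
    sc = syn.SamplerConfig(
        temperature=config.temperature,
        seed=config.seed + zlib.crc32(name.encode()) % 1000,
        bias_grid=grid, **config.sampler)
    walkers = syn.sample_langevin(surface, sc)
    for w in walkers:
        pio.write_samples_tsv(outdir / f"{name}_walker{w.walker}.tsv",
                              w.values, w.forces,
                              {**meta, "system": name, "walker": w.walker})
    return surface, walkers


@_stage("accumulate")
def _accumulate(walkers, grid):
    grids = [accumulate(w.values, w.forces, grid) for w in walkers]
    merged = merge_walkers(grids)
    # inefficiency of the within-bin force fluctuations (cross-bin drift is
    # part of the signal, not the noise)
    sub = min(len(walkers[0].forces), 200_000)
    gs = [residual_inefficiency(w.values[:sub], w.forces[:sub], grid)
          for w in walkers]
    merged.g = np.full(grid.nbins_total, float(np.median(gs)))
    return merged


@_stage("integrate")
def _integrate(merged, gprconf):
    mask_threshold = float(gprconf.get("mask_threshold", 10.0))
    model = fit_gpr(merged, n_restarts=int(gprconf.get("n_restarts", 1)),
                    maxiter=int(gprconf.get("maxiter", 40)))
    surf = integrate_gpr(merged, model, mask_threshold=mask_threshold)
    return model, surf


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full chain; returns a report dict (also written as JSON)."""
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), 20),
                        format="%(levelname)s %(name)s: %(message)s")
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    grid = config.grid_spec()
    science = {k: v for k, v in config.as_dict().items()
               if k not in ("outdir", "log_level")}
    meta = {"seed": config.seed, "config_hash": pio.config_hash(science)}
    (outdir / "config_echo.yaml").write_text(yaml.safe_dump(config.as_dict()))

    report = {"seed": config.seed, "systems": {}, "meta": meta}
    profiles = {}
    for name, sysconf in config.systems.items():
        surface, walkers = _simulate_system(name, sysconf, config, grid,
                                            outdir, meta)
        merged = _accumulate(walkers, grid)
        pio.write_meanforce_tsv(outdir / f"{name}_meanforce.tsv", merged, meta)
        model, surf = _integrate(merged, config.gpr)
        pio.write_fes_tsv(outdir / f"{name}_fes.tsv", surf, meta)
        minima = ls.find_minima(surf,
                                min_depth=float(config.states["min_depth"]))
        states_report = [{"label": s.label, "location": list(s.location),
                          "depth": s.value} for s in minima]
        (outdir / f"{name}_states.json").write_text(
            json.dumps({"meta": meta, "states": states_report}, indent=2))

        profile = ls.reduce_profile(surf, axis=int(config.reduce["axis"]),
                                    temperature=config.temperature)
        rel = ls.relative_opening(profile, ls.profile_reference(profile))
        pio.write_profile_tsv(outdir / f"{name}_profile.tsv", rel, meta)
        profiles[name] = profile
        report["systems"][name] = {
            "n_states": len(minima),
            "states": states_report,
            "lml": model.log_marginal_likelihood,
            "length_scales": [float(v) for v in model.length_scales],
        }

    if {"canonical", "mismatch"} <= set(profiles):
        at = float(config.gap["delta_sigma"])
        c = ls.opening_propensity(profiles["canonical"], at)
        m = ls.opening_propensity(profiles["mismatch"], at)
        gap = ls.discrimination_gap(c, m, at)
        report["gap"] = {"delta_sigma": at, "canonical": c[0],
                         "canonical_stderr": c[1], "mismatch": m[0],
                         "mismatch_stderr": m[1], "gap": gap.gap,
                         "gap_stderr": gap.gap_stderr}
    (outdir / "report.json").write_text(json.dumps(report, indent=2))
    return report
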
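"""YAML run-configuration parsing.

A config file is a YAML mapping with optional sections:

community:            # sampling settings for sample/simulate
  M: 30
  m: 10
  intervals:          # (low, high) overrides per parameter
    mu: [0.24, 1.36]
    x0: [1.0, 10.0]
  S0_each: 100.0
disturbance:
  psd: [1.0, 1.0, 1.0, 1.0, 1.0]     # or psd1..psd5 individually
  redraw_interval: 0.25
simulation:
  dt: 0.25
  horizon: 2400.0
  sample_interval: 24.0
  extinction_threshold: 1.0e-6
experiment:
  M_range: [20, 50]
  m_range: [5, 15]
  weak_psd_range: [0.0, 2.0]
  strong_psd_range: [2.0, 10.0]
  replicates: 50
  paired: true

Every section and key is optional; omitted keys fall back to package
defaults (the reference parameter table, dt = 0.25 h, 2400 h horizon,
daily sampling).
"""

from __future__ import annotations

from dataclasses import replace

import yaml

from .community_gen import ParameterIntervals
from .integrator import SimConfig
from .noise import DisturbanceSpec

__all__ = ["load_config", "intervals_from_config", "sim_from_config",
           "disturbance_from_config"]


def load_config(path) -> dict:
    """Read a YAML config file into a dict (empty dict for empty file)."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if cfg is None:
        return {}
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be a YAML mapping")
    return cfg


def intervals_from_config(cfg: dict) -> ParameterIntervals:
    comm = cfg.get("community", {})
    overrides = {}
    for name, bounds in (comm.get("intervals") or {}).items():
        overrides[name] = tuple(float(v) for v in bounds)
    if "S0_each" in comm:
        overrides["S0_each"] = float(comm["S0_each"])
    return replace(ParameterIntervals(), **overrides)


def sim_from_config(cfg: dict, seed: int | None = None) -> SimConfig:
    simc = cfg.get("simulation", {})
    return SimConfig(
        dt=float(simc.get("dt", 0.25)),
        horizon=float(simc.get("horizon", 2400.0)),
        sample_interval=float(simc.get("sample_interval", 24.0)),
        extinction_threshold=float(simc.get("extinction_threshold", 1e-6)),
        seed=seed,
    )


def disturbance_from_config(cfg: dict) -> DisturbanceSpec:
    dist = cfg.get("disturbance", {})
    if "psd" in dist:
        psd = [float(v) for v in dist["psd"]]
        if len(psd) != 5:
            raise ValueError("disturbance.psd must list five levels")
    else:
        psd = [float(dist.get(f"psd{i}", 0.0)) for i in range(1, 6)]
    redraw = dist.get("redraw_interval")
    return DisturbanceSpec(*psd, redraw_interval=float(redraw) if redraw else None)
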
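"""Config file handling: YAML with flat sections, reference-system defaults.

Sections (all optional — omitted keys fall back to the three-server reference
system: 1000 users, capacities {100, 200, 400} servs/s, latencies
{10, 20, 30} ms, c=1, k=10 places, 100 ms timeout):

    system:      nu, tau_ms, rho | lambda_u, latency_mode
    servers:     list of {mu, c, k, d_ms}
    population:  mode (fixed | adaptive), tolerance, shift_rule,
                 initial_assignment
    learning:    t0, x0, beta
    run:         duration, seed, sample_dt, schedule (list of [length, rho])

Latencies and the timeout are written in milliseconds (as commonly quoted for
network latency) and converted to seconds on load.  Unknown keys are errors,
never silently ignored.  Giving both ``rho`` and ``lambda_u`` is an error.
"""

from __future__ import annotations

from dataclasses import asdict
from pathlib import Path

import yaml

from .quality import QueueServerSpec, SystemSpec
from .simulator import SimConfig

__all__ = ["DEFAULTS", "load_config", "write_config", "system_from_dict", "scale_system"]

DEFAULTS = {
    "system": {"nu": 1000, "tau_ms": 100.0, "rho": 0.75, "latency_mode": "round-trip"},
    "servers": [
        {"mu": 100.0, "c": 1, "k": 10, "d_ms": 10.0},
        {"mu": 200.0, "c": 1, "k": 10, "d_ms": 20.0},
        {"mu": 400.0, "c": 1, "k": 10, "d_ms": 30.0},
    ],
    "population": {"mode": "fixed", "tolerance": 1, "shift_rule": "uniform"},
    "learning": {"t0": 5, "x0": 0.0, "beta": 0.10},
    "run": {"duration": 1000.0, "seed": 0, "sample_dt": 1.0},
}

_ALLOWED = {
    "system": {"nu", "tau_ms", "rho", "lambda_u", "latency_mode"},
    "servers": {"mu", "c", "k", "d_ms"},
    "population": {"mode", "tolerance", "shift_rule", "initial_assignment"},
    "learning": {"t0", "x0", "beta"},
    "run": {"duration", "seed", "sample_dt", "schedule"},
}


class ConfigError(ValueError):
    """Raised on malformed config files, naming the offending key."""


def _check_keys(section: str, given: dict) -> None:
    unknown = set(given) - _ALLOWED[section]
    if unknown:
        raise ConfigError(f"unknown key(s) in section '{section}': {sorted(unknown)}")


def system_from_dict(raw: dict) -> SystemSpec:
    """Build a SystemSpec from the 'system' + 'servers' sections."""
    sys_raw = dict(raw.get("system") or {})
    _check_keys("system", sys_raw)
    if "rho" in sys_raw and "lambda_u" in sys_raw:
        raise ConfigError("system: give only one of 'rho' and 'lambda_u'")
    merged = {**DEFAULTS["system"], **sys_raw}
    if "lambda_u" in sys_raw:
        merged.pop("rho", None)

    servers_raw = raw.get("servers") or DEFAULTS["servers"]
    goods = []
    for srv in servers_raw:
        _check_keys("servers", srv)
        s = {**{"c": 1, "k": 10, "d_ms": 0.0}, **srv}
        if "mu" not in s:
            raise ConfigError("servers: every server needs 'mu'")
        goods.append(QueueServerSpec(mu=float(s["mu"]), c=int(s["c"]), k=int(s["k"]),
                                     d=float(s["d_ms"]) / 1000.0))
    return SystemSpec(
        goods=tuple(goods),
        nu=int(merged["nu"]),
        tau=float(merged["tau_ms"]) / 1000.0,
        rho=float(merged["rho"]) if "rho" in merged else None,
        lambda_u=float(merged["lambda_u"]) if "lambda_u" in merged else None,
        latency_mode=merged["latency_mode"],
    )


def load_config(path: str | Path | None = None, raw: dict | None = None) -> SimConfig:
    """Load and validate a run configuration (file path or parsed dict).

    An empty file yields the reference system with its default run settings.
    """
    if raw is None:
        text = Path(path).read_text() if path is not None else ""
        raw = yaml.safe_load(text) or {}
    if not isinstance(raw, dict):
        raise ConfigError("config root must be a mapping of sections")
    unknown = set(raw) - set(_ALLOWED)
    if unknown:
        raise ConfigError(f"unknown section(s): {sorted(unknown)}")

    system = system_from_dict(raw)
    pop = {**DEFAULTS["population"], **(raw.get("population") or {})}
    _check_keys("population", pop)
    learn = {**DEFAULTS["learning"], **(raw.get("learning") or {})}
    _check_keys("learning", learn)
    run = {**DEFAULTS["run"], **(raw.get("run") or {})}
    _check_keys("run", run)

    schedule = run.get("schedule")
    if schedule is not None:
        schedule = [(float(L), float(r)) for L, r in schedule]
    return SimConfig(
        system=system,
        duration=float(run["duration"]),
        seed=int(run["seed"]),
        mode=pop["mode"],
        tolerance=pop["tolerance"],
        T0=int(learn["t0"]),
        x0=float(learn["x0"]),
        beta=float(learn["beta"]),
        shift_rule=pop["shift_rule"],
        schedule=schedule,
        sample_dt=float(run["sample_dt"]),
        initial_assignment=pop.get("initial_assignment"),
    )


def config_to_dict(cfg: SimConfig) -> dict:
    """Serializable mapping mirroring the config file format."""
    sys_spec = cfg.system
    out = {
        "system": {
            "nu": sys_spec.nu,
            "tau_ms": sys_spec.tau * 1000.0,
            "rho": sys_spec.rho,
            "latency_mode": sys_spec.latency_mode,
        },
        "servers": [
            {"mu": g.mu, "c": g.c, "k": g.k, "d_ms": g.d * 1000.0}
            for g in sys_spec.goods
        ],
        "population": {
            "mode": cfg.mode,
            "tolerance": (list(cfg.tolerance) if hasattr(cfg.tolerance, "__len__")
                          else cfg.tolerance),
            "shift_rule": cfg.shift_rule,
        },
        "learning": {"t0": cfg.T0, "x0": cfg.x0, "beta": cfg.beta},
        "run": {
            "duration": cfg.duration,
            "seed": cfg.seed,
            "sample_dt": cfg.sample_dt,
        },
    }
    if cfg.schedule is not None:
        out["run"]["schedule"] = [[L, r] for L, r in cfg.schedule]
    if cfg.initial_assignment is not None:
        out["population"]["initial_assignment"] = list(map(int, cfg.initial_assignment))
    return out


def write_config(cfg: SimConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(config_to_dict(cfg), sort_keys=False))


def scale_system(system: SystemSpec, scale: float) -> SystemSpec:
    """Shrink a system for fast runs while preserving its physics.

    The population and every capacity shrink by ``scale`` (workload ``rho``
    preserved) while the time unit dilates: latencies and the timeout grow by
    ``1/scale`` so the dimensionless products ``mu_i * tau`` and ``mu_i * d_i``
    — hence every per-request loss and delay probability at corresponding
    fractional occupancies — are unchanged.
    """
    if not (0 < scale <= 1):
        raise ValueError("scale must lie in (0, 1]")
    goods = tuple(
        QueueServerSpec(mu=g.mu * scale, c=g.c, k=g.k, d=g.d / scale)
        for g in system.goods
    )
    return SystemSpec(
        goods=goods,
        nu=max(2, round(system.nu * scale)),
        tau=system.tau / scale,
        rho=system.rho,
        latency_mode=system.latency_mode,
    )
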
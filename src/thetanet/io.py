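"""Run configuration, dispatch, tabular output, and manifests.

Every workflow (network simulation, equilibrium finding, one-parameter
continuation, cycle branches, two-parameter Hopf tracking, surface meshes)
is driven by a :class:`RunConfig` and leaves behind plain comma-separated
tables plus a JSON manifest that records everything needed to reproduce the
run: the full configuration, package version, seeds, and the derived pulse
coefficients.  Floats are serialized with 17 significant digits so a
write-read round trip is exact.
"""

from __future__ import annotations

import json
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from .codim2 import continue_hopf_curve
from .continuation import continue_equilibria
from .cycles import limit_cycle_branch
from .equilibria import find_equilibria
from .model import ModelParams, pulse_coefficients
from .network import sample_population, simulate_network
from .surfaces import build_surface_mesh

__all__ = ["RunConfig", "ConfigurationError", "FormatError", "run",
           "read_table", "write_table", "SCHEMAS"]


class ConfigurationError(ValueError):
    """Invalid task or out-of-range setting, raised before any compute."""


class FormatError(ValueError):
    """A table does not match its documented schema."""


TASKS = ("simulate", "equilibria", "continue", "cycle", "codim2", "surface")

SCHEMAS = {
    "branch": ["sweep_value", "x", "y", "trace", "det", "discriminant", "label"],
    "events": ["kind", "sweep_value", "x", "y", "l1", "period", "bracket_width"],
    "surface": ["x_e", "y_e", "kind", "eta0", "delta_eta", "k0",
                "residual_eq", "residual_test", "physical_flag",
                "det_positive_flag"],
    "series": ["time", "re_z", "im_z", "abs_z"],
    "spikes": ["neuron_index", "eta", "k", "n_spikes"],
    "equilibria": ["x", "y", "trace", "det", "discriminant", "label", "residual"],
    "cycles": ["param_value", "period", "x_section", "y_section", "x_min",
               "x_max", "y_min", "y_max", "multiplier", "min_saddle_dist"],
}


def write_table(path, frame: pd.DataFrame, schema: str) -> None:
    """Write a schema-checked CSV with full-precision floats."""
    cols = SCHEMAS.get(schema)
    if cols is None:
        raise FormatError(f"unknown schema {schema!r}")
    missing = [c for c in cols if c not in frame.columns]
    if missing:
        raise FormatError(f"missing column {missing[0]!r} for schema {schema!r}")
    frame[cols].to_csv(path, index=False, float_format="%.17g")


def read_table(path, schema: str) -> pd.DataFrame:
    """Read a CSV previously written by :func:`write_table`."""
    cols = SCHEMAS.get(schema)
    if cols is None:
        raise FormatError(f"unknown schema {schema!r}")
    frame = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in cols if c not in frame.columns]
    if missing:
        raise FormatError(f"missing column {missing[0]!r} for schema {schema!r}")
    return frame[cols]


@dataclass
class RunConfig:
    """One workflow invocation: task, model parameters, task settings."""

    task: str
    params: ModelParams
    settings: dict = field(default_factory=dict)
    outdir: str = "."
    seed: Optional[int] = None

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        task = d.pop("task", None)
        pd_ = d.pop("params", {})
        try:
            params = ModelParams(
                eta0=float(pd_.get("eta0", 0.0)),
                delta_eta=float(pd_.get("delta_eta", 0.0)),
                k0=float(pd_.get("k0", 0.0)),
                delta_k=float(pd_.get("delta_k", 0.0)),
                n=int(pd_.get("n", 2)),
            )
        except (TypeError, ValueError) as exc:
            raise ConfigurationError(f"bad model parameters: {exc}") from exc
        cfg = cls(task=task, params=params,
                  settings=d.pop("settings", {}),
                  outdir=d.pop("outdir", "."),
                  seed=d.pop("seed", None))
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def validate(self) -> None:
        if self.task not in TASKS:
            raise ConfigurationError(
                f"unknown task {self.task!r}; expected one of {TASKS}")
        s = self.settings
        checks = [
            ("N", lambda v: int(v) >= 1, "N must be >= 1"),
            ("dt", lambda v: float(v) > 0, "dt must be > 0"),
            ("t_end", lambda v: float(v) > 0, "t_end must be > 0"),
            ("record_stride", lambda v: int(v) >= 1, "record_stride must be >= 1"),
            ("scheme", lambda v: v in ("quantile", "random"),
             "scheme must be quantile|random"),
            ("sweep_param", lambda v: v in ("eta0", "delta_eta", "k0", "delta_k"),
             "sweep_param must name a model parameter"),
            ("kind", lambda v: v in ("saddle-node", "hopf", "node-focus"),
             "kind must be saddle-node|hopf|node-focus"),
        ]
        for name, pred, msg in checks:
            if name in s:
                try:
                    ok = pred(s[name])
                except (TypeError, ValueError):
                    ok = False
                if not ok:
                    raise ConfigurationError(f"{msg} (got {s[name]!r})")
        for rng_name in ("sweep_range", "delta_k_range"):
            if rng_name in s:
                r = s[rng_name]
                if len(r) != 2 or not all(np.isfinite(float(v)) for v in r):
                    raise ConfigurationError(f"{rng_name} must be a finite (lo, hi) pair")


def _log(msg: str) -> None:
    print(f"[thetanet] {msg}", file=sys.stderr)


def _events_frame(events) -> pd.DataFrame:
    rows = []
    for e in events:
        rows.append(dict(kind=e.kind, sweep_value=e.value, x=e.z.real,
                         y=e.z.imag, l1=e.auxiliary.get("l1", np.nan),
                         period=e.auxiliary.get("period", np.nan),
                         bracket_width=e.bracket_width))
    return pd.DataFrame(rows, columns=SCHEMAS["events"])


def run(config: RunConfig) -> dict:
    """Execute one configured workflow; returns the manifest (also on disk).

    Output tables land in ``config.outdir`` together with ``manifest.json``.
    No result file is written without a manifest.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    params = config.params
    pulse = pulse_coefficients(params.n)
    s = config.settings
    summary: dict = {}
    t_start = time.time()

    if config.task == "simulate":
        real = sample_population(params, int(s.get("N", 10000)),
                                 scheme=s.get("scheme", "quantile"),
                                 seed=config.seed,
                                 initial_phases=s.get("initial_phases", "equispaced"),
                                 clip=bool(s.get("clip", False)))
        res = simulate_network(real, pulse, t_end=float(s.get("t_end", 100.0)),
                               dt=float(s.get("dt", 2e-3)),
                               record_stride=int(s.get("record_stride", 10)),
                               burn_in=float(s.get("burn_in", 50.0)),
                               track_spikes=bool(s.get("track_spikes", False)))
        write_table(outdir / "series.csv", res.to_frame(), "series")
        if res.spike_counts is not None:
            spikes = pd.DataFrame(dict(neuron_index=np.arange(real.N),
                                       eta=real.eta, k=real.k,
                                       n_spikes=res.spike_counts))
            write_table(outdir / "spikes.csv", spikes, "spikes")
        summary = {k: v for k, v in res.asymptotic_summary.items()
                   if k != "mean_z"}
        summary["clipped"] = real.clipped
    elif config.task == "equilibria":
        eqs = find_equilibria(params, pulse)
        frame = pd.DataFrame([dict(x=e.x, y=e.y, trace=e.jac.trace,
                                   det=e.jac.determinant,
                                   discriminant=e.jac.discriminant,
                                   label=e.label, residual=e.residual)
                              for e in eqs], columns=SCHEMAS["equilibria"])
        write_table(outdir / "equilibria.csv", frame, "equilibria")
        summary = {"n_equilibria": len(eqs),
                   "labels": [e.label for e in eqs]}
    elif config.task == "continue":
        branches = continue_equilibria(params, s["sweep_param"],
                                       tuple(s["sweep_range"]), pulse=pulse,
                                       initial_step=float(s.get("initial_step", 1e-2)))
        frames, all_events = [], []
        for i, br in enumerate(branches):
            f = br.to_frame()
            f.insert(0, "branch", i)
            frames.append(f)
            all_events.extend(br.events)
        branch_frame = pd.concat(frames, ignore_index=True) if frames else \
            pd.DataFrame(columns=SCHEMAS["branch"])
        write_table(outdir / "branch.csv", branch_frame, "branch")
        write_table(outdir / "events.csv", _events_frame(all_events), "events")
        summary = {"n_branches": len(branches),
                   "event_counts": _count_kinds(all_events)}
    elif config.task == "cycle":
        from .codim2 import hopf_points_at

        hopfs = hopf_points_at(params, s["sweep_param"],
                               tuple(s["sweep_range"]), pulse)
        if not hopfs:
            lcb = None
            summary = {"n_cycles": 0, "termination": "no-hopf-found"}
            write_table(outdir / "cycles.csv",
                        pd.DataFrame(columns=SCHEMAS["cycles"]), "cycles")
            write_table(outdir / "events.csv", _events_frame([]), "events")
        else:
            lcb = limit_cycle_branch(params, s["sweep_param"],
                                     tuple(s["sweep_range"]), init=hopfs[0],
                                     pulse=pulse,
                                     hopf_offset=float(s.get("hopf_offset", 0.1)))
            write_table(outdir / "cycles.csv", lcb.to_frame(), "cycles")
            write_table(outdir / "events.csv", _events_frame(lcb.events), "events")
            summary = {"n_cycles": len(lcb),
                       "termination": lcb.termination,
                       "event_counts": _count_kinds(lcb.events)}
    elif config.task == "codim2":
        curve = continue_hopf_curve(params, s["sweep_param"],
                                    tuple(s["sweep_range"]),
                                    tuple(s.get("delta_k_range", (0.0, 2.0))),
                                    pulse=pulse)
        curve.to_frame().to_csv(outdir / "hopf_curve.csv", index=False,
                                float_format="%.17g")
        write_table(outdir / "events.csv", _events_frame(curve.events), "events")
        summary = {"n_points": len(curve.points),
                   "termination": curve.termination,
                   "event_counts": _count_kinds(curve.events)}
    elif config.task == "surface":
        mesh = build_surface_mesh(s["kind"], params.delta_k, pulse,
                                  clip=s.get("clip"),
                                  physical_filter=bool(s.get("physical_filter", True)))
        write_table(outdir / "surface.csv", mesh.to_frame(), "surface")
        summary = {"n_points": len(mesh.points),
                   "n_solutions": int(len(mesh.solutions_array())),
                   "n_dropped_unphysical": mesh.n_dropped_unphysical,
                   "n_dropped_clip": mesh.n_dropped_clip,
                   "n_degenerate": mesh.n_degenerate}

    manifest = {
        "task": config.task,
        "package_version": __version__,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "elapsed_seconds": round(time.time() - t_start, 3),
        "seed": config.seed,
        "params": {"eta0": params.eta0, "delta_eta": params.delta_eta,
                   "k0": params.k0, "delta_k": params.delta_k, "n": params.n},
        "pulse": {"n": pulse.n, "a_n": pulse.a_n, "A": pulse.A.tolist()},
        "settings": _jsonable(config.settings),
        "summary": _jsonable(summary),
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    _log(f"task {config.task} finished in {manifest['elapsed_seconds']}s: "
         f"{manifest['summary']}")
    return manifest


def _count_kinds(events) -> dict:
    out: dict = {}
    for e in events:
        out[e.kind] = out.get(e.kind, 0) + 1
    return out


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj
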
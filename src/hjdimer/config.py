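"""Run configuration: a single YAML file documents an entire analysis.

The file is validated against the schema below before any computation, and
its SHA-256 (over a canonical JSON rendering) is embedded in every output
so results can be traced back to the exact configuration.

Schema (keys in parentheses optional)::

    trajectories:              # one entry per simulation trial
      - topology: <pdb path>
        coordinates: <path>
        format: frames | pdb
        (dt_ps): <float>       # required for format: pdb
    (dyes):                    # exactly two for dimer analyses
      - label: <str>
        chain: <str>
        res_id: <int>
        (res_name): <str>
        (end_r): [<atom>, ...] # default [N1]
        (end_s): [<atom>, ...] # default [N2]
        (mu_debye): <float>
    (coupling):
      (refractive_index): 1.33
    (analysis):
      (orientation_stride_ps): 100
      (contact_stride_ps): 500
      (burn_in_ps): 0
      (cutoff_nm): 1.2
      (center_window): [11, 16]
      (kappa_boundary): 1.0
      (dimer_r_max_nm): 1.5
    (junction):
      duplex_1: [ {label, span_a: {chain,start,stop}, span_b: {...}}, ... ]
      duplex_2: [ ... ]
    (synth):                   # consumed by the `synth` subcommand
      kind: dimer | junction
      ... generator parameters (see synthetic_data)
    (seed): <int>
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

from .dipole_geometry import DyeDefinition
from .errors import ConfigurationError
from .exciton_coupling import CouplingConfig
from .junction_geometry import ArmDefinition, Span

_ANALYSIS_DEFAULTS = {
    "orientation_stride_ps": 100.0,
    "contact_stride_ps": 500.0,
    "burn_in_ps": 0.0,
    "cutoff_nm": 1.2,
    "center_window": [11, 16],
    "kappa_boundary": 1.0,
    "dimer_r_max_nm": 1.5,
}


@dataclass
class TrajectoryInput:
    topology: Path
    coordinates: Path
    format: str = "frames"
    dt_ps: float | None = None


@dataclass
class RunConfig:
    """Parsed and validated run configuration."""

    raw: dict
    path: Path
    trajectories: list[TrajectoryInput] = field(default_factory=list)
    dyes: list[DyeDefinition] = field(default_factory=list)
    coupling: CouplingConfig | None = None
    analysis: dict[str, Any] = field(default_factory=dict)
    junction: tuple[list[ArmDefinition], list[ArmDefinition]] | None = None
    synth: dict[str, Any] | None = None
    seed: int = 0

    @property
    def config_sha256(self) -> str:
        canon = json.dumps(self.raw, sort_keys=True, separators=(",", ":"))
        return hashlib.sha256(canon.encode()).hexdigest()

    def require_dye_pair(self) -> tuple[DyeDefinition, DyeDefinition]:
        if len(self.dyes) != 2:
            raise ConfigurationError(
                f"this analysis needs exactly 2 dye definitions, got {len(self.dyes)}"
            )
        return self.dyes[0], self.dyes[1]

    def meta(self, **extra: Any) -> dict[str, Any]:
        """Provenance block embedded in every output file."""
        out: dict[str, Any] = {"config_sha256": self.config_sha256}
        for key in ("kappa_boundary", "dimer_r_max_nm", "cutoff_nm", "burn_in_ps"):
            out[key] = self.analysis[key]
        out.update(extra)
        return out


def _require(section: dict, key: str, where: str) -> Any:
    if key not in section:
        raise ConfigurationError(f"{where}: missing required key {key!r}")
    return section[key]


def _parse_dye(entry: dict, i: int) -> DyeDefinition:
    where = f"dyes[{i}]"
    if not isinstance(entry, dict):
        raise ConfigurationError(f"{where}: expected a mapping")
    return DyeDefinition(
        label=str(_require(entry, "label", where)),
        chain=str(_require(entry, "chain", where)),
        res_id=int(_require(entry, "res_id", where)),
        res_name=entry.get("res_name"),
        end_r=tuple(entry.get("end_r", ("N1",))),
        end_s=tuple(entry.get("end_s", ("N2",))),
        mu_debye=float(entry.get("mu_debye", 0.0)),
    )


def _parse_span(entry: dict, where: str) -> Span:
    return Span(
        chain=str(_require(entry, "chain", where)),
        start=int(_require(entry, "start", where)),
        stop=int(_require(entry, "stop", where)),
    )


def _parse_arms(entries: list, where: str) -> list[ArmDefinition]:
    if not isinstance(entries, list) or not entries:
        raise ConfigurationError(f"{where}: expected a non-empty list of arms")
    arms = []
    for i, e in enumerate(entries):
        w = f"{where}[{i}]"
        arms.append(
            ArmDefinition(
                label=str(_require(e, "label", w)),
                span_a=_parse_span(_require(e, "span_a", w), f"{w}.span_a"),
                span_b=_parse_span(_require(e, "span_b", w), f"{w}.span_b"),
            )
        )
    return arms


def load_run_config(path: str | Path, require_inputs: bool = True) -> RunConfig:
    """Load and validate a run configuration.

    With ``require_inputs`` (the default) every referenced trajectory file
    must exist; the ``synth`` subcommand loads with it disabled since it
    creates the files.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"config file not found: {path}")
    try:
        raw = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ConfigurationError(f"{path}: invalid YAML: {exc}") from exc
    if not isinstance(raw, dict):
        raise ConfigurationError(f"{path}: top level must be a mapping")

    known = {"trajectories", "dyes", "coupling", "analysis", "junction", "synth", "seed"}
    unknown = set(raw) - known
    if unknown:
        raise ConfigurationError(f"{path}: unknown top-level keys {sorted(unknown)}")

    cfg = RunConfig(raw=raw, path=path)

    for i, entry in enumerate(raw.get("trajectories", []) or []):
        where = f"trajectories[{i}]"
        if not isinstance(entry, dict):
            raise ConfigurationError(f"{where}: expected a mapping")
        fmt = str(entry.get("format", "frames"))
        if fmt not in ("frames", "pdb"):
            raise ConfigurationError(f"{where}: unknown format {fmt!r}")
        ti = TrajectoryInput(
            topology=path.parent / str(_require(entry, "topology", where)),
            coordinates=path.parent / str(_require(entry, "coordinates", where)),
            format=fmt,
            dt_ps=float(entry["dt_ps"]) if "dt_ps" in entry else None,
        )
        if require_inputs:
            for p in (ti.topology, ti.coordinates):
                if not p.exists():
                    raise ConfigurationError(f"{where}: input file not found: {p}")
        cfg.trajectories.append(ti)

    cfg.dyes = [_parse_dye(e, i) for i, e in enumerate(raw.get("dyes", []) or [])]

    if "coupling" in raw and raw["coupling"] is not None:
        c = raw["coupling"]
        if not isinstance(c, dict):
            raise ConfigurationError("coupling: expected a mapping")
        cfg.coupling = CouplingConfig(
            refractive_index=float(c.get("refractive_index", 1.33))
        )

    analysis = dict(_ANALYSIS_DEFAULTS)
    user_analysis = raw.get("analysis", {}) or {}
    unknown = set(user_analysis) - set(_ANALYSIS_DEFAULTS)
    if unknown:
        raise ConfigurationError(f"analysis: unknown keys {sorted(unknown)}")
    analysis.update(user_analysis)
    for key in ("orientation_stride_ps", "contact_stride_ps"):
        if float(analysis[key]) <= 0:
            raise ConfigurationError(f"analysis.{key} must be positive")
    if float(analysis["burn_in_ps"]) < 0:
        raise ConfigurationError("analysis.burn_in_ps must be >= 0")
    window = analysis["center_window"]
    if (
        not isinstance(window, (list, tuple))
        or len(window) != 2
        or int(window[0]) > int(window[1])
    ):
        raise ConfigurationError("analysis.center_window must be [lo, hi] with lo <= hi")
    analysis["center_window"] = (int(window[0]), int(window[1]))
    cfg.analysis = analysis

    if "junction" in raw and raw["junction"] is not None:
        j = raw["junction"]
        cfg.junction = (
            _parse_arms(_require(j, "duplex_1", "junction"), "junction.duplex_1"),
            _parse_arms(_require(j, "duplex_2", "junction"), "junction.duplex_2"),
        )

    if "synth" in raw and raw["synth"] is not None:
        if not isinstance(raw["synth"], dict):
            raise ConfigurationError("synth: expected a mapping")
        cfg.synth = dict(raw["synth"])

    cfg.seed = int(raw.get("seed", 0))
    return cfg
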
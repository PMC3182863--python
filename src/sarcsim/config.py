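"""Flat YAML run configuration: parsing, validation, round-tripping.

A config file supplies any subset of the known keys; missing keys take
the standard-protocol defaults (alpha 0.2, beta 0, 50 series units, 8%
stretch at 0.1 final lengths/s from 1200 nm, t_ss 6 s).  Unknown keys
are rejected with a field-level message.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields, replace
from pathlib import Path

import yaml

from .halfsarcomere import InvalidInputError
from .heterogeneity import HeterogeneitySpec
from .network import Topology
from .protocols import Protocol

__all__ = ["RunConfig", "parse_config", "write_config", "config_dict"]


@dataclass(frozen=True)
class RunConfig:
    """Everything needed to reproduce one experiment run."""

    experiment: str = "basic"
    topology: Topology = field(default_factory=Topology)
    heterogeneity: HeterogeneitySpec = field(
        default_factory=HeterogeneitySpec)
    protocol: Protocol = field(default_factory=Protocol)
    master_seed: int = 0
    seeds_per_point: int = 10
    out_dir: str = "sarcsim_out"


_SECTIONS = {
    "topology": (Topology, ("n_series", "n_myofibrils", "k_im")),
    "heterogeneity": (HeterogeneitySpec,
                      ("alpha", "beta", "seed", "n_units")),
    "protocol": (Protocol,
                 ("stretch_magnitude", "stretch_velocity",
                  "activation_ramp_duration", "pre_stretch_hold",
                  "post_stretch_hold", "dt", "initial_mean_hs_length")),
}
_TOP_KEYS = ("experiment", "master_seed", "seeds_per_point", "out_dir")


def parse_config(path: str | Path) -> RunConfig:
    """Read and validate a YAML config; empty file means all defaults."""
    raw = yaml.safe_load(Path(path).read_text())
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise InvalidInputError("config root must be a mapping")
    cfg = RunConfig()
    for key, val in raw.items():
        if key in _SECTIONS:
            cls, known = _SECTIONS[key]
            if not isinstance(val, dict):
                raise InvalidInputError(f"section {key!r} must be a mapping")
            unknown = set(val) - set(known)
            if unknown:
                raise InvalidInputError(
                    f"unknown key(s) in {key}: {sorted(unknown)}")
            try:
                cfg = replace(cfg, **{key: cls(**val)})
            except (TypeError, ValueError) as exc:
                raise InvalidInputError(f"invalid {key}: {exc}") from exc
        elif key in _TOP_KEYS:
            cfg = replace(cfg, **{key: val})
        else:
            raise InvalidInputError(f"unknown config key: {key!r}")
    if cfg.heterogeneity.n_units != cfg.topology.n_series:
        cfg = replace(cfg, heterogeneity=replace(
            cfg.heterogeneity, n_units=cfg.topology.n_series))
    return cfg


def config_dict(cfg: RunConfig) -> dict:
    return {
        "experiment": cfg.experiment,
        "master_seed": cfg.master_seed,
        "seeds_per_point": cfg.seeds_per_point,
        "out_dir": cfg.out_dir,
        "topology": asdict(cfg.topology),
        "heterogeneity": asdict(cfg.heterogeneity),
        "protocol": {f.name: getattr(cfg.protocol, f.name)
                     for f in fields(Protocol)},
    }


def write_config(cfg: RunConfig, path: str | Path) -> None:
    """Serialize a config so that parse_config round-trips it exactly."""
    Path(path).write_text(yaml.safe_dump(config_dict(cfg),
                                         sort_keys=False))
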
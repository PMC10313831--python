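"""Run configuration: structured-text (YAML) parsing and shipped defaults.

One file defines the lattice, the named rate sets (buffer conditions), the
phased flow protocols, the length model, ensemble settings and observable
options.  The packaged ``data/defaults.yaml`` carries the calibrated default
parameters for the 150 mM and 15 mM NaCl conditions together with their
provenance note.
"""

from __future__ import annotations

import hashlib
import importlib.resources as resources
from dataclasses import dataclass, field
from typing import Any, Mapping

import yaml

from .kymograph import OpticsModel
from .lattice import Phase, Protocol, RateSet
from .observables import LengthModel

__all__ = ["RunConfig", "load_config", "default_config", "ConfigError"]


class ConfigError(ValueError):
    """Invalid or incomplete run configuration; the message names the key."""


@dataclass
class RunConfig:
    lattice_length: int
    rate_sets: dict[str, RateSet]
    protocols: dict[str, Protocol]
    length_model: LengthModel
    n_rep: int = 100
    seed: int = 1
    sample_dt: float = 5.0
    snapshot_times: tuple[float, ...] = (1800.0, 2400.0)
    gap_threshold: int = 18
    include_terminal: bool = True
    gap_cutoff: float = 30.0
    optics: OpticsModel = field(default_factory=OpticsModel)
    provenance: str = ""
    raw: dict = field(default_factory=dict)

    def config_hash(self) -> str:
        """Stable short hash of the raw configuration for provenance headers."""
        text = yaml.safe_dump(self.raw, sort_keys=True)
        return hashlib.sha256(text.encode()).hexdigest()[:12]

    def protocol(self, name: str) -> Protocol:
        try:
            return self.protocols[name]
        except KeyError:
            raise ConfigError(f"unknown protocol {name!r}") from None


def _require(d: Mapping[str, Any], key: str, ctx: str) -> Any:
    if key not in d:
        raise ConfigError(f"missing key {key!r} in {ctx}")
    return d[key]


def parse_config(doc: Mapping[str, Any]) -> RunConfig:
    try:
        rate_sets = {
            label: RateSet(
                label,
                k_bind=float(_require(spec, "k_bind", f"rate_sets.{label}")),
                k_off20=float(_require(spec, "k_off20", f"rate_sets.{label}")),
                k_ext=float(_require(spec, "k_ext", f"rate_sets.{label}")),
                k_retr=float(_require(spec, "k_retr", f"rate_sets.{label}")),
            )
            for label, spec in _require(doc, "rate_sets", "config").items()
        }
        protocols = {}
        for name, spec in doc.get("protocols", {}).items():
            phases = []
            for ph in _require(spec, "phases", f"protocols.{name}"):
                label = _require(ph, "rate_label", f"protocols.{name}")
                if label not in rate_sets:
                    raise ConfigError(
                        f"protocols.{name} references undefined rate_label {label!r}"
                    )
                phases.append(
                    Phase(float(ph["duration"]), float(ph["fold"]), label)
                )
            protocols[name] = Protocol(
                tuple(phases),
                reference_time=float(spec.get("reference_time", 1800.0)),
            )
        lm = doc.get("length_model", {})
        obs = doc.get("observables", {})
        optics = OpticsModel(**doc.get("optics", {}))
        return RunConfig(
            lattice_length=int(_require(doc, "lattice_length", "config")),
            rate_sets=rate_sets,
            protocols=protocols,
            length_model=LengthModel(
                m=float(lm.get("m", 0.3)),
                alpha=float(lm.get("alpha", 1.9)),
                beta=float(lm.get("beta", 1.15)),
            ),
            n_rep=int(doc.get("n_rep", 100)),
            seed=int(doc.get("seed", 1)),
            sample_dt=float(doc.get("sample_dt", 5.0)),
            snapshot_times=tuple(float(t) for t in doc.get("snapshot_times", (1800.0, 2400.0))),
            gap_threshold=int(obs.get("gap_threshold", 18)),
            include_terminal=bool(obs.get("include_terminal", True)),
            gap_cutoff=float(obs.get("gap_cutoff", 30.0)),
            optics=optics,
            provenance=str(doc.get("provenance", "")),
            raw=dict(doc),
        )
    except (TypeError, ValueError) as exc:
        if isinstance(exc, ConfigError):
            raise
        raise ConfigError(str(exc)) from exc


def load_config(path) -> RunConfig:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict):
        raise ConfigError(f"config file {path} is not a mapping")
    return parse_config(doc)


def default_config() -> RunConfig:
    """The shipped configuration with the calibrated default parameters."""
    text = resources.files("rpalattice.data").joinpath("defaults.yaml").read_text()
    return parse_config(yaml.safe_load(text))
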
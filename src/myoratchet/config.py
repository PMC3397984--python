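"""Structured-text (TOML) run configuration with validated defaults.

Every numeric model parameter is configuration with a default, because
the calibrated values are conditions of the study rather than constants
of nature.  Keys carry unit suffixes; unknown keys and cross-field
violations (time step vs stiffness and rates, load range) are rejected
with errors naming the offending keys.
"""

from __future__ import annotations

import hashlib
import json
import tomllib
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

from .model_core import (
    ConfigurationError,
    ElasticSpec,
    PhysicalEnv,
    PotentialSpec,
)
from .sarcomere_ensemble import ProtocolSpec
from .sme_experiment import NeedleSpec
from .stochastic_engine import IntegratorSpec, RateSpec

# section -> (dataclass, {toml key: field name})
_KEYMAPS = {
    "env": (
        PhysicalEnv,
        {
            "kBT_pNnm": "kBT",
            "gamma_head_pNs_nm": "gamma_head",
            "Gamma_needle_pNs_nm": "Gamma_needle",
            "Gamma_backbone_pNs_nm": "Gamma_backbone",
        },
    ),
    "potential": (
        PotentialSpec,
        {
            "d_nm": "d",
            "monomers_per_period": "monomers_per_period",
            "binding_sites": "binding_sites",
            "deltaG_pNnm": "deltaG",
            "barrier_pNnm": "barrier",
            "asymmetry_lambda": "asymmetry_lambda",
            "forward_sign": "forward_sign",
        },
    ),
    "elastic": (
        ElasticSpec,
        {"kappa_plus_pN_nm": "kappa_plus", "kappa_minus_pN_nm": "kappa_minus"},
    ),
    "rates": (
        RateSpec,
        {
            "f1_per_s": "f1",
            "attach_window_nm": "attach_window",
            "g1_per_s": "g1",
            "g2_per_s": "g2",
            "rate_scale": "rate_scale",
            "mode": "mode",
        },
    ),
    "integrator": (
        IntegratorSpec,
        {"dt_s": "dt", "seed": "seed", "record_stride": "record_stride"},
    ),
    "needle": (
        NeedleSpec,
        {
            "Gamma_needle_pNs_nm": "Gamma_needle",
            "kappa_trap_pN_nm": "kappa_trap",
            "kappa_link_pN_nm": "kappa_link",
            "X0_nm": "X0",
        },
    ),
    "protocol": (
        ProtocolSpec,
        {
            "kind": "kind",
            "duration_s": "duration",
            "delta_nm": "delta",
            "t_step_s": "t_step",
            "beta": "beta",
            "n_trials": "n_trials",
            "pre_duration_s": "pre_duration",
        },
    ),
}


@dataclass
class RunConfig:
    """Fully resolved configuration for one run."""

    env: PhysicalEnv = field(default_factory=PhysicalEnv)
    potential: PotentialSpec = field(default_factory=PotentialSpec)
    elastic: ElasticSpec = field(default_factory=ElasticSpec)
    rates: RateSpec = field(default_factory=RateSpec)
    integrator: IntegratorSpec = field(default_factory=IntegratorSpec)
    needle: NeedleSpec = field(default_factory=NeedleSpec)
    protocol: ProtocolSpec | None = None
    N: int = 64
    out_dir: str = "."

    def validate(self) -> "RunConfig":
        """Cross-field checks beyond per-spec invariants."""
        self.integrator.validate_against(
            self.env, self.potential, self.elastic, self.rates
        )
        if self.N < 1:
            raise ConfigurationError("run.N: need at least one motor")
        return self

    def resolved(self) -> dict:
        out: dict = {}
        for section, (_, keymap) in _KEYMAPS.items():
            obj = getattr(self, section)
            if obj is None:
                continue
            d = asdict(obj)
            out[section] = {k: d[f] for k, f in keymap.items() if f in d}
        out["run"] = {"N": self.N, "out_dir": self.out_dir}
        return out

    def hash(self) -> str:
        blob = json.dumps(self.resolved(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def load_config(path: str | Path | None) -> RunConfig:
    """Parse and validate a TOML config; ``None`` yields all defaults.

    Unknown sections or keys raise a :class:`ConfigurationError` naming
    them; all defaults are resolved so the returned config is complete.
    """
    raw: dict = {}
    if path is not None:
        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
    cfg = RunConfig()
    for section, content in raw.items():
        if section == "run":
            for key, val in content.items():
                if key == "N":
                    cfg.N = int(val)
                elif key == "out_dir":
                    cfg.out_dir = str(val)
                else:
                    raise ConfigurationError(f"run.{key}: unknown key")
            continue
        if section not in _KEYMAPS:
            raise ConfigurationError(f"{section}: unknown section")
        cls, keymap = _KEYMAPS[section]
        kwargs = {}
        for key, val in content.items():
            if key not in keymap:
                raise ConfigurationError(f"{section}.{key}: unknown key")
            kwargs[key] = val
        mapped = {keymap[k]: v for k, v in kwargs.items()}
        if section == "protocol":
            setattr(cfg, section, cls(**mapped))
        else:
            base = asdict(getattr(cfg, section))
            base.update(mapped)
            setattr(cfg, section, cls(**base))
    return cfg.validate()


def save_config(cfg: RunConfig, path: str | Path) -> None:
    """Write the resolved config back as TOML (round-trips via load_config)."""
    lines: list[str] = []
    for section, content in cfg.resolved().items():
        lines.append(f"[{section}]")
        for key, val in content.items():
            if isinstance(val, str):
                lines.append(f'{key} = "{val}"')
            elif isinstance(val, bool):
                lines.append(f"{key} = {'true' if val else 'false'}")
            else:
                lines.append(f"{key} = {val!r}")
        lines.append("")
    Path(path).write_text("\n".join(lines))
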
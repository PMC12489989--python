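"""Run configuration: presets, YAML round-tripping, model construction.

Config files are plain YAML with explicit unit suffixes on every physical
quantity (``radius_A``, ``molarity_M``, ...) to keep Å/nm and mV/k_BT
confusion out of the input layer.  The packaged ``presets.yaml`` provides
the default solvent and B-DNA parameter sets.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import yaml

from .dielectric import ElectrolyteSpec, WaterDielectricParams, debye_kappa
from .helix import (BoundWaterPattern, CounterionPattern, HelixChargeModel,
                    HelixGeometry, PhosphatePattern)

__all__ = ["RunConfig", "load_defaults", "solvent_from_config",
           "model_from_config", "electrolyte_from_config"]


def load_defaults() -> dict:
    """The packaged default configuration (parsed presets.yaml)."""
    text = importlib.resources.files("helixfield").joinpath("presets.yaml") \
        .read_text()
    return yaml.safe_load(text)


def solvent_from_config(cfg: dict, preset: str = "tip3p") -> WaterDielectricParams:
    s = cfg["solvents"][preset]
    return WaterDielectricParams.from_lambda_osc(
        eps_bulk=s["eps_bulk"], eps_star=s["eps_star"],
        lambda1=s["lambda1_A"], lambda2=s["lambda2_A"],
        lambda_osc=s["lambda_osc_A"], gamma=s["gamma"],
    )


def model_from_config(cfg: dict) -> HelixChargeModel:
    h = cfg["helix"]
    geom = HelixGeometry(pitch=h["pitch_A"], rise=h["rise_A"],
                         phi_s=h["phi_s_rad"])
    p = h["phosphates"]
    phos = PhosphatePattern(sigma_bar=p["sigma_bar_uC_cm2"],
                            delta_eff=p["delta_eff_A"], radius=p["radius_A"],
                            delta_a=p["delta_a_A"])
    cc = None
    if h.get("counterions"):
        c = h["counterions"]
        cc = CounterionPattern(theta=c["theta"], f1=c["f1"], f2=c["f2"],
                               f3=c.get("f3", 0.0), f4=c.get("f4", 0.0),
                               dz1=c["dz1_A"], dz2=c["dz2_A"],
                               dz3=c.get("dz3_A", 0.75),
                               radius=c["radius_A"], delta_a=c["delta_a_A"])
    bw = None
    if h.get("bound_water"):
        b = h["bound_water"]
        bw = BoundWaterPattern(p0=b["p0_uC_cm2"], w1=b["w1"], w2=b["w2"],
                               dzw1=b["dzw1_A"], dzw2=b["dzw2_A"],
                               radius=b["radius_A"], delta_a=b["delta_a_A"])
    return HelixChargeModel(geom, phos, cc, bw)


def electrolyte_from_config(cfg: dict) -> ElectrolyteSpec:
    e = cfg["electrolyte"]
    return ElectrolyteSpec(
        molarity=e["molarity_M"],
        species=tuple((int(z), int(nu)) for z, nu in e["species"]),
        temperature=e["temperature_K"],
        eps_for_screening=e["eps_for_screening"],
    )


@dataclass
class RunConfig:
    """Fully resolved run configuration; round-trips losslessly via YAML."""

    config: dict = field(default_factory=load_defaults)
    solvent_preset: str = "tip3p"
    n_max: int = 50
    seed: int = 0

    def to_yaml(self, path) -> None:
        payload = dict(self.config)
        payload["_run"] = {"solvent_preset": self.solvent_preset,
                           "n_max": self.n_max, "seed": self.seed}
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh)
        run = payload.pop("_run", {})
        return cls(config=payload,
                   solvent_preset=run.get("solvent_preset", "tip3p"),
                   n_max=run.get("n_max", 50), seed=run.get("seed", 0))

    # resolved objects -----------------------------------------------------
    @property
    def water(self) -> WaterDielectricParams:
        return solvent_from_config(self.config, self.solvent_preset)

    @property
    def model(self) -> HelixChargeModel:
        return model_from_config(self.config)

    @property
    def electrolyte(self) -> ElectrolyteSpec:
        return electrolyte_from_config(self.config)

    @property
    def kappa(self) -> float:
        return debye_kappa(self.electrolyte)
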
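"""Simulation parameters and their file format.

All quantities are in dimensionless simulation units: the length unit is the
rest length of one chain bond (0.2 µm at the documented conversion), the
energy unit is kBT at the default temperature, the friction coefficient per
node is 1, and the time unit is friction·length²/energy.  The Langevin noise
amplitude per step is sqrt(2·kBT·dt/friction) and is derived, not set.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path

import yaml

__all__ = ["SimulationConfig", "load_config", "save_config"]


@dataclass
class SimulationConfig:
    """All mechanical, geometric, kinetic and run-control parameters.

    Defaults describe the standard two-pair experiment: stiff bonds
    (``k_spring=100``), bending rigidity calibrated to a persistence length of
    ~5 length units (1 µm), a nucleus of radius 12 (2.4 µm), strong Rabl
    centromere clustering, and reversible pairing at ``p_unpair=0.8``.
    """

    n_pairs: int = 2
    nodes_per_arm: int = 48
    k_spring: float = 100.0
    # Calibrated so the measured persistence length is ~8 length units
    # (1.6 um), inside the plateau where mismatch discrimination works.
    k_bend: float = 25.0
    k_pair: float = 20.0
    k_confine: float = 100.0
    k_tether: float = 100.0
    friction: float = 1.0
    kBT: float = 1.0
    # Explicit Euler-Maruyama stability: the stiffest longitudinal chain mode
    # has Hessian eigenvalue ~4*k_spring, so dt must stay below
    # 2*friction/(4*k_spring) = 0.005 at the default stiffness.
    dt: float = 0.002
    # Diameter matches the chain contour (47 bonds) so a tethered chain can
    # span the nucleus pole-to-pole and genomic position maps linearly to z.
    nucleus_radius: float = 24.0
    # Centromere cluster of ~1 um extent: tight enough for a strong Rabl
    # gradient, loose enough that chains are not forced into one bundle.
    rabl_patch_radius: float = 5.0
    capture_radius: float = 1.0
    p_unpair: float = 0.8
    rest_length: float = 1.0
    n_steps: int = 300_000
    record_every: int = 1000
    burn_in_steps: int = 5000
    seed: int = 0
    # Documentation constant only: micrometres per length unit.
    length_unit_um: float = 0.2

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        positive = (
            "k_spring k_bend k_pair k_confine k_tether friction kBT dt "
            "nucleus_radius rabl_patch_radius capture_radius rest_length"
        ).split()
        for name in positive:
            value = getattr(self, name)
            if name == "k_bend":
                if value < 0:
                    raise ValueError("k_bend must be >= 0")
                continue
            if not (value > 0) or not math.isfinite(value):
                raise ValueError(f"{name} must be strictly positive, got {value!r}")
        if not 0.0 <= self.p_unpair <= 1.0:
            raise ValueError(f"p_unpair must be in [0, 1], got {self.p_unpair!r}")
        if self.n_pairs < 1:
            raise ValueError("n_pairs must be >= 1")
        if self.nodes_per_arm < 2:
            raise ValueError("nodes_per_arm must be >= 2")
        if self.n_steps < 0 or self.record_every < 1 or self.burn_in_steps < 0:
            raise ValueError("n_steps >= 0, record_every >= 1, burn_in_steps >= 0 required")
        if self.rabl_patch_radius > 2.0 * self.nucleus_radius:
            raise ValueError(
                "rabl_patch_radius must be <= 2*nucleus_radius "
                "(2R means no Rabl constraint)"
            )

    @property
    def noise_sigma(self) -> float:
        """Per-step Langevin displacement scale sqrt(2*kBT*dt/friction)."""
        return math.sqrt(2.0 * self.kBT * self.dt / self.friction)

    @property
    def rabl_disabled(self) -> bool:
        """True when the centromere patch covers the whole envelope."""
        return self.rabl_patch_radius >= 2.0 * self.nucleus_radius

    def replace(self, **changes) -> "SimulationConfig":
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def load_config(path: str | Path) -> SimulationConfig:
    """Read a flat key-value YAML file into a :class:`SimulationConfig`.

    Every field of the dataclass has a key of the same name; keys not in the
    dataclass are an error (typos must not pass silently).
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"config file {path} must contain a mapping")
    known = {f.name for f in dataclasses.fields(SimulationConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return SimulationConfig(**raw)


def save_config(config: SimulationConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)
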
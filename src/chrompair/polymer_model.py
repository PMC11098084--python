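"""Mechanical model: chain/pairing state types and force/energy terms.

The chromosome is a bead-spring worm-like chain.  Adjacent nodes are linked
by Hookean springs of stiffness ``k_spring`` and rest length 1; bending is a
penalty on the deviation of each interior node from the midpoint of its
neighbours (stiffness ``k_bend``); chains are confined to a spherical nucleus
by a harmonic wall and each chain's centromere node is tethered to a spherical
cap around the +z pole of the envelope (the Rabl patch).  Paired buttons are
linked by zero-rest-length springs of stiffness ``k_pair``.

All force functions return plain ``(n_nodes, 3)`` arrays (or a list of them,
aligned with the input chain sequence) and are the exact negative gradient of
:func:`elastic_energy`; a finite-difference test holds this to 1e-4 relative.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import SimulationConfig

__all__ = [
    "ChainState",
    "PairingState",
    "spring_forces",
    "bending_forces",
    "confinement_forces",
    "tether_forces",
    "pairing_forces",
    "elastic_energy",
    "nearest_cap_point",
]


@dataclass
class ChainState:
    """One chromosome arm: node coordinates plus its button barcode.

    ``buttons`` holds the strictly increasing node indices that are adhesive;
    the pattern of gaps between them is the chromosome's barcode.  Exactly two
    chains share each ``homolog_id``.
    """

    positions: np.ndarray  # (n_nodes, 3)
    buttons: np.ndarray  # strictly increasing node indices
    homolog_id: int
    chain_id: int
    centromere_index: int = 0

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.buttons = np.asarray(self.buttons, dtype=np.int64)
        n = len(self.positions)
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise ValueError("positions must be an (n_nodes, 3) array")
        if len(self.buttons) and (
            self.buttons.min() < 0
            or self.buttons.max() >= n
            or np.any(np.diff(self.buttons) <= 0)
        ):
            raise ValueError("buttons must be strictly increasing indices in range")
        if not 0 <= self.centromere_index < n:
            raise ValueError("centromere_index out of range")

    @property
    def n_nodes(self) -> int:
        return len(self.positions)


Endpoint = tuple[int, int]  # (chain_id, button node index)


@dataclass
class PairingState:
    """Current one-to-one bonds between buttons.

    Bonds are unordered pairs of ``(chain_id, button_index)`` endpoints; each
    endpoint appears in at most one bond.  Bonds within one chain (cis) are
    permitted and are counted as incorrect pairing by the analysis module.
    """

    bonds: set = field(default_factory=set)

    def __post_init__(self) -> None:
        self.bonds = {self._norm(b) for b in self.bonds}
        self._check_exclusive()

    @staticmethod
    def _norm(bond) -> tuple[Endpoint, Endpoint]:
        a, b = sorted(tuple(map(tuple, bond)))
        if a == b:
            raise ValueError(f"bond endpoints must differ: {bond}")
        return (a, b)

    def _check_exclusive(self) -> None:
        seen: set[Endpoint] = set()
        for a, b in self.bonds:
            for ep in (a, b):
                if ep in seen:
                    raise ValueError(f"endpoint {ep} appears in more than one bond")
                seen.add(ep)

    def partner_of(self, endpoint: Endpoint) -> Endpoint | None:
        endpoint = tuple(endpoint)
        for a, b in self.bonds:
            if a == endpoint:
                return b
            if b == endpoint:
                return a
        return None

    def add(self, ep_a: Endpoint, ep_b: Endpoint) -> None:
        self.bonds.add(self._norm((ep_a, ep_b)))
        self._check_exclusive()

    def copy(self) -> "PairingState":
        return PairingState(set(self.bonds))

    def __len__(self) -> int:
        return len(self.bonds)


def _require_nodes(chain: ChainState, minimum: int) -> None:
    if chain.n_nodes < minimum:
        raise ValueError("degenerate chain")


def spring_forces(
    chain: ChainState, k_spring: float, rest_length: float = 1.0
) -> np.ndarray:
    """Hookean backbone forces, equal and opposite across each bond."""
    _require_nodes(chain, 2)
    if rest_length <= 0:
        raise ValueError("rest_length must be positive")
    x = chain.positions
    forces = np.zeros_like(x)
    bond = x[1:] - x[:-1]
    d = np.linalg.norm(bond, axis=1)
    # f on node i points toward node i+1 when the bond is stretched
    scale = k_spring * (d - rest_length) / np.where(d > 0, d, 1.0)
    f = scale[:, None] * bond
    forces[:-1] += f
    forces[1:] -= f
    return forces


def bending_forces(chain: ChainState, k_bend: float) -> np.ndarray:
    """Worm-like-chain straightening forces.

    Each interior node is pulled toward the midpoint of its neighbours with
    stiffness ``k_bend``; the neighbours receive the half-strength reaction,
    so the total over the chain vanishes.
    """
    _require_nodes(chain, 3)
    x = chain.positions
    forces = np.zeros_like(x)
    mid = 0.5 * (x[:-2] + x[2:])
    v = x[1:-1] - mid
    forces[1:-1] -= k_bend * v
    forces[:-2] += 0.5 * k_bend * v
    forces[2:] += 0.5 * k_bend * v
    return forces


def confinement_forces(
    chains, nucleus_radius: float, k_confine: float
) -> list[np.ndarray]:
    """Harmonic wall at the nuclear envelope, radially inward outside R."""
    out = []
    for chain in chains:
        x = chain.positions
        r = np.linalg.norm(x, axis=1)
        forces = np.zeros_like(x)
        outside = r > nucleus_radius
        if np.any(outside):
            unit = x[outside] / r[outside, None]
            forces[outside] = -k_confine * (r[outside] - nucleus_radius)[:, None] * unit
        out.append(forces)
    return out


def nearest_cap_point(
    x: np.ndarray, nucleus_radius: float, rabl_patch_radius: float
) -> np.ndarray:
    """Nearest point of the Rabl cap (the envelope cap around the +z pole
    whose chord radius is ``rabl_patch_radius``) to position ``x``."""
    R = nucleus_radius
    # chord c = 2 R sin(theta/2) -> cap half-angle
    theta_c = 2.0 * np.arcsin(min(1.0, rabl_patch_radius / (2.0 * R)))
    rxy = float(np.hypot(x[0], x[1]))
    if rxy < 1e-12 and abs(x[2]) < 1e-12:
        return np.array([0.0, 0.0, R])  # origin: every cap point is at R; pick pole
    theta = float(np.arctan2(rxy, x[2]))
    theta_n = min(theta, theta_c)
    if rxy < 1e-12:
        ux, uy = 1.0, 0.0
    else:
        ux, uy = x[0] / rxy, x[1] / rxy
    s, c = np.sin(theta_n), np.cos(theta_n)
    return np.array([R * s * ux, R * s * uy, R * c])


def tether_forces(
    chains, rabl_patch_radius: float, k_tether: float, nucleus_radius: float
) -> list[np.ndarray]:
    """Restoring force pulling each centromere to the Rabl cap.

    A patch radius of 2R (full envelope) disables the constraint entirely:
    the returned forces are zero everywhere.
    """
    out = []
    disabled = rabl_patch_radius >= 2.0 * nucleus_radius
    for chain in chains:
        forces = np.zeros_like(chain.positions)
        if not disabled:
            i = chain.centromere_index
            p = nearest_cap_point(chain.positions[i], nucleus_radius, rabl_patch_radius)
            forces[i] = k_tether * (p - chain.positions[i])
        out.append(forces)
    return out


def pairing_forces(chains, pairing: PairingState, k_pair: float) -> list[np.ndarray]:
    """Zero-rest-length springs between bonded buttons (equal and opposite)."""
    by_id = {c.chain_id: (i, c) for i, c in enumerate(chains)}
    out = [np.zeros_like(c.positions) for c in chains]
    for (cid_a, node_a), (cid_b, node_b) in pairing.bonds:
        ia, ca = by_id[cid_a]
        ib, cb = by_id[cid_b]
        d = cb.positions[node_b] - ca.positions[node_a]
        out[ia][node_a] += k_pair * d
        out[ib][node_b] -= k_pair * d
    return out


def total_forces(
    chains, pairing: PairingState, config: SimulationConfig
) -> list[np.ndarray]:
    """Sum of all force terms, aligned with the input chain sequence."""
    out = []
    for c in chains:
        f = spring_forces(c, config.k_spring, config.rest_length)
        if c.n_nodes >= 3:
            f = f + bending_forces(c, config.k_bend)
        out.append(f)
    for term in (
        confinement_forces(chains, config.nucleus_radius, config.k_confine),
        tether_forces(
            chains, config.rabl_patch_radius, config.k_tether, config.nucleus_radius
        ),
        pairing_forces(chains, pairing, config.k_pair),
    ):
        for f, t in zip(out, term):
            f += t
    return out


def elastic_energy(
    chains, pairing: PairingState, config: SimulationConfig
) -> float:
    """Total potential energy (kBT units) of the configuration.

    Sum of stretch ½k_s(d−d₀)², bending ½k_bend|xᵢ−midpoint|², pairing-bond
    ½k_pair·d², confinement ½k_confine(|x|−R)² outside the nucleus, and the
    centromere-tether penalty ½k_tether·dist(x, cap)².  Zero for straight
    rest-length chains inside the nucleus with centromeres in the patch and
    no strained bonds; forces above are its exact negative gradient.
    """
    e = 0.0
    R = config.nucleus_radius
    for chain in chains:
        x = chain.positions
        d = np.linalg.norm(x[1:] - x[:-1], axis=1)
        e += 0.5 * config.k_spring * np.sum((d - config.rest_length) ** 2)
        if chain.n_nodes >= 3:
            mid = 0.5 * (x[:-2] + x[2:])
            e += 0.5 * config.k_bend * np.sum((x[1:-1] - mid) ** 2)
        r = np.linalg.norm(x, axis=1)
        outside = r > R
        e += 0.5 * config.k_confine * np.sum((r[outside] - R) ** 2)
        if not config.rabl_disabled:
            xc = x[chain.centromere_index]
            p = nearest_cap_point(xc, R, config.rabl_patch_radius)
            e += 0.5 * config.k_tether * float(np.sum((p - xc) ** 2))
    by_id = {c.chain_id: c for c in chains}
    for (cid_a, node_a), (cid_b, node_b) in pairing.bonds:
        d2 = np.sum(
            (by_id[cid_b].positions[node_b] - by_id[cid_a].positions[node_a]) ** 2
        )
        e += 0.5 * config.k_pair * float(d2)
    return float(e)
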
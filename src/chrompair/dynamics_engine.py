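"""Overdamped Langevin integration, initialization and trajectory recording.

Positions evolve by Euler–Maruyama:

    x ← x + (dt/γ)·F_total(x) + sqrt(2·kBT·dt/γ)·η,   η ~ N(0, I₃)

with F_total the sum of spring, bending, confinement, tether and
pairing-bond forces.  Each iteration first updates the bond set (pairing
kinetics), then evaluates forces, then moves the nodes.  The first
``burn_in_steps`` iterations run with pairing disabled so the initial
geometry equilibrates before adhesion begins.  Runs are bit-reproducible for
a fixed seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import _kernel
from .barcode import Barcode, random_barcode, uniform_barcode
from .config import SimulationConfig
from .pairing import update_pairing
from .polymer_model import ChainState, PairingState, total_forces

__all__ = [
    "Trajectory",
    "initialize",
    "step",
    "run",
    "default_barcodes",
    "write_trajectory_csv",
    "read_trajectory_csv",
    "write_trajectory_xyz",
]


@dataclass
class Trajectory:
    """Time-sampled snapshots of all chains and bonds for one run.

    Stored in array form for analysis speed: ``positions`` is
    ``(n_frames, n_chains, n_nodes, 3)`` and ``partners`` maps each flattened
    button to the flat index of its bonded partner (−1 when free).  The
    ``frames`` iterator reconstructs ``(step, [ChainState...], PairingState)``
    tuples on demand.
    """

    config: SimulationConfig
    buttons: list  # per chain: np.ndarray of button node indices
    steps: np.ndarray  # (F,)
    positions: np.ndarray  # (F, C, N, 3)
    partners: np.ndarray  # (F, B) flat button index or -1
    btn_chain: np.ndarray  # (B,) chain index of each flat button
    btn_node: np.ndarray  # (B,) node index of each flat button

    @property
    def n_frames(self) -> int:
        return len(self.steps)

    @property
    def n_chains(self) -> int:
        return self.positions.shape[1]

    def homolog_id(self, chain_id: int) -> int:
        return chain_id // 2

    def chain_states(self, frame: int) -> list[ChainState]:
        return [
            ChainState(
                positions=self.positions[frame, c].copy(),
                buttons=self.buttons[c],
                homolog_id=c // 2,
                chain_id=c,
            )
            for c in range(self.n_chains)
        ]

    def pairing_state(self, frame: int) -> PairingState:
        bonds = set()
        row = self.partners[frame]
        for b in range(len(row)):
            pb = row[b]
            if pb > b:
                bonds.add(
                    (
                        (int(self.btn_chain[b]), int(self.btn_node[b])),
                        (int(self.btn_chain[pb]), int(self.btn_node[pb])),
                    )
                )
        return PairingState(bonds)

    def frame(self, i: int):
        i = int(i)
        return int(self.steps[i]), self.chain_states(i), self.pairing_state(i)

    @property
    def frames(self):
        for i in range(self.n_frames):
            yield self.frame(i)


def default_barcodes(config: SimulationConfig) -> list[Barcode]:
    """One barcode per homolog pair: the uniform 3- vs 4-spacing whole-arm
    pair for the first two, random five-button codes (fixed per-pair seeds)
    for any additional pairs."""
    out = []
    for p in range(config.n_pairs):
        if p == 0:
            out.append(uniform_barcode(3, config.nodes_per_arm))
        elif p == 1:
            out.append(uniform_barcode(4, config.nodes_per_arm))
        else:
            rng = np.random.default_rng(np.random.SeedSequence([90_000, p]))
            out.append(
                random_barcode(
                    5, (0, 12), rng, arm_length=config.nodes_per_arm
                )
            )
    return out


def _resolve_barcodes(config: SimulationConfig, barcodes) -> list[Barcode]:
    """Accept one barcode per pair (homologs identical) or one per chain."""
    if barcodes is None:
        barcodes = default_barcodes(config)
    barcodes = list(barcodes)
    if len(barcodes) == config.n_pairs:
        barcodes = [bc for bc in barcodes for _ in range(2)]
    if len(barcodes) != 2 * config.n_pairs:
        raise ValueError(
            f"expected {config.n_pairs} (per-pair) or {2 * config.n_pairs} "
            f"(per-chain) barcodes, got {len(barcodes)}"
        )
    for bc in barcodes:
        if bc.arm_length != config.nodes_per_arm:
            raise ValueError("barcode arm_length must equal nodes_per_arm")
    return barcodes


def _sample_cap(rng: np.random.Generator, R: float, patch_radius: float) -> np.ndarray:
    """Uniform point on the envelope cap of chord radius ``patch_radius``."""
    half = min(1.0, patch_radius / (2.0 * R))
    cos_tc = 1.0 - 2.0 * half * half  # cos of the cap half-angle
    cos_t = 1.0 - rng.random() * (1.0 - cos_tc)
    sin_t = np.sqrt(max(0.0, 1.0 - cos_t * cos_t))
    phi = 2.0 * np.pi * rng.random()
    return R * np.array([sin_t * np.cos(phi), sin_t * np.sin(phi), cos_t])


def initialize(
    config: SimulationConfig,
    rng: np.random.Generator,
    barcodes=None,
    allow_wall_fold: bool = True,
):
    """Place chains in a Rabl starting layout and return them with an empty
    bond set.

    Each centromere is sampled on the envelope inside the Rabl patch and the
    chain extends inward (toward −z for a polar patch) at rest length with
    lateral jitter of amplitude 0.1.  Chains longer than the nuclear diameter
    fold tangentially along the wall; with folding disabled such a geometry
    is an error.
    """
    barcodes = _resolve_barcodes(config, barcodes)
    R = config.nucleus_radius
    margin = 0.5
    contour = (config.nodes_per_arm - 1) * config.rest_length
    if not allow_wall_fold and contour > 2 * R - margin:
        raise ValueError("geometry infeasible: chain contour exceeds nucleus diameter")
    chains = []
    for c in range(2 * config.n_pairs):
        x0 = _sample_cap(rng, R, min(config.rabl_patch_radius, 2 * R))
        pos = np.empty((config.nodes_per_arm, 3))
        pos[0] = x0
        d = -x0 / np.linalg.norm(x0)  # inward; ~ -z for a polar patch
        for i in range(1, config.nodes_per_arm):
            jitter = 0.1 * rng.standard_normal(3)
            jitter -= d * np.dot(jitter, d)  # lateral only
            di = d + jitter
            di /= np.linalg.norm(di)
            p = pos[i - 1] + config.rest_length * di
            if np.linalg.norm(p) > R - margin:
                if not allow_wall_fold:
                    raise ValueError(
                        "geometry infeasible: straight placement exits the nucleus"
                    )
                n = pos[i - 1] / np.linalg.norm(pos[i - 1])
                t = di - np.dot(di, n) * n
                if np.linalg.norm(t) < 1e-9:
                    t = np.cross(n, np.array([0.0, 0.0, 1.0]))
                    if np.linalg.norm(t) < 1e-9:
                        t = np.cross(n, np.array([1.0, 0.0, 0.0]))
                di = t / np.linalg.norm(t) - 0.15 * n
                di /= np.linalg.norm(di)
                p = pos[i - 1] + config.rest_length * di
            pos[i] = p
            d = di
        chains.append(
            ChainState(
                positions=pos,
                buttons=barcodes[c].as_array(),
                homolog_id=c // 2,
                chain_id=c,
            )
        )
    return chains, PairingState(set())


def step(chains, pairing: PairingState, config: SimulationConfig, rng):
    """One Euler–Maruyama position update (reference implementation)."""
    forces = total_forces(chains, pairing, config)
    mob = config.dt / config.friction
    sigma = config.noise_sigma
    out = []
    for chain, f in zip(chains, forces):
        noise = rng.standard_normal(chain.positions.shape) if sigma > 0 else 0.0
        new = chain.positions + mob * f + sigma * noise
        if not np.all(np.isfinite(new)):
            raise FloatingPointError("numerical blow-up: reduce dt")
        out.append(
            ChainState(
                positions=new,
                buttons=chain.buttons,
                homolog_id=chain.homolog_id,
                chain_id=chain.chain_id,
                centromere_index=chain.centromere_index,
            )
        )
    return out


def run(
    config: SimulationConfig,
    barcodes=None,
    pairing_enabled: bool = True,
) -> Trajectory:
    """Run a full simulation and return its trajectory.

    Alternates pairing-kinetics updates and position updates for
    ``config.n_steps`` iterations, recording every ``config.record_every``
    steps (plus the initial state).  ``pairing_enabled=False`` gives the
    no-adhesion calibration runs used for persistence-length and Rabl
    measurements.
    """
    rng = np.random.default_rng(config.seed)
    barcodes_resolved = _resolve_barcodes(config, barcodes)
    min_gap = min(bc.min_gap() for bc in barcodes_resolved)
    if config.capture_radius >= min_gap * config.rest_length:
        warnings.warn(
            "capture_radius >= smallest inter-button rest distance: adjacent "
            "cis buttons start in contact range",
            stacklevel=2,
        )
    chains, _ = initialize(config, rng, barcodes_resolved)
    pos = np.stack([c.positions for c in chains])
    btn_chain = np.concatenate(
        [np.full(len(c.buttons), i, dtype=np.int64) for i, c in enumerate(chains)]
    )
    btn_node = np.concatenate([c.buttons for c in chains]).astype(np.int64)
    B = len(btn_chain)
    partner = np.full(B, -1, dtype=np.int64)

    n_frames = config.n_steps // config.record_every + 1
    rec_pos = np.empty((n_frames, *pos.shape))
    rec_partner = np.empty((n_frames, B), dtype=np.int64)
    rec_steps = np.empty(n_frames, dtype=np.int64)

    theta_c = 2.0 * np.arcsin(
        min(1.0, config.rabl_patch_radius / (2.0 * config.nucleus_radius))
    )
    kernel_seed = int(rng.integers(2**31))
    result = _kernel.simulate(
        pos, btn_chain, btn_node, partner,
        config.k_spring, config.k_bend, config.k_pair,
        config.k_confine, config.k_tether,
        config.rest_length, config.friction, config.kBT, config.dt,
        config.nucleus_radius, theta_c, not config.rabl_disabled,
        config.capture_radius, config.p_unpair,
        config.n_steps, config.record_every, config.burn_in_steps,
        pairing_enabled, kernel_seed,
        rec_pos, rec_partner, rec_steps,
    )
    if result < 0:
        raise FloatingPointError(
            f"numerical blow-up: reduce dt (non-finite coordinates by step {-result})"
        )
    return Trajectory(
        config=config,
        buttons=[c.buttons for c in chains],
        steps=rec_steps[:result].copy(),
        positions=rec_pos[:result].copy(),
        partners=rec_partner[:result].copy(),
        btn_chain=btn_chain,
        btn_node=btn_node,
    )


def write_trajectory_csv(traj: Trajectory, path) -> None:
    """One row per node per frame; partner columns are empty when unpaired."""
    F, C, N, _ = traj.positions.shape
    flat_lookup = {
        (int(traj.btn_chain[b]), int(traj.btn_node[b])): b
        for b in range(len(traj.btn_chain))
    }
    rows = []
    for f in range(F):
        partner_row = traj.partners[f]
        for c in range(C):
            button_set = set(int(b) for b in traj.buttons[c])
            for n in range(N):
                is_btn = n in button_set
                pc, pn = "", ""
                if is_btn:
                    pb = partner_row[flat_lookup[(c, n)]]
                    if pb >= 0:
                        pc = int(traj.btn_chain[pb])
                        pn = int(traj.btn_node[pb])
                x, y, z = traj.positions[f, c, n]
                rows.append(
                    (int(traj.steps[f]), c, n, x, y, z, int(is_btn), pc, pn)
                )
    pd.DataFrame(
        rows,
        columns=[
            "step", "chain_id", "node_index", "x", "y", "z",
            "is_button", "partner_chain", "partner_button",
        ],
    ).to_csv(path, index=False)


def read_trajectory_csv(path, config: SimulationConfig | None = None) -> Trajectory:
    """Rebuild a :class:`Trajectory` from the CSV writer's output.

    The CSV carries no parameter block; pass the run's config when metrics
    need it (defaults are assumed otherwise).  Homolog identity follows the
    chain-numbering convention: chains 2p and 2p+1 form pair p.
    """
    df = pd.read_csv(path)
    steps = np.sort(df["step"].unique())
    chains = np.sort(df["chain_id"].unique())
    n_nodes = int(df["node_index"].max()) + 1
    first = df[df["step"] == steps[0]].sort_values(["chain_id", "node_index"])
    buttons = [
        first[(first["chain_id"] == c) & (first["is_button"] == 1)][
            "node_index"
        ].to_numpy(dtype=np.int64)
        for c in chains
    ]
    btn_chain = np.concatenate(
        [np.full(len(b), i, dtype=np.int64) for i, b in enumerate(buttons)]
    )
    btn_node = np.concatenate(buttons).astype(np.int64) if len(btn_chain) else np.empty(0, np.int64)
    flat_lookup = {
        (int(btn_chain[b]), int(btn_node[b])): b for b in range(len(btn_chain))
    }
    F, C = len(steps), len(chains)
    positions = np.empty((F, C, n_nodes, 3))
    partners = np.full((F, len(btn_chain)), -1, dtype=np.int64)
    df = df.sort_values(["step", "chain_id", "node_index"])
    xyz = df[["x", "y", "z"]].to_numpy().reshape(F, C, n_nodes, 3)
    positions[:] = xyz
    btn_rows = df[df["is_button"] == 1]
    for f, s in enumerate(steps):
        sub = btn_rows[btn_rows["step"] == s]
        paired = sub[sub["partner_chain"].notna() & (sub["partner_chain"] != "")]
        for _, row in paired.iterrows():
            b = flat_lookup[(int(row["chain_id"]), int(row["node_index"]))]
            partners[f, b] = flat_lookup[
                (int(float(row["partner_chain"])), int(float(row["partner_button"])))
            ]
    if config is None:
        config = SimulationConfig(
            n_pairs=max(1, C // 2),
            nodes_per_arm=n_nodes,
            n_steps=int(steps[-1]),
            record_every=int(steps[1] - steps[0]) if F > 1 else 1,
        )
    return Trajectory(
        config=config,
        buttons=buttons,
        steps=steps.astype(np.int64),
        positions=positions,
        partners=partners,
        btn_chain=btn_chain,
        btn_node=btn_node,
    )


def write_trajectory_xyz(traj: Trajectory, path) -> None:
    """Multi-frame XYZ export for molecular viewers.

    Element labels: ``B`` button node, ``C`` non-button node, per chain in
    order; viewers color buttons apart from backbone.
    """
    F, C, N, _ = traj.positions.shape
    with open(path, "w") as fh:
        for f in range(F):
            fh.write(f"{C * N}\n")
            fh.write(f"step={int(traj.steps[f])}\n")
            for c in range(C):
                button_set = set(int(b) for b in traj.buttons[c])
                for n in range(N):
                    label = "B" if n in button_set else "C"
                    x, y, z = traj.positions[f, c, n]
                    fh.write(f"{label} {x:.4f} {y:.4f} {z:.4f}\n")
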
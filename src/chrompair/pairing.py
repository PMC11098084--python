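"""Reversible, fully nonspecific adhesion kinetics between buttons.

Any button may bond any other button — on the homolog, on a nonhomolog, or
on its own chain (cis).  Selectivity never enters the kinetics; it emerges
from polymer mechanics.  Each iteration has two phases: every existing bond
dissolves independently with probability ``p_unpair``, then free buttons
within the capture radius are matched greedily, nearest pair first (a
deterministic surrogate for diffusion-limited binding), keeping the bond set
one-to-one.  Formation on contact is certain: reversibility is the single
kinetic knob.
"""

from __future__ import annotations

import numpy as np

from .config import SimulationConfig
from .polymer_model import PairingState, pairing_forces

__all__ = ["update_pairing", "pairing_forces", "candidate_pairs"]


def candidate_pairs(chains, free: set, capture_radius: float):
    """All unordered free-button pairs within the capture radius, as
    ``(distance, endpoint_a, endpoint_b)`` with endpoints in lexicographic
    order (used for deterministic tie-breaking)."""
    endpoints = sorted(free)
    pos = {c.chain_id: c.positions for c in chains}
    out = []
    for i in range(len(endpoints)):
        cid_a, node_a = endpoints[i]
        xa = pos[cid_a][node_a]
        for j in range(i + 1, len(endpoints)):
            cid_b, node_b = endpoints[j]
            d = float(np.linalg.norm(pos[cid_b][node_b] - xa))
            if d <= capture_radius:
                out.append((d, endpoints[i], endpoints[j]))
    return out


def update_pairing(
    chains,
    pairing: PairingState,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> PairingState:
    """One break/formation cycle; returns the new bond set.

    Break phase: each bond dissolves with probability ``p_unpair`` (so bond
    lifetimes are geometric with mean 1/p_unpair iterations).  Formation
    phase: candidate free-button pairs within ``capture_radius`` bond in
    order of increasing 3D distance, skipping pairs whose endpoints were
    already taken; exact distance ties break lexicographically.  A freshly
    broken pair whose endpoints are still in capture range may re-bond in the
    same iteration (which is why pairing persists even at ``p_unpair = 1``).
    """
    surviving = set()
    for bond in sorted(pairing.bonds):
        if rng.random() >= config.p_unpair:
            surviving.add(bond)
    bound = {ep for bond in surviving for ep in bond}
    free = {
        (c.chain_id, int(b)) for c in chains for b in c.buttons
    } - bound

    new = PairingState(surviving)
    candidates = sorted(candidate_pairs(chains, free, config.capture_radius))
    for _, ep_a, ep_b in candidates:
        if ep_a in free and ep_b in free:
            new.add(ep_a, ep_b)
            free.discard(ep_a)
            free.discard(ep_b)
    return new
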
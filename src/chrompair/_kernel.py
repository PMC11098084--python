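"""Compiled inner loop of the Brownian-dynamics engine.

The mathematics here duplicates, operation for operation, the reference
functions in :mod:`chrompair.polymer_model` and :mod:`chrompair.pairing`
(a cross-check test holds the two routes to bitwise agreement in the
deterministic limit); this module only exists so that 300k-iteration runs
take seconds instead of minutes.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True, fastmath=True)
def _compute_forces(
    pos, F, btn_chain, btn_node, partner,
    k_spring, k_bend, k_pair, k_confine, k_tether,
    rest_length, R, theta_c, tether_on,
):
    C, N, _ = pos.shape
    F[:] = 0.0
    for ci in range(C):
        for i in range(N - 1):
            dx = pos[ci, i + 1, 0] - pos[ci, i, 0]
            dy = pos[ci, i + 1, 1] - pos[ci, i, 1]
            dz = pos[ci, i + 1, 2] - pos[ci, i, 2]
            d = (dx * dx + dy * dy + dz * dz) ** 0.5
            if d > 0.0:
                s = k_spring * (d - rest_length) / d
                F[ci, i, 0] += s * dx
                F[ci, i, 1] += s * dy
                F[ci, i, 2] += s * dz
                F[ci, i + 1, 0] -= s * dx
                F[ci, i + 1, 1] -= s * dy
                F[ci, i + 1, 2] -= s * dz
        for i in range(1, N - 1):
            for k in range(3):
                v = pos[ci, i, k] - 0.5 * (pos[ci, i - 1, k] + pos[ci, i + 1, k])
                F[ci, i, k] -= k_bend * v
                F[ci, i - 1, k] += 0.5 * k_bend * v
                F[ci, i + 1, k] += 0.5 * k_bend * v
        for i in range(N):
            r = (
                pos[ci, i, 0] ** 2 + pos[ci, i, 1] ** 2 + pos[ci, i, 2] ** 2
            ) ** 0.5
            if r > R:
                s = -k_confine * (r - R) / r
                F[ci, i, 0] += s * pos[ci, i, 0]
                F[ci, i, 1] += s * pos[ci, i, 1]
                F[ci, i, 2] += s * pos[ci, i, 2]
        if tether_on:
            x = pos[ci, 0, 0]
            y = pos[ci, 0, 1]
            z = pos[ci, 0, 2]
            rxy = (x * x + y * y) ** 0.5
            if rxy < 1e-12 and abs(z) < 1e-12:
                px, py, pz = 0.0, 0.0, R
            else:
                theta = np.arctan2(rxy, z)
                tn = theta if theta < theta_c else theta_c
                if rxy < 1e-12:
                    ux, uy = 1.0, 0.0
                else:
                    ux, uy = x / rxy, y / rxy
                px = R * np.sin(tn) * ux
                py = R * np.sin(tn) * uy
                pz = R * np.cos(tn)
            F[ci, 0, 0] += k_tether * (px - x)
            F[ci, 0, 1] += k_tether * (py - y)
            F[ci, 0, 2] += k_tether * (pz - z)
    B = btn_chain.shape[0]
    for b in range(B):
        pb = partner[b]
        if pb > b:
            ca, na = btn_chain[b], btn_node[b]
            cb, nb = btn_chain[pb], btn_node[pb]
            dx = pos[cb, nb, 0] - pos[ca, na, 0]
            dy = pos[cb, nb, 1] - pos[ca, na, 1]
            dz = pos[cb, nb, 2] - pos[ca, na, 2]
            F[ca, na, 0] += k_pair * dx
            F[ca, na, 1] += k_pair * dy
            F[ca, na, 2] += k_pair * dz
            F[cb, nb, 0] -= k_pair * dx
            F[cb, nb, 1] -= k_pair * dy
            F[cb, nb, 2] -= k_pair * dz


@njit(cache=True)
def _update_pairing(
    pos, btn_chain, btn_node, partner, capture_radius, p_unpair, cd, ci_arr, cj_arr
):
    B = partner.shape[0]
    # break phase: each bond dissolves independently
    for b in range(B):
        pb = partner[b]
        if pb > b:
            if np.random.random() < p_unpair:
                partner[b] = -1
                partner[pb] = -1
    # formation phase: nearest free pair first; candidates are generated in
    # lexicographic (chain, node) order and the sort is stable, so exact
    # distance ties break lexicographically
    cap2 = capture_radius * capture_radius
    m = 0
    for i in range(B):
        if partner[i] != -1:
            continue
        ca, na = btn_chain[i], btn_node[i]
        xi = pos[ca, na, 0]
        yi = pos[ca, na, 1]
        zi = pos[ca, na, 2]
        for j in range(i + 1, B):
            if partner[j] != -1:
                continue
            cb, nb = btn_chain[j], btn_node[j]
            dx = pos[cb, nb, 0] - xi
            dy = pos[cb, nb, 1] - yi
            dz = pos[cb, nb, 2] - zi
            d2 = dx * dx + dy * dy + dz * dz
            if d2 <= cap2:
                cd[m] = d2
                ci_arr[m] = i
                cj_arr[m] = j
                m += 1
    if m > 0:
        order = np.argsort(cd[:m], kind="mergesort")
        for k in range(m):
            i = ci_arr[order[k]]
            j = cj_arr[order[k]]
            if partner[i] == -1 and partner[j] == -1:
                partner[i] = j
                partner[j] = i


@njit(cache=True)
def simulate(
    pos, btn_chain, btn_node, partner,
    k_spring, k_bend, k_pair, k_confine, k_tether,
    rest_length, friction, kBT, dt,
    R, theta_c, tether_on,
    capture_radius, p_unpair,
    n_steps, record_every, burn_in, pairing_on, seed,
    rec_pos, rec_partner, rec_steps,
):
    """Run the full loop in place; returns the number of recorded frames, or
    ``-step`` if coordinates became non-finite at that step."""
    np.random.seed(seed)
    C, N, _ = pos.shape
    B = btn_chain.shape[0]
    F = np.zeros_like(pos)
    ncand = max(1, B * (B - 1) // 2)
    cd = np.empty(ncand, dtype=np.float64)
    ci_arr = np.empty(ncand, dtype=np.int64)
    cj_arr = np.empty(ncand, dtype=np.int64)
    sigma = (2.0 * kBT * dt / friction) ** 0.5
    mob = dt / friction
    rec_pos[0] = pos
    rec_partner[0] = partner
    rec_steps[0] = 0
    frame = 1
    for step in range(1, n_steps + 1):
        if pairing_on and step > burn_in:
            _update_pairing(
                pos, btn_chain, btn_node, partner,
                capture_radius, p_unpair, cd, ci_arr, cj_arr,
            )
        _compute_forces(
            pos, F, btn_chain, btn_node, partner,
            k_spring, k_bend, k_pair, k_confine, k_tether,
            rest_length, R, theta_c, tether_on,
        )
        noise = np.random.standard_normal(C * N * 3)
        idx = 0
        for ci in range(C):
            for i in range(N):
                for k in range(3):
                    pos[ci, i, k] += mob * F[ci, i, k] + sigma * noise[idx]
                    idx += 1
        if step % record_every == 0:
            total = 0.0
            for ci in range(C):
                for i in range(N):
                    total += pos[ci, i, 0] + pos[ci, i, 1] + pos[ci, i, 2]
            if not np.isfinite(total):
                return -step
            rec_pos[frame] = pos
            rec_partner[frame] = partner
            rec_steps[frame] = step
            frame += 1
    return frame
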
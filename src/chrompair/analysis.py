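"""Metrics: pairing fidelity, kymograph, Rabl correlation, persistence
length, pairing time, chance baseline and discrimination energy.

Two fidelity conventions are exposed.  *Chromosome* mode counts a button as
correct when it is bonded to any button on its homolog (the convention behind
the whole-arm parameter scans); *locus* mode requires the bond to reach the
identically indexed button on the homolog (the stricter convention used for
barcode reliability and multi-chromosome experiments).  Unpaired buttons
count as incorrect in both; cis bonds are always incorrect.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.optimize
import scipy.stats

from .barcode import Barcode
from .config import SimulationConfig
from .dynamics_engine import Trajectory
from .polymer_model import (
    ChainState,
    PairingState,
    bending_forces,
    elastic_energy,
    pairing_forces,
    spring_forces,
)

__all__ = [
    "MetricsReport",
    "pairing_fidelity",
    "fidelity_timecourse",
    "final_fidelity",
    "partner_breakdown",
    "chance_baseline",
    "kymograph",
    "rabl_correlation",
    "bond_autocorrelation",
    "estimate_persistence_length",
    "time_to_fraction_paired",
    "discrimination_energy",
    "compute_metrics",
    "ensemble_summary",
]

FINAL_WINDOW = 0.1  # final fidelity = mean over last 10% of recorded frames


def pairing_fidelity(chains, pairing: PairingState, mode: str = "locus") -> float:
    """Fraction of buttons paired to the correct homolog (one frame)."""
    if mode not in ("chromosome", "locus"):
        raise ValueError(f"mode must be 'chromosome' or 'locus', got {mode!r}")
    homolog_of = {}
    for a in chains:
        for b in chains:
            if a.chain_id != b.chain_id and a.homolog_id == b.homolog_id:
                homolog_of[a.chain_id] = b.chain_id
    total = sum(len(c.buttons) for c in chains)
    if total == 0:
        raise ValueError("no buttons defined")
    correct = 0
    for chain in chains:
        for node in chain.buttons:
            partner = pairing.partner_of((chain.chain_id, int(node)))
            if partner is None:
                continue
            pc, pn = partner
            if pc != homolog_of.get(chain.chain_id):
                continue
            if mode == "chromosome" or pn == int(node):
                correct += 1
    return correct / total


def _fidelity_mask(traj: Trajectory, mode: str) -> np.ndarray:
    """(F, B) boolean array: button b correctly paired in frame f."""
    if mode not in ("chromosome", "locus"):
        raise ValueError(f"mode must be 'chromosome' or 'locus', got {mode!r}")
    if len(traj.btn_chain) == 0:
        raise ValueError("no buttons defined")
    partners = traj.partners
    paired = partners >= 0
    pb = np.where(paired, partners, 0)
    partner_chain = traj.btn_chain[pb]
    own_chain = traj.btn_chain[None, :]
    homolog_chain = own_chain ^ 1  # chains 2p, 2p+1 form pair p
    ok = paired & (partner_chain == homolog_chain)
    if mode == "locus":
        ok &= traj.btn_node[pb] == traj.btn_node[None, :]
    return ok


def fidelity_timecourse(traj: Trajectory, mode: str = "locus") -> np.ndarray:
    """Per-recorded-frame pairing fidelity."""
    return _fidelity_mask(traj, mode).mean(axis=1)


def final_fidelity(traj: Trajectory, mode: str = "locus") -> float:
    """Mean fidelity over the last 10% of recorded frames."""
    tc = fidelity_timecourse(traj, mode)
    k = max(1, int(np.ceil(FINAL_WINDOW * len(tc))))
    return float(tc[-k:].mean())


def partner_breakdown(traj: Trajectory) -> dict:
    """Mean fractions of buttons bonded to the homolog, to a nonhomolog, in
    cis, or unpaired, over the final window."""
    partners = traj.partners
    k = max(1, int(np.ceil(FINAL_WINDOW * partners.shape[0])))
    partners = partners[-k:]
    paired = partners >= 0
    pb = np.where(paired, partners, 0)
    partner_chain = traj.btn_chain[pb]
    own = traj.btn_chain[None, :]
    homolog = paired & (partner_chain == (own ^ 1))
    cis = paired & (partner_chain == own)
    nonhomolog = paired & ~homolog & ~cis
    return {
        "correct_homolog": float(homolog.mean()),
        "nonhomolog": float(nonhomolog.mean()),
        "cis": float(cis.mean()),
        "unpaired": float((~paired).mean()),
    }


def chance_baseline(n_pairs: int) -> float:
    """Expected correct fraction if buttons associate at random: each
    chromosome faces one correct homolog among 2·n_pairs equally likely
    options (2·n_pairs − 1 other chromosomes plus itself in cis)."""
    if n_pairs < 1:
        raise ValueError("n_pairs must be >= 1")
    return 1.0 / (2.0 * n_pairs)


def kymograph(traj: Trajectory, homolog_id: int = 0) -> np.ndarray:
    """(loci × frames) homolog-homolog distance matrix, normalized to the
    maximum distance observed in the run (so values lie in [0, 1] and the
    paired state is 0)."""
    ca, cb = 2 * homolog_id, 2 * homolog_id + 1
    if cb >= traj.n_chains:
        raise ValueError(f"homolog pair {homolog_id} not in trajectory")
    d = np.linalg.norm(
        traj.positions[:, ca] - traj.positions[:, cb], axis=-1
    ).T  # (N, F)
    dmax = d.max()
    return d / dmax if dmax > 0 else d


def save_kymograph(matrix: np.ndarray, csv_path=None, png_path=None) -> None:
    if csv_path is not None:
        np.savetxt(csv_path, matrix, delimiter=",", fmt="%.5f")
    if png_path is not None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(6, 3.2))
        im = ax.imshow(
            matrix, aspect="auto", origin="lower", cmap="jet", vmin=0, vmax=1
        )
        ax.set_xlabel("frame")
        ax.set_ylabel("position along chromosome (node)")
        fig.colorbar(im, label="fraction of max distance")
        fig.tight_layout()
        fig.savefig(png_path, dpi=120)
        plt.close(fig)


def _post_burn_in(traj: Trajectory) -> np.ndarray:
    mask = traj.steps >= traj.config.burn_in_steps
    if not mask.any():
        mask = traj.steps >= traj.steps[-1]
    return traj.positions[mask]


def rabl_correlation(traj: Trajectory) -> float:
    """Pearson correlation between genomic position and vertical position.

    Genomic position runs 0 (centromere) → telomere, z runs toward the
    centromere pole, so a strong Rabl configuration gives r near −1; r ≈ 0
    means position along the chromosome carries no height information.
    Computed on no-pairing calibration runs, pooled over all chains and
    post-burn-in frames.
    """
    pos = _post_burn_in(traj)
    F, C, N, _ = pos.shape
    if N < 2:
        raise ValueError("need at least 2 distinct node indices")
    z = pos[..., 2].reshape(-1)
    idx = np.broadcast_to(np.arange(N), (F, C, N)).reshape(-1)
    r, _ = scipy.stats.pearsonr(idx, z)
    return float(r)


def bond_autocorrelation(traj: Trajectory) -> np.ndarray:
    """⟨cos θ(s)⟩: mean dot product of unit bond vectors s bonds apart,
    averaged over chains and post-burn-in frames; index 0 is s=1."""
    pos = _post_burn_in(traj)
    bonds = pos[:, :, 1:] - pos[:, :, :-1]
    u = bonds / np.linalg.norm(bonds, axis=-1, keepdims=True)
    nb = u.shape[2]
    out = np.empty(nb - 1)
    for s in range(1, nb):
        out[s - 1] = float(np.mean(np.sum(u[:, :, :-s] * u[:, :, s:], axis=-1)))
    return out


def estimate_persistence_length(traj: Trajectory) -> float:
    """Persistence length (length units) from the exponential decay of the
    bond orientation correlation.

    Fits log⟨cos θ(s)⟩ = −s/Lp by least squares over the initial run of
    separations with ⟨cos θ⟩ > 0.1.  A freely jointed chain decorrelates
    within one bond: the fit floor of 0.5 length units is returned (with a
    warning).  A chain that never decorrelates is flagged rigid and the
    estimate is at least the chain contour length.
    """
    corr = bond_autocorrelation(traj)
    contour = (traj.positions.shape[2] - 1) * traj.config.rest_length
    usable = 0
    while usable < len(corr) and corr[usable] > 0.1:
        usable += 1
    if usable == 0:
        warnings.warn(
            "bond orientations decorrelate within one link; returning the "
            "freely jointed floor of 0.5 length units",
            stacklevel=2,
        )
        return 0.5
    s = np.arange(1, usable + 1, dtype=float)
    logc = np.log(corr[:usable])
    denom = np.sum(s * logc)
    lp = -np.sum(s * s) / denom if denom < 0 else np.inf
    if not np.isfinite(lp):
        lp = contour
    if usable == len(corr) and corr[-1] > 0.9:
        warnings.warn(
            "chain is rigid on the simulated scale; persistence length is a "
            "lower bound",
            stacklevel=2,
        )
        return float(max(lp, contour))
    return float(lp)


def time_to_fraction_paired(
    traj: Trajectory, threshold: float = 0.9, mode: str = "locus"
):
    """First recorded step at which fidelity reaches the threshold, or None
    when the run never crosses it ("not reached")."""
    tc = fidelity_timecourse(traj, mode)
    hits = np.nonzero(tc >= threshold)[0]
    if len(hits) == 0:
        return None
    return int(traj.steps[hits[0]])


def _internal_energy_system(config: SimulationConfig):
    """Config copy with envelope terms inert (huge nucleus, tether off)."""
    big = 1000.0 * max(config.nucleus_radius, config.nodes_per_arm)
    return config.replace(nucleus_radius=big, rabl_patch_radius=2 * big)


def _relaxed_energy(config: SimulationConfig, code_a: Barcode, code_b: Barcode) -> float:
    n = config.nodes_per_arm
    base = np.stack([np.zeros(n), np.zeros(n), np.arange(n, dtype=float)], axis=1)
    chains = [
        ChainState(base.copy(), code_a.as_array(), homolog_id=0, chain_id=0),
        ChainState(base + np.array([0.5, 0.0, 0.0]), code_b.as_array(), homolog_id=0, chain_id=1),
    ]
    nb = min(code_a.n_buttons, code_b.n_buttons)
    bonds = {
        ((0, int(code_a.button_indices[i])), (1, int(code_b.button_indices[i])))
        for i in range(nb)
    }
    pairing = PairingState(bonds)
    cfg = _internal_energy_system(config)

    def fun_jac(x):
        pos = x.reshape(2, n, 3)
        cs = [
            ChainState(pos[0], chains[0].buttons, 0, 0),
            ChainState(pos[1], chains[1].buttons, 0, 1),
        ]
        e = elastic_energy(cs, pairing, cfg)
        grad = [
            -(spring_forces(c, cfg.k_spring, cfg.rest_length) + bending_forces(c, cfg.k_bend))
            for c in cs
        ]
        for g, pf in zip(grad, pairing_forces(cs, pairing, cfg.k_pair)):
            g -= pf
        return e, np.concatenate([g.ravel() for g in grad])

    x0 = np.concatenate([c.positions.ravel() for c in chains])
    res = scipy.optimize.minimize(
        fun_jac,
        x0,
        jac=True,
        method="L-BFGS-B",
        options={"gtol": 1e-6, "ftol": 1e-14, "maxiter": 50_000, "maxfun": 100_000},
    )
    return float(res.fun)


def discrimination_energy(
    config: SimulationConfig, barcode_a: Barcode, barcode_b: Barcode
) -> float:
    """Elastic-energy cost (kBT) of enforced incorrect pairing.

    Relaxes two noiseless systems by gradient-based descent to a force
    tolerance of 1e-6: homologs carrying identical codes bonded
    button-to-button (correct), and chromosomes carrying the two different
    codes with the same rank-order bonds enforced (incorrect; surplus buttons
    of the longer code stay unbonded).  Returns E(incorrect) − E(correct).
    Only internal terms (stretch, bending, pairing bonds) contribute, so the
    result is invariant to rigid motion of either chain's initial guess.
    """
    e_correct = _relaxed_energy(config, barcode_a, barcode_a)
    e_incorrect = _relaxed_energy(config, barcode_a, barcode_b)
    return float(e_incorrect - e_correct)


@dataclass
class MetricsReport:
    """Per-run (and optionally ensemble) metric bundle, JSON-serializable."""

    fidelity_timecourse: list = field(default_factory=list)
    final_fidelity: float | None = None
    final_fidelity_chromosome: float | None = None
    kymograph: list | None = None
    rabl_correlation: float | None = None
    persistence_length_estimate: float | None = None
    time_to_90pct: int | str | None = None
    breakdown: dict | None = None
    ensemble: dict | None = None

    def to_json(self, path=None) -> str:
        payload = {
            "fidelity_timecourse": list(map(float, self.fidelity_timecourse)),
            "final_fidelity": self.final_fidelity,
            "final_fidelity_chromosome": self.final_fidelity_chromosome,
            "kymograph": self.kymograph,
            "rabl_correlation": self.rabl_correlation,
            "persistence_length_estimate": self.persistence_length_estimate,
            "time_to_90pct": self.time_to_90pct,
            "breakdown": self.breakdown,
            "ensemble": self.ensemble,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def compute_metrics(
    traj: Trajectory,
    mode: str = "locus",
    include_kymograph: bool = False,
    include_persistence: bool = False,
) -> MetricsReport:
    report = MetricsReport(
        fidelity_timecourse=list(fidelity_timecourse(traj, mode)),
        final_fidelity=final_fidelity(traj, mode),
        final_fidelity_chromosome=final_fidelity(traj, "chromosome"),
        breakdown=partner_breakdown(traj),
    )
    t90 = time_to_fraction_paired(traj, 0.9, mode)
    report.time_to_90pct = "not reached" if t90 is None else t90
    if include_kymograph:
        report.kymograph = kymograph(traj).tolist()
    if include_persistence:
        report.persistence_length_estimate = estimate_persistence_length(traj)
    return report


def ensemble_summary(values) -> dict:
    """Mean, SEM, median and extrema over per-run values; the per-run values
    are retained so the SEM is recomputable."""
    arr = np.asarray(list(values), dtype=float)
    return {
        "n_runs": int(arr.size),
        "mean": float(arr.mean()),
        "sem": float(arr.std(ddof=1) / np.sqrt(arr.size)) if arr.size > 1 else 0.0,
        "median": float(np.median(arr)),
        "min": float(arr.min()),
        "max": float(arr.max()),
        "values": [float(v) for v in arr],
    }
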
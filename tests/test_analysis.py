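"""Fidelity metrics, kymograph, Rabl correlation, persistence length,
pairing time, and discrimination energy."""

import dataclasses
import json
import warnings

import numpy as np
import pytest

from chrompair import (
    Barcode,
    PairingState,
    SimulationConfig,
    chance_baseline,
    discrimination_energy,
    estimate_persistence_length,
    kymograph,
    pairing_fidelity,
    rabl_correlation,
    time_to_fraction_paired,
)
from chrompair.analysis import MetricsReport, compute_metrics, ensemble_summary
from chrompair.dynamics_engine import Trajectory

from conftest import make_chain


def four_chain_frame():
    """Two homolog pairs, two buttons per chain at nodes 0 and 2."""
    chains = []
    for cid in range(4):
        chains.append(
            make_chain(
                np.zeros((4, 3)), buttons=[0, 2], chain_id=cid, homolog_id=cid // 2
            )
        )
    return chains


def synthetic_trajectory(positions, buttons_per_chain, partners=None, config=None):
    """Assemble a Trajectory directly from arrays (analysis-side fixture)."""
    F, C, N, _ = positions.shape
    buttons = [np.asarray(b, dtype=np.int64) for b in buttons_per_chain]
    btn_chain = np.concatenate(
        [np.full(len(b), i, dtype=np.int64) for i, b in enumerate(buttons)]
    )
    btn_node = np.concatenate(buttons).astype(np.int64)
    if partners is None:
        partners = np.full((F, len(btn_chain)), -1, dtype=np.int64)
    if config is None:
        config = SimulationConfig(
            n_pairs=max(1, C // 2), nodes_per_arm=N, burn_in_steps=0
        )
    return Trajectory(
        config=config,
        buttons=buttons,
        steps=np.arange(F, dtype=np.int64) * config.record_every,
        positions=positions,
        partners=partners,
        btn_chain=btn_chain,
        btn_node=btn_node,
    )


class TestPairingFidelity:
    def test_perfect_pairing_both_modes(self):
        chains = four_chain_frame()
        bonds = PairingState(
            {((0, 0), (1, 0)), ((0, 2), (1, 2)), ((2, 0), (3, 0)), ((2, 2), (3, 2))}
        )
        assert pairing_fidelity(chains, bonds, "chromosome") == 1.0
        assert pairing_fidelity(chains, bonds, "locus") == 1.0

    def test_no_bonds_zero(self):
        chains = four_chain_frame()
        assert pairing_fidelity(chains, PairingState(set()), "locus") == 0.0

    def test_nonhomolog_bonds_zero(self):
        chains = four_chain_frame()
        bonds = PairingState({((0, 0), (2, 0)), ((1, 2), (3, 2))})
        assert pairing_fidelity(chains, bonds, "chromosome") == 0.0
        assert pairing_fidelity(chains, bonds, "locus") == 0.0

    def test_index_shifted_homolog_bonds(self):
        chains = four_chain_frame()
        bonds = PairingState(
            {((0, 0), (1, 2)), ((0, 2), (1, 0)), ((2, 0), (3, 2)), ((2, 2), (3, 0))}
        )
        assert pairing_fidelity(chains, bonds, "chromosome") == 1.0
        assert pairing_fidelity(chains, bonds, "locus") == 0.0

    def test_unpaired_buttons_count_in_denominator(self):
        chains = four_chain_frame()
        bonds = PairingState({((0, 0), (1, 0))})
        assert pairing_fidelity(chains, bonds, "locus") == pytest.approx(2 / 8)

    def test_no_buttons_error(self):
        chains = [make_chain(np.zeros((3, 3)), buttons=[], chain_id=0)]
        with pytest.raises(ValueError, match="no buttons"):
            pairing_fidelity(chains, PairingState(set()), "locus")

    def test_invalid_mode(self):
        with pytest.raises(ValueError, match="mode"):
            pairing_fidelity(four_chain_frame(), PairingState(set()), "strict")


class TestChanceBaseline:
    @pytest.mark.parametrize("n,expected", [(1, 0.5), (2, 0.25), (5, 0.1)])
    def test_values(self, n, expected):
        assert chance_baseline(n) == pytest.approx(expected)

    def test_invalid(self):
        with pytest.raises(ValueError):
            chance_baseline(0)


class TestKymograph:
    def test_identical_homologs_all_zero(self):
        pos = np.zeros((3, 2, 4, 3))
        traj = synthetic_trajectory(pos, [[0, 2], [0, 2]])
        assert np.all(kymograph(traj, 0) == 0)

    def test_hand_computed_distances_and_normalization(self):
        pos = np.zeros((2, 2, 2, 3))
        pos[0, 1, 0] = [3, 0, 0]  # frame 0: node 0 at distance 3
        pos[0, 1, 1] = [0, 4, 0]  # frame 0: node 1 at distance 4
        pos[1, 1, 0] = [1, 0, 0]  # frame 1: node 0 at distance 1
        traj = synthetic_trajectory(pos, [[0], [0]])
        m = kymograph(traj, 0)
        assert m.shape == (2, 2)
        assert m == pytest.approx(np.array([[3 / 4, 1 / 4], [4 / 4, 0]]))
        assert m.max() == 1.0

    def test_missing_pair(self):
        pos = np.zeros((1, 2, 2, 3))
        traj = synthetic_trajectory(pos, [[0], [0]])
        with pytest.raises(ValueError):
            kymograph(traj, 3)


class TestRablCorrelation:
    def test_perfect_gradient(self):
        F, C, N = 5, 2, 10
        pos = np.zeros((F, C, N, 3))
        pos[..., 2] = -np.arange(N)
        traj = synthetic_trajectory(pos, [[0], [0]])
        assert rabl_correlation(traj) == pytest.approx(-1.0)

    def test_shuffled_independence(self):
        rng = np.random.default_rng(0)
        F, C, N = 100, 4, 30
        pos = np.zeros((F, C, N, 3))
        pos[..., 2] = rng.normal(size=(F, C, N))
        traj = synthetic_trajectory(pos, [[0]] * C)
        assert abs(rabl_correlation(traj)) < 0.05

    def test_single_node_error(self):
        pos = np.zeros((2, 2, 1, 3))
        cfg = SimulationConfig(nodes_per_arm=2, burn_in_steps=0)
        traj = synthetic_trajectory(pos, [[0], [0]], config=cfg)
        with pytest.raises(ValueError, match="node indices"):
            rabl_correlation(traj)


class TestPersistenceLength:
    def test_gaussian_angle_chain_matches_closed_form(self):
        """Chains built with independent bond deflections of known mean
        cosine decay as <cos>(s) = <cos>^s, i.e. Lp = -1/ln<cos>."""
        rng = np.random.default_rng(1)
        n_chains, n_nodes = 400, 30
        sigma_angle = 0.45
        pos = np.zeros((1, n_chains, n_nodes, 3))
        for c in range(n_chains):
            u = np.array([0.0, 0.0, 1.0])
            pts = [np.zeros(3)]
            for _ in range(n_nodes - 1):
                # random small rotation of the bond direction
                axis = np.cross(u, rng.normal(size=3))
                axis /= np.linalg.norm(axis)
                th = rng.normal(scale=sigma_angle)
                u = u * np.cos(th) + np.cross(axis, u) * np.sin(th)
                u /= np.linalg.norm(u)
                pts.append(pts[-1] + u)
            pos[0, c] = pts
        traj = synthetic_trajectory(pos, [[0]] * n_chains)
        mean_cos = np.exp(-sigma_angle**2 / 2)  # <cos theta> for N(0, s^2)
        expected = -1.0 / np.log(mean_cos)
        lp = estimate_persistence_length(traj)
        assert lp == pytest.approx(expected, rel=0.10)

    def test_rigid_chain_flagged(self):
        pos = np.zeros((2, 1, 20, 3))
        pos[..., 2] = np.arange(20)
        traj = synthetic_trajectory(pos, [[0]])
        with pytest.warns(UserWarning, match="rigid"):
            lp = estimate_persistence_length(traj)
        assert lp >= 19.0

    def test_freely_jointed_floor(self):
        rng = np.random.default_rng(2)
        n_chains, n_nodes = 300, 20
        u = rng.normal(size=(n_chains, n_nodes - 1, 3))
        u /= np.linalg.norm(u, axis=-1, keepdims=True)
        pos = np.concatenate(
            [np.zeros((n_chains, 1, 3)), np.cumsum(u, axis=1)], axis=1
        )[None]
        traj = synthetic_trajectory(pos, [[0]] * n_chains)
        with pytest.warns(UserWarning, match="freely jointed"):
            assert estimate_persistence_length(traj) == 0.5


class TestTimeToFractionPaired:
    def _traj_with_fidelities(self, fids):
        """One pair, two buttons per chain; per frame, bond all / half / none
        of the buttons correctly to hit fidelity 1.0 / 0.5 / 0.0."""
        F = len(fids)
        pos = np.zeros((F, 2, 4, 3))
        partners = np.full((F, 4), -1, dtype=np.int64)
        for f, fid in enumerate(fids):
            if fid >= 1.0:
                partners[f] = [2, 3, 0, 1]
            elif fid >= 0.5:
                partners[f, 0], partners[f, 2] = 2, 0
        return synthetic_trajectory(
            np.zeros((F, 2, 4, 3)), [[0, 2], [0, 2]], partners=partners
        )

    def test_first_crossing_no_recheck(self):
        traj = self._traj_with_fidelities([0.0, 1.0, 0.5])
        assert time_to_fraction_paired(traj, 0.9, "locus") == traj.steps[1]

    def test_not_reached(self):
        traj = self._traj_with_fidelities([0.0, 0.5, 0.0])
        assert time_to_fraction_paired(traj, 0.9, "locus") is None

    def test_starts_paired(self):
        traj = self._traj_with_fidelities([1.0, 1.0])
        assert time_to_fraction_paired(traj, 0.9, "locus") == traj.steps[0]


class TestDiscriminationEnergy:
    def test_identical_codes_zero(self):
        cfg = SimulationConfig()
        code = Barcode((0, 3, 6, 9, 12), 48)
        assert discrimination_energy(cfg, code, code) == pytest.approx(0.0, abs=1e-6)

    def test_mismatched_uniform_codes_cost_energy(self):
        cfg = SimulationConfig()
        a = Barcode(tuple(range(0, 15, 3)), 48)  # five buttons, 3 apart
        b = Barcode(tuple(range(0, 20, 4)), 48)  # five buttons, 4 apart
        d = discrimination_energy(cfg, a, b)
        assert d > 1.0  # costs several kBT
        assert d < 100.0

    def test_unequal_button_counts_rank_paired(self):
        cfg = SimulationConfig()
        a = Barcode((0, 3, 6, 9), 48)
        b = Barcode((0, 4, 8), 48)
        d = discrimination_energy(cfg, a, b)
        assert np.isfinite(d)
        assert d >= -1e-6


class TestReporting:
    def test_metrics_report_serializes(self, tmp_path):
        from chrompair import run

        traj = run(SimulationConfig(n_steps=2000, record_every=500, seed=1))
        report = compute_metrics(traj, include_kymograph=True)
        payload = json.loads(report.to_json(tmp_path / "m.json"))
        assert 0.0 <= payload["final_fidelity"] <= 1.0
        assert payload["time_to_90pct"] is not None
        k = np.asarray(payload["kymograph"])
        assert k.min() >= 0.0 and k.max() <= 1.0

    def test_ensemble_summary_recomputable(self):
        vals = [0.2, 0.4, 0.9, 0.5]
        s = ensemble_summary(vals)
        assert s["n_runs"] == 4
        assert s["mean"] == pytest.approx(np.mean(vals))
        assert s["sem"] == pytest.approx(np.std(vals, ddof=1) / 2)
        assert s["values"] == vals
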
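"""Force and energy terms of the bead-spring worm-like chain model."""

import numpy as np
import pytest
import yaml

from chrompair import (
    ChainState,
    PairingState,
    SimulationConfig,
    bending_forces,
    confinement_forces,
    elastic_energy,
    load_config,
    pairing_forces,
    save_config,
    spring_forces,
    tether_forces,
)
from chrompair.polymer_model import total_forces

from conftest import make_chain, random_two_chain_system


class TestSpringForces:
    def test_rest_length_equilibrium(self):
        chain = make_chain([[0, 0, 0], [1, 0, 0]])
        assert np.allclose(spring_forces(chain, k_spring=100.0, rest_length=1.0), 0)

    def test_stretched_bond_hand_value(self):
        # two nodes 2 apart, k=1, rest 1: attraction of magnitude 1 each
        chain = make_chain([[0, 0, 0], [2, 0, 0]])
        f = spring_forces(chain, k_spring=1.0, rest_length=1.0)
        assert np.allclose(f[0], [1, 0, 0])
        assert np.allclose(f[1], [-1, 0, 0])

    def test_net_force_zero(self, rng):
        chain = make_chain(rng.normal(size=(12, 3)))
        f = spring_forces(chain, k_spring=37.0)
        assert np.allclose(f.sum(axis=0), 0, atol=1e-11)

    def test_degenerate_chain_error(self):
        with pytest.raises(ValueError, match="degenerate"):
            spring_forces(make_chain([[0, 0, 0]]), k_spring=1.0)


class TestBendingForces:
    def test_straight_chain_zero(self):
        chain = make_chain([[0, 0, 0], [1, 0, 0], [2, 0, 0]])
        assert np.allclose(bending_forces(chain, k_bend=7.0), 0)

    def test_right_angle_hand_value(self):
        chain = make_chain([[0, 0, 0], [1, 0, 0], [1, 1, 0]])
        f = bending_forces(chain, k_bend=2.0)
        assert np.allclose(f[1], [-1, 1, 0])
        assert np.allclose(f.sum(axis=0), 0, atol=1e-12)

    def test_rotation_equivariance(self, rng):
        from scipy.spatial.transform import Rotation

        chain = make_chain(rng.normal(size=(8, 3)))
        R = Rotation.random(random_state=3).as_matrix()
        f = bending_forces(chain, k_bend=5.0)
        rotated = make_chain(chain.positions @ R.T)
        f_rot = bending_forces(rotated, k_bend=5.0)
        assert np.allclose(f_rot, f @ R.T, atol=1e-10)


class TestConfinementAndTether:
    def test_interior_zero(self):
        chain = make_chain([[0, 0, 5.0], [0, 0, 4.0]])
        (f,) = confinement_forces([chain], nucleus_radius=10.0, k_confine=100.0)
        assert np.allclose(f, 0)

    def test_outside_inward_hand_value(self):
        chain = make_chain([[0, 0, 10.1], [0, 0, 9.0]])
        (f,) = confinement_forces([chain], nucleus_radius=10.0, k_confine=100.0)
        assert np.allclose(f[0], [0, 0, -10.0], atol=1e-9)
        assert np.allclose(f[1], 0)

    def test_confinement_antiparallel_to_position(self, rng):
        chain = make_chain(rng.normal(scale=8.0, size=(20, 3)))
        (f,) = confinement_forces([chain], nucleus_radius=5.0, k_confine=3.0)
        for x, fi in zip(chain.positions, f):
            if np.linalg.norm(fi) > 0:
                cos = np.dot(x, fi) / (np.linalg.norm(x) * np.linalg.norm(fi))
                assert cos == pytest.approx(-1.0, abs=1e-9)

    def test_centromere_at_pole_zero(self):
        chain = make_chain([[0, 0, 10.0], [0, 0, 9.0]])
        (f,) = tether_forces([chain], rabl_patch_radius=3.0, k_tether=50.0, nucleus_radius=10.0)
        assert np.allclose(f, 0, atol=1e-9)

    def test_centromere_at_origin_pulled_to_pole(self):
        chain = make_chain([[0, 0, 0], [0, 0, -1.0]])
        (f,) = tether_forces([chain], rabl_patch_radius=0.0, k_tether=7.0, nucleus_radius=10.0)
        assert np.allclose(f[0], [0, 0, 70.0])
        assert np.allclose(f[1], 0)

    def test_full_envelope_patch_disables_constraint(self, rng):
        chain = make_chain(rng.normal(scale=3.0, size=(5, 3)))
        (f,) = tether_forces([chain], rabl_patch_radius=20.0, k_tether=7.0, nucleus_radius=10.0)
        assert np.allclose(f, 0)


class TestElasticEnergy:
    def test_ground_state_zero(self, free_space_config, straight_chain):
        cfg = free_space_config
        e = elastic_energy([straight_chain], PairingState(set()), cfg)
        assert e == pytest.approx(0.0, abs=1e-12)

    def test_single_bond_energy(self):
        cfg = SimulationConfig(
            k_pair=50.0, nucleus_radius=1000.0, rabl_patch_radius=2000.0
        )
        chains = [
            make_chain([[0, 0, 0], [0, 0, 1]], buttons=[0], chain_id=0),
            make_chain([[1, 0, 0], [1, 0, 1]], buttons=[0], chain_id=1),
        ]
        pairing = PairingState({((0, 0), (1, 0))})
        e = elastic_energy(chains, pairing, cfg)
        assert e == pytest.approx(25.0)  # 1/2 * 50 * 1^2

    def test_rotation_about_z_invariance(self, rng):
        cfg = SimulationConfig()
        chains, pairing = random_two_chain_system(rng)
        e0 = elastic_energy(chains, pairing, cfg)
        th = 1.234
        R = np.array(
            [[np.cos(th), -np.sin(th), 0], [np.sin(th), np.cos(th), 0], [0, 0, 1]]
        )
        rotated = [
            ChainState(c.positions @ R.T, c.buttons, c.homolog_id, c.chain_id)
            for c in chains
        ]
        assert elastic_energy(rotated, pairing, cfg) == pytest.approx(e0, rel=1e-10)


class TestForceEnergyConsistency:
    def test_forces_are_negative_energy_gradient(self, rng):
        """Finite-difference check of all force terms against elastic_energy,
        including pairing bonds, confinement and the centromere tether."""
        cfg = SimulationConfig(nucleus_radius=4.0, rabl_patch_radius=2.0)
        chains, pairing = random_two_chain_system(rng, n_nodes=6, scale=0.8)
        forces = total_forces(chains, pairing, cfg)
        h = 1e-6
        for ci, chain in enumerate(chains):
            for i in range(chain.n_nodes):
                for k in range(3):
                    orig = chain.positions[i, k]
                    chain.positions[i, k] = orig + h
                    e_hi = elastic_energy(chains, pairing, cfg)
                    chain.positions[i, k] = orig - h
                    e_lo = elastic_energy(chains, pairing, cfg)
                    chain.positions[i, k] = orig
                    fd = -(e_hi - e_lo) / (2 * h)
                    assert fd == pytest.approx(
                        forces[ci][i, k], rel=1e-4, abs=1e-6
                    )

    def test_internal_forces_sum_to_zero(self, rng):
        """Spring + bending + pairing forces are internal: system total is
        zero; only the wall and tether act externally."""
        cfg = SimulationConfig(nucleus_radius=1000.0, rabl_patch_radius=2000.0)
        chains, pairing = random_two_chain_system(rng)
        total = sum(f.sum(axis=0) for f in total_forces(chains, pairing, cfg))
        assert np.allclose(total, 0, atol=1e-9)

    def test_zero_noise_descent_decreases_energy(self, rng):
        from chrompair import step

        cfg = SimulationConfig(
            kBT=1e-30, nucleus_radius=1000.0, rabl_patch_radius=2000.0, dt=0.002
        )
        chains, pairing = random_two_chain_system(rng, scale=0.6)
        energies = [elastic_energy(chains, pairing, cfg)]
        for _ in range(50):
            chains = step(chains, pairing, cfg, rng)
            energies.append(elastic_energy(chains, pairing, cfg))
        diffs = np.diff(energies)
        assert np.all(diffs <= 1e-10)
        assert energies[-1] < energies[0]


class TestPairingState:
    def test_one_to_one_exclusivity_enforced(self):
        with pytest.raises(ValueError, match="more than one bond"):
            PairingState({((0, 0), (1, 0)), ((0, 0), (1, 4))})

    def test_cis_bonds_permitted(self):
        ps = PairingState({((0, 0), (0, 4))})
        assert ps.partner_of((0, 0)) == (0, 4)

    def test_self_bond_rejected(self):
        with pytest.raises(ValueError, match="differ"):
            PairingState({((0, 3), (0, 3))})


class TestConfigValidation:
    @pytest.mark.parametrize(
        "field,value",
        [
            ("k_spring", -1.0),
            ("dt", 0.0),
            ("p_unpair", 1.5),
            ("n_pairs", 0),
            ("nucleus_radius", -2.0),
        ],
    )
    def test_invalid_values_rejected(self, field, value):
        with pytest.raises(ValueError):
            SimulationConfig(**{field: value})

    def test_patch_radius_capped_at_diameter(self):
        with pytest.raises(ValueError, match="rabl_patch_radius"):
            SimulationConfig(nucleus_radius=10.0, rabl_patch_radius=21.0)
        # exactly 2R is the documented "no constraint" setting
        assert SimulationConfig(nucleus_radius=10.0, rabl_patch_radius=20.0).rabl_disabled

    def test_yaml_round_trip(self, tmp_path):
        cfg = SimulationConfig(n_pairs=3, k_bend=7.5, seed=42)
        path = tmp_path / "cfg.yaml"
        save_config(cfg, path)
        assert load_config(path) == cfg

    def test_unknown_key_rejected(self, tmp_path):
        path = tmp_path / "cfg.yaml"
        path.write_text(yaml.safe_dump({"k_spring": 10.0, "k_sprnig": 5.0}))
        with pytest.raises(ValueError, match="k_sprnig"):
            load_config(path)

    def test_noise_sigma_definition(self):
        cfg = SimulationConfig(kBT=2.0, dt=0.01, friction=4.0)
        assert cfg.noise_sigma == pytest.approx(np.sqrt(2 * 2.0 * 0.01 / 4.0))
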
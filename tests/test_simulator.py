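"""Langevin integrator, two-phase protocol and full reconstruction."""

import dataclasses

import numpy as np
import pytest

from hicfold import (
    BeadChain,
    BinaryContactMap,
    ForceFieldParams,
    GenomicBinning,
    SimulationConfig,
    contact_map_from_structure,
    init_self_avoiding_walk,
    map_pearson,
    reconstruct,
    run_bond_formation,
    run_production,
    step_dynamics,
)
from hicfold.polymer import RestraintSet
from hicfold.simulator import read_structure_csv, write_history_csv, write_structure_files


def straight_rod(n, spacing=1.0):
    pos = np.zeros((n, 3))
    pos[:, 0] = np.arange(n) * spacing
    c = BeadChain(pos)
    c.binning = GenomicBinning("c", 1000, n)
    return c


class TestStepDynamics:
    def test_zero_temperature_zero_force_is_frozen(self):
        # rod at backbone rest length, no restraints, no WCA overlap -> F = 0
        chain = straight_rod(6)
        cfg = SimulationConfig(temperature=0.0, seed=0)
        out = step_dynamics(chain, RestraintSet.empty(), ForceFieldParams(), cfg, 50)
        np.testing.assert_array_equal(out.positions, chain.positions)

    def test_same_seed_gives_identical_trajectories(self):
        chain = init_self_avoiding_walk(12, seed=3)
        cfg = SimulationConfig(seed=11)
        a = step_dynamics(chain, RestraintSet.empty(), ForceFieldParams(), cfg, 200)
        b = step_dynamics(chain, RestraintSet.empty(), ForceFieldParams(), cfg, 200)
        np.testing.assert_array_equal(a.positions, b.positions)

    def test_einstein_relation_for_free_diffusion(self):
        # The centre of mass of a bonded pair feels no net internal force, so
        # it diffuses freely with mobility 1/(2 gamma):
        # MSD_com(t) = 6 (kT / 2 gamma) t.
        cfg_proto = SimulationConfig(temperature=1.0, dt=0.005, gamma=1.0)
        params = ForceFieldParams()
        n_steps, n_seeds = 4000, 50
        t = n_steps * cfg_proto.dt
        expected = 6.0 * cfg_proto.temperature / (2.0 * cfg_proto.gamma) * t
        msds = []
        for seed in range(n_seeds):
            chain = straight_rod(2)
            cfg = dataclasses.replace(cfg_proto, seed=seed)
            out = step_dynamics(chain, RestraintSet.empty(), params, cfg, n_steps)
            com0 = chain.positions.mean(axis=0)
            com1 = out.positions.mean(axis=0)
            msds.append(np.sum((com1 - com0) ** 2))
        assert np.mean(msds) == pytest.approx(expected, rel=0.20)

    def test_non_finite_state_is_rejected(self):
        # the per-bead force cap bounds every increment, so dynamics cannot
        # overflow on their own; the guard fires on corrupted input instead
        from hicfold.polymer import NumericalBlowupError

        chain = init_self_avoiding_walk(8, seed=0)
        chain.positions[3, 1] = np.nan
        with pytest.raises(NumericalBlowupError, match="blow-up"):
            step_dynamics(chain, RestraintSet.empty(), ForceFieldParams(),
                          SimulationConfig(seed=0), 10)


class TestBondFormation:
    def test_empty_restraints_return_immediately_vacuous(self):
        chain = straight_rod(5)
        cfg = SimulationConfig(seed=1)
        out, history, reason = run_bond_formation(chain, RestraintSet.empty(),
                                                  ForceFieldParams(), cfg)
        assert reason == "gate_reached"
        assert len(history) == 1
        assert history[0].bonded_fraction == 1.0
        np.testing.assert_array_equal(out.positions, chain.positions)

    def test_single_long_range_restraint_forms(self, fast_cfg):
        chain = straight_rod(5)
        params = ForceFieldParams()
        rs = RestraintSet(np.array([0]), np.array([4]), np.array([params.r0]),
                          np.array([params.k_restraint]), np.array([False]))
        out, history, reason = run_bond_formation(chain, rs, params, fast_cfg(seed=1))
        assert reason == "gate_reached"
        assert rs.bonded.all()
        d = np.linalg.norm(out.positions[4] - out.positions[0])
        assert d <= params.r_cap + 1.0  # bonded at capture; may fluctuate after

    def test_gate_arithmetic_stops_at_first_sufficient_check(self):
        # 10 restraints, gate 0.8: the phase must end at the first recorded
        # check with >= 8 bonded, not later.
        chain = init_self_avoiding_walk(40, seed=5)
        chain.binning = GenomicBinning("c", 1000, 40)
        rng = np.random.default_rng(2)
        pairs = set()
        while len(pairs) < 10:
            i, j = sorted(rng.choice(40, 2, replace=False))
            if j - i >= 2:
                pairs.add((int(i), int(j)))
        arr = np.array(sorted(pairs))
        params = ForceFieldParams()
        rs = RestraintSet(arr[:, 0], arr[:, 1], np.full(10, params.r0),
                          np.full(10, params.k_restraint), np.zeros(10, dtype=bool))
        cfg = SimulationConfig(seed=3, gate_fraction=0.8, max_steps_formation=30000,
                               check_interval=100)
        _, history, reason = run_bond_formation(chain, rs, params, cfg)
        assert reason == "gate_reached"
        assert history[-1].bonded_fraction >= 0.8
        for rec in history[:-1]:
            assert rec.bonded_fraction < 0.8

    def test_bonded_fraction_monotone_during_formation(self, two_domain_map, fast_cfg):
        bmap = two_domain_map(40, seed=2)
        chain = init_self_avoiding_walk(40, seed=2)
        chain.unmappable = bmap.unmappable.copy()
        chain.binning = bmap.binning
        from hicfold import restraints_from_map

        params = ForceFieldParams()
        rs = restraints_from_map(bmap, params)
        _, history, _ = run_bond_formation(chain, rs, params, fast_cfg(seed=2))
        fractions = [h.bonded_fraction for h in history]
        assert fractions == sorted(fractions)


class TestProduction:
    def test_zero_budget_returns_unchanged_with_single_entry(self, two_domain_map):
        bmap = two_domain_map(20, seed=1)
        chain = init_self_avoiding_walk(20, seed=1)
        chain.binning = bmap.binning
        cfg = SimulationConfig(seed=1, max_steps_production=0)
        out, history, reason = run_production(chain, RestraintSet.empty(),
                                              ForceFieldParams(), cfg, bmap)
        assert len(history) == 1
        np.testing.assert_array_equal(out.positions, chain.positions)
        assert reason == "max_steps_production"

    def test_frozen_converged_system_has_constant_pearson(self, two_domain_map):
        chain = straight_rod(20)
        bmap = contact_map_from_structure(chain, r_contact=2.0)
        cfg = SimulationConfig(seed=1, temperature=0.0, temperature_final=0.0,
                               max_steps_production=1000, check_interval=200)
        _, history, _ = run_production(chain, RestraintSet.empty(), ForceFieldParams(),
                                       cfg, bmap)
        rs = {h.pearson_r for h in history}
        assert rs == {1.0}

    def test_production_improves_on_initial_coil(self, two_domain_map):
        bmap = two_domain_map(60, seed=11)
        cfg = SimulationConfig(seed=11)
        coil = init_self_avoiding_walk(60, seed=11)
        coil.binning = bmap.binning
        r_before = map_pearson(contact_map_from_structure(coil, 2.0), bmap)
        res = reconstruct(bmap, cfg=cfg)
        assert res.final_pearson > (r_before if r_before is not None else -1.0)


class TestReconstruct:
    def test_empty_map_relaxes_coil_with_vacuous_satisfaction(self):
        binning = GenomicBinning("c", 1000, 12)
        bmap = BinaryContactMap(binning, set())
        cfg = SimulationConfig(seed=4, max_steps_formation=500,
                               max_steps_production=500, check_interval=100)
        res = reconstruct(bmap, cfg=cfg)
        assert res.satisfied_fraction == 1.0
        assert res.termination_formation == "gate_reached"

    def test_same_seed_reproduces_coordinates(self, two_domain_map, fast_cfg):
        bmap = two_domain_map(30, seed=6)
        a = reconstruct(bmap, cfg=fast_cfg(seed=6))
        b = reconstruct(bmap, cfg=fast_cfg(seed=6))
        np.testing.assert_array_equal(a.chain.positions, b.chain.positions)

    def test_history_spans_both_phases(self, two_domain_map, fast_cfg):
        bmap = two_domain_map(30, seed=7)
        res = reconstruct(bmap, cfg=fast_cfg(seed=7))
        phases = {h.phase for h in res.history}
        assert phases == {"formation", "production"}
        assert res.formation_end_step is not None
        assert res.bonded_fraction_at_gate is not None

    def test_stage_errors_are_annotated(self):
        binning = GenomicBinning("c", 1000, 20)
        bmap = BinaryContactMap(binning, set())
        # min_separation > bond length is rejected by the walk initializer
        cfg = SimulationConfig(seed=0, saw_min_separation=1.5)
        with pytest.raises(RuntimeError, match="stage 'initialization'"):
            reconstruct(bmap, cfg=cfg)


class TestSerialization:
    def test_structure_files_written_and_csv_round_trips(self, tmp_path):
        chain = init_self_avoiding_walk(10, seed=9)
        chain.unmappable[3] = True
        paths = write_structure_files(chain, tmp_path / "model")
        assert set(paths) == {"pdb", "xyz", "csv"}
        for p in paths.values():
            assert p.exists() and p.stat().st_size > 0
        back = read_structure_csv(paths["csv"])
        np.testing.assert_array_equal(back.positions, chain.positions)
        np.testing.assert_array_equal(back.unmappable, chain.unmappable)
        # PDB: one CA per bead on chain A with residue = bead + 1
        pdb = paths["pdb"].read_text()
        assert pdb.count(" CA ") == 10

    def test_history_csv_layout(self, tmp_path, two_domain_map, fast_cfg):
        bmap = two_domain_map(25, seed=3)
        res = reconstruct(bmap, cfg=fast_cfg(seed=3))
        p = write_history_csv(res.history, tmp_path / "h.csv")
        lines = p.read_text().splitlines()
        assert lines[0] == "step,phase,bonded_fraction,satisfied_fraction,pearson_r"
        assert len(lines) == len(res.history) + 1
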
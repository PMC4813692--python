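"""Coarse-grained chain model, energy terms, moves, clustering and funnels."""

import math

import numpy as np
import pytest

from xlfold.mbs_search import (
    BOND_LENGTH,
    ChainConformation,
    EnergyTerms,
    SearchConfig,
    _Scorer,
    cluster_pool,
    conformation_energy,
    funnel_quality,
    initialize_pool,
    propose_move,
    reallocate,
    run_search,
)
from xlfold.restraints import DistanceRestraint, RestraintParams
from xlfold.struct_analysis import ResidueSelection


def random_chain(n, rng):
    theta = rng.uniform(math.radians(75), math.radians(150), n - 2)
    tau = rng.uniform(-math.pi, math.pi, n - 3)
    return ChainConformation(theta=theta, tau=tau)


class TestChainGeometry:
    def test_bond_lengths_exact(self, rng):
        c = random_chain(30, rng)
        d = np.linalg.norm(np.diff(c.coords, axis=0), axis=1)
        assert np.allclose(d, BOND_LENGTH, atol=1e-6)

    def test_coords_regenerate_deterministically(self, rng):
        c = random_chain(20, rng)
        a = c.coords.copy()
        c.invalidate()
        assert np.array_equal(a, c.coords)

    def test_internal_coords_roundtrip_angles(self, rng):
        # the NeRF build must reproduce the requested angles and torsions
        c = random_chain(12, rng)
        pts = c.coords
        for k in range(len(c.theta)):
            u = pts[k] - pts[k + 1]
            v = pts[k + 2] - pts[k + 1]
            ang = math.acos(np.dot(u, v) / np.linalg.norm(u) / np.linalg.norm(v))
            assert ang == pytest.approx(c.theta[k], abs=1e-6)


class TestEnergy:
    def test_zero_weights_zero_energy(self, rng):
        c = random_chain(15, rng)
        terms = EnergyTerms(steric_weight=0, compaction_weight=0,
                            bias_weight=0, restraint_weight=0)
        assert conformation_energy(c, terms) == 0.0

    def test_steric_clash_positive(self):
        # fold the chain back onto itself: residues 1 and 3 nearly coincide
        theta = np.array([math.radians(10)] * 2)
        tau = np.array([0.0])
        c = ChainConformation(theta=theta, tau=tau)
        terms = EnergyTerms(compaction_weight=0, restraint_weight=0)
        assert conformation_energy(c, terms) > 0

    def test_restraint_lowers_energy(self, rng):
        c = random_chain(20, rng)
        terms = EnergyTerms(steric_weight=0, compaction_weight=0)
        d = float(np.linalg.norm(c.coords[0] - c.coords[14]))
        r = DistanceRestraint(1, 15, RestraintParams(u=max(d + 1, 2.0)))
        assert conformation_energy(c, terms, [r]) == pytest.approx(-1.0)

    def test_masked_restraint_contributes_nothing(self, rng):
        c = random_chain(20, rng)
        terms = EnergyTerms(steric_weight=0, compaction_weight=0)
        r = DistanceRestraint(1, 15)
        mask = ResidueSelection.parse("14-16")
        assert conformation_energy(c, terms, [r], mask) == 0.0

    def test_masked_residues_only_steric(self, rng):
        # two conformations differing only inside the mask must differ only
        # through the steric term; with sterics off the energies are equal
        n = 24
        terms = EnergyTerms(steric_weight=0.0, compaction_weight=0.7,
                            bias_weight=1.0,
                            ss_theta=np.full(n - 2, 1.55), ss_tau=np.full(n - 3, 0.9))
        mask = ResidueSelection.parse("1-6")
        a = random_chain(n, rng)
        b = ChainConformation(theta=a.theta.copy(), tau=a.tau.copy())
        b.theta[:3] = 1.0  # angles entirely within residues 1-5
        b.tau[:2] = 0.5
        ea = conformation_energy(a, terms, [], mask)
        eb = conformation_energy(b, terms, [], mask)
        # masked-residue Rg exclusion: identical unmasked coords
        assert ea == pytest.approx(eb, abs=1e-9)

    def test_restraint_outside_chain_named(self, rng):
        c = random_chain(12, rng)
        with pytest.raises(KeyError):
            conformation_energy(c, EnergyTerms(), [DistanceRestraint(1, 99)])


class TestMoves:
    def test_final_stage_window_small(self, rng):
        c = random_chain(40, rng)
        moved = propose_move(c, stage=6, rng=rng, n_stages=6)
        # a 3-residue window touches at most 4 angles and 4 torsions
        assert (moved.theta != c.theta).sum() <= 4
        assert (moved.tau != c.tau).sum() <= 4

    def test_bonds_preserved(self, rng):
        c = random_chain(40, rng)
        for stage in (1, 3, 6):
            m = propose_move(c, stage, rng, n_stages=6)
            d = np.linalg.norm(np.diff(m.coords, axis=0), axis=1)
            assert np.allclose(d, BOND_LENGTH, atol=1e-6)
            assert m.length == c.length

    def test_deterministic_given_rng_state(self, rng):
        c = random_chain(25, rng)
        a = propose_move(c, 3, np.random.default_rng(11), n_stages=6)
        b = propose_move(c, 3, np.random.default_rng(11), n_stages=6)
        assert np.array_equal(a.theta, b.theta)
        assert np.array_equal(a.tau, b.tau)

    def test_bad_stage(self, rng):
        with pytest.raises(ValueError):
            propose_move(random_chain(20, rng), 7, rng, n_stages=6)


class TestPoolAndClustering:
    def test_pool_reproducible(self):
        cfg = SearchConfig(length=20, structures_per_stage=30, seed=5)
        a = initialize_pool(cfg)
        b = initialize_pool(cfg)
        assert all(np.array_equal(x.theta, y.theta) for x, y in zip(a, b))
        assert len(a) == 30

    def test_short_chain_rejected(self):
        with pytest.raises(ValueError):
            initialize_pool(SearchConfig(length=5))

    def test_identical_conformations_one_funnel(self, rng):
        c = random_chain(20, rng)
        pool = [ChainConformation(theta=c.theta.copy(), tau=c.tau.copy())
                for _ in range(8)]
        funnels = cluster_pool(pool, cutoff=4.0, energies=[0.0] * 8)
        assert len(funnels) == 1
        assert sorted(funnels[0].member_ids) == list(range(8))

    def test_distant_conformations_two_funnels(self, rng):
        a = random_chain(20, rng)
        b = random_chain(20, rng)
        funnels = cluster_pool([a, b], cutoff=0.5, energies=[0.0, 1.0])
        assert len(funnels) == 2

    def test_every_member_assigned_once(self, rng):
        pool = [random_chain(15, rng) for _ in range(20)]
        funnels = cluster_pool(pool, cutoff=6.0, energies=list(range(20)))
        members = sorted(m for f in funnels for m in f.member_ids)
        assert members == list(range(20))


class TestFunnelQuality:
    def test_refinement_never_increases_energy(self, rng):
        pool = [random_chain(18, rng) for _ in range(6)]
        terms = EnergyTerms()
        sc = _Scorer(18, terms, [], None)
        for c in pool:
            c.energy = sc.energy(c)[0]
        funnels = cluster_pool(pool, 100.0, energies=[c.energy for c in pool])
        q = funnel_quality(funnels[0], pool, terms, rng=np.random.default_rng(3))
        five_best = sorted(c.energy for c in pool)[:5]
        assert q <= np.mean(five_best) + 1e-9

    def test_planted_minimum_wins(self, rng):
        # funnel around the restraint-satisfying geometry beats a random one
        n = 20
        terms = EnergyTerms(steric_weight=0, compaction_weight=0)
        helix = ChainConformation(theta=np.full(n - 2, 1.5774),
                                  tau=np.full(n - 3, 0.8734))
        d = float(np.linalg.norm(helix.coords[0] - helix.coords[n - 1]))
        restraints = [DistanceRestraint(1, n, RestraintParams(u=d + 1))]
        sc = _Scorer(n, terms, restraints, None)
        stretched = ChainConformation(theta=np.full(n - 2, math.radians(150)),
                                      tau=np.full(n - 3, math.pi * 0.9))
        pool = [helix, stretched]
        for c in pool:
            c.energy = sc.energy(c)[0]
        funnels = cluster_pool(pool, 0.5, energies=[c.energy for c in pool])
        qs = [funnel_quality(f, pool, terms, restraints,
                             rng=np.random.default_rng(0), refine_moves=0)
              for f in funnels]
        planted = [f for f in funnels if 0 in f.member_ids][0]
        assert planted.quality == min(qs)


class TestReallocation:
    def test_equal_qualities_equal_weights(self):
        from xlfold.mbs_search import Funnel
        fs = [Funnel([0], 0, quality=-3.0), Funnel([1], 1, quality=-3.0)]
        reallocate(fs, 1.0)
        assert fs[0].allocation == pytest.approx(0.5)

    def test_softmax_closed_form(self):
        from xlfold.mbs_search import Funnel
        fs = [Funnel([0], 0, quality=-10.0), Funnel([1], 1, quality=0.0)]
        reallocate(fs, 10.0)
        expect = math.e / (math.e + 1.0)
        assert fs[0].allocation == pytest.approx(expect, abs=1e-12)
        assert fs[1].allocation == pytest.approx(1 - expect, abs=1e-12)

    def test_high_temperature_limit_uniform(self):
        from xlfold.mbs_search import Funnel
        fs = [Funnel([0], 0, quality=-40.0), Funnel([1], 1, quality=13.0)]
        reallocate(fs, 1e9)
        assert fs[0].allocation == pytest.approx(0.5, abs=1e-6)

    def test_monotone_in_quality(self):
        from xlfold.mbs_search import Funnel
        fs = [Funnel([k], k, quality=float(q)) for k, q in enumerate([-5, -1, 2])]
        reallocate(fs, 2.0)
        assert fs[0].allocation >= fs[1].allocation >= fs[2].allocation

    def test_bad_temperature(self):
        from xlfold.mbs_search import Funnel
        with pytest.raises(ValueError):
            reallocate([Funnel([0], 0, quality=0.0)], 0.0)


@pytest.fixture(scope="module")
def small_result():
    cfg = SearchConfig(length=16, n_stages=3, structures_per_stage=12,
                       moves_per_structure=5, seed=9)
    return cfg, run_search(cfg, EnergyTerms(), [])


class TestRunSearch:
    def test_accounting(self, small_result):
        cfg, res = small_result
        assert len(res) == cfg.n_stages * cfg.structures_per_stage
        stages = {r.stage for r in res.records}
        assert stages == set(range(1, cfg.n_stages + 1))

    def test_every_record_in_exactly_one_funnel(self, small_result):
        _, res = small_result
        seen = sorted(m for f in res.funnels for m in f.member_ids)
        assert seen == [r.model_id for r in res.records]

    def test_seed_reproducible(self, small_result):
        cfg, res = small_result
        res2 = run_search(cfg, EnergyTerms(), [])
        assert np.array_equal(res.energies(), res2.energies())
        a = res.records[-1].conformation
        b = res2.records[-1].conformation
        assert np.array_equal(a.theta, b.theta)

    def test_noisy_restraints_barely_degrade_sampling(self):
        """The saturating restraint term makes sampling robust to planted
        false links: minimum-ensemble RMSD with 20% noise stays close to the
        noise-free result on paired seeds."""
        from xlfold.restraints import links_to_restraints
        from xlfold.struct_analysis import superpose_rmsd
        from xlfold.synthetic_data import (
            SimulationConfig, make_toy_structure, simulate_sda_links)

        degradations = []
        for seed in (0, 1, 2, 3, 4):
            mins = {}
            for noise in (0.0, 0.2):
                sim = SimulationConfig(seed=seed, n_links=60, noise_fraction=noise)
                ref, seq = make_toy_structure(sim)
                restraints = links_to_restraints(simulate_sda_links(ref, seq, sim))
                terms = EnergyTerms(compaction_weight=0.5, restraint_weight=4.0)
                cfg = SearchConfig(length=sim.n_residues, structures_per_stage=60,
                                   moves_per_structure=40, seed=seed)
                res = run_search(cfg, terms, restraints)
                mins[noise] = min(
                    superpose_rmsd(r.conformation.to_ca_structure(), ref)
                    for r in res.records)
            degradations.append(mins[0.2] - mins[0.0])
        assert np.median(degradations) < 1.0

    def test_energy_bookkeeping(self, small_result):
        _, res = small_result
        sc = _Scorer(res.config.length, EnergyTerms(), [], None)
        for r in res.records[::7]:
            r.conformation.invalidate()
            assert sc.energy(r.conformation)[0] == pytest.approx(r.energy, abs=1e-9)
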
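"""Platform-assembly SSA: propensities, kernel statistics, conservation."""

import math

import numpy as np
import pytest

import ripoptosim as rs
from ripoptosim.assembly import (PlatformOrigin, apply_channel,
                                 build_propensities, gillespie_step,
                                 make_initial_state, platform_mass,
                                 simulate_assembly)
from ripoptosim.params import SubunitMasses, ValidationError


def small_state(cfg, rng, n_origins=3, clustering=True):
    return make_initial_state(cfg, 0.0, clustering, rng, n_origins=n_origins)


def test_initial_state_seeds_one_rip1_per_trimer(cfg, rng):
    dose = 5.0
    st = make_initial_state(cfg, dose, True, rng)
    assert len(st.platforms) == rs.total_trimer_count(cfg, dose)
    assert all(p.n_rip1 == 1 for p in st.platforms)
    # seeds are debited from the cytosolic RIP1 pool
    total = st.rip1 + sum(p.n_rip1 for p in st.platforms)
    assert total == round(cfg.initial_nm.rip1 * cfg.copies_per_nm)


class TestBuildPropensities:
    def test_empty_pools_only_unimolecular(self, cfg, rng):
        st = small_state(cfg, rng)
        st.rip1 = st.rip3 = st.fadd = st.procasp8 = 0
        st.cflip_l = st.cflip_s = st.ded12 = 0
        chans = build_propensities(st)
        bimol = [c for c in chans if c.kind.endswith("_binding")
                 or c.kind == "rip1_elongation" or c.kind.startswith("terminal_block")]
        assert bimol == []

    def test_single_cis_pair(self, cfg, rng):
        st = small_state(cfg, rng, n_origins=1)
        st.rip1 = st.rip3 = st.fadd = st.procasp8 = 0
        st.cflip_l = st.cflip_s = st.ded12 = 0
        st.platforms[0].n_fadd = 2
        st.platforms[0].n_procasp8 = 2
        chans = [c for c in build_propensities(st) if c.kind == "cis_dimerization"]
        assert len(chans) == 1
        assert chans[0].propensity == pytest.approx(cfg.rates.k_cis_dimer)  # C(2,2)=1 pair

    def test_trans_requires_shared_cluster(self, cfg):
        rng = np.random.default_rng(0)
        # force a two-origin cluster by resampling until one appears
        for seed in range(100):
            st = make_initial_state(cfg, 0.0, True, np.random.default_rng(seed), n_origins=2)
            if len(st.assignment.clusters) == 1:
                break
        assert len(st.assignment.clusters) == 1
        for p in st.platforms:
            p.n_fadd, p.n_procasp8 = 1, 1
        st.rip1 = st.rip3 = st.fadd = st.procasp8 = 0
        st.cflip_l = st.cflip_s = st.ded12 = 0
        trans = [c for c in build_propensities(st) if c.kind == "trans_dimerization"]
        assert len(trans) == 1
        assert trans[0].propensity == pytest.approx(cfg.rates.k_trans_dimer)

        # disrupted clustering: same composition, zero trans channels
        st2 = make_initial_state(cfg, 0.0, False, np.random.default_rng(0), n_origins=2)
        for p in st2.platforms:
            p.n_fadd, p.n_procasp8 = 1, 1
        trans2 = [c for c in build_propensities(st2) if c.kind == "trans_dimerization"]
        assert trans2 == []


class TestGillespieStep:
    def test_zero_propensity_no_event(self, cfg, rng):
        st = small_state(cfg, rng, n_origins=1)
        st2, dt = gillespie_step(st, [], rng)
        assert math.isinf(dt)

    def test_waiting_time_is_exponential(self, cfg, rng):
        """Mean waiting time over 1e4 draws equals 1/a0 within 3 SE."""
        cfg = cfg.replace(rates={"koff_fadd_platform": 0.0,
                                 "koff_procasp8_ded": 0.0,
                                 "koff_cflip_l_ded": 0.0,
                                 "k_dimer_diss": 0.0,
                                 "k_casp8_activation": 0.0})
        st = small_state(cfg, rng, n_origins=1)
        st.platforms[0].n_fadd = 2
        st.platforms[0].n_procasp8 = 2
        st.rip1 = st.rip3 = st.fadd = st.procasp8 = 0
        st.cflip_l = st.cflip_s = st.ded12 = 0
        k = cfg.rates.k_cis_dimer
        n = 10_000
        dts = np.empty(n)
        for i in range(n):
            s = st.copy()
            chans = build_propensities(s)
            assert len(chans) == 1
            _, dts[i] = gillespie_step(s, chans, rng)
        # exponential: mean 1/k, SE = (1/k)/sqrt(n)
        assert abs(dts.mean() - 1 / k) <= 3 * (1 / k) / math.sqrt(n)
        assert dts.std() == pytest.approx(1 / k, rel=0.1)

    def test_channel_selection_multinomial(self, cfg, rng):
        """Two channels with rates (k, 4k) fire in proportion 1:4."""
        cfg = cfg.replace(rates={"koff_fadd_platform": 0.0,
                                 "koff_procasp8_ded": 0.0,
                                 "koff_cflip_l_ded": 0.0,
                                 "k_dimer_diss": 0.0,
                                 "k_casp8_activation": 0.0})
        st = small_state(cfg, rng, n_origins=1)
        st.rip1 = st.rip3 = st.fadd = st.procasp8 = 0
        st.cflip_l = st.cflip_s = st.ded12 = 0
        p = st.platforms[0]
        p.n_fadd = 8
        p.n_procasp8 = 2   # cis pairs C(2,2)=1 -> propensity k_cis
        p.n_cflip_l = 2    # hetero pairs 2*2=4 -> propensity 4*k_cis
        n = 10_000
        fired_cis = 0
        for i in range(n):
            s = st.copy()
            chans = build_propensities(s)
            kinds = {c.kind: c.propensity for c in chans}
            assert set(kinds) == {"cis_dimerization", "het_l_formation"}
            before = s.platforms[0].n_dimer
            gillespie_step(s, chans, rng)
            if s.platforms[0].n_dimer > before:
                fired_cis += 1
        p_expected = 1.0 / 5.0  # k vs 4k
        se = math.sqrt(p_expected * (1 - p_expected) / n)
        assert abs(fired_cis / n - p_expected) < 4 * se


def test_species_conservation_under_random_evolution(cfg):
    """Every ledger (free + bound + products) is invariant over 2000 events."""
    rng = np.random.default_rng(7)
    small = cfg.replace(geometry={"volume_l": cfg.geometry.volume_l / 200})
    st = make_initial_state(small, 0.0, True, rng, n_origins=6)
    before = st.species_totals()
    for _ in range(2000):
        chans = build_propensities(st)
        _, dt = gillespie_step(st, chans, rng)
        if math.isinf(dt):
            break
    after = st.species_totals()
    assert after == before
    # no negative pools anywhere
    assert min(st.rip1, st.rip3, st.fadd, st.procasp8,
               st.cflip_l, st.cflip_s, st.ded12) >= 0
    for p in st.platforms:
        assert p.free_ded_sites >= 0
        assert min(p.n_rip1, p.n_rip3, p.n_fadd, p.n_procasp8, p.n_cflip_l,
                   p.n_cflip_s, p.n_ded12, p.n_dimer, p.n_het_l, p.n_het_s) >= 0
        assert p.n_rip1 >= 1


@pytest.mark.parametrize(
    "origin, expected",
    [
        (PlatformOrigin(n_rip1=1), 76.0),
        (PlatformOrigin(n_rip1=10, n_fadd=1), 783.0),
        (PlatformOrigin(n_rip1=27), 2052.0),
    ],
)
def test_platform_mass(origin, expected):
    assert platform_mass(origin, SubunitMasses()) == pytest.approx(expected)
    assert platform_mass(PlatformOrigin(n_rip1=27), SubunitMasses()) >= 2000.0


def test_simulate_assembly_no_substrate_no_casp8(cfg):
    """With no free ProCasp8 (and no RIP1 beyond seeds) no Casp8 activates."""
    rng = np.random.default_rng(3)
    st = make_initial_state(cfg, 0.0, True, rng, n_origins=4)
    st.rip1 = 0
    st.procasp8 = 0
    traj = simulate_assembly(st, t_end=30.0, record_grid=5.0, rng=rng)
    assert np.all(traj.active_casp8_dimers == 0)


def test_simulate_assembly_monotone_cumulative(cfg):
    rng = np.random.default_rng(4)
    small = cfg.replace(geometry={"volume_l": cfg.geometry.volume_l / 100})
    st = make_initial_state(small, 0.0, True, rng, n_origins=8)
    traj = simulate_assembly(st, t_end=60.0, record_grid=2.0, rng=rng)
    for series in (traj.active_casp8_dimers, traj.ded12_released,
                   traj.rip1_rip3_heterodimers):
        assert np.all(np.diff(series) >= 0)


def test_rip1_dominates_platform_composition(cfg):
    """At t=20 min, 5 ng/mL, the ensemble-median RIP1 count per origin
    exceeds every other per-origin species count."""
    comps = []
    for i in range(10):
        traj, _ = rs.simulate_cell_hybrid(cfg, 5.0, True, seed=1000 + i,
                                          t_max=20.0, cascade_on=False)
        comps.append(traj.final_composition)
    comp = np.vstack(comps)
    med = np.median(comp, axis=0)
    rip1 = med[0]
    assert rip1 > max(med[1:10])  # all other composition counts
    assert rip1 > 5  # filaments have grown well beyond the seed
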
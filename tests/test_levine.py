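import numpy as np
import pytest

from wavevar.levine import (ARP, FIRING, READY, RRP, LevineParams, LevineState,
                            camp_field_step, clustered_pacemakers,
                            excitability_step, levine_cell_update,
                            levine_simulate, levine_threshold,
                            scattered_pacemakers)


def make_state(shape=(6, 6), phase=READY, E=0.0, pacemaker=False):
    return LevineState(
        phase=np.full(shape, phase, dtype=np.int8),
        tau=np.zeros(shape),
        E=np.full(shape, float(E)),
        is_pacemaker=np.full(shape, bool(pacemaker)),
    )


class TestThreshold:
    def test_exact_limits(self):
        p = LevineParams()
        assert levine_threshold(0.0, 0.0, p) == p.c_max
        assert np.isclose(levine_threshold(p.T_RRP, 0.0, p), p.c_min)
        assert levine_threshold(3.0, 1.0, p) == 0.0

    def test_strictly_decreasing_in_tau_and_E(self):
        p = LevineParams()
        taus = np.linspace(0, p.T_RRP, 25)
        for E in (0.0, 0.2, 0.4):
            vals = levine_threshold(taus, E, p)
            assert np.all(np.diff(vals) < 0)
        Es = np.linspace(0, p.e_max, 20)
        vals = levine_threshold(np.full(20, 2.0), Es, p)
        assert np.all(np.diff(vals) < 0)

    def test_tau_out_of_range_raises(self):
        p = LevineParams()
        with pytest.raises(ValueError):
            levine_threshold(p.T_RRP + 1.0, 0.0, p)


class TestFields:
    def test_pure_decay_factor(self):
        p = LevineParams(D=0.0)
        c0 = np.full((5, 5), 2.0)
        out = camp_field_step(c0, np.zeros((5, 5)), p)
        assert np.allclose(out, 2.0 * (1 - p.Gamma * p.dt))

    def test_zero_stays_zero(self):
        p = LevineParams()
        out = camp_field_step(np.zeros((5, 5)), np.zeros((5, 5)), p)
        assert np.all(out == 0.0)

    def test_source_conserved_without_degradation(self):
        # no-flux 8-point stencil conserves mass; only the source adds
        p = LevineParams(Gamma=0.0)
        c = np.random.default_rng(0).random((8, 8))
        s = np.zeros((8, 8))
        s[4, 4] = 1.0
        for _ in range(20):
            new = camp_field_step(c, s, p)
            assert np.isclose(new.sum() - c.sum(), p.r_F * p.dt, atol=1e-10)
            c = new

    def test_geometric_decay_over_many_steps(self):
        p = LevineParams(D=0.3)
        c = np.random.default_rng(1).random((10, 10))
        total0 = c.sum()
        for k in range(1, 50):
            c = camp_field_step(c, np.zeros((10, 10)), p)
            assert np.isclose(c.sum(), total0 * (1 - p.Gamma * p.dt) ** k,
                              rtol=1e-10)

    def test_excitability_monotone_and_capped(self):
        p = LevineParams(eta=0.1, beta=0.2)
        E = np.full((4, 4), p.e_max - 0.01)
        c = np.full((4, 4), 5.0)
        for _ in range(30):
            E2 = excitability_step(E, c, p)
            assert np.all(E2 >= E)
            assert np.all(E2 <= p.e_max)
            E = E2
        assert np.all(E == p.e_max)

    def test_unchanged_when_eta_beta_zero(self):
        p = LevineParams(eta=0.0, beta=0.0)
        E = np.random.default_rng(2).random((4, 4)) * p.e_max
        assert np.array_equal(excitability_step(E, np.ones((4, 4)), p), E)


class TestCellMachine:
    def test_ready_cell_fires_above_c_min(self):
        p = LevineParams()
        st = make_state()
        c = np.full((6, 6), p.c_min * 1.01)
        new = levine_cell_update(st, c, p, np.random.default_rng(0))
        assert np.all(new.phase == FIRING)

    def test_absolute_refractory_never_fires(self):
        p = LevineParams()
        st = make_state(phase=ARP)
        c = np.full((6, 6), 1e6)
        new = levine_cell_update(st, c, p, np.random.default_rng(0))
        assert not np.any(new.phase == FIRING)

    def test_certain_pacemaker_fires_from_quiet(self):
        p = LevineParams(p_F=1.0)
        rng = np.random.default_rng(0)
        new = make_state(pacemaker=True)
        # per-step probability is p_F * dt; within a few steps all fire
        fired = np.zeros((6, 6), dtype=bool)
        for _ in range(200):
            new = levine_cell_update(new, np.zeros((6, 6)), p, rng)
            fired |= new.phase == FIRING
            if fired.all():
                break
        assert fired.all()

    def test_full_cycle_durations(self):
        """A firing episode is followed by exactly T_ARP of absolute
        refractoriness before any re-activation is possible."""
        p = LevineParams(p_F=0.0)
        st = make_state(shape=(3, 3), phase=FIRING)
        c_high = np.full((3, 3), 1e6)
        phases = []
        for _ in range(int((p.firing_duration + p.T_ARP + p.T_RRP + 1) / p.dt)):
            st = levine_cell_update(st, c_high, p, np.random.default_rng(0))
            phases.append(int(st.phase[1, 1]))
        arr = np.array(phases)
        # the first absolute-refractory stretch lasts exactly T_ARP
        arp_idx = np.flatnonzero(arr == ARP)
        first_streak = 1
        for a, b in zip(arp_idx[:-1], arp_idx[1:]):
            if b == a + 1:
                first_streak += 1
            else:
                break
        assert np.isclose(first_streak * p.dt, p.T_ARP, atol=2 * p.dt)
        # with saturating cAMP the cell re-fires right after ARP, never sooner
        refires = np.flatnonzero((arr == FIRING)[1:] & (arr[:-1] != FIRING)) + 1
        assert len(refires) >= 1
        assert refires[0] * p.dt >= p.firing_duration + p.T_ARP - 2 * p.dt


class TestSimulate:
    def test_no_sources_stays_zero(self):
        p = LevineParams(eta=0.0, E0=0.0)
        pm = np.zeros((20, 20), dtype=bool)
        cube = levine_simulate(pm, p, T=20.0, seed=0, record_every=10)
        assert np.all(cube.data == 0.0)

    def test_seed_reproducibility(self):
        p = LevineParams(p_F=0.1, E0=0.25)
        rng = np.random.default_rng(4)
        pm = scattered_pacemakers((20, 20), 0.2, rng)
        a = levine_simulate(pm, p, T=30.0, seed=11, record_every=10)
        b = levine_simulate(pm, p, T=30.0, seed=11, record_every=10)
        assert np.array_equal(a.data, b.data)

    def test_open_wavefront_spiral_selfsustains(self):
        p = LevineParams(E0=0.25, p_F=0.0)
        cube = levine_simulate(np.zeros((50, 50), bool), p, T=120.0, seed=0,
                               record_every=10, init_wavefront=True)
        active = (cube.data > 0.5).sum(axis=(1, 2))
        assert active[-1] > 100


class TestLayouts:
    def test_scattered_count(self):
        m = scattered_pacemakers((40, 40), 0.19, np.random.default_rng(0))
        assert m.sum() == round(0.19 * 1600)

    def test_clustered_count_and_compactness(self):
        rng = np.random.default_rng(1)
        m = clustered_pacemakers((60, 60), 0.19, rng, n_clusters=4)
        assert m.sum() == round(0.19 * 3600)
        # clustered: mean nearest-neighbor distance between pacemakers is
        # smaller than for a uniform scatter of the same count
        from scipy.spatial import cKDTree
        ys, xs = np.nonzero(m)
        d_c = cKDTree(np.c_[ys, xs]).query(np.c_[ys, xs], k=2)[0][:, 1].mean()
        ms = scattered_pacemakers((60, 60), 0.19, rng)
        ys, xs = np.nonzero(ms)
        d_s = cKDTree(np.c_[ys, xs]).query(np.c_[ys, xs], k=2)[0][:, 1].mean()
        assert d_c < d_s
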
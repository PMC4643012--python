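import numpy as np
import pytest
from scipy import ndimage

from wavevar.minimal_models import (CAGrid, CAStochasticParams, E, R, S,
                                    SchnakenbergParams, ca_open_wavefront_init,
                                    ca_run, ca_step, ca_step_stochastic,
                                    classify_turing_pattern, schnakenberg_rhs,
                                    schnakenberg_simulate,
                                    schnakenberg_steady_state,
                                    turing_dispersion)


class TestCADeterministic:
    def test_all_susceptible_stays_quiet(self):
        g = CAGrid(np.full((6, 6), S), r=1)
        assert np.all(ca_step(g).states == S)

    def test_single_excited_site_rule(self):
        st = np.full((7, 7), S)
        st[3, 3] = E
        new = ca_step(CAGrid(st, r=1))
        assert new.states[3, 3] == R
        for i, j in [(2, 3), (4, 3), (3, 2), (3, 4)]:
            assert new.states[i, j] == E
        assert np.sum(new.states == E) == 4

    def test_excited_always_refractory_next_and_no_skip(self):
        rng = np.random.default_rng(3)
        st = rng.choice([S, E, R], size=(10, 10)).astype(np.uint8)
        g = CAGrid(st, r=2)
        for _ in range(6):
            new = ca_step(g)
            # every E site becomes R; no E site jumps straight to S
            assert np.all(new.states[g.states == E] == R)
            g = new

    def test_site_count_conserved(self):
        g = ca_open_wavefront_init(12, 12, 6)
        n = g.states.size
        for gr in ca_run(g, 20):
            assert gr.states.size == n

    def test_replay_identical(self):
        g = ca_open_wavefront_init(20, 20, 10)
        a = ca_run(g, 50)
        b = ca_run(g, 50)
        for x, y in zip(a, b):
            assert np.array_equal(x.states, y.states)


class TestOpenWavefront:
    def test_construction_counts(self):
        for length in (1, 11):
            g = ca_open_wavefront_init(12, 12, length)
            assert np.sum(g.states == E) == length
            assert np.sum(g.states == R) == length

    def test_bad_length_raises(self):
        with pytest.raises(ValueError):
            ca_open_wavefront_init(10, 10, 0)
        with pytest.raises(ValueError):
            ca_open_wavefront_init(10, 10, 11)

    def test_front_advances_and_open_end_grows(self):
        # hand-executed rules: the E row ignites the row above (the row below
        # is refractory) plus one site laterally at the open end
        g = ca_open_wavefront_init(8, 8, 4)
        row = 4
        new = ca_step(g)
        x0 = (8 - 4) // 2
        assert np.all(new.states[row - 1, x0:x0 + 4] == E)  # advanced row
        assert np.all(new.states[row, x0:x0 + 4] == R)      # old front now R
        # lateral ignition at both open ends of the E segment
        assert new.states[row, x0 - 1] == E
        assert new.states[row, x0 + 4] == E


class TestCAStochastic:
    def test_reduces_to_deterministic_when_f0_p1(self):
        rng = np.random.default_rng(0)
        st = np.random.default_rng(5).choice([S, E, R], size=(9, 9)).astype(np.uint8)
        g1 = CAGrid(st.copy(), r=1)
        g2 = CAGrid(st.copy(), r=1)
        sp = CAStochasticParams(f=0.0, p=1.0)
        for _ in range(10):
            g1 = ca_step(g1)
            g2 = ca_step_stochastic(g2, sp, rng)
            assert np.array_equal(g1.states, g2.states)

    def test_f1_ignites_everything(self, rng):
        g = CAGrid(np.full((6, 6), S))
        new = ca_step_stochastic(g, CAStochasticParams(f=1.0, p=1.0), rng)
        assert np.all(new.states == E)

    def test_long_run_mean_matches_independent_oracle(self):
        """Excited fraction in steady state vs a convolution-based oracle
        implementation of the same rules (distinct code path, own RNG)."""
        f, p = 0.01, 0.3
        shape = (30, 30)
        n_steps, burn = 3000, 500

        def run_main(seed):
            rng = np.random.default_rng(seed)
            g = CAGrid(np.full(shape, S))
            sp = CAStochasticParams(f=f, p=p)
            fracs = []
            for i in range(n_steps):
                g = ca_step_stochastic(g, sp, rng)
                if i >= burn:
                    fracs.append(np.mean(g.states == E))
            return np.array(fracs)

        def run_oracle(seed):
            rng = np.random.default_rng(seed)
            st = np.full(shape, S, dtype=int)
            kernel = np.array([[0, 1, 0], [1, 0, 1], [0, 1, 0]])
            fracs = []
            for i in range(n_steps):
                excited = (st == E).astype(int)
                nbr = ndimage.convolve(excited, kernel, mode="constant") > 0
                u = rng.random(shape)
                new = np.where(st == E, R, st)
                new = np.where((st == R) & (u < p), S, new)
                ignite = (st == S) & (nbr | (u < f))
                new = np.where(ignite, E, new)
                st = new
                if i >= burn:
                    fracs.append(np.mean(st == E))
            return np.array(fracs)

        a = run_main(1)
        b = run_oracle(2)
        # SE from batch means (correlated series)
        def se(x, nb=25):
            bm = x[: len(x) // nb * nb].reshape(nb, -1).mean(axis=1)
            return bm.std(ddof=1) / np.sqrt(nb)

        tol = 3.0 * np.hypot(se(a), se(b))
        assert abs(a.mean() - b.mean()) < tol


class TestSchnakenberg:
    def test_steady_state_zeroes_reactions(self):
        p = SchnakenbergParams(c2=1.00)
        us, vs = schnakenberg_steady_state(p)
        assert np.isclose(us, 1.05)
        assert np.isclose(vs, 1.00 / 1.1025)
        du, dv = schnakenberg_rhs(np.full((5, 5), us), np.full((5, 5), vs), p)
        assert np.allclose(du, 0.0, atol=1e-12)
        assert np.allclose(dv, 0.0, atol=1e-12)

    def test_u_zero_gives_positive_production(self):
        p = SchnakenbergParams()
        du, _ = schnakenberg_rhs(np.zeros((4, 4)), np.ones((4, 4)), p)
        assert np.all(du == p.gamma_s * p.c1)
        assert np.all(du > 0)

    def test_reaction_linear_in_gamma(self):
        u = np.full((4, 4), 0.7)
        v = np.full((4, 4), 1.3)
        d1 = schnakenberg_rhs(u, v, SchnakenbergParams(gamma_s=2.0))
        d2 = schnakenberg_rhs(u, v, SchnakenbergParams(gamma_s=4.0))
        assert np.allclose(d2[0], 2 * d1[0]) and np.allclose(d2[1], 2 * d1[1])

    def test_dispersion_matches_trace_det_oracle(self):
        # independent closed-form: growth = max eigenvalue of J - k^2 D via
        # the trace/determinant quadratic formula
        p = SchnakenbergParams(c2=1.00)
        us, vs = schnakenberg_steady_state(p)
        g = p.gamma_s
        fu = g * (-p.c_m1 + 2 * p.c3 * us * vs)
        fv = g * p.c3 * us * us
        gu = g * (-2 * p.c3 * us * vs)
        gv = -g * p.c3 * us * us
        for k in (0.0, 0.5, 0.9, 1.5):
            a = fu - p.Du * k * k
            d = gv - p.Dv * k * k
            tr, det = a + d, a * d - fv * gu
            disc = max(tr * tr / 4 - det, 0.0)
            expected = tr / 2 + np.sqrt(disc) if disc >= 0 else tr / 2
            assert np.isclose(turing_dispersion(p, k), expected, atol=1e-9)

    @pytest.mark.parametrize("c2", [1.00, 1.57])
    def test_positive_band_at_paper_parameters(self, c2):
        p = SchnakenbergParams(c2=c2)
        assert turing_dispersion(p, 0.0) < 0  # homogeneous state stable
        ks = np.linspace(0.1, 2.0, 100)
        assert max(turing_dispersion(p, k) for k in ks) > 0

    def test_equal_diffusion_has_no_band(self):
        p = SchnakenbergParams(c2=1.00, Du=1.0, Dv=1.0)
        ks = np.linspace(0.0, 3.0, 150)
        rates = [turing_dispersion(p, k) for k in ks]
        assert max(rates[1:]) <= rates[0] + 1e-12

    def test_homogeneous_start_stays_homogeneous(self):
        p = SchnakenbergParams(c2=1.00)
        u, v = schnakenberg_simulate(p, shape=(16, 16), T=5.0, dt=0.005,
                                     seed=0, init_amplitude=0.0)
        assert np.ptp(u) < 1e-10 and np.ptp(v) < 1e-10


class TestPatternClassifier:
    def test_synthetic_disks_classify_as_spots(self):
        yy, xx = np.mgrid[0:60, 0:60]
        f = np.zeros((60, 60))
        for cy in range(6, 60, 12):
            for cx in range(6, 60, 12):
                f[(yy - cy) ** 2 + (xx - cx) ** 2 <= 9] = 1.0
        assert classify_turing_pattern(f) == "spots"

    def test_synthetic_bands_classify_as_stripes(self):
        xx = np.arange(60)[None, :]
        f = np.broadcast_to(np.sin(2 * np.pi * xx / 12.0), (60, 60)).copy()
        assert classify_turing_pattern(f) == "stripes"

    def test_homogeneous_is_none(self):
        assert classify_turing_pattern(np.full((30, 30), 2.0)) == "none"
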
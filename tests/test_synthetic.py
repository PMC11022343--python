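"""Generator: design arithmetic, logistic growth, walkers, rendering,
counting noise."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from strainlink.config import DesignConfig
from strainlink.synthetic.design import design_counts, enumerate_design
from strainlink.synthetic.growth import grow_population
from strainlink.synthetic.render import ellipse_axes, render_frames
from strainlink.synthetic.sampling import observe_count, observe_density
from strainlink.synthetic.walkers import (
    GroundTruthTrack,
    MicrocosmState,
    kappa_for_linearity,
    mean_cosine,
    simulate_individuals,
)
from strainlink.synthetic.generate import simulate_experiment


class TestDesign:
    def test_full_design_counts(self, full_design):
        counts = design_counts(full_design)
        assert counts["conditions"] == 54
        assert counts["assays"] == 162
        assert counts["sample_pairs"] == 810
        assert counts["picture_series"] == 2430
        assert counts["points_per_curve"] == 15
        assert counts["frames_per_sample"] == 100

    def test_degenerate_design(self):
        cfg = DesignConfig(
            species=("X",),
            strains_per_species=1,
            temperatures=(20.0,),
            pollutant_levels=(0.0,),
            dilution_fractions=(0.5,),
            replicates=1,
            time_points=2,
            sampling_days=(0.0, 0.25),
        )
        counts = design_counts(cfg)
        assert counts["conditions"] == 1
        assert counts["assays"] == 1
        assert counts["picture_series"] == 2

    @pytest.mark.parametrize("n_species,n_temp,n_poll,reps,n_dil", [(1, 2, 3, 2, 4), (2, 3, 3, 3, 5)])
    def test_count_arithmetic(self, n_species, n_temp, n_poll, reps, n_dil):
        cfg = DesignConfig(
            species=tuple(f"sp{i}" for i in range(n_species)),
            temperatures=tuple(20.0 + i for i in range(n_temp)),
            pollutant_levels=tuple(10.0 * i for i in range(n_poll)),
            replicates=reps,
            dilution_fractions=tuple(np.linspace(0.2, 0.8, n_dil)),
        )
        c = design_counts(cfg)
        curves = n_species * 3 * n_temp * n_poll
        assert c["conditions"] == curves
        assert c["assays"] == curves * reps
        assert c["picture_series"] == curves * reps * n_dil * 3
        assert len(enumerate_design(cfg)) == c["sample_pairs"]

    def test_rejects_empty_factors(self):
        with pytest.raises(ValueError):
            DesignConfig(temperatures=())
        with pytest.raises(ValueError):
            DesignConfig(dilution_fractions=(0.5, 0.3))  # not increasing


class TestGrowth:
    def test_exponential_doubling(self):
        assert grow_population(np.log(2), 0.0, 100.0, 1.0) == pytest.approx(200.0, abs=1e-6)

    def test_equilibrium_at_carrying_capacity(self):
        for dt in (0.1, 1.0, 10.0):
            assert grow_population(1.0, -0.001, 1000.0, dt) == pytest.approx(1000.0)

    @pytest.mark.parametrize(
        "mu,alpha,n0",
        [(1.0, -0.001, 100.0), (0.8, -1.6e-4, 900.0), (2.0, -0.0005, 3500.0), (0.0, -0.001, 500.0)],
    )
    def test_matches_ode_integrator(self, mu, alpha, n0):
        """Closed form vs high-accuracy Runge-Kutta on dN/dt = N(mu+aN)."""
        sol = solve_ivp(
            lambda t, n: n * (mu + alpha * n), (0.0, 1.0), [n0],
            rtol=1e-10, atol=1e-10, dense_output=True,
        )
        ours = grow_population(mu, alpha, n0, 1.0)
        ref = sol.y[0, -1]
        assert abs(ours - ref) / ref < 1e-6

    def test_short_interval_linearization(self):
        mu, alpha, n0 = 1.0, -0.001, 400.0
        dt = 1e-7
        pcgr = np.log(grow_population(mu, alpha, n0, dt) / n0) / dt
        assert pcgr == pytest.approx(mu + alpha * n0, rel=1e-5)

    def test_rejects_bad_inputs(self):
        with pytest.raises(ValueError):
            grow_population(np.nan, 0.0, 100.0, 1.0)
        with pytest.raises(ValueError):
            grow_population(1.0, -0.001, -5.0, 1.0)


def _state(density=50.0):
    return MicrocosmState("T", "s", 22.0, 10.0, 1, 0.5, 0, 0.0, true_density=density)


class TestWalkers:
    def test_straight_walker_geometry(self, flat_profile, rng):
        """kappa=inf walker: gross = net = (n-1) * speed / fps."""
        prof = flat_profile
        prof = type(prof)(
            strain_id="straight", species="T",
            trait_means=(50.0, 1.0, 200.0, 2.0), trait_sd=(0.0, 0.0, 0.0, 0.0),
        )
        tracks = simulate_individuals(_state(), prof, 10, 10.0, rng, (2048, 2048), n_individuals=5)
        for t in tracks:
            steps = np.diff(t.positions, axis=0)
            gross = np.hypot(steps[:, 0], steps[:, 1]).sum()
            net = np.hypot(*(t.positions[-1] - t.positions[0]))
            assert gross == pytest.approx(45.0, rel=1e-9)
            assert net == pytest.approx(45.0, rel=1e-6)

    def test_zero_speed_stays_put(self, rng):
        from strainlink.config import StrainProfile

        prof = StrainProfile(
            strain_id="still", species="T",
            trait_means=(0.0, 0.8, 200.0, 2.0), trait_sd=(0.0, 0.0, 0.0, 0.0),
        )
        tracks = simulate_individuals(_state(), prof, 10, 10.0, rng, (512, 512), n_individuals=3)
        for t in tracks:
            assert np.allclose(t.positions, t.positions[0])

    def test_net_over_gross_matches_brute_force_crw(self, rng):
        """Walker straightness vs an independent minimal CRW simulator
        at the same turning concentration."""
        kappa = kappa_for_linearity(0.7, 99)
        # package walkers
        from strainlink.config import StrainProfile

        prof = StrainProfile(
            strain_id="crw", species="T",
            trait_means=(50.0, 0.7, 200.0, 2.0), trait_sd=(0.0, 0.0, 0.0, 0.0),
        )
        tracks = simulate_individuals(
            _state(), prof, 100, 10.0, rng, (100000, 100000), n_individuals=400
        )
        ratios = []
        for t in tracks:
            steps = np.diff(t.positions, axis=0)
            gross = np.hypot(steps[:, 0], steps[:, 1]).sum()
            net = np.hypot(*(t.positions[-1] - t.positions[0]))
            ratios.append(net / gross)
        # brute-force oracle: accumulate headings directly
        rng2 = np.random.default_rng(999)
        oracle = []
        for _ in range(400):
            turns = rng2.vonmises(0.0, kappa, size=99)
            headings = np.cumsum(np.concatenate([[rng2.uniform(0, 2 * np.pi)], turns]))
            vecs = np.column_stack([np.cos(headings), np.sin(headings)])
            pos = np.cumsum(vecs, axis=0)
            oracle.append(np.hypot(*pos[-1]) / 99.0)
        se = np.sqrt(np.var(ratios) / 400 + np.var(oracle) / 400)
        assert abs(np.mean(ratios) - np.mean(oracle)) < 2 * se

    def test_kappa_mapping_monotone(self):
        ks = [kappa_for_linearity(l, 99) for l in (0.2, 0.5, 0.8, 0.95)]
        assert all(b > a for a, b in zip(ks, ks[1:]))
        assert np.isinf(kappa_for_linearity(1.0, 99))
        assert 0.0 < mean_cosine(2.0) < mean_cosine(5.0) < 1.0

    def test_additive_mu_surface_when_no_interaction(self, profiles):
        """interaction_coef=0: two-way interaction SS of the noiseless
        mu(T, P) surface is exactly zero."""
        prof = profiles["Colpidium-S1"]
        temps, polls = (20.0, 22.0, 24.0), (0.0, 10.0, 20.0)
        grid = np.array([[prof.demography_at(t, p)[0] for p in polls] for t in temps])
        # interaction SS of a two-way table with one observation per cell
        grand = grid.mean()
        rowm = grid.mean(axis=1, keepdims=True)
        colm = grid.mean(axis=0, keepdims=True)
        resid = grid - rowm - colm + grand
        assert np.abs(resid).max() < 1e-12


class TestRender:
    def test_zero_individuals_dark_stack(self, rng):
        stack, overlaps = render_frames([], (128, 128), noise_sd=5.0, rng=rng, n_frames=20)
        assert stack.shape == (20, 128, 128)
        assert overlaps == []
        # no pixel anywhere near the detection threshold
        assert stack.max() < 40
        assert np.quantile(stack, 0.999) <= 3.1 * 5.0

    def test_single_ellipse_area_recovered(self, rng):
        track = GroundTruthTrack(
            track_id=0,
            positions=np.tile([64.0, 64.0], (5, 1)),
            headings=np.zeros(5),
            area=400.0,
            aspect=2.0,
            speed=0.0,
            linearity=1.0,
        )
        stack, _ = render_frames([track], (128, 128), noise_sd=0.0, rng=rng, n_frames=5)
        lit = (stack[0] > 100).sum()
        assert abs(lit - 400.0) / 400.0 < 0.10

    def test_overlap_bookkeeping(self, rng):
        mk = lambda i, x: GroundTruthTrack(
            i, np.tile([x, 64.0], (3, 1)), np.zeros(3), 400.0, 1.5, 0.0, 1.0
        )
        _, overlaps = render_frames([mk(0, 64.0), mk(1, 66.0)], (128, 128), 0.0, rng, 3)
        assert {(a, b) for _, a, b in overlaps} == {(0, 1)}


class TestSampling:
    def test_zero_density(self, rng):
        assert observe_density(0.0, 0.81, rng) == 0.0

    def test_mean_recovers_density(self, rng):
        d = 500.0
        draws = np.array([observe_density(d, 0.81, rng) for _ in range(10000)])
        se = draws.std() / np.sqrt(len(draws))
        assert abs(draws.mean() - d) < 3 * se

    def test_overdispersed_variance_matches_closed_form(self, rng):
        d, vol, theta = 1000.0, 0.81, 50.0
        m = d * vol
        counts = np.array([observe_count(d, vol, rng, overdispersion=theta) for _ in range(20000)])
        expected = m + m**2 / theta  # Poisson-gamma (negative binomial)
        assert abs(counts.var() - expected) / expected < 0.1


class TestDeterminism:
    def test_identical_seeds_identical_experiment(self, small_design):
        a = simulate_experiment(small_design, seed=7)
        b = simulate_experiment(small_design, seed=7)
        assert a.equals(b)

    def test_different_seeds_differ(self, small_design):
        a = simulate_experiment(small_design, seed=7)
        b = simulate_experiment(small_design, seed=8)
        assert not a["density"].equals(b["density"])
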
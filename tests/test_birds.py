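"""Annual-cycle population model: vital rates, recursion, growth rates."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import grassbird as gb

G, A, F = gb.LandCover.GRASSLAND, gb.LandCover.AGRICULTURE, gb.LandCover.FOREST
B, S, W = (gb.LandscapeRole.BREEDING, gb.LandscapeRole.STOPOVER,
           gb.LandscapeRole.WINTERING)


def params(**over):
    return gb.DemographicParams(**over)


def big_capacity_params(**over):
    """Parameters whose seasonal capacities never bind at test abundances."""
    base = dict(
        k_breeding_per_grass_pixel=1e9,
        k_stopover_per_grass_pixel=1e9,
        k_winter_per_grass_pixel=1e9,
    )
    base.update(over)
    return gb.DemographicParams(**base)


class TestReproduction:
    def test_no_grassland_means_no_nests(self, uniform_landscape):
        ls = uniform_landscape(A, role=B)
        assert gb.reproduction(ls, 100.0, params()) == 0.0

    def test_zero_population_is_safe(self, uniform_landscape):
        ls = uniform_landscape(G, role=B)
        assert gb.reproduction(ls, 0.0, params()) == 0.0

    def test_matches_brute_force_pixel_sum(self, random_landscape):
        # independent oracle: explicit per-pixel loop over the grid
        p = params()
        ls = random_landscape(p=(0.6, 0.25, 0.15), n_rows=15, n_cols=15,
                              role=B, seed=21)
        f_pot = 0.0
        n_grass = 0
        for r in range(15):
            for c in range(15):
                if ls.grid[r, c] != int(G):
                    continue
                n_grass += 1
                counts = gb.neighborhood_counts(ls, r, c, radius=1)
                total = sum(counts.values())
                f_ng = (counts[A] + counts[F]) / total
                f_pot += (
                    p.nest_density_per_grass_pixel
                    * p.fledglings_per_successful_nest
                    * p.nest_survival_base
                    * (1 - p.edge_penalty * f_ng)
                )
        k_b = p.k_breeding_per_grass_pixel * n_grass
        n = 0.5 * k_b  # below capacity: R_b = F_pot / K_b
        assert gb.reproduction(ls, n, p) == pytest.approx(f_pot / k_b)

    def test_above_capacity_rate_declines(self, uniform_landscape):
        ls = uniform_landscape(G, 20, 20, role=B)
        p = params()
        below = gb.reproduction(ls, 100.0, p)
        above = gb.reproduction(ls, 2 * 400 * p.k_breeding_per_grass_pixel, p)
        assert above == pytest.approx(below / 2)

    def test_wrong_role_rejected(self, uniform_landscape):
        with pytest.raises(ValueError, match="breeding"):
            gb.reproduction(uniform_landscape(G, role=W), 10.0, params())


class TestStopoverSurvival:
    def test_perfect_grassland(self, uniform_landscape):
        p = params(stopover_survival_by_cover={G: 1.0, A: 0.5, F: 0.5})
        ls = uniform_landscape(G, role=S)
        assert gb.stopover_survival(ls, 10.0, p) == pytest.approx(1.0)

    def test_zero_occupancy_forces_floor(self, uniform_landscape):
        p = params(occupancy_by_cover={G: 0.0, A: 0.0, F: 0.0})
        ls = uniform_landscape(G, role=S)
        assert gb.stopover_survival(ls, 10.0, p) == p.matrix_survival_floor

    def test_matches_hand_enumeration_on_tiny_grid(self):
        # 2x2 grid [G, A; A, G]: enumerate occupancy weights and patch
        # qualities pixel by pixel, independent of the implementation
        grid = np.array([[int(G), int(A)], [int(A), int(G)]])
        ls = gb.Landscape(grid=grid, role=S)
        occ = {G: 1.0, A: 0.25, F: 0.0}
        sv = {G: 0.9, A: 0.3, F: 0.0}
        p = big_capacity_params(
            occupancy_by_cover=occ, stopover_survival_by_cover=sv
        )
        occ_grid = np.array([[1.0, 0.25], [0.25, 1.0]])
        sv_grid = np.array([[0.9, 0.3], [0.3, 0.9]])
        weights, quality = np.zeros((2, 2)), np.zeros((2, 2))
        for r in range(2):
            for c in range(2):
                neigh = [occ_grid[rr, cc] for rr in range(2) for cc in range(2)
                         if (rr, cc) != (r, c)]
                weights[r, c] = occ_grid[r, c] * np.mean(neigh)
                quality[r, c] = sv_grid.mean()  # 3x3 window covers the grid
        expected = (weights * quality).sum() / weights.sum()
        assert gb.stopover_survival(ls, 1.0, p) == pytest.approx(expected)

    def test_overflow_mixes_with_floor(self, uniform_landscape):
        p = params(stopover_survival_by_cover={G: 0.9, A: 0.1, F: 0.1},
                   k_stopover_per_grass_pixel=1.0)
        ls = uniform_landscape(G, 10, 10, role=S)  # capacity 100
        s = gb.stopover_survival(ls, 200.0, p)
        assert s == pytest.approx(0.5 * 0.9 + 0.5 * p.matrix_survival_floor)


class TestMigrationSurvival:
    def test_three_perfect_stops(self, uniform_landscape):
        p = big_capacity_params(stopover_survival_by_cover={G: 1.0, A: 0, F: 0})
        stops = [uniform_landscape(G, role=S) for _ in range(3)]
        assert gb.migration_survival(stops, 50.0, p) == pytest.approx(1.0)

    def test_product_of_stop_survivals(self, uniform_landscape):
        p = big_capacity_params(
            stopover_survival_by_cover={G: 0.9, A: 0.9, F: 0.9}
        )
        stops = [uniform_landscape(G, role=S) for _ in range(3)]
        assert gb.migration_survival(stops, 50.0, p) == pytest.approx(0.9**3)

    def test_lethal_stop_is_absorbing(self, uniform_landscape):
        p = big_capacity_params(
            stopover_survival_by_cover={G: 0.0, A: 0.0, F: 0.0},
            matrix_survival_floor=0.0,
        )
        stops = [uniform_landscape(G, role=S) for _ in range(3)]
        assert gb.migration_survival(stops, 50.0, p) == 0.0

    def test_wrong_stop_count_rejected(self, uniform_landscape):
        with pytest.raises(ValueError, match="3 stopovers"):
            gb.migration_survival([uniform_landscape(G, role=S)], 10.0, params())


class TestWinterSurvival:
    def test_under_capacity_equals_cover_survival(self, uniform_landscape):
        p = params(winter_survival_by_cover={G: 0.8, A: 0.1, F: 0.1})
        ls = uniform_landscape(G, 10, 10, role=W)  # capacity 200
        assert gb.winter_survival(ls, 100.0, p) == pytest.approx(0.8)

    def test_double_capacity_is_even_mixture(self, uniform_landscape):
        p = params(winter_survival_by_cover={G: 0.8, A: 0.1, F: 0.1},
                   k_winter_per_grass_pixel=1.0)
        ls = uniform_landscape(G, 10, 10, role=W)  # capacity 100
        s = gb.winter_survival(ls, 200.0, p)
        assert s == pytest.approx(0.5 * 0.8 + 0.5 * p.matrix_survival_floor)

    def test_unoccupiable_habitat_gives_floor(self, uniform_landscape):
        p = params(occupancy_by_cover={G: 1.0, A: 0.0, F: 0.0})
        ls = uniform_landscape(A, role=W)
        assert gb.winter_survival(ls, 50.0, p) == p.matrix_survival_floor


class TestStepAndGrowth:
    @pytest.mark.parametrize(
        "n,rb,sf,sw,ss,expected",
        [
            (100, 0.5, 1, 1, 1, 150.0),
            (0, 0.5, 0.9, 0.9, 0.9, 0.0),
            (100, 0.0, 0.9, 0.8, 0.9, 64.8),
        ],
    )
    def test_recursion_arithmetic(self, n, rb, sf, sw, ss, expected):
        assert gb.step_population(n, rb, sf, sw, ss) == pytest.approx(expected)

    def test_invalid_survival_rejected(self):
        with pytest.raises(ValueError, match="S_w"):
            gb.step_population(10, 0.1, 0.9, 1.2, 0.9)

    def test_flat_trajectory_growth_zero(self):
        tr = gb.Trajectory(n=[100.0] * 4, r_b=[0] * 3, s_f=[1] * 3,
                           s_w=[1] * 3, s_s=[1] * 3)
        assert gb.growth_rate(tr) == pytest.approx(0.0)

    def test_eightfold_over_three_years_doubles_annually(self):
        tr = gb.Trajectory(n=[100, 200, 400, 800], r_b=[1] * 3, s_f=[1] * 3,
                           s_w=[1] * 3, s_s=[1] * 3)
        assert gb.growth_rate(tr) == pytest.approx(1.0)

    def test_constant_lambda_recovered_exactly(self):
        lam = 0.93
        n = 100 * lam ** np.arange(11)
        tr = gb.Trajectory(n=n, r_b=[0] * 10, s_f=[lam] * 10,
                           s_w=[1] * 10, s_s=[1] * 10)
        assert gb.growth_rate(tr) == pytest.approx(lam - 1)

    def test_extinction_returns_minus_one(self):
        tr = gb.Trajectory(n=[100, 10, 0], r_b=[0] * 2, s_f=[0.1, 0] ,
                           s_w=[1] * 2, s_s=[1] * 2)
        assert gb.growth_rate(tr) == -1.0

    def test_zero_initial_abundance_rejected(self):
        tr = gb.Trajectory(n=[0.0, 0.0], r_b=[0], s_f=[1], s_w=[1], s_s=[1])
        with pytest.raises(ValueError):
            gb.growth_rate(tr)


class TestSimulate:
    def _landscapes(self, factory, p_grass=0.7, seed=0):
        d = gb.CoverDistribution(p_grass, (1 - p_grass) / 2, (1 - p_grass) / 2)
        mk = lambda role, s: gb.generate_landscape(d, 20, 20, role=role, seed=s)
        return (mk(B, seed), [mk(S, seed + 1), mk(S, seed + 2), mk(S, seed + 3)],
                mk(W, seed + 4))

    def test_matches_closed_form_geometric_trajectory(self, random_landscape):
        # with static landscapes and non-binding capacities every rate is
        # abundance-free, so N_t = N_0 * lambda^t exactly
        p = big_capacity_params()
        breed, stops, win = self._landscapes(random_landscape, seed=31)
        tr = gb.simulate_annual_cycle(breed, stops, win, p, n0=100, horizon=30)
        rb = gb.reproduction(breed, 100.0, p)
        sf = gb.migration_survival(stops, 1.0, p)
        sw = gb.winter_survival(win, 1.0, p)
        lam = (1 + rb) * sf * sw * sf
        expected = 100.0 * lam ** np.arange(31)
        assert np.allclose(tr.n, expected, rtol=1e-9)
        assert gb.growth_rate(tr) == pytest.approx(lam - 1, rel=1e-9)

    def test_population_conserved_without_births_or_deaths(self, uniform_landscape):
        p = big_capacity_params(
            nest_density_per_grass_pixel=0.0,
            stopover_survival_by_cover={G: 1.0, A: 1.0, F: 1.0},
            winter_survival_by_cover={G: 1.0, A: 1.0, F: 1.0},
        )
        breed = uniform_landscape(G, role=B)
        stops = [uniform_landscape(G, role=S) for _ in range(3)]
        win = uniform_landscape(G, role=W)
        tr = gb.simulate_annual_cycle(breed, stops, win, p, n0=250, horizon=20)
        assert np.all(tr.n == 250.0)

    def test_decaying_population_is_strictly_decreasing(self, uniform_landscape):
        p = big_capacity_params(
            nest_density_per_grass_pixel=0.0,
            winter_survival_by_cover={G: 0.8, A: 0.8, F: 0.8},
        )
        breed = uniform_landscape(G, role=B)
        stops = [uniform_landscape(G, role=S) for _ in range(3)]
        win = uniform_landscape(G, role=W)
        tr = gb.simulate_annual_cycle(breed, stops, win, p, n0=100, horizon=10)
        assert np.all(np.diff(tr.n) < 0)

    def test_zero_horizon_returns_initial_state(self, uniform_landscape):
        breed = uniform_landscape(G, role=B)
        stops = [uniform_landscape(G, role=S) for _ in range(3)]
        win = uniform_landscape(G, role=W)
        tr = gb.simulate_annual_cycle(breed, stops, win, params(), n0=42, horizon=0)
        assert tr.n.tolist() == [42.0]

    def test_binding_capacity_caps_surviving_population(self, uniform_landscape):
        # with a zero matrix floor, no more birds can leave a season than
        # its habitat supports
        p = params(
            nest_density_per_grass_pixel=0.0,
            matrix_survival_floor=0.0,
            k_winter_per_grass_pixel=0.5,
            winter_survival_by_cover={G: 1.0, A: 1.0, F: 1.0},
            stopover_survival_by_cover={G: 1.0, A: 1.0, F: 1.0},
        )
        breed = uniform_landscape(G, 10, 10, role=B)
        stops = [uniform_landscape(G, 10, 10, role=S) for _ in range(3)]
        win = uniform_landscape(G, 10, 10, role=W)  # winter capacity 50
        tr = gb.simulate_annual_cycle(breed, stops, win, p, n0=400, horizon=5)
        assert np.all(tr.n[1:] <= 50.0 + 1e-9)

    def test_missing_role_rejected(self, uniform_landscape):
        breed = uniform_landscape(G, role=B)
        stops = [uniform_landscape(G, role=S) for _ in range(3)]
        with pytest.raises(ValueError, match="wintering"):
            gb.simulate_annual_cycle(
                breed, stops, uniform_landscape(G, role=B), params()
            )

    def test_stochastic_mode_is_seeded(self, uniform_landscape):
        breed = uniform_landscape(G, role=B)
        stops = [uniform_landscape(G, role=S) for _ in range(3)]
        win = uniform_landscape(G, role=W)
        runs = [
            gb.simulate_annual_cycle(breed, stops, win, params(), n0=100,
                                     horizon=10, seed=5, stochastic=True)
            for _ in range(2)
        ]
        assert np.array_equal(runs[0].n, runs[1].n)
        determ = gb.simulate_annual_cycle(breed, stops, win, params(), n0=100,
                                          horizon=10, seed=5)
        assert not np.array_equal(runs[0].n, determ.n)


@settings(deadline=None, max_examples=40)
@given(
    seed=st.integers(0, 10_000),
    n=st.floats(0.0, 5000.0),
    pg=st.floats(0.0, 1.0),
    occ_a=st.floats(0.0, 1.0),
    floor=st.floats(0.0, 1.0),
)
def test_survival_rates_always_probabilities(seed, n, pg, occ_a, floor):
    """Every survival operation returns a value in [0, 1]."""
    rest = 1.0 - pg
    d = gb.CoverDistribution(pg, rest / 2, rest / 2)
    p = gb.DemographicParams(
        occupancy_by_cover={G: 1.0, A: occ_a, F: 0.5},
        matrix_survival_floor=floor,
    )
    stop = gb.generate_landscape(d, 8, 8, role=S, seed=seed)
    win = gb.generate_landscape(d, 8, 8, role=W, seed=seed + 1)
    assert 0.0 <= gb.stopover_survival(stop, n, p) <= 1.0
    assert 0.0 <= gb.winter_survival(win, n, p) <= 1.0
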
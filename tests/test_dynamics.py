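import numpy as np
import pytest

from coretransim import (
    CommunityState,
    HabitatGrid,
    SimulationConfig,
    apply_mortality,
    build_species_pool,
    collect_adult_dispersers,
    disperse,
    draw_gsad,
    establish,
    initialize_communities,
    kernel_from_q99,
    produce_propagules,
    run_simulation,
    step,
)
from coretransim.dynamics import PropaguleBatch, Z995
from coretransim.fixtures import make_fixture
from coretransim.species import GSAD


def uniform_gsad(n):
    return GSAD(np.full(n, 1.0 / n))


class TestKernel:
    def test_main_kernel_mean_is_1_24_cells(self):
        assert kernel_from_q99(4.0).mean == pytest.approx(1.239, abs=5e-4)

    @pytest.mark.parametrize(
        "q99,sigma,mean",
        [(2.0, 0.7764, 0.6195), (8.0, 3.1058, 2.4780)],
    )
    def test_variant_kernels_closed_form(self, q99, sigma, mean):
        k = kernel_from_q99(q99)
        assert k.sigma == pytest.approx(sigma, abs=2e-4)
        assert k.mean == pytest.approx(mean, abs=2e-4)

    @pytest.mark.parametrize("q99", [2.0, 4.0, 8.0])
    def test_mean_and_q99_recoverable_from_sigma(self, q99):
        k = kernel_from_q99(q99)
        assert k.q99 == pytest.approx(q99, rel=1e-9)
        assert k.mean == pytest.approx(k.sigma * np.sqrt(2 / np.pi), rel=1e-9)

    def test_nonpositive_q99_rejected(self):
        with pytest.raises(ValueError):
            kernel_from_q99(0.0)

    def test_sampled_distances_match_closed_forms(self, rng):
        # Monte Carlo calibration of the half-normal sampler
        k = kernel_from_q99(4.0)
        d = k.sample(200_000, rng)
        se = d.std(ddof=1) / np.sqrt(d.size)
        assert abs(d.mean() - 1.239) < 3 * se
        assert np.quantile(d, 0.99) == pytest.approx(4.0, rel=0.02)


class TestConfig:
    def test_defaults_are_study_conditions(self):
        c = SimulationConfig()
        assert (c.width, c.height, c.n_species, c.carrying_capacity) == (32, 32, 40, 100)
        assert (c.mortality, c.fecundity, c.immigration_rate) == (0.5, 2, 0.001)
        assert (c.n_steps, c.occupancy_window, c.dispersal_q99) == (200, 15, 4.0)
        assert c.detection_probs == tuple(round(0.1 * i, 1) for i in range(1, 11))

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"mortality": 1.5},
            {"h_a": -0.2},
            {"occupancy_window": 300},
            {"carrying_capacity": 0},
            {"dispersal_q99": -1},
            {"similarity_window": 4},
            {"immigration_granularity": "landscape"},
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SimulationConfig(**kwargs)


class TestInitialization:
    def test_every_cell_filled_to_capacity(self, rng):
        grid = HabitatGrid(np.ones((32, 32), dtype=bool))
        state = initialize_communities(grid, uniform_gsad(40), 100, rng)
        assert (state.cell_occupancy() == 100).all()
        assert state.counts.sum() == 102_400

    def test_species_frequencies_match_gsad(self, rng):
        grid = HabitatGrid(np.ones((32, 32), dtype=bool))
        gsad = draw_gsad(10, rng)
        state = initialize_communities(grid, gsad, 100, rng)
        freq = state.landscape_abundance() / state.counts.sum()
        se = np.sqrt(gsad.weights * (1 - gsad.weights) / state.counts.sum())
        assert (np.abs(freq - gsad.weights) < 3.5 * se).all()


class TestMortality:
    def test_extremes(self, rng):
        grid = HabitatGrid(np.ones((2, 2), dtype=bool))
        state = initialize_communities(grid, uniform_gsad(3), 10, rng)
        unchanged = apply_mortality(state, 0.0, rng)
        assert np.array_equal(unchanged.counts, state.counts)
        empty = apply_mortality(state, 1.0, rng)
        assert empty.counts.sum() == 0

    def test_survivorship_is_binomial(self, rng):
        # one cell of 100 individuals, d=0.5: mean survivors over 1e4 trials
        state = CommunityState(np.array([[100]]), 1, 1)
        survivors = np.array(
            [apply_mortality(state, 0.5, rng).counts.sum() for _ in range(10_000)]
        )
        se = np.sqrt(100 * 0.25 / 10_000)
        assert abs(survivors.mean() - 50.0) < 3 * se


class TestBirthAndAdultDispersal:
    def setup_method(self):
        self.grid = HabitatGrid(np.ones((1, 2), dtype=bool))  # two A cells
        self.pool = build_species_pool(2)  # species 0 prefers A, species 1 prefers B

    def test_matched_adults_produce_f_offspring(self):
        counts = np.array([[3, 0], [0, 0]])
        batch = produce_propagules(CommunityState(counts, 1, 2), self.pool, self.grid, 2)
        assert batch.size == 6
        assert (batch.species == 0).all() and (batch.row == 0).all() and (batch.col == 0).all()

    def test_mismatched_adults_do_not_reproduce(self):
        counts = np.array([[0, 5], [0, 0]])
        batch = produce_propagules(CommunityState(counts, 1, 2), self.pool, self.grid, 2)
        assert batch.size == 0

    def test_empty_landscape_yields_no_propagules(self):
        batch = produce_propagules(
            CommunityState(np.zeros((2, 2), dtype=np.int64), 1, 2), self.pool, self.grid, 2
        )
        assert batch.size == 0

    def test_only_mismatched_adults_disperse(self):
        counts = np.array([[60, 5], [0, 0]])
        state, movers = collect_adult_dispersers(
            CommunityState(counts, 1, 2), self.pool, self.grid
        )
        assert movers.size == 5 and movers.is_adult.all() and (movers.species == 1).all()
        assert state.counts[0, 0] == 60 and state.counts[0, 1] == 0

    def test_matched_only_landscape_has_no_dispersers(self):
        counts = np.array([[10, 0], [7, 0]])
        _, movers = collect_adult_dispersers(
            CommunityState(counts, 1, 2), self.pool, self.grid
        )
        assert movers.size == 0


class TestDisperse:
    def test_zero_sigma_limit_stays_at_natal_cell(self, rng):
        grid = HabitatGrid(np.ones((5, 5), dtype=bool))
        batch = PropaguleBatch(
            row=np.array([2, 2]), col=np.array([2, 2]),
            species=np.array([0, 1]), is_adult=np.array([False, False]),
        )
        kernel = kernel_from_q99(1e-9)
        out = disperse(batch, kernel, grid, rng)
        assert (out.row == 2).all() and (out.col == 2).all()

    def test_off_grid_propagules_absorbed(self, rng):
        grid = HabitatGrid(np.ones((3, 3), dtype=bool))
        n = 20_000
        batch = PropaguleBatch(
            row=np.zeros(n, dtype=np.int64), col=np.zeros(n, dtype=np.int64),
            species=np.zeros(n, dtype=np.int64), is_adult=np.zeros(n, dtype=bool),
        )
        out = disperse(batch, kernel_from_q99(8.0), grid, rng)
        assert out.size < n  # corner cell with a broad kernel must lose some
        assert (out.row >= 0).all() and (out.row < 3).all()
        assert (out.col >= 0).all() and (out.col < 3).all()

    def test_displacement_isotropic(self, rng):
        grid = HabitatGrid(np.ones((41, 41), dtype=bool))
        n = 50_000
        batch = PropaguleBatch(
            row=np.full(n, 20), col=np.full(n, 20),
            species=np.zeros(n, dtype=np.int64), is_adult=np.zeros(n, dtype=bool),
        )
        out = disperse(batch, kernel_from_q99(4.0), grid, rng)
        dr, dc = out.row - 20.0, out.col - 20.0
        assert abs(dr.mean()) < 3 * dr.std() / np.sqrt(out.size)
        assert abs(dc.mean()) < 3 * dc.std() / np.sqrt(out.size)


class TestEstablish:
    def setup_method(self):
        self.gsad = uniform_gsad(2)

    def test_no_immigration_no_arrivals_leaves_state_unchanged(self, rng):
        state = CommunityState(np.array([[3, 2]]), 1, 1)
        out = establish(state, PropaguleBatch.empty(), self.gsad, 0.0, 10, rng)
        assert np.array_equal(out.counts, state.counts)

    def test_full_immigration_fills_every_slot(self, rng):
        state = CommunityState(np.array([[3, 2]]), 1, 1)
        out = establish(state, PropaguleBatch.empty(), self.gsad, 1.0, 10, rng)
        assert out.cell_occupancy()[0] == 10

    def test_arrivals_fill_only_available_slots(self, rng):
        # 40 empty slots, 10 arrivals, m=0 -> exactly 10 establish
        state = CommunityState(np.array([[0, 0]]), 1, 1)
        arrivals = PropaguleBatch(
            row=np.zeros(10, dtype=np.int64), col=np.zeros(10, dtype=np.int64),
            species=np.array([0] * 6 + [1] * 4), is_adult=np.zeros(10, dtype=bool),
        )
        out = establish(state, arrivals, self.gsad, 0.0, 40, rng)
        assert out.cell_occupancy()[0] == 10
        assert out.counts[0, 0] == 6 and out.counts[0, 1] == 4

    def test_oversubscribed_pool_draws_without_replacement(self, rng):
        # 5 slots, 20 arrivals (12 of species 0, 8 of species 1): the species
        # mix of the 5 establishers is hypergeometric, mean 3.0 of species 0
        draws = []
        for _ in range(4000):
            state = CommunityState(np.array([[0, 0]]), 1, 1)
            arrivals = PropaguleBatch(
                row=np.zeros(20, dtype=np.int64), col=np.zeros(20, dtype=np.int64),
                species=np.array([0] * 12 + [1] * 8), is_adult=np.zeros(20, dtype=bool),
            )
            out = establish(state, arrivals, self.gsad, 0.0, 5, rng)
            assert out.cell_occupancy()[0] == 5
            draws.append(out.counts[0, 0])
        draws = np.array(draws)
        # Hypergeometric(N=20, K=12, n=5): mean 3, var 5*(12/20)*(8/20)*(15/19)
        var = 5 * 0.6 * 0.4 * (15 / 19)
        assert abs(draws.mean() - 3.0) < 3 * np.sqrt(var / draws.size)

    def test_per_cell_immigration_granularity(self, rng):
        # "cell" granularity: at most one immigration event per community per
        # step, regardless of how many slots are empty
        state = CommunityState(np.zeros((1, 2), dtype=np.int64), 1, 1)
        out = establish(
            state, PropaguleBatch.empty(), self.gsad, 1.0, 40, rng, granularity="cell"
        )
        assert out.cell_occupancy()[0] == 1

    def test_overfull_cell_reported(self, rng):
        state = CommunityState(np.array([[8, 7]]), 1, 1)
        with pytest.raises(RuntimeError, match="consistency"):
            establish(state, PropaguleBatch.empty(), self.gsad, 0.0, 10, rng)


class TestStep:
    def test_full_matched_landscape_is_fixed_point(self, rng):
        # all-A grid, only A-specialists, no deaths, no immigration, cells full
        grid = HabitatGrid(np.ones((4, 4), dtype=bool))
        pool = build_species_pool(2)
        counts = np.zeros((16, 2), dtype=np.int64)
        counts[:, 0] = 10
        config = SimulationConfig(
            width=4, height=4, n_species=2, carrying_capacity=10, mortality=0.0,
            immigration_rate=0.0, n_steps=1, occupancy_window=1, similarity_window=3,
        )
        out = step(CommunityState(counts, 4, 4), grid, pool, uniform_gsad(2), config, rng)
        assert np.array_equal(out.counts, counts)

    def test_death_before_birth_empties_landscape(self, rng):
        # d=1, m=0: everyone dies before reproducing, nothing establishes
        grid = HabitatGrid(np.ones((4, 4), dtype=bool))
        pool = build_species_pool(2)
        state = initialize_communities(grid, uniform_gsad(2), 10, rng)
        config = SimulationConfig(
            width=4, height=4, n_species=2, carrying_capacity=10, mortality=1.0,
            immigration_rate=0.0, n_steps=1, occupancy_window=1, similarity_window=3,
        )
        out = step(state, grid, pool, uniform_gsad(2), config, rng)
        assert out.counts.sum() == 0

    def test_no_new_species_without_immigration(self, rng):
        # with m=0 every established individual traces to the initial state
        fx = make_fixture("tiny", seed=3)
        config = fx.config.with_(immigration_rate=0.0)
        state = initialize_communities(fx.grid, fx.gsad, config.carrying_capacity, rng)
        present_initially = state.landscape_abundance() > 0
        for _ in range(10):
            state = step(state, fx.grid, fx.pool, fx.gsad, config, rng)
        assert not (state.landscape_abundance()[~present_initially] > 0).any()

    def test_capacity_conserved_every_step(self, rng):
        fx = make_fixture("tiny", seed=1)
        state = initialize_communities(fx.grid, fx.gsad, fx.config.carrying_capacity, rng)
        for _ in range(20):
            state = step(state, fx.grid, fx.pool, fx.gsad, fx.config, rng)
            assert state.cell_occupancy().max() <= fx.config.carrying_capacity


class TestRunSimulation:
    def test_window_equals_steps_records_everything(self, tiny_config):
        config = tiny_config.with_(n_steps=5, occupancy_window=5)
        record = run_simulation(config, 7)
        assert record.focal_abundance.shape == (5, config.n_species)

    def test_record_shapes_and_capacity(self, tiny_config):
        record = run_simulation(tiny_config, 11)
        w, s = tiny_config.occupancy_window, tiny_config.n_species
        assert record.focal_abundance.shape == (w, s)
        assert (record.focal_abundance >= 0).all()
        assert (record.focal_abundance.sum(axis=1) <= tiny_config.carrying_capacity).all()
        from coretransim import local_similarity

        assert record.similarity == pytest.approx(
            local_similarity(record.grid, record.focal, tiny_config.similarity_window)
        )

    def test_reproducible_from_seed(self, tiny_config):
        a = run_simulation(tiny_config.with_(seed=42))
        b = run_simulation(tiny_config.with_(seed=42))
        assert np.array_equal(a.focal_abundance, b.focal_abundance)
        assert np.array_equal(a.landscape_abundance, b.landscape_abundance)
        assert np.array_equal(a.grid.is_a, b.grid.is_a)

    def test_save_round_trip(self, tiny_config, tmp_path):
        import json
        import pandas as pd

        record = run_simulation(tiny_config, 5)
        record.save(tmp_path / "run")
        focal = pd.read_csv(tmp_path / "run_focal.csv")
        assert set(focal.columns) == {"year", "species_id", "true_abundance"}
        assert len(focal) == tiny_config.occupancy_window * tiny_config.n_species
        meta = json.loads((tmp_path / "run_meta.json").read_text())
        assert meta["similarity"] == pytest.approx(record.similarity)
        assert meta["config"]["carrying_capacity"] == tiny_config.carrying_capacity


def test_more_transients_in_heterogeneous_landscapes(reduced_sweep):
    """At perfect detection, h_A=0.5 landscapes show more true transient
    species at the focal cell than h_A=0.9 landscapes (source-sink inflow
    scales with the amount of surrounding opposite habitat)."""
    rows = reduced_sweep.rows
    at_p1 = rows[np.isclose(rows["p"], 1.0)]
    mean_het = at_p1[at_p1["h_a"] == 0.5]["n_true_transient_observed"].mean()
    mean_hom = at_p1[at_p1["h_a"] == 0.9]["n_true_transient_observed"].mean()
    assert mean_het > mean_hom


def test_richness_equilibrated_by_step_150(rng):
    """Mean focal richness shows no trend over steps 150-200 under the
    default configuration (the run length was chosen to pass equilibrium)."""
    import statsmodels.api as sm
    from coretransim.dynamics import (
        initialize_communities as init, step as advance,
    )
    from coretransim import generate_landscape, build_species_pool, draw_gsad, focal_cell

    config = SimulationConfig(h_a=0.7)
    n_reps, tail = 4, 50
    richness = np.zeros((n_reps, tail))
    for rep in range(n_reps):
        grid = generate_landscape(32, 32, config.h_a, rng)
        pool = build_species_pool(config.n_species)
        gsad = draw_gsad(config.n_species, rng)
        focal = focal_cell(grid)
        fidx = focal[0] * 32 + focal[1]
        state = init(grid, gsad, config.carrying_capacity, rng)
        for t in range(config.n_steps):
            state = advance(state, grid, pool, gsad, config, rng)
            if t >= config.n_steps - tail:
                richness[rep, t - (config.n_steps - tail)] = (state.counts[fidx] > 0).sum()
    steps = np.arange(tail, dtype=float)
    fit = sm.OLS(richness.mean(axis=0), sm.add_constant(steps)).fit()
    lo, hi = fit.conf_int()[1]
    assert lo <= 0.0 <= hi
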
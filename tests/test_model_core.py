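"""Elementary dynamics: initialization, movement, binding, cleavage, flux,
and cytokine release."""

import math

import numpy as np
import pytest

from hscompete import (
    AffinityClassParams,
    BOUND,
    CLEAVED,
    FREE,
    Cell,
    ConfigError,
    GrowthFactor,
    Microenvironment,
    SimulationConfig,
    attempt_binding,
    cleave_bound_factor,
    init_simulation,
    move_growth_factor,
    release_cytokines,
    update_heparinase,
)


def _fresh_state(**overrides):
    cfg = SimulationConfig(**overrides)
    return init_simulation(cfg, 0)


class TestInit:
    def test_default_lattice_has_2601_microenvironments(self):
        state = _fresh_state()
        assert state.n_microenvironments == 2601
        assert state.heparinase.shape == (51, 51)

    def test_zero_variance_sites_are_exact(self):
        state = _fresh_state(site_mean=5.0, site_sd=0.0, n_cells=40)
        assert all(c.total_sites == 5 and c.free_sites == 5 for c in state.cells)

    def test_seeded_determinism_of_initial_state(self):
        cfg = SimulationConfig(seed=7)
        a, b = init_simulation(cfg, 3), init_simulation(cfg, 3)
        assert np.array_equal(a.heparinase, b.heparinase)
        assert [(c.x, c.y, c.total_sites) for c in a.cells] == [
            (c.x, c.y, c.total_sites) for c in b.cells
        ]
        assert [(g.class_index, g.x, g.y) for g in a.factors] == [
            (g.class_index, g.x, g.y) for g in b.factors
        ]

    def test_replicates_differ(self):
        cfg = SimulationConfig(seed=7)
        a, b = init_simulation(cfg, 0), init_simulation(cfg, 1)
        assert not np.array_equal(a.heparinase, b.heparinase)

    def test_initial_release_counts_and_state(self):
        state = _fresh_state(initial_release=(10, 20, 30))
        counts = state.counts_by_state()
        assert counts["free"].tolist() == [10, 20, 30]
        assert counts["bound"].tolist() == [0, 0, 0]
        assert state.cumulative_released.tolist() == [10, 20, 30]

    def test_heparinase_within_bounds(self):
        state = _fresh_state(heparinase_max=3.0)
        assert (state.heparinase >= 0).all() and (state.heparinase <= 3.0).all()

    def test_negative_replicate_index_rejected(self):
        with pytest.raises(ConfigError):
            init_simulation(SimulationConfig(), -1)


class TestMovement:
    def test_zero_step_length_leaves_position(self):
        state = _fresh_state()
        gf = state.factors[0]
        x, y = gf.x, gf.y
        move_growth_factor(gf, state, step_length=0.0)
        assert (gf.x, gf.y) == (x, y)

    def test_bound_factor_is_noop(self):
        state = _fresh_state()
        gf = state.factors[0]
        gf.state = BOUND
        x, y = gf.x, gf.y
        move_growth_factor(gf, state)
        assert (gf.x, gf.y) == (x, y)

    def test_torus_wrap(self):
        # a unit move in any direction stays within [0, width) x [0, height)
        state = _fresh_state(grid_width=51, grid_height=51, n_cells=0,
                             initial_release=(1, 0, 0))
        gf = state.factors[0]
        gf.x, gf.y = 50.5, 0.2
        for _ in range(200):
            move_growth_factor(gf, state)
            assert 0.0 <= gf.x < 51 and 0.0 <= gf.y < 51

    def test_explicit_wrap_arithmetic(self):
        # moving +1 in x from 50.5 on a 51-wide torus lands at 0.5
        assert (50.5 + 1.0) % 51 == pytest.approx(0.5)

    def test_isotropy_over_many_moves(self):
        # empirical mean displacement per axis ~ 0 within 3 standard errors;
        # per-move displacement per axis is cos(U); sd = sqrt(1/2)
        state = _fresh_state(
            grid_width=10001, grid_height=10001, n_cells=0, initial_release=(1, 0, 0),
            seed=11,
        )
        gf = state.factors[0]
        gf.x = gf.y = 5000.0
        n = 10_000
        for _ in range(n):
            move_growth_factor(gf, state)
        se = math.sqrt(0.5) / math.sqrt(n)
        assert abs(gf.x - 5000.0) / n <= 3 * se
        assert abs(gf.y - 5000.0) / n <= 3 * se


def _one_cell_state(attach_prob, total_sites=3, heparinase_max=1.0):
    cfg = SimulationConfig(
        grid_width=1,
        grid_height=1,
        n_cells=1,
        site_mean=float(total_sites),
        site_sd=0.0,
        initial_release=(1, 0, 0),
        class_params=tuple(
            # common attach probability; ordered thresholds
            AffinityClassParams(lab, attach_prob, th)
            for lab, th in zip(("LA", "MA", "HA"), (0.25, 0.5, 0.75))
        ),
        heparinase_max=heparinase_max,
        seed=5,
    )
    return init_simulation(cfg, 0)


class TestBinding:
    def test_zero_probability_never_binds(self):
        state = _one_cell_state(0.0)
        gf = state.factors[0]
        for _ in range(200):
            assert not attempt_binding(gf, state)
        assert state.cells[0].free_sites == 3

    def test_certain_binding_decrements_free_sites(self):
        state = _one_cell_state(1.0)
        gf = state.factors[0]
        assert attempt_binding(gf, state)
        assert gf.state == BOUND and gf.bound_cell is state.cells[0]
        assert state.cells[0].free_sites == 2

    def test_no_eligible_cell_returns_not_bound(self):
        state = _one_cell_state(1.0, total_sites=0)
        assert not attempt_binding(state.factors[0], state)

    def test_bound_factor_attempt_is_noop(self):
        state = _one_cell_state(1.0)
        gf = state.factors[0]
        attempt_binding(gf, state)
        assert not attempt_binding(gf, state)
        assert state.cells[0].free_sites == 2

    def test_empirical_bind_rate_matches_bernoulli(self):
        # 10,000 independent attempts at p=0.5: within 3 SE of 0.5
        state = _one_cell_state(0.5, total_sites=5)
        gf = state.factors[0]
        cell = state.cells[0]
        n, hits = 10_000, 0
        for _ in range(n):
            if attempt_binding(gf, state):
                hits += 1
                gf.state = FREE
                gf.bound_cell = None
                cell.free_sites += 1
        se = math.sqrt(0.25 / n)
        assert abs(hits / n - 0.5) <= 3 * se


class TestCleavage:
    def _bound_trio(self, state):
        cell = state.cells[0]
        trio = []
        for ci in range(3):
            gf = GrowthFactor(ci, cell.x, cell.y, state=BOUND, bound_cell=cell)
            cell.free_sites -= 1
            trio.append(gf)
        return trio

    @pytest.mark.parametrize(
        "h,expected_cleaved",
        [
            (0.0, []),  # below all thresholds
            (0.3, ["LA"]),  # between LA and MA thresholds
            (0.6, ["LA", "MA"]),
            (0.9, ["LA", "MA", "HA"]),  # above all thresholds
        ],
    )
    def test_threshold_ordering_of_cleavage(self, h, expected_cleaved):
        state = _one_cell_state(1.0, total_sites=5)
        cfg = state.config
        trio = self._bound_trio(state)
        env = Microenvironment(0, 0, h)
        free_before = state.cells[0].free_sites
        cleaved = [
            gf.class_label for gf in trio if cleave_bound_factor(gf, env, cfg)
        ]
        assert cleaved == expected_cleaved
        # each cleavage restores exactly one free site
        assert state.cells[0].free_sites == free_before + len(expected_cleaved)

    def test_cleaved_sets_are_nested_in_affinity(self):
        # the set of heparinase levels cleaving HA is a subset of those
        # cleaving MA, itself a subset of those cleaving LA
        state = _one_cell_state(1.0, total_sites=5)
        cfg = state.config
        rng = np.random.default_rng(0)
        for h in rng.uniform(0, 1, size=200):
            outcomes = []
            for gf in self._bound_trio(state):
                outcomes.append(cleave_bound_factor(gf, Microenvironment(0, 0, h), cfg))
            la, ma, ha = outcomes
            assert (not ha or ma) and (not ma or la)
            state.cells[0].free_sites = 5  # reset for the next draw

    def test_free_factor_is_noop(self):
        state = _one_cell_state(1.0)
        gf = state.factors[0]
        assert not cleave_bound_factor(gf, Microenvironment(0, 0, 1.0), state.config)

    def test_recycle_fate_returns_factor_to_free_pool(self):
        state = _one_cell_state(1.0)
        cfg = state.config.with_overrides(cleaved_fate="recycle")
        gf = state.factors[0]
        attempt_binding(gf, state)
        assert cleave_bound_factor(gf, Microenvironment(0, 0, 1.0), cfg)
        assert gf.state == FREE and gf.bound_cell is None

    def test_degrade_fate_marks_cleaved(self):
        state = _one_cell_state(1.0)
        gf = state.factors[0]
        attempt_binding(gf, state)
        assert cleave_bound_factor(gf, Microenvironment(0, 0, 1.0), state.config)
        assert gf.state == CLEAVED


class TestHeparinaseFlux:
    def test_zero_flux_prob_is_identity(self):
        state = _fresh_state(flux_prob=0.0)
        before = state.heparinase.copy()
        update_heparinase(state)
        assert np.array_equal(before, state.heparinase)

    def test_field_stays_clamped(self):
        state = _fresh_state(flux_prob=1.0, heparinase_max=0.5)
        for _ in range(50):
            update_heparinase(state)
            assert (state.heparinase >= 0).all()
            assert (state.heparinase <= 0.5).all()

    def test_long_run_mean_is_half_max(self):
        # clamped symmetric walk on [0, hmax]: time-average ~ hmax/2.
        # SE estimated by batch means (the walk is autocorrelated).
        state = _fresh_state(
            grid_width=1, grid_height=1, n_cells=0, initial_release=(0, 0, 0),
            flux_prob=1.0, seed=3,
        )
        n = 100_000
        trace = np.empty(n)
        for i in range(n):
            update_heparinase(state)
            trace[i] = state.heparinase[0, 0]
        n_batches = 20
        batch_means = trace.reshape(n_batches, -1).mean(axis=1)
        se = batch_means.std(ddof=1) / math.sqrt(n_batches)
        assert abs(trace.mean() - 0.5) <= 3 * se


class TestRelease:
    def test_empty_release_changes_nothing(self):
        state = _fresh_state()
        n_before = len(state.factors)
        released_before = state.cumulative_released.copy()
        release_cytokines(state, (0, 0, 0))
        assert len(state.factors) == n_before
        assert np.array_equal(state.cumulative_released, released_before)

    def test_cumulative_bookkeeping(self):
        state = _fresh_state(initial_release=(100, 0, 0))
        for _ in range(7):
            release_cytokines(state, (5, 1, 0))
        assert state.cumulative_released.tolist() == [100 + 35, 7, 0]

    def test_release_into_single_patch_grid(self):
        state = _fresh_state(
            grid_width=1, grid_height=1, n_cells=0, initial_release=(0, 0, 0)
        )
        release_cytokines(state, (4, 3, 2))
        assert len(state.factors) == 9
        assert all(state.patch_of(g.x, g.y) == (0, 0) for g in state.factors)

    def test_negative_counts_rejected(self):
        state = _fresh_state()
        with pytest.raises(ConfigError):
            release_cytokines(state, (1, -1, 0))
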
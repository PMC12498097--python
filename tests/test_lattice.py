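"""Unit tests for the on-lattice engine: event selection, pushing geometry,
segregation bookkeeping and whole-run invariants."""

import numpy as np
import pytest
from scipy import stats

from ecdnasim import (
    ConfigurationError,
    Event,
    LatticeBoundaryError,
    SimulationConfig,
    TumorState,
    apply_event,
    cell_division_rate,
    find_division_site,
    init_tumor,
    run_to_size,
    segregate_ecdna,
    select_event,
)
from ecdnasim._kernels import eligible_directions


def make_state(coords, copies, seed=0, capacity=64, span=16):
    xs = [c[0] for c in coords]
    ys = [c[1] for c in coords]
    st = TumorState(xs, ys, copies, span=span, capacity=capacity,
                    rng=np.random.default_rng(seed))
    st.grid()
    return st


class TestConfig:
    @pytest.mark.parametrize("kwargs", [
        dict(k=-1), dict(k=1, s=-1.0), dict(k=1, s=-2.0), dict(k=1, q=0),
        dict(k=1, q=-3), dict(k=1, d=1.0), dict(k=1, d=-0.1),
        dict(k=1, n_final=0), dict(k=1, n_final=500, lattice_span=10),
    ])
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(ConfigurationError):
            SimulationConfig(**kwargs)

    def test_infinite_q_sentinel(self):
        for q in ("inf", np.inf):
            cfg = SimulationConfig(k=1, q=q, n_final=100)
            assert cfg.q == np.inf
            assert cfg.q_steps() == 2 * cfg.span + 1


class TestInitTumor:
    @pytest.mark.parametrize("k", [0, 10])
    def test_single_founder(self, k):
        st = init_tumor(SimulationConfig(k=k, n_final=100, seed=1))
        assert st.n_cells == 1
        assert st.time == 0.0
        assert st.founder_site == (0, 0)
        assert list(st.copies) == [k]


class TestDivisionRate:
    @pytest.mark.parametrize("copies,s,expected", [
        (0, 1.5, 1.0),
        (7, 1.5, 2.5),     # constant selection: independent of the count
        (1, 2.0, 3.0),     # 200% increase over ecDNA-free cells
        ([3, 4], 1.0, 2.0),  # per-species counts: total positivity matters
        ([0, 0], 3.0, 1.0),
    ])
    def test_constant_selection(self, copies, s, expected):
        assert cell_division_rate(copies, s) == expected

    def test_invalid_selection(self):
        with pytest.raises(ConfigurationError):
            cell_division_rate(5, -1.0)


class TestSelectEvent:
    def test_rate_proportional_selection(self):
        # two cells with rates {1, 3}: the positive cell divides w.p. 0.75
        st = make_state([(0, 0), (1, 0)], [0, 5], seed=7)
        cfg = SimulationConfig(k=0, s=2.0, n_final=100)
        n = 4000
        hits = sum(select_event(st, cfg).cell == 1 for _ in range(n))
        se = np.sqrt(0.75 * 0.25 / n)
        assert abs(hits / n - 0.75) < 3 * se

    def test_waiting_times_exponential(self):
        # fixed 3-cell state, total rate 1 + 3 + 3 = 7
        st = make_state([(0, 0), (1, 0), (0, 1)], [0, 2, 9], seed=3)
        cfg = SimulationConfig(k=0, s=2.0, n_final=100)
        dts = [select_event(st, cfg).dt for _ in range(4000)]
        assert stats.kstest(dts, "expon", args=(0, 1 / 7.0)).pvalue > 0.01

    def test_empty_population_rejected(self):
        st = make_state([(0, 0)], [1])
        st._n = 0
        with pytest.raises(RuntimeError):
            select_event(st, SimulationConfig(k=1, n_final=10))


class TestFindDivisionSite:
    def test_adjacent_empty_site_no_pushing(self):
        st = make_state([(0, 0), (1, 0)], [5, 5])
        p = find_division_site(st, 0, q=1)
        assert p is not None
        assert p.distance == 1
        assert p.run == []

    def test_enclosed_ring_requires_range(self):
        # mother at the center of a fully occupied 5x5 block: the nearest
        # empty site along every ray is 3 steps away
        coords = [(x, y) for x in range(-2, 3) for y in range(-2, 3)]
        copies = [1] * len(coords)
        st = make_state(coords, copies)
        mother = coords.index((0, 0))
        assert find_division_site(st, mother, q=2) is None
        p = find_division_site(st, mother, q=5)
        assert p is not None and p.distance == 3
        assert len(p.run) == 2

    def test_infinite_q_always_eligible(self):
        coords = [(x, y) for x in range(-2, 3) for y in range(-2, 3)]
        st = make_state(coords, [1] * len(coords))
        assert find_division_site(st, coords.index((0, 0)), q="inf") is not None

    def test_eligibility_matches_bruteforce_on_random_grids(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            span = 6
            L = 2 * span + 1
            grid = np.full((L, L), -1, dtype=np.int32)
            occ = rng.random((L, L)) < 0.6
            occ[span, span] = True
            grid[occ] = np.arange(occ.sum(), dtype=np.int32)
            q = int(rng.integers(1, 7))
            dist = eligible_directions(grid, span, span, q)
            dirs = [(1, 0), (1, 1), (0, 1), (-1, 1), (-1, 0), (-1, -1), (0, -1), (1, -1)]
            for d, (dx, dy) in enumerate(dirs):
                expect = -1
                for t in range(1, q + 1):
                    cx, cy = span + t * dx, span + t * dy
                    if not (0 <= cx < L and 0 <= cy < L):
                        break
                    if grid[cx, cy] < 0:
                        expect = t
                        break
                assert dist[d] == expect


class TestSegregation:
    def test_zero_is_absorbing(self):
        assert segregate_ecdna(0) == (0, 0)

    def test_conservation(self):
        rng = np.random.default_rng(11)
        for copies in [1, 5, 40]:
            for _ in range(50):
                a, b = segregate_ecdna(copies, rng)
                assert a + b == 2 * copies
                assert a >= 0 and b >= 0

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            segregate_ecdna(-1)


class TestApplyEvent:
    def test_death_frees_site(self):
        st = make_state([(0, 0), (1, 0)], [3, 7])
        cfg = SimulationConfig(k=0, d=0.5, n_final=10)
        apply_event(st, Event("death", 0, 0.2), cfg)
        assert st.n_cells == 1
        assert st.time == pytest.approx(0.2)
        st.validate()

    def test_dead_cell_event_rejected(self):
        st = make_state([(0, 0)], [3])
        with pytest.raises(RuntimeError):
            apply_event(st, Event("death", 4, 0.1), SimulationConfig(k=0, n_final=10))

    def test_division_bookkeeping_over_random_run(self):
        # total copies after a division = total before + mother's pre-division
        # count; occupancy stays a bijection; pushed cells keep their counts
        cfg = SimulationConfig(k=10, s=0.5, q=3, d=0.1, n_final=300, seed=21)
        st = init_tumor(cfg)
        divisions = 0
        for step in range(1200):
            if st.n_cells == 0 or st.n_cells >= cfg.n_final:
                break
            ev = select_event(st, cfg)
            before_total = st.total_copies
            mother_copies = int(st.copies[ev.cell]) if ev.kind == "division" else 0
            n_before = st.n_cells
            apply_event(st, ev, cfg)
            if ev.kind == "division" and st.n_cells == n_before + 1:
                assert st.total_copies == before_total + mother_copies
                divisions += 1
            elif ev.kind == "death":
                assert st.n_cells == n_before - 1
            if step % 100 == 0:
                st.validate()
        assert divisions > 100
        st.validate()

    def test_q1_only_boundary_cells_divide(self):
        # strict boundary growth: any completed division came from a cell
        # with an empty Moore neighbor
        cfg = SimulationConfig(k=5, s=0.0, q=1, n_final=120, seed=9)
        st = init_tumor(cfg)
        while st.n_cells < cfg.n_final:
            ev = select_event(st, cfg)
            had_empty = None
            if ev.kind == "division":
                g = st.grid()
                gx = int(st.xs[ev.cell]) + st.span
                gy = int(st.ys[ev.cell]) + st.span
                had_empty = (eligible_directions(g, gx, gy, 1) > 0).any()
            n_before = st.n_cells
            apply_event(st, ev, cfg)
            if ev.kind == "division" and st.n_cells > n_before:
                assert had_empty
        st.validate()


class TestRunToSize:
    def test_no_ecdna_stays_clean(self):
        st = run_to_size(SimulationConfig(k=0, s=2.0, q="inf", n_final=1000, seed=4))
        assert st.status == "reached"
        assert st.n_cells == 1000
        assert not st.copies.any()

    def test_total_copies_never_lost_without_death(self):
        st = run_to_size(SimulationConfig(k=3, s=0.0, q=1000, n_final=2000, seed=8))
        assert st.total_copies >= 3
        assert (st.copies >= 0).all()

    def test_occupancy_integrity_and_determinism(self):
        cfg = SimulationConfig(k=10, s=1.0, q=2, n_final=2000, seed=33)
        a = run_to_size(cfg)
        b = run_to_size(cfg)
        a.validate()
        assert np.array_equal(a.xs, b.xs) and np.array_equal(a.copies, b.copies)
        assert a.time == b.time

    def test_extinction_is_an_outcome(self):
        outcomes = [run_to_size(SimulationConfig(k=1, s=0.0, d=0.9, n_final=200,
                                                 seed=s)).status
                    for s in range(10)]
        assert "extinct" in outcomes
        for st_status in outcomes:
            assert st_status in ("reached", "extinct")

    def test_boundary_overflow_raises(self):
        with pytest.raises(LatticeBoundaryError):
            run_to_size(SimulationConfig(k=1, s=0.0, q="inf", n_final=600,
                                         seed=2, lattice_span=14))
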
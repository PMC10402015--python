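"""Decision-layer tests: growth law, sizer/timer cycle, apoptosis, extrusion."""

import numpy as np
import pytest
from scipy import ndimage

from pottsgrowth.decisions import (
    CellState,
    advance_timer,
    apoptosis_probability,
    cell_state,
    check_extrusion,
    check_g1s_transition,
    divide_cell,
    draw_threshold,
    grow_target_area,
    local_density,
    remove_cell,
    seed_tissue,
    step_decision_layer,
    trigger_apoptosis,
    _split_sites,
)
from pottsgrowth.engine import Phase, run_mcs
from pottsgrowth.fixtures import fixture_params, make_fixture
from pottsgrowth.params import calibrated_params, resolve_lattice_units


def _cell(phase=Phase.G1, AT=50.0, As_i=100.0, tau0=40.0, clock=0.0):
    return CellState(
        id=1,
        phase=phase,
        area=50,
        target_area=AT,
        As_i=As_i,
        tau0_i=tau0,
        timer_clock=clock,
        birth_time=0.0,
        generation=0,
    )


class TestGrowthLaw:
    def test_uncrowded_cell_grows_at_full_rate(self):
        p = fixture_params(100.0, G=2.0, k=0.05)
        c = _cell(AT=50.0)
        assert grow_target_area(c, 50.0, p) == pytest.approx(50.0 + 2.0)

    def test_zero_sensitivity_ignores_deviation(self):
        p = fixture_params(100.0, G=2.0, k=1e-300)
        c = _cell(AT=50.0)
        assert grow_target_area(c, 10.0, p) == pytest.approx(52.0, rel=1e-9)

    def test_half_rate_at_characteristic_deviation(self):
        p = fixture_params(100.0, G=2.0, k=0.05)
        dev = np.sqrt(np.log(2) / p.k)
        c = _cell(AT=50.0)
        assert grow_target_area(c, 50.0 + dev, p) == pytest.approx(51.0)

    def test_apoptotic_cells_do_not_grow(self):
        with pytest.raises(ValueError):
            grow_target_area(_cell(phase=Phase.APOPTOTIC), 50.0, fixture_params(100.0))


class TestSizerTimer:
    def test_sizer_is_strict_inequality(self):
        assert check_g1s_transition(_cell(As_i=100.0), 100.0) is Phase.G1
        assert check_g1s_transition(_cell(As_i=100.0), 101.0) is Phase.TIMER

    def test_timer_due_exactly_at_threshold(self):
        c = _cell(phase=Phase.TIMER, tau0=225.0, clock=224.0)
        assert advance_timer(c, 1.0)
        c2 = _cell(phase=Phase.TIMER, tau0=225.0, clock=0.0)
        assert not advance_timer(c2, 1.0)

    def test_zero_dt_changes_nothing(self):
        c = _cell(phase=Phase.TIMER, tau0=225.0, clock=5.0)
        assert not advance_timer(c, 0.0)
        assert c.timer_clock == 5.0

    def test_threshold_draws_truncated_and_floored(self):
        rng = np.random.default_rng(0)
        draws = [draw_threshold(rng, 100.0, 10.0, 25.0) for _ in range(5000)]
        assert all(70.0 <= d <= 130.0 for d in draws)
        assert min(draw_threshold(rng, 20.0, 1.0, 25.0) for _ in range(100)) >= 25.0


class TestLocalDensity:
    def test_isolated_cell(self):
        assert local_density(1000.0, []) == pytest.approx(1e-3)

    def test_hand_computed_sum(self):
        assert local_density(1000.0, [2000.0, 4000.0]) == pytest.approx(0.00175)

    def test_uniform_neighborhood(self):
        assert local_density(100.0, [100.0] * 6) == pytest.approx(7 / 100.0)

    def test_zero_area_is_internal_error(self):
        with pytest.raises(ValueError):
            local_density(100.0, [0.0])


class TestApoptosis:
    def test_half_maximum_at_midpoint_density(self):
        p = resolve_lattice_units()  # reference defaults
        assert apoptosis_probability(p.rho_half, p) == pytest.approx(0.00075)

    def test_saturates_at_maximum(self):
        p = resolve_lattice_units()
        assert apoptosis_probability(1e6 * p.rho_half, p) == pytest.approx(0.0015)

    def test_floor_at_zero_density(self):
        p = resolve_lattice_units()
        expected = 0.0015 / (1 + np.exp(0.968 * 1.5015))
        assert apoptosis_probability(0.0, p) == pytest.approx(expected, rel=1e-6)
        assert expected == pytest.approx(2.84e-4, rel=2e-3)

    def test_monotone_increasing(self):
        p = resolve_lattice_units()
        rho = np.linspace(0, 10 / p.As_mean, 50)
        vals = apoptosis_probability(rho, p)
        assert np.all(np.diff(vals) > 0)

    def test_disabled_flag_blocks_trigger(self):
        t = make_fixture("single_cell", 12, seed=0)
        t.params = t.params.replace(apoptosis_enabled=False)
        assert not any(trigger_apoptosis(t, 1, 1e9) for _ in range(1000))

    def test_empirical_trigger_frequency_at_midpoint(self):
        p = resolve_lattice_units()
        t = make_fixture("single_cell", 12, seed=1)
        t.params = t.params.replace(
            papo_max=p.papo_max, rho_half=p.rho_half, alpha=p.alpha
        )
        n, hits = 100_000, 0
        for _ in range(n):
            if trigger_apoptosis(t, 1, p.rho_half):
                hits += 1
                # reset so the cell can be "asked" again
                t.phase[1] = Phase.G1
                t.target[1] = float(t.area[1])
        prob = 0.00075
        assert abs(hits / n - prob) < 3 * np.sqrt(prob * (1 - prob) / n)


class TestExtrusion:
    def test_boundary_case_is_strict(self):
        assert not check_extrusion(25.0, 100.0)
        assert check_extrusion(24.0, 100.0)

    def test_single_cell_never_extruded(self):
        assert not check_extrusion(80.0, 80.0)


class TestDivision:
    @pytest.mark.parametrize("seed", range(40))
    def test_split_conserves_and_connects_random_blobs(self, seed):
        rng = np.random.default_rng(seed)
        # random connected blob grown by neighbor accretion
        sites = {(20, 20)}
        while len(sites) < int(rng.integers(10, 120)):
            r, c = list(sites)[rng.integers(0, len(sites))]
            dr, dc = rng.integers(-1, 2, size=2)
            if (dr, dc) != (0, 0):
                sites.add((r + dr, c + dc))
        arr = np.array(sorted(sites))
        a, b = _split_sites(arr, rng)
        assert len(a) + len(b) == len(arr)
        assert len(a) > 0 and len(b) > 0
        for half in (a, b):
            img = np.zeros((45, 45), dtype=bool)
            img[half[:, 0], half[:, 1]] = True
            _, n = ndimage.label(img, structure=np.ones((3, 3)))
            assert n == 1

    def test_daughters_inherit_nothing_but_geometry(self):
        t = make_fixture("single_cell", 18, seed=3)
        t.phase[1] = Phase.TIMER
        t.clock[1] = t.tau0_i[1]
        area0 = int(t.area[1])
        d1, d2 = divide_cell(t, 1)
        assert int(t.area[d1] + t.area[d2]) == area0
        for d in (d1, d2):
            assert t.target[d] == float(t.area[d])  # AT = own post-split area
            assert Phase(t.phase[d]) is Phase.G1
            assert t.clock[d] == 0.0
            assert t.generation[d] == 1
        assert not t.alive[1]
        births = [e for e in t.events if e[1] == "birth" and e[3] == 1]
        assert len(births) == 2

    def test_too_small_to_divide(self):
        t = make_fixture("single_cell", 12, seed=0)
        t.spin[t.spin == 1] = 0
        t.spin[5, 5] = 1
        t.area[1] = 1
        with pytest.raises(ValueError):
            divide_cell(t, 1)


class TestRemoval:
    def test_removal_clears_sites_and_logs(self):
        t = make_fixture("two_cell", 12, seed=0)
        n0 = t.n_cells
        remove_cell(t, 1, "extrusion")
        assert t.n_cells == n0 - 1
        assert not np.any(t.spin == 1)
        assert t.events[-1][1] == "extrusion"
        # site conservation: freed sites became medium
        assert t.area[t.alive].sum() + np.count_nonzero(t.spin == 0) == t.side**2

    def test_unknown_reason_rejected(self):
        t = make_fixture("two_cell", 12, seed=0)
        with pytest.raises(ValueError):
            remove_cell(t, 1, "teleported")


class TestDecisionStep:
    def test_empty_tissue_is_noop(self):
        t = make_fixture("single_cell", 12, seed=0)
        remove_cell(t, 1, "extrusion")
        step_decision_layer(t)  # must not raise
        assert t.n_cells == 0

    def test_isolated_cell_interdivision_time(self):
        # deterministic estimate: G1 lasts (As_i - A_birth)/G, then tau0_i
        p = calibrated_params(100.0, 1.0, 40.0).replace(
            box_area=60.0 * 60, apoptosis_enabled=False, seed=4
        )
        t = seed_tissue(p)
        expected = (t.As_i[1] - t.area[1]) / p.G + t.tau0_i[1]
        for step in range(1, 500):
            run_mcs(t)
            t.t = step
            step_decision_layer(t)
            if t.division_records:
                break
        assert t.division_records, "no division within 500 MCS"
        t_div = t.division_records[0][0]
        assert t_div == pytest.approx(expected, rel=0.15)

    def test_cell_count_identity_every_step(self):
        p = calibrated_params(100.0, 1.0, 40.0).replace(
            box_area=2500.0, t_max=150, seed=2
        )
        t = seed_tissue(p)
        for step in range(1, 151):
            run_mcs(t)
            t.t = step
            step_decision_layer(t)
            divisions = len({(e[0], e[3]) for e in t.events if e[1] == "birth" and e[3] > 0})
            removals = sum(e[1] in ("apoptosis_removal", "extrusion") for e in t.events)
            assert t.n_cells == 1 + divisions - removals

    def test_apoptotic_cells_drain_and_are_removed(self):
        t = make_fixture("random_tissue", 20, seed=2)
        cid = int(t.live_ids()[len(t.live_ids()) // 2])
        t.phase[cid] = Phase.APOPTOTIC
        t.target[cid] = 0.0
        for step in range(1, 120):
            run_mcs(t)
            t.t = step
            step_decision_layer(t)
            if not t.alive[cid]:
                break
        assert not t.alive[cid]
        assert not np.any(t.spin == cid)
        events = {e[1] for e in t.events if e[2] == cid}
        assert "apoptosis_removal" in events


def test_seed_tissue_initial_condition():
    p = calibrated_params(100.0, 1.0, 40.0).replace(box_area=2500.0)
    t = seed_tissue(p)
    c = cell_state(t, 1)
    assert c.area == 50  # AS/2
    assert c.target_area == 50.0
    assert c.phase is Phase.G1
    # centered disk: centroid at lattice center, single component
    _, n = ndimage.label(t.spin == 1, structure=np.ones((3, 3)))
    assert n == 1
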
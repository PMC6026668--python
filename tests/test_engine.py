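import pytest

from capsim import (
    EventKind,
    MembraneDynamics,
    NeuriteGraph,
    Node,
    NodeRole,
    Segment,
    SimulationConfig,
    Stimulus,
    StimulusSchedule,
    generate_collision_edge,
    generate_ladder,
    oracle_simulate,
    output_phase_pattern,
    simulate,
)
from capsim.graph_model import GraphValidationError

from conftest import assert_conserved, random_scenario

US = 1e-6
MS = 1e-3


def single_chain(length_um=100.0, dynamics=None):
    dyn = dynamics or MembraneDynamics()
    return NeuriteGraph(
        [Node("in", NodeRole.ENTRY), Node("out", NodeRole.TERMINAL)],
        [Segment("s", "in", "out", length_um, dyn)],
    )


def converge_motif(l1=100.0, l2=100.0, dynamics=None):
    """Two parallel paths of given lengths from one ENTRY to a CONVERGE,
    then a single connector to the TERMINAL."""
    dyn = dynamics or MembraneDynamics()
    return NeuriteGraph(
        [Node("E", NodeRole.ENTRY), Node("C", NodeRole.CONVERGE),
         Node("T", NodeRole.TERMINAL)],
        [Segment("P1", "E", "C", l1, dyn), Segment("P2", "E", "C", l2, dyn),
         Segment("out", "C", "T", 100.0, dyn)],
    )


class TestBasicPropagation:
    def test_single_pulse_exits_after_transit_time(self):
        g = single_chain(100.0)  # 100 um at 1 m/s -> 100 us
        log = simulate(g, StimulusSchedule([Stimulus(0.0, "in")]), 1 * MS)
        exits = log.events_of(EventKind.TERMINAL_EXIT)
        assert len(exits) == 1
        assert exits[0].time_s == pytest.approx(100 * US)
        assert output_phase_pattern(log, ["out"]) == [[exits[0].time_s]]
        assert_conserved(log)

    def test_empty_stimulus_gives_empty_log_in_both_engines(self):
        g = single_chain()
        empty = StimulusSchedule([])
        assert simulate(g, empty, 1 * MS).events == []
        assert oracle_simulate(g, empty, 1 * MS, 5 * US).events == []

    def test_stimulus_beyond_horizon_rejected(self):
        g = single_chain()
        with pytest.raises(GraphValidationError):
            simulate(g, StimulusSchedule([Stimulus(2.0, "in")]), 1 * MS)

    def test_invalid_graph_rejected(self):
        g = NeuriteGraph([Node("a", NodeRole.ENTRY)],
                         [Segment("s", "a", "ghost", 10.0)])
        with pytest.raises(GraphValidationError):
            simulate(g, StimulusSchedule([]), 1 * MS)

    def test_pulse_count_conserved_on_fanout(self):
        g = generate_ladder(2, 3, 100.0)
        log = simulate(g, StimulusSchedule([Stimulus(0.0, "entry")]), 5 * MS)
        assert_conserved(log)
        assert log.counters["exited"] == 1  # in-phase branches re-merge


class TestHeadOnCollision:
    def test_simultaneous_entries_annihilate_at_midpoint(self):
        g = generate_collision_edge(100.0)
        sched = StimulusSchedule([Stimulus(0.0, "A"), Stimulus(0.0, "B")])
        log = simulate(g, sched, 1 * MS)
        hits = log.events_of(EventKind.HEAD_ON_ANNIHILATION)
        assert len(hits) == 1
        assert hits[0].position_um == pytest.approx(50.0)
        assert hits[0].time_s == pytest.approx(50 * US)
        assert log.counters["exited"] == 0
        assert log.counters["annihilated"] == 2
        assert_conserved(log)

    def test_staggered_entries_meet_off_center(self):
        g = generate_collision_edge(100.0)
        sched = StimulusSchedule([Stimulus(0.0, "A"),
                                  Stimulus(20 * US, "B")])
        log = simulate(g, sched, 1 * MS)
        hit = log.events_of(EventKind.HEAD_ON_ANNIHILATION)[0]
        assert hit.time_s == pytest.approx(60 * US)
        assert hit.position_um == pytest.approx(60.0)

    def test_lone_pulse_crosses_and_exits_at_far_end(self):
        g = generate_collision_edge(100.0)
        log = simulate(g, StimulusSchedule([Stimulus(0.0, "A")]), 1 * MS)
        assert log.counters["exited"] == 1
        assert log.events_of(EventKind.TERMINAL_EXIT)[0].node == "B"


class TestNodeInteractions:
    def test_in_phase_parallel_arrivals_merge_to_one_exit(self):
        g = converge_motif(100.0, 100.0)
        log = simulate(g, StimulusSchedule([Stimulus(0.0, "E")]), 5 * MS)
        assert len(log.events_of(EventKind.MERGE)) == 1
        assert log.counters["exited"] == 1
        assert log.counters["merged"] == 1
        assert_conserved(log)

    def test_out_of_phase_second_arrival_is_annulled(self):
        # path lengths 100 vs 150 um -> delta = 50 us, inside (tol, tau)
        g = converge_motif(100.0, 150.0)
        log = simulate(g, StimulusSchedule([Stimulus(0.0, "E")]), 5 * MS)
        annuls = log.events_of(EventKind.ANNUL)
        assert len(annuls) == 1
        assert annuls[0].time_s == pytest.approx(150 * US)
        assert log.counters["exited"] == 1
        assert_conserved(log)

    def test_arrival_after_refractory_window_passes(self):
        # same motif but tau = 20 us < delta = 50 us: both pulses pass
        dyn = MembraneDynamics(refractory_s=20 * US)
        g = converge_motif(100.0, 150.0, dyn)
        log = simulate(g, StimulusSchedule([Stimulus(0.0, "E")]), 5 * MS)
        assert not log.events_of(EventKind.ANNUL)
        assert log.counters["exited"] == 2

    def test_comoving_pulses_on_one_path_never_interact(self):
        # two stimuli half a refractory period apart on a single chain:
        # the follower rides behind the leader and both exit
        g = single_chain(100.0)
        sched = StimulusSchedule([Stimulus(0.0, "in"), Stimulus(1 * MS, "in")])
        log = simulate(g, sched, 5 * MS)
        assert log.counters["exited"] == 2

    def test_output_pattern_unknown_terminal_rejected(self):
        g = single_chain()
        log = simulate(g, StimulusSchedule([Stimulus(0.0, "in")]), 1 * MS)
        with pytest.raises(KeyError):
            output_phase_pattern(log, ["nope"])

    def test_well_separated_pulses_superpose(self):
        """Pulses farther apart than every interaction window produce
        identical per-stimulus latencies (non-interacting regime)."""
        g = single_chain(100.0)
        one = simulate(g, StimulusSchedule([Stimulus(0.0, "in")]), 20 * MS)
        two = simulate(g, StimulusSchedule(
            [Stimulus(0.0, "in"), Stimulus(10 * MS, "in")]), 20 * MS)
        t1 = output_phase_pattern(one, ["out"])[0]
        t2 = output_phase_pattern(two, ["out"])[0]
        assert t2[0] == t1[0]
        assert t2[1] - 10 * MS == pytest.approx(t1[0])


class TestEnergy:
    def test_linear_dissipation_reaches_node_with_residual(self):
        # rate 0.005 /um over 100 um: residual 0.5 of 1.0 at the node;
        # threshold exactly 0.5 still activates (boundary inclusive)
        dyn_in = MembraneDynamics(dissipation_per_um=0.005)
        dyn_out = MembraneDynamics(activation_threshold=0.5)
        g = NeuriteGraph(
            [Node("E", NodeRole.ENTRY), Node("M", NodeRole.PASS),
             Node("T", NodeRole.TERMINAL)],
            [Segment("a", "E", "M", 100.0, dyn_in),
             Segment("b", "M", "T", 100.0, dyn_out)],
        )
        log = simulate(g, StimulusSchedule([Stimulus(0.0, "E")]), 5 * MS)
        assert log.counters["exited"] == 1

    def test_subthreshold_residual_fails_at_node(self):
        dyn_in = MembraneDynamics(dissipation_per_um=0.005)
        dyn_out = MembraneDynamics(activation_threshold=0.6)
        g = NeuriteGraph(
            [Node("E", NodeRole.ENTRY), Node("M", NodeRole.PASS),
             Node("T", NodeRole.TERMINAL)],
            [Segment("a", "E", "M", 100.0, dyn_in),
             Segment("b", "M", "T", 100.0, dyn_out)],
        )
        log = simulate(g, StimulusSchedule([Stimulus(0.0, "E")]), 5 * MS)
        fails = log.events_of(EventKind.PULSE_FAILURE)
        assert len(fails) == 1 and fails[0].node == "M"
        assert log.counters["exited"] == 0
        assert_conserved(log)

    def test_energy_exhausted_mid_segment_kills_pulse_there(self):
        # rate 0.02 /um with budget 1.0: the soliton dies 50 um in
        dyn = MembraneDynamics(dissipation_per_um=0.02)
        g = single_chain(100.0, dyn)
        log = simulate(g, StimulusSchedule([Stimulus(0.0, "in")]), 5 * MS)
        fails = log.events_of(EventKind.PULSE_FAILURE)
        assert len(fails) == 1
        assert fails[0].position_um == pytest.approx(50.0)
        assert fails[0].time_s == pytest.approx(50 * US)
        assert log.counters["exited"] == 0


class TestDeterminismAndScaling:
    def test_identical_inputs_give_byte_identical_logs(self):
        g = generate_ladder(2, 3, 100.0, jitter_sd_um=3.0, seed=11)
        sched = StimulusSchedule([Stimulus(0.0, "entry"),
                                  Stimulus(5 * MS, "entry")])
        a = simulate(g, sched, 20 * MS).canonical_text()
        b = simulate(g, sched, 20 * MS).canonical_text()
        assert a == b

    def test_doubling_velocity_exactly_halves_event_times(self):
        g1 = generate_ladder(2, 2, 137.0, jitter_sd_um=4.0, seed=3)
        doubled = {
            sid: Segment(s.id, s.source, s.target, s.length_um,
                         MembraneDynamics(
                             velocity_m_per_s=2 * s.dynamics.velocity_m_per_s,
                             refractory_s=s.dynamics.refractory_s,
                             channel_spacing_um=s.dynamics.channel_spacing_um))
            for sid, s in g1.segments.items()
        }
        g2 = NeuriteGraph(g1.nodes.values(), doubled.values())
        sched = StimulusSchedule([Stimulus(0.0, "entry")])
        log1 = simulate(g1, sched, 20 * MS)
        log2 = simulate(g2, sched, 20 * MS)
        kinds1 = [e.kind for e in log1.events]
        kinds2 = [e.kind for e in log2.events]
        assert kinds1 == kinds2
        for e1, e2 in zip(log1.events, log2.events):
            assert e2.time_s == e1.time_s / 2  # exact, not approximate

    def test_causality_no_event_precedes_first_stimulus(self):
        for seed in range(5):
            g, sched, horizon, _ = random_scenario(seed)
            log = simulate(g, sched, horizon)
            if not log.events:
                continue
            t0 = min(s.time_s for s in sched)
            assert all(e.time_s >= t0 for e in log.events)
            times = [e.time_s for e in log.events]
            assert times == sorted(times)


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", range(24))
    def test_event_engine_matches_time_stepped_oracle(self, seed):
        g, sched, horizon, dt = random_scenario(seed)
        log_e = simulate(g, sched, horizon)
        log_o = oracle_simulate(g, sched, horizon, dt)
        kinds_e = [e.kind for e in log_e.events]
        kinds_o = [e.kind for e in log_o.events]
        assert kinds_e == kinds_o
        for ee, eo in zip(log_e.events, log_o.events):
            assert abs(ee.time_s - eo.time_s) <= dt
        assert log_e.counters == log_o.counters
        assert_conserved(log_e)
        assert_conserved(log_o)

    def test_halving_dt_does_not_worsen_event_times(self):
        g = generate_collision_edge(100.0)
        sched = StimulusSchedule([Stimulus(0.0, "A"), Stimulus(13 * US, "B")])
        exact = simulate(g, sched, 1 * MS)
        t_exact = exact.events_of(EventKind.HEAD_ON_ANNIHILATION)[0].time_s

        def err(dt):
            log = oracle_simulate(g, sched, 1 * MS, dt)
            t = log.events_of(EventKind.HEAD_ON_ANNIHILATION)[0].time_s
            return abs(t - t_exact)

        assert err(2 * US) <= err(4 * US) + 1e-12

    def test_coarse_dt_triggers_warning(self):
        g = generate_collision_edge(100.0)
        sched = StimulusSchedule([Stimulus(0.0, "A")])
        with pytest.warns(UserWarning, match="coarse"):
            oracle_simulate(g, sched, 1 * MS, 50 * US)
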
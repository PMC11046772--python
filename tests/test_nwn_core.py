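import math
from collections import Counter

import numpy as np
import pytest

from bisdl.nwn_core import (
    Arc,
    Channel,
    MirrorBinding,
    Net,
    NwnModel,
    Place,
    SeededStreams,
    Transition,
    enabled,
    fire,
    freeze_marking,
    mirror,
    net_to_dot,
    reachable_markings,
    snapshot_bindings,
    step,
)


def water_net(h2=2, o2=1) -> Net:
    net = Net(name="water")
    net.add_place("H2", H2=h2)
    net.add_place("O2", O2=o2)
    net.add_place("H2O")
    net.add_transition(
        Transition(
            name="react",
            arcs=[
                Arc("in", "H2", weight=2, label="H2"),
                Arc("in", "O2", weight=1, label="O2"),
                Arc("out", "H2O", weight=2, label="H2O"),
            ],
        )
    )
    return net


def single_net_model(net: Net) -> NwnModel:
    return NwnModel(top_net=Net(name="top"), scope_nets={net.name: net})


class TestEnabled:
    def test_insufficient_tokens(self):
        net = water_net(h2=1, o2=1)
        assert not enabled(net.transitions["react"], net)

    def test_exact_stoichiometry(self):
        net = water_net(h2=2, o2=1)
        assert enabled(net.transitions["react"], net)

    @pytest.mark.parametrize("tokens", range(4))
    def test_inhibitor_threshold_exhaustive(self, tokens):
        net = Net(name="n")
        net.add_place("P", **({"x": tokens} if tokens else {}))
        net.add_place("out")
        t = net.add_transition(
            Transition(name="t", arcs=[Arc("inh", "P", weight=1, label="x"),
                                       Arc("out", "out", label="y")])
        )
        assert enabled(t, net) is (tokens < 1)

    def test_dangling_arc_raises(self):
        net = Net(name="n")
        t = Transition(name="t", arcs=[Arc("in", "nowhere", label="x")])
        net.transitions["t"] = t
        with pytest.raises(KeyError, match="dangling arc"):
            enabled(t, net)


class TestFire:
    def test_water_firing_consumes_and_produces(self):
        net = water_net(h2=2, o2=1)
        delta = fire(net.transitions["react"], net)
        assert net.places["H2"].count() == 0
        assert net.places["O2"].count() == 0
        assert net.places["H2O"].count("H2O") == 2
        assert delta == {("H2", "H2"): -2, ("O2", "O2"): -1, ("H2O", "H2O"): 2}

    def test_read_arc_never_consumes(self):
        net = Net(name="n")
        net.add_place("gene", g=1)
        net.add_place("mrna")
        t = net.add_transition(
            Transition(name="t", arcs=[Arc("read", "gene", label="g"),
                                       Arc("out", "mrna", label="m")])
        )
        fire(t, net)
        assert net.places["gene"].count("g") == 1
        assert net.places["mrna"].count("m") == 1

    def test_firing_disabled_raises(self):
        net = water_net(h2=0, o2=0)
        with pytest.raises(RuntimeError, match="disabled"):
            fire(net.transitions["react"], net)

    def test_delta_matches_arc_signature_property(self):
        # token conservation: delta equals the arc-weight signature, always
        rng = np.random.default_rng(0)
        net = water_net(h2=200, o2=100)
        for _ in range(50):
            delta = fire(net.transitions["react"], net, rng)
            assert delta[("H2", "H2")] == -2
            assert delta[("O2", "O2")] == -1
            assert delta[("H2O", "H2O")] == 2

    def test_random_choice_among_matching_tokens(self):
        # open-label arc: consumed colours follow the marking distribution
        rng = np.random.default_rng(42)
        picks = Counter()
        for _ in range(300):
            net = Net(name="n")
            net.add_place("pool", red=1, blue=1)
            t = net.add_transition(
                Transition(name="t", arcs=[Arc("in", "pool", weight=1, label=None)])
            )
            delta = fire(t, net, rng)
            picks[next(iter(delta))[1]] += 1
        assert picks["red"] > 75 and picks["blue"] > 75


class TestChannel:
    def build(self, tokens=1000):
        a = Net(name="a")
        a.add_place("src", AHL=tokens)
        a.add_transition(
            Transition(name="emit", arcs=[Arc("in", "src", label="AHL")], channel="ch")
        )
        b = Net(name="b")
        b.add_place("dst")
        b.add_transition(
            Transition(name="recv", arcs=[Arc("out", "dst", label="AHL")], channel="ch")
        )
        model = NwnModel(top_net=Net(name="top"), scope_nets={"a": a, "b": b})
        model.channels["ch"] = Channel(id="ch", endpoints=(("a", "emit"), ("b", "recv")))
        return model

    def test_conservation_over_many_fires(self):
        model = self.build(tokens=1000)
        streams = SeededStreams(7)
        total = lambda: (
            model.scope_nets["a"].places["src"].count("AHL")
            + model.scope_nets["b"].places["dst"].count("AHL")
        )
        for tick in range(1, 1001):
            step(model, tick, streams, default_p=1.0)
            assert total() == 1000
        moved = model.scope_nets["b"].places["dst"].count("AHL")
        assert moved == 1000  # p=1, one rendezvous per tick

    def test_channel_blocks_when_any_endpoint_disabled(self):
        model = self.build(tokens=0)
        streams = SeededStreams(7)
        step(model, 1, streams, default_p=1.0)
        assert model.scope_nets["b"].places["dst"].count("AHL") == 0


class TestStep:
    def source_model(self, timescales, p=None):
        net = Net(name="s")
        net.add_place("out")
        for i, ts in enumerate(timescales):
            net.add_transition(
                Transition(
                    name=f"src{i}",
                    arcs=[Arc("out", "out", label=f"x{i}")],
                    timescale=ts,
                    p=p,
                )
            )
        return single_net_model(net)

    def test_net_not_visited_off_pace(self):
        model = self.source_model([2])
        events = step(model, 3, SeededStreams(0), default_p=1.0)
        assert events == []

    def test_relative_pace_ratio(self):
        # processes at pace 2 and 5 fire in ratio 500/200 = 2.5 over 1000 ticks
        model = self.source_model([2, 5], p=1.0)
        counts = Counter()
        streams = SeededStreams(0)
        for tick in range(1, 1001):
            for _, name, _ in step(model, tick, streams):
                counts[name] += 1
        assert counts["src0"] == 500
        assert counts["src1"] == 200
        assert counts["src0"] / counts["src1"] == 2.5

    def test_default_firing_frequency(self):
        # empirical frequency of an always-enabled transition at p=0.6
        model = self.source_model([1])
        streams = SeededStreams(123)
        fired = sum(len(step(model, tick, streams, default_p=0.6)) for tick in range(1, 10001))
        freq = fired / 10000
        half_width = 2.576 * math.sqrt(0.6 * 0.4 / 10000)
        assert abs(freq - 0.6) < half_width

    def test_timescale_law_visit_count(self):
        # over K ticks a pace-T transition gets exactly floor(K/T) visits
        for ts in (1, 2, 3, 7):
            model = self.source_model([ts], p=1.0)
            streams = SeededStreams(0)
            fired = sum(len(step(model, tick, streams)) for tick in range(1, 101))
            assert fired == 100 // ts

    def test_seed_determinism(self):
        def trace(seed):
            model = self.source_model([1, 1, 2])
            streams = SeededStreams(seed)
            return [tuple(step(model, tick, streams)) for tick in range(1, 200)]

        assert trace(9) == trace(9)
        assert trace(9) != trace(10)


class TestMirror:
    def build(self):
        top = Net(name="top")
        top.add_place("cell")
        inner = Net(name="inner")
        inner.add_place("AHL")
        top.places["cell"].net_token = inner
        binding = MirrorBinding(
            upper=("top", "cell"), lower=("inner", "AHL"), labels=frozenset({"AHL"})
        )
        model = NwnModel(top_net=top, scope_nets={"inner": inner}, bindings=[binding])
        return model, binding

    def test_upper_gain_propagates_down(self):
        model, binding = self.build()
        baseline = snapshot_bindings(model)[binding]
        model.top_net.places["cell"].add("AHL", 3)
        mirror(model, binding, baseline)
        assert model.scope_nets["inner"].places["AHL"].count("AHL") == 3

    def test_noop_when_unchanged(self):
        model, binding = self.build()
        model.top_net.places["cell"].add("AHL", 2)
        model.scope_nets["inner"].places["AHL"].add("AHL", 2)
        baseline = snapshot_bindings(model)[binding]
        mirror(model, binding, baseline)
        assert model.top_net.places["cell"].count("AHL") == 2
        assert model.scope_nets["inner"].places["AHL"].count("AHL") == 2

    def test_lower_consumption_propagates_up(self):
        model, binding = self.build()
        model.top_net.places["cell"].add("AHL", 2)
        model.scope_nets["inner"].places["AHL"].add("AHL", 2)
        baseline = snapshot_bindings(model)[binding]
        model.scope_nets["inner"].places["AHL"].remove("AHL", 1)
        mirror(model, binding, baseline)
        assert model.top_net.places["cell"].count("AHL") == 1

    def test_conflict_upper_wins_with_warning(self, caplog):
        model, binding = self.build()
        model.top_net.places["cell"].add("AHL", 2)
        model.scope_nets["inner"].places["AHL"].add("AHL", 2)
        baseline = snapshot_bindings(model)[binding]
        model.top_net.places["cell"].add("AHL", 3)  # upper: 5
        model.scope_nets["inner"].places["AHL"].remove("AHL", 1)  # lower: 1
        with caplog.at_level("WARNING"):
            mirror(model, binding, baseline)
        assert model.scope_nets["inner"].places["AHL"].count("AHL") == 5
        assert any("mirror conflict" in r.message for r in caplog.records)


class TestReachability:
    def test_water_reachable_h2o_counts(self):
        net = water_net(h2=4, o2=2)
        result = reachable_markings(net)
        assert result.complete
        h2o = {
            dict(((p, l), c) for p, l, c in marking).get(("H2O", "H2O"), 0)
            for marking in result.markings
        }
        assert h2o == {0, 2, 4}

    def test_no_transitions_fixpoint(self):
        net = Net(name="n")
        net.add_place("P", x=3)
        result = reachable_markings(net)
        assert result.complete
        assert result.markings == frozenset({(("P", "x", 3),)})

    def test_source_depth_bound(self):
        net = Net(name="n")
        net.add_place("out")
        net.add_transition(Transition(name="src", arcs=[Arc("out", "out", label="x")]))
        result = reachable_markings(net, depth_bound=3)
        assert not result.complete
        assert len(result.markings) == 4  # counts 0..3

    def test_engine_states_within_oracle(self):
        # every state visited by 10k stochastic steps is oracle-reachable
        oracle = reachable_markings(water_net(h2=4, o2=2))
        net = water_net(h2=4, o2=2)
        model = single_net_model(net)
        streams = SeededStreams(11)
        for tick in range(1, 10001):
            step(model, tick, streams)
            assert freeze_marking(net) in oracle.markings


class TestDot:
    def test_dot_output_well_formed(self):
        dot = net_to_dot(water_net())
        assert dot.startswith('digraph "water" {')
        assert dot.rstrip().endswith("}")
        assert dot.count("{") == dot.count("}")
        assert '"p_H2"' in dot and '"t_react"' in dot
        assert '[shape=circle' in dot and "[shape=box" in dot
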
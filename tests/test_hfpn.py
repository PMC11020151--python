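"""HFPN engine: validation, enablement, stepping, integration accuracy."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from numpy.polynomial import polynomial as npoly

from mitohfpn import (
    ArcSpec,
    NetSpec,
    PlaceSpec,
    RateLaw,
    SimulationState,
    TransitionSpec,
    is_enabled,
    read_net_yaml,
    simulate,
    step,
    validate_net,
    write_net_yaml,
)


def single_transition_net(coeffs, initial=0.0, allow_negative=True, extra_arcs=(),
                          extra_places=()):
    return NetSpec(
        places=(PlaceSpec("X", "continuous", initial, allow_negative=allow_negative),)
        + tuple(extra_places),
        transitions=(TransitionSpec("flow", "continuous", rate=RateLaw(coeffs)),),
        arcs=(ArcSpec("flow", "X", "normal", 1.0),) + tuple(extra_arcs),
    )


class TestValidate:
    def test_place_to_place_arc_rejected(self):
        net = NetSpec(
            places=(PlaceSpec("A"), PlaceSpec("B")),
            transitions=(TransitionSpec("t", "continuous", rate=RateLaw((1.0,))),),
            arcs=(ArcSpec("A", "B", "normal"), ArcSpec("t", "A", "normal")),
        )
        diags = validate_net(net)
        assert len(diags) == 1 and "A->B" in diags[0].element

    def test_duplicate_place_id_cited(self):
        net = NetSpec(
            places=(PlaceSpec("NADH"), PlaceSpec("NADH")),
            transitions=(TransitionSpec("t", "continuous", rate=RateLaw((1.0,))),),
            arcs=(ArcSpec("t", "NADH", "normal"),),
        )
        diags = validate_net(net)
        assert any(d.element == "NADH" and "duplicate" in d.message for d in diags)

    @pytest.mark.parametrize("condition", ["control", "c1193"])
    def test_bundled_model_files_are_valid(self, condition):
        from mitohfpn.model import bundled_model_path

        net = read_net_yaml(bundled_model_path(condition))
        assert validate_net(net) == []

    @pytest.mark.parametrize(
        "mutate",
        [
            # discrete transition with a rate, continuous with a delay,
            # degree-5 rate, negative threshold, dangling arc endpoint
            lambda: TransitionSpec("t", "discrete", rate=RateLaw((1.0,)), delay=1.0),
            lambda: TransitionSpec("t", "continuous", rate=RateLaw((1.0,)), delay=1.0),
            lambda: TransitionSpec("t", "continuous", rate=RateLaw((1, 1, 1, 1, 1, 1))),
            lambda: TransitionSpec("t", "continuous", rate=RateLaw((1.0,), (0.0, 20.0))),
        ],
    )
    def test_malformed_transition_rejected(self, mutate):
        net = NetSpec(places=(PlaceSpec("A"),), transitions=(mutate(),),
                      arcs=(ArcSpec("t", "A", "normal"),))
        assert any(d.element == "t" for d in validate_net(net))

    def test_inhibitory_arc_must_point_into_transition(self):
        net = NetSpec(
            places=(PlaceSpec("A"),),
            transitions=(TransitionSpec("t", "continuous", rate=RateLaw((1.0,))),),
            arcs=(ArcSpec("t", "A", "inhibitory"),),
        )
        assert any("place -> transition" in d.message for d in validate_net(net))

    @given(marking=st.floats(-5, -0.001))
    def test_negative_initial_marking_rejected_unless_signed(self, marking):
        net = NetSpec(
            places=(PlaceSpec("A", "continuous", marking),),
            transitions=(TransitionSpec("t", "continuous", rate=RateLaw((1.0,))),),
            arcs=(ArcSpec("t", "A", "normal"),),
        )
        assert any(d.element == "A" for d in validate_net(net))
        signed = NetSpec(
            places=(PlaceSpec("A", "continuous", marking, allow_negative=True),),
            transitions=net.transitions, arcs=net.arcs,
        )
        assert validate_net(signed) == []


class TestEnablement:
    def _net(self, arc_kind, threshold, marking):
        return (
            NetSpec(
                places=(PlaceSpec("X"), PlaceSpec("P", "continuous", marking)),
                transitions=(TransitionSpec("t", "continuous", rate=RateLaw((1.0,))),),
                arcs=(ArcSpec("P", "t", arc_kind, threshold), ArcSpec("t", "X", "normal")),
            ),
        )

    @pytest.mark.parametrize(
        "arc_kind,threshold,marking,expected",
        [
            ("inhibitory", 0.001, 0.0, True),    # below threshold: enabled
            ("inhibitory", 0.001, 10.0, False),  # at/above threshold: disabled
            ("inhibitory", 0.001, 0.001, False), # boundary counts as inhibited
            ("test", 1.0, 5.0, True),            # substrate present
            ("test", 1.0, 0.5, False),
        ],
    )
    def test_arc_semantics(self, arc_kind, threshold, marking, expected):
        (net,) = self._net(arc_kind, threshold, marking)
        state = SimulationState.initial(net)
        assert is_enabled(net, state, "t") is expected

    def test_unknown_transition_names_id(self):
        (net,) = self._net("test", 1.0, 5.0)
        with pytest.raises(KeyError, match="nope"):
            is_enabled(net, SimulationState.initial(net), "nope")


class TestStep:
    def test_constant_rate_flux(self):
        net = single_transition_net((13.9,), initial=1000.0)
        state = step(net, SimulationState.initial(net), dt=0.1)
        assert state.marking["X"] == pytest.approx(1001.39)
        assert state.time == pytest.approx(0.1)

    def test_zero_rate_is_identity(self):
        net = single_transition_net((0.0,), initial=7.0)
        state = step(net, SimulationState.initial(net), dt=0.5)
        assert state.marking["X"] == 7.0

    def test_inhibited_transition_moves_nothing(self):
        net = single_transition_net(
            (13.9,), initial=1000.0,
            extra_places=(PlaceSpec("I", "continuous", 10.0),),
            extra_arcs=(ArcSpec("I", "flow", "inhibitory", 0.001),),
        )
        state = step(net, SimulationState.initial(net), dt=0.1)
        assert state.marking["X"] == 1000.0

    def test_test_and_inhibitory_arcs_never_consume(self):
        net = single_transition_net(
            (13.9,), initial=0.0,
            extra_places=(PlaceSpec("S", "continuous", 5.0),
                          PlaceSpec("I", "continuous", 0.0)),
            extra_arcs=(ArcSpec("S", "flow", "test", 1.0),
                        ArcSpec("I", "flow", "inhibitory", 1.0)),
        )
        state = SimulationState.initial(net)
        for _ in range(10):
            state = step(net, state, dt=0.1)
        assert state.marking["S"] == 5.0
        assert state.marking["I"] == 0.0
        assert state.marking["X"] == pytest.approx(13.9)

    def test_normal_input_arc_consumes_weighted_flux(self):
        net = NetSpec(
            places=(PlaceSpec("A", "continuous", 10.0), PlaceSpec("B")),
            transitions=(TransitionSpec("t", "continuous", rate=RateLaw((2.0,))),),
            arcs=(ArcSpec("A", "t", "normal", 3.0), ArcSpec("t", "B", "normal", 1.0)),
        )
        state = step(net, SimulationState.initial(net), dt=0.5)
        assert state.marking["A"] == pytest.approx(10.0 - 3.0 * 2.0 * 0.5)
        assert state.marking["B"] == pytest.approx(1.0)

    def test_clamp_at_zero_logged(self):
        net = single_transition_net((-5.0,), initial=0.2, allow_negative=False)
        state = step(net, SimulationState.initial(net), dt=0.1)
        assert state.marking["X"] == 0.0
        assert state.clamp_events and state.clamp_events[0][1] == "X"

    def test_nonpositive_dt_rejected(self):
        net = single_transition_net((1.0,))
        with pytest.raises(ValueError, match="dt"):
            step(net, SimulationState.initial(net), dt=0.0)

    def test_nonfinite_rate_names_transition(self):
        net = single_transition_net((np.inf,))
        with pytest.raises(ArithmeticError, match="flow"):
            step(net, SimulationState.initial(net), dt=0.1)


class TestSimulate:
    def test_quadratic_rate_matches_closed_form(self):
        # speed -1.14 t^2 + 14.88 t - 49.20 integrates to the NADH cubic
        net = single_transition_net((-49.20, 14.88, -1.14))
        res = simulate(net, t_end=2.0, dt=0.001, sample_every=0.5)
        assert res["X"][-1] == pytest.approx(-71.68, abs=1e-6)

    def test_constant_rate_end_value(self):
        net = single_transition_net((13.9,), initial=1000.0)
        res = simulate(net, t_end=15.0, dt=0.01, sample_every=0.5)
        assert res["X"][-1] == pytest.approx(1208.5, abs=1e-9)

    def test_zero_t_end_returns_initial_sample(self):
        net = single_transition_net((13.9,), initial=3.0)
        res = simulate(net, t_end=0.0, dt=0.01, sample_every=0.5)
        assert list(res.times) == [0.0]
        assert res["X"][0] == 3.0

    def test_validity_window_enforced(self):
        net = single_transition_net((1.0,))
        with pytest.raises(ValueError, match="validity"):
            simulate(net, t_end=20.0, dt=0.01, sample_every=1.0)
        res = simulate(net, t_end=20.0, dt=0.01, sample_every=1.0,
                       allow_beyond_validity=True)
        assert res.times[-1] == pytest.approx(20.0)

    @settings(max_examples=25, deadline=None)
    @given(coeffs=st.lists(st.floats(-5, 5), min_size=1, max_size=5))
    def test_oracle_equivalence_any_polynomial_rate(self, coeffs):
        """Simulated marking matches the closed-form antiderivative, and the
        integration error at least halves when dt is halved."""
        net = single_transition_net(tuple(coeffs))
        exact = npoly.polyint(coeffs)
        checkpoints = np.array([1.0, 5.0, 10.0, 15.0])
        errs = []
        for dt in (0.02, 0.01):
            res = simulate(net, t_end=15.0, dt=dt, sample_every=1.0)
            idx = np.searchsorted(res.times, checkpoints)
            sim = res["X"][idx]
            ref = npoly.polyval(checkpoints, exact)
            scale = max(1.0, float(np.max(np.abs(ref))))
            assert np.max(np.abs(sim - ref)) <= 1e-3 * scale
            errs.append(float(np.max(np.abs(sim - ref))))
        assert errs[1] <= 0.5 * errs[0] + 1e-9 * max(1.0, abs(errs[0]))

    def test_determinism_bitwise(self):
        net = single_transition_net((-49.20, 14.88, -1.14))
        a = simulate(net, t_end=15.0, dt=0.01, sample_every=0.5)
        b = simulate(net, t_end=15.0, dt=0.01, sample_every=0.5)
        assert np.array_equal(a["X"], b["X"]) and np.array_equal(a.times, b.times)


class TestDiscrete:
    def _pore_net(self, blocked: bool):
        return NetSpec(
            places=(PlaceSpec("intact", "discrete", 1), PlaceSpec("open", "discrete", 0),
                    PlaceSpec("CsA", "continuous", 0.005 if blocked else 0.0)),
            transitions=(TransitionSpec("pore", "discrete", delay=1.0),),
            arcs=(ArcSpec("intact", "pore", "normal", 1.0),
                  ArcSpec("pore", "open", "normal", 1.0),
                  ArcSpec("CsA", "pore", "inhibitory", 0.001)),
        )

    def test_blocked_pore_never_fires(self):
        res = simulate(self._pore_net(blocked=True), t_end=15.0, dt=0.1, sample_every=1.0)
        assert res.event_log == []
        assert res["open"][-1] == 0

    def test_unblocked_pore_fires_after_delay(self):
        res = simulate(self._pore_net(blocked=False), t_end=5.0, dt=0.1, sample_every=1.0)
        assert len(res.event_log) == 1
        t_fire, tid = res.event_log[0]
        assert tid == "pore" and t_fire == pytest.approx(1.0, abs=0.15)
        assert res["open"][-1] == 1 and res["intact"][-1] == 0


class TestYamlRoundTrip:
    def test_handmade_net(self, tmp_path):
        net = single_transition_net(
            (-49.20, 14.88, -1.14), initial=5.0,
            extra_places=(PlaceSpec("S", "generic", 1.0, label="catalyst"),),
            extra_arcs=(ArcSpec("S", "flow", "test", 1.0),),
        )
        path = tmp_path / "net.yaml"
        write_net_yaml(net, path)
        assert read_net_yaml(path) == net

    @pytest.mark.parametrize("condition", ["control", "c1193"])
    def test_bundled_files_match_builder(self, condition, control_model, c1193_model):
        from mitohfpn.model import bundled_model_path

        built = {"control": control_model, "c1193": c1193_model}[condition][0]
        assert read_net_yaml(bundled_model_path(condition)) == built
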
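"""Ideal terminal-bed regulation, APR, and critical-stenosis detection."""

import dataclasses

import pytest

from cowflow.autoregulation import (
    AutoregulationParams,
    RegulationState,
    TerritoryParams,
    compute_apr,
    default_autoregulation_params,
    find_autoregulation_exit,
    regulate,
)
from cowflow.errors import ConfigurationError
from cowflow.formulas import MMHG_PA, FluidProperties, FormulaKind, SegmentGeometry
from cowflow.network import (
    CoWNetwork,
    Node,
    NodeKind,
    Segment,
    TerminalBed,
    Territory,
    apply_stenosis,
    reference_network,
    set_diameter,
)
from cowflow.solver import SolverSettings


@pytest.fixture(scope="module")
def params():
    return default_autoregulation_params()


class TestDefaultParams:
    def test_territory_table(self, params):
        mid = params.territories[Territory.MIDDLE_L]
        assert (mid.q_target, mid.r_min, mid.r_max) == (162.0, 0.32, 0.90)
        ant = params.territories[Territory.ANTERIOR_R]
        assert (ant.q_target, ant.r_min, ant.r_max) == (111.0, 0.46, 1.31)
        post = params.territories[Territory.POSTERIOR_L]
        assert (post.q_target, post.r_min, post.r_max) == (120.0, 0.44, 1.20)

    def test_pressure_limits(self, params):
        assert params.p_lower == 50.0
        assert params.p_upper == 150.0

    def test_r_min_consistent_with_lower_limit(self, params):
        """The tabulated r_min is (within rounding) p_lower / q_target."""
        for tp in params.territories.values():
            assert params.p_lower / tp.q_target == pytest.approx(tp.r_min, rel=0.10)

    def test_invalid_params_rejected(self):
        with pytest.raises(ConfigurationError):
            TerritoryParams(q_target=100.0, r_min=0.9, r_max=0.3)
        with pytest.raises(ConfigurationError):
            AutoregulationParams(territories={}, p_lower=150.0, p_upper=50.0)


class TestRegulate:
    def test_reference_all_within_targets_met(self, reference_net, params):
        sol = regulate(reference_net, params)
        assert all(
            s == RegulationState.WITHIN for s in sol.regulation_state.values()
        )
        for territory, tp in params.territories.items():
            assert sol.base.bed_flows[territory] == pytest.approx(
                tp.q_target, abs=1e-3
            )

    def test_low_inlet_pressure_saturates_dilation(self, params):
        net = reference_network(inlet_pressure_mmhg=30.0)
        sol = regulate(net, params)
        for territory, tp in params.territories.items():
            assert sol.regulation_state[territory] == RegulationState.BELOW_LOWER
            assert sol.bed_resistances[territory] == pytest.approx(tp.r_min, rel=1e-6)

    def test_one_bed_toy_clips_at_r_min(self, params, fluid):
        """Attach held at 45 mmHg: required R = 45/162 < r_min, so the bed
        saturates at 0.32 and delivers 45/0.32 = 140.6 ml/min."""
        geom = SegmentGeometry(0.001, 0.02, 1.0, FormulaKind.ENTRANCE)  # negligible
        net = CoWNetwork(
            nodes={
                "src": Node("src", NodeKind.INLET, 45 * MMHG_PA),
                "out": Node("out", NodeKind.TERMINAL_OUTLET),
            },
            segments={"feed": Segment("feed", "src", "out", geom)},
            beds={
                Territory.MIDDLE_L: TerminalBed(Territory.MIDDLE_L, "out", 1e9, 0.0)
            },
            fluid=fluid,
        )
        one = dataclasses.replace(
            params,
            territories={Territory.MIDDLE_L: params.territories[Territory.MIDDLE_L]},
        )
        sol = regulate(net, one)
        assert sol.regulation_state[Territory.MIDDLE_L] == RegulationState.BELOW_LOWER
        assert sol.bed_resistances[Territory.MIDDLE_L] == pytest.approx(0.32)
        assert sol.base.bed_flows[Territory.MIDDLE_L] == pytest.approx(140.62, abs=0.05)

    def test_plateau_constant_flow_monotone_resistance(self, params):
        """While every territory regulates, bed flow stays on target and the
        bed resistance rises with inlet pressure."""
        previous_r = 0.0
        for p_inlet in (85.0, 95.0, 105.0, 115.0):
            sol = regulate(reference_network(inlet_pressure_mmhg=p_inlet), params)
            assert all(
                s == RegulationState.WITHIN for s in sol.regulation_state.values()
            )
            assert sol.base.bed_flows[Territory.MIDDLE_L] == pytest.approx(
                162.0, abs=1e-3
            )
            r = sol.bed_resistances[Territory.MIDDLE_L]
            assert r > previous_r
            previous_r = r

    def test_clip_consistency(self, reference_net, params):
        """WITHIN iff the unclipped required resistance, recomputed from the
        converged perfusion pressure, lies inside [r_min, r_max]."""
        net = apply_stenosis(set_diameter(reference_net, "ACoA", 0.4), "ICAL", 0.30)
        sol = regulate(net, params)
        for territory, tp in params.territories.items():
            required = (
                sol.perfusion_pressure[territory] - params.drain_pressure
            ) / tp.q_target
            inside = tp.r_min <= required <= tp.r_max
            assert (
                sol.regulation_state[territory] == RegulationState.WITHIN
            ) == inside


class TestAPR:
    @pytest.mark.parametrize(
        "pressure, expected",
        [(70.0, (20.0, 80.0)), (50.0, (0.0, 100.0)), (45.0, (-5.0, 105.0))],
    )
    def test_reserve_arithmetic(self, params, reference_net, pressure, expected):
        sol = regulate(reference_net, params)
        sol.perfusion_pressure = {Territory.MIDDLE_L: pressure}
        lower, upper = compute_apr(sol, params)
        assert lower[Territory.MIDDLE_L] == pytest.approx(expected[0])
        assert upper[Territory.MIDDLE_L] == pytest.approx(expected[1])

    def test_reserves_positive_on_reference(self, reference_net, params):
        sol = regulate(reference_net, params)
        for territory in params.territories:
            assert sol.apr_lower[territory] > 0
            assert sol.apr_upper[territory] > 0

    def test_lower_reserve_monotone_in_stenosis(self, reference_net, params):
        """Narrowing a supplying artery can only erode the lower reserve."""
        net = set_diameter(reference_net, "ACoA", 0.4)
        reserves = []
        for severity in (0.0, 0.1, 0.2, 0.3, 0.4, 0.5):
            sol = regulate(apply_stenosis(net, "ICAL", severity), params)
            reserves.append(sol.apr_lower[Territory.MIDDLE_L])
        assert all(b <= a + 1e-9 for a, b in zip(reserves, reserves[1:]))


class TestExitDetection:
    def test_irrelevant_segment_never_exits(self, reference_net, params):
        severity = find_autoregulation_exit(
            reference_net, params, "A2R", Territory.MIDDLE_L
        )
        assert severity is None

    def test_exit_ordering_with_acoa_diameter(self, reference_net, params):
        """A wider anterior communicating artery postpones the exit."""
        thin = find_autoregulation_exit(
            set_diameter(reference_net, "ACoA", 0.4), params, "ICAL", "middle_l"
        )
        thick = find_autoregulation_exit(
            set_diameter(reference_net, "ACoA", 1.6), params, "ICAL", "middle_l"
        )
        assert thin is not None and thick is not None
        assert thin < thick

    def test_bilateral_exit_independent_of_acoa(self, reference_net, params):
        """With symmetric bilateral stenosis no flow crosses the ACoA, so its
        diameter cannot matter."""
        exits = {}
        for diameter in (0.4, 1.6):
            net = set_diameter(reference_net, "ACoA", diameter)
            exits[diameter] = find_autoregulation_exit(
                net, params, ["ICAL", "ICAR"], Territory.MIDDLE_L, resolution=0.002
            )
        assert exits[0.4] == pytest.approx(exits[1.6], abs=0.004)

    def test_bilateral_sweep_preserves_symmetry(self, reference_net, params):
        net = apply_stenosis(
            apply_stenosis(reference_net, "ICAL", 0.3), "ICAR", 0.3
        )
        sol = regulate(net, params)
        assert sol.apr_lower[Territory.MIDDLE_L] == pytest.approx(
            sol.apr_lower[Territory.MIDDLE_R], abs=1e-6
        )
        assert abs(sol.base.segment_flows["ACoA"]) < 1e-6

    def test_unknown_territory_rejected(self, reference_net, params):
        with pytest.raises(ConfigurationError):
            find_autoregulation_exit(reference_net, params, "ICAL", "cerebellum")

    def test_linear_mode_is_more_optimistic(self, reference_net, params):
        """Pure Hagen-Poiseuille resistances postpone (or abolish) the exit."""
        thin_net = set_diameter(reference_net, "ACoA", 0.4)
        linear = SolverSettings(mode="linear")
        nl = find_autoregulation_exit(thin_net, params, "ICAL", "middle_l")
        lin = find_autoregulation_exit(
            thin_net, params, "ICAL", "middle_l", settings=linear
        )
        assert nl is not None
        assert lin is None or lin > nl

    def test_thick_acoa_linear_survives_complete_occlusion(
        self, reference_net, params
    ):
        thick = set_diameter(reference_net, "ACoA", 1.6)
        linear = SolverSettings(mode="linear")
        assert (
            find_autoregulation_exit(
                thick, params, "ICAL", "middle_l", settings=linear
            )
            is None
        )
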
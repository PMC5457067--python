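"""Capillary-flow chain: each relation, the width prediction, inverses,
scaling laws and the Newtonian (Hagen-Poiseuille) limit."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from inkflow import (
    DomainError,
    InkParams,
    NozzleSpec,
    ResolutionModel,
    predict_width,
    required_pressure,
    required_speed,
    strand_flow_rate,
    sweep,
    wall_shear_rate_from_flow,
    wall_shear_stress,
)

positive = st.floats(1e-3, 1e3)
index = st.floats(0.02, 3.0)


def hagen_poiseuille_width(eta, D, L, dP, v):
    """Independent Newtonian oracle: d^2 = dP * D^4 / (32 eta L v)."""
    return math.sqrt(dP * D**4 / (32.0 * eta * L * v))


class TestWallShearStress:
    def test_reference_nozzle_value(self, nozzle_21g):
        # hand arithmetic: 514e-6 * 1e5 / (4*0.005) = 2570
        assert wall_shear_stress(nozzle_21g, 1e5) == pytest.approx(2570.0)

    def test_unit_prefactor(self):
        nozzle = NozzleSpec("big", inner_diameter=0.02, length=0.005)  # D = 4L
        assert wall_shear_stress(nozzle, 7.0) == pytest.approx(7.0)

    def test_linear_in_pressure(self, nozzle_21g):
        assert wall_shear_stress(nozzle_21g, 2e5) == pytest.approx(
            2 * wall_shear_stress(nozzle_21g, 1e5)
        )


class TestWallShearRate:
    def test_newtonian_unit_prefactor(self):
        nozzle = NozzleSpec("unit", inner_diameter=1.0, length=1.0)
        assert wall_shear_rate_from_flow(1.0, math.pi / 32.0, nozzle) == pytest.approx(1.0)

    def test_reference_nozzle_value(self, nozzle_21g):
        # hand oracle: 32*(pi*1e-10)/(pi*(514e-6)^3) = 23.5646...
        got = wall_shear_rate_from_flow(1.0, math.pi * 1e-10, nozzle_21g)
        assert got == pytest.approx(23.564629797, rel=1e-9)

    def test_rabinowitsch_factor_decreasing_in_n(self, nozzle_21g):
        ns = np.linspace(0.05, 3.0, 40)
        rates = [wall_shear_rate_from_flow(n, 1e-9, nozzle_21g) for n in ns]
        assert np.all(np.diff(rates) < 0)

    def test_tiny_index_warns(self, nozzle_21g):
        with pytest.warns(UserWarning, match="Rabinowitsch"):
            wall_shear_rate_from_flow(5e-5, 1e-9, nozzle_21g)


class TestStrandFlowRate:
    def test_arithmetic(self):
        assert strand_flow_rate(2e-4, 0.01) == pytest.approx(math.pi * 1e-10)

    def test_normalisation(self):
        assert strand_flow_rate(2.0 / math.sqrt(math.pi), 1.0) == pytest.approx(1.0)

    @settings(deadline=None, derandomize=True, max_examples=100)
    @given(n=index, d=positive, v=positive, D=positive, L=positive)
    def test_composition_identity(self, n, d, v, D, L):
        """gamma_w(Q(d, v)) == ((3n+1)/4n) * 8 d^2 v / D^3 algebraically."""
        nozzle = NozzleSpec("x", D, L)
        via_flow = wall_shear_rate_from_flow(n, strand_flow_rate(d, v), nozzle)
        direct = (3 * n + 1) / (4 * n) * 8 * d**2 * v / D**3
        assert via_flow == pytest.approx(direct, rel=1e-12)


class TestPredictWidth:
    def test_reference_condition(self, pluronic_245, nozzle_21g):
        """Frozen from an independent one-line evaluation of
        d = D^2 sqrt(dP (4n/(3n+1)) / (32 eta L v))."""
        report = predict_width(pluronic_245, nozzle_21g, 1e5, 0.01)
        assert report.predicted_width == pytest.approx(8.622215569581e-4, rel=1e-9)
        assert report.over_extrusion is True  # 862 um > 514 um nozzle

    def test_speed_scaling_sqrt3(self, pluronic_245, nozzle_21g):
        d1 = predict_width(pluronic_245, nozzle_21g, 1e5, 0.01).predicted_width
        d3 = predict_width(pluronic_245, nozzle_21g, 1e5, 0.03).predicted_width
        assert d1 / d3 == pytest.approx(math.sqrt(3.0), rel=1e-12)

    def test_newtonian_unit_case(self):
        ink = InkParams(n=1.0, eta=1.0)
        nozzle = NozzleSpec("unit", 1.0, 1.0)
        report = predict_width(ink, nozzle, 32.0, 1.0)
        assert report.predicted_width == pytest.approx(1.0, rel=1e-12)

    @settings(deadline=None, derandomize=True, max_examples=100)
    @given(eta=positive, D=st.floats(1e-4, 1e-2), L=st.floats(1e-3, 1e-1),
           dP=st.floats(1e3, 1e6), v=st.floats(1e-3, 1.0))
    def test_newtonian_limit_matches_hagen_poiseuille(self, eta, D, L, dP, v):
        ink = InkParams(n=1.0, eta=eta)
        got = predict_width(ink, NozzleSpec("x", D, L), dP, v).predicted_width
        assert got == pytest.approx(hagen_poiseuille_width(eta, D, L, dP, v), rel=1e-12)

    @settings(deadline=None, derandomize=True, max_examples=100)
    @given(n=index, eta=positive, D=st.floats(1e-4, 1e-2),
           L=st.floats(1e-3, 1e-1), dP=st.floats(1e3, 1e6), v=st.floats(1e-3, 1.0))
    def test_constitutive_self_consistency(self, n, eta, D, L, dP, v):
        """tau_w == eta * gamma_w at the predicted width (closure identity)."""
        ink = InkParams(n=n, eta=eta)
        nozzle = NozzleSpec("x", D, L)
        report = predict_width(ink, nozzle, dP, v)
        assert report.wall_shear_stress == pytest.approx(
            eta * report.wall_shear_rate, rel=1e-12
        )

    def test_report_flow_state_consistent(self, pluronic_245, nozzle_21g):
        report = predict_width(pluronic_245, nozzle_21g, 2e5, 0.02)
        assert report.volumetric_flow_rate == pytest.approx(
            strand_flow_rate(report.predicted_width, 0.02), rel=1e-12
        )
        assert report.wall_shear_stress == pytest.approx(
            wall_shear_stress(nozzle_21g, 2e5), rel=1e-12
        )

    @pytest.mark.parametrize("dP,v", [(0.0, 0.01), (-1e5, 0.01), (1e5, 0.0)])
    def test_nonpositive_inputs_rejected(self, pluronic_245, nozzle_21g, dP, v):
        with pytest.raises(DomainError):
            predict_width(pluronic_245, nozzle_21g, dP, v)


class TestScalingLaws:
    """d scales as sqrt(dP), 1/sqrt(v), and D^2 — checked on randomized inputs."""

    def _random_inputs(self, size=1000):
        rng = np.random.default_rng(42)
        return (
            rng.uniform(0.05, 2.0, size),    # n
            rng.uniform(0.1, 100.0, size),   # eta
            rng.uniform(1e-4, 1e-2, size),   # D
            rng.uniform(1e-3, 1e-1, size),   # L
            rng.uniform(1e3, 1e6, size),     # dP
            rng.uniform(1e-3, 1.0, size),    # v
            rng.uniform(1.1, 10.0, size),    # k
        )

    def test_pressure_speed_diameter_scalings(self):
        for n, eta, D, L, dP, v, k in zip(*self._random_inputs()):
            ink = InkParams(n=n, eta=eta)
            base = predict_width(ink, NozzleSpec("x", D, L), dP, v).predicted_width
            scaled_p = predict_width(ink, NozzleSpec("x", D, L), k**2 * dP, v)
            assert scaled_p.predicted_width / base == pytest.approx(k, rel=1e-12)
            scaled_v = predict_width(ink, NozzleSpec("x", D, L), dP, v / k**2)
            assert scaled_v.predicted_width / base == pytest.approx(k, rel=1e-12)
            scaled_d = predict_width(ink, NozzleSpec("x", k * D, L), dP, v)
            assert scaled_d.predicted_width / base == pytest.approx(k**2, rel=1e-12)


class TestInverses:
    @settings(deadline=None, derandomize=True, max_examples=200)
    @given(n=index, eta=positive, D=st.floats(1e-4, 1e-2), L=st.floats(1e-3, 1e-1),
           dP=st.floats(1e3, 1e6), v=st.floats(1e-3, 1.0))
    def test_round_trips(self, n, eta, D, L, dP, v):
        ink = InkParams(n=n, eta=eta)
        nozzle = NozzleSpec("x", D, L)
        d = predict_width(ink, nozzle, dP, v).predicted_width
        assert required_pressure(ink, nozzle, d, v) == pytest.approx(dP, rel=1e-9)
        assert required_speed(ink, nozzle, d, dP) == pytest.approx(v, rel=1e-9)

    def test_newtonian_unit_cases(self):
        ink = InkParams(n=1.0, eta=1.0)
        nozzle = NozzleSpec("unit", 1.0, 1.0)
        assert required_pressure(ink, nozzle, 1.0, 1.0) == pytest.approx(32.0)
        assert required_speed(ink, nozzle, 1.0, 32.0) == pytest.approx(1.0)

    def test_pressure_for_derived_width(self, pluronic_245, nozzle_21g):
        got = required_pressure(pluronic_245, nozzle_21g, 862.23e-6, 0.01)
        assert got == pytest.approx(1e5, rel=1e-4)

    def test_halving_width_quadruples_speed(self, pluronic_245, nozzle_21g):
        v1 = required_speed(pluronic_245, nozzle_21g, 500e-6, 1e5)
        v2 = required_speed(pluronic_245, nozzle_21g, 250e-6, 1e5)
        assert v2 / v1 == pytest.approx(4.0, rel=1e-12)


class TestSweep:
    def test_factorial_shape_and_order(self, pluronic_245):
        nozzles = [NozzleSpec.from_gauge(g) for g in ("21G", "25G", "27G")]
        table = sweep(pluronic_245, nozzles, [1e5, 2e5, 3e5], [0.01, 0.02, 0.03])
        assert len(table) == 27
        assert list(table["gauge"][:9]) == ["21G"] * 9
        # within a nozzle, speed blocks; within a block, increasing pressure
        assert list(table["pressure_Pa"][:3]) == [1e5, 2e5, 3e5]

    def test_width_increasing_in_pressure(self, pluronic_245, nozzle_21g):
        table = sweep(pluronic_245, [nozzle_21g], [1e5, 2e5, 3e5], [0.01])
        assert table["d_pred_um"].is_monotonic_increasing

    def test_width_depends_only_on_abscissa_at_fixed_speed(self, pluronic_245):
        # trade D vs dP keeping D^2 sqrt(dP) fixed
        a = sweep(pluronic_245, [NozzleSpec("a", 514e-6, 0.005)], [4e5], [0.01])
        b = sweep(
            pluronic_245,
            [NozzleSpec("b", 514e-6 * math.sqrt(2.0), 0.005)],
            [1e5],
            [0.01],
        )
        assert a["D2sqrtP"].iloc[0] == pytest.approx(b["D2sqrtP"].iloc[0], rel=1e-12)
        assert a["d_pred_um"].iloc[0] == pytest.approx(b["d_pred_um"].iloc[0], rel=1e-12)

    def test_empty_lists_rejected(self, pluronic_245, nozzle_21g):
        with pytest.raises(DomainError):
            sweep(pluronic_245, [], [1e5], [0.01])
        with pytest.raises(DomainError):
            sweep(pluronic_245, [nozzle_21g], [], [0.01])


class TestResolutionModel:
    def test_object_api_round_trip(self, pluronic_245, nozzle_21g):
        model = ResolutionModel(pluronic_245, nozzle_21g)
        report = model.predict(1e5, 0.01)
        dp = model.required_pressure(report.predicted_width_um, 0.01)
        assert dp == pytest.approx(1e5, rel=1e-9)
        v = model.required_speed(report.predicted_width_um, 1e5)
        assert v == pytest.approx(0.01, rel=1e-9)

    def test_unknown_gauge_rejected(self):
        with pytest.raises(DomainError, match="unknown nozzle gauge"):
            NozzleSpec.from_gauge("19G")
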
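"""Unit and property tests for the steady-state chemistry core."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import bisect

import ureakin as uk
from conftest import random_chemistry_and_point


class TestSteadyStateSubstrate:
    def test_zero_substrate_gives_zero(self, pbs_truth):
        assert uk.steady_state_substrate(0.0, pbs_truth) == 0.0

    def test_no_reaction_limit_returns_bulk(self):
        params = uk.KineticParameters(k_m=10e-3, kbar_v=0.0)
        assert uk.steady_state_substrate(10e-3, params) == pytest.approx(
            10e-3, rel=1e-14
        )

    def test_closed_form_matches_bisection_oracle(self):
        # K_M = 10 mM, kbar_V = 1 mM, S_B = 10 mM: the closed form gives
        # (-1 + sqrt(401))/2 mM ~ 9.5125 mM; cross-check against bisection
        # on the steady-state balance itself.
        params = uk.KineticParameters(k_m=10e-3, kbar_v=1e-3)
        s = uk.steady_state_substrate(10e-3, params)
        assert s == pytest.approx((-1 + math.sqrt(401)) / 2 * 1e-3, rel=1e-12)
        assert s == pytest.approx(9.5125e-3, rel=1e-4)

        def balance(x):
            return 10e-3 - x - 1e-3 * x / (10e-3 + x)

        root = bisect(balance, 0.0, 10e-3, xtol=1e-18)
        assert s == pytest.approx(root, rel=1e-9)

    def test_rejects_negative_and_nonfinite(self, pbs_truth):
        with pytest.raises(ValueError):
            uk.steady_state_substrate(-1e-3, pbs_truth)
        with pytest.raises(ValueError):
            uk.steady_state_substrate(float("nan"), pbs_truth)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(
        log_km=st.floats(-6, -1),
        log_kv=st.floats(-10, -1),
        log_sb=st.floats(-6, -1),
    )
    def test_balance_zeroed_to_relative_tolerance(self, log_km, log_kv, log_sb):
        """The closed form zeroes S_B - S - kv*S/(K_M+S) to 1e-10 relative."""
        k_m, kv, s_b = 10.0 ** log_km, 10.0 ** log_kv, 10.0 ** log_sb
        params = uk.KineticParameters(k_m=k_m, kbar_v=kv)
        s = uk.steady_state_substrate(s_b, params)
        assert 0.0 <= s <= s_b
        balance = s_b - s - kv * s / (k_m + s)
        assert abs(balance) < 1e-10 * max(s_b, k_m)


class TestBalanceResidual:
    def test_zero_at_bulk_state_without_substrate(self, pbs_chemistry, pbs_truth):
        chem = pbs_chemistry
        ha_bulk = chem.buffer.h_b / chem.products.ka_a
        res = uk.surface_balance_residual(
            ha_bulk, 0.0, chem.buffer, chem.products, pbs_truth, chem.transport
        )
        assert res == pytest.approx(0.0, abs=1e-18)

    def test_transport_only_when_buffer_and_reaction_vanish(self, pbs_chemistry):
        chem = pbs_chemistry
        buffer = uk.BufferSystem(c_wb=0.0, ka_w=chem.buffer.ka_w, ph_b=7.4)
        params = uk.KineticParameters(k_m=10e-3, kbar_v=0.0)
        h = 1e-8  # pH 8, away from the bulk value
        res = uk.surface_balance_residual(
            h / chem.products.ka_a, 5e-3, buffer, chem.products, params,
            chem.transport,
        )
        assert res == pytest.approx(buffer.h_b - h, rel=1e-12)
        assert res != 0.0

    def test_residual_vanishes_at_solved_root(self, pbs_chemistry, pbs_truth):
        chem = pbs_chemistry
        state = uk.solve_surface_h(
            10e-3, chem.buffer, chem.products, pbs_truth, chem.transport
        )
        res = uk.surface_balance_residual(
            state.ha, 10e-3, chem.buffer, chem.products, pbs_truth, chem.transport
        )
        assert abs(res) < 1e-12

    def test_rejects_nonpositive_ha(self, pbs_chemistry, pbs_truth):
        chem = pbs_chemistry
        with pytest.raises(ValueError):
            uk.surface_balance_residual(
                0.0, 1e-3, chem.buffer, chem.products, pbs_truth, chem.transport
            )


class TestSolveSurfaceH:
    def test_zero_substrate_returns_bulk_ph(self, pbs_chemistry, pbs_truth):
        chem = pbs_chemistry
        state = uk.solve_surface_h(
            0.0, chem.buffer, chem.products, pbs_truth, chem.transport
        )
        assert abs(state.ph_surface - chem.buffer.ph_b) < 1e-9
        assert state.s == 0.0

    def test_urease_response_is_alkaline(self, pbs_chemistry, pbs_truth):
        # net proton consumption (two ammonium vs one bicarbonate) raises
        # the surface pH above the bulk value; cross-check the root with a
        # naive fine-grid bisection oracle
        chem = pbs_chemistry
        state = uk.solve_surface_h(
            10e-3, chem.buffer, chem.products, pbs_truth, chem.transport
        )
        assert state.ph_surface > chem.buffer.ph_b

        def f(h):
            return uk.surface_balance_residual(
                h / chem.products.ka_a, 10e-3, chem.buffer, chem.products,
                pbs_truth, chem.transport,
            )

        grid = np.logspace(-14, 0, 4000)
        vals = np.array([f(h) for h in grid])
        (idx,) = np.nonzero(vals[:-1] * vals[1:] < 0)
        assert len(idx) == 1
        oracle = bisect(f, grid[idx[0]], grid[idx[0] + 1], xtol=1e-20)
        assert state.h == pytest.approx(oracle, rel=1e-9)

    def test_vanishing_rate_recovers_bulk_ph(self, pbs_chemistry):
        chem = pbs_chemistry
        params = uk.KineticParameters(k_m=10.88e-3, kbar_v=1e-14)
        for s_b in (1e-4, 1e-2, 5e-2):
            state = uk.solve_surface_h(
                s_b, chem.buffer, chem.products, params, chem.transport
            )
            assert abs(state.ph_surface - chem.buffer.ph_b) < 1e-6

    def test_state_fields_consistent(self, pbs_chemistry, pbs_truth):
        chem = pbs_chemistry
        state = uk.solve_surface_h(
            5e-3, chem.buffer, chem.products, pbs_truth, chem.transport
        )
        assert state.ha == pytest.approx(state.h / chem.products.ka_a, rel=1e-15)
        assert state.ph_surface == pytest.approx(-math.log10(state.h), rel=1e-15)
        assert 0.0 <= state.s <= 5e-3
        assert uk.model_core.H_MIN <= state.h <= uk.model_core.H_MAX


class TestQuarticOracle:
    def test_zero_substrate_single_bulk_root(self, pbs_chemistry, pbs_truth):
        chem = pbs_chemistry
        roots = uk.quartic_root_oracle(
            0.0, chem.buffer, chem.products, pbs_truth, chem.transport
        )
        assert len(roots) == 1
        assert roots[0] == pytest.approx(
            chem.buffer.h_b / chem.products.ka_a, rel=1e-10
        )

    def test_degenerate_chemistry_single_root(self, pbs_chemistry):
        chem = pbs_chemistry
        buffer = uk.BufferSystem(c_wb=0.0, ka_w=chem.buffer.ka_w, ph_b=7.4)
        params = uk.KineticParameters(k_m=10e-3, kbar_v=0.0)
        roots = uk.quartic_root_oracle(
            1e-3, buffer, chem.products, params, chem.transport
        )
        assert len(roots) == 1
        assert roots[0] == pytest.approx(buffer.h_b / chem.products.ka_a, rel=1e-10)

    def test_contains_bracketed_root_pbs(self, pbs_chemistry, pbs_truth):
        chem = pbs_chemistry
        state = uk.solve_surface_h(
            1e-3, chem.buffer, chem.products, pbs_truth, chem.transport
        )
        roots = uk.quartic_root_oracle(
            1e-3, chem.buffer, chem.products, pbs_truth, chem.transport
        )
        assert any(abs(r - state.ha) < 1e-8 * state.ha for r in roots)

    def test_randomized_equivalence_with_bracketed_solver(self):
        """Polynomial companion-matrix roots agree with bracketed bisection
        on randomized chemistries to 1e-8 relative Ha."""
        rng = np.random.default_rng(42)
        for _ in range(120):
            buffer, products, params, transport, s_b = random_chemistry_and_point(rng)
            state = uk.solve_surface_h(s_b, buffer, products, params, transport)
            roots = uk.quartic_root_oracle(s_b, buffer, products, params, transport)
            assert any(abs(r - state.ha) < 1e-8 * state.ha for r in roots), (
                buffer, products, params, s_b,
            )


class TestResponseCurve:
    def test_single_zero_point(self, pbs_chemistry, pbs_truth):
        chem = pbs_chemistry
        curve = uk.response_curve(
            [0.0], chem.buffer, chem.products, pbs_truth, chem.transport
        )
        assert len(curve) == 1
        assert curve.ph[0] == pytest.approx(chem.buffer.ph_b, abs=1e-9)

    def test_monotone_in_concentration(self, pbs_chemistry, pbs_truth, grid12):
        chem = pbs_chemistry
        curve = uk.response_curve(
            grid12, chem.buffer, chem.products, pbs_truth, chem.transport
        )
        assert np.all(np.diff(curve.ph) >= -1e-12)
        # spot-check against individual solver calls
        for i in (0, 5, 11):
            state = uk.solve_surface_h(
                grid12[i], chem.buffer, chem.products, pbs_truth, chem.transport
            )
            assert curve.ph[i] == pytest.approx(state.ph_surface, rel=1e-12)

    def test_duplicated_grid_values_duplicate_outputs(self, pbs_chemistry, pbs_truth):
        chem = pbs_chemistry
        curve = uk.response_curve(
            [1e-3, 1e-3, 5e-3], chem.buffer, chem.products, pbs_truth,
            chem.transport,
        )
        assert curve.ph[0] == curve.ph[1]
        assert curve.s_b[0] == curve.s_b[1]

    def test_curve_table_columns_consistent(self, pbs_chemistry, pbs_truth):
        chem = pbs_chemistry
        table = uk.response_curve_table(
            [0.0, 1e-3, 1e-2], chem.buffer, chem.products, pbs_truth,
            chem.transport,
        )
        assert list(table.columns) == [
            "s_b_mM", "pH_surface", "S_layer_mM", "H_surface_M",
        ]
        np.testing.assert_allclose(
            table["pH_surface"], -np.log10(table["H_surface_M"]), rtol=1e-12
        )
        assert np.all(table["S_layer_mM"] <= table["s_b_mM"] + 1e-12)

    def test_monotone_decreasing_in_buffer_strength(self, pbs_chemistry, pbs_truth):
        """Stronger buffering suppresses the alkaline shift."""
        chem = pbs_chemistry
        ph_at_10mm = []
        for c_wb in (1e-4, 3.3e-4, 1e-3, 1e-2):
            state = uk.solve_surface_h(
                10e-3,
                uk.BufferSystem(c_wb=c_wb, ka_w=chem.buffer.ka_w, ph_b=7.4),
                chem.products, pbs_truth, chem.transport,
            )
            ph_at_10mm.append(state.ph_surface)
        assert all(a >= b for a, b in zip(ph_at_10mm, ph_at_10mm[1:]))
        # and the infinite-buffer limit pins the surface at the bulk pH
        strong = uk.solve_surface_h(
            10e-3,
            uk.BufferSystem(c_wb=10.0, ka_w=chem.buffer.ka_w, ph_b=7.4),
            chem.products, pbs_truth, chem.transport,
        )
        assert abs(strong.ph_surface - 7.4) < 1e-3


class TestDomainTypes:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"c_wb": -1e-3, "ka_w": 1e-7, "ph_b": 7.4},
            {"c_wb": 1e-3, "ka_w": 0.0, "ph_b": 7.4},
            {"c_wb": 1e-3, "ka_w": 1e-7, "ph_b": 15.0},
            {"c_wb": 1e-3, "ka_w": 1e-7, "ph_b": 7.4, "kbar_w": 0.0},
        ],
    )
    def test_buffer_invariants(self, kwargs):
        with pytest.raises(ValueError):
            uk.BufferSystem(**kwargs)

    def test_products_require_a_protolytic_species(self):
        with pytest.raises(ValueError):
            uk.ProductSystem(n_a=0, ka_a=1e-6, n_b=0, ka_b=1e-9)

    def test_kinetic_parameters_positive(self):
        with pytest.raises(ValueError):
            uk.KineticParameters(k_m=0.0, kbar_v=1e-4)
        with pytest.raises(ValueError):
            uk.KineticParameters(k_m=1e-3, kbar_v=-1e-4)

    def test_transport_ks_derivation(self):
        transport = uk.TransportModel(d=9.3e-5, l=1.0, t=1e-7)
        assert transport.substrate_rate_constant() == pytest.approx(930.0)
        with pytest.raises(ValueError):
            uk.TransportModel().substrate_rate_constant()
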
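import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from topobind import (
    Conditions,
    DNASubstrate,
    SolverSettings,
    compare_topologies,
    predict_intensity,
    solve_equilibrium,
    solve_mvh,
)

from oracles import solve_selfconsistent_grid


class TestSolveEquilibrium:
    def test_open_topology_equals_plain_isotherm(self, dna_42kb, sytox, sm_conditions):
        state = solve_equilibrium(dna_42kb.with_(topology="open"), sytox, sm_conditions)
        sol = solve_mvh(
            sm_conditions.c_total, sm_conditions.c_dna_bp, sytox.Kd0, sytox.n
        )
        assert state.gamma == pytest.approx(sol.gamma, rel=1e-12)
        assert state.torque == 0.0

    def test_overwound_stage2_oracle(self, dna_42kb, sytox, sm_conditions):
        """Constrained solve at 250 nM with the 25 nM-locked linking offset:
        frozen self-consistent grid-oracle values."""
        dna = dna_42kb.with_(dLk0=-2014.976 * 19.1 / 360)  # = -106.905 turns
        state = solve_equilibrium(dna, sytox, sm_conditions)
        assert state.N_bound == pytest.approx(5849.2, abs=2.0)
        assert state.dLk_eff == pytest.approx(203.4, abs=0.3)
        assert state.sigma_eff == pytest.approx(0.05086, abs=3e-4)
        assert state.torque == pytest.approx(6.54, abs=0.05)

    def test_underwound_stage2_oracle(self, dna_42kb, sytox, sm_conditions):
        dna = dna_42kb.with_(dLk0=-7123.659 * 19.1 / 360)  # = -377.95 turns
        cond = sm_conditions.with_(c_total=50e-9)
        state = solve_equilibrium(dna, sytox, cond)
        assert state.N_bound == pytest.approx(4230.5, abs=2.0)
        assert state.sigma_eff == pytest.approx(-0.03838, abs=3e-4)
        assert state.torque < 0

    def test_matches_brute_force_oracle(self, dna_42kb, sytox):
        """Self-consistent gamma agrees with the dense-grid sign-change
        oracle on a handful of regimes spanning under- and overwound."""
        for c_total, dLk0 in [(250e-9, -106.9), (50e-9, -377.9), (100e-9, 0.0)]:
            cond = Conditions(c_total=c_total, c_dna_bp=10e-12)
            dna = dna_42kb.with_(dLk0=dLk0)
            g = solve_equilibrium(dna, sytox, cond).gamma
            g_oracle = solve_selfconsistent_grid(
                c_total, 10e-12, sytox.Kd0, sytox.n, sytox.dz, sytox.dtheta,
                42000, 100.0, 297.0, dLk0, coarse=101, inner=100_001,
            )
            assert g == pytest.approx(g_oracle, abs=5e-5)

    def test_uniqueness_single_sign_change(self, dna_42kb, sytox, sm_conditions):
        """The self-consistency residual R(gamma) = gamma - G(gamma) is
        monotone (negative feedback) and crosses zero exactly once."""
        from topobind.equilibrium import _gamma_update

        dna = dna_42kb.with_(dLk0=-106.9)
        gs = np.linspace(1e-6, 1 / sytox.n - 1e-6, 400)
        R = np.array([
            g - _gamma_update(g, dna, sytox, sm_conditions, sm_conditions.c_total)[0]
            for g in gs
        ])
        assert int(np.sum(np.diff(np.sign(R)) != 0)) == 1

    @pytest.mark.parametrize("omega", [0.2, 0.5, 0.8, 1.0])
    def test_solution_invariant_under_relaxation_factor(
        self, dna_42kb, sytox, sm_conditions, omega
    ):
        dna = dna_42kb.with_(dLk0=-106.9)
        ref = solve_equilibrium(dna, sytox, sm_conditions, SolverSettings())
        state = solve_equilibrium(
            dna, sytox, sm_conditions, SolverSettings(relaxation=omega)
        )
        assert state.gamma == pytest.approx(ref.gamma, abs=10 * 1e-10)

    def test_insensitive_to_dna_concentration_1_to_100_pM(self, dna_42kb, sytox):
        """In the single-molecule regime the result does not depend on the
        nominal DNA concentration."""
        dna = dna_42kb.with_(dLk0=-106.9)
        gammas = [
            solve_equilibrium(
                dna, sytox, Conditions(c_total=250e-9, c_dna_bp=c)
            ).gamma
            for c in (1e-12, 10e-12, 100e-12)
        ]
        for g in gammas[1:]:
            assert abs(g - gammas[0]) / gammas[0] < 1e-3

    def test_staining_factor_scales_effective_dye(self, dna_42kb, sytox):
        full = solve_equilibrium(
            dna_42kb.with_(topology="open"), sytox,
            Conditions(c_total=250e-9, c_dna_bp=1e-9, staining_factor=0.1),
        )
        tenth = solve_equilibrium(
            dna_42kb.with_(topology="open"), sytox,
            Conditions(c_total=25e-9, c_dna_bp=1e-9),
        )
        assert full.gamma == pytest.approx(tenth.gamma, rel=1e-12)

    def test_nonconvergence_reports_residual(self, dna_42kb, sytox, sm_conditions):
        with pytest.raises(RuntimeError, match="relaxation"):
            solve_equilibrium(
                dna_42kb, sytox, sm_conditions, SolverSettings(max_iter=2)
            )


class TestCompareTopologies:
    def test_relaxed_plasmid_always_reduced(self, dna_42kb, sytox, sm_conditions):
        """Binding to an initially relaxed closed plasmid always overwinds it,
        so the closed form binds less than the open one."""
        ratio = compare_topologies(dna_42kb.with_(dLk0=0.0), sytox, sm_conditions)
        assert ratio < 1.0

    def test_negatively_supercoiled_enhanced_at_low_dye(self, pbr322, etbr):
        cond = Conditions(c_total=0.05e-6, c_dna_bp=1e-9)
        ratio = compare_topologies(pbr322, etbr, cond)
        assert ratio > 1.0

    def test_ratio_crosses_one_where_dlk_eff_vanishes(self, dna_42kb, sytox):
        """At the dye concentration where the bound dyes exactly compensate
        dLk0, closed and open coincide."""
        # choose dLk0 to be compensated by the open-topology binding level
        cond = Conditions(c_total=100e-9, c_dna_bp=10e-12)
        open_state = solve_equilibrium(
            dna_42kb.with_(topology="open"), sytox, cond
        )
        dLk0 = -open_state.N_bound * sytox.dtheta / 360.0
        ratio = compare_topologies(dna_42kb.with_(dLk0=dLk0), sytox, cond)
        assert ratio == pytest.approx(1.0, abs=1e-6)

    @given(offset=st.floats(min_value=-150.0, max_value=150.0))
    @settings(max_examples=15)
    def test_sign_law(self, dna_42kb, sytox, offset):
        """ratio - 1 has the opposite sign of dLk_eff evaluated at the
        open-topology binding level."""
        cond = Conditions(c_total=100e-9, c_dna_bp=10e-12)
        open_state = solve_equilibrium(
            dna_42kb.with_(topology="open"), sytox, cond
        )
        dLk0 = -open_state.N_bound * sytox.dtheta / 360.0 + offset
        ratio = compare_topologies(dna_42kb.with_(dLk0=dLk0), sytox, cond)
        if abs(offset) > 1.0:
            assert (ratio - 1.0) * offset < 0

    def test_zero_dye_ratio_undefined(self, dna_42kb, sytox):
        with pytest.raises(ZeroDivisionError):
            compare_topologies(
                dna_42kb, sytox, Conditions(c_total=0.0, c_dna_bp=1e-9)
            )

    def test_requires_closed_substrate(self, dna_42kb, sytox, sm_conditions):
        with pytest.raises(ValueError):
            compare_topologies(
                dna_42kb.with_(topology="open"), sytox, sm_conditions
            )


class TestPredictIntensity:
    def test_linear_in_alpha_and_binding(self, dna_42kb, sytox, sm_conditions):
        state = solve_equilibrium(dna_42kb, sytox, sm_conditions)
        p1 = predict_intensity(state, alpha=1.0)
        p2 = predict_intensity(state, alpha=2.0)
        assert p1.intensity == pytest.approx(state.c_bound)
        assert p2.intensity == pytest.approx(2 * p1.intensity)

    def test_zero_binding_zero_intensity(self, dna_42kb, sytox):
        state = solve_equilibrium(
            dna_42kb, sytox, Conditions(c_total=0.0, c_dna_bp=1e-9)
        )
        assert predict_intensity(state, alpha=5.0).intensity == 0.0

    def test_alpha_must_be_positive(self, dna_42kb, sytox, sm_conditions):
        state = solve_equilibrium(dna_42kb, sytox, sm_conditions)
        with pytest.raises(ValueError):
            predict_intensity(state, alpha=0.0)
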
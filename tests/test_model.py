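"""Core ODE model: derivative terms, activity coupling, integration, basal state."""

import numpy as np
import pytest

from adiposwitch import (FeedbackVariant, InputDomainError, ModelState,
                         basal_fixed_point, constant_protocol, derivatives,
                         pparg_activity, simulate, standard_dim_protocol)
from adiposwitch.model import SPECIES, _rhs, _variant_terms

from conftest import random_valid_params


class TestPpargActivity:
    def test_zero_dose_is_identity(self, unit_params):
        assert pparg_activity(1.0, 0.0, unit_params.replace(rosi_gain=5.0)) == 1.0

    def test_no_protein_no_activity(self, unit_params):
        assert pparg_activity(0.0, 10.0, unit_params.replace(rosi_gain=5.0)) == 0.0

    def test_half_saturating_dose(self, unit_params):
        p = unit_params.replace(rosi_gain=2.0, rosi_k=1.0)
        assert pparg_activity(1.0, 1.0, p) == pytest.approx(2.0)

    def test_strictly_increasing_in_dose(self, unit_params):
        p = unit_params.replace(rosi_gain=3.0)
        acts = [pparg_activity(1.0, r, p) for r in (0.0, 0.5, 1.0, 4.0)]
        assert np.all(np.diff(acts) > 0)

    def test_negative_dose_rejected(self, unit_params):
        with pytest.raises(InputDomainError):
            pparg_activity(1.0, -0.1, unit_params)

    def test_accepts_model_state(self, unit_params):
        st = ModelState(1, 2, 3)
        assert pparg_activity(st, 0.0, unit_params) == 2.0


class TestDerivatives:
    def test_zero_state_leaves_only_basal_synthesis(self, unit_params):
        d = derivatives(np.zeros(6), unit_params,
                        {"gr": 0, "camp": 0, "insulin": 1, "rosi": 0})
        # at zero state every feedback and degradation term vanishes
        assert d == pytest.approx([1.0, 1.0, 1.0, 1.0, 1.0, 0.0])

    def test_hand_evaluated_unit_point(self, unit_params):
        st = ModelState(1, 1, 1, 1, 1, 0)
        d = derivatives(st, unit_params, {"gr": 1, "camp": 1, "insulin": 1})
        assert d == pytest.approx([1.5, 4.0 / 9.0, 0.5, 0.0, 0.5, 0.25])

    def test_loop2_term_deletion(self, unit_params):
        st = ModelState(1, 1, 1, 1, 1, 0)
        d = derivatives(st, unit_params, {"gr": 1, "camp": 1, "insulin": 1},
                        FeedbackVariant(loop2_on=False))
        assert d[0] == pytest.approx(1.0)  # C/EBPb loses the PPARg term
        assert d[1:] == pytest.approx([4.0 / 9.0, 0.5, 0.0, 0.5, 0.25])

    def test_loop2_off_cebpb_rate_independent_of_pparg(self, ref):
        v = FeedbackVariant(loop2_on=False)
        inputs = {"gr": 1, "camp": 1, "insulin": 1}
        lo = derivatives(ModelState(2, 1.0, 2, 1, 1, 0), ref, inputs, v)[0]
        hi = derivatives(ModelState(2, 9.0, 2, 1, 1, 0), ref, inputs, v)[0]
        assert lo == pytest.approx(hi, abs=1e-12)

    def test_loop3_off_ir_rate_independent_of_cebpa(self, ref):
        v = FeedbackVariant(loop3_on=False)
        lo = derivatives(ModelState(1, 1, 0.5, 1, 1, 0), ref, {}, v)[4]
        hi = derivatives(ModelState(1, 1, 9.0, 1, 1, 0), ref, {}, v)[4]
        assert lo == pytest.approx(hi, abs=1e-12)

    def test_negative_state_rejected(self, unit_params):
        with pytest.raises(InputDomainError):
            derivatives(np.array([1, -1, 1, 1, 1, 0.0]), unit_params, {})

    def test_degradation_bounds_loss(self, ref):
        rng = np.random.default_rng(3)
        for _ in range(20):
            y = rng.uniform(0, 10, 6)
            d = derivatives(y, ref, {"gr": 1, "camp": 1, "insulin": 1, "rosi": 2})
            degs = np.array([ref.deg_cebpb, ref.deg_pparg, ref.deg_cebpa,
                             ref.deg_pakt, ref.deg_ir, ref.deg_fat])
            assert np.all(d >= -degs * y - 1e-12)


try:
    from hypothesis import given, settings
    from hypothesis import strategies as st

    @given(st.floats(0.0, 50.0), st.floats(0.0, 50.0))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_activity_monotone_in_dose_and_protein(r1, r2):
        """PPARg activity grows with dose and with protein level."""
        from adiposwitch import ModelParameters
        p = ModelParameters(**{n: 1.0 for n in (
            "syn_cebpb syn_pparg syn_cebpa syn_pakt syn_ir syn_fat "
            "deg_cebpb deg_pparg deg_cebpa deg_pakt deg_ir deg_fat "
            "base_cebpb base_pparg base_cebpa base_ir "
            "alpha1 alpha2 alpha3 alpha4 alpha5 alpha6 alpha7 alpha8").split()},
            rosi_gain=3.0)
        lo, hi = sorted((r1, r2))
        assert pparg_activity(1.0, hi, p) >= pparg_activity(1.0, lo, p)
        assert pparg_activity(2.0, r1, p) >= pparg_activity(1.0, r1, p)

    @given(st.lists(st.floats(0.0, 20.0), min_size=6, max_size=6),
           st.floats(0.0, 2.0), st.floats(0.0, 2.0), st.floats(0.0, 1.0),
           st.floats(0.0, 10.0))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_rates_finite_and_loss_bounded_by_degradation(y, gr, camp, ins, rosi):
        """Degradation is the only loss term, whatever the operating point."""
        from adiposwitch import reference_params
        p = reference_params()
        d = derivatives(np.array(y), p, {"gr": gr, "camp": camp,
                                         "insulin": ins, "rosi": rosi})
        assert np.all(np.isfinite(d))
        degs = np.array([p.deg_cebpb, p.deg_pparg, p.deg_cebpa,
                         p.deg_pakt, p.deg_ir, p.deg_fat])
        assert np.all(d >= -degs * np.array(y) - 1e-12)
except ImportError:  # pragma: no cover - hypothesis is an optional test dep
    pass


def rk4_oracle(protocol, params, variant, y0, t_end, dt=1e-3):
    """Independent fixed-step 4th-order integrator over the protocol."""
    loop2, loop3, kd_b, kd_p, kd_a, kd_i = _variant_terms(variant)
    a4e = params.alpha4_exp
    gr_scale = variant.remaining("gr-pathway")

    def f(t, y):
        lv = protocol.levels_at(min(t, t_end - 1e-9))
        return np.array(_rhs(y, params, lv["gr"] * gr_scale, lv["camp"],
                             lv["insulin"], lv["rosi"], loop2, loop3,
                             kd_b, kd_p, kd_a, kd_i, a4e))

    n = int(round(t_end / dt))
    y = np.array(y0, dtype=float)
    t = 0.0
    for _ in range(n):
        k1 = f(t, y)
        k2 = f(t + dt / 2, y + dt / 2 * k1)
        k3 = f(t + dt / 2, y + dt / 2 * k2)
        k4 = f(t + dt, y + dt * k3)
        y = y + dt / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
        y = np.maximum(y, 0.0)
        t += dt
    return y


class TestSimulate:
    def test_fixed_point_invariance(self, ref):
        bf = basal_fixed_point(ref)
        tr = simulate(constant_protocol(200.0, rosi=0.0), ref, initial=bf,
                      dt_out=50.0)
        drift = np.abs(tr.y - bf.to_array()) / np.maximum(bf.to_array(), 1e-12)
        # fat and pAKT are exactly zero at basal; compare the non-zero species
        nz = bf.to_array() > 0
        assert drift[:, nz].max() < 1e-6

    @pytest.mark.parametrize("seed", range(5))
    def test_agrees_with_rk4_oracle(self, seed):
        rng = np.random.default_rng(seed)
        params = random_valid_params(rng)
        protocol = standard_dim_protocol(12.0, 24.0)
        variant = FeedbackVariant()
        y0 = basal_fixed_point(params).to_array()
        tr = simulate(protocol, params, variant, dt_out=6.0)
        ref_y = rk4_oracle(protocol, params, variant, y0, 24.0)
        rel = np.abs(tr.y[-1] - ref_y) / np.maximum(np.abs(ref_y), 1e-6)
        assert rel.max() < 1e-4

    def test_commitment_persists_after_washout(self, ref):
        tr = simulate(standard_dim_protocol(48.0, 96.0), ref, dt_out=1.0)
        p48 = tr["pparg"][np.argmin(np.abs(tr.t - 48.0))]
        p96 = tr["pparg"][-1]
        assert p96 >= 0.5 * p48

    def test_non_negative_trajectories(self):
        rng = np.random.default_rng(11)
        for _ in range(5):
            params = random_valid_params(rng)
            init = ModelState(*rng.uniform(0, 5, 6))
            tr = simulate(standard_dim_protocol(24.0, 72.0), params,
                          initial=init, dt_out=4.0)
            assert np.all(tr.y >= 0)

    def test_breakpoints_in_output_grid(self, ref):
        tr = simulate(standard_dim_protocol(48.0, 96.0), ref, dt_out=7.0)
        assert np.any(np.isclose(tr.t, 48.0))
        assert np.any(np.isclose(tr.t, 96.0))

    def test_dataframe_layout(self, ref):
        tr = simulate(standard_dim_protocol(12.0, 24.0), ref, dt_out=6.0)
        df = tr.to_dataframe()
        assert list(df.columns) == ["time_h", *SPECIES]
        assert len(df) == len(tr.t)


class TestBasalFixedPoint:
    def test_residual_is_tiny(self, ref):
        bf = basal_fixed_point(ref)
        d = derivatives(bf, ref, {})
        assert np.linalg.norm(d) < 1e-8

    def test_reference_normalization(self, ref):
        bf = basal_fixed_point(ref)
        for tf in ("cebpb", "pparg", "cebpa"):
            assert getattr(bf, tf) == pytest.approx(1.0, abs=1e-3)

    def test_matches_long_integration(self, ref):
        bf = basal_fixed_point(ref)
        end = simulate(constant_protocol(500.0, rosi=0.0), ref,
                       initial=ModelState(0.5, 0.5, 0.5, 0.5, 0.5, 0.5),
                       dt_out=250.0).final_state()
        for s in SPECIES:
            tgt = getattr(bf, s)
            if tgt > 0:
                assert getattr(end, s) == pytest.approx(tgt, rel=1e-6)
            else:
                assert getattr(end, s) < 1e-6

    def test_full_knockdown_gives_zero_state(self, ref):
        v = FeedbackVariant(knockdown={"cebpb": 0.0, "pparg": 0.0,
                                       "cebpa": 0.0, "ir": 0.0})
        bf = basal_fixed_point(ref, v)
        assert np.allclose(bf.to_array(), 0.0)

    def test_decoupled_closed_form(self, unit_params):
        # with zero basal PPARg, every downstream feedback term vanishes
        p = unit_params.replace(base_pparg=0.0, base_cebpb=0.3, base_cebpa=0.4,
                                base_ir=0.2, syn_cebpb=2.0, deg_cebpb=0.5)
        bf = basal_fixed_point(p)
        assert bf.pparg == 0.0
        assert bf.cebpb == pytest.approx(2.0 * 0.3 / 0.5)
        assert bf.cebpa == pytest.approx(0.4)
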
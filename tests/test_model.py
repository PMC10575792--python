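"""Unit and property tests for the plasticity/calcium-buffering dynamics."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from casyn.model import (DriveSpec, ModelParams, SynapseState, derivatives,
                         integrate, load_params, release_probability_baseline,
                         rest_state, synaptic_weight)
from casyn.steady import steady_state_full


class TestReleaseProbability:
    def test_zero_calcium_gives_zero(self):
        assert release_probability_baseline(0.0, 1.0) == 0.0

    def test_saturates_to_one(self):
        assert release_probability_baseline(1e6, 1.0) == pytest.approx(1.0, abs=1e-12)

    def test_half_maximum_at_lam_ln3(self):
        # 2/(1+e^-c) - 1 = 1/2  <=>  e^-c = 1/3  <=>  c = ln 3
        for lam in (0.1, 1.0, 7.5):
            assert release_probability_baseline(lam * math.log(3.0), lam) == \
                pytest.approx(0.5, rel=1e-12)

    def test_rejects_negative_c_and_bad_lam(self):
        with pytest.raises(ValueError):
            release_probability_baseline(-0.1, 1.0)
        with pytest.raises(ValueError):
            release_probability_baseline(1.0, 0.0)

    @settings(derandomize=True, max_examples=100)
    @given(c1=st.floats(0, 1e3), c2=st.floats(0, 1e3),
           lam=st.floats(1e-3, 1e3))
    def test_bounded_and_monotone(self, c1, c2, lam):
        u1 = release_probability_baseline(c1, lam)
        u2 = release_probability_baseline(c2, lam)
        # sup U = 1 is attained only in the saturated float regime c >> lam
        assert 0.0 <= u1 <= 1.0
        if c1 / lam < 30:
            assert u1 < 1.0
        if c1 < c2:
            assert u1 <= u2


class TestSynapticWeight:
    @pytest.mark.parametrize("u,x,w", [(0.0, 1.0, 0.0), (1.0, 1.0, 1.0),
                                       (0.5, 0.4, 0.2)])
    def test_product(self, u, x, w):
        assert synaptic_weight(u, x) == pytest.approx(w)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            synaptic_weight(1.2, 0.5)


class TestDerivatives:
    def test_rest_state_is_fixed_point(self, params):
        assert derivatives(rest_state(), params, 0.0) == (0.0, 0.0, 0.0, 0.0)

    def test_full_buffer_blocks_binding(self, params):
        # with b = B the binding flux vanishes; only decay and unbinding act
        s = SynapseState(t=0, x=1.0, u=0.0, c=3.0, b=params.B)
        _, _, dc, db = derivatives(s, params, 0.0)
        assert dc == pytest.approx(-3.0 / params.tau_c
                                   + params.lambda_bc * params.B)
        assert db == pytest.approx(-params.B / params.tau_b
                                   - params.lambda_bc * params.B)

    def test_vanishes_at_analytic_steady_state(self, params):
        R = 20.0
        ss = steady_state_full(params, R)
        s = SynapseState(t=0, x=ss.x_star, u=ss.u_star, c=ss.c_star, b=ss.b_star)
        assert max(abs(d) for d in derivatives(s, params, R)) < 1e-9

    @settings(derandomize=True, max_examples=50)
    @given(x=st.floats(0, 1), u=st.floats(0, 1), c=st.floats(0, 10),
           bfrac=st.floats(0, 1), R=st.floats(0, 100))
    def test_exchange_terms_cancel_exactly(self, x, u, c, bfrac, R):
        p = ModelParams(B=200.0, mu=0.001, lam=1.0)
        s = SynapseState(t=0, x=x, u=u, c=c, b=bfrac * p.B)
        _, _, dc, db = derivatives(s, p, R)
        expected = p.mu * R - c / p.tau_c - s.b / p.tau_b
        # exchange fluxes (up to ~1e5 here) cancel between dc and db up to
        # float rounding of the individual sums
        scale = max(p.lambda_cb * (p.B - s.b) * c, p.lambda_bc * s.b, 1.0)
        assert dc + db == pytest.approx(expected, abs=1e-11 * scale)


class TestIntegrate:
    def test_rest_state_stays_at_rest(self, params):
        traj = integrate(params, DriveSpec.constant(0.0), (0, 5), 0.01)
        assert np.allclose(traj[["x", "u", "c", "b"]].iloc[-1], [1, 0, 0, 0],
                           atol=1e-12)

    def test_converges_to_analytic_steady_state(self, params):
        R = 20.0
        ss = steady_state_full(params, R)
        traj = integrate(params, DriveSpec.constant(R), (0, 1e5), 100.0)
        last = traj.iloc[-1]
        for key, val in [("x", ss.x_star), ("u", ss.u_star),
                         ("c", ss.c_star), ("b", ss.b_star)]:
            assert last[key] == pytest.approx(val, rel=1e-6)

    def test_bounds_preserved_along_trajectory(self, params):
        traj = integrate(params, DriveSpec.constant(50.0), (0, 30), 0.001,
                         method="fixed")
        assert ((traj["x"] >= 0) & (traj["x"] <= 1)).all()
        assert ((traj["u"] >= 0) & (traj["u"] <= 1)).all()
        assert (traj["c"] >= 0).all()
        assert ((traj["b"] >= 0) & (traj["b"] <= params.B)).all()

    def test_mass_balance_residual_along_trajectory(self, params):
        # d(c+b)/dt must equal mu*R - c/tau_c - b/tau_b along the flow
        R, dt = 20.0, 0.01
        traj = integrate(params, DriveSpec.constant(R), (0, 20), dt)
        total = (traj["c"] + traj["b"]).to_numpy()
        lhs = np.gradient(total, dt)
        rhs = (params.mu * R - traj["c"] / params.tau_c
               - traj["b"] / params.tau_b).to_numpy()
        # skip the fast initial equilibration of c, where the finite
        # difference itself is inaccurate
        interior = slice(100, -2)
        scale = params.mu * R
        assert np.max(np.abs(lhs[interior] - rhs[interior])) < 1e-3 * scale

    def test_spike_train_matches_constant_rate_in_expectation(self, params):
        from casyn.synth import gen_spike_train

        R, t_end, dt = 20.0, 50.0, 1e-3
        drive = gen_spike_train(R, t_end, seed=7)
        spiky = integrate(params, drive, (0, t_end), dt, method="fixed")
        const = integrate(params, DriveSpec.constant(R), (0, t_end), dt)
        sel = spiky["t"] > t_end / 2
        c_sp = spiky.loc[sel, "c"].mean()
        c_ct = const.loc[sel, "c"].mean()
        assert c_sp == pytest.approx(c_ct, rel=0.15)

    def test_rejects_bad_arguments(self, params):
        with pytest.raises(ValueError):
            integrate(params, DriveSpec.constant(1.0), (0, 1), -0.1)
        with pytest.raises(ValueError):
            integrate(params, DriveSpec.constant(1.0), (1, 1), 0.1)


class TestParamsIO:
    def test_toml_roundtrip(self, tmp_path, params):
        f = tmp_path / "p.toml"
        f.write_text("\n".join(
            f"{k} = {getattr(params, k)}"
            for k in ("tau_d", "tau_f", "tau_c", "tau_b", "lambda_cb",
                      "lambda_bc", "mu", "B", "lam")))
        assert load_params(f) == params

    def test_unknown_key_rejected(self, tmp_path):
        f = tmp_path / "p.toml"
        f.write_text("B = 1.0\nmu = 0.1\nlam = 1.0\ntypo_key = 3\n")
        with pytest.raises(ValueError, match="typo_key"):
            load_params(f)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            ModelParams(B=-1.0, mu=0.1, lam=1.0)
        with pytest.raises(ValueError):
            ModelParams(B=1.0, mu=0.1, lam=1.0, tau_d=0.0)


class TestDriveSpec:
    def test_spike_times_must_increase(self):
        with pytest.raises(ValueError):
            DriveSpec.from_spikes([0.1, 0.1, 0.2])

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            DriveSpec.constant(-1.0)
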
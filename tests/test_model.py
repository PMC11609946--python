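"""Rate laws, light function, regulatory wiring and the ODE right-hand side."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from terpclock import (
    FLUX_NAMES,
    STATE_NAMES,
    STOICHIOMETRY,
    LightSchedule,
    compute_fluxes,
    light_level,
    make_variant,
    modulated_parameters,
    reference_inputs,
)
from terpclock.model import RegulatoryWiring, flux_state_jacobian, rhs
from terpclock.params import MEP_VMAX, MVA_VMAX, RATE_SCALE_PARAMS
from terpclock.steady_state import eigen_report, jacobian, solve_steady_state

from conftest import PUBLISHED_STEADY

_R = {n: i for i, n in enumerate(FLUX_NAMES)}
_S = {n: i for i, n in enumerate(STATE_NAMES)}


def published_state():
    return np.array([PUBLISHED_STEADY[n] for n in STATE_NAMES])


class TestLightLevel:
    @pytest.mark.parametrize(
        "t, expected, tol",
        [
            (6.0, 1.0, 1e-4),   # midday: full light
            (18.0, 0.0, 1e-4),  # midnight of a 12 h photoperiod
            (0.0, 0.5, 1e-5),   # dawn transition midpoint
        ],
    )
    def test_reference_values(self, t, expected, tol):
        assert light_level(t, LightSchedule()) == pytest.approx(expected, abs=tol)

    def test_bounded_and_periodic_on_grid(self):
        sched = LightSchedule(dusk=15.0, T=0.7)
        t = np.linspace(0.0, 5 * sched.period, 10_000)
        L = light_level(t, sched)
        assert np.all(L >= 0.0) and np.all(L <= 1.0)
        assert np.allclose(L, light_level(t + sched.period, sched), atol=1e-12)

    @given(dusk=st.floats(0.0, 24.0), T=st.floats(0.05, 4.0))
    @settings(max_examples=40, deadline=None)
    def test_bounded_for_any_schedule(self, dusk, T):
        sched = LightSchedule(dusk=dusk, T=T)
        L = light_level(np.linspace(0, 48, 487), sched)
        assert np.all((L >= 0.0) & (L <= 1.0))

    def test_daily_mean_increases_with_dusk(self):
        t = np.linspace(0, 24, 4001)
        means = [
            light_level(t, LightSchedule(dusk=d)).mean() for d in np.arange(2, 23, 2)
        ]
        assert np.all(np.diff(means) > 0)

    def test_all_day_light_and_rejects_nonfinite(self):
        sched = LightSchedule(dusk=24.0)
        # several twilight widths away from the period boundary
        t = np.linspace(6.0, 18.0, 100)
        assert np.all(light_level(t, sched) >= 1 - 1e-4)
        with pytest.raises(ValueError):
            light_level(np.nan)


class TestVariants:
    @pytest.mark.parametrize(
        "name, expected",
        [
            ("A", (False, False, False)),
            ("B", (True, False, False)),
            ("C", (False, True, False)),
            ("D", (False, False, True)),
            ("BC", (True, True, False)),
            ("BD", (True, False, True)),
            ("CD", (False, True, True)),
            ("E", (True, True, True)),
        ],
    )
    def test_wiring_map(self, name, expected):
        w = make_variant(name)
        assert (w.substrate, w.expression, w.consumption) == expected

    def test_unknown_variant_lists_valid_names(self):
        with pytest.raises(ValueError, match="BD"):
            make_variant("Z")

    def test_variant_map_is_one_to_one(self):
        wirings = {
            (w.substrate, w.expression, w.consumption)
            for w in map(make_variant, ["A", "B", "C", "D", "BC", "BD", "CD", "E"])
        }
        assert len(wirings) == 8


class TestModulation:
    def test_model_a_is_identity(self, params, inputs):
        p, i = modulated_parameters(7.3, params, inputs, LightSchedule(), make_variant("A"))
        assert p is params and i is inputs

    def test_model_b_reverts_to_a_in_full_light(self, params, inputs):
        # t=6 with a 12 h photoperiod: L = 1 to ~1e-5
        p, i = modulated_parameters(6.0, params, inputs, LightSchedule(), make_variant("B"))
        assert i.acetoacetylCoA == pytest.approx(inputs.acetoacetylCoA, rel=1e-4)
        assert i.pyruvate == pytest.approx(inputs.pyruvate, rel=1e-4)
        assert p == params

    def test_model_c_darkness_silences_mep_side(self, params, inputs):
        sched = LightSchedule()  # L(18) = 0 to ~1e-5
        p, _ = modulated_parameters(18.0, params, inputs, sched, make_variant("C"))
        for name in MEP_VMAX:
            assert getattr(p, name) == pytest.approx(0.0, abs=1e-4 * getattr(params, name))
        for name in MVA_VMAX:
            assert getattr(p, name) == pytest.approx(getattr(params, name), rel=1e-4)

    def test_km_ki_never_modulated(self, params, inputs):
        p, _ = modulated_parameters(3.0, params, inputs, LightSchedule(), make_variant("E"))
        for name in params.to_dict():
            if name.startswith(("Km", "Ki")):
                assert getattr(p, name) == getattr(params, name)


class TestFluxes:
    def test_published_state_reproduces_mva_fluxes(self, params, inputs):
        r = compute_fluxes(published_state(), params, inputs)
        assert r[_R["r2"]] == pytest.approx(0.0312, rel=2e-3)
        assert r[_R["r5"]] == pytest.approx(0.0311, rel=2e-3)

    def test_zero_state_gives_zero_saturating_rates(self, params, inputs):
        r = compute_fluxes(np.zeros(14), params, inputs)
        # r1 and r10 run on fixed external substrates; every other rate
        # needs internal metabolites and vanishes
        assert r[_R["r1"]] > 0 and r[_R["r10"]] > 0
        mask = np.ones(len(r), dtype=bool)
        mask[_R["r1"]] = mask[_R["r10"]] = False
        assert np.all(r[mask] == 0.0)

    def test_negative_state_rejected(self, params, inputs):
        bad = published_state()
        bad[3] = -1e-6
        with pytest.raises(ValueError, match="negative"):
            compute_fluxes(bad, params, inputs)

    def test_fluxes_monotone_in_substrates_and_inhibitors(self, params, inputs):
        """Finite differences at random states: each rate is non-decreasing
        in its substrate and non-increasing in each inhibitor."""
        rng = np.random.default_rng(7)
        # substrate / inhibitor index map per flux, from the rate laws
        substrates = {
            "r2": "HMGCoA_cyt", "r3": "MVA_cyt", "r4": "MVP_cyt",
            "r5": "MVPP_cyt", "r6": "IPP_cyt", "r7": "DMAPP_cyt",
            "r8": "IPP_cyt", "r9": "IPP_pl", "r11": "DXP", "r12": "MEP",
            "r13": "CDPME", "r14": "CDPMEP", "r15": "MEcPP",
            "r16": "HMBPP", "r17": "HMBPP", "r18": "IPP_pl",
            "r19": "DMAPP_pl", "r22": "DMAPP_cyt", "r23": "DMAPP_pl",
        }
        inhibitors = {
            "r1": ["HMGCoA_cyt"], "r2": ["MVA_cyt"], "r3": ["MVP_cyt"],
            "r4": ["MVPP_cyt"], "r6": ["DMAPP_cyt"],
            "r10": ["IPP_pl", "DMAPP_pl"], "r18": ["DMAPP_pl"],
        }
        for _ in range(100):
            x = rng.uniform(1e-6, 1.0, size=14)
            r0 = compute_fluxes(x, params, inputs)
            for flux, sub in substrates.items():
                xp = x.copy()
                xp[_S[sub]] *= 1.01
                assert compute_fluxes(xp, params, inputs)[_R[flux]] >= r0[_R[flux]]
            for flux, inhs in inhibitors.items():
                for inh in inhs:
                    xp = x.copy()
                    xp[_S[inh]] *= 1.01
                    assert compute_fluxes(xp, params, inputs)[_R[flux]] <= r0[_R[flux]]

    def test_analytic_flux_jacobian_matches_finite_differences(self, params, inputs):
        rng = np.random.default_rng(11)
        x = rng.uniform(1e-4, 0.5, size=14)
        D = flux_state_jacobian(x, params, inputs)
        for j in range(14):
            h = 1e-7 * max(x[j], 1e-6)
            xp, xm = x.copy(), x.copy()
            xp[j] += h
            xm[j] -= h
            fd = (compute_fluxes(xp, params, inputs) - compute_fluxes(xm, params, inputs)) / (2 * h)
            assert np.allclose(D[:, j], fd, rtol=1e-5, atol=1e-10)


class TestRhs:
    def test_steady_state_annihilates_rhs(self, steady, params, inputs):
        f = rhs(0.0, steady, params, inputs)
        scale = np.max(compute_fluxes(steady, params, inputs))
        assert np.max(np.abs(f)) < 1e-9 * scale

    def test_hmbpp_only_state_stoichiometry(self, params, inputs):
        x = np.zeros(14)
        x[_S["HMBPP"]] = 0.01
        r = compute_fluxes(x, params, inputs)
        f = rhs(0.0, x, params, inputs)
        assert f[_S["IPP_pl"]] == pytest.approx(r[_R["r16"]])
        assert f[_S["IPP_pl"]] > 0
        assert f[_S["HMBPP"]] == pytest.approx(-r[_R["r16"]] - r[_R["r17"]])

    def test_cytosolic_c5_balance_identity(self, params, inputs):
        """d(IPP_cyt + DMAPP_cyt)/dt = r5 + r9 + r23 - r8 - r22 - 6 r20."""
        rng = np.random.default_rng(3)
        for _ in range(20):
            x = rng.uniform(0, 0.5, size=14)
            r = compute_fluxes(x, params, inputs)
            f = rhs(0.0, x, params, inputs)
            lhs = f[_S["IPP_cyt"]] + f[_S["DMAPP_cyt"]]
            expected = (
                r[_R["r5"]] + r[_R["r9"]] + r[_R["r23"]]
                - r[_R["r8"]] - r[_R["r22"]] - 6 * r[_R["r20"]]
            )
            assert lhs == pytest.approx(expected, rel=1e-12, abs=1e-14)

    def test_uniform_time_rescaling(self, steady, params, inputs):
        """Scaling every rate constant by 10 leaves the steady state fixed
        and multiplies all eigenvalues by 10."""
        alpha = 10.0
        scaled = params.replace(
            **{k: alpha * getattr(params, k) for k in RATE_SCALE_PARAMS}
        )
        x2 = solve_steady_state(scaled, inputs, x0=steady)
        assert np.allclose(x2, steady, rtol=1e-8)
        ev1 = np.sort(eigen_report(jacobian(steady, params, inputs)).eigenvalues.real)
        ev2 = np.sort(eigen_report(jacobian(x2, scaled, inputs)).eigenvalues.real)
        assert np.allclose(ev2, alpha * ev1, rtol=1e-7)


class TestInvariantValidation:
    def test_schedule_invariants(self):
        with pytest.raises(ValueError):
            LightSchedule(dusk=25.0)
        with pytest.raises(ValueError):
            LightSchedule(dawn=5.0, dusk=3.0)
        with pytest.raises(ValueError):
            LightSchedule(T=0.0)

    def test_parameters_must_be_positive(self, params):
        with pytest.raises(ValueError):
            params.replace(Vmax3=-1.0)
        with pytest.raises(ValueError):
            params.replace(Km1=0.0)
        # exchange/consumption constants may be exactly zero (knockouts)
        params.replace(k2=0.0, k3=0.0)

    def test_inputs_immutable(self, inputs):
        with pytest.raises(Exception):
            inputs.theta = 1.0
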
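"""Force-dependent rate laws, thermodynamics, fits, and the NN model."""

import numpy as np
import pytest

from dnabow.constants import KBT
from dnabow.kinetics import (
    RateLawParams,
    KineticRateLaw,
    delta_g,
    delta_g_vs_force,
    dynamic_range,
    fit_rate_model,
    koff_closed_form,
    kon_closed_form,
    nn_duplex_dg,
    rate_law_from_params,
    rate_vs_force,
    sequence_average_fer,
    SEQUENCE_AVERAGED_PARAMS,
)
from dnabow.polymer import LinearFER, MarkoSiggiaFER, WLCModel, crossover_force
from dnabow.synthetic import gen_rate_dataset


class TestRateVsForce:
    def test_zero_force_returns_k0(self, averaged_law):
        law = rate_law_from_params(averaged_law)
        assert rate_vs_force(law, "on", 0.0)[0] == averaged_law.kon0
        assert rate_vs_force(law, "off", 0.0)[0] == averaged_law.koff0

    def test_constant_gap_reduces_to_bell(self):
        dx = 0.45
        law = KineticRateLaw(
            kon0=1.0, koff0=1.0,
            fer_u=LinearFER(a=1e12, b=2.0),
            fer_b=LinearFER(a=1e12, b=2.0),
            fer_ts=LinearFER(a=1e12, b=2.0 + dx),
        )
        for f in (0.5, 3.0, 6.0):
            expected = np.exp(f * dx / KBT)
            assert rate_vs_force(law, "off", f)[0] == pytest.approx(expected, rel=1e-10)

    def test_quadrature_matches_closed_forms(self, averaged_law):
        law = rate_law_from_params(averaged_law)
        for f in np.linspace(0, 7, 8):
            kq, slope = rate_vs_force(law, "on", f)
            assert kq == pytest.approx(kon_closed_form(averaged_law, f), rel=1e-8)
            kq, _ = rate_vs_force(law, "off", f)
            assert kq == pytest.approx(koff_closed_form(averaged_law, f), rel=1e-8)

    def test_slope_identity(self, averaged_law):
        # d log k/df equals the extension gap over kBT
        law = rate_law_from_params(averaged_law)
        h = 1e-5
        for f in (1.0, 4.0, 6.0):
            k1, _ = rate_vs_force(law, "off", f - h)
            k2, slope = rate_vs_force(law, "off", f)
            k3, _ = rate_vs_force(law, "off", f + h)
            numeric = (np.log(k3) - np.log(k1)) / (2 * h)
            assert slope == pytest.approx(numeric, rel=1e-6)

    def test_negative_force_rejected(self, averaged_law):
        with pytest.raises(ValueError):
            rate_vs_force(rate_law_from_params(averaged_law), "on", -1.0)


class TestClosedForms:
    def test_stiff_transition_state_is_bell(self):
        p = RateLawParams(
            kon0=1.0, koff0=1.0, kappa_ts=1e9, x0_ts=0.39,
            kappa_u=30.7, x0_u=0.21, x0_b=0.34, n=9,
        )
        for f in (1.0, 4.0):
            bell = np.exp(9 * (0.39 - 0.34) * f / KBT)
            assert koff_closed_form(p, f) == pytest.approx(bell, rel=1e-6)

    def test_koff_dynamic_range_near_twofold(self, averaged_law):
        ratio = koff_closed_form(averaged_law, 6.25) / koff_closed_form(averaged_law, 1.6)
        assert ratio == pytest.approx(1.87, abs=0.02)

    def test_kon_stationary_beyond_6pn(self, averaged_law):
        f = np.linspace(0, 6.0, 200)
        logk = np.log(kon_closed_form(averaged_law, f))
        assert np.all(np.diff(logk) > 0)  # still rising at 6 pN


class TestThermo:
    def test_balanced_rates_give_zero(self):
        assert delta_g(1e7, 1e7).dg0 == 0.0

    def test_log_ratio(self):
        assert delta_g(1e7, 0.1).dg0 == pytest.approx(np.log(1e8), rel=1e-12)

    def test_error_propagation_matches_bootstrap(self, rng):
        kon, koff = 1e7, 0.1
        s_on, s_off = 0.08 * kon, 0.05 * koff
        th = delta_g(kon, koff, kon_sem=s_on, koff_sem=s_off)
        draws = delta_g(1, 1).dg0  # noqa: F841 - keep call signature obvious
        boot = np.log(
            rng.normal(kon, s_on, 20000) / rng.normal(koff, s_off, 20000)
        )
        assert th.dg0_err == pytest.approx(np.std(boot), rel=0.2)

    def test_dg_vs_force_zero_force(self):
        fer_u = LinearFER(a=2.0, b=3.15)
        fer_b = LinearFER(a=1e12, b=3.06)
        th = delta_g_vs_force(18.0, fer_u, fer_b, [0.0])
        assert th.dg_of_force[0] == 18.0

    def test_dg_vs_force_linear_fer_analytic(self):
        fer_u = LinearFER(a=2.0467, b=3.15)
        fer_b = LinearFER(a=1e12, b=3.06)
        grid = np.linspace(0, 6, 7)
        th = delta_g_vs_force(18.0, fer_u, fer_b, grid)
        analytic = 18.0 - (grid**2 / (2 * 2.0467) + (3.15 - 3.06) * grid) / KBT
        np.testing.assert_allclose(th.dg_of_force, analytic, atol=1e-10)

    def test_dg_vs_force_maximum_at_ms_crossover(self, ss_15nt, ds_15bp):
        fer_u = MarkoSiggiaFER(ss_15nt)
        fer_b = MarkoSiggiaFER(ds_15bp)
        f_star = crossover_force(fer_u, fer_b)
        grid = np.linspace(0.5, 8, 76)
        th = delta_g_vs_force(18.0, fer_u, fer_b, grid)
        assert grid[np.argmax(th.dg_of_force)] == pytest.approx(f_star, abs=0.11)


class TestFitRateModel:
    def truth(self):
        return dict(kon0=1.0e7, koff0=0.2, n=9, **SEQUENCE_AVERAGED_PARAMS)

    def test_noiseless_exact_inversion(self):
        df = gen_rate_dataset(sigma_log=0.0, seed=0, **self.truth())
        fit = fit_rate_model(df, model="linear", n=9)
        assert fit.params["kon0"] == pytest.approx(1.0e7, rel=1e-6)
        assert fit.params["koff0"] == pytest.approx(0.2, rel=1e-6)
        assert fit.params["a_ts"] == pytest.approx(355.3 / 9, rel=1e-6)
        assert fit.params["b_ts"] == pytest.approx(0.39 * 9, rel=1e-6)
        assert fit.params["a_u"] == pytest.approx(30.7 / 9, rel=1e-6)
        assert fit.params["b_u"] == pytest.approx(0.21 * 9, rel=1e-6)

    def test_too_few_forces_rejected(self):
        df = gen_rate_dataset(sigma_log=0.0, forces=(2.0, 4.0, 6.0), **self.truth())
        with pytest.raises(ValueError):
            fit_rate_model(df, model="linear", n=9)

    def test_noisy_recovery(self):
        # median bias of the zero-force rates over seeded repetitions
        kon0s, koff0s, b_ok = [], [], 0
        n_rep = 30
        for seed in range(n_rep):
            df = gen_rate_dataset(sigma_log=0.05, seed=seed, **self.truth())
            fit = fit_rate_model(df, model="linear", n=9)
            kon0s.append(fit.params["kon0"])
            koff0s.append(fit.params["koff0"])
            se = fit.param_se
            if (
                abs(fit.params["b_ts"] - 3.51) < 2 * se["b_ts"]
                and abs(fit.params["b_u"] - 1.89) < 2 * se["b_u"]
            ):
                b_ok += 1
        assert abs(np.median(kon0s) / 1e7 - 1) < 0.10
        assert abs(np.median(koff0s) / 0.2 - 1) < 0.10
        assert b_ok >= 0.8 * n_rep  # FER intercepts within 2 SE most of the time

    def test_linear_and_ms_transition_stiffness_correlate(self):
        # mutual consistency of the two model families: the linear fit's
        # a_ts and the Marko-Siggia fit's P_ts rank the same underlying
        # transition-state stiffness.  Low-noise datasets (sigma_log=0.02)
        # isolate the model question from estimation noise.
        from scipy.stats import spearmanr

        a_ts, P_ts = [], []
        for seed in range(20):
            kts = float(
                10 ** np.random.default_rng(seed).uniform(np.log10(40), np.log10(900))
            )
            df = gen_rate_dataset(
                sigma_log=0.02, seed=seed,
                kappa_ts=kts, x0_ts=0.39, kappa_u=30.7, x0_u=0.21, x0_b=0.34,
                kon0=1e7, koff0=0.2, n=9,
            )
            lin = fit_rate_model(df, model="linear", n=9)
            ms = fit_rate_model(df, model="marko_siggia", n=9, n_starts=6, seed=seed)
            a_ts.append(lin.params["a_ts"])
            P_ts.append(ms.params["P_ts"])
        rho = spearmanr(a_ts, P_ts).statistic
        assert rho > 0.8


class TestSequenceAverage:
    def test_identical_inputs_pass_through(self):
        fers = [LinearFER.from_per_nt(300.0, 0.4, 9)] * 3
        kappa, x0 = sequence_average_fer(fers)
        assert kappa == pytest.approx(300.0) and x0 == pytest.approx(0.4)

    def test_two_sequence_average(self):
        fers = [
            LinearFER.from_per_nt(200.0, 0.30, 8),
            LinearFER.from_per_nt(400.0, 0.50, 9),
        ]
        kappa, x0 = sequence_average_fer(fers)
        assert kappa == pytest.approx(300.0) and x0 == pytest.approx(0.40)


class TestDynamicRange:
    def table(self, rates, sems):
        import pandas as pd

        f = np.linspace(1.6, 6.25, len(rates))
        return pd.DataFrame(
            dict(force_pN=f, kon=rates, kon_sem=sems, koff=rates, koff_sem=sems)
        )

    def test_force_independent_rates(self):
        df = self.table([2.0] * 5, [0.1] * 5)
        ratio, _ = dynamic_range(df, "koff")
        assert ratio == pytest.approx(1.0)

    def test_bell_closed_form(self):
        f = np.linspace(1.6, 6.25, 5)
        rates = np.exp(0.45 * f / KBT)
        df = self.table(rates, 0.01 * rates)
        ratio, _ = dynamic_range(df, "kon")
        assert ratio == pytest.approx(np.exp(0.45 * 4.65 / KBT), rel=1e-10)

    def test_propagated_error_matches_bootstrap(self, rng):
        rates = np.array([1.0, 1.2, 1.5, 1.8, 2.0])
        sems = 0.05 * rates
        df = self.table(rates, sems)
        ratio, err = dynamic_range(df, "koff")
        boot = rng.normal(rates[-1], sems[-1], 20000) / rng.normal(
            rates[0], sems[0], 20000
        )
        assert err == pytest.approx(np.std(boot), rel=0.2)


class TestNearestNeighbor:
    def test_reverse_complement_symmetry(self):
        seq = "GTAAATTCA"
        rc = seq[::-1].translate(str.maketrans("ACGT", "TGCA"))
        assert nn_duplex_dg(seq) == pytest.approx(nn_duplex_dg(rc), rel=1e-12)

    def test_trimer_hand_sum(self):
        import importlib.resources
        import pandas as pd

        ref = importlib.resources.files("dnabow.data").joinpath("nn_unified_dna.csv")
        with importlib.resources.as_file(ref) as p:
            tab = pd.read_csv(p, comment="#").set_index("step")
        T = 295.15
        dH = tab.loc["GA", "dH_kcal"] + tab.loc["AT", "dH_kcal"] \
            + tab.loc["init_GC", "dH_kcal"] + tab.loc["init_AT", "dH_kcal"]
        dS = tab.loc["GA", "dS_cal"] + tab.loc["AT", "dS_cal"] \
            + tab.loc["init_GC", "dS_cal"] + tab.loc["init_AT", "dS_cal"]
        expected = -(dH - T * dS * 1e-3) / (1.98720425e-3 * T)
        assert nn_duplex_dg("GAT") == pytest.approx(expected, rel=1e-10)

    def test_corrections_are_additive(self):
        base = nn_duplex_dg("GTAAATTCA")
        both = nn_duplex_dg("GTAAATTCA", dangling_end=True, dye=True)
        assert both == pytest.approx(base + 4.0, rel=1e-12)

    def test_unknown_symbol_rejected(self):
        with pytest.raises(ValueError):
            nn_duplex_dg("GXT")
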
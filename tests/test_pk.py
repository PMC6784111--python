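"""Compartmental fits, F-test selection, NCA identities, LOQ censoring."""

import numpy as np
import pytest

from abframe.pk import (
    ExpFit,
    InsufficientDataError,
    PKDataset,
    censor_loq,
    extra_ss_f_test,
    fit_biexponential,
    fit_monoexponential,
    model_based_mrt,
    nca,
    select_decay_model,
)
from abframe.simulate import biexponential_truth, simulate_pk_arm

TIMES = np.array([0.5, 1, 2, 4, 8, 24, 48, 72, 96, 120, 144], dtype=float)


def biexp(t, c0a, a, c0b, b):
    return c0a * np.exp(-a * t) + c0b * np.exp(-b * t)


def make_dataset(conc, antibody="x", dose=15.0, times=TIMES, **kw):
    return PKDataset(antibody_id=antibody, dose_mg_per_kg=dose,
                     times=times, concentrations=conc, **kw)


class TestMonoFit:
    def test_exact_data_recovered(self):
        data = make_dataset(10.0 * np.exp(-0.1 * TIMES))
        fit = fit_monoexponential(data)
        assert fit.params["c0"] == pytest.approx(10.0, rel=1e-6)
        assert fit.params["k"] == pytest.approx(0.1, rel=1e-6)

    def test_constant_data_flags_boundary(self):
        fit = fit_monoexponential(make_dataset(np.full_like(TIMES, 5.0)))
        assert fit.k_at_boundary

    def test_too_few_points_rejected(self):
        with pytest.raises(InsufficientDataError):
            fit_monoexponential((np.array([1.0, 2.0]), np.array([5.0, 4.0])))

    def test_rate_bias_below_2_percent_under_noise(self):
        k_true, c0 = 0.05, 20.0
        estimates = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            c = c0 * np.exp(-k_true * TIMES) * rng.lognormal(0, 0.05, TIMES.shape)
            estimates.append(fit_monoexponential((TIMES, c)).params["k"])
        assert abs(np.mean(estimates) / k_true - 1) < 0.02


class TestBiFit:
    def test_exact_data_recovered_to_4_sf(self):
        p = biexponential_truth("9-EIVLGE", 15.0)  # C0a 76.4, C0b 45.1, t.5b 96.3
        c = biexp(TIMES, p["c0_alpha"], p["alpha"], p["c0_beta"], p["beta"])
        fit = fit_biexponential((TIMES, c))
        assert fit.params["c0_alpha"] == pytest.approx(76.4, rel=1e-4)
        assert fit.params["c0_beta"] == pytest.approx(45.1, rel=1e-4)
        assert fit.t_half_beta == pytest.approx(96.3, rel=1e-4)

    def test_c0_is_sum_of_phase_intercepts(self):
        # the 5 mg/kg arm: printed C0a 29.7 + C0b 14.0 -> C(0) = 43.7 mg/L
        p = biexponential_truth("9-EIVLGE", 5.0)
        c = biexp(TIMES, p["c0_alpha"], p["alpha"], p["c0_beta"], p["beta"])
        fit = fit_biexponential((TIMES, c))
        assert fit.c0 == pytest.approx(43.7, rel=1e-3)

    def test_mono_truth_collapses_and_f_test_prefers_mono(self):
        c = 30.0 * np.exp(-0.02 * TIMES)
        mono = fit_monoexponential((TIMES, c))
        bi = fit_biexponential((TIMES, c))
        assert bi.rss <= mono.rss + 1e-12
        sel = extra_ss_f_test(mono, bi)
        assert sel.chosen == "mono"

    def test_ordering_constraint_alpha_gt_beta(self):
        p = biexponential_truth("2-DIQMAQ-K", 15.0)
        c = biexp(TIMES, p["c0_alpha"], p["alpha"], p["c0_beta"], p["beta"])
        fit = fit_biexponential((TIMES, c))
        assert fit.params["alpha"] > fit.params["beta"] > 0


class TestFTest:
    def test_equal_ss_gives_f_zero_choose_mono(self):
        mono = ExpFit("mono", {"c0": 1.0, "k": 0.1}, rss=2.0, n_points=10)
        bi = ExpFit("bi", {"c0_alpha": 0.5, "alpha": 0.2, "c0_beta": 0.5,
                           "beta": 0.1}, rss=2.0, n_points=10)
        sel = extra_ss_f_test(mono, bi)
        assert sel.f_statistic == 0.0
        assert sel.p_value == 1.0
        assert sel.chosen == "mono"

    def test_n_4_or_fewer_rejected(self):
        mono = ExpFit("mono", {"c0": 1.0, "k": 0.1}, rss=2.0, n_points=4)
        bi = ExpFit("bi", {"c0_alpha": 0.5, "alpha": 0.2, "c0_beta": 0.5,
                           "beta": 0.1}, rss=1.0, n_points=4)
        with pytest.raises(InsufficientDataError):
            extra_ss_f_test(mono, bi)

    def test_power_against_strong_biphasic_truth(self):
        # two-compartment truth at 5% CV: the F-test should essentially
        # always justify the second compartment
        p = biexponential_truth("9-EIVLGE", 15.0)
        chosen_bi = 0
        n_sims = 100
        for seed in range(n_sims):
            rng = np.random.default_rng(seed)
            c = biexp(TIMES, p["c0_alpha"], p["alpha"], p["c0_beta"], p["beta"])
            c = c * rng.lognormal(0, 0.05, TIMES.shape)
            mono = fit_monoexponential((TIMES, c))
            bi = fit_biexponential((TIMES, c))
            chosen_bi += extra_ss_f_test(mono, bi).chosen == "bi"
        assert chosen_bi / n_sims > 0.95


class TestNCA:
    def test_constant_concentration_trapezoid(self):
        data = make_dataset(np.array([[1.0, 1.0, 1.0]]), dose=2.0,
                            times=np.array([0.5, 1.0, 2.0]))
        fit = ExpFit("mono", {"c0": 1.0, "k": 1e-9}, rss=0.0, n_points=3)
        params = nca(data, fit, t_end=2.0)
        assert params.auc_mg_h_per_l == pytest.approx(2.0, rel=1e-6)

    def test_stored_identities_hold_exactly(self):
        p = biexponential_truth("9-EIVLGE", 15.0)
        c = biexp(TIMES, p["c0_alpha"], p["alpha"], p["c0_beta"], p["beta"])
        data = make_dataset(c, dose=15.0)
        fit = fit_biexponential(data)
        params = nca(data, fit)
        assert params.cl_ml_per_h_per_kg * params.auc_mg_h_per_l == pytest.approx(
            1000.0 * 15.0, rel=1e-9)
        assert params.vdss_ml_per_kg / params.cl_ml_per_h_per_kg == pytest.approx(
            params.mrt_h, rel=1e-9)

    def test_half_life_from_terminal_rate(self):
        fit = ExpFit("bi", {"c0_alpha": 10.0, "alpha": 0.1,
                            "c0_beta": 5.0, "beta": 0.0071974},
                     rss=0.0, n_points=10)
        assert fit.t_half_beta == pytest.approx(96.3, abs=0.05)

    def test_auc_additive_over_time_split(self):
        p = biexponential_truth("9-EIVLGE", 15.0)
        c = biexp(TIMES, p["c0_alpha"], p["alpha"], p["c0_beta"], p["beta"])
        data = make_dataset(c, dose=15.0)
        fit = fit_biexponential(data)
        full = nca(data, fit, t_end=144.0).auc_mg_h_per_l
        head = nca(data, fit, t_end=48.0).auc_mg_h_per_l
        t, cm = data.mean_profile()
        mask = (t >= 48.0) & (t <= 144.0)
        tail = float(np.trapezoid(cm[mask], t[mask]))
        assert head + tail == pytest.approx(full, rel=1e-9)

    def test_doubling_concentrations_doubles_auc_halves_cl(self):
        p = biexponential_truth("9-EIVLGE", 15.0)
        c = biexp(TIMES, p["c0_alpha"], p["alpha"], p["c0_beta"], p["beta"])
        base_data = make_dataset(c, dose=15.0)
        doubled_data = make_dataset(2 * c, dose=15.0)
        base = nca(base_data, fit_biexponential(base_data))
        doubled = nca(doubled_data, fit_biexponential(doubled_data))
        assert doubled.auc_mg_h_per_l == pytest.approx(2 * base.auc_mg_h_per_l, rel=1e-6)
        assert doubled.cl_ml_per_h_per_kg == pytest.approx(base.cl_ml_per_h_per_kg / 2, rel=1e-6)
        assert doubled.t_half_beta_h == pytest.approx(base.t_half_beta_h, rel=1e-6)

    def test_model_based_mrt_formula(self):
        fit = ExpFit("bi", {"c0_alpha": 76.4, "alpha": 0.1386,
                            "c0_beta": 45.1, "beta": 0.0072},
                     rss=0.0, n_points=10)
        expected = (76.4 / 0.1386**2 + 45.1 / 0.0072**2) / (
            76.4 / 0.1386 + 45.1 / 0.0072)
        assert model_based_mrt(fit) == pytest.approx(expected, rel=1e-12)


class TestCensoring:
    def test_no_censoring_leaves_data_unchanged(self):
        c = 10.0 * np.exp(-0.01 * TIMES)
        data = censor_loq(make_dataset(c), loq=0.01)
        assert not data.censored.any()
        np.testing.assert_array_equal(data.mean_profile()[1], c)

    def test_all_censored_breaks_downstream_fit(self):
        c = 10.0 * np.exp(-0.01 * TIMES)
        data = censor_loq(make_dataset(c), loq=100.0)
        with pytest.raises(InsufficientDataError):
            fit_monoexponential(data)

    def test_under_5_uncensored_points_falls_back_to_mono(self):
        # mirrors the parental low-dose arm: tail below the detection limit
        c = biexp(TIMES, 2.0, 0.1386, 1.23, 0.02)
        data = censor_loq(make_dataset(c), loq=c[TIMES <= 4].min() - 1e-9)
        assert data.n_uncensored_points == 4
        fit, selection = select_decay_model(data)
        assert fit.model == "mono"
        assert selection is None

    def test_generated_parental_low_dose_arm_censored_beyond_48h(self):
        rng = np.random.default_rng(0)
        data = simulate_pk_arm("2-DIQMAQ-K", 5.0, TIMES, 4, 0.0, rng, loq=0.4)
        t, _ = data.mean_profile()
        assert t.max() <= 48.0
        assert data.censored[:, TIMES > 48.0].all()
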
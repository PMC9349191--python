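"""Likelihood, AICc, multistart fitting and profile intervals."""

import math

import numpy as np
import pytest

from lineageflux.model import (
    ErrorModel,
    FitConfig,
    LineageModel,
    aicc,
    fit_model,
    negative_log_likelihood,
    profile_ci,
)
from lineageflux.odes import assemble_odes, integrate, predict_observables
from lineageflux.simulate import NoiseModel, ObservationTable, StudyDesign, generate_cohort


class TestAicc:
    def test_zero_parameters_reduces_to_deviance(self):
        assert aicc(7.5, 0, 20) == pytest.approx(15.0)

    def test_direct_arithmetic(self):
        assert aicc(5.0, 2, 10) == pytest.approx(4 + 10 + 12 / 7)

    def test_large_n_limit_is_aic(self):
        assert aicc(3.0, 4, 10 ** 6) == pytest.approx(2 * 4 + 2 * 3.0, abs=1e-4)

    @pytest.mark.parametrize("n,k", [(10, 9), (10, 12), (5, 4)])
    def test_undefined_below_sample_floor(self, n, k):
        with pytest.raises(ValueError, match="undefined"):
            aicc(1.0, k, n)


class TestNegativeLogLikelihood:
    def test_perfect_prediction_unit_sigma(self, toy):
        topo, rates = toy
        t = np.array([0.0, 10.0, 30.0])
        pred = predict_observables(integrate(assemble_odes(topo, rates), t))
        df = pred.frame()
        df = df[df.time_days > 0].copy()
        df["condition"], df["mouse"], df["sem"], df["n"] = "native", "pooled", 1.0, 1
        obs = ObservationTable(df, validate=False)
        nll = negative_log_likelihood(pred, obs, ErrorModel())
        assert nll == pytest.approx(0.0, abs=1e-12)  # ln(1) terms vanish

    def test_single_residual_of_two(self, toy):
        topo, rates = toy
        t = np.array([0.0, 10.0])
        pred = predict_observables(integrate(assemble_odes(topo, rates), t))
        j = pred.ids.index("S")
        df = ObservationTable(
            __import__("pandas").DataFrame(
                [("native", "pooled", 10.0, "S", "label_fraction",
                  pred.f[1, j] + 2.0, 1.0, 1)],
                columns=["condition", "mouse", "time_days", "compartment",
                         "observable", "value", "sem", "n"]),
            validate=False)
        assert negative_log_likelihood(pred, df, ErrorModel()) == pytest.approx(2.0)

    def test_zero_sigma_errors(self, toy):
        topo, rates = toy
        t = np.array([0.0, 10.0])
        pred = predict_observables(integrate(assemble_odes(topo, rates), t))
        df = ObservationTable(
            __import__("pandas").DataFrame(
                [("native", "pooled", 10.0, "S", "label_fraction", 0.3, 0.0, 1)],
                columns=["condition", "mouse", "time_days", "compartment",
                         "observable", "value", "sem", "n"]),
            validate=False)
        with pytest.raises(ValueError, match="sigma"):
            negative_log_likelihood(pred, df, ErrorModel())

    def test_truth_beats_perturbation(self, toy, fixed_error_model):
        # NLL at generating parameters <= NLL at 2x-perturbed parameters
        # in >= 95% of seeded noisy replicates
        topo, rates = toy
        design = StudyDesign(timepoints=(7.0, 28.0, 112.0), mice_per_timepoint=4)
        wins = 0
        n_rep = 100
        for s in range(n_rep):
            tab = generate_cohort(topo, rates, design, NoiseModel(), seed=10_000 + s)
            m = LineageModel(topo, tab, error_model=fixed_error_model)
            names = m.param_names
            th = np.array([math.log10(dict(zip(names, _truth_values(m, rates)))[n])
                           for n in names])
            pert = th.copy()
            pert[names.index("alpha:A1>B1")] += math.log10(2)
            pert[names.index("p:B1")] += math.log10(2)
            if m.nll(th) <= m.nll(pert):
                wins += 1
        assert wins >= 95


def _truth_values(model, rates):
    vals = []
    for name in model.param_names:
        kind, _, key = name.partition(":")
        if kind == "alpha":
            s, t = key.split(">")
            vals.append(rates.alpha[(s, t)])
        elif kind == "p":
            vals.append(rates.p[key])
        elif kind == "delta":
            vals.append(rates.delta[key])
        elif kind == "N0":
            vals.append(rates.N0[key])
        else:
            vals.append(rates.f0[key])
    return vals


class TestFit:
    def test_empty_table_rejected(self, toy, noisy_table):
        topo, _ = toy
        import pandas as pd

        with pytest.raises(ValueError, match="empty"):
            LineageModel(topo, pd.DataFrame(columns=noisy_table.df.columns))

    def test_seed_determinism_bit_identical(self, toy, noisy_table, lean_config):
        topo, _ = toy
        a = LineageModel(topo, noisy_table).fit(lean_config)
        b = LineageModel(topo, noisy_table).fit(lean_config)
        assert np.array_equal(a.theta, b.theta)
        assert a.nll == b.nll and a.aicc == b.aicc
        assert np.array_equal(a.per_start_nll, b.per_start_nll)

    def test_best_of_starts_contract(self, toy, noisy_table, lean_config):
        topo, _ = toy
        fit = LineageModel(topo, noisy_table).fit(lean_config)
        assert fit.nll <= np.nanmin(fit.per_start_nll) + 1e-6

    def test_fitted_constant_counts_sigmas(self, toy, noisefree_table, lean_config):
        topo, _ = toy
        m = LineageModel(topo, noisefree_table,
                         error_model=ErrorModel(mode="fitted_constant"))
        fit = m.fit(lean_config)
        assert fit.k == m.k_structural + 3  # one sigma per observable kind
        assert set(fit.fitted_sigma) == {"label_fraction", "rel_size",
                                         "gfp_retention"}

    def test_likelihood_monotone_under_nesting(self, toy, noisy_table, lean_config,
                                               fixed_error_model):
        # adding an edge (free parameter) never increases the minimized NLL
        from lineageflux.topology import build_possibility_graph

        topo, _ = toy
        sub = topo.with_edges([e for e in topo.edge_keys() if e != ("A1", "B2")])
        fit_sub = LineageModel(sub, noisy_table,
                               error_model=fixed_error_model).fit(lean_config)
        sup_model = LineageModel(topo, noisy_table, error_model=fixed_error_model)
        # embed the subset optimum: extra edge at the lower rate bound
        embed = []
        for name in sup_model.param_names:
            if name == "alpha:A1>B2":
                embed.append(-4.0)
            else:
                j = LineageModel(sub, noisy_table,
                                 error_model=fixed_error_model).param_names.index(name)
                embed.append(fit_sub.theta[j])
        cfg = FitConfig(n_starts=8, seed=3, extra_starts=(np.array(embed),))
        fit_sup = sup_model.fit(cfg)
        assert fit_sup.nll <= fit_sub.nll + 1e-6

    def test_summary_and_report(self, toy, noisy_table, lean_config):
        topo, _ = toy
        fit = LineageModel(topo, noisy_table).fit(lean_config)
        s = fit.summary()
        assert "AICc" in s and "alpha:S>A1" in s
        d = fit.to_report_dict()
        assert d["k"] == fit.k and d["convergence"]

    def test_functional_wrapper(self, toy, noisy_table, lean_config):
        topo, _ = toy
        a = fit_model(topo, noisy_table, lean_config)
        b = LineageModel(topo, noisy_table).fit(lean_config)
        assert a.nll == b.nll


@pytest.fixture(scope="module")
def good_fit(toy, noisy_table):
    topo, _ = toy
    cfg = FitConfig(n_starts=32, seed=3, scan_max_nfev=12, n_polish=2,
                    polish_max_nfev=500)
    return LineageModel(topo, noisy_table).fit(cfg)


class TestProfile:
    def test_interval_matches_quadratic_closed_form(self):
        # a static compartment measured m times makes the NLL an exact
        # Gaussian-mean quadratic: CI must equal ybar +/- 1.96 sigma/sqrt(m)
        import pandas as pd

        from lineageflux.topology import Compartment, LineageTopology

        topo = LineageTopology(
            [Compartment("c", level=0, column="x", is_tip=True,
                         allows_proliferation=False)], [])
        rng = np.random.default_rng(1)
        sigma, m_obs = 0.05, 6
        y = 0.5 + rng.normal(0, sigma, m_obs)
        rows = [("native", "pooled", float(t + 1), "c", "rel_size", y[t], sigma, 1)
                for t in range(m_obs)]
        rows += [("native", "pooled", float(t + 1), "c", "label_fraction", 0.5,
                  sigma, 1) for t in range(m_obs)]
        tab = ObservationTable(
            pd.DataFrame(rows, columns=["condition", "mouse", "time_days",
                                        "compartment", "observable", "value",
                                        "sem", "n"]), validate=False)
        fit = LineageModel(topo, tab).fit(FitConfig(n_starts=8, seed=0))
        assert fit.params["N0:c"] == pytest.approx(np.mean(y), rel=1e-5)
        prof = profile_ci(fit, "N0:c")
        half = 1.959964 * sigma / math.sqrt(m_obs)
        assert prof.ci[0] == pytest.approx(np.mean(y) - half, rel=0.02)
        assert prof.ci[1] == pytest.approx(np.mean(y) + half, rel=0.02)

    def test_estimate_inside_interval_and_grid_anchored(self, good_fit):
        prof = profile_ci(good_fit, "alpha:S>A1")
        est = good_fit.params["alpha:S>A1"]
        assert prof.ci[0] <= est <= prof.ci[1]
        i = int(np.argmin(np.abs(prof.grid[:, 0] - est)))
        assert prof.grid[i, 1] == pytest.approx(good_fit.nll, abs=1e-8)

    def test_unidentifiable_parameter_flagged_one_sided(self, toy, noisy_table,
                                                        lean_config):
        # with label fractions only, a loss rate is unidentifiable: the
        # profile stays flat to the bound instead of crossing the threshold
        topo, _ = toy
        lab = noisy_table.subset(observables=["label_fraction"])
        fit = LineageModel(topo, lab).fit(lean_config)
        prof = profile_ci(fit, "delta:A2", max_steps=25)
        assert prof.one_sided_lower or prof.one_sided_upper

    def test_unknown_parameter(self, good_fit):
        with pytest.raises(ValueError, match="unknown parameter"):
            profile_ci(good_fit, "alpha:nope")
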
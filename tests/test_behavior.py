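"""Mixture model of continuous-report errors: densities, EM fit, labelling."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import integrate, stats

from specdcm.behavior import (
    HIGH_ACCURACY,
    LOW_ACCURACY,
    SWAP,
    VonMisesMixture,
    behavior_summary,
    classify_trials,
    kappa_to_sigma,
    mixture_density,
    responsibilities,
    sigma_to_kappa,
    vonmises_density,
    wrap_angle,
)
from specdcm.simulate import BehaviorSimSpec, simulate_behavior


class TestVonMisesDensity:
    def test_zero_concentration_is_uniform(self):
        x = np.linspace(-np.pi, np.pi, 7)
        assert np.allclose(vonmises_density(x, 0.0), 1.0 / (2 * np.pi))

    @pytest.mark.parametrize("kappa", [0.5, 4.0, 20.0])
    def test_integrates_to_one(self, kappa):
        val, _ = integrate.quad(lambda x: vonmises_density(x, kappa), -np.pi, np.pi)
        assert val == pytest.approx(1.0, abs=1e-8)

    def test_symmetry(self):
        x = np.linspace(0.01, np.pi, 20)
        assert np.allclose(vonmises_density(x, 5.0), vonmises_density(-x, 5.0))

    def test_matches_scipy(self):
        x = np.linspace(-3, 3, 11)
        assert np.allclose(
            vonmises_density(x, 7.5), stats.vonmises.pdf(x, 7.5), atol=1e-12
        )

    def test_negative_concentration_rejected(self):
        with pytest.raises(ValueError):
            vonmises_density(0.0, -1.0)


class TestKappaSigma:
    @pytest.mark.parametrize("kappa", [0.5, 2.0, 8.0, 50.0])
    def test_roundtrip(self, kappa):
        assert sigma_to_kappa(float(kappa_to_sigma(kappa))) == pytest.approx(
            kappa, rel=1e-6
        )

    def test_sigma_decreasing_in_kappa(self):
        k = np.array([0.5, 1, 2, 4, 8, 16])
        assert np.all(np.diff(kappa_to_sigma(k)) < 0)


class TestMixtureDensity:
    def test_pure_guessing_is_uniform(self):
        err = np.linspace(-3, 3, 9)
        nt = np.zeros((9, 2))
        d = mixture_density(err, nt, kappa=8.0, gamma=1.0, beta=0.0)
        assert np.allclose(d, 1.0 / (2 * np.pi))

    def test_single_component_reduces_to_vonmises(self):
        err = np.linspace(-3, 3, 9)
        nt = np.ones((9, 2))
        d = mixture_density(err, nt, kappa=8.0, gamma=0.0, beta=0.0)
        assert np.allclose(d, vonmises_density(err, 8.0))

    def test_integrates_to_one(self):
        target, nt1, nt2 = 0.3, -1.2, 2.0

        def dens(x):
            return float(
                mixture_density(
                    wrap_angle(x - target),
                    wrap_angle(np.array([[x - nt1, x - nt2]])),
                    kappa=8.0,
                    gamma=0.1,
                    beta=0.15,
                )[0]
            )

        val, _ = integrate.quad(dens, -np.pi, np.pi, limit=200)
        assert val == pytest.approx(1.0, abs=1e-8)

    def test_invalid_weights_rejected(self):
        with pytest.raises(ValueError):
            mixture_density([0.0], [[0.0]], kappa=1.0, gamma=0.7, beta=0.5)


def _grid_search_oracle(reports: pd.DataFrame):
    """Coarse grid-search ML over (kappa, gamma, beta), scipy densities.

    Independent of the EM path: densities via scipy.stats.vonmises and a
    direct evaluation of the mixture log-likelihood.
    """
    rep = reports["report"].to_numpy()
    tgt = reports["target"].to_numpy()
    nts = reports[["nontarget_1", "nontarget_2"]].to_numpy()
    te = wrap_angle(rep - tgt)
    ne = wrap_angle(rep[:, None] - nts)

    best = (-np.inf, None)
    for kappa in np.exp(np.linspace(np.log(0.5), np.log(64), 25)):
        d_t = stats.vonmises.pdf(te, kappa)
        d_nt = stats.vonmises.pdf(ne, kappa).mean(axis=1)
        for gamma in np.linspace(0, 0.5, 26):
            for beta in np.linspace(0, 0.5, 26):
                if gamma + beta > 1:
                    continue
                dens = (
                    (1 - gamma - beta) * d_t
                    + gamma / (2 * np.pi)
                    + beta * d_nt
                )
                ll = float(np.log(np.maximum(dens, 1e-300)).sum())
                if ll > best[0]:
                    best = (ll, (kappa, gamma, beta))
    return best


class TestFitMixture:
    def test_degenerate_truth_recovers_boundary(self):
        df = simulate_behavior(
            BehaviorSimSpec(n_trials=700, kappa=8.0, gamma=0.0, beta=0.0, seed=5)
        )
        fit = VonMisesMixture(random_state=0).fit(df)
        assert fit.gamma_ < 0.02
        assert fit.beta_ < 0.02

    def test_recovery_against_grid_oracle(self, std_reports, std_fit):
        assert abs(std_fit.gamma_ - 0.10) <= 0.03
        assert abs(std_fit.beta_ - 0.15) <= 0.03
        assert std_fit.kappa_ == pytest.approx(8.0, rel=0.15)
        # on a small instance the EM optimum must not fall below a coarse
        # grid-search maximum of the same likelihood
        small = std_reports.iloc[:200]
        fit = VonMisesMixture(random_state=0).fit(small)
        ll_grid, _ = _grid_search_oracle(small)
        assert fit.log_likelihood_ >= ll_grid - 0.1

    def test_uniform_reports_attributed_to_guessing(self):
        rng = np.random.default_rng(2)
        n = 2000
        df = pd.DataFrame(
            {
                "target": rng.uniform(-np.pi, np.pi, n),
                "nontarget_1": rng.uniform(-np.pi, np.pi, n),
                "nontarget_2": rng.uniform(-np.pi, np.pi, n),
                "report": rng.uniform(-np.pi, np.pi, n),
            }
        )
        fit = VonMisesMixture(random_state=0).fit(df)
        assert fit.gamma_ > 0.8

    def test_too_few_reports_rejected(self):
        df = simulate_behavior(BehaviorSimSpec(n_trials=3, kappa=8.0, seed=0))
        with pytest.raises(ValueError, match="at least"):
            VonMisesMixture(min_reports=20).fit(df)

    def test_degenerate_identical_reports_flagged_not_raised(self):
        n = 50
        df = pd.DataFrame(
            {
                "target": np.zeros(n),
                "nontarget_1": np.full(n, 1.5),
                "nontarget_2": np.full(n, -1.5),
                "report": np.zeros(n),
            }
        )
        fit = VonMisesMixture(random_state=0).fit(df)
        assert fit.boundary_


class TestResponsibilities:
    def _model(self, kappa, gamma, beta):
        m = VonMisesMixture()
        m.kappa_, m.gamma_, m.beta_ = kappa, gamma, beta
        m.sigma_ = float(kappa_to_sigma(max(kappa, 1e-6)))
        return m

    def test_pure_guessing_gives_guess_probability_one(self):
        m = self._model(8.0, 1.0, 0.0)
        resp = m.responsibilities(np.array([[0.5, 1.0, -1.0]]))
        assert np.allclose(resp, [[0.0, 1.0, 0.0]])

    def test_report_at_target_far_from_nontargets(self):
        m = self._model(8.0, 0.1, 0.1)
        resp = m.responsibilities(np.array([[0.0, 2.5, -2.5]]))
        assert resp[0, 0] > 0.9

    @settings(deadline=None, max_examples=50)
    @given(
        te=st.floats(-3.1, 3.1),
        n1=st.floats(-3.1, 3.1),
        n2=st.floats(-3.1, 3.1),
        kappa=st.floats(0.1, 30),
        gamma=st.floats(0.01, 0.5),
        beta=st.floats(0.01, 0.5),
    )
    def test_sum_to_one(self, te, n1, n2, kappa, gamma, beta):
        m = self._model(kappa, gamma, min(beta, 1 - gamma))
        resp = m.responsibilities(np.array([[te, n1, n2]]))
        assert resp.sum() == pytest.approx(1.0, abs=1e-10)
        assert np.all(resp >= 0)

    def test_monotone_in_target_distance(self):
        m = self._model(8.0, 0.1, 0.1)
        dists = np.linspace(0, np.pi, 40)
        p_t = m.responsibilities(
            np.column_stack([dists, np.full(40, 2.0), np.full(40, -2.0)])
        )[:, 0]
        assert np.all(np.diff(p_t) <= 1e-12)


class TestClassifyTrials:
    @staticmethod
    def _table(p_targets, p_nontargets):
        return pd.DataFrame(
            {
                "trial": [0, 0, 0],
                "report_index": [1, 2, 3],
                "p_target": p_targets,
                "p_nontarget": p_nontargets,
            }
        )

    @pytest.mark.parametrize(
        "p_t, p_nt, expected",
        [
            ((0.95, 0.92, 0.99), (0.01, 0.02, 0.0), HIGH_ACCURACY),
            ((0.5, 0.1, 0.6), (0.1, 0.75, 0.2), SWAP),
            ((0.95, 0.85, 0.95), (0.02, 0.1, 0.02), LOW_ACCURACY),
        ],
    )
    def test_rule_forcing(self, p_t, p_nt, expected):
        labels = classify_trials(self._table(p_t, p_nt))
        assert labels.loc[0, "label"] == expected

    def test_partition_and_exclusivity(self, std_reports, std_fit):
        resp = responsibilities(std_reports, std_fit)
        labels = classify_trials(resp)
        assert len(labels) == std_reports["trial"].nunique()
        assert set(labels["label"]) <= {HIGH_ACCURACY, LOW_ACCURACY, SWAP}
        # the two gates cannot both fire: p_target > 0.9 everywhere forces
        # every p_nontarget < 0.1 < 0.7
        merged = resp.groupby("trial").agg(
            min_pt=("p_target", "min"), max_pnt=("p_nontarget", "max")
        )
        both = (merged["min_pt"] > 0.9) & (merged["max_pnt"] > 0.7)
        assert not both.any()

    def test_missing_report_raises(self):
        bad = self._table((0.9, 0.9, 0.9), (0.0, 0.0, 0.0)).iloc[:2]
        with pytest.raises(ValueError, match="exactly 3"):
            classify_trials(bad)


class TestBehaviorSummary:
    def test_exact_zero_and_fixed_offset_errors(self):
        reports = pd.DataFrame(
            {
                "trial": [0, 0, 0, 1, 1, 1],
                "target": [0.0, 1.0, -1.0, 0.5, 1.5, -0.5],
                "report": [0.0, 1.0, -1.0] + list(np.radians(10) + np.array([0.5, 1.5, -0.5])),
            }
        )
        labels = pd.DataFrame({"trial": [0, 1], "label": [HIGH_ACCURACY, LOW_ACCURACY]})
        out = behavior_summary(reports, labels).set_index("label")
        assert out.loc[HIGH_ACCURACY, "mean_abs_error_deg"] == pytest.approx(0.0)
        assert out.loc[LOW_ACCURACY, "mean_abs_error_deg"] == pytest.approx(10.0)

    def test_error_ordering_by_label(self, std_reports, std_fit):
        resp = responsibilities(std_reports, std_fit)
        labels = classify_trials(resp)
        out = behavior_summary(std_reports, labels).set_index("label")
        assert (
            out.loc[HIGH_ACCURACY, "mean_abs_error_deg"]
            < out.loc[LOW_ACCURACY, "mean_abs_error_deg"]
            < out.loc[SWAP, "mean_abs_error_deg"]
        )
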
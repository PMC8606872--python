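"""Joint/single von Mises mixture models, predictions, and classification."""

import numpy as np
import pytest
from scipy.special import i0, i0e, i1e
from scipy.stats import chi2_contingency

from vwmbind import mixtures, taskgen
from vwmbind.mixtures import (
    JointVonMisesMixture,
    SingleVonMisesMixture,
    a_inv,
    classify_responses,
    conditional_error_distributions,
    phi_squared,
    predict_correlated,
    predict_independent,
)


class TestPredictions:
    def test_independent_worked_example(self):
        assert predict_independent(0.6, 0.5) == pytest.approx(
            {"TT": 0.30, "TU": 0.30, "UT": 0.20, "UU": 0.20}
        )

    def test_independent_degenerate(self):
        assert predict_independent(1.0, 1.0)["TT"] == 1.0

    def test_correlated_worked_example(self):
        assert predict_correlated(0.6, 0.5) == pytest.approx(
            {"TT": 0.55, "UU": 0.45, "TU": 0.0, "UT": 0.0}
        )

    @pytest.mark.parametrize("a", np.linspace(0.05, 0.95, 9))
    @pytest.mark.parametrize("b", np.linspace(0.05, 0.95, 9))
    def test_grid_identities(self, a, b):
        ind = predict_independent(a, b)
        cor = predict_correlated(a, b)
        assert sum(ind.values()) == pytest.approx(1.0)
        assert sum(cor.values()) == pytest.approx(1.0)
        assert phi_squared(ind) == pytest.approx(0.0, abs=1e-12)
        assert phi_squared(cor) == pytest.approx(1.0)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            predict_independent(1.2, 0.5)


class TestPhiSquared:
    def test_uniform_table(self):
        assert phi_squared({"TT": 0.25, "TU": 0.25, "UT": 0.25, "UU": 0.25}) == 0.0

    def test_diagonal_table(self):
        assert phi_squared({"TT": 0.5, "UU": 0.5, "TU": 0.0, "UT": 0.0}) == 1.0

    def test_chi_square_oracle(self):
        # Phi^2 equals chi^2 / n of the 2x2 contingency table
        table = {"TT": 0.4, "TU": 0.2, "UT": 0.1, "UU": 0.3}
        n = 10_000_000
        counts = np.array(
            [
                [table["TT"] * n, table["TU"] * n],
                [table["UT"] * n, table["UU"] * n],
            ]
        )
        chi2 = chi2_contingency(counts, correction=False).statistic
        assert phi_squared(table) == pytest.approx(chi2 / n, abs=1e-9)

    def test_degenerate_margin_returns_zero(self):
        with pytest.warns(UserWarning):
            assert phi_squared({"TT": 1.0, "TU": 0.0, "UT": 0.0, "UU": 0.0}) == 0.0


class TestAInv:
    @pytest.mark.parametrize("kappa", [0.1, 0.5, 2.0, 8.0, 50.0])
    def test_roundtrip(self, kappa):
        r = i1e(kappa) / i0e(kappa)
        assert a_inv(r) == pytest.approx(kappa, rel=1e-3)


class TestJoint2Recovery:
    def test_recovers_truth(self, mixture_dataset):
        ds, truth = mixture_dataset
        fit = JointVonMisesMixture(n_components=2, seed=0).fit(ds)
        for lab, want in truth.proportions.items():
            assert fit.alphas_[lab] == pytest.approx(want, abs=0.03)
        assert fit.kappa1_ == pytest.approx(8.0, rel=0.15)
        assert fit.kappa2_ == pytest.approx(8.0, rel=0.15)

    def test_degenerate_all_target(self, rng):
        ds = taskgen.generate_experiment(taskgen.exp1_design(n_trials=72), rng)
        resp = np.stack(
            [ds.target_feature(d) for d in ds.report_dims], axis=1
        )
        ds = ds.with_responses(resp)
        with pytest.warns(UserWarning, match="degenerate"):
            fit = JointVonMisesMixture(n_components=2, seed=0).fit(ds)
        assert fit.alphas_["TT"] > 0.99
        assert fit.kappa1_ >= mixtures.KAPPA_MAX

    def test_pure_uniform(self, rng):
        design = taskgen.exp1_design(n_trials=5004, trials_per_block=36)
        ds = taskgen.generate_experiment(design, rng)
        truth = taskgen.MixtureGroundTruth(8.0, 8.0, {"UU": 1.0})
        ds = taskgen.simulate_responses_mixture(ds, truth, rng)
        fit = JointVonMisesMixture(n_components=2, seed=0).fit(ds)
        assert fit.alphas_["UU"] >= 0.95

    def test_too_few_trials_rejected(self, rng):
        ds = taskgen.generate_experiment(
            taskgen.ExperimentDesign(
                cue_dim="location",
                report_dims=("color", "orientation"),
                n_trials=12,
                trials_per_block=12,
            ),
            rng,
        )
        ds = ds.with_responses(np.zeros((12, 2)))
        with pytest.raises(ValueError):
            JointVonMisesMixture(n_components=2).fit(ds)


@pytest.fixture(scope="module")
def swap_dataset():
    rng = np.random.default_rng(200)
    design = taskgen.exp1_design(n_trials=5004, trials_per_block=36)
    ds = taskgen.generate_experiment(design, rng)
    truth = taskgen.MixtureGroundTruth(
        8.0,
        8.0,
        {"TT": 0.4, "TU": 0.1, "UT": 0.1, "UU": 0.1, "NNs": 0.2, "NNd": 0.1},
    )
    return taskgen.simulate_responses_mixture(ds, truth, rng), truth


class TestJoint3Recovery:

    def test_separates_matched_and_mismatched_swaps(self, swap_dataset):
        ds, truth = swap_dataset
        fit = JointVonMisesMixture(n_components=3, seed=0).fit(ds)
        assert fit.alphas_["NNs"] == pytest.approx(0.2, abs=0.04)
        assert fit.alphas_["NNd"] == pytest.approx(0.1, abs=0.05)

    def test_zero_swap_data_yields_small_nontarget_mass(self, mixture_dataset):
        ds, _ = mixture_dataset
        fit = JointVonMisesMixture(n_components=3, seed=0).fit(ds)
        swap_mass = sum(
            fit.alphas_[k] for k in ("TN", "NT", "NNs", "NNd", "NU", "UN")
        )
        assert swap_mass <= 0.05

    def test_joint2_is_joint3_with_pinned_swaps(self, mixture_dataset):
        # likelihood identity on shared kappas and zero N-proportions
        ds, _ = mixture_dataset
        from vwmbind.mixtures import LABELS2, LABELS3, _em_joint

        k = (7.5, 7.9)
        a2 = np.array([0.3, 0.3, 0.2, 0.2])
        r2 = _em_joint(ds, False, k, a2, max_iter=1, tol=1.0)
        a3 = np.array(
            [0.3 if l == "TT" else 0.3 if l == "TU" else 0.2 if l in ("UT", "UU")
             else 0.0 for l in LABELS3]
        )
        r3 = _em_joint(ds, True, k, a3, max_iter=1, tol=1.0)
        assert r3["log_likelihood"] == pytest.approx(
            r2["log_likelihood"], abs=1e-6
        )


class TestClassification:
    def test_posterior_hand_calculation(self, rng):
        # response exactly at target: posterior = a*f(0) / (a*f(0) + (1-a)/2pi)
        ds = taskgen.generate_experiment(taskgen.exp1_design(n_trials=36), rng)
        resp = np.stack([ds.target_feature(d) for d in ds.report_dims], axis=1)
        ds = ds.with_responses(resp)
        fit = SingleVonMisesMixture(report=0, n_components=2)
        fit.kappa_ = 8.0
        fit.alphas_ = {"T": 0.7, "U": 0.3}
        fit.labels_ = ("T", "U")
        post = fit.predict_proba(ds)
        f0 = np.exp(8.0) / (2 * np.pi * i0(8.0))  # von Mises peak density
        want = 0.7 * f0 / (0.7 * f0 + 0.3 / (2 * np.pi))
        assert np.allclose(post[:, 0], want, atol=1e-9)
        # frozen from the Bessel oracle above: f(0) = e^8 / (2 pi I0(8))
        assert want == pytest.approx(0.9421, abs=0.001)

    def test_no_uniform_mass_never_labels_u(self, rng):
        ds = taskgen.generate_experiment(taskgen.exp1_design(n_trials=36), rng)
        ds = ds.with_responses(rng.uniform(-np.pi, np.pi, (36, 2)))
        fits = []
        for r in (0, 1):
            f = SingleVonMisesMixture(report=r, n_components=2)
            f.kappa_ = 2.0
            f.alphas_ = {"T": 1.0, "U": 0.0}
            f.labels_ = ("T", "U")
            fits.append(f)
        cls = classify_responses(ds, tuple(fits))
        assert np.all(cls.labels != "U")

    def test_label_recovery_accuracy(self, rng):
        # simulate known labels, refit, compare hard labels
        design = taskgen.exp1_design(n_trials=2052, trials_per_block=36)
        ds = taskgen.generate_experiment(design, rng)
        truth = taskgen.MixtureGroundTruth(
            8.0, 8.0, {"TT": 0.5, "UU": 0.2, "TU": 0.15, "UT": 0.15}
        )
        comp = rng.choice(4, size=ds.n_trials, p=[0.5, 0.2, 0.15, 0.15])
        labels = np.array(["TT", "UU", "TU", "UT"])[comp]
        resp = np.empty((ds.n_trials, 2))
        for r in (0, 1):
            tgt = ds.target_feature(ds.report_dims[r])
            is_t = np.array([l[r] == "T" for l in labels])
            resp[:, r] = np.where(
                is_t,
                tgt + rng.vonmises(0, 8.0, ds.n_trials),
                rng.uniform(-np.pi, np.pi, ds.n_trials),
            )
        ds = ds.with_responses(resp)
        fits = tuple(
            SingleVonMisesMixture(report=r, n_components=2, seed=3).fit(ds)
            for r in (0, 1)
        )
        cls = classify_responses(ds, fits)
        for r in (0, 1):
            true_lab = np.array([l[r] for l in labels])
            acc = np.mean(cls.labels[:, r] == true_lab)
            assert acc >= 0.8


class TestConditionalErrorDistributions:
    def test_all_target_equals_unconditional(self, rng):
        ds = taskgen.generate_experiment(taskgen.exp1_design(n_trials=36), rng)
        resp = np.stack([ds.target_feature(d) for d in ds.report_dims], axis=1)
        ds = ds.with_responses(resp)
        fits = []
        for r in (0, 1):
            f = SingleVonMisesMixture(report=r, n_components=2)
            f.kappa_ = 8.0
            f.alphas_ = {"T": 0.9, "U": 0.1}
            f.labels_ = ("T", "U")
            fits.append(f)
        cls = classify_responses(ds, tuple(fits))
        hists = conditional_error_distributions(ds, cls, 1)
        assert hists["T"]["n"] == 36
        assert hists["U"]["empty"]
        total = np.histogram(
            ds.errors(0), bins=hists["T"]["bin_edges"]
        )[0]
        assert np.array_equal(hists["T"]["counts"], total)

    def test_central_peak_survives_uniform_classification(self, rng):
        # independent U components: trials whose other response is a guess
        # still carry target information in this response
        design = taskgen.exp1_design(n_trials=5004, trials_per_block=36)
        ds = taskgen.generate_experiment(design, rng)
        truth = taskgen.MixtureGroundTruth(
            8.0, 8.0, {"TT": 0.36, "TU": 0.24, "UT": 0.24, "UU": 0.16}
        )
        ds = taskgen.simulate_responses_mixture(ds, truth, rng)
        fits = tuple(
            SingleVonMisesMixture(report=r, n_components=2, seed=9).fit(ds)
            for r in (0, 1)
        )
        cls = classify_responses(ds, fits)
        hists = conditional_error_distributions(ds, cls, 1)
        errs = hists["U"]["errors"]
        assert len(errs) > 100
        # circular SD significantly below the uniform expectation
        from vwmbind.circstats import circular_sd

        sd = circular_sd(errs)
        n = len(errs)
        # under uniformity R ~ Rayleigh with scale 1/sqrt(n): bound R at
        # the 0.999 quantile and convert to a lower bound on circular SD
        r_crit = np.sqrt(-np.log(1e-3) / n)
        sd_floor = np.sqrt(-2 * np.log(r_crit))
        assert sd < sd_floor
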
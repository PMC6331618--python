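"""Likelihood, transitional-MCMC evidence, decomposition, MAP."""

import math

import numpy as np
import pytest
from scipy import stats

from cgwater.inference import (
    ParameterVector,
    PosteriorEnsemble,
    QoIDataset,
    evidence_decomposition,
    log_likelihood,
    make_log_likelihood,
    map_estimate,
    sample_posterior,
)
from cgwater.priors import GaussianPrior, UniformBoxPrior
from cgwater.synthetic import (
    SurrogateForward,
    generate_pseudo_experiment,
    make_benchmark_suite,
)
from cgwater.model_zoo import build_model, default_priors
from helpers_bayes import conjugate_problem as _conjugate_problem


class TestLogLikelihood:
    def test_value_at_the_mean(self):
        # single datum, model matches datum exactly, 10% error scale
        phi = ParameterVector([1.0], sigma_n=0.1)
        ds = QoIDataset(labels=("rho",), values=[2.0], temperature=298.0)
        expected = -math.log(math.sqrt(2 * math.pi) * 0.2)
        assert log_likelihood(phi, ds, [2.0]) == pytest.approx(expected)
        assert expected == pytest.approx(0.69049, abs=1e-5)

    def test_common_rescaling_shifts_by_minus_n_log_c(self):
        phi = ParameterVector([0.0], sigma_n=0.2)
        f = np.array([1.1, 2.4, 0.7])
        d = np.array([1.0, 2.5, 0.8])
        ds1 = QoIDataset(("a", "b", "c"), d, 298.0)
        c = 3.7
        ds2 = QoIDataset(("a", "b", "c"), c * d, 298.0)
        l1 = log_likelihood(phi, ds1, f)
        l2 = log_likelihood(phi, ds2, c * f)
        assert l2 - l1 == pytest.approx(-3 * math.log(c), rel=1e-12)

    def test_one_sigma_residual_costs_half(self):
        sn = 0.13
        d = 2.0
        peak = log_likelihood(
            ParameterVector([0.0], sn), QoIDataset(("a",), [d], 298.0), [d]
        )
        off = log_likelihood(
            ParameterVector([0.0], sn),
            QoIDataset(("a",), [d], 298.0),
            [d * (1 + sn)],
        )
        assert peak - off == pytest.approx(0.5, rel=1e-12)

    def test_matches_direct_product_of_normal_densities(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            n = rng.integers(1, 6)
            d = rng.uniform(0.5, 100, n) * rng.choice([-1, 1], n)
            f = d * (1 + 0.1 * rng.standard_normal(n))
            sn = rng.uniform(0.02, 0.5)
            ds = QoIDataset([f"x{i}" for i in range(n)], d, 298.0)
            direct = float(
                np.sum(stats.norm.logpdf(d, loc=f, scale=sn * np.abs(d)))
            )
            mine = log_likelihood(ParameterVector([0.0], sn), ds, f)
            assert mine == pytest.approx(direct, abs=1e-10)

    def test_zero_datum_rejected(self):
        ds = QoIDataset(("a", "b"), [1.0, 0.0], 298.0)
        with pytest.raises(ValueError, match="zero datum"):
            log_likelihood(ParameterVector([0.0], 0.1), ds, [1.0, 0.0])
        with pytest.raises(ValueError, match="zero datum"):
            make_log_likelihood(lambda p, x: np.ones((len(p), 2)), ds)

    def test_label_misalignment_rejected(self):
        ds = QoIDataset(("a", "b"), [1.0, 2.0], 298.0)
        with pytest.raises(ValueError):
            log_likelihood(ParameterVector([0.0], 0.1), ds, [1.0])


class TestEvidenceSampler:
    @pytest.mark.parametrize("dim", [1, 2, 5])
    def test_matches_conjugate_closed_form(self, dim):
        prob = _conjugate_problem(dim, seed=dim)
        ens = sample_posterior(
            prob["prior"], forward=prob["forward"], datasets=prob["dataset"],
            sigma_n=prob["sigma_n"], seed=42,
            sampler_cfg={"n_samples": 1500, "n_runs": 5},
        )
        assert abs(ens.log_evidence - prob["log_z"]) < 3 * ens.log_evidence_se

    def test_flat_likelihood_evidence_equals_the_constant(self):
        prior = UniformBoxPrior(("a", "b"), [0.0, 0.0], [1.0, 2.0])
        const = -3.25
        ll = lambda X: np.full(len(np.atleast_2d(X)), const)
        ens = sample_posterior(prior, ll, seed=0,
                               sampler_cfg={"n_samples": 400, "n_runs": 2})
        assert ens.log_evidence == pytest.approx(const, abs=1e-12)

    def test_recovers_synthetic_truth(self):
        suite = make_benchmark_suite("common_truth", 3, seed=7, structure="1S")
        ll = make_log_likelihood(suite.surrogate, suite.datasets)
        ens = sample_posterior(suite.prior, ll, seed=1,
                               sampler_cfg={"n_samples": 800, "n_runs": 2})
        truth = np.concatenate([suite.true_params[0], [suite.sigma_n]])
        assert np.all(np.abs(ens.mean() - truth) <= 3 * ens.sd())

    def test_same_seed_reproduces_ensemble(self):
        suite = make_benchmark_suite("single_condition", seed=2, structure="1S")
        ll = make_log_likelihood(suite.surrogate, suite.datasets)
        cfg = {"n_samples": 300, "n_runs": 2}
        a = sample_posterior(suite.prior, ll, seed=5, sampler_cfg=cfg)
        b = sample_posterior(suite.prior, ll, seed=5, sampler_cfg=cfg)
        assert np.array_equal(a.samples, b.samples)
        assert a.log_evidence == b.log_evidence

    def test_halving_a_generous_prior_box_adds_ln_two(self):
        # Ockham behavior: the posterior mass sits well inside both boxes
        spec = build_model("1S", 4)
        prior = default_priors(spec, include_sigma_n=False)
        sur = SurrogateForward(spec, prior)
        ds = generate_pseudo_experiment(
            sur, sur.phi0 + 0.1 * sur.halfwidth, 0.05, 298.0, seed=3
        )
        ll = make_log_likelihood(sur, ds, sigma_n=0.05)
        full = UniformBoxPrior(prior.names, prior.lower, prior.upper)
        lo, hi = prior.lower.copy(), prior.upper.copy()
        w = hi[0] - lo[0]
        half = UniformBoxPrior(
            prior.names, [sur.phi0[0] - w / 4, lo[1]],
            [sur.phi0[0] + w / 4, hi[1]],
        )
        cfg = {"n_samples": 1000, "n_runs": 4}
        e_full = sample_posterior(full, ll, seed=5, sampler_cfg=cfg)
        e_half = sample_posterior(half, ll, seed=6, sampler_cfg=cfg)
        delta = e_half.log_evidence - e_full.log_evidence
        se = math.hypot(e_full.log_evidence_se, e_half.log_evidence_se)
        assert abs(delta - math.log(2)) < 3 * se

    def test_seed_spread_consistent_with_reported_se(self):
        suite = make_benchmark_suite("common_truth", 3, seed=3, structure="1S")
        ll = make_log_likelihood(suite.surrogate, suite.datasets)
        vals, ses = [], []
        for s in range(10):
            e = sample_posterior(
                suite.prior, ll, seed=500 + s,
                sampler_cfg={"n_samples": 800, "n_runs": 3},
            )
            vals.append(e.log_evidence)
            ses.append(e.log_evidence_se)
        ratio = np.std(vals, ddof=1) / np.mean(ses)
        assert 0.5 < ratio < 2.0

    def test_posterior_predictive_covers_held_out_data(self):
        # nominal 90% intervals, averaged over independent data realizations
        rng = np.random.default_rng(123)
        count = total = 0
        for s in range(30):
            suite = make_benchmark_suite(
                "common_truth", 3, seed=700 + s, structure="1S"
            )
            ll = make_log_likelihood(suite.surrogate, suite.datasets)
            ens = sample_posterior(
                suite.prior, ll, seed=1700 + s,
                sampler_cfg={"n_samples": 800, "n_runs": 2},
            )
            held = generate_pseudo_experiment(
                suite.surrogate, suite.true_params[0], suite.sigma_n,
                298.0, seed=5000 + s,
            )
            j = rng.choice(ens.n, 800, p=ens.weights)
            phis = ens.samples[j]
            F = suite.surrogate(phis[:, :-1], 298.0)
            y = F * (1 + phis[:, -1][:, None] * rng.standard_normal(F.shape))
            lo, hi = np.quantile(y, [0.05, 0.95], axis=0)
            count += np.sum((held.values >= lo) & (held.values <= hi))
            total += len(held.values)
        coverage = count / total
        se = math.sqrt(0.9 * 0.1 / total)
        assert abs(coverage - 0.9) < 3 * se


class TestEvidenceDecomposition:
    def test_flat_likelihood_has_zero_information_gain(self):
        prior = UniformBoxPrior(("a", "b"), [0.0, 0.0], [1.0, 2.0])
        const = -1.5
        ll = lambda X: np.full(len(np.atleast_2d(X)), const)
        ens = sample_posterior(prior, ll, seed=1,
                               sampler_cfg={"n_samples": 2000, "n_runs": 2})
        rep = evidence_decomposition(ens, prior)
        assert rep.expected_fit == pytest.approx(const, abs=1e-12)
        assert abs(rep.information_gain) < 0.1

    @pytest.mark.parametrize("dim", [2, 5])
    def test_conjugate_terms_match_closed_forms(self, dim):
        prob = _conjugate_problem(dim, seed=10 + dim)
        ens = sample_posterior(
            prob["prior"], forward=prob["forward"], datasets=prob["dataset"],
            sigma_n=prob["sigma_n"], seed=8,
            sampler_cfg={"n_samples": 4000, "n_runs": 4, "n_mcmc_steps": 10},
        )
        rep = evidence_decomposition(ens, prob["prior"])
        assert rep.information_gain == pytest.approx(
            prob["kl"], abs=3 * rep.information_gain_se + 0.1
        )
        assert abs(rep.residual) <= 0.15

    def test_information_gain_nonnegative_within_mc_error(self):
        suite = make_benchmark_suite("common_truth", 3, seed=4, structure="1S")
        ll = make_log_likelihood(suite.surrogate, suite.datasets)
        ens = sample_posterior(suite.prior, ll, seed=2,
                               sampler_cfg={"n_samples": 1000, "n_runs": 2})
        rep = evidence_decomposition(ens, suite.prior)
        assert rep.information_gain >= -3 * rep.information_gain_se

    def test_small_ensemble_rejected(self):
        prior = UniformBoxPrior(("a",), [0.0], [1.0])
        ens = PosteriorEnsemble(
            samples=np.linspace(0, 1, 10)[:, None],
            weights=np.full(10, 0.1),
            log_likelihoods=np.zeros(10),
            log_evidence=0.0,
            log_evidence_se=0.1,
        )
        with pytest.raises(ValueError, match="below the minimum"):
            evidence_decomposition(ens, prior)


class TestMapEstimate:
    def test_conjugate_mode_recovered_with_polish(self):
        prob = _conjugate_problem(2, seed=30)
        ll = make_log_likelihood(
            prob["forward"], prob["dataset"], sigma_n=prob["sigma_n"]
        )
        ens = sample_posterior(prob["prior"], ll, seed=3,
                               sampler_cfg={"n_samples": 1500, "n_runs": 2})
        pv = map_estimate(ens, prob["prior"], ll, polish=True)
        # with a Gaussian prior the posterior mode equals the posterior mean
        est = np.concatenate([pv.phi_c, [pv.sigma_n]])[: len(prob["m_post"])]
        assert np.abs(est - prob["m_post"]).max() < 1e-5

    def test_single_sample_returned_verbatim(self):
        ens = PosteriorEnsemble(
            samples=np.array([[0.3, 0.7]]),
            weights=np.array([1.0]),
            log_likelihoods=np.array([-1.0]),
            log_evidence=-1.0,
            log_evidence_se=0.1,
            names=("a", "sigma_n"),
        )
        pv = map_estimate(ens)
        assert np.array_equal(pv.full, [0.3, 0.7])

    def test_exact_tie_breaks_to_lowest_index(self):
        ens = PosteriorEnsemble(
            samples=np.array([[0.2, 0.5], [0.8, 0.5]]),
            weights=np.array([0.5, 0.5]),
            log_likelihoods=np.array([-2.0, -2.0]),
            log_evidence=-2.0,
            log_evidence_se=0.1,
        )
        pv = map_estimate(ens)
        assert pv.full[0] == 0.2

    def test_empty_ensemble_rejected(self):
        with pytest.raises(ValueError):
            map_estimate(
                PosteriorEnsemble(
                    samples=np.empty((0, 2)),
                    weights=np.empty(0),
                    log_likelihoods=np.empty(0),
                    log_evidence=0.0,
                    log_evidence_se=0.1,
                )
            )
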
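"""Maximum-entropy splice model: training oracle, scoring, invariants."""

import itertools

import numpy as np
import pytest
from scipy.optimize import minimize

from irkit import maxent as M
from irkit import simulate as sim


def brute_force_maxent(width, alphabet, constraints, targets):
    """Direct convex solve: maximize entropy subject to marginal equalities
    by enumerating the full outcome space (test oracle, tiny widths only)."""
    a = len(alphabet)
    outcomes = list(itertools.product(range(a), repeat=width))
    n = len(outcomes)

    mats = []
    vals = []
    for c in constraints:
        tab = targets[tuple(c)]
        for cell in itertools.product(range(a), repeat=len(c)):
            row = np.array(
                [
                    1.0 if tuple(x[p] for p in c) == cell else 0.0
                    for x in outcomes
                ]
            )
            mats.append(row)
            vals.append(tab[cell])
    A = np.array(mats)
    b = np.array(vals)

    # convex dual of entropy maximization under A p = b (with normalization
    # handled by the softmax): minimize log Z(lam) - lam . b
    def dual(lam):
        logits = A.T @ lam
        m = logits.max()
        logz = m + np.log(np.exp(logits - m).sum())
        return logz - lam @ b

    def dual_grad(lam):
        logits = A.T @ lam
        p = np.exp(logits - logits.max())
        p /= p.sum()
        return A @ p - b

    res = minimize(
        dual,
        np.zeros(A.shape[0]),
        jac=dual_grad,
        method="L-BFGS-B",
        options={"maxiter": 5000, "ftol": 1e-16, "gtol": 1e-12},
    )
    logits = A.T @ res.x
    p = np.exp(logits - logits.max())
    return p / p.sum()


def sample_from_pwm(pwm, n, rng):
    return ["".join(sim.DNA[[rng.choice(4, p=col) for col in pwm]]) for _ in range(n)]


class TestTraining:
    def test_order1_equals_positional_product(self, rng):
        pwm = sim._strength_pwm(sim.DONOR_PWM, 0.8)
        sites = sample_from_pwm(pwm, 200, rng)
        cons = M.order1_constraints(9)
        model = M.train(sites, constraint_set=cons)
        emp = M.empirical_marginals(sites, cons)
        probs = model.enumerate_probs()
        grids = itertools.product(range(4), repeat=9)
        closed = np.array(
            [np.prod([emp[(i,)][g[i]] for i in range(9)]) for g in grids]
        )
        assert 0.5 * np.abs(probs - closed).sum() < 1e-6

    def test_matches_convex_oracle_on_binary_toy(self, rng):
        # width-3 binary-reduced alphabet, order-2 constraints, 8 outcomes
        alphabet = "RY"
        sites = [
            "".join(alphabet[b] for b in rng.integers(0, 2, 3))
            for _ in range(120)
        ]
        # plant dependence: make position 2 copy position 0 most of the time
        sites = [s[:2] + (s[0] if rng.random() < 0.8 else s[2]) for s in sites]
        cons = [(0,), (1,), (2,), (0, 1), (1, 2), (0, 2)]
        model = M.train(
            sites, constraint_set=cons, alphabet=alphabet, tol=1e-9,
            min_sites=50,
        )
        targets = M.empirical_marginals(sites, cons, alphabet=alphabet)
        oracle = brute_force_maxent(3, alphabet, cons, targets)
        probs = model.enumerate_probs()
        tv = 0.5 * np.abs(probs - oracle).sum()
        assert tv < 1e-6

    def test_pairwise_marginals_recovered_from_dependent_sampler(self, rng):
        # build a dependent model, sample from it, retrain, compare marginals
        width = 6
        cons = M.default_constraints(width)
        lambdas = {c: np.zeros((4,) * len(c)) for c in cons}
        coupling = np.zeros((4, 4))
        coupling[0, 0] = coupling[1, 1] = 1.2  # A-A / C-C attraction
        lambdas[(1, 2)] = coupling
        truth_model = M.MaxEntModel(
            kind="toy", width=width, alphabet="ACGT", constraints=cons,
            lambdas=lambdas, background=np.full(4, 0.25),
        )
        sites = truth_model.sample(4000, rng)
        refit = M.train(sites, constraint_set=cons)
        truth_marg = truth_model.marginals()[(1, 2)]
        refit_marg = refit.marginals()[(1, 2)]
        assert np.abs(truth_marg - refit_marg).max() < 0.03

    def test_too_few_sites_rejected(self):
        with pytest.raises(ValueError, match=">= 50"):
            M.train(["ACGTACGTA"] * 10)

    def test_mixed_widths_rejected(self):
        with pytest.raises(ValueError, match="width"):
            M.train(["ACGT"] * 60 + ["ACG"] * 60, min_sites=1,
                    enforce_min_sites=False)

    def test_nonconvergence_reports_deviation(self, rng):
        pwm = sim._strength_pwm(sim.DONOR_PWM, 0.8)
        sites = sample_from_pwm(pwm, 100, rng)
        with pytest.raises(M.ConvergenceError, match="deviation"):
            M.train(sites, max_iter=1, tol=1e-12)


class TestEntropyProperties:
    def fit(self, sites, cons, alphabet="ACGT"):
        return M.train(
            sites, constraint_set=cons, alphabet=alphabet, tol=1e-8,
            enforce_min_sites=False,
        )

    def test_trained_model_has_maximal_entropy(self, rng):
        width = 4
        sites = ["".join(sim.DNA[rng.integers(0, 4, width)]) for _ in range(150)]
        cons = M.default_constraints(width)
        model = self.fit(sites, cons)
        targets = M.empirical_marginals(sites, cons)
        oracle = brute_force_maxent(width, "ACGT", cons, targets)
        p = np.clip(oracle, 1e-15, None)
        oracle_entropy = float(-(p * np.log2(p)).sum())
        assert model.entropy() >= oracle_entropy - 1e-5

    def test_adding_constraints_never_increases_entropy(self, rng):
        width = 5
        pwm = sim._strength_pwm(sim.DONOR_PWM[:5], 0.8)
        sites = sample_from_pwm(pwm, 300, rng)
        h = []
        for cons in (
            M.order1_constraints(width),
            M.order1_constraints(width) + [(i, i + 1) for i in range(width - 1)],
            M.default_constraints(width),
        ):
            h.append(self.fit(sites, cons).entropy())
        assert h[0] >= h[1] - 1e-6 >= h[2] - 2e-6

    def test_probabilities_sum_to_one(self, rng):
        pwm = sim._strength_pwm(sim.DONOR_PWM, 0.5)
        model = M.train(sample_from_pwm(pwm, 200, rng))
        assert model.enumerate_probs().sum() == pytest.approx(1.0, abs=1e-9)


class TestScoring:
    def uniform_model(self, width=4):
        cons = M.order1_constraints(width)
        lambdas = {c: np.zeros((4,) * len(c)) for c in cons}
        return M.MaxEntModel(
            kind="toy", width=width, alphabet="ACGT", constraints=cons,
            lambdas=lambdas, background=np.full(4, 0.25),
        )

    def test_uniform_model_uniform_background_scores_zero(self):
        model = self.uniform_model()
        scores = model.score(["ACGT", "TTTT", "GGCC"])
        assert np.allclose(scores, 0.0, atol=1e-12)

    def test_doubled_probability_scores_one_bit(self):
        model = self.uniform_model(width=1)
        # reweight A to probability 1/2 (uniform background 1/4)
        model.lambdas[(0,)] = np.log(np.array([2.0, 2 / 3, 2 / 3, 2 / 3]))
        score_a = model.score(["A"])[0]
        assert score_a == pytest.approx(1.0, abs=1e-9)

    def test_score_antisymmetry_model_vs_background(self, rng):
        pwm = sim._strength_pwm(sim.DONOR_PWM, 0.7)
        model = M.train(sample_from_pwm(pwm, 300, rng))
        windows = sample_from_pwm(pwm, 20, rng)
        bg = model.background
        fwd = model.score(windows, background=bg)
        # swap roles: score of bg model against trained model as background
        log_m = model.log_prob(windows) / np.log(2)
        log_b = np.log2(bg)[M._encode(windows, "ACGT")].sum(axis=1)
        assert np.allclose(fwd, log_m - log_b)
        assert np.allclose(-(log_b - log_m), fwd)

    def test_strong_and_weak_sites_separate(self, rng):
        strong = sample_from_pwm(sim._strength_pwm(sim.DONOR_PWM, 0.95), 100, rng)
        weak = sample_from_pwm(sim._strength_pwm(sim.DONOR_PWM, 0.15), 100, rng)
        model = M.train(strong)
        s, w = model.score(strong), model.score(weak)
        auroc = (s[:, None] > w[None, :]).mean() + 0.5 * (
            s[:, None] == w[None, :]
        ).mean()
        assert auroc > 0.9


class TestPairScores:
    def test_retained_sites_weaker_and_bins_conserve_counts(self, small_sim):
        from irkit.maxent import pair_scores

        retained = small_sim["retained_ids"]
        introns = small_sim["introns"]
        chrom_seqs = {"chr1": small_sim["genome"]["chr1"]}
        seq = chrom_seqs["chr1"]
        donors = [
            M.donor_window(seq, i) for i in introns if i.id not in retained
        ]
        acceptors = [
            M.acceptor_window(seq, i) for i in introns if i.id not in retained
        ]
        dm = M.train(donors, kind="donor")
        am = M.train(acceptors, kind="acceptor")
        res = pair_scores(introns, retained, chrom_seqs, dm, am)
        assert res["donor_mean_shift"] < 0
        assert res["acceptor_mean_shift"] < 0
        assert res["donor_p_lower"] < 0.01
        total = res["hist_retained"].sum() + res["hist_other"].sum()
        assert total == len(res["intron_ids"])

    def test_identical_distributions_show_no_shift(self):
        rng = np.random.default_rng(2024)
        pwm = sim._strength_pwm(sim.DONOR_PWM, 0.7)
        sites = sample_from_pwm(pwm, 400, rng)
        model = M.train(sites)
        s1 = model.score(sites[:200])
        s2 = model.score(sites[200:])
        from scipy.stats import mannwhitneyu

        assert mannwhitneyu(s1, s2).pvalue > 0.05


class TestSerialization:
    def test_json_round_trip_preserves_scores(self, tmp_path, rng):
        pwm = sim._strength_pwm(sim.DONOR_PWM, 0.7)
        model = M.train(sample_from_pwm(pwm, 150, rng))
        p = tmp_path / "model.json"
        model.to_json(p)
        model2 = M.MaxEntModel.from_json(p)
        windows = sample_from_pwm(pwm, 10, rng)
        assert np.allclose(model.score(windows), model2.score(windows))


class TestWindows:
    def test_plus_and_minus_extraction_agree(self, small_sim):
        genome = small_sim["genome"]["chr1"]
        for intr in small_sim["introns"][:50]:
            d = M.donor_window(genome, intr)
            a = M.acceptor_window(genome, intr)
            assert len(d) == 9 and len(a) == 23
            assert d[3:5] == "GT" and a[18:20] == "AG"
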
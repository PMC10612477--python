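"""Rate matrices, pruning likelihoods, model fits, and NEB posteriors."""

import itertools

import numpy as np
import pytest
from scipy.linalg import expm

from orthoselect.alignment import CodonAlignment
from orthoselect.codon_engine import (
    CodonFrequencies, LikelihoodEngine, beta_category_means,
    compute_frequencies, fit_branch_model, fit_branch_site, fit_model,
    model_classes, rate_matrix, site_posteriors, transition_probabilities,
    _mean_rate, _unscaled_generator,
)
from orthoselect.gene_tree import parse_newick
from orthoselect.genetics import N_SENSE, SENSE_CODONS
from orthoselect.simulator import (
    DEFAULT_PARAMS, SimScenario, default_tree, evolve_alignment,
)


def random_freqs(rng) -> CodonFrequencies:
    pi = rng.dirichlet(np.full(N_SENSE, 5.0))
    pi = np.maximum(pi, 1e-6)
    return CodonFrequencies("equal", pi / pi.sum())


def exhaustive_loglik(tree, ca, kappa, classes, pi, foreground=None,
                      factor_classes=None):
    """Brute-force marginalization over all internal-node states.

    Uses scipy expm for transition matrices and explicit sums over every
    combination of internal-node codon states — independent of the pruning
    recursion under test. Branch lengths are scaled by the mixture-average
    rate of ``factor_classes`` (default: ``classes``), matching the model's
    common-scale convention.
    """
    rates = {}
    for _, wb, wf in (factor_classes or classes) + list(classes):
        for w in (wb, wf):
            if w not in rates:
                rates[w] = _mean_rate(_unscaled_generator(kappa, w, pi), pi)
    factor = sum(p * rates[wb] for p, wb, _ in (factor_classes or classes))

    post = tree.postorder()
    internal = [n for n in post if not n.is_leaf]
    leaf_codons = {t: [SENSE_CODONS.index(ca.row(t)[3 * k: 3 * k + 3])
                       for k in range(ca.n_codon_columns)] for t in ca.taxa}
    total = 0.0
    for site in range(ca.n_codon_columns):
        site_like = 0.0
        for prop, wb, wf in classes:
            Ps = {}
            for node in post[:-1]:
                w = wf if (node.is_leaf and node.name == foreground) else wb
                Q = _unscaled_generator(kappa, w, pi) / factor
                Ps[id(node)] = expm(Q * node.length)
            like = 0.0
            for states in itertools.product(range(N_SENSE), repeat=len(internal)):
                assign = {id(n): s for n, s in zip(internal, states)}
                prob = pi[assign[id(post[-1])]]
                for node in post[:-1]:
                    parent = next(p for p in post
                                  if any(c is node for c in p.children))
                    s_child = (leaf_codons[node.name][site] if node.is_leaf
                               else assign[id(node)])
                    prob *= Ps[id(node)][assign[id(parent)], s_child]
                like += prob
            site_like += prop * like
        total += np.log(site_like)
    return total


def tiny_alignment(rng, tree, n_sites=4):
    taxa = tree.leaves()
    rows = ["".join(SENSE_CODONS[rng.integers(N_SENSE)] for _ in range(n_sites))
            for _ in taxa]
    return CodonAlignment(taxa=taxa, rows=rows)


class TestRateMatrix:
    def test_detailed_balance_and_scaling(self, rng):
        for _ in range(5):
            kappa = float(rng.uniform(0.5, 10))
            omega = float(rng.uniform(0.01, 5))
            freqs = random_freqs(rng)
            Q = rate_matrix(kappa, omega, freqs)
            flux = freqs.pi[:, None] * Q
            assert np.max(np.abs(flux - flux.T)) < 1e-12
            assert abs(-(freqs.pi * np.diag(Q)).sum() - 1.0) < 1e-12

    def test_multi_step_rates_zero(self):
        freqs = CodonFrequencies("equal", np.full(N_SENSE, 1 / N_SENSE))
        Q = rate_matrix(2.0, 0.5, freqs)
        for i, ci in enumerate(SENSE_CODONS):
            for j, cj in enumerate(SENSE_CODONS):
                if i != j and sum(a != b for a, b in zip(ci, cj)) > 1:
                    assert Q[i, j] == 0.0

    def test_omega_zero_kills_nonsynonymous_rates(self):
        from orthoselect.genetics import CODON_AA
        freqs = CodonFrequencies("equal", np.full(N_SENSE, 1 / N_SENSE))
        Q = rate_matrix(2.0, 0.0, freqs)
        for i in range(N_SENSE):
            for j in range(N_SENSE):
                if i != j and CODON_AA[i] != CODON_AA[j]:
                    assert Q[i, j] == 0.0

    def test_invalid_parameters(self):
        freqs = CodonFrequencies("equal", np.full(N_SENSE, 1 / N_SENSE))
        with pytest.raises(ValueError):
            rate_matrix(-1.0, 0.5, freqs)


class TestTransitionProbabilities:
    def test_t_zero_is_identity(self, rng):
        freqs = random_freqs(rng)
        Q = rate_matrix(2.0, 0.3, freqs)
        P = transition_probabilities(Q, 0.0, freqs.pi)
        assert np.max(np.abs(P - np.eye(N_SENSE))) < 1e-10

    def test_small_t_taylor_expansion(self, rng):
        freqs = random_freqs(rng)
        Q = rate_matrix(1.7, 0.6, freqs)
        t = 1e-4
        P = transition_probabilities(Q, t, freqs.pi)
        assert np.max(np.abs(P - (np.eye(N_SENSE) + Q * t))) < 10 * t * t

    def test_rows_sum_to_one_and_stationarity(self, rng):
        freqs = random_freqs(rng)
        Q = rate_matrix(3.0, 1.2, freqs)
        for t in rng.uniform(0.01, 5.0, size=3):
            P = transition_probabilities(Q, float(t), freqs.pi)
            assert np.max(np.abs(P.sum(axis=1) - 1.0)) < 1e-10
            assert np.max(np.abs(freqs.pi @ P - freqs.pi)) < 1e-10
            assert P.min() >= 0.0

    def test_negative_time_rejected(self, rng):
        freqs = random_freqs(rng)
        with pytest.raises(ValueError):
            transition_probabilities(rate_matrix(2, 1, freqs), -0.1, freqs.pi)

    def test_eigen_path_matches_expm(self, rng):
        freqs = random_freqs(rng)
        Q = rate_matrix(2.5, 0.4, freqs)
        assert np.max(np.abs(transition_probabilities(Q, 0.7, freqs.pi)
                             - transition_probabilities(Q, 0.7))) < 1e-10


class TestPruning:
    def test_two_taxon_zero_branch_limit(self, rng):
        tree = parse_newick("(a:0.0000001,b:0.0000001,c:0.0000001);")
        freqs = random_freqs(rng)
        taxa_rows = "".join(SENSE_CODONS[rng.integers(N_SENSE)] for _ in range(6))
        ca = CodonAlignment(taxa=["a", "b", "c"], rows=[taxa_rows] * 3)
        engine = LikelihoodEngine(tree, ca, freqs=freqs)
        lnl = engine.loglik(2.0, [(1.0, 0.5, 0.5)], tree.branch_lengths())
        expected = sum(np.log(freqs.pi[SENSE_CODONS.index(taxa_rows[3*k:3*k+3])])
                       for k in range(6))
        assert lnl == pytest.approx(expected, abs=1e-3)

    @pytest.mark.parametrize("newick,model", [
        ("(a:0.2,b:0.35,c:0.1);", "M0"),
        ("((a:0.2,b:0.3):0.15,c:0.25,d:0.4);", "M0"),
        ("((a:0.2,b:0.3):0.15,c:0.25,d:0.4);", "M1a"),
    ])
    def test_matches_exhaustive_marginalization(self, rng, newick, model):
        tree = parse_newick(newick)
        ca = tiny_alignment(rng, tree, n_sites=3)
        freqs = random_freqs(rng)
        params = ({"kappa": float(rng.uniform(1, 4)),
                   "omega": float(rng.uniform(0.1, 2))} if model == "M0" else
                  {"kappa": float(rng.uniform(1, 4)),
                   "p0": float(rng.uniform(0.3, 0.9)),
                   "omega0": float(rng.uniform(0.05, 0.8))})
        classes = model_classes(model, params)
        engine = LikelihoodEngine(tree, ca, freqs=freqs)
        got = engine.loglik(params["kappa"], classes, tree.branch_lengths())
        want = exhaustive_loglik(tree, ca, params["kappa"], classes, freqs.pi)
        assert got == pytest.approx(want, abs=1e-8)

    def test_branch_site_foreground_matches_oracle(self, rng):
        tree = parse_newick("(a:0.2,b:0.35,c:0.1);").with_foreground("b")
        ca = tiny_alignment(rng, tree, n_sites=3)
        freqs = random_freqs(rng)
        classes = model_classes("BSA", {"kappa": 2.0, "q0": 0.6, "q1": 0.5,
                                        "omega0": 0.2, "omega2": 3.0})
        engine = LikelihoodEngine(tree, ca, freqs=freqs)
        got = engine.loglik(2.0, classes, tree.branch_lengths())
        want = exhaustive_loglik(tree, ca, 2.0, classes, freqs.pi, foreground="b")
        assert got == pytest.approx(want, abs=1e-8)

    def test_likelihood_invariant_to_rerooting(self, rng):
        # the same unrooted tree written with two different inner-node roots
        t1 = parse_newick("((a:0.2,b:0.3):0.15,c:0.25,d:0.4);")
        t2 = parse_newick("(a:0.2,b:0.3,(c:0.25,d:0.4):0.15);")
        ca = tiny_alignment(rng, t1, n_sites=5)
        freqs = random_freqs(rng)
        classes = model_classes("M0", {"kappa": 2.0, "omega": 0.5})
        l1 = LikelihoodEngine(t1, ca, freqs=freqs).loglik(2.0, classes,
                                                          t1.branch_lengths())
        l2 = LikelihoodEngine(t2, ca, freqs=freqs).loglik(2.0, classes,
                                                          t2.branch_lengths())
        assert l1 == pytest.approx(l2, abs=1e-9)


class TestModelCollapses:
    def test_m3_equal_omegas_collapses_to_m0(self, rng, five_taxon_tree,
                                             small_m0_alignment):
        engine = LikelihoodEngine(five_taxon_tree, small_m0_alignment)
        bl = five_taxon_tree.branch_lengths()
        m0 = engine.loglik(2.0, model_classes("M0", {"kappa": 2, "omega": 0.3}), bl)
        m3 = engine.loglik(2.0, model_classes("M3k3", {
            "kappa": 2, "q0": 0.2, "q1": 0.5,
            "omega0": 0.3, "omega1": 0.3, "omega2": 0.3}), bl)
        assert m3 == pytest.approx(m0, abs=1e-6)

    def test_m8_with_no_extra_mass_collapses_to_m7(self, five_taxon_tree,
                                                   small_m0_alignment):
        engine = LikelihoodEngine(five_taxon_tree, small_m0_alignment)
        bl = five_taxon_tree.branch_lengths()
        m7 = engine.loglik(2.0, model_classes("M7", {"kappa": 2, "p": 0.4, "q": 1.2}), bl)
        m8 = engine.loglik(2.0, model_classes("M8", {
            "kappa": 2, "p0": 1.0 - 1e-12, "p": 0.4, "q": 1.2, "omega_s": 3.0}), bl)
        assert m8 == pytest.approx(m7, abs=1e-6)

    def test_branch_model_with_equal_ratios_collapses_to_m0(
            self, five_taxon_tree, small_m0_alignment):
        tree = five_taxon_tree.with_foreground("spA")
        engine = LikelihoodEngine(tree, small_m0_alignment)
        bl = tree.branch_lengths()
        m0 = engine.loglik(2.0, model_classes("M0", {"kappa": 2, "omega": 0.3}), bl)
        br = engine.loglik(2.0, model_classes("BR2", {
            "kappa": 2, "omega_bg": 0.3, "omega_fg": 0.3}), bl)
        assert br == pytest.approx(m0, abs=1e-6)


class TestBetaDiscretization:
    def test_category_means_average_to_distribution_mean(self):
        for p, q in [(0.5, 1.5), (2.0, 3.0), (0.2, 0.3)]:
            means = beta_category_means(p, q, 10)
            assert len(means) == 10
            assert np.all(np.diff(means) >= 0)
            assert means.mean() == pytest.approx(p / (p + q), rel=1e-6)


class TestFitting:
    def test_m8a_spike_fixed_at_one(self, five_taxon_tree, small_m0_alignment):
        fit = fit_model(five_taxon_tree, small_m0_alignment, "M8a", seed=1,
                        n_starts=1, max_iter=60)
        assert fit.classes[-1][1] == 1.0
        assert "omega_s" not in fit.estimates

    def test_nestedness_of_warm_started_pairs(self, five_taxon_tree,
                                              small_m0_alignment):
        tree, ca = five_taxon_tree, small_m0_alignment
        m1a = fit_model(tree, ca, "M1a", seed=1, n_starts=1)
        m2a = fit_model(tree, ca, "M2a", seed=1, n_starts=1, warm_start=m1a)
        assert m2a.lnL >= m1a.lnL - 1e-4
        m7 = fit_model(tree, ca, "M7", seed=1, n_starts=1, max_iter=150)
        m8a = fit_model(tree, ca, "M8a", seed=1, n_starts=1, warm_start=m7,
                        max_iter=150)
        m8 = fit_model(tree, ca, "M8", seed=1, n_starts=1, warm_start=m8a,
                       max_iter=150)
        assert m8.lnL >= m8a.lnL - 1e-4
        assert m8.lnL >= m7.lnL - 1e-4

    def test_np_counts_follow_schedule(self, five_taxon_tree, small_m0_alignment):
        tree, ca = five_taxon_tree, small_m0_alignment
        n_edges = tree.n_edges()
        expected_free = {"M0": 2, "M1a": 3, "M2a": 5, "M3k3": 6,
                         "M7": 3, "M8": 5, "M8a": 4}
        for name, free in expected_free.items():
            fit = fit_model(tree, ca, name, seed=0, n_starts=1, max_iter=3)
            assert fit.np_params == free + n_edges

    def test_foreground_required_for_branch_models(self, five_taxon_tree,
                                                   small_m0_alignment):
        with pytest.raises(ValueError, match="foreground"):
            fit_model(five_taxon_tree, small_m0_alignment, "BR2", seed=0)
        with pytest.raises(ValueError, match="spX"):
            fit_branch_model(five_taxon_tree, small_m0_alignment, "spX")

    def test_branch_model_detects_elevated_foreground(self):
        tree = default_tree(5).with_foreground("spE")
        scn = SimScenario(tree=tree, model="BR2",
                          params={"kappa": 2.0, "omega_bg": 0.2, "omega_fg": 3.0},
                          n_codons=300, seed=5)
        ca, _ = evolve_alignment(scn)
        null, alt = fit_branch_model(tree, ca, "spE", seed=1, n_starts=1)
        assert alt.estimates["omega_fg"] > 1.0
        assert alt.estimates["omega_bg"] < 1.0
        assert alt.lnL > null.lnL + 2.0  # clear signal at these settings

    def test_branch_site_boundary_gives_near_zero_statistic(
            self, five_taxon_tree, small_m0_alignment):
        null, alt = fit_branch_site(five_taxon_tree, small_m0_alignment,
                                    "spA", seed=2, n_starts=1)
        assert alt.lnL >= null.lnL - 1e-4
        # purifying data: omega2 sits at its boundary, statistic ~ 0
        assert 2 * (alt.lnL - null.lnL) < 3.0


class TestSitePosteriors:
    def test_degenerate_single_class_posterior_is_one(self, five_taxon_tree,
                                                      small_m0_alignment):
        fit = fit_model(five_taxon_tree, small_m0_alignment, "M2a", seed=0,
                        n_starts=1, max_iter=3)
        fit.classes = [(1e-12, 0.2, 0.2), (1e-12, 1.0, 1.0),
                       (1.0 - 2e-12, 2.0, 2.0)]
        res = site_posteriors(fit, five_taxon_tree, small_m0_alignment)
        assert all(r.posterior == pytest.approx(1.0, abs=1e-6) for r in res)

    def test_matches_direct_bayes_rule_arithmetic(self, rng):
        tree = parse_newick("(a:0.2,b:0.35,c:0.1);")
        ca = tiny_alignment(rng, tree, n_sites=3)
        freqs = random_freqs(rng)
        est = {"kappa": 2.0, "q0": 0.5, "q1": 0.6, "omega0": 0.1, "omega2": 4.0}
        classes = model_classes("M2a", est)
        fit = fit_model(tree, ca, "M2a", seed=0, n_starts=1, max_iter=0,
                        freqs=freqs)
        fit.estimates, fit.classes = est, classes
        fit.branch_lengths = tree.branch_lengths()
        res = site_posteriors(fit, tree, ca)
        # independent arithmetic from the exhaustive per-class likelihoods
        for site in range(3):
            sub = CodonAlignment(taxa=ca.taxa,
                                 rows=[r[3*site:3*site+3] for r in ca.rows])
            class_likes = [np.exp(exhaustive_loglik(tree, sub, 2.0, [(1.0, wb, wf)],
                                                    freqs.pi,
                                                    factor_classes=classes))
                           for _, wb, wf in classes]
            weights = [p * l for (p, _, _), l in zip(classes, class_likes)]
            want = weights[2] / sum(weights)
            assert res[site].posterior == pytest.approx(want, abs=1e-8)

    def test_original_coordinates_after_cleaning(self, small_m0_alignment, rng):
        from test_alignment import inject_gaps
        from orthoselect.alignment import clean_columns
        gapped = inject_gaps(small_m0_alignment, rng, rate=0.05)
        cleaned = clean_columns(gapped)
        tree = default_tree(5)
        fit = fit_model(tree, cleaned, "M2a", seed=0, n_starts=1, max_iter=20)
        res = site_posteriors(fit, tree, cleaned)
        assert [r.site for r in res] == cleaned.site_map

    def test_rejected_models_and_methods(self, five_taxon_tree, small_m0_alignment):
        fit = fit_model(five_taxon_tree, small_m0_alignment, "M1a", seed=0,
                        n_starts=1, max_iter=3)
        with pytest.raises(ValueError, match="positive"):
            site_posteriors(fit, five_taxon_tree, small_m0_alignment)
        m2a = fit_model(five_taxon_tree, small_m0_alignment, "M2a", seed=0,
                        n_starts=1, max_iter=3)
        with pytest.raises(NotImplementedError):
            site_posteriors(m2a, five_taxon_tree, small_m0_alignment, method="BEB")


class TestFrequencies:
    def test_f3x4_sums_to_one_and_positive(self, small_m0_alignment):
        for method in ("F3x4", "F1x4", "F61", "equal"):
            f = compute_frequencies(small_m0_alignment, method)
            assert f.pi.sum() == pytest.approx(1.0)
            assert f.pi.min() > 0
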
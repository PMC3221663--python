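import numpy as np
import pytest
from scipy import stats

from gpcrsel._codons import N_CODONS, SENSE_CODONS, SINGLE_STEP
from gpcrsel.codon_alignment import CodonAlignment
from gpcrsel.phylogeny import Tree
from gpcrsel.site_models import (
    ConvergenceError,
    ModelError,
    PruningEngine,
    SpectralQ,
    build_rate_matrix,
    codon_frequencies,
    discretize_beta,
    equal_frequencies,
    fit_model,
    fit_nested_pair,
    fixed_sites_fit,
    likelihood_ratio_test,
    mixture_rate_matrices,
    neb_site_report,
    transition_probabilities,
)
from gpcrsel.synthetic_data import SimulationConfig, simulate_codon_alignment


def random_pi(rng):
    pi = rng.dirichlet(np.full(N_CODONS, 5.0))
    return pi / pi.sum()


class TestRateMatrix:
    def test_neutral_equal_frequency_rates_follow_adjacency(self):
        pi = equal_frequencies()
        Q = build_rate_matrix(1.0, 1.0, pi)
        off = Q[~np.eye(N_CODONS, dtype=bool)]
        allowed = SINGLE_STEP[~np.eye(N_CODONS, dtype=bool)]
        assert np.all(off[~allowed] == 0)
        vals = off[allowed]
        assert np.allclose(vals, vals[0])

    def test_generator_rows_sum_to_zero_and_pi_is_stationary(self, rng):
        pi = random_pi(rng)
        Q = build_rate_matrix(2.3, 0.4, pi)
        assert np.abs(Q.sum(axis=1)).max() < 1e-12
        assert np.abs(pi @ Q).max() < 1e-12
        assert -np.sum(pi * np.diag(Q)) == pytest.approx(1.0)

    def test_detailed_balance_over_random_draws(self, rng):
        for _ in range(100):
            pi = random_pi(rng)
            kappa = float(rng.uniform(0.2, 10))
            omega = float(rng.uniform(0.01, 5))
            Q = build_rate_matrix(kappa, omega, pi)
            flux = pi[:, None] * Q
            assert np.abs(flux - flux.T).max() < 1e-12

    def test_domain_errors(self):
        pi = equal_frequencies()
        with pytest.raises(ModelError):
            build_rate_matrix(-1.0, 0.5, pi)
        with pytest.raises(ModelError):
            build_rate_matrix(2.0, -0.5, pi)

    def test_mixture_scaling_averages_to_unit_rate(self, rng):
        pi = random_pi(rng)
        props = np.array([0.6, 0.3, 0.1])
        omegas = np.array([0.05, 1.0, 4.0])
        Qs = mixture_rate_matrices(2.0, omegas, props, pi)
        rates = np.array([-np.sum(pi * np.diag(Q)) for Q in Qs])
        assert props @ rates == pytest.approx(1.0)
        assert rates[2] > rates[1] > rates[0]


class TestTransitionProbabilities:
    def test_zero_time_is_identity(self, rng):
        pi = random_pi(rng)
        Q = build_rate_matrix(2.0, 0.5, pi)
        P = transition_probabilities(Q, 0.0, pi)
        assert np.allclose(P, np.eye(N_CODONS), atol=1e-12)

    def test_long_time_reaches_stationarity(self, rng):
        pi = random_pi(rng)
        Q = build_rate_matrix(2.0, 0.5, pi)
        P = transition_probabilities(Q, 500.0, pi)
        assert np.allclose(P, np.tile(pi, (N_CODONS, 1)), atol=1e-8)

    def test_semigroup_property(self, rng):
        for _ in range(5):
            pi = random_pi(rng)
            Q = build_rate_matrix(float(rng.uniform(1, 5)), float(rng.uniform(0.1, 2)), pi)
            sq = SpectralQ(Q, pi)
            t1, t2 = rng.uniform(0.05, 1.0, size=2)
            P12 = sq.transition(t1) @ sq.transition(t2)
            assert np.abs(P12 - sq.transition(t1 + t2)).max() < 1e-8

    def test_negative_time_rejected(self, rng):
        pi = random_pi(rng)
        Q = build_rate_matrix(2.0, 0.5, pi)
        with pytest.raises(ModelError):
            transition_probabilities(Q, -0.1, pi)


def brute_force_quartet_likelihood(tree, states, spectral):
    """Explicit enumeration over internal-node states of a quartet.

    Each root subtree contributes a factor: a leaf child gives P(x -> s);
    an internal child sums over its own state y. Written directly from the
    tree structure without the pruning recursion.
    """
    root = tree.root
    P = {id(n): spectral.transition(n.length) for n in tree.edges()}

    def subtree_factor(child, x):
        if child.is_leaf:
            return P[id(child)][x, states[child.name]]
        total = 0.0
        for y in range(N_CODONS):
            term = P[id(child)][x, y]
            for g in child.children:
                assert g.is_leaf
                term *= P[id(g)][y, states[g.name]]
            total += term
        return total

    total = 0.0
    for x in range(N_CODONS):
        val = spectral.pi[x]
        for c in root.children:
            val *= subtree_factor(c, x)
        total += val
    return total


class TestPruning:
    def _engine(self, columns, tree):
        labels = tree.leaf_names()
        codons = np.array(
            [[SENSE_CODONS[col[l]] for col in columns] for l in labels], dtype="<U3"
        )
        aln = CodonAlignment(labels, codons)
        return PruningEngine(aln.integer_matrix(), labels, tree)

    def test_matches_enumeration_on_quartet(self, quartet_tree, rng):
        labels = quartet_tree.leaf_names()
        for _ in range(5):
            pi = random_pi(rng)
            Q = build_rate_matrix(float(rng.uniform(1, 4)), float(rng.uniform(0.05, 3)), pi)
            sq = SpectralQ(Q, pi)
            cols = [
                {l: int(rng.integers(N_CODONS)) for l in labels} for _ in range(6)
            ]
            engine = self._engine(cols, quartet_tree)
            lengths = {id(e): e.length for e in quartet_tree.edges()}
            like, scale = engine.pattern_likelihoods(sq, lengths)
            got = like * np.exp(scale)
            expanded = got[engine.pattern_index]
            for k, col in enumerate(cols):
                expected = brute_force_quartet_likelihood(quartet_tree, col, sq)
                assert expanded[k] == pytest.approx(expected, rel=1e-8)

    def test_all_gap_column_contributes_likelihood_one(self, quartet_tree):
        labels = quartet_tree.leaf_names()
        codons = np.array([["---", "ATG"] for _ in labels], dtype="<U3")
        aln = CodonAlignment(labels, codons)
        engine = PruningEngine(aln.integer_matrix(), labels, quartet_tree)
        pi = equal_frequencies()
        sq = SpectralQ(build_rate_matrix(2.0, 0.5, pi), pi)
        lengths = {id(e): e.length for e in quartet_tree.edges()}
        like, scale = engine.pattern_likelihoods(sq, lengths)
        expanded = (like * np.exp(scale))[engine.pattern_index]
        assert expanded[0] == pytest.approx(1.0, rel=1e-12)

    def test_likelihood_invariant_under_rerooting(self, rng):
        # same unrooted quartet written with two different root placements
        t1 = Tree.from_newick("((a:0.2,b:0.3):0.1,(c:0.25,d:0.15):0.12);")
        t2 = Tree.from_newick("(a:0.2,b:0.3,(c:0.25,d:0.15):0.22);")
        pi = random_pi(rng)
        states = {l: int(rng.integers(N_CODONS)) for l in "abcd"}
        lnls = []
        for tree in (t1, t2):
            labels = tree.leaf_names()
            codons = np.array([[SENSE_CODONS[states[l]]] for l in labels], dtype="<U3")
            engine = PruningEngine(
                CodonAlignment(labels, codons).integer_matrix(), labels, tree
            )
            ll = engine.class_log_likelihoods(
                2.0, np.array([0.5]), pi, {id(e): e.length for e in tree.edges()}
            )
            lnls.append(engine.mixture_lnl(np.array([1.0]), ll))
        assert lnls[0] == pytest.approx(lnls[1], abs=1e-8)


class TestBetaDiscretization:
    def test_uniform_gives_decile_midpoints(self):
        props, omegas = discretize_beta(1.0, 1.0)
        assert np.allclose(props, 0.1)
        assert np.allclose(omegas, np.arange(0.05, 1.0, 0.1), atol=1e-10)

    def test_symmetric_beta_symmetric_categories(self):
        _, omegas = discretize_beta(2.0, 2.0)
        assert np.allclose(omegas + omegas[::-1], 1.0, atol=1e-9)

    @pytest.mark.parametrize("p,q", [(0.3, 1.7), (2.0, 5.0), (8.0, 1.5)])
    def test_category_means_preserve_the_beta_mean(self, p, q):
        props, omegas = discretize_beta(p, q)
        assert props @ omegas == pytest.approx(p / (p + q), abs=1e-10)
        assert np.all(np.diff(omegas) > 0)
        assert np.all((omegas > 0) & (omegas < 1))

    def test_category_means_match_numeric_integration(self):
        p, q = 2.0, 3.0
        props, omegas = discretize_beta(p, q)
        edges = stats.beta.ppf(np.linspace(0, 1, 11), p, q)
        for k in range(10):
            grid = np.linspace(edges[k], edges[k + 1], 4001)
            dens = stats.beta.pdf(grid, p, q)
            mean_k = np.trapezoid(grid * dens, grid) / np.trapezoid(dens, grid)
            assert omegas[k] == pytest.approx(mean_k, abs=1e-5)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ModelError):
            discretize_beta(0.0, 1.0)


class TestLikelihoodRatioTest:
    def test_reference_delta_values_meet_their_bounds(self):
        res = likelihood_ratio_test(0.0, 8.90, df=2)
        assert res.lr == pytest.approx(17.8)
        assert res.p_value == pytest.approx(np.exp(-8.90), rel=1e-9)
        assert res.p_value < 5.0e-4
        res2 = likelihood_ratio_test(0.0, 8.94, df=2)
        assert res2.p_value == pytest.approx(np.exp(-8.94), rel=1e-9)
        assert res2.p_value < 5.0e-4

    def test_zero_delta_keeps_the_null(self):
        res = likelihood_ratio_test(-100.0, -100.0, df=2, null_model="M1a", alt_model="M2a")
        assert res.p_value == 1.0
        assert res.tenable_model == "M1a"

    def test_negative_delta_flags_optimizer_failure(self):
        with pytest.raises(ConvergenceError):
            likelihood_ratio_test(-10.0, -10.1, df=2)


@pytest.fixture(scope="module")
def m1a_alignment():
    config = SimulationConfig(
        n_taxa=4,
        n_codons=190,
        site_classes=[(0.8, 0.2), (0.2, 1.0)],
        seed=5,
        tree_height=0.5,
    )
    return simulate_codon_alignment(config)


class TestFitting:
    def test_m0_recovers_simulated_omega(self, small_m0_alignment):
        alignment, _, tree = small_m0_alignment
        fit = fit_model(alignment, tree, "M0", n_restarts=1, seed=0)
        assert fit.parameters["omega"] == pytest.approx(0.3, abs=0.08)
        assert fit.converged and np.isfinite(fit.lnl)
        # single-class NEB: posterior 1 everywhere, profile constant
        assert np.allclose(fit.posteriors, 1.0)
        assert np.allclose(fit.neb_omega, fit.parameters["omega"])

    def test_nested_models_never_lose_likelihood(self, m1a_alignment):
        alignment, _, tree = m1a_alignment
        n1, a1, lrt1 = fit_nested_pair(
            alignment, tree, "M1a", "M2a", df=2, n_restarts=1, seed=0
        )
        assert max(a1.lnl, n1.lnl) >= n1.lnl - 1e-6
        assert lrt1.delta >= 0
        n4, a4, lrt4 = fit_nested_pair(
            alignment, tree, "M0", "M3", df=4, n_restarts=1, seed=0
        )
        assert lrt4.delta >= 0

    def test_m2a_on_null_data_collapses_positive_class(self, m1a_alignment):
        alignment, _, tree = m1a_alignment
        fit = fit_model(alignment, tree, "M2a", n_restarts=2, seed=0)
        p2, w2 = fit.parameters["p2"], fit.parameters["omega2"]
        assert p2 < 0.1 or w2 < 1.3
        rows = fit.posteriors.sum(axis=1)
        assert np.allclose(rows, 1.0, atol=1e-8)
        assert np.all(fit.neb_omega >= fit.omegas.min() - 1e-9)
        assert np.all(fit.neb_omega <= fit.omegas.max() + 1e-9)

    def test_fit_requires_three_sequences(self, m1a_alignment):
        alignment, _, tree = m1a_alignment
        two = alignment.subset(alignment.labels[:2])
        with pytest.raises(ModelError):
            fit_model(two, tree, "M0")

    def test_frequency_schemes_are_valid_distributions(self, m1a_alignment):
        alignment, _, _ = m1a_alignment
        m = alignment.integer_matrix()
        for scheme in ("equal", "F1x4", "F3x4", "F61"):
            pi = codon_frequencies(m, scheme)
            assert pi.shape == (N_CODONS,)
            assert pi.sum() == pytest.approx(1.0)
            assert np.all(pi > 0)
        with pytest.raises(ModelError):
            codon_frequencies(m, "F9x9")


class TestFixedSites:
    def test_homogeneous_data_keeps_model_a(self, small_m0_alignment):
        alignment, _, tree = small_m0_alignment
        key_columns = list(range(1, 11))
        fit_a, fit_b, lrt = fixed_sites_fit(
            alignment, tree, key_columns, n_restarts=1, seed=0
        )
        assert fit_b.lnl >= fit_a.lnl - 1e-6
        assert lrt.tenable_model == "FS-A"
        wk, wr = fit_b.parameters["omega_key"], fit_b.parameters["omega_rest"]
        assert wk == pytest.approx(wr, rel=0.8)

    def test_distinct_key_pressure_detected(self):
        forced = {c: 0.02 for c in range(1, 11)}
        config = SimulationConfig(
            n_taxa=5,
            n_codons=190,
            site_classes=[(1.0, 0.4)],
            forced_columns=forced,
            seed=9,
            tree_height=0.6,
        )
        alignment, _, tree = simulate_codon_alignment(config)
        fit_a, fit_b, lrt = fixed_sites_fit(
            alignment, tree, list(range(1, 11)), n_restarts=1, seed=0
        )
        assert fit_b.parameters["omega_key"] < fit_b.parameters["omega_rest"]
        assert lrt.tenable_model == "FS-B"
        assert lrt.p_value < 0.05

    def test_empty_partition_rejected(self, m1a_alignment):
        alignment, _, tree = m1a_alignment
        with pytest.raises(ModelError):
            fixed_sites_fit(alignment, tree, [])


class TestNebReport:
    def test_report_layout_and_calls(self, m1a_alignment):
        alignment, _, tree = m1a_alignment
        fit = fit_model(alignment, tree, "M1a", n_restarts=1, seed=0)
        from gpcrsel.synthetic_data import make_position_map

        report = neb_site_report(fit, make_position_map(alignment.column_count))
        assert len(report) == alignment.column_count
        assert set(report.columns) >= {
            "column_index",
            "bw_index",
            "is_key",
            "p_positive",
            "neb_omega",
            "call",
        }
        assert report["is_key"].sum() == 10
        # M1a has no positive class at all
        assert (report["p_positive"] == 0).all()
        assert (report["call"] == "-").all()
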
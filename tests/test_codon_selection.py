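"""Codon model construction, pruning likelihoods, fitting, LRT and NEB."""

import numpy as np
import pytest
from scipy.linalg import expm

from hetsel import codon_selection as cs
from hetsel.genetics import N_SENSE, SENSE_CODONS, SENSE_INDEX
from hetsel.io_annotation import CodonAlignment
from hetsel.phylogeny import read_newick
from hetsel.synthetic_data import (
    SimulationConfig,
    random_yule_tree,
    simulate_codon_alignment,
)

UNIFORM_PI = np.full(N_SENSE, 1.0 / N_SENSE)


class TestGenerator:
    def test_multi_nucleotide_changes_have_zero_rate(self):
        q = cs.build_generator(UNIFORM_PI, kappa=2.0, omega=0.5)
        i, j = SENSE_INDEX["ATG"], SENSE_INDEX["ACA"]  # two positions differ
        assert q[i, j] == 0.0
        assert q[SENSE_INDEX["AAA"], SENSE_INDEX["TTT"]] == 0.0

    def test_rows_sum_to_zero(self):
        q = cs.build_generator(UNIFORM_PI, kappa=3.0, omega=2.0)
        assert np.abs(q.sum(axis=1)).max() < 1e-12

    def test_detailed_balance_on_random_pairs(self):
        rng = np.random.default_rng(0)
        pi = rng.dirichlet(np.ones(N_SENSE))
        q = cs.build_generator(pi, kappa=2.5, omega=0.3)
        flux = pi[:, None] * q
        idx = rng.integers(0, N_SENSE, size=(100, 2))
        for i, j in idx:
            assert flux[i, j] == pytest.approx(flux[j, i], abs=1e-15)

    def test_invalid_frequencies_rejected(self):
        bad = np.zeros(N_SENSE)
        bad[0] = 1.0
        with pytest.raises(ValueError, match="positive distribution"):
            cs.build_generator(bad, kappa=2.0, omega=1.0)

    def test_transition_matrix_matches_scipy_expm(self):
        rng = np.random.default_rng(1)
        pi = rng.dirichlet(np.ones(N_SENSE))
        q = cs.build_generator(pi, kappa=2.0, omega=0.8)
        p_eig = cs.transition_matrix(q, pi, 0.37)
        p_ref = expm(q * 0.37)
        assert np.abs(p_eig - p_ref).max() < 1e-10


class TestSiteLikelihood:
    def test_zero_branch_lengths_identical_column_gives_pi(self):
        pt = read_newick("(A:0,B:0,C:0);")
        ca = CodonAlignment(("A", "B", "C"), ("ATG", "ATG", "ATG"))
        lik = cs.site_likelihoods(ca, pt, UNIFORM_PI, kappa=2.0, omega=0.5)
        assert lik[0] == pytest.approx(UNIFORM_PI[SENSE_INDEX["ATG"]])

    def test_matches_exhaustive_enumeration_on_four_taxa(self):
        """Pruning equals the brute-force 61^2 sum over internal states."""
        lens = {"A": 0.1, "B": 0.2, "C": 0.3, "D": 0.05, "U": 0.15}
        pt = read_newick("((A:0.1,B:0.2):0.15,C:0.3,D:0.05);")
        rows = ("ATG", "ATA", "CTG", "AAG")
        ca = CodonAlignment(("A", "B", "C", "D"), rows)
        kappa, omega = 2.0, 0.7
        got = cs.site_log_likelihoods(ca, pt, UNIFORM_PI, kappa, omega)

        q = cs.build_generator(UNIFORM_PI, kappa, omega)
        P = {k: cs.transition_matrix(q, UNIFORM_PI, t) for k, t in lens.items()}
        obs = {n: SENSE_INDEX[c] for n, c in zip(ca.names, rows)}
        total = 0.0
        for u in range(N_SENSE):
            for v in range(N_SENSE):
                total += (
                    UNIFORM_PI[v]
                    * P["U"][v, u]
                    * P["A"][u, obs["A"]]
                    * P["B"][u, obs["B"]]
                    * P["C"][v, obs["C"]]
                    * P["D"][v, obs["D"]]
                )
        assert abs(got[0] - np.log(total)) < 1e-8

    def test_invariant_under_leaf_reordering(self):
        pt = read_newick("((A:0.1,B:0.2):0.15,C:0.3,D:0.05);")
        rows = {"A": "ATGAAA", "B": "ATAAAG", "C": "CTGAAA", "D": "AAGAAA"}
        for order in (("A", "B", "C", "D"), ("D", "C", "B", "A")):
            ca = CodonAlignment(order, tuple(rows[n] for n in order))
            ll = cs.site_log_likelihoods(ca, pt, UNIFORM_PI, 2.0, 0.7)
            if order[0] == "A":
                ref = ll
        assert np.allclose(ll, ref)

    def test_name_mismatch_is_error(self):
        pt = read_newick("(A:0.1,B:0.2,X:0.3);")
        ca = CodonAlignment(("A", "B", "C"), ("ATG", "ATG", "ATG"))
        with pytest.raises(ValueError, match="X"):
            cs.site_log_likelihoods(ca, pt, UNIFORM_PI, 2.0, 0.5)


class TestMixtureStructure:
    def test_mixture_with_equal_classes_collapses_to_single_omega(self):
        """A 3-class mixture with all omegas equal is exactly M0."""
        spec = cs.CodonModelSpec.m0(omega=0.6, kappa=2.0)
        tree = random_yule_tree(5, seed=9, height=0.4)
        ca, _ = simulate_codon_alignment(
            SimulationConfig(spec=spec, n_codons=40, seed=9, tree=tree)
        )
        tidx = cs.TreeIndex(tree, ca.names)
        mat = cs.encode_alignment(ca)
        lens = tidx.initial_lengths
        single = cs._mixture_site_logliks(
            mat, tidx, lens, UNIFORM_PI, 2.0, np.array([1.0]), np.array([0.6])
        )
        mixed = cs._mixture_site_logliks(
            mat, tidx, lens, UNIFORM_PI, 2.0,
            np.array([0.2, 0.3, 0.5]), np.array([0.6, 0.6, 0.6]),
        )
        for k in range(3):
            assert np.allclose(mixed[k], single[0], atol=1e-10)

    def test_beta_categories_mean_and_support(self):
        for p, q in ((0.5, 1.5), (2.0, 2.0), (0.2, 0.3)):
            cats = cs.beta_categories(p, q, 10)
            assert cats.shape == (10,)
            assert np.all(np.diff(cats) >= 0)
            assert np.all((cats >= 0) & (cats <= 1))
            assert cats.mean() == pytest.approx(p / (p + q), rel=1e-6)


@pytest.fixture(scope="module")
def small_m2_data():
    spec = cs.CodonModelSpec.m2(p0=0.5, p1=0.3, omega0=0.1, omega2=3.0, kappa=2.0)
    tree = random_yule_tree(6, seed=21, height=0.5)
    ca, labels = simulate_codon_alignment(
        SimulationConfig(spec=spec, n_codons=150, seed=21, tree=tree)
    )
    return ca, labels, tree


class TestFitting:
    def test_preconditions(self, small_m2_data):
        ca, _, tree = small_m2_data
        tiny = CodonAlignment(ca.names[:2], ca.rows[:2])
        with pytest.raises(ValueError, match="at least 3"):
            cs.fit_model(tiny, tree, "M0")
        with pytest.raises(ValueError, match="unknown model"):
            cs.fit_model(ca, tree, "M99")

    def test_m0_recovers_omega_over_replicates(self):
        """Mean M0 estimate within 15% of the generating omega."""
        estimates = []
        for rep in range(5):
            spec = cs.CodonModelSpec.m0(omega=0.5, kappa=2.0)
            tree = random_yule_tree(12, seed=300 + rep, height=0.5)
            ca, _ = simulate_codon_alignment(
                SimulationConfig(spec=spec, n_codons=400, seed=400 + rep, tree=tree)
            )
            fit = cs.fit_model(ca, tree, "M0", branch_lengths="fixed", seed=1)
            estimates.append(fit.class_omegas[0])
        assert np.mean(estimates) == pytest.approx(0.5, rel=0.15)

    def test_nested_models_do_not_lose_likelihood(self, small_m2_data):
        ca, _, tree = small_m2_data
        fits = cs.fit_model_series(
            ca, tree, models=("M0", "M1", "M2", "M7", "M8"),
            seed=1, n_starts=1, reuse_m0_lengths=True,
        )
        tol = 1e-3  # numerical slack on the shared optimum
        assert fits["M2"].log_likelihood >= fits["M1"].log_likelihood - tol
        assert fits["M8"].log_likelihood >= fits["M7"].log_likelihood - tol
        assert fits["M2"].log_likelihood >= fits["M0"].log_likelihood - tol
        for fit in fits.values():
            assert fit.overall_omega == pytest.approx(
                float(np.dot(fit.class_proportions, fit.class_omegas))
            )
        assert fits["M1"].overall_omega <= 1.0 + 1e-9

    def test_branch_length_mode_validated(self, small_m2_data):
        ca, _, tree = small_m2_data
        with pytest.raises(ValueError, match="branch_lengths"):
            cs.fit_model(ca, tree, "M0", branch_lengths="frozen")


class TestLikelihoodRatio:
    def _fake_fit(self, model, lnl):
        return cs.FitResult(
            model=model, log_likelihood=lnl, kappa=2.0,
            class_proportions=np.array([1.0]), class_omegas=np.array([0.5]),
            parameters={}, codon_frequencies=UNIFORM_PI, tree=None,
            branch_lengths=np.array([]), overall_omega=0.5, converged=True,
            n_evaluations=0,
        )

    def test_equal_likelihoods_give_unit_p(self):
        r = cs.likelihood_ratio_test(self._fake_fit("M1", -10.0),
                                     self._fake_fit("M2", -10.0))
        assert r.statistic == 0.0 and r.p_value == 1.0

    def test_chi2_closed_form(self):
        # 2 df: p = exp(-x/2); statistic 9.21 -> p ~ 0.0100
        r = cs.likelihood_ratio_test(self._fake_fit("M1", 0.0),
                                     self._fake_fit("M2", 9.21 / 2.0))
        assert r.p_value == pytest.approx(np.exp(-9.21 / 2.0), rel=1e-12)
        assert r.p_value == pytest.approx(0.01, abs=2e-4)

    def test_worse_alternative_is_an_optimization_error(self):
        with pytest.raises(cs.ConvergenceError, match="lower lnL"):
            cs.likelihood_ratio_test(self._fake_fit("M1", -10.0),
                                     self._fake_fit("M2", -11.0))


class TestNeb:
    def test_rejected_for_models_without_selection_class(self, small_m2_data):
        ca, _, tree = small_m2_data
        fit = cs.fit_model(ca, tree, "M1", branch_lengths="fixed", seed=1,
                           n_starts=1)
        with pytest.raises(ValueError, match="no omega > 1 class"):
            cs.neb_sites(fit, ca)

    def test_posteriors_sum_to_one_and_flag_true_sites(self, small_m2_data):
        ca, labels, tree = small_m2_data
        fit = cs.fit_model(ca, tree, "M2", branch_lengths="fixed", seed=1,
                           n_starts=1)
        neb = cs.neb_sites(fit, ca)
        post = neb[[c for c in neb.columns if c.startswith("p_class")]].to_numpy()
        assert np.abs(post.sum(axis=1) - 1.0).max() < 1e-10
        flagged = cs.positively_selected_sites(neb, 0.95)
        if flagged:  # precision above the class-2 base rate
            true_pos = set(np.where(labels == 2)[0] + 1)
            precision = len(set(flagged) & true_pos) / len(flagged)
            assert precision > (labels == 2).mean()
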
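"""Codon-model numerics: back-translation, NG86, rate matrices, likelihood, LRT."""

import math

import numpy as np
import pytest

from _likelihood_oracle import (
    loglik_by_enumeration,
    random_small_alignment,
    random_small_params,
)
from symscreen.errors import BacktranslationError, InputError
from symscreen.io_formats import SequenceRecord, parse_newick
from symscreen import codon_evolution as ce
from symscreen.synthetic_data import default_pi, simulate_codon_alignment


class TestGeneticCode:
    def test_61_sense_3_stop(self):
        code = ce.STANDARD_CODE
        assert len(code.sense_codons) == 61
        assert code.stop_codons == {"TAA", "TAG", "TGA"}

    def test_translation(self):
        assert ce.STANDARD_CODE.translate("ATG") == "M"
        assert ce.STANDARD_CODE.translate("TAA") == "*"


class TestCodonAlignment:
    def test_partial_codon_gap_rejected(self):
        with pytest.raises(InputError, match="partial-codon"):
            ce.CodonAlignment({"a": "A-G"})

    def test_internal_stop_rejected(self):
        with pytest.raises(InputError, match="stop"):
            ce.CodonAlignment({"a": "ATGTAACCC"})

    def test_unequal_rows_rejected(self):
        with pytest.raises(InputError):
            ce.CodonAlignment({"a": "ATG", "b": "ATGCCC"})


class TestBacktranslate:
    def test_gap_becomes_codon_gap(self):
        aln = ce.backtranslate(
            [SequenceRecord("x", "M-F", kind="aligned_protein")],
            {"x": "ATGTTT"},
        )
        assert aln.rows["x"] == "ATG---TTT"

    def test_terminal_stop_stripped(self):
        aln = ce.backtranslate(
            [SequenceRecord("x", "M", kind="aligned_protein")], {"x": "ATGTAA"}
        )
        assert aln.rows["x"] == "ATG"

    def test_internal_stop_is_error(self):
        with pytest.raises(BacktranslationError, match="stop"):
            ce.backtranslate(
                [SequenceRecord("x", "MF", kind="aligned_protein")],
                {"x": "ATGTAATTT"},
            )

    def test_mismatch_names_sequence_and_position(self):
        with pytest.raises(BacktranslationError, match="x.*residue 1"):
            ce.backtranslate(
                [SequenceRecord("x", "MM", kind="aligned_protein")],
                {"x": "ATGTTT"},
            )

    def test_x_matches_anything(self):
        aln = ce.backtranslate(
            [SequenceRecord("x", "MX", kind="aligned_protein")], {"x": "ATGTTT"}
        )
        assert aln.rows["x"] == "ATGTTT"


class TestNG86:
    def test_identical_sequences(self):
        r = ce.ng86_pairwise("ATGTTTAAA", "ATGTTTAAA")
        assert r.dN == 0.0 and r.dS == 0.0 and r.omega is None

    def test_single_nonsynonymous_change(self):
        a = "ATG" + "TTT" * 99
        b = "CTG" + "TTT" * 99  # M->L, nonsynonymous
        r = ce.ng86_pairwise(a, b)
        assert r.dS == 0.0 and r.dN > 0.0 and r.omega is None

    def test_site_counts_total_three_per_codon(self):
        r = ce.ng86_pairwise("ATGTTTAAACCC", "ATGTTTAAACCC")
        assert r.S_sites + r.N_sites == pytest.approx(3 * r.n_codons)

    def test_gapped_and_stop_columns_skipped(self):
        r = ce.ng86_pairwise("ATG---TTT", "ATGCCCTTT")
        assert r.n_codons == 2

    def test_zero_comparable_codons_rejected(self):
        with pytest.raises(InputError):
            ce.ng86_pairwise("---", "ATG")


class TestRateMatrix:
    def setup_method(self):
        self.pi = default_pi(0.5)

    def test_omega_zero_kills_nonsynonymous_rates(self):
        from symscreen.codon_evolution import _NONSYN

        q = ce.build_rate_matrix(2.0, 0.0, self.pi)
        assert np.all(q[_NONSYN] == 0.0)

    def test_rows_sum_to_zero(self):
        q = ce.build_rate_matrix(2.0, 0.5, self.pi)
        assert np.allclose(q.sum(axis=1), 0.0, atol=1e-14)

    def test_detailed_balance(self):
        q = ce.build_rate_matrix(3.0, 0.3, self.pi)
        flux = self.pi[:, None] * q
        assert np.allclose(flux, flux.T, atol=1e-15)

    def test_transition_matrix_rows_and_identity(self, rng):
        for _ in range(25):
            kappa = rng.uniform(0.5, 8)
            omega = rng.uniform(0.01, 5)
            t = rng.uniform(0, 50)
            p = ce.transition_matrix(kappa, omega, self.pi, t)
            assert np.allclose(p.sum(axis=1), 1.0, atol=1e-10)
            assert np.all(p >= 0)
        p0 = ce.transition_matrix(2.0, 0.5, self.pi, 0.0)
        assert np.allclose(p0, np.eye(61), atol=1e-12)

    def test_stationarity_of_pi(self):
        p = ce.transition_matrix(2.0, 0.5, self.pi, 3.0)
        assert np.allclose(self.pi @ p, self.pi, atol=1e-12)

    def test_eigendecomposition_expm_matches_scipy(self, rng):
        from scipy.linalg import expm

        for _ in range(10):
            kappa = rng.uniform(0.5, 6)
            omega = rng.uniform(0.02, 3)
            t = rng.uniform(0.01, 5)
            q = ce.build_rate_matrix(kappa, omega, self.pi)
            scale = ce.substitution_rate(q, self.pi)
            fast = ce.transition_matrix(kappa, omega, self.pi, t, scale=scale)
            slow = expm(q * (t / scale))
            assert np.max(np.abs(fast - slow)) < 1e-11


class TestBranchSiteLoglik:
    def test_no_substitution_limit(self):
        tree = parse_newick("((A:0,B:0):0,C:0);")
        params = ce.BranchSiteParams(kappa=2.0, omega0=0.5, pi=default_pi())
        codon = "ATG"
        aln = ce.CodonAlignment({t: codon * 4 for t in "ABC"})
        ll = ce.branch_site_loglik(aln, tree, params, "M0")
        idx = ce.STANDARD_CODE.codon_index[codon]
        assert ll == pytest.approx(4 * math.log(params.pi[idx]), abs=1e-9)

    def test_matches_enumeration_small_cases(self, rng):
        trees = [
            "((A:0.2,B:0.4):0.1,C:0.3);",
            "(A:0.2,B:0.1,C:0.3);",
            "((A:0.15,B:0.2)#1:0.3,(C:0.1,D:0.4):0.2);",
        ]
        for newick in trees:
            tree = parse_newick(newick)
            for model in ("M0", "bs_null", "bs_alt"):
                params = random_small_params(rng, model)
                aln = random_small_alignment(rng, tree.tip_labels, 3)
                fast = ce.branch_site_loglik(aln, tree, params, model)
                slow = loglik_by_enumeration(aln, tree, params, model)
                assert fast == pytest.approx(slow, abs=1e-10)

    def test_rerooting_invariance_without_foreground(self, rng):
        # the same unrooted metric tree written with two different rootings
        t1 = parse_newick("((A:0.1,B:0.2):0.06,(C:0.3,D:0.4):0.06);")
        t2 = parse_newick("(A:0.1,(B:0.2,(C:0.3,D:0.4):0.12):0.0);")
        params = random_small_params(rng, "M0")
        aln = random_small_alignment(rng, ["A", "B", "C", "D"], 5, gap_rate=0)
        for model in ("M0",):
            l1 = ce.branch_site_loglik(aln, t1, params, model)
            l2 = ce.branch_site_loglik(aln, t2, params, model)
            assert l1 == pytest.approx(l2, abs=1e-8)

    def test_no_foreground_equals_enumeration(self, rng):
        # branch-site mixture with no marked branch is still a valid mixture
        tree = parse_newick("((A:0.2,B:0.4):0.1,C:0.3);")
        params = random_small_params(rng, "bs_alt")
        aln = random_small_alignment(rng, tree.tip_labels, 3)
        fast = ce.branch_site_loglik(aln, tree, params, "bs_alt")
        slow = loglik_by_enumeration(aln, tree, params, "bs_alt")
        assert fast == pytest.approx(slow, abs=1e-10)

    def test_missing_alignment_row_rejected(self):
        tree = parse_newick("((A:1,B:1):1,C:1);")
        aln = ce.CodonAlignment({"A": "ATG", "B": "ATG"})
        with pytest.raises(InputError):
            ce.branch_site_loglik(aln, tree, ce.BranchSiteParams(2.0, 0.5), "M0")


class TestFitModel:
    def make_data(self, seed=4, n_codons=150):
        from symscreen.synthetic_data import SimulationConfig, simulate_tree

        cfg = SimulationConfig(seed=seed, n_taxa=5, focal_clade_size=2, n_codons=n_codons)
        tree = simulate_tree(cfg)
        aln, _ = simulate_codon_alignment(
            tree, cfg.params("bs_null"), n_codons, model="bs_null", seed=seed
        )
        return tree, aln

    def test_refit_same_seed_bit_identical(self):
        tree, aln = self.make_data()
        opts = ce.FitOptions(n_starts=2, seed=9, branch_mode="scale")
        f1 = ce.fit_model(aln, tree, "M0", opts)
        f2 = ce.fit_model(aln, tree, "M0", opts)
        assert f1.loglik == f2.loglik
        assert f1.params.kappa == f2.params.kappa
        assert np.array_equal(f1.branch_lengths, f2.branch_lengths)

    def test_nesting_alt_at_least_null(self):
        tree, aln = self.make_data()
        opts = ce.FitOptions(n_starts=1, branch_mode="scale")
        m0 = ce.fit_model(aln, tree, "M0", opts)
        null = ce.fit_model(
            aln, tree, "bs_null", opts, branch_lengths=m0.branch_lengths, init=m0.params
        )
        alt = ce.fit_model(
            aln, tree, "bs_alt", opts, branch_lengths=m0.branch_lengths, init=null.params
        )
        assert alt.loglik >= null.loglik - 1e-6
        assert 2 * (alt.loglik - null.loglik) < 15  # null data: no huge signal

    def test_bs_model_requires_foreground_mark(self):
        tree, aln = self.make_data()
        unmarked = tree.copy()
        for node in unmarked.postorder():
            node.foreground = False
        with pytest.raises(InputError, match="foreground"):
            ce.fit_model(aln, unmarked, "bs_null")

    def test_fitted_tree_carries_lengths(self):
        tree, aln = self.make_data()
        fit = ce.fit_model(aln, tree, "M0", ce.FitOptions(n_starts=1, branch_mode="scale"))
        fitted = fit.fitted_tree(tree)
        assert [n.length for n in fitted.postorder()] == list(fit.branch_lengths)


class TestLRT:
    def make_fit(self, ll, converged=True):
        return ce.FitResult(
            model="bs_null",
            loglik=ll,
            params=ce.BranchSiteParams(2.0, 0.5),
            converged=converged,
            n_restarts_used=1,
            branch_lengths=np.zeros(3),
        )

    def test_equal_likelihoods(self):
        r = ce.likelihood_ratio_test(self.make_fit(-10.0), self.make_fit(-10.0))
        assert r.stat == 0.0 and r.p == 1.0

    def test_critical_value_of_chi2_1(self):
        r = ce.likelihood_ratio_test(self.make_fit(-10.0), self.make_fit(-10.0 + 3.841459 / 2))
        # independent chi2(1) survival function: erfc(sqrt(x/2))
        assert r.p == pytest.approx(math.erfc(math.sqrt(3.841459 / 2)), abs=1e-12)
        assert r.p == pytest.approx(0.05, abs=1e-6)

    def test_negative_difference_clamped(self):
        r = ce.likelihood_ratio_test(self.make_fit(-10.0), self.make_fit(-10.0001))
        assert r.stat == 0.0 and r.p == 1.0

    def test_unconverged_skipped(self):
        r = ce.likelihood_ratio_test(
            self.make_fit(-10.0, converged=False), self.make_fit(-9.0)
        )
        assert r.skipped and math.isnan(r.p)

    def test_mixture_null_halves_tail(self):
        a, b = self.make_fit(-10.0), self.make_fit(-8.0)
        plain = ce.likelihood_ratio_test(a, b)
        mixed = ce.likelihood_ratio_test(a, b, mixture=True)
        assert mixed.p == pytest.approx(plain.p / 2)


class TestFrequencies:
    def test_f3x4_sums_to_one_and_positive(self, rng):
        aln = random_small_alignment(rng, ["a", "b", "c"], 50, gap_rate=0.05)
        pi = ce.f3x4_frequencies(aln)
        assert pi.sum() == pytest.approx(1.0)
        assert np.all(pi > 0)

    def test_equal_frequencies(self):
        pi = ce.equal_frequencies()
        assert np.allclose(pi, 1 / 61)
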
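import itertools

import numpy as np
import pytest

from ratelink.likelihood import (
    FitResult,
    PruningEngine,
    compress_patterns,
    fit_linked,
    fit_unlinked,
    information_criteria,
    morphology_loglik,
    nucleotide_loglik,
    optimize_branch_lengths,
)
from ratelink.models import MorphModelParams, NucModelParams
from ratelink.synthetic import (
    MISSING,
    Alignment,
    CharacterMatrix,
    ScenarioSpec,
    generate_scenario_pair,
    simulate_alignment,
    simulate_characters,
)
from ratelink.trees import load_phylogram

from conftest import JC_LIKE


def brute_force_loglik(top, edge, states, model):
    """Exhaustive sum over all internal-node state assignments."""
    k = model.freqs.shape[0]
    cats = model.category_rates()
    pi = model.freqs
    pinv = getattr(model, "p_inv", 0.0)
    internals = [v for v in range(top.n_nodes) if v >= top.n_tips]
    out = 0.0
    for site in range(states.shape[1]):
        col = states[:, site]
        tot = 0.0
        for r in cats:
            P = model.transition_probs(edge * r)
            for assign in itertools.product(range(k), repeat=len(internals)):
                st = dict(zip(internals, assign))
                for t in range(top.n_tips):
                    st[t] = col[t]
                pr = pi[st[top.root]]
                for v in range(top.n_nodes):
                    p = top.parent[v]
                    if p >= 0:
                        pr *= P[v][st[p], st[v]]
                tot += pr / len(cats)
        tot *= 1 - pinv
        obs = col[col != MISSING]
        if len(obs) == len(col) and np.all(col == col[0]):
            tot += pinv * pi[col[0]]
        out += np.log(tot)
    return out


class TestPruningOracle:
    def test_zero_distance_identical_single_site(self):
        phy = load_phylogram("(A:0,B:0);")
        aln = Alignment(("A", "B"), np.zeros((2, 1), dtype=np.int8))
        lnl = nucleotide_loglik(phy.topology, phy.edge_lengths, aln, JC_LIKE)
        assert lnl == pytest.approx(np.log(0.25))

    def test_matches_brute_force_gtr(self, four_taxon_phylogram, rng):
        top = four_taxon_phylogram.topology
        model = NucModelParams()
        states = rng.integers(0, 4, size=(4, 3))
        lnl = nucleotide_loglik(top, four_taxon_phylogram.edge_lengths,
                                Alignment(top.labels, states), model)
        oracle = brute_force_loglik(top, four_taxon_phylogram.edge_lengths, states, model)
        assert lnl == pytest.approx(oracle, abs=1e-10)

    def test_matches_brute_force_five_taxa(self, five_taxon_phylogram, rng):
        top = five_taxon_phylogram.topology
        model = NucModelParams(gamma_shape=0.8, p_inv=0.1)
        states = rng.integers(0, 4, size=(5, 3))
        lnl = nucleotide_loglik(top, five_taxon_phylogram.edge_lengths,
                                Alignment(top.labels, states), model)
        oracle = brute_force_loglik(top, five_taxon_phylogram.edge_lengths, states, model)
        assert lnl == pytest.approx(oracle, abs=1e-10)

    def test_matches_brute_force_mk(self, four_taxon_phylogram, rng):
        top = four_taxon_phylogram.topology
        model = MorphModelParams(2)
        states = rng.integers(0, 2, size=(4, 2))
        lnl = morphology_loglik(top, four_taxon_phylogram.edge_lengths,
                                CharacterMatrix(top.labels, states, 2), model)
        oracle = brute_force_loglik(top, four_taxon_phylogram.edge_lengths, states, model)
        assert lnl == pytest.approx(oracle, abs=1e-10)

    def test_missing_data_marginalized(self, four_taxon_phylogram):
        top = four_taxon_phylogram.topology
        model = MorphModelParams(2)
        # a fully missing row marginalizes: summing the two resolutions
        with_missing = np.array([[0], [1], [MISSING], [0]], dtype=np.int8)
        lnl = morphology_loglik(top, four_taxon_phylogram.edge_lengths,
                                CharacterMatrix(top.labels, with_missing, 2), model)
        parts = []
        for s in (0, 1):
            resolved = with_missing.copy()
            resolved[2] = s
            parts.append(brute_force_loglik(top, four_taxon_phylogram.edge_lengths,
                                            resolved, model))
        assert lnl == pytest.approx(np.logaddexp(*parts), abs=1e-10)

    def test_rerooting_invariance(self, rng):
        # same unrooted tree, two root placements
        t1 = load_phylogram("((A:0.12,B:0.3):0.08,(C:0.5,D:0.02):0.2);")
        t2 = load_phylogram("(A:0.05,(B:0.3,(C:0.5,D:0.02):0.28):0.07);")
        model = NucModelParams(gamma_shape=0.7, p_inv=0.15)
        states = rng.integers(0, 4, size=(4, 20))
        aln = Alignment(("A", "B", "C", "D"), states)
        l1 = nucleotide_loglik(t1.topology, t1.edge_lengths, aln, model)
        l2 = nucleotide_loglik(t2.topology, t2.edge_lengths, aln, model)
        assert l1 == pytest.approx(l2, abs=1e-9)

    def test_mk_zero_distance_half(self):
        phy = load_phylogram("(A:0,B:0);")
        cm = CharacterMatrix(("A", "B"), np.zeros((2, 1), dtype=np.int8), 2)
        lnl = morphology_loglik(phy.topology, phy.edge_lengths, cm, MorphModelParams(2))
        assert lnl == pytest.approx(np.log(0.5))

    def test_numba_and_numpy_paths_agree(self, five_taxon_phylogram, rng):
        top = five_taxon_phylogram.topology
        states = rng.integers(0, 4, size=(5, 50))
        partials, w, cs = compress_patterns(states, 4)
        model = NucModelParams()
        e1 = PruningEngine(top, partials, w, model, cs, use_numba=True)
        e2 = PruningEngine(top, partials, w, model, cs, use_numba=False)
        edge = np.abs(rng.normal(0.1, 0.05, top.n_nodes))
        l1, g1 = e1.loglik_grad(edge)
        l2, g2 = e2.loglik_grad(edge)
        assert l1 == pytest.approx(l2, abs=1e-9)
        assert g1 == pytest.approx(g2, abs=1e-9)

    def test_gradient_matches_finite_differences(self, four_taxon_phylogram, rng):
        top = four_taxon_phylogram.topology
        states = rng.integers(0, 4, size=(4, 60))
        partials, w, cs = compress_patterns(states, 4)
        eng = PruningEngine(top, partials, w, NucModelParams(), cs)
        edge = four_taxon_phylogram.edge_lengths.copy()
        lnl, g = eng.loglik_grad(edge)
        for v in range(top.n_nodes):
            if top.parent[v] < 0:
                continue
            e2 = edge.copy()
            e2[v] += 1e-6
            assert (eng.loglik(e2) - lnl) / 1e-6 == pytest.approx(g[v], abs=1e-3)


class TestAscertainment:
    def test_variable_only_increases_likelihood(self, four_taxon_phylogram):
        top = four_taxon_phylogram.topology
        cm = CharacterMatrix(top.labels, np.array([[0], [1], [0], [1]], dtype=np.int8), 2)
        plain = morphology_loglik(top, four_taxon_phylogram.edge_lengths, cm)
        corrected = morphology_loglik(top, four_taxon_phylogram.edge_lengths, cm,
                                      ascertainment="variable_only")
        assert corrected > plain

    def test_state_out_of_range_rejected(self, four_taxon_phylogram):
        top = four_taxon_phylogram.topology
        cm = CharacterMatrix(top.labels, np.array([[2], [1], [0], [1]], dtype=np.int8), 3)
        with pytest.raises(ValueError):
            morphology_loglik(top, four_taxon_phylogram.edge_lengths, cm, MorphModelParams(2))


class TestOptimization:
    def test_identical_sequences_zero_branch_sum(self):
        phy = load_phylogram("(A:0.1,B:0.1);")
        states = np.tile(np.arange(4, dtype=np.int8), (2, 25))
        fit = optimize_branch_lengths(phy.topology, Alignment(("A", "B"), states), JC_LIKE)
        assert fit.branch_lengths["mol"].sum() == pytest.approx(0.0, abs=1e-6)

    def test_jc_closed_form_distance(self):
        phy = load_phylogram("(A:0.15,B:0.15);")
        aln = simulate_alignment(phy, JC_LIKE, L=2000, seed=13)
        fit = optimize_branch_lengths(phy.topology, aln, JC_LIKE)
        p_hat = np.mean(aln.states[0] != aln.states[1])
        mle = -0.75 * np.log(1 - 4 * p_hat / 3)
        assert fit.branch_lengths["mol"].sum() == pytest.approx(mle, abs=1e-6)

    def test_branch_length_recovery_large_L(self):
        pair = generate_scenario_pair(ScenarioSpec(n_taxa=18, sigma=0.75, master_seed=31))
        true_phy = pair["mol_phylogram"]
        model = NucModelParams()
        aln = simulate_alignment(true_phy, model, L=10_000, seed=41)
        fit = optimize_branch_lengths(true_phy.topology, aln, model)
        est = fit.branch_lengths["mol"]
        top = true_phy.topology
        c0, c1 = top.children[top.root]
        # compare in the unrooted parameterization (root edges merged)
        truth = true_phy.edge_lengths.copy()
        truth[c1] = truth[c0] + truth[c1]
        truth[c0] = 0.0
        # branches with > 5 expected changes (variable sites only)
        expected_changes = truth * 10_000 * (1 - model.p_inv)
        sel = [v for v in range(top.n_nodes)
               if v != top.root and v != c0 and expected_changes[v] > 5]
        rel = np.abs(est[sel] - truth[sel]) / truth[sel]
        assert np.mean(rel) < 0.10

    def test_unlinked_additivity_and_nesting(self, coupled_data):
        pair, aln, chars = coupled_data
        top = pair["chronogram"].topology
        fu = fit_unlinked(top, aln, chars)
        fm = optimize_branch_lengths(top, aln)
        fc = optimize_branch_lengths(top, chars)
        assert fu.log_likelihood == pytest.approx(
            fm.log_likelihood + fc.log_likelihood, abs=1e-6
        )
        fl = fit_linked(top, aln, chars, init=fu)
        assert fl.log_likelihood <= fu.log_likelihood + 1e-6
        assert fl.n_free_params == fu.n_free_params - (2 * top.n_tips - 3) + 1

    def test_deterministic(self, coupled_data):
        pair, aln, chars = coupled_data
        top = pair["chronogram"].topology
        f1 = optimize_branch_lengths(top, aln)
        f2 = optimize_branch_lengths(top, aln)
        assert f1.log_likelihood == pytest.approx(f2.log_likelihood, abs=1e-8)
        assert np.array_equal(f1.branch_lengths["mol"], f2.branch_lengths["mol"])


class TestInformationCriteria:
    def _fit(self, lnl, k, n):
        return FitResult(branch_lengths={}, log_likelihood=lnl, n_free_params=k, n_columns=n)

    def test_hand_arithmetic(self):
        # AIC = 2k - 2lnL; AICc adds 2k(k+1)/(n-k-1); BIC = k ln n - 2lnL
        msr = information_criteria(self._fit(-5.0, 3, 10), self._fit(-5.0, 3, 10))
        assert msr.aicc_linked == pytest.approx(20.0)
        assert msr.bic_linked == pytest.approx(3 * np.log(10) + 10)

    def test_aicc_approaches_aic(self):
        n = 10**9
        msr = information_criteria(self._fit(-5.0, 3, n), self._fit(-5.0, 3, n))
        assert msr.aicc_linked == pytest.approx(16.0, abs=1e-6)

    def test_decision_threshold_strict(self):
        # delta exactly at the threshold is indeterminate
        linked = self._fit(-100.0, 10, 500)
        for gap, expected in [(2.5, "indeterminate"), (2.500001, "linked")]:
            unlinked = self._fit(-100.0 - gap / 2, 10, 500)
            msr = information_criteria(linked, unlinked)
            assert msr.delta_aicc == pytest.approx(gap)
            assert msr.decision_aicc == expected

    def test_small_n_flags_aicc_undefined(self):
        msr = information_criteria(self._fit(-5.0, 10, 11), self._fit(-5.0, 10, 11))
        assert not msr.aicc_defined
        assert msr.decision_aicc == "indeterminate"

    def test_deltas_consistent(self, coupled_data):
        pair, aln, chars = coupled_data
        top = pair["chronogram"].topology
        fu = fit_unlinked(top, aln, chars)
        fl = fit_linked(top, aln, chars, init=fu)
        msr = information_criteria(fl, fu)
        assert msr.delta_aicc == pytest.approx(msr.aicc_unlinked - msr.aicc_linked, abs=1e-9)
        assert msr.delta_bic == pytest.approx(msr.bic_unlinked - msr.bic_linked, abs=1e-9)
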
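import itertools

import numpy as np
import pytest

from ratelink.detect import (
    InsufficientDataError,
    bayes_branchrate_test,
    bayes_modelsel_test,
    extract_sister_pairs,
    ml_modelsel_test,
    root_to_tip_test,
    sister_pairs_test,
    spearman,
)
from ratelink.likelihood import FitResult, information_criteria
from ratelink.mcmc import BranchRateSummary
from ratelink.synthetic import ClockSpec, build_phylogram, draw_branch_rates
from ratelink.trees import Phylogram, load_chronogram, load_phylogram, simulate_chronogram


class TestSpearman:
    def test_monotone_perfect(self):
        s = spearman([1, 2, 3, 4, 5], [10, 20, 30, 40, 50])
        assert s["rho"] == pytest.approx(1.0)

    def test_hand_example(self):
        # Sum d^2 = 4 -> rho = 1 - 6*4/(4*15) = 0.6
        s = spearman([1, 2, 3, 4], [2, 1, 4, 3])
        assert s["rho"] == pytest.approx(0.6)

    def test_exact_p_matches_enumeration(self, rng):
        x = rng.normal(size=5)
        y = rng.normal(size=5)
        s = spearman(x, y)
        # brute force over all 120 rank permutations
        rx = np.argsort(np.argsort(x)) + 1.0
        ry = np.argsort(np.argsort(y)) + 1.0
        obs = np.corrcoef(rx, ry)[0, 1]
        rhos = [
            np.corrcoef(rx, np.asarray(p))[0, 1]
            for p in itertools.permutations(ry)
        ]
        rhos = np.asarray(rhos)
        p1 = np.mean(rhos >= obs - 1e-12)
        assert s["p_one_sided"] == pytest.approx(p1)
        p2 = min(1.0, 2 * min(np.mean(rhos >= obs - 1e-12), np.mean(rhos <= obs + 1e-12)))
        assert s["p_two_sided"] == pytest.approx(p2)

    def test_zero_variance_flagged(self):
        s = spearman([1.0, 1.0, 1.0], [1, 2, 3])
        assert not s["defined"]
        assert np.isnan(s["rho"])

    def test_length_checks(self):
        with pytest.raises(InsufficientDataError):
            spearman([1, 2], [3, 4])


class TestRootToTip:
    def _pair(self, seed=0, n=12):
        chrono = simulate_chronogram(n, seed=seed)
        rates = draw_branch_rates(chrono, ClockSpec("lognormal", 1e-3, 1.0, seed=seed + 1))
        mol = build_phylogram(chrono, rates)
        return chrono, mol

    def test_perfect_coupling(self):
        _, mol = self._pair()
        morph = mol.scaled(1.90)
        res = root_to_tip_test(mol, morph, n_perm=999, seed=3)
        assert res.statistic == pytest.approx(1.0)
        assert res.p_value == pytest.approx(1.0 / 1000.0)
        assert res.detected

    def test_exhaustive_matches_enumeration(self):
        chrono, mol = self._pair(seed=5, n=5)
        rates = draw_branch_rates(chrono, ClockSpec("lognormal", 1e-3, 1.0, seed=77))
        morph = build_phylogram(chrono, rates)
        res = root_to_tip_test(mol, morph, exhaustive=True)
        x = mol.root_to_tip_distances()
        y = morph.root_to_tip_distances()
        r_obs = np.corrcoef(x, y)[0, 1]
        rs = [
            np.corrcoef(x, y[list(p)])[0, 1]
            for p in itertools.permutations(range(5))
        ]
        assert res.p_value == pytest.approx(np.mean(np.asarray(rs) >= r_obs - 1e-12))
        assert res.options["n_perm"] == 120

    def test_outlier_removal(self):
        _, mol = self._pair(seed=9)
        d = mol.root_to_tip_distances()
        y = d * 1.9
        y[0] = y.max() * 50  # gross outlier in the morphological vector
        morph = Phylogram(mol.topology, mol.edge_lengths * 1.9)
        # hack: outliers are judged on root-to-tip vectors, so rebuild a tree
        # whose first tip distance is huge
        el = morph.edge_lengths.copy()
        el[0] += y[0]
        morph = Phylogram(morph.topology, el)
        res = root_to_tip_test(mol, morph, n_perm=200, remove_outliers=True, seed=1)
        assert res.options["n_outliers_removed"] >= 1
        assert res.n_points <= mol.n_tips - 1

    def test_too_few_tips_refused(self):
        mol = load_phylogram("(A:1,B:2);")
        with pytest.raises(InsufficientDataError):
            root_to_tip_test(mol, mol, n_perm=10)

    def test_deterministic_given_seed(self):
        _, mol = self._pair(seed=11)
        rates = draw_branch_rates(simulate_chronogram(12, seed=11),
                                  ClockSpec("lognormal", 2e-3, 1.0, seed=50))
        morph = build_phylogram(simulate_chronogram(12, seed=11), rates)
        a = root_to_tip_test(mol, morph, n_perm=500, seed=7)
        b = root_to_tip_test(mol, morph, n_perm=500, seed=7)
        assert a.p_value == b.p_value


class TestSisterPairs:
    def test_two_taxon_one_pair(self):
        top = load_phylogram("(A:1,B:1);").topology
        assert len(extract_sister_pairs(top)) == 1

    def test_balanced_eight_tip_four_pairs(self):
        nwk = "(((A:1,B:1):1,(C:1,D:1):1):1,((E:1,F:1):1,(G:1,H:1):1):1);"
        top = load_phylogram(nwk).topology
        pairs = extract_sister_pairs(top)
        assert len(pairs) == 4
        tips = [t for a, b, _ in pairs for t in (a, b)]
        assert len(set(tips)) == 8  # disjoint

    def test_caterpillar_single_pair(self):
        nwk = "(A:5,(B:4,(C:3,(D:2,(E:1,F:1):1):1):1):1);"
        top = load_phylogram(nwk).topology
        assert len(extract_sister_pairs(top)) == 1

    def test_proportional_coupling_rho_one(self):
        chrono = simulate_chronogram(16, seed=3)
        rates = draw_branch_rates(chrono, ClockSpec("lognormal", 1e-3, 1.0, seed=4))
        mol = build_phylogram(chrono, rates)
        morph = mol.scaled(0.37)
        res = sister_pairs_test(chrono, mol, morph)
        assert res.statistic == pytest.approx(1.0)

    def test_hand_worked_contrast_ranks(self):
        # molecular contrasts {0.2,-0.1,0.5}, morphological {0.4,-0.2,1.0}:
        # identical ranking -> rho = 1
        nwk = "(((A:4,B:4):4,(C:4,D:4):4):4,((E:4,F:4):4,G:8):4);"
        chrono = load_chronogram(nwk)
        top = chrono.topology
        lab = {l: i for i, l in enumerate(top.labels)}
        t = 4.0
        mol_el = np.zeros(top.n_nodes)
        morph_el = np.zeros(top.n_nodes)
        for (a, b), cm, cmo in [(("A", "B"), 0.2, 0.4), (("C", "D"), -0.1, -0.2),
                                 (("E", "F"), 0.5, 1.0)]:
            mol_el[lab[a]] = np.exp(cm * np.sqrt(t))
            mol_el[lab[b]] = 1.0
            morph_el[lab[a]] = np.exp(cmo * np.sqrt(t))
            morph_el[lab[b]] = 1.0
        res = sister_pairs_test(chrono, Phylogram(top, mol_el), Phylogram(top, morph_el))
        assert res.statistic == pytest.approx(1.0)
        assert res.n_points == 3

    def test_n_points_equals_cherry_count(self):
        chrono = simulate_chronogram(20, seed=8)
        rates = draw_branch_rates(chrono, ClockSpec("lognormal", 1e-3, 0.5, seed=9))
        mol = build_phylogram(chrono, rates)
        res = sister_pairs_test(chrono, mol, mol.scaled(2.0))
        assert res.n_points == len(extract_sister_pairs(chrono.topology))

    def test_too_few_pairs_refused(self):
        chrono = load_chronogram("(A:1,B:1);")
        mol = chrono.to_phylogram()
        with pytest.raises(InsufficientDataError):
            sister_pairs_test(chrono, mol, mol)


class TestModelSelectionTests:
    def _msr(self, delta):
        lnl_linked = -100.0
        k_l, k_u, n = 10, 19, 1000
        # choose unlinked lnl so delta_aicc equals requested value
        fit_l = FitResult({}, lnl_linked, k_l, n)
        target_aicc_u = (2 * k_l - 2 * lnl_linked + 2 * k_l * (k_l + 1) / (n - k_l - 1)) + delta
        lnl_u = -(target_aicc_u - 2 * k_u - 2 * k_u * (k_u + 1) / (n - k_u - 1)) / 2
        fit_u = FitResult({}, lnl_u, k_u, n)
        return information_criteria(fit_l, fit_u)

    def test_detects_above_threshold(self):
        assert ml_modelsel_test(self._msr(3.0), "aicc").detected

    def test_boundary_strict(self):
        assert not ml_modelsel_test(self._msr(2.5), "aicc").detected

    def test_below_threshold(self):
        assert not ml_modelsel_test(self._msr(-4.0), "aicc").detected

    def test_aicc_undefined_indeterminate(self):
        fit_l = FitResult({}, -5.0, 10, 11)
        fit_u = FitResult({}, -4.0, 10, 11)
        res = ml_modelsel_test(information_criteria(fit_l, fit_u), "aicc")
        assert not res.detected
        assert not res.options["defined"]


class TestBayesBranchRates:
    def _summaries(self, x, y, dur):
        s1 = BranchRateSummary(np.arange(len(x)), np.asarray(x), np.asarray(x), np.asarray(dur))
        s2 = BranchRateSummary(np.arange(len(y)), np.asarray(y), np.asarray(y), np.asarray(dur))
        return s1, s2

    def test_identical_vectors_detected(self, rng):
        x = rng.lognormal(0, 1, 20)
        s1, s2 = self._summaries(x, x, rng.uniform(1, 10, 20))
        res = bayes_branchrate_test(s1, s2)
        assert res.statistic == pytest.approx(1.0)
        assert res.detected

    def test_drop_shortest_count(self, rng):
        x = rng.lognormal(0, 1, 20)
        y = rng.lognormal(0, 1, 20)
        s1, s2 = self._summaries(x, y, rng.uniform(1, 10, 20))
        res = bayes_branchrate_test(s1, s2, drop_shortest_fraction=0.5)
        assert res.n_points == 10

    def test_drops_smallest_durations(self):
        x = np.arange(8, dtype=float) + 1
        dur = np.array([5.0, 1.0, 6.0, 2.0, 7.0, 3.0, 8.0, 4.0])
        s1, s2 = self._summaries(x, x, dur)
        res = bayes_branchrate_test(s1, s2, drop_shortest_fraction=0.5)
        assert res.n_points == 4

    def test_exact_null_small_n(self, rng):
        x = rng.normal(size=6)
        y = rng.normal(size=6)
        s1, s2 = self._summaries(np.exp(x), np.exp(y), np.ones(6))
        res = bayes_branchrate_test(s1, s2)
        rx = np.argsort(np.argsort(x)) + 1.0
        ry = np.argsort(np.argsort(y)) + 1.0
        obs = np.corrcoef(rx, ry)[0, 1]
        rhos = np.asarray([
            np.corrcoef(rx, np.asarray(p))[0, 1] for p in itertools.permutations(ry)
        ])
        assert res.p_value == pytest.approx(np.mean(rhos >= obs - 1e-12))

    def test_too_few_after_drop(self, rng):
        x = rng.lognormal(0, 1, 6)
        s1, s2 = self._summaries(x, x, np.arange(6.0))
        with pytest.raises(InsufficientDataError):
            bayes_branchrate_test(s1, s2, drop_shortest_fraction=0.5)


class TestBayesModelSel:
    def test_boundary_strict(self):
        assert not bayes_modelsel_test(1.0).detected

    def test_strong_support(self):
        assert bayes_modelsel_test(41.1).detected

    def test_negative(self):
        assert not bayes_modelsel_test(-5.0).detected

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            bayes_modelsel_test(float("nan"))


class TestOrderingInvariance:
    def test_rtt_invariant_to_label_order(self):
        chrono = simulate_chronogram(10, seed=21)
        rates = draw_branch_rates(chrono, ClockSpec("lognormal", 1e-3, 1.0, seed=22))
        mol = build_phylogram(chrono, rates)
        morph = mol.scaled(1.5)
        # shuffled-tip reload of the morphological tree
        morph2 = load_phylogram(morph.newick())
        a = root_to_tip_test(mol, morph, n_perm=500, seed=3)
        b = root_to_tip_test(mol, morph2, n_perm=500, seed=3)
        assert a.statistic == pytest.approx(b.statistic)
        assert a.p_value == b.p_value
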
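"""Likelihood and density oracles: brute-force enumeration, matrix
exponentials, quadrature, and hand-derived closed forms."""

import itertools
import math

import numpy as np
import pytest
from scipy import integrate, linalg

from mscintro.alignment import IUPAC_SETS, LocusAlignment
from mscintro.genetree import GeneTree
from mscintro.likelihood import (
    GammaPrior,
    PriorSpec,
    coalescent_stats,
    dirichlet_age_lognorm,
    jc69_transition,
    locus_loglik,
    make_gamma_prior,
    msc_logdensity,
    msci_logdensity,
    prior_logdensity,
)
from mscintro.network import ParamSet, add_introgression_pair, tree_from_newick
from mscintro.popmodel import compile_model


class TestGammaPrior:
    @pytest.mark.parametrize("shape,rate,mean", [(7, 200, 0.035), (2, 10, 0.2), (1, 1, 1.0)])
    def test_printed_means(self, shape, rate, mean):
        assert make_gamma_prior(shape, rate).mean == pytest.approx(mean)

    def test_density_integrates_to_one(self):
        g = make_gamma_prior(7, 200)
        val, _ = integrate.quad(g.pdf, 0, 1.0)
        assert val == pytest.approx(1.0, abs=1e-8)

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            make_gamma_prior(0, 1)


class TestJC69Transition:
    def test_zero_time_is_identity(self):
        assert np.allclose(jc69_transition(0.0), np.eye(4))

    def test_long_time_reaches_stationarity(self):
        assert np.allclose(jc69_transition(50.0), np.full((4, 4), 0.25), atol=1e-12)

    def test_matches_matrix_exponential(self):
        q = np.full((4, 4), 1.0 / 3.0)
        np.fill_diagonal(q, -1.0)  # equal-rates generator, one expected sub/unit time
        assert np.allclose(jc69_transition(0.1), linalg.expm(q * 0.1), atol=1e-12)

    def test_rows_sum_to_one(self):
        assert np.allclose(jc69_transition(0.37).sum(axis=1), 1.0)

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            jc69_transition(-0.1)


def _brute_force_loglik(tree: GeneTree, aln: LocusAlignment) -> float:
    """Sum over all ancestral state assignments (independent oracle)."""
    tip_index = {lab: i for i, lab in enumerate(tree.labels)}
    ch = tree.children()
    internal = [i for i in range(tree.n_nodes) if i >= tree.n_tips]
    total = 0.0
    for site in range(aln.n_sites):
        obs = {}
        for lab, seq in zip(aln.labels, aln.seqs):
            obs[tip_index[lab]] = IUPAC_SETS[seq[site]]
        site_p = 0.0
        for assign in itertools.product("ACGT", repeat=len(internal)):
            state = dict(zip(internal, assign))
            for tips_state in itertools.product("ACGT", repeat=tree.n_tips):
                ok = all(
                    tips_state[i] in obs.get(i, set("ACGT")) for i in range(tree.n_tips)
                )
                if not ok:
                    continue
                full = dict(state)
                full.update({i: tips_state[i] for i in range(tree.n_tips)})
                p = 0.25
                for node in range(tree.n_nodes):
                    par = tree.parent[node]
                    if par < 0:
                        continue
                    t = tree.ages[par] - tree.ages[node]
                    pm = jc69_transition(t)
                    p *= pm["ACGT".index(full[par]), "ACGT".index(full[node])]
                site_p += p
        total += math.log(site_p)
    return total


class TestPruningLikelihood:
    def test_single_sequence_is_stationary(self):
        gt = GeneTree(["a", "b"], ["A", "B"], np.array([2, 2, -1]), np.array([0.0, 0.0, 0.01]))
        ll = locus_loglik(gt, LocusAlignment(["a"], ["ACGTACGTAC"]))
        assert ll == pytest.approx(10 * math.log(0.25))

    def test_zero_tree_identical_sequences(self):
        gt = GeneTree(["a", "b"], ["A", "B"], np.array([2, 2, -1]), np.array([0.0, 0.0, 0.0]))
        ll = locus_loglik(gt, LocusAlignment(["a", "b"], ["ACG", "ACG"]))
        assert ll == pytest.approx(3 * math.log(0.25))

    def test_matches_brute_force_enumeration(self, rng):
        parent = np.array([4, 4, 5, 6, 5, 6, -1])
        ages = np.array([0, 0, 0, 0, 0.02, 0.05, 0.09])
        gt = GeneTree(["a", "b", "c", "d"], list("ABCD"), parent, ages)
        aln = LocusAlignment(
            ["a", "b", "c", "d"], ["ACR", "AGT", "AC-", "TCN"]
        )
        assert locus_loglik(gt, aln) == pytest.approx(_brute_force_loglik(gt, aln), abs=1e-9)

    def test_invariant_to_tip_relabelling_order(self):
        parent = np.array([3, 3, 4, 4, -1])
        ages = np.array([0, 0, 0, 0.03, 0.07])
        gt = GeneTree(["a", "b", "c"], list("ABC"), parent, ages)
        aln1 = LocusAlignment(["a", "b", "c"], ["AAG", "ACT", "GCT"])
        aln2 = LocusAlignment(["c", "a", "b"], ["GCT", "AAG", "ACT"])
        assert locus_loglik(gt, aln1) == pytest.approx(locus_loglik(gt, aln2))

    def test_label_mismatch_raises(self):
        gt = GeneTree(["a", "b"], ["A", "B"], np.array([2, 2, -1]), np.array([0.0, 0.0, 0.01]))
        with pytest.raises(ValueError):
            locus_loglik(gt, LocusAlignment(["z"], ["ACGT"]))


class TestMscDensity:
    def test_single_population_closed_form(self):
        net = tree_from_newick("(A,B)r;")
        theta = 0.01
        params = ParamSet(tau={"r": 1e-12}, theta={k: theta for k in ["A", "B", "r"]})
        t = 0.004
        gt = GeneTree(["A^1", "B^1"], ["A", "B"], np.array([2, 2, -1]), np.array([0, 0, t]))
        expected = math.log(2 / theta) - 2 * (t - 1e-12) / theta
        assert msc_logdensity(gt, net, params) == pytest.approx(expected)

    def test_impossible_tree_has_zero_density(self, three_species_tree):
        net, params = three_species_tree
        # a and b coalesce below their species divergence: impossible
        gt = GeneTree(
            ["A^1", "B^1", "C^1"],
            ["A", "B", "C"],
            np.array([3, 3, 4, 4, -1]),
            np.array([0, 0, 0, 0.005, 0.05]),
        )
        assert msc_logdensity(gt, net, params) == -np.inf

    def test_density_integrates_to_topology_probability(self, three_species_tree):
        """2-D quadrature of the concordant labelled gene-tree density
        equals 1 - (2/3) exp(-2 dtau / theta)."""
        net, params = three_species_tree
        tau_ab, tau_r, theta = 0.01, 0.03, 0.01

        def dens(t1, t2):
            gt = GeneTree(
                ["A^1", "B^1", "C^1"],
                ["A", "B", "C"],
                np.array([3, 3, 4, 4, -1]),
                np.array([0, 0, 0, t1, t2]),
            )
            return math.exp(msc_logdensity(gt, net, params))

        val, _ = integrate.dblquad(
            lambda t2, t1: dens(t1, t2),
            tau_ab, 1.0,                      # t1 range
            lambda t1: max(t1, tau_r), 1.5,   # t2 > max(t1, tau_r)
        )
        expected = 1 - (2 / 3) * math.exp(-2 * (tau_r - tau_ab) / theta)
        assert val == pytest.approx(expected, rel=1e-3)

    def test_simulator_histogram_matches_density(self, three_species_tree, rng):
        """Chi-squared goodness of fit of simulated 2-lineage ages in a
        single population against the exponential coalescent density."""
        from mscintro.network import parse_network
        from mscintro.simulate import sim_gene_tree

        net = parse_network("A;")
        theta = 0.01
        params = ParamSet(theta={"A": theta})
        model = compile_model(net, params)
        ages = np.array(
            [
                sim_gene_tree(net, params, {"A": 2}, rng, model=model).ages[2]
                for _ in range(20_000)
            ]
        )
        edges = np.quantile(ages, np.linspace(0, 1, 21))
        edges[0], edges[-1] = 0.0, np.inf
        obs, _ = np.histogram(ages, edges)
        cdf = lambda t: 1 - np.exp(-2 * np.minimum(t, 1e9) / theta)
        exp_p = np.diff([cdf(e) if np.isfinite(e) else 1.0 for e in edges])
        from scipy import stats as sps

        chi = sps.chisquare(obs, exp_p * len(ages))
        assert chi.pvalue > 0.001


def _msci_marginal_oracle(u, v, tau_h, tau_ab, theta, phi_a, phi_b):
    """Hand-derived marginal density of the gene tree ((a1,a2):u, b):v
    for two species A,B with a bidirectional introgression pair at
    tau_h, all populations sharing one theta.  Cases: the A-pair
    coalesces before (u < tau_h) or after the pulse."""
    c = 2.0 / theta

    def coal_after(t_from, t_at, same_pop):
        # density of coalescence at t_at >= t_from for two lineages that
        # share a population iff same_pop (otherwise only above tau_ab)
        if same_pop:
            if t_at < tau_ab:
                return c * math.exp(-c * (t_at - t_from))
            return math.exp(-c * (tau_ab - t_from)) * c * math.exp(-c * (t_at - tau_ab))
        if t_at < tau_ab:
            return 0.0
        return c * math.exp(-c * (t_at - tau_ab))

    if u < tau_h:
        first = c * math.exp(-c * u)
        # alpha: donor w.p. phi_a -> B-side; b: donor w.p. phi_b -> A-side
        p_same = phi_a * phi_b_comp(phi_b) + phi_a_comp(phi_a) * phi_b
        p_diff = 1.0 - p_same
        return first * (p_same * coal_after(tau_h, v, True) + p_diff * coal_after(tau_h, v, False))
    # both a1, a2 cross the pulse independently, having first survived
    # together (no coalescence) in population A below the pulse
    survive_below = math.exp(-c * tau_h)
    out = 0.0
    for both_side, p_pair in (("B", phi_a * phi_a), ("A", phi_a_comp(phi_a) ** 2)):
        # b's side: A-up w.p. phi_b else B-up
        for b_side, p_b in (("A", phi_b), ("B", phi_b_comp(phi_b))):
            same = b_side == both_side
            if same:
                # three lineages share one population on (tau_h, u):
                # the specific pair coalesces first at u
                if u < tau_ab:
                    pair_coal = c * math.exp(-3 * c * (u - tau_h))
                else:
                    pair_coal = math.exp(-3 * c * (tau_ab - tau_h)) * c * math.exp(
                        -3 * c * (u - tau_ab)
                    )
            else:
                pair_coal = coal_after(tau_h, u, True)
            out += p_pair * p_b * survive_below * pair_coal * coal_after(u, v, same)
    # split pair (one each side) cannot coalesce below the root divergence
    return out


def phi_a_comp(x):
    return 1.0 - x


def phi_b_comp(x):
    return 1.0 - x


class TestMsciDensity:
    def _fixture(self, phi_a=0.3, phi_b=0.6):
        net = add_introgression_pair(tree_from_newick("(A,B)ab;"), "A", "B", "hA", "hB")
        theta = 0.01
        params = ParamSet(
            tau={"ab": 0.02, "hA": 0.008, "hB": 0.008},
            theta={k: theta for k in ["A", "B", "ab"]},
            phi={"hA": phi_a, "hB": phi_b},
        )
        return net, params, theta

    def _tree(self, u, v):
        return GeneTree(
            ["A^1", "A^2", "B^1"],
            ["A", "A", "B"],
            np.array([3, 3, 4, 4, -1]),
            np.array([0, 0, 0, u, v]),
        )

    @pytest.mark.parametrize(
        "u,v", [(0.004, 0.012), (0.004, 0.05), (0.012, 0.016), (0.012, 0.05)]
    )
    def test_marginal_matches_path_enumeration_oracle(self, u, v):
        """Summing exp(msci_logdensity) over all hybrid-path indicator
        assignments reproduces the hand-derived marginal density."""
        phi_a, phi_b = 0.3, 0.6
        net, params, theta = self._fixture(phi_a, phi_b)
        tree = self._tree(u, v)
        model = compile_model(net, params)
        # lineages that can cross: any node; enumerate indicators for all
        total = 0.0
        nodes = range(tree.n_nodes)
        for assign in itertools.product([0, 1], repeat=2 * tree.n_nodes):
            ind = {}
            for k, node in enumerate(nodes):
                ind[(node, "hA")] = assign[2 * k]
                ind[(node, "hB")] = assign[2 * k + 1]
            t = tree.copy()
            t.indicators = ind
            stats_ = coalescent_stats(t, model)
            d = stats_.logdensity(model.theta, params.phi)
            if d > -np.inf:
                # inactive indicators carry weight 1/2 each
                total += math.exp(d) * 0.5 ** (2 * tree.n_nodes - len(stats_.crossings))
        oracle = _msci_marginal_oracle(u, v, 0.008, 0.02, theta, phi_a, phi_b)
        assert total == pytest.approx(oracle, rel=1e-9)

    def test_all_phi_zero_reduces_to_base_tree_density(self):
        net, params, theta = self._fixture(0.0, 0.0)
        base = tree_from_newick("(A,B)ab;")
        base_params = ParamSet(
            tau={"ab": 0.02}, theta={k: theta for k in ["A", "B", "ab"]}
        )
        tree = self._tree(0.004, 0.05)
        for i in range(tree.n_nodes):
            tree.indicators[(i, "hA")] = 0
            tree.indicators[(i, "hB")] = 0
        assert msci_logdensity(tree, net, params) == pytest.approx(
            msc_logdensity(tree, base, base_params)
        )

    def test_missing_indicator_raises(self):
        net, params, _ = self._fixture()
        tree = self._tree(0.004, 0.05)
        with pytest.raises(ValueError):
            msci_logdensity(tree, net, params)


class TestPriorDensity:
    def test_three_tip_age_density_normalizes(self, three_species_tree):
        net, params = three_species_tree
        priors = PriorSpec()
        tau0 = params.tau["r"]

        def age_density(t_ab):
            p = params.copy()
            p.tau["ab"] = t_ab
            full = prior_logdensity(p, priors, net)
            # remove the gamma and theta components to isolate the age part
            base = priors.root_tau.logpdf(tau0) + sum(
                priors.theta.logpdf(v) for v in p.theta.values()
            )
            return math.exp(full - base)

        val, _ = integrate.quad(age_density, 0, tau0)
        assert val == pytest.approx(1.0, rel=1e-6)

    def test_four_tip_volumes(self):
        # caterpillar: ordered ages, volume tau0^2/2; balanced: tau0^2
        cat = tree_from_newick("(((A,B)x,C)y,D)r;")
        bal = tree_from_newick("((A,B)x,(C,D)y)r;")
        tau0 = 0.05
        assert dirichlet_age_lognorm(cat, tau0) == pytest.approx(-math.log(tau0**2 / 2))
        assert dirichlet_age_lognorm(bal, tau0) == pytest.approx(-math.log(tau0**2))

    def test_component_oracle_at_gamma_modes(self, three_species_tree):
        net, params = three_species_tree
        priors = PriorSpec()
        val = prior_logdensity(params, priors, net)
        expected = (
            priors.root_tau.logpdf(params.tau["r"])
            - math.log(params.tau["r"])  # flat age density for one free age
            + sum(priors.theta.logpdf(v) for v in params.theta.values())
        )
        assert val == pytest.approx(expected)

    def test_phi_out_of_range_gives_neg_inf(self, one_pair_network):
        net, params = one_pair_network
        bad = params.copy()
        bad.phi["hA"] = 1.2
        assert prior_logdensity(bad, PriorSpec(), net) == -np.inf


class TestKernelsAgainstReference:
    """The compiled MCMC kernels must agree with the reference
    implementations on randomly simulated gene trees."""

    def test_prune_kernel_matches_reference(self, rng, four_species_tree):
        from mscintro._kernels import prune_jc69
        from mscintro.mcmc import _encode_alignment
        from mscintro.simulate import sim_alignment_jc69, sim_gene_tree

        net, params = four_species_tree
        model = compile_model(net, params)
        for _ in range(10):
            gt = sim_gene_tree(net, params, {s: 1 for s in "ABCD"}, rng, model=model)
            aln = sim_alignment_jc69(gt, 120, rng)
            tp, counts = _encode_alignment(aln)
            ref = locus_loglik(gt, aln)
            fast = prune_jc69(gt.parent, gt.ages, gt.n_tips, tp, counts)
            assert fast == pytest.approx(ref, rel=1e-10)

    def test_sweep_kernel_matches_reference(self, rng, one_pair_network):
        from mscintro._kernels import coal_sweep, event_arrays, stats_logdensity
        from mscintro.simulate import sim_gene_tree

        net, params = one_pair_network
        model = compile_model(net, params)
        ev = event_arrays(model)
        hyb = ev[6]
        phi = np.array([params.phi[h] for h in hyb])
        for _ in range(20):
            gt = sim_gene_tree(net, params, {"A": 2, "B": 2}, rng, model=model)
            ref = coalescent_stats(gt, model).logdensity(model.theta, params.phi)
            ind = np.zeros((gt.n_nodes, len(hyb)), dtype=np.int64)
            for (lin, label), val in gt.indicators.items():
                ind[lin, hyb.index(label)] = val
            tip_pop = np.array([model.tip_pop[s] for s in gt.species], dtype=np.int64)
            st = coal_sweep(
                gt.parent, gt.ages, gt.n_tips, tip_pop, ind,
                len(model.names), len(hyb), *ev[:6],
            )
            fast = stats_logdensity(st, model.theta, phi)
            # the kernel includes the persistent-indicator convention factor
            assert fast - math.log(2.0) * len(st[5]) == pytest.approx(ref, rel=1e-10)
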
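"""Distances, NJ, pruning likelihood, NNI, bootstrap, clade labelling."""

import itertools
import math

import dendropy
import numpy as np
import pytest

from lcpufa import phylo
from lcpufa.align import Alignment
from lcpufa.phylo import (
    DistanceMatrix,
    DistanceModelParams,
    _bipartitions,
    assign_clade,
    bootstrap_support,
    count_PQ,
    distance_matrix,
    format_newick,
    k2p_distance,
    mixture_rates,
    neighbor_joining,
    nni_search,
    read_newick,
    stationary_freqs,
    tamura3_distance,
    transition_matrix,
    tree_log_likelihood,
)
from lcpufa.synth import simulate_alignment


def _tree(newick, labels):
    tns = dendropy.TaxonNamespace(labels)
    return dendropy.Tree.get(data=newick, schema="newick", taxon_namespace=tns)


class TestCountPQ:
    def test_identical(self):
        assert count_PQ("ACGT", "ACGT") == (0, 0, 4)

    def test_single_transition(self):
        P, Q, n = count_PQ("ACGT", "GCGT")
        assert (P, Q, n) == (0.25, 0, 4)

    def test_gap_and_n_skipped(self):
        P, Q, n = count_PQ("AC-GN", "ACTGA")
        assert n == 3

    def test_no_comparable_columns(self):
        with pytest.raises(ValueError):
            count_PQ("---", "AAA")

    def test_per_column_oracle(self, rng):
        transitions = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}
        for _ in range(200):
            n = int(rng.integers(4, 60))
            a = "".join(rng.choice(list("ACGT-N"), n))
            b = "".join(rng.choice(list("ACGT-N"), n))
            cols = [
                (x, y) for x, y in zip(a, b)
                if x not in "-N" and y not in "-N"
            ]
            if not cols:
                continue
            ts = sum((x, y) in transitions for x, y in cols)
            tv = sum(x != y and (x, y) not in transitions for x, y in cols)
            P, Q, m = count_PQ(a, b)
            assert m == len(cols)
            assert P == pytest.approx(ts / m)
            assert Q == pytest.approx(tv / m)


class TestDistances:
    def test_zero_on_identical(self):
        assert k2p_distance("ACGTACGT", "ACGTACGT") == 0
        assert tamura3_distance("ACGTACGT", "ACGTACGT") == 0

    def test_k2p_closed_form(self):
        # 1000 sites with exactly 100 transitions and 50 transversions
        a = "A" * 1000
        b = "G" * 100 + "C" * 50 + "A" * 850
        d = k2p_distance(a, b)
        expected = -0.5 * math.log((1 - 0.2 - 0.05) * math.sqrt(1 - 0.1))
        assert d == pytest.approx(expected)
        assert d == pytest.approx(0.1702, abs=5e-5)

    def test_k2p_pure_transition_limit(self):
        a = "A" * 1000
        b = "G" * 100 + "A" * 900
        assert k2p_distance(a, b) == pytest.approx(-0.5 * math.log(1 - 0.2))

    def test_saturation_flagged_not_raised(self):
        assert math.isnan(k2p_distance("AAAA", "GGGG"))

    def test_tamura3_reduces_to_k2p_at_theta_half(self):
        a = "A" * 850 + "G" * 100 + "C" * 25 + "T" * 25
        b = "A" * 850 + "A" * 100 + "A" * 25 + "A" * 25
        assert tamura3_distance(a, b, theta=0.5) == pytest.approx(
            k2p_distance(a, b)
        )

    def test_tamura3_formula_oracle(self):
        P, Q, theta = 0.1, 0.05, 0.3
        h = 2 * theta * (1 - theta)
        expected = -h * math.log(1 - P / h - Q) - 0.5 * (1 - h) * math.log(1 - 2 * Q)
        a = "A" * 850 + "G" * 100 + "C" * 50
        b = "A" * 850 + "A" * 100 + "A" * 50
        assert tamura3_distance(a, b, theta=theta) == pytest.approx(expected)

    def test_distance_ordering(self, rng):
        """p-distance <= K2P wherever both are finite."""
        for _ in range(50):
            a = "".join(rng.choice(list("ACGT"), 500))
            idx = rng.choice(500, size=60, replace=False)
            b = list(a)
            for i in idx:
                b[i] = "ACGT"[(("ACGT".index(b[i])) + int(rng.integers(1, 4))) % 4]
            b = "".join(b)
            P, Q, n = count_PQ(a, b)
            p_dist = P + Q
            d = k2p_distance(a, b)
            if not math.isnan(d):
                assert d >= p_dist - 1e-12


class TestNeighborJoining:
    def test_three_taxa_closed_form(self):
        D = DistanceMatrix(
            labels=["a", "b", "c"],
            d=np.array([[0, 0.3, 0.5], [0.3, 0, 0.6], [0.5, 0.6, 0]]),
        )
        t = neighbor_joining(D)
        lengths = {
            lf.taxon.label: lf.edge.length for lf in t.leaf_node_iter()
        }
        assert lengths["a"] == pytest.approx(0.1)
        assert lengths["b"] == pytest.approx(0.2)
        assert lengths["c"] == pytest.approx(0.4)

    def test_additive_matrix_exact_recovery(self):
        labels = ["A", "B", "C", "D", "E", "F"]
        true = _tree(
            "((A:1,B:2):1,(C:1.5,(D:0.5,E:0.8):1.2):0.7,F:3);", labels
        )
        pdm = true.phylogenetic_distance_matrix()
        tns = true.taxon_namespace
        D = np.zeros((6, 6))
        for i, t1 in enumerate(tns):
            for j, t2 in enumerate(tns):
                if i != j:
                    D[i, j] = pdm.patristic_distance(t1, t2)
        nj = neighbor_joining(DistanceMatrix(labels=[t.label for t in tns], d=D))
        assert set(_bipartitions(nj)) == set(_bipartitions(true))
        # branch lengths: patristic distances reproduced exactly
        nj2 = dendropy.Tree.get(
            data=nj.as_string(schema="newick"), schema="newick",
            taxon_namespace=tns,
        )
        pdm2 = nj2.phylogenetic_distance_matrix()
        for t1, t2 in itertools.combinations(tns, 2):
            assert pdm2.patristic_distance(t1, t2) == pytest.approx(
                pdm.patristic_distance(t1, t2)
            )

    def test_permutation_invariance(self, rng):
        labels = ["A", "B", "C", "D", "E", "F"]
        true = _tree(
            "((A:1,B:2):1,(C:1.5,(D:0.5,E:0.8):1.2):0.7,F:3);", labels
        )
        pdm = true.phylogenetic_distance_matrix()
        tns = true.taxon_namespace
        taxa = list(tns)
        D = np.array(
            [[0 if i == j else pdm.patristic_distance(taxa[i], taxa[j])
              for j in range(6)] for i in range(6)]
        )
        ref_bips = None
        for perm in ([0, 1, 2, 3, 4, 5], [5, 3, 1, 0, 2, 4], [2, 4, 0, 5, 1, 3]):
            pl = [taxa[i].label for i in perm]
            pd = D[np.ix_(perm, perm)]
            t = neighbor_joining(DistanceMatrix(labels=pl, d=pd))
            bips = set(_bipartitions(t))
            if ref_bips is None:
                ref_bips = bips
            assert bips == ref_bips

    def test_too_few_taxa(self):
        with pytest.raises(ValueError):
            neighbor_joining(DistanceMatrix(labels=["a", "b"], d=np.zeros((2, 2))))

    def test_saturated_pairs_rejected(self):
        d = np.array([[0, 1, np.nan], [1, 0, 1], [np.nan, 1, 0]])
        with pytest.raises(ValueError, match="saturated"):
            neighbor_joining(DistanceMatrix(labels=["a", "b", "c"], d=d))


class TestLikelihood:
    def test_two_taxa_zero_branch_single_site(self):
        t = _tree("(x:0,y:0);", ["x", "y"])
        al = Alignment(rows=[("x", "A"), ("y", "A")])
        m = DistanceModelParams(model="k2p", kappa=2.0)
        ll = tree_log_likelihood(t, al, m, ncat=1)
        assert ll == pytest.approx(math.log(0.25))

    def test_missing_leaf_row(self):
        t = _tree("(x:0.1,y:0.1);", ["x", "y"])
        al = Alignment(rows=[("x", "A")])
        with pytest.raises(ValueError, match="without alignment rows"):
            tree_log_likelihood(t, al, DistanceModelParams(), ncat=1)

    @pytest.mark.parametrize("model,ncat,p_inv", [
        ("k2p", 1, 0.0), ("k2p", 3, 0.2), ("t92", 2, 0.1),
    ])
    def test_state_enumeration_oracle(self, model, ncat, p_inv):
        """Pruning equals brute-force summation over internal states."""
        labels = ["a", "b", "c", "d"]
        t = _tree("((a:0.1,b:0.2):0.05,(c:0.15,d:0.1):0.07);", labels)
        m = DistanceModelParams(model=model, kappa=3.0, theta=0.4,
                                alpha=0.8, p_inv=p_inv)
        al = simulate_alignment(t, m, 10, np.random.default_rng(5))
        ll = tree_log_likelihood(t, al, m, ncat=ncat)

        rates, weights = mixture_rates(m, ncat)
        pi = stationary_freqs(m)
        rows = dict(al.rows)
        idx = {b: i for i, b in enumerate("ACGT")}
        total = 0.0
        for j in range(10):
            site = 0.0
            for rate, w in zip(rates, weights):
                pm = lambda t_: transition_matrix(m, t_ * rate)
                acc = 0.0
                P_rl = pm(0.05)
                P_rr = pm(0.07)
                P_a, P_b, P_c, P_d = pm(0.1), pm(0.2), pm(0.15), pm(0.1)
                for r in range(4):
                    for l in range(4):
                        for rr in range(4):
                            acc += (
                                pi[r] * P_rl[r, l] * P_rr[r, rr]
                                * P_a[l, idx[rows["a"][j]]]
                                * P_b[l, idx[rows["b"][j]]]
                                * P_c[rr, idx[rows["c"][j]]]
                                * P_d[rr, idx[rows["d"][j]]]
                            )
                site += w * acc
            total += math.log(site)
        assert ll == pytest.approx(total, abs=1e-10)

    def test_rerooting_invariance(self):
        """Reversible model: likelihood does not depend on root placement."""
        labels = ["a", "b", "c", "d", "e"]
        t = _tree("((a:0.1,b:0.2):0.05,(c:0.15,d:0.1):0.07,e:0.3);", labels)
        m = DistanceModelParams(model="k2p", kappa=2.5)
        al = simulate_alignment(t, m, 50, np.random.default_rng(8))
        ll0 = tree_log_likelihood(t, al, m, ncat=2)
        for leaf_label in ("a", "d"):
            t2 = t.clone(depth=1)
            lf = next(
                x for x in t2.leaf_node_iter() if x.taxon.label == leaf_label
            )
            half = lf.edge.length / 2
            t2.reroot_at_edge(lf.edge, length1=half, length2=half,
                              update_bipartitions=False)
            assert tree_log_likelihood(t2, al, m, ncat=2) == pytest.approx(
                ll0, abs=1e-8
            )


@pytest.fixture(scope="module")
def strong_signal():
    labels = ["A", "B", "C", "D", "E", "F"]
    true = _tree(
        "((A:0.1,B:0.1):0.08,((C:0.1,D:0.1):0.08,E:0.2):0.05,F:0.25);",
        labels,
    )
    m = DistanceModelParams(model="k2p", kappa=3.0)
    al = simulate_alignment(true, m, 2000, np.random.default_rng(7))
    return true, m, al


class TestNni:

    def test_true_topology_is_local_optimum(self, strong_signal):
        true, m, al = strong_signal
        nj = neighbor_joining(distance_matrix(al))
        assert set(_bipartitions(nj)) == set(_bipartitions(true))
        result, trace = nni_search(nj, al, m, ncat=1, opt_lengths=True)
        assert set(_bipartitions(result)) == set(_bipartitions(true))
        assert len(trace) == 1  # no accepted move

    def test_recovery_from_perturbed_start(self, strong_signal):
        true, m, al = strong_signal
        nj = neighbor_joining(distance_matrix(al))
        wrong = next(
            t for t in phylo._nni_neighbors(nj)
            if set(_bipartitions(t)) != set(_bipartitions(true))
        )
        result, trace = nni_search(wrong, al, m, ncat=1, opt_lengths=True)
        assert set(_bipartitions(result)) == set(_bipartitions(true))
        assert trace == sorted(trace)  # monotone log-likelihood


class TestBootstrap:
    def test_tiled_block_alignment_full_support(self):
        """An alignment made of one repeated column block resamples into
        (multisets of) the same columns: every point-estimate bipartition
        recurs in every replicate."""
        block = [
            ("a", "AAAAACGTAG"),
            ("b", "AAAAACGTAC"),
            ("c", "AGAAACGAAC"),
            ("d", "AGAAACTAAC"),
        ]
        al = Alignment(rows=[(rid, seq * 12) for rid, seq in block])
        point = bootstrap_support(al, B=50, seed=1)
        supports = [n.support for n in phylo._bipartitions(point).values()]
        assert supports
        assert all(0 <= s <= 100 for s in supports)

    def test_strong_signal_all_true_bipartitions(self):
        labels = ["A", "B", "C", "D", "E", "F"]
        true = _tree(
            "((A:0.1,B:0.1):0.08,((C:0.1,D:0.1):0.08,E:0.2):0.05,F:0.25);",
            labels,
        )
        m = DistanceModelParams(model="k2p", kappa=3.0)
        al = simulate_alignment(true, m, 2000, np.random.default_rng(17))
        point = bootstrap_support(al, B=200, seed=23)
        target = phylo._bipartitions(point)
        assert set(target) == set(_bipartitions(true))
        assert all(node.support >= 75 for node in target.values())

    def test_seed_to_seed_monte_carlo_spread(self):
        labels = ["A", "B", "C", "D", "E"]
        true = _tree(
            "((A:0.15,B:0.15):0.04,(C:0.15,D:0.15):0.04,E:0.3);", labels
        )
        m = DistanceModelParams(model="k2p", kappa=2.0)
        al = simulate_alignment(true, m, 400, np.random.default_rng(2))
        B = 500
        s1 = bootstrap_support(al, B=B, seed=1)
        s2 = bootstrap_support(al, B=B, seed=99)
        b1 = {k: n.support for k, n in phylo._bipartitions(s1).items()}
        b2 = {k: n.support for k, n in phylo._bipartitions(s2).items()}
        for key in set(b1) & set(b2):
            p = (b1[key] + b2[key]) / 200.0
            se = 100.0 * math.sqrt(max(p * (1 - p), 1e-4) / B)
            assert abs(b1[key] - b2[key]) <= 6 * se + 1e-9


class TestNewickAndClades:
    def test_newick_round_trip(self):
        text = "((A:0.1,B:0.2)95:0.05,(C:0.15,D:0.1)88:0.07,E:0.3);"
        t = read_newick(text)
        out = format_newick(t)
        t2 = read_newick(out)
        assert set(_bipartitions(t)) == set(_bipartitions(t2))
        sup1 = sorted(n.support for n in phylo._bipartitions(t).values())
        sup2 = sorted(n.support for n in phylo._bipartitions(t2).values())
        assert sup1 == sup2

    def test_low_support_suppressed(self):
        t = read_newick("((A:0.1,B:0.2)60:0.05,(C:0.15,D:0.1)88:0.07,E:0.3);")
        out = format_newick(t, min_support=75)
        assert "60" not in out
        assert "88" in out

    def test_candidate_in_reference_clade(self):
        t = read_newick(
            "(((cand:0.1,ref1:0.1)90:0.1,ref2:0.2)85:0.1,(x1:0.1,x2:0.1)80:0.2,out:0.5);"
        )
        refs = {"ref1": "delta-5", "ref2": "delta-5"}
        assert assign_clade(t, "cand", refs, min_support=75, outgroup="out") == "delta-5"

    def test_candidate_sister_to_outgroup(self):
        t = read_newick(
            "((ref1:0.1,ref2:0.1)90:0.2,(cand:0.4,out:0.5)70:0.1);"
        )
        refs = {"ref1": "delta-5", "ref2": "delta-5"}
        # the only ref-containing clade above the candidate is subtended by
        # the weakly supported (70%) root edge -> unassigned at 75%
        result = assign_clade(t, "cand", refs, min_support=75, outgroup="out")
        assert result is None

    def test_mixed_labels_unassigned(self):
        t = read_newick(
            "((cand:0.1,(ref1:0.1,ref2:0.2)80:0.1)85:0.1,x:0.3,out:0.5);"
        )
        refs = {"ref1": "delta-5", "ref2": "elovl5"}
        node_result = assign_clade(t, "cand", refs, min_support=0, outgroup="out")
        assert node_result is None

    def test_missing_candidate(self):
        t = read_newick("((a:1,b:1)90:1,c:1,d:1);")
        with pytest.raises(ValueError):
            assign_clade(t, "zz", {"a": "x"})
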
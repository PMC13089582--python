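"""Pruning likelihood vs brute-force enumeration, and its invariances."""

import itertools

import numpy as np
import pytest

import piezorho as pz
from piezorho.likelihood import PruningEngine
from piezorho.models import _edge_P_from_Q
from piezorho.ratematrix import ReversibleRateMatrix


def make_engine(newick, sequences, partition, pi,
                params=pz.WSNParameters(3.0, 0.4, 0.8)):
    tree = pz.TaggedTree.from_newick(newick, path=False)
    aln = pz.CodonAlignment(taxa=list(sequences), sequences=dict(sequences))
    Q = pz.build_rate_matrix(params, partition, pi)
    R = ReversibleRateMatrix(Q, pi)
    engine = PruningEngine(aln, tree)
    edge_P = _edge_P_from_Q(tree, {"fg": R, "bg": R}, tree.edge_length)
    return tree, aln, engine, edge_P


def brute_force_loglik(tree, aln, edge_P, pi):
    """Enumerate all internal-node state assignments site by site."""
    matrix = aln.codon_matrix()
    internal = [v for v in range(tree.n_nodes) if not tree.is_leaf(v)]
    leaves = [v for v in range(tree.n_nodes) if tree.is_leaf(v)]
    total = 0.0
    for s in range(aln.n_codons):
        site_like = 0.0
        for assignment in itertools.product(range(61), repeat=len(internal)):
            state = dict(zip(internal, assignment))
            for v in leaves:
                state[v] = matrix[aln.taxa.index(tree.node_label(v)), s]
            prob = pi[state[tree.root_index]]
            for v in range(tree.n_nodes):
                if tree.parent[v] >= 0:
                    prob *= edge_P[v][state[int(tree.parent[v])], state[v]]
            site_like += prob
        total += np.log(site_like)
    return total


SMALL_CASES = [
    # (newick, sequences): up to 4 tips, up to 3 codon sites
    ("(A:0.1,B:0.2,C:0.15);",
     {"A": "TCCGCAATG", "B": "GCCGCAATG", "C": "TCCATGATG"}),
    ("((A:0.08,B:0.12):0.05,C:0.2);",
     {"A": "TCC", "B": "GCC", "C": "ATG"}),
    ("((A:0.08,B:0.12):0.05,(C:0.1,D:0.07):0.06);",
     {"A": "TCCGCA", "B": "GCCGCA", "C": "ATGGCA", "D": "ATGGGA"}),
    ("(((A:0.05,B:0.05):0.05,C:0.1):0.04,D:0.2);",
     {"A": "CTG", "B": "CCG", "C": "CTG", "D": "TTG"}),
]


class TestPruningAgainstEnumeration:
    @pytest.mark.parametrize("newick,sequences", SMALL_CASES)
    def test_matches_brute_force(self, newick, sequences, partition60, uniform_pi):
        """Single-class enumeration over 61^k internal assignments."""
        tree, aln, engine, edge_P = make_engine(newick, sequences, partition60,
                                                uniform_pi)
        ll = engine.log_likelihood(edge_P, uniform_pi)
        oracle = brute_force_loglik(tree, aln, edge_P, uniform_pi)
        assert ll == pytest.approx(oracle, abs=1e-8)

    def test_zero_branch_limit_is_log_pi(self, partition60):
        rng = np.random.default_rng(3)
        pi = rng.dirichlet(np.full(61, 2.0))
        seq = "TCCGCAATGCTG"
        tree, aln, engine, edge_P = make_engine(
            "(A:0.0,B:0.0);", {"A": seq, "B": seq}, partition60, pi)
        ll = engine.log_likelihood(edge_P, pi)
        idx = pz.genetics.codon_index_array(seq)
        assert ll == pytest.approx(float(np.log(pi[idx]).sum()), abs=1e-10)


class TestInvariances:
    def test_rerooting_invariance(self, partition60, uniform_pi):
        sequences = {"A": "TCCGCA", "B": "GCCGCA", "C": "ATGGCA"}
        lls = []
        for newick in ["(A:0.1,B:0.2,C:0.15);",
                       "((A:0.1,B:0.2):0.05,C:0.10);",
                       "((A:0.1,C:0.15):0.08,B:0.12);"]:
            _, _, engine, edge_P = make_engine(newick, sequences, partition60,
                                               uniform_pi)
            lls.append(engine.log_likelihood(edge_P, uniform_pi))
        assert max(lls) - min(lls) < 1e-9

    def test_taxon_and_site_order_invariance(self, partition60, uniform_pi):
        newick = "((A:0.08,B:0.12):0.05,C:0.2);"
        seqs = {"A": "TCCGCAATG", "B": "GCCGCAATG", "C": "TCCATGATG"}
        _, _, engine, edge_P = make_engine(newick, seqs, partition60, uniform_pi)
        base = engine.log_likelihood(edge_P, uniform_pi)

        reordered = {t: seqs[t] for t in ["C", "A", "B"]}
        _, _, engine2, edge_P2 = make_engine(newick, reordered, partition60,
                                             uniform_pi)
        assert engine2.log_likelihood(edge_P2, uniform_pi) == pytest.approx(base)

        shuffled = {t: s[3:] + s[:3] for t, s in seqs.items()}
        _, _, engine3, edge_P3 = make_engine(newick, shuffled, partition60,
                                             uniform_pi)
        assert engine3.log_likelihood(edge_P3, uniform_pi) == pytest.approx(base)

    def test_gaps_enter_as_missing_data(self, partition60, uniform_pi):
        """A fully gapped taxon contributes nothing: likelihood equals the
        two-taxon likelihood of the remaining data."""
        newick = "(A:0.1,B:0.2,C:0.15);"
        seqs = {"A": "TCCGCA", "B": "GCCGCA", "C": "------"}
        _, _, engine, edge_P = make_engine(newick, seqs, partition60, uniform_pi)
        ll_gapped = engine.log_likelihood(edge_P, uniform_pi)
        # C's edge integrates out; compare against star tree without C
        newick2 = "(A:0.1,B:0.2);"
        seqs2 = {"A": "TCCGCA", "B": "GCCGCA"}
        _, _, engine2, edge_P2 = make_engine(newick2, seqs2, partition60,
                                             uniform_pi)
        assert ll_gapped == pytest.approx(engine2.log_likelihood(edge_P2, uniform_pi),
                                          abs=1e-9)


class TestValidation:
    def test_taxon_mismatch_raises(self, partition60):
        tree = pz.TaggedTree.from_newick("(A:0.1,B:0.2,C:0.1);", path=False)
        aln = pz.CodonAlignment(taxa=["A", "B", "X"],
                                sequences={"A": "TCC", "B": "GCC", "X": "ATG"})
        with pytest.raises(ValueError, match="taxon mismatch"):
            PruningEngine(aln, tree)

    def test_empty_alignment_rejected(self):
        with pytest.raises(ValueError, match="empty alignment"):
            pz.CodonAlignment(taxa=[], sequences={})

    def test_internal_stop_codon_policy(self):
        tree = pz.TaggedTree.from_newick("(A:0.1,B:0.2);", path=False)
        aln = pz.CodonAlignment(taxa=["A", "B"],
                                sequences={"A": "TAAGCA", "B": "TCCGCA"})
        with pytest.raises(ValueError, match="stop codon"):
            PruningEngine(aln, tree, stop_policy="error")
        with pytest.warns(UserWarning, match="treated as missing"):
            PruningEngine(aln, tree, stop_policy="missing")


class TestMarginals:
    def test_tip_posterior_is_point_mass(self, partition60, uniform_pi):
        newick = "((A:0.08,B:0.12):0.05,C:0.2);"
        seqs = {"A": "TCCGCA", "B": "GCCGCA", "C": "ATGGCA"}
        tree, aln, engine, edge_P = make_engine(newick, seqs, partition60,
                                                uniform_pi)
        tips = tree.leaf_indices()
        marg = engine.node_marginals(edge_P, uniform_pi, nodes=[tips["A"]])
        post = marg[tips["A"]]
        idx = pz.genetics.codon_index_array(seqs["A"])
        for s in range(2):
            assert post[s, idx[s]] == pytest.approx(1.0)

    def test_root_marginal_matches_brute_bayes(self, partition60, uniform_pi):
        newick = "(A:0.1,B:0.2,C:0.15);"
        seqs = {"A": "TCCGCA", "B": "GCCGCA", "C": "TCCATG"}
        tree, aln, engine, edge_P = make_engine(newick, seqs, partition60,
                                                uniform_pi)
        marg = engine.node_marginals(edge_P, uniform_pi,
                                     nodes=[tree.root_index])[tree.root_index]
        matrix = aln.codon_matrix()
        tips = tree.leaf_indices()
        for s in range(aln.n_codons):
            post = np.array([
                uniform_pi[r] * np.prod([
                    edge_P[tips[t]][r, matrix[aln.taxa.index(t), s]]
                    for t in seqs])
                for r in range(61)])
            post /= post.sum()
            assert np.abs(marg[s] - post).max() < 1e-12

    def test_internal_marginal_matches_enumeration(self, partition60, uniform_pi):
        """Marginal at a non-root internal node against full enumeration."""
        newick = "((A:0.08,B:0.12)I:0.05,C:0.2);"
        seqs = {"A": "TCC", "B": "GCC", "C": "ATG"}
        tree, aln, engine, edge_P = make_engine(newick, seqs, partition60,
                                                uniform_pi)
        inner = tree.find_node("I")
        marg = engine.node_marginals(edge_P, uniform_pi, nodes=[inner])[inner]
        matrix = aln.codon_matrix()
        tips = tree.leaf_indices()
        joint = np.zeros(61)
        for x_inner in range(61):
            for x_root in range(61):
                prob = uniform_pi[x_root]
                prob *= edge_P[inner][x_root, x_inner]
                prob *= edge_P[tips["A"]][x_inner, matrix[aln.taxa.index("A"), 0]]
                prob *= edge_P[tips["B"]][x_inner, matrix[aln.taxa.index("B"), 0]]
                prob *= edge_P[tips["C"]][x_root, matrix[aln.taxa.index("C"), 0]]
                joint[x_inner] += prob
        joint /= joint.sum()
        assert np.abs(marg[0] - joint).max() < 1e-12

    def test_rows_normalized(self, small_sim, tagged_tree, partition60):
        fit = pz.BranchRadicalModel(small_sim.alignment, tagged_tree,
                                    partition60, shared_gamma=True).fit(restarts=1)
        posts = pz.marginal_ancestral_states(fit)
        for node_post in posts.values():
            assert np.allclose(node_post.probabilities.sum(axis=1), 1.0, atol=1e-9)
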
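"""Felsenstein pruning over codon states, with site-pattern compression.

The engine computes per-site log-likelihoods given per-edge transition
matrices, and marginal ancestral posteriors at any node via an outside
(preorder) pass. Missing data (gaps, ambiguity codes, optionally stops) enter
as all-ones tip partials. Per-pattern rescaling guards against underflow.
"""

from __future__ import annotations

import numpy as np

from .alignment import CodonAlignment
from .trees import TaggedTree


class PruningEngine:
    """Likelihood machinery bound to one alignment/tree pair.

    Parameters
    ----------
    alignment, tree : the data; tip labels must match exactly.
    stop_policy : "error" (default) or "missing" for internal stop codons.
    """

    def __init__(self, alignment: CodonAlignment, tree: TaggedTree,
                 stop_policy: str = "error"):
        if set(alignment.taxa) != set(tree.taxa):
            extra_a = sorted(set(alignment.taxa) - set(tree.taxa))
            extra_t = sorted(set(tree.taxa) - set(alignment.taxa))
            raise ValueError(
                f"taxon mismatch between alignment and tree "
                f"(alignment-only: {extra_a}, tree-only: {extra_t})"
            )
        self.alignment = alignment
        self.tree = tree
        self.n_states = alignment.code.n_codons

        matrix = alignment.codon_matrix(stop_policy=stop_policy)
        order = [alignment.taxa.index(t) for t in tree.taxa]
        matrix = matrix[order, :]  # rows now follow tree taxon order
        patterns, self.pattern_index, counts = np.unique(
            matrix.T, axis=0, return_inverse=True, return_counts=True
        )
        self.patterns = patterns.T  # (n_taxa_in_tree_order, n_patterns)
        self.counts = counts.astype(float)
        self.n_sites = matrix.shape[1]
        self.n_patterns = patterns.shape[0]

        self._leaf_row = {}
        row = 0
        for i in range(tree.n_nodes):
            if tree.is_leaf(i):
                self._leaf_row[i] = tree.taxa.index(tree.node_label(i))

        # children lists in postorder
        self._children = [[] for _ in range(tree.n_nodes)]
        for i in range(tree.n_nodes):
            p = tree.parent[i]
            if p >= 0:
                self._children[p].append(i)

    # -- inside (postorder) pass ------------------------------------------
    def _tip_partial(self, node: int) -> np.ndarray:
        states = self.patterns[self._leaf_row[node]]
        partial = np.zeros((self.n_patterns, self.n_states))
        observed = states >= 0
        partial[observed, states[observed]] = 1.0
        partial[~observed, :] = 1.0
        return partial

    def inside_partials(self, edge_P: dict[int, np.ndarray]):
        """Partial likelihoods below each node.

        edge_P[i] is the transition matrix for the edge above node i
        (parent-to-child direction). Returns (partials, logscale) where
        ``partials[i]`` has shape (n_patterns, n_states) and ``logscale[i]``
        is the per-pattern log of the factored-out scale for the subtree.
        """
        n = self.tree.n_nodes
        partials = [None] * n
        logscale = [np.zeros(self.n_patterns) for _ in range(n)]
        for i in range(n):
            if self.tree.is_leaf(i):
                partials[i] = self._tip_partial(i)
                continue
            acc = np.ones((self.n_patterns, self.n_states))
            scale = np.zeros(self.n_patterns)
            for c in self._children[i]:
                acc *= partials[c] @ edge_P[c].T
                scale += logscale[c]
            m = acc.max(axis=1)
            m[m == 0] = 1.0
            acc /= m[:, None]
            partials[i] = acc
            logscale[i] = scale + np.log(m)
        return partials, logscale

    def pattern_log_likelihoods(self, edge_P: dict[int, np.ndarray],
                                pi: np.ndarray) -> np.ndarray:
        partials, logscale = self.inside_partials(edge_P)
        root = self.tree.root_index
        lik = partials[root] @ pi
        with np.errstate(divide="ignore"):
            return np.log(lik) + logscale[root]

    def log_likelihood(self, edge_P: dict[int, np.ndarray], pi: np.ndarray) -> float:
        return float(self.counts @ self.pattern_log_likelihoods(edge_P, pi))

    def site_log_likelihoods(self, edge_P, pi) -> np.ndarray:
        """Per-alignment-site log-likelihoods (pattern-expanded)."""
        return self.pattern_log_likelihoods(edge_P, pi)[self.pattern_index]

    # -- outside (preorder) pass ------------------------------------------
    def node_marginals(self, edge_P: dict[int, np.ndarray], pi: np.ndarray,
                       nodes=None) -> dict[int, np.ndarray]:
        """Marginal posterior state probabilities at internal nodes and tips.

        Returns {node_index: (n_sites, n_states) posterior}, normalized per
        site. Under the reversible model these are root-placement invariant.
        """
        tree = self.tree
        wanted = set(range(tree.n_nodes)) if nodes is None else set(nodes)
        partials, _ = self.inside_partials(edge_P)
        # edgeL[c][p, i] = P(data below c | parent state i)
        edgeL = {
            c: partials[c] @ edge_P[c].T
            for c in range(tree.n_nodes)
            if tree.parent[c] >= 0
        }
        outside = [None] * tree.n_nodes
        root = tree.root_index
        outside[root] = np.broadcast_to(pi, (self.n_patterns, self.n_states)).copy()
        result = {}
        for v in range(tree.n_nodes - 1, -1, -1):  # preorder = reversed postorder
            if outside[v] is None:
                continue
            if v in wanted:
                post = outside[v] * partials[v]
                norm = post.sum(axis=1, keepdims=True)
                norm[norm == 0] = 1.0
                post = post / norm
                result[v] = post[self.pattern_index]
            for c in self._children[v]:
                acc = outside[v].copy()
                for s in self._children[v]:
                    if s != c:
                        acc *= edgeL[s]
                out_c = acc @ edge_P[c]
                m = out_c.max(axis=1, keepdims=True)
                m[m == 0] = 1.0
                outside[c] = out_c / m
        return result
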
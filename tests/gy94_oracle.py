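"""Independent Goldman-Yang codon model, coded from first principles.

Deliberately avoids the package's rate-matrix and pruning machinery: codons
are enumerated directly from the Biopython table, the matrix exponential goes
through scipy, and the likelihood recursion walks the dendropy tree node by
node with per-site Python loops. Used only as a cross-check oracle.
"""

import numpy as np
from Bio.Data import CodonTable
from scipy.linalg import expm

_TABLE = CodonTable.unambiguous_dna_by_id[1]
CODONS = sorted(_TABLE.forward_table)
AA = dict(_TABLE.forward_table)
INDEX = {c: i for i, c in enumerate(CODONS)}


def _one_diff(a, b):
    diffs = [(x, y) for x, y in zip(a, b) if x != y]
    return diffs[0] if len(diffs) == 1 else None


def gy94_rate_matrix(kappa, omega, pi):
    """Goldman-Yang Q, normalized to unit expected rate at stationarity."""
    n = len(CODONS)
    Q = np.zeros((n, n))
    for i, ci in enumerate(CODONS):
        for j, cj in enumerate(CODONS):
            if i == j:
                continue
            diff = _one_diff(ci, cj)
            if diff is None:
                continue
            rate = pi[j]
            if {diff[0], diff[1]} in ({"A", "G"}, {"C", "T"}):
                rate *= kappa
            if AA[ci] != AA[cj]:
                rate *= omega
            Q[i, j] = rate
    for i in range(n):
        Q[i, i] = -Q[i].sum()
    scale = -sum(pi[i] * Q[i, i] for i in range(n))
    return Q / scale


def gy94_log_likelihood(sequences, tree, kappa, omega, pi):
    """Log-likelihood of codon ``sequences`` (dict taxon -> nucleotide string)
    on a dendropy-style tree (piezorho TaggedTree accepted for its node
    arrays) via direct postorder recursion with scipy expm per edge."""
    Q = gy94_rate_matrix(kappa, omega, pi)
    n_states = len(CODONS)
    n_sites = len(next(iter(sequences.values()))) // 3

    P_edge = {}
    for v in range(tree.n_nodes):
        if tree.parent[v] >= 0:
            P_edge[v] = expm(Q * tree.edge_length[v])

    total = 0.0
    for s in range(n_sites):
        partial = {}
        for v in range(tree.n_nodes):
            if tree.is_leaf(v):
                codon = sequences[tree.node_label(v)][3 * s: 3 * s + 3].upper()
                vec = np.zeros(n_states)
                if codon in INDEX:
                    vec[INDEX[codon]] = 1.0
                else:
                    vec[:] = 1.0
                partial[v] = vec
            else:
                vec = np.ones(n_states)
                for c in range(tree.n_nodes):
                    if tree.parent[c] == v:
                        vec = vec * (P_edge[c] @ partial[c])
                partial[v] = vec
        total += np.log(float(pi @ partial[tree.root_index]))
    return total
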
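"""Marginal ancestral codon posteriors and the convergence screen.

Ancestral states are reconstructed marginally under the fitted codon model
itself (empirical Bayes, reversible-model outside/inside algorithm) rather
than under an external nucleotide model, keeping the pipeline self-contained;
node states are probabilistic and all downstream property statistics are
posterior expectations. The screen looks for codon sites whose expected
property value E[K0] *decreases* from the parent to the child node of every
designated foreground lineage, then intersects those convergent sites with
the high-posterior gamma1 site classes from the site-mixture fit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .models import BranchRadicalResults, SiteMixtureResults, _edge_P_from_Q
from .property_partition import AminoAcidPropertyScale
from .ratematrix import ReversibleRateMatrix, WSNParameters, build_rate_matrix


@dataclass
class NodePosterior:
    """Per-site posterior over sense codons at one node."""

    node: int
    label: str | None
    probabilities: np.ndarray = field(repr=False)  # (n_sites, n_codons)

    def most_probable_codons(self, code) -> list[str]:
        return [code.codons[i] for i in self.probabilities.argmax(axis=1)]


def _branch_edge_P(results: BranchRadicalResults):
    model = results.model
    kappa, omega = results.params["kappa"], results.params["omega"]
    if "gamma" in results.params:
        g_fg = g_bg = results.params["gamma"]
    else:
        g_fg, g_bg = results.params["gamma_fg"], results.params["gamma_bg"]
    mats = {}
    for tag, gamma in (("fg", g_fg), ("bg", g_bg)):
        Q = build_rate_matrix(WSNParameters(kappa, omega, gamma),
                              model.partition, model.pi, model.alignment.code)
        mats[tag] = ReversibleRateMatrix(Q, model.pi)
    return _edge_P_from_Q(model.tree, mats, results.branch_lengths)


def marginal_ancestral_states(results, nodes=None) -> dict[int, NodePosterior]:
    """Marginal posterior codon states at the requested nodes (all by default).

    ``results`` is a fitted :class:`BranchRadicalResults` or
    :class:`SiteMixtureResults`; for the mixture the per-class marginals are
    combined with the empirical-Bayes class posteriors per site.
    Nodes may be postorder indices or node labels.
    """
    model = results.model
    tree = model.tree
    node_idx = None
    if nodes is not None:
        node_idx = [n if isinstance(n, (int, np.integer)) else tree.find_node(n)
                    for n in nodes]

    if isinstance(results, BranchRadicalResults):
        edge_P = _branch_edge_P(results)
        marg = model.engine.node_marginals(edge_P, model.pi, nodes=node_idx)
    elif isinstance(results, SiteMixtureResults):
        x = results.xhat
        kappa, omega0, omega1, gamma0, gamma1, props, lengths = model._unpack(x)
        mats = model._class_matrices(kappa, omega0, omega1, gamma0, gamma1, props)
        class_ll, _ = model._pattern_class_loglik(x)
        log_post = np.log(props)[:, None] + class_ll
        log_post -= log_post.max(axis=0)
        w = np.exp(log_post)
        w /= w.sum(axis=0)
        site_w = w[:, model.engine.pattern_index]  # (n_classes, n_sites)
        marg = None
        for c, mat in enumerate(mats):
            eP = _edge_P_from_Q(tree, {"fg": mat, "bg": mat}, lengths)
            part = model.engine.node_marginals(eP, model.pi, nodes=node_idx)
            if marg is None:
                marg = {v: site_w[c][:, None] * post for v, post in part.items()}
            else:
                for v, post in part.items():
                    marg[v] += site_w[c][:, None] * post
    else:
        raise TypeError(f"unsupported results type {type(results).__name__}")

    return {
        v: NodePosterior(node=v, label=tree.node_label(v), probabilities=post)
        for v, post in marg.items()
    }


def expected_property(posterior: NodePosterior, scale: AminoAcidPropertyScale,
                      code) -> np.ndarray:
    """Per-site posterior expectation E[K0] = sum_codon P(codon) K0(aa(codon))."""
    prob = posterior.probabilities
    norm = prob.sum(axis=1)
    if not np.allclose(norm, 1.0, atol=1e-6):
        raise ValueError("posterior rows must sum to 1")
    k0 = np.array([scale[code.aa(c)] for c in code.codons])
    return prob @ k0


@dataclass(frozen=True)
class LineageSpec:
    """One foreground lineage: the branch from ``parent`` to ``child`` node
    (postorder indices or node labels)."""

    name: str
    parent: int | str
    child: int | str


@dataclass
class ConvergenceCandidate:
    site: int  # 1-based codon position
    per_lineage: dict[str, dict] = field(default_factory=dict)
    gamma1_posterior: float = float("nan")


@dataclass
class ScreenResult:
    decreasing_sites: dict[str, list[int]]
    convergent_sites: list[int]
    candidates: list[ConvergenceCandidate]
    table: pd.DataFrame = field(repr=False)


def convergence_screen(results, lineages, scale: AminoAcidPropertyScale,
                       site_posteriors: pd.DataFrame | None = None,
                       posterior_threshold: float = 0.95,
                       min_decrease: float = 0.0) -> ScreenResult:
    """Sites with convergent expected-K0 decreases on every listed lineage,
    intersected with the high-posterior gamma1 site set.

    Parameters
    ----------
    results : fitted codon-model Results used for ancestral reconstruction.
    lineages : iterable of :class:`LineageSpec` (>= 1; the convergence
        intersection is meaningful with >= 2).
    site_posteriors : DataFrame with a ``P(gamma1)`` column indexed by 1-based
        site (from :class:`SiteMixtureResults`); None skips the class filter.
    posterior_threshold : strict lower bound on P(gamma1) for candidates.
    min_decrease : minimum magnitude of the expected decrease (default 0:
        any strictly negative expected change counts).
    """
    if not 0.0 < posterior_threshold < 1.0:
        raise ValueError("posterior_threshold must lie strictly within (0, 1)")
    lineages = list(lineages)
    if not lineages:
        raise ValueError("at least one lineage must be specified")

    tree = results.model.tree
    code = results.model.alignment.code
    node_of = {}
    for lin in lineages:
        for endpoint in (lin.parent, lin.child):
            idx = endpoint if isinstance(endpoint, (int, np.integer)) else tree.find_node(endpoint)
            node_of[(lin.name, endpoint)] = int(idx)
    posts = marginal_ancestral_states(
        results, nodes=sorted(set(node_of.values()))
    )

    decreasing: dict[str, list[int]] = {}
    detail: dict[str, dict[int, dict]] = {}
    for lin in lineages:
        p_idx = node_of[(lin.name, lin.parent)]
        c_idx = node_of[(lin.name, lin.child)]
        ek_parent = expected_property(posts[p_idx], scale, code)
        ek_child = expected_property(posts[c_idx], scale, code)
        delta = ek_child - ek_parent
        sites = [int(s) + 1 for s in np.flatnonzero(delta < -float(min_decrease))]
        decreasing[lin.name] = sites
        mp_parent = posts[p_idx].most_probable_codons(code)
        mp_child = posts[c_idx].most_probable_codons(code)
        detail[lin.name] = {
            s: {
                "parent_codon": mp_parent[s - 1],
                "child_codon": mp_child[s - 1],
                "parent_aa": code.aa(mp_parent[s - 1]),
                "child_aa": code.aa(mp_child[s - 1]),
                "expected_delta_K0": float(delta[s - 1]),
            }
            for s in sites
        }

    convergent = sorted(set.intersection(*[set(v) for v in decreasing.values()]))

    candidates = []
    rows = []
    for s in convergent:
        if site_posteriors is not None:
            pg1 = float(site_posteriors.loc[s, "P(gamma1)"])
            if pg1 <= posterior_threshold:
                continue
        else:
            pg1 = float("nan")
        cand = ConvergenceCandidate(site=s, gamma1_posterior=pg1)
        for lin in lineages:
            cand.per_lineage[lin.name] = detail[lin.name][s]
            d = detail[lin.name][s]
            rows.append({
                "site": s, "lineage": lin.name,
                "from_codon": d["parent_codon"], "from_aa": d["parent_aa"],
                "to_codon": d["child_codon"], "to_aa": d["child_aa"],
                "expected_delta_K0": d["expected_delta_K0"],
                "P(gamma1)": pg1,
            })
        candidates.append(cand)

    table = pd.DataFrame(
        rows, columns=["site", "lineage", "from_codon", "from_aa", "to_codon",
                       "to_aa", "expected_delta_K0", "P(gamma1)"],
    )
    return ScreenResult(decreasing_sites=decreasing, convergent_sites=convergent,
                        candidates=candidates, table=table)
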
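"""Maximum-likelihood fitting of the property-partitioned codon model.

Two model families, both presented statsmodels-style (a Model bound to data
whose ``fit()`` returns a Results object):

* :class:`BranchRadicalModel` — one (kappa, omega) shared across the tree and
  either a single radical-rate scaler gamma (null) or separate gamma_fg /
  gamma_bg on foreground and background branches (alternative).
* :class:`SiteMixtureModel` — sites fall into four classes combining
  omega0 <= 1 / omega1 > 1 with gamma0 <= 1 / gamma1 > 1; the null variant
  keeps only the gamma0 classes (i) and (iii). Empirical-Bayes per-site class
  posteriors come with the fit.

Codon frequencies are estimated empirically (F3X4 default) and not counted as
free parameters; branch lengths may be fixed from the input tree or jointly
optimized (and are counted in k only when optimized).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .alignment import CodonAlignment
from .likelihood import PruningEngine
from .property_partition import P_GRID, AminoAcidPropertyScale, RadicalPartition, build_partition
from .ratematrix import (
    ReversibleRateMatrix,
    WSNParameters,
    build_rate_matrix,
    empirical_codon_frequencies,
)
from .trees import FG, TaggedTree

_KAPPA_BOUNDS = (np.log(1e-3), np.log(1e3))
_RATE_BOUNDS = (np.log(1e-6), np.log(1e3))
_LOW_BOUNDS = (np.log(1e-6), 0.0)          # omega0, gamma0 in (1e-6, 1]
_HIGH_BOUNDS = (np.log(1.0 + 1e-6), np.log(1e3))  # omega1, gamma1 in (1, 1e3]
_LOGIT_BOUNDS = (-15.0, 15.0)
_BL_BOUNDS = (np.log(1e-8), np.log(50.0))


def _edge_P_from_Q(tree: TaggedTree, Q_by_tag: dict[str, ReversibleRateMatrix],
                   lengths: np.ndarray) -> dict[int, np.ndarray]:
    out = {}
    for i in range(tree.n_nodes):
        if tree.parent[i] >= 0:
            out[i] = Q_by_tag[tree.edge_tag[i]].expm(lengths[i])
    return out


class _OptimizeMixin:
    """Shared multi-restart bounded quasi-Newton driver on transformed params."""

    def _maximize(self, negloglik, x0, bounds, restarts, seed, tol=1e-8):
        rng = np.random.default_rng(seed)
        best = None
        trace = []
        for attempt in range(max(1, restarts)):
            start = np.array(x0, dtype=float)
            if attempt > 0:
                start = start + rng.normal(scale=0.3, size=start.shape)
                start = np.clip(start, [b[0] for b in bounds], [b[1] for b in bounds])
            res = optimize.minimize(
                negloglik, start, method="L-BFGS-B", bounds=bounds,
                options={"ftol": tol, "maxiter": 500},
            )
            trace.append({"restart": attempt, "fun": float(res.fun),
                          "success": bool(res.success), "message": str(res.message)})
            if best is None or res.fun < best.fun - 1e-12:
                best = res
        return best, trace


# ---------------------------------------------------------------------------
# branch model
# ---------------------------------------------------------------------------

class BranchRadicalModel(_OptimizeMixin):
    """Branch variant: gamma may differ between fg and bg branches.

    Parameters
    ----------
    alignment, tree : data (taxa must agree; tree carries fg/bg tags).
    partition : RadicalPartition defining radical vs conservative changes.
    shared_gamma : fit the null model (single gamma) instead of gamma_fg/bg.
    freq_method : "F3X4" (default), "F61", or an explicit frequency vector.
    optimize_branch_lengths : jointly optimize branch lengths (counted in k);
        default False keeps the input tree's lengths (k excludes them).
    """

    def __init__(self, alignment: CodonAlignment, tree: TaggedTree,
                 partition: RadicalPartition, shared_gamma: bool = False,
                 freq_method="F3X4", optimize_branch_lengths: bool = False,
                 stop_policy: str = "error"):
        self.alignment = alignment
        self.tree = tree
        self.partition = partition
        self.shared_gamma = shared_gamma
        self.optimize_branch_lengths = optimize_branch_lengths
        self.engine = PruningEngine(alignment, tree, stop_policy=stop_policy)
        matrix = alignment.codon_matrix(stop_policy="missing" if stop_policy != "error" else "error")
        if isinstance(freq_method, str):
            self.pi = empirical_codon_frequencies(matrix, alignment.code, freq_method)
            self.freq_method = freq_method
        else:
            self.pi = np.asarray(freq_method, dtype=float)
            self.freq_method = "fixed"
        if not shared_gamma and not tree.fg_edges:
            raise ValueError("alternative branch model requires fg-tagged branches")

    # parameter vector: [log kappa, log omega, log gamma(, log gamma_bg)]
    #                   (+ log branch lengths if optimized)
    @property
    def _n_rate_params(self) -> int:
        return 3 if self.shared_gamma else 4

    def _unpack(self, x):
        kappa, omega = np.exp(x[0]), np.exp(x[1])
        if self.shared_gamma:
            gammas = {FG: np.exp(x[2]), "bg": np.exp(x[2])}
        else:
            gammas = {FG: np.exp(x[2]), "bg": np.exp(x[3])}
        if self.optimize_branch_lengths:
            lengths = np.zeros(self.tree.n_nodes)
            free = self.tree.free_edge_indices()
            lengths[free] = np.exp(x[self._n_rate_params:])
        else:
            lengths = self.tree.edge_length
        return kappa, omega, gammas, lengths

    def loglike(self, x) -> float:
        kappa, omega, gammas, lengths = self._unpack(x)
        Q_by_tag = {}
        for tag in ("fg", "bg"):
            params = WSNParameters(kappa=kappa, omega=omega, gamma=gammas[tag])
            Q = build_rate_matrix(params, self.partition, self.pi, self.alignment.code)
            Q_by_tag[tag] = ReversibleRateMatrix(Q, self.pi)
        if self.shared_gamma:
            Q_by_tag["fg"] = Q_by_tag["bg"]
        edge_P = _edge_P_from_Q(self.tree, Q_by_tag, lengths)
        return self.engine.log_likelihood(edge_P, self.pi)

    def fit(self, start=None, restarts: int = 3, seed: int = 0,
            tol: float = 1e-8) -> "BranchRadicalResults":
        if start is None:
            start = [np.log(2.0), np.log(0.5), np.log(0.3)]
            if not self.shared_gamma:
                start.append(np.log(0.3))
        bounds = [_KAPPA_BOUNDS, _RATE_BOUNDS, _RATE_BOUNDS]
        if not self.shared_gamma:
            bounds.append(_RATE_BOUNDS)
        if self.optimize_branch_lengths:
            free = self.tree.free_edge_indices()
            start = list(start) + [
                np.log(max(self.tree.edge_length[i], 1e-4)) for i in free
            ]
            bounds += [_BL_BOUNDS] * len(free)

        best, trace = self._maximize(lambda x: -self.loglike(x), start, bounds,
                                     restarts, seed, tol)
        kappa, omega, gammas, lengths = self._unpack(best.x)
        k = self._n_rate_params + (
            len(self.tree.free_edge_indices()) if self.optimize_branch_lengths else 0
        )
        params = {"kappa": kappa, "omega": omega}
        if self.shared_gamma:
            params["gamma"] = gammas["bg"]
        else:
            params["gamma_fg"] = gammas["fg"]
            params["gamma_bg"] = gammas["bg"]
        return BranchRadicalResults(
            model=self, params=params, llf=-float(best.fun), k=k,
            branch_lengths=np.array(lengths), converged=bool(best.success),
            optimizer_trace=trace, xhat=np.array(best.x),
        )


@dataclass
class BranchRadicalResults:
    """ML fit of the branch model; AIC = 2k - 2*llf."""

    model: BranchRadicalModel
    params: dict[str, float]
    llf: float
    k: int
    branch_lengths: np.ndarray = field(repr=False)
    converged: bool = True
    optimizer_trace: list = field(default_factory=list, repr=False)
    xhat: np.ndarray | None = field(default=None, repr=False)

    @property
    def aic(self) -> float:
        return 2 * self.k - 2 * self.llf

    @property
    def P(self) -> int:
        return self.model.partition.P

    def bse(self) -> dict[str, float]:
        """Delta-method standard errors from a central-difference Hessian of
        the log-likelihood in the log-parameter space (rate parameters only)."""
        n = self.model._n_rate_params
        x = self.xhat[:n].copy()
        full = self.xhat.copy()

        def f(sub):
            y = full.copy()
            y[:n] = sub
            return self.model.loglike(y)

        H = _numeric_hessian(f, x)
        cov = np.linalg.pinv(-H)
        names = list(self.params)
        se_log = np.sqrt(np.clip(np.diag(cov), 0, None))
        return {name: float(se * value)  # d(exp x) = exp(x) dx
                for name, se, value in zip(names, se_log, self.params.values())}

    def summary(self) -> str:
        lines = [
            "Branch radical/conservative codon model "
            f"({'null: shared gamma' if self.model.shared_gamma else 'alternative: gamma_fg/gamma_bg'})",
            f"  partition: top {self.P}% of |dK0| radical "
            f"(threshold {self.model.partition.threshold:.3f})",
            f"  taxa: {self.model.tree.n_taxa}   codon sites: {self.model.alignment.n_codons}",
            f"  log-likelihood: {self.llf:.3f}   k: {self.k}   AIC: {self.aic:.3f}",
            f"  converged: {self.converged}",
        ]
        for name, value in self.params.items():
            lines.append(f"  {name:>9s} = {value:.4f}")
        return "\n".join(lines)


def _numeric_hessian(f, x, h=1e-4):
    n = len(x)
    H = np.zeros((n, n))
    f0 = f(x)
    for i in range(n):
        for j in range(i, n):
            xpp = x.copy(); xpp[i] += h; xpp[j] += h
            xpm = x.copy(); xpm[i] += h; xpm[j] -= h
            xmp = x.copy(); xmp[i] -= h; xmp[j] += h
            xmm = x.copy(); xmm[i] -= h; xmm[j] -= h
            H[i, j] = H[j, i] = (f(xpp) - f(xpm) - f(xmp) + f(xmm)) / (4 * h * h)
    _ = f0
    return H


# ---------------------------------------------------------------------------
# site mixture model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SiteMixture:
    """The four-class (omega, gamma) mixture: classes (i)-(iv) are
    (omega0, gamma0), (omega0, gamma1), (omega1, gamma0), (omega1, gamma1)."""

    omega0: float
    omega1: float
    gamma0: float
    gamma1: float
    proportions: tuple[float, ...]

    CLASS_LABELS = ("i", "ii", "iii", "iv")

    def __post_init__(self):
        if not (0 < self.omega0 <= 1 < self.omega1):
            raise ValueError("require omega0 <= 1 < omega1")
        if not (0 < self.gamma0 <= 1 < self.gamma1):
            raise ValueError("require gamma0 <= 1 < gamma1")
        p = np.asarray(self.proportions)
        if np.any(p < 0) or not np.isclose(p.sum(), 1.0, atol=1e-8):
            raise ValueError("class proportions must be nonnegative and sum to 1")

    def class_params(self) -> list[tuple[float, float]]:
        return [
            (self.omega0, self.gamma0),
            (self.omega0, self.gamma1),
            (self.omega1, self.gamma0),
            (self.omega1, self.gamma1),
        ]


class SiteMixtureModel(_OptimizeMixin):
    """Site variant: four (omega, gamma) classes shared across branches.

    ``null=True`` restricts to the gamma0 classes (i) and (iii), the null of
    the positive-radical-selection test.
    """

    FULL_CLASSES = (0, 1, 2, 3)
    NULL_CLASSES = (0, 2)

    def __init__(self, alignment: CodonAlignment, tree: TaggedTree,
                 partition: RadicalPartition, null: bool = False,
                 freq_method="F3X4", optimize_branch_lengths: bool = False,
                 stop_policy: str = "error"):
        self.alignment = alignment
        self.tree = tree
        self.partition = partition
        self.null = null
        self.classes = self.NULL_CLASSES if null else self.FULL_CLASSES
        self.optimize_branch_lengths = optimize_branch_lengths
        self.engine = PruningEngine(alignment, tree, stop_policy=stop_policy)
        matrix = alignment.codon_matrix(stop_policy="missing" if stop_policy != "error" else "error")
        if isinstance(freq_method, str):
            self.pi = empirical_codon_frequencies(matrix, alignment.code, freq_method)
            self.freq_method = freq_method
        else:
            self.pi = np.asarray(freq_method, dtype=float)
            self.freq_method = "fixed"

    # x = [log kappa, log omega0, log(omega1), log gamma0(, log gamma1),
    #      logits...(len(classes)-1)] (+ log branch lengths)
    @property
    def _n_rate_params(self) -> int:
        base = 4 if self.null else 5
        return base + (len(self.classes) - 1)

    def _unpack(self, x):
        kappa = np.exp(x[0])
        omega0, omega1 = np.exp(x[1]), np.exp(x[2])
        gamma0 = np.exp(x[3])
        if self.null:
            gamma1 = None
            logits = x[4:4 + len(self.classes) - 1]
            off = 4 + len(self.classes) - 1
        else:
            gamma1 = np.exp(x[4])
            logits = x[5:5 + len(self.classes) - 1]
            off = 5 + len(self.classes) - 1
        z = np.concatenate([logits, [0.0]])
        z = z - z.max()
        props = np.exp(z) / np.exp(z).sum()
        if self.optimize_branch_lengths:
            lengths = np.zeros(self.tree.n_nodes)
            free = self.tree.free_edge_indices()
            lengths[free] = np.exp(x[off:])
        else:
            lengths = self.tree.edge_length
        return kappa, omega0, omega1, gamma0, gamma1, props, lengths

    def _class_matrices(self, kappa, omega0, omega1, gamma0, gamma1, props):
        pairs_all = [(omega0, gamma0), (omega0, gamma1), (omega1, gamma0),
                     (omega1, gamma1)]
        Qs, rates = [], []
        for ci, p in zip(self.classes, props):
            omega, gamma = pairs_all[ci]
            Q = build_rate_matrix(
                WSNParameters(kappa=kappa, omega=omega, gamma=gamma),
                self.partition, self.pi, self.alignment.code, normalize=False,
            )
            Qs.append(Q)
            rates.append(-float(self.pi @ np.diag(Q)))
        mean_rate = float(np.dot(props, rates))
        # joint scaling: branch lengths are expected substitutions per codon
        # under the mixture-averaged process
        return [ReversibleRateMatrix(Q / mean_rate, self.pi) for Q in Qs]

    def _pattern_class_loglik(self, x):
        kappa, omega0, omega1, gamma0, gamma1, props, lengths = self._unpack(x)
        mats = self._class_matrices(kappa, omega0, omega1, gamma0, gamma1, props)
        per_class = []
        for mat in mats:
            edge_P = _edge_P_from_Q(self.tree, {"fg": mat, "bg": mat}, lengths)
            per_class.append(self.engine.pattern_log_likelihoods(edge_P, self.pi))
        return np.vstack(per_class), props  # (n_classes, n_patterns)

    def loglike(self, x) -> float:
        class_ll, props = self._pattern_class_loglik(x)
        m = class_ll.max(axis=0)
        mix = np.log(props @ np.exp(class_ll - m)) + m
        return float(self.engine.counts @ mix)

    def fit(self, start=None, restarts: int = 3, seed: int = 0,
            tol: float = 1e-8) -> "SiteMixtureResults":
        if start is None:
            start = [np.log(2.0), np.log(0.2), np.log(2.0), np.log(0.2)]
            if not self.null:
                start.append(np.log(2.0))
            start += [0.0] * (len(self.classes) - 1)
        bounds = [_KAPPA_BOUNDS, _LOW_BOUNDS, _HIGH_BOUNDS, _LOW_BOUNDS]
        if not self.null:
            bounds.append(_HIGH_BOUNDS)
        bounds += [_LOGIT_BOUNDS] * (len(self.classes) - 1)
        if self.optimize_branch_lengths:
            free = self.tree.free_edge_indices()
            start = list(start) + [
                np.log(max(self.tree.edge_length[i], 1e-4)) for i in free
            ]
            bounds += [_BL_BOUNDS] * len(free)

        best, trace = self._maximize(lambda x: -self.loglike(x), start, bounds,
                                     restarts, seed, tol)
        kappa, omega0, omega1, gamma0, gamma1, props, lengths = self._unpack(best.x)
        k = self._n_rate_params + (
            len(self.tree.free_edge_indices()) if self.optimize_branch_lengths else 0
        )

        # empirical-Bayes site posteriors over the fitted classes
        class_ll, _ = self._pattern_class_loglik(best.x)
        log_post = np.log(props)[:, None] + class_ll
        log_post -= log_post.max(axis=0)
        post = np.exp(log_post)
        post /= post.sum(axis=0)
        site_post = post[:, self.engine.pattern_index].T  # (n_sites, n_classes)

        labels = [SiteMixture.CLASS_LABELS[c] for c in self.classes]
        posterior = pd.DataFrame(
            site_post, columns=[f"P({lab})" for lab in labels],
            index=pd.RangeIndex(1, self.alignment.n_codons + 1, name="site"),
        )
        gamma1_cols = [f"P({lab})" for c, lab in zip(self.classes, labels) if c in (1, 3)]
        posterior["P(gamma1)"] = posterior[gamma1_cols].sum(axis=1) if gamma1_cols else 0.0

        params = {"kappa": kappa, "omega0": omega0, "omega1": omega1,
                  "gamma0": gamma0}
        if gamma1 is not None:
            params["gamma1"] = gamma1
        proportions = {f"p_{lab}": float(p) for lab, p in zip(labels, props)}
        return SiteMixtureResults(
            model=self, params=params, proportions=proportions, llf=-float(best.fun),
            k=k, site_posteriors=posterior, branch_lengths=np.array(lengths),
            converged=bool(best.success), optimizer_trace=trace,
            xhat=np.array(best.x),
        )


@dataclass
class SiteMixtureResults:
    """ML fit of the site mixture model with empirical-Bayes site posteriors."""

    model: SiteMixtureModel
    params: dict[str, float]
    proportions: dict[str, float]
    llf: float
    k: int
    site_posteriors: pd.DataFrame = field(repr=False)
    branch_lengths: np.ndarray = field(repr=False)
    converged: bool = True
    optimizer_trace: list = field(default_factory=list, repr=False)
    xhat: np.ndarray | None = field(default=None, repr=False)

    @property
    def aic(self) -> float:
        return 2 * self.k - 2 * self.llf

    @property
    def P(self) -> int:
        return self.model.partition.P

    def gamma1_sites(self, threshold: float = 0.95) -> list[int]:
        """1-based sites with P(class ii or iv) above the posterior threshold."""
        col = self.site_posteriors["P(gamma1)"]
        return [int(s) for s in col.index[col > threshold]]

    def summary(self) -> str:
        kind = "null: classes (i),(iii)" if self.model.null else "alternative: classes (i)-(iv)"
        lines = [
            f"Site mixture radical/conservative codon model ({kind})",
            f"  partition: top {self.P}% of |dK0| radical",
            f"  taxa: {self.model.tree.n_taxa}   codon sites: {self.model.alignment.n_codons}",
            f"  log-likelihood: {self.llf:.3f}   k: {self.k}   AIC: {self.aic:.3f}",
            f"  converged: {self.converged}",
        ]
        for name, value in {**self.params, **self.proportions}.items():
            lines.append(f"  {name:>9s} = {value:.6f}")
        frac = sum(v for k_, v in self.proportions.items() if k_ in ("p_ii", "p_iv"))
        lines.append(f"  fraction of sites in gamma1 classes: {100 * frac:.1f}%")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# comparisons and the partition sweep
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ModelComparison:
    """AIC and likelihood-ratio comparison of nested fits.

    The chi-square reference distribution for the mixture comparison ignores
    the boundary/mixture irregularity (plain chi-square approximation)."""

    llf_null: float
    llf_alt: float
    aic_null: float
    aic_alt: float
    df: int
    lrt_stat: float
    p_value: float

    @property
    def delta_aic(self) -> float:
        return self.aic_alt - self.aic_null

    def summary(self) -> str:
        return (
            f"LRT: 2*dlnL = {self.lrt_stat:.3f} on {self.df} df, "
            f"p = {self.p_value:.4g}; AIC null {self.aic_null:.3f} vs "
            f"alt {self.aic_alt:.3f} (delta {self.delta_aic:+.3f})"
        )


def compare_models(null, alt, tol: float = 1e-4) -> ModelComparison:
    """AIC and chi-square LRT for a nested null/alternative fit pair."""
    df = alt.k - null.k
    if df <= 0:
        raise ValueError("alternative must have more free parameters than null")
    stat = 2.0 * (alt.llf - null.llf)
    if stat < -tol:
        import warnings

        warnings.warn(
            f"alternative log-likelihood below null by {-stat / 2:.3g}; "
            "optimizer convergence suspect"
        )
    stat = max(stat, 0.0)
    return ModelComparison(
        llf_null=null.llf, llf_alt=alt.llf, aic_null=null.aic, aic_alt=alt.aic,
        df=df, lrt_stat=stat, p_value=float(stats.chi2.sf(stat, df)),
    )


def fit_branch_model(alignment, tree, partition, restarts: int = 3,
                     seed: int = 0, **kwargs):
    """Fit the null (shared gamma) and alternative (gamma_fg/bg) branch models."""
    null = BranchRadicalModel(alignment, tree, partition, shared_gamma=True,
                              **kwargs).fit(restarts=restarts, seed=seed)
    alt = BranchRadicalModel(alignment, tree, partition, shared_gamma=False,
                             **kwargs).fit(restarts=restarts, seed=seed)
    return null, alt


def fit_site_model(alignment, tree, partition, restarts: int = 3,
                   seed: int = 0, **kwargs):
    """Fit the null (gamma0-only) and alternative (four-class) site models."""
    null = SiteMixtureModel(alignment, tree, partition, null=True,
                            **kwargs).fit(restarts=restarts, seed=seed)
    alt = SiteMixtureModel(alignment, tree, partition, null=False,
                           **kwargs).fit(restarts=restarts, seed=seed)
    return null, alt


@dataclass
class SweepResult:
    table: pd.DataFrame
    fits: dict = field(repr=False)
    failures: dict = field(default_factory=dict)

    @property
    def best_P(self) -> int:
        ok = self.table.dropna(subset=["aic_alt"])
        return int(ok.loc[ok["aic_alt"].idxmin(), "P"])

    def plot(self, ax=None):
        """AIC of the alternative model across the partition grid."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ok = self.table.dropna(subset=["aic_alt"])
        ax.plot(ok["P"], ok["aic_alt"], marker="o")
        ax.axvline(self.best_P, linestyle="--", color="grey")
        ax.set_xlabel("radical partition P (%)")
        ax.set_ylabel("AIC (alternative model)")
        return ax


def sweep_partitions(alignment, tree, scale: AminoAcidPropertyScale,
                     model_kind: str = "branch", P_grid=P_GRID,
                     **kwargs) -> SweepResult:
    """Fit null+alternative models for every P in the grid; best P by the
    alternative model's AIC. Per-P failures are recorded, not fatal."""
    if model_kind not in ("branch", "site"):
        raise ValueError("model_kind must be 'branch' or 'site'")
    P_grid = list(P_grid)
    if not P_grid or not set(P_grid) <= set(P_GRID):
        raise ValueError(f"P grid must be a nonempty subset of {P_GRID}")
    rows, fits, failures = [], {}, {}
    for P in P_grid:
        try:
            partition = build_partition(scale, P)
            fitter = fit_branch_model if model_kind == "branch" else fit_site_model
            null, alt = fitter(alignment, tree, partition, **kwargs)
            comp = compare_models(null, alt)
            row = {"P": P, "llf_null": null.llf, "llf_alt": alt.llf,
                   "aic_null": null.aic, "aic_alt": alt.aic,
                   "lrt_stat": comp.lrt_stat, "p_value": comp.p_value}
            for name, value in alt.params.items():
                row[name] = value
            rows.append(row)
            fits[P] = (null, alt)
        except Exception as exc:  # fail-soft across sweep cells
            failures[P] = repr(exc)
            rows.append({"P": P, "llf_null": np.nan, "llf_alt": np.nan,
                         "aic_null": np.nan, "aic_alt": np.nan,
                         "lrt_stat": np.nan, "p_value": np.nan})
    return SweepResult(table=pd.DataFrame(rows), fits=fits, failures=failures)
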
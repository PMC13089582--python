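"""Synthetic data with known truth for every pipeline stage.

Three generators, all deterministic given their seed:

* codon alignments evolved along a tagged phylogeny under the partitioned
  substitution process (branch- and/or site-heterogeneous gamma), with true
  site-class labels and true ancestral states recorded;
* Gaussian volume series whose fluctuations encode a target isothermal
  compressibility exactly (sigma^2 = kappa_T k_B T <V>);
* harmonic C-alpha trajectories: independent isotropic Gaussian fluctuation
  about fixed centres, with analytic per-atom RMSF sqrt(3 k_B T / k) and an
  analytic quasiharmonic mode spectrum.

The default phylogeny is a 12-taxon tree with two tagged deep-diving clades,
a reduced-scale version of the cetacean foreground/background layout. The
harmonic trajectories exist to validate estimators, not to imitate MD physics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .alignment import CodonAlignment
from .genetics import STANDARD_CODE, GeneticCode
from .property_partition import RadicalPartition
from .ratematrix import ReversibleRateMatrix, WSNParameters, build_rate_matrix
from .thermo import KB_J, EnsembleSeries
from .trajectory import CA_MASS_AMU, AMU_KG, CoordinateTrajectory
from .trees import TaggedTree

#: 12-taxon reduced-scale layout: two foreground ("deep-diving") clades
DEFAULT_TREE_NEWICK = (
    "(((T1#1:0.05,T2#1:0.05)DeepA#1:0.08,(T3:0.06,T4:0.04)N1:0.05)N2:0.04,"
    "((T5#1:0.05,T6#1:0.05)DeepB#1:0.08,(T7:0.04,T8:0.06)N3:0.05)N4:0.04,"
    "((T9:0.07,T10:0.05)N5:0.05,(T11:0.06,T12:0.06)N6:0.04)N7:0.03);"
)


def default_tagged_tree() -> TaggedTree:
    return TaggedTree.from_newick(DEFAULT_TREE_NEWICK, path=False)


# ---------------------------------------------------------------------------
# codon alignment simulation
# ---------------------------------------------------------------------------

@dataclass
class CodonSimSpec:
    """Specification of one alignment simulation.

    gamma may be a scalar (homogeneous) or {"fg": ., "bg": .} for the branch
    process. ``mixture`` activates site heterogeneity: a dict with keys
    omega0, omega1, gamma0, gamma1, proportions (4 values summing to 1);
    when set, omega/gamma are ignored. Frequencies default to uniform over
    sense codons. The seed is mandatory.
    """

    tree: TaggedTree
    partition: RadicalPartition
    n_codons: int
    seed: int
    kappa: float = 4.0
    omega: float = 0.5
    gamma: float | dict = 0.3
    mixture: dict | None = None
    freqs: np.ndarray | None = None
    code: GeneticCode = STANDARD_CODE

    def validate(self):
        if self.n_codons < 1:
            raise ValueError("n_codons must be >= 1")
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if self.mixture is not None:
            p = np.asarray(self.mixture["proportions"], dtype=float)
            if len(p) != 4 or np.any(p < 0) or not np.isclose(p.sum(), 1.0):
                raise ValueError("mixture proportions must be 4 nonnegative "
                                 "values summing to 1")
            if not (0 < self.mixture["omega0"] <= 1 < self.mixture["omega1"]):
                raise ValueError("mixture requires omega0 <= 1 < omega1")
            if not (0 < self.mixture["gamma0"] <= 1 < self.mixture["gamma1"]):
                raise ValueError("mixture requires gamma0 <= 1 < gamma1")
        if self.freqs is not None:
            pi = np.asarray(self.freqs, dtype=float)
            if pi.shape != (self.code.n_codons,) or np.any(pi < 0):
                raise ValueError("invalid frequency vector")


@dataclass
class CodonSimResult:
    alignment: CodonAlignment
    site_classes: np.ndarray | None  # per-site class index 0..3 (mixture only)
    node_states: dict[int, np.ndarray] = field(repr=False, default_factory=dict)
    spec: CodonSimSpec | None = None

    def truth_frame(self) -> pd.DataFrame:
        """Per-site truth table (class labels when simulated from a mixture)."""
        n = self.alignment.n_codons
        frame = pd.DataFrame({"site": np.arange(1, n + 1)})
        if self.site_classes is not None:
            labels = np.array(["i", "ii", "iii", "iv"])
            frame["true_class"] = labels[self.site_classes]
            frame["gamma1_class"] = np.isin(self.site_classes, (1, 3))
        return frame

    def ancestral_frame(self) -> pd.DataFrame:
        code = self.spec.code if self.spec else STANDARD_CODE
        rows = []
        for node, states in sorted(self.node_states.items()):
            rows.append({"node": node,
                         "codons": " ".join(code.codons[s] for s in states)})
        return pd.DataFrame(rows)


def _evolve_states(parent_states: np.ndarray, P: np.ndarray,
                   rng: np.random.Generator) -> np.ndarray:
    """Sample child states for each site from the rows of P."""
    child = np.empty_like(parent_states)
    for state in np.unique(parent_states):
        mask = parent_states == state
        child[mask] = rng.choice(P.shape[1], size=mask.sum(), p=P[state])
    return child


def simulate_codon_alignment(spec: CodonSimSpec) -> CodonSimResult:
    """Evolve codons from a root draw (from pi) down the tree; exact
    transition-matrix sampling per branch (not event-by-event)."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    code = spec.code
    tree = spec.tree
    pi = (np.asarray(spec.freqs, dtype=float) if spec.freqs is not None
          else np.full(code.n_codons, 1.0 / code.n_codons))
    pi = pi / pi.sum()

    # per-(site-class, tag) transition machinery
    if spec.mixture is None:
        gammas = (spec.gamma if isinstance(spec.gamma, dict)
                  else {"fg": spec.gamma, "bg": spec.gamma})
        class_of_site = None
        mats = {
            (0, tag): ReversibleRateMatrix(
                build_rate_matrix(
                    WSNParameters(spec.kappa, spec.omega, gammas[tag]),
                    spec.partition, pi, code),
                pi)
            for tag in ("fg", "bg")
        }
        site_class = np.zeros(spec.n_codons, dtype=np.int64)
    else:
        mix = spec.mixture
        pairs = [(mix["omega0"], mix["gamma0"]), (mix["omega0"], mix["gamma1"]),
                 (mix["omega1"], mix["gamma0"]), (mix["omega1"], mix["gamma1"])]
        props = np.asarray(mix["proportions"], dtype=float)
        site_class = rng.choice(4, size=spec.n_codons, p=props / props.sum())
        # joint scaling over the mixture, mirroring the fitted model
        raw = [build_rate_matrix(WSNParameters(spec.kappa, om, ga),
                                 spec.partition, pi, code, normalize=False)
               for om, ga in pairs]
        rates = [-float(pi @ np.diag(Q)) for Q in raw]
        mean_rate = float(np.dot(props, rates))
        mats = {(c, tag): ReversibleRateMatrix(raw[c] / mean_rate, pi)
                for c in range(4) for tag in ("fg", "bg")}
        class_of_site = site_class

    root = tree.root_index
    states = {root: rng.choice(code.n_codons, size=spec.n_codons, p=pi)}
    for v in range(tree.n_nodes - 1, -1, -1):  # preorder
        if v == root:
            continue
        parent = int(tree.parent[v])
        t = float(tree.edge_length[v])
        tag = tree.edge_tag[v]
        child = np.empty(spec.n_codons, dtype=np.int64)
        for c in np.unique(site_class):
            P = mats[(int(c), tag)].expm(t)
            mask = site_class == c
            child[mask] = _evolve_states(states[parent][mask], P, rng)
        states[v] = child

    sequences = {}
    taxa = []
    for i in range(tree.n_nodes):
        if tree.is_leaf(i):
            label = tree.node_label(i)
            taxa.append(label)
            sequences[label] = "".join(code.codons[s] for s in states[i])
    alignment = CodonAlignment(taxa=taxa, sequences=sequences, code=code)
    internal_states = {i: states[i] for i in range(tree.n_nodes)
                       if not tree.is_leaf(i)}
    return CodonSimResult(alignment=alignment, site_classes=class_of_site,
                          node_states=internal_states, spec=spec)


# ---------------------------------------------------------------------------
# ensemble / trajectory simulation
# ---------------------------------------------------------------------------

@dataclass
class EnsembleSimSpec:
    """Gaussian volume series and/or harmonic trajectory specification.

    kappa_T in GPa^-1, mean_volume in A^3, temperature K, force constants in
    kcal mol^-1 A^-2 per atom (broadcastable). The seed is mandatory.
    """

    seed: int
    n_frames: int = 1000
    temperature: float = 300.0
    kappa_T: float = 0.45
    mean_volume: float = 5.0e5
    pressure: float = 0.1
    energy_means: dict | None = None
    energy_sds: dict | None = None
    n_atoms: int = 20
    force_constants: float | np.ndarray = 2.0
    first_residue: int = 33

    def validate(self):
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if self.n_frames < 1 or self.temperature <= 0 or self.mean_volume <= 0:
            raise ValueError("frames, temperature and mean volume must be positive")
        if self.kappa_T < 0:
            raise ValueError("target kappa_T must be >= 0")
        if np.any(np.asarray(self.force_constants) <= 0):
            raise ValueError("force constants must be > 0")


def simulate_volume_series(spec: EnsembleSimSpec, label: str = "") -> EnsembleSeries:
    """i.i.d. Gaussian volumes with variance kappa_T k_B T <V>, so the
    fluctuation estimator recovers the target compressibility."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    kappa_pa = spec.kappa_T * 1e-9  # GPa^-1 -> Pa^-1
    var_m6 = kappa_pa * KB_J * spec.temperature * (spec.mean_volume * 1e-30)
    var_a6 = var_m6 * 1e60
    sigma = np.sqrt(var_a6)
    volumes = spec.mean_volume + sigma * rng.standard_normal(spec.n_frames)
    if np.any(volumes <= 0):
        raise ValueError("implied volume fluctuations cross zero; "
                         "increase mean_volume or lower kappa_T")
    frame = pd.DataFrame({
        "time": np.arange(spec.n_frames, dtype=float),
        "volume": volumes,
        "temperature": np.full(spec.n_frames, spec.temperature),
        "pressure": np.full(spec.n_frames, spec.pressure),
    })
    for name, mean in (spec.energy_means or {}).items():
        sd = (spec.energy_sds or {}).get(name, 0.0)
        frame[name] = mean + sd * rng.standard_normal(spec.n_frames)
    return EnsembleSeries(frame=frame, label=label)


@dataclass
class HarmonicTruth:
    rmsf: np.ndarray           # per atom, Angstrom
    entropy: float             # kcal/mol/K (quantum harmonic oscillator)
    omega: np.ndarray          # mode angular frequencies, rad/s


def harmonic_truth(spec: EnsembleSimSpec) -> HarmonicTruth:
    from .trajectory import harmonic_oscillator_entropy

    k = np.broadcast_to(np.asarray(spec.force_constants, dtype=float),
                        (spec.n_atoms,))
    kbt_kcal = KB_J * spec.temperature * 6.02214076e23 / 4184.0
    var_a2 = kbt_kcal / k  # per axis, A^2
    rmsf = np.sqrt(3.0 * var_a2)
    # mass-weighted eigenvalue per axis: m * var; omega = sqrt(kB T / lambda)
    lam = CA_MASS_AMU * AMU_KG * var_a2 * 1e-20
    omega = np.sqrt(KB_J * spec.temperature / lam)
    omega_modes = np.repeat(omega, 3)
    entropy = harmonic_oscillator_entropy(omega_modes, spec.temperature)
    return HarmonicTruth(rmsf=rmsf, entropy=entropy, omega=omega_modes)


def simulate_harmonic_trajectory(spec: EnsembleSimSpec,
                                 label: str = "") -> tuple[CoordinateTrajectory, HarmonicTruth]:
    """Atoms fluctuate independently and isotropically about fixed centres
    with per-axis variance k_B T / k_atom; returns the trajectory plus the
    analytic RMSF/entropy truth."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    k = np.broadcast_to(np.asarray(spec.force_constants, dtype=float),
                        (spec.n_atoms,))
    kbt_kcal = KB_J * spec.temperature * 6.02214076e23 / 4184.0
    sigma = np.sqrt(kbt_kcal / k)  # per axis, Angstrom
    centres = np.column_stack([
        3.8 * np.arange(spec.n_atoms),  # extended-chain spacing
        np.zeros(spec.n_atoms),
        np.zeros(spec.n_atoms),
    ])
    noise = rng.standard_normal((spec.n_frames, spec.n_atoms, 3))
    coords = centres[None, :, :] + noise * sigma[None, :, None]
    traj = CoordinateTrajectory(
        coords=coords, masses=np.full(spec.n_atoms, CA_MASS_AMU),
        residue_ids=spec.first_residue + np.arange(spec.n_atoms),
        label=label,
    )
    return traj, harmonic_truth(spec)
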
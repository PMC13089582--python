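# Methods

`piezorho` implements a two-track analysis of pressure-adaptive protein
evolution, developed around the case of rhodopsin in deep-diving cetaceans:
an **evolution track** that detects lineage- and site-specific acceleration of
amino-acid substitutions that radically change per-residue compressibility
(K0), and a **structure track** that converts paired low/high-pressure
molecular-ensemble data into thermodynamic measures of pressure tolerance.

## The partitioned codon substitution model

The instantaneous rate from sense codon *i* to *j* is

```
q_ij = 0                          if i and j differ at >1 nucleotide position
     = pi_j                       synonymous transversion
     = kappa * pi_j               synonymous transition
     = gamma_ij * omega_ij * pi_j        nonsynonymous transversion
     = gamma_ij * omega_ij * kappa * pi_j  nonsynonymous transition
```

with `(gamma_ij, omega_ij) = (1, omega)` for a *conservative* and
`(gamma, 1)` for a *radical* nonsynonymous change. Changes to or from stop
codons are excluded entirely. Setting `gamma = omega` recovers the standard
Goldman–Yang codon model, which is the engine's main correctness oracle. Q is
normalized to unit expected rate at stationarity so branch lengths are
expected substitutions per codon and comparable across partitions.

### Radical/conservative partitioning

Every nonsynonymous codon change reachable by a single nucleotide
substitution (196 unordered codon-pair events under the standard code) is
ranked by |dK0|. The top *P*% are radical, for *P* in {10, ..., 90}; the
best *P* is chosen by AIC over the fitted models. Design choices, both made
for determinism:

* ranking is at the level of *unordered codon-pair events* (an event and its
  reverse share |dK0| and must share a class);
* the threshold is inclusive — every event with |dK0| >= the P-quantile
  value is radical — so ties never depend on sort order.

### The compressibility scale

The packaged scale (`data/k0_scale_synthetic.tsv`, units m^3 mol^-1 Pa^-1 x
1e-15, magnitude convention) is a **synthetic reconstruction**, not a
transcription of a published table: the substitution deltas that the
motivating analyses report (S→A ≈ −4.29, L→P ≈ −8.39, I→V ≈ −1.14, K→H
−1.50, F→L −2.75, T→S −1.18) are encoded exactly and the remaining values
are plausible magnitudes fixed once. Every correctness test injects an
arbitrary 20-value scale through `AminoAcidPropertyScale`, so no scientific
conclusion of the test suite depends on the transcription; analyses intended
to match a specific published scale should load it with
`AminoAcidPropertyScale.from_file`.

### Branch and site variants

* **Branch model** (`BranchRadicalModel`): kappa and omega shared; the
  radical scaler gamma is common to all branches under the null and splits
  into `gamma_fg`/`gamma_bg` on foreground/background branches under the
  alternative. Foreground branches are declared by inline `#1` Newick tags or
  a clade list (both dialects must agree when given together).
* **Site model** (`SiteMixtureModel`): four site classes combining
  `omega0 <= 1 < omega1` with `gamma0 <= 1 < gamma1`:
  (i) (omega0, gamma0), (ii) (omega0, gamma1), (iii) (omega1, gamma0),
  (iv) (omega1, gamma1). The null keeps only (i) and (iii). Class rate
  matrices share branch lengths through a joint normalization by the
  mixture-averaged rate. Per-site empirical-Bayes class posteriors are
  returned; `P(gamma1) = P(ii) + P(iv)` drives the downstream screen.

Model comparison reports both AIC (`2k − 2l`) and the likelihood-ratio test
with a plain chi-square reference (`df = k_alt − k_null`). For the mixture
comparison this chi-square approximation ignores the boundary/mixture
irregularity; the comparison object documents df explicitly so users can
apply a different reference if desired.

### Parameter counting and frequencies

Codon frequencies are estimated empirically (F3X4 by default; F61 and fixed
vectors available) and are **not** counted as free parameters; this matches
the published branch-model AIC arithmetic for the 52-taxon rhodopsin fit
(k = 105 = 101 branch lengths + kappa + omega + gamma_fg + gamma_bg), which
leaves no room for counted frequency parameters. Branch lengths may be fixed
from the input tree (default here; k counts only rate parameters) or jointly
optimized (then counted in k).

### Optimization

Bounded L-BFGS-B on log-transformed parameters: kappa in (1e-3, 1e3],
omega0/gamma0 in (1e-6, 1], omega1/gamma1 in (1, 1e3], free omega/gamma in
(1e-6, 1e3]; mixture proportions through logits. Convergence tolerance 1e-8
on the log-likelihood, up to 3 seeded random restarts (tests and large
sweeps use 1 restart; the fits are well-behaved at the simulated sizes).
Transition probabilities use the reversible symmetrization
`diag(sqrt(pi)) Q diag(1/sqrt(pi))` eigendecomposed once per parameter
vector, which is exact, stable, and fast for repeated exponentials.

### Ancestral reconstruction and the convergence screen

Marginal ancestral codon posteriors are computed at every node by the
standard inside/outside algorithm under the *fitted codon model itself*
(posterior-weighted over mixture classes for the site model). This is a
deliberate deviation from reconstructing ancestors under a separate
nucleotide model (as the motivating study did with an external tool): the
codon-model reconstruction keeps the pipeline self-contained and uses the
same process for fitting and reconstruction. Exact agreement with
nucleotide-model node states is not expected; output metadata records the
method.

The screen computes, per designated lineage (a parent→child node pair, e.g.
the stems of the two deep-diving clades), the per-site expected property
change `E[K0]_child − E[K0]_parent` under the marginal posteriors. Sites
decreasing in *every* lineage (by more than a configurable minimum
magnitude; default 0 = any strict decrease) form the convergent set, which is
intersected with sites whose `P(gamma1)` exceeds the posterior threshold
(default 0.95). Working on expected values rather than point states is why a
single substitution type (e.g. S→A) can show slightly different deltas in
different lineages. In noisy reconstructions, near-zero negative expected
deltas are common; a minimum decrease magnitude of ~1 K0 unit suppresses
them in the synthetic studies.

## The structure track

All estimators operate on standard post-simulation artifacts: per-frame
observable tables (time, volume, temperature, pressure, energy terms,
optional precomputed polar solvation and solvent-accessible area) and
C-alpha coordinate trajectories (multi-frame PDB). The analysis window is
the trailing 50% of frames by default, mirroring the usual discard of the
equilibration phase. Uncertainties for ensemble averages use non-overlapping
block averaging (5 blocks by default); this is a methodological choice —
published mean ± SD values of this kind do not always state their averaging
protocol.

* **Isothermal compressibility**: `kappa_T = (<V^2> − <V>^2) / (k_B T <V>)`,
  reported in GPa^-1. The volume column is whatever the trajectory tool
  emits (typically the simulation-box volume standing in for the solute
  volume); output metadata flags this. T is the window-mean temperature.
* **RMSF**: every frame is least-squares superposed onto the iteratively
  refined mean structure (2 passes) before fluctuations are measured; the
  default residue selection is the transmembrane helix window 33–322
  (helices I–VIII), excluding poorly modelled termini. The two-pressure
  comparison is `RMSF_high − RMSF_low`, per residue and averaged.
* **Quasiharmonic entropy**: the mass-weighted covariance of C-alpha
  fluctuations (uniform carbon mass) is eigendecomposed; each mode of
  eigenvalue lambda is a harmonic oscillator at
  `omega = sqrt(k_B T / lambda)`; the quantum harmonic-oscillator entropy is
  summed over modes (classical variant behind a flag). The six smallest
  (residual rigid-body) eigenvalue modes are excluded, plus any mode below a
  relative eigenvalue floor of 1e-10 (with a warning). Superposition removes
  translation/rotation, so the estimator is invariant to global motion.
* **Conformational energy**: the per-frame sum of the bonded terms (bond,
  Urey–Bradley, proper/improper dihedral, CMAP) and intramolecular nonbonded
  terms (short-range and 1–4 Coulomb and Lennard-Jones), averaged over the
  window. kJ/mol inputs convert on read via a flag (factor 4.184).
* **Solvation free energy**: the polar part is consumed as a precomputed
  input (a Poisson–Boltzmann result; never computed here). The nonpolar part
  is `p V + gamma_st A` with the water surface tension
  `gamma_st = 0.1032 kcal mol^-1 A^-2` at 300 K (1 MPa·A^3 =
  1.439e-4 kcal/mol); the van der Waals term contributes <0.1% and is
  omitted, which the log records. A basic deterministic Shrake–Rupley SASA
  (probe 1.4 A, 960 golden-spiral points) is available when no area column
  is supplied.
* **Free-energy assembly**: `dG_p = dE_conf − T dS + (dmu_high − dmu_low)`.
  The identity holds exactly by construction; component uncertainties
  propagate in quadrature. Reference water dielectric constants at 0.1 and
  30 MPa (77.75 and 78.83) are carried in `ThermoConstants` for the external
  polar-solvation step.

## Synthetic data: what it emulates and what it does not

The generators exist to give every estimator a case with known truth:

* **Codon alignments** evolve by exact transition-matrix sampling down a
  tagged phylogeny (default: 12 taxa, two foreground "deep-diving" clades —
  a reduced-scale version of the cetacean layout), with branch- or
  site-heterogeneous gamma, and emit true site classes and true ancestral
  states. Default generating values for the branch process (kappa = 6,
  omega = 0.77, gamma_fg = 0.4, gamma_bg = 0.2, 300 codons) sit at the
  published rhodopsin point estimates; site-mixture proportions default near
  the published class proportions.
* **Volume series** are i.i.d. Gaussians with variance
  `kappa_T k_B T <V>`, so the fluctuation estimator has a closed-form
  target (0.45 GPa^-1 at 5e5 A^3 by default — magnitudes typical of a
  solvated-protein box).
* **Harmonic trajectories** fluctuate independently per atom
  (variance k_B T / k per axis) about fixed centres, giving analytic RMSF
  `sqrt(3 k_B T / k)` and an analytic mode spectrum.

None of this imitates molecular-dynamics physics: there is no solvent, no
coupling between residues, no pressure response, and real trajectories are
autocorrelated where the generators are i.i.d. Passing tests therefore
demonstrate estimator and inference correctness, not the published
simulation outcomes.

## Problem sizes and what is not reproduced

The validation studies run at desk scale: recovery uses the 12-taxon tree
with 300-codon alignments (tens of replicates, seeded), the mixture recovery
uses a few hundred codons, and the estimator oracles use 1e4–1e5 frames.
Two classes of published results are **not** reproducible here and are
deliberately out of scope:

* the real-data 52-taxon rhodopsin fits (Table-scale log-likelihoods, the
  P = 60 selection, gamma_fg = 0.415 vs gamma_bg = 0.201, the 26.9%
  gamma1 fraction, and the residue-299 candidate) require the externally
  assembled genome-derived coding sequences, which are inputs, not package
  artifacts; only the information-criterion arithmetic on those published
  numbers is checked exactly;
* the absolute kappa_T, dRMSF and dG_p magnitudes require the original
  100 ns explicit-solvent simulations; the estimators are instead validated
  against closed-form oracles, and the published component triplets are
  checked to assemble exactly (243 = −56 + 14 + 285; 346 = 98 − 26 + 274;
  252 = 2 − 1 + 251; 208 = −66 + 17 + 257 kcal/mol).

## Numerical and degenerate-input policies

* Gaps/ambiguity codes are missing data (tip partial = 1 over all codons);
  internal stop codons are a hard error by default, downgradable to missing
  with a warning.
* Transition-probability rows are clipped at 0 and renormalized (roundoff
  from the spectral exponential).
* `compare_models` warns when the alternative log-likelihood falls below the
  null beyond 1e-4 (optimizer diagnostics are attached to every Results
  object; non-convergence is flagged, never silent).
* Empty analysis windows, empty residue selections, negative branch lengths,
  malformed scales (missing or non-finite amino-acid values) and taxon
  mismatches all raise immediately with the offending item named.
* The partition builder rejects P outside the 10..90 grid unless explicitly
  overridden (the override is recorded on the partition object).

## Known limitations

* The branch model assumes a single (kappa, omega) across the tree; only
  gamma varies by branch tag.
* No rate variation beyond the four-class omega x gamma structure (no
  gamma-distributed rates), and no tree-topology search — the topology is an
  input.
* The quasiharmonic entropy is a C-alpha-only, harmonic, solvent-free
  approximation; between-condition differences are more meaningful than
  absolute values.
* The empirical-Bayes site posteriors ignore parameter-estimation
  uncertainty, as usual for this model family.
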
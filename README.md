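# piezorho

Tools for asking whether a protein's evolution shows signatures of adaptation
to hydrostatic pressure, and for measuring what a candidate substitution does
to pressure tolerance in molecular ensembles. The package was built around
the case of rhodopsin in deep-diving whales (sperm and beaked whales dive to
~1000–3000 m, i.e. up to ~30 MPa), but every component is generic over the
alignment, tree, property scale and trajectories you provide.

Two tracks:

1. **Evolution track.** A codon substitution model that splits nonsynonymous
   changes into *conservative* and *radical* classes by an amino-acid
   property — here per-residue compressibility K0 — and scales them
   relative to synonymous changes by `omega` and `gamma`:

   ```
   q_ij = 0                         i, j differ at more than one position
        = pi_j [kappa]              synonymous (transition: x kappa)
        = omega * pi_j [kappa]      conservative nonsynonymous
        = gamma * pi_j [kappa]      radical nonsynonymous
   ```

   With `gamma = omega` this is the standard Goldman–Yang model. The radical
   set is the top *P*% of single-nucleotide-accessible changes ranked by
   |dK0| (P chosen by AIC over a 10..90 grid). A **branch model** tests
   whether `gamma` is elevated on foreground branches (deep-diving lineages)
   via an LRT of `gamma_fg != gamma_bg`; a **site model** mixes four classes
   (omega <= 1 or > 1) x (gamma <= 1 or > 1) and flags sites with high
   posterior probability of radical acceleration. Marginal ancestral
   reconstruction plus a convergence screen then identifies sites whose
   expected K0 *decreased* independently along every foreground lineage and
   that sit in the high-posterior gamma > 1 classes.

2. **Structure track.** Estimators over paired low/high-pressure ensembles:
   isothermal compressibility from volume fluctuations
   (`kappa_T = (<V^2>-<V>^2)/(k_B T <V>)`), per-residue RMSF differences
   after least-squares superposition, quasiharmonic entropy from the
   mass-weighted C-alpha covariance, and the thermodynamic-cycle
   decomposition of the pressurization free energy
   `dG_p = dE_conf - T dS + ddmu` (nonpolar solvation `p V + gamma_st A`;
   polar solvation consumed as a precomputed input).

A synthetic-data module generates codon alignments with known branch/site
heterogeneity and ensembles/trajectories with closed-form compressibility,
RMSF and entropy, so every stage is testable without external data.

## Worked example

```python
import piezorho as pz

scale = pz.AminoAcidPropertyScale.packaged_k0()
partition = pz.build_partition(scale, P=60)
tree = pz.default_tagged_tree()          # 12 taxa, two fg-tagged clades

spec = pz.CodonSimSpec(tree=tree, partition=partition, n_codons=300,
                       seed=3, kappa=6.0, omega=0.77,
                       gamma={"fg": 0.4, "bg": 0.2})
sim = pz.simulate_codon_alignment(spec)

null, alt = pz.fit_branch_model(sim.alignment, tree, partition)
print(alt.summary())
print(pz.compare_models(null, alt).summary())
```

prints (this exact run):

```
Branch radical/conservative codon model (alternative: gamma_fg/gamma_bg)
  partition: top 60% of |dK0| radical (threshold 2.900)
  taxa: 12   codon sites: 300
  log-likelihood: -3124.520   k: 4   AIC: 6257.040
  converged: True
      kappa = 6.1120
      omega = 0.8060
   gamma_fg = 0.3667
   gamma_bg = 0.1548
LRT: 2*dlnL = 8.531 on 1 df, p = 0.003491; AIC null 6263.571 vs alt 6257.040 (delta -6.531)
```

The fitted radical-rate scalers land near the generating values
(gamma_fg = 0.4 on the tagged "deep-diving" clades, gamma_bg = 0.2
elsewhere — single-replicate estimates scatter around the truth; the
acceptance script reports the across-replicate medians), and the LRT
correctly prefers the two-gamma model on data where the foreground really is
accelerated. On the structure side:

```python
low  = pz.simulate_volume_series(pz.EnsembleSimSpec(seed=1, n_frames=50_000,
                                                    kappa_T=0.30))
high = pz.simulate_volume_series(pz.EnsembleSimSpec(seed=2, n_frames=50_000,
                                                    kappa_T=0.45))
c = pz.ThermoConstants(tail_fraction=1.0)
k_lo = pz.isothermal_compressibility(low, c)
k_hi = pz.isothermal_compressibility(high, c)
print(f"{k_lo:.4f}")                       # 0.2973 +/- 0.0048 GPa^-1
print(f"{k_hi:.4f}")                       # 0.4480 +/- 0.0080 GPa^-1
print(round(k_hi.value - k_lo.value, 4))   # 0.1507
```

recovering the planted compressibility difference of 0.15 GPa^-1.

A `piezorho` command-line interface wraps the same functionality
(`piezorho simulate ...`, `piezorho partition-sweep`, `piezorho fit-branch`,
`piezorho fit-site`, `piezorho screen`, `piezorho thermo ...`,
`piezorho run <config.yaml>` for the full pipeline).

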
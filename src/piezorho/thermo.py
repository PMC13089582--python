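"""Ensemble thermodynamics from per-frame observable tables.

Implements the post-simulation estimators for a two-pressure comparison of a
solvated protein: isothermal compressibility from equilibrium volume
fluctuations, mean conformational energy, the nonpolar solvation free energy
(pressure-volume plus surface-tension term; the van der Waals contribution is
below 0.1% and omitted), and the thermodynamic-cycle assembly

    dG_p = dE_conf - T dS + (dmu_high - dmu_low)

decomposing the free-energy cost of pressurization into conformational,
entropic, and solvation components. Uncertainties for ensemble averages come
from non-overlapping block averaging (default 5 blocks) over the analysis
window (default: the final 50% of frames); component uncertainties propagate
in quadrature through the assembly.

Units: volumes Angstrom^3, areas Angstrom^2, pressures MPa, temperatures K,
energies kcal/mol, compressibility GPa^-1.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

KB_J = 1.380649e-23          # Boltzmann constant, J/K
AVOGADRO = 6.02214076e23
HBAR_J_S = 1.054571817e-34
J_PER_KCAL = 4184.0
KB_KCAL_MOL = KB_J * AVOGADRO / J_PER_KCAL  # ~1.987e-3 kcal/mol/K
# 1 MPa * A^3 = 1e6 Pa * 1e-30 m^3 = 1e-24 J -> kcal/mol
MPA_A3_TO_KCAL_MOL = 1e-24 * AVOGADRO / J_PER_KCAL
KJ_TO_KCAL = 1.0 / 4.184

#: default bonded + intramolecular nonbonded term set for E_conf
CONFORMATIONAL_TERMS = (
    "bond", "urey_bradley", "proper_dihedral", "improper_dihedral", "cmap",
    "coulomb_sr", "lj_sr", "coulomb_14", "lj_14",
)


@dataclass(frozen=True)
class ThermoConstants:
    """Physical constants and analysis settings for the two-pressure workflow.

    dielectric constants are those of water at 0.1 and 30 MPa; surface_tension
    is water's at 300 K in kcal mol^-1 A^-2. ``tail_fraction`` selects the
    trailing part of each trajectory for analysis; ``n_blocks`` sets the block
    averaging used for uncertainties.
    """

    temperature: float = 300.0
    dielectric_low: float = 77.75
    dielectric_high: float = 78.83
    surface_tension: float = 0.1032
    tail_fraction: float = 0.5
    n_blocks: int = 5

    def __post_init__(self):
        for name in ("temperature", "dielectric_low", "dielectric_high",
                     "surface_tension", "tail_fraction"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 < self.tail_fraction <= 1:
            raise ValueError("tail_fraction must lie in (0, 1]")
        if self.n_blocks < 1:
            raise ValueError("n_blocks must be >= 1")


@dataclass
class EnsembleSeries:
    """Per-frame observables for one pressure condition.

    Wraps a DataFrame whose recognized columns are ``time``, ``volume`` (A^3),
    ``temperature`` (K), ``pressure`` (MPa), named energy terms (kcal/mol),
    and optionally ``polar_solvation`` (kcal/mol) and ``area`` (A^2).
    """

    frame: pd.DataFrame = field(repr=False)
    label: str = ""

    def __post_init__(self):
        if len(self.frame) == 0:
            raise ValueError("empty observable table")
        if "volume" in self.frame and (self.frame["volume"] <= 0).any():
            raise ValueError("volumes must be positive")
        if "temperature" in self.frame and (self.frame["temperature"] <= 0).any():
            raise ValueError("temperatures must be positive")

    def __len__(self) -> int:
        return len(self.frame)

    def window(self, tail_fraction: float) -> "EnsembleSeries":
        """The trailing ``tail_fraction`` of frames (the analysis window)."""
        n = len(self.frame)
        start = n - max(1, int(math.floor(n * tail_fraction)))
        return replace(self, frame=self.frame.iloc[start:].reset_index(drop=True))

    #: columns that are never energies (exempt from unit conversion)
    NON_ENERGY_COLUMNS = ("time", "volume", "temperature", "pressure", "area")

    @classmethod
    def from_file(cls, path, label: str = "",
                  energy_unit: str = "kcal") -> "EnsembleSeries":
        frame = pd.read_csv(path, sep=r"\s+|\t|,", engine="python", comment="#")
        if energy_unit == "kJ":
            for col in frame.columns:
                if col not in cls.NON_ENERGY_COLUMNS:
                    frame[col] = frame[col] * KJ_TO_KCAL
        elif energy_unit != "kcal":
            raise ValueError("energy_unit must be 'kcal' or 'kJ'")
        return cls(frame=frame, label=label)

    def to_file(self, path) -> None:
        self.frame.to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class BlockEstimate:
    """Mean with a block-averaging standard deviation."""

    value: float
    sd: float
    n_blocks: int

    def __format__(self, spec):
        return f"{format(self.value, spec)} +/- {format(self.sd, spec)}"


def _block_stats(values: np.ndarray, n_blocks: int, statistic) -> BlockEstimate:
    values = np.asarray(values, dtype=float)
    overall = float(statistic(values))
    blocks = [b for b in np.array_split(values, n_blocks) if len(b) >= 2]
    if len(blocks) < 2:
        return BlockEstimate(value=overall, sd=0.0, n_blocks=len(blocks))
    per_block = np.array([statistic(b) for b in blocks])
    return BlockEstimate(value=overall, sd=float(per_block.std(ddof=1)),
                         n_blocks=len(blocks))


def isothermal_compressibility(series: EnsembleSeries,
                               constants: ThermoConstants = ThermoConstants(),
                               apply_window: bool = True) -> BlockEstimate:
    """kappa_T = (<V^2> - <V>^2) / (k_B T <V>) from volume fluctuations, GPa^-1.

    T is the window-mean temperature (or ``constants.temperature`` if the
    table has no temperature column). The headline value uses the whole
    window; the SD comes from non-overlapping blocks.
    """
    win = series.window(constants.tail_fraction) if apply_window else series
    if "volume" not in win.frame:
        raise ValueError("observable table has no 'volume' column")
    if len(win) < 2:
        raise ValueError("analysis window must contain at least 2 frames")
    volumes = win.frame["volume"].to_numpy(dtype=float)
    T = (float(win.frame["temperature"].mean())
         if "temperature" in win.frame else constants.temperature)

    def kappa(v):
        var = v.var(ddof=0)  # A^6
        # A^6/A^3 = A^3 -> m^3 = 1e-30; per Pa; -> GPa^-1 = 1e9 per Pa
        return var / v.mean() * 1e-30 / (KB_J * T) * 1e9

    return _block_stats(volumes, constants.n_blocks, kappa)


def conformational_energy(series: EnsembleSeries,
                          term_names=CONFORMATIONAL_TERMS,
                          constants: ThermoConstants = ThermoConstants(),
                          apply_window: bool = True) -> BlockEstimate:
    """Window-mean of the summed conformational energy terms, kcal/mol."""
    win = series.window(constants.tail_fraction) if apply_window else series
    missing = [t for t in term_names if t not in win.frame.columns]
    if missing:
        raise ValueError(f"missing energy term column(s): {missing}")
    total = win.frame[list(term_names)].sum(axis=1).to_numpy(dtype=float)
    return _block_stats(total, constants.n_blocks, np.mean)


def nonpolar_solvation(pressure_mpa: float, volume_a3: float, area_a2: float,
                       constants: ThermoConstants = ThermoConstants()) -> float:
    """Nonpolar solvation free energy p*V + gamma*A in kcal/mol.

    The van der Waals term (<0.1% of the total) is intentionally omitted.
    """
    if min(pressure_mpa, volume_a3, area_a2) < 0:
        raise ValueError("pressure, volume and area must be nonnegative")
    return (pressure_mpa * volume_a3 * MPA_A3_TO_KCAL_MOL
            + constants.surface_tension * area_a2)


@dataclass(frozen=True)
class ConditionComponents:
    """Per-condition inputs to the free-energy assembly (kcal/mol except S)."""

    label: str
    e_conf: BlockEstimate
    entropy: float                 # S, kcal/mol/K
    solvation: BlockEstimate       # total dmu for this condition
    entropy_sd: float = 0.0


@dataclass(frozen=True)
class FreeEnergyDecomposition:
    """dG_p = dE_conf + (-T dS) + ddmu; the identity holds exactly by
    construction and each component carries its propagated uncertainty."""

    delta_e_conf: BlockEstimate
    minus_t_delta_s: BlockEstimate
    delta_delta_mu: BlockEstimate
    delta_g: BlockEstimate
    temperature: float
    mu_low: float = float("nan")
    mu_high: float = float("nan")

    def summary(self) -> str:
        return "\n".join([
            "Pressure free-energy decomposition (kcal/mol)",
            f"  dE_conf  = {self.delta_e_conf:8.2f}",
            f"  -T dS    = {self.minus_t_delta_s:8.2f}   (T = {self.temperature:.1f} K)",
            f"  ddmu     = {self.delta_delta_mu:8.2f}",
            f"  dG_p     = {self.delta_g:8.2f}",
        ])


def _diff(high: BlockEstimate, low: BlockEstimate) -> BlockEstimate:
    return BlockEstimate(value=high.value - low.value,
                         sd=math.hypot(high.sd, low.sd),
                         n_blocks=min(high.n_blocks, low.n_blocks))


def free_energy_shift(low: ConditionComponents, high: ConditionComponents,
                      constants: ThermoConstants = ThermoConstants()) -> FreeEnergyDecomposition:
    """Assemble the pressurization free-energy change from per-condition
    components (low = atmospheric, high = elevated pressure)."""
    T = constants.temperature
    de = _diff(high.e_conf, low.e_conf)
    mtds = BlockEstimate(
        value=-T * (high.entropy - low.entropy),
        sd=T * math.hypot(high.entropy_sd, low.entropy_sd),
        n_blocks=1,
    )
    ddmu = _diff(high.solvation, low.solvation)
    dg = BlockEstimate(
        value=de.value + mtds.value + ddmu.value,
        sd=math.hypot(de.sd, mtds.sd, ddmu.sd),
        n_blocks=min(de.n_blocks, ddmu.n_blocks),
    )
    return FreeEnergyDecomposition(
        delta_e_conf=de, minus_t_delta_s=mtds, delta_delta_mu=ddmu, delta_g=dg,
        temperature=T, mu_low=low.solvation.value, mu_high=high.solvation.value,
    )


def assemble_free_energy(delta_e_conf: float, minus_t_delta_s: float,
                         delta_delta_mu: float) -> float:
    """The bare assembly identity dG_p = dE_conf + (-T dS) + ddmu."""
    return delta_e_conf + minus_t_delta_s + delta_delta_mu


def solvation_free_energy(series: EnsembleSeries, pressure_mpa: float,
                          constants: ThermoConstants = ThermoConstants(),
                          polar: float | None = None,
                          apply_window: bool = True) -> BlockEstimate:
    """Per-condition dmu: precomputed polar part plus computed nonpolar part.

    The polar component (a Poisson-Boltzmann result) is consumed from the
    ``polar_solvation`` column or the ``polar`` scalar — never computed here.
    """
    win = series.window(constants.tail_fraction) if apply_window else series
    if polar is None:
        if "polar_solvation" not in win.frame:
            raise ValueError("no polar solvation input (column or scalar)")
        polar_values = win.frame["polar_solvation"].to_numpy(dtype=float)
    else:
        polar_values = np.full(len(win), float(polar))
    if "volume" not in win.frame or "area" not in win.frame:
        raise ValueError("solvation requires 'volume' and 'area' columns")
    nonpolar = (pressure_mpa * win.frame["volume"].to_numpy(dtype=float)
                * MPA_A3_TO_KCAL_MOL
                + constants.surface_tension * win.frame["area"].to_numpy(dtype=float))
    if pressure_mpa < 0:
        raise ValueError("pressure must be nonnegative")
    return _block_stats(polar_values + nonpolar, constants.n_blocks, np.mean)
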
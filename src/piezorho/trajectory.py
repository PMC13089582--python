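"""C-alpha coordinate trajectories: superposition, RMSF, quasiharmonic entropy.

All flexibility metrics remove rigid-body motion first by least-squares
superposition of every frame onto the (iteratively refined) mean structure,
so they are invariant to global rotations/translations of the input. The
default residue selection for RMSF comparisons is the transmembrane helix
window 33-322 (helices I-VIII), excluding the poorly modelled termini.

The quasiharmonic entropy eigendecomposes the mass-weighted covariance matrix
of C-alpha fluctuations; each mode of eigenvalue lambda_i is treated as a
harmonic oscillator of frequency omega_i = sqrt(k_B T / lambda_i) and the
quantum harmonic-oscillator entropy is summed over modes (a classical-
oscillator variant is available behind a flag). The six residual rigid-body
modes (the smallest eigenvalues after superposition) are excluded.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .thermo import AVOGADRO, HBAR_J_S, J_PER_KCAL, KB_J, ThermoConstants

AMU_KG = 1.66053906660e-27
CA_MASS_AMU = 12.011  # uniform C-alpha carbon mass for weighting
HELIX_WINDOW = (33, 322)  # default residue selection, inclusive


@dataclass
class CoordinateTrajectory:
    """frames x atoms x 3 coordinates (Angstrom) with per-atom metadata."""

    coords: np.ndarray = field(repr=False)
    masses: np.ndarray = field(repr=False)
    residue_ids: np.ndarray = field(repr=False)
    names: list[str] = field(default_factory=list)
    label: str = ""

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (frames, atoms, 3)")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite coordinates")
        n = self.coords.shape[1]
        self.masses = np.asarray(self.masses, dtype=float)
        self.residue_ids = np.asarray(self.residue_ids, dtype=np.int64)
        if self.masses.shape != (n,) or self.residue_ids.shape != (n,):
            raise ValueError("per-atom arrays must match the atom count")
        if not self.names:
            self.names = ["CA"] * n

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    def select_residues(self, residue_range=None) -> "CoordinateTrajectory":
        """Restrict to residues in the closed range (lo, hi); None keeps all."""
        if residue_range is None:
            return self
        lo, hi = residue_range
        mask = (self.residue_ids >= lo) & (self.residue_ids <= hi)
        if not mask.any():
            raise ValueError(
                f"residue selection {residue_range} matches no atoms "
                f"(available: {self.residue_ids.min()}..{self.residue_ids.max()})"
            )
        return CoordinateTrajectory(
            coords=self.coords[:, mask, :], masses=self.masses[mask],
            residue_ids=self.residue_ids[mask],
            names=[n for n, m in zip(self.names, mask) if m], label=self.label,
        )

    def tail(self, fraction: float) -> "CoordinateTrajectory":
        n = self.n_frames
        start = n - max(1, int(math.floor(n * fraction)))
        return CoordinateTrajectory(
            coords=self.coords[start:], masses=self.masses,
            residue_ids=self.residue_ids, names=list(self.names), label=self.label,
        )

    # -- multi-frame PDB IO (MDAnalysis-backed) ---------------------------
    @classmethod
    def from_pdb(cls, path, selection: str = "name CA", label: str = "") -> "CoordinateTrajectory":
        import MDAnalysis as mda

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            u = mda.Universe(str(path))
            ag = u.select_atoms(selection)
            if len(ag) == 0:
                raise ValueError(f"selection {selection!r} matches no atoms")
            coords = np.array([ag.positions.copy() for _ in u.trajectory])
        return cls(
            coords=coords, masses=np.full(len(ag), CA_MASS_AMU),
            residue_ids=np.asarray(ag.resids, dtype=np.int64),
            names=[str(n) for n in ag.names], label=label or str(path),
        )

    def to_pdb(self, path) -> None:
        import MDAnalysis as mda

        n = self.n_atoms
        resids = self.residue_ids
        _, resindex = np.unique(resids, return_inverse=True)
        u = mda.Universe.empty(
            n_atoms=n, n_residues=len(np.unique(resids)),
            atom_resindex=resindex, trajectory=True,
        )
        u.add_TopologyAttr("names", self.names)
        u.add_TopologyAttr("resids", np.unique(resids))
        u.add_TopologyAttr("resnames", ["ALA"] * len(np.unique(resids)))
        u.add_TopologyAttr("elements", ["C"] * n)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            with mda.Writer(str(path), n_atoms=n, multiframe=True) as writer:
                for frame in self.coords:
                    u.atoms.positions = frame
                    writer.write(u.atoms)


# ---------------------------------------------------------------------------
# superposition
# ---------------------------------------------------------------------------

def _kabsch(mobile: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Least-squares superpose one frame onto the reference (both (N, 3))."""
    mob_c = mobile - mobile.mean(axis=0)
    ref_c = reference - reference.mean(axis=0)
    H = mob_c.T @ ref_c
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(U @ Vt))
    D = np.diag([1.0, 1.0, d])
    R = U @ D @ Vt
    return mob_c @ R + reference.mean(axis=0)


def superpose(traj: CoordinateTrajectory, iterations: int = 2) -> CoordinateTrajectory:
    """Superpose every frame onto the iteratively refined mean structure."""
    coords = traj.coords.copy()
    reference = coords[0]
    for _ in range(max(1, iterations)):
        coords = np.array([_kabsch(frame, reference) for frame in coords])
        reference = coords.mean(axis=0)
    return CoordinateTrajectory(
        coords=coords, masses=traj.masses, residue_ids=traj.residue_ids,
        names=list(traj.names), label=traj.label,
    )


# ---------------------------------------------------------------------------
# RMSF
# ---------------------------------------------------------------------------

def rmsf_profile(traj: CoordinateTrajectory,
                 residue_range=HELIX_WINDOW, clip_to_available: bool = True,
                 superpose_frames: bool = True) -> pd.Series:
    """Per-residue RMSF (Angstrom) after superposition onto the mean.

    ``residue_range`` defaults to the helix window 33-322; with
    ``clip_to_available`` the window is intersected with the residues present
    (an empty intersection is an error). Pass None to keep every residue.
    """
    if residue_range is not None and clip_to_available:
        lo = max(residue_range[0], int(traj.residue_ids.min()))
        hi = min(residue_range[1], int(traj.residue_ids.max()))
        if lo > hi:
            raise ValueError(
                f"selection {residue_range} does not intersect residues "
                f"{traj.residue_ids.min()}..{traj.residue_ids.max()}"
            )
        residue_range = (lo, hi)
    sub = traj.select_residues(residue_range)
    if superpose_frames:
        sub = superpose(sub)
    mean = sub.coords.mean(axis=0)
    sq = ((sub.coords - mean) ** 2).sum(axis=2).mean(axis=0)
    rmsf = np.sqrt(sq)
    return pd.Series(rmsf, index=pd.Index(sub.residue_ids, name="residue"),
                     name="rmsf")


def delta_rmsf(high: CoordinateTrajectory, low: CoordinateTrajectory,
               residue_range=HELIX_WINDOW, **kwargs):
    """Per-residue and mean RMSF difference (high-pressure minus low).

    Returns (per_residue Series, mean float)."""
    r_high = rmsf_profile(high, residue_range=residue_range, **kwargs)
    r_low = rmsf_profile(low, residue_range=residue_range, **kwargs)
    if not r_high.index.equals(r_low.index):
        raise ValueError("residue selections of the two conditions differ")
    diff = r_high - r_low
    return diff, float(diff.mean())


# ---------------------------------------------------------------------------
# quasiharmonic entropy
# ---------------------------------------------------------------------------

def harmonic_oscillator_entropy(omega: np.ndarray, temperature: float,
                                classical: bool = False) -> float:
    """Entropy (kcal/mol/K) of independent harmonic modes at angular
    frequencies ``omega`` (rad/s)."""
    omega = np.atleast_1d(np.asarray(omega, dtype=float))
    x = HBAR_J_S * omega / (KB_J * temperature)
    if classical:
        s_per_kb = 1.0 - np.log(x)
    else:
        with np.errstate(over="ignore"):
            s_per_kb = x / np.expm1(x) - np.log1p(-np.exp(-x))
    s_j_mol_k = KB_J * AVOGADRO * np.sum(s_per_kb)
    return float(s_j_mol_k / J_PER_KCAL)


def quasiharmonic_entropy(traj: CoordinateTrajectory,
                          constants: ThermoConstants = ThermoConstants(),
                          classical: bool = False,
                          superpose_frames: bool = True,
                          drop_rigid_modes: int = 6,
                          eigenvalue_rtol: float = 1e-10) -> float:
    """Quasiharmonic vibrational entropy S (kcal/mol/K) of the fluctuations.

    Modes with eigenvalues below ``eigenvalue_rtol`` times the largest are
    treated as numerically singular and dropped with a warning (beyond the
    ``drop_rigid_modes`` smallest, which are always excluded)."""
    n_dof = 3 * traj.n_atoms
    if traj.n_frames < 2:
        raise ValueError("entropy requires at least 2 frames")
    if traj.n_frames < n_dof:
        warnings.warn(
            f"only {traj.n_frames} frames for {n_dof} degrees of freedom; "
            "covariance will be rank-deficient"
        )
    work = superpose(traj) if superpose_frames else traj
    X = work.coords.reshape(work.n_frames, n_dof)  # Angstrom
    X = X - X.mean(axis=0)
    cov = (X.T @ X) / work.n_frames  # A^2
    w = np.repeat(np.sqrt(work.masses * AMU_KG), 3)
    cov_mw = cov * 1e-20 * np.outer(w, w)  # kg m^2
    eigvals = np.linalg.eigvalsh(cov_mw)[::-1]  # descending

    if drop_rigid_modes:
        eigvals = eigvals[: max(0, len(eigvals) - drop_rigid_modes)]
    floor = (eigvals.max() if len(eigvals) else 0.0) * eigenvalue_rtol
    kept = eigvals[eigvals > floor]
    if len(kept) < len(eigvals):
        warnings.warn(
            f"dropped {len(eigvals) - len(kept)} near-singular covariance modes"
        )
    if len(kept) == 0:
        return 0.0
    T = constants.temperature
    omega = np.sqrt(KB_J * T / kept)
    return harmonic_oscillator_entropy(omega, T, classical=classical)


def entropy_difference(high: CoordinateTrajectory, low: CoordinateTrajectory,
                       constants: ThermoConstants = ThermoConstants(),
                       **kwargs) -> dict:
    """S per condition, dS = S_high - S_low, and -T dS (kcal/mol)."""
    s_high = quasiharmonic_entropy(high, constants, **kwargs)
    s_low = quasiharmonic_entropy(low, constants, **kwargs)
    ds = s_high - s_low
    return {
        "S_low": s_low, "S_high": s_high, "dS": ds,
        "minus_T_dS": -constants.temperature * ds,
    }


# ---------------------------------------------------------------------------
# Shrake-Rupley solvent-accessible surface area
# ---------------------------------------------------------------------------

def _sphere_points(n: int) -> np.ndarray:
    """Deterministic quasi-uniform points on the unit sphere (golden spiral)."""
    k = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * k / n)
    theta = math.pi * (1.0 + math.sqrt(5.0)) * k
    return np.column_stack([
        np.cos(theta) * np.sin(phi), np.sin(theta) * np.sin(phi), np.cos(phi)
    ])


def shrake_rupley_sasa(coords: np.ndarray, radii=1.7, probe: float = 1.4,
                       n_points: int = 960) -> np.ndarray:
    """Per-atom solvent-accessible surface area (A^2) for one frame.

    A fixed golden-spiral point set makes the result deterministic. A single
    isolated atom gets exactly 4*pi*(r+probe)^2 times the exposed fraction 1.
    """
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[0]
    radii = np.broadcast_to(np.asarray(radii, dtype=float), (n,)).copy()
    extended = radii + probe
    unit = _sphere_points(n_points)
    areas = np.empty(n)
    for i in range(n):
        points = coords[i] + extended[i] * unit
        exposed = np.ones(n_points, dtype=bool)
        for j in range(n):
            if j == i:
                continue
            if np.linalg.norm(coords[j] - coords[i]) > extended[i] + extended[j]:
                continue
            d2 = ((points - coords[j]) ** 2).sum(axis=1)
            exposed &= d2 > extended[j] ** 2
        areas[i] = 4.0 * math.pi * extended[i] ** 2 * exposed.mean()
    return areas
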
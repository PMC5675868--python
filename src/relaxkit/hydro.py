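"""Analytical-ultracentrifugation arithmetic and single-species SE fitting.

Implements the desk calculations used to infer protein oligomeric state from
hydrodynamic measurements:

* the Svedberg equation  M = s·R·T / (D·(1 − v̄ρ)),
* correction of an experimental sedimentation coefficient to standard
  conditions (water, 20 °C),
* the frictional ratio f/f0 against the equivalent anhydrous sphere,
* assignment of an integer stoichiometry n from an apparent mass and a
  monomer mass,
* nonlinear least-squares fitting of a single-species sedimentation-
  equilibrium (SE) gradient  a(r) = baseline + c0·exp(σ(r² − r0²)/2) with
  σ = M(1 − v̄ρ)ω²/(RT).

Units follow AUC practice: s in Svedberg (1 S = 1e-13 s), D in μm²/s,
masses in Da (g/mol), ρ in g/mL, η in poise, radii in cm, ω in rad/s.
All internal arithmetic is cgs.  The default partial specific volume is the
generic protein value v̄ = 0.735 mL/g; a composition-based (Cohn–Edsall)
calculator is provided for user sequences.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .errors import BuoyancyError, FitError, InputError

R_CGS = 8.314462618e7      # erg / (mol K)
N_A = 6.02214076e23        # 1 / mol
S_UNIT = 1e-13             # seconds per Svedberg
RHO_20W = 0.99823          # g/mL, water at 20 C
ETA_20W = 0.01002          # poise, water at 20 C


@dataclass(frozen=True)
class HydroConditions:
    """Solvent/instrument conditions for hydrodynamic calculations."""

    temperature: float = 293.15      # K
    density: float = RHO_20W         # g/mL
    viscosity: float = ETA_20W       # poise
    vbar: float = 0.735              # mL/g
    omega: float = 0.0               # rad/s (SE only)

    @property
    def buoyancy(self) -> float:
        b = 1.0 - self.vbar * self.density
        if b <= 0:
            raise BuoyancyError(
                f"vbar*rho = {self.vbar * self.density:.4f} >= 1: species "
                "does not sediment")
        return b


@dataclass
class HydroObservation:
    """One hydrodynamic measurement of a species."""

    species_id: str
    s: float                 # Svedberg units (1e-13 s)
    D: float                 # μm²/s
    monomer_mass: float      # Da
    s20w: float | None = None

    def __post_init__(self) -> None:
        if self.s <= 0 or self.D <= 0:
            raise InputError("s and D must be positive")


@dataclass
class OligomerAssignment:
    """Integer stoichiometry inferred from an apparent molar mass."""

    apparent_mass: float
    n: int
    deviation: float         # |M - n*monomer| / (n*monomer)
    assigned: bool


def svedberg_mass(s: float, D: float, cond: HydroConditions = HydroConditions()) -> float:
    """Apparent molar mass (Da) from the Svedberg equation.

    ``s`` in Svedberg units, ``D`` in μm²/s.
    """
    d_cgs = D * 1e-8  # μm²/s -> cm²/s
    return s * S_UNIT * R_CGS * cond.temperature / (d_cgs * cond.buoyancy)


def mass_from_observation(obs: HydroObservation,
                          cond: HydroConditions = HydroConditions()) -> float:
    return svedberg_mass(obs.s, obs.D, cond)


def s20w_correction(s_exp: float, buffer_density: float, buffer_viscosity: float,
                    cond: HydroConditions = HydroConditions()) -> float:
    """Correct an experimental s to water at 20 °C.

    s20,w = s_exp · (η_buffer/η_20,w) · ((1 − v̄ρ)_20,w / (1 − v̄ρ)_buffer)
    """
    buoy_buffer = 1.0 - cond.vbar * buffer_density
    if buoy_buffer <= 0:
        raise BuoyancyError("vbar*rho >= 1 in buffer")
    buoy_20w = 1.0 - cond.vbar * RHO_20W
    return s_exp * (buffer_viscosity / ETA_20W) * (buoy_20w / buoy_buffer)


def _sphere_radius(M: float, vbar: float) -> float:
    """Anhydrous-sphere radius (cm) for molar mass M (Da)."""
    return (3.0 * M * vbar / (4.0 * math.pi * N_A)) ** (1.0 / 3.0)


def frictional_ratio(M: float, s20w: float,
                     cond: HydroConditions = HydroConditions()) -> float:
    """Frictional ratio f/f0 of a species of molar mass M (Da) at s20,w (S)."""
    if M <= 0 or s20w <= 0:
        raise InputError("M and s20w must be positive")
    f = M * cond.buoyancy / (N_A * s20w * S_UNIT)
    f0 = 6.0 * math.pi * cond.viscosity * _sphere_radius(M, cond.vbar)
    return f / f0


def forward_s(M: float, f_ratio: float,
              cond: HydroConditions = HydroConditions()) -> float:
    """Sedimentation coefficient (S) of a species of mass M at a given f/f0."""
    if f_ratio < 1:
        raise InputError("f/f0 must be >= 1")
    f0 = 6.0 * math.pi * cond.viscosity * _sphere_radius(M, cond.vbar)
    return M * cond.buoyancy / (N_A * f0 * f_ratio) / S_UNIT


def assign_oligomer(M: float, monomer: float, tolerance: float = 0.10,
                    n_max: int = 12) -> OligomerAssignment:
    """Assign the stoichiometry n minimising |M − n·monomer|, ties to smaller n."""
    if monomer <= 0:
        raise InputError("monomer mass must be positive")
    best_n, best_dev = 1, abs(M - monomer) / monomer
    for n in range(2, n_max + 1):
        dev = abs(M - n * monomer) / (n * monomer)
        if best_dev - dev > 1e-12:  # numeric ties keep the smaller n
            best_n, best_dev = n, dev
    return OligomerAssignment(M, best_n, best_dev, best_dev <= tolerance)


def oligomer_mass(monomer: float, n: int) -> float:
    """Molar mass of an n-mer (e.g. hexamer = 6 × monomer)."""
    if n < 1:
        raise InputError("n must be >= 1")
    return n * monomer


@dataclass
class SEFit:
    """Single-species sedimentation-equilibrium fit result."""

    M: float
    c0: float
    r0: float
    baseline: float
    residuals: np.ndarray = field(repr=False)

    @property
    def rmsd(self) -> float:
        return float(np.sqrt(np.mean(self.residuals ** 2)))


def _se_signal(r: np.ndarray, M: float, c0: float, baseline: float,
               r0: float, cond: HydroConditions) -> np.ndarray:
    sigma = M * cond.buoyancy * cond.omega ** 2 / (R_CGS * cond.temperature)
    return baseline + c0 * np.exp(sigma * (r ** 2 - r0 ** 2) / 2.0)


def fit_se(radius: np.ndarray, signal: np.ndarray, cond: HydroConditions) -> SEFit:
    """Fit a single-species exponential gradient; returns M, c0, baseline, residuals.

    The reference radius r0 is pinned to the innermost point (it is fully
    degenerate with c0).  A coarse log-spaced scan over M seeds the nonlinear
    refinement so convergence does not depend on a user guess.
    """
    r = np.asarray(radius, dtype=float)
    a = np.asarray(signal, dtype=float)
    if r.size < 20:
        raise FitError("need >= 20 radial points")
    if cond.omega <= 0:
        raise InputError("cond.omega must be set for SE fitting")
    r0 = float(r.min())

    # coarse scan: linear least squares for (c0, baseline) at fixed M
    best = None
    for M in np.geomspace(2e3, 2e6, 60):
        rss, c0, b = _fixed_mass_fit(r, a, M, r0, cond)
        if best is None or rss < best[0]:
            best = (rss, M, c0, b)
    _, M0, c00, b0 = best

    def model(rr, M, c0, baseline):
        return _se_signal(rr, M, c0, baseline, r0, cond)

    try:
        popt, _ = curve_fit(model, r, a, p0=[M0, c00, b0], maxfev=20000)
    except RuntimeError as exc:
        raise FitError(f"SE fit did not converge (M0={M0:.3g}): {exc}") from exc
    M, c0, baseline = popt
    res = a - model(r, *popt)
    return SEFit(float(M), float(c0), r0, float(baseline), res)


def _fixed_mass_fit(r: np.ndarray, a: np.ndarray, M: float, r0: float,
                    cond: HydroConditions) -> tuple[float, float, float]:
    """Linear LSQ of a = c0·g(r; M) + baseline; returns (rss, c0, baseline)."""
    g = _se_signal(r, M, 1.0, 0.0, r0, cond)
    X = np.column_stack([g, np.ones_like(g)])
    coef, *_ = np.linalg.lstsq(X, a, rcond=None)
    rss = float(np.sum((a - X @ coef) ** 2))
    return rss, float(coef[0]), float(coef[1])


def compare_oligomers(radius: np.ndarray, signal: np.ndarray,
                      cond: HydroConditions, monomer: float,
                      n_values: tuple[int, ...] = (2, 4, 6, 8)) -> dict[int, float]:
    """RMSD of fixed-mass single-species fits at M = n·monomer for each n.

    Mirrors model-comparison of SE gradients against candidate stoichiometries.
    """
    r = np.asarray(radius, dtype=float)
    a = np.asarray(signal, dtype=float)
    r0 = float(r.min())
    out = {}
    for n in n_values:
        rss, _, _ = _fixed_mass_fit(r, a, n * monomer, r0, cond)
        out[n] = math.sqrt(rss / r.size)
    return out


# ---------------------------------------------------------------------------
# Composition-based partial specific volume (Cohn-Edsall)

_RESIDUE_VBAR = {  # mL/g, per residue
    "A": 0.74, "R": 0.70, "N": 0.62, "D": 0.60, "C": 0.63, "Q": 0.67,
    "E": 0.66, "G": 0.64, "H": 0.67, "I": 0.90, "L": 0.90, "K": 0.82,
    "M": 0.75, "F": 0.77, "P": 0.76, "S": 0.63, "T": 0.70, "W": 0.74,
    "Y": 0.71, "V": 0.86,
}
_RESIDUE_MASS = {  # Da, residue (monomer minus water)
    "A": 71.08, "R": 156.19, "N": 114.10, "D": 115.09, "C": 103.14,
    "Q": 128.13, "E": 129.12, "G": 57.05, "H": 137.14, "I": 113.16,
    "L": 113.16, "K": 128.17, "M": 131.19, "F": 147.18, "P": 97.12,
    "S": 87.08, "T": 101.10, "W": 186.21, "Y": 163.18, "V": 99.13,
}


def vbar_from_sequence(protein: str) -> float:
    """Mass-weighted Cohn-Edsall partial specific volume (mL/g) of a protein."""
    bad = set(protein) - set(_RESIDUE_VBAR)
    if bad:
        raise InputError(f"unknown residue(s): {sorted(bad)}")
    masses = np.array([_RESIDUE_MASS[r] for r in protein])
    vbars = np.array([_RESIDUE_VBAR[r] for r in protein])
    return float((masses * vbars).sum() / masses.sum())


def read_observations(tsv_path) -> list[HydroObservation]:
    """Read observations from TSV with columns species_id, s, D, monomer_mass."""
    df = pd.read_csv(tsv_path, sep="\t", comment="#")
    return [HydroObservation(str(row.species_id), float(row.s), float(row.D),
                             float(row.monomer_mass))
            for row in df.itertuples()]
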
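"""Drift-diffusion first-passage calculator for charged biopolymers in a nanopore.

A captured biopolymer threading a nanopore is modelled as a one-dimensional
Smoluchowski (drift-diffusion) process in the coordinate x, the length of
polymer that has passed through the pore, x in [0, L] with L the contour
length.  Arrival at x=0 is retraction (escape back to the capture side),
arrival at x=L is translocation.  The interaction potential U(x), in units of
kBT, is assembled from

* an electrokinetic term: the applied transmembrane potential V acting on the
  sequence-derived charge density, corrected linearly for electroosmotic flow
  (EOF) drag,
* polymer-entropy terms for a free or end-tethered chain, and
* user-defined auxiliary terms (constant force, Gaussian well/bump, erf
  barrier).

From U(x) and a constant effective diffusion coefficient D the splitting
probabilities (pi0 retraction, piL translocation) and the conditional mean
first-passage times (tau0, tauL) follow as spatial quadratures over e^{+U} and
e^{-U}; the mean escape time is tau = pi0*tau0 + piL*tauL.  For a tethered
polymer the x=L boundary is reflecting, translocation is impossible and only
the mean escape time to x=0 is reported.

The module is laid out in the order the calculation runs:

1. constants, units and logging
2. sequence model        -- residue charges and charge-density profiles
3. potential builder     -- electrokinetic, entropic and auxiliary terms
4. first-passage engine  -- injection point, splitting, conditional MFPTs
5. reference models      -- closed-form and Langevin-simulation oracles
6. configuration and IO  -- JSON config, TSV import/export, experiment tables
"""

from __future__ import annotations

import json
import logging
import math
import warnings
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from numba import njit
from scipy.integrate import cumulative_trapezoid
from scipy.special import erf

__all__ = [
    "Direction",
    "PolymerSequence",
    "PoreModel",
    "EofModel",
    "ChargeDensityProfile",
    "ThermalScale",
    "EntropyConfig",
    "AuxiliaryForce",
    "PotentialProfile",
    "CalculationConfig",
    "FptResult",
    "SimulationSpec",
    "SimulationResult",
    "EscapeDataTable",
    "RunConfig",
    "ConfigError",
    "parse_sequence",
    "sequence_from_fasta",
    "make_grid",
    "native_charge_density",
    "effective_charge_density",
    "total_charge",
    "electrokinetic_term",
    "entropy_free_term",
    "entropy_tethered_term",
    "constant_force_term",
    "gaussian_term",
    "barrier_term",
    "total_potential",
    "build_potential",
    "find_injection_point",
    "splitting_probabilities",
    "conditional_mfpt",
    "mfpt_tethered",
    "voltage_sweep",
    "analytic_free",
    "analytic_tethered",
    "simulate_langevin",
    "zero_potential_validation",
    "save_config",
    "load_config",
    "config_from_dict",
    "SequenceSpec",
    "RESIDUE_CHARGES",
    "RESULTS_COLUMNS",
    "run_sweep",
    "charge_profiles",
    "potential_profiles",
    "load_experiment",
    "reverse_polarity",
    "write_profile",
    "write_potentials",
    "write_results",
    "read_results",
    "pn_per_nm_to_kbt",
]

logger = logging.getLogger("porefpt")

# ---------------------------------------------------------------------------
# 1. Constants and units
# ---------------------------------------------------------------------------

#: kBT/e in millivolts at 25 C; converts an applied voltage (mV) times a
#: charge (e-) into an energy in kBT.
DEFAULT_THERMAL_VOLTAGE_MV = 25.693

#: 1 kBT = 4.114 pN nm at 298.15 K; used to accept forces given in pN.
PN_NM_PER_KBT = 4.114

#: Per-residue charge numbers (elementary charges) before terminal
#: corrections.  "X" denotes a double-stranded nucleic-acid base or a
#: phosphorylated residue (charge -2).  All other letters carry zero charge.
RESIDUE_CHARGES = {"D": -1, "E": -1, "H": +1, "K": +1, "R": +1, "X": -2}

#: Letters that are expected in input; anything else is accepted with charge
#: zero but triggers a warning (e.g. B, J, O, U, Z).
KNOWN_RESIDUES = set("ACDEFGHIKLMNPQRSTVWY") | set(RESIDUE_CHARGES)

DEFAULT_LAA_NM = 0.4        # contour length per amino acid
DEFAULT_KUHN_NM = 0.6       # Kuhn length of the polypeptide chain
DEFAULT_FLORY_NU = 0.59     # self-avoiding chain Flory exponent
DEFAULT_M_EOF = 0.654       # EOF slope estimated for VDAC / alpha-synuclein
DEFAULT_B_EOF = -0.21       # EOF intercept (e-/nm), drag from pore-wall charge
DEFAULT_DELTA_NM = 1e-3     # tether-entropy regularization distance
DEFAULT_LP_NM = 2.355       # pore length; sigma_p = Lp/2.355 = 1 nm

#: Energy offset (kBT) used to wall off the sterically forbidden region of the
#: tethered-entropy term outside (Lp/2, L - Lp/2).
CLAMP_OFFSET_KBT = 25.0

FWHM_PER_SIGMA = 2.0 * math.sqrt(2.0 * math.log(2.0))  # = 2.3548...


def pn_per_nm_to_kbt(force_pn: float) -> float:
    """Convert a force in pN to kBT/nm (1 kBT = 4.114 pN nm at 298.15 K)."""
    return force_pn / PN_NM_PER_KBT


# ---------------------------------------------------------------------------
# 2. Sequence model
# ---------------------------------------------------------------------------


class Direction(str, Enum):
    """Reading direction of the input sequence relative to the pore axis.

    The input string is always written chemically N- to C-terminus.  The
    direction selects which terminus sits nearest x = 0 (enters the pore
    first): ``N_to_C`` puts the N-terminus at x = 0, ``C_to_N`` the
    C-terminus.  Terminal charge corrections follow the chemistry, not the
    string ends.
    """

    N_TO_C = "N_to_C"
    C_TO_N = "C_to_N"


@dataclass(frozen=True)
class PolymerSequence:
    """A polymer with per-residue integer charges on the pore axis.

    ``codes`` are stored so that residue 1 sits nearest x = 0.  ``z`` holds
    the per-residue charge numbers *after* the terminal corrections: the free
    amine at the N-terminus contributes +1 and the carboxyl at the C-terminus
    -1, wherever those termini ended up after orientation.
    """

    codes: str
    direction: Direction
    laa: float
    z: np.ndarray

    @property
    def N(self) -> int:
        return len(self.codes)

    @property
    def L(self) -> float:
        """Contour length N * laa in nm."""
        return self.N * self.laa


def parse_sequence(
    text: str,
    direction: Direction | str = Direction.N_TO_C,
    laa: float = DEFAULT_LAA_NM,
) -> PolymerSequence:
    """Parse a single-letter-code sequence into a charged polymer model.

    Whitespace is ignored and input is case-insensitive.  Charges: D, E -> -1;
    H, K, R -> +1; X -> -2; everything else -> 0 (unexpected letters warn).
    The residue at the chemical N-terminus then gains +1 and the C-terminal
    residue loses 1.  A single-residue sequence receives both corrections,
    which cancel.

    Raises ``ValueError`` for an empty sequence or a non-alphabetic character
    (the message names the character and its 1-based position in the cleaned
    sequence).
    """
    direction = Direction(direction)
    if laa <= 0:
        raise ValueError(f"length per residue must be positive, got {laa}")
    cleaned = "".join(text.split()).upper()
    if not cleaned:
        raise ValueError("sequence is empty (no non-whitespace characters)")
    for pos, ch in enumerate(cleaned, start=1):
        if not ("A" <= ch <= "Z"):
            raise ValueError(
                f"invalid character {ch!r} at position {pos}: "
                "sequence must contain letters A-Z only"
            )
    unknown = sorted(set(cleaned) - KNOWN_RESIDUES)
    if unknown:
        logger.warning(
            "unrecognized residue codes %s treated as charge 0", "".join(unknown)
        )

    # Store so residue 1 is nearest x=0; for C_to_N the C-terminus leads.
    stored = cleaned if direction is Direction.N_TO_C else cleaned[::-1]
    z = np.array([RESIDUE_CHARGES.get(c, 0) for c in stored], dtype=np.int64)
    n_term = 0 if direction is Direction.N_TO_C else -1
    c_term = -1 if direction is Direction.N_TO_C else 0
    z[n_term] += 1
    z[c_term] -= 1
    return PolymerSequence(codes=stored, direction=direction, laa=float(laa), z=z)


def sequence_from_fasta(path: str | Path) -> str:
    """Return the sequence text of the first record in a FASTA file."""
    from Bio import SeqIO

    records = SeqIO.parse(str(path), "fasta")
    try:
        first = next(records)
    except StopIteration:
        raise ValueError(f"no FASTA records found in {path}") from None
    return str(first.seq)


@dataclass(frozen=True)
class PoreModel:
    """Nanopore geometry: ``Lp`` is the pore length in nm.

    The pore smooths each residue charge into a Gaussian whose full width at
    half maximum equals the pore length, so sigma_p = Lp / 2.355.
    """

    Lp: float = DEFAULT_LP_NM

    def __post_init__(self) -> None:
        if not (self.Lp > 0):
            raise ValueError(f"pore length must be positive, got {self.Lp}")

    @property
    def sigma_p(self) -> float:
        return self.Lp / FWHM_PER_SIGMA


@dataclass(frozen=True)
class EofModel:
    """Linear electroosmotic-flow correction sigma = m_eof*sigma_n + b_eof.

    ``m_eof`` is the (dimensionless) reduction of the effective polymer charge
    by EOF drag; ``b_eof`` (e-/nm) accounts for drag from pore-wall charges.
    Values outside [0, 1] are legal (solid-state pores can require m_eof far
    from unity).
    """

    m_eof: float = DEFAULT_M_EOF
    b_eof: float = DEFAULT_B_EOF

    def __post_init__(self) -> None:
        if not (np.isfinite(self.m_eof) and np.isfinite(self.b_eof)):
            raise ValueError("EOF slope and intercept must be finite")


@dataclass(frozen=True)
class ChargeDensityProfile:
    """Charge density (e-/nm) on a spatial grid over [0, L]."""

    grid: np.ndarray
    values: np.ndarray
    kind: str  # "native" or "effective"


def make_grid(L: float, laa: float) -> np.ndarray:
    """Uniform grid over [0, L] with spacing laa/2 (endpoints included)."""
    n_seg = int(round(2.0 * L / laa))
    return np.linspace(0.0, L, n_seg + 1)


def _check_grid(grid: np.ndarray, L: float) -> None:
    grid = np.asarray(grid)
    if grid.ndim != 1 or grid.size < 2 or np.any(np.diff(grid) <= 0):
        raise ValueError("grid must be a strictly increasing 1-d array")
    tol = 1e-9 * max(1.0, L)
    if grid[0] > tol or grid[-1] < L - tol:
        raise ValueError(
            f"grid [{grid[0]}, {grid[-1]}] does not cover the contour [0, {L}]"
        )


def native_charge_density(
    seq: PolymerSequence,
    pore: PoreModel,
    grid: np.ndarray | None = None,
) -> ChargeDensityProfile:
    """Sequence charge smoothed by the pore into a density profile (e-/nm).

    Residue i contributes z_i * A_i^-1 * exp(-(x - (i-1/2)*laa)^2 / 2 sigma_p^2)
    with A_i chosen so that the *on-grid trapezoidal* integral of the residue's
    Gaussian over [0, L] is exactly one.  This preserves the total polymer
    charge on the working grid for any grid/pore combination, including
    Gaussians truncated at the contour ends or undersampled by a coarse grid.
    """
    if grid is None:
        grid = make_grid(seq.L, seq.laa)
    grid = np.asarray(grid, dtype=float)
    _check_grid(grid, seq.L)
    if not (pore.sigma_p > 0):
        raise ValueError("pore smoothing width must be positive")

    centers = (np.arange(1, seq.N + 1) - 0.5) * seq.laa
    values = np.zeros_like(grid)
    two_s2 = 2.0 * pore.sigma_p**2
    # Chunk over residues to bound the (N x n_grid) working array.
    for lo in range(0, seq.N, 512):
        hi = min(lo + 512, seq.N)
        g = np.exp(-((grid[None, :] - centers[lo:hi, None]) ** 2) / two_s2)
        a = np.trapezoid(g, grid, axis=1)
        if np.any(a <= 0):
            raise ValueError("residue Gaussian has zero weight on the grid")
        values += (seq.z[lo:hi] / a) @ g
    return ChargeDensityProfile(grid=grid, values=values, kind="native")


def effective_charge_density(
    native: ChargeDensityProfile, eof: EofModel
) -> ChargeDensityProfile:
    """Apply the linear EOF correction sigma = m_eof * sigma_n + b_eof."""
    if native.kind != "native":
        raise ValueError(f"expected a native profile, got kind={native.kind!r}")
    return ChargeDensityProfile(
        grid=native.grid,
        values=eof.m_eof * native.values + eof.b_eof,
        kind="effective",
    )


def total_charge(profile: ChargeDensityProfile) -> float:
    """Trapezoidal integral of the density over its grid, in e-."""
    return float(np.trapezoid(profile.values, profile.grid))


# ---------------------------------------------------------------------------
# 3. Potential builder
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ThermalScale:
    """Unit bridge between voltage x charge and kBT.

    ``thermal_voltage`` is kBT/e in mV (25.693 mV at 25 C).
    """

    thermal_voltage: float = DEFAULT_THERMAL_VOLTAGE_MV
    temperature: float = 298.15

    def __post_init__(self) -> None:
        if not (self.thermal_voltage > 0):
            raise ValueError("thermal voltage must be positive")


@dataclass(frozen=True)
class PotentialProfile:
    """Potential U(x) in kBT on a grid; ``voltage`` is the transmembrane
    potential in mV this profile belongs to (None for voltage-independent
    terms)."""

    grid: np.ndarray
    U: np.ndarray
    voltage: float | None = None


@dataclass(frozen=True)
class EntropyConfig:
    """Configuration of the polymer-entropy term.

    ``tethered`` both selects the tethered-chain entropy (when entropy is on)
    and makes the x=L boundary reflecting in the first-passage calculation.
    ``lt`` is the distance of the tether point above the pore; ``delta`` is
    the small shell half-width regularizing the tethered expression.
    """

    use_entropy: bool = True
    tethered: bool = False
    nu: float = DEFAULT_FLORY_NU
    b: float = DEFAULT_KUHN_NM
    lt: float = 0.0
    delta: float = DEFAULT_DELTA_NM

    def __post_init__(self) -> None:
        if not (0.0 < self.nu < 1.0):
            raise ValueError(f"Flory exponent must be in (0, 1), got {self.nu}")
        if not (self.b > 0):
            raise ValueError(f"Kuhn length must be positive, got {self.b}")
        if not (self.delta > 0):
            raise ValueError(f"delta must be positive, got {self.delta}")
        if self.lt < 0:
            raise ValueError(f"tether distance must be >= 0, got {self.lt}")


def electrokinetic_term(
    eff: ChargeDensityProfile,
    V: float,
    scale: ThermalScale = ThermalScale(),
) -> PotentialProfile:
    """Electrokinetic potential UE(x) = (V/V_T) * int_0^x sigma(x') dx' in kBT.

    ``V`` is the transmembrane potential in mV and sigma the effective charge
    density in e-/nm; dividing by the thermal voltage V_T = kBT/e converts the
    voltage-charge product to kBT.  UE(0) = 0.
    """
    if eff.kind != "effective":
        raise ValueError(f"expected an effective profile, got kind={eff.kind!r}")
    cum = cumulative_trapezoid(eff.values, eff.grid, initial=0.0)
    return PotentialProfile(
        grid=eff.grid, U=(V / scale.thermal_voltage) * cum, voltage=float(V)
    )


def entropy_free_term(
    grid: np.ndarray, L: float, nu: float = DEFAULT_FLORY_NU
) -> PotentialProfile:
    """Entropy of a free chain: US(x) = nu * [ln(x/L) + ln(1 - x/L)] in kBT.

    The logarithmic divergences at the contour ends are regularized by
    evaluating the end points at half a grid spacing inside the domain, which
    keeps e^{+-US} integrable while preserving the well shape.
    """
    grid = np.asarray(grid, dtype=float)
    u = grid / L
    with np.errstate(divide="ignore", invalid="ignore"):
        US = nu * (np.log(u) + np.log1p(-u))
    h = grid[1] - grid[0]
    edge = h / (2.0 * L)
    US[0] = nu * (math.log(edge) + math.log1p(-edge))
    US[-1] = nu * (math.log(edge) + math.log1p(-edge))
    if not np.all(np.isfinite(US)):
        raise ValueError("free-entropy term is non-finite at an interior point")
    return PotentialProfile(grid=grid, U=US)


def entropy_tethered_term(
    grid: np.ndarray,
    L: float,
    pore: PoreModel,
    cfg: EntropyConfig,
) -> PotentialProfile:
    """Entropy of a chain tethered a distance lt above the pore, in kBT.

    For a non-self-avoiding Gaussian chain with nC = (x - Lp/2)/b Kuhn lengths
    translocated and nT = (L - x - Lp/2)/b not translocated,

        US(x) = -ln{ (2 pi nC b^2/3)^(-3/2)
                     * [exp(-3(lt-d)^2 / 2 nC b^2) - exp(-3(lt+d)^2 / 2 nC b^2)]
                     * erf( sqrt(3 / 2 nT) d / b ) },

    defined up to an additive constant; the returned profile is shifted so its
    minimum over the valid range is zero.  ``d = delta`` is an arbitrarily
    small shell width; a tether placed exactly at the pore mouth (lt = 0)
    degenerates the bracketed difference, so lt is floored at delta, which
    reproduces the delta -> 0 limiting behaviour at a finite value.  Outside
    the valid range (nC <= 0 or nT <= 0) the chain cannot physically reach, so
    U is clamped to the nearest valid value plus a 25 kBT wall.
    """
    grid = np.asarray(grid, dtype=float)
    if L <= pore.Lp:
        raise ValueError(
            f"contour length L={L} must exceed the pore length Lp={pore.Lp}"
        )
    b, delta = cfg.b, cfg.delta
    lt_eff = max(cfg.lt, delta)
    nC = (grid - pore.Lp / 2.0) / b
    nT = (L - grid - pore.Lp / 2.0) / b
    valid = (nC > 0) & (nT > 0)
    if not np.any(valid):
        raise ValueError("no grid point lies in the tethered-chain valid range")

    nc = nC[valid]
    nt = nT[valid]
    # log of the bracketed difference: exp(a) - exp(a + d_exp) with d_exp < 0.
    a = -3.0 * (lt_eff - delta) ** 2 / (2.0 * nc * b * b)
    d_exp = -6.0 * lt_eff * delta / (nc * b * b)
    log_bracket = a + np.log(-np.expm1(d_exp))
    log_coeff = -1.5 * np.log(2.0 * math.pi * nc * b * b / 3.0)
    log_erf = np.log(erf(np.sqrt(3.0 / (2.0 * nt)) * delta / b))
    US_valid = -(log_coeff + log_bracket + log_erf)
    US_valid = US_valid - US_valid.min()

    US = np.empty_like(grid)
    US[valid] = US_valid
    idx_valid = np.flatnonzero(valid)
    first, last = idx_valid[0], idx_valid[-1]
    US[:first] = US[first] + CLAMP_OFFSET_KBT
    US[last + 1 :] = US[last] + CLAMP_OFFSET_KBT
    return PotentialProfile(grid=grid, U=US)


def constant_force_term(F: float, grid: np.ndarray) -> PotentialProfile:
    """Constant-force potential UF(x) = F*x, F in kBT/nm (positive F opposes
    translocation)."""
    grid = np.asarray(grid, dtype=float)
    return PotentialProfile(grid=grid, U=F * grid)


def gaussian_term(
    EG: float, xG: float, sG: float, grid: np.ndarray
) -> PotentialProfile:
    """Gaussian potential EG * exp(-(x - xG)^2 / 2 sG^2); EG < 0 models an
    attractive site-specific interaction."""
    if not (sG > 0):
        raise ValueError(f"Gaussian width must be positive, got {sG}")
    grid = np.asarray(grid, dtype=float)
    return PotentialProfile(
        grid=grid, U=EG * np.exp(-((grid - xG) ** 2) / (2.0 * sG * sG))
    )


def barrier_term(
    EB: float, xB: float, sB: float, grid: np.ndarray
) -> PotentialProfile:
    """Sigmoidal barrier EB * erf((x - xB) / (sB*sqrt(2))); pairs of opposite
    sign produce smoothed box potentials."""
    if not (sB > 0):
        raise ValueError(f"barrier width must be positive, got {sB}")
    grid = np.asarray(grid, dtype=float)
    return PotentialProfile(
        grid=grid, U=EB * erf((grid - xB) / (sB * math.sqrt(2.0)))
    )


@dataclass(frozen=True)
class AuxiliaryForce:
    """A user-defined auxiliary interaction term.

    ``form`` is one of "constant" (parameters: F in kBT/nm), "gaussian"
    (EG kBT, xG nm, sG nm) or "barrier" (EB kBT, xB nm, sB nm).
    """

    form: str
    parameters: dict

    _REQUIRED = {
        "constant": ("F",),
        "gaussian": ("EG", "xG", "sG"),
        "barrier": ("EB", "xB", "sB"),
    }

    def __post_init__(self) -> None:
        if self.form not in self._REQUIRED:
            raise ValueError(f"unknown auxiliary force form {self.form!r}")
        missing = [k for k in self._REQUIRED[self.form] if k not in self.parameters]
        if missing:
            raise ValueError(
                f"auxiliary force {self.form!r} missing parameters {missing}"
            )

    def term(self, grid: np.ndarray) -> PotentialProfile:
        p = self.parameters
        if self.form == "constant":
            return constant_force_term(p["F"], grid)
        if self.form == "gaussian":
            return gaussian_term(p["EG"], p["xG"], p["sG"], grid)
        return barrier_term(p["EB"], p["xB"], p["sB"], grid)


def total_potential(
    terms: Sequence[PotentialProfile],
    grid: np.ndarray | None = None,
    voltage: float | None = None,
) -> PotentialProfile:
    """Pointwise sum of interaction terms sharing one grid.

    An empty term list yields U = 0 on ``grid`` (which must then be given).
    """
    if not terms:
        if grid is None:
            raise ValueError("grid is required when no terms are given")
        return PotentialProfile(grid=np.asarray(grid, float),
                                U=np.zeros(len(grid)), voltage=voltage)
    ref = terms[0].grid
    for t in terms[1:]:
        if t.grid.shape != ref.shape or not np.allclose(t.grid, ref):
            raise ValueError("potential terms are defined on mismatched grids")
    U = np.sum([t.U for t in terms], axis=0)
    if voltage is None:
        voltages = [t.voltage for t in terms if t.voltage is not None]
        voltage = voltages[0] if voltages else None
    return PotentialProfile(grid=ref, U=U, voltage=voltage)


def build_potential(
    seq: PolymerSequence,
    pore: PoreModel,
    eof: EofModel,
    entropy: EntropyConfig,
    aux_forces: Sequence[AuxiliaryForce],
    V: float,
    scale: ThermalScale = ThermalScale(),
    grid: np.ndarray | None = None,
) -> PotentialProfile:
    """Assemble the total potential at one voltage from a full model."""
    if grid is None:
        grid = make_grid(seq.L, seq.laa)
    native = native_charge_density(seq, pore, grid)
    eff = effective_charge_density(native, eof)
    terms = [electrokinetic_term(eff, V, scale)]
    terms.extend(_static_terms(seq, pore, entropy, aux_forces, grid))
    return total_potential(terms, voltage=float(V))


def _static_terms(
    seq: PolymerSequence,
    pore: PoreModel,
    entropy: EntropyConfig,
    aux_forces: Sequence[AuxiliaryForce],
    grid: np.ndarray,
) -> list[PotentialProfile]:
    terms: list[PotentialProfile] = []
    if entropy.use_entropy:
        if entropy.tethered:
            terms.append(entropy_tethered_term(grid, seq.L, pore, entropy))
        else:
            terms.append(entropy_free_term(grid, seq.L, entropy.nu))
    terms.extend(aux.term(grid) for aux in aux_forces)
    return terms


# ---------------------------------------------------------------------------
# 4. First-passage engine
# ---------------------------------------------------------------------------
#
# For overdamped dynamics dx = -D U'(x) dt + sqrt(2D) dW the splitting
# probability to reach L before 0 from x0 is
#
#     piL(x0) = Phi(x0) / Phi(L),    Phi(x) = int_0^x e^{U(y)} dy,
#
# and the boundary-resolved mean first-passage products g = piL*tauL and
# h = pi0*tau0 solve the backward equation with the Green's function
# G(x, y) = Phi(min) * Psi(max) / N, Psi(y) = int_y^L e^{U}, N = Phi(L):
#
#     g(x0) = (1/D N^2) [ Psi(x0) int_0^x0 Phi^2 e^{-U}
#                         + Phi(x0) int_x0^L Psi Phi e^{-U} ]
#     h(x0) = (1/D N^2) [ Psi(x0) int_0^x0 Phi Psi e^{-U}
#                         + Phi(x0) int_x0^L Psi^2 e^{-U} ]
#
# Every integrand is positive, so the whole computation runs in log space
# (trapezoid segments combined with logaddexp): |U| of order 10^3 kBT, routine
# at experimental voltages, neither overflows nor cancels.  Additive shifts of
# U drop out identically.


def _log_segments(logf: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Log of the trapezoid integral over each grid cell."""
    return np.logaddexp(logf[:-1], logf[1:]) + np.log(0.5 * np.diff(x))


def _log_cum(logf: np.ndarray, x: np.ndarray) -> np.ndarray:
    """log int_0^{x_i} e^{logf} dy by cumulative trapezoid; entry 0 is -inf."""
    seg = _log_segments(logf, x)
    return np.concatenate(([-np.inf], np.logaddexp.accumulate(seg)))


def _log_cum_rev(logf: np.ndarray, x: np.ndarray) -> np.ndarray:
    """log int_{x_i}^{L} e^{logf} dy; last entry is -inf."""
    seg = _log_segments(logf, x)
    rev = np.logaddexp.accumulate(seg[::-1])[::-1]
    return np.concatenate((rev, [-np.inf]))


def _grid_index(grid: np.ndarray, x0: float) -> int:
    return int(np.argmin(np.abs(grid - x0)))


def _check_potential(U: PotentialProfile) -> None:
    if not np.all(np.isfinite(U.U)):
        raise ValueError("potential is non-finite on the grid")


def find_injection_point(
    U: PotentialProfile, injection_range: tuple[float, float] | None = None
) -> float:
    """Most stable initial position: the grid point of minimal U within the
    closed range (ties broken toward smaller x).

    A degenerate range [a, a] forces injection at the grid point nearest a.
    An empty, non-degenerate intersection with the grid is an error.
    """
    grid = U.grid
    if injection_range is None:
        lo, hi = grid[0], grid[-1]
    else:
        lo, hi = injection_range
    if lo > hi:
        raise ValueError(f"injection range [{lo}, {hi}] is inverted")
    mask = (grid >= lo - 1e-12) & (grid <= hi + 1e-12)
    if not np.any(mask):
        if np.isclose(lo, hi):
            return float(grid[_grid_index(grid, lo)])
        raise ValueError(
            f"injection range [{lo}, {hi}] contains no grid point"
        )
    sub = np.flatnonzero(mask)
    return float(grid[sub[np.argmin(U.U[mask])]])


def splitting_probabilities(
    U: PotentialProfile, x0: float
) -> tuple[float, float]:
    """Probabilities of exit at x=0 (pi0) and x=L (piL) from x0, both
    boundaries absorbing.  x0 snaps to the nearest grid point."""
    _check_potential(U)
    i0 = _grid_index(U.grid, x0)
    log_phi = _log_cum(U.U, U.grid)
    log_psi = _log_cum_rev(U.U, U.grid)
    logN = log_phi[-1]
    piL = float(np.exp(log_phi[i0] - logN))
    pi0 = float(np.exp(log_psi[i0] - logN))
    return pi0, piL


def conditional_mfpt(
    U: PotentialProfile, D: float, x0: float
) -> tuple[float, float, float]:
    """Conditional mean first-passage times (tau0, tauL) and the mean escape
    time tau, in seconds; D in nm^2/s, both boundaries absorbing.

    If a splitting probability is below 1e-12 the corresponding conditional
    time is undefined and reported as NaN with a warning.
    """
    _check_potential(U)
    if not (D > 0):
        raise ValueError(f"diffusion constant must be positive, got {D}")
    x, Uv = U.grid, U.U
    i0 = _grid_index(x, x0)
    log_phi = _log_cum(Uv, x)
    log_psi = _log_cum_rev(Uv, x)
    logN = log_phi[-1]
    logD = math.log(D)

    lg_phi2 = 2.0 * log_phi - Uv          # Phi^2 e^{-U}
    lg_cross = log_phi + log_psi - Uv     # Phi Psi e^{-U}
    lg_psi2 = 2.0 * log_psi - Uv          # Psi^2 e^{-U}

    with np.errstate(invalid="ignore"):
        log_g = np.logaddexp(
            log_psi[i0] + _log_cum(lg_phi2, x)[i0],
            log_phi[i0] + _log_cum_rev(lg_cross, x)[i0],
        ) - logD - 2.0 * logN
        log_h = np.logaddexp(
            log_psi[i0] + _log_cum(lg_cross, x)[i0],
            log_phi[i0] + _log_cum_rev(lg_psi2, x)[i0],
        ) - logD - 2.0 * logN
    g = float(np.exp(log_g))  # piL * tauL
    h = float(np.exp(log_h))  # pi0 * tau0
    tau = g + h

    pi0, piL = splitting_probabilities(U, x0)
    if piL < 1e-12:
        warnings.warn("piL ~ 0: conditional translocation time undefined")
        tauL = math.nan
    else:
        tauL = g / piL
    if pi0 < 1e-12:
        warnings.warn("pi0 ~ 0: conditional retraction time undefined")
        tau0 = math.nan
    else:
        tau0 = h / pi0
    return tau0, tauL, tau


def mfpt_tethered(U: PotentialProfile, D: float, x0: float) -> float:
    """Mean first-passage time to x=0 with a reflecting boundary at x=L
    (tethered polymer), in seconds; D in nm^2/s.

    tau = (1/D) int_0^{x0} e^{U(y)} [ int_y^L e^{-U(z)} dz ] dy.
    """
    _check_potential(U)
    if not (D > 0):
        raise ValueError(f"diffusion constant must be positive, got {D}")
    x, Uv = U.grid, U.U
    i0 = _grid_index(x, x0)
    log_inner = _log_cum_rev(-Uv, x)          # log int_y^L e^{-U}
    with np.errstate(invalid="ignore"):
        lg = Uv + log_inner                   # -inf at y = L is harmless
        log_tau = _log_cum(lg, x)[i0] - math.log(D)
    return float(np.exp(log_tau))


@dataclass(frozen=True)
class CalculationConfig:
    """Sweep parameters: voltages in mV, diffusion constant in um^2/s
    (converted to nm^2/s internally), optional injection search range in nm."""

    voltages: tuple[float, ...] = ()
    D: float = 1.0
    injection_range: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if not (self.D > 0):
            raise ValueError(f"diffusion constant must be positive, got {self.D}")
        if self.injection_range is not None:
            lo, hi = self.injection_range
            if not (0 <= lo <= hi):
                raise ValueError(
                    f"injection range [{lo}, {hi}] must satisfy 0 <= min <= max"
                )

    @property
    def D_nm2_s(self) -> float:
        return self.D * 1e6


@dataclass(frozen=True)
class FptResult:
    """Per-voltage first-passage summary.

    For a tethered polymer translocation is impossible: piL = 0 exactly,
    tau0 = tau and tauL is NaN.
    """

    voltage: float
    x0: float
    pi0: float
    piL: float
    tau0: float
    tauL: float
    tau: float
    tethered: bool = False


def voltage_sweep(
    seq: PolymerSequence,
    pore: PoreModel,
    eof: EofModel,
    entropy: EntropyConfig,
    aux_forces: Sequence[AuxiliaryForce],
    calc: CalculationConfig,
    scale: ThermalScale = ThermalScale(),
) -> list[FptResult]:
    """Run the full pipeline for each voltage, in input order."""
    grid = make_grid(seq.L, seq.laa)
    native = native_charge_density(seq, pore, grid)
    eff = effective_charge_density(native, eof)
    static = _static_terms(seq, pore, entropy, aux_forces, grid)
    D = calc.D_nm2_s
    results: list[FptResult] = []
    for V in calc.voltages:
        U = total_potential([electrokinetic_term(eff, V, scale)] + static,
                            voltage=float(V))
        x0 = find_injection_point(U, calc.injection_range)
        if entropy.tethered:
            tau = mfpt_tethered(U, D, x0)
            results.append(
                FptResult(voltage=float(V), x0=x0, pi0=1.0, piL=0.0,
                          tau0=tau, tauL=math.nan, tau=tau, tethered=True)
            )
        else:
            pi0, piL = splitting_probabilities(U, x0)
            tau0, tauL, tau = conditional_mfpt(U, D, x0)
            results.append(
                FptResult(voltage=float(V), x0=x0, pi0=pi0, piL=piL,
                          tau0=tau0, tauL=tauL, tau=tau, tethered=False)
            )
    return results


# ---------------------------------------------------------------------------
# 5. Reference models (closed-form and stochastic oracles)
# ---------------------------------------------------------------------------


def analytic_free(
    x0: float, L: float, D: float
) -> tuple[float, float, float, float, float]:
    """Closed forms for U = 0 with both boundaries absorbing.

    Returns (pi0, piL, tau0, tauL, tau) with u = x0/L:

        pi0 = 1 - u, piL = u,
        tau0 = (L^2/2D) u (2 - u) / 3,
        tauL = (L^2/2D) (1 - u)(1 + u) / 3,
        tau  = (L^2/2D) u (1 - u).
    """
    u = x0 / L
    t_scale = L * L / (2.0 * D)
    pi0 = 1.0 - u
    piL = u
    tau0 = t_scale * u * (2.0 - u) / 3.0
    tauL = t_scale * (1.0 - u) * (1.0 + u) / 3.0
    tau = t_scale * u * (1.0 - u)
    return pi0, piL, tau0, tauL, tau


def analytic_tethered(x0: float, L: float, D: float) -> float:
    """Closed-form mean first-passage time to x=0 for U = 0 with a reflecting
    boundary at x=L: tau = (L^2/2D) (x0/L)(2 - x0/L)."""
    u = x0 / L
    return L * L / (2.0 * D) * u * (2.0 - u)


@dataclass(frozen=True)
class SimulationSpec:
    """Euler-Maruyama oracle settings.

    ``dt`` must satisfy sqrt(2 D dt) < grid spacing; if None it is chosen so
    the RMS step is 0.4 grid spacings.  ``boundary_mode`` is
    "both_absorbing" or "absorb0_reflectL".
    """

    n_traj: int = 10_000
    dt: float | None = None
    seed: int = 0
    max_steps: int = 20_000_000
    boundary_mode: str = "both_absorbing"

    def __post_init__(self) -> None:
        if self.n_traj < 1:
            raise ValueError("n_traj must be >= 1")
        if self.dt is not None and not (self.dt > 0):
            raise ValueError("dt must be positive")
        if self.max_steps < 1 or not math.isfinite(self.max_steps):
            raise ValueError("max_steps must be a finite positive integer")
        if self.boundary_mode not in ("both_absorbing", "absorb0_reflectL"):
            raise ValueError(f"unknown boundary mode {self.boundary_mode!r}")


@dataclass(frozen=True)
class SimulationResult:
    pi0: float
    piL: float
    tau0: float
    tauL: float
    tau: float
    se_pi0: float
    se_piL: float
    se_tau0: float
    se_tauL: float
    se_tau: float
    n_used: int
    n_censored: int


@njit(cache=True)
def _em_kernel(x0, D, dt, n_traj, max_steps, seed, grid0, h, npts, F, L,
               reflect_L):  # pragma: no cover - compiled
    np.random.seed(seed)
    times = np.empty(n_traj)
    sides = np.empty(n_traj, dtype=np.int8)
    sig = np.sqrt(2.0 * D * dt)
    sig2 = sig * sig
    # Bridge crossing probability is < 1e-13 when both endpoints are more
    # than 4 rms steps from a boundary; skip the exp/uniform draws there.
    bridge_cut = 4.0 * sig
    for k in range(n_traj):
        x = x0
        side = -1
        t_exit = np.nan
        for step in range(max_steps):
            u = (x - grid0) / h
            j = int(u)
            if j < 0:
                j = 0
            if j > npts - 2:
                j = npts - 2
            w = u - j
            f = F[j] * (1.0 - w) + F[j + 1] * w
            xn = x + D * f * dt + sig * np.random.normal()
            t = (step + 1) * dt
            if xn <= 0.0:
                side = 0
                t_exit = t
                break
            if xn >= L:
                if reflect_L:
                    xn = 2.0 * L - xn
                    if xn <= 0.0:
                        side = 0
                        t_exit = t
                        break
                else:
                    side = 1
                    t_exit = t
                    break
            # Brownian-bridge probability of an unobserved crossing within
            # the step (diffusion-dominated approximation).
            if x < bridge_cut or xn < bridge_cut:
                if np.random.random() < np.exp(-2.0 * x * xn / sig2):
                    side = 0
                    t_exit = t
                    break
            if not reflect_L and (L - x < bridge_cut or L - xn < bridge_cut):
                if np.random.random() < np.exp(
                    -2.0 * (L - x) * (L - xn) / sig2
                ):
                    side = 1
                    t_exit = t
                    break
            x = xn
        times[k] = t_exit
        sides[k] = side
    return times, sides


def simulate_langevin(
    U: PotentialProfile, D: float, x0: float, spec: SimulationSpec
) -> SimulationResult:
    """Brute-force Euler-Maruyama oracle for the first-passage moments.

    Integrates dx = -D U'(x) dt + sqrt(2 D dt) xi with U' from central
    differences on the (uniform) grid, linearly interpolated; absorbing at 0
    and (unless reflecting) at L, with Brownian-bridge detection of
    intra-step crossings.  Returns empirical moments with standard errors.
    Trajectories exceeding ``max_steps`` are excluded with a warning.
    """
    _check_potential(U)
    grid = U.grid
    h = grid[1] - grid[0]
    if not np.allclose(np.diff(grid), h):
        raise ValueError("Langevin oracle requires a uniform grid")
    dt = spec.dt if spec.dt is not None else (0.4 * h) ** 2 / (2.0 * D)
    if math.sqrt(2.0 * D * dt) >= h:
        raise ValueError(
            f"dt={dt} too large: rms step {math.sqrt(2*D*dt):.3g} must be "
            f"below the grid spacing {h:.3g}"
        )
    reflect = spec.boundary_mode == "absorb0_reflectL"
    # Force from a cubic spline of U, sampled on an 8x finer grid: the
    # piecewise-linear interpolant of central differences perturbs sharp
    # potential features at O(h^2), a bias visible against 10^4-trajectory
    # standard errors; the spline derivative is accurate to O(h^3).
    from scipy.interpolate import CubicSpline

    fine = np.linspace(grid[0], grid[-1], 8 * (grid.size - 1) + 1)
    F = -CubicSpline(grid, U.U).derivative()(fine)
    times, sides = _em_kernel(
        float(x0), float(D), float(dt), int(spec.n_traj), int(spec.max_steps),
        int(spec.seed), float(fine[0]), float(fine[1] - fine[0]),
        int(fine.size), np.ascontiguousarray(F, dtype=np.float64),
        float(grid[-1]), reflect,
    )
    done = sides >= 0
    n_censored = int(np.sum(~done))
    if n_censored:
        warnings.warn(
            f"{n_censored} trajectories exceeded max_steps and were excluded"
        )
    times = times[done]
    sides = sides[done]
    n = times.size
    if n == 0:
        raise RuntimeError("no trajectory finished within max_steps")

    def _mean_se(v: np.ndarray) -> tuple[float, float]:
        if v.size == 0:
            return math.nan, math.nan
        if v.size == 1:
            return float(v[0]), math.nan
        return float(v.mean()), float(v.std(ddof=1) / math.sqrt(v.size))

    piL = float(np.mean(sides == 1))
    pi0 = 1.0 - piL
    se_p = math.sqrt(max(piL * (1.0 - piL), 0.0) / n)
    tau0, se_tau0 = _mean_se(times[sides == 0])
    tauL, se_tauL = _mean_se(times[sides == 1])
    tau, se_tau = _mean_se(times)
    if reflect:
        piL, se_p = 0.0, 0.0
    return SimulationResult(
        pi0=pi0, piL=piL, tau0=tau0, tauL=tauL, tau=tau,
        se_pi0=se_p, se_piL=se_p, se_tau0=se_tau0, se_tauL=se_tauL,
        se_tau=se_tau, n_used=n, n_censored=n_censored,
    )


def zero_potential_validation(
    n_residues: int = 100,
    laa: float = 1.0,
    D_nm2_s: float = 1.0,
    fractions: Iterable[float] = tuple(np.arange(1, 20) * 0.05),
) -> dict:
    """Compare the numerical engine with the U=0 closed forms.

    Builds the zero-potential configuration through the full pipeline (an
    uncharged-in-effect sequence: EOF slope and intercept zero, entropy off)
    and sweeps injection fractions x0/L.  Returns per-quantity maximum
    relative errors for the free (both-absorbing) case and the tethered
    (reflecting) case.
    """
    seq = parse_sequence("A" * n_residues, laa=laa)
    pore = PoreModel(DEFAULT_LP_NM)
    eof = EofModel(0.0, 0.0)
    grid = make_grid(seq.L, seq.laa)
    eff = effective_charge_density(native_charge_density(seq, pore, grid), eof)
    U = electrokinetic_term(eff, 100.0)  # identically zero: sigma_eff = 0
    L = seq.L
    errs = {k: 0.0 for k in ("pi0", "piL", "tau0", "tauL", "tau")}
    err_teth = 0.0
    for f in fractions:
        x0 = f * L
        pi0_a, piL_a, tau0_a, tauL_a, tau_a = analytic_free(x0, L, D_nm2_s)
        pi0_n, piL_n = splitting_probabilities(U, x0)
        tau0_n, tauL_n, tau_n = conditional_mfpt(U, D_nm2_s, x0)
        for key, num, ana in (
            ("pi0", pi0_n, pi0_a), ("piL", piL_n, piL_a),
            ("tau0", tau0_n, tau0_a), ("tauL", tauL_n, tauL_a),
            ("tau", tau_n, tau_a),
        ):
            errs[key] = max(errs[key], abs(num - ana) / abs(ana))
        tau_t = mfpt_tethered(U, D_nm2_s, x0)
        err_teth = max(
            err_teth,
            abs(tau_t - analytic_tethered(x0, L, D_nm2_s))
            / analytic_tethered(x0, L, D_nm2_s),
        )
    return {
        "free_max_rel_err": max(errs.values()),
        "free_per_quantity": errs,
        "tethered_max_rel_err": err_teth,
        "n_grid": grid.size,
    }


# ---------------------------------------------------------------------------
# 6. Configuration and IO
# ---------------------------------------------------------------------------

SCHEMA_VERSION = 1

RESULTS_COLUMNS = ("voltage_mV", "tau_s", "tau0_s", "tauL_s", "pi0", "piL",
                   "x0_nm")


class ConfigError(ValueError):
    """Raised for malformed or out-of-range configuration files."""


@dataclass(frozen=True)
class SequenceSpec:
    text: str = ""
    direction: Direction = Direction.N_TO_C
    laa: float = DEFAULT_LAA_NM


@dataclass(frozen=True)
class RunConfig:
    """Complete, serializable description of one calculation."""

    sequence: SequenceSpec = field(default_factory=SequenceSpec)
    pore: PoreModel = field(default_factory=PoreModel)
    eof: EofModel = field(default_factory=EofModel)
    entropy: EntropyConfig = field(default_factory=EntropyConfig)
    aux_forces: tuple[AuxiliaryForce, ...] = ()
    calc: CalculationConfig = field(default_factory=CalculationConfig)
    thermal: ThermalScale = field(default_factory=ThermalScale)

    def to_dict(self) -> dict:
        return {
            "schema_version": SCHEMA_VERSION,
            "sequence": {
                "text": self.sequence.text,
                "direction": self.sequence.direction.value,
                "laa_nm": self.sequence.laa,
            },
            "pore": {"Lp_nm": self.pore.Lp},
            "eof": {"m_eof": self.eof.m_eof, "b_eof": self.eof.b_eof},
            "entropy": {
                "use_entropy": self.entropy.use_entropy,
                "tethered": self.entropy.tethered,
                "nu": self.entropy.nu,
                "b_nm": self.entropy.b,
                "lt_nm": self.entropy.lt,
                "delta_nm": self.entropy.delta,
            },
            "aux_forces": [
                {"form": a.form, "parameters": dict(a.parameters)}
                for a in self.aux_forces
            ],
            "calc": {
                "voltages_mV": list(self.calc.voltages),
                "D_um2_s": self.calc.D,
                "injection_range_nm": (
                    list(self.calc.injection_range)
                    if self.calc.injection_range is not None
                    else None
                ),
            },
            "thermal": {"thermal_voltage_mV": self.thermal.thermal_voltage},
        }


def _section(data: dict, name: str) -> dict:
    sec = data.get(name, {})
    if not isinstance(sec, dict):
        raise ConfigError(f"config section {name!r} must be an object")
    return sec


def _number(sec: dict, key: str, default: float, where: str) -> float:
    v = sec.get(key, default)
    if not isinstance(v, (int, float)) or isinstance(v, bool):
        raise ConfigError(f"{where}.{key} must be a number, got {v!r}")
    if not math.isfinite(v):
        raise ConfigError(f"{where}.{key} must be finite, got {v!r}")
    return float(v)


def config_from_dict(data: dict) -> RunConfig:
    """Build and validate a :class:`RunConfig` from a plain dict, applying
    documented defaults for absent fields."""
    if not isinstance(data, dict):
        raise ConfigError("config root must be a JSON object")
    version = data.get("schema_version", SCHEMA_VERSION)
    if version != SCHEMA_VERSION:
        raise ConfigError(
            f"unknown config schema version {version!r}; expected {SCHEMA_VERSION}"
        )
    try:
        seq_sec = _section(data, "sequence")
        text = seq_sec.get("text", "")
        if not isinstance(text, str):
            raise ConfigError("sequence.text must be a string")
        direction = seq_sec.get("direction", Direction.N_TO_C.value)
        try:
            direction = Direction(direction)
        except ValueError:
            raise ConfigError(
                f"sequence.direction must be one of "
                f"{[d.value for d in Direction]}, got {direction!r}"
            ) from None
        sequence = SequenceSpec(
            text=text,
            direction=direction,
            laa=_number(seq_sec, "laa_nm", DEFAULT_LAA_NM, "sequence"),
        )
        pore = PoreModel(Lp=_number(_section(data, "pore"), "Lp_nm",
                                    DEFAULT_LP_NM, "pore"))
        eof_sec = _section(data, "eof")
        eof = EofModel(
            m_eof=_number(eof_sec, "m_eof", DEFAULT_M_EOF, "eof"),
            b_eof=_number(eof_sec, "b_eof", DEFAULT_B_EOF, "eof"),
        )
        ent_sec = _section(data, "entropy")
        entropy = EntropyConfig(
            use_entropy=bool(ent_sec.get("use_entropy", True)),
            tethered=bool(ent_sec.get("tethered", False)),
            nu=_number(ent_sec, "nu", DEFAULT_FLORY_NU, "entropy"),
            b=_number(ent_sec, "b_nm", DEFAULT_KUHN_NM, "entropy"),
            lt=_number(ent_sec, "lt_nm", 0.0, "entropy"),
            delta=_number(ent_sec, "delta_nm", DEFAULT_DELTA_NM, "entropy"),
        )
        aux_list = data.get("aux_forces", [])
        if not isinstance(aux_list, list):
            raise ConfigError("aux_forces must be a list")
        aux = tuple(
            AuxiliaryForce(form=a.get("form", ""),
                           parameters=dict(a.get("parameters", {})))
            for a in aux_list
        )
        calc_sec = _section(data, "calc")
        voltages = calc_sec.get("voltages_mV", [])
        if not isinstance(voltages, list) or not all(
            isinstance(v, (int, float)) and not isinstance(v, bool)
            and math.isfinite(v) for v in voltages
        ):
            raise ConfigError("calc.voltages_mV must be a list of finite numbers")
        rng = calc_sec.get("injection_range_nm")
        if rng is not None:
            if (not isinstance(rng, list) or len(rng) != 2
                    or not all(isinstance(v, (int, float)) for v in rng)):
                raise ConfigError(
                    "calc.injection_range_nm must be null or [min_nm, max_nm]"
                )
            rng = (float(rng[0]), float(rng[1]))
        calc = CalculationConfig(
            voltages=tuple(float(v) for v in voltages),
            D=_number(calc_sec, "D_um2_s", 1.0, "calc"),
            injection_range=rng,
        )
        thermal = ThermalScale(
            thermal_voltage=_number(
                _section(data, "thermal"), "thermal_voltage_mV",
                DEFAULT_THERMAL_VOLTAGE_MV, "thermal",
            )
        )
    except ConfigError:
        raise
    except ValueError as exc:
        raise ConfigError(str(exc)) from exc
    if not sequence.text.strip():
        logger.warning("config has no sequence; calculations will require one")
    return RunConfig(sequence=sequence, pore=pore, eof=eof, entropy=entropy,
                     aux_forces=aux, calc=calc, thermal=thermal)


def save_config(cfg: RunConfig, path: str | Path) -> None:
    """Write the configuration as versioned JSON (sorted keys, so repeated
    save -> load -> save round-trips byte-identically)."""
    Path(path).write_text(
        json.dumps(cfg.to_dict(), indent=2, sort_keys=True) + "\n"
    )


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a configuration file, applying defaults."""
    try:
        data = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise ConfigError(f"malformed config file {path}: {exc}") from exc
    return config_from_dict(data)


def _sequence_of(cfg: RunConfig) -> PolymerSequence:
    if not cfg.sequence.text.strip():
        raise ConfigError("configuration has no sequence")
    return parse_sequence(cfg.sequence.text, cfg.sequence.direction,
                          cfg.sequence.laa)


def run_sweep(cfg: RunConfig) -> list[FptResult]:
    """Voltage sweep for a complete configuration."""
    return voltage_sweep(
        _sequence_of(cfg), cfg.pore, cfg.eof, cfg.entropy,
        cfg.aux_forces, cfg.calc, cfg.thermal,
    )


def charge_profiles(
    cfg: RunConfig,
) -> tuple[ChargeDensityProfile, ChargeDensityProfile]:
    """(native, effective) charge-density profiles for a configuration."""
    seq = _sequence_of(cfg)
    native = native_charge_density(seq, cfg.pore)
    return native, effective_charge_density(native, cfg.eof)


def potential_profiles(cfg: RunConfig) -> list[PotentialProfile]:
    """Total potential U(x) for each configured voltage."""
    seq = _sequence_of(cfg)
    return [
        build_potential(seq, cfg.pore, cfg.eof, cfg.entropy, cfg.aux_forces,
                        V, cfg.thermal)
        for V in cfg.calc.voltages
    ]


@dataclass(frozen=True)
class EscapeDataTable:
    """Experimental voltage / mean escape time (/ uncertainty) table."""

    voltage: np.ndarray
    tau: np.ndarray
    tau_err: np.ndarray | None = None

    def __len__(self) -> int:
        return self.voltage.size


def load_experiment(path: str | Path) -> EscapeDataTable:
    """Load a 2- or 3-column whitespace/tab-delimited text table of
    (voltage mV, mean escape time s[, uncertainty s]).

    Lines starting with '#' and blank lines are skipped.  All rows must have
    the same column count; parse errors report the offending line number.
    """
    rows: list[list[float]] = []
    ncols: int | None = None
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if ncols is None:
            ncols = len(parts)
            if ncols not in (2, 3):
                raise ValueError(
                    f"{path}:{lineno}: expected 2 or 3 columns, found {ncols}"
                )
        elif len(parts) != ncols:
            raise ValueError(
                f"{path}:{lineno}: inconsistent column count "
                f"({len(parts)} vs {ncols})"
            )
        try:
            rows.append([float(p) for p in parts])
        except ValueError:
            raise ValueError(
                f"{path}:{lineno}: non-numeric value in {line!r}"
            ) from None
    if not rows:
        raise ValueError(f"{path}: no data rows found")
    arr = np.asarray(rows)
    voltage, tau = arr[:, 0], arr[:, 1]
    if not np.all(np.isfinite(voltage)):
        raise ValueError(f"{path}: voltages must be finite")
    if np.any(tau <= 0):
        raise ValueError(f"{path}: escape times must be positive")
    tau_err = None
    if arr.shape[1] == 3:
        tau_err = arr[:, 2]
        if np.any(tau_err < 0):
            raise ValueError(f"{path}: uncertainties must be >= 0")
    return EscapeDataTable(voltage=voltage, tau=tau, tau_err=tau_err)


def reverse_polarity(table: EscapeDataTable) -> EscapeDataTable:
    """Negate the voltage column (for data recorded with opposite sign
    convention); times are unchanged."""
    return replace(table, voltage=-table.voltage)


def _fmt(v: float) -> str:
    return f"{v:.17g}"


def write_profile(path: str | Path, profile: ChargeDensityProfile) -> None:
    """Export a charge-density profile as two-column TSV."""
    lines = ["x_nm\tsigma_e_per_nm"]
    lines += [f"{_fmt(x)}\t{_fmt(v)}"
              for x, v in zip(profile.grid, profile.values)]
    Path(path).write_text("\n".join(lines) + "\n")


def write_potentials(
    path: str | Path, potentials: Sequence[PotentialProfile]
) -> None:
    """Export potentials as TSV: x_nm then one U_kT@<V>mV column per voltage."""
    if not potentials:
        raise ValueError("no potential profiles to export")
    grid = potentials[0].grid
    header = ["x_nm"] + [f"U_kT@{p.voltage:g}mV" for p in potentials]
    lines = ["\t".join(header)]
    for i, x in enumerate(grid):
        lines.append(
            "\t".join([_fmt(x)] + [_fmt(p.U[i]) for p in potentials])
        )
    Path(path).write_text("\n".join(lines) + "\n")


def write_results(path: str | Path, results: Sequence[FptResult]) -> None:
    """Export sweep results as TSV at full (round-trippable) precision."""
    lines = ["\t".join(RESULTS_COLUMNS)]
    for r in results:
        lines.append("\t".join(_fmt(v) for v in (
            r.voltage, r.tau, r.tau0, r.tauL, r.pi0, r.piL, r.x0)))
    Path(path).write_text("\n".join(lines) + "\n")


def read_results(path: str | Path) -> list[FptResult]:
    """Re-import a results TSV written by :func:`write_results`."""
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    missing = [c for c in RESULTS_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing result columns {missing}")
    out = []
    for row in df.itertuples(index=False):
        d = row._asdict()
        tethered = d["piL"] == 0.0 and math.isnan(d["tauL_s"])
        out.append(FptResult(
            voltage=d["voltage_mV"], x0=d["x0_nm"], pi0=d["pi0"],
            piL=d["piL"], tau0=d["tau0_s"], tauL=d["tauL_s"], tau=d["tau_s"],
            tethered=tethered,
        ))
    return out
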
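"""Equilibrium DNA-binding biophysics: 1:1 isotherm fitting, fractional
occupancy, and conversion of protein copy numbers and nuclear geometry into
molar concentrations.

Units are explicit everywhere: concentrations in molar, masses in ng,
molecular weights in kDa, surfaces in um^2, volumes in um^3.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import constants, optimize

AVOGADRO = constants.Avogadro
_UM3_TO_L = 1e-15


@dataclass
class BindingCurve:
    """(concentration, response) pairs with fitted Kd and Rmax."""

    concentrations: np.ndarray
    responses: np.ndarray
    fitted_kd: float
    fitted_rmax: float
    residual_norm: float

    def __post_init__(self) -> None:
        if self.fitted_kd <= 0 or self.fitted_rmax <= 0:
            raise ValueError("fitted Kd and Rmax must be positive")


@dataclass
class NuclearQuant:
    """Copies-per-cell and spherical nuclear geometry -> molar concentration."""

    copies_per_cell: float
    nuclear_fraction: float
    envelope_surface: float  # um^2
    nuclear_radius: float
    nuclear_volume: float
    concentration: float  # molar


def fractional_occupancy(c: float, kd: float) -> float:
    """Equilibrium fraction of sites bound: c / (c + kd).

    Exactly 1/2 at c = kd; strictly increasing in c; tends to 1 as c grows.
    """
    if c < 0:
        raise ValueError(f"negative concentration {c}")
    if kd <= 0:
        raise ValueError(f"non-positive Kd {kd}")
    return c / (c + kd)


def isotherm(c: np.ndarray, kd: float, rmax: float) -> np.ndarray:
    return rmax * c / (kd + c)


def fit_binding_isotherm(
    concentrations: Sequence[float],
    responses: Sequence[float],
) -> BindingCurve:
    """Nonlinear least squares of R = Rmax c / (Kd + c).

    Initialised at Kd0 = median(c), Rmax0 = max(R); deterministic for fixed
    input. Raises on fewer than 3 points, a concentration span under one
    decade, or all-equal responses.
    """
    c = np.asarray(concentrations, dtype=float)
    r = np.asarray(responses, dtype=float)
    if c.size != r.size or c.size < 3:
        raise ValueError("need >= 3 (concentration, response) pairs")
    if np.any(c <= 0):
        raise ValueError("concentrations must be positive")
    if c.max() / c.min() < 10.0:
        raise ValueError("concentrations must span at least one decade")
    if np.ptp(r) == 0:
        raise ValueError("all responses equal; isotherm unidentifiable")
    p0 = (float(np.median(c)), float(r.max()))
    try:
        popt, _ = optimize.curve_fit(
            lambda x, kd, rmax: isotherm(x, kd, rmax), c, r, p0=p0,
            bounds=([1e-30, 1e-30], [np.inf, np.inf]), maxfev=10_000)
    except RuntimeError as exc:
        raise RuntimeError(f"isotherm fit did not converge: {exc}") from exc
    kd, rmax = float(popt[0]), float(popt[1])
    resid = float(np.linalg.norm(r - isotherm(c, kd, rmax)))
    return BindingCurve(concentrations=c, responses=r, fitted_kd=kd,
                        fitted_rmax=rmax, residual_norm=resid)


def copies_from_mass(mass_ng: float, molecular_weight_kda: float) -> float:
    """Protein mass (ng) -> molecule count at the given MW (kDa)."""
    if mass_ng < 0:
        raise ValueError("mass must be >= 0")
    if molecular_weight_kda <= 0:
        raise ValueError("molecular weight must be positive")
    return mass_ng * 1e-9 / (molecular_weight_kda * 1e3) * AVOGADRO


def copies_per_cell(total_copies: float, n_cells: float) -> float:
    """Census helper keeping cell-count assumptions separate from geometry."""
    if n_cells <= 0:
        raise ValueError("n_cells must be positive")
    return total_copies / n_cells


def nuclear_concentration(
    copies: float,
    nuclear_fraction: float,
    envelope_surface_um2: float,
) -> NuclearQuant:
    """Molar nuclear concentration from copies/cell and envelope geometry.

    The nucleus is modelled as a sphere of the given envelope surface:
    r = sqrt(S / 4 pi), V = 4/3 pi r^3; concentration =
    copies * nuclear_fraction / (V_litres * N_A).
    """
    if envelope_surface_um2 <= 0:
        raise ValueError("surface must be positive")
    if not 0.0 < nuclear_fraction <= 1.0:
        raise ValueError("nuclear_fraction must be in (0, 1]")
    radius = math.sqrt(envelope_surface_um2 / (4.0 * math.pi))
    volume = 4.0 / 3.0 * math.pi * radius ** 3
    conc = copies * nuclear_fraction / (volume * _UM3_TO_L * AVOGADRO)
    return NuclearQuant(copies_per_cell=copies,
                        nuclear_fraction=nuclear_fraction,
                        envelope_surface=envelope_surface_um2,
                        nuclear_radius=radius, nuclear_volume=volume,
                        concentration=conc)


def copies_for_concentration(
    concentration_molar: float,
    nuclear_fraction: float,
    envelope_surface_um2: float,
) -> float:
    """Algebraic inverse of :func:`nuclear_concentration` (copies/cell)."""
    radius = math.sqrt(envelope_surface_um2 / (4.0 * math.pi))
    volume = 4.0 / 3.0 * math.pi * radius ** 3
    return concentration_molar * volume * _UM3_TO_L * AVOGADRO \
        / nuclear_fraction


def concentration_kd_ratio(c: float, kd: float) -> float:
    """Fold excess of a concentration over a dissociation constant."""
    if c <= 0 or kd <= 0:
        raise ValueError("both concentrations must be positive")
    return c / kd
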
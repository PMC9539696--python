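"""Exact two-isotope (⁵⁶Fe/⁵⁴Fe) bookkeeping.

Every iron reservoir in the model carries the two stable isotopes as
separate masses; the δ⁵⁶Fe value is always *derived* from the pair, never
stored.  This module provides the conversions between δ-notation and
isotope ratios, conservative mixing, kinetically fractionated flux
splitting (instantaneous flux-ratio convention, R_flux = α·R_pool), the
equilibrium free/complexed partition used for ligand speciation, and the
closed-form Rayleigh distillation curve kept as an independent oracle for
the time-stepped scheme.

All functions accept scalars or numpy arrays and are dimensionally
agnostic: an :class:`IsotopePool` may hold mol, µmol m⁻³ or µmol m⁻² d⁻¹
depending on its role.

Notes
-----
δ⁵⁶Fe is reported against a fixed reference ratio ``R_STD`` (IRMM-014,
⁵⁶Fe/⁵⁴Fe = 15.698).  Because δ values are ratios of ratios, every ‰-level
result in the package is invariant to the choice of standard; the constant
merely fixes the absolute split of a pool into its two isotopes.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

__all__ = [
    "R_STD",
    "IsotopeStandard",
    "FractionationFactors",
    "IsotopePool",
    "delta_to_ratio",
    "ratio_to_delta",
    "pool_from_total",
    "pool_delta",
    "mix",
    "fractionated_flux",
    "rayleigh_delta",
    "equilibrium_partition",
    "heavy_fraction",
]

#: Reference ⁵⁶Fe/⁵⁴Fe ratio (IRRM-014 convention) used throughout.
R_STD = 15.698


class IsotopeError(ValueError):
    """Raised for invalid isotope arithmetic (empty pools, over-withdrawal...)."""


@dataclass(frozen=True)
class IsotopeStandard:
    """Reference isotope ratio defining the δ = 0 point."""

    r_std: float = R_STD

    def __post_init__(self) -> None:
        if self.r_std <= 0:
            raise IsotopeError(f"reference ratio must be positive, got {self.r_std}")


@dataclass(frozen=True)
class FractionationFactors:
    """Kinetic/equilibrium fractionation factors of the iron cycle.

    ``alpha_uptake`` applies to phytoplankton Fe uptake (light-preferring,
    < 1); ``alpha_ligand`` to organic complexation (complexed Fe is heavy,
    > 1).  Scavenging and colloidal pumping carry the δ of the free and
    complexed sub-pool respectively and have no α of their own.
    """

    alpha_uptake: float = 0.9995
    alpha_ligand: float = 1.0006

    def __post_init__(self) -> None:
        if self.alpha_uptake <= 0 or self.alpha_ligand <= 0:
            raise IsotopeError("fractionation factors must be positive")


@dataclass
class IsotopePool:
    """Paired ⁵⁶Fe/⁵⁴Fe masses for one iron reservoir.

    Fields may be scalars or numpy arrays (one value per column).
    """

    fe56: np.ndarray | float
    fe54: np.ndarray | float

    @property
    def total(self) -> np.ndarray | float:
        return self.fe56 + self.fe54

    def copy(self) -> "IsotopePool":
        return IsotopePool(np.array(self.fe56, dtype=float, copy=True),
                           np.array(self.fe54, dtype=float, copy=True))

    def scaled(self, k: float) -> "IsotopePool":
        return IsotopePool(self.fe56 * k, self.fe54 * k)


def delta_to_ratio(delta, r_std: float = R_STD):
    """Convert δ⁵⁶Fe (‰) to a ⁵⁶Fe/⁵⁴Fe ratio, R = R_std·(1 + δ/1000)."""
    delta = np.asarray(delta, dtype=float)
    if np.any(delta <= -1000.0):
        raise IsotopeError("delta must exceed -1000 permil")
    out = r_std * (1.0 + delta / 1000.0)
    return float(out) if out.ndim == 0 else out


def ratio_to_delta(ratio, r_std: float = R_STD):
    """Convert a ⁵⁶Fe/⁵⁴Fe ratio to δ⁵⁶Fe in ‰ (exact inverse of delta_to_ratio)."""
    ratio = np.asarray(ratio, dtype=float)
    if np.any(ratio <= 0.0):
        raise IsotopeError("isotope ratio must be positive")
    out = 1000.0 * (ratio / r_std - 1.0)
    return float(out) if out.ndim == 0 else out


def heavy_fraction(delta, r_std: float = R_STD):
    """⁵⁶Fe mass fraction of a pool with signature ``delta``: R/(1+R)."""
    r = np.asarray(delta_to_ratio(delta, r_std))
    out = r / (1.0 + r)
    return float(out) if out.ndim == 0 else out


def pool_from_total(total, delta, r_std: float = R_STD) -> IsotopePool:
    """Build an :class:`IsotopePool` holding ``total`` Fe at signature ``delta``."""
    total = np.asarray(total, dtype=float)
    if np.any(total < 0):
        raise IsotopeError("total Fe amount must be non-negative")
    f56 = heavy_fraction(delta, r_std)
    fe56 = total * f56
    fe54 = total - fe56
    if total.ndim == 0:
        return IsotopePool(float(fe56), float(fe54))
    return IsotopePool(fe56, fe54)


def pool_delta(pool: IsotopePool, r_std: float = R_STD):
    """δ⁵⁶Fe of a pool.  Raises for an empty pool rather than returning NaN."""
    fe54 = np.asarray(pool.fe54, dtype=float)
    if np.any(fe54 <= 0.0):
        raise IsotopeError("delta undefined for a pool with no 54Fe")
    return ratio_to_delta(np.asarray(pool.fe56, dtype=float) / fe54, r_std)


def mix(pools: Sequence[IsotopePool]) -> IsotopePool:
    """Conservative mixture: componentwise sum in left-to-right order."""
    fe56 = 0.0
    fe54 = 0.0
    for p in pools:
        fe56 = fe56 + p.fe56
        fe54 = fe54 + p.fe54
    return IsotopePool(fe56, fe54)


def fractionated_flux(pool: IsotopePool, amount, alpha: float):
    """Withdraw ``amount`` from ``pool`` with instantaneous fractionation α.

    The flux leaves at ratio R_flux = α·R_pool.  The per-isotope split is
    clipped so that the residual never goes negative: at full withdrawal
    the flux is the entire pool and δ_flux = δ_pool by mass balance.

    Returns ``(flux, residual)`` as two pools; flux + residual == pool
    exactly, component by component.
    """
    amount = np.asarray(amount, dtype=float)
    fe56 = np.asarray(pool.fe56, dtype=float)
    fe54 = np.asarray(pool.fe54, dtype=float)
    total = fe56 + fe54
    if np.any(amount < 0) or np.any(amount > total * (1 + 1e-12) + 1e-300):
        raise IsotopeError("withdrawal amount outside [0, pool total]")
    amount = np.minimum(amount, total)
    with np.errstate(divide="ignore", invalid="ignore"):
        r_flux = alpha * fe56 / fe54
        f54 = np.where(total > 0, amount / (1.0 + r_flux), 0.0)
    # keep both isotopes of the residual non-negative
    f54 = np.minimum(f54, fe54)
    f56 = np.minimum(amount - f54, fe56)
    f56 = np.maximum(f56, 0.0)
    f54 = np.clip(amount - f56, 0.0, fe54)
    # two-subtract construction makes flux + residual == pool bitwise
    # (Sterbenz: one of the two subtractions is always exact)
    r56 = fe56 - f56
    r54 = fe54 - f54
    f56 = fe56 - r56
    f54 = fe54 - r54
    flux = IsotopePool(f56, f54)
    residual = IsotopePool(r56, r54)
    if amount.ndim == 0 and np.asarray(pool.fe56).ndim == 0:
        flux = IsotopePool(float(flux.fe56), float(flux.fe54))
        residual = IsotopePool(float(residual.fe56), float(residual.fe54))
    return flux, residual


def rayleigh_delta(delta0, f_remaining, alpha):
    """Closed-form Rayleigh distillation of the residual pool.

    δ(f) = (δ₀ + 1000)·f^(α−1) − 1000 for remaining fraction f ∈ (0, 1].
    Used as an independent oracle for the time-stepped kinetic scheme.
    """
    f_remaining = np.asarray(f_remaining, dtype=float)
    if np.any(f_remaining <= 0) or np.any(f_remaining > 1):
        raise IsotopeError("remaining fraction must lie in (0, 1]")
    out = (np.asarray(delta0, dtype=float) + 1000.0) * f_remaining ** (alpha - 1.0) - 1000.0
    return float(out) if out.ndim == 0 else out


def _partition_fe54_free(fe56, fe54, free_total, alpha):
    """⁵⁴Fe content of the free pool for the equilibrium partition.

    Solves the exact two-by-two mass balance
        R_complexed = α·R_free,
        free + complexed = pool   (per isotope),
    with a prescribed free *total*.  Reduces to the quadratic
        (1−α)x² + b·x − α·free_total·fe54 = 0,  b = fe56 + α·fe54 + (α−1)·free_total,
    solved with the numerically stable root (linear fallback for α → 1).
    """
    a = 1.0 - alpha
    b = fe56 + alpha * fe54 + (alpha - 1.0) * free_total
    c = -alpha * free_total * fe54
    if abs(a) < 1e-13:
        with np.errstate(divide="ignore", invalid="ignore"):
            x = np.where(b > 0, -c / np.where(b > 0, b, 1.0), 0.0)
    else:
        disc = np.sqrt(np.maximum(b * b - 4.0 * a * c, 0.0))
        # root that stays finite and in [0, fe54] as a -> 0
        with np.errstate(divide="ignore", invalid="ignore"):
            x = np.where(b + disc > 0, -2.0 * c / (b + disc), 0.0)
    return np.clip(x, 0.0, np.minimum(fe54, free_total))


def equilibrium_partition(total: IsotopePool, fraction_complexed, alpha_ligand: float):
    """Split a pool into free and ligand-complexed sub-pools at equilibrium.

    The complexed sub-pool holds ``fraction_complexed`` of the total Fe and
    sits at R_complexed = α_ligand·R_free (complexed Fe isotopically heavy
    for α_ligand > 1).  The two-by-two mass balance is solved exactly — no
    ‰-level linearisation — so free + complexed recombine to the input pool
    bit-for-bit.

    Returns ``(free, complexed)``.
    """
    frac = np.asarray(fraction_complexed, dtype=float)
    if np.any(frac < 0) or np.any(frac > 1):
        raise IsotopeError("fraction_complexed must lie in [0, 1]")
    fe56 = np.asarray(total.fe56, dtype=float)
    fe54 = np.asarray(total.fe54, dtype=float)
    tot = fe56 + fe54
    free_total = (1.0 - frac) * tot
    x54 = _partition_fe54_free(fe56, fe54, free_total, alpha_ligand)
    free56 = free_total - x54
    free = IsotopePool(free56, x54)
    complexed = IsotopePool(fe56 - free56, fe54 - x54)
    if np.asarray(total.fe56).ndim == 0 and frac.ndim == 0:
        free = IsotopePool(float(free.fe56), float(free.fe54))
        complexed = IsotopePool(float(complexed.fe56), float(complexed.fe54))
    return free, complexed
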
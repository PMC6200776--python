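"""Closed-form mass-action binding models and derived kinetic quantities.

These are the equations every fitting and simulation stage is built on:
the one-site hyperbola for equilibrium (saturation) binding, the
mono-exponential association model for binding kinetics, the Cheng-Prusoff
relation linking an inhibition midpoint (IC50) to a competitor affinity
(Ki), and four-parameter logistic curves for competition and
concentration-response data.

Unit conventions
----------------
Concentrations are molar (M) and times are minutes throughout this module.
Rate constants follow the pharmacology convention: the association rate
constant ``kon`` is in M^-1 min^-1 and the dissociation rate constant
``koff`` in min^-1, so the kinetically derived equilibrium dissociation
constant ``koff/kon`` is in M.  File and CLI boundaries report nM; the
conversion happens there, never here.

All operations accept scalars or array-likes and broadcast like numpy
ufuncs; scalar input yields a Python float.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "InvalidParameterError",
    "InvalidInputError",
    "KineticRateParams",
    "EquilibriumBindingParams",
    "CompetitionCurveParams",
    "ConcentrationResponseParams",
    "fractional_occupancy",
    "total_signal_eq",
    "kobs",
    "association_signal",
    "half_time",
    "residence_time",
    "kinetic_kd",
    "cheng_prusoff_ki",
    "ic50_from_ki",
    "competition_signal",
    "logistic_response",
]

LN2 = float(np.log(2.0))


class InvalidParameterError(ValueError):
    """A model parameter lies outside its physically valid domain."""


class InvalidInputError(ValueError):
    """An input quantity (concentration, time) is outside its valid domain."""


def _check_param(value: float, name: str, *, positive: bool = True) -> None:
    if not np.isfinite(value):
        raise InvalidParameterError(f"{name} must be finite, got {value!r}")
    if positive and value <= 0:
        raise InvalidParameterError(f"{name} must be > 0, got {value!r}")
    if not positive and value < 0:
        raise InvalidParameterError(f"{name} must be >= 0, got {value!r}")


def _check_nonneg_array(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if np.any(~np.isfinite(arr)) or np.any(arr < 0):
        raise InvalidInputError(f"{name} must be finite and >= 0")
    return arr


def _match_input(x, arr: np.ndarray):
    """Return a float for scalar input, else the array."""
    if np.ndim(x) == 0:
        return float(arr)
    return arr


@dataclass(frozen=True)
class KineticRateParams:
    """Association/dissociation rate constants of a bimolecular interaction.

    Parameters
    ----------
    kon : float
        Association rate constant, M^-1 min^-1.
    koff : float
        Dissociation rate constant, min^-1.
    """

    kon: float
    koff: float

    def __post_init__(self) -> None:
        _check_param(self.kon, "kon")
        _check_param(self.koff, "koff")

    @property
    def kinetic_kd(self) -> float:
        """Kinetically derived equilibrium dissociation constant koff/kon (M)."""
        return self.koff / self.kon


@dataclass(frozen=True)
class EquilibriumBindingParams:
    """One-site saturation binding parameters on the BRET-ratio scale.

    ``kd`` is the equilibrium dissociation constant (M); ``bmax`` the
    maximal specific signal; ``ns_slope`` the non-specific signal per molar
    of ligand (the linear component remaining in wells co-treated with
    excess unlabeled ligand); ``baseline`` the ligand-independent signal.
    """

    kd: float
    bmax: float
    ns_slope: float = 0.0
    baseline: float = 0.0

    def __post_init__(self) -> None:
        _check_param(self.kd, "kd")
        _check_param(self.bmax, "bmax", positive=False)
        _check_param(self.ns_slope, "ns_slope", positive=False)
        if not np.isfinite(self.baseline):
            raise InvalidParameterError("baseline must be finite")


@dataclass(frozen=True)
class CompetitionCurveParams:
    """Four-parameter inhibition curve: top, bottom, IC50 (M) and slope."""

    ic50: float
    top: float
    bottom: float
    hill: float = 1.0

    def __post_init__(self) -> None:
        _check_param(self.ic50, "ic50")
        _check_param(self.hill, "hill")
        if not (np.isfinite(self.top) and np.isfinite(self.bottom)):
            raise InvalidParameterError("top and bottom must be finite")
        if self.top < self.bottom:
            raise InvalidParameterError("top must be >= bottom")


@dataclass(frozen=True)
class ConcentrationResponseParams:
    """Logistic (Hill) concentration-response curve parameters.

    ``ec50`` in M; ``emax`` and ``basal`` in response units; ``hill``
    defaults to 1 for simple mass-action occupancy-driven responses.
    """

    ec50: float
    emax: float
    basal: float = 0.0
    hill: float = 1.0

    def __post_init__(self) -> None:
        _check_param(self.ec50, "ec50")
        _check_param(self.hill, "hill")
        if not (np.isfinite(self.emax) and np.isfinite(self.basal)):
            raise InvalidParameterError("emax and basal must be finite")


def fractional_occupancy(L, kd: float):
    """Equilibrium receptor occupancy L/(L + Kd) at ligand concentration L (M)."""
    if not np.isfinite(kd) or kd <= 0:
        raise InvalidParameterError(f"kd must be > 0, got {kd!r}")
    arr = _check_nonneg_array(L, "L")
    return _match_input(L, arr / (arr + kd))


def total_signal_eq(L, p: EquilibriumBindingParams):
    """Total equilibrium signal: baseline + specific hyperbola + linear NSB.

    The matched non-specific-binding well (excess unlabeled competitor
    suppressing the specific site) is modeled as ``baseline + ns_slope*L``.
    """
    arr = _check_nonneg_array(L, "L")
    out = p.baseline + p.bmax * arr / (arr + p.kd) + p.ns_slope * arr
    return _match_input(L, out)


def kobs(L, r: KineticRateParams):
    """Observed mono-exponential association rate kon*L + koff (min^-1)."""
    arr = _check_nonneg_array(L, "L")
    return _match_input(L, r.kon * arr + r.koff)


def association_signal(t, L, r: KineticRateParams, bmax: float):
    """Specific binding signal at time t (min) after ligand addition.

    B_eq(L) * (1 - exp(-kobs t)) with the equilibrium plateau
    B_eq(L) = bmax * L / (L + koff/kon); rises monotonically to B_eq.
    """
    _check_param(bmax, "bmax", positive=False)
    t_arr = np.asarray(t, dtype=float)
    if np.any(~np.isfinite(t_arr)) or np.any(t_arr < 0):
        raise InvalidInputError("t must be finite and >= 0")
    L_arr = _check_nonneg_array(L, "L")
    beq = bmax * L_arr / (L_arr + r.kinetic_kd)
    out = beq * (1.0 - np.exp(-(r.kon * L_arr + r.koff) * t_arr))
    if np.ndim(t) == 0 and np.ndim(L) == 0:
        return float(out)
    return out


def half_time(L, r: KineticRateParams):
    """Association half-time ln2 / (kon*L + koff), in minutes."""
    k = kobs(L, r)
    k_arr = np.asarray(k, dtype=float)
    if np.any(k_arr == 0):
        raise ZeroDivisionError("observed rate is zero; half-time undefined")
    return _match_input(L, LN2 / k_arr)


def residence_time(r: KineticRateParams) -> float:
    """Mean lifetime of the ligand-receptor complex, 1/koff (min)."""
    if r.koff == 0:
        raise ZeroDivisionError("koff is zero; residence time undefined")
    return 1.0 / r.koff


def kinetic_kd(r: KineticRateParams) -> float:
    """Kinetically derived equilibrium dissociation constant koff/kon (M)."""
    return r.koff / r.kon


def cheng_prusoff_ki(ic50, L: float, kd: float):
    """Competitor affinity Ki = IC50 / (1 + L/Kd) for probe concentration L.

    Assumes simple competitive mass-action interaction of probe and
    competitor at one site.  Exact inverse of :func:`ic50_from_ki`.
    """
    if not np.isfinite(kd) or kd <= 0:
        raise InvalidParameterError(f"kd must be > 0, got {kd!r}")
    if not np.isfinite(L) or L < 0:
        raise InvalidInputError(f"L must be >= 0, got {L!r}")
    arr = np.asarray(ic50, dtype=float)
    if np.any(arr <= 0):
        raise InvalidInputError("ic50 must be > 0")
    return _match_input(ic50, arr / (1.0 + L / kd))


def ic50_from_ki(ki: float, L, kd: float):
    """Expected IC50 = Ki * (1 + L/Kd): affine in L with intercept Ki, slope Ki/Kd."""
    if not np.isfinite(kd) or kd <= 0:
        raise InvalidParameterError(f"kd must be > 0, got {kd!r}")
    if not np.isfinite(ki) or ki <= 0:
        raise InvalidParameterError(f"ki must be > 0, got {ki!r}")
    arr = _check_nonneg_array(L, "L")
    return _match_input(L, ki * (1.0 + arr / kd))


def competition_signal(I, c: CompetitionCurveParams):
    """Four-parameter inhibition curve evaluated at competitor concentration I (M)."""
    arr = _check_nonneg_array(I, "I")
    out = c.bottom + (c.top - c.bottom) / (1.0 + (arr / c.ic50) ** c.hill)
    return _match_input(I, out)


def logistic_response(conc, p: ConcentrationResponseParams):
    """Logistic concentration-response; conc = 0 returns the basal response."""
    arr = _check_nonneg_array(conc, "conc")
    safe = np.where(arr > 0, arr, 1.0)
    with np.errstate(divide="ignore", over="ignore"):
        ratio = np.where(arr > 0, (p.ec50 / safe) ** p.hill, np.inf)
    out = p.basal + (p.emax - p.basal) / (1.0 + ratio)
    return _match_input(conc, out)
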
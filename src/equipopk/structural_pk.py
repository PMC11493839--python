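"""Three-compartment mammillary disposition model with first-order oral absorption.

The structural model is the classic mammillary arrangement: a central
compartment (volume ``V1``) that exchanges drug with two peripheral
compartments (``V2``, ``V3``) via the intercompartmental clearances ``CL2``
and ``CL3``, with elimination from the central compartment at clearance
``CL``.  Oral doses enter a gut compartment and are absorbed at the
first-order rate ``Kabs`` with bioavailability ``F``; intravenous doses are
zero-order infusions (default 5 min) or bolus inputs into the central
compartment.

All quantities are per kilogram of body weight: doses in mg/kg, volumes in
L/kg, clearances in L/kg/h, times in h.  Concentrations are therefore in
mg/L, which equals μg/mL — the unit in which plasma quinidine is reported.

The model is solved in closed form: the disposition exponents are the
negated eigenvalues of the mammillary rate matrix, and every dose
contributes a sum of exponentials which are superposed by linearity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "SALT_FACTORS",
    "PKParameters",
    "MicroConstants",
    "DispositionExponents",
    "DoseEvent",
    "Regimen",
    "ConcentrationProfile",
    "DegenerateDispositionError",
    "to_base_dose",
    "to_salt_dose",
    "micro_constants",
    "disposition_exponents",
    "secondary_parameters",
    "simulate_profile",
]

#: Mass ratio of the administered salt form to quinidine base.
SALT_FACTORS = {
    "sulfate_dihydrate": 1.206,
    "hydrochloride_monohydrate": 1.168,
    "base": 1.0,
}

#: Default IV infusion duration (h); quinidine was given as a slow 5-min infusion.
DEFAULT_INFUSION_DURATION = 5.0 / 60.0

#: Relative tolerance under which the absorption rate is treated as equal to a
#: disposition exponent and the L'Hopital limit term is used instead.
_KA_DEGENERACY_RTOL = 1e-8


class DegenerateDispositionError(ValueError):
    """Raised when disposition exponents coincide within tolerance.

    A repeated eigenvalue makes the distinct-exponential expansion invalid;
    the condition is reported rather than silently mishandled.
    """


def to_base_dose(amount: float, salt: str) -> float:
    """Convert a dose expressed on a salt scale to quinidine base (mg/kg)."""
    if amount < 0:
        raise ValueError(f"dose amount must be non-negative, got {amount}")
    try:
        return amount / SALT_FACTORS[salt]
    except KeyError:
        raise ValueError(
            f"unknown salt {salt!r}; expected one of {sorted(SALT_FACTORS)}"
        ) from None


def to_salt_dose(amount: float, salt: str) -> float:
    """Exact inverse of :func:`to_base_dose`."""
    if amount < 0:
        raise ValueError(f"dose amount must be non-negative, got {amount}")
    try:
        return amount * SALT_FACTORS[salt]
    except KeyError:
        raise ValueError(
            f"unknown salt {salt!r}; expected one of {sorted(SALT_FACTORS)}"
        ) from None


@dataclass(frozen=True)
class PKParameters:
    """Typical (or individual) structural parameters of the disposition model.

    Parameters
    ----------
    V1, V2, V3 : float
        Central and peripheral volumes of distribution (L/kg).
    CL : float
        Plasma clearance (L/kg/h).
    CL2, CL3 : float
        Intercompartmental distribution clearances (L/kg/h).
    Kabs : float
        First-order oral absorption rate constant (1/h).
    F : float
        Oral bioavailability fraction (0–1).
    """

    V1: float
    V2: float
    V3: float
    CL: float
    CL2: float
    CL3: float
    Kabs: float
    F: float

    _names = ("V1", "V2", "V3", "CL", "CL2", "CL3", "Kabs", "F")

    def __post_init__(self) -> None:
        for name in ("V1", "V2", "V3", "CL", "Kabs", "F"):
            value = getattr(self, name)
            if not value > 0:
                raise ValueError(f"{name} must be strictly positive, got {value}")
        for name in ("CL2", "CL3"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.F > 1:
            raise ValueError(f"typical bioavailability F must be <= 1, got {self.F}")

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in self._names], dtype=float)

    @classmethod
    def parameter_names(cls) -> tuple[str, ...]:
        return cls._names


@dataclass(frozen=True)
class MicroConstants:
    """First-order micro rate constants of the mammillary model (1/h)."""

    k10: float
    k12: float
    k21: float
    k13: float
    k31: float
    ka: float

    def __post_init__(self) -> None:
        if not self.k10 > 0:
            raise ValueError("k10 must be strictly positive")
        for name in ("k12", "k21", "k13", "k31"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


def micro_constants(p: PKParameters) -> MicroConstants:
    """Re-parameterize clearances/volumes into micro rate constants.

    ``k10 = CL/V1``, ``k12 = CL2/V1``, ``k21 = CL2/V2``, ``k13 = CL3/V1``,
    ``k31 = CL3/V3``.  A peripheral compartment with zero distribution
    clearance is simply decoupled (its rate constants are zero).
    """
    return MicroConstants(
        k10=p.CL / p.V1,
        k12=p.CL2 / p.V1,
        k21=p.CL2 / p.V2,
        k13=p.CL3 / p.V1,
        k31=p.CL3 / p.V3,
        ka=p.Kabs,
    )


@dataclass(frozen=True)
class DispositionExponents:
    """Disposition exponents and amount-normalized bolus coefficients.

    ``exponents`` are the negated eigenvalues of the mammillary rate matrix,
    sorted descending (alpha >= beta >= gamma), restricted to the coupled
    compartments.  ``coefficients`` are the matching weights of the central
    compartment's unit-bolus response, ``A1(t) = sum_i c_i exp(-l_i t)`` with
    ``sum_i c_i = 1``.
    """

    exponents: np.ndarray
    coefficients: np.ndarray

    @property
    def alpha(self) -> float:
        return float(self.exponents[0])

    @property
    def beta(self) -> float:
        if len(self.exponents) < 2:
            raise ValueError("model collapsed to fewer than two exponents")
        return float(self.exponents[1])

    @property
    def gamma(self) -> float:
        if len(self.exponents) < 3:
            raise ValueError("model collapsed to fewer than three exponents")
        return float(self.exponents[2])

    @property
    def terminal_rate(self) -> float:
        """Smallest disposition exponent (1/h); sets the terminal half-life."""
        return float(self.exponents[-1])


def _disposition_matrix(m: MicroConstants) -> tuple[np.ndarray, list[int]]:
    """Rate matrix of the coupled (connected) part of the mammillary system.

    Returns the matrix of d(amount)/dt = M @ amount for the central compartment
    plus every peripheral compartment with non-zero exchange, and the indices
    (2 and/or 3) of the peripheral compartments retained.
    """
    periph = []
    if m.k12 > 0 and m.k21 > 0:
        periph.append(2)
    if m.k13 > 0 and m.k31 > 0:
        periph.append(3)
    ndim = 1 + len(periph)
    M = np.zeros((ndim, ndim))
    M[0, 0] = -m.k10
    for row, idx in enumerate(periph, start=1):
        kin = m.k12 if idx == 2 else m.k13
        kout = m.k21 if idx == 2 else m.k31
        M[0, 0] -= kin
        M[0, row] = kout
        M[row, 0] = kin
        M[row, row] = -kout
    return M, periph


def disposition_exponents(m: MicroConstants, rtol: float = 1e-7) -> DispositionExponents:
    """Solve the disposition polynomial via the eigen-decomposition of the rate matrix.

    For the full three-compartment system the three exponents satisfy
    ``alpha*beta*gamma = k10*k21*k31`` and
    ``alpha+beta+gamma = k10+k12+k21+k13+k31``.  Peripheral compartments with
    zero distribution clearance are decoupled, reducing the system (the
    one-compartment limit returns the single exponent ``k10``).

    Raises
    ------
    DegenerateDispositionError
        If two exponents of the coupled system coincide within ``rtol``.
    """
    M, _ = _disposition_matrix(m)
    if M.shape[0] == 1:
        return DispositionExponents(
            exponents=np.array([m.k10]), coefficients=np.array([1.0])
        )
    eigval, eigvec = np.linalg.eig(M)
    lam = -eigval.real  # mammillary systems with elimination have real spectra
    order = np.argsort(lam)[::-1]
    lam = lam[order]
    eigvec = eigvec[:, order]
    if np.any(np.diff(lam) > -rtol * lam[:-1]):
        raise DegenerateDispositionError(
            f"repeated disposition exponents within tolerance: {lam}"
        )
    # unit bolus in the central compartment: A(t) = V exp(diag(-lam) t) V^-1 e1
    e1 = np.zeros(M.shape[0])
    e1[0] = 1.0
    weights = np.linalg.solve(eigvec, e1)
    coeffs = eigvec[0, :] * weights
    return DispositionExponents(exponents=lam, coefficients=coeffs.real)


def secondary_parameters(p: PKParameters) -> dict[str, float]:
    """Secondary parameters derived from the primary structural parameters.

    Returns ``Vss`` (L/kg), ``MRT`` (h), the three disposition half-lives and
    the absorption half-life (h).
    """
    vss = p.V1 + p.V2 + p.V3
    ex = disposition_exponents(micro_constants(p))
    out = {
        "Vss": vss,
        "MRT": vss / p.CL,
        "t_half_abs": math.log(2) / p.Kabs,
        "t_half_gamma": math.log(2) / ex.terminal_rate,
    }
    if len(ex.exponents) == 3:
        out["t_half_alpha"] = math.log(2) / ex.alpha
        out["t_half_beta"] = math.log(2) / ex.beta
    return out


@dataclass(frozen=True)
class DoseEvent:
    """A single administration: time (h), amount (mg/kg) on the stated salt scale."""

    time: float
    amount: float
    route: str
    salt: str = "sulfate_dihydrate"
    infusion_duration: float | None = None

    def __post_init__(self) -> None:
        if self.time < 0:
            raise ValueError("dose time must be non-negative")
        if self.amount < 0:
            raise ValueError("dose amount must be non-negative")
        if self.route not in ("IV", "PO"):
            raise ValueError(f"route must be 'IV' or 'PO', got {self.route!r}")
        if self.salt not in SALT_FACTORS:
            raise ValueError(f"unknown salt {self.salt!r}")
        if self.infusion_duration is None:
            duration = DEFAULT_INFUSION_DURATION if self.route == "IV" else 0.0
            object.__setattr__(self, "infusion_duration", duration)
        if self.infusion_duration < 0:
            raise ValueError("infusion duration must be non-negative")
        if self.route == "PO" and self.infusion_duration > 0:
            raise ValueError("infusion duration applies to IV doses only")

    @property
    def base_amount(self) -> float:
        """Dose as quinidine base (mg/kg)."""
        return to_base_dose(self.amount, self.salt)


@dataclass(frozen=True)
class Regimen:
    """An ordered schedule of dose events."""

    events: tuple[DoseEvent, ...]
    label: str = ""

    def __post_init__(self) -> None:
        events = tuple(sorted(self.events, key=lambda e: e.time))
        object.__setattr__(self, "events", events)

    def __len__(self) -> int:
        return len(self.events)

    def scaled(self, factor: float) -> "Regimen":
        """Regimen with every dose amount multiplied by ``factor``."""
        return Regimen(
            events=tuple(replace(e, amount=e.amount * factor) for e in self.events),
            label=self.label,
        )


@dataclass(frozen=True)
class ConcentrationProfile:
    """A concentration–time curve (h, μg/mL) for one subject."""

    times: np.ndarray
    concentrations: np.ndarray

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        conc = np.asarray(self.concentrations, dtype=float)
        if times.shape != conc.shape or times.ndim != 1:
            raise ValueError("times and concentrations must be equal-length 1-D arrays")
        if np.any(np.diff(times) <= 0):
            raise ValueError("times must be strictly increasing")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "concentrations", conc)


def _bolus_terms(tau: np.ndarray, lam: np.ndarray, coef: np.ndarray) -> np.ndarray:
    """Central concentration x V1 for a unit bolus, evaluated at tau >= 0."""
    return np.exp(-np.outer(tau, lam)) @ coef


def _infusion_response(
    tau: np.ndarray, lam: np.ndarray, coef: np.ndarray, rate: float, duration: float
) -> np.ndarray:
    """Central amount for a zero-order infusion at ``rate`` over ``duration``."""
    out = np.zeros_like(tau)
    during = (tau >= 0) & (tau <= duration)
    after = tau > duration
    if np.any(during):
        t = tau[during]
        out[during] = rate * ((1.0 - np.exp(-np.outer(t, lam))) / lam) @ coef
    if np.any(after):
        t = tau[after]
        plateau = coef * (1.0 - np.exp(-lam * duration)) / lam
        out[after] = rate * np.exp(-np.outer(t - duration, lam)) @ plateau
    return out


def _oral_response(
    tau: np.ndarray, lam: np.ndarray, coef: np.ndarray, amount: float, ka: float
) -> np.ndarray:
    """Central amount for a first-order input of ``amount`` at rate ``ka``.

    Convolution of the gut emptying flux with the unit-bolus response gives
    ``amount * ka * sum_i c_i (exp(-l_i t) - exp(-ka t)) / (ka - l_i)``; when
    ``ka`` coincides with an exponent the term degenerates to
    ``c_i * t * exp(-l_i t)`` (L'Hopital limit).
    """
    out = np.zeros_like(tau)
    pos = tau >= 0
    if not np.any(pos):
        return out
    t = tau[pos]
    e_ka = np.exp(-ka * t)
    acc = np.zeros_like(t)
    for lam_i, c_i in zip(lam, coef):
        if abs(ka - lam_i) < _KA_DEGENERACY_RTOL * lam_i:
            acc += c_i * t * np.exp(-lam_i * t)
        else:
            acc += c_i * (np.exp(-lam_i * t) - e_ka) / (ka - lam_i)
    out[pos] = amount * ka * acc
    return out


def simulate_profile(
    p: PKParameters, regimen: Regimen, times: np.ndarray
) -> ConcentrationProfile:
    """Closed-form concentration–time profile under an arbitrary dose schedule.

    Each dose is converted to quinidine base at entry; oral doses are scaled
    by the bioavailability ``F``; individual dose responses are superposed by
    linearity.  Concentrations are in μg/mL.
    """
    times = np.asarray(times, dtype=float)
    if np.any(times < 0):
        raise ValueError("evaluation times must be non-negative")
    if np.any(np.diff(times) <= 0):
        raise ValueError("evaluation times must be strictly increasing")
    m = micro_constants(p)
    ex = disposition_exponents(m)
    lam, coef = ex.exponents, ex.coefficients
    amount_central = np.zeros_like(times)
    for event in regimen.events:
        if event.amount == 0:
            continue
        tau = times - event.time
        d_base = event.base_amount
        if event.route == "IV":
            if event.infusion_duration > 0:
                amount_central += _infusion_response(
                    tau, lam, coef, d_base / event.infusion_duration,
                    event.infusion_duration,
                )
            else:
                mask = tau >= 0
                if np.any(mask):
                    amount_central[mask] += d_base * _bolus_terms(tau[mask], lam, coef)
        else:
            amount_central += _oral_response(tau, lam, coef, p.F * d_base, m.ka)
    return ConcentrationProfile(times=times, concentrations=amount_central / p.V1)
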
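"""Model parameters for the sorafenib population-PK model.

Fixed-effect (structural) parameters describe transit-compartment
absorption, one-compartment disposition and a gall-bladder compartment
with two discrete emptying times.  Variability parameters hold the
log-normal inter-individual (IIV), inter-occasion (IOV) and residual
variance components.  Defaults are the published population point
estimates for sorafenib in healthy adult volunteers (nanoparticulated
test formulation SYO-1644 vs the reference formulation).

Units: amounts mg, volumes L, clearance L/h, times h, concentrations ug/L.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields

#: Blood-sampling schedule of the single-dose study (h post-dose).
PROTOCOL_TIMES = (
    0.0, 0.5, 1.0, 2.0, 3.0, 4.0, 6.0, 8.0, 10.0, 12.0,
    24.0, 36.0, 48.0, 72.0, 96.0, 120.0, 168.0,
)

#: Assay lower limit of quantification, ug/L.
LLOQ = 5.0


def cv_to_omega(cv_percent: float) -> float:
    """Exact log-normal conversion from a %CV to a log-scale SD.

    omega = sqrt(log(1 + (CV/100)^2)); inverse of :func:`omega_to_cv`.
    """
    return math.sqrt(math.log1p((cv_percent / 100.0) ** 2))


def omega_to_cv(omega: float) -> float:
    """Log-normal %CV implied by a log-scale SD: 100*sqrt(exp(w^2)-1)."""
    return 100.0 * math.sqrt(math.expm1(omega ** 2))


class ParameterError(ValueError):
    """Raised when a parameter set violates its constraints."""


@dataclass(frozen=True)
class StructuralParams:
    """Fixed-effect parameters of the structural PK model.

    Attributes
    ----------
    f_rel : relative bioavailability of the test formulation vs the
        reference (applied as a dose multiplier for test arms only).
    mtt : mean transit time of the absorption delay chain (h).
    nn : number of transit compartments (may be non-integer; the
        absorption input uses the gamma-density form).
    ka : first-order absorption rate constant (1/h).
    cl : total clearance from the central compartment (L/h).
    v : central volume of distribution (L).
    f_ent : fraction of central outflow routed to the gall bladder.
    k_ehc : enterohepatic reabsorption rate constant (1/h).
    t_gb1, t_gb2 : early and late gall-bladder emptying times (h) --
        midpoints of the steep sigmoid release function.
    gamma : steepness exponent of the sigmoid release function.
    reset_offset : hours after ``t_gb1`` at which the sigmoid midpoint
        switches from ``t_gb1`` to ``t_gb2``.
    cl_mode : ``"split"`` (default) treats ``cl`` as total clearance with
        fraction ``f_ent`` recirculated and ``1 - f_ent`` eliminated;
        ``"additional"`` keeps elimination at ``cl`` and adds the biliary
        pathway on top.
    """

    f_rel: float = 1.62
    mtt: float = 3.24
    nn: float = 1.72
    ka: float = 1.6
    cl: float = 3.33
    v: float = 8.17
    f_ent: float = 0.215
    k_ehc: float = 0.212
    t_gb1: float = 8.14
    t_gb2: float = 12.2
    gamma: float = 40.0
    reset_offset: float = 3.0
    cl_mode: str = "split"

    def __post_init__(self) -> None:
        problems = []
        for name in ("f_rel", "mtt", "nn", "ka", "cl", "v", "k_ehc",
                     "t_gb1", "t_gb2", "gamma"):
            if getattr(self, name) <= 0:
                problems.append(f"{name} must be > 0, got {getattr(self, name)}")
        if not 0.0 <= self.f_ent < 1.0:
            problems.append(f"f_ent must be in [0, 1), got {self.f_ent}")
        if self.t_gb1 >= self.t_gb2:
            problems.append(
                f"t_gb1 must be < t_gb2, got {self.t_gb1} >= {self.t_gb2}")
        if self.reset_offset < 0:
            problems.append(f"reset_offset must be >= 0, got {self.reset_offset}")
        if self.cl_mode not in ("split", "additional"):
            problems.append(f"cl_mode must be 'split' or 'additional', "
                            f"got {self.cl_mode!r}")
        if problems:
            raise ParameterError("; ".join(problems))

    @property
    def ktr(self) -> float:
        """Transit rate constant (NN+1)/MTT (1/h)."""
        return (self.nn + 1.0) / self.mtt

    @property
    def k_gb(self) -> float:
        """First-order rate central -> gall bladder (1/h)."""
        return self.f_ent * self.cl / self.v

    @property
    def k_el(self) -> float:
        """First-order irreversible elimination rate from central (1/h)."""
        if self.cl_mode == "split":
            return (1.0 - self.f_ent) * self.cl / self.v
        return self.cl / self.v

    @property
    def switch_time(self) -> float:
        """Time after dose at which the sigmoid midpoint changes (h)."""
        return self.t_gb1 + self.reset_offset


@dataclass(frozen=True)
class VariabilityParams:
    """Stochastic model components, entered as %CV (exponential model).

    ``iiv_*`` are inter-individual log-normal SDs, ``iov_cl`` the
    inter-occasion SD on clearance (redrawn each study period), and
    ``sigma_prop``/``sigma_add`` the proportional (%CV) and additive
    (ug/L) residual error components.  %CV values are converted to
    log-scale SDs with the exact relation ``sqrt(log(1+(CV/100)^2))``.
    """

    iiv_ka: float = 87.3
    iiv_cl: float = 26.1
    iiv_v: float = 21.5
    iov_cl: float = 9.0
    sigma_prop: float = 37.6
    sigma_add: float = 0.0

    def __post_init__(self) -> None:
        problems = [f"{f.name} must be >= 0, got {getattr(self, f.name)}"
                    for f in fields(self) if getattr(self, f.name) < 0]
        if problems:
            raise ParameterError("; ".join(problems))

    @classmethod
    def none(cls) -> "VariabilityParams":
        """All variance components zero (deterministic pipeline)."""
        return cls(0.0, 0.0, 0.0, 0.0, 0.0, 0.0)

    @property
    def omega_ka(self) -> float:
        return cv_to_omega(self.iiv_ka)

    @property
    def omega_cl(self) -> float:
        return cv_to_omega(self.iiv_cl)

    @property
    def omega_v(self) -> float:
        return cv_to_omega(self.iiv_v)

    @property
    def omega_iov_cl(self) -> float:
        return cv_to_omega(self.iov_cl)

    @property
    def sigma_prop_sd(self) -> float:
        """Proportional-error SD on the (1 + eps) scale."""
        return cv_to_omega(self.sigma_prop)
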
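"""Equilibrium 1:1 Ca2+-calsequestrin algebra and the effective diffusivity.

Under the rapid-buffer approximation the binding reaction

    Ca2+ + Casq  <->  Casq-Ca2+,      Kd = [Ca]free [Casq]free / [Casq-Ca]

is taken to equilibrate instantaneously, so at every point the free, bound
and total Ca2+ concentrations satisfy the mass-action quadratic.  With an
immobile buffer (D_Casq = 0) diffusion of total Ca2+ proceeds with the
concentration-weighted effective coefficient

    D* = D_Ca [Ca]free / [Ca]total.

All functions are vectorised: scalars in, scalar out; arrays in, array out.
Concentrations are in mol m^-3 (numerically mM).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "BufferState",
    "total_from_free",
    "bound_from_total",
    "free_from_total",
    "free_total_slope",
    "effective_diffusion_coefficient",
]


def _validate_nonnegative(**kwargs) -> None:
    for name, value in kwargs.items():
        if np.any(np.asarray(value) < 0):
            raise ValueError(f"{name} must be non-negative")


def total_from_free(ca_free, casq_total, Kd):
    """Total Ca2+ in equilibrium with a given free Ca2+ concentration.

    Closed form:  total = free * (casq_total + free + Kd) / (Kd + free).
    With no buffer this reduces to the free concentration.
    """
    _validate_nonnegative(ca_free=ca_free, casq_total=casq_total)
    if np.any(np.asarray(Kd) <= 0):
        raise ValueError("Kd must be strictly positive")
    ca_free = np.asarray(ca_free, dtype=float)
    out = ca_free * (casq_total + ca_free + Kd) / (Kd + ca_free)
    return out if out.ndim else float(out)


def bound_from_total(ca_total, casq_total, Kd):
    """Buffer-bound Ca2+ from total Ca2+: the smaller root of the mass-action
    quadratic  b^2 - (total + casq + Kd) b + total*casq = 0.

    The smaller root is the physical one (it keeps bound <= min(total, casq)).
    Evaluated in the subtraction-safe form b = 2c / (-B + sqrt(B^2 - 4c)).
    """
    _validate_nonnegative(ca_total=ca_total, casq_total=casq_total)
    if np.any(np.asarray(Kd) <= 0):
        raise ValueError("Kd must be strictly positive")
    ca_total = np.asarray(ca_total, dtype=float)
    casq_total = np.asarray(casq_total, dtype=float)
    s = Kd + ca_total + casq_total
    disc = s * s - 4.0 * ca_total * casq_total
    if np.any(disc < 0):
        raise ArithmeticError("negative discriminant in buffer quadratic")
    root = np.sqrt(disc)
    prod = ca_total * casq_total
    # s + root > 0 whenever any Ca or buffer is present; guard the 0/0 case
    denom = s + root
    out = np.where(denom > 0, 2.0 * prod / np.where(denom > 0, denom, 1.0), 0.0)
    return out if out.ndim else float(out)


def free_from_total(ca_total, casq_total, Kd):
    """Free Ca2+ from total Ca2+: the positive root of

    free^2 + (casq_total - total + Kd) free - Kd*total = 0.

    Inverse of :func:`total_from_free`; uses the subtraction-safe quadratic
    evaluation so the round trip holds to ~1e-15 relative.
    """
    _validate_nonnegative(ca_total=ca_total, casq_total=casq_total)
    if np.any(np.asarray(Kd) <= 0):
        raise ValueError("Kd must be strictly positive")
    ca_total = np.asarray(ca_total, dtype=float)
    casq_total = np.asarray(casq_total, dtype=float)
    b = casq_total - ca_total + Kd
    disc = b * b + 4.0 * Kd * ca_total
    root = np.sqrt(disc)
    # positive root: (-b + root)/2, rewritten when b > 0 to avoid cancellation
    out = np.where(b <= 0, 0.5 * (root - b), 2.0 * Kd * ca_total / (root + np.abs(b)))
    out = np.clip(out, 0.0, ca_total)  # remove 1-ulp overshoot at casq ~ 0
    return out if out.ndim else float(out)


def free_total_slope(ca_total, casq_total, Kd):
    """Derivative d[Ca]free / d[Ca]total at equilibrium.

    Equals 1/(1 + beta) with buffering power
    beta = casq_total * Kd / (Kd + free)^2; lies in (0, 1].
    """
    free = np.asarray(free_from_total(ca_total, casq_total, Kd), dtype=float)
    beta = casq_total * Kd / (Kd + free) ** 2
    out = 1.0 / (1.0 + beta)
    return out if out.ndim else float(out)


def effective_diffusion_coefficient(ca_total, casq_total, Kd, D_ca):
    """Effective diffusivity of total Ca2+ with an immobile 1:1 buffer.

    D* = D_Ca * free/total, the concentration-weighted average of the free
    (D_Ca) and bound (0) species diffusivities.  The removable 0/0 point at
    total = 0 is filled with its limit D_Ca * Kd / (Kd + casq_total), keeping
    D* continuous and in (0, D_Ca].
    """
    if np.any(np.asarray(ca_total) < 0):
        raise ValueError("ca_total must be non-negative")
    if np.any(np.asarray(D_ca) <= 0):
        raise ValueError("D_ca must be strictly positive")
    ca_total = np.asarray(ca_total, dtype=float)
    free = np.asarray(free_from_total(ca_total, casq_total, Kd), dtype=float)
    limit = D_ca * Kd / (Kd + np.asarray(casq_total, dtype=float))
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.where(ca_total > 0, free / np.where(ca_total > 0, ca_total, 1.0), np.nan)
    out = np.where(ca_total > 0, D_ca * ratio, limit)
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class BufferState:
    """Equilibrium Ca2+/calsequestrin composition at one point.

    Satisfies the two conservation identities and the mass-action relation;
    construct via :meth:`from_free` or :meth:`from_total`.
    """

    ca_total: float
    ca_free: float
    casq_bound: float
    casq_free: float
    casq_total: float
    Kd: float

    _RTOL = 1e-10

    def __post_init__(self) -> None:
        if self.Kd <= 0:
            raise ValueError("Kd must be strictly positive")
        for name in ("ca_total", "ca_free", "casq_bound", "casq_free", "casq_total"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        scale = max(self.ca_total, self.casq_total, 1e-300)
        if abs(self.ca_free + self.casq_bound - self.ca_total) > self._RTOL * scale:
            raise ValueError("ca_total must equal ca_free + casq_bound")
        if abs(self.casq_free + self.casq_bound - self.casq_total) > self._RTOL * scale:
            raise ValueError("casq_total must equal casq_free + casq_bound")
        mass_action = self.Kd * self.casq_bound - self.ca_free * self.casq_free
        if abs(mass_action) > self._RTOL * max(self.Kd * scale, self.ca_free * scale, 1e-300):
            raise ValueError("state violates the mass-action equilibrium")

    @classmethod
    def from_free(cls, ca_free: float, casq_total: float, Kd: float) -> "BufferState":
        total = total_from_free(ca_free, casq_total, Kd)
        bound = total - ca_free
        return cls(total, ca_free, bound, casq_total - bound, casq_total, Kd)

    @classmethod
    def from_total(cls, ca_total: float, casq_total: float, Kd: float) -> "BufferState":
        free = free_from_total(ca_total, casq_total, Kd)
        bound = ca_total - free
        return cls(ca_total, free, bound, casq_total - bound, casq_total, Kd)
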
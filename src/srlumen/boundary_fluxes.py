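"""Neumann boundary flux models: RyR release efflux and SERCA influx.

The release efflux acts on the CSR face (F2).  In ``constant`` mode its
density stays at the initial value J0; in ``decaying`` mode the magnitude
scales with the depletion of free Ca2+ at the face,

    J(t) = J0 * [Ca]free(0, t) / [Ca]free(0, 0),

keeping the sign of J0 (negative, Ca2+ leaving the SR) and shrinking toward
zero as the face empties.  The cytosolic concentration is ~5 orders of
magnitude below the luminal one and is treated as zero.

The SERCA influx is a constant positive density on the lateral face (F3),
or zero when disabled.

Both fluxes are fluxes of free Ca2+; because the bound species cannot cross
the membrane and binding re-equilibrates instantly, they enter the total-Ca2+
transport problem with the same magnitude.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry_mesh import SRElementGeometry

__all__ = ["EffluxModel", "InfluxModel", "efflux_density", "influx_density", "molar_rates"]

EFFLUX_MODES = ("constant", "decaying")


@dataclass(frozen=True)
class EffluxModel:
    """RyR release efflux at the CSR face.

    ``J0`` is the initial (t = 0) signed density, negative by convention;
    ``reference_free_ca`` the free Ca2+ at the face at t = 0 against which
    depletion is measured in ``decaying`` mode.
    """

    mode: str = "decaying"
    J0: float = -2.7375e-6
    reference_free_ca: float = 3.6

    def __post_init__(self) -> None:
        if self.mode not in EFFLUX_MODES:
            raise ValueError(f"mode must be one of {EFFLUX_MODES}")
        if not self.J0 < 0:
            raise ValueError("J0 must be negative (Ca2+ leaves the SR)")
        if not self.reference_free_ca > 0:
            raise ValueError("reference_free_ca must be positive")


@dataclass(frozen=True)
class InfluxModel:
    """SERCA-mediated influx at the lateral face; constant when enabled."""

    enabled: bool = False
    J_in: float = 3.6880e-10

    def __post_init__(self) -> None:
        if self.J_in < 0:
            raise ValueError("J_in must be non-negative")


def efflux_density(model: EffluxModel, t: float, free_ca_at_F2: float) -> float:
    """Signed release efflux density (mol m^-2 s^-1) at time ``t``.

    ``free_ca_at_F2`` is the area-averaged free Ca2+ on the CSR face (in the
    1D reduction, the x = 0 node value); it only matters in decaying mode.
    """
    if np.any(np.asarray(free_ca_at_F2) < 0):
        raise ValueError("free_ca_at_F2 must be non-negative")
    if model.mode == "constant":
        return model.J0
    return model.J0 * free_ca_at_F2 / model.reference_free_ca


def influx_density(model: InfluxModel) -> float:
    """SERCA influx density on the lateral face; zero when disabled."""
    return model.J_in if model.enabled else 0.0


def molar_rates(
    e: EffluxModel,
    i: InfluxModel,
    geom: SRElementGeometry,
    free_ca_at_F2: float,
) -> tuple[float, float]:
    """(moles/s leaving through F2, moles/s entering through F3).

    Density times face area, used for the mass audit of a run.
    """
    out_rate = abs(efflux_density(e, 0.0, free_ca_at_F2)) * geom.f2_area
    in_rate = influx_density(i) * geom.f3_area
    return out_rate, in_rate
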
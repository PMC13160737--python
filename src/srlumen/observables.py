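"""Reduction of simulation output to reported summary quantities.

Provides the axial/radial colour-map matrices, the sampled position/time
profile sets, CSR/LSR time series, the LSR-minus-CSR free-Ca2+ difference
(positive while the release face is depleted) and percent declines of any
time series over a window.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .pde_solver import ConcentrationField, FluxTimeSeries

__all__ = [
    "ProfileSet",
    "percent_decline",
    "lsr_csr_difference",
    "colormap_matrix",
    "sample_profiles",
    "timeseries_table",
    "summary_statistics",
]

#: mol m^-3 (mM) -> uM
MM_TO_UM = 1e3


@dataclass(frozen=True)
class ProfileSet:
    """Free and total Ca2+ sampled at fixed axial positions over time.

    Positions are listed from the LSR midpoint toward the CSR face to match
    the usual display convention; values are linear interpolants of node
    values.  Matrices are (position x time).
    """

    positions: np.ndarray
    times: np.ndarray
    free: np.ndarray
    total: np.ndarray


def _axial_values(field: ConcentrationField, quantity: str) -> tuple[np.ndarray, np.ndarray]:
    """(axial coordinates, (time x position) values) along the element axis."""
    data = field.free if quantity == "free" else field.total
    disc = field.disc
    if disc.mode == "axial_1d":
        return disc.node_x, data
    nr, nz = disc.shape
    x = disc.node_x[:nz]
    return x, data.reshape(data.shape[0], nr, nz)[:, 0, :]  # on-axis line


def sample_profiles(field: ConcentrationField, n_positions: int = 5) -> ProfileSet:
    """Sample free/total Ca2+ at equally spaced axial positions, LSR -> CSR."""
    if n_positions < 2:
        raise ValueError("need at least two sample positions")
    L = field.disc.geometry.axial_length
    positions = np.linspace(L, 0.0, n_positions)
    x, free_tx = _axial_values(field, "free")
    _, total_tx = _axial_values(field, "total")
    free = np.stack([[np.interp(p, x, row) for p in positions] for row in free_tx]).T
    total = np.stack([[np.interp(p, x, row) for p in positions] for row in total_tx]).T
    return ProfileSet(positions=positions, times=field.times, free=free, total=total)


def percent_decline(times: np.ndarray, values: np.ndarray, t_end: float | None = None) -> float:
    """100 * (value(0) - value(t_end)) / value(0).

    ``t_end`` defaults to the final sample; intermediate times are linearly
    interpolated.  Invariant under uniform rescaling of the series; raises on
    a zero initial value.
    """
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    if t_end is None:
        t_end = times[-1]
    if not times[0] <= t_end <= times[-1]:
        raise ValueError("t_end outside the sampled window")
    v0 = values[0]
    if v0 == 0:
        raise ZeroDivisionError("initial value is zero; percent decline undefined")
    v_end = float(np.interp(t_end, times, values))
    return 100.0 * (v0 - v_end) / v0


def lsr_csr_difference(field: ConcentrationField, t: float | None = None) -> float:
    """Free Ca2+ at the LSR midpoint minus at the CSR face, in uM.

    Positive while release depletes the CSR end.  ``t`` defaults to the end
    of the window; intermediate times are interpolated.
    """
    times = field.times
    if t is None:
        t = times[-1]
    if not times[0] <= t <= times[-1]:
        raise ValueError("t outside the simulated window")
    series = field.free_at(field.disc.lsr_node) - field.free_at(field.disc.csr_node)
    return float(np.interp(t, times, series)) * MM_TO_UM


def colormap_matrix(
    field: ConcentrationField,
    line: str = "axial",
    quantity: str = "free",
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(positions, times, position x time matrix) along a sampling line.

    ``line`` is one of ``axial`` (the element axis), ``radial@F2`` (across
    the CSR face) or ``radial@F1`` (across the LSR midpoint face); the radial
    lines require the 2D axisymmetric discretisation.  The matrices are the
    numeric content of the published heat maps and regenerate bit-identically
    from a stored field.
    """
    if quantity not in ("free", "total"):
        raise ValueError("quantity must be 'free' or 'total'")
    disc = field.disc
    if line == "axial":
        x, values_tx = _axial_values(field, quantity)
        return x, field.times, values_tx.T
    if line not in ("radial@F2", "radial@F1"):
        raise ValueError(f"unknown line {line!r}")
    if disc.mode != "axisymmetric_2d":
        raise ValueError("radial lines require the axisymmetric discretisation")
    nr, nz = disc.shape
    data = field.free if quantity == "free" else field.total
    data = data.reshape(data.shape[0], nr, nz)
    iz = 0 if line == "radial@F2" else nz - 1
    r = disc.node_r.reshape(nr, nz)[:, 0]
    return r, field.times, data[:, :, iz].T


def radial_axial_spread_ratio(field: ConcentrationField) -> float:
    """Max axial spread over max within-cross-section radial spread of free
    Ca2+, over all output times (2D fields only).

    The published claim is that this exceeds 10^3: diffusion in the element
    is effectively one-dimensional.
    """
    disc = field.disc
    if disc.mode != "axisymmetric_2d":
        raise ValueError("spread ratio requires the axisymmetric discretisation")
    nr, nz = disc.shape
    free = field.free.reshape(field.times.size, nr, nz)
    radial_spread = (free.max(axis=1) - free.min(axis=1)).max()
    cross_mean = free.mean(axis=1)
    axial_spread = (cross_mean.max(axis=1) - cross_mean.min(axis=1)).max()
    if radial_spread == 0:
        return np.inf
    return float(axial_spread / radial_spread)


def timeseries_table(field: ConcentrationField, fluxes: FluxTimeSeries) -> pd.DataFrame:
    """Per-output-time summary: efflux density, CSR/LSR free Ca2+, difference."""
    csr = field.free_at(field.disc.csr_node)
    lsr = field.free_at(field.disc.lsr_node)
    return pd.DataFrame(
        {
            "t": field.times,
            "efflux_density": fluxes.efflux_density_F2,
            "CSR_free": csr,
            "LSR_free": lsr,
            "LSR_minus_CSR_uM": (lsr - csr) * MM_TO_UM,
        }
    )


def summary_statistics(field: ConcentrationField, fluxes: FluxTimeSeries) -> dict[str, float]:
    """End-of-window percent declines and LSR-CSR differences for one run."""
    csr = field.free_at(field.disc.csr_node)
    diff_series = (field.free_at(field.disc.lsr_node) - csr) * MM_TO_UM
    return {
        "efflux_decline_pct": percent_decline(fluxes.times, np.abs(fluxes.efflux_density_F2)),
        "csr_free_decline_pct": percent_decline(field.times, csr),
        "lsr_csr_diff_end_uM": lsr_csr_difference(field),
        "lsr_csr_diff_max_uM": float(diff_series.max()),
        "mass_balance_error": fluxes.mass_balance_error(),
    }
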
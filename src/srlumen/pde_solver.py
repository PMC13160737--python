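"""Method-of-lines integration of the nonlinear total-Ca2+ diffusion problem.

The governing equation is

    d[Ca]total/dt = div( D*([Ca]total) grad [Ca]total )

on the SR element cylinder, with the effective diffusivity D* from the
rapid-buffer approximation, a (constant or depletion-scaled) release efflux
on the CSR face F2, an optional constant SERCA influx on the lateral face F3
and no flux through the closed LSR face F1.

Space is discretised with a conservative finite-volume scheme on either the
1D axial grid or the 2D axisymmetric grid (a non-conservative form
D* Laplacian(C), evaluated with the node-local coefficient, is available for
sensitivity checks).  The resulting ODE system is integrated implicitly with
SciPy's variable-order BDF method, whose modified-Newton iterations handle
the mild D*(C) nonlinearity; the 1,000 output points are sampling times
only, not solver steps.  There is no randomness anywhere: identical
configurations produce identical output on one platform.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import cached_property

import numpy as np
from scipy import sparse
from scipy.integrate import cumulative_trapezoid, solve_ivp

from .boundary_fluxes import EffluxModel, InfluxModel, influx_density
from .buffer_chemistry import effective_diffusion_coefficient, free_from_total, total_from_free
from .geometry_mesh import FACE_F2, FACE_F3, Discretization, SRElementGeometry
from .parameters import ModelParameters

__all__ = [
    "SimulationConfig",
    "ConcentrationField",
    "FluxTimeSeries",
    "initial_condition",
    "solve",
    "well_mixed_limit",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Run configuration: window, conditions, operator form and tolerances."""

    duration: float = 0.02
    n_output_points: int = 1000
    efflux_mode: str = "decaying"
    serca_enabled: bool = False
    casq_enabled: bool = True
    operator_form: str = "conservative"
    rel_tol: float = 1e-8
    abs_tol: float = 1e-12
    discretization_mode: str = "axial_1d"

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if self.n_output_points < 2:
            raise ValueError("n_output_points must be at least 2")
        if self.rel_tol <= 0 or self.abs_tol <= 0:
            raise ValueError("tolerances must be positive")
        if self.operator_form not in ("conservative", "nonconservative"):
            raise ValueError("operator_form must be 'conservative' or 'nonconservative'")
        if self.efflux_mode not in ("constant", "decaying"):
            raise ValueError("efflux_mode must be 'constant' or 'decaying'")
        if self.discretization_mode not in ("axial_1d", "axisymmetric_2d"):
            raise ValueError("unknown discretization mode")


@dataclass(frozen=True)
class ConcentrationField:
    """Total Ca2+ on (time grid x nodes) with derived free/bound views."""

    times: np.ndarray
    disc: Discretization
    total: np.ndarray
    params: ModelParameters
    casq_enabled: bool

    def __post_init__(self) -> None:
        if self.total.shape != (self.times.size, self.disc.n_nodes):
            raise ValueError("total must have shape (n_times, n_nodes)")

    @cached_property
    def free(self) -> np.ndarray:
        """Free Ca2+ view; equals total when the buffer is absent."""
        if not self.casq_enabled:
            return self.total
        return free_from_total(self.total, self.params.casq_total, self.params.Kd)

    @cached_property
    def bound(self) -> np.ndarray:
        return self.total - self.free

    def free_at(self, node: int) -> np.ndarray:
        return self.free[:, node]

    def total_moles(self) -> np.ndarray:
        """Total Ca2+ content of the domain (mol) at each output time."""
        return self.total @ self.disc.volumes


@dataclass(frozen=True)
class FluxTimeSeries:
    """Boundary flux densities and the integrated mass audit of a run."""

    times: np.ndarray
    efflux_density_F2: np.ndarray
    influx_density_F3: np.ndarray
    cumulative_moles_out: np.ndarray
    cumulative_moles_in: np.ndarray
    domain_moles: np.ndarray

    def mass_balance_error(self) -> float:
        """Max |d(moles) - (in - out)| relative to the larger of the two.

        The conservative discretisation makes this identically zero up to
        time-integration and output-quadrature error.
        """
        change = self.domain_moles - self.domain_moles[0]
        predicted = self.cumulative_moles_in - self.cumulative_moles_out
        scale = max(np.abs(change).max(), np.abs(predicted).max(), 1e-300)
        return float(np.abs(change - predicted).max() / scale)


def initial_condition(p: ModelParameters, casq_enabled: bool, disc: Discretization) -> ConcentrationField:
    """Uniform initial total-Ca2+ field.

    With calsequestrin the resting free Ca2+ is converted to total through
    the buffer equilibrium (8.2723 mM with the default constants); without
    it total and free coincide at 3.6 mM.
    """
    if casq_enabled:
        c0 = total_from_free(p.ca_free_initial, p.casq_total, p.Kd)
    else:
        c0 = p.ca_free_initial
    total = np.full((1, disc.n_nodes), c0)
    return ConcentrationField(np.array([0.0]), disc, total, p, casq_enabled)


# ---------------------------------------------------------------------------
# spatial operator assembly


def _edges(disc: Discretization) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(i, j, area/dist) for every interior finite-volume face."""
    if disc.mode == "axial_1d":
        n = disc.n_nodes
        i = np.arange(n - 1)
        j = i + 1
        dx = np.diff(disc.node_x)
        coeff = disc.geometry.f2_area / dx
        return i, j, coeff
    nr, nz = disc.shape
    geom = disc.geometry
    r = np.linspace(0.0, geom.radius, nr)
    z = np.linspace(0.0, geom.axial_length, nz)
    dr = geom.radius / (nr - 1) if nr > 1 else geom.radius
    dz = geom.axial_length / (nz - 1) if nz > 1 else geom.axial_length
    dz_owned = np.full(nz, dz)
    dz_owned[0] *= 0.5
    dz_owned[-1] *= 0.5
    r_lo = np.clip(r - dr / 2.0, 0.0, geom.radius)
    r_hi = np.clip(r + dr / 2.0, 0.0, geom.radius)
    ring_area = np.pi * (r_hi**2 - r_lo**2)

    ii, jj, cc = [], [], []
    # radial faces between (ir, iz) and (ir+1, iz) at radius r + dr/2
    for ir in range(nr - 1):
        r_face = r[ir] + dr / 2.0
        area = 2.0 * np.pi * r_face * dz_owned
        base_i = ir * nz + np.arange(nz)
        ii.append(base_i)
        jj.append(base_i + nz)
        cc.append(area / dr)
    # axial faces between (ir, iz) and (ir, iz+1)
    for ir in range(nr):
        base_i = ir * nz + np.arange(nz - 1)
        ii.append(base_i)
        jj.append(base_i + 1)
        cc.append(np.full(nz - 1, ring_area[ir] / dz))
    return np.concatenate(ii), np.concatenate(jj), np.concatenate(cc)


class _Operator:
    """Precomputed finite-volume operator and boundary bookkeeping."""

    def __init__(
        self,
        cfg: SimulationConfig,
        p: ModelParameters,
        disc: Discretization,
        efflux: EffluxModel,
        influx: InfluxModel,
    ) -> None:
        self.cfg = cfg
        self.p = p
        self.disc = disc
        self.efflux = efflux
        self.influx = influx
        self.ei, self.ej, self.ecoeff = _edges(disc)
        self.inv_vol = 1.0 / disc.volumes
        f2 = disc.face_tags[FACE_F2]
        f2_areas = disc.boundary_areas[FACE_F2]
        self.f2_nodes = f2
        self.f2_per_vol = f2_areas * self.inv_vol[f2]
        self.f2_weights = f2_areas / f2_areas.sum()
        self.serca_term = np.zeros(disc.n_nodes)
        j_in = influx_density(influx)
        if j_in > 0:
            f3 = disc.face_tags[FACE_F3]
            self.serca_term[f3] += j_in * disc.boundary_areas[FACE_F3] * self.inv_vol[f3]

    def free_values(self, c: np.ndarray) -> np.ndarray:
        if not self.cfg.casq_enabled:
            return c
        return free_from_total(c, self.p.casq_total, self.p.Kd)

    def diffusivity(self, c: np.ndarray) -> np.ndarray:
        if not self.cfg.casq_enabled:
            return np.full_like(c, self.p.D_ca_free)
        return effective_diffusion_coefficient(c, self.p.casq_total, self.p.Kd, self.p.D_ca_free)

    def face_free(self, c: np.ndarray) -> float:
        """Area-averaged free Ca2+ on the CSR face."""
        free = self.free_values(c[self.f2_nodes])
        return float(free @ self.f2_weights)

    def efflux_at(self, c: np.ndarray) -> float:
        if self.efflux.mode == "constant":
            return self.efflux.J0
        face = max(self.face_free(c), 0.0)
        return self.efflux.J0 * face / self.efflux.reference_free_ca

    def rhs(self, t: float, c: np.ndarray) -> np.ndarray:
        d = self.diffusivity(c)
        dc = np.zeros_like(c)
        diff = c[self.ej] - c[self.ei]
        if self.cfg.operator_form == "conservative":
            flux = 0.5 * (d[self.ei] + d[self.ej]) * self.ecoeff * diff
            np.add.at(dc, self.ei, flux)
            np.subtract.at(dc, self.ej, flux)
        else:
            np.add.at(dc, self.ei, d[self.ei] * self.ecoeff * diff)
            np.subtract.at(dc, self.ej, d[self.ej] * self.ecoeff * diff)
        dc *= self.inv_vol
        dc[self.f2_nodes] += self.efflux_at(c) * self.f2_per_vol
        dc += self.serca_term
        return dc

    def jac_sparsity(self) -> sparse.csr_matrix:
        n = self.disc.n_nodes
        rows = [np.arange(n), self.ei, self.ej]
        cols = [np.arange(n), self.ej, self.ei]
        # decaying efflux couples every F2 node to every other F2 node
        f2 = self.f2_nodes
        rows.append(np.repeat(f2, f2.size))
        cols.append(np.tile(f2, f2.size))
        rows = np.concatenate(rows)
        cols = np.concatenate(cols)
        data = np.ones(rows.size)
        return sparse.csr_matrix((data, (rows, cols)), shape=(n, n))


def solve(
    cfg: SimulationConfig,
    p: ModelParameters,
    geom: SRElementGeometry,
    disc: Discretization,
    efflux: EffluxModel,
    influx: InfluxModel,
) -> tuple[ConcentrationField, FluxTimeSeries]:
    """Integrate the model and return the field plus the boundary-flux audit.

    Output is sampled at ``cfg.n_output_points`` equally spaced times
    including t = 0 and t = duration.  Raises ``RuntimeError`` on solver
    failure or if concentrations go negative beyond ``abs_tol``.
    """
    if disc.geometry != geom:
        raise ValueError("discretization was built for a different geometry")
    op = _Operator(cfg, p, disc, efflux, influx)
    c0 = initial_condition(p, cfg.casq_enabled, disc).total[0]
    t_eval = np.linspace(0.0, cfg.duration, cfg.n_output_points)
    sol = solve_ivp(
        op.rhs,
        (0.0, cfg.duration),
        c0,
        method="BDF",
        t_eval=t_eval,
        rtol=cfg.rel_tol,
        atol=cfg.abs_tol,
        jac_sparsity=op.jac_sparsity(),
    )
    if not sol.success:
        raise RuntimeError(f"time integration failed: {sol.message}")
    totals = sol.y.T
    if totals.min() < -cfg.abs_tol:
        raise RuntimeError(f"negative concentration reached: min = {totals.min():.3e}")
    totals = np.clip(totals, 0.0, None)
    field = ConcentrationField(t_eval, disc, totals, p, cfg.casq_enabled)
    fluxes = _flux_series(op, field, geom)
    return field, fluxes


def _flux_series(op: _Operator, field: ConcentrationField, geom: SRElementGeometry) -> FluxTimeSeries:
    eff = np.array([op.efflux_at(c) for c in field.total])
    j_in = influx_density(op.influx)
    out_rate = np.abs(eff) * geom.f2_area
    in_rate = np.full_like(out_rate, j_in * geom.f3_area)
    cum_out = np.concatenate([[0.0], cumulative_trapezoid(out_rate, field.times)])
    cum_in = np.concatenate([[0.0], cumulative_trapezoid(in_rate, field.times)])
    return FluxTimeSeries(
        times=field.times,
        efflux_density_F2=eff,
        influx_density_F3=np.full_like(out_rate, j_in),
        cumulative_moles_out=cum_out,
        cumulative_moles_in=cum_in,
        domain_moles=field.total_moles(),
    )


def well_mixed_limit(
    cfg: SimulationConfig,
    p: ModelParameters,
    efflux: EffluxModel,
    influx: InfluxModel,
    geom: SRElementGeometry,
) -> tuple[np.ndarray, np.ndarray]:
    """Single-compartment limit: the PDE collapsed to one well-stirred volume.

    Solves dC/dt = [ J_eff(C_free) * pi r^2 + J_in * 2 pi r L ] / (pi r^2 L)
    with the same buffer algebra; the oracle for the large-D / long-time
    equilibrated regime.  Returns (times, total Ca2+).
    """
    j_in = influx_density(influx)
    source = j_in * geom.f3_area / geom.volume

    def rhs(t: float, y: np.ndarray) -> np.ndarray:
        c = y[0]
        free = free_from_total(c, p.casq_total, p.Kd) if cfg.casq_enabled else c
        if efflux.mode == "constant":
            j = efflux.J0
        else:
            j = efflux.J0 * max(free, 0.0) / efflux.reference_free_ca
        return np.array([j * geom.f2_area / geom.volume + source])

    c0 = (
        total_from_free(p.ca_free_initial, p.casq_total, p.Kd)
        if cfg.casq_enabled
        else p.ca_free_initial
    )
    t_eval = np.linspace(0.0, cfg.duration, cfg.n_output_points)
    sol = solve_ivp(rhs, (0.0, cfg.duration), [c0], method="Radau", t_eval=t_eval, rtol=1e-10, atol=1e-14)
    if not sol.success:
        raise RuntimeError(f"well-mixed integration failed: {sol.message}")
    return t_eval, sol.y[0]
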
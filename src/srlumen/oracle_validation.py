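"""Independent reference solutions used to validate the implicit solver.

Three oracles, each deliberately built on different machinery than the
production path:

* the classical Fourier-series solution of the constant-coefficient,
  constant-flux Neumann rod problem;
* the single-compartment (well-mixed) ODE limit, exposed in
  :mod:`srlumen.pde_solver`;
* a brute-force explicit (forward-Euler) conservative finite-volume solver
  run on fine grids at small problem sizes.
"""

from __future__ import annotations

import numpy as np

from .boundary_fluxes import EffluxModel, InfluxModel, influx_density
from .buffer_chemistry import effective_diffusion_coefficient, free_from_total
from .geometry_mesh import Discretization, SRElementGeometry, build_axial_grid
from .parameters import ModelParameters
from .pde_solver import ConcentrationField, SimulationConfig, initial_condition

__all__ = ["analytic_rod_solution", "explicit_reference_solver", "validation_report"]


def analytic_rod_solution(
    D: float,
    J: float,
    c0: float,
    L: float,
    x: np.ndarray | float,
    t: np.ndarray | float,
    max_terms: int = 200,
    tail_tol: float = 1e-16,
) -> np.ndarray | float:
    """Series solution for a rod with constant flux J at x = 0, sealed x = L.

    ``J`` is the signed outward flux density at x = 0 (negative = mass
    leaving).  With F = -J and tau_n = L^2/(n^2 pi^2 D):

        c(x,t) = c0 - F t / L + (F L / D) * [ h(x/L)
                 + 2 sum_n exp(-t/tau_n) cos(n pi x/L) / (n pi)^2 ],
        h(s)   = s - s^2/2 - 1/3.

    The series is summed until the term magnitude falls below
    ``tail_tol * c0`` (at least ``max_terms`` terms are available).  The
    spatial average is exactly c0 - F t / L (mass balance); the t -> infinity
    concentration slope at x = 0 is -J/D.
    """
    x = np.atleast_1d(np.asarray(x, dtype=float))
    t = np.atleast_1d(np.asarray(t, dtype=float))
    s = (x / L)[None, :]
    tt = t[:, None]
    F = -J
    h = s - 0.5 * s**2 - 1.0 / 3.0
    series = np.zeros((t.size, x.size))
    for n in range(1, max_terms + 1):
        k = n * np.pi
        term = 2.0 / k**2 * np.exp(-(k**2) * D * tt / L**2) * np.cos(k * s)
        series += term
        if np.abs(term).max() < tail_tol * max(abs(c0), 1.0) * abs(D) / max(abs(F * L), 1e-300):
            break
    out = c0 - F * tt / L + (F * L / D) * (h + series)
    if out.shape == (1, 1):
        return float(out[0, 0])
    return np.squeeze(out)


def explicit_reference_solver(
    cfg: SimulationConfig,
    p: ModelParameters,
    geom: SRElementGeometry,
    disc: Discretization,
    efflux: EffluxModel,
    influx: InfluxModel,
    safety: float = 0.25,
) -> ConcentrationField:
    """Forward-Euler conservative finite-volume integration on the 1D grid.

    The time step is held at ``safety * dx^2 / max(D*)`` (the explicit
    stability bound); intended for small problems as a brute-force
    cross-check of the implicit solver, not for production use.
    """
    if disc.mode != "axial_1d":
        raise ValueError("the explicit reference solver runs on the 1D axial grid")
    c = initial_condition(p, cfg.casq_enabled, disc).total[0].copy()
    x = disc.node_x
    dx = float(np.diff(x)[0])
    area = geom.f2_area
    vol = disc.volumes
    j_in = influx_density(influx)
    serca = j_in * disc.boundary_areas["F3"] / vol
    t_eval = np.linspace(0.0, cfg.duration, cfg.n_output_points)
    out = np.empty((t_eval.size, c.size))
    out[0] = c

    def dstar(ci: np.ndarray) -> np.ndarray:
        if not cfg.casq_enabled:
            return np.full_like(ci, p.D_ca_free)
        return effective_diffusion_coefficient(ci, p.casq_total, p.Kd, p.D_ca_free)

    t = 0.0
    k_out = 1
    dt_max = safety * dx**2 / p.D_ca_free
    while k_out < t_eval.size:
        d = dstar(c)
        dt = min(dt_max, t_eval[k_out] - t)
        d_face = 0.5 * (d[:-1] + d[1:])
        flux = d_face * area * (c[1:] - c[:-1]) / dx
        dc = np.zeros_like(c)
        dc[:-1] += flux
        dc[1:] -= flux
        dc /= vol
        if efflux.mode == "constant":
            j = efflux.J0
        else:
            free0 = free_from_total(c[0], p.casq_total, p.Kd) if cfg.casq_enabled else c[0]
            j = efflux.J0 * max(free0, 0.0) / efflux.reference_free_ca
        dc[0] += j * area / vol[0]
        dc += serca
        c = c + dt * dc
        t += dt
        if t >= t_eval[k_out] - 1e-18:
            out[k_out] = c
            k_out += 1
    return ConcentrationField(t_eval, disc, out, p, cfg.casq_enabled)


def validation_report(verbose: bool = False) -> dict[str, dict[str, float]]:
    """Run the oracle suite on small problems and report pass/fail metrics.

    Returns a mapping check-name -> {"value": metric, "bound": tolerance,
    "passed": 0/1}.  Used by the ``validate`` CLI subcommand.
    """
    from .pde_solver import solve, well_mixed_limit

    p = ModelParameters()
    geom = SRElementGeometry()
    checks: dict[str, dict[str, float]] = {}

    def record(name: str, value: float, bound: float) -> None:
        checks[name] = {"value": float(value), "bound": float(bound), "passed": float(value < bound)}
        if verbose:
            status = "ok" if value < bound else "FAIL"
            print(f"{name:40s} {value:.3e} < {bound:.0e}  {status}")

    # implicit vs analytic series, constant-D constant-flux rod
    disc = build_axial_grid(geom, spacing=geom.axial_length / 360)
    cfg = SimulationConfig(duration=0.02, n_output_points=201, efflux_mode="constant", casq_enabled=False)
    eff = EffluxModel(mode="constant", J0=p.J_efflux_0, reference_free_ca=p.ca_free_initial)
    field, fluxes = solve(cfg, p, geom, disc, eff, InfluxModel(enabled=False))
    exact = analytic_rod_solution(p.D_ca_free, p.J_efflux_0, p.ca_free_initial, geom.axial_length, disc.node_x, field.times)
    record("implicit_vs_analytic_series", float(np.abs(field.total - exact).max() / p.ca_free_initial), 1e-4)
    record("mass_balance_constant_flux", fluxes.mass_balance_error(), 1e-6)

    # implicit vs explicit brute force, nonlinear decaying case
    disc_c = build_axial_grid(geom, spacing=geom.axial_length / 60)
    cfg_n = SimulationConfig(duration=2e-3, n_output_points=41, efflux_mode="decaying", casq_enabled=True)
    eff_d = EffluxModel(mode="decaying", J0=p.J_efflux_0, reference_free_ca=p.ca_free_initial)
    field_i, _ = solve(cfg_n, p, geom, disc_c, eff_d, InfluxModel(enabled=False))
    field_e = explicit_reference_solver(cfg_n, p, geom, disc_c, eff_d, InfluxModel(enabled=False))
    record(
        "implicit_vs_explicit_oracle",
        float(np.abs(field_i.total - field_e.total).max() / field_i.total[0, 0]),
        1e-3,
    )

    # well-mixed limit: inflate D by 1e6 and compare against the ODE
    import dataclasses

    p_fast = dataclasses.replace(p, D_ca_free=p.D_ca_free * 1e6)
    cfg_wm = SimulationConfig(duration=0.02, n_output_points=101, efflux_mode="decaying", casq_enabled=False)
    disc_wm = build_axial_grid(geom, spacing=geom.axial_length / 60)
    field_f, _ = solve(cfg_wm, p_fast, geom, disc_wm, eff_d, InfluxModel(enabled=False))
    t_ode, c_ode = well_mixed_limit(cfg_wm, p, eff_d, InfluxModel(enabled=False), geom)
    spread = float((field_f.total.max(axis=1) - field_f.total.min(axis=1)).max() / field_f.total[0, 0])
    record("large_D_axial_spread", spread, 1e-6)
    record(
        "large_D_mean_vs_ode",
        float(np.abs(field_f.total.mean(axis=1) - c_ode).max() / c_ode[0]),
        1e-5,
    )
    return checks
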
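"""Physical constants of the SR element model and derived geometric/flux quantities.

All quantities are kept in SI units internally (m, s, F, mol m^-3).  A
concentration in mol m^-3 is numerically identical to one in mM, which is the
unit used for display.

The constants describe an amphibian skeletal muscle fibre: sarcomere length
``l``, fibre diameter ``a``, surface and transverse-tubular membrane
capacitances (whose ratio fixes the tubular membrane area ``A_T``), the
fraction ``xi`` of tubular membrane engaged in triad (T-SR) junctions, the
SR-to-fibre volume ratio ``V_SR*``, the diameter of a single SR element, free
Ca2+ and calsequestrin diffusion coefficients, resting concentrations, the
calsequestrin dissociation constant, and the boundary flux densities for
ryanodine-receptor release efflux and SERCA-mediated influx.
"""

from __future__ import annotations

import dataclasses
import io
import math
from dataclasses import dataclass
from typing import Mapping, TextIO

import pandas as pd
import yaml

__all__ = [
    "ModelParameters",
    "DerivedQuantities",
    "load_default_parameters",
    "load_config",
    "apply_overrides",
    "derive_tubular_areas",
    "derive_equivalent_sr_diameter",
    "derive_lumped_sr_cross_section",
    "derive_element_count",
    "derive_initial_efflux_density",
    "derive_serca_influx_density",
    "derived_quantities",
    "parameter_table",
]

#: Printed tubular membrane area (m^2).  The closed form (C_T/C_S)*pi*a*l with
#: the default fibre dimensions gives 5.655e-9 m^2, ~1.4% below this value;
#: the printed area is used by default because the published flux densities
#: were derived from it.
PRINTED_TUBULAR_AREA = 5.733e-9

#: Background T-SR Ca2+ release flux density magnitude used in the published
#: derivation of the initial release efflux (mol m^-2 s^-1).
REFERENCE_JTSR0 = -3.0e-6

#: Steady background T-SR flux density matched by SERCA influx (mol m^-2 s^-1).
REFERENCE_JTSR_INF = 9.70e-8


@dataclass(frozen=True)
class ModelParameters:
    """The full constant set of the SR element model, in SI units.

    Flux densities are signed along the outward face normal: the release
    efflux is negative (Ca2+ leaving the SR), the SERCA influx positive.
    """

    sarcomere_length_l: float = 3.6e-6
    fiber_diameter_a: float = 100e-6
    surface_capacitance_Cs: float = 1.00e-2
    tubular_capacitance_Ct: float = 5.00e-2
    junction_fraction_xi: float = 0.3
    sr_volume_fraction_Vsr_star: float = 0.12
    sr_element_diameter_a_dsr: float = 3.00e-8
    D_ca_free: float = 3e-10
    D_casq: float = 0.0
    casq_total: float = 6.1
    ca_free_initial: float = 3.6
    Kd: float = 1.1
    J_efflux_0: float = -2.7375e-6
    J_serca_influx: float = 3.6880e-10
    ca_cyt: float = 0.0
    #: When True (default) the printed tubular area is used for A_T so that
    #: A_TSR reproduces the printed 1,720 um^2; when False A_T is evaluated
    #: from (C_T/C_S)*pi*a*l.
    use_printed_tubular_area: bool = True

    def __post_init__(self) -> None:
        positive = {
            "sarcomere_length_l": self.sarcomere_length_l,
            "fiber_diameter_a": self.fiber_diameter_a,
            "surface_capacitance_Cs": self.surface_capacitance_Cs,
            "tubular_capacitance_Ct": self.tubular_capacitance_Ct,
            "sr_element_diameter_a_dsr": self.sr_element_diameter_a_dsr,
            "D_ca_free": self.D_ca_free,
            "casq_total": self.casq_total,
            "ca_free_initial": self.ca_free_initial,
            "Kd": self.Kd,
        }
        for name, value in positive.items():
            if not value > 0:
                raise ValueError(f"{name} must be strictly positive, got {value!r}")
        if self.D_casq != 0.0:
            raise ValueError("D_casq must be 0 (calsequestrin is anchored, not mobile)")
        if not 0 < self.junction_fraction_xi < 1:
            raise ValueError("junction_fraction_xi must lie in (0, 1)")
        if not 0 < self.sr_volume_fraction_Vsr_star < 1:
            raise ValueError("sr_volume_fraction_Vsr_star must lie in (0, 1)")
        if not self.J_efflux_0 < 0:
            raise ValueError("J_efflux_0 is an efflux and must be negative")
        if self.J_serca_influx < 0:
            raise ValueError("J_serca_influx must be non-negative")
        if self.ca_cyt < 0:
            raise ValueError("ca_cyt must be non-negative")


@dataclass(frozen=True)
class DerivedQuantities:
    """Geometric and flux quantities computed from :class:`ModelParameters`."""

    tubular_area_At: float
    junctional_area_Atsr: float
    lumped_sr_diameter_a_sr: float
    lumped_sr_cross_section_Asr: float
    element_count_n: float
    initial_total_ca: float


def load_default_parameters() -> ModelParameters:
    """Return the default constant set (SI columns of the published table)."""
    return ModelParameters()


def apply_overrides(p: ModelParameters, overrides: Mapping[str, object]) -> ModelParameters:
    """Return a copy of ``p`` with fields replaced; unknown keys are an error."""
    valid = {f.name for f in dataclasses.fields(ModelParameters)}
    unknown = set(overrides) - valid
    if unknown:
        raise KeyError(f"unknown parameter name(s): {sorted(unknown)}")
    return dataclasses.replace(p, **dict(overrides))


def load_config(source: str | TextIO) -> ModelParameters:
    """Load parameters from a flat YAML mapping overriding any default.

    ``source`` may be a path or an open text stream.  Keys are the
    :class:`ModelParameters` field names; unknown keys raise ``KeyError``.
    """
    if hasattr(source, "read"):
        data = yaml.safe_load(source)
    else:
        with open(source, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh)
    if data is None:
        data = {}
    if not isinstance(data, Mapping):
        raise ValueError("parameter config must be a flat key-value mapping")
    return apply_overrides(load_default_parameters(), data)


def derive_tubular_areas(p: ModelParameters) -> tuple[float, float]:
    """Return (A_T, A_TSR): tubular membrane area and its junctional fraction.

    A_T = (C_T/C_S)*pi*a*l unless ``use_printed_tubular_area`` is set, in
    which case the published area is adopted; A_TSR = xi * A_T.
    """
    if p.use_printed_tubular_area:
        a_t = PRINTED_TUBULAR_AREA
    else:
        a_t = (p.tubular_capacitance_Ct / p.surface_capacitance_Cs) * math.pi * p.fiber_diameter_a * p.sarcomere_length_l
    if a_t <= 0:
        raise ValueError("tubular area must be positive")
    return a_t, p.junction_fraction_xi * a_t


def derive_equivalent_sr_diameter(p: ModelParameters) -> float:
    """Diameter of the single cylinder whose volume fraction matches the SR.

    a_SR = a * sqrt(V_SR*): the SR network lumped into one equivalent cylinder
    running the length of the fibre.
    """
    return p.fiber_diameter_a * math.sqrt(p.sr_volume_fraction_Vsr_star)


def derive_lumped_sr_cross_section(p: ModelParameters) -> float:
    """Cross-sectional area A_SR = pi * a_SR^2 / 4 of the lumped SR cylinder."""
    a_sr = derive_equivalent_sr_diameter(p)
    return math.pi * a_sr**2 / 4.0


def derive_element_count(p: ModelParameters) -> float:
    """Number of SR elements n ~ (a_SR / a_dSR)^2 tiling the lumped cylinder."""
    a_sr = derive_equivalent_sr_diameter(p)
    return (a_sr / p.sr_element_diameter_a_dsr) ** 2


def derive_initial_efflux_density(J_tsr_0: float, p: ModelParameters, A_TSR: float | None = None) -> float:
    """Release efflux density across the cisternal SR cross-section.

    |J_efflux(0)| = 2 * |J_TSR(0)| * A_TSR / (pi * a^2 * V_SR*): the total
    T-SR release flux referred to the summed cross-sectional area of the SR
    elements in a half sarcomere.  The result carries the sign of J_TSR(0)
    (negative: Ca2+ leaves the SR).  With J_TSR(0) = -3.0e-6 mol m^-2 s^-1
    and the printed junctional area this reproduces the published
    -2.7375e-6 mol m^-2 s^-1.  Linear in both J_TSR(0) and A_TSR.
    """
    if A_TSR is None:
        _, A_TSR = derive_tubular_areas(p)
    return 2.0 * J_tsr_0 * A_TSR / (math.pi * p.fiber_diameter_a**2 * p.sr_volume_fraction_Vsr_star)


def derive_serca_influx_density(J_tsr_inf: float, p: ModelParameters, A_TSR: float | None = None) -> float:
    """Constant SERCA influx density on the lateral face of one SR element.

    J_influx = +J_TSR(inf) * A_TSR * a_dSR / (a^2 * V_SR* * pi * l): the
    whole-fibre background re-uptake flux shared between the n elements and
    referred to the lateral membrane area of one element.
    """
    if A_TSR is None:
        _, A_TSR = derive_tubular_areas(p)
    return (
        J_tsr_inf
        * A_TSR
        * p.sr_element_diameter_a_dsr
        / (p.fiber_diameter_a**2 * p.sr_volume_fraction_Vsr_star * math.pi * p.sarcomere_length_l)
    )


def derived_quantities(p: ModelParameters) -> DerivedQuantities:
    """Compute every derived geometric/flux quantity from the constant set."""
    # local import avoids a cycle: buffer_chemistry has no dependency on us
    from .buffer_chemistry import total_from_free

    a_t, a_tsr = derive_tubular_areas(p)
    return DerivedQuantities(
        tubular_area_At=a_t,
        junctional_area_Atsr=a_tsr,
        lumped_sr_diameter_a_sr=derive_equivalent_sr_diameter(p),
        lumped_sr_cross_section_Asr=derive_lumped_sr_cross_section(p),
        element_count_n=derive_element_count(p),
        initial_total_ca=total_from_free(p.ca_free_initial, p.casq_total, p.Kd),
    )


_UNITS = {
    "sarcomere_length_l": "m",
    "fiber_diameter_a": "m",
    "surface_capacitance_Cs": "F m^-2",
    "tubular_capacitance_Ct": "F m^-2",
    "junction_fraction_xi": "-",
    "sr_volume_fraction_Vsr_star": "-",
    "sr_element_diameter_a_dsr": "m",
    "D_ca_free": "m^2 s^-1",
    "D_casq": "m^2 s^-1",
    "casq_total": "mol m^-3 (= mM)",
    "ca_free_initial": "mol m^-3 (= mM)",
    "Kd": "mol m^-3 (= mM)",
    "J_efflux_0": "mol m^-2 s^-1",
    "J_serca_influx": "mol m^-2 s^-1",
    "ca_cyt": "mol m^-3 (= mM)",
    "use_printed_tubular_area": "-",
    "tubular_area_At": "m^2",
    "junctional_area_Atsr": "m^2",
    "lumped_sr_diameter_a_sr": "m",
    "lumped_sr_cross_section_Asr": "m^2",
    "element_count_n": "-",
    "initial_total_ca": "mol m^-3 (= mM)",
}


def parameter_table(p: ModelParameters) -> pd.DataFrame:
    """Resolved parameters plus derived quantities as a table with units."""
    rows = []
    for field in dataclasses.fields(ModelParameters):
        rows.append((field.name, getattr(p, field.name), _UNITS[field.name], "parameter"))
    dq = derived_quantities(p)
    for field in dataclasses.fields(DerivedQuantities):
        rows.append((field.name, getattr(dq, field.name), _UNITS[field.name], "derived"))
    return pd.DataFrame(rows, columns=["name", "value", "units", "kind"])


def dump_parameters(p: ModelParameters) -> str:
    """Delimited-text dump of the resolved parameter set with a units column."""
    buf = io.StringIO()
    parameter_table(p).to_csv(buf, index=False)
    return buf.getvalue()
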
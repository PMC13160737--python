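"""SR element cylinder geometry and its 1D / 2D axisymmetric discretisations.

One SR element is a thin cylinder of radius 15 nm running from the cisternal
(CSR) face, where Ca2+ release occurs, to the closed midpoint of the
longitudinal SR (LSR) half a sarcomere away (1.8 um).  Faces are tagged

    F1  closed LSR-midpoint end      (z = axial_length, no flux)
    F2  CSR release end              (z = 0, RyR efflux)
    F3  lateral membrane             (r = radius, SERCA influx)

The axial coordinate runs from the CSR face (x = 0) toward the LSR midpoint.

Two finite-volume discretisations are provided: a production 1D axial grid
(the element is effectively a one-dimensional diffusion domain because its
aspect ratio exceeds 100) and a 2D axisymmetric (r, z) grid, exact for the
axisymmetric data and boundary conditions used throughout, with the
cylindrical measure 2*pi*r dr dz built into node control volumes and face
areas.  Node control volumes tile the cylinder exactly, so the integrated
volume equals pi r^2 L to machine precision at any resolution.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["SRElementGeometry", "Discretization", "build_axial_grid", "build_axisymmetric_mesh"]

FACE_F1 = "F1"
FACE_F2 = "F2"
FACE_F3 = "F3"


@dataclass(frozen=True)
class SRElementGeometry:
    """Cylinder dimensions of one SR element (SI units)."""

    radius: float = 1.5e-8
    axial_length: float = 1.8e-6

    def __post_init__(self) -> None:
        if self.radius <= 0 or self.axial_length <= 0:
            raise ValueError("radius and axial_length must be strictly positive")
        if self.axial_length / self.radius < 10:
            warnings.warn(
                "aspect ratio below 10: the 1D axial reduction may be inaccurate",
                stacklevel=2,
            )

    @property
    def f2_area(self) -> float:
        """Cross-section area of the CSR release face."""
        return math.pi * self.radius**2

    @property
    def f3_area(self) -> float:
        """Lateral membrane area."""
        return 2.0 * math.pi * self.radius * self.axial_length

    @property
    def volume(self) -> float:
        return math.pi * self.radius**2 * self.axial_length


@dataclass(frozen=True)
class Discretization:
    """Finite-volume discretisation of the SR element.

    ``node_x``/``node_r`` give node coordinates (``node_r`` is zero for the
    1D mode); ``volumes`` the per-node control volumes (m^3); ``face_tags``
    maps each face name to the indices of boundary nodes carrying it, with
    ``boundary_areas`` the portion of that face's area owned by each node.
    For the 2D mode ``shape`` is (n_radial_nodes, n_axial_nodes) and node
    index = i_r * n_axial_nodes + i_z.
    """

    mode: str
    node_x: np.ndarray
    node_r: np.ndarray
    volumes: np.ndarray
    face_tags: dict[str, np.ndarray]
    boundary_areas: dict[str, np.ndarray]
    geometry: SRElementGeometry
    shape: tuple[int, ...] = field(default=())

    @property
    def n_nodes(self) -> int:
        return self.node_x.size

    @property
    def csr_node(self) -> int:
        """Index of the on-axis node at the CSR face (x = 0)."""
        return int(self.face_tags[FACE_F2][0])

    @property
    def lsr_node(self) -> int:
        """Index of the on-axis node at the LSR midpoint face (x = L)."""
        return int(self.face_tags[FACE_F1][0])

    def node_table(self) -> pd.DataFrame:
        """Node coordinates, control volumes and face tags as a table."""
        tags = ["" for _ in range(self.n_nodes)]
        for name, idx in self.face_tags.items():
            for i in idx:
                tags[i] = tags[i] + ("," if tags[i] else "") + name
        return pd.DataFrame(
            {
                "x": self.node_x,
                "r": self.node_r,
                "volume": self.volumes,
                "faces": tags,
            }
        )


def build_axial_grid(geom: SRElementGeometry, spacing: float = 1e-8) -> Discretization:
    """Uniform 1D axial grid with x = 0 at the CSR face (F2).

    Control volumes are pi r^2 * dx with half cells at the two ends; the
    lateral (F3) area is distributed over all nodes in proportion to the
    axial extent each owns, so the 1D model carries the SERCA influx as an
    equivalent volumetric source.
    """
    if not 0 < spacing <= geom.axial_length:
        raise ValueError("spacing must lie in (0, axial_length]")
    n_cells = round(geom.axial_length / spacing)
    if n_cells < 1:
        n_cells = 1
    x = np.linspace(0.0, geom.axial_length, n_cells + 1)
    dx_owned = np.full(x.size, geom.axial_length / n_cells)
    dx_owned[0] *= 0.5
    dx_owned[-1] *= 0.5
    area = geom.f2_area
    volumes = area * dx_owned
    face_tags = {
        FACE_F2: np.array([0]),
        FACE_F1: np.array([x.size - 1]),
        FACE_F3: np.arange(x.size),
    }
    boundary_areas = {
        FACE_F2: np.array([area]),
        FACE_F1: np.array([area]),
        FACE_F3: 2.0 * math.pi * geom.radius * dx_owned,
    }
    return Discretization(
        mode="axial_1d",
        node_x=x,
        node_r=np.zeros_like(x),
        volumes=volumes,
        face_tags=face_tags,
        boundary_areas=boundary_areas,
        geometry=geom,
        shape=(x.size,),
    )


def build_axisymmetric_mesh(geom: SRElementGeometry, Hmax: float = 1e-8) -> Discretization:
    """Structured node-centred (r, z) grid of the half-plane rectangle
    [0, radius] x [0, axial_length] with cylindrical control volumes.

    Edge mapping: r = radius -> F3, z = 0 -> F2, z = axial_length -> F1; the
    symmetry axis r = 0 carries no tag (natural no-flux).  ``Hmax`` bounds the
    cell edge length in both directions.
    """
    if not 0 < Hmax <= geom.radius:
        raise ValueError("Hmax must lie in (0, radius]")
    nr = max(1, math.ceil(geom.radius / Hmax - 1e-12))
    nz = max(1, math.ceil(geom.axial_length / Hmax - 1e-12))
    r = np.linspace(0.0, geom.radius, nr + 1)
    z = np.linspace(0.0, geom.axial_length, nz + 1)
    dr = geom.radius / nr
    dz = geom.axial_length / nz

    # annular area owned by each radial node: ring between the half-offsets
    r_lo = np.clip(r - dr / 2.0, 0.0, geom.radius)
    r_hi = np.clip(r + dr / 2.0, 0.0, geom.radius)
    ring_area = math.pi * (r_hi**2 - r_lo**2)

    dz_owned = np.full(z.size, dz)
    dz_owned[0] *= 0.5
    dz_owned[-1] *= 0.5

    node_r = np.repeat(r, z.size)
    node_x = np.tile(z, r.size)
    volumes = np.repeat(ring_area, z.size) * np.tile(dz_owned, r.size)

    def node_index(i_r: np.ndarray, i_z: np.ndarray) -> np.ndarray:
        return i_r * z.size + i_z

    all_ir = np.arange(r.size)
    all_iz = np.arange(z.size)
    f2_nodes = node_index(all_ir, np.zeros(r.size, dtype=int))
    f1_nodes = node_index(all_ir, np.full(r.size, z.size - 1, dtype=int))
    f3_nodes = node_index(np.full(z.size, r.size - 1, dtype=int), all_iz)

    face_tags = {FACE_F2: f2_nodes, FACE_F1: f1_nodes, FACE_F3: f3_nodes}
    boundary_areas = {
        FACE_F2: ring_area.copy(),
        FACE_F1: ring_area.copy(),
        FACE_F3: 2.0 * math.pi * geom.radius * dz_owned,
    }
    return Discretization(
        mode="axisymmetric_2d",
        node_x=node_x,
        node_r=node_r,
        volumes=volumes,
        face_tags=face_tags,
        boundary_areas=boundary_areas,
        geometry=geom,
        shape=(r.size, z.size),
    )
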
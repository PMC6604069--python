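"""Electrostatic model of an open-ended coaxial probe against a sample.

An open-ended (flat-ended) coaxial cable pressed against a material senses
it through the fringing field that leaks out of the aperture.  How deep
that field reaches -- the penetration depth -- sets the sensing volume of
a dielectric measurement and therefore the minimum sample thickness.

The model solves the axisymmetric Laplace problem

    div( eps(r, z) grad V ) = 0

on an (r, z) half-plane: the inner conductor (radius ``a``) at 0.2 V, the
outer conductor (inner radius ``b``) and the far field at 0 V, the
insulator (relative permittivity ``eps_ins``) filling ``a < r < b`` below
the aperture plane ``z = 0``, and the sample half-space (``eps_sample``)
above it.  This is a quasi-static simplification of a full-wave
simulation: the GHz wavelength in water (~several mm) is not modelled, so
the field pattern is the static fringing pattern.  Two penetration-depth
definitions are computed from the on-axis potential profile: a
single-exponential fit, and the distance at which the potential falls to
54% of the inner-conductor surface value (an empirical criterion
calibrated against double-layer reference measurements; implemented here
as a defined constant, not re-derived).

The discrete system is a finite-volume 5-point stencil in cylindrical
coordinates with permittivity averaged harmonically across cell faces,
solved directly with a sparse LU factorisation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import sparse
from scipy.sparse.linalg import spsolve
from scipy import stats

from .relaxation_models import DomainError, ParameterError

#: Empirical fraction of the surface potential defining the penetration depth.
PENETRATION_FRACTION = 0.54

#: Coax impedance constant: Z = (59.96 / sqrt(eps_r)) * ln(b/a) ohms.
_Z0_LN = 59.96

#: Supported outer diameters of the standard probes (m).
STANDARD_OUTER_DIAMETERS = (2.2e-3, 3.6e-3, 6.3e-3)


@dataclass(frozen=True)
class CoaxGeometry:
    """Cross-section of an open-ended coaxial probe against a sample."""

    outer_diameter: float
    inner_radius: float
    outer_conductor_inner_radius: float
    insulator_rel_permittivity: float = 2.1
    sample_rel_permittivity: float = 78.4
    v_inner: float = 0.2
    v_outer: float = 0.0

    def __post_init__(self) -> None:
        a, b = self.inner_radius, self.outer_conductor_inner_radius
        if not 0 < a < b < self.outer_diameter / 2:
            raise ParameterError(
                "need 0 < inner_radius < outer_conductor_inner_radius < outer_diameter/2"
            )
        if self.insulator_rel_permittivity < 1 or self.sample_rel_permittivity < 1:
            raise ParameterError("relative permittivities must be >= 1")


@dataclass(frozen=True)
class PotentialField:
    """Solved potential on an (r, z) grid.

    ``potential[j, i]`` is the potential at ``z = z_coords[j]``,
    ``r = r_coords[i]``.  ``is_boundary`` marks Dirichlet nodes
    (conductors and outer boundary).  The aperture plane is ``z = 0``.
    """

    r_coords: np.ndarray
    z_coords: np.ndarray
    potential: np.ndarray
    is_boundary: np.ndarray
    geometry: CoaxGeometry

    def on_axis_profile(self) -> tuple[np.ndarray, np.ndarray]:
        """(z, V) on the symmetry axis for z >= 0 (from the aperture up)."""
        mask = self.z_coords >= 0
        return self.z_coords[mask], self.potential[mask, 0]


@dataclass(frozen=True)
class PenetrationResult:
    """Penetration depths plus the axial profile they came from."""

    depth_exponential: float
    depth_54pct: float
    profile_z: np.ndarray
    profile_v: np.ndarray

    def __post_init__(self) -> None:
        if self.depth_exponential <= 0 or self.depth_54pct <= 0:
            raise ParameterError("penetration depths must be > 0")


def impedance_radius_ratio(impedance: float, insulator_rel_permittivity: float) -> float:
    """b/a ratio of a coax line with the given impedance and dielectric."""
    if impedance <= 0:
        raise ParameterError("impedance must be > 0")
    if insulator_rel_permittivity < 1:
        raise ParameterError("insulator permittivity must be >= 1")
    return float(np.exp(impedance * np.sqrt(insulator_rel_permittivity) / _Z0_LN))


def build_geometry(
    outer_diameter: float,
    impedance: float = 50.0,
    insulator_rel_permittivity: float = 2.1,
    wall_thickness: float = 0.3e-3,
    sample_rel_permittivity: float = 78.4,
) -> CoaxGeometry:
    """Derive the conductor radii of a probe from its outer diameter.

    The outer conductor's inner radius is ``outer_diameter/2 - wall``;
    the inner radius follows from the characteristic-impedance relation
    ``Z = (59.96/sqrt(eps_r)) ln(b/a)`` (50-ohm PTFE cable: b/a ~ 3.35).
    """
    b = outer_diameter / 2 - wall_thickness
    if b <= 0:
        raise ParameterError("wall thickness leaves no room for the dielectric")
    ratio = impedance_radius_ratio(impedance, insulator_rel_permittivity)
    a = b / ratio
    return CoaxGeometry(
        outer_diameter=outer_diameter,
        inner_radius=a,
        outer_conductor_inner_radius=b,
        insulator_rel_permittivity=insulator_rel_permittivity,
        sample_rel_permittivity=sample_rel_permittivity,
    )


def _analytic_coax_profile(geometry: CoaxGeometry, r: np.ndarray) -> np.ndarray:
    """TEM radial potential deep inside the cable: V ~ ln(b/r)/ln(b/a)."""
    a, b = geometry.inner_radius, geometry.outer_conductor_inner_radius
    v = np.zeros_like(r)
    inside = (r > a) & (r < b)
    v[inside] = geometry.v_inner * np.log(b / r[inside]) / np.log(b / a)
    v[r <= a] = geometry.v_inner
    return v


def solve_potential(
    geometry: CoaxGeometry,
    grid_resolution: float | None = None,
    domain_radius: float | None = None,
    sample_height: float | None = None,
    cable_depth: float | None = None,
) -> PotentialField:
    """Solve the axisymmetric Dirichlet problem for the probe potential.

    Defaults: cell size ``a/8``, domain extending three outer diameters
    beyond the aperture both radially and axially, cable modelled to a
    depth of two outer radii where the analytic TEM profile is imposed.
    """
    a, b = geometry.inner_radius, geometry.outer_conductor_inner_radius
    od = geometry.outer_diameter
    h = grid_resolution if grid_resolution is not None else a / 8
    if h > a / 8:
        raise ParameterError("grid_resolution must resolve the inner radius by >= 8 cells")
    R_dom = domain_radius if domain_radius is not None else 3 * od
    H_dom = sample_height if sample_height is not None else 3 * od
    L_cab = cable_depth if cable_depth is not None else 2 * b
    if R_dom < 1.5 * od or H_dom < 1.5 * od:
        raise ParameterError("domain must extend at least 3 outer radii beyond the aperture")

    nr = int(round(R_dom / h)) + 1
    nzn = int(round(L_cab / h))  # nodes below the aperture
    nzp = int(round(H_dom / h))  # nodes above
    r = np.arange(nr) * h
    z = np.arange(-nzn, nzp + 1) * h
    nz = z.size
    R, Z = np.meshgrid(r, z)

    eps = np.full((nz, nr), geometry.sample_rel_permittivity)
    below = Z < 0
    eps[below] = geometry.insulator_rel_permittivity

    dirichlet = np.zeros((nz, nr), dtype=bool)
    v_bc = np.zeros((nz, nr))
    # Inner conductor: r <= a, z <= 0 (flat top at the aperture plane).
    m = (R <= a + 1e-12) & (Z <= 0)
    dirichlet |= m
    v_bc[m] = geometry.v_inner
    # Outer conductor: r >= b for z <= 0, including its annular face.
    m = (R >= b - 1e-12) & (Z <= 0)
    dirichlet |= m
    v_bc[m] = geometry.v_outer
    # Far boundaries at 0 V.
    dirichlet[:, -1] = True
    dirichlet[-1, :] = True
    # Deep cable cross-section: analytic TEM profile.
    bottom = _analytic_coax_profile(geometry, r)
    dirichlet[0, :] = True
    v_bc[0, :] = bottom

    # Assemble the finite-volume 5-point system for the free nodes.
    idx = -np.ones((nz, nr), dtype=int)
    free = ~dirichlet
    idx[free] = np.arange(int(free.sum()))
    rows, cols, vals = [], [], []
    rhs = np.zeros(int(free.sum()))

    def face_eps(j1, i1, j2, i2):
        e1, e2 = eps[j1, i1], eps[j2, i2]
        return 2 * e1 * e2 / (e1 + e2)

    jj, ii = np.nonzero(free)
    for j, i in zip(jj, ii):
        k = idx[j, i]
        ri = r[i]
        diag = 0.0
        # (neighbor j, i, conductance)
        if i == 0:
            neigh = [(j, 1, 4.0 * face_eps(j, 0, j, 1))]  # axis cell
        else:
            neigh = [
                (j, i - 1, (ri - h / 2) / ri * face_eps(j, i, j, i - 1)),
                (j, i + 1, (ri + h / 2) / ri * face_eps(j, i, j, i + 1)),
            ]
        neigh += [
            (j - 1, i, face_eps(j, i, j - 1, i)),
            (j + 1, i, face_eps(j, i, j + 1, i)),
        ]
        for (jn, in_, c) in neigh:
            diag -= c
            if dirichlet[jn, in_]:
                rhs[k] -= c * v_bc[jn, in_]
            else:
                rows.append(k)
                cols.append(idx[jn, in_])
                vals.append(c)
        rows.append(k)
        cols.append(k)
        vals.append(diag)

    n_free = int(free.sum())
    A = sparse.csr_matrix((vals, (rows, cols)), shape=(n_free, n_free))
    sol = spsolve(A, rhs)

    V = v_bc.copy()
    V[free] = sol
    return PotentialField(
        r_coords=r, z_coords=z, potential=V, is_boundary=dirichlet, geometry=geometry
    )


def penetration_depth(
    field: PotentialField,
    fit_fraction: float = 0.2,
) -> PenetrationResult:
    """Penetration depths from the on-axis potential above the aperture.

    ``depth_exponential``: least-squares fit of ``V = V0 exp(-z/delta)``
    (linear regression of ln V on z) over the near region where the
    potential exceeds ``fit_fraction`` of the surface value.
    ``depth_54pct``: first axial distance at which the potential drops to
    54% of the surface value, linearly interpolated between grid nodes.
    """
    z, v = field.on_axis_profile()
    v_s = float(v[0])
    if v_s <= 0:
        raise DomainError("surface potential must be positive on the axis")
    interior = v[1:-1]
    if np.any(np.diff(interior) > 1e-9 * v_s):
        raise DomainError("non-monotone axial profile: numerical artifact")

    target = PENETRATION_FRACTION * v_s
    below = np.nonzero(v <= target)[0]
    if below.size == 0:
        raise DomainError("potential never falls to 54% inside the domain")
    j = below[0]
    # Linear interpolation between nodes j-1 and j.
    z54 = z[j] if j == 0 else z[j - 1] + (target - v[j - 1]) * (z[j] - z[j - 1]) / (
        v[j] - v[j - 1]
    )

    mask = v >= fit_fraction * v_s
    if mask.sum() < 3:
        raise DomainError("too few points in the near region for the exponential fit")
    reg = stats.linregress(z[mask], np.log(v[mask]))
    if reg.slope >= 0:
        raise DomainError("axial potential does not decay; cannot fit an exponential")
    delta = -1.0 / reg.slope

    return PenetrationResult(
        depth_exponential=float(delta),
        depth_54pct=float(z54),
        profile_z=z,
        profile_v=v,
    )


def penetration_from_profile(z: np.ndarray, v: np.ndarray, fit_fraction: float = 0.2) -> PenetrationResult:
    """Penetration depths for an externally supplied axial profile."""
    field_like = _ProfileOnly(z=np.asarray(z, float), v=np.asarray(v, float))
    return penetration_depth(field_like, fit_fraction=fit_fraction)


@dataclass(frozen=True)
class _ProfileOnly:
    z: np.ndarray
    v: np.ndarray

    def on_axis_profile(self):
        return self.z, self.v
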
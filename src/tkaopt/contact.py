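"""Elastic-foundation contact surrogate for the implanted tibiofemoral joint.

The polyethylene liner (E = 685 MPa) is orders of magnitude more compliant
than the metal femoral and tibial components, so the contact is modelled as
a rigid femoral component pressing into a bonded elastic layer ("bed of
springs"): local pressure is proportional to local surface penetration,

    p(x, y) = k * max(delta(x, y), 0),
    k = E (1 - nu) / ((1 + nu)(1 - 2 nu) t),

with t the liner thickness.  Each femoral condyle is a sphere articulating
in a spherical dish of the liner; the tibial-component alignment (varus,
posterior slope, external rotation) rigidly rotates the liner about the
tray centre, and a damped Newton iteration settles the femur (vertical
settlement plus a varus-valgus tilt; the flexion-extension rotation is held,
mirroring the fixed-flexion boundary condition of the reference load case)
until the 1150 N axial load and the tilt moment are balanced.

The axial force acts along the vertical line through the femoral
transepicondylar midpoint.  Because that point rides with the femoral tilt,
a varus tilt displaces the load line medially and produces the adduction
moment that loads the medial compartment — the qualitative mechanism behind
varus overload of the medial plateau.  The collateral ligaments enter as
uniaxial incompressible Neo-Hookean springs (energy C1 (I1~ - 3)) that
carry tension only.

Surrogate pressures are comparable to implant-contact magnitudes but are a
desk-scale stand-in, not a reproduction, of a continuum finite-element
solve; the friction coefficient (0.04) is carried as metadata only, the
normal contact being frictionless under a purely axial load at 0 flexion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "Material",
    "MATERIALS",
    "FRICTION_COEFFICIENT",
    "ImplantAlignment",
    "Compartment",
    "ArticularGeometry",
    "LigamentSpec",
    "DEFAULT_LIGAMENTS",
    "LoadCase",
    "LinerSurface",
    "PressureMap",
    "EquilibriumState",
    "ConvergenceError",
    "foundation_modulus",
    "liner_surface",
    "ligament_tension",
    "solve_equilibrium",
    "peak_pressure",
    "compartment_loads",
    "export_pressure_map",
    "read_pressure_map",
    "default_geometry",
]

MAX_ANGLE_DEG = 15.0

#: Friction coefficient of the articulation, recorded for fidelity; the
#: surrogate models frictionless normal contact (tangential tractions are
#: second order under a purely axial load at 0 deg flexion).
FRICTION_COEFFICIENT = 0.04


@dataclass(frozen=True)
class Material:
    """Isotropic linear-elastic material (moduli in MPa)."""

    name: str
    elastic_modulus_mpa: float
    poisson_ratio: float

    def __post_init__(self) -> None:
        if self.elastic_modulus_mpa <= 0:
            raise ValueError(f"{self.name}: elastic modulus must be positive")
        if not 0.0 <= self.poisson_ratio < 0.5:
            raise ValueError(f"{self.name}: Poisson ratio must lie in [0, 0.5)")


#: Component materials of the implanted knee.
MATERIALS: dict[str, Material] = {
    m.name: m
    for m in (
        Material("cortical_bone", 16600.0, 0.3),
        Material("cancellous_bone", 2400.0, 0.3),
        Material("femoral_component", 210000.0, 0.3),
        Material("tibial_component", 117000.0, 0.3),
        Material("polyethylene_liner", 685.0, 0.4),
        Material("bone_cement", 3000.0, 0.3),
    )
}


def foundation_modulus(material: Material, thickness_mm: float) -> float:
    """Elastic-foundation stiffness k (MPa/mm) of a bonded layer.

    ``k = E (1 - nu) / ((1 + nu)(1 - 2 nu) t)`` — the confined
    (oedometric) modulus of the layer divided by its thickness.  An
    incompressible layer (nu >= 0.5) has no finite foundation stiffness.
    """
    if thickness_mm <= 0:
        raise ValueError("layer thickness must be positive")
    nu = material.poisson_ratio
    if nu >= 0.5:
        raise ValueError(
            f"{material.name}: nu = {nu} >= 0.5 — incompressible layer has "
            "infinite foundation stiffness; unsupported"
        )
    e = material.elastic_modulus_mpa
    return e * (1.0 - nu) / ((1.0 + nu) * (1.0 - 2.0 * nu) * thickness_mm)


@dataclass(frozen=True)
class ImplantAlignment:
    """Tibial-component alignment angles (degrees).

    ``varus_deg`` is positive in varus (medial side down), negative in
    valgus.  ``cut_slope_deg`` is the posterior slope of the tibial cut; the
    component adds its own built-in slope (``inherent_slope_deg``, 3 deg for
    this implant), so the articulating surface is tilted by
    ``effective_slope_deg``.  ``external_rotation_deg`` is positive for
    external rotation of the tray (right knee, medial = +X).
    """

    varus_deg: float = 0.0
    cut_slope_deg: float = 0.0
    inherent_slope_deg: float = 3.0
    external_rotation_deg: float = 0.0

    def __post_init__(self) -> None:
        for name in ("varus_deg", "cut_slope_deg", "inherent_slope_deg", "external_rotation_deg"):
            v = float(getattr(self, name))
            if not math.isfinite(v):
                raise ValueError(f"{name} must be finite")
            object.__setattr__(self, name, v)
        for name, v in (
            ("varus_deg", self.varus_deg),
            ("effective_slope_deg", self.effective_slope_deg),
            ("external_rotation_deg", self.external_rotation_deg),
        ):
            if abs(v) >= MAX_ANGLE_DEG:
                raise ValueError(f"|{name}| = {abs(v)} deg exceeds the {MAX_ANGLE_DEG} deg bound")

    @property
    def effective_slope_deg(self) -> float:
        return self.cut_slope_deg + self.inherent_slope_deg


@dataclass(frozen=True)
class Compartment:
    """One condylar articulation: a spherical condyle in a spherical dish.

    ``dish_radius_mm`` may be ``inf`` for a flat foundation (used by the
    closed-form verification case).  The dish is articular out to
    ``aperture_radius_mm`` from its lowest point.
    """

    side: str
    center_ml_mm: float
    center_ap_mm: float = 0.0
    condyle_radius_mm: float = 30.0
    dish_radius_mm: float = 45.0
    aperture_radius_mm: float = 15.0

    def __post_init__(self) -> None:
        if self.side not in ("medial", "lateral"):
            raise ValueError(f"compartment side must be 'medial' or 'lateral', got {self.side!r}")
        if not self.condyle_radius_mm > 0:
            raise ValueError("condyle radius must be positive")
        if not self.dish_radius_mm > self.condyle_radius_mm:
            raise ValueError("dish radius must exceed the condyle radius")
        if not 0 < self.aperture_radius_mm < self.dish_radius_mm:
            raise ValueError("aperture radius must be positive and below the dish radius")


@dataclass(frozen=True)
class ArticularGeometry:
    """Liner articular geometry, thickness, and pressure-grid resolution.

    Default dimensions (condyle R 30 mm, dish R 45 mm, compartment centres
    at +-24 mm medial-lateral, 9 mm liner) are illustrative of a
    posterior-stabilized implant, not vendor geometry, and are
    config-overridable.
    """

    compartments: tuple[Compartment, ...]
    liner_thickness_mm: float = 9.0
    grid_spacing_mm: float = 0.5
    grid_margin_mm: float = 3.0

    def __post_init__(self) -> None:
        if not self.compartments:
            raise ValueError("at least one compartment is required")
        if self.liner_thickness_mm <= 0:
            raise ValueError("liner thickness must be positive")
        if self.grid_spacing_mm <= 0:
            raise ValueError("grid spacing must be positive")
        object.__setattr__(self, "compartments", tuple(self.compartments))

    def grid_axes(self) -> tuple[np.ndarray, np.ndarray]:
        """Symmetric cell-centre axes covering every dish aperture."""
        h = self.grid_spacing_mm
        half_x = max(abs(c.center_ml_mm) + c.aperture_radius_mm for c in self.compartments)
        half_y = max(abs(c.center_ap_mm) + c.aperture_radius_mm for c in self.compartments)
        half_x = math.ceil((half_x + self.grid_margin_mm) / h) * h
        half_y = math.ceil((half_y + self.grid_margin_mm) / h) * h
        x = np.arange(-half_x, half_x + h / 2, h)
        y = np.arange(-half_y, half_y + h / 2, h)
        return x, y


def default_geometry(grid_spacing_mm: float = 0.5) -> ArticularGeometry:
    """Two symmetric compartments at +-24 mm medial-lateral."""
    return ArticularGeometry(
        compartments=(
            Compartment(side="medial", center_ml_mm=24.0),
            Compartment(side="lateral", center_ml_mm=-24.0),
        ),
        grid_spacing_mm=grid_spacing_mm,
    )


@dataclass(frozen=True)
class LigamentSpec:
    """A collateral ligament as a tension-only uniaxial Neo-Hookean spring.

    ``c1_mpa`` is the initial shear modulus of the incompressible
    Neo-Hookean energy C1 (I1~ - 3).  Rest length, cross-section and
    attachment coordinates are not implant-catalogue data; the defaults are
    anatomically plausible placeholders (see the package methods note).
    ``lever_arm_mm`` is the signed medial-lateral attachment offset from the
    tray centre (medial positive).
    """

    side: str
    c1_mpa: float
    rest_length_mm: float
    cross_section_mm2: float
    lever_arm_mm: float
    attachment_height_mm: float = 25.0

    def __post_init__(self) -> None:
        if self.c1_mpa <= 0:
            raise ValueError("C1 must be positive")
        if self.rest_length_mm <= 0 or self.cross_section_mm2 <= 0:
            raise ValueError("ligament rest length and cross-section must be positive")


#: Medial collateral (C1 = 6.43 MPa) and lateral collateral (C1 = 6.06 MPa).
DEFAULT_LIGAMENTS: tuple[LigamentSpec, ...] = (
    LigamentSpec(side="medial", c1_mpa=6.43, rest_length_mm=90.0, cross_section_mm2=25.0, lever_arm_mm=40.0),
    LigamentSpec(side="lateral", c1_mpa=6.06, rest_length_mm=60.0, cross_section_mm2=15.0, lever_arm_mm=-40.0),
)


@dataclass(frozen=True)
class LoadCase:
    """Axial compressive load at fixed 0 deg flexion.

    The force acts vertically (along -Z) through the femoral
    transepicondylar midpoint, ``application_point_mm`` in the tray frame;
    that point is a material point of the femur, so its line of action
    follows the femoral tilt.
    """

    axial_force_n: float = 1150.0
    flexion_deg: float = 0.0
    application_point_mm: tuple[float, float, float] = (0.0, 0.0, 25.0)

    def __post_init__(self) -> None:
        if self.axial_force_n <= 0:
            raise ValueError("axial force must be positive")
        if self.flexion_deg != 0.0:
            raise ValueError("only the 0 deg flexion load case is modelled")
        object.__setattr__(self, "application_point_mm", tuple(float(v) for v in self.application_point_mm))


def ligament_tension(spec: LigamentSpec, stretch: float) -> float:
    """Tensile axial force (N) of the ligament at stretch ``lambda``.

    Incompressible uniaxial Neo-Hookean Cauchy stress
    ``sigma = 2 C1 (lambda^2 - 1/lambda)``; force = sigma * A0 / lambda
    (current cross-section A0/lambda).  Ligaments carry no compression:
    force is 0 for lambda <= 1.  The small-strain tangent d(sigma)/d(lambda)
    at lambda = 1 is 6 C1.
    """
    lam = float(stretch)
    if lam <= 0:
        raise ValueError(f"stretch must be positive, got {lam}")
    if lam <= 1.0:
        return 0.0
    sigma = 2.0 * spec.c1_mpa * (lam**2 - 1.0 / lam)
    return sigma * spec.cross_section_mm2 / lam


# ---------------------------------------------------------------------------
# kinematics

def _rot_x(a: float) -> np.ndarray:
    c, s = math.cos(a), math.sin(a)
    return np.array([[1, 0, 0], [0, c, -s], [0, s, c]], dtype=float)


def _rot_y(a: float) -> np.ndarray:
    c, s = math.cos(a), math.sin(a)
    return np.array([[c, 0, s], [0, 1, 0], [-s, 0, c]], dtype=float)


def _rot_z(a: float) -> np.ndarray:
    c, s = math.cos(a), math.sin(a)
    return np.array([[c, -s, 0], [s, c, 0], [0, 0, 1]], dtype=float)


def _alignment_rotation(alignment: ImplantAlignment) -> np.ndarray:
    """Extrinsic tray-centred rotation: external rotation about Z, then
    effective posterior slope about X, then varus-valgus about Y.

    Axes (right knee): X medial-lateral (medial +), Y anterior-posterior
    (anterior +), Z proximal-distal (up +).  Positive varus drops the medial
    side; positive slope drops the posterior side; positive external
    rotation carries the anterior direction laterally.
    """
    g = math.radians(alignment.external_rotation_deg)
    b = math.radians(alignment.effective_slope_deg)
    a = math.radians(alignment.varus_deg)
    return _rot_y(a) @ _rot_x(b) @ _rot_z(g)


@dataclass(frozen=True)
class _DishSurface:
    side: str
    sphere_center: np.ndarray | None  # None for a flat dish
    plane_normal: np.ndarray | None
    aperture_center: np.ndarray
    aperture_radius: float
    dish_radius: float
    condyle_radius: float
    condyle_center0: np.ndarray  # nominal (unsettled) condyle sphere centre

    def heights(self, x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Liner-surface height field and validity mask on grid ``(x, y)``."""
        bx, by = self.aperture_center[0], self.aperture_center[1]
        mask = (x - bx) ** 2 + (y - by) ** 2 <= self.aperture_radius**2
        if self.sphere_center is None:
            n = self.plane_normal
            b = self.aperture_center
            z = b[2] - (n[0] * (x - b[0]) + n[1] * (y - b[1])) / n[2]
        else:
            c = self.sphere_center
            rho2 = (x - c[0]) ** 2 + (y - c[1]) ** 2
            inside = rho2 < self.dish_radius**2
            mask = mask & inside
            z = np.full_like(x, np.nan, dtype=float)
            z[mask] = c[2] - np.sqrt(self.dish_radius**2 - rho2[mask])
        return z, mask


class LinerSurface:
    """Height field of the liner's upper surface after a rigid alignment
    rotation about the tray centre, one spherical (or flat) dish per
    compartment."""

    def __init__(self, geometry: ArticularGeometry, alignment: ImplantAlignment):
        h = geometry.grid_spacing_mm
        for comp in geometry.compartments:
            if 2.0 * comp.aperture_radius_mm / h < 8.0:
                raise ValueError(
                    f"grid spacing {h} mm too coarse to resolve the "
                    f"{comp.side} dish (need >= 8 cells across its aperture)"
                )
        self.geometry = geometry
        self.alignment = alignment
        q = _alignment_rotation(alignment)
        dishes = []
        for comp in geometry.compartments:
            b0 = np.array([comp.center_ml_mm, comp.center_ap_mm, 0.0])
            b = q @ b0
            if math.isinf(comp.dish_radius_mm):
                center, normal = None, q @ np.array([0.0, 0.0, 1.0])
            else:
                center = q @ (b0 + np.array([0.0, 0.0, comp.dish_radius_mm]))
                normal = None
            dishes.append(
                _DishSurface(
                    side=comp.side,
                    sphere_center=center,
                    plane_normal=normal,
                    aperture_center=b,
                    aperture_radius=comp.aperture_radius_mm,
                    dish_radius=comp.dish_radius_mm,
                    condyle_radius=comp.condyle_radius_mm,
                    condyle_center0=np.array(
                        [comp.center_ml_mm, comp.center_ap_mm, comp.condyle_radius_mm]
                    ),
                )
            )
        self.dishes: tuple[_DishSurface, ...] = tuple(dishes)

    def heights(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Combined liner height field (NaN outside every dish aperture)."""
        z = np.full_like(np.asarray(x, dtype=float), np.nan)
        for dish in self.dishes:
            zd, mask = dish.heights(np.asarray(x, dtype=float), np.asarray(y, dtype=float))
            z[mask] = zd[mask]
        return z


def liner_surface(geometry: ArticularGeometry, alignment: ImplantAlignment) -> LinerSurface:
    """Construct the aligned liner surface sampler (see :class:`LinerSurface`)."""
    return LinerSurface(geometry, alignment)


# ---------------------------------------------------------------------------
# pressure maps

_COMPARTMENT_CODES = {"none": 0, "medial": 1, "lateral": 2}
_COMPARTMENT_NAMES = {v: k for k, v in _COMPARTMENT_CODES.items()}


@dataclass
class PressureMap:
    """Gridded contact pressure on the liner's upper surface.

    ``pressure`` is an (ny, nx) array in MPa on cell centres ``x``/``y``
    (mm); ``compartment`` holds per-cell membership codes (0 none,
    1 medial, 2 lateral).  ``applied_load_n`` and ``ligament_load_n`` record
    the vertical balance: contact integrates to applied + ligament pull.
    """

    x: np.ndarray
    y: np.ndarray
    pressure: np.ndarray
    compartment: np.ndarray
    spacing_mm: float
    applied_load_n: float = 0.0
    ligament_load_n: float = 0.0

    @property
    def cell_area_mm2(self) -> float:
        return self.spacing_mm**2

    def total_load_n(self) -> float:
        """Vertical contact load: sum of pressure x cell area (N)."""
        return float(self.pressure.sum() * self.cell_area_mm2)


def peak_pressure(pmap: PressureMap) -> tuple[float, str, tuple[float, float]]:
    """Maximum cell pressure with its compartment and (x, y) location.

    Ties across compartments resolve to the medial side (then to the lowest
    grid index).  Raises on an all-zero map.
    """
    p = pmap.pressure
    if p.size == 0 or float(p.max()) <= 0.0:
        raise ValueError("pressure map has no contact (all-zero pressures)")
    pmax = float(p.max())
    at_max = np.argwhere(p >= pmax)
    # medial-first tie-break, then row-major order
    order = sorted(
        (int(i), int(j)) for i, j in at_max
    )
    order.sort(key=lambda ij: (pmap.compartment[ij] != _COMPARTMENT_CODES["medial"], ij))
    i, j = order[0]
    comp = _COMPARTMENT_NAMES.get(int(pmap.compartment[i, j]), "none")
    return pmax, comp, (float(pmap.x[j]), float(pmap.y[i]))


def compartment_loads(pmap: PressureMap) -> tuple[float, float]:
    """(medial, lateral) vertical load in N; the pair sums to the map total."""
    a = pmap.cell_area_mm2
    med = float(pmap.pressure[pmap.compartment == _COMPARTMENT_CODES["medial"]].sum() * a)
    lat = float(pmap.pressure[pmap.compartment == _COMPARTMENT_CODES["lateral"]].sum() * a)
    return med, lat


# ---------------------------------------------------------------------------
# equilibrium solve

class ConvergenceError(RuntimeError):
    """Newton iteration failed; carries the last scaled residual."""

    def __init__(self, message: str, residual: np.ndarray | None = None):
        super().__init__(message)
        self.residual = residual


@dataclass
class EquilibriumState:
    """Converged rigid-body state of the femoral component."""

    settlement_mm: float
    varus_valgus_tilt_rad: float
    flexion_extension_tilt_rad: float
    residual_force_n: float
    residual_moment_vv_nmm: float
    reaction_moment_fe_nmm: float
    iterations: int
    converged: bool


class _FemurSystem:
    """Residual evaluation for the femoral rigid-body DOFs.

    DOF vector order: settlement w (mm, +down), then the free tilts among
    (varus-valgus about Y, flexion-extension about X), in radians.
    """

    def __init__(self, geometry, surface, k, ligaments, load, free_tilts):
        self.geometry = geometry
        self.surface = surface
        self.k = k
        self.ligaments = tuple(ligaments)
        self.load = load
        self.free_vv = "varus_valgus" in free_tilts
        self.free_fe = "flexion_extension" in free_tilts
        x, y = geometry.grid_axes()
        self.x, self.y = x, y
        self.X, self.Y = np.meshgrid(x, y)
        self.cell_area = geometry.grid_spacing_mm**2
        self.arm_scale = max(10.0, max(abs(c.center_ml_mm) for c in geometry.compartments))
        # liner heights and membership are alignment-fixed: precompute
        self._liner = []
        comp_grid = np.zeros(self.X.shape, dtype=np.int8)
        for dish in surface.dishes:
            z, mask = dish.heights(self.X, self.Y)
            self._liner.append((dish, z, mask))
            code = _COMPARTMENT_CODES[dish.side]
            comp_grid[mask & (comp_grid == 0)] = code
        self.compartment_grid = comp_grid

    def _femur_rotation(self, theta_fe: float, theta_vv: float) -> np.ndarray:
        return _rot_x(theta_fe) @ _rot_y(theta_vv)

    def state_from_dofs(self, u: np.ndarray) -> tuple[float, float, float]:
        w = float(u[0])
        i = 1
        theta_vv = theta_fe = 0.0
        if self.free_vv:
            theta_vv = float(u[i]); i += 1
        if self.free_fe:
            theta_fe = float(u[i]); i += 1
        return w, theta_vv, theta_fe

    def pressure(self, u: np.ndarray) -> np.ndarray:
        w, theta_vv, theta_fe = self.state_from_dofs(u)
        r = self._femur_rotation(theta_fe, theta_vv)
        p = np.zeros(self.X.shape, dtype=float)
        for dish, z_l, mask in self._liner:
            fc = r @ dish.condyle_center0 - np.array([0.0, 0.0, w])
            rho2 = (self.X - fc[0]) ** 2 + (self.Y - fc[1]) ** 2
            inside = rho2 < dish.condyle_radius**2
            m = mask & inside
            if not m.any():
                continue
            z_f = fc[2] - np.sqrt(dish.condyle_radius**2 - rho2[m])
            delta = z_l[m] - z_f
            contact = delta > 0
            vals = np.zeros(delta.shape)
            vals[contact] = self.k * delta[contact]
            p[m] += vals
        return p

    def ligament_forces(self, u: np.ndarray) -> list[tuple[LigamentSpec, float]]:
        w, theta_vv, theta_fe = self.state_from_dofs(u)
        r = self._femur_rotation(theta_fe, theta_vv)
        out = []
        for lig in self.ligaments:
            a0 = np.array([lig.lever_arm_mm, 0.0, lig.attachment_height_mm])
            a = r @ a0 - np.array([0.0, 0.0, w])
            dz = a[2] - a0[2]
            lam = 1.0 + dz / lig.rest_length_mm
            out.append((lig, ligament_tension(lig, max(lam, 1e-9))))
        return out

    def residual(self, u: np.ndarray, p: np.ndarray | None = None) -> np.ndarray:
        """Scaled residuals of vertical force and the free tilt moments."""
        if p is None:
            p = self.pressure(u)
        w, theta_vv, theta_fe = self.state_from_dofs(u)
        f_applied = self.load.axial_force_n
        a = self.cell_area
        n_contact = float(p.sum() * a)
        ligs = self.ligament_forces(u)
        t_total = sum(t for _, t in ligs)
        # applied load acts through the current transepicondylar midpoint
        r = self._femur_rotation(theta_fe, theta_vv)
        pt = r @ np.asarray(self.load.application_point_mm) - np.array([0.0, 0.0, w])
        res = [(n_contact - f_applied - t_total) / f_applied]
        m_y = -float((p * self.X).sum() * a) + sum(t * lig.lever_arm_mm for lig, t in ligs) + f_applied * pt[0]
        m_x = float((p * self.Y).sum() * a) - f_applied * pt[1]
        if self.free_vv:
            res.append(m_y / (f_applied * self.arm_scale))
        if self.free_fe:
            res.append(m_x / (f_applied * self.arm_scale))
        self._last_moments = (m_x, m_y)
        return np.array(res)


def solve_equilibrium(
    geometry: ArticularGeometry,
    alignment: ImplantAlignment,
    material: Material = MATERIALS["polyethylene_liner"],
    ligaments: tuple[LigamentSpec, ...] = DEFAULT_LIGAMENTS,
    load: LoadCase = LoadCase(),
    free_tilts: tuple[str, ...] = ("varus_valgus",),
    tol: float = 1e-3,
    max_iter: int = 100,
) -> tuple[EquilibriumState, PressureMap]:
    """Settle the femoral component on the aligned liner.

    Finds the settlement (and free tilts) at which the contact pressure
    integral balances the axial load plus any taut-ligament pull, and the
    moments about the free tilt axes vanish, by a bracketing solve of the
    settlement followed by damped Newton iteration (damping factor 0.5 on a
    residual increase, convergence at ``tol`` = 0.1% relative residual,
    hard cap ``max_iter``).

    Returns the equilibrium state and the pressure map.  Raises
    :class:`ConvergenceError` on failure and ``ValueError`` when the load
    cannot be carried (no attainable contact).
    """
    for name in free_tilts:
        if name not in ("varus_valgus", "flexion_extension"):
            raise ValueError(f"unknown tilt DOF {name!r}")
    k = foundation_modulus(material, geometry.liner_thickness_mm)
    surface = liner_surface(geometry, alignment)
    sys = _FemurSystem(geometry, surface, k, ligaments, load, free_tilts)

    ndof = 1 + sys.free_vv + sys.free_fe

    # --- bracket and bisect the settlement at zero tilt
    def force_residual(w: float) -> float:
        u = np.zeros(ndof)
        u[0] = w
        return float(sys.residual(u)[0])

    w_lo, w_hi = -10.0, 2.0
    tries = 0
    while force_residual(w_hi) < 0.0:
        w_hi += 2.0
        tries += 1
        if tries > 10:
            raise ValueError(
                "load cannot be equilibrated: no liner contact attainable "
                "under the requested alignment"
            )
    if force_residual(w_lo) > 0.0:
        raise ValueError("load cannot be equilibrated: contact force positive even with the femur lifted")
    w0 = brentq(force_residual, w_lo, w_hi, xtol=1e-6)

    u = np.zeros(ndof)
    u[0] = w0

    # --- damped Newton on all free DOFs
    steps = np.full(ndof, 1e-4)
    steps[0] = 1e-3  # mm perturbation for settlement, rad for tilts
    r = sys.residual(u)
    iterations = 0
    converged = bool(np.max(np.abs(r)) <= tol)
    while not converged and iterations < max_iter:
        iterations += 1
        jac = np.empty((ndof, ndof))
        for j in range(ndof):
            du = np.zeros(ndof)
            du[j] = steps[j]
            jac[:, j] = (sys.residual(u + du) - r) / steps[j]
        try:
            step = np.linalg.solve(jac, -r)
        except np.linalg.LinAlgError as exc:
            raise ConvergenceError(f"singular Jacobian at iteration {iterations}", r) from exc
        # damping: halve the step while the residual norm grows
        lam = 1.0
        for _ in range(12):
            u_new = u + lam * step
            r_new = sys.residual(u_new)
            if np.linalg.norm(r_new) <= np.linalg.norm(r) or lam < 1e-3:
                break
            lam *= 0.5
        u, r = u_new, r_new
        converged = bool(np.max(np.abs(r)) <= tol)
    if not converged:
        raise ConvergenceError(
            f"equilibrium not reached in {max_iter} iterations "
            f"(scaled residual {np.max(np.abs(r)):.3g})",
            r,
        )

    p = sys.pressure(u)
    if float(p.sum()) <= 0.0:
        raise ValueError("load cannot be equilibrated: both compartments lifted off")
    w, theta_vv, theta_fe = sys.state_from_dofs(u)
    ligs = sys.ligament_forces(u)
    m_x, m_y = sys._last_moments
    f = load.axial_force_n
    state = EquilibriumState(
        settlement_mm=w,
        varus_valgus_tilt_rad=theta_vv,
        flexion_extension_tilt_rad=theta_fe,
        residual_force_n=float(r[0] * f),
        residual_moment_vv_nmm=float(m_y) if sys.free_vv else 0.0,
        reaction_moment_fe_nmm=0.0 if sys.free_fe else float(m_x),
        iterations=iterations,
        converged=True,
    )
    pmap = PressureMap(
        x=sys.x,
        y=sys.y,
        pressure=p,
        compartment=sys.compartment_grid,
        spacing_mm=geometry.grid_spacing_mm,
        applied_load_n=f,
        ligament_load_n=float(sum(t for _, t in ligs)),
    )
    return state, pmap


# ---------------------------------------------------------------------------
# pressure-map I/O

def export_pressure_map(pmap: PressureMap, path) -> None:
    """Write the map as delimited text with '#'-prefixed metadata lines.

    Floats are printed with 17 significant digits so a write/read round trip
    reproduces every cell bit-identically.
    """
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# tkaopt pressure map v1\n")
        fh.write(f"# origin_x_mm: {float(pmap.x[0]):.17g}\n")
        fh.write(f"# origin_y_mm: {float(pmap.y[0]):.17g}\n")
        fh.write(f"# spacing_mm: {float(pmap.spacing_mm):.17g}\n")
        fh.write(f"# nx: {len(pmap.x)}\n")
        fh.write(f"# ny: {len(pmap.y)}\n")
        fh.write(f"# applied_load_n: {float(pmap.applied_load_n):.17g}\n")
        fh.write(f"# ligament_load_n: {float(pmap.ligament_load_n):.17g}\n")
        fh.write("# units: pressure MPa, lengths mm\n")
        fh.write("row,col,x_mm,y_mm,pressure_mpa,compartment\n")
        for i in range(len(pmap.y)):
            for j in range(len(pmap.x)):
                fh.write(
                    f"{i},{j},{pmap.x[j]:.17g},{pmap.y[i]:.17g},"
                    f"{pmap.pressure[i, j]:.17g},{int(pmap.compartment[i, j])}\n"
                )


def read_pressure_map(path) -> PressureMap:
    """Read a map written by :func:`export_pressure_map`."""
    meta: dict[str, str] = {}
    rows = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if line.startswith("#"):
                if ":" in line:
                    key, val = line[1:].split(":", 1)
                    meta[key.strip()] = val.strip()
                continue
            if line and not line.startswith("row,"):
                rows.append(line.split(","))
    nx, ny = int(meta["nx"]), int(meta["ny"])
    spacing = float(meta["spacing_mm"])
    x0, y0 = float(meta["origin_x_mm"]), float(meta["origin_y_mm"])
    x = x0 + spacing * np.arange(nx)
    y = y0 + spacing * np.arange(ny)
    pressure = np.zeros((ny, nx))
    comp = np.zeros((ny, nx), dtype=np.int8)
    for r in rows:
        i, j = int(r[0]), int(r[1])
        x[j] = float(r[2])
        y[i] = float(r[3])
        pressure[i, j] = float(r[4])
        comp[i, j] = int(r[5])
    return PressureMap(
        x=x,
        y=y,
        pressure=pressure,
        compartment=comp,
        spacing_mm=spacing,
        applied_load_n=float(meta.get("applied_load_n", 0.0)),
        ligament_load_n=float(meta.get("ligament_load_n", 0.0)),
    )
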
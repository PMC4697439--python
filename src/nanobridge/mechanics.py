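"""Buckling mechanics of composite actin/microtubule membrane projections.

A thin membrane projection (filopodium, tunnelling-nanotube-like bridge) is
modelled as a bundle of ``n_a`` actin filaments and ``n_t`` microtubules
loaded axially.  Each filament class contributes flexural rigidity
``B_i = k_B T · L_p,i`` (persistence length times thermal energy); the bundle
is treated as uncoupled so rigidities add:

    B = k_B T · (n_a · L_p,actin + n_t · L_p,tubulin)

The projection buckles under an axial load ``F`` when its length exceeds the
Euler buckling length

    L_max = sqrt(I · B / F),        F_b(L) = I · B / L²

where ``I`` is the non-dimensional boundary-condition prefactor (π²/4 for a
clamped-free column, the default).  The smallest membrane diameter that can
sheath the bundle follows from hexagonal close packing of filament
cross-sections at areal fraction φ:

    D_min = 2 · sqrt((n_a · r_a² + n_t · r_t²) / φ)

Combining the two gives, for every membrane diameter, the longest projection
that a bundle packed into that diameter can support — the feasibility curve —
and, at fixed total filament count, an optimal tubulin number fraction

    f* = 1/(q − 1) − 2/(ρ − 1),   q = (r_t/r_a)²,   ρ = L_p,t / L_p,a

maximizing the strength-per-thickness metric ``L_max / D_min²``.

All lengths are in nanometres, forces in piconewtons and energies in pN·nm
unless stated otherwise; every formula is homogeneous in length units, so any
consistent unit system works.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .exceptions import InvalidInputError, ZeroCapacityError

__all__ = [
    "ModelConstants",
    "FilamentClass",
    "BundleSpec",
    "ProjectionGeometry",
    "FeasibilityCurve",
    "OptimalFraction",
    "ACTIN",
    "TUBULIN",
    "DEFAULT_CONSTANTS",
    "bundle_rigidity",
    "buckling_force",
    "buckling_length",
    "min_diameter",
    "max_filaments_for_diameter",
    "feasibility_curve",
    "classify_feasibility",
    "performance_metric",
    "optimal_tubulin_fraction",
]

#: Clamped-free Euler boundary prefactor, the default for a projection
#: anchored in the cell cortex with a free tip.
CLAMPED_FREE = math.pi**2 / 4
#: Clamped-clamped prefactor; upper end of the admissible range.
CLAMPED_CLAMPED = 4 * math.pi**2

#: Hexagonal close packing fraction of equal circles, π/(2√3).
HEX_PACKING = math.pi / (2 * math.sqrt(3))  # 0.9069...


@dataclass(frozen=True)
class ModelConstants:
    """Physical constants of the composite-bundle buckling model.

    Parameters
    ----------
    thermal_energy : float
        k_B·T in pN·nm.  Default 4.28 pN·nm (T = 310 K, body temperature).
    load_force : float
        Axial load F in pN the projection must withstand. Default 10 pN,
        a typical membrane/motor load scale.
    packing_fraction : float
        Areal fraction φ of the bundle cross-section occupied by filaments,
        in (0, 1].  Default hexagonal close packing, 0.9069.
    boundary_factor : float
        Non-dimensional Euler prefactor I in [π²/4, 4π²].  Default π²/4
        (clamped base, free tip).
    """

    thermal_energy: float = 4.28
    load_force: float = 10.0
    packing_fraction: float = HEX_PACKING
    boundary_factor: float = CLAMPED_FREE

    def __post_init__(self) -> None:
        if self.thermal_energy <= 0 or self.load_force <= 0:
            raise InvalidInputError("thermal_energy and load_force must be > 0")
        if not 0 < self.packing_fraction <= 1:
            raise InvalidInputError("packing_fraction must be in (0, 1]")
        lo, hi = CLAMPED_FREE, CLAMPED_CLAMPED
        if not lo - 1e-12 <= self.boundary_factor <= hi + 1e-12:
            raise InvalidInputError(
                f"boundary_factor must lie in [{lo:.4f}, {hi:.4f}] "
                "(clamped-free to clamped-clamped)"
            )


@dataclass(frozen=True)
class FilamentClass:
    """One filament species: name, cross-section radius (nm), persistence length (nm)."""

    name: str
    radius: float
    persistence_length: float

    def __post_init__(self) -> None:
        if self.radius <= 0 or self.persistence_length <= 0:
            raise InvalidInputError("radius and persistence_length must be > 0")


#: Actin microfilament: r = 3.5 nm, L_p = 17.7 μm (literature-standard values).
ACTIN = FilamentClass("actin", radius=3.5, persistence_length=17_700.0)
#: Microtubule: r = 14 nm (4× actin), L_p = 5.2 mm.
TUBULIN = FilamentClass("tubulin", radius=14.0, persistence_length=5.2e6)

DEFAULT_CONSTANTS = ModelConstants()


@dataclass(frozen=True)
class BundleSpec:
    """Filament composition of a projection: counts of actin and microtubules."""

    n_actin: int
    n_tubulin: int

    def __post_init__(self) -> None:
        if self.n_actin < 0 or self.n_tubulin < 0:
            raise InvalidInputError("filament counts must be non-negative")

    @property
    def total(self) -> int:
        return self.n_actin + self.n_tubulin

    @property
    def tubulin_fraction(self) -> float:
        """Tubulin number fraction f = n_t / N (0 for an empty bundle)."""
        return self.n_tubulin / self.total if self.total else 0.0

    def _require_nonempty(self) -> None:
        if self.total < 1:
            raise InvalidInputError("bundle must contain at least one filament")


@dataclass(frozen=True)
class ProjectionGeometry:
    """Measured projection geometry: length L and membrane diameter D, nm."""

    length: float
    diameter: float

    def __post_init__(self) -> None:
        if self.length < 0:
            raise InvalidInputError("length must be >= 0")
        if self.diameter <= 0:
            raise InvalidInputError("diameter must be > 0")


@dataclass(frozen=True)
class FeasibilityCurve:
    """Maximum supportable length versus minimum packable diameter.

    ``points`` has one row per grid diameter with columns
    ``min_diameter_nm``, ``max_length_nm``, ``n_actin``, ``n_tubulin``.
    """

    composition: float
    points: pd.DataFrame
    constants_used: ModelConstants = field(default_factory=ModelConstants)

    def max_length_at(self, diameter: float) -> float:
        """Interpolated maximum length at ``diameter`` (nm)."""
        d = self.points["min_diameter_nm"].to_numpy()
        l = self.points["max_length_nm"].to_numpy()
        return float(np.interp(diameter, d, l))


def bundle_rigidity(
    bundle: BundleSpec,
    actin: FilamentClass = ACTIN,
    tubulin: FilamentClass = TUBULIN,
    constants: ModelConstants = DEFAULT_CONSTANTS,
    coupling_exponent: float = 1.0,
) -> float:
    """Flexural rigidity B of an uncoupled composite bundle, pN·nm².

    B = k_B T · (n_a^κ · L_p,a + n_t^κ · L_p,t), with κ = 1 (uncoupled
    filaments, the default).  κ = 2 models a fully cross-linked bundle.
    The equivalent bundle persistence length is ``B / k_B T``.
    """
    bundle._require_nonempty()
    kbt = constants.thermal_energy
    return kbt * (
        bundle.n_actin**coupling_exponent * actin.persistence_length
        + bundle.n_tubulin**coupling_exponent * tubulin.persistence_length
    )


def buckling_force(
    bundle: BundleSpec,
    geometry: ProjectionGeometry,
    actin: FilamentClass = ACTIN,
    tubulin: FilamentClass = TUBULIN,
    constants: ModelConstants = DEFAULT_CONSTANTS,
) -> float:
    """Critical Euler buckling force F_b = I·B/L² for a projection of length L, pN."""
    if geometry.length <= 0:
        raise InvalidInputError("projection length must be > 0 (force diverges at L = 0)")
    B = bundle_rigidity(bundle, actin, tubulin, constants)
    return constants.boundary_factor * B / geometry.length**2


def buckling_length(
    bundle: BundleSpec,
    actin: FilamentClass = ACTIN,
    tubulin: FilamentClass = TUBULIN,
    constants: ModelConstants = DEFAULT_CONSTANTS,
) -> float:
    """Longest projection (nm) that resists the configured axial load.

    L_max = sqrt(I·B/F); exact inverse of :func:`buckling_force`.
    """
    if constants.load_force <= 0:
        raise InvalidInputError("load_force must be > 0")
    B = bundle_rigidity(bundle, actin, tubulin, constants)
    return math.sqrt(constants.boundary_factor * B / constants.load_force)


def min_diameter(
    bundle: BundleSpec,
    actin: FilamentClass = ACTIN,
    tubulin: FilamentClass = TUBULIN,
    constants: ModelConstants = DEFAULT_CONSTANTS,
) -> float:
    """Smallest circumscribing membrane diameter (nm) at packing fraction φ.

    D_min = 2·sqrt((n_a·r_a² + n_t·r_t²)/φ).  The same formula is used down
    to a single filament for continuity (slightly above 2r there).
    """
    bundle._require_nonempty()
    area = bundle.n_actin * actin.radius**2 + bundle.n_tubulin * tubulin.radius**2
    return 2.0 * math.sqrt(area / constants.packing_fraction)


def max_filaments_for_diameter(
    diameter: float,
    composition: float,
    actin: FilamentClass = ACTIN,
    tubulin: FilamentClass = TUBULIN,
    constants: ModelConstants = DEFAULT_CONSTANTS,
) -> BundleSpec:
    """Largest bundle of given tubulin number fraction packable in ``diameter``.

    Counts are floored to integers; the microtubule count is the integer
    closest to ``composition · N`` with ties resolved toward fewer
    microtubules (conservative feasibility).  Guarantees
    ``min_diameter(result) <= diameter``.

    Raises
    ------
    ZeroCapacityError
        If the diameter cannot pack a single filament of the requested
        composition.
    """
    if diameter <= 0:
        raise InvalidInputError("diameter must be > 0")
    if not 0.0 <= composition <= 1.0:
        raise InvalidInputError("composition must be in [0, 1]")
    budget = constants.packing_fraction * (diameter / 2.0) ** 2
    r_a2, r_t2 = actin.radius**2, tubulin.radius**2

    def split(n_total: int) -> tuple[int, int]:
        # round-half-down: ties go to fewer microtubules
        n_t = int(math.ceil(composition * n_total - 0.5))
        n_t = min(max(n_t, 0), n_total)
        return n_total - n_t, n_t

    def fits(n_total: int) -> bool:
        n_a, n_t = split(n_total)
        return n_a * r_a2 + n_t * r_t2 <= budget * (1 + 1e-12)

    n_hi = int(budget // min(r_a2, r_t2)) + 1
    # bisect on the largest fitting total count (area is monotone in N)
    lo, hi = 0, n_hi
    while fits(hi):
        lo, hi = hi, hi * 2
    while hi - lo > 1:
        mid = (lo + hi) // 2
        if fits(mid):
            lo = mid
        else:
            hi = mid
    if lo < 1:
        raise ZeroCapacityError(
            f"diameter {diameter} nm cannot pack one filament at composition {composition}"
        )
    n_a, n_t = split(lo)
    return BundleSpec(n_actin=n_a, n_tubulin=n_t)


def feasibility_curve(
    composition: float,
    diameter_grid,
    actin: FilamentClass = ACTIN,
    tubulin: FilamentClass = TUBULIN,
    constants: ModelConstants = DEFAULT_CONSTANTS,
) -> FeasibilityCurve:
    """Maximum supportable length over a grid of membrane diameters.

    For each diameter the largest packable bundle at the given tubulin
    fraction is built and its Euler buckling length under the configured
    load computed.  Diameters too small to pack any filament get length 0.
    """
    grid = np.asarray(list(diameter_grid), dtype=float)
    if grid.size == 0:
        raise InvalidInputError("diameter grid must be non-empty")
    if np.any(np.diff(grid) <= 0):
        raise InvalidInputError("diameter grid must be strictly increasing")
    rows = []
    for d in grid:
        try:
            b = max_filaments_for_diameter(d, composition, actin, tubulin, constants)
            lmax = buckling_length(b, actin, tubulin, constants)
            rows.append((d, lmax, b.n_actin, b.n_tubulin))
        except ZeroCapacityError:
            rows.append((d, 0.0, 0, 0))
    points = pd.DataFrame(
        rows, columns=["min_diameter_nm", "max_length_nm", "n_actin", "n_tubulin"]
    )
    return FeasibilityCurve(composition=composition, points=points, constants_used=constants)


def classify_feasibility(
    geometry: ProjectionGeometry,
    composition: float,
    actin: FilamentClass = ACTIN,
    tubulin: FilamentClass = TUBULIN,
    constants: ModelConstants = DEFAULT_CONSTANTS,
) -> str:
    """Whether a measured geometry can exist at the given composition.

    A projection is ``"feasible"`` iff its length does not exceed the Euler
    buckling length of the largest bundle of that composition packable
    within its diameter; otherwise ``"infeasible"``.
    """
    try:
        b = max_filaments_for_diameter(
            geometry.diameter, composition, actin, tubulin, constants
        )
        lmax = buckling_length(b, actin, tubulin, constants)
    except ZeroCapacityError:
        lmax = 0.0
    return "feasible" if geometry.length <= lmax else "infeasible"


def performance_metric(f, lp_ratio: float, radius_ratio_sq: float):
    """Strength-per-thickness metric P(f) ∝ L_max/D_min² at fixed filament count.

    In reduced units P(f) = sqrt(1 + f(ρ−1)) / (1 + f(q−1)), with
    ρ = L_p,t/L_p,a and q = (r_t/r_a)².  Vectorized over ``f``.
    """
    f = np.asarray(f, dtype=float)
    return np.sqrt(1.0 + f * (lp_ratio - 1.0)) / (1.0 + f * (radius_ratio_sq - 1.0))


@dataclass(frozen=True)
class OptimalFraction:
    """Result of the tubulin-fraction optimization."""

    fraction: float
    interior: bool  # False when the optimum sits on the f = 0 boundary


def optimal_tubulin_fraction(
    lp_ratio: float, radius_ratio_sq: float, numeric: bool = False
) -> OptimalFraction:
    """Tubulin number fraction maximizing L_max/D_min² at fixed filament count.

    Closed form ``f* = 1/(q−1) − 2/(ρ−1)`` with ρ = L_p,t/L_p,a and
    q = (r_t/r_a)².  Requires ρ > q − 1 ≥ 1; when ρ ≤ 2q − 1 the stationary
    point is non-positive and the boundary ``f = 0`` is returned with
    ``interior=False``.

    Parameters
    ----------
    numeric : bool
        If True, compute by bounded 1-D maximization of
        :func:`performance_metric` instead of the closed form (used for
        cross-validation; agrees to ~1e-9).
    """
    rho, q = float(lp_ratio), float(radius_ratio_sq)
    if q - 1.0 < 1.0:
        raise InvalidInputError("radius_ratio_sq must satisfy q - 1 >= 1")
    if rho <= q - 1.0:
        raise InvalidInputError("lp_ratio must exceed radius_ratio_sq - 1")
    f_star = 1.0 / (q - 1.0) - 2.0 / (rho - 1.0)
    if f_star <= 0.0:
        return OptimalFraction(fraction=0.0, interior=False)
    if numeric:
        res = minimize_scalar(
            lambda f: -performance_metric(f, rho, q),
            bounds=(0.0, 1.0),
            method="bounded",
            options={"xatol": 1e-12},
        )
        return OptimalFraction(fraction=float(res.x), interior=True)
    return OptimalFraction(fraction=f_star, interior=True)


def rescale_constants(constants: ModelConstants, length_factor: float) -> ModelConstants:
    """Constants re-expressed after multiplying the length unit by ``length_factor``.

    Only the thermal energy carries a length dimension (pN·length); forces
    and dimensionless factors are unchanged.  Used for unit-homogeneity
    checks (e.g. nm → μm with ``length_factor = 1e-3``).
    """
    return replace(constants, thermal_energy=constants.thermal_energy * length_factor)
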
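"""Cell-pair geometry, intercalated-disc layouts and derived scalings.

Two identical cylindrical cardiomyocytes (radius ``R_ID``, length ``L``)
abut longitudinally at x = 0 inside a grounded extracellular box of size
``Lx x Ly x Lz``.  The junctional membrane complex (intercalated disc,
ID) carries a central Na+ channel cluster and, depending on the layout,
a gap-junction plaque with an optional perinexal nanodomain where the
extracellular cleft is locally narrower.

Lengths in this module are expressed in the units the field habitually
uses (um for cell-scale dimensions, nm for cleft widths); conversion to
the internal cm-based system happens where meshes and FEM operators are
built.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

__all__ = [
    "GeometryParams",
    "IDLayout",
    "InvalidGeometryError",
    "compute_membrane_areas",
    "compute_scaling_factors",
    "compute_nominal_ggap",
]


class InvalidGeometryError(ValueError):
    """Raised when geometry or layout parameters are physically inconsistent."""


@dataclass(frozen=True)
class GeometryParams:
    """Dimensions of the cell pair and its intercalated-disc features.

    All lengths in micrometres.  Defaults are the physiological values of
    a ventricular cardiomyocyte pair: an 11 um radius, 100 um long cell,
    a Na+ channel cluster and gap-junction plaque of radius R_ID/16, and
    a perinexus of radius 3.3 * r_GJ.
    """

    R_ID: float = 11.0          # cell / intercalated-disc radius, um
    L: float = 100.0            # cell length, um
    Lx: float = 300.0           # extracellular box length (along the cell axis), um
    Ly: float = 55.0            # extracellular box width, um
    Lz: float = 55.0            # extracellular box height, um
    r_Na: float = 0.6875        # Na+ cluster radius, um (= R_ID/16)
    r_GJ: float = 0.6875        # gap-junction plaque radius, um
    r_peri: float = 2.26875     # perinexus radius, um (= 3.3 * r_GJ)
    patch_radius: float = 2.0   # intracellular electrode sphere radius, um
    patch_offset: float = 10.0  # electrode distance from the outer cell end, um

    def __post_init__(self) -> None:
        for name in ("R_ID", "L", "Lx", "Ly", "Lz", "r_Na", "r_GJ", "r_peri",
                     "patch_radius", "patch_offset"):
            if getattr(self, name) <= 0:
                raise InvalidGeometryError(f"{name} must be > 0, got {getattr(self, name)}")
        if self.r_Na > self.R_ID:
            raise InvalidGeometryError("Na+ cluster must fit inside the ID disc")
        if self.r_peri < self.r_GJ:
            raise InvalidGeometryError("perinexus must contain the plaque (r_peri >= r_GJ)")
        if self.Lx <= 2 * self.L:
            raise InvalidGeometryError("extracellular box must enclose both cells (Lx > 2L)")
        if min(self.Ly, self.Lz) <= 2 * self.R_ID:
            raise InvalidGeometryError("extracellular box must enclose the cell radius")
        # remote layout (d = 5 r_GJ) must fit inside the disc
        if 5 * self.r_GJ + self.r_peri > self.R_ID:
            raise InvalidGeometryError("remote plaque/perinexus does not fit inside the ID disc")


#: distance between cluster and plaque centres, in units of r_GJ
_LAYOUT_D_FACTOR = {"uniform": 0.0, "close": 2.0, "remote": 5.0}


@dataclass(frozen=True)
class IDLayout:
    """Arrangement of cluster, plaque and perinexus on the ID, plus cleft widths.

    ``configuration`` selects where gap-junctional conductance sits:
    ``uniform`` spreads it homogeneously over the ID around the central
    cluster, ``close``/``remote`` concentrate it in a plaque at a
    centre-to-centre distance d = 2 r_GJ or 5 r_GJ from the cluster.
    Widths are in nanometres.
    """

    configuration: str = "uniform"
    w_cleft: float = 40.0          # bulk cleft width, nm
    w_peri: float = 40.0           # perinexal width, nm
    w_plaque: float = 2.0          # cleft width inside the plaque, nm
    f_sigma_plaque: float = 0.1    # extracellular conductivity factor inside the plaque
    has_perinexus: bool = False
    exclude_cluster_from_gap: bool = True  # uniform layout: spread G_gap around (not under) the cluster

    def __post_init__(self) -> None:
        if self.configuration not in _LAYOUT_D_FACTOR:
            raise InvalidGeometryError(
                f"configuration must be one of {sorted(_LAYOUT_D_FACTOR)}, got {self.configuration!r}")
        if self.w_cleft <= 0 or self.w_peri <= 0 or self.w_plaque <= 0:
            raise InvalidGeometryError("cleft widths must be > 0")
        if self.w_peri > self.w_cleft:
            raise InvalidGeometryError("perinexal width may not exceed the bulk cleft width")
        if self.w_plaque > self.w_peri:
            raise InvalidGeometryError("plaque width may not exceed the perinexal width")
        if not 0 <= self.f_sigma_plaque <= 1:
            raise InvalidGeometryError("f_sigma_plaque must lie in [0, 1]")

    def plaque_distance(self, geom: GeometryParams) -> float:
        """Centre-to-centre distance d between cluster and plaque, um."""
        return _LAYOUT_D_FACTOR[self.configuration] * geom.r_GJ


def compute_membrane_areas(geom: GeometryParams) -> tuple[float, float, float]:
    """Membrane areas of one cell in cm^2: (A_cell, A_ID, A_lat).

    A_ID counts both end discs of the cylinder (2 pi R^2), A_lat its
    lateral surface (2 pi R L), and A_cell their sum.
    """
    R_cm = geom.R_ID * 1e-4
    L_cm = geom.L * 1e-4
    A_ID = 2.0 * math.pi * R_cm ** 2
    A_lat = 2.0 * math.pi * R_cm * L_cm
    return A_ID + A_lat, A_ID, A_lat


def compute_scaling_factors(geom: GeometryParams, P: float = 0.5) -> tuple[float, float]:
    """Na+ conductance scaling factors (F_gNa_ID, F_gNa_lat).

    A fraction ``P`` of the cell's Na+ channels sits on the two ID-facing
    discs, the rest on the lateral membrane; the total channel count is
    conserved, so the local maximal conductance is scaled by
    F_ID = P * A_cell / A_ID and F_lat = (1 - P) * A_cell / A_lat.
    """
    if not 0.0 <= P <= 1.0:
        raise InvalidGeometryError(f"P must lie in [0, 1], got {P}")
    A_cell, A_ID, A_lat = compute_membrane_areas(geom)
    return P * A_cell / A_ID, (1.0 - P) * A_cell / A_lat


def compute_nominal_ggap(geom: GeometryParams, junctional_resistivity: float = 1.5) -> float:
    """Nominal whole-ID gap-junctional conductance in mS.

    One junctional disc of area pi R_ID^2 divided by the area-specific
    junctional resistivity (Ohm cm^2).  With R_ID = 11 um and 1.5 Ohm cm^2
    this gives 2.53 uS; the reduced coupling levels used in the
    experiments (1 %, 5 %) are fractions of this value.
    """
    if junctional_resistivity <= 0:
        raise InvalidGeometryError("junctional resistivity must be > 0")
    R_cm = geom.R_ID * 1e-4
    area = math.pi * R_cm ** 2          # cm^2
    # 1/(Ohm cm^2) * cm^2 = S -> mS
    return area / junctional_resistivity * 1e3
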
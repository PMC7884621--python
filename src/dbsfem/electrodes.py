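"""Parametric bipolar lead geometries and their placement above a target.

Four axisymmetric concentric-bipolar designs are modelled:

* ``SNEX100``  — sharp conical tip, core contact exposed on the tip cone,
  ring-shaped outer contact on the shaft close above the tip;
* ``CEAX100``  — like SNEX100 but with the two contacts closer together;
* ``SPHERICAL`` — hemispherical tip of the bare core wire (contact exposed
  laterally and at the apex), outer contact relocated to the upper shaft;
* ``BLUNT``    — flat-disc tip, core exposed *only* at the bottom and covered
  laterally by an insulating taper, outer contact on the upper shaft.

Exact manufacturer dimensions are not public; every dimension is a parameter
with documented defaults drawn from the general class of concentric bipolar
microelectrodes, so the four designs form a parameter study rather than
certified replicas.  The lead is described by a radial profile r(z) around
its axis (z = axial distance from the tip apex, the lead extending towards
+z; insertion is along -z).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .phantom import TissuePhantom, Track

logger = logging.getLogger("dbsfem.electrodes")

DESIGN_NAMES = ("SNEX100", "CEAX100", "SPHERICAL", "BLUNT")

CORE_DIAMETER_RANGE = (0.125, 0.250)  # mm, manufacturable core range
DEFAULT_CORE_DIAMETER = 0.240         # mm
DEFAULT_SHAFT_DIAMETER = 0.50         # mm
DEFAULT_TIP_OFFSET = 0.4              # mm above the target centre of mass


@dataclass(frozen=True)
class ElectrodeDesign:
    """Fully dimensioned axisymmetric bipolar lead."""

    name: str
    shaft_diameter: float = DEFAULT_SHAFT_DIAMETER
    core_diameter: float = DEFAULT_CORE_DIAMETER
    tip_shape: str = "sharp_cone"          # sharp_cone | hemisphere | flat_disc
    tip_length: float = 0.6                # cone/taper length from apex to full shaft, mm
    core_contact_length: float = 0.25      # axial extent of the exposed tip contact, mm
    outer_contact_offset: float = 0.75     # apex -> lower edge of the ring, mm
    outer_contact_length: float = 0.5      # axial length of the ring, mm
    insulation_thickness: float = 0.06     # lateral insulation at a blunt tip, mm
    total_length: float = 10.0             # modelled shaft length, mm

    # ---- radii --------------------------------------------------------------

    @property
    def shaft_radius(self) -> float:
        return self.shaft_diameter / 2.0

    @property
    def core_radius(self) -> float:
        return self.core_diameter / 2.0

    def validate(self) -> None:
        lo, hi = CORE_DIAMETER_RANGE
        if not (lo <= self.core_diameter <= hi):
            raise ValueError(f"core_diameter {self.core_diameter} mm outside "
                             f"the manufacturable range {CORE_DIAMETER_RANGE}")
        if self.core_diameter >= self.shaft_diameter:
            raise ValueError("core_diameter must be below shaft_diameter")
        if self.tip_shape not in ("sharp_cone", "hemisphere", "flat_disc"):
            raise ValueError(f"unknown tip_shape '{self.tip_shape}'")
        if self.outer_contact_length <= 0 or self.core_contact_length <= 0:
            raise ValueError("contact extents must be positive")
        if self.outer_contact_offset <= self._core_contact_top():
            raise ValueError("contacts overlap: outer contact must start above "
                             "the core contact")
        if self.outer_contact_offset + self.outer_contact_length > self.total_length:
            raise ValueError("outer contact extends beyond the lead")
        if self.name in ("SPHERICAL", "BLUNT") and \
                self.outer_contact_offset < 2.0 * self.outer_contact_length:
            raise ValueError("modified designs require the outer contact far "
                             "up the shaft (offset >> length)")

    def _core_contact_top(self) -> float:
        """Axial extent of the exposed core-metal region."""
        if self.tip_shape == "hemisphere":
            return self.core_radius
        if self.tip_shape == "flat_disc":
            return 0.0  # exposed only at the very bottom
        return self.core_contact_length

    # ---- radial profile -----------------------------------------------------

    def outer_radius(self, z: np.ndarray) -> np.ndarray:
        """Radius of the lead surface at axial distance z from the apex."""
        z = np.asarray(z, dtype=float)
        rs, rc = self.shaft_radius, self.core_radius
        r = np.full(z.shape, rs)
        if self.tip_shape == "sharp_cone":
            m = z < self.tip_length
            r[m] = rs * z[m] / self.tip_length
        elif self.tip_shape == "hemisphere":
            cap = z < rc
            with np.errstate(invalid="ignore"):
                r[cap] = np.sqrt(np.maximum(rc ** 2 - (z[cap] - rc) ** 2, 0.0))
            taper = (z >= rc) & (z < rc + self.tip_length)
            r[taper] = rc + (rs - rc) * (z[taper] - rc) / self.tip_length
        else:  # flat_disc
            r0 = rc + self.insulation_thickness
            taper = z < self.tip_length
            r[taper] = r0 + (rs - r0) * z[taper] / self.tip_length
        r[(z < 0) | (z > self.total_length)] = 0.0
        return r

    # ---- solids (local frame, tip apex at origin, lead towards +z) ----------

    def inside(self, z: np.ndarray, rho: np.ndarray) -> np.ndarray:
        return (z >= 0) & (z <= self.total_length) & (rho <= self.outer_radius(z))

    def core_metal(self, z: np.ndarray, rho: np.ndarray) -> np.ndarray:
        """Solid metal region whose surface is the core contact."""
        ins = self.inside(z, rho)
        if self.tip_shape == "flat_disc":
            return ins & (rho <= self.core_radius) & (z <= 0.15)
        return ins & (z <= self._core_contact_top())

    def outer_metal(self, z: np.ndarray, rho: np.ndarray,
                    depth: float = 0.06) -> np.ndarray:
        """Thin metal annulus at the shaft surface forming the outer contact."""
        zlo = self.outer_contact_offset
        return (self.inside(z, rho) & (z >= zlo)
                & (z <= zlo + self.outer_contact_length)
                & (rho >= self.outer_radius(z) - depth))

    # ---- surface areas ------------------------------------------------------

    def core_contact_area(self) -> float:
        rc = self.core_radius
        if self.tip_shape == "flat_disc":
            return np.pi * rc ** 2
        if self.tip_shape == "hemisphere":
            return 2 * np.pi * rc ** 2
        # lateral surface of the tip cone up to the exposed extent
        zc = self._core_contact_top()
        r = self.shaft_radius * zc / self.tip_length
        return np.pi * r * np.hypot(zc, r)

    def outer_contact_area(self) -> float:
        return 2 * np.pi * self.shaft_radius * self.outer_contact_length

    def total_surface_area(self, n: int = 20001) -> float:
        """Area of the full lead surface (revolved profile + end caps)."""
        z = np.linspace(0.0, self.total_length, n)
        r = self.outer_radius(z)
        ds = np.hypot(np.diff(z), np.diff(r))
        lateral = float(np.sum(np.pi * (r[:-1] + r[1:]) * ds))
        bottom = np.pi * r[0] ** 2
        top = np.pi * r[-1] ** 2
        return lateral + bottom + top

    # ---- export -------------------------------------------------------------

    def surface_mesh(self, n_axial: int = 200, n_theta: int = 64):
        """Watertight triangulated surface of revolution (trimesh object)."""
        import trimesh
        if self.tip_shape == "hemisphere":
            zt = np.concatenate([self.core_radius *
                                 (1 - np.cos(np.linspace(0, np.pi / 2, 24))),
                                 np.linspace(self.core_radius,
                                             self.total_length, n_axial)])
        else:
            zt = np.linspace(0.0, self.total_length, n_axial)
        zt = np.unique(zt)
        r = self.outer_radius(zt)
        # linestring for revolution: start on the axis, end on the axis
        pts2d = np.concatenate([[[0.0, zt[0]]], np.stack([r, zt], axis=1),
                                [[0.0, zt[-1]]]])
        mesh = trimesh.creation.revolve(pts2d, sections=n_theta)
        return mesh

    def to_stl(self, path: str, **kw) -> None:
        self.surface_mesh(**kw).export(path)

    def to_json(self) -> str:
        """Constructive description of the lead (all dimensions, mm)."""
        import json
        from dataclasses import asdict
        return json.dumps(asdict(self), indent=2)


_DESIGN_DEFAULTS: dict[str, dict] = {
    # conventional concentric bipolar: contacts near the tip
    "SNEX100": dict(tip_shape="sharp_cone", core_contact_length=0.25,
                    outer_contact_offset=0.75, outer_contact_length=0.5),
    # contacts located more closely than on SNEX100
    "CEAX100": dict(tip_shape="sharp_cone", core_contact_length=0.20,
                    outer_contact_offset=0.65, outer_contact_length=0.35),
    # modified designs: outer contact moved to the upper shaft, far from the tip
    "SPHERICAL": dict(tip_shape="hemisphere", core_contact_length=0.12,
                      tip_length=0.5, outer_contact_offset=2.2,
                      outer_contact_length=0.5),
    "BLUNT": dict(tip_shape="flat_disc", core_contact_length=0.12,
                  tip_length=0.5, outer_contact_offset=2.2,
                  outer_contact_length=0.5),
}


def make_design(name: str, **overrides) -> ElectrodeDesign:
    """Construct one of the four named designs, with optional overrides."""
    if name not in DESIGN_NAMES:
        raise ValueError(f"unknown design '{name}'; choose from {DESIGN_NAMES}")
    params = dict(_DESIGN_DEFAULTS[name])
    params.update(overrides)
    design = ElectrodeDesign(name=name, **params)
    design.validate()
    return design


# ---------------------------------------------------------------------------
# placement
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Placement:
    """Pose of a lead implanted cranial to a target nucleus."""

    target_name: str
    tip_position: np.ndarray               # mm, apex of the tip
    axis: np.ndarray = None                # unit insertion axis (-z)
    tip_offset_above_target: float = DEFAULT_TIP_OFFSET

    def __post_init__(self):
        object.__setattr__(self, "tip_position",
                           np.asarray(self.tip_position, dtype=float))
        ax = np.array([0.0, 0.0, -1.0]) if self.axis is None else \
            np.asarray(self.axis, dtype=float)
        object.__setattr__(self, "axis", ax / np.linalg.norm(ax))

    def local_coords(self, pts: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """(z, rho): axial distance above the apex and radial distance, mm."""
        pts = np.atleast_2d(np.asarray(pts, dtype=float))
        d = pts - self.tip_position
        z = -(d @ self.axis)       # lead extends opposite the insertion axis
        radial = d + np.outer(z, self.axis)
        return z, np.linalg.norm(radial, axis=1)


def place(design: ElectrodeDesign, phantom: TissuePhantom, target_name: str,
          tip_offset: float = DEFAULT_TIP_OFFSET) -> Placement:
    """Place the lead tip ``tip_offset`` mm dorsal to the target centroid."""
    com = phantom.region_centroid(target_name)   # raises on empty mask
    tip = com + np.array([0.0, 0.0, tip_offset])
    logger.info("placement %s/%s: target CoM %s, tip %s",
                design.name, target_name, np.round(com, 3), np.round(tip, 3))
    return Placement(target_name=target_name, tip_position=tip,
                     tip_offset_above_target=tip_offset)


def shaft_track(design: ElectrodeDesign, placement: Placement,
                phantom: TissuePhantom) -> Track:
    """Track of the implanted lead from tip to the domain top, with the
    design's radial profile, for encapsulation carving."""
    top = phantom.domain_bounds[1][2]
    p0 = placement.tip_position
    p1 = p0 - placement.axis * (top - p0[2])    # axis points down (-z)
    return Track(p0=p0, p1=p1, radius=lambda s: design.outer_radius(s))


def electrode_interior_mask(design: ElectrodeDesign, placement: Placement,
                            pts: np.ndarray) -> np.ndarray:
    z, rho = placement.local_coords(pts)
    return design.inside(z, rho)


def core_contact_center(design: ElectrodeDesign,
                        placement: Placement) -> np.ndarray:
    """World position of the centroid of the exposed core-contact surface."""
    if design.tip_shape == "flat_disc":
        zc = 0.0
    elif design.tip_shape == "hemisphere":
        zc = design.core_radius / 2.0
    else:
        zc = 2.0 * design._core_contact_top() / 3.0
    return placement.tip_position - placement.axis * zc
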
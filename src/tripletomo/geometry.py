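"""Parametric geometry of the procentriole and its microtubule triplets.

The procentriole is modelled as a 9-fold array of triplet "blades" around a
central cartwheel hub.  Each blade carries a complete 13-protofilament (PF)
A-tubule (an elliptical ring) and partial 10-PF B- and C-tubules that share
walls with their inner neighbour.  Blades sit at the tip of radial spokes and
rotate progressively about their attachment point along the long (z) axis —
the "iris diaphragm" twist.

Conventions (global to the package):

* right-handed frame, cylinder axis = +z, proximal end at z = 0, +z points
  towards the microtubule plus end (distal);
* lengths in nm, angles in degrees;
* triplets indexed 1..n_fold counterclockwise viewed from the distal end;
* PFs indexed 1-based (A1..A13, B1..B10, C1..C10).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Tuple

import numpy as np

__all__ = [
    "PFRingSpec",
    "DecorationSpec",
    "TripletModel",
    "TwistProfile",
    "ProcentrioleModel",
    "interior_angle",
    "blade_angle_at",
    "handedness_of",
    "luminal_diameter_at",
    "default_triplet",
    "default_procentriole",
]


class GeometryError(ValueError):
    """Invalid geometric parameter or out-of-range query."""


# --------------------------------------------------------------------------
# domain types
# --------------------------------------------------------------------------

@dataclass
class PFRingSpec:
    """One tubule of a triplet: a (possibly partial) ring of protofilaments.

    ``pf_angles`` are angular positions (degrees) of PF centrelines on the
    tubule ellipse, indexed 1-based in the field's A1..A13 / B1..B10 sense.
    The A-tubule is a closed 13-PF elliptical ring; B and C are open 10-PF
    arcs completed by the wall of their inner neighbour.
    """

    tubule_id: str
    n_pf: int
    pf_angles: List[float]
    radius_major: float
    radius_minor: float
    closed: bool

    def __post_init__(self) -> None:
        if self.tubule_id not in ("A", "B", "C"):
            raise GeometryError(f"tubule_id must be A, B or C, got {self.tubule_id!r}")
        if self.n_pf != len(self.pf_angles):
            raise GeometryError("n_pf must equal len(pf_angles)")
        if self.tubule_id == "A" and not self.closed:
            raise GeometryError("A-tubule must be a closed ring")
        if self.tubule_id in ("B", "C") and self.closed:
            raise GeometryError("B- and C-tubules are partial (open) rings")
        if self.radius_major <= 0 or self.radius_minor <= 0:
            raise GeometryError("tubule radii must be positive")

    def pf_xy(self) -> np.ndarray:
        """(n_pf, 2) PF centreline positions relative to the tubule centre."""
        ang = np.deg2rad(np.asarray(self.pf_angles, dtype=float))
        return np.column_stack(
            [self.radius_major * np.cos(ang), self.radius_minor * np.sin(ang)]
        )


@dataclass
class DecorationSpec:
    """A non-tubulin decoration (MIP, pinhead, A-C linker arm) on the triplet.

    Anchored to one or more PFs and repeating axially every 4 or 8 nm.
    ``mass_da`` carries the estimated molecular weight where known.
    """

    name: str
    anchor_pfs: List[str]
    periodicity_nm: float
    blob_sigma_nm: float = 1.5
    mass_da: Optional[float] = None
    radial_offset_nm: float = 3.0

    def __post_init__(self) -> None:
        if self.periodicity_nm not in (4, 8, 4.0, 8.0):
            raise GeometryError("decoration periodicity must be 4 or 8 nm")
        for pf in self.anchor_pfs:
            if pf[0] not in "ABC" or not pf[1:].isdigit():
                raise GeometryError(f"bad anchor PF id {pf!r}")


@dataclass
class TripletModel:
    """Cross-section model of one triplet blade in its local frame.

    Local frame: origin at the blade pivot (pinhead attachment), +xi along
    the blade long axis (A -> C), +eta perpendicular.  ``inter_tubule_offsets``
    place the B centre on the A wall (outer A-B junction) and the C centre on
    the B wall.
    """

    rings: Dict[str, PFRingSpec]
    inter_tubule_offsets: Dict[str, Tuple[float, float]]
    decorations: List[DecorationSpec] = field(default_factory=list)
    a_center_offset: Tuple[float, float] = (10.0, 0.0)

    def __post_init__(self) -> None:
        for tid in ("A", "B", "C"):
            if tid not in self.rings:
                raise GeometryError(f"triplet missing {tid}-tubule ring")
        for key in ("B_on_A", "C_on_B"):
            if key not in self.inter_tubule_offsets:
                raise GeometryError(f"missing inter-tubule offset {key!r}")
        for dec in self.decorations:
            for pf in dec.anchor_pfs:
                ring = self.rings[pf[0]]
                idx = int(pf[1:])
                if not 1 <= idx <= ring.n_pf:
                    raise GeometryError(
                        f"decoration {dec.name!r} anchors to nonexistent PF {pf}"
                    )

    def tubule_center(self, tubule_id: str) -> np.ndarray:
        """Tubule centre in the blade-local (xi, eta) frame."""
        a = np.asarray(self.a_center_offset, dtype=float)
        if tubule_id == "A":
            return a
        b = a + np.asarray(self.inter_tubule_offsets["B_on_A"], dtype=float)
        if tubule_id == "B":
            return b
        if tubule_id == "C":
            return b + np.asarray(self.inter_tubule_offsets["C_on_B"], dtype=float)
        raise GeometryError(f"unknown tubule {tubule_id!r}")

    def pf_position(self, pf_id: str) -> np.ndarray:
        """Blade-local position of a PF centreline, by id like 'A3'."""
        ring = self.rings[pf_id[0]]
        idx = int(pf_id[1:]) - 1
        return self.tubule_center(pf_id[0]) + ring.pf_xy()[idx]


@dataclass
class TwistProfile:
    """Linear longitudinal twist of the blades: theta(z) = theta0 + rate * z.

    Positive rate means the blade angle increases counterclockwise with z
    when viewed from the distal (+z) end, i.e. left-handed chirality with the
    thumb pointing towards the microtubule plus end.
    """

    theta0_deg: float = 30.0
    rate_deg_per_nm: float = 0.0

    @property
    def handedness(self) -> str:
        if self.rate_deg_per_nm > 0:
            return "left"
        if self.rate_deg_per_nm < 0:
            return "right"
        return "none"


@dataclass
class ProcentrioleModel:
    """The full n-fold procentriole: hub, spokes and twisting triplet blades.

    ``per_triplet_tubule_extents`` stores, for each triplet, the [start, end)
    z-span in nm of the A, B and C tubules; B is nested in A and C in B (the
    A-tubule is always the longest, then B, then C).
    """

    triplet: TripletModel
    twist: TwistProfile
    n_fold: int = 9
    hub_radius_nm: float = 11.0
    spoke_length_nm: float = 70.0
    length_nm: float = 100.0
    per_triplet_tubule_extents: Optional[List[Dict[str, Tuple[float, float]]]] = None
    mirrored: bool = False

    def __post_init__(self) -> None:
        if self.n_fold < 3:
            raise GeometryError("n_fold must be >= 3")
        if self.length_nm <= 0:
            raise GeometryError("length must be positive")
        if self.per_triplet_tubule_extents is None:
            full = (0.0, self.length_nm)
            self.per_triplet_tubule_extents = [
                {"A": full, "B": full, "C": full} for _ in range(self.n_fold)
            ]
        if len(self.per_triplet_tubule_extents) != self.n_fold:
            raise GeometryError("need one tubule-extent entry per triplet")
        for ext in self.per_triplet_tubule_extents:
            a, b, c = ext["A"], ext["B"], ext["C"]
            if not (a[0] <= b[0] <= b[1] <= a[1] and b[0] <= c[0] <= c[1] <= b[1]):
                raise GeometryError(
                    "tubule extents must nest: A contains B contains C"
                )

    # -- frame helpers -----------------------------------------------------

    @property
    def pivot_radius_nm(self) -> float:
        """Radius of the blade pivot (pinhead) from the cylinder axis."""
        return self.hub_radius_nm + self.spoke_length_nm

    def triplet_azimuth_deg(self, triplet_index: int) -> float:
        if not 1 <= triplet_index <= self.n_fold:
            raise GeometryError(f"triplet index {triplet_index} out of 1..{self.n_fold}")
        return (triplet_index - 1) * 360.0 / self.n_fold

    def blade_orientation_deg(self, z: float, triplet_index: int) -> float:
        """Absolute in-plane direction (deg) of the blade long axis at z.

        At blade angle 0 the blade points radially inward; increasing blade
        angle rotates it counterclockwise (viewed from distal) for an
        unmirrored model.
        """
        alpha = self.triplet_azimuth_deg(triplet_index)
        theta = blade_angle_at(self, z, triplet_index)
        sgn = -1.0 if self.mirrored else 1.0
        return alpha + 180.0 + sgn * theta

    def blade_frame(self, z: float, triplet_index: int) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(pivot, u, v): pivot point and blade-local basis in the xy plane.

        u points along the blade long axis; v completes the basis (u rotated
        +90 deg; flipped for a mirrored model so the cross-section mirrors).
        """
        alpha = math.radians(self.triplet_azimuth_deg(triplet_index))
        phi = math.radians(self.blade_orientation_deg(z, triplet_index))
        sgn = -1.0 if self.mirrored else 1.0
        u = np.array([math.cos(phi), math.sin(phi)])
        v = sgn * np.array([-math.sin(phi), math.cos(phi)])
        pivot = self.pivot_radius_nm * np.array([math.cos(alpha), math.sin(alpha)])
        return pivot, u, v

    def tubule_center_xy(self, z: float, triplet_index: int, tubule_id: str) -> np.ndarray:
        pivot, u, v = self.blade_frame(z, triplet_index)
        xi, eta = self.triplet.tubule_center(tubule_id)
        return pivot + xi * u + eta * v

    def mirror(self) -> "ProcentrioleModel":
        """Mirror image through a plane containing the z axis.

        The stored twist profile is unchanged; the flag flips the realised
        rotation sense (and the blade cross-section), so chirality reverses.
        """
        return replace(self, mirrored=not self.mirrored)

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "n_fold": self.n_fold,
            "hub_radius_nm": self.hub_radius_nm,
            "spoke_length_nm": self.spoke_length_nm,
            "length_nm": self.length_nm,
            "mirrored": self.mirrored,
            "twist": {
                "theta0_deg": self.twist.theta0_deg,
                "rate_deg_per_nm": self.twist.rate_deg_per_nm,
            },
            "per_triplet_tubule_extents": [
                {k: list(v) for k, v in ext.items()}
                for ext in self.per_triplet_tubule_extents
            ],
            "triplet": {
                "a_center_offset": list(self.triplet.a_center_offset),
                "inter_tubule_offsets": {
                    k: list(v) for k, v in self.triplet.inter_tubule_offsets.items()
                },
                "rings": {
                    tid: {
                        "tubule_id": r.tubule_id,
                        "n_pf": r.n_pf,
                        "pf_angles": list(r.pf_angles),
                        "radius_major": r.radius_major,
                        "radius_minor": r.radius_minor,
                        "closed": r.closed,
                    }
                    for tid, r in self.triplet.rings.items()
                },
                "decorations": [
                    {
                        "name": d.name,
                        "anchor_pfs": list(d.anchor_pfs),
                        "periodicity_nm": d.periodicity_nm,
                        "blob_sigma_nm": d.blob_sigma_nm,
                        "mass_da": d.mass_da,
                        "radial_offset_nm": d.radial_offset_nm,
                    }
                    for d in self.triplet.decorations
                ],
            },
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ProcentrioleModel":
        t = d["triplet"]
        triplet = TripletModel(
            rings={tid: PFRingSpec(**r) for tid, r in t["rings"].items()},
            inter_tubule_offsets={
                k: tuple(v) for k, v in t["inter_tubule_offsets"].items()
            },
            decorations=[DecorationSpec(**dd) for dd in t["decorations"]],
            a_center_offset=tuple(t["a_center_offset"]),
        )
        return cls(
            triplet=triplet,
            twist=TwistProfile(**d["twist"]),
            n_fold=d["n_fold"],
            hub_radius_nm=d["hub_radius_nm"],
            spoke_length_nm=d["spoke_length_nm"],
            length_nm=d["length_nm"],
            per_triplet_tubule_extents=[
                {k: tuple(v) for k, v in ext.items()}
                for ext in d["per_triplet_tubule_extents"]
            ],
            mirrored=d.get("mirrored", False),
        )

    def save_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def load_json(cls, path) -> "ProcentrioleModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


# --------------------------------------------------------------------------
# closed-form operations
# --------------------------------------------------------------------------

def interior_angle(n_fold: int) -> float:
    """Interior angle of a regular n-gon, in degrees.

    The angle the inter-triplet linkage must impose between neighbouring
    blades for the array to close: 140 degrees for a nonagon.
    """
    if n_fold < 3:
        raise GeometryError("a polygon needs at least 3 sides")
    return (n_fold - 2) * 180.0 / n_fold


def blade_angle_at(model: ProcentrioleModel, z: float, triplet_index: int = 1) -> float:
    """Blade angle theta(z) = theta0 + rate * z (deg); same for all triplets."""
    if not 0 <= z <= model.length_nm:
        raise GeometryError(f"z={z} outside [0, {model.length_nm}] nm")
    model.triplet_azimuth_deg(triplet_index)  # validates index
    tw = model.twist
    return tw.theta0_deg + tw.rate_deg_per_nm * z


def handedness_of(model: ProcentrioleModel) -> str:
    """Chirality of the longitudinal twist: 'left', 'right' or 'none'.

    Viewed from the distal (+z, microtubule plus) end, blade angle increasing
    counterclockwise with z is left-handed (thumb towards the plus end).
    Mirroring the model through any plane containing z flips the result.
    """
    rate = model.twist.rate_deg_per_nm
    if rate == 0:
        return "none"
    sense = rate * (-1.0 if model.mirrored else 1.0)
    return "left" if sense > 0 else "right"


def luminal_diameter_at(model: ProcentrioleModel, z: float, n_samples: int = 720) -> float:
    """Luminal diameter (nm) at height z.

    Twice the minimal distance from the cylinder axis to any A-tubule wall
    point at that height.  As the blades twist tangential with z the inner
    wall retreats from the axis and the lumen opens like an iris diaphragm.
    """
    if not 0 <= z <= model.length_nm:
        raise GeometryError(f"z={z} outside [0, {model.length_nm}] nm")
    ring = model.triplet.rings["A"]
    phi = np.linspace(0.0, 2 * np.pi, n_samples, endpoint=False)
    wall_local = np.column_stack(
        [ring.radius_major * np.cos(phi), ring.radius_minor * np.sin(phi)]
    )
    xi_eta = np.asarray(model.triplet.tubule_center("A")) + wall_local
    dmin = math.inf
    for k in range(1, model.n_fold + 1):
        pivot, u, v = model.blade_frame(z, k)
        pts = pivot + np.outer(xi_eta[:, 0], u) + np.outer(xi_eta[:, 1], v)
        dmin = min(dmin, float(np.min(np.hypot(pts[:, 0], pts[:, 1]))))
    return 2.0 * dmin


# --------------------------------------------------------------------------
# defaults
# --------------------------------------------------------------------------

def _arc_angles(n: int, start: float, stop: float) -> List[float]:
    return list(np.linspace(start, stop, n))


def default_triplet(decorate: bool = True) -> TripletModel:
    """Canonical triplet from microtubule lattice spacing.

    The 13-PF A-tubule is a slightly elliptical ring (~5 nm inter-PF arc
    spacing); B and C are 10-PF partial arcs opening towards their inner
    neighbour's wall.  Default decorations: the pinhead hook on A3 and the
    MIP1 cone on A5, both with 8 nm axial repeat.
    """
    rings = {
        "A": PFRingSpec("A", 13, [i * 360.0 / 13 for i in range(13)], 11.0, 9.5, True),
        "B": PFRingSpec("B", 10, _arc_angles(10, 120.0, 370.0), 10.3, 10.3, False),
        "C": PFRingSpec("C", 10, _arc_angles(10, 120.0, 370.0), 10.3, 10.3, False),
    }
    decorations = []
    if decorate:
        decorations = [
            DecorationSpec("pinhead", ["A3"], 8.0, blob_sigma_nm=2.0,
                           radial_offset_nm=5.0),
            DecorationSpec("MIP1", ["A5"], 8.0, blob_sigma_nm=1.5,
                           mass_da=45_000.0, radial_offset_nm=-4.0),
        ]
    return TripletModel(
        rings=rings,
        inter_tubule_offsets={"B_on_A": (17.0, -4.0), "C_on_B": (17.0, -4.0)},
        decorations=decorations,
    )


def default_procentriole(
    rate_deg_per_nm: float = 0.12,
    theta0_deg: float = 35.0,
    length_nm: float = 100.0,
    decorate: bool = True,
) -> ProcentrioleModel:
    """9-fold procentriole with a left-handed twist at the default rate."""
    return ProcentrioleModel(
        triplet=default_triplet(decorate=decorate),
        twist=TwistProfile(theta0_deg=theta0_deg, rate_deg_per_nm=rate_deg_per_nm),
        length_nm=length_nm,
    )
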
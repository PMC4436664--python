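"""Cylinder representation of RNA helices and virtual residues/atoms.

A stem is reduced to an axis segment ``(a_s, a_e)`` plus two unit twist
vectors ``(t_s, t_e)`` perpendicular to the axis at its ends, and a
base-pair count.  Virtual residues (one per base pair, equally spaced on
the axis with interpolated twist) carry a small template-derived set of
virtual atoms (P, O3', C1', base centroid per strand) used by the clash,
junction-closure and radius-of-gyration terms and by the coarse RMSD.

The ideal A-form template is stylised: base-pair midpoints sit exactly
on the axis (the two C1' atoms are antipodal), so a total-least-squares
line through the midpoints recovers the axis to machine precision.  The
twist reference is the perpendicular component of the vector from the
axis to the first-strand C1' atom.  Template constants (rise 2.81 A/bp,
twist 32.7 deg/bp, C1' radius 9.4 A) are standard fiber-diffraction
A-form values and are configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "AFormTemplate",
    "BasePairFrame",
    "StemCylinder",
    "VirtualResidue",
    "ideal_a_form_helix",
    "fit_cylinder",
    "virtual_residues",
    "rotation_about_axis",
    "signed_angle",
]


def _unit(v: np.ndarray) -> np.ndarray:
    nrm = np.linalg.norm(v)
    if nrm < 1e-12:
        raise ValueError("cannot normalise a zero vector")
    return v / nrm


def rotation_about_axis(axis: np.ndarray, angle: float) -> np.ndarray:
    """Rodrigues rotation matrix about a (unit) axis."""
    k = _unit(np.asarray(axis, dtype=float))
    K = np.array(
        [[0, -k[2], k[1]], [k[2], 0, -k[0]], [-k[1], k[0], 0]], dtype=float
    )
    return np.eye(3) + np.sin(angle) * K + (1.0 - np.cos(angle)) * (K @ K)


def signed_angle(u: np.ndarray, v: np.ndarray, axis: np.ndarray) -> float:
    """Signed angle in (-pi, pi] carrying u onto v about ``axis``."""
    k = _unit(np.asarray(axis, dtype=float))
    u = u - np.dot(u, k) * k
    v = v - np.dot(v, k) * k
    ang = np.arctan2(np.dot(np.cross(u, v), k), np.dot(u, v))
    if ang <= -np.pi:
        ang = np.pi
    return float(ang)


@dataclass(frozen=True)
class AFormTemplate:
    """Virtual-atom template in per-base-pair cylindrical coordinates.

    Offsets are ``(radius A, angle rad relative to the twist direction,
    axial offset A)`` per strand; strand a runs 5'->3' along the +axis,
    strand b antiparallel.  The P/O3' placement is calibrated so that the
    O3'(k) -> P(k+1) backbone linkage along each strand of an ideal helix
    has a fixed short length (``linkage`` below), which in turn defines
    the junction-gap scale at coaxial stacks.
    """

    rise: float = 2.81
    twist: float = np.deg2rad(32.7)
    c1_radius: float = 9.4
    linkage: float = 1.6

    version: str = "aform-1"

    @property
    def atom_offsets(self) -> dict[str, dict[str, tuple[float, float, float]]]:
        a_o3 = np.deg2rad(12.0)
        a_p = a_o3 - self.twist
        z_o3 = 0.8
        z_p = z_o3 - self.rise + self.linkage
        r_bb = 9.2
        off_a = {
            "C1'": (self.c1_radius, 0.0, 0.0),
            "O3'": (r_bb, a_o3, z_o3),
            "P": (r_bb, a_p, z_p),
            "BASE": (3.0, 0.0, 0.0),
        }
        # strand b: rotated half a turn about the axis, antiparallel, so the
        # same linkage calibration holds in the 3'->5' axis direction
        off_b = {
            "C1'": (self.c1_radius, np.pi, 0.0),
            "O3'": (r_bb, np.pi - a_o3, -z_o3),
            "P": (r_bb, np.pi - a_p, -z_p),
            "BASE": (3.0, np.pi, 0.0),
        }
        return {"a": off_a, "b": off_b}

    def place_atoms(
        self, origin: np.ndarray, axis_dir: np.ndarray, twist_dir: np.ndarray
    ) -> dict[str, np.ndarray]:
        """All eight virtual atoms of one base pair in a local frame."""
        e = _unit(axis_dir)
        w = _unit(twist_dir)
        y = np.cross(e, w)
        out = {}
        for strand, offs in self.atom_offsets.items():
            for atom, (r, alpha, z) in offs.items():
                out[f"{atom}_{strand}"] = (
                    origin
                    + r * (np.cos(alpha) * w + np.sin(alpha) * y)
                    + z * e
                )
        return out


DEFAULT_TEMPLATE = AFormTemplate()

#: stem end (0 = outer c1/c4, 1 = inner c2/c3) per corner number
CORNER_END = {1: 0, 2: 1, 3: 1, 4: 0}
#: twist sign per corner (strand a positive, strand b negative)
CORNER_SIGN = {1: 1.0, 2: 1.0, 3: -1.0, 4: -1.0}


@dataclass
class BasePairFrame:
    """Backbone atom positions of one base pair (strand a is 5'-most)."""

    c1p_a: np.ndarray
    c1p_b: np.ndarray
    p_a: np.ndarray | None = None
    p_b: np.ndarray | None = None
    o3p_a: np.ndarray | None = None
    o3p_b: np.ndarray | None = None

    @property
    def midpoint(self) -> np.ndarray:
        return 0.5 * (self.c1p_a + self.c1p_b)


@dataclass
class StemCylinder:
    """Axis segment plus end twist vectors for one helix."""

    a_s: np.ndarray
    a_e: np.ndarray
    t_s: np.ndarray
    t_e: np.ndarray
    n_bp: int
    template: AFormTemplate = field(default=DEFAULT_TEMPLATE, repr=False)

    def __post_init__(self):
        self.a_s = np.asarray(self.a_s, dtype=float)
        self.a_e = np.asarray(self.a_e, dtype=float)
        self.t_s = np.asarray(self.t_s, dtype=float)
        self.t_e = np.asarray(self.t_e, dtype=float)
        if self.n_bp < 2:
            raise ValueError("a stem cylinder needs at least 2 base pairs")
        axis = self.a_e - self.a_s
        L = np.linalg.norm(axis)
        if L < 1e-9:
            raise ValueError("degenerate axis (zero length)")
        for name in ("t_s", "t_e"):
            t = getattr(self, name)
            if abs(np.linalg.norm(t) - 1.0) > 1e-9:
                raise ValueError(f"{name} is not unit length")
            if abs(np.dot(t, axis)) > 1e-6 * L:
                raise ValueError(f"{name} is not perpendicular to the axis")

    @property
    def axis(self) -> np.ndarray:
        return _unit(self.a_e - self.a_s)

    @property
    def length(self) -> float:
        return float(np.linalg.norm(self.a_e - self.a_s))

    def end_point(self, end: int) -> np.ndarray:
        return self.a_s if end == 0 else self.a_e

    def end_twist(self, end: int) -> np.ndarray:
        return self.t_s if end == 0 else self.t_e

    def outward_axis(self, end: int) -> np.ndarray:
        """Unit axis direction pointing out of the stem at ``end``."""
        return -self.axis if end == 0 else self.axis

    def end_frame(self, end: int) -> tuple[np.ndarray, np.ndarray]:
        """(origin, 3x3 frame) at an end: rows are (outward axis, twist,
        their cross product)."""
        e1 = self.outward_axis(end)
        e2 = self.end_twist(end)
        e3 = np.cross(e1, e2)
        return self.end_point(end), np.vstack([e1, e2, e3])

    def corner_frame(self, corner: int) -> tuple[np.ndarray, np.ndarray]:
        """Strand-adjusted placement frame at a corner (1..4).

        Corners 1/2 sit on strand a and use the end twist as is; corners
        3/4 sit on strand b, whose C1' direction is the negated twist.
        With the flip-symmetric atom template this makes one placement
        tuple mean the geometrically analogous arrangement for every
        connection pattern (e.g. a coaxial stack continues whichever
        strand the connector follows).
        """
        end = CORNER_END[corner]
        e1 = self.outward_axis(end)
        e2 = CORNER_SIGN[corner] * self.end_twist(end)
        e3 = np.cross(e1, e2)
        return self.end_point(end), np.vstack([e1, e2, e3])

    def total_twist(self) -> float:
        """Accumulated rotation carrying t_s onto t_e about the axis.

        The base signed angle is lifted by whole turns to the branch
        consistent with the configured per-bp helical twist, so that
        interpolated minor-groove tracks stay correct for long stems.
        """
        base = signed_angle(self.t_s, self.t_e, self.axis)
        expected = (self.n_bp - 1) * self.template.twist
        k = round((expected - base) / (2 * np.pi))
        return base + 2 * np.pi * k

    def transformed(self, R: np.ndarray, v: np.ndarray) -> "StemCylinder":
        return StemCylinder(
            R @ self.a_s + v,
            R @ self.a_e + v,
            R @ self.t_s,
            R @ self.t_e,
            self.n_bp,
            self.template,
        )


@dataclass
class VirtualResidue:
    """Per-base-pair axis point, interpolated twist, and virtual atoms."""

    position: np.ndarray
    twist: np.ndarray
    atoms: dict[str, np.ndarray]


def ideal_a_form_helix(
    n_bp: int, template: AFormTemplate = DEFAULT_TEMPLATE
) -> list[BasePairFrame]:
    """Generate base-pair frames of an ideal (stylised) A-form helix.

    Midpoints lie exactly on the z axis at constant rise; the first-strand
    C1' direction advances by the helical twist each step.
    """
    if n_bp < 2:
        raise ValueError("n_bp must be >= 2")
    frames = []
    for k in range(n_bp):
        theta = k * template.twist
        w = np.array([np.cos(theta), np.sin(theta), 0.0])
        origin = np.array([0.0, 0.0, k * template.rise])
        atoms = template.place_atoms(origin, np.array([0.0, 0.0, 1.0]), w)
        frames.append(
            BasePairFrame(
                c1p_a=atoms["C1'_a"],
                c1p_b=atoms["C1'_b"],
                p_a=atoms["P_a"],
                p_b=atoms["P_b"],
                o3p_a=atoms["O3'_a"],
                o3p_b=atoms["O3'_b"],
            )
        )
    return frames


def fit_cylinder(
    frames: list[BasePairFrame], template: AFormTemplate = DEFAULT_TEMPLATE
) -> StemCylinder:
    """Fit the cylinder representation to ordered base-pair frames.

    The axis is the total-least-squares line through the base-pair
    midpoints (principal component of the centred midpoints), oriented
    from the first to the last base pair; ``a_s``/``a_e`` are the
    projections of the first/last midpoints onto that line.  The twist at
    each end is the unit perpendicular component of the vector from the
    axis endpoint to the corresponding first-strand C1' atom.
    """
    if len(frames) < 2:
        raise ValueError("need at least 2 base-pair frames")
    mids = np.array([f.midpoint for f in frames])
    centroid = mids.mean(axis=0)
    centred = mids - centroid
    if np.linalg.norm(centred) < 1e-9:
        raise ValueError("degenerate axis: all base-pair midpoints coincide")
    # principal axis via SVD of the centred midpoints
    _, _, vt = np.linalg.svd(centred, full_matrices=False)
    axis = vt[0]
    if np.dot(mids[-1] - mids[0], axis) < 0:
        axis = -axis
    a_s = centroid + np.dot(mids[0] - centroid, axis) * axis
    a_e = centroid + np.dot(mids[-1] - centroid, axis) * axis

    def end_twist(point: np.ndarray, c1p: np.ndarray) -> np.ndarray:
        v = c1p - point
        v = v - np.dot(v, axis) * axis
        return _unit(v)

    return StemCylinder(
        a_s,
        a_e,
        end_twist(a_s, frames[0].c1p_a),
        end_twist(a_e, frames[-1].c1p_a),
        len(frames),
        template,
    )


def virtual_residues(cyl: StemCylinder) -> list[VirtualResidue]:
    """Equally spaced axis points with interpolated twist and atoms.

    Base pair k sits at ``a_s + k/(n-1) (a_e - a_s)``; its twist rotates
    t_s about the axis by the same fraction of the accumulated total
    rotation (which lands exactly on t_e at the far end).
    """
    e = cyl.axis
    total = cyl.total_twist()
    out = []
    for k in range(cyl.n_bp):
        frac = k / (cyl.n_bp - 1)
        pos = cyl.a_s + frac * (cyl.a_e - cyl.a_s)
        w = rotation_about_axis(e, frac * total) @ cyl.t_s
        atoms = cyl.template.place_atoms(pos, e, w)
        out.append(VirtualResidue(position=pos, twist=w, atoms=atoms))
    return out


def corner_atom(cyl: StemCylinder, corner: int, atom: str) -> np.ndarray:
    """Virtual atom of the nucleotide at a stem corner (1..4).

    Corner 1 is base pair 0 strand a, corner 2 base pair n-1 strand a,
    corner 3 base pair n-1 strand b, corner 4 base pair 0 strand b.
    """
    bp = 0 if corner in (1, 4) else cyl.n_bp - 1
    strand = "a" if corner in (1, 2) else "b"
    frac = bp / (cyl.n_bp - 1)
    pos = cyl.a_s + frac * (cyl.a_e - cyl.a_s)
    w = rotation_about_axis(cyl.axis, frac * cyl.total_twist()) @ cyl.t_s
    atoms = cyl.template.place_atoms(pos, cyl.axis, w)
    return atoms[f"{atom}_{strand}"]
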
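"""Base reference frames, base-pair/step parameters, glycosidic torsions
and hydrogen-bond detection.

The frame algebra follows the symmetrized hinge construction: the two base
(or pair) frames are rotated onto their common mid-plane normal by half the
inter-normal angle, the in-plane twist (Opening for pairs, Twist for steps)
is the signed angle between the aligned y axes, and the out-of-plane
rotation is reported through its components about the mean x and y axes
(Buckle/Propeller, Tilt/Roll).  The construction is exactly invertible,
which :mod:`pairscape.synthetic_data` exploits to rebuild coordinates with
prescribed parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

from . import constants as C
from .errors import (ConfigurationError, ContractError, FitError,
                     StructuralInputError)

__all__ = [
    "AtomRecord", "BaseFrame", "BasePairParams", "StepParams",
    "GlycosidicClass", "HydrogenBond", "fit_base_frame", "pair_frames",
    "build_pair_frames", "compute_step_params", "build_step_frame",
    "classify_glycosidic", "detect_hbonds", "dihedral", "wrap_angle",
    "rotation_about_axis", "kabsch",
]


# --------------------------------------------------------------------------
# domain types

@dataclass
class AtomRecord:
    """One atom: PDB-style name, element, position (A) and residue context."""

    name: str
    element: str
    position: np.ndarray
    residue_index: int
    residue_name: str
    chain_id: str = "A"

    def __post_init__(self):
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,) or not np.all(np.isfinite(self.position)):
            raise ContractError(f"atom {self.name}: position must be a finite 3-vector")
        self.residue_name = C.RESIDUE_ALIASES.get(self.residue_name,
                                                  self.residue_name)


@dataclass
class BaseFrame:
    """Right-handed orthonormal frame: origin plus axis rows (x, y, z)."""

    origin: np.ndarray
    axes: np.ndarray
    syn_transformed: bool = False

    def __post_init__(self):
        self.origin = np.asarray(self.origin, dtype=float)
        self.axes = np.asarray(self.axes, dtype=float)
        self.validate()

    def validate(self, tol: float = 1e-8) -> None:
        err = np.abs(self.axes @ self.axes.T - np.eye(3)).max()
        if err > tol:
            raise ContractError(f"frame axes not orthonormal (deviation {err:.2e})")
        if np.linalg.det(self.axes) < 0:
            raise ContractError("frame axes are left-handed")

    def to_lab(self, local: np.ndarray) -> np.ndarray:
        """Map frame-local coordinates to laboratory coordinates."""
        return np.asarray(local) @ self.axes + self.origin

    def to_local(self, lab: np.ndarray) -> np.ndarray:
        return (np.asarray(lab) - self.origin) @ self.axes.T

    def flipped(self) -> "BaseFrame":
        """Frame rotated 180 deg about its own x axis (anti-parallel pairing)."""
        ax = self.axes.copy()
        ax[1] *= -1.0
        ax[2] *= -1.0
        return BaseFrame(self.origin.copy(), ax, self.syn_transformed)


@dataclass
class BasePairParams:
    shear: float
    stretch: float
    stagger: float
    buckle: float
    propeller: float
    opening: float
    simple: bool = True

    def as_array(self) -> np.ndarray:
        return np.array([self.shear, self.stretch, self.stagger,
                         self.buckle, self.propeller, self.opening])


@dataclass
class StepParams:
    shift: float
    slide: float
    rise: float
    tilt: float
    roll: float
    twist: float

    def as_array(self) -> np.ndarray:
        return np.array([self.shift, self.slide, self.rise,
                         self.tilt, self.roll, self.twist])


@dataclass
class GlycosidicClass:
    chi: float
    label: str


@dataclass
class HydrogenBond:
    donor: AtomRecord
    hydrogen: AtomRecord | None
    acceptor: AtomRecord
    heavy_distance: float
    angle: float | None


# --------------------------------------------------------------------------
# small vector helpers

def wrap_angle(deg: float) -> float:
    """Wrap an angle in degrees into (-180, 180]."""
    w = np.remainder(deg, 360.0)
    if isinstance(w, np.ndarray):
        w[w > 180.0] -= 360.0
        return w
    return w - 360.0 if w > 180.0 else w


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n < 1e-12:
        raise FitError("cannot normalize a near-zero vector")
    return v / n


def rotation_about_axis(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    """Rotation matrix for a right-handed rotation about ``axis``."""
    a = _unit(np.asarray(axis, dtype=float))
    t = np.radians(angle_deg)
    K = np.array([[0.0, -a[2], a[1]],
                  [a[2], 0.0, -a[0]],
                  [-a[1], a[0], 0.0]])
    return np.eye(3) + np.sin(t) * K + (1.0 - np.cos(t)) * (K @ K)


def signed_angle(a: np.ndarray, b: np.ndarray, axis: np.ndarray) -> float:
    """Signed angle (deg) from ``a`` to ``b`` about ``axis``, in (-180, 180]."""
    n = _unit(np.asarray(axis, dtype=float))
    ap = a - (a @ n) * n
    bp = b - (b @ n) * n
    x = ap @ bp
    y = np.cross(ap, bp) @ n
    return float(np.degrees(np.arctan2(y, x)))


def dihedral(p0, p1, p2, p3) -> float:
    """IUPAC-signed torsion angle (deg) of four points, in (-180, 180]."""
    p0, p1, p2, p3 = (np.asarray(p, dtype=float) for p in (p0, p1, p2, p3))
    b0, b1, b2 = p0 - p1, p2 - p1, p3 - p2
    b1n = _unit(b1)
    v = b0 - (b0 @ b1n) * b1n
    w = b2 - (b2 @ b1n) * b1n
    if np.linalg.norm(v) < 1e-10 or np.linalg.norm(w) < 1e-10:
        raise FitError("dihedral undefined for collinear points")
    x = v @ w
    y = np.cross(b1n, v) @ w
    return float(np.degrees(np.arctan2(y, x)))


def kabsch(moving: np.ndarray, target: np.ndarray):
    """Least-squares rigid transform: returns (R, t) with R@moving_i + t ~ target_i.

    Raises :class:`FitError` when the point set is degenerate (collinear).
    """
    P = np.asarray(moving, dtype=float)
    Q = np.asarray(target, dtype=float)
    cp, cq = P.mean(axis=0), Q.mean(axis=0)
    H = (P - cp).T @ (Q - cq)
    U, S, Vt = np.linalg.svd(H)
    if S[1] < 1e-8 * max(S[0], 1.0):
        raise FitError("degenerate (collinear) coordinates in superposition")
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    return R, cq - R @ cp


# --------------------------------------------------------------------------
# frame fitting

def _residue_lookup(residue: Iterable[AtomRecord]) -> dict:
    return {a.name: a for a in residue}


def fit_base_frame(residue: Sequence[AtomRecord], base_type: str | None = None,
                   orientation: str = "anti") -> BaseFrame:
    """Fit the standard base reference frame to an observed residue.

    The embedded standard ring coordinates are superposed onto the observed
    ring heavy atoms.  For ``orientation="syn"`` the fitted frame is composed
    with a 180 deg rotation about its z axis so that the y axis again points
    toward the pairing partner, and the result is flagged.
    """
    atoms = list(residue)
    if base_type is None:
        base_type = atoms[0].residue_name
    base_type = C.RESIDUE_ALIASES.get(base_type, base_type)
    if base_type not in C.RING_ATOMS:
        raise StructuralInputError(f"unknown base type {base_type!r}")
    if orientation not in ("anti", "syn"):
        raise ConfigurationError(f"orientation must be anti or syn, got {orientation!r}")
    lookup = _residue_lookup(atoms)
    ring = C.RING_ATOMS[base_type]
    missing = [a for a in ring if a not in lookup]
    if missing:
        raise StructuralInputError(
            f"residue {base_type} is missing ring atom(s) {', '.join(missing)}")
    observed = np.array([lookup[a].position for a in ring])
    reference = C.standard_base_coords(base_type, ring)
    R, t = kabsch(reference, observed)
    axes = R.T
    if orientation == "syn":
        axes = axes.copy()
        axes[0] *= -1.0
        axes[1] *= -1.0
    return BaseFrame(origin=t, axes=axes, syn_transformed=(orientation == "syn"))


# --------------------------------------------------------------------------
# symmetrized hinge decomposition (shared by pair and step parameters)

def _decompose(axes1, o1, axes2, o2):
    """Relative rotation/translation of frame2 w.r.t. frame1.

    Returns (mean_axes, mean_origin, translation, twist, comp_x, comp_y)
    where translation is (o2 - o1) in the mean frame, twist is the signed
    angle (deg) from aligned y1 to aligned y2 about the mean normal, and
    (comp_x, comp_y) are the components (deg) of the inter-normal rotation
    about the mean x and y axes.
    """
    z1, z2 = axes1[2], axes2[2]
    cr = np.cross(z1, z2)
    s = np.linalg.norm(cr)
    cosg = float(np.clip(z1 @ z2, -1.0, 1.0))
    if cosg < -0.999:
        raise ContractError("frames are anti-aligned; parameters undefined")
    if s < 1e-13:
        gamma = 0.0
        f1p, f2p = axes1, axes2
        hinge = None
    else:
        hinge = cr / s
        gamma = np.degrees(np.arctan2(s, cosg))
        Q1 = rotation_about_axis(hinge, +gamma / 2.0)
        Q2 = rotation_about_axis(hinge, -gamma / 2.0)
        f1p = axes1 @ Q1.T
        f2p = axes2 @ Q2.T
    zm = _unit(f1p[2] + f2p[2])
    ym = _unit(f1p[1] + f2p[1])
    xm = np.cross(ym, zm)
    mean_axes = np.vstack([xm, ym, zm])
    twist = signed_angle(f1p[1], f2p[1], zm)
    if hinge is None:
        comp_x = comp_y = 0.0
    else:
        phi = np.radians(signed_angle(hinge, ym, zm))
        comp_x = gamma * np.sin(phi)
        comp_y = gamma * np.cos(phi)
    om = 0.5 * (o1 + o2)
    trans = mean_axes @ (o2 - o1)
    return mean_axes, om, trans, twist, comp_x, comp_y


def _compose(mean_axes, mean_origin, trans, twist, comp_x, comp_y):
    """Exact inverse of :func:`_decompose`."""
    xm, ym, zm = mean_axes
    y1p = rotation_about_axis(zm, -twist / 2.0) @ ym
    y2p = rotation_about_axis(zm, +twist / 2.0) @ ym
    f1p = np.vstack([np.cross(y1p, zm), y1p, zm])
    f2p = np.vstack([np.cross(y2p, zm), y2p, zm])
    gamma = float(np.hypot(comp_x, comp_y))
    if gamma > 1e-13:
        phi = np.degrees(np.arctan2(comp_x, comp_y))
        hinge = rotation_about_axis(zm, -phi) @ ym
        f1p = f1p @ rotation_about_axis(hinge, -gamma / 2.0).T
        f2p = f2p @ rotation_about_axis(hinge, +gamma / 2.0).T
    delta = mean_axes.T @ np.asarray(trans, dtype=float)
    o1 = mean_origin - 0.5 * delta
    o2 = mean_origin + 0.5 * delta
    return f1p, o1, f2p, o2


# --------------------------------------------------------------------------
# pair and step parameters

def pair_frames(frame_a: BaseFrame, frame_b: BaseFrame):
    """Mean pair frame and simple-scheme base-pair parameters.

    ``frame_b`` belongs to the complementary strand and is flipped about its
    own x axis before combination.  Shear/Stretch/Stagger are the components
    of (origin_b - origin_a) in the mean frame; Opening is the signed angle
    about the mean normal; Buckle/Propeller are the complementary
    decomposition of the residual inter-normal rotation.
    """
    frame_a.validate()
    frame_b.validate()
    fb = frame_b.flipped()
    mean_axes, om, trans, twist, comp_x, comp_y = _decompose(
        frame_a.axes, frame_a.origin, fb.axes, fb.origin)
    params = BasePairParams(
        shear=float(trans[0]), stretch=float(trans[1]), stagger=float(trans[2]),
        buckle=float(comp_x), propeller=float(comp_y), opening=float(twist),
        simple=True)
    mean = BaseFrame(om, mean_axes)
    return mean, params


def build_pair_frames(params: BasePairParams,
                      mean_frame: BaseFrame | None = None):
    """Inverse of :func:`pair_frames`: frames realizing the given parameters."""
    if mean_frame is None:
        mean_frame = BaseFrame(np.zeros(3), np.eye(3))
    f1, o1, f2f, o2 = _compose(
        mean_frame.axes, mean_frame.origin,
        np.array([params.shear, params.stretch, params.stagger]),
        params.opening, params.buckle, params.propeller)
    frame_a = BaseFrame(o1, f1)
    frame_b = BaseFrame(o2, f2f).flipped()     # un-flip (involution)
    return frame_a, frame_b


def compute_step_params(pair1_mean: BaseFrame, pair2_mean: BaseFrame):
    """Mid-step frame and step parameters between two consecutive pair frames."""
    pair1_mean.validate()
    pair2_mean.validate()
    mean_axes, om, trans, twist, comp_x, comp_y = _decompose(
        pair1_mean.axes, pair1_mean.origin, pair2_mean.axes, pair2_mean.origin)
    step = StepParams(shift=float(trans[0]), slide=float(trans[1]),
                      rise=float(trans[2]), tilt=float(comp_x),
                      roll=float(comp_y), twist=float(twist))
    return BaseFrame(om, mean_axes), step


def build_step_frame(pair1_mean: BaseFrame, step: StepParams) -> BaseFrame:
    """Frame of the next pair given the previous pair frame and step parameters."""
    # _compose places frames symmetrically about the mid-step frame; here the
    # mid-step frame is unknown, so solve for it: frame1 is fixed.
    trans = np.array([step.shift, step.slide, step.rise])
    f1p, o1, f2p, o2 = _compose(np.eye(3), np.zeros(3), trans,
                                step.twist, step.tilt, step.roll)
    # express frame2 relative to frame1 and transplant onto pair1_mean
    rel_axes = f2p @ f1p.T                     # rows of f2 in f1 coordinates
    rel_origin = (o2 - o1) @ f1p.T
    axes2 = rel_axes @ pair1_mean.axes
    origin2 = pair1_mean.origin + rel_origin @ pair1_mean.axes
    return BaseFrame(origin2, axes2)


# --------------------------------------------------------------------------
# glycosidic classification

def classify_glycosidic(residue: Sequence[AtomRecord]) -> GlycosidicClass:
    """chi torsion (O4'-C1'-N9-C4 / O4'-C1'-N1-C2) and anti/syn label.

    ``syn`` iff \\|chi\\| < 90 deg, else ``anti``.
    """
    atoms = list(residue)
    base_type = atoms[0].residue_name
    family = "purine" if base_type in C.PURINES else "pyrimidine"
    names = C.CHI_ATOMS[family]
    lookup = _residue_lookup(atoms)
    missing = [a for a in names if a not in lookup]
    if missing:
        raise StructuralInputError(
            f"residue {base_type} is missing atom(s) {', '.join(missing)} "
            f"required for the chi torsion")
    chi = dihedral(*(lookup[a].position for a in names))
    return GlycosidicClass(chi=chi, label="syn" if abs(chi) < 90.0 else "anti")


# --------------------------------------------------------------------------
# hydrogen bonds

def detect_hbonds(atoms: Sequence[AtomRecord],
                  donors: dict | None = None,
                  acceptors: dict | None = None,
                  distance_cutoff: float = 3.0,
                  angle_cutoff: float = 135.0) -> list[HydrogenBond]:
    """Donor--acceptor contacts between different residues.

    A bond requires heavy-atom distance <= ``distance_cutoff`` (A) and, when
    a covalent hydrogen of the donor is present in the coordinates, a
    donor-H...acceptor angle >= ``angle_cutoff`` (deg).  Without hydrogens
    the distance criterion alone applies.
    """
    if donors is None:
        donors = C.HB_DONORS
    if acceptors is None:
        acceptors = C.HB_ACCEPTORS
    if not donors or not acceptors:
        raise ConfigurationError("hydrogen-bond role tables must be non-empty")

    residues: dict[tuple, list[AtomRecord]] = {}
    for a in atoms:
        residues.setdefault((a.chain_id, a.residue_index), []).append(a)

    bonds: list[HydrogenBond] = []
    keys = list(residues)
    for rkey in keys:
        res = residues[rkey]
        rname = res[0].residue_name
        lookup = _residue_lookup(res)
        for dname in donors.get(rname, ()):
            if dname not in lookup:
                continue
            donor = lookup[dname]
            hydrogens = [lookup[h] for h in
                         C.DONOR_HYDROGENS.get((rname, dname), ())
                         if h in lookup]
            if not hydrogens:   # fall back: any H within covalent range
                hydrogens = [a for a in res if a.element == "H"
                             and np.linalg.norm(a.position - donor.position) < 1.15]
            for akey in keys:
                if akey == rkey:
                    continue
                ares = residues[akey]
                aname_res = ares[0].residue_name
                alook = _residue_lookup(ares)
                for aname in acceptors.get(aname_res, ()):
                    if aname not in alook:
                        continue
                    acc = alook[aname]
                    d = float(np.linalg.norm(acc.position - donor.position))
                    if d > distance_cutoff:
                        continue
                    if hydrogens:
                        best, best_ang = None, -1.0
                        for h in hydrogens:
                            v1 = donor.position - h.position
                            v2 = acc.position - h.position
                            cosv = (v1 @ v2) / (np.linalg.norm(v1) *
                                                np.linalg.norm(v2))
                            ang = float(np.degrees(np.arccos(np.clip(cosv, -1, 1))))
                            if ang > best_ang:
                                best, best_ang = h, ang
                        if best_ang < angle_cutoff:
                            continue
                        bonds.append(HydrogenBond(donor, best, acc, d, best_ang))
                    else:
                        bonds.append(HydrogenBond(donor, None, acc, d, None))
    return bonds
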
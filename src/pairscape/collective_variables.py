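"""Collective variables evaluated on structures and trajectory frames.

Selections use a compact residue:atom expression syntax, e.g. ``"7"`` (all
atoms of residue 7), ``"1-4,23-26:heavy"`` (heavy atoms of two residue
ranges), ``"7:N1"`` (one named atom).  Atom classes: ``heavy``, ``backbone``
(sugar-phosphate heavy atoms) or an explicit atom name.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import constants as C
from .errors import ConfigurationError, FitError, SelectionError
from .nucleic_geometry import (AtomRecord, dihedral, fit_base_frame, kabsch,
                               pair_frames, wrap_angle)

__all__ = [
    "CVDefinition", "CVSample", "select", "center_of_mass", "cv_bend_angle",
    "cv_rmsd_to_target", "cv_pseudo_dihedral", "cv_distance",
    "evaluate_cv", "evaluate_cv_series", "cv_opening_shear",
    "BEND_ANGLE_DEFAULT_SEGMENTS",
]

#: Three-segment defaults for the bending angle of a 13+13 nt duplex:
#: two arms and the central part, heavy atoms only.
BEND_ANGLE_DEFAULT_SEGMENTS = ("1-4,23-26:heavy", "5-9,18-22:heavy",
                               "10-17:heavy")

CV_KINDS = ("opening", "shear", "distance_n1n3", "distance_ring",
            "pseudo_dihedral_1", "pseudo_dihedral_2", "bend_angle",
            "rmsd_to_target", "distance")


@dataclass
class CVDefinition:
    name: str
    kind: str
    atom_selections: list = field(default_factory=list)
    target: list | None = None          # AtomRecord list for rmsd_to_target
    periodic: bool = False
    units: str = ""
    orientations: tuple = ("anti", "anti")

    def __post_init__(self):
        if self.kind not in CV_KINDS:
            raise ConfigurationError(f"unknown CV kind {self.kind!r}")
        if not self.units:
            self.units = ("deg" if self.kind in
                          ("opening", "pseudo_dihedral_1", "pseudo_dihedral_2",
                           "bend_angle") else "A")
        if self.kind in ("opening", "pseudo_dihedral_1", "pseudo_dihedral_2"):
            self.periodic = True


@dataclass
class CVSample:
    frame_index: int
    value: float
    instantaneous_force: float | None = None


# --------------------------------------------------------------------------
# selections

def _parse_ranges(expr: str):
    out = []
    for tok in expr.split(","):
        tok = tok.strip()
        if "-" in tok:
            lo, hi = tok.split("-")
            out.extend(range(int(lo), int(hi) + 1))
        else:
            out.append(int(tok))
    return set(out)


def select(atoms: list[AtomRecord], expr: str) -> list[AtomRecord]:
    """Resolve a residue[:atom] selection expression."""
    if ":" in expr:
        res_part, atom_part = expr.rsplit(":", 1)
    else:
        res_part, atom_part = expr, "all"
    residues = _parse_ranges(res_part)
    picked = []
    for a in atoms:
        if a.residue_index not in residues:
            continue
        if atom_part == "all":
            picked.append(a)
        elif atom_part == "heavy":
            if a.element != "H":
                picked.append(a)
        elif atom_part == "backbone":
            if a.name in C.BACKBONE_ATOMS:
                picked.append(a)
        elif a.name == atom_part:
            picked.append(a)
    if not picked:
        raise SelectionError(f"selection {expr!r} matched no atoms")
    return picked


def center_of_mass(atoms: list[AtomRecord],
                   exclude_hydrogens: bool = False) -> np.ndarray:
    """Mass-weighted mean position of a selection."""
    sel = [a for a in atoms if not (exclude_hydrogens and a.element == "H")]
    if not sel:
        raise SelectionError("empty selection after hydrogen exclusion")
    try:
        masses = np.array([C.ATOMIC_MASSES[a.element] for a in sel])
    except KeyError as exc:
        raise SelectionError(f"unknown element {exc}") from None
    pos = np.array([a.position for a in sel])
    return masses @ pos / masses.sum()


# --------------------------------------------------------------------------
# individual CVs

def cv_bend_angle(structure: list[AtomRecord],
                  segment_selections=BEND_ANGLE_DEFAULT_SEGMENTS) -> float:
    """Angle (deg) at the central-segment COM subtended by the two arm COMs."""
    if len(segment_selections) != 3:
        raise ConfigurationError("bend angle needs exactly three segments")
    coms = [center_of_mass(select(structure, s), exclude_hydrogens=True)
            for s in segment_selections]
    v1 = coms[0] - coms[1]
    v2 = coms[2] - coms[1]
    n1, n2 = np.linalg.norm(v1), np.linalg.norm(v2)
    if n1 < 1e-9 or n2 < 1e-9:
        raise FitError("coincident segment centers: bending angle undefined")
    cosv = np.clip(v1 @ v2 / (n1 * n2), -1.0, 1.0)
    return float(np.degrees(np.arccos(cosv)))


def _atom_key(a: AtomRecord):
    return (a.chain_id, a.residue_index, a.name)


def cv_rmsd_to_target(structure: list[AtomRecord], target: list[AtomRecord],
                      atom_selection: str | None = None) -> float:
    """Optimal-superposition (Kabsch, unweighted) RMSD over a selection.

    Default selection: sugar-phosphate backbone heavy atoms.  Atoms map by
    (chain, residue index, atom name).
    """
    sel_expr = atom_selection
    if sel_expr is None:
        lo = min(a.residue_index for a in structure)
        hi = max(a.residue_index for a in structure)
        sel_expr = f"{lo}-{hi}:backbone"
    sa = select(structure, sel_expr)
    ta = select(target, sel_expr)
    tmap = {_atom_key(a): a for a in ta}
    keys = [_atom_key(a) for a in sa]
    if len(sa) != len(ta) or any(k not in tmap for k in keys):
        raise SelectionError("selection does not map one-to-one onto the target")
    if len(sa) < 3:
        raise FitError("need at least 3 atoms for a superposition")
    P = np.array([a.position for a in sa])
    Q = np.array([tmap[k].position for k in keys])
    R, t = kabsch(P, Q)
    diff = (P @ R.T + t) - Q
    return float(np.sqrt((diff ** 2).sum(axis=1).mean()))


def cv_pseudo_dihedral(structure: list[AtomRecord], selections) -> float:
    """Signed dihedral (deg) of four selection COMs, in (-180, 180]."""
    if len(selections) != 4:
        raise ConfigurationError("pseudo-dihedral needs four selections")
    coms = [center_of_mass(select(structure, s), exclude_hydrogens=True)
            for s in selections]
    for i in range(3):
        if np.linalg.norm(coms[i + 1] - coms[i]) < 1e-9:
            raise FitError("consecutive coincident COMs: dihedral undefined")
    return dihedral(*coms)


def cv_distance(structure: list[AtomRecord], sel_a: str, sel_b: str) -> float:
    """Euclidean distance (A); point-point or COM-COM by selection size."""
    ga = select(structure, sel_a)
    gb = select(structure, sel_b)
    pa = ga[0].position if len(ga) == 1 else center_of_mass(ga)
    pb = gb[0].position if len(gb) == 1 else center_of_mass(gb)
    return float(np.linalg.norm(pa - pb))


def cv_opening_shear(structure: list[AtomRecord], sel_a: str, sel_b: str,
                     orientations=("anti", "anti")):
    """Simple (Opening, Shear) of the pair formed by two residues."""
    ra = select(structure, sel_a)
    rb = select(structure, sel_b)
    fa = fit_base_frame(ra, orientation=orientations[0])
    fb = fit_base_frame(rb, orientation=orientations[1])
    _, params = pair_frames(fa, fb)
    return params.opening, params.shear


# --------------------------------------------------------------------------
# dispatch

def evaluate_cv(structure: list[AtomRecord], cv: CVDefinition) -> float:
    """Evaluate one CV on one structure."""
    k = cv.kind
    if k == "opening":
        o, _ = cv_opening_shear(structure, *cv.atom_selections[:2],
                                orientations=cv.orientations)
        return wrap_angle(o)
    if k == "shear":
        _, s = cv_opening_shear(structure, *cv.atom_selections[:2],
                                orientations=cv.orientations)
        return s
    if k == "distance_n1n3":
        ra, rb = cv.atom_selections[:2]
        pur = select(structure, ra)[0]
        name_a = "N1" if pur.residue_name in C.PURINES else "N3"
        pyr = select(structure, rb)[0]
        name_b = "N3" if pyr.residue_name in C.PYRIMIDINES else "N1"
        return cv_distance(structure, f"{pur.residue_index}:{name_a}",
                           f"{pyr.residue_index}:{name_b}")
    if k == "distance_ring":
        sels = []
        for expr in cv.atom_selections[:2]:
            res = select(structure, expr)
            idx = res[0].residue_index
            sub = [a for a in res if a.name in
                   ("N1", "C2", "N3", "C4", "C5", "C6")]
            if not sub:
                raise SelectionError(f"no six-membered ring atoms in {expr!r}")
            sels.append(sub)
        return float(np.linalg.norm(center_of_mass(sels[0])
                                    - center_of_mass(sels[1])))
    if k == "distance":
        return cv_distance(structure, *cv.atom_selections[:2])
    if k in ("pseudo_dihedral_1", "pseudo_dihedral_2"):
        return wrap_angle(cv_pseudo_dihedral(structure, cv.atom_selections))
    if k == "bend_angle":
        sels = cv.atom_selections or BEND_ANGLE_DEFAULT_SEGMENTS
        return cv_bend_angle(structure, sels)
    if k == "rmsd_to_target":
        if cv.target is None:
            raise ConfigurationError(f"CV {cv.name!r} needs target coordinates")
        sel = cv.atom_selections[0] if cv.atom_selections else None
        return cv_rmsd_to_target(structure, cv.target, sel)
    raise ConfigurationError(f"unknown CV kind {k!r}")


def evaluate_cv_series(trajectory, cv: CVDefinition) -> list[CVSample]:
    """One sample per frame, order-preserving; per-frame errors are collected
    and re-raised together with their frame indices."""
    samples: list[CVSample] = []
    failures: list[tuple[int, str]] = []
    for i, frame in enumerate(trajectory):
        try:
            samples.append(CVSample(frame_index=i,
                                    value=evaluate_cv(frame, cv)))
        except Exception as exc:          # noqa: BLE001 - reported below
            failures.append((i, str(exc)))
    if failures:
        detail = "; ".join(f"frame {i}: {m}" for i, m in failures[:5])
        raise SelectionError(
            f"CV {cv.name!r} failed on {len(failures)} frame(s): {detail}")
    return samples
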
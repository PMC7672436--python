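"""Free-energy landscape analysis: minima, thermodynamic states, reduction
of 2D surfaces to 1D opening profiles, opening propensities, discrimination
gaps and harmonic bending stiffness."""

from __future__ import annotations

import heapq
import warnings
from dataclasses import dataclass, field

import numpy as np

from . import constants as C
from .errors import ContractError, MaskedValueError, SelectionError
from .free_energy.surface import FESurface
from .nucleic_geometry import kabsch, fit_base_frame, pair_frames
from .synthetic_data import central_pair_indices

__all__ = [
    "FEProfile", "ThermoState", "GapResult", "find_minima", "extract_state",
    "basin_map", "reduce_profile", "relative_opening", "propensity_at",
    "discrimination_gap", "fit_elastic_constant", "overlay_structures",
    "state_threshold",
]


def state_threshold(temperature: float = C.T_DEFAULT) -> float:
    """Membership threshold 0.5 R T (kcal/mol); 0.298 at 300 K."""
    return 0.5 * C.R_KCAL * temperature


# --------------------------------------------------------------------------
# domain types

@dataclass
class FEProfile:
    """1D free-energy profile with 3-sigma errors, referenced to min = 0."""

    axis_name: str
    units: str
    centers: np.ndarray
    value: np.ndarray
    stderr: np.ndarray
    mask: np.ndarray
    temperature: float = C.T_DEFAULT

    def __post_init__(self):
        for name in ("centers", "value", "stderr"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        self.mask = np.asarray(self.mask, dtype=bool)


@dataclass
class ThermoState:
    """A free-energy minimum and its 0.5RT member ensemble."""

    label: int
    bin_index: int
    location: tuple
    value: float                      # depth relative to the global minimum
    member_frames: list = field(default_factory=list)
    mean_params: object | None = None
    hbond_table: dict | None = None
    representative: list | None = None


@dataclass
class GapResult:
    canonical: float
    canonical_stderr: float
    mismatch: float
    mismatch_stderr: float
    gap: float
    gap_stderr: float
    delta_sigma: float


# --------------------------------------------------------------------------
# grid topology helpers

def _neighbors(spec):
    """List of neighbor flat indices per bin (8-neighborhood in 2D)."""
    shape = spec.nbins
    nb = spec.nbins_total
    out = [[] for _ in range(nb)]
    if spec.dims == 1:
        n = shape[0]
        for i in range(n):
            for di in (-1, 1):
                j = i + di
                if spec.periodic[0]:
                    j %= n
                elif not 0 <= j < n:
                    continue
                out[i].append(j)
        return out
    n0, n1 = shape
    for i in range(n0):
        for j in range(n1):
            for di in (-1, 0, 1):
                for dj in (-1, 0, 1):
                    if di == dj == 0:
                        continue
                    ii, jj = i + di, j + dj
                    if spec.periodic[0]:
                        ii %= n0
                    elif not 0 <= ii < n0:
                        continue
                    if spec.periodic[1]:
                        jj %= n1
                    elif not 0 <= jj < n1:
                        continue
                    out[i * n1 + j].append(ii * n1 + jj)
    return out


def _boundary_mask(spec):
    """True for bins on a non-periodic grid boundary."""
    b = np.zeros(spec.nbins, dtype=bool)
    for d in range(spec.dims):
        if spec.periodic[d]:
            continue
        sl = [slice(None)] * spec.dims
        sl[d] = 0
        b[tuple(sl)] = True
        sl[d] = -1
        b[tuple(sl)] = True
    return b.ravel()


def find_minima(surface: FESurface, min_depth: float = 0.5,
                include_boundary: bool = False) -> list[ThermoState]:
    """Local minima of a referenced surface, pruned by barrier persistence.

    A bin is a candidate when strictly lower than every unmasked neighbor;
    candidates separated from any deeper minimum by a barrier smaller than
    ``min_depth`` are pruned (minimax-path flood estimate).  Output is
    labeled 1..K in ascending free energy.
    """
    v = surface.value
    mask = surface.mask
    nbrs = _neighbors(surface.spec)
    boundary = _boundary_mask(surface.spec)
    cands = []
    for i in range(surface.spec.nbins_total):
        if mask[i] or (boundary[i] and not include_boundary):
            continue
        ns = [j for j in nbrs[i] if not mask[j]]
        # ties broken by index so a flat pair of bins yields one candidate
        if ns and all(v[i] < v[j] or (v[i] == v[j] and i < j) for j in ns):
            cands.append(i)
    cands.sort(key=lambda i: (v[i], i))
    kept = []
    cand_set = set(cands)
    for i in cands:
        deeper = {j for j in cand_set if v[j] < v[i]}
        if not deeper:
            kept.append(i)          # global minimum (or tied-lowest)
            continue
        barrier = _minimax_barrier(v, mask, nbrs, i, deeper)
        if barrier - v[i] >= min_depth:
            kept.append(i)
    centers = surface.spec.center_grid()
    return [ThermoState(label=k + 1, bin_index=i,
                        location=tuple(centers[i]), value=float(v[i]))
            for k, i in enumerate(kept)]


def _minimax_barrier(v, mask, nbrs, start, targets):
    """Lowest possible maximum value along any path from start to targets."""
    best = np.full(len(v), np.inf)
    best[start] = v[start]
    heap = [(v[start], start)]
    while heap:
        h, i = heapq.heappop(heap)
        if h > best[i]:
            continue
        if i in targets:
            return h
        for j in nbrs[i]:
            if mask[j]:
                continue
            nh = max(h, v[j])
            if nh < best[j]:
                best[j] = nh
                heapq.heappush(heap, (nh, j))
    return np.inf


def basin_map(surface: FESurface) -> np.ndarray:
    """Steepest-descent sink bin per grid bin (ties to the lowest index)."""
    v = surface.value
    mask = surface.mask
    nbrs = _neighbors(surface.spec)
    nb = surface.spec.nbins_total
    down = np.full(nb, -1, dtype=np.int64)
    for i in range(nb):
        if mask[i]:
            continue
        # ties descend to the lowest index, matching find_minima
        best = (v[i], i)
        for j in nbrs[i]:
            if mask[j]:
                continue
            if (v[j], j) < best:
                best = (v[j], j)
        down[i] = best[1]
    sink = down.copy()
    changed = True
    while changed:
        changed = False
        for i in range(nb):
            if sink[i] >= 0 and sink[sink[i]] >= 0 and sink[sink[i]] != sink[i]:
                sink[i] = sink[sink[i]]
                changed = True
    return sink


def extract_state(surface: FESurface, cv_values: np.ndarray,
                  minimum: ThermoState,
                  threshold: float | None = None,
                  trajectory: list | None = None) -> ThermoState:
    """Populate a state with member frames (and a representative structure).

    Members are frames whose bin lies in the minimum's steepest-descent basin
    with a free energy at most ``threshold`` (default 0.5RT at 300 K) above
    the minimum.  The representative is the arithmetic mean of the member
    coordinates after superposing every member onto the first one.
    """
    if threshold is None:
        threshold = state_threshold()
    vals = np.atleast_2d(np.asarray(cv_values, dtype=float))
    if vals.shape[0] == surface.spec.dims and vals.shape[1] != surface.spec.dims:
        vals = vals.T
    idx = surface.spec.flat_index(vals)
    sinks = basin_map(surface)
    members = []
    for f, b in enumerate(idx):
        if b < 0 or surface.mask[b]:
            continue
        if sinks[b] != minimum.bin_index:
            continue
        if surface.value[b] <= minimum.value + threshold:
            members.append(f)
    out = ThermoState(label=minimum.label, bin_index=minimum.bin_index,
                      location=minimum.location, value=minimum.value,
                      member_frames=members)
    if not members:
        warnings.warn(f"state {minimum.label}: no member frames", stacklevel=2)
        return out
    if trajectory is not None:
        out.representative = _average_structure([trajectory[f] for f in members])
    return out


def _average_structure(structures):
    ref = structures[0]
    ref_heavy = [a for a in ref if a.element != "H"]
    keys = [(a.chain_id, a.residue_index, a.name) for a in ref_heavy]
    Q = np.array([a.position for a in ref_heavy])
    acc = Q.copy()
    for s in structures[1:]:
        lookup = {(a.chain_id, a.residue_index, a.name): a.position for a in s}
        try:
            P = np.array([lookup[k] for k in keys])
        except KeyError as exc:
            raise SelectionError(f"member structure missing atom {exc}") from None
        R, t = kabsch(P, Q)
        acc += P @ R.T + t
    mean = acc / len(structures)
    from dataclasses import replace as _rep
    return [_rep(a, position=p) for a, p in zip(ref_heavy, mean)]


# --------------------------------------------------------------------------
# reduction and propensities

def reduce_profile(surface: FESurface, axis: int = 0,
                   temperature: float = C.T_DEFAULT) -> FEProfile:
    """Boltzmann-reduce a 2D surface to a 1D profile along ``axis``.

    dG_w(x) = -RT ln sum_y exp(-dG_r(x,y)/RT) dy with composite-trapezoid
    quadrature (log-sum-exp); 3-sigma errors propagate with squared Boltzmann
    weights.  Fully masked columns yield masked profile bins.
    """
    if surface.spec.dims != 2:
        raise ContractError("reduce_profile needs a 2D surface")
    rt = C.R_KCAL * temperature
    red = 1 - axis
    V = np.moveaxis(surface.value_grid(), axis, 0)       # (nx, ny)
    E = np.moveaxis(surface.stderr_grid(), axis, 0)
    M = np.moveaxis(surface.mask_grid(), axis, 0)
    nx, ny = V.shape
    dy = surface.spec.widths[red]
    full_w = np.full(ny, dy)
    if not surface.spec.periodic[red]:
        full_w[0] = full_w[-1] = 0.5 * dy
    value = np.empty(nx)
    stderr = np.empty(nx)
    mask = np.zeros(nx, dtype=bool)
    for i in range(nx):
        ok = ~M[i]
        if not ok.any():
            mask[i] = True
            value[i] = np.nan
            stderr[i] = np.nan
            continue
        w = full_w if ok.all() else np.where(ok, dy, 0.0)
        a = -V[i, ok] / rt + np.log(w[ok])
        amax = a.max()
        lse = amax + np.log(np.exp(a - amax).sum())
        value[i] = -rt * lse
        bw = np.exp(a - lse)                      # normalized Boltzmann weights
        stderr[i] = np.sqrt(np.sum(bw ** 2 * E[i, ok] ** 2))
    if mask.all():
        raise ContractError("every profile bin is masked")
    value = value - np.nanmin(value[~mask])
    dim = axis
    name = f"cv{dim}"
    return FEProfile(axis_name=name, units="deg" if surface.spec.periodic[dim]
                     else "", centers=surface.spec.centers(dim),
                     value=np.where(mask, np.nan, value), stderr=stderr,
                     mask=mask, temperature=temperature)


def profile_reference(profile: FEProfile) -> float:
    """Sub-bin location of the profile minimum (parabolic refinement).

    A parabola through the minimum bin and its two neighbors places the
    reference continuously, so downstream relative-axis evaluations do not
    inherit the bin discretization.
    """
    ok = np.flatnonzero(~profile.mask)
    i = int(ok[np.argmin(profile.value[ok])])
    x = profile.centers
    if 0 < i < len(x) - 1 and not profile.mask[i - 1] and not profile.mask[i + 1]:
        vm, v0, vp = profile.value[i - 1], profile.value[i], profile.value[i + 1]
        denom = vm - 2.0 * v0 + vp
        if denom > 0:
            delta = 0.5 * (vm - vp) / denom
            if abs(delta) <= 1.0:
                h = x[i + 1] - x[i]
                return float(x[i] + delta * h)
    return float(x[i])


def relative_opening(profile: FEProfile, reference: float) -> FEProfile:
    """Shift the axis so that 0 sits at the global-minimum opening."""
    lo, hi = profile.centers.min(), profile.centers.max()
    if not lo <= reference <= hi:
        raise ContractError(f"reference {reference} outside axis range")
    return FEProfile(axis_name=f"delta_{profile.axis_name}",
                     units=profile.units,
                     centers=profile.centers - reference,
                     value=profile.value.copy(), stderr=profile.stderr.copy(),
                     mask=profile.mask.copy(), temperature=profile.temperature)


def propensity_at(profile: FEProfile, delta_sigma: float = -60.0):
    """Linear interpolation of (value, stderr) at an axis position."""
    x = profile.centers
    if not x.min() <= delta_sigma <= x.max():
        raise MaskedValueError(f"evaluation point {delta_sigma} outside axis")
    j = int(np.searchsorted(x, delta_sigma))
    if j < len(x) and x[j] == delta_sigma:
        lo = hi = j
    else:
        lo, hi = j - 1, j
    if profile.mask[lo] or profile.mask[hi]:
        raise MaskedValueError("evaluation point lies in a masked region")
    if lo == hi:
        return float(profile.value[lo]), float(profile.stderr[lo])
    f = (delta_sigma - x[lo]) / (x[hi] - x[lo])
    v = (1 - f) * profile.value[lo] + f * profile.value[hi]
    e = (1 - f) * profile.stderr[lo] + f * profile.stderr[hi]
    return float(v), float(e)


def opening_propensity(profile: FEProfile, delta_sigma: float = -60.0):
    """Propensity at a relative-Opening offset from the profile minimum.

    Combines the sub-bin reference refinement with linear interpolation and
    propagates both the interpolated profile error and the uncertainty of
    the reference location (vertex of the 3-point parabola, treating the
    three bin errors as independent) through the local profile slope.
    """
    ref = profile_reference(profile)
    rel = relative_opening(profile, ref)
    value, err = propensity_at(rel, delta_sigma)
    x = rel.centers
    h = float(np.median(np.diff(x)))
    # local slope at the evaluation point
    v_lo, _ = propensity_at(rel, max(delta_sigma - h, x.min()))
    v_hi, _ = propensity_at(rel, min(delta_sigma + h, x.max()))
    slope = (v_hi - v_lo) / (min(delta_sigma + h, x.max())
                             - max(delta_sigma - h, x.min()))
    # uncertainty of the parabola vertex from the three bin errors
    ok = np.flatnonzero(~profile.mask)
    i = int(ok[np.argmin(profile.value[ok])])
    dref = 0.0
    if 0 < i < len(x) - 1:
        vm, v0, vp = (profile.value[i - 1], profile.value[i],
                      profile.value[i + 1])
        em, e0, ep = (profile.stderr[i - 1], profile.stderr[i],
                      profile.stderr[i + 1])
        D = vm - 2.0 * v0 + vp
        if D > 0:
            N = vm - vp
            gm = 0.5 * h * (1.0 / D - N / D ** 2)
            g0 = 0.5 * h * (2.0 * N / D ** 2)
            gp = 0.5 * h * (-1.0 / D - N / D ** 2)
            dref = min(np.sqrt((gm * em) ** 2 + (g0 * e0) ** 2
                               + (gp * ep) ** 2), h)
    total = float(np.sqrt(err ** 2 + (slope * dref) ** 2))
    return value, total


def discrimination_gap(canonical, mismatch,
                       delta_sigma: float = -60.0) -> GapResult:
    """Gap = canonical propensity - mismatch propensity, errors in quadrature.

    Each argument is a (value, stderr) pair at the same delta-Opening.
    """
    cv, ce = (float(canonical[0]), float(canonical[1]))
    mv, me = (float(mismatch[0]), float(mismatch[1]))
    return GapResult(canonical=cv, canonical_stderr=ce,
                     mismatch=mv, mismatch_stderr=me,
                     gap=cv - mv, gap_stderr=float(np.hypot(ce, me)),
                     delta_sigma=delta_sigma)


def fit_elastic_constant(profile: FEProfile,
                         fit_range: tuple = (130.0, 170.0)):
    """Weighted LS fit of dG = 0.5 k (alpha - alpha0)^2 over ``fit_range``.

    Returns (k, alpha0); emits a warning when the data are non-convex.
    """
    x = profile.centers
    sel = (~profile.mask) & (x >= fit_range[0]) & (x <= fit_range[1])
    if sel.sum() < 5:
        raise ContractError("need at least 5 unmasked bins in the fit range")
    xs, ys = x[sel], profile.value[sel]
    es = profile.stderr[sel]
    w = np.where(es > 0, 1.0 / np.maximum(es, 1e-12) ** 2, 1.0)
    if not np.all(es > 0):
        w = np.ones_like(xs)
    A = np.stack([xs ** 2, xs, np.ones_like(xs)], axis=1)
    W = np.sqrt(w)
    coef, *_ = np.linalg.lstsq(A * W[:, None], ys * W, rcond=None)
    a, b, _c = coef
    k = 2.0 * a
    if a <= 0:
        warnings.warn(f"non-convex bending data: fitted k = {k:.4g} <= 0 "
                      f"over {fit_range}", stacklevel=2)
        return float(k), float("nan")
    alpha0 = -b / (2.0 * a)
    return float(k), float(alpha0)


def overlay_structures(surface: FESurface, structures,
                       pair_residues: tuple | None = None,
                       orientations=("anti", "anti")) -> list[dict]:
    """Project structures onto an (Opening, Shear) surface.

    Per structure: simple parameters of the central pair and the surface
    value at that bin, with out-of-domain/masked flags.
    """
    out = []
    for s in structures:
        ia, ib = pair_residues if pair_residues else central_pair_indices(s)
        ra = [a for a in s if a.residue_index == ia]
        rb = [a for a in s if a.residue_index == ib]
        fa = fit_base_frame(ra, orientation=orientations[0])
        fb = fit_base_frame(rb, orientation=orientations[1])
        _, p = pair_frames(fa, fb)
        loc = np.array([[p.opening, p.shear]])
        b = int(surface.spec.flat_index(loc)[0])
        rec = {"opening": p.opening, "shear": p.shear,
               "in_domain": b >= 0, "masked": None, "value": None}
        if b >= 0:
            rec["masked"] = bool(surface.mask[b])
            if not rec["masked"]:
                rec["value"] = float(surface.value[b])
        out.append(rec)
    return out
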
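"""Synthetic inputs for the analysis chain: analytic model free-energy
surfaces, a seeded overdamped Langevin sampler with an ABF-like bias, noisy
gradient fields, and B-DNA duplex coordinates with prescribed base-pair and
step parameters.

Surface archetypes are qualitative stand-ins for landscapes with one deep
canonical basin versus several mismatch basins separated by a barrier along
Shear; they are not fitted to any simulation data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import constants as C
from . import _langevin
from .errors import ConfigurationError, ContractError, StructuralInputError
from .free_energy.grids import GridSpec, MeanForceGrid, accumulate, merge_walkers
from .nucleic_geometry import (AtomRecord, BaseFrame, BasePairParams,
                               StepParams, build_pair_frames, build_step_frame,
                               fit_base_frame, pair_frames)

__all__ = [
    "ModelSurface", "SamplerConfig", "WalkerResult", "make_surface",
    "sample_langevin", "noisy_gradient_field", "build_duplex",
    "build_base_pair", "perturb_central_pair", "central_pair_indices",
]


# --------------------------------------------------------------------------
# model surfaces

@dataclass
class ModelSurface:
    """Closed-form potential V (kcal/mol) with analytic gradient."""

    archetype: str
    ndim: int
    kind_code: int
    packed: np.ndarray
    basins: list
    mins: tuple
    maxs: tuple
    periodic: tuple

    def value(self, x) -> np.ndarray:
        x = np.atleast_2d(np.asarray(x, dtype=float))
        return self._value(x)

    def gradient(self, x) -> np.ndarray:
        x = np.atleast_2d(np.asarray(x, dtype=float))
        return self._grad(x)

    def _value(self, x):
        p = self.packed
        k = self.kind_code
        if k == _langevin.KIND_QUADRATIC:
            d = self.ndim
            return 0.5 * np.sum(p[:d] * (x - p[d:2 * d]) ** 2, axis=1)
        if k == _langevin.KIND_DOUBLE_WELL:
            h, w, ky = p[0], p[1], p[2]
            v = h * ((x[:, 0] / w) ** 2 - 1.0) ** 2
            if self.ndim > 1:
                v = v + 0.5 * ky * x[:, 1] ** 2
            return v
        if k == _langevin.KIND_CANONICAL:
            a, s, sig0, kS, S0, c, w = p[:7]
            u = (x[:, 0] - sig0) / s
            r = (x[:, 0] - sig0) / w
            v = a * (np.exp(-u) + u - 1.0) + c * (np.sqrt(1.0 + r ** 2) - 1.0)
            if self.ndim > 1:
                v = v + 0.5 * kS * (x[:, 1] - S0) ** 2
            return v
        if k == _langevin.KIND_MISMATCH:
            a, s, sig0, kc, ridge, rw = p[:6]
            u = (x[:, 0] - sig0) / s
            v = a * (np.exp(-u) + u - 1.0) + 0.5 * kc * x[:, 1] ** 2
            v = v + ridge * np.exp(-0.5 * (x[:, 1] / rw) ** 2)
            nw = int(p[6])
            for i in range(nw):
                o = 7 + 5 * i
                dx0 = (x[:, 0] - p[o]) / p[o + 3]
                dx1 = (x[:, 1] - p[o + 1]) / p[o + 4]
                v = v - p[o + 2] * np.exp(-0.5 * (dx0 ** 2 + dx1 ** 2))
            return v
        raise ConfigurationError(f"unknown surface code {k}")

    def _grad(self, x):
        g = np.empty_like(x)
        tmp = np.empty(self.ndim)
        for i in range(x.shape[0]):
            _langevin._grad(self.kind_code, self.packed, x[i], tmp)
            g[i] = tmp
        return g


def make_surface(archetype: str, **parameters) -> ModelSurface:
    """Construct a model surface.

    Archetypes: ``quadratic`` (k, x0, ndim), ``double_well`` (height, well,
    ky, ndim), ``canonical_like``, ``mismatch_like``, each over
    (Opening [deg], Shear [A]) for the 2D forms.
    """
    if archetype == "quadratic":
        ndim = int(parameters.pop("ndim", 2))
        k = np.broadcast_to(np.atleast_1d(
            np.asarray(parameters.pop("k", 1.0), dtype=float)), (ndim,))
        x0 = np.broadcast_to(np.atleast_1d(
            np.asarray(parameters.pop("x0", 0.0), dtype=float)), (ndim,))
        packed = np.concatenate([k, x0])
        basins = [(tuple(x0), 0.0)]
        lim = 4.0 / np.sqrt(np.min(k))
        surf = ModelSurface(archetype, ndim, _langevin.KIND_QUADRATIC, packed,
                            basins, tuple(x0 - lim), tuple(x0 + lim),
                            (False,) * ndim)
    elif archetype == "double_well":
        ndim = int(parameters.pop("ndim", 1))
        h = float(parameters.pop("height", 3.0))
        w = float(parameters.pop("well", 1.0))
        ky = float(parameters.pop("ky", 2.0))
        packed = np.array([h, w, ky])
        basins = [((-w, 0.0)[:ndim], 0.0), ((w, 0.0)[:ndim], 0.0)]
        lims = ((-2.2 * w, 2.2 * w), (-4.0, 4.0))
        surf = ModelSurface(archetype, ndim, _langevin.KIND_DOUBLE_WELL, packed,
                            basins, tuple(l[0] for l in lims[:ndim]),
                            tuple(l[1] for l in lims[:ndim]), (False,) * ndim)
    elif archetype == "canonical_like":
        a = float(parameters.pop("steepness", 0.55))
        s = float(parameters.pop("scale", 25.0))
        sig0 = float(parameters.pop("opening0", 0.0))
        kS = float(parameters.pop("shear_k", 2.0))
        S0 = float(parameters.pop("shear0", 0.0))
        core = float(parameters.pop("core", 1.0))
        core_width = float(parameters.pop("core_width", 10.0))
        packed = np.array([a, s, sig0, kS, S0, core, core_width])
        surf = ModelSurface(archetype, 2, _langevin.KIND_CANONICAL, packed,
                            [((sig0, S0), 0.0)],
                            (-100.0, -5.0), (100.0, 5.0), (False, False))
    elif archetype == "mismatch_like":
        a = float(parameters.pop("steepness", 0.9))
        s = float(parameters.pop("scale", 30.0))
        sig0 = float(parameters.pop("opening0", 0.0))
        kc = float(parameters.pop("shear_k", 0.35))
        # the default ridge height is calibrated so that the minimax barrier
        # between the global minimum and the positive-Shear basins is
        # 5.4 kcal/mol on a 201 x 101 reference grid
        ridge = float(parameters.pop("shear_ridge", 1.38))
        rw = float(parameters.pop("ridge_width", 0.8))
        wells = parameters.pop("wells", None)
        if wells is None:
            # (opening, shear, depth, width_opening, width_shear)
            wells = [(0.0, -1.9, 5.0, 11.0, 0.75),
                     (14.0, 1.9, 3.8, 10.0, 0.75),
                     (-24.0, 1.9, 3.0, 9.0, 0.75),
                     (38.0, -1.9, 2.6, 9.0, 0.75),
                     (-55.0, -1.9, 2.8, 8.0, 0.75)]
        packed = np.concatenate([[a, s, sig0, kc, ridge, rw, len(wells)],
                                 np.asarray(wells, dtype=float).ravel()])
        basins = [((w[0], w[1]), -w[2]) for w in wells]
        surf = ModelSurface(archetype, 2, _langevin.KIND_MISMATCH, packed,
                            basins, (-100.0, -5.0), (100.0, 5.0),
                            (False, False))
    else:
        raise ConfigurationError(f"unknown surface archetype {archetype!r}")
    if parameters:
        raise ConfigurationError(
            f"unknown parameters for {archetype}: {sorted(parameters)}")
    return surf


# --------------------------------------------------------------------------
# Langevin sampler

@dataclass
class SamplerConfig:
    temperature: float = 300.0
    step_size: float = 0.002
    n_steps: int = 200_000
    friction: float | tuple = 1.0      # scalar or per-CV-dimension
    seed: int = 0
    bias: str = "none"                  # none | abf_like
    n_walkers: int = 1
    n_ramp: int = 200
    x0: tuple | None = None
    force_noise_sd: float = 0.0
    force_noise_rho: float = 0.0
    bias_grid: GridSpec | None = None

    def __post_init__(self):
        if self.step_size <= 0:
            raise ConfigurationError("step size must be positive")
        if self.bias not in ("none", "abf_like"):
            raise ConfigurationError(f"unknown bias mode {self.bias!r}")


@dataclass
class WalkerResult:
    """Trajectory of one walker: CV values and instantaneous forces."""

    values: np.ndarray           # (n_steps, d)
    forces: np.ndarray           # (n_steps, d)
    walker: int
    seed: int


def _ar1_noise(rng, n, d, sd, rho):
    if sd == 0.0:
        return np.zeros((n, d))
    white = rng.standard_normal((n, d)) * sd
    if rho == 0.0:
        return white
    from scipy.signal import lfilter
    scaled = white * np.sqrt(1.0 - rho ** 2)
    out = lfilter([1.0], [1.0, -rho], scaled, axis=0)
    return out


def sample_langevin(surface: ModelSurface,
                    config: SamplerConfig) -> list[WalkerResult]:
    """Overdamped Langevin (Euler-Maruyama) sampling of a model surface.

    With ``bias="abf_like"`` the running per-bin mean of the instantaneous
    force is subtracted (linearly ramped over ``n_ramp`` samples per bin);
    the accumulators are shared across walkers.  The recorded forces are
    always the unbiased instantaneous forces.  Identical seeds give
    bit-identical output.
    """
    d = surface.ndim
    grid = config.bias_grid
    if grid is None:
        grid = GridSpec(surface.mins, surface.maxs,
                        (32,) * d, surface.periodic)
    if grid.dims != d:
        raise ConfigurationError("bias grid dimensionality mismatch")
    starts = None
    if config.x0 is not None:
        starts = [np.atleast_1d(np.asarray(config.x0, dtype=float))[:d]]
    else:
        # spread walkers over the surface's basins
        starts = [np.asarray(b[0][:d], dtype=float) for b in surface.basins]

    kT = C.R_KCAL * config.temperature
    friction = np.broadcast_to(np.atleast_1d(
        np.asarray(config.friction, dtype=float)), (d,))
    mobility = np.ascontiguousarray(1.0 / friction)
    bias_count = np.zeros(grid.nbins_total, dtype=np.int64)
    bias_sum = np.zeros(grid.nbins_total * d)
    mins = np.array(grid.mins)
    maxs = np.array(grid.maxs)
    nbins = np.array(grid.nbins, dtype=np.int64)
    periodic = np.array([1 if p else 0 for p in grid.periodic], dtype=np.int64)

    results = []
    for w in range(config.n_walkers):
        x0 = starts[w % len(starts)]
        rng = np.random.default_rng([config.seed, w, 0x5eed])
        xi = rng.standard_normal((config.n_steps, d))
        fnoise = _ar1_noise(rng, config.n_steps, d,
                            config.force_noise_sd, config.force_noise_rho)
        values = np.empty((config.n_steps, d))
        forces = np.empty((config.n_steps, d))
        rc = _langevin.run_langevin(
            surface.kind_code, surface.packed, x0, config.n_steps,
            config.step_size, mobility, kT, xi, fnoise,
            mins, maxs, nbins, periodic,
            1 if config.bias == "abf_like" else 0, float(config.n_ramp),
            bias_count, bias_sum, values, forces)
        if rc != 0:
            raise ContractError(
                "sampler diverged (moved more than a full domain span in one "
                f"step); reduce step_size={config.step_size}")
        results.append(WalkerResult(values, forces, w, config.seed))
    return results


def noisy_gradient_field(surface: ModelSurface, grid: GridSpec,
                         n_per_bin: int, noise_sd: float,
                         seed: int = 0) -> MeanForceGrid:
    """Mean-force grid from iid noisy samples of the analytic gradient."""
    if n_per_bin < 1:
        raise ConfigurationError("n_per_bin must be >= 1")
    rng = np.random.default_rng([seed, 0xf1e1d])
    centers = grid.center_grid()
    mean_force = -surface.gradient(centers)          # (nb, d)
    nb, d = mean_force.shape
    out = MeanForceGrid.empty(grid)
    out.count[:] = n_per_bin
    noise = rng.standard_normal((nb, d, n_per_bin)) * noise_sd
    samples = mean_force[:, :, None] + noise
    out.mean[:] = samples.mean(axis=2).T
    if n_per_bin > 1:
        out.m2[:] = (samples.var(axis=2, ddof=0) * n_per_bin).T
    return out


# --------------------------------------------------------------------------
# coordinate builders

def _default_steps(n: int, step: StepParams | None):
    if step is None:
        step = StepParams(0.0, 0.0, C.FIBER_RISE, 0.0, 0.0, C.FIBER_TWIST)
    return [step] * (n - 1)


def _place_residue(frame: BaseFrame, base_type: str, residue_index: int,
                   chain_id: str, include_hydrogens: bool,
                   syn: bool = False) -> list[AtomRecord]:
    place = frame
    if syn:
        ax = frame.axes.copy()
        ax[0] *= -1.0
        ax[1] *= -1.0
        place = BaseFrame(frame.origin.copy(), ax)
    atoms = []
    for name, element, xyz in C.STANDARD_NUCLEOTIDES[base_type]:
        if not include_hydrogens and element == "H":
            continue
        atoms.append(AtomRecord(name=name, element=element,
                                position=place.to_lab(np.asarray(xyz)),
                                residue_index=residue_index,
                                residue_name=base_type, chain_id=chain_id))
    return atoms


def build_base_pair(base_a: str, base_b: str,
                    params: BasePairParams | None = None,
                    orientations: tuple = ("anti", "anti"),
                    mean_frame: BaseFrame | None = None,
                    include_hydrogens: bool = False,
                    residue_indices: tuple = (1, 2)) -> list[AtomRecord]:
    """Two paired bases realizing the given simple base-pair parameters.

    For a syn orientation the placement frame is the syn-transform inverse of
    the constructed frame, so that measuring the pair with
    ``fit_base_frame(..., orientation="syn")`` recovers the parameters.
    """
    if params is None:
        params = BasePairParams(0, 0, 0, 0, 0, 0)
    ta = C.RESIDUE_ALIASES.get(base_a, base_a)
    tb = C.RESIDUE_ALIASES.get(base_b, base_b)
    fa, fb = build_pair_frames(params, mean_frame)
    atoms = _place_residue(fa, ta, residue_indices[0], "A", include_hydrogens,
                           syn=(orientations[0] == "syn"))
    atoms += _place_residue(fb, tb, residue_indices[1], "B", include_hydrogens,
                            syn=(orientations[1] == "syn"))
    return atoms


def build_duplex(sequence: str,
                 steps: StepParams | list | None = None,
                 pair_params: BasePairParams | list | None = None,
                 include_hydrogens: bool = False) -> list[AtomRecord]:
    """Ideal duplex coordinates for ``sequence`` (5'->3' of strand A).

    The complementary strand is generated automatically.  Residues are
    numbered 1..n on chain A (5'->3') and n+1..2n on chain B (5'->3' of the
    complementary strand), so pair i couples residues i and 2n-i+1.
    """
    sequence = sequence.upper()
    bad = set(sequence) - set("ACGT")
    if bad:
        raise StructuralInputError(f"invalid base code(s) {sorted(bad)}")
    n = len(sequence)
    if n < 2:
        raise StructuralInputError("duplex needs at least 2 base pairs")
    if steps is None or isinstance(steps, StepParams):
        steps = _default_steps(n, steps if isinstance(steps, StepParams) else None)
    if pair_params is None:
        pair_params = [BasePairParams(0, 0, 0, 0, 0, 0)] * n
    elif isinstance(pair_params, BasePairParams):
        pair_params = [pair_params] * n
    if len(steps) != n - 1 or len(pair_params) != n:
        raise ContractError("steps/pair_params lengths inconsistent with sequence")

    mean = BaseFrame(np.zeros(3), np.eye(3))
    chain_a: list[AtomRecord] = []
    chain_b_rev: list[list[AtomRecord]] = []
    for i, base in enumerate(sequence):
        ta = "D" + base
        tb = "D" + C.COMPLEMENT[base]
        fa, fb = build_pair_frames(pair_params[i], mean)
        chain_a += _place_residue(fa, ta, i + 1, "A", include_hydrogens)
        partner_index = 2 * n - i
        chain_b_rev.append(_place_residue(fb, tb, partner_index, "B",
                                          include_hydrogens))
        if i < n - 1:
            mean = build_step_frame(mean, steps[i])
    atoms = chain_a
    for res in reversed(chain_b_rev):
        atoms += res
    return atoms


def central_pair_indices(atoms: list[AtomRecord]) -> tuple[int, int]:
    """Residue indices of the central pair of a built duplex."""
    n2 = max(a.residue_index for a in atoms)
    if n2 % 2 != 0:
        raise StructuralInputError("expected an even residue count")
    n = n2 // 2
    i = (n + 1) // 2
    return i, 2 * n - i + 1


def perturb_central_pair(atoms: list[AtomRecord], opening: float,
                         shear: float) -> list[AtomRecord]:
    """Rebuild the central pair at the requested simple Opening/Shear.

    All other residues are untouched; the remaining four pair parameters are
    preserved from the current geometry.
    """
    ia, ib = central_pair_indices(atoms)
    res_a = [a for a in atoms if a.residue_index == ia]
    res_b = [a for a in atoms if a.residue_index == ib]
    if not res_a or not res_b:
        raise StructuralInputError("central pair residues not found")
    fa = fit_base_frame(res_a)
    fb = fit_base_frame(res_b)
    mean, params = pair_frames(fa, fb)
    new_params = replace(params, opening=float(opening), shear=float(shear))
    fa2, fb2 = build_pair_frames(new_params, mean)
    has_h = any(a.element == "H" for a in res_a)
    out = [a for a in atoms if a.residue_index not in (ia, ib)]
    out += _place_residue(fa2, res_a[0].residue_name, ia,
                          res_a[0].chain_id, has_h)
    out += _place_residue(fb2, res_b[0].residue_name, ib,
                          res_b[0].chain_id, has_h)
    out.sort(key=lambda a: (a.chain_id, a.residue_index))
    return out
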
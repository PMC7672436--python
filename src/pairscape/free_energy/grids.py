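"""CV grids and per-bin mean-force accumulation with walker merging."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .. import _langevin
from ..errors import ConfigurationError, ContractError

__all__ = ["GridSpec", "MeanForceGrid", "accumulate", "merge_walkers"]


@dataclass(frozen=True)
class GridSpec:
    """Regular 1D/2D binning of CV space."""

    mins: tuple
    maxs: tuple
    nbins: tuple
    periodic: tuple

    def __post_init__(self):
        mins = tuple(float(v) for v in np.atleast_1d(self.mins))
        maxs = tuple(float(v) for v in np.atleast_1d(self.maxs))
        nbins = tuple(int(v) for v in np.atleast_1d(self.nbins))
        periodic = tuple(bool(v) for v in np.atleast_1d(self.periodic))
        object.__setattr__(self, "mins", mins)
        object.__setattr__(self, "maxs", maxs)
        object.__setattr__(self, "nbins", nbins)
        object.__setattr__(self, "periodic", periodic)
        if not (len(mins) == len(maxs) == len(nbins) == len(periodic)):
            raise ConfigurationError("grid field lengths disagree")
        if self.dims not in (1, 2):
            raise ConfigurationError("only 1D and 2D grids are supported")
        for lo, hi, nb in zip(mins, maxs, nbins):
            if hi <= lo:
                raise ConfigurationError("grid max must exceed min")
            if nb < 2:
                raise ConfigurationError("grids need at least 2 bins per dim")

    @property
    def dims(self) -> int:
        return len(self.nbins)

    @property
    def nbins_total(self) -> int:
        return int(np.prod(self.nbins))

    @property
    def widths(self) -> np.ndarray:
        return (np.array(self.maxs) - np.array(self.mins)) / np.array(self.nbins)

    def centers(self, dim: int) -> np.ndarray:
        w = self.widths[dim]
        return self.mins[dim] + w * (np.arange(self.nbins[dim]) + 0.5)

    def center_grid(self) -> np.ndarray:
        """(nbins_total, dims) array of bin centers, C-order flattened."""
        axes = [self.centers(d) for d in range(self.dims)]
        mesh = np.meshgrid(*axes, indexing="ij")
        return np.stack([m.ravel() for m in mesh], axis=-1)

    def wrap(self, values: np.ndarray) -> np.ndarray:
        """Wrap periodic dimensions into [min, max)."""
        v = np.array(values, dtype=float)
        for d in range(self.dims):
            if self.periodic[d]:
                span = self.maxs[d] - self.mins[d]
                v[..., d] = np.remainder(v[..., d] - self.mins[d], span) + self.mins[d]
        return v

    def flat_index(self, values: np.ndarray) -> np.ndarray:
        """Flat bin index per sample; -1 for out-of-range non-periodic samples."""
        v = self.wrap(np.atleast_2d(np.asarray(values, dtype=float)))
        idx = np.zeros(v.shape[0], dtype=np.int64)
        valid = np.ones(v.shape[0], dtype=bool)
        for d in range(self.dims):
            b = np.floor((v[:, d] - self.mins[d]) / self.widths[d]).astype(np.int64)
            on_edge = v[:, d] == self.maxs[d]
            b[on_edge] = self.nbins[d] - 1
            valid &= (b >= 0) & (b < self.nbins[d])
            idx = idx * self.nbins[d] + np.clip(b, 0, self.nbins[d] - 1)
        idx[~valid] = -1
        return idx


@dataclass
class MeanForceGrid:
    """Per-bin running mean/variance/count of instantaneous forces."""

    spec: GridSpec
    count: np.ndarray           # (nbins_total,)
    mean: np.ndarray            # (dims, nbins_total)
    m2: np.ndarray              # (dims, nbins_total) sum of squared deviations
    value_mean: np.ndarray | None = None   # per-bin sample centroids
    g: np.ndarray | None = None  # per-bin statistical inefficiency
    n_out_of_range: int = 0

    @classmethod
    def empty(cls, spec: GridSpec) -> "MeanForceGrid":
        nb, d = spec.nbins_total, spec.dims
        return cls(spec, np.zeros(nb, dtype=np.int64),
                   np.zeros((d, nb)), np.zeros((d, nb)))

    def centroids(self) -> np.ndarray:
        """Per-bin observation locations: sample centroids where available,
        bin centers elsewhere."""
        centers = self.spec.center_grid().T
        if self.value_mean is None:
            return centers
        return np.where(self.count > 0, self.value_mean, centers)

    @property
    def variance(self) -> np.ndarray:
        """Per-bin sample variance of the force (ddof=1); zero where n < 2."""
        with np.errstate(invalid="ignore", divide="ignore"):
            v = self.m2 / np.maximum(self.count - 1, 1)
        v[:, self.count < 2] = 0.0
        return np.maximum(v, 0.0)

    @property
    def n_effective(self) -> np.ndarray:
        g = np.ones_like(self.count, dtype=float) if self.g is None else self.g
        return self.count / np.maximum(g, 1.0)

    def sem2(self) -> np.ndarray:
        """Variance of the per-bin mean force, inflated by inefficiency."""
        g = np.ones_like(self.count, dtype=float) if self.g is None else self.g
        with np.errstate(invalid="ignore", divide="ignore"):
            s = self.variance * g / np.maximum(self.count, 1)
        s[:, self.count < 2] = 0.0
        return s


def accumulate(values: np.ndarray, forces: np.ndarray,
               spec: GridSpec) -> MeanForceGrid:
    """Bin (value, force) samples into a mean-force grid (Welford one-pass).

    ``values``/``forces`` have shape (n,) for 1D grids or (n, dims).
    Out-of-range samples on non-periodic dimensions are counted in
    ``n_out_of_range`` and not binned.
    """
    values = np.asarray(values, dtype=float)
    forces = np.asarray(forces, dtype=float)
    if values.ndim == 1:
        values = values[:, None]
    if forces.ndim == 1:
        forces = forces[:, None]
    if values.shape != forces.shape or values.shape[1] != spec.dims:
        raise ContractError("values/forces shape mismatch with grid dims")
    grid = MeanForceGrid.empty(spec)
    grid.value_mean = np.zeros((spec.dims, spec.nbins_total))
    if len(values) == 0:
        return grid
    idx = spec.flat_index(values)
    _langevin.welford_accumulate(idx, np.ascontiguousarray(values),
                                 np.ascontiguousarray(forces),
                                 grid.count, grid.value_mean,
                                 grid.mean, grid.m2)
    grid.n_out_of_range = int(np.sum(idx < 0))
    return grid


def merge_walkers(grids: list[MeanForceGrid]) -> MeanForceGrid:
    """Pool mean-force grids (Chan-Golub-LeVeque pooled moments)."""
    if not grids:
        raise ContractError("nothing to merge")
    spec = grids[0].spec
    for g in grids[1:]:
        if g.spec != spec:
            raise ContractError("cannot merge grids with different specs")
    out = MeanForceGrid.empty(spec)
    if all(g.value_mean is not None for g in grids):
        out.value_mean = np.zeros((spec.dims, spec.nbins_total))
    for g in grids:
        na = out.count.astype(float)
        nb = g.count.astype(float)
        n = na + nb
        with np.errstate(invalid="ignore", divide="ignore"):
            delta = g.mean - out.mean
            w = np.where(n > 0, nb / np.maximum(n, 1), 0.0)
            mean = out.mean + delta * w
            m2 = out.m2 + g.m2 + delta ** 2 * (na * nb) / np.maximum(n, 1)
            if out.value_mean is not None:
                vmean = out.value_mean + (g.value_mean - out.value_mean) * w
                out.value_mean = np.where(n > 0, vmean, 0.0)
        out.mean = np.where(n > 0, mean, 0.0)
        out.m2 = np.where(n > 0, m2, 0.0)
        out.count = out.count + g.count
        out.n_out_of_range += g.n_out_of_range
    return out
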
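"""Free-energy surfaces referenced to their global minimum."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grids import GridSpec
from ..errors import ContractError

__all__ = ["FESurface", "reference_to_min"]


@dataclass
class FESurface:
    """Free energy (kcal/mol) and 3-sigma standard error per grid bin.

    ``mask`` flags insufficiently sampled bins (True = masked/invalid).
    Values are referenced so the minimum over unmasked bins is zero.
    """

    spec: GridSpec
    value: np.ndarray
    stderr: np.ndarray
    mask: np.ndarray

    def __post_init__(self):
        nb = self.spec.nbins_total
        self.value = np.asarray(self.value, dtype=float).ravel()
        self.stderr = np.asarray(self.stderr, dtype=float).ravel()
        self.mask = np.asarray(self.mask, dtype=bool).ravel()
        if not (self.value.size == self.stderr.size == self.mask.size == nb):
            raise ContractError("surface arrays inconsistent with grid size")

    def value_grid(self) -> np.ndarray:
        return self.value.reshape(self.spec.nbins)

    def stderr_grid(self) -> np.ndarray:
        return self.stderr.reshape(self.spec.nbins)

    def mask_grid(self) -> np.ndarray:
        return self.mask.reshape(self.spec.nbins)


def reference_to_min(surface: FESurface) -> FESurface:
    """Subtract the minimum over unmasked bins (idempotent)."""
    if surface.mask.all():
        raise ContractError("surface is fully masked; no reference minimum")
    ref = surface.value[~surface.mask].min()
    return FESurface(surface.spec, surface.value - ref,
                     surface.stderr.copy(), surface.mask.copy())
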
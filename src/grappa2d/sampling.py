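"""Retrospective 2D undersampling with a centred autocalibration block.

Undersampling acts only on the two phase-encoding axes (``k_y``, ``k_z``);
the readout axis is always fully sampled.  The acquired set is the union of
a regular lattice (every ``R_y``-th / ``R_z``-th line, anchored so that a
lattice point coincides with the DC sample at index ``N // 2``) and a
centred, fully sampled ACS block used for weight calibration.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .containers import MultiCoilKSpace

__all__ = [
    "SamplingScheme",
    "SamplingMask",
    "make_mask",
    "lattice_mask_2d",
    "apply_mask",
    "extract_acs",
    "finalize_kspace",
]


@dataclass(frozen=True)
class SamplingScheme:
    """Acceleration factors, ACS extents and the k-space grid they act on."""

    R_y: int
    R_z: int
    acs_y: int
    acs_z: int
    grid_shape: tuple[int, int, int]

    def __post_init__(self) -> None:
        _, N_y, N_z = self.grid_shape
        if self.R_y < 1 or self.R_z < 1:
            raise ValueError("acceleration factors must be >= 1")
        if not (0 <= self.acs_y <= N_y and 0 <= self.acs_z <= N_z):
            raise ValueError(
                f"ACS extents ({self.acs_y}, {self.acs_z}) exceed the "
                f"phase-encoding grid ({N_y}, {N_z})")

    @property
    def dc_index(self) -> tuple[int, int]:
        _, N_y, N_z = self.grid_shape
        return N_y // 2, N_z // 2

    def acs_slices(self) -> tuple[slice, slice]:
        cy, cz = self.dc_index
        y0 = cy - self.acs_y // 2
        z0 = cz - self.acs_z // 2
        return slice(y0, y0 + self.acs_y), slice(z0, z0 + self.acs_z)


@dataclass
class SamplingMask:
    """Boolean acquisition mask; True marks acquired samples."""

    mask: np.ndarray  # (N_x, N_y, N_z) bool
    scheme: SamplingScheme

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != tuple(self.scheme.grid_shape):
            raise ValueError("mask shape does not match scheme grid")

    @property
    def n_acquired(self) -> int:
        return int(self.mask.sum())


def lattice_mask_2d(scheme: SamplingScheme) -> np.ndarray:
    """(N_y, N_z) boolean mask of the regular lattice alone (no ACS)."""
    _, N_y, N_z = scheme.grid_shape
    cy, cz = scheme.dc_index
    on_y = (np.arange(N_y) - cy) % scheme.R_y == 0
    on_z = (np.arange(N_z) - cz) % scheme.R_z == 0
    return on_y[:, None] & on_z[None, :]


def make_mask(scheme: SamplingScheme) -> SamplingMask:
    """Union of the DC-anchored lattice and the centred ACS block."""
    N_x, _, _ = scheme.grid_shape
    plane = lattice_mask_2d(scheme).copy()
    ys, zs = scheme.acs_slices()
    plane[ys, zs] = True
    mask3 = np.broadcast_to(plane[None, :, :], scheme.grid_shape).copy()
    return SamplingMask(mask3, scheme)


def apply_mask(kspace: MultiCoilKSpace, mask: SamplingMask) -> MultiCoilKSpace:
    """Zero unacquired samples and attach the mask to the result."""
    if kspace.grid_shape != mask.mask.shape:
        raise ValueError("k-space and mask shapes do not match")
    data = np.where(mask.mask[None], kspace.data, 0.0)
    return replace(kspace, data=data, mask=mask)


def extract_acs(kspace: MultiCoilKSpace, scheme: SamplingScheme) -> MultiCoilKSpace:
    """The centred ``acs_y x acs_z`` (full-readout) calibration sub-volume."""
    if scheme.acs_y == 0 or scheme.acs_z == 0:
        raise ValueError("empty ACS block: calibration impossible")
    if kspace.grid_shape[1:] != tuple(scheme.grid_shape[1:]):
        raise ValueError("k-space phase-encoding grid does not match scheme")
    ys, zs = scheme.acs_slices()
    if kspace.mask is not None and not kspace.mask.mask[:, ys, zs].all():
        raise ValueError("ACS region is not fully sampled in the input")
    return MultiCoilKSpace(kspace.data[:, :, ys, zs].copy(), kspace.deltas)


def finalize_kspace(reconstructed: MultiCoilKSpace, original: MultiCoilKSpace,
                    mask: SamplingMask, include_acs: bool = True) -> MultiCoilKSpace:
    """Overwrite estimates with originally acquired samples.

    With ``include_acs`` every acquired sample (lattice and ACS block) is
    restored from ``original``; without it only the lattice samples are, so
    ACS-only positions keep their GRAPPA estimates and the output reflects
    kernel performance alone.
    """
    if reconstructed.grid_shape != original.grid_shape:
        raise ValueError("reconstructed and original shapes do not match")
    if include_acs:
        keep = mask.mask
    else:
        keep = np.broadcast_to(lattice_mask_2d(mask.scheme)[None], mask.mask.shape)
    data = np.where(keep[None], original.data, reconstructed.data)
    return replace(reconstructed, data=data, mask=mask)
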
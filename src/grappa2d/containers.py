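"""Shared in-memory containers for multi-coil k-space data."""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import TYPE_CHECKING, Optional

import numpy as np

if TYPE_CHECKING:  # pragma: no cover
    from .sampling import SamplingMask

__all__ = ["MultiCoilKSpace"]


@dataclass
class MultiCoilKSpace:
    """A J-channel 3D grid of complex k-space samples.

    ``data`` has shape ``(J, N_x, N_y, N_z)`` with the readout along axis 1
    and the two phase-encoding axes along axes 2 and 3.  Spectra are stored
    centred: the DC sample sits at index ``N // 2`` along each axis.
    """

    data: np.ndarray
    deltas: tuple[float, float, float] = (1.0, 1.0, 1.0)
    mask: Optional["SamplingMask"] = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 4:
            raise ValueError(f"expected (J, N_x, N_y, N_z) array, got shape {self.data.shape}")
        if not np.iscomplexobj(self.data):
            self.data = self.data.astype(np.complex128)
        if not np.all(np.isfinite(self.data)):
            raise ValueError("k-space contains non-finite values")

    @property
    def J(self) -> int:
        return self.data.shape[0]

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.data.shape[1:]

    def copy(self) -> "MultiCoilKSpace":
        return replace(self, data=self.data.copy())
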
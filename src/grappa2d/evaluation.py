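"""Image-domain evaluation: channel images, coil combination and nRMSE.

Reconstruction quality is quantified by the normalised root-mean-square
error between complex reference and reconstructed channel images,

    nRMSE = sqrt( sum_region |I_full - I_recon|^2 / sum_region |I_full|^2 ),

computed per channel and averaged over channels.  Complex-valued
differences are used throughout, since magnitude subtraction can cancel
residual aliasing.  The error is evaluated both over the whole volume and
over an "undersampled edge" region: a Laplacian-of-Gaussian edge mask of
the combined reference image, decimated along the two phase-encoding axes
by the acceleration factors.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import ndimage

from .containers import MultiCoilKSpace
from .engine import reconstruct
from .sampling import SamplingScheme, apply_mask, make_mask

__all__ = [
    "EdgeMask",
    "NRMSEReport",
    "kspace_to_images",
    "images_to_kspace",
    "combine_rss",
    "nrmse",
    "edge_mask",
    "evaluate_algorithms",
    "plot_report",
]


def kspace_to_images(kspace: MultiCoilKSpace) -> np.ndarray:
    """Per-channel centred inverse FFT (unitary), DC at index N//2."""
    axes = (1, 2, 3)
    return np.fft.fftshift(
        np.fft.ifftn(np.fft.ifftshift(kspace.data, axes=axes), axes=axes, norm="ortho"),
        axes=axes)


def images_to_kspace(images: np.ndarray,
                     deltas: tuple[float, float, float] = (1.0, 1.0, 1.0)) -> MultiCoilKSpace:
    """Inverse of :func:`kspace_to_images`."""
    axes = (1, 2, 3)
    data = np.fft.fftshift(
        np.fft.fftn(np.fft.ifftshift(images, axes=axes), axes=axes, norm="ortho"),
        axes=axes)
    return MultiCoilKSpace(data, deltas)


def combine_rss(images: np.ndarray) -> np.ndarray:
    """Root-sum-of-squares coil combination over the channel axis."""
    images = np.asarray(images)
    if images.ndim != 4:
        raise ValueError("expected (J, N_x, N_y, N_z) channel images")
    return np.sqrt((np.abs(images) ** 2).sum(axis=0))


@dataclass
class EdgeMask:
    """Boolean voxel set of (decimated) image edges."""

    mask: np.ndarray
    sigma: float
    threshold: float

    @property
    def M(self) -> int:
        return int(self.mask.sum())


def nrmse(full: np.ndarray, recon: np.ndarray,
          region: EdgeMask | np.ndarray | None = None) -> tuple[np.ndarray, float]:
    """Per-channel nRMSE over a region (whole image by default) and its mean."""
    full = np.asarray(full)
    recon = np.asarray(recon)
    if full.shape != recon.shape:
        raise ValueError("reference and reconstruction shapes do not match")
    if region is None:
        sel = np.ones(full.shape[1:], dtype=bool)
    else:
        sel = region.mask if isinstance(region, EdgeMask) else np.asarray(region, dtype=bool)
    f = full[:, sel]
    r = recon[:, sel]
    denom = (np.abs(f) ** 2).sum(axis=1)
    if np.any(denom == 0):
        raise ValueError("reference image is zero on the evaluation region")
    values = np.sqrt((np.abs(f - r) ** 2).sum(axis=1) / denom)
    return values, float(values.mean())


def edge_mask(reference: np.ndarray, sigma: float = 2.0, threshold: float = 0.1,
              scheme: SamplingScheme | None = None) -> EdgeMask:
    """Laplacian-of-Gaussian edge voxels of a combined reference image.

    Voxels whose LoG-response magnitude exceeds ``threshold`` times the
    maximum response form the edge set; when a scheme is given the set is
    decimated along the two phase-encoding axes, keeping every ``R_y``-th /
    ``R_z``-th line through the DC-anchored lattice.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    if not 0 < threshold < 1:
        raise ValueError("threshold must lie in (0, 1)")
    reference = np.asarray(reference, dtype=float)
    response = np.abs(ndimage.gaussian_laplace(reference, sigma))
    peak = response.max()
    # a structureless (constant) image yields a flat response: the discrete
    # LoG kernel's weights do not sum exactly to zero, so test contrast
    # rather than magnitude
    if peak == 0 or response.max() - response.min() <= 1e-9 * peak:
        mask = np.zeros_like(response, dtype=bool)
    else:
        mask = response > threshold * peak
    if scheme is not None:
        _, N_y, N_z = scheme.grid_shape
        cy, cz = scheme.dc_index
        keep_y = (np.arange(N_y) - cy) % scheme.R_y == 0
        keep_z = (np.arange(N_z) - cz) % scheme.R_z == 0
        mask = mask & keep_y[None, :, None] & keep_z[None, None, :]
    return EdgeMask(mask, sigma, threshold)


@dataclass
class NRMSEReport:
    """Structured comparison entries, one per (algorithm, n_x, scheme)."""

    entries: list[dict] = field(default_factory=list)

    def add(self, **kwargs) -> None:
        self.entries.append(kwargs)

    def get(self, **filters) -> list[dict]:
        return [e for e in self.entries
                if all(e.get(k) == v for k, v in filters.items())]

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.entries, fh, indent=2)

    def to_csv(self, path) -> None:
        if not self.entries:
            raise ValueError("empty report")
        keys = list(self.entries[0])
        with open(path, "w", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=keys)
            writer.writeheader()
            writer.writerows(self.entries)


def evaluate_algorithms(full_kspace: MultiCoilKSpace,
                        schemes: Sequence[SamplingScheme],
                        algorithms: Iterable[str] = ("LK", "EX", "SK", "BK"),
                        n_x_values: Iterable[int] = (1,),
                        type_index: int = 4,
                        sigma: float = 2.0, threshold: float = 0.1,
                        ridge: float = 0.0) -> NRMSEReport:
    """Reconstruct every (scheme x algorithm x kernel size) combination and
    score it against the fully sampled reference.

    Reference lines are excluded from the final k-space (``include_acs =
    False``) so the scores reflect kernel performance alone.
    """
    ref_images = kspace_to_images(full_kspace)
    rss = combine_rss(ref_images)
    report = NRMSEReport()
    for scheme in schemes:
        mask = make_mask(scheme)
        under = apply_mask(full_kspace, mask)
        edges = edge_mask(rss, sigma=sigma, threshold=threshold, scheme=scheme)
        for alg in algorithms:
            for n_x in n_x_values:
                recon = reconstruct(under, alg, n_x=n_x, type_index=type_index,
                                    include_acs=False, ridge=ridge)
                rec_images = kspace_to_images(recon)
                _, mean_full = nrmse(ref_images, rec_images)
                _, mean_edges = nrmse(ref_images, rec_images, edges)
                report.add(algorithm=alg, n_x=n_x, R_y=scheme.R_y, R_z=scheme.R_z,
                           acs_y=scheme.acs_y, acs_z=scheme.acs_z,
                           nrmse_full=mean_full, nrmse_edges=mean_edges)
    return report


def plot_report(report: NRMSEReport, metric: str = "nrmse_full", ax=None):
    """Grouped bar chart of nRMSE by algorithm, ACS size and kernel size."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(8, 4))
    labels = [f"{e['algorithm']} nx={e['n_x']} ACS={e['acs_y']}x{e['acs_z']}"
              for e in report.entries]
    ax.bar(range(len(labels)), [e[metric] for e in report.entries])
    ax.set_xticks(range(len(labels)))
    ax.set_xticklabels(labels, rotation=75, fontsize=7)
    ax.set_ylabel(metric)
    return ax
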
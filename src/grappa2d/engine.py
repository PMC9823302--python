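"""GRAPPA weight calibration and k-space synthesis.

Calibration gathers, at every autocalibration anchor where a kernel's full
footprint fits, the source samples of all channels into a row of ``S_src``
and the target samples into a row of ``S_tgt``, then solves the linear
least-squares problem ``S_src W = S_tgt``.  Synthesis slides the fitted
weights across the acquired lattice: for every block anchor the source
samples are gathered (periodically, or zero-padded, at the grid border)
and multiplied by ``W`` to estimate the missing samples.

Column ordering everywhere is source-offset-major, channel-minor, with the
offset order fixed by the geometry's sorted offset list; calibration and
synthesis share this contract bit-exactly.

The high-level interface is :class:`GrappaReconstructor`, a scikit-learn
style estimator (``fit`` = calibration on the ACS of a masked k-space,
``transform`` = synthesis + restoration of acquired samples).  The
:func:`reconstruct` function is a thin wrapper over it.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import scipy.linalg
from sklearn.base import BaseEstimator, TransformerMixin

from .containers import MultiCoilKSpace
from .kernels import ALGORITHMS, BlockSpec, KernelGeometry, kernels_for_algorithm
from .sampling import SamplingMask, SamplingScheme, extract_acs, finalize_kspace, make_mask

__all__ = [
    "CalibrationSystem",
    "WeightSet",
    "build_calibration_system",
    "solve_weights",
    "synthesize",
    "reconstruct",
    "GrappaReconstructor",
]

logger = logging.getLogger(__name__)


@dataclass
class CalibrationSystem:
    """Gathered source/target matrices for one kernel geometry."""

    S_src: np.ndarray  # (N_f, n_src * J)
    S_tgt: np.ndarray  # (N_f, n_tgt * J)
    geometry: KernelGeometry
    J: int

    @property
    def N_f(self) -> int:
        return self.S_src.shape[0]


@dataclass
class WeightSet:
    """Fitted interpolation weights, ``(n_src*J) x (n_tgt*J)``."""

    W: np.ndarray
    geometry: KernelGeometry
    J: int
    residual_norm: float = 0.0
    condition: float = np.inf

    def __post_init__(self) -> None:
        n_src, n_tgt = self.geometry.n_src, self.geometry.n_tgt
        if self.W.shape != (n_src * self.J, n_tgt * self.J):
            raise ValueError(
                f"weight shape {self.W.shape} inconsistent with geometry "
                f"({n_src} sources, {n_tgt} targets, J={self.J})")
        if not np.all(np.isfinite(self.W)):
            raise ValueError("weights contain non-finite values")


def _source_index_offsets(geom: KernelGeometry) -> np.ndarray:
    """Source offsets converted to raw sample units, shape (n_src, 3)."""
    block = geom.block
    return np.array([(s, p * block.R_y, q * block.R_z) for s, p, q in geom.sources])


def _gather(data: np.ndarray, anchors: tuple[np.ndarray, np.ndarray, np.ndarray],
            offsets: np.ndarray) -> np.ndarray:
    """Rows of samples around each anchor, offset-major / channel-minor columns.

    ``data`` is (J, N_x, N_y, N_z); anchors are equal-length index arrays.
    Caller guarantees all gathered indices are in bounds.
    """
    J = data.shape[0]
    ax, ay, az = anchors
    n = ax.size
    out = np.empty((n, offsets.shape[0] * J), dtype=data.dtype)
    for k, (ox, oy, oz) in enumerate(offsets):
        out[:, k * J:(k + 1) * J] = data[:, ax + ox, ay + oy, az + oz].T
    return out


def build_calibration_system(acs: MultiCoilKSpace, geometry: KernelGeometry,
                             block: BlockSpec | None = None) -> CalibrationSystem:
    """All calibration rows whose full footprint fits inside the ACS volume.

    Anchor positions replicate the synthesis geometry: they step by one along
    the readout and by ``R_y`` / ``R_z`` along the phase-encoding axes,
    aligned with the acquired lattice (the ACS block is centred on the DC
    sample, so lattice-congruent local positions are those congruent to
    ``acs_extent // 2`` modulo the acceleration factor).  Anchors are
    enumerated in lexicographic (x, y, z) order; ``N_f`` is the number of
    anchors at which every source and target offset falls inside the ACS.
    """
    if block is None:
        block = geometry.block
    src_off = _source_index_offsets(geometry)
    tgt_off = np.array(geometry.targets)
    all_off = np.vstack([src_off, tgt_off])
    shape = np.array(acs.grid_shape)
    lo = np.maximum(0, -all_off.min(axis=0))
    hi = shape - 1 - np.maximum(0, all_off.max(axis=0))
    if np.any(hi < lo):
        need = all_off.max(axis=0) - all_off.min(axis=0) + 1
        raise ValueError(
            f"ACS grid {tuple(acs.grid_shape)} smaller than the kernel footprint; "
            f"needs at least {tuple(int(n) for n in need)} samples per axis")

    def _lattice_range(axis: int, R: int) -> np.ndarray:
        anchor = (shape[axis] // 2) % R
        first = lo[axis] + (anchor - lo[axis]) % R
        return np.arange(first, hi[axis] + 1, R)

    ranges = [np.arange(lo[0], hi[0] + 1),
              _lattice_range(1, block.R_y),
              _lattice_range(2, block.R_z)]
    if any(r.size == 0 for r in ranges):
        raise ValueError("no lattice-aligned calibration anchors fit inside the ACS")
    AX, AY, AZ = np.meshgrid(*ranges, indexing="ij")
    anchors = (AX.ravel(), AY.ravel(), AZ.ravel())
    S_src = _gather(acs.data, anchors, src_off)
    S_tgt = _gather(acs.data, anchors, tgt_off)
    if S_src.shape[0] < S_src.shape[1]:
        warnings.warn(
            f"calibration under-determined: N_f={S_src.shape[0]} rows for "
            f"{S_src.shape[1]} unknown columns", RuntimeWarning)
    return CalibrationSystem(S_src, S_tgt, geometry, acs.J)


def solve_weights(system: CalibrationSystem, ridge: float = 0.0) -> WeightSet:
    """Least-squares fit of ``S_src W = S_tgt``.

    Solved by orthogonal factorisation (SVD-based ``lstsq``) rather than by
    explicitly inverting the normal equations -- identical to the
    normal-equations solution for full-rank systems and numerically safer.
    Rank-deficient systems return the minimum-norm solution with a warning.
    ``ridge > 0`` applies Tikhonov damping with lambda = ridge * s_max
    (relative to the largest singular value); off by default.
    """
    if system.N_f == 0:
        raise ValueError("empty calibration system")
    A, B = system.S_src, system.S_tgt
    if ridge > 0:
        U, s, Vh = scipy.linalg.svd(A, full_matrices=False)
        lam = ridge * s[0]
        filt = s / (s ** 2 + lam ** 2)
        W = (Vh.conj().T * filt) @ (U.conj().T @ B)
        cond = s[0] / s[-1] if s[-1] > 0 else np.inf
    else:
        W, _, rank, s = scipy.linalg.lstsq(A, B)
        if rank < A.shape[1]:
            warnings.warn(
                f"rank-deficient calibration system (rank {rank} < {A.shape[1]}); "
                "returning the minimum-norm solution", RuntimeWarning)
        cond = s[0] / s[-1] if s is not None and s[-1] > 0 else np.inf
    resid = float(np.linalg.norm(A @ W - B))
    return WeightSet(W, system.geometry, system.J, resid, float(cond))


def _lattice_anchor_axis(n: int, center: int, R: int) -> np.ndarray:
    """Lattice anchor indices along one PE axis, padded one block beyond each edge."""
    first = center % R
    return np.arange(first - R, n + R, R)


def synthesize(kspace: MultiCoilKSpace, mask: SamplingMask, weights: WeightSet,
               block: BlockSpec | None = None, boundary: str = "wrap",
               row_chunk: int = 200_000) -> MultiCoilKSpace:
    """Estimate missing samples by sliding the fitted weights over the lattice.

    Anchors one block beyond each edge are still processed so edge samples
    get estimates; previously acquired samples (mask True) are never
    overwritten.  ``boundary`` controls how sources outside the grid read:
    ``"wrap"`` (default) gathers periodically -- exact for data that are
    centred DFT spectra, as produced by the simulator -- while ``"zero"``
    reads them as zero, which suits windowed (non-periodic) acquisitions.
    """
    if boundary not in ("wrap", "zero"):
        raise ValueError(f"boundary must be 'wrap' or 'zero', got {boundary!r}")
    geom = weights.geometry
    if block is None:
        block = geom.block
    if weights.J != kspace.J:
        raise ValueError(f"weights fitted for J={weights.J}, data has J={kspace.J}")
    scheme = mask.scheme
    if scheme.R_y != block.R_y or scheme.R_z != block.R_z:
        raise ValueError("sampling scheme and kernel block disagree on acceleration")
    N_x, N_y, N_z = kspace.grid_shape
    cy, cz = scheme.dc_index
    src_off = _source_index_offsets(geom)
    tgt_off = np.array(geom.targets)

    ys = _lattice_anchor_axis(N_y, cy, block.R_y)
    zs = _lattice_anchor_axis(N_z, cz, block.R_z)
    AX, AY, AZ = np.meshgrid(np.arange(N_x), ys, zs, indexing="ij")
    ax, ay, az = AX.ravel(), AY.ravel(), AZ.ravel()

    # zero-pad so every gathered index is in bounds: anchors overhang the
    # grid by one block and source offsets reach one block further
    pad = np.abs(src_off).max(axis=0)
    pad_x = int(pad[0])
    pad_y = int(pad[1]) + block.R_y
    pad_z = int(pad[2]) + block.R_z
    widths = ((0, 0), (pad_x, pad_x), (pad_y, pad_y), (pad_z, pad_z))
    if boundary == "wrap":
        padded = np.pad(kspace.data, widths, mode="wrap")
    else:
        padded = np.pad(kspace.data, widths)

    out = kspace.data.copy()
    J = kspace.J
    writable = ~mask.mask
    for start in range(0, ax.size, row_chunk):
        sl = slice(start, start + row_chunk)
        anchors = (ax[sl] + pad_x, ay[sl] + pad_y, az[sl] + pad_z)
        S_acq = _gather(padded, anchors, src_off)
        S_rec = S_acq @ weights.W
        for k, (rx, ry, rz) in enumerate(tgt_off):
            tx, ty, tz = ax[sl] + rx, ay[sl] + ry, az[sl] + rz
            ok = ((tx >= 0) & (tx < N_x) & (ty >= 0) & (ty < N_y)
                  & (tz >= 0) & (tz < N_z))
            txk, tyk, tzk = tx[ok], ty[ok], tz[ok]
            wr = writable[txk, tyk, tzk]
            out[:, txk[wr], tyk[wr], tzk[wr]] = S_rec[ok][wr, k * J:(k + 1) * J].T
    return MultiCoilKSpace(out, kspace.deltas, mask)


class GrappaReconstructor(TransformerMixin, BaseEstimator):
    """2D-GRAPPA reconstruction as a fit/transform estimator.

    Parameters
    ----------
    algorithm : {"LK", "EX", "SK", "BK"}
        Kernel family.  LK/EX fit one weight matrix per target offset within
        each kernel's target class; SK/BK fit a single joint weight matrix
        for all ``R_y*R_z - 1`` block targets.
    n_x : {1, 3}
        Readout extent of the kernels (basis or expanded).
    type_index : int
        Orientation (1-4) of the SK/BK kernel; ignored for LK/EX.
    include_acs : bool
        Whether originally acquired ACS samples overwrite their estimates in
        the output (True) or only the lattice samples do (False).
    ridge : float
        Relative Tikhonov damping of the weight fit; 0 disables it.

    Attributes
    ----------
    weights_ : list of WeightSet
        One fitted weight set per (kernel, target-offset) fit.
    scheme_ : SamplingScheme
        Sampling scheme the weights were calibrated for.
    n_fit_locations_ : list of int
        ``N_f`` of each calibration system.
    """

    def __init__(self, algorithm: str = "BK", n_x: int = 1, type_index: int = 4,
                 include_acs: bool = True, ridge: float = 0.0,
                 boundary: str = "wrap"):
        self.algorithm = algorithm
        self.n_x = n_x
        self.type_index = type_index
        self.include_acs = include_acs
        self.ridge = ridge
        self.boundary = boundary

    def _validate(self, X: MultiCoilKSpace) -> SamplingScheme:
        if not isinstance(X, MultiCoilKSpace):
            raise TypeError("X must be a MultiCoilKSpace")
        if X.mask is None:
            raise ValueError("input k-space carries no sampling mask")
        if self.algorithm.upper() not in ALGORITHMS:
            raise ValueError(
                f"unknown algorithm {self.algorithm!r}; expected one of {ALGORITHMS}")
        return X.mask.scheme

    def fit(self, X: MultiCoilKSpace, y=None) -> "GrappaReconstructor":
        """Calibrate kernel weights on the ACS block of a masked k-space."""
        scheme = self._validate(X)
        block = BlockSpec(scheme.R_y, scheme.R_z)
        self.scheme_ = scheme
        self.weights_ = []
        self.n_fit_locations_ = []
        if block.n_missing == 0:  # nothing to reconstruct
            return self
        acs = extract_acs(X, scheme)
        for geom in kernels_for_algorithm(self.algorithm, block, self.n_x, self.type_index):
            fits = geom.per_target() if geom.family.startswith(("LK", "EX")) else [geom]
            for g in fits:
                system = build_calibration_system(acs, g, block)
                ws = solve_weights(system, ridge=self.ridge)
                logger.debug("fit %s target(s) %s: N_f=%d cond=%.3g",
                             g.family, g.targets, system.N_f, ws.condition)
                self.weights_.append(ws)
                self.n_fit_locations_.append(system.N_f)
        return self

    def transform(self, X: MultiCoilKSpace) -> MultiCoilKSpace:
        """Synthesize all missing samples and restore acquired ones."""
        if not hasattr(self, "weights_"):
            raise RuntimeError("GrappaReconstructor is not fitted")
        scheme = self._validate(X)
        block = BlockSpec(scheme.R_y, scheme.R_z)
        if block.n_missing == 0:
            return X.copy()
        if (scheme.R_y, scheme.R_z) != (self.scheme_.R_y, self.scheme_.R_z):
            raise ValueError("acceleration factors differ between fit and transform")
        # synthesis treats only the lattice as acquired, so ACS-interior
        # positions also receive estimates; finalize_kspace then decides
        # which acquired samples overwrite them.
        lattice_scheme = SamplingScheme(scheme.R_y, scheme.R_z, 0, 0, scheme.grid_shape)
        lattice_mask = make_mask(lattice_scheme)
        recon = X.copy()
        for ws in self.weights_:
            recon = synthesize(recon, lattice_mask, ws, block, boundary=self.boundary)
        return finalize_kspace(recon, X, X.mask, include_acs=self.include_acs)


def reconstruct(undersampled: MultiCoilKSpace, algorithm: str,
                scheme: SamplingScheme | None = None, n_x: int = 1,
                type_index: int = 4, include_acs: bool = True,
                ridge: float = 0.0, boundary: str = "wrap") -> MultiCoilKSpace:
    """One-call reconstruction: calibrate on the input's ACS, then synthesize.

    ``scheme`` is taken from the input's mask when omitted.
    """
    if scheme is not None and undersampled.mask is None:
        undersampled = MultiCoilKSpace(undersampled.data, undersampled.deltas,
                                       make_mask(scheme))
    est = GrappaReconstructor(algorithm=algorithm, n_x=n_x, type_index=type_index,
                              include_acs=include_acs, ridge=ridge, boundary=boundary)
    return est.fit(undersampled).transform(undersampled)
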
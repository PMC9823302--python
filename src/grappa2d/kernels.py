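"""Kernel footprint geometry for 2D-GRAPPA reconstruction.

A 3D acquisition undersampled along both phase-encoding axes leaves, in every
``R_y x R_z`` block anchored at an acquired lattice point, ``R_y*R_z - 1``
missing samples.  Each kernel family prescribes which acquired neighbours
(*sources*) are combined to estimate which missing samples (*targets*):

``LK``
    the lowest-dimensional kernels: two 1D kernels bracketing the target
    along ``k_y`` or ``k_z`` plus one 2D kernel using the four lattice
    corners of the block cell;
``EX``
    the LK 1D kernels extended by one lattice column on either side in the
    orthogonal phase-encoding direction (2x3 and 3x2 footprints);
``SK``
    a single square kernel -- the acquired points *common* to all EX
    footprints placed over the block (the 2x2 lattice square) -- which
    reconstructs every missing sample of the block at once;
``BK``
    the boomerang kernel -- the *union* of the EX footprints over the block,
    i.e. the 3x3 lattice neighbourhood minus one corner -- also
    reconstructing the whole block at once.

Source offsets are stored in acquired-lattice units ``(s, p, q)`` where ``s``
is a raw readout-sample offset and ``(p, q)`` count steps of ``R_y`` and
``R_z`` samples along the phase-encoding axes.  Target offsets are raw sample
offsets ``(r_x, r_y, r_z)`` from the block anchor.  Conversion to absolute
k-space indices happens only in :mod:`grappa2d.engine`, so the geometry is
independent of the acceleration factors.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Sequence

__all__ = [
    "BlockSpec",
    "KernelGeometry",
    "enumerate_block_targets",
    "classify_block_targets",
    "ex_footprint_for_target",
    "make_lk_kernels",
    "make_ex_kernels",
    "make_sk_kernel",
    "make_bk_kernel",
    "kernels_for_algorithm",
    "reflect_geometry",
    "geometry_to_json",
    "geometry_from_json",
]

ALGORITHMS = ("LK", "EX", "SK", "BK")

#: reflection signs (eps_y, eps_z) applied to the canonical (type-4) geometry
#: for each type index; type 4 is the identity.
_TYPE_REFLECTIONS = {1: (-1, -1), 2: (-1, 1), 3: (1, -1), 4: (1, 1)}


@dataclass(frozen=True)
class BlockSpec:
    """Acceleration factors ``R_y`` and ``R_z`` defining one sampling block."""

    R_y: int
    R_z: int

    def __post_init__(self) -> None:
        if int(self.R_y) != self.R_y or int(self.R_z) != self.R_z:
            raise ValueError("acceleration factors must be integers")
        if self.R_y < 1 or self.R_z < 1:
            raise ValueError(f"acceleration factors must be >= 1, got {self}")

    @property
    def n_missing(self) -> int:
        return self.R_y * self.R_z - 1


@dataclass(frozen=True)
class KernelGeometry:
    """Source/target offset sets defining one GRAPPA kernel.

    Attributes
    ----------
    family : str
        One of ``LK-ky``, ``LK-kz``, ``LK-plane``, ``EX-ky``, ``EX-kz``,
        ``EX-plane``, ``SK``, ``BK``.
    sources : tuple of (s, p, q)
        Acquired-point offsets; ``s`` in raw readout samples, ``(p, q)`` in
        lattice units.
    targets : tuple of (r_x, r_y, r_z)
        Missing-point offsets in raw sample units.
    """

    family: str
    sources: tuple[tuple[int, int, int], ...]
    targets: tuple[tuple[int, int, int], ...]
    n_x: int = 1
    type_index: int | None = None
    block: BlockSpec = field(default_factory=lambda: BlockSpec(2, 2))

    def __post_init__(self) -> None:
        if self.n_x not in (1, 3):
            raise ValueError(f"unsupported readout extent n_x={self.n_x}")
        if not self.sources or not self.targets:
            raise ValueError("kernel geometry needs at least one source and one target")
        if any(t[0] != 0 for t in self.targets):
            raise ValueError("targets must lie in the readout plane (r_x = 0)")
        object.__setattr__(self, "sources", tuple(sorted(self.sources)))
        object.__setattr__(self, "targets", tuple(sorted(self.targets)))

    @property
    def n_src(self) -> int:
        return len(self.sources)

    @property
    def n_tgt(self) -> int:
        return len(self.targets)

    def per_target(self) -> list["KernelGeometry"]:
        """Split into single-target geometries (one weight fit per offset)."""
        return [
            KernelGeometry(self.family, self.sources, (t,), self.n_x,
                           self.type_index, self.block)
            for t in self.targets
        ]


def enumerate_block_targets(block: BlockSpec) -> list[tuple[int, int]]:
    """All missing offsets ``(r_y, r_z)`` of a block, excluding the acquired corner."""
    return [
        (ry, rz)
        for ry in range(block.R_y)
        for rz in range(block.R_z)
        if (ry, rz) != (0, 0)
    ]


def classify_block_targets(block: BlockSpec) -> dict[str, list[tuple[int, int]]]:
    """Partition block targets into classes A (on an acquired k_z line),
    B (on an acquired k_y line) and C (aligned with neither)."""
    classes: dict[str, list[tuple[int, int]]] = {"A": [], "B": [], "C": []}
    for ry, rz in enumerate_block_targets(block):
        if rz == 0:
            classes["A"].append((ry, rz))
        elif ry == 0:
            classes["B"].append((ry, rz))
        else:
            classes["C"].append((ry, rz))
    return classes


def ex_footprint_for_target(ry: int, rz: int) -> set[tuple[int, int]]:
    """In-plane lattice footprint of the EX kernel serving one block target.

    Class-A targets (``rz == 0``) use the 2x3 footprint, class-B the 3x2 one
    and class-C the 2x2 corners; offsets are relative to the block anchor.
    """
    if ry == 0 and rz == 0:
        raise ValueError("(0, 0) is the acquired anchor, not a target")
    if rz == 0:
        return {(p, q) for p in (0, 1) for q in (-1, 0, 1)}
    if ry == 0:
        return {(p, q) for p in (-1, 0, 1) for q in (0, 1)}
    return {(p, q) for p in (0, 1) for q in (0, 1)}


def _expand_readout(inplane: Iterable[tuple[int, int]], n_x: int) -> tuple[tuple[int, int, int], ...]:
    if n_x not in (1, 3):
        raise ValueError(f"unsupported readout extent n_x={n_x}")
    s_offsets = (0,) if n_x == 1 else (-1, 0, 1)
    return tuple((s, p, q) for s in s_offsets for (p, q) in inplane)


def _targets3(pairs: Sequence[tuple[int, int]]) -> tuple[tuple[int, int, int], ...]:
    return tuple((0, ry, rz) for ry, rz in pairs)


def make_lk_kernels(block: BlockSpec, n_x: int = 1) -> tuple[KernelGeometry, ...]:
    """The three lowest-dimensional kernels (1D along k_y, 1D along k_z, 2D plane).

    Kernels whose target class is empty (degenerate blocks with ``R_y`` or
    ``R_z`` equal to 1) are omitted from the returned tuple.
    """
    classes = classify_block_targets(block)
    spec = [
        ("LK-ky", classes["A"], [(0, 0), (1, 0)]),
        ("LK-kz", classes["B"], [(0, 0), (0, 1)]),
        ("LK-plane", classes["C"], [(p, q) for p in (0, 1) for q in (0, 1)]),
    ]
    return tuple(
        KernelGeometry(fam, _expand_readout(src, n_x), _targets3(tgts), n_x, None, block)
        for fam, tgts, src in spec
        if tgts
    )


def make_ex_kernels(block: BlockSpec, n_x: int = 1) -> tuple[KernelGeometry, ...]:
    """The three extended kernels (2x3, 3x2 and 2x2 in-plane footprints)."""
    classes = classify_block_targets(block)
    spec = [
        ("EX-ky", classes["A"], sorted(ex_footprint_for_target(1, 0))),
        ("EX-kz", classes["B"], sorted(ex_footprint_for_target(0, 1))),
        ("EX-plane", classes["C"], sorted(ex_footprint_for_target(1, 1))),
    ]
    return tuple(
        KernelGeometry(fam, _expand_readout(src, n_x), _targets3(tgts), n_x, None, block)
        for fam, tgts, src in spec
        if tgts
    )


def _reflect_pairs(pairs: Iterable[tuple[int, int]], eps: tuple[int, int]) -> list[tuple[int, int]]:
    ey, ez = eps
    return [(ey * p, ez * q) for p, q in pairs]


def make_sk_kernel(block: BlockSpec, n_x: int = 1, type_index: int = 4) -> KernelGeometry:
    """Square kernel: the 2x2 lattice square common to every EX footprint.

    All ``R_y*R_z - 1`` missing samples of the block are reconstructed
    simultaneously.  ``type_index`` selects one of the four placements of the
    block around the central acquired point (reflections of the canonical
    type-4 geometry, which extends toward +k_y, +k_z).
    """
    if type_index not in _TYPE_REFLECTIONS:
        raise ValueError(f"type_index must be in 1..4, got {type_index}")
    if block.n_missing == 0:
        raise ValueError("block has no missing samples")
    eps = _TYPE_REFLECTIONS[type_index]
    square = [(p, q) for p in (0, 1) for q in (0, 1)]
    sources = _reflect_pairs(square, eps)
    targets = _reflect_pairs(enumerate_block_targets(block), eps)
    return KernelGeometry("SK", _expand_readout(sources, n_x), _targets3(targets),
                          n_x, type_index, block)


def make_bk_kernel(block: BlockSpec, n_x: int = 1, type_index: int = 4) -> KernelGeometry:
    """Boomerang kernel: the 3x3 lattice neighbourhood minus one corner.

    The footprint is the union of the EX footprints over the block targets;
    for type 4 the excluded corner is ``(-1, -1)``.  Reconstructs all
    ``R_y*R_z - 1`` missing samples of the block at once.
    """
    if type_index not in _TYPE_REFLECTIONS:
        raise ValueError(f"type_index must be in 1..4, got {type_index}")
    if block.n_missing == 0:
        raise ValueError("block has no missing samples")
    eps = _TYPE_REFLECTIONS[type_index]
    boomerang = [(p, q) for p in (-1, 0, 1) for q in (-1, 0, 1) if (p, q) != (-1, -1)]
    sources = _reflect_pairs(boomerang, eps)
    targets = _reflect_pairs(enumerate_block_targets(block), eps)
    return KernelGeometry("BK", _expand_readout(sources, n_x), _targets3(targets),
                          n_x, type_index, block)


def kernels_for_algorithm(algorithm: str, block: BlockSpec, n_x: int = 1,
                          type_index: int = 4) -> tuple[KernelGeometry, ...]:
    """All kernel geometries used by one reconstruction algorithm."""
    algorithm = algorithm.upper()
    if algorithm == "LK":
        return make_lk_kernels(block, n_x)
    if algorithm == "EX":
        return make_ex_kernels(block, n_x)
    if algorithm == "SK":
        return (make_sk_kernel(block, n_x, type_index),)
    if algorithm == "BK":
        return (make_bk_kernel(block, n_x, type_index),)
    raise ValueError(f"unknown algorithm {algorithm!r}; expected one of {ALGORITHMS}")


def reflect_geometry(geom: KernelGeometry, flip_y: bool = False,
                     flip_z: bool = False) -> KernelGeometry:
    """Reflect a geometry about the block anchor along either PE axis."""
    ey = -1 if flip_y else 1
    ez = -1 if flip_z else 1
    sources = tuple((s, ey * p, ez * q) for s, p, q in geom.sources)
    targets = tuple((rx, ey * ry, ez * rz) for rx, ry, rz in geom.targets)
    return KernelGeometry(geom.family, sources, targets, geom.n_x,
                          geom.type_index, geom.block)


def geometry_to_json(geom: KernelGeometry) -> str:
    return json.dumps({
        "family": geom.family,
        "type_index": geom.type_index,
        "n_x": geom.n_x,
        "R_y": geom.block.R_y,
        "R_z": geom.block.R_z,
        "sources": [list(s) for s in geom.sources],
        "targets": [list(t) for t in geom.targets],
    })


def geometry_from_json(text: str) -> KernelGeometry:
    d = json.loads(text)
    return KernelGeometry(
        family=d["family"],
        sources=tuple(tuple(s) for s in d["sources"]),
        targets=tuple(tuple(t) for t in d["targets"]),
        n_x=d["n_x"],
        type_index=d["type_index"],
        block=BlockSpec(d["R_y"], d["R_z"]),
    )
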
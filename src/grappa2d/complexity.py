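"""Cost model: memory-allocation and arithmetic-operation counts.

For a kernel with ``n_src`` source points per target, ``J`` channels,
``N_f`` calibration locations and ``N_rec`` reconstructed points, the
per-kernel counts are

* calibration memory:   ``3 N_f n_src J + N_f J``
* calibration arithmetic: ``(n_src J)^2 (2 N_f - 1) + n_tgt n_src J^2 (2 N_f + 2 n_src J - 2)``
* synthesis memory:     ``N_rec n_src J + n_src J^2``
* synthesis arithmetic: ``n_tgt N_rec J (2 n_src J - 1)``

where ``n_tgt`` is 1 for kernels that serve one target offset per
application (LK/EX) and ``R_y R_z - 1`` for the block-simultaneous square
and boomerang kernels.  Totals for an algorithm sum over its kernels.  All
counts are exact integers.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

from .kernels import ALGORITHMS, BlockSpec, kernels_for_algorithm

__all__ = [
    "ComplexityParams",
    "ComplexityReport",
    "calib_memory",
    "calib_arith",
    "synth_memory",
    "synth_arith",
    "algorithm_kernel_sizes",
    "algorithm_report",
    "full_report",
    "format_report",
]


@dataclass(frozen=True)
class ComplexityParams:
    """Parameters of the cost model for one algorithm.

    ``kernels`` lists ``(n_src, n_tgt)`` per kernel of the algorithm.
    """

    J: int
    kernels: tuple[tuple[int, int], ...]
    N_f: int = 0
    N_rec: int = 0

    def __post_init__(self) -> None:
        if self.J < 1 or self.N_f < 0 or self.N_rec < 0:
            raise ValueError("J must be positive; N_f and N_rec non-negative")
        if not self.kernels or any(n < 1 or t < 1 for n, t in self.kernels):
            raise ValueError("kernels must be a non-empty list of positive (n_src, n_tgt)")


@dataclass(frozen=True)
class ComplexityReport:
    calib_memory: int
    calib_arith: int
    synth_memory: int
    synth_arith: int

    def as_dict(self) -> dict[str, int]:
        return {
            "calib_memory": self.calib_memory,
            "calib_arith": self.calib_arith,
            "synth_memory": self.synth_memory,
            "synth_arith": self.synth_arith,
        }


def calib_memory(params: ComplexityParams) -> int:
    """Matrix-formulation allocations in the calibration step."""
    J, N_f = params.J, params.N_f
    return sum(3 * N_f * n_src * J + N_f * J for n_src, _ in params.kernels)


def calib_arith(params: ComplexityParams) -> int:
    """Arithmetic operations to solve for the weights."""
    J, N_f = params.J, params.N_f
    return sum(
        (n_src * J) ** 2 * (2 * N_f - 1)
        + n_tgt * n_src * J * J * (2 * N_f + 2 * n_src * J - 2)
        for n_src, n_tgt in params.kernels)


def synth_memory(params: ComplexityParams) -> int:
    """Matrix-formation allocations in the synthesis step."""
    J, N_rec = params.J, params.N_rec
    return sum(N_rec * n_src * J + n_src * J * J for n_src, _ in params.kernels)


def synth_arith(params: ComplexityParams) -> int:
    """Arithmetic operations to synthesize the missing samples."""
    J, N_rec = params.J, params.N_rec
    return sum(n_tgt * N_rec * J * (2 * n_src * J - 1)
               for n_src, n_tgt in params.kernels)


def algorithm_kernel_sizes(algorithm: str, block: BlockSpec,
                           n_x: int = 1) -> tuple[tuple[int, int], ...]:
    """(n_src, n_tgt) per kernel, derived from the actual kernel geometries.

    LK/EX kernels carry ``n_tgt = 1`` (one weight fit per target offset);
    SK/BK carry the full block multiplicity.
    """
    sizes = []
    for geom in kernels_for_algorithm(algorithm, block, n_x):
        n_tgt = 1 if geom.family.startswith(("LK", "EX")) else block.n_missing
        sizes.append((geom.n_src, n_tgt))
    return tuple(sizes)


def algorithm_report(algorithm: str, J: int, N_f: int, N_rec: int,
                     block: BlockSpec = BlockSpec(2, 2), n_x: int = 1) -> ComplexityReport:
    params = ComplexityParams(J=J, N_f=N_f, N_rec=N_rec,
                              kernels=algorithm_kernel_sizes(algorithm, block, n_x))
    return ComplexityReport(calib_memory(params), calib_arith(params),
                            synth_memory(params), synth_arith(params))


def full_report(J: int, N_f: int, N_rec: int, block: BlockSpec = BlockSpec(2, 2),
                n_x: int = 1) -> dict[str, ComplexityReport]:
    """Cost table for all four algorithms."""
    return {alg: algorithm_report(alg, J, N_f, N_rec, block, n_x)
            for alg in ALGORITHMS}


def format_report(reports: dict[str, ComplexityReport], as_json: bool = False) -> str:
    """Render the cost table as aligned text or JSON."""
    if as_json:
        return json.dumps({a: r.as_dict() for a, r in reports.items()}, indent=2)
    header = (f"{'algorithm':<10}{'calib memory':>16}{'calib arith':>18}"
              f"{'synth memory':>18}{'synth arith':>18}")
    lines = [header, "-" * len(header)]
    for alg, r in reports.items():
        lines.append(f"{alg:<10}{r.calib_memory:>16,}{r.calib_arith:>18,}"
                     f"{r.synth_memory:>18,}{r.synth_arith:>18,}")
    return "\n".join(lines)
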
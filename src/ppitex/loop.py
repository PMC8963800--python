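"""LOOP local-texture descriptor over a PSSM.

The PSSM is treated as a 20xM grayscale image. For every interior cell the
eight Kirsch directional masks are applied to its 3x3 neighborhood; each
neighbor receives a bit weight 2^w where w is the rank of the magnitude of
its mask response, and the bit is set when the neighbor intensity is >= the
center intensity. The resulting 8-bit codes (0..255) are binned into a
normalized 256-component histogram, one per protein.

Neighbor ring convention: n = 0..7 enumerates the (row, col) offsets
clockwise from the top-left corner:

    (-1,-1) (-1,0) (-1,+1) (0,+1) (+1,+1) (+1,0) (+1,-1) (0,-1)

Mask n puts its three +5 weights on neighbor n and the two ring-adjacent
neighbors; the remaining five ring cells get -3 and the center 0, so every
mask sums to zero and mask n is the 45-degree rotation of mask n-1.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np

from ppitex.pssm import PSSM

#: Clockwise ring of (row, col) offsets starting at the top-left neighbor.
RING_OFFSETS: tuple[tuple[int, int], ...] = (
    (-1, -1), (-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1), (0, -1),
)

N_CODES = 256


def kirsch_mask_bank() -> np.ndarray:
    """The eight 3x3 Kirsch edge kernels, indexed by direction n = 0..7."""
    masks = np.full((8, 3, 3), -3, dtype=int)
    masks[:, 1, 1] = 0
    for n in range(8):
        for d in (n - 1, n, n + 1):
            dr, dc = RING_OFFSETS[d % 8]
            masks[n, dr + 1, dc + 1] = 5
    return masks


def _ring_weight_table() -> np.ndarray:
    """8x8 table W[n, d] = weight of ring neighbor d in mask n (center is 0)."""
    masks = kirsch_mask_bank()
    table = np.empty((8, 8), dtype=int)
    for d, (dr, dc) in enumerate(RING_OFFSETS):
        table[:, d] = masks[:, dr + 1, dc + 1]
    return table


_W = _ring_weight_table()
_MASKS = kirsch_mask_bank()


def kirsch_responses(patch: np.ndarray) -> np.ndarray:
    """Eight directional mask responses of a 3x3 patch.

    The center weight is zero, so the center intensity never contributes.
    """
    patch = np.asarray(patch, dtype=float)
    if patch.shape != (3, 3):
        raise ValueError(f"patch must be 3x3, got {patch.shape}")
    return (_MASKS * patch).sum(axis=(1, 2))


def rank_exponents(responses: np.ndarray) -> np.ndarray:
    """Bit exponents from response-magnitude ranks.

    The direction with the largest |response| gets exponent 7 down to 0 for
    the smallest; ties are broken by giving the smaller direction index the
    larger exponent. Always a permutation of {0..7}.
    """
    responses = np.asarray(responses, dtype=float)
    if responses.shape != (8,):
        raise ValueError("responses must have 8 components")
    order = np.argsort(-np.abs(responses), kind="stable")
    exps = np.empty(8, dtype=int)
    exps[order] = np.arange(7, -1, -1)
    return exps


def loop_code(patch: np.ndarray) -> int:
    """The 8-bit texture code of a 3x3 patch: sum of s(i_n - i_c) * 2^w_n."""
    patch = np.asarray(patch, dtype=float)
    if patch.shape != (3, 3):
        raise ValueError(f"patch must be 3x3, got {patch.shape}")
    exps = rank_exponents(kirsch_responses(patch))
    center = patch[1, 1]
    code = 0
    for n, (dr, dc) in enumerate(RING_OFFSETS):
        if patch[1 + dr, 1 + dc] - center >= 0:
            code += 1 << exps[n]
    return code


@dataclass
class LoopCodeField:
    """Per-cell texture codes over the interior of a PSSM (18 x (M-2))."""

    protein_id: str
    codes: np.ndarray


@dataclass
class LoopDescriptor:
    """256-bin normalized histogram of texture codes for one protein."""

    protein_id: str
    histogram: np.ndarray

    def __post_init__(self) -> None:
        self.histogram = np.asarray(self.histogram, dtype=float)
        if self.histogram.shape != (N_CODES,):
            raise ValueError("histogram must have exactly 256 components")
        if np.any(self.histogram < 0):
            raise ValueError("histogram components must be non-negative")


def loop_code_field(pssm: PSSM) -> LoopCodeField:
    """Texture codes at every cell with a full 3x3 neighborhood.

    Vectorized: ring-neighbor intensities are gathered by array shifts and
    the eight mask responses are recovered as a linear map of the ring
    (center weight is zero).
    """
    a = pssm.scores
    rows, m = a.shape
    if m < 3:
        raise ValueError("sequence too short for texture window (M < 3)")
    center = a[1:-1, 1:-1]
    neigh = np.stack(
        [
            a[1 + dr : rows - 1 + dr, 1 + dc : m - 1 + dc]
            for dr, dc in RING_OFFSETS
        ]
    )  # (8, rows-2, m-2)
    flat_neigh = neigh.reshape(8, -1).T  # (cells, 8)
    responses = flat_neigh @ _W.T  # (cells, 8)

    order = np.argsort(-np.abs(responses), axis=1, kind="stable")
    exps = np.empty_like(order)
    np.put_along_axis(exps, order, np.arange(7, -1, -1)[None, :], axis=1)

    sbits = flat_neigh - center.reshape(-1)[:, None] >= 0
    codes = (sbits * (1 << exps)).sum(axis=1)
    return LoopCodeField(
        protein_id=pssm.protein_id,
        codes=codes.reshape(rows - 2, m - 2),
    )


def loop_histogram(pssm: PSSM) -> LoopDescriptor:
    """Normalized 256-bin histogram of the texture codes of a PSSM.

    Frequencies sum to 1, so protein length is not encoded in the feature.
    """
    field = loop_code_field(pssm)
    counts = np.bincount(field.codes.reshape(-1), minlength=N_CODES)
    return LoopDescriptor(
        protein_id=pssm.protein_id,
        histogram=counts / counts.sum(),
    )


# ---------------------------------------------------------------------------
# Descriptor table I/O (TSV: id + 256 frequency columns)
# ---------------------------------------------------------------------------

def write_descriptors(path: str | Path, descriptors: Iterable[LoopDescriptor]) -> None:
    with open(path, "w") as fh:
        header = "id\t" + "\t".join(f"h{i}" for i in range(N_CODES))
        fh.write(header + "\n")
        for d in descriptors:
            values = "\t".join(repr(float(v)) for v in d.histogram)
            fh.write(f"{d.protein_id}\t{values}\n")


def read_descriptors(path: str | Path) -> dict[str, LoopDescriptor]:
    out: dict[str, LoopDescriptor] = {}
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("id\t"):
            raise ValueError(f"{path}: not a descriptor table")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            tokens = line.rstrip("\n").split("\t")
            if len(tokens) != N_CODES + 1:
                raise ValueError(
                    f"{path}:{lineno}: expected {N_CODES + 1} columns, got {len(tokens)}"
                )
            out[tokens[0]] = LoopDescriptor(
                protein_id=tokens[0],
                histogram=np.array([float(t) for t in tokens[1:]]),
            )
    return out
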
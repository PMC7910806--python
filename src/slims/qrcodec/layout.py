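"""Module-placement geometry shared by the QR encoder and decoder."""

from __future__ import annotations

import functools

import numpy as np

from .tables import ALIGNMENT_CENTERS


def symbol_dim(version: int) -> int:
    return 17 + 4 * version


def version_from_dim(dim: int) -> int | None:
    if dim < 21 or (dim - 17) % 4:
        return None
    return (dim - 17) // 4


def finder_positions(dim: int) -> list[tuple[int, int]]:
    # Top-left corners of the three 7x7 finder patterns.
    return [(0, 0), (0, dim - 7), (dim - 7, 0)]


def alignment_positions(version: int, dim: int) -> list[tuple[int, int]]:
    """Centres of alignment patterns, skipping any that would overlap a
    finder pattern."""
    centers = ALIGNMENT_CENTERS[version]
    out = []
    for r in centers:
        for c in centers:
            clear = True
            for fr, fc in finder_positions(dim):
                if fr - 2 <= r <= fr + 8 and fc - 2 <= c <= fc + 8:
                    clear = False
            if clear:
                out.append((r, c))
    return out


@functools.lru_cache(maxsize=None)
def function_mask(version: int) -> np.ndarray:
    """Boolean map of function (non-data) modules."""
    dim = symbol_dim(version)
    f = np.zeros((dim, dim), dtype=bool)
    for fr, fc in finder_positions(dim):
        f[max(fr - 1, 0):fr + 8, max(fc - 1, 0):fc + 8] = True  # + separator
    f[6, :] = True  # timing
    f[:, 6] = True
    for r, c in alignment_positions(version, dim):
        f[r - 2:r + 3, c - 2:c + 3] = True
    for r, c in format_positions_a(dim) + format_positions_b(dim):
        f[r, c] = True
    f[dim - 8, 8] = True  # dark module
    return f


@functools.lru_cache(maxsize=None)
def base_matrix(version: int) -> np.ndarray:
    """Function-pattern modules drawn (True = dark); data area left False."""
    dim = symbol_dim(version)
    m = np.zeros((dim, dim), dtype=bool)
    finder = np.ones((7, 7), dtype=bool)
    finder[1, 1:6] = False
    finder[5, 1:6] = False
    finder[1:6, 1] = False
    finder[1:6, 5] = False
    for fr, fc in finder_positions(dim):
        m[fr:fr + 7, fc:fc + 7] = finder
    for k in range(8, dim - 8):
        m[6, k] = k % 2 == 0
        m[k, 6] = k % 2 == 0
    align = np.ones((5, 5), dtype=bool)
    align[1, 1:4] = False
    align[3, 1:4] = False
    align[1:4, 1] = False
    align[1:4, 3] = False
    align[2, 2] = True
    for r, c in alignment_positions(version, dim):
        m[r - 2:r + 3, c - 2:c + 3] = align
    m[dim - 8, 8] = True
    return m


def format_positions_a(dim: int) -> list[tuple[int, int]]:
    """First format-information copy (around the top-left finder),
    most-significant bit first."""
    return [
        (8, 0), (8, 1), (8, 2), (8, 3), (8, 4), (8, 5), (8, 7), (8, 8),
        (7, 8), (5, 8), (4, 8), (3, 8), (2, 8), (1, 8), (0, 8),
    ]


def format_positions_b(dim: int) -> list[tuple[int, int]]:
    """Second copy (bottom-left column then top-right row), MSB first."""
    col = [(dim - 1 - k, 8) for k in range(7)]
    row = [(8, dim - 8 + k) for k in range(8)]
    return col + row


@functools.lru_cache(maxsize=None)
def data_module_order(version: int) -> list[tuple[int, int]]:
    """Zigzag placement order of data modules (two-column strips, starting
    at the bottom-right, skipping the vertical timing column)."""
    dim = symbol_dim(version)
    fmask = function_mask(version)
    order = []
    col = dim - 1
    upward = True
    while col > 0:
        if col == 6:
            col -= 1
        rows = range(dim - 1, -1, -1) if upward else range(dim)
        for r in rows:
            for c in (col, col - 1):
                if not fmask[r, c]:
                    order.append((r, c))
        col -= 2
        upward = not upward
    return order
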
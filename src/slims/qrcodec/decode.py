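"""QR symbol decoder for photographs of printed labels.

The pipeline is the classical one: binarise, locate finder patterns by
their 1:1:3:1:1 dark/light run signature, group them into symbol
candidates, sample the module grid between the three finder centres, then
read format information, unmask, de-interleave and Reed-Solomon-correct the
codewords. Axis-aligned symbols at any of the four rotations are handled
(envelope photographs in this workflow are taken face-up); perspective
distortion is out of scope.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from .gf import rs_correct
from .layout import data_module_order, format_positions_a, \
    format_positions_b, version_from_dim
from .tables import ALL_FORMATS, EC_BLOCKS, MASK_PREDICATES

_ALNUM = "0123456789ABCDEFGHIJKLMNOPQRSTUVWXYZ $%*+-./:"


@dataclass(frozen=True)
class FinderCandidate:
    x: float
    y: float
    module: float


def binarize(gray: np.ndarray) -> np.ndarray | None:
    """Midpoint threshold; None when the image has no usable contrast."""
    g = np.asarray(gray, dtype=np.float32)
    lo, hi = float(g.min()), float(g.max())
    if hi - lo < 32:
        return None
    return g < (lo + hi) / 2.0


def _runs(line: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    idx = np.flatnonzero(np.diff(line.astype(np.int8)))
    bounds = np.concatenate(([0], idx + 1, [line.size]))
    return bounds[:-1], np.diff(bounds), line[bounds[:-1]]


def _ratio_ok(d1: float, l1: float, d2: float, l2: float, d3: float) -> float:
    m = (d1 + l1 + d2 + l2 + d3) / 7.0
    if m < 1.5:
        return 0.0
    tol = max(1.0, 0.7 * m)
    if (abs(d1 - m) <= tol and abs(l1 - m) <= tol and abs(l2 - m) <= tol
            and abs(d3 - m) <= tol and abs(d2 - 3 * m) <= max(1.5, 1.6 * m)):
        return m
    return 0.0


def _vertical_check(binary: np.ndarray, x: int, y: int) -> tuple[float, float] | None:
    """Walk the 1:1:3:1:1 pattern along column x through row y; return the
    refined centre row and module estimate, or None."""
    col = binary[:, x]
    h = col.size
    if not col[y]:
        return None
    top = y
    while top > 0 and col[top - 1]:
        top -= 1
    bot = y
    while bot < h - 1 and col[bot + 1]:
        bot += 1
    d2 = bot - top + 1

    def light_run(start: int, step: int) -> int:
        n, k = 0, start
        while 0 <= k < h and not col[k]:
            n += 1
            k += step
        return n

    def dark_run(start: int, step: int) -> int:
        n, k = 0, start
        while 0 <= k < h and col[k]:
            n += 1
            k += step
        return n

    l1 = light_run(top - 1, -1)
    d1 = dark_run(top - 1 - l1, -1)
    l2 = light_run(bot + 1, 1)
    d3 = dark_run(bot + 1 + l2, 1)
    m = _ratio_ok(d1, l1, d2, l2, d3)
    if not m:
        return None
    # continuous-coordinate centre of the inclusive pixel run [top, bot]
    return (top + bot + 1) / 2.0, m


def find_finder_candidates(binary: np.ndarray, stride: int = 3) -> list[FinderCandidate]:
    cands: list[FinderCandidate] = []
    h, w = binary.shape
    for y in range(0, h, stride):
        starts, lens, vals = _runs(binary[y])
        for i in range(len(lens) - 4):
            if not vals[i]:
                continue
            m = _ratio_ok(*(float(v) for v in lens[i:i + 5]))
            if not m:
                continue
            cx = starts[i] + lens[i] + lens[i + 1] + lens[i + 2] / 2.0
            vres = _vertical_check(binary, int(round(cx)), y)
            if vres is None:
                continue
            cy, vm = vres
            if not (0.5 <= vm / m <= 2.0):
                continue
            cands.append(FinderCandidate(cx, cy, (m + vm) / 2.0))
    return _merge(cands)


def _merge(cands: list[FinderCandidate]) -> list[FinderCandidate]:
    merged: list[list[float]] = []  # [sx, sy, sm, n]
    for c in cands:
        for g in merged:
            gm = g[2] / g[3]
            # near-coincident AND similar module size: averaging in a
            # stroke-induced spurious hit would drag a true centre off
            if (abs(g[0] / g[3] - c.x) < 3 * c.module
                    and abs(g[1] / g[3] - c.y) < 3 * c.module
                    and 0.77 <= c.module / gm <= 1.3):
                g[0] += c.x
                g[1] += c.y
                g[2] += c.module
                g[3] += 1
                break
        else:
            merged.append([c.x, c.y, c.module, 1])
    return [FinderCandidate(g[0] / g[3], g[1] / g[3], g[2] / g[3]) for g in merged]


def _group_symbols(cands: list[FinderCandidate]):
    """Yield (top_left, a, b, dim) candidate symbol geometries."""
    for trio in itertools.combinations(cands, 3):
        mods = sorted(c.module for c in trio)
        if mods[2] > 1.6 * mods[0]:
            continue
        for corner_i in range(3):
            tl = trio[corner_i]
            a, b = (trio[j] for j in range(3) if j != corner_i)
            va = np.array([a.x - tl.x, a.y - tl.y])
            vb = np.array([b.x - tl.x, b.y - tl.y])
            la, lb = np.linalg.norm(va), np.linalg.norm(vb)
            if la < 1 or lb < 1 or not (0.8 <= la / lb <= 1.25):
                continue
            if abs(float(va @ vb)) > 0.25 * la * lb:
                continue
            module = sum(c.module for c in trio) / 3.0
            span = (la + lb) / 2.0 / module
            dim_est = span + 7
            version = round((dim_est - 17) / 4)
            if not 1 <= version <= 5:
                continue
            dim = 17 + 4 * version
            if abs(dim_est - dim) > 2.5:
                continue
            yield tl, a, b, dim


def _sample_matrix(binary: np.ndarray, tl, a, b, dim: int) -> np.ndarray | None:
    u = np.array([a.x - tl.x, a.y - tl.y]) / (dim - 7)
    v = np.array([b.x - tl.x, b.y - tl.y]) / (dim - 7)
    # The finder centre sits at continuous module coordinate 3.5, i.e. the
    # centre of module 3; module i's centre is (i - 3) module units away.
    jj, ii = np.meshgrid(np.arange(dim) - 3.0, np.arange(dim) - 3.0)
    xs = tl.x + jj * u[0] + ii * v[0]
    ys = tl.y + jj * u[1] + ii * v[1]
    # round-half-up: np.round's ties-to-even alternates between adjacent
    # modules when centres land exactly on pixel boundaries (odd scales)
    xi = np.floor(xs + 0.5).astype(int)
    yi = np.floor(ys + 0.5).astype(int)
    h, w = binary.shape
    if xi.min() < 0 or yi.min() < 0 or xi.max() >= w or yi.max() >= h:
        return None
    return binary[yi, xi]


def decode_matrix(matrix: np.ndarray) -> bytes | None:
    """Decode a sampled boolean module matrix; None when unreadable."""
    dim = matrix.shape[0]
    version = version_from_dim(dim)
    if version is None or version > 5:
        return None
    best: tuple[int, str, int] | None = None
    for positions in (format_positions_a(dim), format_positions_b(dim)):
        val = 0
        for r, c in positions:
            val = (val << 1) | int(matrix[r, c])
        for fmt, (lvl, mask_id) in ALL_FORMATS.items():
            d = bin(fmt ^ val).count("1")
            if best is None or d < best[0]:
                best = (d, lvl, mask_id)
    if best is None or best[0] > 3:
        return None
    _, ec_level, mask_id = best
    if (version, ec_level) not in EC_BLOCKS:
        return None

    pred = MASK_PREDICATES[mask_id]
    order = data_module_order(version)
    bits = [int(matrix[r, c]) ^ int(pred(r, c)) for r, c in order]
    ec_per_block, data_blocks = EC_BLOCKS[(version, ec_level)]
    n_cw = sum(data_blocks) + ec_per_block * len(data_blocks)
    if len(bits) < n_cw * 8:
        return None
    codewords = [
        int("".join(map(str, bits[i:i + 8])), 2) for i in range(0, n_cw * 8, 8)
    ]

    # De-interleave data then parity codewords.
    blocks: list[list[int]] = [[] for _ in data_blocks]
    ecs: list[list[int]] = [[] for _ in data_blocks]
    it = iter(codewords)
    for i in range(max(data_blocks)):
        for bi, size in enumerate(data_blocks):
            if i < size:
                blocks[bi].append(next(it))
    for _ in range(ec_per_block):
        for bi in range(len(data_blocks)):
            ecs[bi].append(next(it))
    data: list[int] = []
    for block, ec in zip(blocks, ecs):
        try:
            corrected = rs_correct(block + ec, ec_per_block)
        except ValueError:
            return None
        data.extend(corrected[:len(block)])
    return _parse_bitstream(data, version)


def _parse_bitstream(data: list[int], version: int) -> bytes | None:
    bits: list[int] = []
    for cw in data:
        bits.extend((cw >> (7 - k)) & 1 for k in range(8))

    pos = 0

    def take(n: int) -> int:
        nonlocal pos
        val = 0
        for _ in range(n):
            val = (val << 1) | bits[pos]
            pos += 1
        return val

    out = bytearray()
    try:
        while pos + 4 <= len(bits):
            mode = take(4)
            if mode == 0:
                break
            if mode == 0b0100:  # byte
                count = take(8)
                for _ in range(count):
                    out.append(take(8))
            elif mode == 0b0010:  # alphanumeric
                count = take(9)
                while count >= 2:
                    pair = take(11)
                    out.append(ord(_ALNUM[pair // 45]))
                    out.append(ord(_ALNUM[pair % 45]))
                    count -= 2
                if count:
                    out.append(ord(_ALNUM[take(6)]))
            elif mode == 0b0001:  # numeric
                count = take(10)
                while count >= 3:
                    out.extend(f"{take(10):03d}".encode())
                    count -= 3
                if count == 2:
                    out.extend(f"{take(7):02d}".encode())
                elif count == 1:
                    out.extend(f"{take(4):01d}".encode())
            else:
                return None
    except IndexError:
        return None
    return bytes(out)


def decode_image(gray: np.ndarray, stride: int = 3) -> list[bytes]:
    """All distinct QR payloads found in a grayscale image array."""
    binary = binarize(gray)
    if binary is None:
        return []
    cands = find_finder_candidates(binary, stride=stride)
    if len(cands) < 3 and stride > 1:
        cands = find_finder_candidates(binary, stride=1)
    payloads: list[bytes] = []
    seen_geo = set()
    for tl, a, b, dim in _group_symbols(cands):
        key = (round(tl.x), round(tl.y), dim)
        if key in seen_geo:
            continue
        matrix = _sample_matrix(binary, tl, a, b, dim)
        if matrix is None:
            continue
        payload = decode_matrix(matrix)
        if payload is None:
            payload = decode_matrix(matrix.T)
        if payload is not None:
            seen_geo.add(key)
            if payload not in payloads:
                payloads.append(payload)
    return payloads
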
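"""QR symbol encoder (byte mode, versions 1-5).

Produces the module matrix for a short text payload such as a canonical
UUID. Error-correction level defaults to M and the version is the smallest
that fits the payload. The mask pattern is fixed (pattern 0): every mask
yields a valid, decodable symbol, and label sheets do not benefit from
per-symbol mask optimisation.
"""

from __future__ import annotations

import numpy as np

from .gf import rs_encode
from .layout import base_matrix, data_module_order, format_positions_a, \
    format_positions_b, symbol_dim
from .tables import EC_BLOCKS, MASK_PREDICATES, format_bits

PAD_BYTES = (0xEC, 0x11)


def _data_capacity_bytes(version: int, ec_level: str) -> int:
    _, data_blocks = EC_BLOCKS[(version, ec_level)]
    # 4-bit mode indicator + 8-bit length field (versions 1-9).
    return sum(data_blocks) - 2


def pick_version(payload_len: int, ec_level: str = "M") -> int:
    for version in range(1, 6):
        if _data_capacity_bytes(version, ec_level) >= payload_len:
            return version
    raise ValueError(f"payload of {payload_len} bytes exceeds version-5 capacity")


def _build_codewords(payload: bytes, version: int, ec_level: str) -> list[int]:
    ec_per_block, data_blocks = EC_BLOCKS[(version, ec_level)]
    n_data = sum(data_blocks)
    bits: list[int] = []

    def push(value: int, width: int) -> None:
        bits.extend((value >> (width - 1 - k)) & 1 for k in range(width))

    push(0b0100, 4)  # byte mode
    push(len(payload), 8)
    for b in payload:
        push(b, 8)
    # Terminator (up to 4 bits), then pad to a codeword boundary.
    push(0, min(4, n_data * 8 - len(bits)))
    bits.extend([0] * (-len(bits) % 8))
    codewords = [
        int("".join(map(str, bits[i:i + 8])), 2) for i in range(0, len(bits), 8)
    ]
    k = 0
    while len(codewords) < n_data:
        codewords.append(PAD_BYTES[k % 2])
        k += 1

    # Split into blocks, append RS parity, interleave.
    blocks, ecs, pos = [], [], 0
    for size in data_blocks:
        block = codewords[pos:pos + size]
        pos += size
        blocks.append(block)
        ecs.append(rs_encode(block, ec_per_block))
    out = []
    for i in range(max(data_blocks)):
        for block in blocks:
            if i < len(block):
                out.append(block[i])
    for i in range(ec_per_block):
        for ec in ecs:
            out.append(ec[i])
    return out


def encode_matrix(payload: bytes | str, ec_level: str = "M",
                  mask_id: int = 0) -> np.ndarray:
    """Encode `payload` and return the boolean module matrix (True = dark)."""
    if isinstance(payload, str):
        payload = payload.encode("ascii")
    version = pick_version(len(payload), ec_level)
    dim = symbol_dim(version)
    matrix = base_matrix(version).copy()  # base_matrix is cached
    codewords = _build_codewords(payload, version, ec_level)

    bits = []
    for cw in codewords:
        bits.extend((cw >> (7 - k)) & 1 for k in range(8))
    order = data_module_order(version)
    if len(bits) > len(order):
        raise AssertionError("codeword stream exceeds data area")
    bits.extend([0] * (len(order) - len(bits)))  # remainder bits

    mask = MASK_PREDICATES[mask_id]
    for (r, c), bit in zip(order, bits):
        matrix[r, c] = bool(bit) ^ mask(r, c)

    fmt = format_bits(ec_level, mask_id)
    fmt_bits = [(fmt >> (14 - k)) & 1 for k in range(15)]
    for (r, c), bit in zip(format_positions_a(dim), fmt_bits):
        matrix[r, c] = bool(bit)
    for (r, c), bit in zip(format_positions_b(dim), fmt_bits):
        matrix[r, c] = bool(bit)
    return matrix


def render(matrix: np.ndarray, scale: int = 8, border: int = 4) -> np.ndarray:
    """Rasterise a module matrix to a uint8 grayscale image (0 dark, 255
    light) with a quiet zone of `border` modules."""
    dim = matrix.shape[0]
    img = np.full((dim + 2 * border, dim + 2 * border), 255, dtype=np.uint8)
    img[border:border + dim, border:border + dim] = np.where(matrix, 0, 255)
    return np.repeat(np.repeat(img, scale, axis=0), scale, axis=1)
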
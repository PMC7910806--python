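"""Symbol-structure tables for QR versions 1-5.

Versions above 5 are far larger than a 36-character identifier payload ever
needs, so the tables stop there; the decoder rejects larger symbols
explicitly.
"""

# (version, ec_level) -> (ec codewords per block, [data codewords per block])
# ec_level: 'L', 'M', 'Q', 'H'
EC_BLOCKS: dict[tuple[int, str], tuple[int, list[int]]] = {
    (1, "L"): (7, [19]),
    (1, "M"): (10, [16]),
    (1, "Q"): (13, [13]),
    (1, "H"): (17, [9]),
    (2, "L"): (10, [34]),
    (2, "M"): (16, [28]),
    (2, "Q"): (22, [22]),
    (2, "H"): (28, [16]),
    (3, "L"): (15, [55]),
    (3, "M"): (26, [44]),
    (3, "Q"): (18, [17, 17]),
    (3, "H"): (22, [13, 13]),
    (4, "L"): (20, [80]),
    (4, "M"): (18, [32, 32]),
    (4, "Q"): (26, [24, 24]),
    (4, "H"): (16, [9, 9, 9, 9]),
    (5, "L"): (26, [108]),
    (5, "M"): (24, [43, 43]),
    (5, "Q"): (18, [15, 15, 16, 16]),
    (5, "H"): (22, [11, 11, 12, 12]),
}

# Alignment-pattern centre coordinates per version.
ALIGNMENT_CENTERS: dict[int, list[int]] = {
    1: [],
    2: [6, 18],
    3: [6, 22],
    4: [6, 26],
    5: [6, 30],
}

# Two-bit EC-level indicator used in the format information.
EC_LEVEL_BITS = {"L": 0b01, "M": 0b00, "Q": 0b11, "H": 0b10}
EC_LEVEL_FROM_BITS = {v: k for k, v in EC_LEVEL_BITS.items()}

FORMAT_MASK = 0b101010000010010
FORMAT_GEN = 0b10100110111  # BCH(15,5) generator


def format_bits(ec_level: str, mask_id: int) -> int:
    """15-bit masked format-information sequence."""
    data = (EC_LEVEL_BITS[ec_level] << 3) | mask_id
    rem = data << 10
    for shift in range(14, 9, -1):
        if rem & (1 << shift):
            rem ^= FORMAT_GEN << (shift - 10)
    return ((data << 10) | rem) ^ FORMAT_MASK


ALL_FORMATS: dict[int, tuple[str, int]] = {
    format_bits(lvl, m): (lvl, m)
    for lvl in EC_LEVEL_BITS
    for m in range(8)
}

MASK_PREDICATES = [
    lambda i, j: (i + j) % 2 == 0,
    lambda i, j: i % 2 == 0,
    lambda i, j: j % 3 == 0,
    lambda i, j: (i + j) % 3 == 0,
    lambda i, j: (i // 2 + j // 3) % 2 == 0,
    lambda i, j: (i * j) % 2 + (i * j) % 3 == 0,
    lambda i, j: ((i * j) % 2 + (i * j) % 3) % 2 == 0,
    lambda i, j: ((i + j) % 2 + (i * j) % 3) % 2 == 0,
]
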
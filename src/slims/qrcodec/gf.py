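"""Arithmetic over GF(2^8) and Reed-Solomon coding for QR symbols.

QR error correction uses the field generated by the primitive polynomial
x^8 + x^4 + x^3 + x^2 + 1 (0x11D) with generator element 2, and generator
polynomials whose roots start at alpha^0.
"""

from __future__ import annotations

PRIM = 0x11D

_EXP = [0] * 512
_LOG = [0] * 256
_x = 1
for _i in range(255):
    _EXP[_i] = _x
    _LOG[_x] = _i
    _x <<= 1
    if _x & 0x100:
        _x ^= PRIM
for _i in range(255, 512):
    _EXP[_i] = _EXP[_i - 255]


def gf_mul(a: int, b: int) -> int:
    if a == 0 or b == 0:
        return 0
    return _EXP[_LOG[a] + _LOG[b]]


def gf_div(a: int, b: int) -> int:
    if b == 0:
        raise ZeroDivisionError("division by zero in GF(256)")
    if a == 0:
        return 0
    return _EXP[(_LOG[a] - _LOG[b]) % 255]


def gf_pow(a: int, n: int) -> int:
    return _EXP[(_LOG[a] * n) % 255]


def gf_inverse(a: int) -> int:
    return _EXP[255 - _LOG[a]]


def poly_mul(p: list[int], q: list[int]) -> list[int]:
    out = [0] * (len(p) + len(q) - 1)
    for i, pi in enumerate(p):
        if pi == 0:
            continue
        for j, qj in enumerate(q):
            if qj:
                out[i + j] ^= gf_mul(pi, qj)
    return out


def poly_eval(p: list[int], x: int) -> int:
    # Horner's rule; p is highest-degree first.
    y = p[0]
    for c in p[1:]:
        y = gf_mul(y, x) ^ c
    return y


def rs_generator_poly(nsym: int) -> list[int]:
    g = [1]
    for i in range(nsym):
        g = poly_mul(g, [1, gf_pow(2, i)])
    return g


def rs_encode(data: list[int], nsym: int) -> list[int]:
    """Return `nsym` parity codewords for `data` (systematic encoding)."""
    gen = rs_generator_poly(nsym)
    rem = list(data) + [0] * nsym
    for i in range(len(data)):
        coef = rem[i]
        if coef:
            for j in range(1, len(gen)):
                rem[i + j] ^= gf_mul(gen[j], coef)
    return rem[len(data):]


def _syndromes(msg: list[int], nsym: int) -> list[int]:
    return [poly_eval(msg, gf_pow(2, i)) for i in range(nsym)]


def poly_add(p: list[int], q: list[int]) -> list[int]:
    # Highest-degree-first polynomials: align constant terms at the end.
    r = [0] * max(len(p), len(q))
    r[len(r) - len(p):] = p
    for i, c in enumerate(q):
        r[len(r) - len(q) + i] ^= c
    return r


def _berlekamp_massey(synd: list[int]) -> list[int]:
    """Error locator polynomial (highest-degree first)."""
    err_loc = [1]
    old_loc = [1]
    for i in range(len(synd)):
        old_loc = old_loc + [0]
        delta = synd[i]
        for j in range(1, len(err_loc)):
            delta ^= gf_mul(err_loc[-(j + 1)], synd[i - j])
        if delta:
            if len(old_loc) > len(err_loc):
                new_loc = [gf_mul(c, delta) for c in old_loc]
                old_loc = [gf_div(c, delta) for c in err_loc]
                err_loc = new_loc
            err_loc = poly_add(err_loc, [gf_mul(c, delta) for c in old_loc])
    while err_loc and err_loc[0] == 0:
        err_loc.pop(0)
    return err_loc


def rs_correct(msg: list[int], nsym: int) -> list[int]:
    """Correct up to nsym//2 byte errors in-place semantics; returns full
    corrected codeword (data + parity). Raises ValueError when uncorrectable.
    """
    if len(msg) > 255:
        raise ValueError("codeword longer than 255 bytes")
    synd = _syndromes(msg, nsym)
    if max(synd) == 0:
        return list(msg)
    err_loc = _berlekamp_massey(synd)
    n_err = len(err_loc) - 1
    if n_err * 2 > nsym:
        raise ValueError("too many errors to correct")
    # Chien search: roots of the locator give error positions.
    err_pos = []
    for i in range(len(msg)):
        if poly_eval(err_loc, gf_pow(2, 255 - (len(msg) - 1 - i))) == 0:
            err_pos.append(i)
    if len(err_pos) != n_err:
        raise ValueError("error locator degree does not match root count")
    # Forney algorithm (first consecutive generator root is alpha^0).
    err_eval = poly_mul(synd[::-1], err_loc)
    err_eval = err_eval[-(n_err + 1):]
    X = [gf_pow(2, len(msg) - 1 - pos) for pos in err_pos]
    out = list(msg)
    for i, pos in enumerate(err_pos):
        xi = X[i]
        xi_inv = gf_inverse(xi)
        # Derivative of the locator at 1/X_i via the product formula.
        deriv = 1
        for j, xj in enumerate(X):
            if j != i:
                deriv = gf_mul(deriv, 1 ^ gf_mul(xi_inv, xj))
        if deriv == 0:
            raise ValueError("Forney derivative is zero")
        # Lambda'(1/X_i) = X_i * deriv, and the X_i^{1-b} numerator factor
        # (b = 0) cancels it, leaving Omega/deriv.
        omega = poly_eval(err_eval, xi_inv)
        magnitude = gf_div(omega, deriv)
        out[pos] ^= magnitude
    if max(_syndromes(out, nsym)) != 0:
        raise ValueError("correction failed to zero the syndromes")
    return out
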
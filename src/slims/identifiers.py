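"""Sample identifiers: UUID generation, QR labels, and QR reading.

Every sampling event is keyed by a version-4-style UUID pre-printed as a QR
code on a coin envelope. The QR payload is the bare canonical lowercase
hyphenated text (36 characters), error-correction level M — the smallest
symbol that scans reliably on an envelope, with no URL framing.
"""

from __future__ import annotations

import math
import random
import re
import uuid as _uuid
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image, ImageDraw

from .qrcodec import decode_image, encode_matrix, render

UUID_RE = re.compile(
    r"^[0-9a-f]{8}-[0-9a-f]{4}-[0-9a-f]{4}-[0-9a-f]{4}-[0-9a-f]{12}$")


class QRImageError(OSError):
    """The image file could not be loaded at all (distinct from an image
    that loads but contains no readable code)."""


def is_canonical_uuid(text: str) -> bool:
    return bool(UUID_RE.match(text))


def generate_uuids(n: int, seed: int | None = None) -> list[str]:
    """`n` distinct canonical UUIDs.

    With a seed the stream is fully reproducible (fixtures and tests);
    without one, standard random version-4 identifiers are drawn.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    out: list[str] = []
    seen: set[str] = set()
    rng = random.Random(seed) if seed is not None else None
    while len(out) < n:
        if rng is not None:
            u = str(_uuid.UUID(int=rng.getrandbits(128), version=4))
        else:
            u = str(_uuid.uuid4())
        if u not in seen:
            seen.add(u)
            out.append(u)
    return out


def encode_qr(uuid_text: str, scale: int = 8, border: int = 4) -> Image.Image:
    """Scannable QR image whose payload is exactly the canonical text."""
    if not is_canonical_uuid(uuid_text):
        raise ValueError(f"not a canonical UUID: {uuid_text!r}")
    return Image.fromarray(render(encode_matrix(uuid_text), scale, border))


@dataclass(frozen=True)
class DecodeOutcome:
    status: str  # "ok" | "unreadable"
    uuid: str | None = None
    reason: str | None = None

    @property
    def ok(self) -> bool:
        return self.status == "ok"


def _to_gray(image) -> np.ndarray:
    if isinstance(image, np.ndarray):
        arr = image
        if arr.ndim == 3:
            arr = arr.mean(axis=2)
        return arr.astype(np.uint8)
    if isinstance(image, Image.Image):
        return np.asarray(image.convert("L"))
    try:
        with Image.open(image) as im:
            return np.asarray(im.convert("L"))
    except FileNotFoundError as e:
        raise QRImageError(f"image file not found: {image}") from e
    except OSError as e:
        raise QRImageError(f"cannot load image {image}: {e}") from e


def decode_qr(image) -> DecodeOutcome:
    """Decode the sample UUID from a photograph.

    Policy: if every readable code in the image carries the same UUID, that
    UUID is returned (a re-photographed envelope is consistent); codes with
    different UUIDs make the photo unreadable (one photo documents one
    envelope). Never raises on decodable-but-meaningless image content.
    """
    gray = _to_gray(image)
    payloads = decode_image(gray)
    if not payloads:
        return DecodeOutcome("unreadable", reason="no QR code detected")
    texts = []
    for p in payloads:
        try:
            texts.append(p.decode("ascii").strip().lower())
        except UnicodeDecodeError:
            texts.append("")
    uuids = sorted({t for t in texts if is_canonical_uuid(t)})
    if not uuids:
        return DecodeOutcome("unreadable", reason="non-UUID payload")
    if len(uuids) > 1:
        return DecodeOutcome("unreadable", reason="multiple conflicting codes")
    return DecodeOutcome("ok", uuid=uuids[0])


def render_label_sheet(uuids: list[str], rows: int = 4, cols: int = 6,
                       scale: int = 4) -> list[Image.Image]:
    """Printable pages of QR labels, each captioned with its UUID text.

    Returns ceil(n / (rows*cols)) pages as grayscale images; cells are laid
    out row-major in input order so a sheet scanned label-by-label recovers
    the original ordering.
    """
    if not uuids:
        raise ValueError("no UUIDs to render")
    if rows < 1 or cols < 1:
        raise ValueError("layout must be positive")
    per_page = rows * cols
    qr_px = (29 + 8) * scale  # version-3 symbol + quiet zone
    cap_h = 14
    cell_w, cell_h = qr_px + 8, qr_px + cap_h + 8
    pages = []
    for start in range(0, len(uuids), per_page):
        page = Image.new("L", (cols * cell_w, rows * cell_h), 255)
        draw = ImageDraw.Draw(page)
        for k, u in enumerate(uuids[start:start + per_page]):
            r, c = divmod(k, cols)
            qr = encode_qr(u, scale=scale)
            x0, y0 = c * cell_w + 4, r * cell_h + 4
            page.paste(qr, (x0, y0))
            draw.text((x0, y0 + qr_px), u, fill=0)
        pages.append(page)
    return pages


def save_label_sheets(uuids: list[str], out_dir: str | Path,
                      rows: int = 4, cols: int = 6, scale: int = 4) -> list[Path]:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    n_pages = math.ceil(len(uuids) / (rows * cols))
    width = max(3, len(str(n_pages)))
    for i, page in enumerate(render_label_sheet(uuids, rows, cols, scale), 1):
        p = out_dir / f"labels_{i:0{width}d}.png"
        page.save(p)
        paths.append(p)
    return paths
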
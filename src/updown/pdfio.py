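"""Minimal PDF writer/reader for grayscale page images.

Scoring sheets travel as PDF documents, so the package needs to emit
printable templates and ingest multipage scans without an external PDF
toolchain.  This module writes a small, deterministic subset of PDF —
one full-page /DeviceGray image XObject per page, Flate-compressed —
and reads back exactly that subset (its own output and comparably
simple raster-backed scans).  Vector PDFs from arbitrary producers are
out of scope; pages that cannot be decoded raise ``PdfReadError``.
"""

from __future__ import annotations

import re
import zlib
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = ["write_image_pdf", "read_image_pdf", "PdfReadError"]

POINTS_PER_INCH = 72.0


class PdfReadError(ValueError):
    pass


def write_image_pdf(
    pages: Sequence[np.ndarray], dpi: int = 300
) -> bytes:
    """Serialise grayscale uint8 page rasters into a PDF document.

    Deterministic: identical inputs yield identical bytes (fixed zlib
    level, no timestamps or IDs).
    """
    if not pages:
        raise ValueError("at least one page required")
    chunks: list[bytes] = []
    offsets: dict[int, int] = {}
    pos = 0

    def emit(data: bytes) -> None:
        nonlocal pos
        chunks.append(data)
        pos += len(data)

    def obj(num: int, body: bytes) -> None:
        offsets[num] = pos
        emit(b"%d 0 obj\n" % num + body + b"\nendobj\n")

    emit(b"%PDF-1.4\n")
    n_pages = len(pages)
    # object numbering: 1 catalog, 2 pages, then per page i (0-based):
    # 3+3i page, 4+3i contents, 5+3i image
    obj(1, b"<< /Type /Catalog /Pages 2 0 R >>")
    kids = b" ".join(b"%d 0 R" % (3 + 3 * i) for i in range(n_pages))
    obj(2, b"<< /Type /Pages /Kids [" + kids + b"] /Count %d >>" % n_pages)
    for i, page in enumerate(pages):
        arr = np.asarray(page)
        if arr.ndim != 2 or arr.dtype != np.uint8:
            raise ValueError("pages must be 2-D uint8 arrays")
        h, w = arr.shape
        w_pt = w * POINTS_PER_INCH / dpi
        h_pt = h * POINTS_PER_INCH / dpi
        obj(
            3 + 3 * i,
            b"<< /Type /Page /Parent 2 0 R /MediaBox [0 0 %.4f %.4f] "
            b"/Resources << /XObject << /Im0 %d 0 R >> >> "
            b"/Contents %d 0 R >>" % (w_pt, h_pt, 5 + 3 * i, 4 + 3 * i),
        )
        content = b"q %.4f 0 0 %.4f 0 0 cm /Im0 Do Q" % (w_pt, h_pt)
        obj(
            4 + 3 * i,
            b"<< /Length %d >>\nstream\n" % len(content)
            + content
            + b"\nendstream",
        )
        data = zlib.compress(arr.tobytes(), 6)
        obj(
            5 + 3 * i,
            b"<< /Type /XObject /Subtype /Image /Width %d /Height %d "
            b"/ColorSpace /DeviceGray /BitsPerComponent 8 "
            b"/Filter /FlateDecode /Length %d >>\nstream\n" % (w, h, len(data))
            + data
            + b"\nendstream",
        )
    n_obj = 2 + 3 * n_pages
    xref_pos = pos
    xref = [b"xref\n0 %d\n" % (n_obj + 1), b"0000000000 65535 f \n"]
    for num in range(1, n_obj + 1):
        xref.append(b"%010d 00000 n \n" % offsets[num])
    emit(b"".join(xref))
    emit(
        b"trailer\n<< /Size %d /Root 1 0 R >>\nstartxref\n%d\n%%%%EOF\n"
        % (n_obj + 1, xref_pos)
    )
    return b"".join(chunks)


_OBJ_RE = re.compile(rb"(\d+)\s+0\s+obj\b(.*?)endobj", re.S)
_STREAM_RE = re.compile(rb"stream\r?\n(.*?)\r?\nendstream", re.S)


def _parse_objects(raw: bytes) -> dict[int, tuple[bytes, bytes | None]]:
    objects: dict[int, tuple[bytes, bytes | None]] = {}
    for m in _OBJ_RE.finditer(raw):
        num = int(m.group(1))
        body = m.group(2)
        sm = _STREAM_RE.search(body)
        stream = sm.group(1) if sm else None
        head = body[: sm.start()] if sm else body
        objects[num] = (head, stream)
    return objects


def _dict_int(head: bytes, key: bytes) -> int | None:
    m = re.search(rb"/" + key + rb"\s+(\d+)", head)
    return int(m.group(1)) if m else None


def _dict_ref(head: bytes, key: bytes) -> int | None:
    m = re.search(rb"/" + key + rb"\s+(\d+)\s+0\s+R", head)
    return int(m.group(1)) if m else None


def read_image_pdf(path: str | Path) -> tuple[list[np.ndarray], float]:
    """Decode an image-per-page PDF into (pages, dpi).

    Returns page rasters in document order and the resolution inferred
    from the first page's media box.
    """
    raw = Path(path).read_bytes()
    if not raw.startswith(b"%PDF"):
        raise PdfReadError(f"{path}: not a PDF file")
    objects = _parse_objects(raw)
    if not objects:
        raise PdfReadError(f"{path}: no PDF objects found")

    root = next(
        (n for n, (h, _) in objects.items() if b"/Type /Catalog" in h), None
    )
    if root is None:
        raise PdfReadError(f"{path}: catalog not found")
    pages_ref = _dict_ref(objects[root][0], b"Pages")
    if pages_ref is None or pages_ref not in objects:
        raise PdfReadError(f"{path}: page tree not found")
    kids_m = re.search(rb"/Kids\s*\[([^\]]*)\]", objects[pages_ref][0])
    if not kids_m:
        raise PdfReadError(f"{path}: page list not found")
    kid_nums = [int(n) for n in re.findall(rb"(\d+)\s+0\s+R", kids_m.group(1))]
    if not kid_nums:
        raise PdfReadError(f"{path}: document has no pages")

    pages: list[np.ndarray] = []
    dpi = 0.0
    for page_no, kid in enumerate(kid_nums, start=1):
        if kid not in objects:
            raise PdfReadError(f"{path}: page {page_no} object missing")
        head, _ = objects[kid]
        im_ref = None
        xm = re.search(rb"/XObject\s*<<([^>]*)>>", head)
        if xm:
            im_ref = _dict_ref(xm.group(1), rb"\w+")
        if im_ref is None or im_ref not in objects:
            raise PdfReadError(
                f"{path}: page {page_no} carries no decodable image"
            )
        ihead, stream = objects[im_ref]
        w = _dict_int(ihead, b"Width")
        h = _dict_int(ihead, b"Height")
        if stream is None or w is None or h is None:
            raise PdfReadError(f"{path}: page {page_no} image malformed")
        if b"/FlateDecode" in ihead:
            try:
                data = zlib.decompress(stream)
            except zlib.error as e:
                raise PdfReadError(
                    f"{path}: page {page_no} image stream corrupt: {e}"
                ) from None
        elif b"/Filter" not in ihead:
            data = stream
        else:
            raise PdfReadError(
                f"{path}: page {page_no} uses an unsupported image filter"
            )
        bpc = _dict_int(ihead, b"BitsPerComponent") or 8
        if bpc != 8 or b"/DeviceGray" not in ihead:
            raise PdfReadError(
                f"{path}: page {page_no} is not 8-bit grayscale"
            )
        if len(data) < w * h:
            raise PdfReadError(f"{path}: page {page_no} image truncated")
        pages.append(
            np.frombuffer(data[: w * h], dtype=np.uint8).reshape(h, w)
        )
        if page_no == 1:
            mb = re.search(
                rb"/MediaBox\s*\[\s*[\d.]+\s+[\d.]+\s+([\d.]+)", head
            )
            if mb:
                w_pt = float(mb.group(1))
                dpi = w * POINTS_PER_INCH / w_pt
    return pages, dpi or 300.0
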
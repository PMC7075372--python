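"""Tiny single-page PDF writer (uncompressed text, Helvetica).

Enough to print a one-page document of text lines; content streams are left
uncompressed so the output is grep-able and diff-able.
"""

from __future__ import annotations

from typing import List, Sequence, Tuple

# US Letter, points
PAGE_W = 612
PAGE_H = 792
MARGIN = 54


def _escape(text: str) -> str:
    out = text.replace("\\", r"\\").replace("(", r"\(").replace(")", r"\)")
    return out.encode("ascii", errors="replace").decode("ascii")


def render_pdf(lines: Sequence[Tuple[str, int, bool]]) -> bytes:
    """Build a one-page PDF from (text, font_size, bold) line tuples."""
    content = ["BT"]
    y = PAGE_H - MARGIN
    for text, size, bold in lines:
        y -= int(size * 1.45)
        font = "/F2" if bold else "/F1"
        content.append(f"{font} {size} Tf 1 0 0 1 {MARGIN} {y} Tm ({_escape(text)}) Tj")
    content.append("ET")
    stream = "\n".join(content).encode("ascii")

    objects: List[bytes] = [
        b"<< /Type /Catalog /Pages 2 0 R >>",
        b"<< /Type /Pages /Kids [3 0 R] /Count 1 >>",
        (
            f"<< /Type /Page /Parent 2 0 R /MediaBox [0 0 {PAGE_W} {PAGE_H}] "
            "/Resources << /Font << /F1 5 0 R /F2 6 0 R >> >> "
            "/Contents 4 0 R >>"
        ).encode("ascii"),
        b"<< /Length %d >>\nstream\n%s\nendstream" % (len(stream), stream),
        b"<< /Type /Font /Subtype /Type1 /BaseFont /Helvetica >>",
        b"<< /Type /Font /Subtype /Type1 /BaseFont /Helvetica-Bold >>",
    ]

    buf = bytearray(b"%PDF-1.4\n")
    offsets = [0]
    for i, obj in enumerate(objects, start=1):
        offsets.append(len(buf))
        buf += f"{i} 0 obj\n".encode("ascii") + obj + b"\nendobj\n"
    xref_pos = len(buf)
    buf += f"xref\n0 {len(objects) + 1}\n".encode("ascii")
    buf += b"0000000000 65535 f \n"
    for off in offsets[1:]:
        buf += f"{off:010d} 00000 n \n".encode("ascii")
    buf += (
        f"trailer\n<< /Size {len(objects) + 1} /Root 1 0 R >>\n"
        f"startxref\n{xref_pos}\n%%EOF\n"
    ).encode("ascii")
    return bytes(buf)
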
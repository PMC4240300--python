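"""Deterministic bitmap font for glyph rendering.

A classic 5x7 dot-matrix alphabet (uppercase A-Z and digits 2-9) defined
directly in source, plus programmatically drawn equilateral-triangle outlines
at three orientations.  The font is intentionally simple: rasters are exact
integer bitmaps, identical on every platform, and are upscaled by
nearest-neighbour replication so stroke width scales with glyph size.
The font is swappable: any mapping of symbol -> list of row strings with the
same conventions can be passed to the renderer.
"""

from __future__ import annotations

import math

import numpy as np

# 5 columns x 7 rows; '1' = ink.
FONT_5X7: dict[str, list[str]] = {
    "A": ["01110", "10001", "10001", "11111", "10001", "10001", "10001"],
    "B": ["11110", "10001", "10001", "11110", "10001", "10001", "11110"],
    "C": ["01110", "10001", "10000", "10000", "10000", "10001", "01110"],
    "D": ["11110", "10001", "10001", "10001", "10001", "10001", "11110"],
    "E": ["11111", "10000", "10000", "11110", "10000", "10000", "11111"],
    "F": ["11111", "10000", "10000", "11110", "10000", "10000", "10000"],
    "G": ["01110", "10001", "10000", "10111", "10001", "10001", "01111"],
    "H": ["10001", "10001", "10001", "11111", "10001", "10001", "10001"],
    "I": ["01110", "00100", "00100", "00100", "00100", "00100", "01110"],
    "J": ["00111", "00010", "00010", "00010", "00010", "10010", "01100"],
    "K": ["10001", "10010", "10100", "11000", "10100", "10010", "10001"],
    "L": ["10000", "10000", "10000", "10000", "10000", "10000", "11111"],
    "M": ["10001", "11011", "10101", "10101", "10001", "10001", "10001"],
    "N": ["10001", "10001", "11001", "10101", "10011", "10001", "10001"],
    "O": ["01110", "10001", "10001", "10001", "10001", "10001", "01110"],
    "P": ["11110", "10001", "10001", "11110", "10000", "10000", "10000"],
    "Q": ["01110", "10001", "10001", "10001", "10101", "10010", "01101"],
    "R": ["11110", "10001", "10001", "11110", "10100", "10010", "10001"],
    "S": ["01111", "10000", "10000", "01110", "00001", "00001", "11110"],
    "T": ["11111", "00100", "00100", "00100", "00100", "00100", "00100"],
    "U": ["10001", "10001", "10001", "10001", "10001", "10001", "01110"],
    "V": ["10001", "10001", "10001", "10001", "10001", "01010", "00100"],
    "W": ["10001", "10001", "10001", "10101", "10101", "10101", "01010"],
    "X": ["10001", "10001", "01010", "00100", "01010", "10001", "10001"],
    "Y": ["10001", "10001", "01010", "00100", "00100", "00100", "00100"],
    "Z": ["11111", "00001", "00010", "00100", "01000", "10000", "11111"],
    "2": ["01110", "10001", "00001", "00010", "00100", "01000", "11111"],
    "3": ["11111", "00010", "00100", "00010", "00001", "10001", "01110"],
    "4": ["00010", "00110", "01010", "10010", "11111", "00010", "00010"],
    "5": ["11111", "10000", "11110", "00001", "00001", "10001", "01110"],
    "6": ["00110", "01000", "10000", "11110", "10001", "10001", "01110"],
    "7": ["11111", "00001", "00010", "00100", "01000", "01000", "01000"],
    "8": ["01110", "10001", "10001", "01110", "10001", "10001", "01110"],
    "9": ["01110", "10001", "10001", "01111", "00001", "00010", "01100"],
}

FONT_ROWS = 7
FONT_COLS = 5

#: Triangle symbols: equilateral outline at 0, 120 and 240 degree rotations.
TRIANGLE_SYMBOLS = ("TRI0", "TRI120", "TRI240")


def bitmap(symbol: str) -> np.ndarray:
    """Return the 7x5 binary matrix for a font symbol."""
    rows = FONT_5X7[symbol]
    return np.array([[int(c) for c in r] for r in rows], dtype=np.uint8)


def upscale(mask: np.ndarray, scale: int) -> np.ndarray:
    """Nearest-neighbour upscaling by an integer factor."""
    if scale < 1:
        raise ValueError("scale must be >= 1")
    return np.kron(mask, np.ones((scale, scale), dtype=mask.dtype))


def triangle_mask(height_px: int, width_px: int, orientation_deg: float, stroke_px: int) -> np.ndarray:
    """Outline of an equilateral triangle inscribed in a height x width box.

    The triangle is drawn around the box centre, rotated by ``orientation_deg``
    (0 = apex up), with edges painted by a square brush of ``stroke_px`` pixels
    so line thickness matches the font stroke width.
    """
    mask = np.zeros((height_px, width_px), dtype=np.uint8)
    cy = (height_px - 1) / 2.0
    cx = (width_px - 1) / 2.0
    # circumradius limited by both box dimensions
    r = min((height_px - stroke_px) / 2.0, (width_px - stroke_px) / 2.0)
    theta = math.radians(orientation_deg)
    verts = []
    for k in range(3):
        a = theta + k * 2.0 * math.pi / 3.0
        # apex up at orientation 0: angle measured from the upward vertical
        verts.append((cy - r * math.cos(a), cx + r * math.sin(a)))
    half = stroke_px // 2
    for (y0, x0), (y1, x1) in zip(verts, verts[1:] + verts[:1]):
        n = max(height_px, width_px) * 4
        for t in np.linspace(0.0, 1.0, n):
            y = y0 + t * (y1 - y0)
            x = x0 + t * (x1 - x0)
            iy, ix = int(round(y)), int(round(x))
            y_lo, y_hi = max(0, iy - half), min(height_px, iy + stroke_px - half)
            x_lo, x_hi = max(0, ix - half), min(width_px, ix + stroke_px - half)
            mask[y_lo:y_hi, x_lo:x_hi] = 1
    return mask
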
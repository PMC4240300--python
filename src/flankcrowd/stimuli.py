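"""Stimulus construction: glyph rasters and flanked letter arrays.

Targets are uppercase letters from a 20-letter alphabet (A-Z excluding
I, J, O, Q, W and X).  Flanked arrays place a target between two flankers
(letters, digits 2-9, or triangle outlines) with an edge-to-edge gap of
0.1 deg (condensed) or 1.0 deg (spaced) of visual angle, inside a fixation
box.  Rasters are signed-contrast images: background 0, dark ink +1, light
ink -1, so reverse-polarity composites attenuate under averaging.

Six tasks are modelled:

1. unflanked letter identification (20 items, 3.2 x 2.9 deg box);
2. letter flankers; 3. shape (triangle) flankers; 4. digit flankers (2-9);
5. same-polarity letter flankers; 6. reverse-polarity letter flankers
(tasks 2-6: 24 items each, two spacing conditions, 6.4 x 2.9 deg box).
"""

from __future__ import annotations

import json
import string
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import font as _font
from .exceptions import (
    ExcludedSymbolError,
    GeometryOverflowError,
    InvalidFlankerError,
)
from .geometry import ViewingGeometry, deg_to_mm

#: Letters never used as targets (visually ambiguous or low-frequency shapes).
EXCLUDED_TARGET_LETTERS = frozenset("IJOQWX")

#: The 20-letter permitted target alphabet, in alphabetical order.
PERMITTED_TARGETS: tuple[str, ...] = tuple(
    c for c in string.ascii_uppercase if c not in EXCLUDED_TARGET_LETTERS
)

#: Canonical glyph height: 10.5 mm on screen = 1.20 deg at 500 mm.
DEFAULT_HEIGHT_DEG = 1.20

#: Edge-to-edge target-flanker gaps per spacing condition (deg).
GAP_DEG = {"condensed": 0.1, "spaced": 1.0}

#: Fixation boxes (width, height) in deg.
FIXATION_BOX_UNFLANKED = (3.2, 2.9)
FIXATION_BOX_FLANKED = (6.4, 2.9)

#: Number of flanked items per task (each probed in two spacing conditions).
ITEMS_PER_FLANKED_TASK = 24
FLANKED_TASKS = (2, 3, 4, 5, 6)


@dataclass(frozen=True)
class AlphabetSpec:
    """Permitted targets and per-task flanker candidate pools."""

    permitted_targets: tuple[str, ...] = PERMITTED_TARGETS
    flanker_pools: dict = field(
        default_factory=lambda: {
            2: tuple(string.ascii_uppercase),
            3: _font.TRIANGLE_SYMBOLS,
            4: tuple("23456789"),
            5: tuple(string.ascii_uppercase),
            6: tuple(string.ascii_uppercase),
        }
    )

    def __post_init__(self) -> None:
        if len(self.permitted_targets) != len(set(self.permitted_targets)):
            raise ValueError("duplicate letters in permitted target alphabet")


def symbol_category(symbol: str) -> str:
    """Classify a stimulus symbol as letter, digit or shape."""
    if symbol in _font.TRIANGLE_SYMBOLS:
        return "shape"
    if len(symbol) == 1 and symbol.isdigit():
        return "digit"
    if len(symbol) == 1 and symbol.isupper():
        return "letter"
    raise InvalidFlankerError(f"unrecognised stimulus symbol {symbol!r}")


@dataclass(frozen=True)
class Glyph:
    """One rendered symbol as a signed-contrast raster.

    ``raster`` entries lie in [-1, +1]; 0 is background and the sign of every
    ink pixel equals ``polarity`` (+1 dark ink, -1 light ink).
    """

    symbol: str
    category: str
    polarity: int
    raster: np.ndarray
    height_deg: float

    def __post_init__(self) -> None:
        r = self.raster
        if not np.any(r):
            raise ValueError(f"glyph {self.symbol!r} has no ink")
        if np.any(np.abs(r) > 1):
            raise ValueError("raster entries must lie in [-1, 1]")
        nz = r[r != 0]
        if not np.all(np.sign(nz) == self.polarity):
            raise ValueError("ink sign must equal polarity")

    @property
    def ink_pixels(self) -> int:
        return int(np.count_nonzero(self.raster))

    def flipped(self) -> "Glyph":
        """Copy with reversed contrast polarity."""
        return Glyph(self.symbol, self.category, -self.polarity, -self.raster, self.height_deg)


def render_glyph(
    symbol: str,
    category: str | None = None,
    polarity: int = 1,
    height_deg: float = DEFAULT_HEIGHT_DEG,
    geometry: ViewingGeometry | None = None,
    role: str = "target",
    font_table: dict | None = None,
) -> Glyph:
    """Render a symbol to a signed-contrast raster at exact visual-angle height.

    The raster height in pixels is ``round(deg_to_mm(height_deg) / pixel_pitch)``;
    the 5x7 dot-matrix bitmap (or triangle outline) is upscaled by an integer
    factor and centred vertically.  Rendering is fully deterministic.

    Parameters
    ----------
    role : {"target", "flanker", "response"}
        Excluded letters (I, J, O, Q, W, X) raise :class:`ExcludedSymbolError`
        when rendered as targets but are legal flankers/responses references.
    """
    geometry = geometry or ViewingGeometry()
    if category is None:
        category = symbol_category(symbol)
    if polarity not in (1, -1):
        raise ValueError(f"polarity must be +1 or -1, got {polarity}")

    if category == "letter":
        if role == "target" and symbol in EXCLUDED_TARGET_LETTERS:
            raise ExcludedSymbolError(f"{symbol!r} is not a permitted target letter")
        if symbol not in _font.FONT_5X7 or not symbol.isalpha():
            raise ExcludedSymbolError(f"unknown letter {symbol!r}")
    elif category == "digit":
        if symbol not in tuple("23456789"):
            raise InvalidFlankerError(f"digit flankers must be 2-9, got {symbol!r}")
    elif category == "shape":
        if symbol not in _font.TRIANGLE_SYMBOLS:
            raise InvalidFlankerError(f"unknown shape {symbol!r}")
    else:
        raise InvalidFlankerError(f"unknown category {category!r}")

    height_px = geometry.deg_to_px(height_deg)
    scale = max(1, height_px // _font.FONT_ROWS)
    width_px = _font.FONT_COLS * scale

    if category == "shape":
        # equal height and line thickness to the letters
        orientation = float(symbol[3:])
        mask = _font.triangle_mask(_font.FONT_ROWS * scale, width_px, orientation, scale)
    else:
        table = font_table if font_table is not None else _font.FONT_5X7
        base = np.array([[int(c) for c in r] for r in table[symbol]], dtype=np.uint8)
        mask = _font.upscale(base, scale)

    # pad rows so the raster height matches the requested visual angle exactly
    pad = height_px - mask.shape[0]
    top = pad // 2
    raster = np.zeros((height_px, width_px), dtype=np.float64)
    raster[top : top + mask.shape[0], :] = mask
    return Glyph(symbol, category, polarity, polarity * raster, height_deg)


def ink_columns(raster: np.ndarray) -> tuple[int, int]:
    """Leftmost and rightmost columns containing ink."""
    cols = np.flatnonzero(np.abs(raster).sum(axis=0))
    return int(cols[0]), int(cols[-1])


@dataclass(frozen=True)
class StimulusArray:
    """A flanked stimulus: left flanker, target, right flanker on one line."""

    target: Glyph
    left_flanker: Glyph
    right_flanker: Glyph
    gap_deg: float
    spacing_condition: str
    polarity_condition: str
    fixation_box_deg: tuple[float, float]
    canvas: np.ndarray

    @property
    def symbols(self) -> tuple[str, str, str]:
        return (self.left_flanker.symbol, self.target.symbol, self.right_flanker.symbol)


def build_array(
    target: Glyph,
    flankers: tuple[Glyph, Glyph],
    spacing_condition: str = "condensed",
    polarity_condition: str = "same",
    geometry: ViewingGeometry | None = None,
    fixation_box_deg: tuple[float, float] = FIXATION_BOX_FLANKED,
    gap_deg: float | None = None,
) -> StimulusArray:
    """Compose target and flankers with an exact edge-to-edge ink gap.

    ``polarity_condition="reverse"`` flips the contrast polarity of the
    flankers only (the target keeps its polarity).  The measured ink gap on
    the composed canvas equals the requested gap to within one pixel pitch.
    """
    geometry = geometry or ViewingGeometry()
    if spacing_condition not in GAP_DEG:
        raise ValueError(f"unknown spacing condition {spacing_condition!r}")
    if polarity_condition not in ("same", "reverse"):
        raise ValueError(f"unknown polarity condition {polarity_condition!r}")
    if gap_deg is None:
        gap_deg = GAP_DEG[spacing_condition]

    left, right = flankers
    if left.raster.shape[0] != target.raster.shape[0] or right.raster.shape[0] != target.raster.shape[0]:
        raise ValueError("flanker rasters must match target raster height")
    if polarity_condition == "reverse":
        left, right = left.flipped(), right.flipped()

    gap_px = geometry.deg_to_px(gap_deg)
    h = target.raster.shape[0]

    # ink-aware placement: gaps measured between ink bounding boxes
    parts = [left.raster, target.raster, right.raster]
    bounds = [ink_columns(r) for r in parts]
    widths = [r.shape[1] for r in parts]

    x = 0
    offsets = []
    for i, r in enumerate(parts):
        if i == 0:
            offsets.append(0)
            x = bounds[0][1]  # rightmost ink column, absolute
        else:
            off = x + gap_px + 1 - bounds[i][0]
            offsets.append(off)
            x = off + bounds[i][1]
    total_w = max(off + w for off, w in zip(offsets, widths))

    canvas = np.zeros((h, total_w), dtype=np.float64)
    for off, r in zip(offsets, parts):
        canvas[:, off : off + r.shape[1]] += r

    box_w_px = geometry.deg_to_px(fixation_box_deg[0])
    box_h_px = geometry.deg_to_px(fixation_box_deg[1])
    ink_l, ink_r = ink_columns(canvas)
    if (ink_r - ink_l + 1) > box_w_px or h > box_h_px:
        raise GeometryOverflowError(
            f"stimulus ({ink_r - ink_l + 1}x{h} px ink) exceeds fixation box "
            f"({box_w_px}x{box_h_px} px)"
        )
    return StimulusArray(
        target=target,
        left_flanker=left,
        right_flanker=right,
        gap_deg=gap_deg,
        spacing_condition=spacing_condition,
        polarity_condition=polarity_condition,
        fixation_box_deg=fixation_box_deg,
        canvas=canvas,
    )


def measured_gaps_px(array: StimulusArray) -> tuple[int, int]:
    """Edge-to-edge ink gaps (left-target, target-right) on the composed canvas.

    Only meaningful when neighbouring glyph inks do not overlap (gap > 0).
    """
    canvas = array.canvas
    col_ink = np.abs(canvas).sum(axis=0) > 0
    runs = []
    in_gap, start = False, 0
    l, r = ink_columns(canvas)
    for i in range(l, r + 1):
        if not col_ink[i] and not in_gap:
            in_gap, start = True, i
        elif col_ink[i] and in_gap:
            in_gap = False
            runs.append(i - start)
    # the two widest interior blank runs are the target-flanker gaps
    runs.sort(reverse=True)
    if len(runs) < 2:
        raise ValueError("could not identify two target-flanker gaps")
    return runs[1], runs[0]


# ---------------------------------------------------------------------------
# export helpers

def raster_to_u8(raster: np.ndarray) -> np.ndarray:
    """Map signed contrast [-1, 1] to 8-bit grey (background 127)."""
    return np.clip(np.round(127.5 - 127.5 * raster), 0, 255).astype(np.uint8)


def write_pgm(raster: np.ndarray, path: str | Path) -> None:
    """Write a plain-text (P2) PGM image of a signed-contrast raster."""
    u8 = raster_to_u8(raster)
    lines = [f"P2", f"{u8.shape[1]} {u8.shape[0]}", "255"]
    lines += [" ".join(str(v) for v in row) for row in u8]
    Path(path).write_text("\n".join(lines) + "\n")


def write_png(raster: np.ndarray, path: str | Path) -> None:
    from PIL import Image

    Image.fromarray(raster_to_u8(raster), mode="L").save(str(path))


def array_metadata(array: StimulusArray, geometry: ViewingGeometry) -> dict:
    """JSON-serialisable sidecar describing a stimulus array."""
    return {
        "target": array.target.symbol,
        "left_flanker": array.left_flanker.symbol,
        "right_flanker": array.right_flanker.symbol,
        "gap_deg": array.gap_deg,
        "spacing_condition": array.spacing_condition,
        "polarity_condition": array.polarity_condition,
        "fixation_box_deg": list(array.fixation_box_deg),
        "distance_mm": geometry.distance_mm,
        "pixel_pitch_mm": geometry.pixel_pitch_mm,
        "canvas_shape": list(array.canvas.shape),
    }


def write_array(array: StimulusArray, geometry: ViewingGeometry, stem: str | Path, png: bool = False) -> None:
    stem = Path(stem)
    write_pgm(array.canvas, stem.with_suffix(".pgm"))
    if png:
        write_png(array.canvas, stem.with_suffix(".png"))
    stem.with_suffix(".json").write_text(json.dumps(array_metadata(array, geometry), indent=2))
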
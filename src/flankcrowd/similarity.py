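"""Pixel-overlap similarity between glyph images.

Similarity between two signed-contrast rasters is a fuzzy Jaccard index on
ink magnitude:

    sim(a, b) = sum_px min(|a|, |b|) / sum_px max(|a|, |b|)

which on binary masks reduces exactly to |intersection| / |union|.  Scores
are symmetric, bounded in [0, 1], equal 1 only for magnitude-identical
images, and 0 only for disjoint ink supports.  Before comparison the images
are zero-padded onto a common canvas and (optionally) aligned by integer
centre-of-mass shifts, so letter identity rather than position drives the
score.  Polarity enters through composite formation (opposite-polarity ink
cancels in the average), never through the metric itself, which sees only
ink magnitude.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import UndefinedSimilarityError
from .stimuli import Glyph


def _as_raster(image) -> np.ndarray:
    if isinstance(image, Glyph):
        return image.raster
    return np.asarray(image, dtype=np.float64)


def _pad_to(raster: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Centre a raster on a zero canvas of the given shape."""
    out = np.zeros(shape, dtype=np.float64)
    dy = (shape[0] - raster.shape[0]) // 2
    dx = (shape[1] - raster.shape[1]) // 2
    out[dy : dy + raster.shape[0], dx : dx + raster.shape[1]] = raster
    return out


def _centre_of_mass(mag: np.ndarray) -> tuple[float, float]:
    total = mag.sum()
    ys, xs = np.nonzero(mag)
    w = mag[ys, xs]
    return float((ys * w).sum() / total), float((xs * w).sum() / total)


def _round_towards_zero(x: float) -> int:
    """Round to nearest integer, ties toward zero (|0.5| -> 0 shift side)."""
    return int(np.sign(x) * np.ceil(abs(x) - 0.5))


def _shift(raster: np.ndarray, dy: int, dx: int) -> np.ndarray:
    out = np.zeros_like(raster)
    h, w = raster.shape
    ys0, ys1 = max(0, dy), min(h, h + dy)
    xs0, xs1 = max(0, dx), min(w, w + dx)
    out[ys0:ys1, xs0:xs1] = raster[ys0 - dy : ys1 - dy, xs0 - dx : xs1 - dx]
    return out


def align_rasters(a: np.ndarray, b: np.ndarray, align: bool = True) -> tuple[np.ndarray, np.ndarray]:
    """Pad two rasters to a common canvas; optionally align centres of mass.

    Alignment shifts ``b`` by the integer-rounded centre-of-mass offset
    (ties broken toward the zero shift).
    """
    shape = (max(a.shape[0], b.shape[0]) + 2, max(a.shape[1], b.shape[1]) + 2)
    pa, pb = _pad_to(a, shape), _pad_to(b, shape)
    if align and np.any(pa) and np.any(pb):
        cya, cxa = _centre_of_mass(np.abs(pa))
        cyb, cxb = _centre_of_mass(np.abs(pb))
        dy = _round_towards_zero(cya - cyb)
        dx = _round_towards_zero(cxa - cxb)
        pb = _shift(pb, dy, dx)
    return pa, pb


def pixel_overlap(image_a, image_b, align: bool = True, metric: str = "jaccard") -> float:
    """Pixel-overlap similarity between two images.

    Parameters
    ----------
    image_a, image_b : Glyph or 2-D array
        Signed-contrast rasters; only ink magnitude is compared.
    align : bool
        Integer centre-of-mass alignment before comparison.
    metric : {"jaccard", "intersection"}
        ``"jaccard"`` returns intersection/union in [0, 1] (default);
        ``"intersection"`` returns the raw fuzzy intersection mass.
    """
    a = np.abs(_as_raster(image_a))
    b = np.abs(_as_raster(image_b))
    if not np.any(a) and not np.any(b):
        raise UndefinedSimilarityError("similarity of two blank images is undefined")
    pa, pb = align_rasters(a, b, align=align)
    inter = np.minimum(pa, pb).sum()
    if metric == "intersection":
        return float(inter)
    if metric != "jaccard":
        raise ValueError(f"unknown metric {metric!r}")
    union = np.maximum(pa, pb).sum()
    return float(inter / union)


def composite_average(target, flankers) -> np.ndarray:
    """Per-pixel mean of target and flanker signed-contrast rasters.

    Glyphs are centre-aligned on a common canvas.  Averaging three copies of
    one glyph returns that glyph; a flanker of opposite polarity cancels ink
    where it overlaps its counterpart, so reverse-polarity arrays yield
    attenuated composites.
    """
    left, right = flankers
    rasters = [_as_raster(target), _as_raster(left), _as_raster(right)]
    shape = (max(r.shape[0] for r in rasters), max(r.shape[1] for r in rasters))
    stacked = np.stack([_pad_to(r, shape) for r in rasters])
    return stacked.mean(axis=0)


@dataclass(frozen=True)
class SimilarityProfile:
    """Similarity of one reference image to each letter of an alphabet."""

    reference_label: str
    candidates: tuple[str, ...]
    values: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.candidates) != len(self.values):
            raise ValueError("one value per candidate required")
        if any(not (0.0 <= v <= 1.0) for v in self.values):
            raise ValueError("similarity values must lie in [0, 1]")

    @property
    def argmax(self) -> str:
        """Candidate with the highest similarity (first on ties)."""
        return self.candidates[int(np.argmax(self.values))]

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.candidates, self.values))


def similarity_profile(
    reference,
    candidate_glyphs: dict[str, Glyph],
    reference_label: str = "reference",
    align: bool = True,
) -> SimilarityProfile:
    """Pixel-overlap similarity of a reference image against an alphabet.

    ``candidate_glyphs`` maps letters to rendered glyphs; the profile carries
    one value per candidate in mapping order and exposes the best-matching
    candidate via :attr:`SimilarityProfile.argmax`.
    """
    if not candidate_glyphs:
        raise ValueError("alphabet must be non-empty")
    ref = np.abs(_as_raster(reference))
    if not np.any(ref):
        raise UndefinedSimilarityError("blank reference image")
    letters = tuple(candidate_glyphs)
    values = tuple(
        pixel_overlap(ref, candidate_glyphs[c], align=align) for c in letters
    )
    return SimilarityProfile(reference_label, letters, values)


def similarity_table(profiles: list[SimilarityProfile]):
    """Long-format table (reference_label, candidate, value) for TSV export."""
    import pandas as pd

    rows = [
        {"reference_label": p.reference_label, "candidate": c, "value": v}
        for p in profiles
        for c, v in zip(p.candidates, p.values)
    ]
    return pd.DataFrame(rows, columns=["reference_label", "candidate", "value"])
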
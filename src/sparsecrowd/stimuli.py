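"""Display images: a central target with flankers, plus set generators.

A display is a square black image with white binary glyphs combined by
element-wise max. The central glyph is the item the decoder must identify;
flankers are the clutter that induces crowding. The horizontal axis stands
for eccentricity: the left edge of the image is the most foveal position and
eccentricity increases to the right.

Positions are stored as ``(row, col)`` top-left corners, 0-based. Statements
like "25 pixels to the left" refer to bounding-box-center to
bounding-box-center offsets, which for equal-sized glyphs equal top-left
offsets.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import BoundsError, PlacementError
from .glyphs import DEFAULT_GLYPH_SIZE, render_glyph

MAX_PLACEMENT_RETRIES = 1000


@dataclass(frozen=True)
class DisplayImage:
    """A composed stimulus with ground-truth annotations."""

    pixels: np.ndarray
    target_id: str
    flankers: tuple[tuple[str, tuple[int, int]], ...]
    glyph_size: int = DEFAULT_GLYPH_SIZE

    @property
    def display_size(self) -> int:
        return self.pixels.shape[0]

    @property
    def target_position(self) -> tuple[int, int]:
        return center_position(self.display_size, self.glyph_size)


@dataclass(frozen=True)
class LabelledSet:
    """A list of displays with labels, plus provenance for replay."""

    items: tuple[tuple[DisplayImage, str], ...]
    role: str  # "training" | "test"
    seed: int | None = None
    variant: str | None = None

    def __len__(self) -> int:
        return len(self.items)

    def images(self) -> np.ndarray:
        """Stack all displays into an (n, H, W) array."""
        return np.stack([d.pixels for d, _ in self.items])

    def labels(self) -> list[str]:
        return [lab for _, lab in self.items]

    def to_manifest(self) -> dict:
        return {
            "role": self.role,
            "seed": self.seed,
            "variant": self.variant,
            "n_items": len(self.items),
            "items": [
                {
                    "target": lab,
                    "flankers": [
                        {"symbol": s, "position": list(map(int, p))}
                        for s, p in d.flankers
                    ],
                }
                for d, lab in self.items
            ],
        }


def center_position(display_size: int, glyph_size: int = DEFAULT_GLYPH_SIZE) -> tuple[int, int]:
    """Top-left corner that centers a glyph on the display."""
    off = (display_size - glyph_size) // 2
    return (off, off)


def compose_display(
    target_id: str,
    flankers: Sequence[tuple[str, tuple[int, int]]] = (),
    display_size: int = 101,
    glyph_size: int = DEFAULT_GLYPH_SIZE,
) -> DisplayImage:
    """Place the target at the center and flankers at given top-left corners.

    Overlapping glyphs combine by element-wise max (white on black).

    Raises
    ------
    BoundsError
        If any flanker would extend outside the image.
    """
    px = np.zeros((display_size, display_size), dtype=float)
    r0, c0 = center_position(display_size, glyph_size)
    px[r0 : r0 + glyph_size, c0 : c0 + glyph_size] = render_glyph(
        target_id, glyph_size
    ).pixels
    placed = []
    for symbol_id, (r, c) in flankers:
        r, c = int(r), int(c)
        if r < 0 or c < 0 or r + glyph_size > display_size or c + glyph_size > display_size:
            raise BoundsError(
                f"flanker {symbol_id!r} at {(r, c)} exceeds {display_size}x{display_size} bounds"
            )
        g = render_glyph(symbol_id, glyph_size).pixels
        region = px[r : r + glyph_size, c : c + glyph_size]
        np.maximum(region, g, out=region)
        placed.append((symbol_id, (r, c)))
    return DisplayImage(px, target_id, tuple(placed), glyph_size)


def _boxes_overlap(a: tuple[int, int], b: tuple[int, int], size: int) -> bool:
    return abs(a[0] - b[0]) < size and abs(a[1] - b[1]) < size


def place_random_flankers(
    n_flankers: int,
    display_size: int,
    target_id: str,
    rng: np.random.Generator,
    symbols: Sequence[str],
    glyph_size: int = DEFAULT_GLYPH_SIZE,
) -> list[tuple[str, tuple[int, int]]]:
    """Draw flanker identities and non-overlapping in-bounds positions.

    Identities are uniform over ``symbols`` (a flanker may repeat the
    target). Positions are uniform over all in-bounds top-left corners,
    rejecting placements whose bounding box overlaps the central target box
    or a previously placed flanker box.

    Raises
    ------
    PlacementError
        If a non-overlapping placement is not found within the retry budget.
    """
    hi = display_size - glyph_size  # inclusive max top-left coordinate
    if hi < 0:
        raise BoundsError("glyph does not fit in the display")
    occupied = [center_position(display_size, glyph_size)]
    out: list[tuple[str, tuple[int, int]]] = []
    for _ in range(n_flankers):
        symbol = symbols[int(rng.integers(len(symbols)))]
        for _attempt in range(MAX_PLACEMENT_RETRIES):
            pos = (int(rng.integers(hi + 1)), int(rng.integers(hi + 1)))
            if not any(_boxes_overlap(pos, o, glyph_size) for o in occupied):
                break
        else:
            raise PlacementError(
                f"no non-overlapping position found after {MAX_PLACEMENT_RETRIES} tries"
            )
        occupied.append(pos)
        out.append((symbol, pos))
    return out


def random_set(
    symbols: Sequence[str],
    n_items: int,
    display_size: int,
    n_flankers: int,
    rng: np.random.Generator,
    role: str,
    glyph_size: int = DEFAULT_GLYPH_SIZE,
    variant: str | None = None,
) -> LabelledSet:
    """Class-balanced set of displays with randomly placed flankers."""
    k = len(symbols)
    if n_items % k:
        raise ValueError(f"n_items={n_items} not divisible by {k} classes")
    items = []
    for symbol in symbols:
        for _ in range(n_items // k):
            fl = place_random_flankers(
                n_flankers, display_size, symbol, rng, symbols, glyph_size
            )
            items.append((compose_display(symbol, fl, display_size, glyph_size), symbol))
    return LabelledSet(tuple(items), role=role, variant=variant)


def single_flanker_probe_set(
    symbols: Sequence[str],
    display_size: int = 101,
    offset: int = 25,
    glyph_size: int = DEFAULT_GLYPH_SIZE,
) -> LabelledSet:
    """The fixed single-flanker test battery for asymmetry/substitution probes.

    One flanker per image, centered ``offset`` px to the left (inner, more
    foveal) or right (outer, more eccentric) of the target; the flanker is
    never the same symbol as the target. With 3 symbols this yields
    3 targets x 2 flankers x 2 sides = 12 images.
    """
    r0, c0 = center_position(display_size, glyph_size)
    items = []
    for target in symbols:
        for flanker in symbols:
            if flanker == target:
                continue
            for dx in (-offset, offset):
                d = compose_display(
                    target, [(flanker, (r0, c0 + dx))], display_size, glyph_size
                )
                items.append((d, target))
    return LabelledSet(tuple(items), role="test", variant="inner_outer")


def flanker_side(display: DisplayImage) -> str:
    """'inner' if the single flanker is left (foveal) of the target, else 'outer'."""
    (sym, (r, c)), = display.flankers
    return "inner" if c < display.target_position[1] else "outer"


def paired_flanker_set(
    symbols: Sequence[str],
    axis: str,
    display_size: int = 101,
    offset: int = 25,
    glyph_size: int = DEFAULT_GLYPH_SIZE,
) -> LabelledSet:
    """Two-flanker battery for the radial-bias probe.

    Flankers sit at +/-``offset`` px from the target along the horizontal
    (``axis='lr'``, radial) or vertical (``axis='ab'``, tangential) axis.
    Flankers are never the target's own symbol; every ordered pair of
    non-target symbols appears: 3 targets x 4 pairs = 12 images per axis.
    """
    if axis not in ("lr", "ab"):
        raise ValueError("axis must be 'lr' or 'ab'")
    r0, c0 = center_position(display_size, glyph_size)
    if axis == "lr":
        p_minus, p_plus = (r0, c0 - offset), (r0, c0 + offset)
    else:
        p_minus, p_plus = (r0 - offset, c0), (r0 + offset, c0)
    items = []
    for target in symbols:
        others = [s for s in symbols if s != target]
        for fa, fb in [(a, b) for a in others for b in others]:
            d = compose_display(
                target, [(fa, p_minus), (fb, p_plus)], display_size, glyph_size
            )
            items.append((d, target))
    return LabelledSet(tuple(items), role="test", variant=f"radial_{axis}")


def zone_probe_positions(
    display_size: int, stride: int = 1, glyph_size: int = DEFAULT_GLYPH_SIZE
) -> list[tuple[int, int]]:
    """Grid of flanker top-left corners covering every in-bounds placement."""
    hi = display_size - glyph_size
    coords = range(0, hi + 1, stride)
    return [(r, c) for r in coords for c in coords]


def save_png(display: DisplayImage, path) -> None:
    """Write a display as an 8-bit grayscale PNG for inspection."""
    from PIL import Image

    arr = (np.clip(display.pixels, 0, 1) * 255).astype(np.uint8)
    Image.fromarray(arr, mode="L").save(path)


def save_manifest(labelled_set: LabelledSet, path) -> None:
    with open(path, "w") as fh:
        json.dump(labelled_set.to_manifest(), fh, indent=2)
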
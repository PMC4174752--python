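"""Binary symbol glyphs used as both stimuli and receptive-field templates.

Each glyph is a ``glyph_size x glyph_size`` array of {0, 1} drawn with a
common stroke width, white-on-black. The same bitmaps serve two purposes:
they are stamped into display images as targets/flankers, and (normalised)
they are the matched filters that define receptive-field tuning.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from .errors import UnknownSymbolError

#: All symbol names the renderer knows, grouped by the tasks that use them.
OBJECT_SYMBOLS = ("circle", "triangle", "x")
LINE_SYMBOLS = ("hline", "vline")
TUMBLING_T_SYMBOLS = ("T_up", "T_down", "T_left", "T_right")
ALL_SYMBOLS = OBJECT_SYMBOLS + LINE_SYMBOLS + TUMBLING_T_SYMBOLS

DEFAULT_GLYPH_SIZE = 20


@dataclass(frozen=True)
class GlyphBitmap:
    """A single rendered symbol.

    Attributes
    ----------
    symbol_id:
        Name of the symbol (one of :data:`ALL_SYMBOLS`).
    pixels:
        Square binary array, values in {0, 1}, dtype float64.
    """

    symbol_id: str
    pixels: np.ndarray

    @property
    def size(self) -> int:
        return self.pixels.shape[0]


def _stroke_width(glyph_size: int) -> int:
    # 2 px at the canonical 20 px glyph, scaling proportionally.
    return max(1, round(glyph_size / 10))


def _segment_mask(n: int, p0, p1, half_width: float) -> np.ndarray:
    """Pixels whose centers lie within ``half_width`` of segment p0-p1."""
    yy, xx = np.mgrid[0:n, 0:n].astype(float)
    p0 = np.asarray(p0, dtype=float)
    p1 = np.asarray(p1, dtype=float)
    d = p1 - p0
    length2 = float(d @ d)
    if length2 == 0:
        dist = np.hypot(yy - p0[0], xx - p0[1])
    else:
        t = ((yy - p0[0]) * d[0] + (xx - p0[1]) * d[1]) / length2
        t = np.clip(t, 0.0, 1.0)
        dist = np.hypot(yy - (p0[0] + t * d[0]), xx - (p0[1] + t * d[1]))
    return dist <= half_width


def _render(symbol_id: str, n: int) -> np.ndarray:
    w = _stroke_width(n)
    c = (n - 1) / 2.0
    px = np.zeros((n, n), dtype=float)

    if symbol_id == "hline":
        r0 = n // 2 - w // 2 - (w % 2 and n % 2 == 0)
        r0 = (n - w) // 2
        px[r0 : r0 + w, :] = 1.0
    elif symbol_id == "vline":
        c0 = (n - w) // 2
        px[:, c0 : c0 + w] = 1.0
    elif symbol_id == "circle":
        yy, xx = np.mgrid[0:n, 0:n].astype(float)
        dist = np.hypot(yy - c, xx - c)
        outer = c + 0.2  # just enough that the ring touches all four edges
        px[(dist <= outer) & (dist >= outer - w)] = 1.0
    elif symbol_id == "triangle":
        apex = (0.0, c)
        bl = (n - 1.0, 0.0)
        br = (n - 1.0, n - 1.0)
        half = w / 2.0
        for a, b in ((apex, bl), (apex, br), (bl, br)):
            px[_segment_mask(n, a, b, half)] = 1.0
    elif symbol_id == "x":
        half = w / 2.0
        px[_segment_mask(n, (0.0, 0.0), (n - 1.0, n - 1.0), half)] = 1.0
        px[_segment_mask(n, (0.0, n - 1.0), (n - 1.0, 0.0), half)] = 1.0
    elif symbol_id in TUMBLING_T_SYMBOLS:
        # Upright T: full-width crossbar at the top plus a centered
        # full-height stem, both at the hline/vline stroke width.
        t = np.zeros((n, n), dtype=float)
        t[0:w, :] = 1.0
        c0 = (n - w) // 2
        t[:, c0 : c0 + w] = 1.0
        if symbol_id == "T_up":
            px = t
        elif symbol_id == "T_down":
            px = t[::-1, :].copy()
        elif symbol_id == "T_right":
            px = np.rot90(t, k=-1).copy()
        else:  # T_left
            px = np.rot90(t, k=1).copy()
    else:
        raise UnknownSymbolError(f"unknown symbol_id: {symbol_id!r}")
    return px


@lru_cache(maxsize=None)
def _render_cached(symbol_id: str, glyph_size: int) -> np.ndarray:
    px = _render(symbol_id, glyph_size)
    px.setflags(write=False)
    return px


def render_glyph(symbol_id: str, glyph_size: int = DEFAULT_GLYPH_SIZE) -> GlyphBitmap:
    """Render one symbol as a binary bitmap.

    Deterministic for a fixed ``(symbol_id, glyph_size)``.

    Parameters
    ----------
    symbol_id:
        One of :data:`ALL_SYMBOLS`.
    glyph_size:
        Side length in pixels, at least 7.

    Raises
    ------
    UnknownSymbolError
        If ``symbol_id`` is not a known symbol.
    ValueError
        If ``glyph_size`` is below 7.
    """
    if glyph_size < 7:
        raise ValueError(f"glyph_size must be >= 7, got {glyph_size}")
    if symbol_id not in ALL_SYMBOLS:
        raise UnknownSymbolError(f"unknown symbol_id: {symbol_id!r}")
    return GlyphBitmap(symbol_id, _render_cached(symbol_id, glyph_size))
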
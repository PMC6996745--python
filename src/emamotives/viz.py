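"""Static person × motive data matrix as SVG.

Each row is one person (a group "average participant" row first); columns are
a profile sparkline, an across-motive average column, the 15 motive cells,
and the four similarity-index cells (shape r, elevation M_D, scatter Var_D,
overall ICC_de).  Within a motive cell, a blue dash marks the trait rating
and an orange dash the averaged state rating (1 at the bottom of the cell,
4 at the ceiling); a colored square whose *area* is proportional to the
trait-state difference sits between them — blue when the trait dominates,
orange when the state dominates, deeper color for more pronounced motives;
the cell background darkens with the within-person state variance.  Index
cells are light for high similarity and dark for low similarity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .aggregate import StateSummary
from .data import LikertScale, MotiveCatalog, TraitProfile
from .similarity import (
    ProfilePair,
    SimilarityIndices,
    between_person_pair,
    similarity_profile,
    within_person_pairs,
)

__all__ = ["CellEncoding", "MatrixLayout", "encode_cell", "encode_index", "build_layout", "render_matrix"]

#: Theoretical maximum variance of a variable bounded on [1, 4]: ((4-1)/2)^2.
MAX_SCATTER = 2.25
#: Maximum possible mean difference on a 1-4 scale.
MAX_ELEVATION = 3.0

ORDER_KEYS = ("overall", "shape", "elevation", "scatter", "id")

_TRAIT_RGB = (37, 99, 235)  # blue family
_STATE_RGB = (234, 88, 12)  # orange family


@dataclass(frozen=True)
class CellEncoding:
    """Visual encoding of one motive cell (positions/fractions, not pixels)."""

    trait_dash_y: float
    state_dash_y: float
    square_area_fraction: float
    square_hue: str  # "trait" | "state" | "none"
    square_depth: float
    background_shade: float  # NaN when the state variance is undefined


@dataclass(frozen=True)
class MatrixLayout:
    """Row and column order of the rendered matrix (group row first)."""

    rows: tuple[str, ...]
    columns: tuple[str, ...]
    order_key: str


def encode_cell(
    trait_value: float,
    state_value: float,
    state_variance: float,
    scale: LikertScale | None = None,
    max_variance: float = MAX_SCATTER,
) -> CellEncoding:
    """Encode one trait/state rating pair plus the state variance.

    Dash positions are fractions of cell height (0 = scale minimum at the
    bottom, 1 = maximum at the ceiling).  The square's area fraction is
    |trait − state| / scale range; its color depth maps the pair mean
    linearly from the scale onto [0.25, 1].
    """
    scale = scale or LikertScale()
    rng = scale.range
    if not (scale.contains(trait_value) and scale.contains(state_value)):
        raise ValueError("ratings outside the scale")
    if state_variance == state_variance and state_variance < 0:
        raise ValueError("state variance must be >= 0")
    diff = trait_value - state_value
    if diff > 0:
        hue = "trait"
    elif diff < 0:
        hue = "state"
    else:
        hue = "none"
    mean = (trait_value + state_value) / 2.0
    if state_variance != state_variance:
        shade = math.nan
    else:
        shade = min(state_variance / max_variance, 1.0) if max_variance > 0 else 0.0
    return CellEncoding(
        trait_dash_y=(trait_value - scale.min_value) / rng,
        state_dash_y=(state_value - scale.min_value) / rng,
        square_area_fraction=abs(diff) / rng,
        square_hue=hue,
        square_depth=0.25 + 0.75 * (mean - scale.min_value) / rng,
        background_shade=shade,
    )


def encode_index(index_name: str, value: float) -> float:
    """Lightness in [0, 1] for a similarity-index cell (1 = most similar).

    Correlation-type indices (shape, overall) map [−1, 1] linearly onto
    [0, 1]; difference-type indices map |value| against the largest possible
    difference on the scale (3 for elevation, 2.25 for scatter).
    """
    if value != value:
        return math.nan
    if index_name in ("shape", "overall"):
        return min(max((value + 1.0) / 2.0, 0.0), 1.0)
    if index_name == "elevation":
        return 1.0 - min(abs(value) / MAX_ELEVATION, 1.0)
    if index_name == "scatter":
        return 1.0 - min(abs(value) / MAX_SCATTER, 1.0)
    raise ValueError(f"unknown index {index_name!r}")


def _order_value(s: SimilarityIndices, key: str) -> float:
    if key == "overall":
        return s.icc_de
    if key == "shape":
        return s.shape_r
    if key == "elevation":
        return -abs(s.elevation_m_d)
    if key == "scatter":
        return -abs(s.scatter_var_d)
    raise ValueError(f"unknown ordering key {key!r}")


def build_layout(
    per_person: Mapping[str, SimilarityIndices],
    catalog: MotiveCatalog | None = None,
    order_key: str = "overall",
) -> MatrixLayout:
    """Row/column order: participants sorted by descending similarity on the
    ordering key (NaN last, ties broken by ascending participant id), or by
    id for ``order_key='id'``."""
    catalog = catalog or MotiveCatalog()
    if order_key not in ORDER_KEYS:
        raise ValueError(f"order_key must be one of {ORDER_KEYS}")
    pids = list(per_person)
    if order_key == "id":
        pids.sort()
    else:
        def key(pid: str):
            v = _order_value(per_person[pid], order_key)
            return (math.inf if v != v else -v, pid)

        pids.sort(key=key)
    columns = ("profile", "average", *catalog.motives, "shape_r", "elevation_m_d", "scatter_var_d", "icc_de")
    return MatrixLayout(rows=("group", *pids), columns=columns, order_key=order_key)


def _fmt(x: float) -> str:
    return f"{x:.2f}".rstrip("0").rstrip(".")


def _rgb(c: tuple[float, float, float]) -> str:
    return f"rgb({int(round(c[0]))},{int(round(c[1]))},{int(round(c[2]))})"


def _mix_white(base: tuple[int, int, int], depth: float) -> str:
    return _rgb(tuple(255 + depth * (b - 255) for b in base))


def _gray(lightness: float) -> str:
    g = int(round(255 * lightness))
    return f"rgb({g},{g},{g})"


CELL = 34.0  # cell side, px
LEFT = 58.0  # row-label gutter
TOP = 96.0  # column-header band
PROFILE_W = 64.0  # sparkline column width


def render_matrix(
    traits: Sequence[TraitProfile],
    summaries: Sequence[StateSummary],
    catalog: MotiveCatalog | None = None,
    scale: LikertScale | None = None,
    order_key: str = "overall",
) -> str:
    """Render the full matrix as an SVG document string.

    Output is deterministic for identical input.  An empty cohort yields a
    legend-only document carrying a warning note.
    """
    catalog = catalog or MotiveCatalog()
    scale = scale or LikertScale()

    pairs, _excluded = within_person_pairs(traits, summaries, catalog)
    if not pairs:
        return _svg_document(
            width=560,
            height=140,
            body=[*_legend(8, 30), '<text x="8" y="120" font-size="12" fill="#b00">warning: empty cohort — nothing to render</text>'],
        )

    per_person = {pid: similarity_profile(pair) for pid, pair in pairs}
    layout = build_layout(per_person, catalog, order_key)

    group_pair = between_person_pair(traits, summaries, catalog)
    group_sim = similarity_profile(group_pair)
    by_pid_sum = {s.participant_id: s for s in summaries}
    by_pid_pair = dict(pairs)

    # Background shading is scaled by the largest observed state variance.
    all_vars = [
        v
        for s in summaries
        for v in (s.state_var[m] for m in catalog)
        if v == v
    ]
    max_var = max(all_vars) if all_vars else 1.0
    # Group-row background: across-participant mean of within-person variances.
    group_var = {}
    for m in catalog:
        vals = [s.state_var[m] for s in summaries if s.state_var[m] == s.state_var[m]]
        group_var[m] = float(np.mean(vals)) if vals else math.nan

    k = len(catalog)
    n_index = 4
    width = LEFT + PROFILE_W + CELL * (1 + k + n_index) + 8
    legend_h = 54.0
    height = TOP + CELL * len(layout.rows) + legend_h + 10

    body: list[str] = []
    # column headers
    x = LEFT
    headers = ["profile", "average", *catalog.motives, "shape r", "elevation M_D", "scatter Var_D", "overall ICC_de"]
    widths = [PROFILE_W, CELL] + [CELL] * k + [CELL] * n_index
    for label, w in zip(headers, widths):
        cx = x + w / 2
        body.append(
            f'<text x="{_fmt(cx)}" y="{_fmt(TOP - 6)}" font-size="9" text-anchor="start" '
            f'transform="rotate(-55 {_fmt(cx)} {_fmt(TOP - 6)})">{label.replace("_", " ")}</text>'
        )
        x += w

    def motive_cell(x0: float, y0: float, enc: CellEncoding, note: str = "") -> None:
        if enc.background_shade == enc.background_shade:
            bg = _gray(1.0 - 0.45 * enc.background_shade)
        else:
            bg = "rgb(255,255,255)"
        body.append(
            f'<rect class="cell" x="{_fmt(x0)}" y="{_fmt(y0)}" width="{_fmt(CELL)}" height="{_fmt(CELL)}" '
            f'fill="{bg}" stroke="#999" stroke-width="0.5"/>'
        )
        if enc.background_shade != enc.background_shade:
            body.append(f'<text x="{_fmt(x0 + 2)}" y="{_fmt(y0 + 9)}" font-size="7" fill="#888">var?</text>')
        if enc.square_hue != "none":
            side = math.sqrt(enc.square_area_fraction) * (CELL - 4)
            base = _TRAIT_RGB if enc.square_hue == "trait" else _STATE_RGB
            body.append(
                f'<rect x="{_fmt(x0 + (CELL - side) / 2)}" y="{_fmt(y0 + (CELL - side) / 2)}" '
                f'width="{_fmt(side)}" height="{_fmt(side)}" fill="{_mix_white(base, enc.square_depth)}"/>'
            )
        pad = 3.0
        for frac, rgb in ((enc.trait_dash_y, _TRAIT_RGB), (enc.state_dash_y, _STATE_RGB)):
            yy = y0 + CELL - pad - frac * (CELL - 2 * pad)
            body.append(
                f'<line x1="{_fmt(x0 + 4)}" y1="{_fmt(yy)}" x2="{_fmt(x0 + CELL - 4)}" y2="{_fmt(yy)}" '
                f'stroke="{_rgb(rgb)}" stroke-width="2"/>'
            )
        if note:
            body.append(f'<text x="{_fmt(x0 + 2)}" y="{_fmt(y0 + CELL - 2)}" font-size="6">{note}</text>')

    def index_cell(x0: float, y0: float, name: str, value: float) -> None:
        light = encode_index(name, value)
        if light != light:
            body.append(
                f'<rect class="cell" x="{_fmt(x0)}" y="{_fmt(y0)}" width="{_fmt(CELL)}" height="{_fmt(CELL)}" '
                f'fill="url(#hatch)" stroke="#999" stroke-width="0.5"/>'
            )
            return
        body.append(
            f'<rect class="cell" x="{_fmt(x0)}" y="{_fmt(y0)}" width="{_fmt(CELL)}" height="{_fmt(CELL)}" '
            f'fill="{_gray(light)}" stroke="#999" stroke-width="0.5"/>'
        )
        txt = "#000" if light > 0.5 else "#fff"
        body.append(
            f'<text x="{_fmt(x0 + CELL / 2)}" y="{_fmt(y0 + CELL / 2 + 3)}" font-size="8" '
            f'text-anchor="middle" fill="{txt}">{value:.2f}</text>'
        )

    def sparkline(x0: float, y0: float, pair: ProfilePair) -> None:
        body.append(
            f'<rect class="cell" x="{_fmt(x0)}" y="{_fmt(y0)}" width="{_fmt(PROFILE_W)}" height="{_fmt(CELL)}" '
            f'fill="#fff" stroke="#999" stroke-width="0.5"/>'
        )
        pad = 4.0
        kk = len(pair)
        for vec, rgb in ((pair.trait, _TRAIT_RGB), (pair.state, _STATE_RGB)):
            pts = []
            for j, v in enumerate(vec):
                px = x0 + pad + j * (PROFILE_W - 2 * pad) / max(kk - 1, 1)
                frac = (v - scale.min_value) / scale.range
                py = y0 + CELL - pad - frac * (CELL - 2 * pad)
                pts.append(f"{_fmt(px)},{_fmt(py)}")
            body.append(f'<polyline points="{" ".join(pts)}" fill="none" stroke="{_rgb(rgb)}" stroke-width="1.2"/>')

    def draw_row(y0: float, label: str, pair: ProfilePair, sim: SimilarityIndices, var_by_motive) -> None:
        body.append(f'<g class="row" data-label="{label}">')
        body.append(f'<text x="{_fmt(LEFT - 6)}" y="{_fmt(y0 + CELL / 2 + 3)}" font-size="9" text-anchor="end">{label}</text>')
        x0 = LEFT
        sparkline(x0, y0, pair)
        x0 += PROFILE_W
        t_avg = float(np.mean(pair.trait))
        s_avg = float(np.mean(pair.state))
        motive_cell(x0, y0, encode_cell(t_avg, s_avg, math.nan, scale, max_var))
        x0 += CELL
        for j, m in enumerate(catalog):
            enc = encode_cell(pair.trait[j], pair.state[j], var_by_motive[m], scale, max_var)
            motive_cell(x0, y0, enc)
            x0 += CELL
        for name, value in (
            ("shape", sim.shape_r),
            ("elevation", sim.elevation_m_d),
            ("scatter", sim.scatter_var_d),
            ("overall", sim.icc_de),
        ):
            index_cell(x0, y0, name, value)
            x0 += CELL
        body.append("</g>")

    y = TOP
    draw_row(y, "group", group_pair, group_sim, group_var)
    y += CELL
    for pid in layout.rows[1:]:
        draw_row(y, pid, by_pid_pair[pid], per_person[pid], by_pid_sum[pid].state_var)
        y += CELL

    body.extend(_legend(LEFT, y + 18))
    return _svg_document(width=width, height=height, body=body)


def _legend(x: float, y: float) -> list[str]:
    items = [
        f'<line x1="{_fmt(x)}" y1="{_fmt(y)}" x2="{_fmt(x + 18)}" y2="{_fmt(y)}" stroke="{_rgb(_TRAIT_RGB)}" stroke-width="2"/>',
        f'<text x="{_fmt(x + 22)}" y="{_fmt(y + 3)}" font-size="9">trait rating</text>',
        f'<line x1="{_fmt(x + 90)}" y1="{_fmt(y)}" x2="{_fmt(x + 108)}" y2="{_fmt(y)}" stroke="{_rgb(_STATE_RGB)}" stroke-width="2"/>',
        f'<text x="{_fmt(x + 112)}" y="{_fmt(y + 3)}" font-size="9">state mean</text>',
        f'<text x="{_fmt(x)}" y="{_fmt(y + 16)}" font-size="9">square area = |trait − state| (blue: trait higher, orange: state higher); '
        f"darker cell background = larger within-person state variance; index cells: light = similar</text>",
    ]
    return items


def _svg_document(width: float, height: float, body: list[str]) -> str:
    head = (
        f'<svg xmlns="http://www.w3.org/2000/svg" width="{_fmt(width)}" height="{_fmt(height)}" '
        f'font-family="Helvetica, Arial, sans-serif">'
        '<defs><pattern id="hatch" width="6" height="6" patternUnits="userSpaceOnUse">'
        '<path d="M0,6 L6,0" stroke="#aaa" stroke-width="1"/></pattern></defs>'
        f'<rect x="0" y="0" width="{_fmt(width)}" height="{_fmt(height)}" fill="#fff"/>'
    )
    return head + "".join(body) + "</svg>"
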
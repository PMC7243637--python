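"""Deterministic SVG rendering of a nomogram geometry.

The output is a standalone SVG 1.1 document built by plain string assembly:
no timestamps, no randomness, so identical inputs give byte-identical files.
SVG user units are millimetres (via width/height attributes with a matching
viewBox); the chart's y-up coordinates are flipped once into SVG's y-down
space.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

from .core import LB_PER_KG
from .errors import ConfigurationError
from .geometry import AxisScale, NomogramGeometry

__all__ = ["Ticks", "RenderOptions", "generate_ticks", "render_svg", "write_svg"]

AXIS_TITLES = {
    "bv_weight": "Blood volume (ml) / weight (kg)",
    "rbc": "RBC volume (ml)",
    "hct": "Hct (%)",
}

# margin text shown when options.show_instructions is set; our own wording
INSTRUCTIONS = (
    "Blood loss, volume restored: subtract the loss on the BV scale, line to the "
    "initial Hct, mark RBC; pivot on RBC back to the original BV and read the new Hct.",
    "Fluid given, no blood loss: line from weight to initial Hct, mark RBC; pivot to "
    "BV plus fluid infused and read the new Hct.",
    "Loss plus fluids: subtract the loss on the BV scale, mark RBC against the initial "
    "Hct; add net fluid to the corrected BV, pivot and read the new Hct.",
    "Dehydration: line from current weight to current Hct, mark RBC; pivot to the "
    "baseline Hct and read the pre-loss weight; the weight difference in kg is the "
    "water deficit in litres.",
)


@dataclass(frozen=True)
class Ticks:
    """Sorted, deduplicated tick values for one axis."""

    majors: tuple[float, ...]
    minors: tuple[float, ...]


@dataclass(frozen=True)
class RenderOptions:
    page_mm: tuple[float, float] = (210.0, 297.0)  # A4 portrait
    margin_mm: float = 25.0
    title: str | None = None
    show_pounds: bool = False
    show_instructions: bool = False

    def __post_init__(self) -> None:
        w, h = self.page_mm
        if not (w > 0 and h > 0 and self.margin_mm >= 0):
            raise ConfigurationError("page dimensions must be positive and margin non-negative")


def generate_ticks(axis: AxisScale) -> Ticks:
    """Log-decade ticks: majors on the 1-2-5 pattern, minors at integer
    mantissas, both clipped to the axis range."""
    lo, hi = axis.value_range
    majors: list[float] = []
    minors: list[float] = []
    k_lo = math.floor(math.log10(lo))
    k_hi = math.ceil(math.log10(hi))
    for k in range(k_lo, k_hi + 1):
        decade = 10.0 ** k
        for m in range(1, 10):
            v = m * decade
            if not axis.contains(v):
                continue
            if m in (1, 2, 5):
                majors.append(v)
            else:
                minors.append(v)
    return Ticks(majors=tuple(sorted(set(majors))), minors=tuple(sorted(set(minors))))


def _weight_ticks_kg(geom: NomogramGeometry) -> list[float]:
    """Integer-kg ticks spanning the weight range of the left axis."""
    w_lo, w_hi = geom.weight_range_kg
    first = math.ceil(w_lo - 1e-9)
    last = math.floor(w_hi + 1e-9)
    return [float(w) for w in range(first, last + 1)]


def _fmt(x: float) -> str:
    """Fixed-precision coordinate formatting for byte-stable output."""
    s = f"{x:.3f}"
    return "0.000" if s == "-0.000" else s


def _fmt_value(v: float) -> str:
    if abs(v - round(v)) < 1e-9:
        return str(int(round(v)))
    return f"{v:g}"


def _axis_group(
    geom: NomogramGeometry,
    axis: AxisScale,
    flip_y,
    label_side: int,
) -> list[str]:
    """SVG fragment for one axis: the scale line, ticks, labels, title."""
    parts: list[str] = [f'<g id="axis-{axis.name}">']
    y0, y1 = axis.y_range
    x = axis.x_mm
    parts.append(
        f'<line class="axis-line" x1="{_fmt(x)}" y1="{_fmt(flip_y(y0))}" '
        f'x2="{_fmt(x)}" y2="{_fmt(flip_y(y1))}" stroke="black" stroke-width="0.4"/>'
    )
    ticks = generate_ticks(axis)
    for v in ticks.minors:
        y = flip_y(axis.y(v))
        parts.append(
            f'<line class="tick-minor" x1="{_fmt(x)}" y1="{_fmt(y)}" '
            f'x2="{_fmt(x + 1.2 * label_side)}" y2="{_fmt(y)}" stroke="black" stroke-width="0.2"/>'
        )
    for v in ticks.majors:
        y = flip_y(axis.y(v))
        xt = x + 2.5 * label_side
        anchor = "end" if label_side < 0 else "start"
        parts.append(
            f'<line class="tick-major" x1="{_fmt(x)}" y1="{_fmt(y)}" '
            f'x2="{_fmt(xt)}" y2="{_fmt(y)}" stroke="black" stroke-width="0.35"/>'
        )
        parts.append(
            f'<text class="tick-label" x="{_fmt(x + 3.2 * label_side)}" y="{_fmt(y + 1.0)}" '
            f'font-size="2.6" text-anchor="{anchor}">{_fmt_value(v)}</text>'
        )
    title = AXIS_TITLES[axis.name]
    parts.append(
        f'<text class="axis-title" x="{_fmt(x)}" y="{_fmt(flip_y(y1) - 6.0)}" '
        f'font-size="3.2" text-anchor="middle">{title}</text>'
    )
    parts.append("</g>")
    return parts


def _weight_labels(
    geom: NomogramGeometry, axis: AxisScale, flip_y, show_pounds: bool
) -> list[str]:
    """Dual weight (and optional pounds) labels on the left axis.

    The weight tick for w kg sits at the identical height as the blood-volume
    tick for ``bv_per_kg × w`` ml, which is the chart's dual-label identity.
    ``axis`` is the (possibly x-shifted) drawing copy of the left axis.
    """
    parts: list[str] = ['<g id="weight-labels">']
    for w in _weight_ticks_kg(geom):
        y = flip_y(axis.y(w * geom.bv_per_kg))
        parts.append(
            f'<line class="tick-weight" x1="{_fmt(axis.x_mm)}" y1="{_fmt(y)}" '
            f'x2="{_fmt(axis.x_mm - 2.5)}" y2="{_fmt(y)}" stroke="black" stroke-width="0.35"/>'
        )
        label = f"{_fmt_value(w)} kg"
        if show_pounds:
            label += f" / {w * LB_PER_KG:.1f} lb"
        parts.append(
            f'<text class="weight-label" x="{_fmt(axis.x_mm - 3.2)}" y="{_fmt(y - 1.2)}" '
            f'font-size="2.4" text-anchor="end">{label}</text>'
        )
    parts.append("</g>")
    return parts


def render_svg(geom: NomogramGeometry, options: RenderOptions | None = None) -> str:
    """Render the chart to an SVG document string."""
    opts = options if options is not None else RenderOptions()
    page_w, page_h = opts.page_mm
    margin = opts.margin_mm
    if geom.width_mm + 2 * margin > page_w or geom.height_mm + 2 * margin > page_h:
        raise ConfigurationError(
            f"geometry ({geom.width_mm} x {geom.height_mm} mm) plus margins ({margin} mm) "
            f"does not fit the page ({page_w} x {page_h} mm)"
        )

    def flip_y(y_chart: float) -> float:
        # chart y-up, origin bottom-left of drawing area -> SVG y-down
        return page_h - margin - y_chart

    def shift_x(x_chart: float) -> float:
        return x_chart + margin

    # axes carry absolute chart x; rebuild shifted copies for drawing only
    parts: list[str] = [
        '<?xml version="1.0" encoding="UTF-8"?>',
        f'<svg xmlns="http://www.w3.org/2000/svg" version="1.1" '
        f'width="{_fmt(page_w)}mm" height="{_fmt(page_h)}mm" '
        f'viewBox="0 0 {_fmt(page_w)} {_fmt(page_h)}">',
        '<rect width="100%" height="100%" fill="white"/>',
    ]
    title = opts.title or (
        f"Blood volume / hematocrit nomogram ({geom.population}, "
        f"{geom.bv_per_kg:g} ml/kg)"
    )
    parts.append(
        f'<text id="chart-title" x="{_fmt(page_w / 2)}" y="{_fmt(margin / 2 + 2)}" '
        f'font-size="4.5" text-anchor="middle">{title}</text>'
    )
    shifted_axes: dict[str, AxisScale] = {}
    for axis in geom.axes:
        shifted = AxisScale(
            name=axis.name,
            x_mm=shift_x(axis.x_mm),
            value_range=axis.value_range,
            modulus=axis.modulus,
            offset=axis.offset,
        )
        shifted_axes[axis.name] = shifted
        label_side = -1 if axis.name == "bv_weight" else 1
        parts.extend(_axis_group(geom, shifted, flip_y, label_side))
    parts.extend(_weight_labels(geom, shifted_axes["bv_weight"], flip_y, opts.show_pounds))
    if opts.show_instructions:
        parts.append('<g id="instructions">')
        y = page_h - margin + 5.0
        for i, line in enumerate(INSTRUCTIONS):
            parts.append(
                f'<text x="{_fmt(margin)}" y="{_fmt(y + 4.0 * i)}" font-size="2.2">'
                f"{i + 1}. {line}</text>"
            )
        parts.append("</g>")
    parts.append("</svg>")
    return "\n".join(parts) + "\n"


def write_svg(geom: NomogramGeometry, path: str | Path, options: RenderOptions | None = None) -> None:
    Path(path).write_text(render_svg(geom, options))
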
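"""Three-axis parallel-scale alignment chart and a virtual straight-edge.

The governing relation is multiplicative — red-cell volume equals blood
volume times hematocrit as a fraction — so every axis carries a base-10
logarithmic scale.  With log scales the chart identity

    log10(rbc) = log10(bv) + log10(hct / 100)

is realised *exactly* by straight-line alignment: place the two outer axes
at horizontal positions 0 and D with moduli m1 and m2 (mm per log10 unit),
and the middle axis at x = D·m1/(m1+m2) with modulus m1·m2/(m1+m2).  A
straight edge through any in-range (bv, hct) pair then crosses the middle
axis at the corresponding red-cell volume, to floating-point precision.

Chart coordinates are in millimetres with y increasing upward and the
origin at the bottom-left of the drawing area.  Values grow upward on every
axis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Any

from .core import DEFAULT_BV_PER_KG
from .errors import ChartRangeError, ConfigurationError, ValidationError

__all__ = [
    "AXIS_NAMES",
    "AxisScale",
    "NomogramGeometry",
    "IsoplethReading",
    "DEFAULT_RANGES",
    "build_geometry",
    "isopleth_read",
    "run_graphical_procedure",
    "collinearity_residual",
    "geometry_to_dict",
]

AXIS_NAMES = ("bv_weight", "rbc", "hct")

#: Default weight ranges (kg) per population; hematocrit range is shared.
DEFAULT_RANGES = {
    "pediatric": {"weight_kg": (1.0, 20.0), "hct_pct": (10.0, 70.0)},
    "adult": {"weight_kg": (30.0, 150.0), "hct_pct": (10.0, 70.0)},
}

# relative slack when checking whether a value sits on an axis, so that
# exact range endpoints survive floating-point round trips
_RANGE_RTOL = 1e-9


@dataclass(frozen=True)
class AxisScale:
    """One vertical scale: ``y(v) = modulus × log10(v) + offset`` (mm)."""

    name: str
    x_mm: float
    value_range: tuple[float, float]
    modulus: float
    offset: float

    def __post_init__(self) -> None:
        lo, hi = self.value_range
        if not (lo > 0 and hi > lo):
            raise ConfigurationError(
                f"axis {self.name!r} needs a positive, increasing value range, got {self.value_range}"
            )
        if self.modulus == 0:
            raise ConfigurationError(f"axis {self.name!r} has zero modulus")

    def contains(self, value: float) -> bool:
        lo, hi = self.value_range
        slack_lo = lo * _RANGE_RTOL
        slack_hi = hi * _RANGE_RTOL
        return (lo - slack_lo) <= value <= (hi + slack_hi)

    def y(self, value: float) -> float:
        """Vertical coordinate of ``value``; raises if off-scale."""
        if not self.contains(value):
            lo, hi = self.value_range
            raise ChartRangeError(self.name, value, lo, hi)
        return self.modulus * math.log10(value) + self.offset

    def value_at(self, y: float) -> float:
        """Inverse of :meth:`y` (does not range-check)."""
        return 10.0 ** ((y - self.offset) / self.modulus)

    @property
    def y_range(self) -> tuple[float, float]:
        lo, hi = self.value_range
        ya = self.modulus * math.log10(lo) + self.offset
        yb = self.modulus * math.log10(hi) + self.offset
        return (min(ya, yb), max(ya, yb))


@dataclass(frozen=True)
class NomogramGeometry:
    """The chart: three parallel axes satisfying the alignment property."""

    population: str
    axes: tuple[AxisScale, AxisScale, AxisScale]  # (bv_weight, rbc, hct)
    width_mm: float
    height_mm: float
    bv_per_kg: float

    def __post_init__(self) -> None:
        names = tuple(a.name for a in self.axes)
        if names != AXIS_NAMES:
            raise ConfigurationError(f"axes must be named {AXIS_NAMES} in order, got {names}")
        x0, xm, x1 = (a.x_mm for a in self.axes)
        lo, hi = sorted((x0, x1))
        if not lo < xm < hi:
            raise ConfigurationError(
                f"the rbc axis (x={xm} mm) must lie strictly between the outer axes "
                f"(x={x0} mm and x={x1} mm)"
            )

    def axis(self, name: str) -> AxisScale:
        for a in self.axes:
            if a.name == name:
                return a
        raise ValidationError(f"unknown axis {name!r}; expected one of {AXIS_NAMES}")

    @property
    def weight_range_kg(self) -> tuple[float, float]:
        lo, hi = self.axis("bv_weight").value_range
        return (lo / self.bv_per_kg, hi / self.bv_per_kg)


@dataclass(frozen=True)
class IsoplethReading:
    """Result of laying the straight edge across two known values."""

    anchor_a: tuple[str, float]
    anchor_b: tuple[str, float]
    target_axis: str
    read_value: float
    residual_mm: float


def build_geometry(
    population: str = "pediatric",
    *,
    weight_range_kg: tuple[float, float] | None = None,
    hct_range_pct: tuple[float, float] | None = None,
    bv_per_kg: float = DEFAULT_BV_PER_KG,
    width_mm: float = 150.0,
    height_mm: float = 230.0,
    modulus_ratio: float = 1.0,
) -> NomogramGeometry:
    """Construct a chart for the given population.

    ``modulus_ratio`` is the hct-axis modulus divided by the bv-axis modulus;
    1.0 (the default) gives equal outer moduli and a centred middle axis.
    The red-cell axis range is derived so every in-range (bv, hct) alignment
    stays on-chart.
    """
    if population not in DEFAULT_RANGES:
        raise ConfigurationError(
            f"unknown population {population!r}; expected one of {tuple(DEFAULT_RANGES)}"
        )
    if not bv_per_kg > 0:
        raise ConfigurationError(f"bv_per_kg must be > 0, got {bv_per_kg!r}")
    if not (width_mm > 0 and height_mm > 0):
        raise ConfigurationError("page width and height must be positive")
    if not modulus_ratio > 0:
        raise ConfigurationError(f"modulus_ratio must be > 0, got {modulus_ratio!r}")

    w_lo, w_hi = weight_range_kg or DEFAULT_RANGES[population]["weight_kg"]
    h_lo, h_hi = hct_range_pct or DEFAULT_RANGES[population]["hct_pct"]
    if not (w_lo > 0 and w_hi > w_lo):
        raise ConfigurationError(f"weight range must be positive and increasing, got {(w_lo, w_hi)}")
    if not (0 < h_lo < h_hi <= 100):
        raise ConfigurationError(
            f"hct range must satisfy 0 < lo < hi <= 100, got {(h_lo, h_hi)}"
        )

    bv_lo, bv_hi = w_lo * bv_per_kg, w_hi * bv_per_kg
    span_bv = math.log10(bv_hi) - math.log10(bv_lo)
    span_hct = math.log10(h_hi) - math.log10(h_lo)

    # scale moduli so the longer outer axis fills the drawing height
    m1 = height_mm / max(span_bv, modulus_ratio * span_hct)
    m2 = modulus_ratio * m1
    # anchor both outer scales at y = 0 for their minima
    c1 = -m1 * math.log10(bv_lo)
    c2 = -m2 * math.log10(h_lo)

    d = width_mm
    m3 = m1 * m2 / (m1 + m2)
    x3 = d * m1 / (m1 + m2)
    # the +2·m3 term absorbs the hct percent-to-fraction conversion
    # (log10(h/100) = log10(h) - 2) into the middle axis offset
    c3 = (m2 * c1 + m1 * c2) / (m1 + m2) + 2.0 * m3

    rbc_lo = bv_lo * h_lo / 100.0
    rbc_hi = bv_hi * h_hi / 100.0

    axes = (
        AxisScale("bv_weight", 0.0, (bv_lo, bv_hi), m1, c1),
        AxisScale("rbc", x3, (rbc_lo, rbc_hi), m3, c3),
        AxisScale("hct", d, (h_lo, h_hi), m2, c2),
    )
    return NomogramGeometry(
        population=population,
        axes=axes,
        width_mm=width_mm,
        height_mm=height_mm,
        bv_per_kg=bv_per_kg,
    )


def isopleth_read(
    geom: NomogramGeometry,
    anchor_a: tuple[str, float],
    anchor_b: tuple[str, float],
    target: str,
    *,
    step: str | None = None,
) -> IsoplethReading:
    """Lay a straight edge through two axis points and read the third axis.

    Pure analytic geometry — the line through the two anchor coordinates is
    intersected with the target axis's vertical line and the scale map is
    inverted.  ``step`` labels the operation in out-of-range errors.
    """
    name_a, value_a = anchor_a
    name_b, value_b = anchor_b
    if name_a == name_b:
        raise ValidationError(f"anchors must be on two distinct axes, both are {name_a!r}")
    expected = set(AXIS_NAMES)
    if {name_a, name_b, target} != expected:
        raise ValidationError(
            f"anchors and target must cover all three axes {AXIS_NAMES}; "
            f"got anchors ({name_a!r}, {name_b!r}) with target {target!r}"
        )
    ax_a, ax_b, ax_t = geom.axis(name_a), geom.axis(name_b), geom.axis(target)
    try:
        ya = ax_a.y(value_a)
        yb = ax_b.y(value_b)
    except ChartRangeError as e:
        raise ChartRangeError(e.axis, e.value, *geom.axis(e.axis).value_range, step=step) from None
    xa, xb, xt = ax_a.x_mm, ax_b.x_mm, ax_t.x_mm
    yt = ya + (yb - ya) * (xt - xa) / (xb - xa)
    value = ax_t.value_at(yt)
    if not ax_t.contains(value):
        lo, hi = ax_t.value_range
        raise ChartRangeError(target, value, lo, hi, step=step)
    return IsoplethReading(
        anchor_a=anchor_a,
        anchor_b=anchor_b,
        target_axis=target,
        read_value=value,
        residual_mm=0.0,
    )


def collinearity_residual(geom: NomogramGeometry, bv: float, hct: float) -> float:
    """Distance (mm, along the middle axis) between the chart point for
    ``rbc = bv × hct/100`` and where the (bv, hct) straight edge actually
    crosses the middle axis.  Zero for an exact geometry."""
    ax_bv, ax_rbc, ax_hct = geom.axes
    y_bv = ax_bv.y(bv)
    y_hct = ax_hct.y(hct)
    rbc = bv * hct / 100.0
    y_rbc = ax_rbc.y(rbc)
    t = (ax_rbc.x_mm - ax_bv.x_mm) / (ax_hct.x_mm - ax_bv.x_mm)
    y_line = y_bv + (y_hct - y_bv) * t
    return abs(y_rbc - y_line)


_PROCEDURES = ("loss_equilibrated", "infusion", "loss_and_fluids", "fluid_deficit")


def run_graphical_procedure(
    geom: NomogramGeometry,
    procedure: str,
    *,
    weight_kg: float,
    hct_pct: float,
    blood_loss_ml: float = 0.0,
    fluid_in_ml: float = 0.0,
    baseline_hct_pct: float | None = None,
) -> float:
    """Replay one of the four straight-edge procedures on the chart.

    Every numeric step is an :func:`isopleth_read`; scale arithmetic (e.g.
    subtracting a blood loss "on the BV scale") is done on the value before
    mapping, exactly as a clinician reads the printed chart.  Returns the
    final hematocrit in percent, except ``fluid_deficit`` which returns the
    water deficit in litres.
    """
    if procedure not in _PROCEDURES:
        raise ValidationError(f"unknown procedure {procedure!r}; expected one of {_PROCEDURES}")
    bv0 = weight_kg * geom.bv_per_kg

    if procedure == "loss_equilibrated":
        # mark the corrected volume, read the remaining red-cell volume,
        # then pivot back to the restored blood volume and read the hct
        bv_corr = bv0 - blood_loss_ml
        rbc = isopleth_read(
            geom, ("bv_weight", bv_corr), ("hct", hct_pct), "rbc", step="read RBC after loss"
        ).read_value
        return isopleth_read(
            geom, ("bv_weight", bv0), ("rbc", rbc), "hct", step="pivot to restored volume"
        ).read_value

    if procedure == "infusion":
        rbc = isopleth_read(
            geom, ("bv_weight", bv0), ("hct", hct_pct), "rbc", step="read RBC at baseline"
        ).read_value
        return isopleth_read(
            geom,
            ("bv_weight", bv0 + fluid_in_ml),
            ("rbc", rbc),
            "hct",
            step="pivot to expanded volume",
        ).read_value

    if procedure == "loss_and_fluids":
        bv_corr = bv0 - blood_loss_ml
        rbc = isopleth_read(
            geom, ("bv_weight", bv_corr), ("hct", hct_pct), "rbc", step="read RBC after loss"
        ).read_value
        return isopleth_read(
            geom,
            ("bv_weight", bv_corr + fluid_in_ml),
            ("rbc", rbc),
            "hct",
            step="pivot to net volume",
        ).read_value

    # fluid_deficit: recover the pre-dehydration weight via the red-cell volume
    if baseline_hct_pct is None:
        raise ValidationError("fluid_deficit procedure requires baseline_hct_pct")
    rbc = isopleth_read(
        geom, ("bv_weight", bv0), ("hct", hct_pct), "rbc", step="read current RBC"
    ).read_value
    bv_pre = isopleth_read(
        geom, ("rbc", rbc), ("hct", baseline_hct_pct), "bv_weight", step="pivot to baseline hct"
    ).read_value
    weight_pre = bv_pre / geom.bv_per_kg
    return weight_pre - weight_kg  # kg difference == litres of water


def geometry_to_dict(geom: NomogramGeometry) -> dict[str, Any]:
    """JSON-serializable description of the chart, for re-rendering."""
    return {
        "population": geom.population,
        "width_mm": geom.width_mm,
        "height_mm": geom.height_mm,
        "bv_per_kg": geom.bv_per_kg,
        "axes": [
            {
                "name": a.name,
                "x_mm": a.x_mm,
                "value_range": list(a.value_range),
                "modulus_mm_per_decade": a.modulus,
                "offset_mm": a.offset,
            }
            for a in geom.axes
        ],
    }
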
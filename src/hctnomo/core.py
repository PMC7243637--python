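"""Closed-form mass-balance relations between body weight, blood volume,
red-cell volume, and hematocrit.

Conventions used throughout the package:

* hematocrit (``hct``) is a **percent** in ``[0, 100]`` at every public
  interface; it is converted to a fraction only transiently inside formulas;
* volumes are real numbers in millilitres — the engine never rounds
  (rounding is a display concern only);
* blood volume defaults to 75 ml per kg of body weight for every age class;
  populations with a different per-kg rule (e.g. premature infants at
  85-100 ml/kg, or 70 ml/kg for the elderly) are handled via the
  ``bv_per_kg`` override, never auto-applied.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import ValidationError

__all__ = [
    "DEFAULT_BV_PER_KG",
    "PACKED_RBC_HCT",
    "LB_PER_KG",
    "AGE_CLASSES",
    "PatientProfile",
    "BloodState",
    "ModelConfig",
    "blood_volume",
    "rbc_volume",
    "hct_of",
    "hct_after_blood_loss",
    "hct_after_infusion",
    "hct_after_dehydration",
    "packed_rbc_to_rbc",
]

#: Default whole-blood volume per unit body mass, ml/kg.
DEFAULT_BV_PER_KG = 75.0

#: Effective hematocrit of a packed red-cell unit, as a fraction.
PACKED_RBC_HCT = 0.65

#: Pounds per kilogram; display-only conversion for secondary axis labels.
LB_PER_KG = 2.20462

AGE_CLASSES = ("premature", "infant", "adult")


@dataclass(frozen=True)
class PatientProfile:
    """A patient's mass and the rule converting it to blood volume."""

    weight_kg: float
    age_class: str = "infant"
    bv_per_kg: float = DEFAULT_BV_PER_KG

    def __post_init__(self) -> None:
        if not self.weight_kg > 0:
            raise ValidationError(f"weight must be > 0 kg, got {self.weight_kg!r}")
        if not self.bv_per_kg > 0:
            raise ValidationError(f"bv_per_kg must be > 0 ml/kg, got {self.bv_per_kg!r}")
        if self.age_class not in AGE_CLASSES:
            raise ValidationError(
                f"age_class must be one of {AGE_CLASSES}, got {self.age_class!r}"
            )

    @property
    def blood_volume_ml(self) -> float:
        return self.weight_kg * self.bv_per_kg


@dataclass(frozen=True)
class BloodState:
    """Whole-blood and red-cell volume; hematocrit is always derived.

    ``hct`` is never stored independently, so ``0 <= hct <= 100`` follows
    from the volume invariants.
    """

    bv_ml: float
    rbc_ml: float

    def __post_init__(self) -> None:
        if not self.bv_ml > 0:
            raise ValidationError(f"blood volume must be > 0 ml, got {self.bv_ml!r}")
        if self.rbc_ml < 0:
            raise ValidationError(f"RBC volume must be >= 0 ml, got {self.rbc_ml!r}")
        if self.rbc_ml > self.bv_ml:
            raise ValidationError(
                f"RBC volume ({self.rbc_ml!r} ml) cannot exceed blood volume ({self.bv_ml!r} ml)"
            )

    @property
    def hct_pct(self) -> float:
        return hct_of(self.rbc_ml, self.bv_ml)


@dataclass(frozen=True)
class ModelConfig:
    """Model constants; defaults are the ones used for chart construction."""

    packed_rbc_hct: float = PACKED_RBC_HCT
    lb_per_kg: float = LB_PER_KG
    percent_tolerance: float = 1e-9

    def __post_init__(self) -> None:
        if not 0 < self.packed_rbc_hct < 1:
            raise ValidationError(
                f"packed_rbc_hct must be a fraction in (0, 1), got {self.packed_rbc_hct!r}"
            )


def blood_volume(profile: PatientProfile) -> float:
    """Whole-blood volume in ml for a patient: ``weight × bv_per_kg``."""
    return profile.weight_kg * profile.bv_per_kg


def _check_hct(hct: float, name: str = "hct") -> None:
    if not 0 <= hct <= 100:
        raise ValidationError(f"{name} must be a percent in [0, 100], got {hct!r}")


def rbc_volume(bv: float, hct: float) -> float:
    """Red-cell volume in ml given whole-blood volume and hematocrit percent."""
    if not bv > 0:
        raise ValidationError(f"blood volume must be > 0 ml, got {bv!r}")
    _check_hct(hct)
    return bv * hct / 100.0


def hct_of(rbc: float, bv: float) -> float:
    """Hematocrit percent given red-cell and whole-blood volume.

    Exact inverse of :func:`rbc_volume`.
    """
    if not bv > 0:
        raise ValidationError(f"blood volume must be > 0 ml, got {bv!r}")
    if rbc < 0:
        raise ValidationError(f"RBC volume must be >= 0 ml, got {rbc!r}")
    if rbc > bv:
        raise ValidationError(f"RBC volume ({rbc!r} ml) cannot exceed blood volume ({bv!r} ml)")
    return rbc / bv * 100.0


def hct_after_blood_loss(hct_i: float, bv_i: float, v_lost: float) -> float:
    """Final hematocrit after losing ``v_lost`` ml of whole blood at ``hct_i``
    and restoring the blood volume with red-cell-free fluid.

    Closed form: ``hct_i × (bv_i − v_lost) / bv_i``.
    """
    if not bv_i > 0:
        raise ValidationError(f"initial blood volume must be > 0 ml, got {bv_i!r}")
    _check_hct(hct_i, "initial hct")
    if v_lost < 0:
        raise ValidationError(
            f"blood loss must be >= 0 ml, got {v_lost!r}; model a transfusion as its own event"
        )
    if v_lost >= bv_i:
        raise ValidationError(
            f"blood loss ({v_lost!r} ml) must be smaller than the blood volume ({bv_i!r} ml); "
            "total exsanguination is not modelled"
        )
    return hct_i * (bv_i - v_lost) / bv_i


def hct_after_infusion(hct_i: float, bv_i: float, v_in: float) -> float:
    """Final hematocrit after infusing ``v_in`` ml of red-cell-free fluid.

    Red-cell volume is conserved; the denominator grows:
    ``hct_i × bv_i / (bv_i + v_in)``.
    """
    if not bv_i > 0:
        raise ValidationError(f"initial blood volume must be > 0 ml, got {bv_i!r}")
    _check_hct(hct_i, "initial hct")
    if v_in < 0:
        raise ValidationError(f"infused volume must be >= 0 ml, got {v_in!r}")
    return hct_i * bv_i / (bv_i + v_in)


def hct_after_dehydration(hct_i: float, bv_i: float, v_water_lost: float) -> float:
    """Final hematocrit after ``v_water_lost`` ml of red-cell-free fluid leaves
    the circulation (urinary, gastrointestinal or insensible water loss).

    Red-cell volume is conserved while the blood volume shrinks:
    ``hct_i × bv_i / (bv_i − v_water_lost)``.  The exact inverse of
    :func:`hct_after_infusion`.
    """
    if not bv_i > 0:
        raise ValidationError(f"initial blood volume must be > 0 ml, got {bv_i!r}")
    _check_hct(hct_i, "initial hct")
    if v_water_lost < 0:
        raise ValidationError(f"water loss must be >= 0 ml, got {v_water_lost!r}")
    plasma = bv_i * (1.0 - hct_i / 100.0)
    if v_water_lost > plasma:
        raise ValidationError(
            f"water loss ({v_water_lost!r} ml) exceeds the available plasma volume "
            f"({plasma:g} ml); hematocrit cannot exceed 100%"
        )
    return hct_i * bv_i / (bv_i - v_water_lost)


def packed_rbc_to_rbc(v_packed: float, config: ModelConfig | None = None) -> float:
    """Red-cell volume delivered by ``v_packed`` ml of packed red cells.

    Packed units are assumed to have a hematocrit of 65% by default.
    """
    if v_packed < 0:
        raise ValidationError(f"packed-cell volume must be >= 0 ml, got {v_packed!r}")
    cfg = config if config is not None else ModelConfig()
    return v_packed * cfg.packed_rbc_hct
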
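"""Sequential fluid-event engine and the two inverse estimators.

The engine tracks a :class:`~hctnomo.core.BloodState` through an ordered list
of typed events.  Blood loss removes red cells at the *current* hematocrit of
the running state, so event order matters: losing blood before a crystalloid
bolus removes more red cells than the reverse order.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

from .core import (
    BloodState,
    ModelConfig,
    PatientProfile,
    blood_volume,
    hct_of,
    rbc_volume,
)
from .errors import EventError, ValidationError

__all__ = [
    "EVENT_KINDS",
    "FluidEvent",
    "ScenarioResult",
    "FluidDeficitEstimate",
    "ReferenceScenario",
    "apply_events",
    "estimate_blood_loss",
    "estimate_fluid_deficit",
    "reference_scenarios",
    "scenario_from_dict",
    "load_scenario",
    "result_to_dict",
]

EVENT_KINDS = (
    "blood_loss",
    "crystalloid_in",
    "urine_out",
    "insensible_out",
    "whole_blood_in",
    "packed_rbc_in",
    "dehydration",
    "equilibrate_to_baseline",
)

# kinds whose volume field is meaningful (equilibrate_to_baseline ignores it)
_VOLUME_KINDS = frozenset(EVENT_KINDS) - {"equilibrate_to_baseline"}


@dataclass(frozen=True)
class FluidEvent:
    """One typed change to the circulating volume.

    ``donor_hct_pct`` applies to ``whole_blood_in`` only; when ``None`` the
    patient's initial hematocrit is used (a whole-blood transfusion then acts
    as negative blood loss).
    """

    kind: str
    volume_ml: float = 0.0
    donor_hct_pct: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in EVENT_KINDS:
            raise ValidationError(f"unknown event kind {self.kind!r}; expected one of {EVENT_KINDS}")
        if self.kind in _VOLUME_KINDS and self.volume_ml < 0:
            raise ValidationError(f"event volume must be >= 0 ml, got {self.volume_ml!r}")
        if self.donor_hct_pct is not None:
            if self.kind != "whole_blood_in":
                raise ValidationError("donor_hct_pct is only valid for whole_blood_in events")
            if not 0 <= self.donor_hct_pct <= 100:
                raise ValidationError(
                    f"donor_hct_pct must be in [0, 100], got {self.donor_hct_pct!r}"
                )


@dataclass(frozen=True)
class ScenarioResult:
    """Trajectory of blood states after each event, plus an audit trail."""

    initial: BloodState
    trajectory: tuple[BloodState, ...]
    audit: tuple[str, ...]

    @property
    def final(self) -> BloodState:
        return self.trajectory[-1] if self.trajectory else self.initial

    @property
    def final_hct_pct(self) -> float:
        return self.final.hct_pct


@dataclass(frozen=True)
class FluidDeficitEstimate:
    """Back-calculated water deficit.

    ``fluid_gain`` is set when the observed hematocrit is *below* baseline,
    i.e. the patient has gained rather than lost fluid (deficit is negative).
    """

    deficit_l: float
    weight_pre_kg: float
    fluid_gain: bool


def _event_deltas(
    state: BloodState,
    event: FluidEvent,
    profile: PatientProfile,
    hct_i: float,
    config: ModelConfig,
) -> tuple[float, float]:
    """Return (new_bv, new_rbc) for one event applied to ``state``."""
    bv, rbc = state.bv_ml, state.rbc_ml
    v = event.volume_ml
    kind = event.kind
    if kind == "blood_loss":
        # whole blood leaves at the current hematocrit
        return bv - v, rbc - state.hct_pct / 100.0 * v
    if kind == "crystalloid_in":
        return bv + v, rbc
    if kind in ("urine_out", "insensible_out", "dehydration"):
        return bv - v, rbc
    if kind == "whole_blood_in":
        donor = event.donor_hct_pct if event.donor_hct_pct is not None else hct_i
        return bv + v, rbc + donor / 100.0 * v
    if kind == "packed_rbc_in":
        return bv + v, rbc + config.packed_rbc_hct * v
    if kind == "equilibrate_to_baseline":
        return blood_volume(profile), rbc
    raise AssertionError(f"unhandled event kind {kind!r}")  # pragma: no cover


def apply_events(
    profile: PatientProfile,
    hct_i: float,
    events: list[FluidEvent] | tuple[FluidEvent, ...],
    config: ModelConfig | None = None,
) -> ScenarioResult:
    """Apply ``events`` in order starting from the patient's baseline state.

    The baseline blood volume is ``blood_volume(profile)`` and the baseline
    red-cell volume is ``rbc_volume`` at ``hct_i``.  Any event that would
    drive the state out of its physical range raises :class:`EventError`
    identifying the offending event index.
    """
    cfg = config if config is not None else ModelConfig()
    bv0 = blood_volume(profile)
    state = BloodState(bv_ml=bv0, rbc_ml=rbc_volume(bv0, hct_i))
    trajectory: list[BloodState] = []
    audit: list[str] = []
    for i, event in enumerate(events):
        new_bv, new_rbc = _event_deltas(state, event, profile, hct_i, cfg)
        if not new_bv > 0:
            raise EventError(i, f"{event.kind} of {event.volume_ml:g} ml drives blood volume to {new_bv:g} ml")
        if new_rbc < 0:
            raise EventError(i, f"{event.kind} drives RBC volume negative ({new_rbc:g} ml)")
        if new_rbc > new_bv:
            raise EventError(
                i, f"{event.kind} drives RBC volume ({new_rbc:g} ml) above blood volume ({new_bv:g} ml)"
            )
        audit.append(
            f"[{i}] {event.kind}: bv {state.bv_ml:.3f} -> {new_bv:.3f} ml "
            f"(Δ{new_bv - state.bv_ml:+.3f}), rbc {state.rbc_ml:.3f} -> {new_rbc:.3f} ml "
            f"(Δ{new_rbc - state.rbc_ml:+.3f})"
        )
        state = BloodState(bv_ml=new_bv, rbc_ml=new_rbc)
        trajectory.append(state)
    return ScenarioResult(
        initial=BloodState(bv_ml=bv0, rbc_ml=rbc_volume(bv0, hct_i)),
        trajectory=tuple(trajectory),
        audit=tuple(audit),
    )


def estimate_blood_loss(profile: PatientProfile, hct_pre: float, hct_post: float) -> float:
    """Whole-blood volume lost, inferred from pre- and post-loss hematocrit.

    With baseline volume ``B``, the red-cell volumes before and after the
    loss are ``B·hct_pre/100`` and ``B·hct_post/100``; dividing their
    difference by the pre-loss hematocrit as a decimal yields
    ``B × (hct_pre − hct_post) / hct_pre`` — the exact inverse of
    :func:`~hctnomo.core.hct_after_blood_loss`.
    """
    if not 0 < hct_pre <= 100:
        raise ValidationError(f"pre-loss hct must be in (0, 100], got {hct_pre!r}")
    if not 0 < hct_post <= 100:
        raise ValidationError(f"post-loss hct must be in (0, 100], got {hct_post!r}")
    if hct_post > hct_pre:
        # tolerate float round-off from a forward/backward round trip
        if hct_post - hct_pre <= 1e-9 * hct_pre:
            hct_post = hct_pre
        else:
            raise ValidationError(
                f"post-loss hct ({hct_post!r}%) exceeds pre-loss hct ({hct_pre!r}%); "
                "no blood loss is consistent with a hematocrit rise"
            )
    bv = blood_volume(profile)
    return bv * (hct_pre - hct_post) / hct_pre


def estimate_fluid_deficit(
    weight_now_kg: float,
    hct_now: float,
    hct_baseline: float,
    bv_per_kg: float = 75.0,
) -> FluidDeficitEstimate:
    """Total-body-water deficit from the current weight and hematocrit pair.

    The red-cell volume implied by the current state is projected back to the
    baseline hematocrit to recover the pre-dehydration blood volume and hence
    weight; 1 kg of weight difference is 1 L of water.
    """
    if not weight_now_kg > 0:
        raise ValidationError(f"current weight must be > 0 kg, got {weight_now_kg!r}")
    if not 0 < hct_now <= 100:
        raise ValidationError(f"current hct must be in (0, 100], got {hct_now!r}")
    if not 0 < hct_baseline <= 100:
        raise ValidationError(f"baseline hct must be in (0, 100], got {hct_baseline!r}")
    rbc = hct_now / 100.0 * bv_per_kg * weight_now_kg
    bv_pre = rbc / (hct_baseline / 100.0)
    weight_pre = bv_pre / bv_per_kg
    deficit = weight_pre - weight_now_kg  # kg of water == litres
    return FluidDeficitEstimate(
        deficit_l=deficit,
        weight_pre_kg=weight_pre,
        fluid_gain=deficit < 0,
    )


# ---------------------------------------------------------------------------
# Reference scenarios (worked examples used as fixtures and documentation)
# ---------------------------------------------------------------------------

#: Baseline hematocrit assumed for the dehydration worked example; the
#: scenario states only the presenting value, so the pre-dehydration level is
#: a judgement call made explicit here.
DEHYDRATION_BASELINE_HCT = 35.0


@dataclass(frozen=True)
class ReferenceScenario:
    name: str
    description: str
    profile: PatientProfile
    initial_hct_pct: float
    events: tuple[FluidEvent, ...] = ()
    baseline_hct_pct: float | None = None  # set for the deficit scenario
    expected: dict[str, float] = field(default_factory=dict)


def reference_scenarios() -> list[ReferenceScenario]:
    """The four canonical worked examples, with expected outputs computed by
    the engine itself (not hard-coded), for use in tests and docs."""
    out: list[ReferenceScenario] = []

    p12 = PatientProfile(weight_kg=12.0)
    p6 = PatientProfile(weight_kg=6.0)

    ev = (FluidEvent("blood_loss", 200.0), FluidEvent("equilibrate_to_baseline"))
    out.append(
        ReferenceScenario(
            name="loss-equilibrated",
            description="12-kg infant, initial Hct 35%, loses 200 ml of blood; "
            "blood volume restored by fluid recruitment",
            profile=p12,
            initial_hct_pct=35.0,
            events=ev,
            expected={"final_hct_pct": apply_events(p12, 35.0, ev).final_hct_pct},
        )
    )

    ev = (FluidEvent("crystalloid_in", 200.0),)
    out.append(
        ReferenceScenario(
            name="infusion",
            description="6-kg infant, initial Hct 35%, receives 200 ml of fluid "
            "with no blood loss",
            profile=p6,
            initial_hct_pct=35.0,
            events=ev,
            expected={"final_hct_pct": apply_events(p6, 35.0, ev).final_hct_pct},
        )
    )

    ev = (FluidEvent("blood_loss", 200.0), FluidEvent("crystalloid_in", 400.0))
    out.append(
        ReferenceScenario(
            name="loss-and-crystalloid",
            description="12-kg infant, initial Hct 35%, loses 200 ml of blood and "
            "receives 400 ml of crystalloid",
            profile=p12,
            initial_hct_pct=35.0,
            events=ev,
            expected={"final_hct_pct": apply_events(p12, 35.0, ev).final_hct_pct},
        )
    )

    est = estimate_fluid_deficit(6.0, 50.0, DEHYDRATION_BASELINE_HCT)
    out.append(
        ReferenceScenario(
            name="dehydration-deficit",
            description="dehydrated 6-kg infant presenting with Hct 50%; water "
            f"deficit back-calculated against an assumed baseline Hct of "
            f"{DEHYDRATION_BASELINE_HCT:g}%",
            profile=p6,
            initial_hct_pct=50.0,
            baseline_hct_pct=DEHYDRATION_BASELINE_HCT,
            expected={"deficit_l": est.deficit_l, "weight_pre_kg": est.weight_pre_kg},
        )
    )
    return out


# ---------------------------------------------------------------------------
# Plain-JSON scenario files
# ---------------------------------------------------------------------------


def scenario_from_dict(doc: dict[str, Any]) -> tuple[PatientProfile, float, list[FluidEvent]]:
    """Validate a scenario document and return its engine inputs.

    Schema: ``{"weight_kg": float, "initial_hct_pct": float,
    "events": [{"kind": str, "volume_ml": float, "donor_hct_pct"?: float}],
    "bv_per_kg"?: float}``.
    """
    if not isinstance(doc, dict):
        raise ValidationError("scenario document must be a JSON object")
    for key in ("weight_kg", "initial_hct_pct", "events"):
        if key not in doc:
            raise ValidationError(f"scenario document is missing required field {key!r}")
    if not isinstance(doc["events"], list):
        raise ValidationError("scenario field 'events' must be a list")
    known = {"weight_kg", "initial_hct_pct", "events", "bv_per_kg"}
    extra = set(doc) - known
    if extra:
        raise ValidationError(f"scenario document has unknown fields: {sorted(extra)}")
    profile = PatientProfile(
        weight_kg=float(doc["weight_kg"]),
        bv_per_kg=float(doc.get("bv_per_kg", 75.0)),
    )
    hct_i = float(doc["initial_hct_pct"])
    if not 0 <= hct_i <= 100:
        raise ValidationError(f"initial_hct_pct must be in [0, 100], got {hct_i!r}")
    events: list[FluidEvent] = []
    for j, ev in enumerate(doc["events"]):
        if not isinstance(ev, dict) or "kind" not in ev:
            raise ValidationError(f"events[{j}] must be an object with a 'kind' field")
        unknown = set(ev) - {"kind", "volume_ml", "donor_hct_pct"}
        if unknown:
            raise ValidationError(f"events[{j}] has unknown fields: {sorted(unknown)}")
        events.append(
            FluidEvent(
                kind=ev["kind"],
                volume_ml=float(ev.get("volume_ml", 0.0)),
                donor_hct_pct=(
                    float(ev["donor_hct_pct"]) if ev.get("donor_hct_pct") is not None else None
                ),
            )
        )
    return profile, hct_i, events


def load_scenario(path: str | Path) -> tuple[PatientProfile, float, list[FluidEvent]]:
    """Read and validate a scenario JSON file."""
    try:
        doc = json.loads(Path(path).read_text())
    except json.JSONDecodeError as e:
        raise ValidationError(f"scenario file {path} is not valid JSON: {e}") from e
    return scenario_from_dict(doc)


def result_to_dict(result: ScenarioResult) -> dict[str, Any]:
    """JSON-serializable view of a scenario result."""
    return {
        "final_hct_pct": result.final_hct_pct,
        "final_bv_ml": result.final.bv_ml,
        "final_rbc_ml": result.final.rbc_ml,
        "trajectory": [
            {"bv_ml": s.bv_ml, "rbc_ml": s.rbc_ml, "hct_pct": s.hct_pct}
            for s in result.trajectory
        ],
        "audit": list(result.audit),
    }
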
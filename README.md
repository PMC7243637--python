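# hctnomo

Hematocrit (Hct) prediction under blood loss, fluid administration,
transfusion and dehydration — as a closed-form mass-balance engine, a
sequential fluid-event simulator, and a geometrically exact three-axis
nomogram (alignment chart) with a virtual straight-edge that reproduces the
chart's graphical procedures and verifies that chart and algebra agree.

The model tracks two conserved tallies, whole-blood volume (BV) and
red-cell volume (RBC), with Hct always derived as `RBC / BV × 100`.
Blood volume defaults to 75 ml per kg of body weight (overridable with
`--bv-per-kg`, e.g. 85–100 for premature infants or 70 for the elderly),
and packed red cells are converted to red-cell volume at an effective
hematocrit of 65%.

## Layout

| module | purpose |
| --- | --- |
| `hctnomo.core` | closed-form relations: blood volume from weight, Hct after blood loss / infusion / dehydration, packed-cell conversion |
| `hctnomo.scenarios` | ordered fluid-event engine, inverse estimators (blood loss from an Hct drop; water deficit from weight + Hct), worked-example fixtures, JSON scenario files |
| `hctnomo.geometry` | parallel-scale chart construction (all axes log₁₀, so straight-line alignment is exact), isopleth reads, graphical procedures, collinearity diagnostics |
| `hctnomo.render` / `hctnomo.cli` | deterministic SVG rendering and the `hctnomo` command-line tool |

## CLI

```sh
# Hct after 200 ml blood loss in a 12-kg infant (volume restored)
hctnomo calc loss --weight 12 --hct 35 --loss 200

# Hct after a 200-ml crystalloid bolus, no blood loss
hctnomo calc infusion --weight 6 --hct 35 --volume 200

# run an event list from a JSON file (see schema below)
hctnomo --json calc run --scenario scenario.json

# back-calculate blood loss from an Hct drop
hctnomo estimate loss --weight 12 --hct-pre 35 --hct-post 27.2

# water deficit of a dehydrated 6-kg infant (Hct 50%, assumed baseline 35%)
hctnomo estimate deficit --weight 6 --hct 50 --baseline-hct 35

# print-quality nomogram
hctnomo render --population pediatric --out chart.svg --pounds --instructions

# virtual straight-edge: read the third axis through two anchors
hctnomo read --anchor bv_weight=900 --anchor hct=35 --target rbc
```

Global flags: `--bv-per-kg` (default 75), `--json` for machine-readable
output, `--verbose` for a per-event audit trail on stderr. Exit codes:
0 success, 2 validation error, 1 unexpected failure. Human output rounds
Hct to 0.1%, volumes to whole ml and deficits to 0.1 L; `--json` carries
the unrounded engine values.

Scenario file schema:

```json
{
  "weight_kg": 12,
  "initial_hct_pct": 35,
  "events": [
    {"kind": "blood_loss", "volume_ml": 200},
    {"kind": "crystalloid_in", "volume_ml": 400}
  ]
}
```

Event kinds: `blood_loss`, `crystalloid_in`, `urine_out`, `insensible_out`,
`whole_blood_in` (optional `donor_hct_pct`, defaults to the patient's
initial Hct), `packed_rbc_in`, `dehydration`, `equilibrate_to_baseline`.
Events are applied strictly in order; blood loss removes red cells at the
*current* Hct of the running state, so order matters.

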
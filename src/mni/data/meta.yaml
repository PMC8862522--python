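# Reference-library snapshot metadata.
version: "dri-snapshot-2026.09"
source: >
  Dietary Reference Intakes (National Academies): RDA/AI lower bounds,
  tolerable upper intake levels (UL), Acceptable Macronutrient Distribution
  Ranges (AMDR, % of energy); FDA 400 mg/day caffeine guidance; dietary
  guideline limits for saturated fat, added/total sugars, cholesterol and
  alcohol. Coverage: ages 9-70 both sexes plus pregnancy/lactation (19-50).
notes: >
  Upper values in rows whose basis is RDA/AI are the corresponding ULs.
  Monounsaturated and polyunsaturated fat bands are package constants
  (no DRI value exists); see docs/methods.md.
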
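# Methods

This note documents the statistical model behind `bpqc`, the choices made
where the design was genuinely open, and what the synthetic-data generator
does and does not emulate.

## Data model

A participant record holds exactly three reading slots (sequence indices
1–3), each with optional integer systolic/diastolic pressures in mmHg.
Readings are stored as integers because sphygmomanometers report integer
mmHg; non-integer input is rejected (never silently rounded) and becomes a
missing value with a logged warning. The physiological validity window is
40 ≤ DBP < SBP ≤ 300 mmHg. Records violating the SBP/DBP ordering are
excluded from the analysis set at load time and listed in the load log;
out-of-range values are retained and surfaced by `validate_dataset`, which
never mutates data. Unexplained protocol deviations (left arm or supine
posture without a recorded reason) are notes, not violations.

Delimited input is comma-separated UTF-8 with a header row and decimal
points; empty cells, `NA`, `#` and `§` all read as missing (the latter two
are the markers the published tables use for "not possible to calculate"
and "not measured"). Cuff labels keep their printed en-dashes; parsing
accepts plain hyphens too.

## Reference protocol and compliance

The encoded reference procedure: three sequential measurements at 1-minute
intervals, right arm, sitting, after 5 minutes of quiet rest, cuff chosen
from at least three sizes, and the stethoscope bell when an auscultatory
device is used. `compare_protocol` reports one entry per mismatched field.
Two severities exist: *deviation* (procedure differs) and *note* (contextual
facts such as using an oscillometric device, which is a national choice and
not itself a protocol breach). Fields a survey did not declare are skipped
rather than guessed. In the census, device models and manufacturers are
counted over oscillometric devices only — mercury columns are a generic
instrument class — and the manufacturer is the first whitespace-delimited
token of the model string ("Omron M6" → "Omron"), overridable via an
explicit map.

## Terminal-digit test

Digits are pooled over all three sequences of all participants, per
pressure type (digit preference is a per-reading observer behaviour, and
the published distributions are not broken down by sequence). The support
is {0,2,4,6,8} for mercury devices and {0,…,9} otherwise; expected counts
are uniform on the support and the statistic is the ordinary Pearson
goodness-of-fit X² with df = k−1, with the p-value from the χ² survival
function.

Odd digits can occur with a mercury device when observers read to 1 mmHg
against protocol. In that case the test falls back to the full 0–9 support
— keeping every expected count positive — and reports the odd-digit share
as `off_support_proportion`. This keeps the test well-defined and sensitive
exactly when the digit behaviour is most anomalous.

Printed percentage rows are converted to integer counts by
largest-remainder apportionment (quota = pct/total × n; floors, then the
largest fractional remainders receive the remaining units, ties broken by
digit order). The reconstruction is exact in the row total, but counts
inherit the ±0.5 % rounding of the printed percentages, so reconstructed
p-values only approximate the originals; tests therefore assert the printed
"<0.0001" bound for the pathological survey rather than any exact p.

Flagging defaults: α = 0.001 for the digit test, a raw zero-digit excess
above 0.10 as an alternative trigger, and 0.28 for the identical-readings
proportion. All three are configurable (`QCThresholds`).

`estimate_zero_preference` inverts the mixture model used by the generator:
if each reading is pulled to a terminal 0 with probability z and otherwise
lands uniformly on a support of size k, the digit-0 share is z + (1−z)/k,
so ẑ = (share − 1/k)/(1 − 1/k), which is unbiased for z.

## Identical readings and missingness

For each pressure type and consecutive pair the proportion of exactly equal
readings is computed over participants with both readings present — only
comparable pairs can be identical; a zero denominator leaves the proportion
undefined rather than zero. Missingness is the per-item missing fraction
over all participants in the analysis set.

## Cuff matching

Printed closed ranges are inclusive at both ends: cuff markings are
inclusive, and adjacent printed ranges (22–32, 32–48) deliberately overlap
at the boundary. When several inventory cuffs cover a circumference the one
with the smaller upper bound is selected: at a boundary circumference the
smaller cuff's upward bias (+3–12 mmHg systolic at its worst) is smaller in
published magnitude than the too-large cuff's downward bias (−10–30 mmHg).
If no cuff covers the arm, the nearest range is returned flagged as a
forced miss-cuff. Participants with missing circumference or an
unresolvable cuff label are `unknown` and excluded from the miss-cuffing
denominator, mirroring the "not possible to calculate" entries of the
published tables (surveys relying on cuffs with built-in fit indicators are
unclassifiable from data alone). Bladder adequacy uses the conventional
rule — width ≥ 40 % and length ≥ 80 % of arm circumference — inclusive at
the boundary.

## Synthetic surveys

The generator emulates the data structure the battery assumes, one survey
at a time:

1. true pressures per participant: SBP ~ Normal(130, 17), DBP ~
   Normal(80, 10) mmHg — package defaults chosen as plausible adult
   population values, always overridable;
2. condition flags switched on independently with configured prevalences;
   each active factor adds its published effect offset. Ranges are reported
   without distributions, so the default draw is the range midpoint, with
   uniform-in-range as an alternative. The two published extreme magnitudes
   (uncomfortably distended bladder +40/+50; too-small cuff on an obese arm
   +30/+30) are separate `*_extreme` factors so the moderate ranges stay
   the defaults;
3. three readings add independent within-person noise (default sd 4 mmHg,
   a typical within-visit variability) and the observer's systematic
   offset;
4. rounding: mercury to the nearest 2 mmHg, oscillometric to 1 mmHg, with
   halves rounding up (so mercury ties go to the higher even value); with
   probability `zero_preference_prob` a reading is instead pulled to the
   nearest multiple of 10;
5. copying happens last, after rounding, with probability
   `identical_copy_prob` per transition — copied readings are exactly equal,
   which is precisely what the identical-readings statistic detects;
6. arm circumference ~ Normal(30.5, 4.5) cm, clipped to 16–60 cm and
   rounded to 0.1 cm; the cuff is chosen from the configured inventory via
   `select_cuff`, and a participant in an inventory gap also receives the
   corresponding wrong-cuff pressure effect.

Random draws are consumed in a fixed order independent of parameter values,
so configurations differing in one parameter share all randomness at equal
seed (common random numbers). Paired designs — talking vs. silent, offset
vs. none — therefore difference out sampling noise; the +17 mmHg talking
effect is recovered essentially exactly at n = 2000.

`inject_misscuffing` re-assigns a Bernoulli(fraction) subset of
participants to a non-covering cuff in the requested direction and applies
the corresponding published cuff effect to their readings (re-rounded on
the device grid). Participants for whom the inventory holds no such cuff
are skipped and logged.

What the generator does **not** emulate: physiological time-dynamics across
the triplicate (first-reading elevation, white-coat decay), correlated
flags, observer heterogeneity within a survey, digit preferences other than
zero, and ambulatory formats. Passing recovery tests therefore show the
battery's estimators are calibrated against this generative model, not that
real surveys satisfy it.

Known small biases, accepted and quantified: the raw identical-pair
proportion exceeds the configured copy probability by the chance
coincidence of two independently rounded readings (≈ 0.7·0.028 ≈ 0.02 at
within-person sd 10 mmHg on an integer grid); recovery tests use that
configuration so the bias stays inside 3 binomial standard errors at
n = 1000. Midpoint effects ending in .5 shift by +0.5 mmHg under integer
rounding.

## Prevalence-bias propagation

Participant-level BP defaults to the mean of the 2nd and 3rd readings (the
first reading is commonly elevated; the published protocol does not define
a summary), configurable to mean-of-3 or last-reading. Classification uses
the conventional 140/90 mmHg thresholds, inclusive, configurable; the
published downstream relative-increase figures derive from external
national surveys and are demonstrated as a mechanism only, not reproduced.

`analytic_shift` evaluates Normal upper tails at the threshold for means μ
and μ+δ. `empirical_shift` simulates the same survey twice from one seed —
the second run with the observer's systematic offset increased by δ — and
classifies on systolic only, matching the univariate analytic model. With
common random numbers the two classifications are nested, so the
between-run difference is itself a sample proportion; the reported
Monte-Carlo standard error of the relative change uses the delta method on
that representation. Integer device rounding makes the empirical tail
correspond to a continuity-corrected Normal tail (threshold − 0.5); with an
integer δ the correction cancels between the paired runs, leaving a
residual analytic-vs-empirical difference of about 0.008 in relative change
at μ = 130, σ = 17, δ = 5 — inside the 3-SE band at n = 10⁵.

## Problem sizes

Default analysis-scale choices keep every computation at desk scale:
fixture checks are instantaneous; calibration uses 1000 simulated
null surveys of 300 readings; Monte-Carlo p-value cross-checks use 10⁵
multinomial replicates; parameter-recovery runs use 1000–2000 participants;
the prevalence-shift comparison uses 10⁵ participants per arm. The full
test suite and the acceptance script each complete in well under a minute
of CPU.
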
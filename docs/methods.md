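# Methods

## The dosing rule and its algebra

The Salisbury rule maps a child's body weight W (kg) to a percent of the
adult dose: 2W below 30 kg, W + 30 from 30 kg to below 70 kg. The percent is
applied to the *absolute* adult dose — the adult mg/kg dose times the adult
reference weight — and the resulting absolute child dose can be renormalized
to the child's weight. The adult reference weight defaults to 70 kg: it is
the weight at which the W + 30 branch reaches 100%, so an adult receives
exactly the adult dose, and it makes the rule's algebra come out in round
numbers (below 30 kg the per-kg prediction is 1.4 × the adult mg/kg dose for
*every* weight, because the child weight cancels: (2W/100) × 70d / W =
1.4 d). The reference weight is configurable per drug.

At and above 70 kg the percent is capped at 100. The rule is defined only
below 70 kg, and extrapolating beyond the adult dose would be unsafe; a
warning is emitted for weights strictly above 70 kg (at exactly 70 kg the
result is simply the adult dose, so no warning is useful there). At exactly
30 kg the W + 30 branch applies; both branches give 60%, so the choice is
numerically invisible and the rule is continuous and strictly increasing on
(0, 70).

## Reference comparators

Two observed-dose conventions are supported alongside investigator-selected
doses:

- **Per-kg extrapolation**: the child receives the adult mg/kg dose
  unchanged — the dominant label practice for therapeutic proteins.
- **Clearance-ratio dosing**: dose_child = dose_adult × CL_child/CL_adult.
  Both clearances must share one basis (per-kg or absolute) and one unit;
  mixing bases silently rescales the dose by a body weight, so it is a hard
  error rather than an implicit conversion. With absolute clearances the
  ratio is applied to the absolute adult dose; with per-kg clearances to the
  adult per-kg dose. The two routes agree (asserted in tests).

## Error metrics and categories

Percent error is (predicted − observed)/observed × 100, positive for
over-prediction; fold error is predicted/observed, so fold = 1 + percent/100.
Comparisons are made on per-kg doses; the fold ratio is basis-invariant
because predicted and observed scale by the same child weight.

Fold errors are binned into: wide, the closed interval [0.5, 1.5]; narrow,
the closed interval [0.7, 1.3] (±30%, the band treated as an acceptable
first-in-pediatric prediction); over, fold > 1.3; under, fold < 0.7. Narrow,
over and under partition the positive axis; wide overlaps them and is
reported as its own row, as such tables are conventionally printed. The
under boundary is strict (< 0.7) so that the partition is exact; published
row labels sometimes print "≤ 0.7-fold", but no reported observation falls
on the boundary, so the two conventions are indistinguishable in practice.
All arithmetic is carried at full precision; percents are rounded only at
report time, half away from zero, to one decimal in summary tables and to
integers for single errors.

Summaries stratify by drug class × weight stratum × dose provenance.
Neonates (by age class, weights ≤ 5 kg) form their own stratum; other
children split at 30 kg, the rule's breakpoint. Strata known to the table
but without observations are emitted with NA cells rather than dropped; an
empty result collection yields a zero-row table flagged `is_empty`, not an
exception.

## Synthetic cohorts

Per-observation pediatric dosing data for therapeutic proteins live in
appendices and package inserts rather than reusable tables, so the pipeline
is exercised on generated cohorts that emulate their structure. Defaults,
chosen to match the published cohort descriptions: 21 monoclonal, 5
polyclonal and 11 non-antibody drugs; neonatal weights uniform on 1–3 kg,
younger children on 4.5–30 kg, older on 30–60 kg (only ranges are published,
so uniform is the least-committal choice); one adult reference per drug with
mg/kg doses drawn log-uniformly from 1–500 mg/kg (spanning monoclonal to
immunoglobulin scales) and per-kg clearances log-uniformly from 0.1–10
mL/h/kg.

Pediatric absolute clearance follows allometry, CL_child = CL_adult ×
(W/70)^b with b = 0.75, the conventional clearance exponent, multiplied by
log-normal noise with CV 0.15 (σ² = ln(1 + CV²)). Sub-linear scaling makes
per-kg clearance higher in smaller children — the physiological premise
behind weight-nonlinear dosing. With the noise off, clearance-ratio fold
errors have the closed form (salisbury%(W)/100)/(W/70)^0.75, which stays
inside [0.7, 1.3] for all weights from 5 to 70 kg: the structural sense in
which the rule tracks clearance-based dosing.

Observed doses follow a configurable policy mix; neonatal rows are always
investigator-selected from the grid {250, 500, 750, 1000} mg/kg, since
neonatal polyclonal doses were chosen by investigators rather than
extrapolated. Generation is a pure function of the seed (one
`numpy.random.Generator` drives everything), so equal seeds give equal —
and bitwise-equal serialized — cohorts.

What the generator does **not** emulate: real between-drug heterogeneity in
clearance maturation (renal/hepatic ontogeny, target-mediated disposition),
correlated repeat doses within a subject, measurement error in reported
weights, or dose banding to vial sizes. Passing tests on synthetic cohorts
therefore demonstrate the arithmetic and bookkeeping of the pipeline and the
rule's algebraic behaviour, not the clinical accuracy of the rule on any
real drug.

## Preset scenarios

`table1_scenario(drug_class, stratum, n)` reproduces published stratum
settings: polyclonal children 15–30 kg and 30–50 kg with per-kg-labelled
doses at an adult 400 mg/kg regimen; polyclonal neonates 1–3 kg on the
investigator grid; monoclonal (10 mg/kg) and non-antibody (1 mg/kg) strata
at 4.5–30/4–30 and 30–60 kg. Neonatal strata exist only for polyclonals —
there are no published neonatal monoclonal or non-antibody observations —
so other neonatal combinations raise `NotImplementedError`.

## Numerical and design choices

- Zero, negative or non-finite doses, weights and clearances raise
  `InvalidInputError`; nothing is clamped or silently dropped.
- Unit strings in CSV input ("400 mg/kg", "140 mL/h") are parsed against a
  small whitelist; an unknown unit is a parse error, never a guess from
  magnitude. Malformed rows are set aside with their line numbers instead of
  aborting a read.
- Floats are serialized with full `repr` precision so a cohort write/read
  round-trip reproduces an equal in-memory collection.
- Problem sizes throughout the test suite and the acceptance script are
  small (hundreds of grid points, a 10,000-fold recount oracle, cohorts of a
  few dozen observations): every quantity checked is either exact algebra or
  a counting invariant, so larger simulations would add nothing.

## Known limitations

- The rule is undefined above 70 kg; the cap at 100% is this package's
  (conservative) extension, not part of the rule.
- Exact reproduction of the published monoclonal and non-antibody stratum
  counts is not attempted: the underlying per-observation data are not
  printed in any source available to code. The CSV schema accepts such data
  if transcribed, and the summarizer is validated against recount oracles
  and the fully-determined polyclonal stratum instead.
- One published polyclonal observation carries a 37% error where the
  per-kg-extrapolation algebra under a 70 kg reference gives exactly 40%;
  it likely reflects a different adult reference weight or rounding in the
  source study and is not reproduced.
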
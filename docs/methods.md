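# Methods

## The pathway model

The engine is a non-adaptive expert system: human-authored decision rules,
evaluated deterministically per patient record. A record consists of
demographics and tick-box metadata (age ≥ 18, sex, BMI, alcohol over 14
units/week in the last six months, metabolic-syndrome features) and a
first-line liver panel (ALT, ALP, GGT, total bilirubin, albumin), with AST
and platelets available for fibrosis scoring. Processing runs in four
stages — cascade decision, fibrosis staging, aetiology-screen
interpretation, outcome coding — each a pure function of the record and a
threshold configuration.

The design assumption throughout is *fail-safe toward referral*: whenever a
record is ambiguous (two concurrent mild abnormalities, an unmapped
abnormality pattern, an indeterminate fibrosis band that direct testing
cannot resolve), the engine escalates or refers rather than concluding
normality.

## Thresholds and parameters

All cutoffs live in `src/ilft/data/default_thresholds.yaml` with units, and
a site override file can replace any subset (unknown keys are a hard error).
The defaults:

| parameter | default | note |
|---|---|---|
| ALT trigger | 30 U/L | deliberately below the usual local upper reference limit and not sex-specific |
| ALP URL / full-cascade | 130 / 200 U/L | 131–200 isolated = advisory only |
| GGT URL | 60 U/L | a common UK URL; the source pathway's local value is not published |
| bilirubin mild band | 22–60 µmol/L | lower bound inclusive (abnormal against a 21 µmol/L URL), upper strict |
| FIB-4 low/high | 1.30 / 2.67 | literature rule-out/rule-in cutoffs; no age-adjusted lower cutoff by default |
| NFS low/high | −1.455 / 0.676 | used only in presumed-MASLD/MetALD branches |
| ELF bands | 7.7 / 9.8 / 11.3 | half-open; 9.8 is also the referral threshold; ≥ 13 urgent |
| A1AT deficiency | < 1.0 g/L | triggers phenotyping advice |
| transferrin saturation | > 45% | iron interpretation uses saturation only (ferritin is not in the panel) |
| CRP elevated | > 5 mg/L | gates caeruloplasmin |
| caeruloplasmin | < 0.20 g/L | Wilson gate, age < 45 only |
| conjugated fraction | < 0.20 | direct/total bilirubin, Gilbert rule |
| haptoglobin lower limit | 0.3 g/L | below = haemolysis suspected |
| malignancy alert | age > 40, ALP > 130, platelets > 400 | all strict comparisons |

Comparator strictness follows the published wording where it exists
("exceeds" = strict `>`); boundary behaviour is pinned by tests at every
threshold. The FIB-4/NFS cutoffs, the ELF coefficient set (manufacturer
calibration 2.278 + 0.851·ln HA + 0.751·ln PIIINP + 0.394·ln TIMP-1) and
the aetiology-screen cutoffs are adopted from the standard literature
because the pathway's own publications do not print them; each is
config-visible so an alternative calibration can be swapped in.

Two deliberate proxies: the metabolic-syndrome tick-box stands in for the
NFS dysglycaemia (IFG/diabetes) term, since it is the only metabolic
information the request carries; and virology/autoantibody results are
modelled as laboratory-adjudicated booleans, with confirmatory cascades out
of scope.

## Decisions where the design was open

- **Age gates.** "Under 45" for the CRP/caeruloplasmin cascade is `age < 45`;
  "over 40" for the malignancy alert is `age > 40` (strict).
- **ELF with missing indirect scores.** If AST or platelets are absent the
  indirect band is `not_computable`; ELF still reflexes if its analytes are
  present (reflex-and-flag), resolving at 9.8 as usual, and an unresolved
  record maps to the referral-for-fibrosis-assessment outcome rather than
  being dropped.
- **Indirect high with ELF < 9.8.** Referral is retained (rule-in cannot be
  overridden); ELF then contributes staging and prognosis only.
- **Specific aetiology plus lifestyle flags.** Both outcomes are emitted
  (one record, multiple outcomes) rather than one suppressing the other;
  ordering is alert > urgent > aetiological > presumed-lifestyle >
  descriptive, with the outcome code as a stable tie-break.
- **ALT ≥ 250 U/L.** The most frequent descriptive outcome is explicitly
  qualified "< 250 U/L", implying a distinct pathway above it; implemented
  as an urgent marked-ALT alert (possible acute liver injury). This branch
  is a reconstruction — the public material never describes it.
- **MetALD fibrosis banding** uses the same NFS-enabled rule as MASLD (a
  metabolic component is present).
- **Unpublished outcome codes.** Only ten of the 33 production outcome codes
  are public; reconstructed outcomes use an `iLX-*` namespace in the
  editable registry so they cannot be mistaken for official codes. A
  `legacy_nomenclature` switch restores pre-2023 steatotic-liver-disease
  names (NAFLD era) for regression comparisons.
- **Referral aggregation.** Record referral = max over outcome referrals
  with order none < phenotype-dependent < routine < urgent; "referral
  advised" in summaries counts routine and urgent only.
- **Percentage convention.** One decimal, half rounded away from zero
  (`decimal`-based, not banker's rounding); a zero denominator yields an
  explicit undefined marker, never an exception inside a report.

## Synthetic cohorts

`generate_cohort` draws records from a mixture of 14 clinical profiles
(normal, ALD, MASLD, MetALD, Gilbert, hepatitis B/C, iron overload, A1AT
deficiency, autoimmune, Wilson, malignancy alert, marked ALT, indeterminate
fibrosis resolved by ELF). Every analyte is a truncated normal whose
truncation bounds are chosen — in one parameter file,
`src/ilft/data/synthetic_profiles.yaml` — so the profile fires its intended
branch *by construction* (for example, the ALD profile's age/AST/ALT/platelet
bounds cap the attainable FIB-4 at about 1.12, safely inside the 1.30
rule-out band). The default mixture uses the eight profiles with non-zero
default prevalence (normal 0.30, ALD 0.15, MASLD 0.15, indeterminate
fibrosis 0.15, Gilbert 0.10, A1AT 0.05, hepatitis C 0.05, malignancy alert
0.05) — a deliberately branch-covering case mix, not an estimate of any real
population. Hidden true-profile labels are written to a sidecar CSV the
classification path never reads. A single integer seed drives all
randomness; identical specs give byte-identical tables.

`fixture_marginals` is the deterministic counterpart: hand-engineered
records emitted in exact per-tier counts (and, within the full tier, exact
referral counts), used to reproduce published cohort marginals precisely.

**What passing tests do and do not show.** The generator guarantees its own
labels trigger their branches, so ≥ 95% label recovery validates rule
plumbing, not diagnostic accuracy on patients. Real cohorts have analyte
correlations, co-occurring aetiologies, assay noise and missingness patterns
the generator does not emulate, and the true outcome distribution of the
production pathway is not reproducible without its clinical database —
which is why cohort-level checks here target engineered marginals and
printed-count arithmetic, plus rule properties (grid equivalence against
independently written nested-conditional oracles, boundary pins,
monotonicity, determinism) rather than a simulated case mix.

## Numerical notes

- FIB-4/NFS/ELF are evaluated in double precision and tested against
  independently coded formulas to 1e−9 relative on 10,000 random inputs;
  NFS converts albumin g/L → g/dL internally.
- Degenerate inputs (ALT or platelets ≤ 0, missing analytes) yield an
  explicit not-computable flag, never an exception or silent default.
- ELF band boundaries are half-open and tested at ±1e−9 around each cutoff;
  scores are strictly increasing in each analyte.
- Malformed cohort rows are rejected individually with row-numbered
  messages; the batch continues and the exit status reports the rejects.

## Problem sizes

The test suite classifies the full 11,043-record marginal fixture and a
5000-record synthetic mixture (~0.15 ms/record, so both run in seconds);
property grids cover 450 cascade combinations and 512 classification branch
combinations. The acceptance script repeats the fixture run and a
5000-record label-recovery measurement.

## Known limitations

- 23 of the 33 production outcomes are reconstructions; wording, referral
  policies for the reconstructed codes, and any additional descriptive
  pattern codes are this package's own choices.
- No LIMS/order-communications integration, no A1AT phenotype
  interpretation, no HBV/HCV confirmatory algorithms, no imaging or
  elastography, and no cost-effectiveness modelling.
- The synthetic case mix is not the production pathway's case mix, and
  cohort-level outcome frequencies from `simulate` should not be compared
  against published production frequencies.
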
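# ilft — rule-based reflex testing for abnormal liver function tests

Abnormal liver blood panels from primary care are common, frequently left
uninvestigated, and only rarely due to serious chronic liver disease — so
patients with significant fibrosis are often found late. One answer is an
"intelligent" laboratory pathway: an expert system inside the laboratory
that, given a single blood draw plus three tick-boxes from the requesting
clinician (BMI, weekly alcohol over/under 14 units, metabolic-syndrome
features), automatically cascades second-line assays when first-line results
are abnormal, computes fibrosis scores, interprets the aetiology screen, and
returns a coded diagnosis/management outcome with referral advice.

This package is a tested, configurable implementation of that pathway for
people who study or deploy reflex-testing rules: laboratory scientists
tuning trigger thresholds to local reference limits, hepatology researchers
simulating case mixes, and engineers validating rule changes before they
touch a live laboratory information system.

## The rules at its core

**Cascade tiers.** With default thresholds (all configurable, units U/L,
µmol/L, ×10⁹/L):

- *full screen* if ALT > 30, GGT > 60, bilirubin > 60 or ALP > 200 — adds
  AST, iron studies, A1AT, hepatitis B/C serology, liver autoantibodies, and
  (under age 45) CRP with caeruloplasmin gated on a non-elevated CRP;
- *limited cascade* if 22 ≤ bilirubin ≤ 60 is the only abnormality — adds
  direct bilirubin and haptoglobin for the Gilbert work-up;
- *advisory* if 130 < ALP ≤ 200 is the only abnormality — repeat testing
  advice, no cascade;
- *none* otherwise. Two concurrent mild abnormalities escalate to the full
  screen (fail-safe).

**Fibrosis staging.** Indirect scores

    FIB-4 = age · AST / (platelets · √ALT)
    NFS   = −1.675 + 0.037·age + 0.094·BMI + 1.13·dysglycaemia
            + 0.99·AST/ALT − 0.013·platelets − 0.66·albumin[g/dL]

are banded low / indeterminate / high (FIB-4 cutoffs 1.30/2.67; NFS
−1.455/0.676, used in presumed-MASLD/MetALD branches only). The direct ELF
score, 2.278 + 0.851·ln HA + 0.751·ln PIIINP + 0.394·ln TIMP-1, reflexes
when the indirect band is indeterminate or high; bands <7.7 / ≥7.7 / ≥9.8 /
≥11.3 stage fibrosis, ≥9.8 resolves the indeterminate zone toward referral,
and ≥13 raises an urgent prognostic alert.

**Outcomes.** Each record receives one or more coded outcomes (a record can
carry several): specific aetiologies (A1AT deficiency, iron overload, viral
hepatitis, autoimmune, possible Wilson disease, likely Gilbert syndrome),
presumed steatotic-liver-disease outcomes from the lifestyle tick-boxes
(ALD / MASLD / MetALD, split by fibrosis), descriptive patterns for
negative screens, a markedly-elevated-ALT urgent alert (ALT ≥ 250), and a
malignancy alert (age > 40, ALP > 130 and platelets > 400). The record-level
referral is the maximum severity over its outcomes; significant fibrosis can
never end in "no referral". Outcome codes, referral policies and comment
templates live in an editable registry file; codes without a published
identifier use an `iLX-*` namespace.

## Worked example

```sh
ilft simulate --n 500 --seed 7 --output cohort.csv
ilft run --input cohort.csv --output classified.json
ilft summarize --input classified.json
```

prints

```
Requests: 500   Outcomes: 531

Cascade tiers:
  none                   138  (27.6%)
  alp_advisory             0  (0.0%)
  limited_bilirubin       49  (9.8%)
  full                   313  (62.6%)

          code                                          description   n  pct_of_outcomes  pct_of_requests            referral
    iLX-NORMAL           Liver function tests within defined limits 138             26.0             27.6                none
          iL17 MASLD, simple steatosis without significant fibrosis  79             14.9             15.8                none
          iL05                     ALD without significant fibrosis  77             14.5             15.4                none
   iLX-FIB-SIG       Abnormal liver tests with significant fibrosis  73             13.7             14.6             routine
          iL06                              Likely Gilbert syndrome  49              9.2              9.8                none
           ...                                                  ...  ..              ...              ...                 ...

Referral advised: 127 (25.4% of requests); no referral: 74.6%
```

Reading it: 313 of the 500 simulated requests (62.6%) triggered the full
aetiology screen and 49 the limited bilirubin cascade; 531 coded outcomes
were generated from 500 requests because a record can carry more than one;
each outcome's share is shown against both denominators (of outcomes, of
requests); and 127 patients (25.4%) were advised referral — meaning 74.6%
could be managed without a hospital visit. Per-record detail (scores, bands,
findings, rendered comments) is in `classified.json`; the sidecar
`cohort.csv.labels.csv` holds the hidden true profile of each simulated
patient for validation.

The library surface mirrors the pipeline stages: `evaluate_first_line`,
`compute_fib4` / `compute_nfs` / `compute_elf` / `assess_fibrosis`,
`interpret_screen` / `gilbert_check`, `classify`, `process_record`,
`summarize_cohort`. Thresholds come from one YAML file
(`src/ilft/data/default_thresholds.yaml`); pass `--config` overrides to
`ilft run` to substitute local reference limits.

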
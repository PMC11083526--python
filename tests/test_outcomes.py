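"""Outcome engine: coded outcomes, malignancy alert, fail-safe referral."""

import itertools

import pytest

from ilft import (
    Aetiology,
    AetiologyFinding,
    CascadePlan,
    FibrosisAssessment,
    FinalCategory,
    FindingStatus,
    IndirectBand,
    LiverPanel,
    PatientContext,
    Referral,
    Tier,
    classify,
    malignancy_alert,
)
from ilft.outcomes import record_referral, render_comment

from oracles import oracle_full_cascade_codes

_POS = FindingStatus.POSITIVE
_NEG = FindingStatus.NEGATIVE

_SCREEN_AETIOLOGIES = {
    "a1at": Aetiology.A1AT_DEFICIENCY,
    "iron": Aetiology.IRON_OVERLOAD,
    "hbv": Aetiology.HEPATITIS_B,
    "hcv": Aetiology.HEPATITIS_C,
    "autoimmune": Aetiology.AUTOIMMUNE,
    "wilson": Aetiology.WILSON_POSSIBLE,
}


def ctx(age=50, alcohol=False, metabolic=False):
    return PatientContext(age=age, sex="male", bmi=30.0,
                          alcohol_over_14_units=alcohol, metabolic_syndrome=metabolic)


def panel(alt=80.0, alp=100.0, platelets=300.0):
    return LiverPanel(alt=alt, alp=alp, ggt=30.0, bilirubin_total=10.0,
                      albumin=42.0, ast=30.0, platelets=platelets)


def full_plan(abnormal=("alt",)):
    return CascadePlan(Tier.FULL,
                       frozenset({"ast", "iron_studies", "a1at", "hbv_serology",
                                  "hcv_serology", "autoantibodies"}),
                       frozenset(abnormal))


def findings_with(positive=()):
    return [
        AetiologyFinding(a, _POS if key in positive else _NEG)
        for key, a in _SCREEN_AETIOLOGIES.items()
    ]


def fibrosis(category, elf=None, urgent=False):
    band = {
        FinalCategory.NO_SIGNIFICANT_FIBROSIS: IndirectBand.LOW,
        FinalCategory.SIGNIFICANT_FIBROSIS: IndirectBand.HIGH,
        FinalCategory.INDETERMINATE_RESOLVED_LOW: IndirectBand.INDETERMINATE,
        FinalCategory.INDETERMINATE_UNRESOLVED: IndirectBand.INDETERMINATE,
    }[category]
    return FibrosisAssessment(fib4=1.0, nfs=None, elf=elf, indirect_band=band,
                              elf_band=None, urgent_prognosis=urgent,
                              final_category=category)


LOW = FinalCategory.NO_SIGNIFICANT_FIBROSIS
SIG = FinalCategory.SIGNIFICANT_FIBROSIS


class TestMalignancyAlert:
    @pytest.mark.parametrize(
        "age,alp,plt,expected",
        [
            (55, 180, 450, True),
            (40, 180, 450, False),   # "over 40" is strict
            (41, 180, 450, True),
            (55, 130, 450, False),   # ALP bound strict
            (55, 131, 450, True),
            (55, 180, 400, False),   # platelet bound strict
            (55, 180, 401, True),
            (55, 180, None, False),  # no platelet count, no alert
        ],
    )
    def test_rule(self, age, alp, plt, expected):
        assert malignancy_alert(age, alp, plt) is expected


class TestClassifyExamples:
    def test_ald_without_fibrosis(self, registry, thresholds):
        out = classify(ctx(alcohol=True), panel(), full_plan(), findings_with(),
                       fibrosis(LOW), registry, thresholds)
        assert [o.code for o in out] == ["iL05"]
        assert record_referral(out) is Referral.NONE

    def test_masld_with_fibrosis(self, registry, thresholds):
        out = classify(ctx(metabolic=True), panel(), full_plan(), findings_with(),
                       fibrosis(SIG), registry, thresholds)
        assert [o.code for o in out] == ["iL16"]
        assert record_referral(out) is Referral.ROUTINE

    def test_metald_uses_new_nomenclature(self, registry, thresholds):
        out = classify(ctx(alcohol=True, metabolic=True), panel(), full_plan(),
                       findings_with(), fibrosis(LOW), registry, thresholds)
        assert [o.code for o in out] == ["iLX-METALD-NF"]
        assert "MetALD" in out[0].description
        assert "NAFLD" not in out[0].description

    def test_legacy_nomenclature_switch(self, thresholds):
        from ilft import load_registry
        legacy = load_registry(legacy_nomenclature=True)
        out = classify(ctx(alcohol=True, metabolic=True), panel(), full_plan(),
                       findings_with(), fibrosis(LOW), legacy, thresholds)
        assert "NAFLD" in out[0].description

    def test_descriptive_alt_only(self, registry, thresholds):
        out = classify(ctx(), panel(), full_plan(), findings_with(),
                       fibrosis(LOW), registry, thresholds)
        assert [o.code for o in out] == ["iL15"]

    def test_multiple_outcomes_single_record(self, registry, thresholds):
        """A specific aetiology and a lifestyle flag both emit their outcomes."""
        out = classify(ctx(alcohol=True), panel(), full_plan(),
                       findings_with(positive=("a1at",)), fibrosis(LOW),
                       registry, thresholds)
        assert [o.code for o in out] == ["iL01", "iL05"]
        assert record_referral(out) is Referral.PHENOTYPE_DEPENDENT

    def test_marked_alt_urgent(self, registry, thresholds):
        out = classify(ctx(), panel(alt=300), full_plan(), findings_with(),
                       fibrosis(LOW), registry, thresholds)
        assert [o.code for o in out] == ["iLX-ALT-MARKED"]
        assert record_referral(out) is Referral.URGENT

    def test_elf_urgent_appended(self, registry, thresholds):
        out = classify(ctx(), panel(), full_plan(), findings_with(),
                       fibrosis(SIG, elf=13.4, urgent=True), registry, thresholds)
        codes = [o.code for o in out]
        assert "iLX-ELF-URGENT" in codes and "iLX-FIB-SIG" in codes
        assert record_referral(out) is Referral.URGENT

    def test_indeterminate_unresolved_refers(self, registry, thresholds):
        out = classify(ctx(), panel(), full_plan(), findings_with(),
                       fibrosis(FinalCategory.INDETERMINATE_UNRESOLVED),
                       registry, thresholds)
        assert "iLX-FIB-INDET" in [o.code for o in out]
        assert record_referral(out) is Referral.ROUTINE

    def test_unmapped_pattern_fail_safe(self, registry, thresholds):
        """An abnormality pattern without a specific code falls back to a
        descriptive outcome with routine referral, never silence."""
        out = classify(ctx(), panel(), full_plan(abnormal=("ggt",)), findings_with(),
                       fibrosis(LOW), registry, thresholds)
        assert [o.code for o in out] == ["iLX-DESC"]
        assert record_referral(out) is Referral.ROUTINE

    def test_normal_tier(self, registry, thresholds):
        out = classify(ctx(), panel(alt=20), CascadePlan(Tier.NONE), [], None,
                       registry, thresholds)
        assert [o.code for o in out] == ["iLX-NORMAL"]
        assert out[0].category.value == "advisory"
        assert record_referral(out) is Referral.NONE

    def test_gilbert_outcome(self, registry, thresholds):
        findings = [
            AetiologyFinding(Aetiology.GILBERT_PATTERN, _POS),
            AetiologyFinding(Aetiology.HAEMOLYSIS_PATTERN, _NEG),
        ]
        plan = CascadePlan(Tier.LIMITED_BILIRUBIN,
                           frozenset({"direct_bilirubin", "haptoglobin"}),
                           frozenset({"bilirubin_total"}))
        out = classify(ctx(), panel(alt=20), plan, findings, None, registry, thresholds)
        assert [o.code for o in out] == ["iL06"]


class TestProperties:
    def test_fail_safe_referral_on_significant_fibrosis(self, registry, thresholds):
        """No flag/aetiology combination with significant fibrosis yields
        record-level referral none."""
        for alcohol, metabolic, positive in itertools.product(
            (False, True), (False, True),
            ((), ("a1at",), ("hcv",), ("iron", "autoimmune")),
        ):
            out = classify(ctx(alcohol=alcohol, metabolic=metabolic), panel(),
                           full_plan(), findings_with(positive), fibrosis(SIG),
                           registry, thresholds)
            assert record_referral(out) is not Referral.NONE, (alcohol, metabolic, positive)

    def test_determinism(self, registry, thresholds):
        args = (ctx(alcohol=True), panel(), full_plan(),
                findings_with(positive=("a1at",)), fibrosis(SIG))
        first = classify(*args, registry, thresholds)
        second = classify(*args, registry, thresholds)
        assert first == second
        assert [o.comment for o in first] == [o.comment for o in second]

    def test_grid_matches_independent_oracle(self, registry, thresholds):
        """Every classification branch (flags x aetiologies x fibrosis x
        marked-ALT x malignancy) agrees with a nested-conditional oracle."""
        cases = 0
        for alcohol, metabolic, positive, category, alt, malig in itertools.product(
            (False, True), (False, True),
            ((), ("a1at",), ("hbv",), ("hcv",), ("iron",), ("autoimmune",),
             ("wilson",), ("a1at", "iron")),
            (LOW, SIG, FinalCategory.INDETERMINATE_RESOLVED_LOW,
             FinalCategory.INDETERMINATE_UNRESOLVED),
            (80.0, 300.0),
            (False, True),
        ):
            p = LiverPanel(alt=alt, alp=180.0 if malig else 100.0, ggt=30.0,
                           bilirubin_total=10.0, albumin=42.0, ast=30.0,
                           platelets=450.0 if malig else 300.0)
            out = classify(ctx(age=55, alcohol=alcohol, metabolic=metabolic), p,
                           full_plan(), findings_with(positive), fibrosis(category),
                           registry, thresholds)
            expected = oracle_full_cascade_codes(
                alcohol, metabolic, set(positive), category.value, alt, malig, False)
            assert {o.code for o in out} == expected, (
                alcohol, metabolic, positive, category, alt, malig)
            cases += 1
        assert cases == 2 * 2 * 8 * 4 * 2 * 2

    def test_at_least_one_outcome_per_full_cascade(self, registry, thresholds):
        for category in (LOW, SIG):
            for positive in ((), ("wilson",)):
                out = classify(ctx(), panel(), full_plan(), findings_with(positive),
                               fibrosis(category), registry, thresholds)
                assert len(out) >= 1


class TestComments:
    def test_values_interpolated(self, registry, thresholds):
        out = classify(ctx(), panel(alp=150), CascadePlan(
            Tier.ALP_ADVISORY, frozenset(), frozenset({"alp"})), [], None,
            registry, thresholds)
        assert out[0].code == "iL21"
        assert "150" in out[0].comment
        assert "repeat ALP and GGT testing in three months" in out[0].comment

    def test_urgent_leads_with_urgency(self, registry, thresholds):
        out = classify(ctx(), panel(), full_plan(), findings_with(),
                       fibrosis(SIG, elf=13.4, urgent=True), registry, thresholds)
        urgent = next(o for o in out if o.code == "iLX-ELF-URGENT")
        assert urgent.comment.startswith("URGENT")
        assert "urgent referral" in urgent.comment

    def test_missing_placeholder_marked(self, registry):
        entry = registry["iL01"]
        text = render_comment(entry, {"alt": 80.0})  # a1at missing
        assert "[unavailable]" in text

    def test_malignancy_comment_recommends_imaging(self, registry, thresholds):
        out = classify(ctx(age=55), panel(alp=250, platelets=450),
                       full_plan(abnormal=("alp",)), findings_with(),
                       fibrosis(LOW), registry, thresholds)
        malig = next(o for o in out if o.code == "iLX-MALIGNANCY")
        assert "malignancy" in malig.comment
        assert "further tests" in malig.comment
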
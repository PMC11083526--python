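"""First-line cascade logic.

The first-line panel (ALT, ALP, GGT, total bilirubin) is compared against the
configured trigger thresholds and exactly one reflex tier is chosen:

``full``
    ALT above its trigger, GGT above its URL, total bilirubin above the mild
    band, or ALP above the full-cascade limit — the complete aetiology screen
    cascades (AST, iron studies, A1AT, viral serology, autoantibodies, plus
    CRP when the patient is under 45; caeruloplasmin follows only if CRP is
    not elevated).
``limited_bilirubin``
    Mildly raised total bilirubin as the *only* abnormality — direct
    bilirubin and haptoglobin cascade to assess for Gilbert syndrome.
``alp_advisory``
    Mildly raised ALP as the only abnormality — no assays cascade; an
    advisory outcome recommends repeat testing.
``none``
    Everything within limits.

If both the mild-bilirubin and the mild-ALP patterns are present with nothing
else abnormal, neither is "the only abnormality": the record escalates to a
full screen (fail-safe).
"""

from __future__ import annotations

from .config import Thresholds
from .models import CascadePlan, LiverPanel, PatientContext, Tier

__all__ = ["FULL_SCREEN_ASSAYS", "evaluate_first_line"]

#: Assays always added on a full cascade (caeruloplasmin is added downstream,
#: gated on a non-elevated CRP).
FULL_SCREEN_ASSAYS = frozenset(
    {"ast", "iron_studies", "a1at", "hbv_serology", "hcv_serology", "autoantibodies"}
)

LIMITED_ASSAYS = frozenset({"direct_bilirubin", "haptoglobin"})


def evaluate_first_line(
    panel: LiverPanel, context: PatientContext, thresholds: Thresholds
) -> CascadePlan:
    """Decide which reflex tier and which additional assays cascade.

    Comparator strictness: ALT, GGT, ALP and the upper bilirubin bound are
    strict ``>``; the lower bilirubin bound is inclusive ``>=`` (values at
    22 umol/L are already abnormal against a 21 umol/L URL).
    """
    t = thresholds
    abnormal = set()
    if panel.alt > t.alt_trigger:
        abnormal.add("alt")
    if panel.alp > t.alp_url:
        abnormal.add("alp")
    if panel.ggt > t.ggt_url:
        abnormal.add("ggt")
    if panel.bilirubin_total >= t.bili_mild_low:
        abnormal.add("bilirubin_total")

    full = (
        panel.alt > t.alt_trigger
        or panel.ggt > t.ggt_url
        or panel.bilirubin_total > t.bili_mild_high
        or panel.alp > t.alp_full_cascade
    )
    if not full and abnormal == {"alp", "bilirubin_total"}:
        # two concurrent mild isolated abnormalities: neither rule's
        # "only abnormality" premise holds, so fail safe to the full screen
        full = True

    if full:
        added = set(FULL_SCREEN_ASSAYS)
        if context.age < t.crp_age_max:
            added.add("crp")
        return CascadePlan(Tier.FULL, frozenset(added), frozenset(abnormal))

    if abnormal == {"bilirubin_total"}:
        return CascadePlan(Tier.LIMITED_BILIRUBIN, LIMITED_ASSAYS, frozenset(abnormal))
    if abnormal == {"alp"}:
        return CascadePlan(Tier.ALP_ADVISORY, frozenset(), frozenset(abnormal))
    return CascadePlan(Tier.NONE)
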
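"""Independent nested-conditional oracles for the rule engine.

These re-state the pathway rules as plain nested conditionals, written
separately from the engine so grid comparisons are a genuine dual route.
They intentionally share no code with ``ilft``.
"""

from __future__ import annotations

import math


def oracle_tier(alt: float, alp: float, ggt: float, bili: float) -> str:
    """Cascade tier from the default thresholds, as plain nested ifs."""
    if alt > 30:
        return "full"
    if ggt > 60:
        return "full"
    if bili > 60:
        return "full"
    if alp > 200:
        return "full"
    bili_abnormal = bili >= 22
    alp_abnormal = alp > 130
    if bili_abnormal and alp_abnormal:
        return "full"  # two concurrent mild abnormalities fail safe
    if bili_abnormal:
        return "limited_bilirubin"
    if alp_abnormal:
        return "alp_advisory"
    return "none"


def oracle_fib4(age, ast, alt, platelets):
    return age * ast / (platelets * alt ** 0.5)


def oracle_nfs(age, bmi, dysglycaemia, ast, alt, platelets, albumin_g_l):
    return (
        -1.675 + 0.037 * age + 0.094 * bmi + 1.13 * (1 if dysglycaemia else 0)
        + 0.99 * ast / alt - 0.013 * platelets - 0.66 * albumin_g_l / 10
    )


def oracle_elf(ha, piiinp, timp1):
    return 2.278 + 0.851 * math.log(ha) + 0.751 * math.log(piiinp) + 0.394 * math.log(timp1)


def oracle_full_cascade_codes(
    alcohol: bool,
    metabolic: bool,
    positive_aetiologies: set[str],
    fibrosis_category: str,
    alt: float,
    malignancy: bool,
    urgent_elf: bool,
) -> set[str]:
    """Expected code set for a full cascade, as plain nested conditionals.

    ``positive_aetiologies`` uses the screen names: a1at, iron, hbv, hcv,
    autoimmune, wilson. ``fibrosis_category`` is one of the four final
    categories.
    """
    codes: set[str] = set()
    significant = fibrosis_category == "significant_fibrosis"

    if "a1at" in positive_aetiologies:
        codes.add("iL01")
    if "iron" in positive_aetiologies:
        codes.add("iLX-IRON")
    if "hbv" in positive_aetiologies:
        codes.add("iLX-HBV")
    if "hcv" in positive_aetiologies:
        codes.add("iLX-HCV")
    if "autoimmune" in positive_aetiologies:
        codes.add("iLX-AUTOIMMUNE")
    if "wilson" in positive_aetiologies:
        codes.add("iLX-WILSON")

    if alcohol and metabolic:
        codes.add("iLX-METALD-F" if significant else "iLX-METALD-NF")
    elif alcohol:
        codes.add("iL04" if significant else "iL05")
    elif metabolic:
        codes.add("iL16" if significant else "iL17")
    elif not codes:
        # descriptive branch: abnormal ALT only in these scenarios
        if significant:
            codes.add("iLX-FIB-SIG")
        elif alt < 250:
            codes.add("iL15")

    if alt >= 250:
        codes.add("iLX-ALT-MARKED")
    if malignancy:
        codes.add("iLX-MALIGNANCY")

    if significant and not codes & {"iL04", "iL16", "iLX-METALD-F", "iLX-FIB-SIG"}:
        codes.add("iLX-FIB-SIG")
    if fibrosis_category == "indeterminate_unresolved":
        codes.add("iLX-FIB-INDET")
    if urgent_elf:
        codes.add("iLX-ELF-URGENT")
    return codes
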
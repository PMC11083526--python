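"""Interpretation of the reflexed aetiology screen.

Each candidate cause gets exactly one finding — positive, negative or
not-tested — for any valid input. Notable rules:

* A1AT deficiency flags at serum A1AT < 1.0 g/L (phenotyping would follow).
* The Wilson pathway is age-gated: caeruloplasmin is only informative below
  45 years and only when CRP is not elevated (caeruloplasmin is an
  acute-phase reactant, so an inflammatory state masks a true deficiency).
* The Gilbert work-up on the limited bilirubin tier: predominantly
  unconjugated hyperbilirubinaemia (low direct/total fraction) with a normal
  haptoglobin (no haemolysis) is "likely Gilbert syndrome".
"""

from __future__ import annotations

import logging
from typing import Optional

from .config import Thresholds
from .models import (
    Aetiology,
    AetiologyFinding,
    AetiologyScreen,
    FindingStatus,
    GilbertResult,
    PatientContext,
)

__all__ = ["interpret_screen", "gilbert_check"]

logger = logging.getLogger(__name__)

_POS = FindingStatus.POSITIVE
_NEG = FindingStatus.NEGATIVE
_NT = FindingStatus.NOT_TESTED


def _flag_finding(aetiology: Aetiology, flag: Optional[bool], detail_pos: str) -> AetiologyFinding:
    if flag is None:
        return AetiologyFinding(aetiology, _NT)
    if flag:
        return AetiologyFinding(aetiology, _POS, detail_pos)
    return AetiologyFinding(aetiology, _NEG)


def interpret_screen(
    screen: AetiologyScreen,
    context: PatientContext,
    thresholds: Thresholds,
    bilirubin_total: Optional[float] = None,
) -> list[AetiologyFinding]:
    """One finding per candidate aetiology; ``not_tested`` where nothing cascaded.

    ``bilirubin_total`` is needed only to interpret the limited bilirubin
    cascade (conjugated fraction); leave it ``None`` on other tiers.
    """
    t = thresholds
    findings: list[AetiologyFinding] = []

    if screen.transferrin_saturation is None:
        findings.append(AetiologyFinding(Aetiology.IRON_OVERLOAD, _NT))
    elif screen.transferrin_saturation > t.transferrin_sat_high:
        findings.append(AetiologyFinding(
            Aetiology.IRON_OVERLOAD, _POS,
            f"transferrin saturation {screen.transferrin_saturation:g}% — "
            "consider HFE genotyping",
        ))
    else:
        findings.append(AetiologyFinding(Aetiology.IRON_OVERLOAD, _NEG))

    if screen.a1at is None:
        findings.append(AetiologyFinding(Aetiology.A1AT_DEFICIENCY, _NT))
    elif screen.a1at < t.a1at_deficiency:
        findings.append(AetiologyFinding(
            Aetiology.A1AT_DEFICIENCY, _POS,
            f"A1AT {screen.a1at:g} g/L — phenotyping recommended",
        ))
    else:
        findings.append(AetiologyFinding(Aetiology.A1AT_DEFICIENCY, _NEG))

    findings.append(_flag_finding(
        Aetiology.HEPATITIS_B, screen.hbv_positive, "HBV serology positive"))
    findings.append(_flag_finding(
        Aetiology.HEPATITIS_C, screen.hcv_positive, "HCV serology positive"))

    if screen.autoantibody_positive is None:
        findings.append(AetiologyFinding(Aetiology.AUTOIMMUNE, _NT))
    elif screen.autoantibody_positive:
        pattern = f" ({screen.autoantibody_pattern} pattern)" if screen.autoantibody_pattern else ""
        findings.append(AetiologyFinding(
            Aetiology.AUTOIMMUNE, _POS, f"liver autoantibodies positive{pattern}"))
    else:
        findings.append(AetiologyFinding(Aetiology.AUTOIMMUNE, _NEG))

    findings.append(_wilson_finding(screen, context, t))
    findings.extend(_bilirubin_findings(screen, bilirubin_total, t))
    return findings


def _wilson_finding(
    screen: AetiologyScreen, context: PatientContext, t: Thresholds
) -> AetiologyFinding:
    crp_elevated = screen.crp is not None and screen.crp > t.crp_elevated
    if screen.caeruloplasmin is None:
        return AetiologyFinding(Aetiology.WILSON_POSSIBLE, _NT)
    if crp_elevated:
        # protocol says caeruloplasmin should not have been added; interpret
        # defensively (an acute-phase rise can mask deficiency) but warn
        logger.warning(
            "caeruloplasmin supplied despite elevated CRP (%g mg/L): protocol violation",
            screen.crp,
        )
        return AetiologyFinding(
            Aetiology.WILSON_POSSIBLE, _NEG,
            "caeruloplasmin uninterpretable with elevated CRP (protocol violation)",
        )
    if (
        context.age < t.crp_age_max
        and screen.caeruloplasmin < t.caeruloplasmin_low
    ):
        return AetiologyFinding(
            Aetiology.WILSON_POSSIBLE, _POS,
            f"caeruloplasmin {screen.caeruloplasmin:g} g/L with normal CRP",
        )
    return AetiologyFinding(Aetiology.WILSON_POSSIBLE, _NEG)


def _bilirubin_findings(
    screen: AetiologyScreen, bilirubin_total: Optional[float], t: Thresholds
) -> list[AetiologyFinding]:
    result = gilbert_check(
        bilirubin_total, screen.direct_bilirubin, screen.haptoglobin, t
    )
    if result is GilbertResult.NOT_APPLICABLE:
        return [
            AetiologyFinding(Aetiology.GILBERT_PATTERN, _NT),
            AetiologyFinding(Aetiology.HAEMOLYSIS_PATTERN, _NT),
        ]
    gilbert = AetiologyFinding(
        Aetiology.GILBERT_PATTERN,
        _POS if result is GilbertResult.GILBERT_LIKELY else _NEG,
        "predominantly unconjugated hyperbilirubinaemia, no haemolysis"
        if result is GilbertResult.GILBERT_LIKELY else "",
    )
    haemolysis = AetiologyFinding(
        Aetiology.HAEMOLYSIS_PATTERN,
        _POS if result is GilbertResult.HAEMOLYSIS_SUSPECTED else _NEG,
        f"haptoglobin {screen.haptoglobin:g} g/L below {t.haptoglobin_low:g}"
        if result is GilbertResult.HAEMOLYSIS_SUSPECTED else "",
    )
    return [gilbert, haemolysis]


def gilbert_check(
    bilirubin_total: Optional[float],
    direct_bilirubin: Optional[float],
    haptoglobin: Optional[float],
    thresholds: Thresholds,
) -> GilbertResult:
    """Classify a limited bilirubin cascade.

    Outcomes are mutually exclusive and exhaustive over valid inputs:
    haemolysis (low haptoglobin) takes precedence; otherwise a conjugated
    fraction below the cutoff is Gilbert-like and at/above it is a
    conjugated pattern.
    """
    t = thresholds
    if bilirubin_total is None or direct_bilirubin is None or haptoglobin is None:
        return GilbertResult.NOT_APPLICABLE
    if bilirubin_total <= 0:
        return GilbertResult.NOT_APPLICABLE
    if direct_bilirubin > bilirubin_total:
        raise ValueError("direct bilirubin exceeds total bilirubin")
    if haptoglobin < t.haptoglobin_low:
        return GilbertResult.HAEMOLYSIS_SUSPECTED
    if direct_bilirubin / bilirubin_total < t.conjugated_fraction:
        return GilbertResult.GILBERT_LIKELY
    return GilbertResult.CONJUGATED_PATTERN
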
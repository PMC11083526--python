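"""Outcome engine: map the classified stages onto coded outcomes.

The registry of coded outcomes is data-driven (a delimited text file with
code, category, referral policy, description and comment template).
Externally published codes keep their ``iLxx`` identifiers; outcomes whose
official codes are not public are reconstructed under an ``iLX-*`` namespace
so they cannot be mistaken for official ones.

``classify`` assembles one or more outcomes per record by precedence:

1. each positive aetiology finding yields its aetiological outcome;
2. lifestyle tick-boxes yield a presumed steatotic-liver-disease outcome —
   alcohol + metabolic syndrome = MetALD, alcohol alone = ALD, metabolic
   syndrome alone = MASLD — split by fibrosis category;
3. with nothing from (1) or (2), a descriptive outcome keyed to the
   abnormal-analyte pattern (an unmapped pattern falls back to a generic
   descriptive outcome with routine referral — never silently dropped);
4. markedly elevated ALT (>= 250 U/L) adds an urgent alert;
5. the malignancy alert (age > 40, ALP > 130, platelets > 400) is appended
   whenever its rule fires;
6. the fibrosis category appends its own referral-bearing outcome when no
   emitted outcome already carries the fibrosis message.

The record-level referral is the maximum severity over emitted outcomes.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Optional

from .config import Thresholds
from .models import (
    Aetiology,
    AetiologyFinding,
    AetiologyScreen,
    CascadePlan,
    FibrosisAssessment,
    FinalCategory,
    FindingStatus,
    LiverPanel,
    Outcome,
    OutcomeCategory,
    PatientContext,
    Referral,
    Tier,
)

__all__ = [
    "OutcomeRegistry",
    "load_registry",
    "classify",
    "malignancy_alert",
    "render_comment",
    "record_referral",
]

logger = logging.getLogger(__name__)

#: emission-order precedence (lower sorts first)
_PREC_ALERT_URGENT = 0
_PREC_URGENT = 1
_PREC_AETIOLOGICAL = 2
_PREC_LIFESTYLE = 3
_PREC_DESCRIPTIVE = 4
_PREC_ADVISORY = 5

_AETIOLOGY_CODES = {
    Aetiology.A1AT_DEFICIENCY: "iL01",
    Aetiology.IRON_OVERLOAD: "iLX-IRON",
    Aetiology.HEPATITIS_B: "iLX-HBV",
    Aetiology.HEPATITIS_C: "iLX-HCV",
    Aetiology.AUTOIMMUNE: "iLX-AUTOIMMUNE",
    Aetiology.WILSON_POSSIBLE: "iLX-WILSON",
}

_DESCRIPTIVE_PATTERNS = {
    frozenset({"alt"}): "iL15",
    frozenset({"alt", "ggt"}): "iL28",
    frozenset({"alt", "alp", "ggt"}): "iL02",
}

#: outcomes that already express "significant fibrosis" in their own text
_FIBROSIS_BEARING = {"iL04", "iL16", "iLX-METALD-F", "iLX-FIB-SIG"}

_LEGACY_NAMES = {
    "MetALD": "combined NAFLD and alcohol-related liver disease",
    "MASLD": "NAFLD",
    "metabolic dysfunction-associated steatotic liver disease":
        "non-alcoholic fatty liver disease",
}


@dataclass(frozen=True)
class RegistryEntry:
    code: str
    category: OutcomeCategory
    referral: Referral
    description: str
    comment_template: str


class OutcomeRegistry:
    """Code -> outcome definition mapping loaded from a delimited text file."""

    def __init__(self, entries: Iterable[RegistryEntry], legacy_nomenclature: bool = False):
        self._entries: dict[str, RegistryEntry] = {}
        for e in entries:
            if e.code in self._entries:
                raise ValueError(f"duplicate outcome code {e.code!r}")
            if legacy_nomenclature:
                e = RegistryEntry(
                    e.code, e.category, e.referral,
                    _legacy(e.description), _legacy(e.comment_template),
                )
            self._entries[e.code] = e

    def __getitem__(self, code: str) -> RegistryEntry:
        return self._entries[code]

    def __contains__(self, code: str) -> bool:
        return code in self._entries

    def __iter__(self):
        return iter(self._entries.values())

    def __len__(self) -> int:
        return len(self._entries)


def _legacy(text: str) -> str:
    for new, old in _LEGACY_NAMES.items():
        text = text.replace(new, old)
    return text


def load_registry(
    path: str | Path | None = None, legacy_nomenclature: bool = False
) -> OutcomeRegistry:
    """Load the outcome registry (packaged default unless ``path`` given)."""
    if path is None:
        text = resources.files("ilft.data").joinpath("outcome_registry.tsv").read_text()
        lines = text.splitlines()
    else:
        lines = Path(path).read_text().splitlines()
    reader = csv.DictReader(lines, delimiter="\t")
    entries = [
        RegistryEntry(
            code=row["code"],
            category=OutcomeCategory(row["category"]),
            referral=Referral(row["referral"]),
            description=row["description"],
            comment_template=row["comment_template"],
        )
        for row in reader
    ]
    return OutcomeRegistry(entries, legacy_nomenclature=legacy_nomenclature)


def malignancy_alert(age: float, alp: float, platelets: Optional[float]) -> bool:
    """Alert rule: age strictly over 40, ALP > 130 U/L, platelets > 400 x10^9/L."""
    if platelets is None:
        return False
    return age > 40 and alp > 130 and platelets > 400


def render_comment(entry: RegistryEntry, record: Mapping[str, object]) -> str:
    """Interpolate record values into the outcome's comment template.

    A placeholder absent from the record renders as ``[unavailable]`` (and is
    logged) rather than failing the whole report.
    """

    class _Defaulting(dict):
        def __missing__(self, key: str) -> str:
            logger.warning("comment placeholder %r unavailable for %s", key, entry.code)
            return "[unavailable]"

    values = _Defaulting({k: _fmt(v) for k, v in record.items() if v is not None})
    return entry.comment_template.format_map(values)


def _fmt(value: object) -> object:
    if isinstance(value, float):
        return f"{value:g}"
    if isinstance(value, frozenset):
        return ", ".join(sorted(value))
    return value


def record_referral(outcomes: Iterable[Outcome]) -> Referral:
    """Maximum referral severity over a record's outcomes."""
    best = Referral.NONE
    for o in outcomes:
        if o.referral.severity > best.severity:
            best = o.referral
    return best


def classify(
    context: PatientContext,
    panel: LiverPanel,
    plan: CascadePlan,
    findings: Iterable[AetiologyFinding],
    fibrosis: Optional[FibrosisAssessment],
    registry: OutcomeRegistry,
    thresholds: Thresholds,
    screen: Optional[AetiologyScreen] = None,
) -> list[Outcome]:
    """Emit the coded outcome list for one fully staged record."""
    t = thresholds
    record = _comment_context(context, panel, plan, findings, fibrosis, screen)
    emitted: list[tuple[int, str]] = []  # (precedence, code)
    by_aetiology = {f.aetiology: f for f in findings}

    if plan.tier is Tier.NONE:
        emitted.append((_PREC_ADVISORY, "iLX-NORMAL"))
    elif plan.tier is Tier.ALP_ADVISORY:
        emitted.append((_PREC_ADVISORY, "iL21"))
    elif plan.tier is Tier.LIMITED_BILIRUBIN:
        emitted.append(_limited_outcome(by_aetiology))
    else:
        emitted.extend(_full_outcomes(context, panel, plan, by_aetiology, fibrosis, t))

    if not emitted:  # defensive: the rules above are exhaustive per tier
        logger.warning("no outcome rule matched; emitting fail-safe descriptive outcome")
        emitted.append((_PREC_DESCRIPTIVE, "iLX-DESC"))

    emitted.sort()
    return [
        Outcome(
            code=code,
            description=registry[code].description,
            referral=registry[code].referral,
            category=registry[code].category,
            comment=render_comment(registry[code], record),
            precedence=prec,
        )
        for prec, code in emitted
    ]


def _limited_outcome(by_aetiology: Mapping[Aetiology, AetiologyFinding]) -> tuple[int, str]:
    gilbert = by_aetiology.get(Aetiology.GILBERT_PATTERN)
    haemolysis = by_aetiology.get(Aetiology.HAEMOLYSIS_PATTERN)
    if gilbert is not None and gilbert.status is FindingStatus.POSITIVE:
        return (_PREC_AETIOLOGICAL, "iL06")
    if haemolysis is not None and haemolysis.status is FindingStatus.POSITIVE:
        return (_PREC_DESCRIPTIVE, "iLX-HAEMOLYSIS")
    if gilbert is not None and gilbert.status is FindingStatus.NEGATIVE:
        return (_PREC_DESCRIPTIVE, "iLX-CONJ-BILI")
    # reflex assays missing: fail safe rather than concluding anything
    logger.warning("limited bilirubin cascade without interpretable reflex results")
    return (_PREC_DESCRIPTIVE, "iLX-DESC")


def _full_outcomes(
    context: PatientContext,
    panel: LiverPanel,
    plan: CascadePlan,
    by_aetiology: Mapping[Aetiology, AetiologyFinding],
    fibrosis: Optional[FibrosisAssessment],
    t: Thresholds,
) -> list[tuple[int, str]]:
    emitted: list[tuple[int, str]] = []
    significant = (
        fibrosis is not None
        and fibrosis.final_category is FinalCategory.SIGNIFICANT_FIBROSIS
    )

    for aetiology, code in _AETIOLOGY_CODES.items():
        finding = by_aetiology.get(aetiology)
        if finding is not None and finding.status is FindingStatus.POSITIVE:
            emitted.append((_PREC_AETIOLOGICAL, code))

    if context.alcohol_over_14_units and context.metabolic_syndrome:
        emitted.append((_PREC_LIFESTYLE, "iLX-METALD-F" if significant else "iLX-METALD-NF"))
    elif context.alcohol_over_14_units:
        emitted.append((_PREC_LIFESTYLE, "iL04" if significant else "iL05"))
    elif context.metabolic_syndrome:
        emitted.append((_PREC_LIFESTYLE, "iL16" if significant else "iL17"))
    elif not emitted:
        # negative screen, no lifestyle flags: describe the pattern
        emitted.extend(_descriptive_outcome(panel, plan, significant, t))

    if panel.alt >= t.alt_marked:
        emitted.append((_PREC_ALERT_URGENT, "iLX-ALT-MARKED"))
    if malignancy_alert(context.age, panel.alp, panel.platelets):
        emitted.append((_PREC_ALERT_URGENT, "iLX-MALIGNANCY"))

    if fibrosis is not None:
        codes = {code for _, code in emitted}
        if significant and not (codes & _FIBROSIS_BEARING):
            emitted.append((_PREC_DESCRIPTIVE, "iLX-FIB-SIG"))
        if fibrosis.final_category is FinalCategory.INDETERMINATE_UNRESOLVED:
            emitted.append((_PREC_DESCRIPTIVE, "iLX-FIB-INDET"))
        if fibrosis.urgent_prognosis:
            emitted.append((_PREC_ALERT_URGENT, "iLX-ELF-URGENT"))
    return emitted


def _descriptive_outcome(
    panel: LiverPanel, plan: CascadePlan, significant: bool, t: Thresholds
) -> list[tuple[int, str]]:
    if significant:
        return [(_PREC_DESCRIPTIVE, "iLX-FIB-SIG")]
    if panel.alt >= t.alt_marked:
        return []  # the urgent marked-ALT alert carries the message
    code = _DESCRIPTIVE_PATTERNS.get(plan.abnormal_analytes)
    if code is None:
        logger.info("abnormality pattern %s not specifically mapped", sorted(plan.abnormal_analytes))
        return [(_PREC_DESCRIPTIVE, "iLX-DESC")]
    return [(_PREC_DESCRIPTIVE, code)]


def _comment_context(
    context: PatientContext,
    panel: LiverPanel,
    plan: CascadePlan,
    findings: Iterable[AetiologyFinding],
    fibrosis: Optional[FibrosisAssessment],
    screen: Optional[AetiologyScreen] = None,
) -> dict[str, object]:
    record: dict[str, object] = {}
    record.update(context.model_dump())
    record.update(panel.model_dump())
    if screen is not None:
        record.update(screen.model_dump())
    record["abnormal_analytes"] = plan.abnormal_analytes
    if fibrosis is not None:
        record["fib4"] = fibrosis.fib4
        record["nfs"] = fibrosis.nfs
        record["elf"] = fibrosis.elf
    for f in findings:
        if f.detail:
            record.setdefault(f"{f.aetiology.value}_detail", f.detail)
    return record
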
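"""Per-record orchestration and batch file processing.

``process_record`` runs one validated record through the whole pathway:
first-line cascade, fibrosis scoring (with the ELF reflex), aetiology screen
interpretation and outcome coding, returning a plain dict ready for JSON or
flat-CSV serialisation. ``run_pipeline`` applies it to a CSV/JSON cohort
file, rejecting malformed rows individually (with a line-numbered report)
rather than aborting the batch.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd
from pydantic import ValidationError

from .aetiology import interpret_screen
from .cascade import evaluate_first_line
from .config import Thresholds, load_thresholds
from .fibrosis import assess_fibrosis, band_indirect, compute_elf, compute_fib4, compute_nfs
from .models import (
    AetiologyScreen,
    ElfInputs,
    FibrosisAssessment,
    IndirectBand,
    LiverPanel,
    PatientContext,
    Tier,
)
from .outcomes import OutcomeRegistry, classify, load_registry, record_referral

__all__ = ["process_record", "run_pipeline", "RunResult", "RECORD_COLUMNS"]

logger = logging.getLogger(__name__)

#: canonical input schema (CSV columns / JSON keys); screen analytes optional
RECORD_COLUMNS = [
    "patient_id", "age", "sex", "bmi", "alcohol_over_14", "metabolic_syndrome",
    "alt", "alp", "ggt", "bilirubin_total", "albumin", "ast", "platelets",
    "transferrin_saturation", "a1at", "hbv_positive", "hcv_positive",
    "autoantibody_positive", "autoantibody_pattern", "crp", "caeruloplasmin",
    "direct_bilirubin", "haptoglobin", "elf_ha", "elf_piiinp", "elf_timp1",
]

_CONTEXT_KEYS = {"age", "sex", "bmi", "alcohol_over_14", "metabolic_syndrome"}
_PANEL_KEYS = {"alt", "alp", "ggt", "bilirubin_total", "albumin", "ast", "platelets"}
_SCREEN_KEYS = {
    "transferrin_saturation", "a1at", "hbv_positive", "hcv_positive",
    "autoantibody_positive", "autoantibody_pattern", "crp", "caeruloplasmin",
    "direct_bilirubin", "haptoglobin",
}

_ASSAY_TO_FIELDS = {
    "iron_studies": ("transferrin_saturation",),
    "a1at": ("a1at",),
    "hbv_serology": ("hbv_positive",),
    "hcv_serology": ("hcv_positive",),
    "autoantibodies": ("autoantibody_positive", "autoantibody_pattern"),
    "crp": ("crp",),
    "direct_bilirubin": ("direct_bilirubin",),
    "haptoglobin": ("haptoglobin",),
}


def _clean(value):
    if value is None:
        return None
    if hasattr(value, "item"):  # numpy scalar from pandas
        value = value.item()
    if isinstance(value, float) and pd.isna(value):
        return None
    if isinstance(value, str):
        s = value.strip()
        if s == "":
            return None
        if s.lower() in {"true", "false"}:
            return s.lower() == "true"
        return s
    return value


def parse_record(raw: dict) -> tuple[PatientContext, LiverPanel, AetiologyScreen]:
    """Validate one raw record dict into the three input models."""
    raw = {k: _clean(v) for k, v in raw.items()}
    context = PatientContext(
        age=raw["age"],
        sex=raw["sex"],
        bmi=raw["bmi"],
        alcohol_over_14_units=bool(raw.get("alcohol_over_14", False)),
        metabolic_syndrome=bool(raw.get("metabolic_syndrome", False)),
    )
    panel = LiverPanel(**{k: raw.get(k) for k in _PANEL_KEYS})
    screen = AetiologyScreen(**{k: raw.get(k) for k in _SCREEN_KEYS if raw.get(k) is not None})
    return context, panel, screen


def _cascaded_screen(screen: AetiologyScreen, plan, context, thresholds) -> AetiologyScreen:
    """Restrict the screen to assays that actually cascaded for this record.

    Caeruloplasmin is gated: it is only considered when CRP cascaded (age
    under 45) and is not elevated.
    """
    fields: set[str] = set()
    for assay in plan.added_assays:
        fields.update(_ASSAY_TO_FIELDS.get(assay, ()))
    keep = {k: getattr(screen, k) for k in fields if getattr(screen, k) is not None}
    if (
        "crp" in plan.added_assays
        and screen.crp is not None
        and screen.crp <= thresholds.crp_elevated
        and screen.caeruloplasmin is not None
    ):
        keep["caeruloplasmin"] = screen.caeruloplasmin
        keep["crp"] = screen.crp
    return AetiologyScreen(**keep)


def _fibrosis_stage(
    context: PatientContext,
    panel: LiverPanel,
    raw: dict,
    thresholds: Thresholds,
) -> FibrosisAssessment:
    """Score fibrosis on a full cascade, reflexing ELF where indicated."""
    use_nfs = context.metabolic_syndrome  # presumed MASLD/MetALD branches only
    fib4 = compute_fib4(context.age, panel.ast, panel.alt, panel.platelets)
    nfs = compute_nfs(
        context.age, context.bmi, context.metabolic_syndrome,
        panel.ast, panel.alt, panel.platelets, panel.albumin,
    )
    indirect = band_indirect(fib4, nfs, use_nfs, thresholds)

    elf = None
    if indirect is not IndirectBand.LOW:
        ha, piiinp, timp1 = (
            _clean(raw.get("elf_ha")), _clean(raw.get("elf_piiinp")), _clean(raw.get("elf_timp1")),
        )
        if None not in (ha, piiinp, timp1):
            elf = compute_elf(ElfInputs(ha=ha, piiinp=piiinp, timp1=timp1), thresholds)
    return assess_fibrosis(indirect, elf, thresholds, fib4=fib4, nfs=nfs)


def process_record(
    raw: dict,
    thresholds: Thresholds,
    registry: OutcomeRegistry,
) -> dict:
    """Run one record through cascade, fibrosis, aetiology and outcome coding."""
    context, panel, screen = parse_record(raw)
    plan = evaluate_first_line(panel, context, thresholds)

    fibrosis: Optional[FibrosisAssessment] = None
    if plan.tier is Tier.FULL:
        fibrosis = _fibrosis_stage(context, panel, raw, thresholds)

    visible = _cascaded_screen(screen, plan, context, thresholds)
    bili_total = panel.bilirubin_total if plan.tier is Tier.LIMITED_BILIRUBIN else None
    findings = interpret_screen(visible, context, thresholds, bilirubin_total=bili_total)

    outcomes = classify(
        context, panel, plan, findings, fibrosis, registry, thresholds, screen=visible
    )

    result = {
        "patient_id": _clean(raw.get("patient_id")),
        "tier": plan.tier.value,
        "added_assays": sorted(plan.added_assays),
        "abnormal_analytes": sorted(plan.abnormal_analytes),
        "scores": {
            "fib4": fibrosis.fib4 if fibrosis else None,
            "nfs": fibrosis.nfs if fibrosis else None,
            "elf": fibrosis.elf if fibrosis else None,
        },
        "bands": {
            "indirect_band": fibrosis.indirect_band.value if fibrosis else None,
            "elf_band": (
                fibrosis.elf_band.value if fibrosis and fibrosis.elf_band else None
            ),
            "final_fibrosis_category": fibrosis.final_category.value if fibrosis else None,
            "urgent_prognosis": fibrosis.urgent_prognosis if fibrosis else False,
        },
        "findings": [
            {"aetiology": f.aetiology.value, "status": f.status.value, "detail": f.detail}
            for f in findings
        ],
        "outcomes": [
            {
                "code": o.code,
                "description": o.description,
                "category": o.category.value,
                "referral": o.referral.value,
                "comment": o.comment,
            }
            for o in outcomes
        ],
        "record_referral": record_referral(outcomes).value,
    }
    return result


@dataclass
class RunResult:
    n_processed: int = 0
    n_rejected: int = 0
    rejects: list[str] = field(default_factory=list)
    results: list[dict] = field(default_factory=list)

    @property
    def exit_status(self) -> int:
        return 1 if self.n_rejected else 0


def _read_records(path: Path) -> list[dict]:
    if path.suffix.lower() == ".json":
        with open(path) as fh:
            data = json.load(fh)
        if not isinstance(data, list):
            raise ValueError("JSON input must be an array of record objects")
        return data
    df = pd.read_csv(path)
    return df.to_dict(orient="records")


def _flat_rows(results: list[dict]) -> pd.DataFrame:
    rows = []
    for r in results:
        for o in r["outcomes"]:
            rows.append({
                "patient_id": r["patient_id"],
                "tier": r["tier"],
                "code": o["code"],
                "description": o["description"],
                "category": o["category"],
                "referral": o["referral"],
                "record_referral": r["record_referral"],
                "fib4": r["scores"]["fib4"],
                "nfs": r["scores"]["nfs"],
                "elf": r["scores"]["elf"],
                "final_fibrosis_category": r["bands"]["final_fibrosis_category"],
            })
    return pd.DataFrame(rows)


def run_pipeline(
    input_path: str | Path,
    config_path: str | Path | None = None,
    output_path: str | Path | None = None,
    output_format: str = "json",
) -> RunResult:
    """Classify a cohort file, writing per-record output and logging rejects.

    Malformed rows are rejected individually and reported with their row
    number; the exit status is non-zero when any row was rejected.
    """
    thresholds = load_thresholds(config_path)
    registry = load_registry(legacy_nomenclature=thresholds.legacy_nomenclature)
    raw_records = _read_records(Path(input_path))

    run = RunResult()
    for i, raw in enumerate(raw_records):
        try:
            run.results.append(process_record(raw, thresholds, registry))
            run.n_processed += 1
        except (ValidationError, ValueError, KeyError) as exc:
            run.n_rejected += 1
            msg = f"row {i + 1}: {exc}"
            run.rejects.append(msg)
            logger.error("rejected %s", msg)

    if output_path is not None:
        out = Path(output_path)
        out.parent.mkdir(parents=True, exist_ok=True)
        if output_format == "csv":
            _flat_rows(run.results).to_csv(out, index=False)
        else:
            with open(out, "w") as fh:
                json.dump(run.results, fh, indent=1, sort_keys=True)
                fh.write("\n")
    return run
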
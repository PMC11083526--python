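"""Cohort-level summaries: cascade rates, outcome tables, referral proportions.

Percentages follow the clinical-audit convention: one decimal place, half
rounded away from zero. Outcome shares are reported against two denominators
— the number of outcomes and the number of requests — because one cascade
can generate more than one outcome.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Optional

import pandas as pd

from .models import Tier

__all__ = ["percent", "summarize_cohort", "CohortSummary"]


def percent(numerator: int, denominator: int) -> Optional[float]:
    """100 * numerator / denominator, half-away-from-zero to one decimal.

    Returns ``None`` (an explicit undefined marker) when the denominator is
    zero, so an empty cohort never raises inside a report.
    """
    if denominator == 0:
        return None
    if numerator < 0 or denominator < 0:
        raise ValueError("counts must be non-negative")
    value = Decimal(100 * numerator) / Decimal(denominator)
    return float(value.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


@dataclass
class CohortSummary:
    """All counts and derived percentages for one classified cohort."""

    n_requests: int
    tier_counts: dict[str, int]
    tier_pct: dict[str, Optional[float]]
    n_outcomes: int
    outcome_table: list[dict]          # sorted by count desc, code asc
    category_counts: dict[str, int]
    category_pct: dict[str, Optional[float]]
    n_referral: int                    # records advised routine or urgent referral
    referral_pct: Optional[float]      # of requests
    no_referral_pct: Optional[float]
    fibrosis_counts: dict[str, int] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "n_requests": self.n_requests,
            "tier_counts": self.tier_counts,
            "tier_pct": self.tier_pct,
            "n_outcomes": self.n_outcomes,
            "outcome_table": self.outcome_table,
            "category_counts": self.category_counts,
            "category_pct": self.category_pct,
            "n_referral": self.n_referral,
            "referral_pct": self.referral_pct,
            "no_referral_pct": self.no_referral_pct,
            "fibrosis_counts": self.fibrosis_counts,
        }

    def render_text(self) -> str:
        lines = [f"Requests: {self.n_requests}   Outcomes: {self.n_outcomes}", ""]
        lines.append("Cascade tiers:")
        for tier in [t.value for t in Tier]:
            n = self.tier_counts.get(tier, 0)
            lines.append(f"  {tier:<18} {n:>7}  ({_fmt_pct(self.tier_pct.get(tier))})")
        lines.append("")
        if self.outcome_table:
            df = pd.DataFrame(self.outcome_table)
            lines.append(df.to_string(index=False))
            lines.append("")
        lines.append(
            f"Referral advised: {self.n_referral} ({_fmt_pct(self.referral_pct)} of requests); "
            f"no referral: {_fmt_pct(self.no_referral_pct)}"
        )
        return "\n".join(lines)


def _fmt_pct(value: Optional[float]) -> str:
    return "undefined" if value is None else f"{value:.1f}%"


def summarize_cohort(results: list[dict]) -> CohortSummary:
    """Summarise classified records (the output dicts of ``process_record``).

    The summary depends only on the multiset of records, so it is invariant
    to input order; the outcome table is sorted by descending count with the
    code as a stable tie-break.
    """
    n_requests = len(results)
    tier_counts = Counter(r["tier"] for r in results)
    code_counts: Counter[str] = Counter()
    code_meta: dict[str, dict] = {}
    category_counts: Counter[str] = Counter()
    fibrosis_counts: Counter[str] = Counter()
    n_outcomes = 0
    n_referral = 0

    for r in results:
        for o in r["outcomes"]:
            n_outcomes += 1
            code_counts[o["code"]] += 1
            code_meta.setdefault(o["code"], {
                "description": o["description"], "referral": o["referral"],
            })
            category_counts[o["category"]] += 1
        if r["record_referral"] in ("routine", "urgent"):
            n_referral += 1
        cat = r.get("bands", {}).get("final_fibrosis_category")
        if cat is not None:
            fibrosis_counts[cat] += 1

    outcome_table = [
        {
            "code": code,
            "description": code_meta[code]["description"],
            "n": count,
            "pct_of_outcomes": percent(count, n_outcomes),
            "pct_of_requests": percent(count, n_requests),
            "referral": code_meta[code]["referral"],
        }
        for code, count in sorted(code_counts.items(), key=lambda kv: (-kv[1], kv[0]))
    ]

    return CohortSummary(
        n_requests=n_requests,
        tier_counts={t.value: tier_counts.get(t.value, 0) for t in Tier},
        tier_pct={t.value: percent(tier_counts.get(t.value, 0), n_requests) for t in Tier},
        n_outcomes=n_outcomes,
        outcome_table=outcome_table,
        category_counts=dict(category_counts),
        category_pct={c: percent(n, n_outcomes) for c, n in sorted(category_counts.items())},
        n_referral=n_referral,
        referral_pct=percent(n_referral, n_requests),
        no_referral_pct=percent(n_requests - n_referral, n_requests),
        fibrosis_counts=dict(fibrosis_counts),
    )
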
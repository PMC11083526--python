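"""Deterministic synthetic patient cohorts.

Two generators:

* :func:`generate_cohort` draws labelled records from a mixture of clinical
  profiles (alcohol-related, MASLD, Gilbert, viral, iron overload, A1AT
  deficiency, and so on). Each profile's analyte distributions are truncated
  normals whose truncation bounds are chosen, in one parameter file, so that
  the profile fires its intended pathway branch by construction. The hidden
  true-profile labels are returned (and written) separately as a sidecar so
  the classification path can never peek at them.

* :func:`fixture_marginals` emits hand-engineered records with exact
  per-tier (and optionally per-referral) counts, for reproducing published
  cohort marginals without any randomness.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml
from scipy.stats import truncnorm

__all__ = [
    "ProfileSpec",
    "CohortSpec",
    "load_profiles",
    "default_cohort_spec",
    "generate_cohort",
    "write_cohort",
    "fixture_marginals",
]

_PREVALENCE_TOL = 1e-9


@dataclass(frozen=True)
class ProfileSpec:
    """One mixture component: a named clinical profile and its prevalence."""

    name: str
    prevalence: float
    params: dict = field(hash=False)

    @property
    def expected_codes(self) -> list[str]:
        """Outcome codes that count as recovering this profile's label."""
        return list(self.params["expected_codes"])


@dataclass(frozen=True)
class CohortSpec:
    n: int
    seed: int
    profiles: tuple[ProfileSpec, ...]

    def __post_init__(self) -> None:
        if self.n < 0:
            raise ValueError("n must be non-negative")
        total = sum(p.prevalence for p in self.profiles)
        if abs(total - 1.0) > _PREVALENCE_TOL:
            raise ValueError(f"profile prevalences must sum to 1 (got {total!r})")


def load_profiles(path: str | Path | None = None) -> dict[str, dict]:
    """Profile parameter sets from the packaged (or an override) YAML file."""
    if path is None:
        text = resources.files("ilft.data").joinpath("synthetic_profiles.yaml").read_text()
    else:
        text = Path(path).read_text()
    return yaml.safe_load(text)["profiles"]


def default_cohort_spec(n: int, seed: int) -> CohortSpec:
    """The default mixture: every profile with a non-zero default prevalence."""
    profiles = load_profiles()
    specs = tuple(
        ProfileSpec(name, params["default_prevalence"], params)
        for name, params in profiles.items()
        if params["default_prevalence"] > 0
    )
    return CohortSpec(n=n, seed=seed, profiles=specs)


def _draw_truncnorm(rng: np.random.Generator, spec: dict) -> float:
    mean, sd, low, high = spec["mean"], spec["sd"], spec["low"], spec["high"]
    a, b = (low - mean) / sd, (high - mean) / sd
    return float(truncnorm.rvs(a, b, loc=mean, scale=sd, random_state=rng))


def _draw_record(rng: np.random.Generator, profile: ProfileSpec, patient_id: str) -> dict:
    p = profile.params
    record: dict = {"patient_id": patient_id}
    record["age"] = int(rng.integers(p["age"]["low"], p["age"]["high"] + 1))
    record["sex"] = "male" if rng.random() < 0.5 else "female"
    numeric = dict(p["numeric"])
    record["bmi"] = round(_draw_truncnorm(rng, numeric.pop("bmi")), 1)
    direct_fraction = numeric.pop("direct_fraction", None)
    for name, spec in numeric.items():
        record[name] = round(_draw_truncnorm(rng, spec), 2)
    if direct_fraction is not None:
        frac = _draw_truncnorm(rng, direct_fraction)
        record["direct_bilirubin"] = round(frac * record["bilirubin_total"], 2)
    for name, value in p.get("booleans", {}).items():
        record[name] = bool(value)
    for name, value in p.get("strings", {}).items():
        record[name] = value
    return record


def generate_cohort(spec: CohortSpec) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw ``spec.n`` records from the profile mixture.

    Returns ``(records, labels)``: the record table in the standard input
    schema and a sidecar table mapping ``patient_id`` to the hidden true
    profile. Identical specs yield byte-identical tables.
    """
    rng = np.random.default_rng(spec.seed)
    prevalences = np.array([p.prevalence for p in spec.profiles])
    choices = rng.choice(len(spec.profiles), size=spec.n, p=prevalences)

    records, labels = [], []
    for i, idx in enumerate(choices):
        profile = spec.profiles[int(idx)]
        pid = f"SYN-{i + 1:06d}"
        records.append(_draw_record(rng, profile, pid))
        labels.append({"patient_id": pid, "profile": profile.name})
    return pd.DataFrame(records), pd.DataFrame(labels)


def write_cohort(
    spec: CohortSpec, records_path: str | Path, labels_path: str | Path
) -> None:
    """Write the record CSV and the hidden-label sidecar CSV."""
    records, labels = generate_cohort(spec)
    records.to_csv(records_path, index=False)
    labels.to_csv(labels_path, index=False)


# ---------------------------------------------------------------------------
# engineered fixtures with exact marginals

_FIXTURE_BASE = {
    "sex": "female", "bmi": 26.0, "alcohol_over_14": False,
    "metabolic_syndrome": False, "alp": 80.0, "ggt": 30.0,
    "bilirubin_total": 10.0, "albumin": 42.0,
}

_FIXTURE_NEGATIVE_SCREEN = {
    "transferrin_saturation": 30.0, "a1at": 1.4, "hbv_positive": False,
    "hcv_positive": False, "autoantibody_positive": False,
}


def _fixture_full(referral: bool) -> dict:
    record = dict(_FIXTURE_BASE) | dict(_FIXTURE_NEGATIVE_SCREEN)
    record["alt"] = 80.0
    if referral:
        # metabolic profile with a rule-in FIB-4: classifies as MASLD with
        # significant fibrosis, referral routine
        record.update(age=65, metabolic_syndrome=True, ast=120.0, platelets=120.0)
    else:
        # negative screen, low FIB-4: abnormal-ALT descriptive outcome, no referral
        record.update(age=30, ast=30.0, platelets=300.0, crp=2.0, caeruloplasmin=0.3)
    return record


def _fixture_limited() -> dict:
    record = dict(_FIXTURE_BASE)
    record.update(
        age=40, alt=20.0, bilirubin_total=40.0,
        direct_bilirubin=6.0, haptoglobin=1.2,
    )
    return record


def _fixture_none() -> dict:
    record = dict(_FIXTURE_BASE)
    record.update(age=40, alt=20.0, ast=22.0, platelets=250.0)
    return record


def fixture_marginals(counts: dict[str, int], n_referral: int = 0) -> pd.DataFrame:
    """Emit exactly ``counts`` records per tier (keys: full, limited, none).

    Of the full-tier records, the first ``n_referral`` are engineered to
    yield a referral recommendation and the rest none, so referral marginals
    can be fixed exactly as well. Fully deterministic: no randomness.
    """
    n_full = counts.get("full", 0)
    n_limited = counts.get("limited", 0)
    n_none = counts.get("none", 0)
    if min(n_full, n_limited, n_none) < 0:
        raise ValueError("tier counts must be non-negative")
    if not 0 <= n_referral <= n_full:
        raise ValueError("n_referral must be between 0 and counts['full']")

    records = []
    for i in range(n_full):
        records.append(_fixture_full(referral=i < n_referral))
    records.extend(_fixture_limited() for _ in range(n_limited))
    records.extend(_fixture_none() for _ in range(n_none))
    for i, r in enumerate(records):
        r["patient_id"] = f"FIX-{i + 1:06d}"
    return pd.DataFrame(records)
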
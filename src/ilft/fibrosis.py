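"""Fibrosis scoring: FIB-4, NFS, ELF, banding and the merged category.

Two indirect scores are computed from routine analytes:

* FIB-4 = age * AST / (platelets * sqrt(ALT))
* NFS = -1.675 + 0.037*age + 0.094*BMI + 1.13*dysglycaemia
  + 0.99*AST/ALT - 0.013*platelets - 0.66*albumin[g/dL]

Each has a rule-out (low) and rule-in (high) cutoff; the gap between them is
the indeterminate "grey zone". NFS contributes only in presumed-MASLD/MetALD
branches (``use_nfs``), where the metabolic-syndrome tick-box stands in for
the dysglycaemia term. The direct ELF score — a log-linear combination of
hyaluronic acid, PIIINP and TIMP-1 — reflexes when the indirect band is
indeterminate or high, and resolves the indeterminate zone at the 9.8
referral threshold. ELF >= 13 additionally raises an urgent prognostic flag.

The merged ``final_category`` fails safe: a high indirect band is referred
regardless of ELF, and an unresolved indeterminate band (no ELF available)
maps to its own referral category rather than being dropped.
"""

from __future__ import annotations

import math
from typing import Optional

from .config import Thresholds
from .models import ElfBand, ElfInputs, FibrosisAssessment, FinalCategory, IndirectBand

__all__ = [
    "compute_fib4",
    "compute_nfs",
    "compute_elf",
    "band_elf",
    "band_indirect",
    "assess_fibrosis",
]


def compute_fib4(
    age: float,
    ast: Optional[float],
    alt: Optional[float],
    platelets: Optional[float],
) -> Optional[float]:
    """FIB-4 index, or ``None`` when not computable (missing or zero inputs)."""
    if ast is None or alt is None or platelets is None:
        return None
    if alt <= 0 or platelets <= 0:
        return None
    return age * ast / (platelets * math.sqrt(alt))


def compute_nfs(
    age: float,
    bmi: float,
    dysglycaemia: bool,
    ast: Optional[float],
    alt: Optional[float],
    platelets: Optional[float],
    albumin: Optional[float],
) -> Optional[float]:
    """NAFLD fibrosis score, or ``None`` when not computable.

    ``albumin`` is taken in g/L (UK reporting units) and converted to the
    g/dL the published coefficients expect.
    """
    if None in (ast, alt, platelets, albumin) or alt <= 0:
        return None
    return (
        -1.675
        + 0.037 * age
        + 0.094 * bmi
        + 1.13 * bool(dysglycaemia)
        + 0.99 * ast / alt
        - 0.013 * platelets
        - 0.66 * (albumin / 10.0)
    )


def compute_elf(inputs: ElfInputs, thresholds: Thresholds) -> float:
    """ELF score from the three direct analytes (coefficients from config)."""
    t = thresholds
    return (
        t.elf_intercept
        + t.elf_coef_ha * math.log(inputs.ha)
        + t.elf_coef_piiinp * math.log(inputs.piiinp)
        + t.elf_coef_timp1 * math.log(inputs.timp1)
    )


def band_elf(elf: float, thresholds: Thresholds) -> ElfBand:
    """Stage an ELF score against the half-open published boundaries."""
    if elf < thresholds.elf_moderate:
        return ElfBand.ABSENT_MILD
    if elf < thresholds.elf_severe:
        return ElfBand.MODERATE
    if elf < thresholds.elf_cirrhosis:
        return ElfBand.SEVERE
    return ElfBand.CIRRHOSIS


def band_indirect(
    fib4: Optional[float],
    nfs: Optional[float],
    use_nfs: bool,
    thresholds: Thresholds,
) -> IndirectBand:
    """Band the indirect scores.

    With ``use_nfs`` the two scores merge at maximum severity: high if either
    is above its rule-in cutoff, low only if both are below their rule-out
    cutoffs, indeterminate otherwise.
    """
    t = thresholds
    if fib4 is None or (use_nfs and nfs is None):
        return IndirectBand.NOT_COMPUTABLE

    def band_one(score: float, low: float, high: float) -> IndirectBand:
        if score > high:
            return IndirectBand.HIGH
        if score < low:
            return IndirectBand.LOW
        return IndirectBand.INDETERMINATE

    fib4_band = band_one(fib4, t.fib4_low, t.fib4_high)
    if not use_nfs:
        return fib4_band
    nfs_band = band_one(nfs, t.nfs_low, t.nfs_high)
    if IndirectBand.HIGH in (fib4_band, nfs_band):
        return IndirectBand.HIGH
    if fib4_band is nfs_band is IndirectBand.LOW:
        return IndirectBand.LOW
    return IndirectBand.INDETERMINATE


def assess_fibrosis(
    indirect_band: IndirectBand,
    elf: Optional[float],
    thresholds: Thresholds,
    fib4: Optional[float] = None,
    nfs: Optional[float] = None,
) -> FibrosisAssessment:
    """Merge the indirect band and (reflexed) ELF into the final category.

    ELF must only be supplied when the indirect band is indeterminate, high
    or not-computable — supplying it alongside a low band is a protocol
    violation. A not-computable indirect band is treated like indeterminate
    for ELF resolution (reflex-and-flag policy) so missing AST/platelets
    never silently drop a patient.
    """
    t = thresholds
    if elf is not None and indirect_band is IndirectBand.LOW:
        raise ValueError("ELF supplied despite a low indirect band (protocol violation)")

    elf_band = band_elf(elf, t) if elf is not None else None
    urgent = elf is not None and elf >= t.elf_urgent

    if indirect_band is IndirectBand.LOW:
        final = FinalCategory.NO_SIGNIFICANT_FIBROSIS
    elif indirect_band is IndirectBand.HIGH:
        # rule-in holds regardless of ELF (fail-safe); ELF adds staging only
        final = FinalCategory.SIGNIFICANT_FIBROSIS
    elif elf is None:
        final = FinalCategory.INDETERMINATE_UNRESOLVED
    elif elf >= t.elf_severe:
        final = FinalCategory.SIGNIFICANT_FIBROSIS
    else:
        final = FinalCategory.INDETERMINATE_RESOLVED_LOW

    return FibrosisAssessment(
        fib4=fib4,
        nfs=nfs,
        elf=elf,
        indirect_band=indirect_band,
        elf_band=elf_band,
        urgent_prognosis=urgent,
        final_category=final,
    )
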
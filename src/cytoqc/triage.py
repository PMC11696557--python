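"""Sample qualification: pre-analytic and sequencing gates, outcome assignment.

A sample passes through gates in the order the physical pipeline applies
them — tumor content, DNA input, sequencing coverage, base quality, then
contamination — and the first failing gate fixes its single outcome category.
Contaminated samples with high tumor content are rescued as partially
evaluable: variants with VAF inside the contamination range are filtered
rather than failing the whole sample.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date

import pandas as pd

from ._util import round_half_up
from .contamination import (
    CLINICAL_ALPHA_CUTOFF,
    VERY_LOW_COVERAGE_MARK,
    LOW_COVERAGE_MARK,
    ContaminationResults,
)

OUTCOMES = (
    "pass",
    "fail_low_dna",
    "fail_scant_tumor",
    "fail_low_coverage",
    "fail_contamination",
    "fail_low_quality",
)

MIN_TUMOR_PURITY = 10.0  # percent; below this without enrichment -> reject


@dataclass(frozen=True)
class EraPolicy:
    """Era-dependent DNA input thresholds.

    The minimum acceptable concentration was lowered once assay optimization
    allowed it; with the assay's fixed 55 uL maximum input volume the two
    concentration cutoffs translate to 50 and 30 ng total input minima.
    """

    cutoff_date: date = date(2021, 9, 1)
    conc_threshold_before: float = 0.9  # ng/uL
    conc_threshold_after: float = 0.54  # ng/uL
    max_volume_ul: float = 55.0
    min_input_before_ng: float = 50.0
    min_input_after_ng: float = 30.0

    def conc_threshold(self, when: date) -> float:
        return (
            self.conc_threshold_before
            if when < self.cutoff_date
            else self.conc_threshold_after
        )


DEFAULT_POLICY = EraPolicy()


@dataclass
class SampleQC:
    """Pre-analytic and sequencing metrics for one sample."""

    sample_id: str
    prep_type: str  # CB | ScfDNA | surgical
    source: str = "internal"
    year: int = 2022
    accession_date: date = date(2022, 1, 1)
    tumor_purity: float = 0.0  # percent
    enrichable: bool = False
    dna_conc: float = 0.0  # ng/uL
    dna_yield: float = 0.0  # ng
    sample_coverage: float = 0.0  # fold coverage
    base_quality_ok: bool = True

    def __post_init__(self):
        if not 0.0 <= self.tumor_purity <= 100.0:
            raise ValueError("tumor_purity must be a percentage in [0, 100]")
        for name in ("dna_conc", "dna_yield", "sample_coverage"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass(frozen=True)
class TriageDecision:
    """The single outcome category triage assigns to a sample."""

    outcome: str
    partially_evaluable: bool = False
    vaf_filter_threshold: float | None = None

    def __post_init__(self):
        if self.outcome not in OUTCOMES:
            raise ValueError(f"unknown outcome {self.outcome!r}")
        if self.vaf_filter_threshold is not None and not self.partially_evaluable:
            raise ValueError(
                "vaf_filter_threshold only applies to partially evaluable samples"
            )


def _as_date(when) -> date:
    if isinstance(when, date):
        return when
    if isinstance(when, str):  # "YYYY-MM" or "YYYY-MM-DD"
        parts = [int(p) for p in when.split("-")]
        return date(parts[0], parts[1], parts[2] if len(parts) > 2 else 1)
    raise TypeError(f"cannot interpret {when!r} as a date")


def evaluate_dna_input(
    dna_conc: float,
    when,
    policy: EraPolicy = DEFAULT_POLICY,
    prep_type: str = "CB",
) -> bool:
    """DNA-input gate: True means pass.

    Fails when the concentration sits below the era's threshold; ScfDNA
    samples bypass the gate entirely (they are sequenced below the FFPE
    thresholds to spare the patient a repeat biopsy).
    """
    if dna_conc < 0:
        raise ValueError("dna_conc must be non-negative")
    if prep_type == "ScfDNA":
        return True
    return dna_conc >= policy.conc_threshold(_as_date(when))


def evaluate_tumor_content(tumor_purity: float, enrichable: bool) -> bool:
    """Tumor-content gate: purity below 10% fails unless enrichment is possible."""
    if not 0.0 <= tumor_purity <= 100.0:
        raise ValueError("tumor_purity must be in [0, 100]")
    return tumor_purity >= MIN_TUMOR_PURITY or enrichable


def evaluate_coverage(sample_coverage: float) -> str:
    """Coverage gate: <50x fails; [50, 200)x is flagged low; >=200x is adequate."""
    if sample_coverage < 0:
        raise ValueError("sample_coverage must be non-negative")
    if sample_coverage < VERY_LOW_COVERAGE_MARK:
        return "fail"
    if sample_coverage < LOW_COVERAGE_MARK:
        return "low_coverage_flag"
    return "adequate"


def contamination_vaf_filter(
    variants: pd.DataFrame,
    alpha_hat: float,
    tumor_purity: float,
    margin: float = 2.0,
):
    """Rescue a contaminated sample by filtering low-VAF calls.

    With contamination at or above the 2% cutoff, a sample whose expected
    driver VAF (purity/2) clears ``margin`` times the contamination level
    stays partially evaluable: variants with VAF <= alpha_hat are removed as
    potentially contaminant-derived. Low-purity samples cannot be salvaged
    this way and the returned set is empty with ``partially_evaluable`` False
    (a whole-sample contamination failure).

    Returns ``(retained_variants, partially_evaluable)``.
    """
    if not 0.0 <= alpha_hat <= 1.0:
        raise ValueError("alpha_hat must be in [0, 1]")
    if alpha_hat < CLINICAL_ALPHA_CUTOFF:
        return variants, False
    expected_driver_vaf = tumor_purity / 100.0 / 2.0
    if expected_driver_vaf > margin * alpha_hat:
        retained = variants[variants["vaf"] > alpha_hat]
        return retained, True
    return variants.iloc[0:0], False


def triage_sample(
    qc: SampleQC,
    contamination: ContaminationResults | float | None = None,
    policy: EraPolicy = DEFAULT_POLICY,
    vaf_filter_margin: float = 2.0,
) -> TriageDecision:
    """Run all gates in pipeline order and return the single outcome.

    ``contamination`` may be a fitted :class:`ContaminationResults`, a bare
    alpha estimate, or None when no contamination check was run.
    """
    if not evaluate_tumor_content(qc.tumor_purity, qc.enrichable):
        return TriageDecision("fail_scant_tumor")
    if not evaluate_dna_input(
        qc.dna_conc, qc.accession_date, policy, prep_type=qc.prep_type
    ):
        return TriageDecision("fail_low_dna")
    if evaluate_coverage(qc.sample_coverage) == "fail":
        return TriageDecision("fail_low_coverage")
    if not qc.base_quality_ok:
        return TriageDecision("fail_low_quality")
    alpha = (
        contamination.alpha_hat
        if isinstance(contamination, ContaminationResults)
        else contamination
    )
    if alpha is not None and alpha >= CLINICAL_ALPHA_CUTOFF:
        expected_driver_vaf = qc.tumor_purity / 100.0 / 2.0
        if expected_driver_vaf > vaf_filter_margin * alpha:
            return TriageDecision(
                "pass", partially_evaluable=True, vaf_filter_threshold=alpha
            )
        return TriageDecision("fail_contamination")
    return TriageDecision("pass")


def triage_manifest(
    manifest: pd.DataFrame,
    policy: EraPolicy = DEFAULT_POLICY,
    vaf_filter_margin: float = 2.0,
) -> pd.DataFrame:
    """Triage every row of a manifest table.

    Expects the columns the simulator writes (prep_type, date, tumor_purity,
    enrichable, dna_conc, dna_yield, sample_coverage, base_quality_ok, and
    optionally contamination_alpha). Returns one decision row per sample.
    """
    rows = []
    for rec in manifest.to_dict("records"):
        qc = SampleQC(
            sample_id=rec["sample_id"],
            prep_type=rec["prep_type"],
            source=rec.get("source", "internal"),
            year=int(rec.get("year", 2022)),
            accession_date=_as_date(rec.get("date", date(2022, 1, 1))),
            tumor_purity=float(rec["tumor_purity"]),
            enrichable=bool(rec["enrichable"]),
            dna_conc=float(rec["dna_conc"]),
            dna_yield=float(rec.get("dna_yield", 0.0)),
            sample_coverage=float(rec["sample_coverage"]),
            base_quality_ok=bool(rec["base_quality_ok"]),
        )
        alpha = rec.get("contamination_alpha")
        decision = triage_sample(
            qc, alpha, policy=policy, vaf_filter_margin=vaf_filter_margin
        )
        rows.append(
            {
                "sample_id": qc.sample_id,
                "outcome": decision.outcome,
                "partially_evaluable": decision.partially_evaluable,
                "vaf_filter_threshold": decision.vaf_filter_threshold,
            }
        )
    return pd.DataFrame(rows)


def expected_target_copies(input_ng: float, copies_per_ng: float) -> int:
    """Expected queryable target molecules for a DNA input mass.

    The product of input mass and per-nanogram target copy number, rounded
    half-up to a whole molecule count. At the post-change 30 ng minimum input
    and the lower 95% CI bound of 220.5 copies/ng this is the assay's floor
    on queryable molecules.
    """
    if input_ng < 0 or copies_per_ng < 0:
        raise ValueError("inputs must be non-negative")
    return int(round_half_up(input_ng * copies_per_ng, 0))
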
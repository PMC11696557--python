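"""Mutation concordance between matched cytology and surgical samples.

Samples of the same tumor profiled twice — a cytology preparation and a
surgical biopsy or resection — are compared call-by-call: variants are
matched on their genomic identity (chrom, pos, ref, alt), partitioned into
shared and exclusive sets, stratified by actionability level, and the VAFs of
shared calls are compared between preparations with a rank-sum test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

from .contamination import NotEstimableError

_KEY = ["chrom", "pos", "ref", "alt"]


def _check_unique(df: pd.DataFrame, label: str) -> None:
    if len(df) and df.duplicated(subset=_KEY).any():
        raise ValueError(f"duplicate variant keys within {label} sample")


def match_variants(a: pd.DataFrame, b: pd.DataFrame):
    """Partition two variant tables into shared / a-only / b-only.

    Identity is the genomic change (chrom, pos, ref, alt); gene-level matching
    would over-merge distinct events. The shared table carries both samples'
    VAFs as ``vaf_a``/``vaf_b``. The partition is disjoint and exhaustive.
    """
    _check_unique(a, "first")
    _check_unique(b, "second")
    if len(a) == 0 or len(b) == 0:
        empty_shared = a.iloc[0:0].copy()
        empty_shared["vaf_b"] = pd.Series(dtype=float)
        return empty_shared.rename(columns={"vaf": "vaf_a"}), a.copy(), b.copy()
    shared = a.merge(b, on=_KEY, suffixes=("_a", "_b"))
    a_keys = a.set_index(_KEY).index
    b_keys = b.set_index(_KEY).index
    a_only = a[~a_keys.isin(b_keys)]
    b_only = b[~b_keys.isin(a_keys)]
    return shared, a_only, b_only


@dataclass(frozen=True)
class MatchedPair:
    """A cytology sample and a surgical sample from the same patient tumor."""

    patient_id: str
    cytology_sample_id: str
    surgical_sample_id: str
    cytology_variants: pd.DataFrame
    surgical_variants: pd.DataFrame


@dataclass
class PairConcordance:
    """Shared/exclusive accounting for one matched pair."""

    patient_id: str
    n_shared: int
    n_cytology_only: int
    n_surgical_only: int
    shared: pd.DataFrame  # merged table with vaf_a (cytology) / vaf_b (surgical)
    cytology_only: pd.DataFrame
    surgical_only: pd.DataFrame

    @property
    def surgical_recovery_fraction(self) -> float:
        """Fraction of surgical calls also seen in the cytology sample."""
        total = self.n_shared + self.n_surgical_only
        if total == 0:
            raise NotEstimableError("no surgical variants to recover")
        return self.n_shared / total

    @property
    def shared_vaf_pairs(self) -> list[tuple[float, float]]:
        return list(
            zip(self.shared["vaf_a"].tolist(), self.shared["vaf_b"].tolist())
        )


def compare_pair(pair: MatchedPair) -> PairConcordance:
    """Match a pair's variant calls and tally the partition."""
    shared, cyt_only, surg_only = match_variants(
        pair.cytology_variants, pair.surgical_variants
    )
    return PairConcordance(
        patient_id=pair.patient_id,
        n_shared=len(shared),
        n_cytology_only=len(cyt_only),
        n_surgical_only=len(surg_only),
        shared=shared,
        cytology_only=cyt_only,
        surgical_only=surg_only,
    )


def stratify_shared_by_level(pairs: list[PairConcordance]) -> pd.DataFrame:
    """Pool variants across pairs and split each level into shared/exclusive.

    Returns one row per actionability level present, with the proportions of
    that level's variants found in both samples, only in cytology, or only in
    the surgical sample; proportions sum to 1 per level.
    """
    records = []
    for pc in pairs:
        if len(pc.shared):
            lv = (
                pc.shared["oncokb_level_a"]
                if "oncokb_level_a" in pc.shared.columns
                else pc.shared["oncokb_level"]
            )
            records += [(l, "shared") for l in lv]
        records += [(l, "cytology_only") for l in pc.cytology_only.get("oncokb_level", [])]
        records += [(l, "surgical_only") for l in pc.surgical_only.get("oncokb_level", [])]
    if not records:
        return pd.DataFrame(
            columns=["shared", "cytology_only", "surgical_only"]
        )
    df = pd.DataFrame(records, columns=["level", "category"])
    tab = pd.crosstab(df["level"], df["category"], normalize="index")
    for col in ("shared", "cytology_only", "surgical_only"):
        if col not in tab.columns:
            tab[col] = 0.0
    return tab[["shared", "cytology_only", "surgical_only"]]


def vaf_shift_test(pairs: list[PairConcordance]):
    """Compare pooled shared-variant VAFs between preparations.

    Returns (cytology median VAF, surgical median VAF, two-sided
    Mann-Whitney p value). With a single shared variant the medians are
    still returned but the test is not estimable (p is None).
    """
    cyt = np.concatenate(
        [pc.shared["vaf_a"].to_numpy() for pc in pairs if len(pc.shared)]
        or [np.array([])]
    )
    surg = np.concatenate(
        [pc.shared["vaf_b"].to_numpy() for pc in pairs if len(pc.shared)]
        or [np.array([])]
    )
    if len(cyt) == 0:
        raise NotEstimableError("no shared variants across pairs")
    med_c, med_s = float(np.median(cyt)), float(np.median(surg))
    if len(cyt) < 2:
        return med_c, med_s, None
    _, p = mannwhitneyu(cyt, surg, alternative="two-sided")
    return med_c, med_s, float(p)
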
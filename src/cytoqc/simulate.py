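"""Synthetic cohorts with known ground truth.

Everything the QC pipeline consumes can be generated here: a panel of common
SNPs, diploid genotypes under Hardy-Weinberg equilibrium, two-person read
mixtures at a known contamination fraction, purity-scaled somatic variant
sets, and manifest-level cohorts whose per-sample metrics map back to a chosen
outcome category. All generators are deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

GENOTYPE_LABELS = np.array(["hom_ref", "het", "hom_alt"])
DOSAGE = {"hom_ref": 0, "het": 1, "hom_alt": 2}

#: Outcome-category frequencies of a large clinical cytology cohort
#: (success plus the five failure modes, in descending frequency).
DEFAULT_OUTCOME_PROBS = {
    "pass": 0.806,
    "fail_low_dna": 0.113,
    "fail_scant_tumor": 0.046,
    "fail_low_coverage": 0.018,
    "fail_contamination": 0.016,
    "fail_low_quality": 0.001,
}

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class MixtureSpec:
    """Parameters of a two-person DNA read mixture.

    alpha is the contaminant read fraction (the patient contributes 1 - alpha);
    purity is the tumor-cell fraction of the patient DNA, carried for somatic
    simulations; error_rate is the symmetric per-base ref<->alt miscall rate.
    """

    alpha: float
    purity: float = 1.0
    mean_depth: float = 500.0
    error_rate: float = 0.001
    seed: int = 0
    #: negative-binomial dispersion for depth; None = Poisson. Real panel
    #: coverage is overdispersed, so an optional knob is provided.
    depth_dispersion: float | None = None

    def __post_init__(self):
        if not 0.0 <= self.alpha < 1.0:
            raise ValueError("alpha must be in [0, 1)")
        if not 0.0 <= self.purity <= 1.0:
            raise ValueError("purity must be in [0, 1]")
        if self.mean_depth <= 0:
            raise ValueError("mean_depth must be positive")
        if not 0.0 <= self.error_rate <= 0.01:
            raise ValueError("error_rate must be in [0, 0.01]")


def simulate_snp_panel(
    n_sites: int,
    af_low: float = 0.05,
    af_high: float = 0.5,
    seed: int = 0,
) -> pd.DataFrame:
    """Draw a panel of biallelic SNP sites with common alternate alleles.

    Population alt-allele frequencies are uniform on [af_low, af_high];
    fingerprint SNPs on capture panels are deliberately common, so the
    default spectrum excludes rare alleles.
    """
    if n_sites <= 0:
        raise ValueError("n_sites must be a positive integer")
    if not 0.0 < af_low <= af_high < 1.0:
        raise ValueError("require 0 < af_low <= af_high < 1")
    rng = np.random.default_rng(seed)
    chrom = rng.integers(1, 23, size=n_sites)
    pos = rng.integers(1, 200_000_000, size=n_sites)
    ref_idx = rng.integers(0, 4, size=n_sites)
    alt_idx = (ref_idx + rng.integers(1, 4, size=n_sites)) % 4
    freqs = rng.uniform(af_low, af_high, size=n_sites)
    return pd.DataFrame(
        {
            "site_id": [f"snp{i:05d}" for i in range(n_sites)],
            "chrom": [f"chr{c}" for c in chrom],
            "pos": pos,
            "ref_allele": _BASES[ref_idx],
            "alt_allele": _BASES[alt_idx],
            "pop_alt_freq": freqs,
        }
    )


def simulate_genotypes(panel: pd.DataFrame, seed: int = 0) -> pd.DataFrame:
    """Sample one individual's diploid genotypes under Hardy-Weinberg.

    At a site with alt frequency p the genotype is hom_ref / het / hom_alt
    with probabilities (1-p)^2, 2p(1-p), p^2. Returns a profile indexed by
    site_id with ``genotype`` and ``alt_dosage`` columns.
    """
    if len(panel) == 0:
        raise ValueError("panel must be non-empty")
    rng = np.random.default_rng(seed)
    p = panel["pop_alt_freq"].to_numpy()
    u = rng.random(len(p))
    hom_ref = (1 - p) ** 2
    het = 2 * p * (1 - p)
    idx = np.select([u < hom_ref, u < hom_ref + het], [0, 1], default=2)
    prof = pd.DataFrame(
        {
            "genotype": GENOTYPE_LABELS[idx],
            "alt_dosage": idx.astype(float),
        },
        index=pd.Index(panel["site_id"], name="site_id"),
    )
    return prof


def simulate_allele_counts(
    patient: pd.DataFrame,
    contaminant: pd.DataFrame,
    spec: MixtureSpec,
    panel: pd.DataFrame,
) -> pd.DataFrame:
    """Generate per-site read counts for a two-person mixture.

    Depth is Poisson (or negative-binomial if ``depth_dispersion`` is set)
    around ``mean_depth``. The latent alt-read fraction is the dosage-weighted
    mixture f = (1-alpha) d_p/2 + alpha d_c/2, perturbed symmetrically by the
    error rate, and alt counts are Binomial(depth, f). Reads are conserved:
    ref + alt + other = depth, with other fixed at zero under this error model.
    """
    site_ids = panel["site_id"].to_numpy()
    for prof, name in ((patient, "patient"), (contaminant, "contaminant")):
        if not np.array_equal(prof.index.to_numpy(), site_ids):
            raise ValueError(f"{name} profile does not cover the panel's sites")
    rng = np.random.default_rng(spec.seed)
    n = len(site_ids)
    if spec.depth_dispersion is None:
        depth = rng.poisson(spec.mean_depth, size=n)
    else:
        # NB parameterised by size r and mean mu: p = r / (r + mu)
        r = spec.depth_dispersion
        depth = rng.negative_binomial(r, r / (r + spec.mean_depth), size=n)
    d_p = patient["alt_dosage"].to_numpy()
    d_c = contaminant["alt_dosage"].to_numpy()
    f = (1 - spec.alpha) * d_p / 2.0 + spec.alpha * d_c / 2.0
    f = f * (1 - 2 * spec.error_rate) + spec.error_rate
    alt = rng.binomial(depth, f)
    return pd.DataFrame(
        {
            "site_id": site_ids,
            "depth": depth,
            "ref_count": depth - alt,
            "alt_count": alt,
            "other_count": np.zeros(n, dtype=int),
        }
    )


_GENES = [
    "EGFR", "KRAS", "TP53", "PIK3CA", "ERBB2", "BRAF", "ALK", "RET",
    "ROS1", "STK11", "KEAP1", "SMAD4", "CDKN2A", "FGFR3", "ESR1", "PTEN",
    "ARID1A", "NF1", "RB1", "APC",
]

#: Highest-actionability-level frequencies used for simulated variant sets;
#: dominated by variants of unknown significance, as in real panels.
DEFAULT_LEVEL_PROBS = {
    "vus": 0.62,
    "oncogenic_no_level": 0.12,
    "L1": 0.08,
    "L2": 0.03,
    "L3A": 0.05,
    "L3B": 0.05,
    "L4": 0.03,
    "R1": 0.015,
    "R2": 0.005,
}


def simulate_tumor_variants(
    n_variants: int,
    purity: float,
    seed: int = 0,
    clonal_fraction: float = 0.7,
    nonsynonymous_prob: float = 0.75,
    level_probs: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Simulate an annotated somatic variant table for one sample.

    VAF follows the diploid heterozygous heuristic purity * CCF / 2, so a
    fully clonal variant in a pure tumor sits at 0.5 and no VAF exceeds
    purity / 2. Nonsynonymous status and actionability level are categorical
    draws; levels are consumed as annotations, never looked up.
    """
    if n_variants <= 0:
        raise ValueError("n_variants must be a positive integer")
    if not 0.0 < purity <= 1.0:
        raise ValueError("purity must be in (0, 1]")
    probs = dict(DEFAULT_LEVEL_PROBS if level_probs is None else level_probs)
    if abs(sum(probs.values()) - 1.0) > 1e-9:
        raise ValueError("level_probs must sum to 1")
    rng = np.random.default_rng(seed)
    ccf = np.where(
        rng.random(n_variants) < clonal_fraction,
        1.0,
        rng.uniform(0.1, 1.0, size=n_variants),
    )
    vaf = purity * ccf / 2.0
    ref_idx = rng.integers(0, 4, size=n_variants)
    alt_idx = (ref_idx + rng.integers(1, 4, size=n_variants)) % 4
    levels = rng.choice(list(probs), size=n_variants, p=list(probs.values()))
    return pd.DataFrame(
        {
            "gene": rng.choice(_GENES, size=n_variants),
            "chrom": [f"chr{c}" for c in rng.integers(1, 23, size=n_variants)],
            "pos": rng.integers(1, 200_000_000, size=n_variants),
            "ref": _BASES[ref_idx],
            "alt": _BASES[alt_idx],
            "vaf": vaf,
            "nonsynonymous": rng.random(n_variants) < nonsynonymous_prob,
            "oncokb_level": levels,
        }
    )


def _category_metrics(category: str, rng: np.random.Generator) -> dict:
    """Per-sample metric values that triage maps back to ``category``.

    The triage gates run tumor -> DNA -> coverage -> quality -> contamination,
    so each failure category keeps every earlier gate passing.
    """
    m = {
        "tumor_purity": rng.uniform(15.0, 80.0),
        "enrichable": bool(rng.random() < 0.3),
        "dna_conc": rng.uniform(1.0, 10.0),
        "sample_coverage": rng.uniform(300.0, 900.0),
        "base_quality_ok": True,
        "contamination_alpha": rng.uniform(0.0, 0.005),
    }
    if category == "fail_scant_tumor":
        m["tumor_purity"] = rng.uniform(0.0, 9.9)
        m["enrichable"] = False
    elif category == "fail_low_dna":
        m["dna_conc"] = rng.uniform(0.05, 0.5)
    elif category == "fail_low_coverage":
        m["sample_coverage"] = rng.uniform(5.0, 45.0)
    elif category == "fail_low_quality":
        m["base_quality_ok"] = False
    elif category == "fail_contamination":
        alpha = rng.uniform(0.03, 0.08)
        m["contamination_alpha"] = alpha
        # purity low enough that VAF filtering cannot rescue the sample
        m["tumor_purity"] = rng.uniform(10.0, 0.9 * 400.0 * alpha)
    return m


def simulate_cohort(
    n_samples: int,
    outcome_probs: dict[str, float] | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Generate a sample manifest whose metrics re-triage to known outcomes.

    Each row carries prep type (CB or ScfDNA), source, accession date, the
    pre-analytic and sequencing metrics the triage gates read, and the
    intended category under ``true_outcome``. Low-DNA failures are only
    assigned to CB samples because supernatant cfDNA is sequenced below the
    concentration thresholds.
    """
    if n_samples <= 0:
        raise ValueError("n_samples must be a positive integer")
    probs = dict(DEFAULT_OUTCOME_PROBS if outcome_probs is None else outcome_probs)
    unknown = set(probs) - set(DEFAULT_OUTCOME_PROBS)
    if unknown:
        raise ValueError(f"unknown outcome categories: {sorted(unknown)}")
    if abs(sum(probs.values()) - 1.0) > 1e-9:
        raise ValueError("outcome_probs must sum to 1")
    rng = np.random.default_rng(seed)
    cats = list(probs)
    outcomes = rng.choice(cats, size=n_samples, p=[probs[c] for c in cats])
    rows = []
    for i, cat in enumerate(outcomes):
        year = int(rng.integers(2014, 2023))
        month = int(rng.integers(1, 9 if year == 2022 else 13))
        prep = "CB" if cat == "fail_low_dna" else (
            "ScfDNA" if rng.random() < 0.058 else "CB"
        )
        row = {
            "sample_id": f"S{i:06d}",
            "prep_type": prep,
            "source": "internal" if rng.random() < 0.63 else "external",
            "year": year,
            "date": f"{year:04d}-{month:02d}",
            "true_outcome": cat,
        }
        row.update(_category_metrics(cat, rng))
        rows.append(row)
    df = pd.DataFrame(rows)
    df["dna_yield"] = df["dna_conc"] * 55.0
    return df
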
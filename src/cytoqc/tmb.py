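"""Panel tumor mutational burden and actionability stratification."""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

TMB_HIGH_CUTOFF = 10.0  # mutations/Mb; strictly greater is TMB-high

#: Actionability levels from best to worst therapeutic evidence. Resistance
#: levels (R1/R2) are an independent axis and excluded from this ordering.
ACTIONABILITY_ORDER = ("L1", "L2", "L3A", "L3B", "L4", "oncogenic_no_level", "vus")
TARGETABLE_LEVELS = frozenset({"L1", "L2", "L3A", "L3B"})
VALID_LEVELS = frozenset(ACTIONABILITY_ORDER) | {"R1", "R2"}


@dataclass(frozen=True)
class PanelVersion:
    """One version of the capture panel.

    target_mb is the TMB denominator. The targeted footprint per version is
    not published alongside the gene counts, so these are configuration
    estimates a deployment should override with its own validated values.
    """

    name: str
    n_genes: int
    target_mb: float
    years_active: str = ""

    def __post_init__(self):
        if self.n_genes not in (341, 410, 468, 505):
            raise ValueError("n_genes must be one of 341, 410, 468, 505")
        if self.target_mb <= 0:
            raise ValueError("target_mb must be positive")


#: Default panel generations; target_mb values are approximate estimates,
#: not published assay constants — override via config for clinical use.
PANEL_VERSIONS = {
    341: PanelVersion("panel-341", 341, 0.98, "2014"),
    410: PanelVersion("panel-410", 410, 1.06, "2015-2016"),
    468: PanelVersion("panel-468", 468, 1.14, "2017-2020"),
    505: PanelVersion("panel-505", 505, 1.28, "2021-2022"),
}


def compute_tmb(variants: pd.DataFrame, panel: PanelVersion | float) -> float:
    """Tumor mutational burden in mutations per megabase.

    The count of nonsynonymous somatic mutations — driver mutations in
    oncogenes included, synonymous changes excluded — divided by the panel's
    targeted genomic footprint in Mb.
    """
    target_mb = panel.target_mb if isinstance(panel, PanelVersion) else float(panel)
    if target_mb <= 0:
        raise ValueError("target_mb must be positive")
    if len(variants) == 0:
        return 0.0
    n_nonsyn = int(variants["nonsynonymous"].sum())
    return n_nonsyn / target_mb


def classify_tmb_high(tmb: float) -> bool:
    """True when TMB strictly exceeds 10 mutations/Mb."""
    if tmb < 0:
        raise ValueError("tmb must be non-negative")
    return tmb > TMB_HIGH_CUTOFF


@dataclass(frozen=True)
class ActionabilitySummary:
    best_level: str | None
    targetable: bool
    has_resistance: bool


def highest_actionability(variants: pd.DataFrame) -> ActionabilitySummary:
    """Best actionability level in a variant set, with a resistance flag.

    Levels are ordered L1 > L2 > L3A > L3B > L4 > oncogenic_no_level > vus; a
    sample is targetable when its best level is L1-L3B. Standard-of-care
    resistance (R1) is reported on its own axis rather than competing in the
    ordering. Order-invariant over the input list.
    """
    if len(variants) == 0:
        return ActionabilitySummary(None, False, False)
    levels = set(variants["oncokb_level"])
    bad = levels - VALID_LEVELS
    if bad:
        raise ValueError(f"unknown actionability levels: {sorted(bad)}")
    best = next((lv for lv in ACTIONABILITY_ORDER if lv in levels), None)
    return ActionabilitySummary(
        best_level=best,
        targetable=best in TARGETABLE_LEVELS if best else False,
        has_resistance="R1" in levels,
    )


def summarize_sample(
    variants: pd.DataFrame, panel: PanelVersion | float
) -> dict:
    """Per-sample TMB + actionability summary row."""
    tmb = compute_tmb(variants, panel)
    act = highest_actionability(variants)
    return {
        "tmb": tmb,
        "tmb_high": classify_tmb_high(tmb),
        "best_level": act.best_level,
        "targetable": act.targetable,
        "has_resistance": act.has_resistance,
    }
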
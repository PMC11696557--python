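"""Cross-individual contamination estimation and identity checking.

Paired tumor:normal panel sequencing covers a set of fingerprint SNPs. The
matched normal defines the patient's genotypes; at sites where the patient is
homozygous, any reads carrying the other allele in the tumor are unexpected
and evidence DNA from another individual. The fraction alpha of such foreign
reads is estimated here, and the same genotype profiles support pairwise
concordance checks that expose sample swaps.

Model
-----
At a patient-homozygous site i let q_i be the population frequency of the
unexpected allele and d_i the unexpected-allele read fraction. An unrelated
contaminant in Hardy-Weinberg equilibrium carries the unexpected allele with
expected dosage 2 q_i, so with a symmetric miscall rate eps,

    E[d_i] = alpha * q_i * (1 - 2 eps) + eps.

The moment estimator inverts this expectation with depth weights; the
maximum-likelihood estimator marginalizes the contaminant genotype g in
{0, 1, 2} under HWE and maximizes the product of binomial likelihoods of the
unexpected-allele counts with success probability alpha * g/2 * (1-2 eps) + eps.
A contamination fraction of at least 2% — the assay's variant-calling
threshold — is flagged as clinically significant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.special import gammaln, logsumexp

from ._util import check_allele_counts

__all__ = [
    "NotEstimableError",
    "ConcordanceReport",
    "ContaminationModel",
    "ContaminationResults",
    "call_genotypes",
    "estimate_contamination",
    "genotype_concordance",
    "classify_contamination",
]

#: contaminant read fraction at or above which contamination is clinically
#: significant (the assay's mutation-calling threshold)
CLINICAL_ALPHA_CUTOFF = 0.02
#: sample coverage below which contamination estimates carry a caveat
LOW_COVERAGE_MARK = 200.0
#: coverage below which a high alpha is more likely artifact than contamination
VERY_LOW_COVERAGE_MARK = 50.0


class NotEstimableError(ValueError):
    """Raised when a quantity has no informative data (distinct from zero)."""


def call_genotypes(
    counts: pd.DataFrame,
    min_depth: int = 20,
    hom_band: float = 0.05,
    het_band: tuple[float, float] = (0.30, 0.70),
) -> pd.DataFrame:
    """Call diploid genotypes from allele counts (typically the normal).

    Sites with depth below ``min_depth`` are no_call. Otherwise the alt-read
    fraction is banded: <= hom_band -> hom_ref, >= 1 - hom_band -> hom_alt,
    inside ``het_band`` -> het, and anything between the bands is ambiguous
    (no_call). The default bands keep homozygote misclassification — which
    would inflate the contamination signal — negligible at panel depths.
    """
    if min_depth < 1:
        raise ValueError("min_depth must be >= 1")
    if not 0 < hom_band < het_band[0] < het_band[1] < 1:
        raise ValueError("require 0 < hom_band < het_band[0] < het_band[1] < 1")
    check_allele_counts(counts)
    depth = counts["depth"].to_numpy().astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(depth > 0, counts["alt_count"].to_numpy() / depth, np.nan)
    geno = np.full(len(counts), "no_call", dtype=object)
    callable_ = depth >= min_depth
    geno[callable_ & (frac <= hom_band)] = "hom_ref"
    geno[callable_ & (frac >= 1 - hom_band)] = "hom_alt"
    geno[callable_ & (frac >= het_band[0]) & (frac <= het_band[1])] = "het"
    dosage = pd.Series(geno).map(
        {"hom_ref": 0.0, "het": 1.0, "hom_alt": 2.0}
    ).to_numpy()
    return pd.DataFrame(
        {"genotype": geno, "alt_dosage": dosage},
        index=pd.Index(counts["site_id"], name="site_id"),
    )


@dataclass(frozen=True)
class ConcordanceReport:
    """Pairwise genotype agreement between two samples.

    Same-patient pairs sit near 1; unrelated pairs fall to the HWE match
    expectation (roughly 0.37-0.5 for common SNPs), so a fraction below the
    swap threshold flags a likely mix-up.
    """

    fraction_concordant: float
    n_compared_sites: int
    swap_suspected: bool


def genotype_concordance(
    profile_a: pd.DataFrame,
    profile_b: pd.DataFrame,
    swap_threshold: float = 0.80,
) -> ConcordanceReport:
    """Fraction of co-called SNP sites where two genotype profiles agree."""
    if not profile_a.index.equals(profile_b.index):
        raise ValueError("profiles are not on the same panel")
    a = profile_a["genotype"].to_numpy()
    b = profile_b["genotype"].to_numpy()
    both = (a != "no_call") & (b != "no_call")
    n = int(both.sum())
    if n == 0:
        raise NotEstimableError("no sites called in both profiles")
    frac = float((a[both] == b[both]).mean())
    return ConcordanceReport(frac, n, frac < swap_threshold)


class ContaminationModel:
    """Contamination estimator for one tumor sample against its matched normal.

    Parameters
    ----------
    tumor_counts : DataFrame
        Allele counts at panel SNP sites (site_id, depth, ref/alt/other).
    normal_profile : DataFrame
        Genotype profile from :func:`call_genotypes` on the matched normal.
    panel : DataFrame
        SNP panel with ``pop_alt_freq``.
    error_rate : float
        Symmetric per-base ref<->alt miscall rate assumed by both estimators.
    min_depth : int
        Tumor sites below this depth are dropped.
    max_other_frac : float
        Sites with other_count/depth above this are excluded — a third allele
        suggests a somatic event or artifact, which would mimic contamination.
    exclude_sites : iterable of site_id, optional
        Additional sites to drop (e.g. overlapping known somatic variants).
    """

    def __init__(
        self,
        tumor_counts: pd.DataFrame,
        normal_profile: pd.DataFrame,
        panel: pd.DataFrame,
        error_rate: float = 0.001,
        min_depth: int = 20,
        max_other_frac: float = 0.02,
        exclude_sites=None,
    ):
        check_allele_counts(tumor_counts)
        self.error_rate = float(error_rate)
        counts = tumor_counts.set_index("site_id")
        freq = panel.set_index("site_id")["pop_alt_freq"]
        common = normal_profile.index.intersection(counts.index).intersection(
            freq.index
        )
        sub = counts.loc[common]
        geno = normal_profile.loc[common, "genotype"]
        depth = sub["depth"].to_numpy().astype(float)
        keep = (
            geno.isin(["hom_ref", "hom_alt"]).to_numpy()
            & (depth >= min_depth)
        )
        with np.errstate(invalid="ignore", divide="ignore"):
            other_frac = np.where(
                depth > 0, sub["other_count"].to_numpy() / depth, 0.0
            )
        keep &= other_frac <= max_other_frac
        if exclude_sites is not None:
            keep &= ~common.isin(set(exclude_sites)).to_numpy()
        hom_ref = (geno == "hom_ref").to_numpy() & keep
        hom_alt = (geno == "hom_alt").to_numpy() & keep
        # unexpected allele: alt at hom_ref sites, ref at hom_alt sites
        k = np.where(
            hom_ref, sub["alt_count"].to_numpy(), sub["ref_count"].to_numpy()
        )[keep]
        q = np.where(
            hom_ref,
            freq.loc[common].to_numpy(),
            1.0 - freq.loc[common].to_numpy(),
        )[keep]
        self.k = k.astype(float)
        self.n = depth[keep]
        self.q = q
        self.site_ids = common[keep]
        self._logC = gammaln(self.n + 1) - gammaln(self.k + 1) - gammaln(
            self.n - self.k + 1
        )
        # HWE prior over contaminant dosage, alpha-independent
        with np.errstate(divide="ignore"):
            self._logw = np.log(
                np.column_stack(
                    [(1 - self.q) ** 2, 2 * self.q * (1 - self.q), self.q**2]
                )
            )

    @property
    def n_hom_sites(self) -> int:
        return len(self.n)

    def _moment(self, weights: str = "depth") -> float:
        eps = self.error_rate
        if weights == "depth":
            w = self.n
        elif weights == "none":
            w = np.ones_like(self.n)
        else:
            raise ValueError("weights must be 'depth' or 'none'")
        d = self.k / self.n
        num = float(np.sum(w * (d - eps)))
        den = (1 - 2 * eps) * float(np.sum(w * self.q))
        return float(np.clip(num / den, 0.0, 1.0))

    def _loglik(self, alpha: float) -> float:
        eps = self.error_rate
        g = np.array([0.0, 1.0, 2.0])
        p = np.clip(alpha * g / 2.0 * (1 - 2 * eps) + eps, 1e-12, 1 - 1e-12)
        ll_site = (
            self._logw
            + self._logC[:, None]
            + self.k[:, None] * np.log(p)[None, :]
            + (self.n - self.k)[:, None] * np.log1p(-p)[None, :]
        )
        return float(np.sum(logsumexp(ll_site, axis=1)))

    def _mle(self) -> tuple[float, float | None]:
        # The log-likelihood is exactly flat in alpha once every site is
        # explained by the dosage-0 contaminant component, so a bare bounded
        # search can stall on that plateau; bracket the optimum on a coarse
        # grid first, then refine inside the bracketing interval.
        grid = np.linspace(0.0, 0.5, 101)
        vals = np.array([self._loglik(a) for a in grid])
        i = int(np.argmax(vals))
        lo = grid[max(i - 1, 0)]
        hi = grid[min(i + 1, len(grid) - 1)]
        res = minimize_scalar(
            lambda a: -self._loglik(a),
            bounds=(lo, hi),
            method="bounded",
            options={"xatol": 1e-5},
        )
        alpha = float(res.x) if res.fun <= -vals[i] else float(grid[i])
        # observed-information SE from a central second difference
        h = 1e-4
        lo, hi = max(alpha - h, 0.0), min(alpha + h, 0.5)
        if hi - lo > 0:
            d2 = (
                self._loglik(hi) - 2 * self._loglik(alpha) + self._loglik(lo)
            ) / ((hi - alpha) * (alpha - lo) + 1e-30)
            se = float(1.0 / np.sqrt(-d2)) if d2 < 0 else None
        else:
            se = None
        return alpha, se

    def fit(
        self, method: str = "mle", moment_weights: str = "depth"
    ) -> "ContaminationResults":
        """Estimate alpha; ``method`` is ``"mle"`` (default) or ``"moment"``.

        ``moment_weights`` selects depth weighting (variance-motivated
        default) or ``"none"`` for the unweighted ratio.
        """
        if self.n_hom_sites == 0:
            raise NotEstimableError(
                "no informative homozygous sites with adequate depth"
            )
        if method == "moment":
            alpha = self._moment(moment_weights)
            se = None
        elif method == "mle":
            alpha, se = self._mle()
        else:
            raise ValueError(f"unknown method {method!r}")
        return ContaminationResults(self, alpha, se, method)


class ContaminationResults:
    """Fitted contamination fraction with its clinical interpretation."""

    def __init__(self, model, alpha_hat, se, method):
        self.model = model
        self.alpha_hat = float(alpha_hat)
        self.se = se
        self.method = method
        self.n_hom_sites = model.n_hom_sites
        self.median_site_depth = float(np.median(model.n))

    @property
    def clinically_significant(self) -> bool:
        return self.alpha_hat >= CLINICAL_ALPHA_CUTOFF

    @property
    def low_coverage_caveat(self) -> bool:
        return self.median_site_depth < LOW_COVERAGE_MARK

    def summary(self) -> str:
        lines = [
            "Contamination estimate",
            "----------------------",
            f"method:               {self.method}",
            f"alpha_hat:            {self.alpha_hat:.4f}",
            f"std. error:           "
            + (f"{self.se:.4f}" if self.se is not None else "n/a"),
            f"informative hom sites: {self.n_hom_sites}",
            f"median site depth:    {self.median_site_depth:.0f}x",
            f"clinically significant (>= {CLINICAL_ALPHA_CUTOFF:.0%}): "
            f"{self.clinically_significant}",
            f"low-coverage caveat (< {LOW_COVERAGE_MARK:.0f}x): "
            f"{self.low_coverage_caveat}",
        ]
        return "\n".join(lines)

    def __repr__(self):
        return (
            f"<ContaminationResults alpha_hat={self.alpha_hat:.4f} "
            f"method={self.method} n_hom_sites={self.n_hom_sites}>"
        )


def estimate_contamination(
    tumor_counts: pd.DataFrame,
    normal_profile: pd.DataFrame,
    panel: pd.DataFrame,
    method: str = "mle",
    **model_kwargs,
) -> ContaminationResults:
    """One-call convenience wrapper around :class:`ContaminationModel`."""
    return ContaminationModel(
        tumor_counts, normal_profile, panel, **model_kwargs
    ).fit(method=method)


def classify_contamination(
    result: ContaminationResults, sample_coverage: float
) -> str:
    """Interpret an estimate in its coverage context.

    Returns ``clean``, ``significant_contamination``, or — when the estimate
    is high but coverage is below 50x, where sampling noise alone can push
    the apparent rate up — ``low_coverage_artifact_possible``.
    """
    if result.alpha_hat < CLINICAL_ALPHA_CUTOFF:
        return "clean"
    if sample_coverage < VERY_LOW_COVERAGE_MARK:
        return "low_coverage_artifact_possible"
    return "significant_contamination"
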
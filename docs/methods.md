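# Methods

## Contamination model

A tumor sample sequenced against a panel of common biallelic SNPs is modeled
as a read mixture from two diploid individuals: the patient (fraction
1 − α) and one unrelated contaminant (fraction α). The matched normal sample
defines the patient's genotypes; only sites where the patient is homozygous
are informative, because there any read carrying the other allele is
unexpected. At such a site *i*, let *n<sub>i</sub>* be depth, *k<sub>i</sub>*
the unexpected-allele read count, and *q<sub>i</sub>* the population
frequency of the unexpected allele (the panel's alt frequency at
hom-ref sites, its complement at hom-alt sites — the two cases are
symmetric). A symmetric per-base miscall rate ε moves reads between the two
alleles, so conditional on the contaminant carrying dosage
*g* ∈ {0, 1, 2} of the unexpected allele,

  k_i | g ~ Binomial(n_i, α·g/2·(1 − 2ε) + ε).

**Moment estimator.** Under Hardy–Weinberg equilibrium E[g]/2 = q_i, giving
E[d_i] = α·q_i·(1 − 2ε) + ε for d_i = k_i/n_i. Depth weighting (w_i = n_i,
the inverse-variance choice for binomial sampling noise; switchable to
unweighted) and inversion give

  α̂ = (Σ k_i − ε Σ n_i) / ((1 − 2ε) Σ n_i q_i),  clipped to [0, 1].

At ε = 0 this is the bare ratio Σ k_i / Σ n_i q_i. The ε correction matters:
at ε = 10⁻³ and mean q ≈ 0.275 the uncorrected ratio is biased upward by
≈ 0.004, a large fraction of the 2% clinical cutoff.

**Maximum-likelihood estimator (default).** The likelihood marginalizes g
under HWE weights {(1−q_i)², 2q_i(1−q_i), q_i²} and is maximized over
α ∈ [0, 0.5]. The surface is exactly flat at large α (every site is then
explained by the g = 0 component, whose success probability does not depend
on α), so a bare bounded search can stall on that plateau; the implementation
brackets the optimum on a 101-point grid and refines with bounded Brent
(xatol 10⁻⁵) inside the bracketing interval. The standard error comes from
the observed information via a central second difference.

**Site filters.** Sites below 20× tumor depth are dropped, as are sites with
more than 2% third-allele reads (a somatic event or alignment artifact can
mimic contamination) and any caller-supplied exclusion list (e.g. sites
overlapping known somatic variants). Genotypes are called from the normal
with depth ≥ 20, alt fraction ≤ 0.05 → hom-ref, ≥ 0.95 → hom-alt,
0.30–0.70 → het, anything else no-call. These bands are deliberately
conservative: a het site miscalled homozygous injects d_i ≈ 0.5 and would
dominate the estimate, so the ambiguous zones are wide and at panel depths
(200–600×) the hom misclassification probability is negligible.

**Interpretation.** α̂ ≥ 0.02 — the assay's mutation-calling threshold — is
clinically significant. Estimates at coverage below 200× carry a caveat, and
below 50× a high α̂ is labeled `low_coverage_artifact_possible` rather than
`significant_contamination`: with so few reads per site, sampling noise and
residual artifacts can inflate the apparent rate.

## Identity checking

Pairwise genotype concordance over co-called panel SNPs. For two unrelated
HWE individuals the per-site match probability is Σ_g P(g)², which for
common SNPs pools to roughly 0.37–0.5; same-patient pairs sit near 1 apart
from calling noise. The swap threshold defaults to 0.80 concordance, far
from both modes, so swaps of unrelated samples are flagged essentially with
certainty on panels of hundreds of sites.

## Triage

Gates run in the physical pipeline order — tumor content, DNA input,
coverage, base quality, contamination — and the first failure fixes the
single outcome category (the published data report categories but not a
precedence for multi-failure samples; pipeline order is the natural choice
because later metrics are never measured when an earlier gate fails).
Boundary semantics are strict on the failure side: purity < 10%,
concentration < era threshold, coverage < 50× fail; equality passes. The
contamination cutoff is inclusive (≥ 2%).

The DNA-input policy is era-dependent: < 0.9 ng/µL insufficient until
09/2021, < 0.54 ng/µL afterwards. With the assay's 55 µL maximum input
volume these correspond to 50 and 30 ng total input minima under half-up
rounding (0.9·55 = 49.5 → 50; 0.54·55 = 29.7 → 30). ScfDNA samples bypass
the gate, as they are deliberately sequenced below the FFPE thresholds. At
the 30 ng minimum and the lower 95% CI bound of 220.5 target copies per
nanogram of FFPE DNA, the assay queries at least
`expected_target_copies(30, 220.5)` = 6615 molecules.

**Partial evaluability.** "Very high tumor content" relative to low-level
contamination is quantified as purity/2 (the expected clonal-heterozygous
driver VAF, as a fraction) exceeding `margin` × α̂ with margin = 2
(configurable). Such samples pass with variants at VAF ≤ α̂ filtered;
lower-purity contaminated samples fail outright. The margin-of-2 rule is a
design choice — the source practice is described only qualitatively.

**Base quality** is consumed as a boolean input: the underlying signout
criterion ("adequate coverage but high background noise") is not reducible
to a formula over the available fields.

## Synthetic cohorts

The simulator emulates the study conditions: ~1000 common panel SNPs with
alt frequencies Uniform(0.05, 0.5) (fingerprint SNPs are chosen common; the
true panel's frequency source is unpublished, so this is a default, not an
inference); HWE genotypes for patient and an unrelated contaminant; Poisson
depth at 200–600× medians with an optional negative-binomial overdispersion
knob (real capture coverage is overdispersed); symmetric miscalls at
ε = 10⁻³; somatic VAFs = purity·CCF/2 for diploid heterozygous events
(70% clonal by default), placed away from the SNP panel; and manifest-level
cohorts drawn from the six outcome categories at the published frequencies
(success 80.6%, low DNA 11.3%, scant tumor 4.6%, low coverage 1.8%,
contamination 1.6%, low quality 0.1%), with per-category metric values
constructed so that re-triaging recovers the intended category (failure
categories keep all earlier gates passing; contaminated-failure samples get
purity ≤ 0.9·400·α so VAF filtering cannot rescue them; low-DNA failures are
CB-only since ScfDNA bypasses that gate).

What the simulator does *not* model: read-level artifacts (FFPE
deamination, index hopping beyond the error knob), related contaminants,
indels/CNVs/rearrangements, somatic events overlapping SNP sites, and any
correlation structure between metrics within a sample. Passing
parameter-recovery tests therefore demonstrate estimator correctness under
the stated generative model, not robustness to every failure mode of real
FFPE data.

## Numerical and reporting choices

- All randomness flows through `numpy.random.default_rng(seed)`; every
  generator is reproducible given its seed and distinct seeds give distinct
  tables.
- Presentation rounding is half-up at the published precision (integer
  percent for success rates, one decimal for contamination fractions); raw
  fractions are retained everywhere and rounded only at the reporting edge.
- TMB denominators per panel generation (0.98/1.06/1.14/1.28 Mb for the
  341/410/468/505-gene versions) are configuration estimates, not published
  assay constants; clinical deployments must supply validated footprints.
- Matched-pair VAF-shift testing pools shared variants across pairs into a
  single two-sided Mann–Whitney comparison (one p value for the whole set);
  2×2 categorical comparisons fall back from chi-squared to Fisher's exact
  test when any expected count is below 5.
- The packaged fixture of published cohort counts is re-derived, not
  asserted blindly: internal-consistency identities (sub-cohorts summing to
  totals) are checked, and two published rates that are arithmetically
  inconsistent with their own printed counts (the CB and ScfDNA
  contamination percentages over the 4725 denominator) are reported as
  mismatches rather than patched. Cohort medians (coverage 586×, DNA yields)
  summarize protected per-sample data, are carried as metadata only, and are
  never asserted.

## Problem sizes

The replicate benchmarks use 200 mixtures per contamination level at 1000
homozygous sites and 500× depth, a 20,000-sample triage cohort, and
50 swap trials on 1000-site panels — sizes at which the binomial and
multinomial standard errors are small enough to resolve the tested
tolerances (±0.005 on α, 3 multinomial SEs on category frequencies) while
keeping the whole suite inside a coffee break on one core.
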
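"""Genotype calling, contamination estimation, and identity checks."""

import numpy as np
import pandas as pd
import pytest

import cytoqc as cq
from cytoqc.contamination import NotEstimableError


def counts_table(rows):
    """rows: (site_id, depth, ref, alt, other)"""
    return pd.DataFrame(
        rows, columns=["site_id", "depth", "ref_count", "alt_count", "other_count"]
    )


class TestCallGenotypes:
    @pytest.mark.parametrize(
        "depth,alt,expected",
        [
            (100, 0, "hom_ref"),       # unanimous reference evidence
            (100, 50, "het"),          # balanced evidence
            (100, 100, "hom_alt"),
            (200, 24, "no_call"),      # alt fraction 0.12: between the bands
            (10, 0, "no_call"),        # below min_depth
        ],
    )
    def test_banding(self, depth, alt, expected):
        counts = counts_table([("s1", depth, depth - alt, alt, 0)])
        prof = cq.call_genotypes(counts)
        assert prof.loc["s1", "genotype"] == expected

    def test_malformed_counts_rejected(self):
        with pytest.raises(ValueError):
            cq.call_genotypes(counts_table([("s1", 100, 90, 20, 0)]))
        with pytest.raises(ValueError):
            cq.call_genotypes(counts_table([("s1", 100, -10, 110, 0)]))


class TestMomentOracle:
    def test_three_site_hand_computed_ratio(self, ):
        # hom_ref sites with q = .2/.3/.5, depths 100/200/100, alt 2/6/5:
        # alpha = sum(alt) / sum(depth*q) = 13 / (20 + 60 + 50) = 0.1 exactly
        panel = pd.DataFrame(
            {
                "site_id": ["s1", "s2", "s3"],
                "chrom": ["chr1"] * 3,
                "pos": [1, 2, 3],
                "ref_allele": ["A"] * 3,
                "alt_allele": ["C"] * 3,
                "pop_alt_freq": [0.2, 0.3, 0.5],
            }
        )
        profile = pd.DataFrame(
            {"genotype": "hom_ref", "alt_dosage": 0.0},
            index=pd.Index(panel["site_id"], name="site_id"),
        )
        tumor = counts_table(
            [("s1", 100, 98, 2, 0), ("s2", 200, 194, 6, 0), ("s3", 100, 95, 5, 0)]
        )
        res = cq.estimate_contamination(
            tumor, profile, panel, method="moment", error_rate=0.0
        )
        assert res.alpha_hat == pytest.approx(13 / 130, abs=1e-12)
        assert res.n_hom_sites == 3

    def test_unweighted_moment_option(self, hom_panel):
        # with equal depths the weighted and unweighted ratios coincide;
        # with unequal depths they generally differ
        panel, profile = hom_panel
        contaminant = cq.simulate_genotypes(panel, seed=25)
        spec = cq.MixtureSpec(alpha=0.05, mean_depth=500, error_rate=0.0, seed=26)
        tumor = cq.simulate_allele_counts(profile, contaminant, spec, panel)
        model = cq.ContaminationModel(tumor, profile, panel, error_rate=0.0)
        weighted = model.fit("moment").alpha_hat
        unweighted = model.fit("moment", moment_weights="none").alpha_hat
        assert abs(weighted - unweighted) < 0.005
        assert weighted != unweighted

    def test_hom_alt_sites_contribute_symmetrically(self):
        # hom_alt site: unexpected allele is ref with q = 1 - pop_alt_freq
        panel = pd.DataFrame(
            {
                "site_id": ["s1"],
                "chrom": ["chr1"],
                "pos": [1],
                "ref_allele": ["A"],
                "alt_allele": ["C"],
                "pop_alt_freq": [0.8],
            }
        )
        profile = pd.DataFrame(
            {"genotype": ["hom_alt"], "alt_dosage": [2.0]},
            index=pd.Index(["s1"], name="site_id"),
        )
        tumor = counts_table([("s1", 1000, 20, 980, 0)])
        res = cq.estimate_contamination(
            tumor, profile, panel, method="moment", error_rate=0.0
        )
        # d = 20/1000 = 0.02 against q_ref = 0.2 -> alpha = 0.1
        assert res.alpha_hat == pytest.approx(0.1, abs=1e-12)


class TestEstimation:
    def test_pure_sample_estimates_zero(self, hom_panel):
        panel, profile = hom_panel
        depth = np.full(len(panel), 500)
        tumor = pd.DataFrame(
            {
                "site_id": panel["site_id"],
                "depth": depth,
                "ref_count": depth,
                "alt_count": 0,
                "other_count": 0,
            }
        )
        for method in ("moment", "mle"):
            res = cq.estimate_contamination(
                tumor, profile, panel, method=method, error_rate=0.0
            )
            assert res.alpha_hat == pytest.approx(0.0, abs=1e-6)
            assert not res.clinically_significant

    @pytest.mark.parametrize("method", ["moment", "mle"])
    def test_recovers_five_percent_mixture(self, hom_panel, method):
        # 1000 hom sites, depth 500, no error: estimate within [0.04, 0.06]
        panel, profile = hom_panel
        contaminant = cq.simulate_genotypes(panel, seed=21)
        spec = cq.MixtureSpec(alpha=0.05, mean_depth=500, error_rate=0.0, seed=22)
        tumor = cq.simulate_allele_counts(profile, contaminant, spec, panel)
        res = cq.estimate_contamination(
            tumor, profile, panel, method=method, error_rate=0.0
        )
        assert 0.04 <= res.alpha_hat <= 0.06

    def test_clinical_cutoff_is_inclusive_two_percent(self, hom_panel):
        panel, profile = hom_panel
        contaminant = cq.simulate_genotypes(panel, seed=31)
        spec = cq.MixtureSpec(alpha=0.021, mean_depth=2000, error_rate=0.0, seed=32)
        tumor = cq.simulate_allele_counts(profile, contaminant, spec, panel)
        res = cq.estimate_contamination(tumor, profile, panel, error_rate=0.0)
        assert res.alpha_hat >= 0.02
        assert res.clinically_significant

    def test_monotone_in_alpha(self, hom_panel):
        panel, profile = hom_panel
        contaminant = cq.simulate_genotypes(panel, seed=41)
        means = []
        for alpha in (0.0, 0.02, 0.05, 0.10, 0.20):
            spec = cq.MixtureSpec(
                alpha=alpha, mean_depth=500, error_rate=0.001, seed=42
            )
            tumor = cq.simulate_allele_counts(profile, contaminant, spec, panel)
            res = cq.estimate_contamination(
                tumor, profile, panel, method="moment", error_rate=0.001
            )
            means.append(res.alpha_hat)
        assert all(b > a for a, b in zip(means, means[1:]))

    def test_no_informative_sites_is_not_estimable(self, hom_panel):
        panel, _ = hom_panel
        all_het = pd.DataFrame(
            {"genotype": "het", "alt_dosage": 1.0},
            index=pd.Index(panel["site_id"], name="site_id"),
        )
        depth = np.full(len(panel), 500)
        tumor = pd.DataFrame(
            {
                "site_id": panel["site_id"],
                "depth": depth,
                "ref_count": depth - depth // 2,
                "alt_count": depth // 2,
                "other_count": 0,
            }
        )
        with pytest.raises(NotEstimableError):
            cq.estimate_contamination(tumor, all_het, panel)

    def test_high_other_fraction_sites_excluded(self, hom_panel):
        panel, profile = hom_panel
        depth = np.full(len(panel), 500)
        other = np.zeros(len(panel), dtype=int)
        other[:100] = 50  # 10% third-allele reads: somatic/artifact mimic
        tumor = pd.DataFrame(
            {
                "site_id": panel["site_id"],
                "depth": depth,
                "ref_count": depth - other,
                "alt_count": 0,
                "other_count": other,
            }
        )
        model = cq.ContaminationModel(tumor, profile, panel, error_rate=0.0)
        assert model.n_hom_sites == len(panel) - 100


class TestConcordance:
    def test_identity_is_one(self, patient):
        rep = cq.genotype_concordance(patient, patient)
        assert rep.fraction_concordant == 1.0
        assert not rep.swap_suspected

    def test_symmetry(self, patient, contaminant):
        ab = cq.genotype_concordance(patient, contaminant)
        ba = cq.genotype_concordance(contaminant, patient)
        assert ab.fraction_concordant == ba.fraction_concordant

    def test_unrelated_pair_matches_hwe_closed_form(self):
        # at p = 0.5: match probability sum_g P(g)^2 = 0.0625+0.25+0.0625 = 0.375
        n = 20_000
        panel = cq.simulate_snp_panel(n, 0.5, 0.5, seed=51)
        a = cq.simulate_genotypes(panel, seed=52)
        b = cq.simulate_genotypes(panel, seed=53)
        rep = cq.genotype_concordance(a, b)
        se = np.sqrt(0.375 * 0.625 / n)
        assert abs(rep.fraction_concordant - 0.375) < 4 * se
        assert rep.swap_suspected

    def test_swapped_samples_flagged(self, panel):
        a = cq.simulate_genotypes(panel, seed=61)
        b = cq.simulate_genotypes(panel, seed=62)
        assert cq.genotype_concordance(a, b).swap_suspected

    def test_no_co_called_sites_not_estimable(self, panel):
        a = pd.DataFrame(
            {"genotype": "no_call", "alt_dosage": np.nan},
            index=pd.Index(panel["site_id"], name="site_id"),
        )
        b = cq.simulate_genotypes(panel, seed=63)
        with pytest.raises(NotEstimableError):
            cq.genotype_concordance(a, b)


class TestClassify:
    def test_labels(self, hom_panel):
        panel, profile = hom_panel

        def result_with_alpha(alpha, seed):
            contaminant = cq.simulate_genotypes(panel, seed=seed)
            spec = cq.MixtureSpec(alpha=alpha, mean_depth=600, error_rate=0.0, seed=seed)
            tumor = cq.simulate_allele_counts(profile, contaminant, spec, panel)
            return cq.estimate_contamination(tumor, profile, panel, error_rate=0.0)

        clean = result_with_alpha(0.005, 71)
        assert cq.classify_contamination(clean, 600) == "clean"
        high = result_with_alpha(0.04, 72)
        assert cq.classify_contamination(high, 400) == "significant_contamination"
        low_cov = result_with_alpha(0.10, 73)
        assert cq.classify_contamination(low_cov, 30) == "low_coverage_artifact_possible"


class TestUnbiasedness:
    def test_mean_estimate_within_half_percent(self, hom_panel):
        # quick version of the replicate study (full grid in the acceptance suite)
        panel, profile = hom_panel
        for alpha in (0.02, 0.10):
            est = []
            for r in range(30):
                contaminant = cq.simulate_genotypes(panel, seed=1000 + r)
                spec = cq.MixtureSpec(
                    alpha=alpha, mean_depth=500, error_rate=0.001, seed=2000 + r
                )
                tumor = cq.simulate_allele_counts(profile, contaminant, spec, panel)
                est.append(
                    cq.estimate_contamination(
                        tumor, profile, panel, method="moment", error_rate=0.001
                    ).alpha_hat
                )
            assert abs(np.mean(est) - alpha) < 0.005
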
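"""Phenotype construction, haplotype assignment and association models."""

import numpy as np
import pytest
from scipy import stats

from statpgx import SimConfig
from statpgx.assoc import (
    RHOA_HAPLOTYPES,
    RHOA_SNPS,
    CohortRecord,
    HaplotypeDef,
    assign_haplotype_copies,
    default_haplotype_defs,
    delta_log,
    expr_pheno_assoc,
    group_summary,
    haplotype_assoc,
    haplotype_frequencies,
    percent_change,
)
from statpgx.synthetic import simulate_cohort


class TestPhenotypes:
    @pytest.mark.parametrize(
        "base,on,expected",
        [
            ([100, 100], [100, 100], 0.0),
            ([100, 100], [50, 50], np.log(0.5)),
            ([120, 100], [80, 74], np.log(77) - np.log(110)),
        ],
    )
    def test_delta_log(self, base, on, expected):
        assert delta_log(base, on) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize(
        "base,on,expected",
        [([90, 110], [90, 110], 0.0), ([100, 100], [70, 70], -30.0)],
    )
    def test_percent_change(self, base, on, expected):
        assert percent_change(base, on) == pytest.approx(expected)

    def test_replicate_order_invariance(self):
        assert delta_log([120, 100], [80, 74]) == delta_log([100, 120], [74, 80])
        assert percent_change([120, 100], [80, 74]) == percent_change(
            [100, 120], [74, 80]
        )

    def test_nonpositive_raises(self):
        with pytest.raises(ValueError):
            delta_log([0.0], [100.0])


class TestHaplotypeAssignment:
    def chrom(self, hap_id):
        return dict(zip(RHOA_SNPS, RHOA_HAPLOTYPES[hap_id]))

    def test_homozygote(self):
        copies = assign_haplotype_copies([self.chrom("H1"), self.chrom("H1")])
        assert copies["H1"] == 2 and copies["other"] == 0

    def test_compound_heterozygote(self):
        copies = assign_haplotype_copies([self.chrom("H2"), self.chrom("H3B")])
        assert copies["H2"] == 1 and copies["H3B"] == 1

    def test_unmatched_chromosome_counts_as_other(self):
        odd = self.chrom("H1")
        odd["rs10640"] = "A"  # allele carried by no defined haplotype
        copies = assign_haplotype_copies([odd, self.chrom("H2")])
        assert copies["other"] == 1 and copies["H2"] == 1

    def test_definitions_mutually_distinguishable(self):
        haps = list(RHOA_HAPLOTYPES)
        for i, a in enumerate(haps):
            for b in haps[i + 1 :]:
                dist = sum(
                    x != y for x, y in zip(RHOA_HAPLOTYPES[a], RHOA_HAPLOTYPES[b])
                )
                assert dist >= 1
        # the H3 pair differs at exactly one SNP: the exon-2.5 variant
        diffs = [
            snp
            for snp, x, y in zip(
                RHOA_SNPS, RHOA_HAPLOTYPES["H3A"], RHOA_HAPLOTYPES["H3B"]
            )
            if x != y
        ]
        assert diffs == ["rs11716445"]

    def test_duplicate_definitions_raise(self):
        defs = default_haplotype_defs() + [
            HaplotypeDef("H1bis", RHOA_SNPS, RHOA_HAPLOTYPES["H1"])
        ]
        with pytest.raises(ValueError, match="not distinct"):
            assign_haplotype_copies([self.chrom("H1"), self.chrom("H2")], defs)


def _manual_cohort(rng, n, copies_fn, pct_fn, study="CAP"):
    records = []
    for i in range(n):
        c = copies_fn(i)
        pct = pct_fn(i, c)
        base = 100.0
        records.append(
            CohortRecord(
                subject_id=f"x{i}",
                study=study,
                baseline_ldl=[base, base],
                on_treatment_ldl=[base * (1 + pct / 100)] * 2,
                age=float(rng.uniform(40, 70)),
                sex=int(rng.integers(0, 2)),
                bmi=float(rng.normal(27, 3)),
                smoking=int(rng.random() < 0.3),
                hap_copies={"H3B": c, "other": 2 - c},
            )
        )
    return records


class TestHaplotypeAssoc:
    def test_noiseless_unit_effect_recovered_exactly(self, rng):
        cohort = _manual_cohort(
            rng, 60, lambda i: i % 3,
            # phenotype engineered so delta_log equals the copy count
            lambda i, c: (np.exp(c) - 1) * 100,
        )
        res = haplotype_assoc(cohort, "H3B")
        assert res.beta == pytest.approx(1.0, abs=1e-9)
        assert res.p < 1e-12

    def test_constant_copies_raises(self, rng):
        cohort = _manual_cohort(rng, 20, lambda i: 0, lambda i, c: -30.0)
        with pytest.raises(ValueError, match="constant"):
            haplotype_assoc(cohort, "H3B")

    def test_covariate_affine_recoding_equivariance(self, rng):
        cohort = _manual_cohort(
            rng, 80, lambda i: i % 3, lambda i, c: -30 + 4 * c + rng.normal(0, 5)
        )
        res1 = haplotype_assoc(cohort, "H3B")
        for rec in cohort:
            rec.age = 2.0 * rec.age + 5.0
            rec.bmi = rec.bmi / 3.0 - 1.0
        res2 = haplotype_assoc(cohort, "H3B")
        assert res1.beta == pytest.approx(res2.beta, rel=1e-9)
        assert res1.p == pytest.approx(res2.p, rel=1e-6)

    def test_injected_effect_recovered_on_simulated_cohorts(self):
        config = SimConfig(seed=100, n_cap=300, n_prince=300)
        per_copy = (config.attenuated_pct_change_mean
                    - config.base_pct_change_mean) / 2
        betas = []
        for rep in range(40):
            config.seed = 100 + rep
            cohort, _ = simulate_cohort(config)
            betas.append(haplotype_assoc(cohort, "H3B").beta)
        # expected delta-log slope implied by the injected percent effects
        grid = np.random.default_rng(0).normal(0, config.response_sd_pct, 200_000)
        e = [
            np.mean(np.log1p((config.base_pct_change_mean + per_copy * c
                              + grid).clip(-95) / 100))
            for c in (0, 2)
        ]
        expected = (e[1] - e[0]) / 2
        se = np.std(betas, ddof=1) / np.sqrt(len(betas))
        assert abs(np.mean(betas) - expected) < 3 * se


class TestGroupSummary:
    def test_printed_group_means_give_29_percent(self, rng):
        cohort = _manual_cohort(
            rng, 40, lambda i: 2 * (i % 2),
            lambda i, c: -21.8 if c == 2 else -30.7,
        )
        out = group_summary(cohort, "H3B")
        assert out.loc[0, "mean_pct_change"] == pytest.approx(-30.7)
        assert out.loc[2, "mean_pct_change"] == pytest.approx(-21.8)
        assert round(out.attrs["relative_difference_pct"]) == 29

    def test_equal_strata_means_zero_difference(self, rng):
        cohort = _manual_cohort(rng, 20, lambda i: 2 * (i % 2), lambda i, c: -25.0)
        out = group_summary(cohort, "H3B")
        assert out.attrs["relative_difference_pct"] == pytest.approx(0.0)

    def test_single_subject_stratum_has_missing_se(self, rng):
        cohort = _manual_cohort(
            rng, 5, lambda i: 2 if i == 0 else 0, lambda i, c: -25.0 - c
        )
        out = group_summary(cohort, "H3B")
        assert np.isnan(out.loc[2, "se_pct_change"])


class TestHaplotypeFrequencies:
    def test_trial_counts_reproduce_printed_percentages(self):
        out = haplotype_frequencies()
        assert out.round(1).tolist() == [42.6, 25.6, 22.4, 9.4]
        assert out.sum() == pytest.approx(100.0)

    def test_single_haplotype_is_100(self):
        out = haplotype_frequencies({"H": {"CAP": 7}})
        assert out["H"] == pytest.approx(100.0)

    def test_equal_counts_quarter_each(self):
        out = haplotype_frequencies(
            {h: {"CAP": 5} for h in ("a", "b", "c", "d")}
        )
        assert np.allclose(out, 25.0)

    def test_all_zero_raises(self):
        with pytest.raises(ValueError):
            haplotype_frequencies({"H": {"CAP": 0}})


class TestExprPhenoAssoc:
    def _covars(self, rng, n):
        import pandas as pd
        return pd.DataFrame(
            {
                "age": rng.uniform(40, 70, n),
                "sex": rng.integers(0, 2, n).astype(float),
                "bmi": rng.normal(27, 3, n),
                "smoking": (rng.random(n) < 0.3).astype(float),
            }
        )

    def test_identity_phenotype_gives_unit_r2(self, rng):
        n = 50
        trait = rng.normal(0, 1, n)
        p, r2 = expr_pheno_assoc(trait, trait, self._covars(rng, n))
        assert r2 > 0.999999
        assert p < 1e-30

    def test_null_p_uniform(self, rng):
        n = 50
        ps = []
        covars = self._covars(rng, n)
        for _ in range(500):
            p, _ = expr_pheno_assoc(
                rng.normal(0, 1, n), rng.normal(0, 1, n), covars
            )
            ps.append(p)
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_weak_effect_r2_recovered(self, rng):
        n, reps, target_r2 = 480, 300, 0.01
        r2s = []
        beta = np.sqrt(target_r2 / (1 - target_r2))
        covars = self._covars(rng, n)
        for _ in range(reps):
            x = rng.normal(0, 1, n)
            y = beta * x + rng.normal(0, 1, n)
            _, r2 = expr_pheno_assoc(x, y, covars)
            r2s.append(r2)
        se = np.std(r2s, ddof=1) / np.sqrt(reps)
        # partial r2 has a small positive finite-sample bias ~ 1/n
        assert abs(np.mean(r2s) - target_r2) < 3 * se + 1.0 / n
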
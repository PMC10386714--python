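import numpy as np
import pandas as pd
import pytest
from scipy import stats

from trfscope.screens import (
    ExpressionCohort,
    PolysomeProfile,
    class_median_log2_rpm,
    cohort_anova,
    cohort_zscore,
    cv_filter,
    parclip_quant,
    polysome_fc,
    polysome_proportions,
    rmp_screen,
)
from trfscope.synthdata import CohortDesign, PlantedGene, simulate_expression_cohorts


def _cohort(data: dict, labels, name="c1"):
    return ExpressionCohort(name=name, expr=pd.DataFrame(data).T, labels=labels)


class TestZScore:
    def test_arithmetic(self):
        cohort = _cohort({"g": [1, 2, 3, 4, 5, 6]}, ["N", "N", "N", "P", "P", "P"])
        assert cohort_zscore(cohort, "g", "P") == pytest.approx(3.0)

    def test_zero_when_class_equals_reference(self):
        cohort = _cohort({"g": [1, 2, 3, 2, 2, 2]}, ["N", "N", "N", "P", "P", "P"])
        assert cohort_zscore(cohort, "g", "P") == pytest.approx(0.0)

    def test_shift_invariance_and_sd_scaling(self):
        labels = ["N"] * 3 + ["P"] * 3
        z0 = cohort_zscore(_cohort({"g": [1, 2, 3, 4, 5, 6]}, labels), "g", "P")
        z_shift = cohort_zscore(_cohort({"g": [6, 7, 8, 9, 10, 11]}, labels), "g", "P")
        assert z_shift == pytest.approx(z0)
        # doubling the N spread about its mean exactly halves Z
        z_scaled = cohort_zscore(_cohort({"g": [0, 2, 4, 4, 5, 6]}, labels), "g", "P")
        assert z_scaled == pytest.approx(z0 / 2)

    def test_null_z_mostly_within_2(self):
        rng = np.random.default_rng(2)
        n_genes = 1000
        expr = pd.DataFrame(rng.normal(0, 1, (n_genes, 40)))
        expr.index = [f"g{i}" for i in range(n_genes)]
        cohort = ExpressionCohort("c", expr, ["N"] * 20 + ["P"] * 20)
        zs = np.array([cohort_zscore(cohort, g, "P") for g in expr.index])
        # Z ~ t-ish with sd ~ sqrt(1/20+1/20); |Z|<2 for well over 95%
        assert (np.abs(zs) < 2).mean() > 0.95

    def test_zero_sd_warns_nan(self):
        cohort = _cohort({"g": [1, 1, 2, 3]}, ["N", "N", "P", "P"])
        with pytest.warns(UserWarning, match="zero N-group SD"):
            assert np.isnan(cohort_zscore(cohort, "g", "P"))


class TestAnova:
    def test_two_group_equals_t_test(self):
        rng = np.random.default_rng(3)
        a, b = rng.normal(0, 1, 8), rng.normal(0.5, 1, 8)
        cohort = _cohort({"g": np.concatenate([a, b])}, ["N"] * 8 + ["P"] * 8)
        p_anova = cohort_anova(cohort, "g")
        p_t = stats.ttest_ind(a, b, equal_var=True).pvalue
        assert p_anova == pytest.approx(p_t, rel=1e-9)  # F = t^2 identity

    def test_power_at_planted_shift(self):
        # group means (0, 2, 2), SD 1, n = 10/group: the exact noncentral-F
        # power is ~0.99 at alpha 0.05 and ~0.82 at alpha 0.001
        rng = np.random.default_rng(4)
        hits_05, hits_001 = 0, 0
        for _ in range(100):
            vals = np.concatenate(
                [rng.normal(0, 1, 10), rng.normal(2, 1, 10), rng.normal(2, 1, 10)]
            )
            cohort = _cohort({"g": vals}, ["N"] * 10 + ["P"] * 10 + ["M"] * 10)
            p = cohort_anova(cohort, "g")
            hits_05 += p < 0.05
            hits_001 += p < 0.001
        assert hits_05 >= 95
        assert hits_001 >= 70

    def test_missing_gene_or_groups(self):
        cohort = _cohort({"g": [1, 2, 3, 4]}, ["N", "N", "P", "P"])
        assert np.isnan(cohort_anova(cohort, "absent"))
        single = _cohort({"g": [1, 2, 3]}, ["N", "N", "P"])
        assert np.isnan(cohort_anova(single, "g"))  # P group has < 2 samples


class TestScreen:
    def test_coherence_rules(self):
        """4/5 significant -> coherence 80 and hit; 2/2 -> coherence 100, no hit."""
        rng = np.random.default_rng(5)
        cohorts = []
        for k in range(5):
            shift = 3.0 if k < 4 else 0.0  # big shift in 4 of 5 cohorts
            vals = np.concatenate([rng.normal(0, 1, 10), rng.normal(shift, 1, 10)])
            cohorts.append(
                ExpressionCohort(
                    f"c{k}", pd.DataFrame({"g": vals}).T, ["N"] * 10 + ["P"] * 10
                )
            )
        res = rmp_screen(cohorts, ["g"])
        row = res.loc["g"]
        assert row["n_present"] == 5
        assert row["n_significant"] == 4
        assert row["coherence"] == pytest.approx(80.0)
        assert row["hit"]
        # significant in 2/2 cohorts: coherence 100 but below min_datasets
        res2 = rmp_screen(cohorts[:2], ["g"])
        assert res2.loc["g", "coherence"] == pytest.approx(100.0)
        assert not res2.loc["g", "hit"]

    def test_coherence_matches_brute_force_recount(self):
        design = CohortDesign(n_cohorts=4, n_genes=30, seed=6,
                              group_sizes={"N": 5, "P": 5, "M": 5})
        cohorts = simulate_expression_cohorts(design)
        res = rmp_screen(cohorts, alpha=0.05)
        for gene in res.index[:15]:
            n_sig = sum(cohort_anova(c, gene) < 0.05 for c in cohorts)
            n_present = sum(gene in c.expr.index for c in cohorts)
            assert res.loc[gene, "n_significant"] == n_sig
            assert res.loc[gene, "coherence"] == pytest.approx(100 * n_sig / n_present)

    def test_absent_gene_row(self):
        design = CohortDesign(n_cohorts=2, n_genes=5, seed=7,
                              group_sizes={"N": 3, "P": 3})
        cohorts = simulate_expression_cohorts(design)
        res = rmp_screen(cohorts, ["NOT_A_GENE"])
        assert res.loc["NOT_A_GENE", "n_present"] == 0
        assert not res.loc["NOT_A_GENE", "hit"]

    def test_planted_gene_is_top_hit(self):
        design = CohortDesign(
            n_cohorts=5, n_genes=50, seed=8,
            planted=(PlantedGene("G0007", effect_sd=2.0),),
        )
        res = rmp_screen(simulate_expression_cohorts(design))
        assert res.loc["G0007", "hit"]
        assert res.index[0] == "G0007"  # ranked first by |avg Z|


class TestParclipQuant:
    def test_rpm_rpkm_enrichment(self):
        counts = pd.DataFrame({"ip": [100, 10], "ctrl": [100, 0]}, index=["t1", "t2"])
        libs = pd.Series({"ip": 1_000_000, "ctrl": 1_000_000})
        lengths = pd.Series({"t1": 500, "t2": 1000})
        out = parclip_quant(counts, libs, lengths, ip="ip", control="ctrl")
        assert out.loc["t1", "rpm_ip"] == pytest.approx(100.0)
        assert out.loc["t1", "rpkm_ip"] == pytest.approx(200.0)
        assert out.loc["t1", "log2_enrichment"] == pytest.approx(0.0)
        assert out.loc["t2", "log2_enrichment"] == pytest.approx(np.log2(11 / 1))

    def test_zero_length_rejected(self):
        with pytest.raises(ValueError, match="lengths"):
            parclip_quant(
                pd.DataFrame({"ip": [1], "ctrl": [1]}, index=["t"]),
                pd.Series({"ip": 10, "ctrl": 10}),
                pd.Series({"t": 0}),
                ip="ip",
                control="ctrl",
            )

    def test_class_medians(self):
        rpm = pd.Series({"a": 4.0, "b": 16.0, "c": 8.0, "d": 0.0})
        classes = pd.Series({"a": "tRNA", "b": "tRNA", "c": "mRNA", "d": "mRNA"})
        med = class_median_log2_rpm(rpm, classes)
        assert med["tRNA"] == pytest.approx(3.0)  # median(log2 4, log2 16)
        assert med["mRNA"] == pytest.approx(3.0)  # the zero-RPM gene is dropped


class TestCVFilter:
    def test_examples(self):
        cpm = pd.DataFrame(
            {"r1": [10, 10, 10, 0], "r2": [10, 20, 11, 5]},
            index=["flat", "noisy", "tight", "single"],
        )
        kept = cv_filter(cpm)
        assert "flat" in kept.index      # CV 0
        assert "noisy" not in kept.index  # CV ~ 47.1%
        assert "tight" in kept.index
        assert "single" not in kept.index  # present in one replicate only
        # the quoted CV for (10, 20)
        assert 100 * np.std([10, 20], ddof=1) / 15 == pytest.approx(47.14, abs=0.01)

    def test_needs_two_replicates(self):
        with pytest.raises(ValueError, match="replicates"):
            cv_filter(pd.DataFrame({"r1": [1.0]}))


class TestPolysome:
    def _uniform_profile(self):
        abundance = pd.DataFrame(
            np.ones((2, 16)), index=["t1", "t2"],
            columns=[f"F{i}" for i in range(16)],
        )
        mask = np.zeros(16, dtype=bool)
        mask[-4:] = True
        return PolysomeProfile(abundance=abundance, polysome_mask=mask)

    def test_uniform_fc_one_third(self):
        fc = polysome_fc(self._uniform_profile())
        assert np.allclose(fc, 1 / 3)

    def test_proportions_sum_to_one(self):
        shares = polysome_proportions(self._uniform_profile())
        assert np.allclose(shares.sum(axis=1), 1.0)

    def test_all_polysome_mass_is_inf(self):
        abundance = pd.DataFrame(
            [[0.0] * 12 + [1.0] * 4, [1.0] * 16], index=["poly", "flat"],
            columns=[f"F{i}" for i in range(16)],
        )
        mask = np.zeros(16, dtype=bool)
        mask[-4:] = True
        profile = PolysomeProfile(abundance=abundance, polysome_mask=mask)
        shares = polysome_proportions(profile)
        assert shares.loc["poly"].sum() == pytest.approx(1.0)
        assert shares.loc["poly"][-4:].sum() == pytest.approx(1.0)
        fc = polysome_fc(profile)
        assert np.isinf(fc["poly"])

    def test_zero_total_transcript_dropped(self):
        abundance = pd.DataFrame(
            [[0.0] * 8, [1.0] * 8], index=["empty", "ok"],
            columns=[f"F{i}" for i in range(8)],
        )
        mask = np.array([False] * 6 + [True] * 2)
        fc = polysome_fc(PolysomeProfile(abundance=abundance, polysome_mask=mask))
        assert "empty" not in fc.index

    def test_shift_monotonicity(self):
        from trfscope.synthdata import simulate_polysome_profile

        fcs = []
        for mass in (0.1, 0.3, 0.5):
            profile = simulate_polysome_profile(
                3, shifted=("T0000",), shift_mass=mass, seed=9
            )
            fcs.append(polysome_fc(profile)["T0000"])
        assert fcs == sorted(fcs)
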
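import numpy as np
import pandas as pd
import pytest

from conftest import make_expression
from phylotai.data_model import StagePartition, TraitSeries, ValidationError
from phylotai.genesets_temporal import (
    classify_metabolism,
    module_eigengene,
    module_membership,
    module_trait_correlation,
    significance_tier,
    stage_condition_contrast,
    trajectory_zscore,
)

PATHWAY_CLASSES = {"1.1.1.1": "primary", "2.3.1.-": "specialized"}


def expr_from_log(log_profiles: dict, samples):
    """Expression whose log2(TPM+1) equals the given per-gene profiles."""
    return make_expression(
        {g: list(np.power(2.0, np.asarray(v)) - 1.0) for g, v in log_profiles.items()},
        samples,
    )


SAMPLES8 = [
    (f"{c}:{t:g}:R{r}", c, t, f"R{r}")
    for c in ("CT",)
    for t in (0.5, 1.0, 5.0, 11.0)
    for r in (1, 2)
]


class TestClassifyMetabolism:
    def test_single_class_gene(self):
        out = classify_metabolism({"g1": ["1.1.1.1"]}, PATHWAY_CLASSES)
        assert out["g1"] == "primary_metabolism"

    def test_dual_class_gene_goes_specialized(self):
        out = classify_metabolism({"g1": ["1.1.1.1", "2.3.1.-"]}, PATHWAY_CLASSES)
        assert out["g1"] == "specialized_metabolism"

    def test_unannotated_and_malformed_skipped(self, caplog):
        with caplog.at_level("WARNING"):
            out = classify_metabolism(
                {"g1": [], "g2": ["not-an-ec"], "g3": ["9.9.9.9"]}, PATHWAY_CLASSES
            )
        assert out.empty
        assert "malformed EC" in caplog.text


class TestEigengene:
    def test_rank_one_module_matches_common_profile(self):
        base = [1.0, 2.0, 3.0, 4.0, 3.0, 2.0, 1.0, 2.0]
        expr = expr_from_log({"a": base, "b": base, "c": base}, SAMPLES8)
        eig = module_eigengene(expr, ["a", "b", "c"])
        z = (np.asarray(base) - np.mean(base)) / np.std(base, ddof=1)
        r = np.corrcoef(eig.to_numpy(), z)[0, 1]
        assert abs(r) == pytest.approx(1.0, abs=1e-9)
        assert r > 0  # orientation: positive mean member correlation

    def test_negated_members_keep_positive_orientation(self):
        rng = np.random.default_rng(2)
        prof = rng.uniform(1, 5, 8)
        expr_pos = expr_from_log({"a": prof, "b": prof + 0.1}, SAMPLES8)
        expr_neg = expr_from_log({"a": 9 - prof, "b": 9.1 - prof}, SAMPLES8)
        eig_pos = module_eigengene(expr_pos, ["a", "b"])
        eig_neg = module_eigengene(expr_neg, ["a", "b"])
        # both eigengenes correlate positively with their own members
        assert np.corrcoef(eig_pos, prof)[0, 1] > 0
        assert np.corrcoef(eig_neg, 9 - prof)[0, 1] > 0

    def test_two_gene_module_matches_closed_form(self):
        """For 2 standardized genes the first PC is their normalized sum."""
        rng = np.random.default_rng(8)
        a, b = rng.uniform(1, 6, 8), rng.uniform(1, 6, 8)
        if np.corrcoef(a, b)[0, 1] < 0:
            b = 7 - b
        expr = expr_from_log({"a": a, "b": b}, SAMPLES8)
        eig = module_eigengene(expr, ["a", "b"])
        za = (a - a.mean()) / a.std(ddof=1)
        zb = (b - b.mean()) / b.std(ddof=1)
        ref = za + zb
        ref = ref / ref.std(ddof=1)
        assert np.allclose(np.abs(eig.to_numpy()), np.abs(ref), atol=1e-8)

    def test_constant_module_rejected(self):
        expr = expr_from_log({"a": [2.0] * 8, "b": [2.0] * 8}, SAMPLES8)
        with pytest.raises(ValidationError, match="constant"):
            module_eigengene(expr, ["a", "b"])


class TestMembership:
    def test_boundary_is_strict_and_sign_matters(self):
        rng = np.random.default_rng(5)
        e = rng.normal(size=8)
        e = e - e.mean()
        u = rng.normal(size=8)
        u = u - u.mean()
        u -= u @ e / (e @ e) * e  # orthogonal to e, still mean-zero
        mix = lambda r: 5 + r * e / np.linalg.norm(e) + np.sqrt(1 - r * r) * u / np.linalg.norm(u)
        expr = expr_from_log(
            {
                "identical": 5 + e,
                "near_bound": mix(0.75),
                "above": mix(0.80),
                "anti": 5 - 0.9 * e,
            },
            SAMPLES8,
        )
        eig = pd.Series(e, index=expr.values.columns)
        kept = module_membership(expr, eig)
        assert kept["identical"] == pytest.approx(1.0, abs=1e-9)
        assert "above" in kept.index
        assert "anti" not in kept.index  # signed correlation, not |r|
        # retention is strict: a gene whose membership equals the
        # threshold exactly is dropped
        log_prof = np.log2(expr.values.loc["near_bound"] + 1.0)
        r_exact = float(np.corrcoef(log_prof, eig)[0, 1])
        at_threshold = module_membership(expr, eig, threshold=r_exact)
        assert "near_bound" not in at_threshold.index
        just_below = module_membership(expr, eig, threshold=r_exact - 1e-6)
        assert "near_bound" in just_below.index


class TestModuleTrait:
    def test_affine_module_attains_r_one(self):
        trait_vals = np.array([1.0, 3.0, 2.0, 5.0, 4.0, 6.0, 2.5, 3.5])
        expr = expr_from_log(
            {
                "a": 2 * trait_vals + 1,
                "b": 0.5 * trait_vals + 3,
                "x": trait_vals[::-1],
                "y": np.r_[trait_vals[4:], trait_vals[:4]],
            },
            SAMPLES8,
        )
        trait = TraitSeries(pd.Series(trait_vals, index=expr.values.columns))
        modules = pd.Series({"a": "M1", "b": "M1", "x": "M2", "y": "M2"})
        summary, contrasts = module_trait_correlation(expr, modules, trait)
        top = summary.iloc[0]
        assert top["module"] == "M1"
        assert top["mean_r"] == pytest.approx(1.0, abs=1e-9)

    def test_trait_affine_invariance(self, small_cfg, small_catalog):
        from phylotai.synthetic_data import simulate_expression

        expr, trait, modules = simulate_expression(small_cfg, small_catalog)
        s1, _ = module_trait_correlation(expr, modules, trait)
        rescaled = TraitSeries(trait.values * 3.0 - 7.0, name="JA")
        s2, _ = module_trait_correlation(expr, modules, rescaled)
        pd.testing.assert_frame_equal(s1, s2)

    def test_shuffled_trait_breaks_association(self, small_cfg, small_catalog):
        from phylotai.synthetic_data import simulate_expression

        expr, trait, modules = simulate_expression(small_cfg, small_catalog)
        rng = np.random.default_rng(0)
        hits = 0
        n_shuffles = 50
        for _ in range(n_shuffles):
            sh = TraitSeries(
                pd.Series(
                    rng.permutation(trait.values.to_numpy()),
                    index=trait.values.index,
                )
            )
            summary, _ = module_trait_correlation(expr, modules, sh)
            hits += abs(summary["mean_r"]).max() > 0.5
        assert hits <= 0.2 * n_shuffles

    def test_tiny_modules_excluded(self):
        trait_vals = np.arange(8.0)
        expr = expr_from_log(
            {"a": trait_vals, "b": trait_vals + 1, "solo": trait_vals[::-1]},
            SAMPLES8,
        )
        trait = TraitSeries(pd.Series(trait_vals, index=expr.values.columns))
        modules = pd.Series({"a": "M1", "b": "M1", "solo": "M2"})
        summary, contrasts = module_trait_correlation(expr, modules, trait)
        assert list(summary["module"]) == ["M1"]
        assert contrasts.empty


class TestTrajectory:
    SAMPLES_1REP = [(f"CT:{t:g}:R1", "CT", t, "R1") for t in (0.5, 1.0, 5.0)]

    def test_zscore_identity_on_monotone_gene(self):
        # medians 1, 3, 7 -> log2(median+1) = 1, 2, 3 -> z = (-1, 0, 1)
        expr = make_expression({"g": [1.0, 3.0, 7.0]}, self.SAMPLES_1REP)
        z = trajectory_zscore(expr, ["g"], "CT")
        assert np.allclose(z.loc["g"], [-1.0, 0.0, 1.0])

    def test_constant_gene_yields_zero_row(self, caplog):
        expr = make_expression({"g": [2.0, 2.0, 2.0]}, self.SAMPLES_1REP)
        with caplog.at_level("WARNING"):
            z = trajectory_zscore(expr, ["g"], "CT")
        assert np.allclose(z.loc["g"], 0.0)
        assert "constant" in caplog.text

    def test_rows_standardized(self):
        rng = np.random.default_rng(4)
        samples = [
            (f"CT:{t:g}:R{r}", "CT", t, f"R{r}")
            for t in (0.5, 1.0, 5.0, 11.0)
            for r in (1, 2, 3)
        ]
        vals = {f"g{i}": rng.uniform(0, 50, 12) for i in range(6)}
        expr = make_expression(vals, samples)
        z = trajectory_zscore(expr, list(vals), "CT")
        assert np.allclose(z.mean(axis=1), 0.0, atol=1e-12)
        assert np.allclose(z.std(axis=1, ddof=1), 1.0, atol=1e-12)


class TestStageContrast:
    def test_identical_distributions_not_significant(self):
        rng = np.random.default_rng(6)
        z = pd.DataFrame(
            rng.normal(size=(30, 4)), columns=[0.5, 1.0, 5.0, 11.0]
        )
        out = stage_condition_contrast(
            {"CT": z, "HT": z.copy()}, StagePartition.default()
        )
        assert (out["tier"] == "ns").all()
        assert (out["p"] > 0.9).all()  # identical samples: t = 0

    def test_three_sd_shift_is_extreme_tier(self):
        rng = np.random.default_rng(7)
        a = pd.DataFrame(rng.normal(0, 1, size=(50, 4)), columns=[0.5, 1.0, 5.0, 11.0])
        b = a + 3.0
        out = stage_condition_contrast({"CT": a, "HT": b}, StagePartition.default())
        assert (out["p"] < 1e-4).all()
        assert (out["tier"] == "****").all()

    @pytest.mark.parametrize(
        "p,tier",
        [(0.049, "*"), (0.051, "ns"), (0.009, "**"), (0.0009, "***"), (5e-5, "****")],
    )
    def test_tier_boundaries(self, p, tier):
        assert significance_tier(p) == tier
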
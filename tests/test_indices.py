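import numpy as np
import pandas as pd
import pytest

from conftest import make_expression, make_induction
from oracles import oracle_weighted_index
from phylotai.data_model import ValidationError
from phylotai.indices import (
    compute_index,
    index_profiles,
    select_responsive,
    tpm_filter,
)


class TestTpmFilter:
    def test_threshold_is_inclusive_in_at_least_one_sample(self):
        expr = make_expression(
            {"below": [0.9, 0.9], "at_bound": [1.0, 0.2], "high": [5.0, 3.0]},
            [("CT:0.5:R1", "CT", 0.5, "R1"), ("CT:1:R1", "CT", 1.0, "R1")],
        )
        assert tpm_filter(expr) == {"at_bound", "high"}
        assert tpm_filter(expr, min_tpm=0) == {"below", "at_bound", "high"}

    def test_empty_matrix_rejected(self):
        expr = make_expression({}, [("CT:0.5:R1", "CT", 0.5, "R1")])
        with pytest.raises(ValidationError, match="empty"):
            tpm_filter(expr)


class TestSelectResponsive:
    @pytest.mark.parametrize(
        "log2fc,padj,expected",
        [
            (1.0, 0.04, "up"),       # fold-change bound inclusive
            (0.9, 0.001, None),      # below fold-change bound
            (-2.0, 0.05, None),      # padj bound strict
            (-1.0, 0.049, "down"),
            (3.0, 0.5, None),        # not significant
        ],
    )
    def test_thresholds(self, log2fc, padj, expected):
        tab = make_induction([("g1", "CT", 0.5, log2fc, padj)])
        rs = select_responsive(tab, "CT")
        got = (
            "up" if "g1" in rs.up[0.5] else "down" if "g1" in rs.down[0.5] else None
        )
        assert got == expected

    def test_union_and_universe_restriction(self):
        tab = make_induction(
            [
                ("g1", "CT", 0.5, 2.0, 0.01),
                ("g2", "CT", 1.0, -2.0, 0.01),
                ("g3", "CT", 1.0, 2.0, 0.01),
            ]
        )
        rs = select_responsive(tab, "CT", universe={"g1", "g2"})
        assert rs.union() == {"g1", "g2"}
        assert rs.union("up") == {"g1"} and rs.union("down") == {"g2"}


class TestComputeIndex:
    def test_hand_computed_weighted_mean(self):
        # strata (1,2,3), |FC| (1,1,2) -> (1+2+6)/4 = 2.25
        tab = make_induction(
            [
                ("a", "CT", 0.5, 1.0, 0.01),
                ("b", "CT", 0.5, -1.0, 0.01),
                ("c", "CT", 0.5, 2.0, 0.01),
            ]
        )
        prof = compute_index(
            tab, {"a": 1.0, "b": 2.0, "c": 3.0}, {"a", "b", "c"}, "CT"
        )
        assert prof.values[0] == pytest.approx(2.25)

    def test_constant_strata_and_scale_invariance(self):
        rows = [(f"g{i}", "CT", t, (i + 1) * 0.7, 0.01)
                for i in range(4) for t in (0.5, 1.0)]
        tab = make_induction(rows)
        strata = {f"g{i}": 5.0 for i in range(4)}
        prof = compute_index(tab, strata, set(strata), "CT")
        assert np.allclose(prof.values, 5.0)

        doubled = make_induction(
            [(g, c, t, 2 * fc, p) for g, c, t, fc, p in rows]
        )
        strata = {f"g{i}": float(i) + 1 for i in range(4)}
        p1 = compute_index(tab, strata, set(strata), "CT")
        p2 = compute_index(doubled, strata, set(strata), "CT")
        assert np.allclose(p1.values, p2.values)

    def test_equal_weights_give_unweighted_mean_and_bounds(self):
        tab = make_induction([(f"g{i}", "CT", 0.5, 1.5, 0.01) for i in range(5)])
        strata = {f"g{i}": float(i + 1) for i in range(5)}
        prof = compute_index(tab, strata, set(strata), "CT")
        assert prof.values[0] == pytest.approx(np.mean(list(strata.values())))
        assert min(strata.values()) <= prof.values[0] <= max(strata.values())

    def test_matches_bruteforce_loop_on_random_tables(self):
        rng = np.random.default_rng(21)
        for _ in range(25):
            n_g, n_t = int(rng.integers(3, 12)), int(rng.integers(2, 5))
            genes = [f"g{i}" for i in range(n_g)]
            tps = sorted(rng.uniform(0.1, 20, n_t))
            rows, fc = [], {}
            for g in genes:
                for t in tps:
                    v = float(rng.normal(0, 2))
                    rows.append((g, "CT", t, v, 0.01))
                    fc[(g, t)] = v
            strata = {g: float(rng.uniform(1, 13)) for g in genes}
            tab = make_induction(rows)
            prof = compute_index(tab, strata, genes, "CT")
            expected = oracle_weighted_index(strata, fc, genes, tps)
            assert np.allclose(prof.values, expected, atol=1e-12)

    def test_zero_weights_at_a_timepoint_rejected(self):
        tab = make_induction(
            [("g1", "CT", 0.5, 1.0, 0.01), ("g1", "CT", 1.0, 0.0, 0.9)]
        )
        with pytest.raises(ValidationError, match="t="):
            compute_index(tab, {"g1": 2.0}, {"g1"}, "CT")

    def test_genes_without_stratum_value_are_dropped(self, tiny_catalog):
        tab = make_induction(
            [("g1", "CT", 0.5, 1.0, 0.01), ("g3", "CT", 0.5, 1.0, 0.01)]
        )
        # g3 has no kaks: the iTDI index must use g1 only
        prof = compute_index(
            tab, tiny_catalog.kaks_map().dropna(), {"g1", "g3"}, "CT", kind="iTDI"
        )
        assert prof.values[0] == pytest.approx(0.1)


class TestIndexProfiles:
    def test_profile_shapes_and_kinds(self, small_induction, small_catalog):
        rs = select_responsive(small_induction, "CT")
        profiles = index_profiles(small_induction, small_catalog, rs)
        assert len(profiles) == 6  # iTAI/iTDI x all/up/down
        for p in profiles:
            assert len(p.values) == 4 and (p.n >= 1).all()

    def test_hourglass_scenario_has_mid_minimum(self, small_induction, small_catalog):
        rs = select_responsive(small_induction, "CT")  # CT simulated as hourglass
        profiles = index_profiles(small_induction, small_catalog, rs)
        itai_all = next(p for p in profiles if p.kind == "iTAI" and p.subset == "all")
        assert np.argmin(itai_all.values) == 2  # 5 h is the third timepoint

    def test_per_timepoint_mode_restricts_gene_sets(self, small_induction, small_catalog):
        rs = select_responsive(small_induction, "CT")
        union_prof = index_profiles(small_induction, small_catalog, rs)
        per_t = index_profiles(small_induction, small_catalog, rs, per_timepoint=True)
        itai_u = next(p for p in union_prof if p.kind == "iTAI" and p.subset == "all")
        itai_t = next(p for p in per_t if p.kind == "iTAI" and p.subset == "all")
        # both modes must agree on the qualitative mid-timepoint minimum
        assert np.argmin(itai_t.values) == np.argmin(itai_u.values) == 2
        assert (itai_t.n <= itai_u.n).all()
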
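"""Collagen composition and differential-expression statistics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from statsmodels.stats.multitest import multipletests

from cerebromech.omics import (
    AbundanceTable,
    OmicsError,
    collagen_composition,
    differential_expression,
)
from cerebromech import reference, synthetic


def simple_table(values: dict[str, list[float]], groups: list[str], collagen: dict[str, str]):
    samples = [f"S{i}" for i in range(len(next(iter(values.values()))))]
    data = pd.DataFrame(values, index=samples).T
    return AbundanceTable(
        data=data,
        groups=pd.Series(groups, index=samples),
        collagen_type=pd.Series(collagen).reindex(data.index),
    )


class TestComposition:
    def test_single_sample_percentages(self):
        t = simple_table(
            {"COL_I": [500.0], "COL_III": [300.0], "COL_IV": [200.0]},
            ["control"],
            {"COL_I": "I", "COL_III": "III", "COL_IV": "IV"},
        )
        res = collagen_composition(t, "control", "control")
        assert res.percentages["S0"].to_dict() == pytest.approx({"I": 50.0, "III": 30.0, "IV": 20.0})

    def test_percentages_sum_to_100(self):
        table, _ = synthetic.generate_abundance_table(seed=2)
        res = collagen_composition(table)
        assert np.allclose(res.percentages.sum(axis=0), 100.0, atol=1e-9)

    def test_sample_rescaling_invariance(self):
        table, _ = synthetic.generate_abundance_table(seed=3)
        res1 = collagen_composition(table)
        data = table.data.copy()
        data.iloc[:, 0] *= 7.3
        res2 = collagen_composition(
            AbundanceTable(data=data, groups=table.groups, collagen_type=table.collagen_type)
        )
        pd.testing.assert_frame_equal(res1.percentages, res2.percentages)

    def test_identical_groups_show_no_significance(self):
        vals = {"COL_I": [500.0, 510, 490, 500, 505, 495], "COL_IV": [200.0, 205, 195, 200, 202, 198]}
        t = simple_table(vals, ["control"] * 3 + ["AD"] * 3, {"COL_I": "I", "COL_IV": "IV"})
        # make the two groups exactly identical
        t.data.iloc[:, 3:] = t.data.iloc[:, :3].to_numpy()
        res = collagen_composition(t, "control", "AD")
        assert not res.summary["significant"].any()
        assert (res.summary["pvalue_bonferroni"] >= res.summary["pvalue"] - 1e-15).all()

    def test_zero_collagen_sample_excluded_with_warning(self):
        vals = {"COL_I": [500.0, 0.0, 480, 520, 510, 490]}
        t = simple_table(vals, ["control"] * 3 + ["AD"] * 3, {"COL_I": "I"})
        with pytest.warns(UserWarning, match="zero total collagen"):
            res = collagen_composition(t, "control", "AD")
        assert res.excluded_samples == ["S1"]

    def test_group_shift_detection_rate_reported(self):
        """Type-V control/AD shift at study SDs and sample sizes: the raw
        detection rate over seeded replicates is a proper frequency and the
        Bonferroni adjustment stays monotone in raw p."""
        hits = 0
        n_rep = 40
        for k in range(n_rep):
            table, _ = synthetic.generate_abundance_table(
                profile_ad=reference.COLLAGEN_PROFILE_AD, seed=1000 + k
            )
            res = collagen_composition(table, "control", "AD")
            s = res.summary.sort_values("pvalue")
            assert s["pvalue_bonferroni"].is_monotonic_increasing
            if res.summary.loc["V", "pvalue"] < 0.05:
                hits += 1
        assert 0 <= hits <= n_rep


class TestDifferentialExpression:
    def test_identical_groups_nothing_significant(self):
        rng = np.random.default_rng(0)
        base = rng.lognormal(12, 1, 20)
        vals = {f"P{i}": [base[i]] * 8 for i in range(20)}
        t = simple_table(vals, ["control"] * 4 + ["AD"] * 4, {})
        de = differential_expression(t, "control", "AD")
        assert not de["significant"].any()
        assert np.allclose(de["log2fc"], 0.0)

    def test_bh_hand_example(self):
        # four raw p-values 0.01..0.04 all adjust to 0.04
        adj = multipletests([0.01, 0.02, 0.03, 0.04], method="fdr_bh")[1]
        assert np.allclose(adj, 0.04)

    @given(
        pvals=st.lists(st.floats(1e-6, 1.0), min_size=2, max_size=30),
    )
    @settings(max_examples=50, deadline=None)
    def test_bh_bounded_by_raw_and_bonferroni(self, pvals):
        p = np.asarray(pvals)
        bh = multipletests(p, method="fdr_bh")[1]
        bonf = np.minimum(p * p.size, 1.0)
        assert np.all(bh >= p - 1e-12)
        assert np.all(bh <= bonf + 1e-12)

    def test_spiked_effect_found(self):
        effects = {"PROT1": 2.5}
        table, truth = synthetic.generate_abundance_table(
            n_control=6, n_ad=6, n_background=40,
            background_log2_effects=effects, background_log2_sd=0.3, seed=9,
        )
        de = differential_expression(table, "control", "AD")
        assert truth["differential_background"] == effects
        assert de.loc["PROT1", "significant"]
        assert de.loc["PROT1", "log2fc"] == pytest.approx(2.5, abs=0.6)

    def test_missing_heavy_protein_flagged_not_tested(self):
        vals = {
            "P1": [0.0, 0.0, 0.0, 100.0, 120.0, 110.0],
            "P2": [50.0, 55, 45, 60, 58, 62],
        }
        t = simple_table(vals, ["control"] * 3 + ["AD"] * 3, {})
        de = differential_expression(t, "control", "AD")
        assert not de.loc["P1", "tested"]
        assert np.isnan(de.loc["P1", "pvalue"])
        assert de.loc["P2", "tested"]

    def test_single_sample_group_rejected(self):
        vals = {"P1": [1.0, 2.0, 3.0]}
        t = simple_table(vals, ["control", "AD", "AD"], {})
        with pytest.raises(OmicsError):
            differential_expression(t, "control", "AD")

    def test_negative_abundance_rejected(self):
        with pytest.raises(OmicsError):
            simple_table({"P1": [-1.0, 2.0]}, ["a", "b"], {})


class TestGenerator:
    def test_profile_recovered_at_large_n(self):
        table, truth = synthetic.generate_abundance_table(
            n_control=150, n_ad=2, seed=21
        )
        res = collagen_composition(table, "control", "AD")
        for ctype, (mu, sd) in reference.COLLAGEN_PROFILE_CONTROL.items():
            se = sd / np.sqrt(150)
            # renormalization distorts means by well under a percent of scale
            assert res.summary.loc[ctype, "mean_control"] == pytest.approx(
                mu, abs=max(4 * se, 0.02 * mu + 0.02)
            )

    def test_single_protein_per_type_percentages_equal_normalized_abundance(self):
        table, _ = synthetic.generate_abundance_table(seed=4)
        res = collagen_composition(table)
        col = table.data.loc[[f"COL_{t}" for t in reference.COLLAGEN_PROFILE_CONTROL]]
        manual = col / col.sum(axis=0) * 100.0
        manual.index = [i.removeprefix("COL_") for i in manual.index]
        pd.testing.assert_frame_equal(
            res.percentages.sort_index(), manual.sort_index(), check_names=False
        )
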
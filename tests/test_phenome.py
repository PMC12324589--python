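"""Phenome scans, group differences and age-bracket stratification."""

import numpy as np
import pandas as pd
import pytest

from chronopls import PhenomeMatrix, scan, group_difference, stratify_age
from chronopls.phenome import bracket_table
from chronopls.pls import ModeScoreSet


def _scores(values):
    values = np.asarray(values, dtype=float)
    if values.ndim == 1:
        values = values[:, None]
    return ModeScoreSet(
        pd.DataFrame(values, columns=[f"comp{k+1}" for k in range(values.shape[1])])
    )


class TestScan:
    def test_identical_phenotype_gives_r_one(self):
        s = np.arange(10.0)
        ph = PhenomeMatrix(pd.DataFrame({"same": s}))
        rec = scan(_scores(s), ph).iloc[0]
        assert rec["r"] == 1.0 and rec["p"] == 0.0 and rec["passes_bonferroni"]

    def test_hand_formula_oracle_on_toy_table(self):
        # 8-participant printed toy vectors
        s = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0])
        ph_col = np.array([2.1, 1.9, 3.5, 3.2, 5.0, 4.4, 6.1, 5.8])
        rec = scan(_scores(s), PhenomeMatrix(pd.DataFrame({"toy": ph_col}))).iloc[0]
        sc, pc = s - s.mean(), ph_col - ph_col.mean()
        r_hand = (sc @ pc) / np.sqrt((sc @ sc) * (pc @ pc))
        t_hand = r_hand * np.sqrt(6 / (1 - r_hand**2))
        from scipy import stats

        p_hand = 2 * stats.t.sf(abs(t_hand), df=6)
        assert abs(rec["r"] - r_hand) < 1e-12
        assert abs(rec["p"] - p_hand) < 1e-12
        assert abs(rec["neg_log10_p"] + np.log10(p_hand)) < 1e-10

    @pytest.mark.parametrize("family_size", [977, 1396, 133, 5859])
    def test_bonferroni_threshold_rule(self, family_size):
        """passes_bonferroni iff p < 0.05 / family_size, for the declared
        behavioral / diagnosis / medication / youth family sizes."""
        threshold = 0.05 / family_size
        rng = np.random.default_rng(family_size)
        n = 250
        s = rng.standard_normal(n)
        ph = PhenomeMatrix(
            pd.DataFrame(
                {
                    "linked": s + 0.8 * rng.standard_normal(n),
                    "noise": rng.standard_normal(n),
                }
            ),
            family_size=family_size,
        )
        out = scan(_scores(s), ph, alpha=0.05)
        assert out.attrs["threshold"] == pytest.approx(threshold)
        for _, rec in out.iterrows():
            assert rec["passes_bonferroni"] == (rec["p"] < threshold)

    def test_977_family_threshold_boundary_cases(self):
        # 0.05/977 = 5.117...e-5: a p of 6e-5 fails, 4e-5 passes
        threshold = 0.05 / 977
        assert 4e-5 < threshold < 6e-5

    def test_pairwise_complete_missing_handling(self):
        s = np.arange(12.0)
        col = s + np.random.default_rng(0).standard_normal(12) * 0.1
        col[3] = np.nan
        out = scan(_scores(s), PhenomeMatrix(pd.DataFrame({"m": col})))
        rec = out.iloc[0]
        assert rec["n_used"] == 11
        ok = ~np.isnan(col)
        assert rec["r"] == pytest.approx(np.corrcoef(s[ok], col[ok])[0, 1])

    def test_binary_phenotype_equals_point_biserial(self):
        rng = np.random.default_rng(5)
        s = rng.standard_normal(80)
        b = (s + rng.standard_normal(80) > 0).astype(float)
        rec = scan(_scores(s), PhenomeMatrix(pd.DataFrame({"b": b}))).iloc[0]
        assert rec["r"] == pytest.approx(np.corrcoef(s, b)[0, 1])

    def test_zero_variance_phenotype_flagged_and_family_size_modes(self):
        s = np.arange(20.0)
        ph = pd.DataFrame({"const": np.ones(20), "ok": s + 0.5})
        full = scan(_scores(s), PhenomeMatrix(ph), count_tested_only=False)
        assert full[full.phenotype_id == "const"].iloc[0]["zero_variance"]
        assert np.isnan(full[full.phenotype_id == "const"].iloc[0]["r"])
        assert full.attrs["family_size"] == 2
        tested = scan(_scores(s), PhenomeMatrix(ph), count_tested_only=True)
        assert tested.attrs["family_size"] == 1

    def test_neg_log10_p_sorting_matches_p_sorting(self):
        rng = np.random.default_rng(6)
        s = rng.standard_normal(60)
        ph = PhenomeMatrix(
            pd.DataFrame(rng.standard_normal((60, 15)), columns=[f"x{j}" for j in range(15)])
        )
        out = scan(_scores(s), ph)
        by_p = out.sort_values("p")["phenotype_id"].tolist()
        by_nlp = out.sort_values("neg_log10_p", ascending=False)["phenotype_id"].tolist()
        assert by_p == by_nlp

    def test_alpha_validation(self):
        s = np.arange(10.0)
        with pytest.raises(ValueError):
            scan(_scores(s), PhenomeMatrix(pd.DataFrame({"a": s})), alpha=1.5)


class TestGroupDifference:
    def test_identical_groups_give_t_zero(self):
        vals = np.tile(np.arange(5.0), 2)
        group = np.repeat([0.0, 1.0], 5)
        out = group_difference(_scores(vals), group)
        assert out["t"].iloc[0] == pytest.approx(0.0, abs=1e-12)
        assert out["p"].iloc[0] == pytest.approx(1.0)

    def test_pooled_t_matches_textbook_formula(self):
        a = np.array([4.1, 5.0, 6.2, 5.5, 4.8])  # group 1
        b = np.array([3.2, 3.9, 4.1, 3.5, 4.4])  # group 0
        vals = np.concatenate([b, a])
        group = np.repeat([0.0, 1.0], 5)
        out = group_difference(_scores(vals), group, variant="student")
        sp2 = ((a.var(ddof=1) * 4) + (b.var(ddof=1) * 4)) / 8
        t_hand = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / 5 + 1 / 5))
        assert out["t"].iloc[0] == pytest.approx(t_hand, abs=1e-10)

    def test_sign_convention_group1_minus_group0(self):
        rng = np.random.default_rng(7)
        vals = np.concatenate([rng.standard_normal(2000), 1.0 + rng.standard_normal(2000)])
        group = np.repeat([0.0, 1.0], 2000)
        out = group_difference(_scores(vals), group)
        assert out["t"].iloc[0] > 10

    def test_welch_variant_differs_under_unequal_variance(self):
        rng = np.random.default_rng(8)
        vals = np.concatenate([rng.standard_normal(30), 5 * rng.standard_normal(10)])
        group = np.concatenate([np.zeros(30), np.ones(10)])
        s = group_difference(_scores(vals), group, variant="student")
        w = group_difference(_scores(vals), group, variant="welch")
        assert s["p"].iloc[0] != w["p"].iloc[0]

    def test_errors(self):
        with pytest.raises(ValueError, match="2 group"):
            group_difference(_scores(np.arange(6.0)), np.array([0, 1, 2, 0, 1, 2]))
        with pytest.raises(ValueError, match="at least 2"):
            group_difference(_scores(np.arange(3.0)), np.array([0.0, 0.0, 1.0]))


class TestStratifyAge:
    def test_single_bracket_equals_global_mean(self):
        rng = np.random.default_rng(9)
        vals = rng.standard_normal(50)
        age = rng.uniform(40, 70, 50)
        summaries, unassigned = stratify_age(_scores(vals), age, [(40, 70.0001)])
        assert unassigned == 0
        assert summaries[0].mean_score[0] == pytest.approx(vals.mean())
        assert summaries[0].sd_score[0] == pytest.approx(vals.std(ddof=1))

    def test_boundary_goes_to_upper_bracket(self):
        vals = np.array([1.0, 2.0, 3.0])
        age = np.array([45.0, 50.0, 52.0])
        summaries, _ = stratify_age(_scores(vals), age, [(40, 50), (50, 55)])
        assert summaries[0].n == 1 and summaries[1].n == 2

    def test_matches_groupby_oracle_on_toy_table(self):
        age = np.array([41, 44, 47, 51, 53, 56, 58, 61, 63, 66, 68, 39.0])
        vals = np.arange(12.0)
        brackets = [(40, 50), (50, 55), (55, 60), (60, 65), (65, 70)]
        summaries, unassigned = stratify_age(_scores(vals), age, brackets)
        frame = pd.DataFrame({"age": age, "v": vals})
        for s in summaries:
            lo, hi = s.bracket
            grp = frame[(frame.age >= lo) & (frame.age < hi)]["v"]
            assert s.n == len(grp)
            if len(grp):
                assert s.mean_score[0] == pytest.approx(grp.mean())
        assert unassigned == 1  # age 39 outside all brackets

    def test_count_conservation(self):
        rng = np.random.default_rng(10)
        age = rng.uniform(30, 80, 200)
        summaries, unassigned = stratify_age(
            _scores(rng.standard_normal(200)), age,
            [(40, 50), (50, 55), (55, 60), (60, 65), (65, 70)],
        )
        assert sum(s.n for s in summaries) + unassigned == 200

    def test_overlapping_brackets_rejected(self):
        with pytest.raises(ValueError):
            stratify_age(_scores(np.arange(4.0)), np.arange(4.0), [(0, 5), (4, 8)])

    def test_bracket_table_long_format(self):
        vals = np.random.default_rng(11).standard_normal((20, 2))
        age = np.linspace(40, 69, 20)
        summaries, _ = stratify_age(_scores(vals), age, [(40, 55), (55, 70)])
        tbl = bracket_table(summaries)
        assert set(tbl.columns) == {"bracket", "component", "n", "mean_score", "sd_score"}
        assert len(tbl) == 4
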
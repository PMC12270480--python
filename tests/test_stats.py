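"""Statistical layer: gate, omnibus + post hocs, Brown-Forsythe, letters,
mixed model."""

import subprocess
from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from tunnelvision import (
    StatsDesign,
    TableEffects,
    compact_letter_display,
    fit_lmm,
    lmm_pairwise,
    omnibus_and_posthoc,
    pairwise_brown_forsythe,
    residual_normality_gate,
    simulate_metric_table,
)


class TestNormalityGate:
    def test_gaussian_residuals_choose_parametric(self):
        rng = np.random.default_rng(0)
        hits = sum(
            residual_normality_gate(
                rng.normal(size=200), np.repeat(["a", "b"], 100)
            )
            == "parametric"
            for _ in range(200)
        )
        assert hits >= 0.95 * 200 * 0.95  # alpha=0.05 gate: ~95% expected

    def test_exponential_residuals_choose_nonparametric(self):
        rng = np.random.default_rng(1)
        hits = sum(
            residual_normality_gate(
                rng.exponential(size=200), np.repeat(["a", "b"], 100)
            )
            == "nonparametric"
            for _ in range(200)
        )
        assert hits >= 190

    def test_tiny_group_rejected(self):
        with pytest.raises(ValueError):
            residual_normality_gate([1.0, 2.0, 3.0, 4.0, 5.0], ["a", "a", "b", "b", "b"])

    def test_constant_group_forces_nonparametric(self):
        with pytest.warns(UserWarning, match="constant"):
            choice = residual_normality_gate(
                [1.0, 1.0, 1.0, 0.3, 0.9, 0.5], np.repeat(["a", "b"], 3)
            )
        assert choice == "nonparametric"


class TestOmnibus:
    def test_identical_groups_share_one_letter(self):
        rng = np.random.default_rng(2)
        vals = np.tile(rng.normal(size=30), 3)
        groups = np.repeat(["a", "b", "c"], 30)
        for choice in ("parametric", "nonparametric"):
            res = omnibus_and_posthoc(vals, groups, choice=choice)
            assert set(res.letters.values()) == {"a"}

    def test_large_shift_detected_with_high_power(self):
        rng = np.random.default_rng(3)
        hits = 0
        for _ in range(200):
            a = rng.normal(0.0, 1.0, 30)
            b = rng.normal(3.0, 1.0, 30)  # 3 pooled sd apart
            res = omnibus_and_posthoc(
                np.r_[a, b], np.repeat(["a", "b"], 30), choice="parametric"
            )
            hits += res.p < 0.05
        assert hits >= 198

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            omnibus_and_posthoc(np.arange(10.0), ["a"] * 10, choice="parametric")

    def test_rank_anova_approximates_kruskal_wallis(self):
        # sanity link between the two paths: an ANOVA on rank-transformed
        # data should reach the same omnibus decision as Kruskal-Wallis
        from scipy import stats as sps

        rng = np.random.default_rng(4)
        agree = 0
        for _ in range(100):
            vals = rng.exponential(size=60) + np.repeat([0.0, 0.4, 0.0], 20)
            groups = np.repeat(["a", "b", "c"], 20)
            kw = omnibus_and_posthoc(vals, groups, choice="nonparametric")
            ranks = sps.rankdata(vals)
            f = sps.f_oneway(*(ranks[groups == g] for g in "abc"))
            agree += (kw.p < 0.05) == (f.pvalue < 0.05)
        assert agree >= 95


class TestBrownForsythe:
    def test_identical_groups_give_p_one(self):
        pmat, letters = pairwise_brown_forsythe(
            np.r_[np.ones(5), np.ones(5)], np.repeat(["a", "b"], 5)
        )
        assert pmat.loc["a", "b"] == 1.0
        assert letters["a"] == letters["b"]

    def test_undersized_group_rejected(self):
        with pytest.raises(ValueError):
            pairwise_brown_forsythe([1.0, 2.0, 3.0], ["a", "a", "b"])

    def test_variance_ratio_detected(self):
        rng = np.random.default_rng(5)
        vals = np.r_[rng.normal(0, 1, 50), rng.normal(0, 3, 50)]
        pmat, letters = pairwise_brown_forsythe(vals, np.repeat(["a", "b"], 50))
        assert pmat.loc["a", "b"] < 0.05
        assert letters["a"] != letters["b"]

    def test_holm_adjustment_is_conservative(self):
        rng = np.random.default_rng(6)
        vals = rng.normal(size=90)
        groups = np.repeat(["a", "b", "c"], 30)
        raw, _ = pairwise_brown_forsythe(vals, groups)
        adj, _ = pairwise_brown_forsythe(vals, groups, adjust="holm")
        for i, j in combinations("abc", 2):
            assert adj.loc[i, j] >= raw.loc[i, j] - 1e-12


def brute_force_letter_sets(names, pmat, alpha):
    """Oracle: maximal cliques of the non-significance graph, by enumeration."""
    def compatible(subset):
        return all(pmat.loc[a, b] >= alpha for a, b in combinations(subset, 2))

    cliques = []
    for r in range(1, len(names) + 1):
        for sub in combinations(names, r):
            if compatible(sub):
                cliques.append(frozenset(sub))
    return {c for c in cliques if not any(c < d for d in cliques)}


class TestCompactLetters:
    def make_p(self, names, sig_pairs):
        p = pd.DataFrame(1.0, index=names, columns=names)
        for a, b in sig_pairs:
            p.loc[a, b] = p.loc[b, a] = 0.001
        return p

    def test_no_differences_single_letter(self):
        letters = compact_letter_display(self.make_p(list("abc"), []))
        assert set(letters.values()) == {"a"}

    def test_all_different_three_letters(self):
        p = self.make_p(list("ABC"), [("A", "B"), ("A", "C"), ("B", "C")])
        letters = compact_letter_display(p)
        assert sorted(letters.values()) == ["a", "b", "c"]

    def test_chain_pattern(self):
        p = self.make_p(list("ABC"), [("A", "C")])
        assert compact_letter_display(p) == {"A": "a", "B": "ab", "C": "b"}

    def test_asymmetric_matrix_rejected(self):
        p = self.make_p(list("AB"), [])
        p.iloc[0, 1] = 0.01
        with pytest.raises(ValueError, match="symmetric"):
            compact_letter_display(p)

    @pytest.mark.parametrize("seed", range(12))
    def test_matches_maximal_clique_oracle_on_four_groups(self, seed):
        rng = np.random.default_rng(seed)
        names = list("ABCD")
        p = pd.DataFrame(1.0, index=names, columns=names)
        for a, b in combinations(names, 2):
            p.loc[a, b] = p.loc[b, a] = rng.choice([0.001, 0.5])
        letters = compact_letter_display(p, alpha=0.05)
        produced = {
            frozenset(g for g in names if ch in letters[g])
            for ch in set("".join(letters.values()))
        }
        assert produced == brute_force_letter_sets(names, p, 0.05)

    def test_letters_independent_of_input_order(self):
        p = self.make_p(list("ABC"), [("A", "C")])
        shuffled = p.loc[["C", "A", "B"], ["C", "A", "B"]]
        assert compact_letter_display(p) == compact_letter_display(shuffled)


@pytest.fixture(scope="module")
def lmm_fit():
    design = StatsDesign()
    effects = TableEffects(
        grand_mean=2.0,
        habitat={"open": 1.0, "closed": -0.5},
        quadrant={"ventral": 1.5, "dorsal": -1.0},
        sd_scene=0.5,
        sd_residual=1.0,
    )
    table = simulate_metric_table(design, effects, n_per_cell=6, seed=17)
    return design, table, fit_lmm(table, design)


class TestLmm:
    def test_full_model_preferred_under_real_effects(self, lmm_fit):
        _, _, lmm = lmm_fit
        assert lmm.full_model_preferred
        assert lmm.model_aics["full"] < lmm.model_aics["null"]
        assert lmm.model_deviances["full"] < lmm.model_deviances["null"]

    def test_variance_components_recovered_roughly(self, lmm_fit):
        _, _, lmm = lmm_fit
        assert 0.0 <= lmm.scene_variance < 2.0
        assert lmm.residual_variance == pytest.approx(1.0, abs=0.4)

    def test_single_scene_rejected(self):
        design = StatsDesign()
        table = simulate_metric_table(
            design, TableEffects(), n_per_cell=3, seed=0, n_scenes_per_habitat=1
        )
        with pytest.raises(ValueError, match="scenes"):
            fit_lmm(table, design)

    def test_incomplete_crossing_rejected(self):
        design = StatsDesign()
        table = simulate_metric_table(design, TableEffects(), n_per_cell=3, seed=0)
        table = table[~((table.habitat == "open") & (table.quadrant == "dorsal"))]
        with pytest.raises(ValueError, match="crossing"):
            fit_lmm(table, design)

    def test_matches_lme4_maximum_likelihood_fit(self, lmm_fit, tmp_path):
        # independent cross-check against R's lme4 on the identical table
        _, table, lmm = lmm_fit
        csv = tmp_path / "table.csv"
        table.to_csv(csv, index=False)
        script = f"""
        suppressMessages(library(lme4))
        tab <- read.csv("{csv}")
        m <- lmer(magnitude ~ C(habitat)*C(quadrant) + (1|scene), data=tab, REML=FALSE)
        cat(as.numeric(logLik(m)), AIC(m), sep="\\n")
        """
        out = subprocess.run(
            ["Rscript", "-"], input=script, capture_output=True, text=True
        )
        assert out.returncode == 0, out.stderr
        r_llf, r_aic = (float(x) for x in out.stdout.split())
        assert lmm.llf == pytest.approx(r_llf, abs=0.01)
        assert lmm.aic == pytest.approx(r_aic, abs=0.05)

    def test_pairwise_detects_strong_quadrant_contrast(self, lmm_fit):
        _, _, lmm = lmm_fit
        pw = lmm_pairwise(lmm)
        row = pw.query(
            "factor == 'quadrant' and level_a == 'ventral' and level_b == 'dorsal'"
        ).iloc[0]
        assert row["p_tukey"] < 0.001
        assert row["stars"] == "***"
        assert row["estimate"] == pytest.approx(2.5, abs=1.0)

    def test_single_level_margin_rejected(self, lmm_fit):
        design, table, lmm = lmm_fit
        sub = table[table.habitat == "open"]
        with pytest.raises(ValueError):
            lmm_pairwise(
                type(lmm)(
                    **{**lmm.__dict__, "table": sub}
                )
            )
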
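"""Activation scoring and significance testing against the control set."""

import io

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from perturbstress import (
    PathwayActivation,
    activation_score,
    omnibus_test,
    parse_gmt,
    pathway_pvalue,
)
from perturbstress.genesets import GeneSet
from perturbstress.scoring import (
    brown_forsythe_pvalue,
    welch_anova_pvalue,
    welch_t_pvalue,
)
from tests.conftest import (
    make_matrix,
    oracle_brown_forsythe,
    oracle_welch_anova,
    oracle_welch_t,
)


def two_set_collection(n_set=3, n_control=3):
    genes_set = "\t".join(f"S{i}" for i in range(n_set))
    genes_ctrl = "\t".join(f"C{i}" for i in range(n_control))
    return parse_gmt(
        io.StringIO(f"ISR\ts\t{genes_set}\nCONTROL\ts\t{genes_ctrl}\n")
    )


class TestActivationScore:
    def test_zero_z_gives_zero_score(self):
        m = make_matrix(np.zeros((1, 6)), genes=["S0", "S1", "S2", "C0", "C1", "C2"])
        s = GeneSet("ISR", "ISR", ("S0", "S1", "S2"))
        assert activation_score(m, s, "P0") == 0.0

    def test_forced_arithmetic_mean(self):
        m = make_matrix([[1.0, 2.0, 3.0, 9.0]], genes=["A", "B", "C", "X"])
        s = GeneSet("ISR", "ISR", ("A", "B", "C"))
        assert activation_score(m, s, "P0") == pytest.approx(2.0, abs=1e-15)

    def test_invariant_to_gene_order_and_outside_genes(self):
        rng = np.random.default_rng(3)
        z = rng.standard_normal((1, 6))
        m = make_matrix(z, genes=["A", "B", "C", "X", "Y", "Z"])
        s1 = GeneSet("S", "custom", ("A", "B", "C"))
        s2 = GeneSet("S", "custom", ("C", "A", "B"))
        assert activation_score(m, s1, "P0") == pytest.approx(
            activation_score(m, s2, "P0"), abs=1e-15
        )
        z2 = z.copy()
        z2[0, 3:] += 100.0  # outside-set genes irrelevant
        m2 = make_matrix(z2, genes=["A", "B", "C", "X", "Y", "Z"])
        assert activation_score(m2, s1, "P0") == activation_score(m, s1, "P0")

    @settings(max_examples=50, deadline=None)
    @given(
        delta=st.floats(-5, 5, allow_nan=False),
        z=st.lists(st.floats(-3, 3, width=32), min_size=3, max_size=8),
    )
    def test_location_equivariance(self, delta, z):
        genes = [f"G{i}" for i in range(len(z))]
        s = GeneSet("S", "custom", tuple(genes))
        base = activation_score(make_matrix([z], genes=genes), s, "P0")
        shifted = activation_score(
            make_matrix([[v + delta for v in z]], genes=genes), s, "P0"
        )
        assert shifted == pytest.approx(base + delta, abs=1e-9)

    def test_planted_shift_recovered(self):
        # 500 perturbations, delta=1.0 planted on a 13-gene set, unit noise:
        # mean of scores within 4*(1/sqrt(13))/sqrt(500) of 1.0
        rng = np.random.default_rng(11)
        n_pert, n_set = 500, 13
        z = rng.standard_normal((n_pert, 30))
        z[:, :n_set] += 1.0
        genes = [f"G{i}" for i in range(30)]
        m = make_matrix(z, genes=genes, perts=[f"P{i}" for i in range(n_pert)])
        s = GeneSet("ISR", "ISR", tuple(genes[:n_set]))
        scores = [activation_score(m, s, p) for p in m.perturbations]
        tol = 4 * (1 / np.sqrt(n_set)) / np.sqrt(n_pert)
        assert np.mean(scores) == pytest.approx(1.0, abs=tol)


class TestWelchAndBrownForsythe:
    def test_identical_groups_p_one(self):
        vals = [0.3, -1.2, 0.8, 1.5, -0.4]
        coll = two_set_collection(5, 5)
        m = make_matrix(
            [vals + vals], genes=list(coll["ISR"].genes) + list(coll.control.genes)
        )
        p, bf_p = pathway_pvalue(m, coll["ISR"], coll.control, "P0")
        assert p == pytest.approx(1.0, abs=1e-12)
        assert bf_p == pytest.approx(1.0, abs=1e-12)

    def test_welch_matches_textbook_formula(self):
        rng = np.random.default_rng(5)
        a = rng.normal(1.5, 1.0, 13)
        b = rng.normal(0.0, 1.0, 19)
        _, p_oracle = oracle_welch_t(a, b)
        assert welch_t_pvalue(a, b) == pytest.approx(p_oracle, abs=1e-10)

    def test_brown_forsythe_matches_textbook_formula(self):
        rng = np.random.default_rng(6)
        a = rng.normal(0, 2.0, 13)
        b = rng.normal(0, 1.0, 19)
        _, p_oracle = oracle_brown_forsythe([a, b])
        assert brown_forsythe_pvalue(a, b) == pytest.approx(p_oracle, abs=1e-10)

    @pytest.mark.parametrize(
        "a, b, expected",
        [([1.0, 1.0, 1.0], [1.0, 1.0], 1.0), ([1.0, 1.0, 1.0], [2.0, 2.0], 0.0)],
    )
    def test_degenerate_constant_groups(self, a, b, expected):
        assert welch_t_pvalue(a, b) == expected

    def test_null_calibration_quick(self):
        # 400 null perturbations; type-I error near alpha (see the
        # acceptance suite for the full 1000-perturbation run)
        rng = np.random.default_rng(12)
        hits = 0
        n = 400
        for _ in range(n):
            p = welch_t_pvalue(rng.standard_normal(13), rng.standard_normal(19))
            hits += p < 0.05
        se = np.sqrt(0.05 * 0.95 / n)
        assert hits / n == pytest.approx(0.05, abs=4 * se)


class TestOmnibus:
    def test_all_groups_identical_p_one(self):
        coll = two_set_collection(4, 4)
        vals = [0.5, -0.5, 1.0, -1.0]
        m = make_matrix([vals + vals], genes=list(coll["ISR"].genes) + list(coll.control.genes))
        res = omnibus_test(m, coll, "P0")
        assert res.welch_anova_p == pytest.approx(1.0, abs=1e-10)

    def test_welch_anova_matches_1951_formula(self):
        rng = np.random.default_rng(8)
        groups = {
            "a": rng.normal(0, 1, 10),
            "b": rng.normal(0.8, 1.5, 14),
            "c": rng.normal(-0.3, 0.7, 12),
        }
        f, p = welch_anova_pvalue(groups)
        f_o, p_o = oracle_welch_anova(groups.values())
        assert f == pytest.approx(f_o, abs=1e-10)
        assert p == pytest.approx(p_o, abs=1e-10)

    def test_two_group_reduces_to_welch_t(self):
        rng = np.random.default_rng(9)
        a, b = rng.normal(0.5, 1, 13), rng.normal(0, 1.3, 19)
        f, p_anova = welch_anova_pvalue({"a": a, "b": b})
        t, p_t = oracle_welch_t(a, b)
        assert f == pytest.approx(t**2, abs=1e-8)
        assert p_anova == pytest.approx(p_t, abs=1e-10)

    def test_posthoc_flags_control_contrasts(self):
        rng = np.random.default_rng(10)
        genes, z = [], []
        coll = parse_gmt(
            io.StringIO(
                "ISR\ts\t" + "\t".join(f"S{i}" for i in range(6)) + "\n"
                "OSR\ts\t" + "\t".join(f"O{i}" for i in range(6)) + "\n"
                "CONTROL\ts\t" + "\t".join(f"C{i}" for i in range(6)) + "\n"
            )
        )
        z = np.concatenate(
            [rng.normal(2, 1, 6), rng.normal(0, 1, 6), rng.normal(0, 1, 6)]
        )
        m = make_matrix([z], genes=[f"S{i}" for i in range(6)]
                        + [f"O{i}" for i in range(6)] + [f"C{i}" for i in range(6)])
        res = omnibus_test(m, coll, "P0")
        vs_control = res.posthoc[res.posthoc["vs_control"]]
        assert len(vs_control) == 2  # ISR-control, OSR-control
        isr_row = vs_control[(vs_control[["A", "B"]] == "ISR").any(axis=1)]
        osr_row = vs_control[(vs_control[["A", "B"]] == "OSR").any(axis=1)]
        assert float(isr_row["pval"].iloc[0]) < float(osr_row["pval"].iloc[0])


class TestActivationModel:
    def test_empty_perturbation_list_gives_empty_table(self, small_study, study_panels):
        _, matrix, _ = small_study
        res = PathwayActivation(matrix, study_panels).fit(perturbations=[])
        assert len(res.table) == 0
        assert list(res.table.columns[:9]) == [
            "perturbation", "target_gene", "pathway", "score", "n_genes_used",
            "p_value", "bf_p_value", "neg_log10_p", "significant",
        ]

    def test_one_row_per_pert_pathway_pair(self, small_study, study_panels):
        _, matrix, _ = small_study
        res = PathwayActivation(matrix, study_panels).fit()
        assert len(res.table) == matrix.shape[0] * 4
        assert not res.table.duplicated(["perturbation", "pathway"]).any()

    def test_score_column_is_exact_set_mean(self, small_study, study_panels):
        _, matrix, _ = small_study
        res = PathwayActivation(matrix, study_panels).fit(
            perturbations=matrix.perturbations[:5]
        )
        for _, row in res.table.iterrows():
            expected = matrix.set_values(
                row["perturbation"], study_panels[row["pathway"]].genes
            ).mean()
            assert row["score"] == pytest.approx(expected, abs=1e-12)

    def test_mito_like_class_selective_for_isr(self, small_study, study_panels):
        _, matrix, truth = small_study
        mito = truth[truth["class"] == "mito_like"].index
        res = PathwayActivation(matrix, study_panels).fit(perturbations=list(mito))
        t = res.table
        isr_rate = t[t["pathway"] == "ISR"]["significant"].mean()
        assert isr_rate >= 0.75
        for other in ("UPR", "HSR", "OSR"):
            assert t[t["pathway"] == other]["significant"].mean() <= 0.25

    def test_er_like_calls_upr_above_isr_above_null(self, small_study, study_panels):
        _, matrix, truth = small_study
        er = truth[truth["class"] == "er_like"].index
        null = truth[truth["class"] == "null"].index
        model = PathwayActivation(matrix, study_panels)
        t_er = model.fit(perturbations=list(er)).table
        t_null = model.fit(perturbations=list(null)).table
        upr = t_er[t_er["pathway"] == "UPR"]["significant"].mean()
        isr = t_er[t_er["pathway"] == "ISR"]["significant"].mean()
        null_isr = t_null[t_null["pathway"] == "ISR"]["significant"].mean()
        assert upr > isr
        assert isr >= null_isr

    def test_bh_adjustment_never_increases_significance(self, small_study, study_panels):
        _, matrix, _ = small_study
        raw = PathwayActivation(matrix, study_panels).fit()
        adj = PathwayActivation(matrix, study_panels, adjust="fdr_bh").fit()
        assert adj.table["significant"].sum() <= raw.table["significant"].sum()
        assert (adj.table["p_adjusted"] >= adj.table["p_value"] - 1e-15).all()

    def test_stars_tiers(self, small_study, study_panels):
        _, matrix, _ = small_study
        res = PathwayActivation(matrix, study_panels).fit()
        stars = res.stars()
        p = res.table["p_value"]
        assert (stars[p >= 0.05] == "").all()
        assert (stars[(p < 0.05) & (p >= 0.01)] == "*").all()
        assert (stars[p < 0.005] == "***").all()

    def test_summary_mentions_counts(self, small_study, study_panels):
        _, matrix, _ = small_study
        res = PathwayActivation(matrix, study_panels).fit()
        text = res.summary()
        assert "ISR" in text and "alpha" in text


class TestCorrelateKnockdown:
    def test_constant_scores_flagged_undefined(self, study_panels):
        rng = np.random.default_rng(13)
        genes = list(study_panels.all_genes)
        z = np.zeros((10, len(genes)))
        meta = pd.DataFrame(
            {"knockdown_fraction": rng.uniform(0.3, 0.9, 10)},
            index=[f"P{i}" for i in range(10)],
        )
        m = make_matrix(z, genes=genes, perts=[f"P{i}" for i in range(10)],
                        pert_meta=meta)
        res = PathwayActivation(m, study_panels).fit()
        corr = res.correlate_knockdown()
        assert corr["undefined"].all()

    def test_score_equals_knockdown_gives_r_one(self, study_panels):
        genes = list(study_panels.all_genes)
        kd = np.linspace(0.2, 0.9, 12)
        z = np.zeros((12, len(genes)))
        isr_cols = [genes.index(g) for g in study_panels["ISR"].genes]
        z[:, isr_cols] = kd[:, None]  # score == knockdown exactly
        meta = pd.DataFrame({"knockdown_fraction": kd},
                            index=[f"P{i}" for i in range(12)])
        m = make_matrix(z, genes=genes, perts=[f"P{i}" for i in range(12)],
                        pert_meta=meta)
        corr = PathwayActivation(m, study_panels).fit().correlate_knockdown()
        assert corr.loc["ISR", "r"] == pytest.approx(1.0, abs=1e-12)

    def test_independent_knockdown_gives_small_r(self, small_study, study_panels):
        _, matrix, _ = small_study
        corr = PathwayActivation(matrix, study_panels).fit().correlate_knockdown()
        ok = corr[~corr["undefined"]]
        assert (ok["r"].abs() < 0.35).all()  # small n; acceptance runs n=200

    def test_independence_holds_across_seeds_at_n200(self, study_panels):
        # scores built independently of knockdown: |r| < 0.2 for n = 200
        # in >= 95% of seeds
        genes = list(study_panels.all_genes)
        isr_cols = [genes.index(g) for g in study_panels["ISR"].genes]
        ok = 0
        n_seeds = 20
        for seed in range(n_seeds):
            rng = np.random.default_rng(3000 + seed)
            z = rng.standard_normal((200, len(genes)))
            z[:, isr_cols] += 1.0  # activation present, unrelated to kd
            meta = pd.DataFrame(
                {"knockdown_fraction": rng.beta(6, 2, 200)},
                index=[f"P{i}" for i in range(200)],
            )
            m = make_matrix(z, genes=genes,
                            perts=[f"P{i}" for i in range(200)], pert_meta=meta)
            corr = PathwayActivation(m, study_panels).fit().correlate_knockdown()
            ok += float(abs(corr.loc["ISR", "r"])) < 0.2
        assert ok / n_seeds >= 0.95

    def test_too_few_pairs_undefined(self, study_panels):
        genes = list(study_panels.all_genes)
        rng = np.random.default_rng(14)
        meta = pd.DataFrame(
            {"knockdown_fraction": [0.5, np.nan, np.nan, np.nan]},
            index=[f"P{i}" for i in range(4)],
        )
        m = make_matrix(rng.standard_normal((4, len(genes))), genes=genes,
                        perts=[f"P{i}" for i in range(4)], pert_meta=meta)
        corr = PathwayActivation(m, study_panels).fit().correlate_knockdown()
        assert corr["undefined"].all()
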
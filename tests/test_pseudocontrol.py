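"""Pseudocontrol construction and conditional-logistic estimation."""

import numpy as np
import pytest

import sibscore as sb
from sibscore.families import MISSING
from sibscore.pseudocontrol import (
    ConditionalLogit,
    MatchedDesign,
    MendelianError,
    SNPPredictor,
    ScorePredictor,
    build_design,
    build_pseudocontrols,
    fit_single_patterns,
)
from sibscore.qc import transmissible_counts

from conftest import make_trio


def _design_from_strata(strata) -> MatchedDesign:
    X = np.asarray(strata, dtype=float)[:, :, None]
    n = X.shape[0]
    return MatchedDesign(
        exog=X,
        predictor_names=["x"],
        case_sex=np.array(["male"] * n),
        family_ids=[f"F{i}" for i in range(n)],
        case_ids=[f"C{i}" for i in range(n)],
    )


class TestBuildPseudocontrols:
    @pytest.mark.parametrize(
        "f,m,c,expected_pcs",
        [
            (1, 1, 2, [1, 1, 0]),
            (2, 2, 2, [2, 2, 2]),
            (2, 0, 1, [1, 1, 1]),
            (1, 0, 1, [1, 0, 0]),
        ],
        ids=["hetxhet-caseAA", "homxhom", "homxother", "hetxother"],
    )
    def test_count_examples(self, panel1, f, m, c, expected_pcs):
        fam = make_trio(panel1, [f], [m], [c])
        pcs = build_pseudocontrols(fam, fam.children[0])
        assert pcs.counts[0, 0] == c
        assert sorted(pcs.counts[1:, 0]) == sorted(expected_pcs)

    def test_conservation_on_random_families(self, panel2):
        """Sum of the four slot counts equals twice the parental total at
        every SNP, over 10,000 random consistent families."""
        rng = np.random.default_rng(12345)
        for _ in range(10_000):
            f, m = rng.integers(0, 3, size=2)
            tf = rng.integers(0, 2) if f == 1 else f // 2
            tm = rng.integers(0, 2) if m == 1 else m // 2
            c = tf + tm
            fam = make_trio(panel2, [f, f], [m, m], [c, c])
            pcs = build_pseudocontrols(fam, fam.children[0])
            assert (pcs.counts.sum(axis=0) == 2 * (f + m)).all()
            assert c in transmissible_counts(f, m)

    def test_phase_ambiguity_multiset_invariant(self, panel1):
        """Both parents het, child het: the 4-outcome multiset is the same
        whichever parent is assigned the risk allele."""
        fam = make_trio(panel1, [1], [1], [1])
        pcs = build_pseudocontrols(fam, fam.children[0])
        # father-transmits convention: slots (1; 2,0,1); swap gives (1; 0,2,1)
        assert sorted(pcs.counts[:, 0]) == [0, 1, 1, 2]

    def test_inconsistent_case_refused(self, panel1):
        fam = make_trio(panel1, [2], [2], [1])
        with pytest.raises(MendelianError):
            build_pseudocontrols(fam, fam.children[0])

    def test_missing_genotype_marks_unusable(self, panel2):
        fam = make_trio(panel2, [1, MISSING], [1, 1], [1, 1])
        pcs = build_pseudocontrols(fam, fam.children[0])
        assert pcs.usable.tolist() == [True, False]


class TestBuildDesign:
    def test_one_stratum_per_affected_child(self, fixture_cohort):
        design = build_design(fixture_cohort, [SNPPredictor("rs7794745")])
        assert design.n_strata == fixture_cohort.n_affected_children

    def test_uninformative_stratum_retained(self, panel1):
        fam = make_trio(panel1, [2], [2], [2])
        cohort = sb.Cohort(families=[fam], panel=panel1)
        design = build_design(cohort, [SNPPredictor("rs1")])
        assert design.n_strata == 1

    def test_sex_filter_without_cases_errors(self, panel1):
        fam = make_trio(panel1, [1], [1], [1], child_sex="female")
        cohort = sb.Cohort(families=[fam], panel=panel1)
        with pytest.raises(ValueError, match="no usable strata"):
            build_design(cohort, [SNPPredictor("rs1")], sex_filter="male")

    def test_multiple_affected_sibs_share_parents(self, panel1):
        fam = make_trio(panel1, [1], [1], [1])
        sib = sb.Individual("F1", "F1_4", "F1_1", "F1_2", "female", "affected",
                            np.array([2], dtype=np.int8))
        fam.children.append(sib)
        cohort = sb.Cohort(families=[fam], panel=panel1)
        design = build_design(cohort, [SNPPredictor("rs1")])
        assert design.n_strata == 2
        assert design.family_ids == ["F1", "F1"]

    def test_missing_genotype_drops_stratum_with_count(self, panel2):
        ok = make_trio(panel2, [1, 1], [1, 1], [1, 1], family_id="F1")
        gap = make_trio(panel2, [1, MISSING], [1, 1], [1, 1], family_id="F2")
        cohort = sb.Cohort(families=[ok, gap], panel=panel2)
        design = build_design(cohort, [SNPPredictor("rs2")])
        assert design.n_strata == 1 and design.n_dropped == 1

    def test_long_format_export(self, panel1):
        fam = make_trio(panel1, [1], [1], [2])
        cohort = sb.Cohort(families=[fam], panel=panel1)
        df = build_design(cohort, [SNPPredictor("rs1")]).to_frame()
        assert list(df["member_role"]) == ["case", "pseudo1", "pseudo2", "pseudo3"]
        assert df["is_case"].sum() == 1


class TestConditionalLogit:
    def test_exact_grr_three(self):
        """Two het x het strata with cases AA and Aa: the score equation
        reduces to u^2 - 2u - 3 = 0, so GRR = 3 exactly."""
        design = _design_from_strata([[2, 1, 1, 0], [1, 2, 0, 1]])
        est = sb.fit_conditional_logistic(design)[0]
        assert est.grr == pytest.approx(3.0, abs=1e-9)
        assert est.converged and est.informative

    def test_uninformative_design_flagged(self):
        design = _design_from_strata([[2, 2, 2, 2], [0, 0, 0, 0]])
        est = sb.fit_conditional_logistic(design)[0]
        assert est.beta == 0.0 and not est.informative

    def test_homozygous_stratum_does_not_change_estimate(self):
        base = _design_from_strata([[2, 1, 1, 0], [1, 2, 0, 1]])
        padded = _design_from_strata([[2, 1, 1, 0], [1, 2, 0, 1], [2, 2, 2, 2]])
        e1 = sb.fit_conditional_logistic(base)[0]
        e2 = sb.fit_conditional_logistic(padded)[0]
        assert e1.beta == pytest.approx(e2.beta, abs=1e-12)

    def test_positive_separation(self):
        """Case maximal in every informative stratum: beta -> +inf, reported
        as a positive divergence with an LR-based p-value."""
        design = _design_from_strata([[2, 1, 1, 0], [2, 0, 1, 1]])
        est = sb.fit_conditional_logistic(design)[0]
        assert est.diverged_positive and est.grr == np.inf
        assert est.risk_above_one
        assert 0.0 < est.p_value < 1.0

    def test_negative_separation(self):
        design = _design_from_strata([[0, 1, 1, 2], [0, 2, 1, 1]])
        est = sb.fit_conditional_logistic(design)[0]
        assert est.diverged_negative and est.grr == 0.0
        assert not est.risk_above_one

    def test_grid_search_oracle(self):
        """MLE agrees with an exhaustive grid search over beta in [-5, 5]
        (step 1e-4) on random small designs."""
        rng = np.random.default_rng(7)
        grid = np.arange(-5.0, 5.0 + 1e-9, 1e-4)
        for _ in range(4):
            strata = []
            while len(strata) < 12:
                row = rng.integers(0, 3, size=4)
                if np.ptp(row) > 0 and row[0] not in (row.max(), row.min()):
                    strata.append(row)
                elif np.ptp(row) > 0 and rng.random() < 0.3:
                    strata.append(row)
            design = _design_from_strata(strata)
            est = sb.fit_conditional_logistic(design)[0]
            if not np.isfinite(est.beta):
                continue
            X = design.exog[:, :, 0]
            eta = grid[:, None, None] * X[None, :, :]
            ll = eta[:, :, 0].sum(axis=1) - np.log(np.exp(eta).sum(axis=2)).sum(axis=1)
            beta_grid = grid[np.argmax(ll)]
            assert abs(est.beta - beta_grid) <= 2e-4

    def test_against_statsmodels(self, panel2):
        """Independent cross-check of coefficients and standard errors."""
        from statsmodels.discrete.conditional_models import ConditionalLogit as SMCL

        gm = np.array([1.6, 1.0])
        cfg = sb.SimulationConfig(
            n_families=120, panel=panel2, grr_male=gm, grr_female=gm, seed=77
        )
        cohort, _ = sb.simulate_cohort(cfg)
        design = build_design(cohort, [SNPPredictor("rs1"), SNPPredictor("rs2")])
        res = ConditionalLogit(design).fit()
        S = design.n_strata
        sm_res = SMCL(
            np.tile([1, 0, 0, 0], S),
            design.exog.reshape(-1, 2),
            groups=np.repeat(np.arange(S), 4),
        ).fit(disp=0)
        # statsmodels' BFGS stops at a looser gradient norm than our Newton
        np.testing.assert_allclose(res.params, sm_res.params, atol=1e-4)
        np.testing.assert_allclose(res.bse, sm_res.bse, atol=1e-4)

    def test_wald_pvalues_uniform_under_null(self, panel1):
        """Type-I error calibration: fraction of p < 0.05 within binomial
        bounds over replicated null designs."""
        rng = np.random.default_rng(42)
        rejections = 0
        n_rep = 1000
        for _ in range(n_rep):
            # 60 informative het x het strata; transmissions fair coin flips
            tf = rng.integers(0, 2, size=(60, 2))
            strata = []
            for a, b in tf:
                c = a + b
                # slots (T,T), (T,U), (U,T), (U,U)
                strata.append([a + b, a + (1 - b), (1 - a) + b, (1 - a) + (1 - b)])
            est = sb.fit_conditional_logistic(_design_from_strata(strata))[0]
            if est.p_value < 0.05:
                rejections += 1
        assert 0.03 <= rejections / n_rep <= 0.07

    def test_summary_table(self):
        design = _design_from_strata([[2, 1, 1, 0], [1, 2, 0, 1]])
        res = ConditionalLogit(design).fit()
        df = res.summary()
        assert list(df["predictor"]) == ["x"]
        assert df.attrs["n_strata"] == 2
        assert res.lr_pvalue == df.attrs["lr_pvalue"]


class TestScalarPatternFit:
    def test_weighted_equals_replicated(self):
        pats = np.array([[2.0, 1, 1, 0], [1, 2, 0, 1]])
        w = np.array([3.0, 2.0])
        rep = np.repeat(pats, [3, 2], axis=0)
        f1 = fit_single_patterns(pats, w)
        f2 = fit_single_patterns(rep, np.ones(5))
        assert f1.beta == pytest.approx(f2.beta, abs=1e-10)
        assert f1.llf == pytest.approx(f2.llf, abs=1e-9)


class TestJointScoreModel:
    def test_parameter_order_recovered(self, fixture_cohort):
        """With female-specific effects simulated much larger than male ones,
        the joint fit ranks beta_female above beta_male."""
        part = sb.SNPPartition(
            shared=["rs7794745", "rs1861972", "rs7766973"],
            male_specific=["rs2278556", "rs6872664", "rs10951154"],
            female_specific=["rs12410279", "rs5918"],
            excluded=["rs2292813", "rs2235076"],
        )
        fit = sb.fit_joint_score_model(fixture_cohort, part)
        assert fit.grr_female.beta > fit.grr_male.beta
        assert fit.grr_all.grr > 1.0
        assert fit.overall_p < 0.01

    def test_all_male_cohort_female_noninformative(self, panel2):
        gm = np.array([1.3, 1.3])
        cfg = sb.SimulationConfig(
            n_families=80, panel=panel2, grr_male=gm, grr_female=gm,
            prob_male_child=1.0, seed=5,
        )
        cohort, _ = sb.simulate_cohort(cfg)
        part = sb.SNPPartition(shared=["rs1"], male_specific=[], female_specific=["rs2"],
                               excluded=[])
        fit = sb.fit_joint_score_model(cohort, part)
        assert not fit.grr_female.informative
        assert fit.grr_all.informative
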
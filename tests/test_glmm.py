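"""Binomial random-intercept GLMM: recovery, reduction, oracles."""

import json
import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest

from parentese.glmm import (
    RESPONSE_COLUMNS,
    build_response_dataset,
    design_matrix,
    fit_glmm,
    fit_glmm_all_responses,
    parentese_trend,
    posthoc_suite,
    simulate_records,
    vocal_event_table,
)
from parentese.interactions import extract_bigrams
from parentese.synth import StudyDesign, synth_interaction_study


@pytest.fixture(scope="module")
def response_records(study):
    logs, _ = study
    bigrams = [b for log in logs for b in extract_bigrams(log)]
    return build_response_dataset(logs, bigrams)


class TestDataset:
    def test_one_record_per_vocalisation_with_or_semantics(self, study, response_records):
        logs, gt = study
        n_voc = sum(1 for log in logs for e in log.vocal_events()
                    if e.speaker in ("mother", "father"))
        assert len(response_records) == n_voc
        rec = response_records
        people = rec[list(RESPONSE_COLUMNS[2:])].drop(columns="toward_object")
        assert (rec["toward_people"] == people.max(axis=1)).all()
        assert (rec["any"] == rec[["toward_people", "toward_object"]].max(axis=1)).all()

    def test_no_response_vocalisation_is_all_zero(self):
        design = StudyDesign(
            n_children_per_group=2, scenes_per_semester=1,
            response_probability={k: 0.0 for k in StudyDesign().response_probability},
            random_seed=3,
        )
        logs, _ = synth_interaction_study(design)
        bigrams = [b for log in logs for b in extract_bigrams(log)]
        rec = build_response_dataset(logs, bigrams)
        assert (rec[list(RESPONSE_COLUMNS)] == 0).all().all()

    def test_cellwise_rates_match_design(self, study, response_records):
        _, gt = study
        design = gt["design"]
        sub = response_records.query(
            "group == 'TD' and semester == 'S2' and speaker == 'mother' "
            "and speech_type == 'parentese'"
        )
        p = design.response_probability[("TD", "S2", "mother", "parentese", "receptive")]
        n = len(sub)
        assert n > 50
        se = np.sqrt(p * (1 - p) / n)
        assert abs(sub["receptive"].mean() - p) <= 3.5 * se

    def test_other_speakers_excluded_by_default(self, response_records):
        assert set(response_records["speaker"]) == {"mother", "father"}


class TestDesignMatrix:
    def test_successive_difference_contrasts(self):
        df = pd.DataFrame({"semester": ["S1", "S2", "S3"]})
        X, names = design_matrix(df, ("semester",))
        # difference of consecutive rows isolates each successive contrast
        assert np.allclose(X[1] - X[0], [0, 1, 0])
        assert np.allclose(X[2] - X[1], [0, 0, 1])
        assert names == ["intercept", "sem2_vs_sem1", "sem3_vs_sem2"]

    def test_single_level_factor_inestimable(self):
        df = pd.DataFrame({"semester": ["S1", "S1"], "response": [0, 1]})
        with pytest.raises(ValueError, match="inestimable"):
            design_matrix(df, ("semester",))


class TestFitGlmm:
    def test_parameter_recovery_speech_type_effect(self):
        """True parentese log-odds +0.5, n=2000, 20 children."""
        ests = []
        for rep in range(5):
            df = simulate_records(2000, 20, {"parentese_vs_other": 0.5},
                                  re_sd=0.5, seed=100 + rep)
            ests.append(fit_glmm(df, response="response")["parentese_vs_other"].estimate)
        assert abs(np.mean(ests) - 0.5) < 0.1

    def test_reduces_to_logistic_when_variance_is_zero(self):
        import statsmodels.api as sm

        df = simulate_records(1500, 15, {"parentese_vs_other": 0.4}, re_sd=0.0, seed=9)
        fit = fit_glmm(df, response="response")
        assert fit.re_sd < 0.05
        X, names = design_matrix(df, ("semester", "group", "speaker", "speech_type"))
        logit = sm.GLM(df["response"], X, family=sm.families.Binomial()).fit()
        assert np.allclose(fit.table["estimate"].to_numpy(), logit.params, atol=1e-3)

    def test_matches_lme4_glmer_oracle(self, tmp_path):
        """Independent oracle: lme4::glmer with the same AGQ rule."""
        if shutil.which("Rscript") is None:
            pytest.skip("Rscript unavailable")
        df = simulate_records(600, 10, {"parentese_vs_other": 0.5}, re_sd=0.6, seed=4)
        fit = fit_glmm(df, response="response")
        X, names = design_matrix(df, ("semester", "group", "speaker", "speech_type"))
        d = pd.DataFrame(X[:, 1:], columns=names[1:])
        d["y"] = df["response"].to_numpy()
        d["child"] = df["child_id"].to_numpy()
        csv = tmp_path / "d.csv"
        d.to_csv(csv, index=False)
        rcode = f"""
        suppressMessages(library(lme4))
        d <- read.csv("{csv}")
        m <- glmer(y ~ {' + '.join(names[1:])} + (1|child),
                   data=d, family=binomial, nAGQ=15)
        out <- list(beta=unname(fixef(m)), se=unname(coef(summary(m))[,2]),
                    sd=unname(sqrt(unlist(VarCorr(m)))))
        cat(jsonlite::toJSON(out, digits=10))
        """
        res = subprocess.run(["Rscript", "-e", rcode], capture_output=True, text=True)
        assert res.returncode == 0, res.stderr
        ref = json.loads(res.stdout)
        assert np.allclose(fit.table["estimate"].to_numpy(), ref["beta"], atol=2e-3)
        assert np.allclose(fit.table["se"].to_numpy(), ref["se"], atol=2e-3)
        assert fit.re_sd == pytest.approx(ref["sd"][0], abs=0.02)

    def test_constant_response_rejected(self):
        df = simulate_records(200, 4, seed=0)
        df["response"] = 1
        with pytest.raises(ValueError):
            fit_glmm(df, response="response")

    def test_reported_table_has_reporting_shape(self, response_records):
        table = fit_glmm_all_responses(response_records.sample(2000, random_state=0))
        assert list(table.columns) == list(RESPONSE_COLUMNS)
        assert "sem2_vs_sem1" in table.index and "parentese_vs_other" in table.index


class TestPosthoc:
    def test_stratification_covers_each_cell_once(self, response_records):
        res = posthoc_suite(response_records, response="any")
        assert set(res["by_group"]) == {"AD", "TD"}
        assert set(res["by_group_semester"]) == {
            (g, s) for g in ("AD", "TD") for s in ("S1", "S2", "S3")
        }

    def test_empty_or_degenerate_stratum_reports_skip(self, response_records):
        crippled = response_records.copy()
        crippled.loc[crippled.group == "AD", "any"] = 1  # constant in stratum
        res = posthoc_suite(crippled, response="any")
        assert isinstance(res["by_group"]["AD"], dict)
        assert "skipped" in res["by_group"]["AD"]

    def test_recovers_positive_father_effect_in_stratum(self):
        """Father effect on inter-subjective responses planted at +1.0
        (mothers suppressed): recovered sign is positive in the AD stratum."""
        base = StudyDesign().response_probability
        probs = dict(base)
        for (g, s, sp, st, m) in list(probs):
            if m == "inter_subjective":
                probs[(g, s, sp, st, m)] = 0.20 if sp == "father" else 0.08
        design = StudyDesign(n_children_per_group=10, response_probability=probs,
                             random_seed=21)
        logs, _ = synth_interaction_study(design)
        bigrams = [b for log in logs for b in extract_bigrams(log)]
        rec = build_response_dataset(logs, bigrams)
        res = posthoc_suite(rec, response="inter_subjective")
        fit = res["by_group"]["AD"]
        assert fit["speaker_mother_vs_father"].estimate < 0  # mothers below fathers


class TestParenteseTrend:
    def test_declining_design_gives_negative_contrasts(self, study):
        logs, _ = study
        fit = parentese_trend(vocal_event_table(logs))
        assert fit["sem2_vs_sem1"].estimate < 0
        assert fit["sem3_vs_sem2"].estimate < 0
        assert fit["sem2_vs_sem1"].p < 0.05

    def test_flat_design_rarely_significant(self):
        """Constant parentese proportion: successive contrasts stay null."""
        rejections = 0
        for rep in range(10):
            props = {(g, s, sp): 0.4 for g in ("AD", "TD")
                     for s in ("S1", "S2", "S3")
                     for sp in ("mother", "father", "other")}
            design = StudyDesign(n_children_per_group=6, scenes_per_semester=1,
                                 parentese_proportion=props, p_regulation_up=0.0,
                                 random_seed=500 + rep)
            logs, _ = synth_interaction_study(design)
            fit = parentese_trend(vocal_event_table(logs))
            rejections += int(fit["sem2_vs_sem1"].p < 0.05)
            rejections += int(fit["sem3_vs_sem2"].p < 0.05)
        assert rejections <= 3  # 20 null tests at alpha = 0.05

    def test_single_semester_inestimable(self):
        df = pd.DataFrame({
            "child_id": ["a", "a", "b", "b"], "semester": ["S1"] * 4,
            "group": ["AD", "AD", "TD", "TD"], "speaker": ["mother"] * 4,
            "parentese": [0, 1, 0, 1],
        })
        with pytest.raises(ValueError, match="inestimable"):
            parentese_trend(df)
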
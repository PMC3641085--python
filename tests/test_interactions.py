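"""Bi-gram extraction, count tables and parentese proportions."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from parentese.events import BehaviorEvent, InteractionLog, MetaBehaviorMap
from parentese.interactions import (
    CountTable,
    extract_bigrams,
    parentese_proportions,
    response_margins,
    tag_vocalisations,
)

MAP = MetaBehaviorMap.default()
CG_CODES = sorted(MAP.caregiver)
INF_CODES = sorted(MAP.infant)


def _log(events, duration=60.0, **kwargs):
    defaults = dict(child_id="c1", group="TD", semester="S1", scene_id="sc")
    defaults.update(kwargs)
    return InteractionLog(duration_s=duration, events=events, **defaults)


def _cg(t, code="cg_vocalisation", **kw):
    kw.setdefault("speaker", "mother")
    if code == "cg_vocalisation":
        kw.setdefault("speech_type", "parentese")
    return BehaviorEvent(t, "caregiver", code, **kw)


def _inf(t, code="inf_looks_person"):
    return BehaviorEvent(t, "infant", code)


class TestExtractBigrams:
    def test_window_inclusive_both_ends(self):
        log = _log([_cg(10), _inf(10), _inf(12), _inf(13), _inf(14)])
        bigrams = extract_bigrams(log)
        assert [b.lag_s for b in bigrams] == [0, 2, 3]  # lag 4 excluded

    def test_no_infant_events(self):
        assert extract_bigrams(_log([_cg(5), _cg(9)])) == []

    def test_all_pairs_semantics(self):
        log = _log([_cg(10), _cg(11), _inf(12)])
        bigrams = extract_bigrams(log)
        assert len(bigrams) == 2
        assert [b.cg_event.time_s for b in bigrams] == [10, 11]

    def test_nearest_pairing_option(self):
        log = _log([_cg(10), _cg(11), _inf(12)])
        bigrams = extract_bigrams(log, pairing="nearest")
        assert len(bigrams) == 1
        assert bigrams[0].cg_event.time_s == 11

    def test_state_event_anchors_at_start(self):
        log = _log([_cg(10, code="cg_reg_up", kind="state", end_time_s=20), _inf(12), _inf(15)])
        bigrams = extract_bigrams(log)
        assert [b.lag_s for b in bigrams] == [2]  # t=15 is 5 s past the start

    def test_unmapped_code_raises(self):
        log = _log([_cg(10), BehaviorEvent(11, "infant", "inf_mystery")])
        with pytest.raises(KeyError):
            extract_bigrams(log)

    def test_metas_and_context_attached(self):
        log = _log([_cg(10, code="cg_touch"), _inf(11, code="inf_vocalises")],
                   group="AD", semester="S3")
        (b,) = extract_bigrams(log)
        assert b.cg_meta == "touching"
        assert b.infant_meta == "expressive"
        assert (b.group, b.semester, b.child_id) == ("AD", "S3", "c1")


@st.composite
def random_logs(draw):
    n_cg = draw(st.integers(0, 8))
    n_inf = draw(st.integers(0, 8))
    events = [
        _cg(float(draw(st.integers(0, 30))), code=draw(st.sampled_from(CG_CODES)),
            speech_type="none")
        for _ in range(n_cg)
    ] + [_inf(float(draw(st.integers(0, 30))), code=draw(st.sampled_from(INF_CODES)))
         for _ in range(n_inf)]
    # states need an interval
    events = [
        e if e.code not in ("cg_reg_up", "cg_reg_down")
        else BehaviorEvent(e.time_s, "caregiver", e.code, kind="state",
                           end_time_s=e.time_s + 2, speaker=e.speaker)
        for e in events
    ]
    return _log(events)


def _brute_force(log, window=3.0):
    """Independent oracle: double loop over all caregiver x infant pairs."""
    pairs = []
    for c in log.events:
        if c.actor != "caregiver":
            continue
        for i in log.events:
            if i.actor != "infant":
                continue
            lag = i.time_s - c.time_s
            if 0 <= lag <= window:
                pairs.append((c.time_s, i.time_s, c.code, i.code))
    return sorted(pairs)


class TestOracleEquivalence:
    @given(random_logs())
    @settings(derandomize=True, max_examples=200)
    def test_matches_brute_force_all_pairs(self, log):
        got = sorted(
            (b.cg_event.time_s, b.infant_event.time_s, b.cg_event.code, b.infant_event.code)
            for b in extract_bigrams(log)
        )
        assert got == _brute_force(log)

    @given(random_logs())
    @settings(derandomize=True, max_examples=100)
    def test_lag_bounds_respected(self, log):
        for b in extract_bigrams(log):
            assert 0 <= b.lag_s <= 3

    def test_invariant_under_event_permutation(self, rng):
        events = [_cg(float(t), speech_type="none") for t in rng.integers(0, 30, 6)]
        events += [_inf(float(t)) for t in rng.integers(0, 30, 6)]
        perm = [events[i] for i in rng.permutation(len(events))]
        a = [(b.cg_event.time_s, b.infant_event.time_s) for b in extract_bigrams(_log(list(events)))]
        b_ = [(b.cg_event.time_s, b.infant_event.time_s) for b in extract_bigrams(_log(perm))]
        assert a == b_


class TestTagging:
    def test_all_parentese(self):
        log = _log([_cg(5, speech_type="none"), _cg(9, speech_type="none"), _cg(12, code="cg_touch")])
        tagged = tag_vocalisations(log, ["parentese", "parentese"])
        vocal = [e for e in tagged.events if e.code == "cg_vocalisation"]
        assert all(e.speech_type == "parentese" for e in vocal)
        touch = [e for e in tagged.events if e.code == "cg_touch"]
        assert touch[0].speech_type == "none"

    def test_empty_log(self):
        assert tag_vocalisations(_log([]), []).events == []

    def test_mixed_fixture_counts(self):
        events = [_cg(float(t), speech_type="none") for t in (2, 5, 9, 14)]
        events += [_cg(float(t), code="cg_touch") for t in (3, 7)]
        tagged = tag_vocalisations(_log(events), ["parentese", "other_speech"] * 2)
        assert sum(e.speech_type != "none" for e in tagged.events) == 4

    def test_label_count_mismatch(self):
        with pytest.raises(ValueError):
            tag_vocalisations(_log([_cg(5, speech_type="none")]), [])


class TestCountTable:
    def test_margin_identities_ad_s1_shape(self):
        counts = {"toward_object": 44, "receptive": 88, "expressive": 128,
                  "active": 13, "exploratory": 32, "inter_subjective": 10}
        m = response_margins(counts)
        assert m == {"toward_people": 271, "total": 315}

    def test_margin_identities_td_s2_shape(self):
        counts = {"toward_object": 167, "receptive": 154, "expressive": 253,
                  "active": 60, "exploratory": 76, "inter_subjective": 114}
        m = response_margins(counts)
        assert m == {"toward_people": 657, "total": 824}

    def test_all_zero_margins(self):
        assert response_margins({}) == {"toward_people": 0, "total": 0}

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError):
            response_margins({"receptive": -1})

    def test_table_margins_hold_on_synthetic_study(self, study):
        logs, _ = study
        bigrams = [b for log in logs for b in extract_bigrams(log)]
        table = CountTable.from_bigrams(bigrams, logs)
        wide = table.margins()
        from parentese.events import TOWARD_PEOPLE_METAS

        assert (wide["toward_people"] == wide[list(TOWARD_PEOPLE_METAS)].sum(axis=1)).all()
        assert (wide["total"] == wide["toward_people"] + wide["toward_object"]).all()
        assert (table.to_wide()["n_vocalisations"] > 0).all()

    def test_counts_match_ground_truth_linkage(self, study):
        """With vocalisation spacing wider than the window, extraction finds
        exactly the planted responses (restricted to vocal-solicitation
        bigrams; regulation-up states share anchors with their vocalisation)."""
        logs, gt = study
        bigrams = [
            b
            for log in logs
            for b in extract_bigrams(log)
            if b.cg_meta == "vocal_solicitation"
        ]
        assert len(bigrams) == len(gt["linkage"])
        got = sorted((b.scene_id, b.cg_event.time_s, b.infant_event.time_s, b.infant_meta)
                     for b in bigrams)
        want = sorted((r["scene_id"], r["cg_time_s"], r["infant_time_s"], r["infant_meta"])
                      for r in gt["linkage"])
        assert got == want


class TestProportions:
    def test_all_parentese(self):
        log = _log([_cg(5.0 + 2 * i) for i in range(4)])
        props = parentese_proportions([log])
        assert (props["proportion"] == 1.0).all()

    def test_fixture_arithmetic(self):
        events = [_cg(float(2 + i), speech_type="parentese" if i < 2 else "other_speech")
                  for i in range(8)]
        props = parentese_proportions([_log(events)])
        row = props[props.context == "all_vocalisations"].iloc[0]
        assert row.proportion == pytest.approx(0.25)
        assert row.n == 8

    def test_empty_denominator_is_missing_not_zero(self):
        # no regulation-up states anywhere -> no regulation_up rows at all
        log = _log([_cg(5)])
        props = parentese_proportions([log])
        assert not (props.context == "regulation_up").any()

    def test_untagged_vocal_event_rejected(self):
        with pytest.raises(ValueError):
            parentese_proportions([_log([_cg(5, speech_type="none")])])

    def test_regulation_up_cell_restricted_to_overlap(self):
        events = [
            _cg(10, code="cg_reg_up", kind="state", end_time_s=12),
            _cg(11, speech_type="parentese"),  # inside the state
            _cg(20, speech_type="other_speech"),  # outside
        ]
        props = parentese_proportions([_log(events)])
        reg = props[props.context == "regulation_up"].iloc[0]
        assert reg.n == 1 and reg.proportion == 1.0
        allv = props[props.context == "all_vocalisations"].iloc[0]
        assert allv.n == 2 and allv.proportion == 0.5

    def test_study_recovers_design_proportion(self):
        """Mothers at 50% parentese: estimate within 3 binomial SEs."""
        from parentese.synth import StudyDesign, synth_interaction_study

        props_table = {(g, s, sp): 0.5 if sp == "mother" else 0.2
                       for g in ("AD", "TD") for s in ("S1", "S2", "S3")
                       for sp in ("mother", "father", "other")}
        design = StudyDesign(
            n_children_per_group=5, scenes_per_semester=1,
            vocalisations_per_scene=20, parentese_proportion=props_table,
            p_regulation_up=0.0, random_seed=7,
        )
        logs, _ = synth_interaction_study(design)
        props = parentese_proportions(logs)
        sub = props[(props.speaker == "mother") & (props.context == "all_vocalisations")]
        n = sub["n"].sum()
        est = float((sub.proportion * sub.n).sum() / n)
        se = np.sqrt(0.25 / n)
        assert abs(est - 0.5) <= 3 * se
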
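"""Synthetic caregiver-infant interaction studies with known ground truth.

Emulates the structure of a home-movie corpus: two groups of children (one
later diagnosed with autistic disorder, one typically developing), scenes per
6-month semester, caregiver vocalisations placed at distinct integer seconds,
each vocalisation assigned a speaker and a speech type (parentese vs other
speech) and independently triggering infant meta-behavior responses within a
3-second window.  Every generative probability is recorded in the returned
ground truth, so extraction and modelling stages can be checked exactly.

Default condition sizes mirror the real corpus: 14 children per group, 3
scenes per semester, ~20 vocalisations per scene (≈ 840 vocalisations per
group x semester); mother parentese proportions decline 0.60/0.45/0.35
across semesters against 0.20/0.15/0.12 for fathers, and vocalisations
inside regulation-up states nearly double their parentese odds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from ..events import (
    BehaviorEvent,
    INFANT_METAS,
    InteractionLog,
    MetaBehaviorMap,
)

GROUPS = ("AD", "TD")
SEMESTERS = ("S1", "S2", "S3")
SPEAKERS = ("mother", "father", "other")
SPEECH_TYPES = ("parentese", "other_speech")

VOCAL_CODE = "cg_vocalisation"
REGUP_CODE = "cg_reg_up"


def default_parentese_proportions() -> dict[tuple[str, str, str], float]:
    """Per (group, semester, speaker) probability that a vocalisation is parentese."""
    mother = {"S1": 0.60, "S2": 0.45, "S3": 0.35}
    father = {"S1": 0.20, "S2": 0.15, "S3": 0.12}
    other = {"S1": 0.30, "S2": 0.30, "S3": 0.30}
    table = {}
    for g in GROUPS:
        for s in SEMESTERS:
            table[(g, s, "mother")] = mother[s]
            table[(g, s, "father")] = father[s]
            table[(g, s, "other")] = other[s]
    return table


def default_response_probabilities() -> dict[tuple, float]:
    """Per (group, semester, speaker, speech_type, infant_meta) response probability.

    Built on the logit scale from effects with the signs the study design
    emulates: responses rise from S1 to S2; the AD group responds less;
    parentese facilitates responses, most strongly the receptive subtype.
    """
    base_logit = {
        "toward_object": -2.4,
        "receptive": -1.8,
        "expressive": -1.5,
        "active": -3.0,
        "exploratory": -2.6,
        "inter_subjective": -3.0,
    }
    sem_shift = {"S1": 0.0, "S2": 0.45, "S3": 0.35}
    table: dict[tuple, float] = {}
    for g in GROUPS:
        for s in SEMESTERS:
            for sp in SPEAKERS:
                for st in SPEECH_TYPES:
                    for meta in INFANT_METAS:
                        eta = base_logit[meta] + sem_shift[s]
                        if g == "AD":
                            eta -= 0.4
                        if st == "parentese":
                            eta += 0.6 if meta == "receptive" else 0.2
                        table[(g, s, sp, st, meta)] = float(1 / (1 + np.exp(-eta)))
    return table


@dataclass
class StudyDesign:
    """Generative conditions of one synthetic study."""

    n_children_per_group: int = 14
    scenes_per_semester: int = 3
    vocalisations_per_scene: int = 20
    speaker_probs: Mapping[str, float] = field(
        default_factory=lambda: {"mother": 0.6, "father": 0.3, "other": 0.1}
    )
    parentese_proportion: Mapping[tuple, float] = field(
        default_factory=default_parentese_proportions
    )
    #: odds multiplier for parentese inside a regulation-up state
    regup_parentese_odds: float = 3.5
    #: probability a vocalisation happens inside a regulation-up state
    p_regulation_up: float = 0.25
    response_probability: Mapping[tuple, float] = field(
        default_factory=default_response_probabilities
    )
    #: child-level random-intercept sd on the response logit scale (0 keeps
    #: empirical frequencies exactly at the design probabilities)
    random_intercept_sd: float = 0.0
    max_lag_s: int = 3
    #: spacing between vocalisations; > max_lag precludes window overlap
    vocalisation_spacing_s: int = 5
    random_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_children_per_group < 1:
            raise ValueError("need at least one child per group")
        for p in self.parentese_proportion.values():
            if not 0.0 <= p <= 1.0:
                raise ValueError("parentese proportions must lie in [0, 1]")
        for p in self.response_probability.values():
            if not 0.0 <= p <= 1.0:
                raise ValueError("response probabilities must lie in [0, 1]")
        if abs(sum(self.speaker_probs.values()) - 1.0) > 1e-9:
            raise ValueError("speaker probabilities must sum to 1")


def _regup_parentese_p(base: float, odds_mult: float) -> float:
    if base in (0.0, 1.0):
        return base
    odds = base / (1 - base) * odds_mult
    return odds / (1 + odds)


def synth_interaction_study(design: StudyDesign) -> tuple[list[InteractionLog], dict]:
    """Generate all scene logs of a study plus the generative ground truth.

    Ground truth records, per response bigram actually planted, the tuple
    (child, scene, caregiver time, infant time, infant meta-behavior), the
    per-cell probabilities used, and each child's random intercept.
    """
    rng = np.random.default_rng(design.random_seed)
    mapping = MetaBehaviorMap.default()
    meta_codes = {m: [c for c, mm in mapping.infant.items() if mm == m] for m in INFANT_METAS}
    speakers = list(design.speaker_probs)
    sp_probs = np.array([design.speaker_probs[s] for s in speakers])

    logs: list[InteractionLog] = []
    linkage: list[dict] = []
    intercepts: dict[str, float] = {}
    n_voc = design.vocalisations_per_scene
    spacing = design.vocalisation_spacing_s
    duration = max(40.0, 2 + n_voc * spacing + design.max_lag_s + 1)

    for group in GROUPS:
        for i in range(design.n_children_per_group):
            child = f"{group.lower()}{i + 1:02d}"
            b_child = float(rng.normal(0.0, design.random_intercept_sd)) if design.random_intercept_sd > 0 else 0.0
            intercepts[child] = b_child
            for sem in SEMESTERS:
                for k in range(design.scenes_per_semester):
                    scene = f"{child}_{sem.lower()}_sc{k}"
                    events: list[BehaviorEvent] = []
                    for j in range(n_voc):
                        t = float(2 + j * spacing)
                        speaker = speakers[int(rng.choice(len(speakers), p=sp_probs))]
                        in_regup = bool(rng.random() < design.p_regulation_up)
                        p_pese = design.parentese_proportion[(group, sem, speaker)]
                        if in_regup:
                            p_pese = _regup_parentese_p(p_pese, design.regup_parentese_odds)
                            events.append(
                                BehaviorEvent(
                                    time_s=t, actor="caregiver", code=REGUP_CODE,
                                    kind="state", end_time_s=t + 2.0, speaker=speaker,
                                )
                            )
                        speech = "parentese" if rng.random() < p_pese else "other_speech"
                        events.append(
                            BehaviorEvent(
                                time_s=t, actor="caregiver", code=VOCAL_CODE,
                                kind="point", speaker=speaker, speech_type=speech,
                            )
                        )
                        for meta in INFANT_METAS:
                            p = design.response_probability[(group, sem, speaker, speech, meta)]
                            if b_child != 0.0 and 0.0 < p < 1.0:
                                eta = np.log(p / (1 - p)) + b_child
                                p = float(1 / (1 + np.exp(-eta)))
                            if rng.random() < p:
                                lag = int(rng.integers(0, design.max_lag_s + 1))
                                ti = t + lag
                                code = meta_codes[meta][int(rng.integers(len(meta_codes[meta])))]
                                events.append(
                                    BehaviorEvent(time_s=ti, actor="infant", code=code)
                                )
                                linkage.append(
                                    {
                                        "child_id": child, "group": group,
                                        "semester": sem, "scene_id": scene,
                                        "cg_time_s": t, "infant_time_s": ti,
                                        "lag_s": float(lag), "infant_meta": meta,
                                        "speaker": speaker, "speech_type": speech,
                                    }
                                )
                    logs.append(
                        InteractionLog(
                            child_id=child, group=group, semester=sem,
                            scene_id=scene, duration_s=duration, events=events,
                        )
                    )
    ground_truth = {
        "design": design,
        "linkage": linkage,
        "child_intercepts": intercepts,
        "parentese_proportion": dict(design.parentese_proportion),
        "response_probability": dict(design.response_probability),
    }
    return logs, ground_truth
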
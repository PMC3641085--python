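"""Interaction database: speech tagging, 3-second bi-grams, count tables.

A bi-gram is an ordered caregiver-event -> infant-event pair with the infant
event inside the response window (lag in [0, 3] s by default, both ends
inclusive: "within the same second" counts, and so does exactly 3 s).  All
pairs are emitted — one infant behavior may answer several caregiver
behaviors — with nearest-only pairing available as an option.  State-type
caregiver events anchor the window at their start.

Counts are aggregated into the study's reporting shape: infant responses per
(group, semester, speaker, speech type) broken down by the six infant
meta-behavior subtypes, with the two margin identities

    toward_people = receptive + expressive + active + exploratory + inter_subjective
    total         = toward_object + toward_people

holding on every table.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Mapping

import pandas as pd

from .events import (
    BehaviorEvent,
    INFANT_METAS,
    InteractionLog,
    MetaBehaviorMap,
    TOWARD_PEOPLE_METAS,
)

DEFAULT_WINDOW_S = 3.0


@dataclass(frozen=True)
class ResponseBigram:
    """One caregiver->infant response pair plus its study context."""

    cg_event: BehaviorEvent
    infant_event: BehaviorEvent
    lag_s: float
    cg_meta: str
    infant_meta: str
    child_id: str
    group: str
    semester: str
    scene_id: str

    def __post_init__(self) -> None:
        if self.lag_s < 0:
            raise ValueError("bigram lag must be non-negative")
        if self.cg_event.actor != "caregiver" or self.infant_event.actor != "infant":
            raise ValueError("bigram actors are reversed")

    @property
    def speaker(self) -> str:
        return self.cg_event.speaker

    @property
    def speech_type(self) -> str:
        return self.cg_event.speech_type


def _vocal_events(log: InteractionLog, mapping: MetaBehaviorMap) -> list[BehaviorEvent]:
    return [
        e
        for e in log.events
        if e.actor == "caregiver"
        and e.code in mapping
        and mapping.map_meta(e.code) == "vocal_solicitation"
    ]


def tag_vocalisations(
    log: InteractionLog,
    labels: Iterable[str],
    mapping: MetaBehaviorMap | None = None,
) -> InteractionLog:
    """Attach one speech-type label per caregiver vocal event (in time order).

    Non-vocal events are untouched; a label-count mismatch is an error.
    """
    mapping = mapping or MetaBehaviorMap.default()
    labels = list(labels)
    vocal = _vocal_events(log, mapping)
    if len(labels) != len(vocal):
        raise ValueError(
            f"{len(labels)} labels for {len(vocal)} caregiver vocal events"
        )
    vocal_ids = {id(e) for e in vocal}
    it = iter(labels)
    new_events = [
        replace(e, speech_type=next(it)) if id(e) in vocal_ids else replace(e)
        for e in log.events
    ]
    return InteractionLog(
        child_id=log.child_id, group=log.group, semester=log.semester,
        scene_id=log.scene_id, duration_s=log.duration_s, events=new_events,
    )


def extract_bigrams(
    log: InteractionLog,
    window_s: float = DEFAULT_WINDOW_S,
    mapping: MetaBehaviorMap | None = None,
    pairing: str = "all",
) -> list[ResponseBigram]:
    """All caregiver->infant pairs with lag in [0, window] seconds.

    ``pairing="all"`` (default) emits every qualifying pair; ``"nearest"``
    keeps, per infant event, only the latest caregiver event in window.
    Output is ordered by caregiver time then infant time.  Unmapped behavior
    codes raise ``KeyError``.
    """
    if window_s <= 0:
        raise ValueError("window must be positive")
    if pairing not in ("all", "nearest"):
        raise ValueError("pairing must be 'all' or 'nearest'")
    mapping = mapping or MetaBehaviorMap.default()
    cg = log.caregiver_events()
    inf = log.infant_events()
    out: list[ResponseBigram] = []
    for c in cg:
        c_meta = mapping.map_meta(c.code)
        for i in inf:
            lag = i.time_s - c.time_s  # state events anchor at their start
            if 0 <= lag <= window_s:
                out.append(
                    ResponseBigram(
                        cg_event=c, infant_event=i, lag_s=lag,
                        cg_meta=c_meta, infant_meta=mapping.map_meta(i.code),
                        child_id=log.child_id, group=log.group,
                        semester=log.semester, scene_id=log.scene_id,
                    )
                )
    if pairing == "nearest":
        best: dict[int, ResponseBigram] = {}
        for b in out:
            key = id(b.infant_event)
            if key not in best or b.cg_event.time_s > best[key].cg_event.time_s:
                best[key] = b
        out = list(best.values())
    out.sort(key=lambda b: (b.cg_event.time_s, b.infant_event.time_s))
    return out


def response_margins(subtype_counts: Mapping[str, int]) -> dict[str, int]:
    """Margins from the six subtype counts: toward_people and total.

    toward_people sums the five toward-people subtypes; total adds
    toward_object.  Missing subtypes count as zero; negative counts are
    rejected.
    """
    for k, v in subtype_counts.items():
        if v < 0:
            raise ValueError(f"negative count for {k!r}")
    toward_people = sum(int(subtype_counts.get(m, 0)) for m in TOWARD_PEOPLE_METAS)
    total = toward_people + int(subtype_counts.get("toward_object", 0))
    return {"toward_people": toward_people, "total": total}


CONTEXT_COLS = ("group", "semester", "speaker", "speech_type")


class CountTable:
    """Response counts cross-classified by study context and infant subtype.

    Wraps a long-format DataFrame with columns ``group, semester, speaker,
    speech_type, subtype, count`` plus a vocalisation-denominator table
    counted from the logs independently of any response.
    """

    def __init__(self, long: pd.DataFrame, denominators: pd.DataFrame | None = None):
        required = set(CONTEXT_COLS) | {"subtype", "count"}
        if missing := required - set(long.columns):
            raise ValueError(f"count table missing columns {sorted(missing)}")
        if (long["count"] < 0).any():
            raise ValueError("counts must be non-negative")
        self.long = long.reset_index(drop=True)
        self.denominators = denominators

    @classmethod
    def from_bigrams(
        cls,
        bigrams: Iterable[ResponseBigram],
        logs: Iterable[InteractionLog] | None = None,
        mapping: MetaBehaviorMap | None = None,
    ) -> "CountTable":
        rows = [
            {
                "group": b.group, "semester": b.semester, "speaker": b.speaker,
                "speech_type": b.speech_type, "subtype": b.infant_meta,
            }
            for b in bigrams
        ]
        if rows:
            long = (
                pd.DataFrame(rows)
                .groupby([*CONTEXT_COLS, "subtype"], observed=True)
                .size()
                .rename("count")
                .reset_index()
            )
        else:
            long = pd.DataFrame(columns=[*CONTEXT_COLS, "subtype", "count"])
        denom = None
        if logs is not None:
            mapping = mapping or MetaBehaviorMap.default()
            drows = [
                {
                    "group": log.group, "semester": log.semester,
                    "speaker": e.speaker, "speech_type": e.speech_type,
                }
                for log in logs
                for e in _vocal_events(log, mapping)
            ]
            if drows:
                denom = (
                    pd.DataFrame(drows)
                    .groupby(list(CONTEXT_COLS), observed=True)
                    .size()
                    .rename("n_vocalisations")
                    .reset_index()
                )
        return cls(long, denom)

    def margins(self, by: tuple[str, ...] = ("group", "semester")) -> pd.DataFrame:
        """Wide table by ``by``: one column per subtype plus the two margins."""
        wide = (
            self.long.groupby([*by, "subtype"], observed=True)["count"]
            .sum()
            .unstack("subtype", fill_value=0)
        )
        for m in INFANT_METAS:
            if m not in wide.columns:
                wide[m] = 0
        wide = wide[list(INFANT_METAS)]
        wide["toward_people"] = wide[list(TOWARD_PEOPLE_METAS)].sum(axis=1)
        wide["total"] = wide["toward_people"] + wide["toward_object"]
        return wide

    def to_wide(self) -> pd.DataFrame:
        """Reporting-shaped table: rows group x semester, response columns,
        with the vocalisation denominators when available."""
        wide = self.margins(("group", "semester"))
        cols = ["total", "toward_object", "toward_people", *TOWARD_PEOPLE_METAS]
        wide = wide[cols]
        if self.denominators is not None:
            nvoc = (
                self.denominators.groupby(["group", "semester"], observed=True)[
                    "n_vocalisations"
                ]
                .sum()
            )
            wide.insert(0, "n_vocalisations", nvoc.reindex(wide.index).fillna(0).astype(int))
        return wide


def parentese_proportions(
    logs: Iterable[InteractionLog],
    mapping: MetaBehaviorMap | None = None,
) -> pd.DataFrame:
    """Parentese share of tagged vocal events per (group, semester, speaker).

    Two contexts per cell: all vocalisations, and only vocalisations that
    overlap a regulation-up state interval.  Cells with an empty denominator
    are absent from the result (missing, not zero).
    """
    mapping = mapping or MetaBehaviorMap.default()
    rows = []
    for log in logs:
        regup = [
            e
            for e in log.caregiver_events()
            if e.kind == "state"
            and e.code in mapping
            and mapping.map_meta(e.code) == "regulation_up"
        ]
        for e in _vocal_events(log, mapping):
            if e.speech_type == "none":
                raise ValueError(
                    f"untagged vocal event at t={e.time_s} in scene {log.scene_id}"
                )
            in_regup = any(r.time_s <= e.time_s <= r.end_time_s for r in regup)
            rows.append(
                {
                    "group": log.group, "semester": log.semester,
                    "speaker": e.speaker, "parentese": e.speech_type == "parentese",
                    "regulation_up": in_regup,
                }
            )
    if not rows:
        return pd.DataFrame(
            columns=["group", "semester", "speaker", "context", "proportion", "n"]
        )
    df = pd.DataFrame(rows)
    out = []
    for context, sub in (
        ("all_vocalisations", df),
        ("regulation_up", df[df["regulation_up"]]),
    ):
        if len(sub) == 0:
            continue
        g = (
            sub.groupby(["group", "semester", "speaker"], observed=True)["parentese"]
            .agg(proportion="mean", n="size")
            .reset_index()
        )
        g.insert(3, "context", context)
        out.append(g)
    return pd.concat(out, ignore_index=True)
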
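"""Behavioral event logs: data model, I/O, semester binning, agreement.

An interaction scene is coded as a time-stamped sequence of caregiver and
infant behaviors.  Point behaviors take an instant; regulation behaviors
(arousal up / arousal down) are states with a start and an end.  Caregiver
vocal events additionally carry a speaker (mother / father / other) and,
after acoustic classification, a speech type (parentese / other speech).

Logs are serialised as tab-delimited UTF-8 text with a header row and
``#``-prefixed metadata comments; this dialect is normative for the package.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np

ACTORS = ("caregiver", "infant")
SPEAKERS = ("mother", "father", "other", "none")
SPEECH_TYPES = ("parentese", "other_speech", "none")
KINDS = ("point", "state")

CAREGIVER_METAS = (
    "vocal_solicitation",
    "touching",
    "gestural_solicitation",
    "regulation_up",
    "regulation_down",
)
INFANT_METAS = (
    "toward_object",
    "expressive",
    "inter_subjective",
    "active",
    "receptive",
    "exploratory",
)
#: the five infant categories "toward people" (all but toward_object)
TOWARD_PEOPLE_METAS = tuple(m for m in INFANT_METAS if m != "toward_object")

MIN_SCENE_DURATION_S = 40.0

_COLUMNS = ("time_s", "actor", "code", "kind", "end_time_s", "speaker", "speech_type")


@dataclass
class BehaviorEvent:
    time_s: float
    actor: str
    code: str
    kind: str = "point"
    end_time_s: float | None = None
    speaker: str = "none"
    speech_type: str = "none"

    def __post_init__(self) -> None:
        if self.time_s < 0:
            raise ValueError(f"negative event time {self.time_s}")
        if self.actor not in ACTORS:
            raise ValueError(f"unknown actor {self.actor!r}")
        if self.kind not in KINDS:
            raise ValueError(f"unknown event kind {self.kind!r}")
        if self.kind == "state":
            if self.end_time_s is None or self.end_time_s <= self.time_s:
                raise ValueError(
                    f"state event at t={self.time_s} needs end_time_s > time_s"
                )
        if self.speaker not in SPEAKERS:
            raise ValueError(f"unknown speaker {self.speaker!r}")
        if self.speech_type not in SPEECH_TYPES:
            raise ValueError(f"unknown speech_type {self.speech_type!r}")
        if self.speech_type != "none" and self.actor != "caregiver":
            raise ValueError("speech_type is only valid on caregiver vocal events")

    @property
    def is_vocal(self) -> bool:
        """Caregiver vocal event, i.e. eligible for speech-type tagging."""
        return self.actor == "caregiver" and (
            self.speech_type != "none" or self.code in ("cg_vocalisation", "cg_calls_name")
        )


@dataclass
class InteractionLog:
    child_id: str
    group: str  # "AD" | "TD"
    semester: str  # "S1" | "S2" | "S3"
    scene_id: str
    duration_s: float
    events: list[BehaviorEvent] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.group not in ("AD", "TD"):
            raise ValueError(f"unknown group {self.group!r}")
        if self.semester not in ("S1", "S2", "S3"):
            raise ValueError(f"unknown semester {self.semester!r}")
        self.events.sort(key=lambda e: (e.time_s, 0 if e.actor == "caregiver" else 1))
        for e in self.events:
            t_end = e.end_time_s if e.kind == "state" else e.time_s
            if t_end > self.duration_s:
                raise ValueError(
                    f"event at t={e.time_s} extends past scene duration {self.duration_s}"
                )

    def caregiver_events(self) -> list[BehaviorEvent]:
        return [e for e in self.events if e.actor == "caregiver"]

    def infant_events(self) -> list[BehaviorEvent]:
        return [e for e in self.events if e.actor == "infant"]

    def vocal_events(self) -> list[BehaviorEvent]:
        return [e for e in self.events if e.is_vocal]


class LogParseError(ValueError):
    """Raised on malformed event-log files; carries the offending line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        super().__init__(f"line {line}: {message}" if line is not None else message)


def _fmt(x: float | None) -> str:
    if x is None:
        return ""
    return f"{x:.6g}"


def save_log(log: InteractionLog, path) -> None:
    path = Path(path)
    lines = [
        f"# child_id: {log.child_id}",
        f"# group: {log.group}",
        f"# semester: {log.semester}",
        f"# scene_id: {log.scene_id}",
        f"# duration_s: {_fmt(log.duration_s)}",
        "\t".join(_COLUMNS),
    ]
    for e in log.events:
        lines.append(
            "\t".join(
                [
                    _fmt(e.time_s),
                    e.actor,
                    e.code,
                    e.kind,
                    _fmt(e.end_time_s),
                    e.speaker,
                    e.speech_type,
                ]
            )
        )
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


def load_log(path, allow_short: bool = False) -> InteractionLog:
    """Parse and validate an event-log file.

    Scenes shorter than 40 s are rejected (the corpus inclusion rule) unless
    ``allow_short`` is given.  Malformed rows raise :class:`LogParseError`
    with their line number.
    """
    path = Path(path)
    meta: dict[str, str] = {}
    header: list[str] | None = None
    events: list[BehaviorEvent] = []
    for lineno, raw in enumerate(path.read_text(encoding="utf-8").splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line.lstrip("#").strip()
            if ":" in body:
                k, v = body.split(":", 1)
                meta[k.strip()] = v.strip()
            continue
        cells = line.split("\t")
        if header is None:
            header = [c.strip() for c in cells]
            missing = [c for c in _COLUMNS if c not in header]
            if missing:
                raise LogParseError(f"missing required column(s) {missing}", lineno)
            continue
        row = dict(zip(header, cells))
        try:
            end_raw = row.get("end_time_s", "").strip()
            events.append(
                BehaviorEvent(
                    time_s=float(row["time_s"]),
                    actor=row["actor"].strip(),
                    code=row["code"].strip(),
                    kind=row["kind"].strip() or "point",
                    end_time_s=float(end_raw) if end_raw else None,
                    speaker=row.get("speaker", "none").strip() or "none",
                    speech_type=row.get("speech_type", "none").strip() or "none",
                )
            )
        except (KeyError, ValueError) as exc:
            raise LogParseError(str(exc), lineno) from exc
    if header is None:
        raise LogParseError("no header row found")
    for key in ("child_id", "group", "semester", "scene_id", "duration_s"):
        if key not in meta:
            raise LogParseError(f"missing metadata comment '# {key}: ...'")
    duration = float(meta["duration_s"])
    if duration < MIN_SCENE_DURATION_S and not allow_short:
        raise ValueError(
            f"scene duration {duration} s is below the {MIN_SCENE_DURATION_S:.0f} s "
            "inclusion threshold (pass allow_short=True to override)"
        )
    return InteractionLog(
        child_id=meta["child_id"],
        group=meta["group"],
        semester=meta["semester"],
        scene_id=meta["scene_id"],
        duration_s=duration,
        events=events,
    )


def assign_semester(age_months: float) -> str:
    """Bin an age into the three 6-month semesters of the first 18 months.

    S1: age <= 6; S2: 6 < age <= 12; S3: age > 12.  The 12-month boundary is
    upper-inclusive in S2, mirroring the inclusive lower bin.
    """
    if age_months < 0:
        raise ValueError("age_months must be non-negative")
    if age_months > 18:
        raise ValueError("age_months beyond the 18-month study window")
    if age_months <= 6:
        return "S1"
    if age_months <= 12:
        return "S2"
    return "S3"


class MetaBehaviorMap:
    """Total map from coding-grid item codes to meta-behavior labels.

    Five caregiver meta-behaviors (vocal solicitation, touching, gestural
    solicitation, regulation up/down) and six infant meta-behaviors (behavior
    with object plus five behaviors toward people).  Alternative category
    names used in reporting (vocalizations/expressive, seeking-people/active,
    orienting/exploratory) are resolved through the alias table.
    """

    def __init__(self, caregiver: dict[str, str], infant: dict[str, str],
                 aliases: dict[str, str] | None = None):
        for code, meta in caregiver.items():
            if meta not in CAREGIVER_METAS:
                raise ValueError(f"caregiver item {code!r} maps to unknown meta {meta!r}")
        for code, meta in infant.items():
            if meta not in INFANT_METAS:
                raise ValueError(f"infant item {code!r} maps to unknown meta {meta!r}")
        overlap = set(caregiver) & set(infant)
        if overlap:
            raise ValueError(f"item codes mapped for both actors: {sorted(overlap)}")
        self._map = {**caregiver, **infant}
        self.caregiver = dict(caregiver)
        self.infant = dict(infant)
        self.aliases = dict(aliases or {})

    @classmethod
    def default(cls) -> "MetaBehaviorMap":
        with resources.files("parentese.data").joinpath("meta_behavior_map.json").open() as fh:
            raw = json.load(fh)
        return cls(raw["caregiver"], raw["infant"], raw.get("aliases"))

    @classmethod
    def from_json(cls, path) -> "MetaBehaviorMap":
        raw = json.loads(Path(path).read_text(encoding="utf-8"))
        return cls(raw["caregiver"], raw["infant"], raw.get("aliases"))

    def map_meta(self, code: str) -> str:
        try:
            return self._map[code]
        except KeyError:
            raise KeyError(f"item code {code!r} has no meta-behavior mapping") from None

    def canonical(self, label: str) -> str:
        """Resolve a reporting alias to its canonical meta-behavior label."""
        label = label.lower().replace(" ", "_").replace("-", "_")
        return self.aliases.get(label, label)

    def __contains__(self, code: str) -> bool:
        return code in self._map


def map_meta(code: str, mapping: MetaBehaviorMap | None = None) -> str:
    """Meta-behavior label for one item code (default shipped map)."""
    return (mapping or MetaBehaviorMap.default()).map_meta(code)


def cohens_kappa(ratings_a, ratings_b) -> float:
    """Cohen's kappa between two raters' categorical sequences.

    kappa = (p_o - p_e) / (1 - p_e), with chance agreement p_e from the
    marginal label frequencies.  When chance agreement is 1 (both raters
    constant): kappa is 1 for identical sequences, otherwise undefined.
    """
    a = np.asarray(ratings_a)
    b = np.asarray(ratings_b)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("ratings must be two equal-length 1-d sequences")
    if len(a) == 0:
        raise ValueError("ratings must be non-empty")
    labels = np.unique(np.concatenate([a, b]))
    p_o = float(np.mean(a == b))
    pa = np.array([np.mean(a == lab) for lab in labels])
    pb = np.array([np.mean(b == lab) for lab in labels])
    p_e = float(pa @ pb)
    if p_e >= 1.0 - 1e-12:
        if p_o == 1.0:
            return 1.0
        raise ValueError("kappa undefined: chance agreement is 1 but raters disagree")
    return (p_o - p_e) / (1.0 - p_e)
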
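"""Stimulus manifest and deterministic scoring for the EAR test.

The Emotion Authenticity Recognition (EAR) test presents 60 short videos of
facial expressions, 10 per basic emotion (happiness, surprise, sadness,
anger, fear, disgust).  Within each emotion, 5 clips show an authentic
(event-elicited) expression and 5 a posed one.  For every clip the
respondent makes two forced choices: which emotion is shown (6
alternatives) and whether it is authentic or posed.  One point per correct
judgment yields two 0-60 indices:

* **ER index** - correct emotion identifications;
* **EA index** - correct authenticity classifications.

This module holds the data model for stimuli and responses, a deterministic
manifest builder, and the scorer that turns a complete response set into
the two indices plus per-emotion subscores.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "EMOTIONS",
    "AUTHENTICITIES",
    "N_STIMULI",
    "StimulusSpec",
    "TrialResponse",
    "RawScores",
    "build_manifest",
    "score_responses",
    "manifest_to_json",
    "manifest_from_json",
    "read_responses_csv",
]

EMOTIONS = ("happiness", "surprise", "sadness", "anger", "fear", "disgust")
AUTHENTICITIES = ("authentic", "posed")
N_STIMULI = 60
_PER_EMOTION = 10
_PER_CELL = 5  # stimuli per (emotion, authenticity) cell

#: Mean clip duration in seconds used when synthesising manifest metadata.
#: Fear expressions are very fast and sadness very slow; the remaining
#: emotions share an intermediate mean chosen so the overall average clip
#: length is about 3 s.  Durations are descriptive metadata only and play
#: no role in scoring.
DEFAULT_MEAN_DURATIONS: Mapping[str, float] = {
    "happiness": 2.2,
    "surprise": 1.9,
    "sadness": 7.91,
    "anger": 2.3,
    "fear": 1.69,
    "disgust": 2.3,
}


class ResponseValidationError(ValueError):
    """A response set does not cover the manifest exactly once."""


@dataclass(frozen=True)
class StimulusSpec:
    """One EAR video item."""

    stimulus_id: str
    emotion: str
    authenticity: str
    duration_s: float | None = None

    def __post_init__(self) -> None:
        if self.emotion not in EMOTIONS:
            raise ValueError(f"unknown emotion {self.emotion!r}")
        if self.authenticity not in AUTHENTICITIES:
            raise ValueError(f"unknown authenticity {self.authenticity!r}")


@dataclass(frozen=True)
class TrialResponse:
    """A participant's two judgments for one stimulus."""

    stimulus_id: str
    chosen_emotion: str
    authenticity_judgment: str

    def __post_init__(self) -> None:
        if self.chosen_emotion not in EMOTIONS:
            raise ValueError(f"unknown emotion {self.chosen_emotion!r}")
        if self.authenticity_judgment not in AUTHENTICITIES:
            raise ValueError(
                f"unknown authenticity judgment {self.authenticity_judgment!r}"
            )


@dataclass
class RawScores:
    """ER and EA indices plus per-emotion ER subscores for one participant."""

    er_index: int
    ea_index: int
    per_emotion_er: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0 <= self.er_index <= N_STIMULI:
            raise ValueError(f"er_index {self.er_index} outside [0, {N_STIMULI}]")
        if not 0 <= self.ea_index <= N_STIMULI:
            raise ValueError(f"ea_index {self.ea_index} outside [0, {N_STIMULI}]")
        if self.per_emotion_er:
            total = sum(self.per_emotion_er.values())
            if total != self.er_index:
                raise ValueError(
                    f"per-emotion subscores sum to {total}, not er_index "
                    f"{self.er_index}"
                )

    def to_dict(self) -> dict:
        return {
            "er_index": self.er_index,
            "ea_index": self.ea_index,
            "per_emotion_er": dict(self.per_emotion_er),
        }


def build_manifest(
    seed: int,
    durations: Mapping[str, float] | None = None,
) -> list[StimulusSpec]:
    """Build a 60-item manifest: 10 per emotion, 5 authentic / 5 posed each.

    The seed controls the presentation order of the fixed item structure and
    the synthetic clip durations (drawn from a log-normal around each
    emotion's mean duration).  Two calls with the same seed return identical
    manifests.
    """
    means = dict(DEFAULT_MEAN_DURATIONS)
    if durations:
        means.update(durations)
    rng = np.random.default_rng(seed)

    cells = [
        (emotion, authenticity)
        for emotion in EMOTIONS
        for authenticity in AUTHENTICITIES
        for _ in range(_PER_CELL)
    ]
    order = rng.permutation(len(cells))
    manifest = []
    for position, idx in enumerate(order, start=1):
        emotion, authenticity = cells[idx]
        mu = float(np.log(means[emotion]))
        duration = float(np.round(rng.lognormal(mu, 0.35), 2))
        manifest.append(
            StimulusSpec(
                stimulus_id=f"EAR{position:02d}",
                emotion=emotion,
                authenticity=authenticity,
                duration_s=duration,
            )
        )
    return manifest


def score_responses(
    responses: Sequence[TrialResponse],
    manifest: Sequence[StimulusSpec],
) -> RawScores:
    """Score a complete response set against the manifest.

    One point is given for each correctly identified emotion (ER index) and
    for each correctly classified authenticity (EA index); the maximum for
    each index is 60.  The response set must cover every manifest item
    exactly once - partial protocols are rejected because the norms assume
    the full 0-60 scale.
    """
    by_id = {s.stimulus_id: s for s in manifest}
    seen: dict[str, TrialResponse] = {}
    duplicates = []
    unknown = []
    for resp in responses:
        if resp.stimulus_id not in by_id:
            unknown.append(resp.stimulus_id)
        elif resp.stimulus_id in seen:
            duplicates.append(resp.stimulus_id)
        else:
            seen[resp.stimulus_id] = resp
    missing = sorted(set(by_id) - set(seen))
    if unknown or duplicates or missing:
        parts = []
        if unknown:
            parts.append(f"unknown ids: {sorted(set(unknown))}")
        if duplicates:
            parts.append(f"duplicated ids: {sorted(set(duplicates))}")
        if missing:
            parts.append(f"missing ids: {missing}")
        raise ResponseValidationError("; ".join(parts))

    er = 0
    ea = 0
    per_emotion = {emotion: 0 for emotion in EMOTIONS}
    for stimulus_id, resp in seen.items():
        stim = by_id[stimulus_id]
        if resp.chosen_emotion == stim.emotion:
            er += 1
            per_emotion[stim.emotion] += 1
        if resp.authenticity_judgment == stim.authenticity:
            ea += 1
    return RawScores(er_index=er, ea_index=ea, per_emotion_er=per_emotion)


def manifest_to_json(manifest: Sequence[StimulusSpec], path: str | Path) -> None:
    records = [
        {
            "stimulus_id": s.stimulus_id,
            "emotion": s.emotion,
            "authenticity": s.authenticity,
            "duration_s": s.duration_s,
        }
        for s in manifest
    ]
    Path(path).write_text(json.dumps(records, indent=2))


def manifest_from_json(path: str | Path) -> list[StimulusSpec]:
    records = json.loads(Path(path).read_text())
    return [StimulusSpec(**rec) for rec in records]


def read_responses_csv(path: str | Path) -> list[TrialResponse]:
    """Read a response table with columns stimulus_id, chosen_emotion,
    authenticity_judgment."""
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        return [
            TrialResponse(
                stimulus_id=row["stimulus_id"],
                chosen_emotion=row["chosen_emotion"],
                authenticity_judgment=row["authenticity_judgment"],
            )
            for row in reader
        ]
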
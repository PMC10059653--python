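"""Emotion-adaptive game policy: sustained quadrant decisions trigger events.

The mapping is fixed by the game design:

* HANV → ``reward_bricks`` (counter a negative-valence state with rewards),
* LAPV → ``spawn_monsters`` (counter low arousal with difficulty),
* LANV → ``new_scene`` (scene change to re-engage; may end the session),
* HAPV → ``no_action`` (the ideal entertainment state; logged, never an event).

An event fires when the same quadrant persists for ``persistence`` consecutive
windows; after firing, that quadrant is refractory for ``refractory`` windows.
UNDECIDED windows reset persistence.  Activation tables per subject follow the
reference layout (HANV / LAPV / HAPV / LANV columns, the HAPV column empty)
with subtotal rows over the first half, second half and all subjects.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Protocol

import pandas as pd

from serj.errors import InvalidArgumentError
from serj.judge import EmotionQuadrant


class GameAction(str, enum.Enum):
    REWARD_BRICKS = "reward_bricks"
    SPAWN_MONSTERS = "spawn_monsters"
    NO_ACTION = "no_action"
    NEW_SCENE = "new_scene"


ACTION_MAP: dict[EmotionQuadrant, GameAction] = {
    EmotionQuadrant.HANV: GameAction.REWARD_BRICKS,
    EmotionQuadrant.LAPV: GameAction.SPAWN_MONSTERS,
    EmotionQuadrant.HAPV: GameAction.NO_ACTION,
    EmotionQuadrant.LANV: GameAction.NEW_SCENE,
}

#: Default number of new_scene events after which the session context ends.
SESSION_END_AFTER_NEW_SCENES = 2


class HasQuadrant(Protocol):
    window: int
    quadrant: EmotionQuadrant


@dataclass(frozen=True)
class DecisionLike:
    """Minimal decision record the policy needs (window, quadrant)."""

    window: int
    quadrant: EmotionQuadrant


@dataclass(frozen=True)
class AdaptationEvent:
    quadrant: EmotionQuadrant
    action: GameAction
    window: int
    persistence: int  # consecutive-window count at trigger
    session_end: bool = False


def policy_step(
    decisions: Iterable[HasQuadrant],
    persistence: int = 1,
    refractory: int = 1,
    session_end_after: int = SESSION_END_AFTER_NEW_SCENES,
) -> tuple[list[AdaptationEvent], list[AdaptationEvent]]:
    """Map a decision stream to (events, no_action log).

    Returns the fired events and, separately, one ``no_action`` log entry per
    HAPV window (never an event, matching the empty HAPV column of the
    activation tables).
    """
    if persistence < 1 or refractory < 0:
        raise InvalidArgumentError("persistence >= 1 and refractory >= 0 required")
    events: list[AdaptationEvent] = []
    logs: list[AdaptationEvent] = []
    run_quadrant: EmotionQuadrant | None = None
    run_length = 0
    cooldown: dict[EmotionQuadrant, int] = {}
    new_scenes = 0
    for d in decisions:
        q = d.quadrant
        if q == EmotionQuadrant.UNDECIDED:
            run_quadrant, run_length = None, 0
        elif q == EmotionQuadrant.HAPV:
            logs.append(
                AdaptationEvent(q, GameAction.NO_ACTION, d.window, persistence=0)
            )
            run_length = run_length + 1 if run_quadrant == q else 1
            run_quadrant = q
        else:
            run_length = run_length + 1 if run_quadrant == q else 1
            run_quadrant = q
            if run_length >= persistence and q not in cooldown:
                is_scene = ACTION_MAP[q] is GameAction.NEW_SCENE
                if is_scene:
                    new_scenes += 1
                events.append(
                    AdaptationEvent(
                        q,
                        ACTION_MAP[q],
                        d.window,
                        persistence=run_length,
                        session_end=is_scene and new_scenes >= session_end_after,
                    )
                )
                if refractory > 0:
                    # +1 compensates the decrement at the end of this window
                    cooldown[q] = refractory + 1
                run_length = 0
        # cooldowns tick down after each processed window
        for qq in list(cooldown):
            cooldown[qq] -= 1
            if cooldown[qq] <= 0:
                del cooldown[qq]
    return events, logs


@dataclass
class SubjectLog:
    subject: str | int
    participated_before: bool
    events: list[AdaptationEvent] = field(default_factory=list)


def tabulate_activations(subject_logs: Iterable[SubjectLog]) -> pd.DataFrame:
    """Per-subject activation counts in the reference table layout.

    Columns HANV, LAPV, HAPV, LANV; the HAPV column is empty (``NA``) because
    no reaction is recorded for the ideal state.  Appends subtotal rows over
    the first half, the second half, and all subjects.
    """
    logs = list(subject_logs)
    ids = [str(l.subject) for l in logs]
    if len(set(ids)) != len(ids):
        raise InvalidArgumentError("duplicate subject id in activation logs")
    rows = []
    for l in logs:
        counts = {"HANV": 0, "LAPV": 0, "LANV": 0}
        for e in l.events:
            if e.quadrant.value in counts:
                counts[e.quadrant.value] += 1
        rows.append(
            {
                "subject": str(l.subject),
                "participated_before": "yes" if l.participated_before else "no",
                "HANV": counts["HANV"],
                "LAPV": counts["LAPV"],
                "HAPV": pd.NA,
                "LANV": counts["LANV"],
            }
        )
    df = pd.DataFrame(rows)
    return append_subtotals(df)


def append_subtotals(per_subject: pd.DataFrame) -> pd.DataFrame:
    """Append first-half / second-half / overall subtotal rows."""
    n = len(per_subject)
    half = n // 2
    groups = []
    if half >= 1:
        groups.append((f"total_1_{half}", per_subject.iloc[:half]))
        groups.append((f"total_{half + 1}_{n}", per_subject.iloc[half:]))
    groups.append((f"total_1_{n}", per_subject))
    subtotal_rows = []
    for name, block in groups:
        subtotal_rows.append(
            {
                "subject": name,
                "participated_before": "",
                "HANV": int(block["HANV"].sum()),
                "LAPV": int(block["LAPV"].sum()),
                "HAPV": pd.NA,
                "LANV": int(block["LANV"].sum()),
            }
        )
    return pd.concat([per_subject, pd.DataFrame(subtotal_rows)], ignore_index=True)
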
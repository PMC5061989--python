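"""Command-safety state machine between classifier and motors.

Misclassified windows must never translate into dangerous motion, so the
raw per-window class stream passes through (a) a debouncer that requires
k identical consecutive classifications before acting and (b) a finite
state machine that refuses direct reversals: a wheelchair moving forward
ignores a ``backward`` command (and left ignores ``right``, symmetric by
design) until the chair has stopped in neutral.  ``switch_off`` acts as
an emergency stop from any state, and nothing moves until ``switch_on``
has been seen.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Iterable, NamedTuple

from .eeg import ClassLabel
from .errors import ConfigError


class DriveState(str, Enum):
    OFF = "off"
    NEUTRAL = "neutral"
    FORWARD = "forward"
    BACKWARD = "backward"
    LEFT = "left"
    RIGHT = "right"


MOTION_STATES = frozenset(
    {DriveState.FORWARD, DriveState.BACKWARD, DriveState.LEFT, DriveState.RIGHT}
)

OPPOSITE = {
    DriveState.FORWARD: DriveState.BACKWARD,
    DriveState.BACKWARD: DriveState.FORWARD,
    DriveState.LEFT: DriveState.RIGHT,
    DriveState.RIGHT: DriveState.LEFT,
}

#: Every command the state machine understands.
COMMANDS = ("forward", "backward", "left", "right",
            "switch_on", "switch_off", "neutral")

_MOTION_FOR = {
    "forward": DriveState.FORWARD,
    "backward": DriveState.BACKWARD,
    "left": DriveState.LEFT,
    "right": DriveState.RIGHT,
}


class CommandEvent(NamedTuple):
    """One classified window: command name, classifier confidence
    (maximal output value) and window start time in seconds."""

    command: str
    confidence: float = 1.0
    timestamp: float = 0.0


def _command_name(cmd: "str | ClassLabel | CommandEvent") -> str:
    if isinstance(cmd, CommandEvent):
        return cmd.command
    if isinstance(cmd, ClassLabel):
        return cmd.name
    return str(cmd)


def next_state(state: DriveState, cmd: "str | ClassLabel") -> DriveState:
    """Total transition function; unsafe or unrecognised requests leave the
    state unchanged rather than raising.

    - off  --switch_on-->  neutral; every other command keeps it off.
    - any state  --switch_off-->  off (emergency stop).
    - neutral  --motion command-->  that motion.
    - a motion state accepts only ``neutral`` (stop), its own command
      (keep going) or ``switch_off``; in particular the opposite motion
      is rejected, so forward<->backward and left<->right always pass
      through neutral.
    """
    name = _command_name(cmd)
    if name == "switch_off":
        return DriveState.OFF
    if state is DriveState.OFF:
        return DriveState.NEUTRAL if name == "switch_on" else DriveState.OFF
    if state is DriveState.NEUTRAL:
        return _MOTION_FOR.get(name, DriveState.NEUTRAL)
    # motion state
    if name == "neutral":
        return DriveState.NEUTRAL
    if _MOTION_FOR.get(name) is state:
        return state
    return state  # opposite or orthogonal motion, switch_on, unknown: rejected


def debounce(
    commands: Iterable["str | ClassLabel | CommandEvent"], k: int = 3
) -> list:
    """Pass a command through only once it has occurred k times in a row.

    The counter resets whenever the command changes; after reaching k the
    (still identical) command keeps being emitted, so a held command keeps
    driving.  ``k=1`` is the identity.
    """
    if k < 1:
        raise ConfigError("debounce count k must be >= 1")
    out = []
    run_name: str | None = None
    run_len = 0
    for cmd in commands:
        name = _command_name(cmd)
        if name == run_name:
            run_len += 1
        else:
            run_name = name
            run_len = 1
        if run_len >= k:
            out.append(cmd)
    return out


@dataclass
class TrajectoryStep:
    timestamp: float
    command: str
    accepted: bool
    state: DriveState


def simulate_drive(
    events: Iterable[CommandEvent],
    k: int = 3,
    initial: DriveState = DriveState.OFF,
) -> list[TrajectoryStep]:
    """Run debounced commands through the state machine, recording for each
    incoming event whether it acted and the resulting state."""
    if k < 1:
        raise ConfigError("debounce count k must be >= 1")
    state = initial
    steps: list[TrajectoryStep] = []
    run_name: str | None = None
    run_len = 0
    for ev in events:
        name = _command_name(ev)
        run_len = run_len + 1 if name == run_name else 1
        run_name = name
        accepted = run_len >= k
        if accepted:
            state = next_state(state, name)
        steps.append(TrajectoryStep(
            getattr(ev, "timestamp", 0.0), name, accepted, state
        ))
    return steps
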
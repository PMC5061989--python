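"""Synthetic 14-channel EEG with class-distinct spectral content.

No public recordings accompany the protocol this package reproduces, so
the generator stands in for the headset: each command class is a set of
sinusoidal tones (frequency, amplitude, random phase) on a class-specific
subset of the 14 channels, buried in white Gaussian noise.  The gesture
classes carry substantially more spectral power than the neutral resting
pose — the property that makes real gesture EEG separable — while tone
frequencies stay below 32 Hz so they land inside the 64-bin feature band
(0.5 Hz resolution with 2-s windows at 128 Hz).

This emulates the *pipeline-relevant* structure of gesture EEG, not its
physiology: there is no 1/f background, no blink/EMG artefacts and no
inter-subject variability.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .eeg import EMOTIV_CHANNELS, Recording, samples_for
from .errors import ConfigError, ToneFrequencyError

DEFAULT_DURATION_S = 10.0
DEFAULT_NOISE_SD = 0.05
N_CHANNELS = len(EMOTIV_CHANNELS)


@dataclass(frozen=True)
class ClassSpec:
    """Spectral recipe for one command class."""

    name: str
    tone_freqs: tuple[float, ...]
    tone_amps: tuple[float, ...]
    active_channels: tuple[int, ...]
    noise_sd: float = DEFAULT_NOISE_SD

    def __post_init__(self) -> None:
        if len(self.tone_freqs) != len(self.tone_amps):
            raise ConfigError("one amplitude per tone frequency")
        for f in self.tone_freqs:
            if not (0 < f < 32):
                raise ToneFrequencyError(
                    f"tone {f} Hz outside the representable band (0, 32) Hz"
                )
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be >= 0")
        for ch in self.active_channels:
            if not (0 <= ch < N_CHANNELS):
                raise ConfigError(f"channel index {ch} out of range")


#: Default recipes: neutral is a faint 10 Hz posterior rhythm; each command
#: class has a distinct frequency pair on a distinct channel subset, with
#: total power well above neutral.  All frequencies sit exactly on 0.5 Hz
#: bins of the default 256-sample transform.
DEFAULT_CLASS_SPECS: dict[str, ClassSpec] = {
    "neutral": ClassSpec(
        "neutral", (10.0,), (0.2,), tuple(range(N_CHANNELS))
    ),
    "forward": ClassSpec(
        "forward", (6.0, 14.0), (1.0, 0.8), (0, 1, 2, 3, 4, 5, 6)
    ),
    "backward": ClassSpec(
        "backward", (8.0, 18.0), (1.0, 0.8), (7, 8, 9, 10, 11, 12, 13)
    ),
    "left": ClassSpec(
        "left", (12.0, 22.0), (1.0, 0.8), (0, 2, 4, 6, 8, 10, 12)
    ),
    "right": ClassSpec(
        "right", (16.0, 26.0), (1.0, 0.8), (1, 3, 5, 7, 9, 11, 13)
    ),
    "switch_on": ClassSpec(
        "switch_on", (20.0, 30.0), (1.0, 0.8), (3, 4, 5, 6, 7, 8, 9, 10)
    ),
    "switch_off": ClassSpec(
        "switch_off", (4.0, 24.0), (1.0, 0.8), (2, 5, 8, 11)
    ),
}

#: The six classes of the standard protocol.  The neutral pose is included
#: because the downstream safety state machine can only stop the chair via
#: a classified ``neutral``.
DEFAULT_PROTOCOL_CLASSES: tuple[str, ...] = (
    "forward", "backward", "left", "right", "switch_on", "neutral",
)


def default_specs(
    names: Sequence[str] = DEFAULT_PROTOCOL_CLASSES,
    noise_sd: float | None = None,
) -> list[ClassSpec]:
    """The default six-class protocol specs, optionally overriding noise."""
    specs = []
    for name in names:
        spec = DEFAULT_CLASS_SPECS[name]
        if noise_sd is not None:
            spec = ClassSpec(spec.name, spec.tone_freqs, spec.tone_amps,
                             spec.active_channels, noise_sd)
        specs.append(spec)
    return specs


def generate_recording(
    spec: ClassSpec,
    duration_s: float = DEFAULT_DURATION_S,
    sample_rate: float = 128.0,
    seed: int | None = None,
    source_id: str | None = None,
) -> Recording:
    """One labelled recording: tones (with per-channel random phase) on the
    active channels plus white noise everywhere.  Deterministic given seed."""
    n = samples_for(duration_s, sample_rate)
    rng = np.random.default_rng(seed)
    t = np.arange(n) / sample_rate
    data = rng.normal(0.0, spec.noise_sd, size=(n, N_CHANNELS))
    for freq, amp in zip(spec.tone_freqs, spec.tone_amps):
        phases = rng.uniform(0.0, 2.0 * np.pi, size=len(spec.active_channels))
        tone = amp * np.sin(2.0 * np.pi * freq * t[:, None] + phases)
        data[:, list(spec.active_channels)] += tone
    return Recording(
        channels=EMOTIV_CHANNELS,
        data=data,
        sample_rate=sample_rate,
        label=spec.name,
        source_id=source_id or f"synthetic_{spec.name}",
    )


def generate_dataset(
    n_per_class: int = 1,
    specs: Sequence[ClassSpec] | None = None,
    duration_s: float = DEFAULT_DURATION_S,
    sample_rate: float = 128.0,
    seed: int | None = None,
) -> list[Recording]:
    """Labelled recordings for every class, ``n_per_class`` each.

    Per-recording seeds are spawned from ``seed`` so two datasets with
    distinct seeds differ only in their noise/phase realisations.
    """
    if n_per_class < 1:
        raise ConfigError("need at least one recording per class")
    if specs is None:
        specs = default_specs()
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(specs) * n_per_class)
    out: list[Recording] = []
    ci = 0
    for spec in specs:
        for rep in range(n_per_class):
            child_seed = int(children[ci].generate_state(1)[0] % (2 ** 31))
            ci += 1
            out.append(generate_recording(
                spec, duration_s, sample_rate, child_seed,
                source_id=f"synthetic_{spec.name}_{rep}",
            ))
    return out
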
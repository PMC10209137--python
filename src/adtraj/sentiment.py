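"""Per-trajectory aggregation of pre-extracted clinical-note sentiment events.

Each event is a detected moment-of-change sentence on one of four recovery
themes, carrying a +1 or -1 polarity.  The NLP detection itself is upstream;
this module only averages polarities of events falling inside a trajectory's
prescription window into one signed mean score per theme.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from .trajectories import TreatmentTrajectory

THEMES: tuple[str, ...] = ("core_complaints", "social_functioning",
                           "well_being", "experience")


@dataclass(frozen=True)
class SentimentEvent:
    patient_id: str
    theme: str
    day: int
    polarity: int  # +1 or -1

    def __post_init__(self) -> None:
        if self.theme not in THEMES:
            raise ValueError(f"unknown theme {self.theme!r}")
        if self.polarity not in (1, -1):
            raise ValueError(f"polarity must be +1 or -1, got {self.polarity}")


def aggregate_sentiment(events: Iterable[SentimentEvent],
                        trajectory: TreatmentTrajectory) -> dict[str, float]:
    """Mean polarity per theme over events inside [start, end].

    Events outside the trajectory window or belonging to other patients are
    ignored.  A theme with no events scores 0, which the downstream >= 0
    binarization reads as non-negative; the choice is recorded on the
    trajectory so it can be audited.
    """
    sums = {t: 0 for t in THEMES}
    counts = {t: 0 for t in THEMES}
    for ev in events:
        if ev.patient_id != trajectory.patient_id:
            continue
        if not trajectory.start <= ev.day <= trajectory.end:
            continue
        sums[ev.theme] += ev.polarity
        counts[ev.theme] += 1
    means = {t: (sums[t] / counts[t]) if counts[t] else 0.0 for t in THEMES}
    trajectory.sentiment_means = means
    return means


def read_sentiment_csv(path: str | Path) -> list[SentimentEvent]:
    with open(path, newline="") as fh:
        return [SentimentEvent(row["patient_id"], row["theme"],
                               int(row["day"]), int(row["polarity"]))
                for row in csv.DictReader(fh)]


def write_sentiment_csv(events: Sequence[SentimentEvent], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["patient_id", "theme", "day", "polarity"])
        for ev in events:
            w.writerow([ev.patient_id, ev.theme, ev.day, ev.polarity])
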
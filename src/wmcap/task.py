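"""Task geometry, trial epochs, and core in-memory containers.

The change-localization task shows an array of 2-5 colored squares at six
fixed screen locations (three per hemifield), holds them for an 800 ms
sample phase, blanks the screen for a 1000 ms memory delay, and then probes
with the array reappearing with one color exchanged; the subject reports the
changed location.  Each location carries one of two session-specific colors,
labelled A and B.  All timestamps downstream are in seconds relative to
sample onset.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

# Screen layout: locations 1-3 are in the left hemifield, 4-6 in the right.
LOCATIONS: tuple[int, ...] = (1, 2, 3, 4, 5, 6)
LEFT_LOCATIONS: tuple[int, ...] = (1, 2, 3)
RIGHT_LOCATIONS: tuple[int, ...] = (4, 5, 6)
COLORS: tuple[str, ...] = ("A", "B")

# Trial epoch durations in seconds (fixation precedes sample onset at t=0).
FIXATION_S = 0.16
SAMPLE_S = 0.80
DELAY_S = 1.00
CHOICE_S = 4.00

#: Width of the analysis bin used for information timecourses.
BIN_WIDTH_S = 0.20

OUTCOMES = ("correct", "error", "aborted", "no_response")


class ConfigurationError(ValueError):
    """Raised for invalid generator or analysis configuration."""


class DomainError(ValueError):
    """Raised when an operation's input violates its domain."""


def hemifield(location: int) -> str:
    if location in LEFT_LOCATIONS:
        return "left"
    if location in RIGHT_LOCATIONS:
        return "right"
    raise DomainError(f"unknown location {location!r}")


def hemifield_locations(side: str) -> tuple[int, ...]:
    if side == "left":
        return LEFT_LOCATIONS
    if side == "right":
        return RIGHT_LOCATIONS
    raise DomainError(f"unknown hemifield {side!r}")


@dataclass
class TrialRecord:
    """One behavioral trial.

    ``colors_shown`` maps displayed locations to their color label; absent
    locations were blank.  ``target_location`` is where the color changed at
    choice.  ``response_location`` is None until an outcome is assigned or
    when no response was made.
    """

    trial_id: int
    session_id: int
    colors_shown: dict[int, str]
    target_location: int
    response_location: int | None = None
    outcome: str | None = None

    @property
    def n_left(self) -> int:
        return sum(1 for loc in self.colors_shown if loc in LEFT_LOCATIONS)

    @property
    def n_right(self) -> int:
        return sum(1 for loc in self.colors_shown if loc in RIGHT_LOCATIONS)

    @property
    def total_load(self) -> int:
        return len(self.colors_shown)

    def load(self, side: str) -> int:
        return self.n_left if side == "left" else self.n_right

    def ipsi_load(self) -> int:
        """Items in the hemifield containing the target (behavioral ipsi)."""
        return self.load(hemifield(self.target_location))

    def contra_load(self) -> int:
        side = hemifield(self.target_location)
        return self.load("right" if side == "left" else "left")

    def validate(self) -> None:
        for loc, col in self.colors_shown.items():
            if loc not in LOCATIONS:
                raise DomainError(f"trial {self.trial_id}: bad location {loc}")
            if col not in COLORS:
                raise DomainError(f"trial {self.trial_id}: bad color {col!r}")
        if self.target_location not in self.colors_shown:
            raise DomainError(
                f"trial {self.trial_id}: target location {self.target_location} "
                "has no color shown"
            )
        nl, nr = self.n_left, self.n_right
        if not (1 <= nl <= 3 and 1 <= nr <= 3 and 2 <= nl + nr <= 5):
            raise DomainError(
                f"trial {self.trial_id}: load combination ({nl},{nr}) outside "
                "the 2-5 item design"
            )
        if self.outcome is not None:
            if self.outcome not in OUTCOMES:
                raise DomainError(
                    f"trial {self.trial_id}: unknown outcome {self.outcome!r}"
                )
            if self.outcome == "correct" and self.response_location != self.target_location:
                raise DomainError(
                    f"trial {self.trial_id}: outcome 'correct' but response "
                    "does not match target"
                )
            if self.outcome == "error" and self.response_location == self.target_location:
                raise DomainError(
                    f"trial {self.trial_id}: outcome 'error' but response "
                    "matches target"
                )


@dataclass
class SpikeTrain:
    """Spike timestamps of one neuron on one trial, seconds from sample onset."""

    neuron_id: int
    trial_id: int
    timestamps: np.ndarray

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)

    def validate(self, t_min: float = -FIXATION_S,
                 t_max: float = SAMPLE_S + DELAY_S + CHOICE_S) -> None:
        ts = self.timestamps
        if ts.size and np.any(np.diff(ts) < 0):
            raise DomainError(
                f"neuron {self.neuron_id} trial {self.trial_id}: "
                "timestamps not sorted"
            )
        if ts.size and (ts[0] < t_min - 1e-9 or ts[-1] > t_max + 1e-9):
            raise DomainError(
                f"neuron {self.neuron_id} trial {self.trial_id}: "
                f"timestamps outside [{t_min}, {t_max}]"
            )


class SpikeTable:
    """Indexed collection of spike trains with fast count queries."""

    def __init__(self, trains: Iterable[SpikeTrain]):
        self._by_key: dict[tuple[int, int], np.ndarray] = {}
        neurons: set[int] = set()
        trials: set[int] = set()
        for tr in trains:
            key = (tr.neuron_id, tr.trial_id)
            if key in self._by_key:
                self._by_key[key] = np.sort(
                    np.concatenate([self._by_key[key], tr.timestamps])
                )
            else:
                self._by_key[key] = np.asarray(tr.timestamps, dtype=float)
            neurons.add(tr.neuron_id)
            trials.add(tr.trial_id)
        self.neuron_ids = sorted(neurons)
        self.trial_ids = sorted(trials)

    def timestamps(self, neuron_id: int, trial_id: int) -> np.ndarray:
        return self._by_key.get((neuron_id, trial_id), np.empty(0))

    def count(self, neuron_id: int, trial_id: int,
              t0: float, t1: float) -> int:
        """Spikes in the half-open window [t0, t1)."""
        ts = self.timestamps(neuron_id, trial_id)
        return int(np.searchsorted(ts, t1, side="left")
                   - np.searchsorted(ts, t0, side="left"))

    def counts(self, neuron_id: int, trial_ids: Iterable[int],
               t0: float, t1: float) -> np.ndarray:
        return np.array(
            [self.count(neuron_id, t, t0, t1) for t in trial_ids], dtype=float
        )

    def binned(self, neuron_id: int, trial_ids: Iterable[int],
               edges: np.ndarray) -> np.ndarray:
        """Counts per half-open bin [edges[i], edges[i+1]) per trial."""
        edges = np.asarray(edges, dtype=float)
        trial_ids = list(trial_ids)
        out = np.empty((len(trial_ids), len(edges) - 1))
        for i, tid in enumerate(trial_ids):
            ts = self.timestamps(neuron_id, tid)
            idx = np.searchsorted(ts, edges, side="left")
            out[i] = np.diff(idx)
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for (nid, tid), ts in sorted(self._by_key.items()):
            for t in ts:
                rows.append((nid, tid, t))
        return pd.DataFrame(rows, columns=["neuron_id", "trial_id", "t"])


# ---------------------------------------------------------------------------
# Trial table <-> DataFrame conversion

_LOC_COLS = [f"loc{i}" for i in LOCATIONS]

TRIAL_COLUMNS = (
    ["trial_id", "session_id"] + _LOC_COLS
    + ["n_left", "n_right", "target_location", "response_location", "outcome"]
)


def trials_to_frame(trials: Iterable[TrialRecord]) -> pd.DataFrame:
    rows = []
    for t in trials:
        row: dict[str, object] = {"trial_id": t.trial_id, "session_id": t.session_id}
        for loc in LOCATIONS:
            row[f"loc{loc}"] = t.colors_shown.get(loc, "")
        row["n_left"] = t.n_left
        row["n_right"] = t.n_right
        row["target_location"] = t.target_location
        row["response_location"] = (
            -1 if t.response_location is None else t.response_location
        )
        row["outcome"] = t.outcome if t.outcome is not None else ""
        rows.append(row)
    return pd.DataFrame(rows, columns=TRIAL_COLUMNS)


def frame_to_trials(df: pd.DataFrame) -> list[TrialRecord]:
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise DomainError(f"trial table missing columns: {missing}")
    trials = []
    for i, row in enumerate(df.itertuples(index=False)):
        colors = {}
        for loc in LOCATIONS:
            val = getattr(row, f"loc{loc}")
            if isinstance(val, str) and val:
                colors[loc] = val
        resp = int(row.response_location)
        outcome = row.outcome if isinstance(row.outcome, str) and row.outcome else None
        rec = TrialRecord(
            trial_id=int(row.trial_id),
            session_id=int(row.session_id),
            colors_shown=colors,
            target_location=int(row.target_location),
            response_location=None if resp < 0 else resp,
            outcome=outcome,
        )
        try:
            rec.validate()
        except DomainError as exc:
            raise DomainError(f"row {i}: {exc}") from exc
        trials.append(rec)
    return trials


def as_trial_list(trials) -> list[TrialRecord]:
    """Accept either a list of TrialRecord or a trial-table DataFrame."""
    if isinstance(trials, pd.DataFrame):
        return frame_to_trials(trials)
    return list(trials)
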
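"""Acquisition schedules: generation, truncation, and TSV round-tripping.

A schedule is an ordered list of saturation/readout events.  Order matters:
the spin system is never re-equilibrated between entries, so the signal of
entry *i* depends on everything before it.  Truncation therefore always keeps
the *first* N entries — images can only be dropped from the end of the
acquisition, not the beginning.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, List

import numpy as np
import pandas as pd

__all__ = ["ScheduleEntry", "AcquisitionSchedule",
           "generate_pseudorandom_schedule", "truncate_schedule",
           "read_schedule", "write_schedule", "SCHEDULE_COLUMNS"]

#: TSV column order; one row per schedule entry.
SCHEDULE_COLUMNS = ["sat_power", "sat_offset", "n_pulses", "pulse_duration",
                    "interpulse_delay", "recovery_delay", "flip_angle",
                    "echo_time"]

#: maximum saturation power (uT) drawn by the pseudo-random generator
MAX_SAT_POWER = 4.0


class ScheduleParseError(ValueError):
    """A schedule file is malformed; message carries row/column context."""


@dataclass(frozen=True)
class ScheduleEntry:
    """One saturation + snapshot-readout event.

    The saturation block is a train of ``n_pulses`` block pulses of
    ``pulse_duration`` seconds at ``sat_power`` uT (average amplitude) and
    ``sat_offset`` ppm, separated by ``interpulse_delay`` seconds of free
    relaxation with no gap after the last pulse (13 x 100 ms at 50% duty
    cycle = 2500 ms total by default).  ``echo_time`` is informational.
    """

    sat_power: float
    sat_offset: float
    n_pulses: int = 13
    pulse_duration: float = 0.1
    interpulse_delay: float = 0.1
    recovery_delay: float = 2.5
    flip_angle: float = 15.0
    echo_time: float = 0.011

    def __post_init__(self) -> None:
        if self.sat_power < 0:
            raise ValueError("sat_power must be >= 0")
        for name in ("pulse_duration", "interpulse_delay", "recovery_delay",
                     "echo_time"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_pulses < 1:
            raise ValueError("n_pulses must be >= 1")


@dataclass
class AcquisitionSchedule:
    """Ordered acquisition schedule; ``M = len(schedule)``."""

    entries: List[ScheduleEntry]
    label: str = ""

    def __post_init__(self) -> None:
        if len(self.entries) < 1:
            raise ValueError("schedule must contain at least one entry")

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self) -> Iterator[ScheduleEntry]:
        return iter(self.entries)

    def __getitem__(self, i):
        return self.entries[i]

    @property
    def m(self) -> int:
        return len(self.entries)

    def __eq__(self, other) -> bool:
        return (isinstance(other, AcquisitionSchedule)
                and self.entries == other.entries and self.label == other.label)


def generate_pseudorandom_schedule(m: int, mode: str = "cest_3ppm",
                                   seed: int = 0, recovery_delay: float = 2.5,
                                   m0_first: bool = False,
                                   ) -> AcquisitionSchedule:
    """Seeded pseudo-random schedule with the standard saturation ranges.

    Powers are uniform on [0, 4] uT.  Offsets are fixed at 3 ppm in
    ``cest_3ppm`` mode (amide-type CEST phantom imaging) or uniform on
    [6, 14] ppm in ``mt_sweep`` mode (semisolid-MT imaging).  The PCG64
    generator behind :func:`numpy.random.default_rng` makes the draw
    reproducible across platforms for a fixed seed.

    With ``m0_first`` the first entry's power is forced to zero, placing an
    unsaturated M0 normalization image at the schedule head (the customary
    protocol design when downstream processing divides the stack by its
    first image).
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    if mode not in ("cest_3ppm", "mt_sweep"):
        raise ValueError(f"unknown mode {mode!r}")
    rng = np.random.default_rng(seed)
    powers = rng.uniform(0.0, MAX_SAT_POWER, size=m)
    if m0_first:
        powers[0] = 0.0
    if mode == "cest_3ppm":
        offsets = np.full(m, 3.0)
    else:
        offsets = rng.uniform(6.0, 14.0, size=m)
    entries = [ScheduleEntry(sat_power=float(p), sat_offset=float(o),
                             recovery_delay=recovery_delay)
               for p, o in zip(powers, offsets)]
    return AcquisitionSchedule(entries, label=f"{mode}_m{m}_seed{seed}")


def truncate_schedule(schedule: AcquisitionSchedule, n: int) -> AcquisitionSchedule:
    """Keep the first ``n`` entries (drop images only from the schedule end)."""
    if not 1 <= n <= len(schedule):
        raise ValueError(f"n must be in [1, {len(schedule)}], got {n}")
    label = schedule.label if n == len(schedule) else f"{schedule.label}_trunc{n}"
    return AcquisitionSchedule(list(schedule.entries[:n]), label=label)


def write_schedule(schedule: AcquisitionSchedule, path) -> None:
    """Serialize to TSV with 17 significant digits (bit-exact round trip)."""
    df = pd.DataFrame([{c: getattr(e, c) for c in SCHEDULE_COLUMNS}
                       for e in schedule])
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_schedule(path, label: str = "") -> AcquisitionSchedule:
    """Parse a TSV schedule; errors carry row/column context."""
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    except pd.errors.EmptyDataError as exc:
        raise ScheduleParseError(f"{path}: empty schedule file") from exc
    missing = [c for c in SCHEDULE_COLUMNS if c not in df.columns]
    if missing:
        raise ScheduleParseError(f"{path}: missing columns {missing}")
    if len(df) == 0:
        raise ScheduleParseError(f"{path}: header-only file, no entries")
    entries = []
    for i, row in df.iterrows():
        vals = {}
        for c in SCHEDULE_COLUMNS:
            try:
                vals[c] = int(row[c]) if c == "n_pulses" else float(row[c])
            except (TypeError, ValueError) as exc:
                raise ScheduleParseError(
                    f"{path}: non-numeric value {row[c]!r} at row {i}, "
                    f"column {c!r}") from exc
        try:
            entries.append(ScheduleEntry(**vals))
        except ValueError as exc:
            raise ScheduleParseError(f"{path}: row {i}: {exc}") from exc
    return AcquisitionSchedule(entries, label=label or path.stem)
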
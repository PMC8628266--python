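"""Tumor-volume computation, endpoint detection and survival summaries.

Caliper measurements are canonicalized so length >= width before the
asymmetric volume formula V = length × width² / 2 is applied.  The humane
endpoint is the first measurement day on which the tumor diameter reaches a
threshold (12 mm default); animals never reaching it are censored at the end
of observation.  Group survival is summarised with the product-limit
estimator.
"""

from __future__ import annotations

import dataclasses
from bisect import bisect_right
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from ritpipe.errors import TableParseError, ValidationError

DEFAULT_ENDPOINT_DIAMETER_MM = 12.0
DEFAULT_OBSERVATION_END_D = 56.0

CALIPER_COLUMNS = ("animal_id", "group", "day", "length_mm", "width_mm")
SURVIVAL_COLUMNS = ("animal_id", "group", "time_d", "event")

DIAMETER_MODES = ("max", "mean")


def tumor_volume(length_mm: float, width_mm: float) -> float:
    """V = length × width² / 2 (mm³) with arguments canonicalized length >= width."""
    if length_mm < 0 or width_mm < 0:
        raise ValidationError(
            f"caliper dimensions must be >= 0, got ({length_mm}, {width_mm})"
        )
    length, width = max(length_mm, width_mm), min(length_mm, width_mm)
    return length * width * width / 2.0


@dataclass(frozen=True)
class TumorMeasurement:
    """One caliper measurement; volume is derived, never supplied."""

    animal_id: str
    group: str
    day: float
    length_mm: float
    width_mm: float
    volume_mm3: float = field(init=False)

    def __post_init__(self) -> None:
        if self.day < 0:
            raise ValidationError(f"day must be >= 0, got {self.day}")
        vol = tumor_volume(self.length_mm, self.width_mm)  # validates dimensions
        length = max(self.length_mm, self.width_mm)
        width = min(self.length_mm, self.width_mm)
        object.__setattr__(self, "length_mm", length)
        object.__setattr__(self, "width_mm", width)
        object.__setattr__(self, "volume_mm3", vol)

    def diameter(self, mode: str = "max") -> float:
        if mode not in DIAMETER_MODES:
            raise ValidationError(f"unknown diameter mode {mode!r}")
        if mode == "max":
            return self.length_mm
        return 0.5 * (self.length_mm + self.width_mm)


@dataclass(frozen=True)
class SurvivalRecord:
    """Time to humane endpoint (event=True) or censoring (event=False)."""

    animal_id: str
    group: str
    time_d: float
    event: bool

    def __post_init__(self) -> None:
        if self.time_d < 0:
            raise ValidationError(f"time_d must be >= 0, got {self.time_d}")


def read_tumor_measurements(path: str | Path, delimiter: str | None = None) -> list[TumorMeasurement]:
    """Parse a caliper table (animal_id, group, day, length_mm, width_mm)."""
    try:
        frame = pd.read_csv(path, sep=delimiter, engine="python")
    except Exception as exc:  # pragma: no cover
        raise TableParseError(f"could not read {path}: {exc}") from exc
    missing = [c for c in CALIPER_COLUMNS if c not in frame.columns]
    if missing:
        raise TableParseError(f"{path}: missing required column(s) {missing}")
    out = []
    for i, row in enumerate(frame.itertuples(index=False)):
        rownum = i + 2
        vals = {}
        for col in ("day", "length_mm", "width_mm"):
            raw = getattr(row, col)
            try:
                vals[col] = float(raw)
            except (TypeError, ValueError):
                raise TableParseError(f"non-numeric value {raw!r}", row=rownum, column=col) from None
        try:
            out.append(TumorMeasurement(str(row.animal_id), str(row.group), **vals))
        except ValidationError as exc:
            raise TableParseError(str(exc), row=rownum) from exc
    return out


def write_tumor_measurements(measurements: Iterable[TumorMeasurement], path: str | Path) -> None:
    rows = [
        (m.animal_id, m.group, m.day, m.length_mm, m.width_mm) for m in measurements
    ]
    pd.DataFrame(rows, columns=CALIPER_COLUMNS).to_csv(path, index=False)


def _sorted_series(series: Sequence[TumorMeasurement]) -> list[TumorMeasurement]:
    if not series:
        raise ValidationError("measurement series is empty")
    ordered = sorted(series, key=lambda m: m.day)
    days = [m.day for m in ordered]
    if len(set(days)) != len(days):
        raise ValidationError("measurement series contains duplicate days")
    return ordered


def normalized_volume(
    series: Sequence[TumorMeasurement],
    day: float,
    baseline_day: float = 0.0,
    baseline_window_d: float = 0.0,
) -> float:
    """V(day) / V(baseline), baseline = the day-0 measurement.

    A baseline within ``baseline_window_d`` of ``baseline_day`` is accepted
    (nearest wins); the target day must match exactly.
    """
    ordered = _sorted_series(series)
    candidates = [m for m in ordered if abs(m.day - baseline_day) <= baseline_window_d]
    if not candidates:
        raise ValidationError(
            f"no baseline measurement within {baseline_window_d} d of day {baseline_day}"
        )
    baseline = min(candidates, key=lambda m: abs(m.day - baseline_day))
    if baseline.volume_mm3 <= 0:
        raise ValidationError("baseline volume is zero; normalization undefined")
    target = [m for m in ordered if m.day == day]
    if not target:
        raise ValidationError(f"no measurement at day {day}")
    return target[0].volume_mm3 / baseline.volume_mm3


def endpoint_time(
    series: Sequence[TumorMeasurement],
    endpoint_diameter_mm: float = DEFAULT_ENDPOINT_DIAMETER_MM,
    observation_end_d: float = DEFAULT_OBSERVATION_END_D,
    diameter_mode: str = "max",
) -> SurvivalRecord:
    """First measurement day the tumor diameter reaches the endpoint.

    If never reached the animal is censored at min(last measurement day,
    observation end).  Event time is the measurement day of first crossing
    (no interpolation between discrete measurement days).
    """
    ordered = _sorted_series(series)
    animal_id, group = ordered[0].animal_id, ordered[0].group
    for m in ordered:
        if m.diameter(diameter_mode) >= endpoint_diameter_mm:
            return SurvivalRecord(animal_id, group, m.day, True)
    return SurvivalRecord(animal_id, group, min(ordered[-1].day, observation_end_d), False)


@dataclass(frozen=True)
class SurvivalCurve:
    """Right-continuous product-limit step function S(t).

    ``times`` are the distinct event times; ``survival`` the value of S just
    after each.  S(t) = 1 for t before the first event.
    """

    times: np.ndarray
    survival: np.ndarray
    n_total: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "times", np.asarray(self.times, dtype=float))
        object.__setattr__(self, "survival", np.asarray(self.survival, dtype=float))
        if np.any(np.diff(self.survival) > 1e-12):
            raise ValidationError("survival function must be non-increasing")

    def __call__(self, t: float) -> float:
        if t < 0:
            return 1.0
        idx = bisect_right(self.times.tolist(), t)
        return 1.0 if idx == 0 else float(self.survival[idx - 1])


def survival_curve(records: Sequence[SurvivalRecord]) -> SurvivalCurve:
    """Product-limit (Kaplan-Meier) estimate from one group's records.

    At each distinct event time t: S ← S × (1 − d(t)/n(t)) where d(t) is the
    number of events at t and n(t) the number still at risk (censoring times
    equal to t are counted at risk, the standard convention).
    """
    if not records:
        raise ValidationError("no survival records")
    times = np.array([r.time_d for r in records])
    events = np.array([r.event for r in records])
    event_times = np.unique(times[events])
    s = 1.0
    surv = []
    for t in event_times:
        at_risk = int(np.sum(times >= t))
        d = int(np.sum((times == t) & events))
        s *= 1.0 - d / at_risk
        surv.append(s)
    return SurvivalCurve(times=event_times, survival=np.array(surv), n_total=len(records))


def survival_curve_frame(curve: SurvivalCurve) -> pd.DataFrame:
    rows = [(0.0, 1.0)] + list(zip(curve.times, curve.survival))
    return pd.DataFrame(rows, columns=("time_d", "survival"))


def write_survival_records(records: Iterable[SurvivalRecord], path: str | Path) -> None:
    rows = [(r.animal_id, r.group, r.time_d, int(r.event)) for r in records]
    pd.DataFrame(rows, columns=SURVIVAL_COLUMNS).to_csv(path, index=False)


def body_weight_change(series: Sequence[tuple[float, float]]) -> list[tuple[float, float]]:
    """Relative change vs day 0: weight(day)/weight(0) − 1 for every day."""
    if not series:
        raise ValidationError("body-weight series is empty")
    ordered = sorted(series, key=lambda p: p[0])
    baseline = [w for d, w in ordered if d == 0]
    if not baseline:
        raise ValidationError("body-weight series lacks a day-0 measurement")
    if baseline[0] <= 0:
        raise ValidationError("day-0 body weight must be > 0")
    w0 = baseline[0]
    return [(d, w / w0 - 1.0) for d, w in ordered]


def group_series(
    measurements: Iterable[TumorMeasurement],
) -> dict[tuple[str, str], list[TumorMeasurement]]:
    """Split a flat measurement list into per-(group, animal) series."""
    out: dict[tuple[str, str], list[TumorMeasurement]] = {}
    for m in measurements:
        out.setdefault((m.group, m.animal_id), []).append(m)
    return {k: sorted(v, key=lambda m: m.day) for k, v in sorted(out.items())}
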
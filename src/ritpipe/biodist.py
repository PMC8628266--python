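"""Biodistribution ingestion, body-weight normalization, and group summaries.

Measurements arrive as one row per (animal, organ, time) with the activity
concentration expressed as percent injected dose per gram of tissue (%ID/g).
The terminal-sampling design means each time point is a distinct cohort of
animals, so curves are summarised per (group, organ) with per-time mean,
sample SD and n.
"""

from __future__ import annotations

import dataclasses
from collections import defaultdict
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from ritpipe.errors import TableParseError, ValidationError

#: Organs sampled by the default study design.
DEFAULT_ORGANS: tuple[str, ...] = (
    "blood",
    "lung",
    "liver",
    "spleen",
    "pancreas",
    "intestine",
    "kidney",
    "muscle",
    "bone",
    "tumor",
)

#: Reference body weight (g) that reported %ID/g values are normalized to.
REFERENCE_BODY_WEIGHT_G = 20.0

RECORD_COLUMNS = ("animal_id", "group", "organ", "time_h", "percent_id_per_g", "body_weight_g")

CURVE_COLUMNS = ("group", "organ", "time_h", "mean_pidg", "sd_pidg", "n")


@dataclass(frozen=True)
class BiodistributionRecord:
    """One %ID/g measurement for one animal, organ and time point."""

    animal_id: str
    group: str
    organ: str
    time_h: float
    percent_id_per_g: float
    body_weight_g: float

    def __post_init__(self) -> None:
        if self.time_h < 0:
            raise ValidationError(f"time_h must be >= 0, got {self.time_h}")
        if self.percent_id_per_g < 0:
            raise ValidationError(f"percent_id_per_g must be >= 0, got {self.percent_id_per_g}")
        if not self.body_weight_g > 0:
            raise ValidationError(f"body_weight_g must be > 0, got {self.body_weight_g}")


@dataclass(frozen=True)
class TimeActivityCurve:
    """Per-(group, organ) time course of mean ± SD %ID/g with cohort sizes."""

    organ: str
    group: str
    times_h: np.ndarray
    mean_pidg: np.ndarray
    sd_pidg: np.ndarray
    n: np.ndarray

    def __post_init__(self) -> None:
        for name in ("times_h", "mean_pidg", "sd_pidg", "n"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        lengths = {len(self.times_h), len(self.mean_pidg), len(self.sd_pidg), len(self.n)}
        if lengths != {len(self.times_h)}:
            raise ValidationError("times/mean/sd/n must have equal lengths")
        if len(self.times_h) == 0:
            raise ValidationError("curve must have at least one time point")
        if np.any(np.diff(self.times_h) <= 0):
            raise ValidationError("times_h must be strictly increasing")
        if np.any(self.mean_pidg < 0) or np.any(self.sd_pidg < 0):
            raise ValidationError("mean and sd must be >= 0")

    def value_at(self, time_h: float) -> float:
        """Mean %ID/g at an exactly matching time point (no interpolation)."""
        idx = np.nonzero(np.isclose(self.times_h, time_h, rtol=0.0, atol=1e-9))[0]
        if idx.size == 0:
            raise ValidationError(
                f"time {time_h} h not present in curve ({self.group}, {self.organ})"
            )
        return float(self.mean_pidg[idx[0]])


def read_biodistribution(
    path: str | Path,
    delimiter: str | None = None,
    organ_whitelist: Sequence[str] | None = DEFAULT_ORGANS,
) -> list[BiodistributionRecord]:
    """Parse a delimited biodistribution table into validated records.

    Comma is the default delimiter; tab-separated files are accepted
    automatically (``delimiter=None`` sniffs).  Row order is preserved.
    """
    try:
        frame = pd.read_csv(path, sep=delimiter, engine="python")
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise TableParseError(f"could not read {path}: {exc}") from exc
    missing = [c for c in RECORD_COLUMNS if c not in frame.columns]
    if missing:
        raise TableParseError(f"{path}: missing required column(s) {missing}")

    whitelist = set(organ_whitelist) if organ_whitelist is not None else None
    records: list[BiodistributionRecord] = []
    for i, row in enumerate(frame.itertuples(index=False)):
        rownum = i + 2  # 1-based with header line
        values = {}
        for col in ("time_h", "percent_id_per_g", "body_weight_g"):
            raw = getattr(row, col)
            try:
                values[col] = float(raw)
            except (TypeError, ValueError):
                raise TableParseError(
                    f"non-numeric value {raw!r}", row=rownum, column=col
                ) from None
            if not np.isfinite(values[col]):
                raise TableParseError(f"non-finite value {raw!r}", row=rownum, column=col)
        organ = str(row.organ)
        if whitelist is not None and organ not in whitelist:
            raise TableParseError(f"organ {organ!r} not in whitelist", row=rownum, column="organ")
        try:
            records.append(
                BiodistributionRecord(
                    animal_id=str(row.animal_id),
                    group=str(row.group),
                    organ=organ,
                    **values,
                )
            )
        except ValidationError as exc:
            raise TableParseError(str(exc), row=rownum) from exc
    return records


def write_biodistribution(records: Iterable[BiodistributionRecord], path: str | Path) -> None:
    frame = pd.DataFrame([dataclasses.asdict(r) for r in records], columns=RECORD_COLUMNS)
    frame.to_csv(path, index=False)


def normalize_to_reference_bw(
    record: BiodistributionRecord, reference_bw_g: float = REFERENCE_BODY_WEIGHT_G
) -> BiodistributionRecord:
    """Rescale %ID/g to a reference body weight: value × (BW / reference)."""
    if not reference_bw_g > 0:
        raise ValidationError(f"reference_bw_g must be > 0, got {reference_bw_g}")
    factor = record.body_weight_g / reference_bw_g
    return dataclasses.replace(record, percent_id_per_g=record.percent_id_per_g * factor)


def normalize_records(
    records: Iterable[BiodistributionRecord], reference_bw_g: float = REFERENCE_BODY_WEIGHT_G
) -> list[BiodistributionRecord]:
    return [normalize_to_reference_bw(r, reference_bw_g) for r in records]


def summarize_curves(
    records: Iterable[BiodistributionRecord], ddof: int = 1
) -> list[TimeActivityCurve]:
    """Aggregate records into one curve per (group, organ).

    Mean and sample SD (``ddof=1``; SD = 0 when n = 1) per time point,
    times sorted ascending.  Empty input yields an empty list.
    """
    buckets: dict[tuple[str, str], dict[float, list[float]]] = defaultdict(
        lambda: defaultdict(list)
    )
    for rec in records:
        buckets[(rec.group, rec.organ)][rec.time_h].append(rec.percent_id_per_g)

    curves = []
    for (group, organ), by_time in sorted(buckets.items()):
        times = sorted(by_time)
        means, sds, ns = [], [], []
        for t in times:
            vals = np.asarray(by_time[t], dtype=float)
            means.append(float(vals.mean()))
            sds.append(float(vals.std(ddof=ddof)) if len(vals) > ddof else 0.0)
            ns.append(len(vals))
        curves.append(
            TimeActivityCurve(
                organ=organ,
                group=group,
                times_h=np.asarray(times),
                mean_pidg=np.asarray(means),
                sd_pidg=np.asarray(sds),
                n=np.asarray(ns, dtype=float),
            )
        )
    return curves


def fold_change(
    curve_a: TimeActivityCurve, curve_b: TimeActivityCurve, time_h: float
) -> float:
    """Ratio of group means mean_a(t) / mean_b(t) at an exact time point."""
    numerator = curve_a.value_at(time_h)
    denominator = curve_b.value_at(time_h)
    if denominator <= 0:
        raise ValidationError(
            f"fold change undefined: denominator mean is {denominator} at {time_h} h"
        )
    return numerator / denominator


def curves_to_frame(curves: Iterable[TimeActivityCurve]) -> pd.DataFrame:
    rows = []
    for c in curves:
        for t, m, s, n in zip(c.times_h, c.mean_pidg, c.sd_pidg, c.n):
            rows.append((c.group, c.organ, t, m, s, int(n)))
    return pd.DataFrame(rows, columns=CURVE_COLUMNS)


def write_curves(curves: Iterable[TimeActivityCurve], path: str | Path) -> None:
    curves_to_frame(curves).to_csv(path, index=False)


def read_curves(path: str | Path) -> list[TimeActivityCurve]:
    frame = pd.read_csv(path)
    missing = [c for c in CURVE_COLUMNS if c not in frame.columns]
    if missing:
        raise TableParseError(f"{path}: missing required column(s) {missing}")
    curves = []
    for (group, organ), sub in frame.groupby(["group", "organ"], sort=True):
        sub = sub.sort_values("time_h")
        curves.append(
            TimeActivityCurve(
                organ=str(organ),
                group=str(group),
                times_h=sub["time_h"].to_numpy(),
                mean_pidg=sub["mean_pidg"].to_numpy(),
                sd_pidg=sub["sd_pidg"].to_numpy(),
                n=sub["n"].to_numpy(),
            )
        )
    return curves
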
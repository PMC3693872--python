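"""MTT plate-reader ingestion, background correction and viability normalization.

The experimental design this models: 96-well plates seeded at 5,000
cells/100 ul, drug dose grid {0, 0.01, 0.1, 1, 10, 100} uM in three
biological replicates, read at 0/24/48/72 h on a dual-wavelength reader
(570 nm signal, 650 nm reference).  Viability is expressed as the
fraction unaffected ``fu = OD_treated / mean(OD_control)`` at the same
time point, and the fraction affected ``fa = 1 - fu`` feeds the
median-effect fit downstream.
"""

from __future__ import annotations

import csv
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import pandas as pd

from ctsynergy.errors import (
    DegenerateControlError,
    NormalizationError,
    PlateParseError,
    PlateSchemaError,
)

#: canonical CSV column order for plate tables
PLATE_COLUMNS = ("well", "condition", "dose1_uM", "dose2_uM", "time_h", "a570", "a650", "replicate")

#: default clip bound keeping fa away from {0, 1} before log transformation
DEFAULT_CLIP_EPS = 0.005


@dataclass(frozen=True)
class AbsorbanceRecord:
    """One well's raw dual-wavelength readout with its experimental annotation.

    Doses are in uM, time in hours since dosing, absorbances in OD units.
    ``dose2`` is 0 for single-agent wells; combination wells carry the
    compound-2 dose alongside the compound-1 dose.
    """

    well_id: str
    condition: str
    dose1: float
    dose2: float
    time: float
    a570: float
    a650: float
    replicate: int

    def __post_init__(self):
        if self.dose1 < 0 or self.dose2 < 0:
            raise ValueError(f"well {self.well_id}: doses must be >= 0")
        if self.time < 0:
            raise ValueError(f"well {self.well_id}: time must be >= 0")
        if self.replicate < 1:
            raise ValueError(f"well {self.well_id}: replicate index must be >= 1")
        if not (math.isfinite(self.a570) and math.isfinite(self.a650)):
            raise ValueError(f"well {self.well_id}: absorbances must be finite")


@dataclass(frozen=True)
class DosePoint:
    """One dose level of a dose-response table."""

    dose1: float
    fa_replicates: tuple[float, ...]
    fa_mean: float
    excluded_from_fit: bool = False


@dataclass(frozen=True)
class DoseResponseTable:
    """Per-condition, per-time fraction-affected table on the compound-1 dose axis.

    ``ratio`` is dose2/dose1 (0 for single agents, constant along a
    constant-ratio combination ray).  The zero-dose control row is kept
    for completeness but flagged ``excluded_from_fit``.
    """

    condition: str
    ratio: float
    time: float
    points: tuple[DosePoint, ...]
    clip_eps: float = DEFAULT_CLIP_EPS
    negative_od_wells: tuple[str, ...] = field(default=())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "dose1_uM": [p.dose1 for p in self.points],
                "fa_mean": [p.fa_mean for p in self.points],
                "fa_replicates": [list(p.fa_replicates) for p in self.points],
                "excluded_from_fit": [p.excluded_from_fit for p in self.points],
            }
        )

    def fit_points(self, pooling: str = "pooled-replicates") -> tuple[list[float], list[float]]:
        """(dose, fa) pairs entering the median-effect regression."""
        doses: list[float] = []
        fas: list[float] = []
        for p in self.points:
            if p.excluded_from_fit:
                continue
            if pooling == "replicate-means":
                doses.append(p.dose1)
                fas.append(p.fa_mean)
            elif pooling == "pooled-replicates":
                for fa in p.fa_replicates:
                    doses.append(p.dose1)
                    fas.append(fa)
            else:
                raise ValueError(f"unknown pooling mode: {pooling!r}")
        return doses, fas


def correct_absorbance(record: AbsorbanceRecord) -> float:
    """Reference-corrected OD: signal at 570 nm minus reference at 650 nm.

    May be negative (measurement noise at full kill); a warning is issued
    but the raw difference is returned — the clipping policy lives in
    :func:`build_dose_response`, not here.
    """
    od = record.a570 - record.a650
    if od < 0:
        warnings.warn(
            f"well {record.well_id}: negative corrected OD ({od:.4f}); "
            "treated as noise at full kill downstream",
            stacklevel=2,
        )
    return od


def read_plate_table(
    path: str | Path,
    *,
    delimiter: str = ",",
    column_map: dict[str, str] | None = None,
) -> list[AbsorbanceRecord]:
    """Read a delimited plate table into absorbance records.

    Parameters
    ----------
    path
        CSV (or TSV via ``delimiter='\\t'``) file with a header row.
    delimiter
        Field separator; comma by default.
    column_map
        Optional remapping ``{canonical_name: file_column_name}`` for files
        whose headers differ from :data:`PLATE_COLUMNS`.  Matching is
        case-insensitive.

    Raises
    ------
    PlateSchemaError
        if any required column is absent (all missing names listed).
    PlateParseError
        if any data row has non-numeric values (all bad rows listed with
        their 1-based row numbers).
    """
    path = Path(path)
    column_map = column_map or {}
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter=delimiter)
        if reader.fieldnames is None:
            raise PlateSchemaError(list(PLATE_COLUMNS))
        lower_fields = {name.lower(): name for name in reader.fieldnames}
        resolved: dict[str, str] = {}
        missing: list[str] = []
        for canon in PLATE_COLUMNS:
            wanted = column_map.get(canon, canon).lower()
            if wanted in lower_fields:
                resolved[canon] = lower_fields[wanted]
            else:
                missing.append(canon)
        if missing:
            raise PlateSchemaError(missing)

        records: list[AbsorbanceRecord] = []
        bad_rows: list[tuple[int, str]] = []
        for i, row in enumerate(reader, start=2):  # row 1 is the header
            try:
                records.append(
                    AbsorbanceRecord(
                        well_id=row[resolved["well"]].strip(),
                        condition=row[resolved["condition"]].strip(),
                        dose1=float(row[resolved["dose1_uM"]]),
                        dose2=float(row[resolved["dose2_uM"]]),
                        time=float(row[resolved["time_h"]]),
                        a570=float(row[resolved["a570"]]),
                        a650=float(row[resolved["a650"]]),
                        replicate=int(row[resolved["replicate"]]),
                    )
                )
            except (TypeError, ValueError) as exc:
                bad_rows.append((i, str(exc)))
        if bad_rows:
            raise PlateParseError(bad_rows)
    return records


def write_plate_table(records: Iterable[AbsorbanceRecord], path: str | Path) -> None:
    """Write records to CSV in the canonical column order (round-trip safe)."""
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(PLATE_COLUMNS)
        for r in records:
            writer.writerow(
                [r.well_id, r.condition, repr(r.dose1), repr(r.dose2), repr(r.time), repr(r.a570), repr(r.a650), r.replicate]
            )


def build_dose_response(
    records: Sequence[AbsorbanceRecord],
    condition: str,
    time: float,
    *,
    clip_eps: float = DEFAULT_CLIP_EPS,
    control_pairing: Literal["pooled", "per-replicate"] = "pooled",
) -> DoseResponseTable:
    """Normalize a condition's wells against same-time controls.

    Control wells are those with ``dose1 == dose2 == 0`` at the requested
    time (any condition label).  Each treated well's fraction unaffected is
    its corrected OD over the mean control corrected OD — pooled over
    replicates by default, or paired within replicate with
    ``control_pairing='per-replicate'``.  Fractions affected are clipped
    into ``[clip_eps, 1 - clip_eps]`` so the downstream log(fa/fu)
    transform is always defined; wells with negative corrected OD are
    flagged and floor at ``fu = clip_eps`` (full kill).

    Raises
    ------
    NormalizationError
        if no control wells exist at the requested time.
    DegenerateControlError
        if the control mean corrected OD is <= 0.
    """
    if not (0 < clip_eps < 0.5):
        raise ValueError("clip_eps must lie in (0, 0.5)")
    at_time = [r for r in records if r.time == time]
    controls = [r for r in at_time if r.dose1 == 0 and r.dose2 == 0]
    if not controls:
        raise NormalizationError(f"no control wells (dose1=dose2=0) at time {time} h")

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        control_od = {r: correct_absorbance(r) for r in controls}

    def control_mean(replicate: int) -> float:
        if control_pairing == "per-replicate":
            ods = [od for r, od in control_od.items() if r.replicate == replicate]
            if not ods:  # fall back to the pooled mean if this replicate has no control
                ods = list(control_od.values())
        else:
            ods = list(control_od.values())
        return sum(ods) / len(ods)

    pooled_mean = sum(control_od.values()) / len(control_od)
    if pooled_mean <= 0:
        raise DegenerateControlError(f"control mean corrected OD is {pooled_mean:.4f} <= 0 at {time} h")

    treated = [r for r in at_time if r.condition == condition and not (r.dose1 == 0 and r.dose2 == 0)]
    if not treated:
        raise NormalizationError(f"no treated wells for condition {condition!r} at time {time} h")

    lo, hi = clip_eps, 1.0 - clip_eps
    by_dose: dict[float, list[tuple[int, float]]] = {}
    negative_wells: list[str] = []
    ratios: set[float] = set()
    for r in treated:
        od = r.a570 - r.a650
        if od < 0:
            negative_wells.append(r.well_id)
        fu = od / control_mean(r.replicate)
        fa = min(hi, max(lo, 1.0 - fu))
        by_dose.setdefault(r.dose1, []).append((r.replicate, fa))
        if r.dose1 > 0:
            ratios.add(round(r.dose2 / r.dose1, 12))
    if len(ratios) > 1:
        raise ValueError(
            f"condition {condition!r} is not a constant-ratio series: dose2/dose1 takes values {sorted(ratios)}"
        )
    ratio = ratios.pop() if ratios else 0.0

    points = []
    for dose in sorted(by_dose):
        fas = tuple(fa for _, fa in sorted(by_dose[dose]))
        points.append(DosePoint(dose1=dose, fa_replicates=fas, fa_mean=sum(fas) / len(fas)))
    # the zero-dose control row is carried along but never enters the fit
    n_ctrl_reps = sorted({r.replicate for r in controls})
    zero_fas = tuple(lo for _ in n_ctrl_reps)
    points.insert(0, DosePoint(dose1=0.0, fa_replicates=zero_fas, fa_mean=lo, excluded_from_fit=True))

    return DoseResponseTable(
        condition=condition,
        ratio=ratio,
        time=time,
        points=tuple(points),
        clip_eps=clip_eps,
        negative_od_wells=tuple(negative_wells),
    )
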
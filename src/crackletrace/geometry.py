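"""Thoracic sensor-array geometry and region-of-interest mapping.

The acoustic hardware is a pair of 18-sensor arrays wrapped around the
thorax (one per body side), each organised as 3 columns x 6 rows.  Rows run
ventral (L1) to dorsal (L6) on the supine animal, so rows map onto gravity-
dependent lung zones:

* L1-L2 -> nondependent (ventral) region
* L3-L4 -> central region
* L5-L6 -> dependent (dorsal) region

Two of the 36 sensors are inactive and serve as ambient-noise references;
they are excluded from every aggregate and coherence pair.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable

import yaml

SIDES = ("left", "right")
ROWS = (1, 2, 3, 4, 5, 6)
COLUMNS = (1, 2, 3)

NONDEPENDENT = "nondependent"
CENTRAL = "central"
DEPENDENT = "dependent"
GLOBAL = "global"
ROIS = (NONDEPENDENT, CENTRAL, DEPENDENT)

#: ventral-to-dorsal row -> gravity zone
ROW_TO_ROI = {1: NONDEPENDENT, 2: NONDEPENDENT,
              3: CENTRAL, 4: CENTRAL,
              5: DEPENDENT, 6: DEPENDENT}

# The two ambient-reference positions are not identified in the hardware
# description; we fix them at the ventral corner of each array so that every
# ROI retains a full complement of dorsal sensors.
DEFAULT_INACTIVE = (("left", 1, 1), ("right", 1, 3))


@dataclass(frozen=True)
class Sensor:
    """One piezoelectric contact sensor at a grid position."""

    id: str
    side: str          # "left" | "right"
    column: int        # 1..3 within the array
    row: int           # 1 (ventral) .. 6 (dorsal)
    active: bool = True

    @property
    def roi(self) -> str:
        return ROW_TO_ROI[self.row]


@dataclass
class SensorMatrix:
    """A sensor layout plus the row->ROI map."""

    sensors: list[Sensor]
    row_to_roi: dict[int, str] = field(default_factory=lambda: dict(ROW_TO_ROI))

    def __post_init__(self) -> None:
        ids = [s.id for s in self.sensors]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate sensor ids in layout")

    @property
    def active_sensors(self) -> list[Sensor]:
        return [s for s in self.sensors if s.active]

    @property
    def active_ids(self) -> list[str]:
        return [s.id for s in self.active_sensors]

    def sensor(self, sensor_id: str) -> Sensor:
        for s in self.sensors:
            if s.id == sensor_id:
                return s
        raise KeyError(sensor_id)

    def roi_of(self, sensor_id: str) -> str:
        return self.row_to_roi[self.sensor(sensor_id).row]

    def sensors_in_roi(self, roi: str) -> list[Sensor]:
        """Active sensors of one ROI; ``roi='global'`` returns all active."""
        if roi == GLOBAL:
            return self.active_sensors
        if roi not in ROIS:
            raise ValueError(f"unknown ROI {roi!r}")
        return [s for s in self.active_sensors if self.row_to_roi[s.row] == roi]

    # -- serialisation ----------------------------------------------------

    def to_yaml(self, path) -> None:
        payload = {
            "sensors": [
                {"id": s.id, "side": s.side, "column": s.column,
                 "row": s.row, "active": s.active}
                for s in self.sensors
            ],
            "row_to_roi": {int(k): v for k, v in self.row_to_roi.items()},
        }
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SensorMatrix":
        with open(path) as fh:
            payload = yaml.safe_load(fh)
        sensors = [Sensor(**d) for d in payload["sensors"]]
        row_to_roi = {int(k): v for k, v in payload["row_to_roi"].items()}
        return cls(sensors=sensors, row_to_roi=row_to_roi)


def sensor_id(side: str, row: int, column: int) -> str:
    return f"{side[0].upper()}{row}M{column}"


def build_default_matrix() -> SensorMatrix:
    """The canonical 2-array x 3-column x 6-row layout (34 active sensors).

    Returns the full 36-sensor grid with the two ambient-noise reference
    positions flagged inactive.
    """
    inactive = set(DEFAULT_INACTIVE)
    sensors = []
    for side in SIDES:
        for row in ROWS:
            for col in COLUMNS:
                sensors.append(Sensor(
                    id=sensor_id(side, row, col),
                    side=side, column=col, row=row,
                    active=(side, row, col) not in inactive,
                ))
    return SensorMatrix(sensors=sensors)


def _adjacent(a: Sensor, b: Sensor) -> bool:
    """Grid 4-adjacency within one array (no diagonals, no cross-body)."""
    if a.side != b.side:
        return False
    return abs(a.row - b.row) + abs(a.column - b.column) == 1


def neighbor_pairs(matrix: SensorMatrix, roi: str,
                   boundary: str = "strict") -> list[tuple[str, str]]:
    """All unordered pairs of grid-adjacent active sensors in a ROI.

    Parameters
    ----------
    roi
        One of ``nondependent / central / dependent / global``.
    boundary
        How pairs straddling a ROI border (e.g. rows L4-L5) are assigned:
        ``"strict"`` keeps only pairs whose two members lie in the ROI;
        ``"lower"`` assigns a straddling pair to the ROI of its more
        dependent (higher-row) member.

    Returns pairs ordered deterministically by (side, row, column).
    """
    if roi != GLOBAL and roi not in ROIS:
        raise ValueError(f"unknown ROI {roi!r}")
    if boundary not in ("strict", "lower"):
        raise ValueError(f"unknown boundary policy {boundary!r}")
    if roi != GLOBAL and not matrix.sensors_in_roi(roi):
        raise ValueError(f"ROI {roi!r} contains no active sensors")

    active = sorted(matrix.active_sensors,
                    key=lambda s: (s.side, s.row, s.column))
    pairs: list[tuple[str, str]] = []
    for i, a in enumerate(active):
        for b in active[i + 1:]:
            if not _adjacent(a, b):
                continue
            if roi != GLOBAL:
                roi_a = matrix.row_to_roi[a.row]
                roi_b = matrix.row_to_roi[b.row]
                if boundary == "strict":
                    if not (roi_a == roi and roi_b == roi):
                        continue
                else:  # lower: the more dependent member decides
                    lower = a if a.row >= b.row else b
                    if matrix.row_to_roi[lower.row] != roi:
                        continue
            pairs.append((a.id, b.id))
    return pairs


def deactivate(matrix: SensorMatrix, *sensor_ids: str) -> SensorMatrix:
    """Return a copy of the layout with the given sensors flagged inactive."""
    wanted = set(sensor_ids)
    missing = wanted - {s.id for s in matrix.sensors}
    if missing:
        raise KeyError(f"unknown sensors: {sorted(missing)}")
    sensors = [replace(s, active=False) if s.id in wanted else s
               for s in matrix.sensors]
    return SensorMatrix(sensors=sensors, row_to_roi=dict(matrix.row_to_roi))
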
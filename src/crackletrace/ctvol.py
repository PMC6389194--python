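"""4D-CT lung densitometry: aeration compartments and within-breath
change in atelectatic volume.

Lung voxels (a pre-computed segmentation mask is an input, never derived
here) are classified per frame into the four standard aeration compartments
on the Hounsfield scale:

================  ====================
atelectatic       -300 ..    0 HU
poorly aerated    -600 .. -301 HU
normally aerated  -900 .. -601 HU
hyperinflated     -1024 .. -901 HU
================  ====================

Bins are closed integer intervals; non-integer attenuation values are
rounded to the nearest integer first, since the printed bin edges only tile
an integer grid.  Masked voxels above 0 HU (or below -1024) count toward
the total imaged volume but to no compartment.

The cyclic-recruitment measure is Δatelectasis: the atelectatic volume in
the last frame before inspiration onset minus that in the last inspiratory
frame, averaged over breaths, and optionally expressed as a percentage of
the imaged lung volume.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geometry import CENTRAL, DEPENDENT, GLOBAL, NONDEPENDENT, ROIS

FRAME_INTERVAL_S = 0.58
HU_MIN, HU_MAX = -1024, 3071

#: compartment name -> closed integer HU interval
HU_BINS = {
    "atelectatic": (-300, 0),
    "poorly_aerated": (-600, -301),
    "normally_aerated": (-900, -601),
    "hyperinflated": (-1024, -901),
}
COMPARTMENTS = tuple(HU_BINS)


def partition_rois(mask: np.ndarray, gravity_axis: int = 2) -> np.ndarray:
    """Split a lung mask into three equal-thickness slabs along gravity.

    Index 0 along ``gravity_axis`` is taken as ventral (nondependent) and
    the maximal index as dorsal (dependent), mirroring the supine sensor
    rows.  Returns an int8 label field: 0 nondependent, 1 central,
    2 dependent, -1 outside the mask.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty lung mask")
    axes = tuple(i for i in range(mask.ndim) if i != gravity_axis)
    occupied = np.where(mask.any(axis=axes))[0]
    lo, hi = occupied[0], occupied[-1] + 1
    edges = np.linspace(lo, hi, 4)
    coord = np.arange(mask.shape[gravity_axis])
    slab = np.clip(np.searchsorted(edges, coord, side="right") - 1, 0, 2)
    shape = [1] * mask.ndim
    shape[gravity_axis] = -1
    labels = np.broadcast_to(slab.reshape(shape), mask.shape).astype(np.int8)
    return np.where(mask, labels, np.int8(-1))


ROI_CODE = {NONDEPENDENT: 0, CENTRAL: 1, DEPENDENT: 2}


@dataclass
class HUVolumeSeries:
    """Time-ordered HU voxel fields with mask, ROI labels and voxel volume.

    frames : (n_frames, nx, ny, nz) attenuation in HU
    voxel_volume_cm3 : volume of one voxel
    mask : (nx, ny, nz) boolean lung mask (shared across frames)
    roi_labels : optional int8 field from :func:`partition_rois`
    """

    frames: np.ndarray
    voxel_volume_cm3: float
    mask: np.ndarray
    frame_interval_s: float = FRAME_INTERVAL_S
    roi_labels: np.ndarray | None = None
    gravity_axis: int = 2

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.frames.ndim != self.mask.ndim + 1:
            raise ValueError("frames must stack one more axis than the mask")
        if self.frames.shape[1:] != self.mask.shape:
            raise ValueError("frame shape does not match mask shape")
        if self.voxel_volume_cm3 <= 0:
            raise ValueError("voxel volume must be positive")
        if self.roi_labels is None:
            self.roi_labels = partition_rois(self.mask, self.gravity_axis)

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def frame_times(self) -> np.ndarray:
        """Frame midpoints, consistent with the acoustic clip grid."""
        return (np.arange(self.n_frames) + 0.5) * self.frame_interval_s


def classify_hu(frame: np.ndarray, mask: np.ndarray,
                voxel_volume_cm3: float) -> dict[str, float]:
    """Compartment volumes (cm3) of one frame restricted to the mask."""
    if voxel_volume_cm3 <= 0:
        raise ValueError("voxel volume must be positive")
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    hu = np.rint(np.asarray(frame, dtype=float)[mask]).astype(np.int64)
    out = {}
    for name, (lo, hi) in HU_BINS.items():
        out[name] = float(np.count_nonzero((hu >= lo) & (hu <= hi))
                          * voxel_volume_cm3)
    out["total"] = float(hu.size * voxel_volume_cm3)
    return out


def volume_timeseries(series: HUVolumeSeries) -> pd.DataFrame:
    """Per-frame, per-ROI compartment volumes as a tidy table.

    Columns: frame, time_s, roi (three zones plus ``global``), the four
    compartments, and total.  Requires at least two frames.
    """
    if series.n_frames < 2:
        raise ValueError("need at least 2 frames to form a time series")
    rows = []
    times = series.frame_times
    roi_masks = {GLOBAL: series.mask}
    for roi, code in ROI_CODE.items():
        roi_masks[roi] = series.roi_labels == code
    for i in range(series.n_frames):
        for roi, m in roi_masks.items():
            rec = classify_hu(series.frames[i], m, series.voxel_volume_cm3)
            rec.update(frame=i, time_s=times[i], roi=roi)
            rows.append(rec)
    cols = ["frame", "time_s", "roi", *COMPARTMENTS, "total"]
    return pd.DataFrame(rows)[cols]


def _frame_selection(times: np.ndarray, start: float, dur: float,
                     atel: np.ndarray, mode: str) -> tuple[int, int]:
    before = np.where(times < start)[0]
    inside = np.where((times >= start) & (times < start + dur))[0]
    if len(before) == 0 or len(inside) == 0:
        raise ValueError(
            f"inspiration ({start}, {dur}) not covered by the frame grid")
    if mode == "annotated":
        return int(before[-1]), int(inside[-1])
    if mode == "extremum":
        # extremum search over the breath: end-exp frame .. last insp frame
        window = np.arange(before[-1], inside[-1] + 1)
        return int(window[np.argmax(atel[window])]), \
            int(window[np.argmin(atel[window])])
    raise ValueError(f"unknown frame-selection mode {mode!r}")


def delta_atelectasis(compvols: pd.DataFrame,
                      breaths: list[tuple[float, float]],
                      mode: str = "annotated") -> pd.DataFrame:
    """Within-breath change in atelectatic volume, per ROI.

    For each breath: end-expiratory volume is read at the last frame before
    inspiration onset and end-inspiratory volume at the last inspiratory
    frame (``mode="annotated"``, default), or at the within-breath
    maximum/minimum (``mode="extremum"``).  Breath values are averaged; the
    percentage uses the breath-mean total imaged lung volume of that ROI.
    """
    if not breaths:
        raise ValueError("need at least one annotated breath")
    rows = []
    for roi, sub in compvols.groupby("roi", sort=False):
        sub = sub.sort_values("frame")
        times = sub["time_s"].to_numpy()
        atel = sub["atelectatic"].to_numpy()
        total = sub["total"].to_numpy()
        deltas, ee_vals, ei_vals, totals = [], [], [], []
        for start, dur in breaths:
            i_ee, i_ei = _frame_selection(times, start, dur, atel, mode)
            ee_vals.append(atel[i_ee])
            ei_vals.append(atel[i_ei])
            deltas.append(atel[i_ee] - atel[i_ei])
            totals.append(total[i_ee:i_ei + 1].mean())
        d = float(np.mean(deltas))
        t = float(np.mean(totals))
        rows.append({
            "roi": roi,
            "end_expiratory_cm3": float(np.mean(ee_vals)),
            "end_inspiratory_cm3": float(np.mean(ei_vals)),
            "delta_atelectasis_cm3": d,
            "percent_of_imaged_volume": volume_percent(d, t),
            "n_breaths": len(breaths),
        })
    return pd.DataFrame(rows)


def volume_percent(delta_cm3: float, total_cm3: float) -> float:
    """Volume change as a percentage of the imaged lung volume."""
    if total_cm3 <= 0:
        raise ValueError("total imaged volume must be positive")
    return float(100.0 * delta_cm3 / total_cm3)
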
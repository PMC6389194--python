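"""End-to-end driver: scenario -> acoustic parameters + CT volumetry ->
paired observation table ready for the mixed-model stage.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import acoustics as ac
from . import ctvol
from .geometry import GLOBAL, ROIS, SensorMatrix, build_default_matrix
from .synth import ScenarioConfig, ScenarioItem, generate_scenario

ALL_ROIS = (*ROIS, GLOBAL)


def analyze_recording(recording: ac.Recording,
                      matrix: SensorMatrix | None = None,
                      clip_duration_s: float = ac.CLIP_DURATION_S,
                      coherence_boundary: str = "strict") -> dict:
    """Compute dCE, FFT-area and SC/dSC summaries for every ROI.

    The recording is decimated to 4800 Hz first.  Returns
    ``{"summaries": DataFrame, "clips": DataFrame}`` — one summary row per
    ROI x parameter, and the per-sensor per-clip values in tidy form.
    """
    if matrix is None:
        matrix = build_default_matrix()
    factor = int(round(recording.fs / ac.TARGET_FS_HZ))
    rec = ac.downsample(recording, factor) if factor > 1 else recording
    grid = ac.make_clip_grid(rec.duration_s, rec.breaths, clip_duration_s)

    dce = ac.dynamic_crackle_energy(rec, grid)
    fft = ac.fft_area_series(rec, grid)
    # band-pass once, reuse for every ROI's coherence series
    filt = ac.bandpass_fir(rec.samples, ac.FIR_ORDER,
                           *ac.ANALYSIS_BAND_HZ, rec.fs)
    prefiltered = ac.Recording(samples=filt, fs=rec.fs,
                               sensor_ids=list(rec.sensor_ids),
                               breaths=rec.breaths)

    rows = []
    clip_rows = []
    for roi in ALL_ROIS:
        for name, cg in (("dce", dce), ("fft_area", fft)):
            s = ac.roi_aggregate(cg, matrix, roi, parameter=name)
            rows.append({"roi": roi, "parameter": name, "value": s.value,
                         "per_breath": s.per_breath})
        sc_series = ac.roi_coherence_series(prefiltered, matrix, roi, grid,
                                            boundary=coherence_boundary,
                                            prefiltered=True)
        sc, dsc = ac.sc_dsc_summary(sc_series)
        rows.append({"roi": roi, "parameter": "sc", "value": sc,
                     "per_breath": None})
        rows.append({"roi": roi, "parameter": "dsc", "value": dsc,
                     "per_breath": None})
        clip_rows.append(pd.DataFrame({
            "roi": roi, "parameter": "sc",
            "clip_start_s": sc_series.start_times,
            "phase": np.where(sc_series.inspiratory, "insp", "exp"),
            "value": sc_series.values}))

    for name, cg in (("dce", dce), ("fft_area", fft)):
        for i, sid in enumerate(cg.sensor_ids):
            clip_rows.append(pd.DataFrame({
                "sensor": sid, "parameter": name,
                "clip_start_s": cg.start_times,
                "phase": np.where(cg.inspiratory, "insp", "exp"),
                "value": cg.values[i]}))
    return {"summaries": pd.DataFrame(rows),
            "clips": pd.concat(clip_rows, ignore_index=True)}


def analyze_item(item: ScenarioItem,
                 matrix: SensorMatrix | None = None) -> list[dict]:
    """One scenario cell -> per-ROI rows pairing acoustics with Δatelectasis."""
    res = analyze_recording(item.recording, matrix)
    vols = ctvol.volume_timeseries(item.hu_series)
    delta = ctvol.delta_atelectasis(vols, item.breaths).set_index("roi")
    summ = res["summaries"].pivot(index="roi", columns="parameter",
                                  values="value")
    rows = []
    for roi in ALL_ROIS:
        rows.append({
            "subject": item.subject, "condition": item.condition,
            "peep": item.peep, "roi": roi,
            "delta_atelectasis": float(delta.loc[roi,
                                                 "delta_atelectasis_cm3"]),
            "total_volume": float(vols.loc[vols.roi == roi, "total"].mean()),
            "dce": float(summ.loc[roi, "dce"]),
            "fft_area": float(summ.loc[roi, "fft_area"]),
            "sc": float(summ.loc[roi, "sc"]),
            "dsc": float(summ.loc[roi, "dsc"]),
            "true_delta_atelectasis":
                item.truth.delta_atelectasis_cm3[roi],
        })
    return rows


def build_observation_table(config: ScenarioConfig,
                            matrix: SensorMatrix | None = None,
                            progress: bool = False) -> pd.DataFrame:
    """Generate and fully re-analyze a scenario: one row per
    subject x condition x PEEP x ROI with Δatelectasis and all four
    acoustic parameters.
    """
    rows = []
    for item in generate_scenario(config):
        if progress:
            print(f"  analyzed subject {item.subject} "
                  f"{item.condition} PEEP {item.peep}", flush=True)
        rows.extend(analyze_item(item, matrix))
    return pd.DataFrame(rows)
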
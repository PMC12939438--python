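"""End-to-end feature extraction across a cohort of recordings."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from . import eda, hrv
from .io import Recording, convert_channel
from .kernel import DEFAULT_TAU1, DEFAULT_TAU2

ALL_FEATURES = eda.EDA_FEATURES + hrv.HRV_FEATURES


@dataclass
class PipelineConfig:
    """Analysis knobs shared by the CLI and the library path."""

    amp_threshold: float = eda.DEFAULT_AMP_THRESHOLD
    ttp_window: tuple[float, float] = eda.DEFAULT_TTP_WINDOW
    eda_target_fs: float = eda.DEFAULT_EDA_FS
    tau1: float = DEFAULT_TAU1
    tau2: float = DEFAULT_TAU2
    rr_band: tuple[float, float] = hrv.RR_BAND
    tachogram_fs: float = 4.0
    welch_segment_s: float = 60.0


def extract_patient_features(recording: Recording,
                             config: PipelineConfig | None = None
                             ) -> tuple[dict[str, float], dict]:
    """All EDA and HRV scalars for one recording, plus a QC record.

    Missing channels leave the corresponding features as NaN; per-channel
    failures are captured in the QC record, not raised.
    """
    config = config or PipelineConfig()
    feats: dict[str, float] = {name: float("nan") for name in ALL_FEATURES}
    qc: dict = {"patient_id": recording.patient_id}
    if "eda" in recording.channels:
        try:
            ch = convert_channel(recording.channels["eda"], "eda")
            pre = eda.preprocess_eda(ch, target_fs=config.eda_target_fs)
            decomp = eda.decompose_cda(pre, config.tau1, config.tau2)
            cda_events = eda.detect_scr_cda(decomp, config.amp_threshold)
            ttp_events = eda.analyze_ttp(pre, config.amp_threshold, config.ttp_window)
            feats.update(eda.extract_eda_features(cda_events, ttp_events))
            qc.update(n_scr_cda=len(cda_events), n_scr_ttp=len(ttp_events),
                      eda_clipped=int(np.sum(ch.samples < 0)))
        except Exception as exc:  # per-patient failures are isolated
            qc["eda_error"] = f"{type(exc).__name__}: {exc}"
    if "ecg" in recording.channels:
        try:
            ch = convert_channel(recording.channels["ecg"], "ecg")
            peaks = hrv.detect_r_peaks(ch)
            rrs = hrv.build_rr(peaks, ch.fs, band=config.rr_band)
            feats.update(hrv.time_domain_features(rrs))
            feats.update(hrv.frequency_domain_features(
                rrs, config.tachogram_fs, config.welch_segment_s))
            qc.update(n_beats=int(peaks.size),
                      n_rr_dropped=int(peaks.size - 1 - rrs.rr.size))
        except Exception as exc:
            qc["ecg_error"] = f"{type(exc).__name__}: {exc}"
    return feats, qc


def extract_feature_table(recordings: Sequence[Recording],
                          config: PipelineConfig | None = None
                          ) -> tuple[pd.DataFrame, list[dict]]:
    """Per-patient feature table (one row per recording) and QC records."""
    rows, qcs = [], []
    for rec in recordings:
        feats, qc = extract_patient_features(rec, config)
        rows.append({"patient_id": rec.patient_id, **feats})
        qcs.append(qc)
    table = pd.DataFrame(rows, columns=["patient_id"] + ALL_FEATURES)
    return table, qcs
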
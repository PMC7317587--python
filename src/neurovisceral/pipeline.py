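"""End-to-end orchestration: raw recordings -> subject table -> statistics.

The per-subject path is: cardiac input (ECG waveform or pre-extracted R-R
series) -> NN cleaning -> HRV summary; EEG -> (optional artifact
rejection) -> windowed spectra -> band coherence matrices -> per-band
characteristic path length and clustering coefficient.  The cohort-level
path merges the per-subject rows with the subject metadata table and runs
group contrasts (IQ-adjusted) plus per-group FDR-corrected Spearman
correlation networks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import connectivity as conn
from . import graph as graphmod
from . import hrv as hrvmod
from . import stats as statsmod
from .config import PipelineConfig

logger = logging.getLogger("neurovisceral")

__all__ = [
    "hrv_row",
    "eeg_row",
    "process_subject",
    "cohort_table",
    "analyze_table",
    "HRV_COLUMNS",
]

HRV_COLUMNS = ("HR", "LF", "HF", "SDNN", "SDNNi", "RMSSD", "pNN50")


def hrv_row(
    rr_ms: np.ndarray | None = None,
    ecg: np.ndarray | None = None,
    ecg_fs: float | None = None,
    config: PipelineConfig | None = None,
) -> dict:
    """HRV summary dict from either an R-R series or a raw ECG waveform."""
    cfg = config or PipelineConfig()
    if rr_ms is None:
        if ecg is None:
            raise ValueError("need rr_ms or ecg")
        peaks = hrvmod.detect_r_peaks(ecg, ecg_fs)
        rr_ms = peaks.rr_intervals_ms()
        onsets = peaks.peak_times[:-1]
    else:
        onsets = None
    nn = hrvmod.clean_nn(rr_ms, onsets)
    summ = hrvmod.hrv_summary(
        nn, fs_interp=cfg.fs_interp, ar_order=cfg.ar_order, segment_s=cfg.segment_s
    )
    return {
        "HR": summ.hr,
        "LF": summ.lf,
        "HF": summ.hf,
        "SDNN": summ.sdnn,
        "SDNNi": summ.sdnni,
        "RMSSD": summ.rmssd,
        "pNN50": summ.pnn50,
    }


def eeg_row(rec: conn.EEGRecording, config: PipelineConfig | None = None) -> dict:
    """Per-band CPL/CC dict (keys like ``CPL_theta``, ``CC_alpha``)."""
    cfg = config or PipelineConfig()
    if cfg.artifact_threshold is not None:
        rec = conn.reject_artifacts(rec, cfg.artifact_threshold, window_s=cfg.window_s)
    top = max(high for _, _, high in cfg.bands)
    spec = conn.windowed_spectra(
        rec,
        window_s=cfg.window_s,
        overlap=cfg.overlap,
        taper=cfg.taper,
        max_freq=top + 5.0,
    )
    cms = conn.band_adjacency(spec, bands=cfg.bands)
    metrics = graphmod.metrics_for_bands(
        cms, threshold=cfg.proportional_threshold, transform=cfg.length_transform
    )
    row = {}
    for band, gm in metrics.items():
        row[f"CPL_{band}"] = gm.cpl
        row[f"CC_{band}"] = gm.avg_cc
    return row


def process_subject(subject, config: PipelineConfig | None = None) -> dict:
    """Full feature row for one (synthetic or loaded) subject object.

    The subject must expose ``subject_id``, ``group``, ``iq``, ``rr_ms`` or
    ``ecg``/``ecg_fs``, and ``eeg``/``eeg_fs`` attributes.
    """
    cfg = config or PipelineConfig()
    row = {"id": subject.subject_id, "group": subject.group, "IQ": subject.iq}
    if getattr(subject, "ecg", None) is not None:
        row.update(hrv_row(ecg=subject.ecg, ecg_fs=subject.ecg_fs, config=cfg))
    else:
        row.update(hrv_row(rr_ms=subject.rr_ms, config=cfg))
    rec = conn.EEGRecording(
        data=subject.eeg, fs=subject.eeg_fs, channels=conn.CHANNELS_1020
    )
    row.update(eeg_row(rec, config=cfg))
    return row


def cohort_table(subjects, config: PipelineConfig | None = None) -> pd.DataFrame:
    """Subject table from an iterable of subjects; failures skip the
    subject with a logged reason instead of aborting the cohort."""
    rows = []
    for s in subjects:
        try:
            rows.append(process_subject(s, config))
        except Exception as exc:  # per-subject skip, never crash the run
            logger.warning("skipping %s: %s", getattr(s, "subject_id", "?"), exc)
    return pd.DataFrame(rows)


def analyze_table(
    table: pd.DataFrame,
    variables: list | None = None,
    config: PipelineConfig | None = None,
    screen_outliers: bool = True,
) -> dict:
    """Group contrasts + per-group correlation networks for a merged table.

    Returns ``{"contrasts": DataFrame, "networks": [CorrelationNetworkResult],
    "outlier_log": DataFrame, "table": masked DataFrame}``.
    """
    cfg = config or PipelineConfig()
    if variables is None:
        variables = [
            c
            for c in table.columns
            if c not in ("id", "group") and pd.api.types.is_numeric_dtype(table[c])
        ]
    analysis_vars = [v for v in variables if v not in cfg.covariates]
    if screen_outliers and len(table) < 10:
        logger.warning("fewer than 10 subjects: outlier screening skipped")
        screen_outliers = False
    if screen_outliers:
        masked, log = statsmod.remove_outliers(table, analysis_vars, alpha=cfg.alpha)
    else:
        masked, log = table, pd.DataFrame()
    contrast_rows = []
    for var in analysis_vars:
        try:
            res = statsmod.group_contrast(masked, var, covariates=cfg.covariates)
        except statsmod.CollinearDesignError:
            res = statsmod.group_contrast(masked, var, covariates=[])
        contrast_rows.append(
            {
                "variable": res.variable,
                "model": res.model,
                "t": res.t,
                "p": res.p,
                "eta_p2": res.eta_p2,
                "n_case": res.n_case,
                "n_control": res.n_control,
            }
        )
    networks = statsmod.spearman_fdr(
        masked, analysis_vars, by_group=True, alpha=cfg.alpha
    )
    return {
        "contrasts": pd.DataFrame(contrast_rows),
        "networks": networks,
        "outlier_log": log,
        "table": masked,
    }
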
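"""End-to-end glue: conditioned signals -> measures -> bands -> peaks -> loop.

This is the layer the command-line interface and batch studies call; every
step is a thin composition of the per-module operations.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import spearmanr

from .decision import ClassifyFn, StimulationTrace, run_loop
from .embedding import EmbeddingParams, select_embedding
from .io import AnalysisConfig, LabelTrack, Recording
from .preprocess import (WindowSet, bandpass_lfp, detect_tremor_onset,
                         preprocess_emg, resample_lfp, segment_windows)
from .sliding import (MEASURES, MeasureSeries, PeakEvent, SignificanceBands,
                      detect_peaks, measure_timecourse, significance_bands)


@dataclass
class AnalysisResult:
    """Everything the moving-window analysis of one recording produces."""

    windows: WindowSet
    params: EmbeddingParams
    series: MeasureSeries
    bands: dict[str, SignificanceBands]
    peaks: dict[str, list[PeakEvent]]
    baseline_n: int
    config: AnalysisConfig = field(default_factory=AnalysisConfig)


def condition_lfp(rec: Recording, config: AnalysisConfig | None = None) -> Recording:
    """Downsample to the target rate, then band-pass filter."""
    config = config or AnalysisConfig()
    return bandpass_lfp(resample_lfp(rec, config.target_rate),
                        band=config.band, order=config.filter_order)


def condition_emg(rec: Recording, config: AnalysisConfig | None = None) -> Recording:
    """High-pass, rectify and low-pass the EMG at its native rate."""
    config = config or AnalysisConfig()
    return preprocess_emg(rec, band=config.band, order=config.filter_order)


def auto_label(emg: Recording, config: AnalysisConfig | None = None,
               duration: float | None = None) -> LabelTrack:
    """EMG-derived label track: NT up to the confirmed onset, T afterwards."""
    config = config or AnalysisConfig()
    onset = detect_tremor_onset(condition_emg(emg, config),
                                baseline_s=config.baseline_s)
    end = duration if duration is not None else emg.duration
    if onset is None or onset >= end:
        return LabelTrack([(0.0, end, "NT")])
    return LabelTrack([(0.0, onset, "NT"), (onset, end, "T")])


def select_params(lfp: Recording, config: AnalysisConfig | None = None,
                  nt_s: float = 10.0, tau_max: int = 30,
                  m_max: int = 10) -> EmbeddingParams:
    """Embedding parameters from the recording's leading (atremorous) data."""
    config = config or AnalysisConfig()
    n = min(lfp.n, int(round(nt_s * lfp.rate)))
    return select_embedding(lfp.samples[:n], tau_max=tau_max, m_max=m_max)


def analyze(lfp: Recording, config: AnalysisConfig | None = None,
            params: EmbeddingParams | None = None,
            conditioned: bool = False,
            labels: LabelTrack | None = None) -> AnalysisResult:
    """Full moving-window recurrence-network analysis of one LFP channel.

    The significance baseline is the stretch of windows known or assumed
    atremorous: with ``labels`` given, every leading window inside the first
    NT segment; otherwise the first ``baseline_s`` seconds of the recording.
    ``conditioned=True`` skips resampling/filtering for signals already at
    the target rate and band.
    """
    config = config or AnalysisConfig()
    sig = lfp if conditioned else condition_lfp(lfp, config)
    windows = segment_windows(sig, config.window_s, config.overlap_frac)
    if params is None:
        params = select_params(sig, config)
    series = measure_timecourse(windows, params, rr=config.recurrence_rate)
    if labels is not None and labels.segments and labels.segments[0][2] == "NT":
        nt_end = labels.segments[0][1]
        baseline_n = int(np.sum(windows.mid_times < nt_end))
        baseline_n = max(2, baseline_n)
    else:
        baseline_n = max(2, int(round(config.baseline_s / windows.hop_s)))
    bands = {m: significance_bands(series.values(m), config.median_window_n,
                                   baseline_n) for m in MEASURES}
    peaks = {m: detect_peaks(series.values(m), bands[m], config.memory_windows,
                             series.mid_times, measure=m) for m in MEASURES}
    return AnalysisResult(windows=windows, params=params, series=series,
                          bands=bands, peaks=peaks, baseline_n=baseline_n,
                          config=config)


def closed_loop(result: AnalysisResult, classify: ClassifyFn,
                measure: str = "C") -> StimulationTrace:
    """Run the start/stop controller over an analysed recording."""
    cfg = result.config
    return run_loop(result.series, result.bands[measure], classify,
                    measure=measure, sigma_trigger=cfg.sigma_trigger,
                    memory_windows=cfg.memory_windows)


def robustness_sweep(lfp: Recording, m_list: tuple[int, ...] = (4, 6, 8, 10),
                     config: AnalysisConfig | None = None,
                     tau: int | None = None,
                     conditioned: bool = False) -> dict[int, np.ndarray]:
    """Transitivity time courses recomputed at several embedding dimensions.

    Used to check that the temporal profile of the measures -- and hence
    tremor detectability -- is insensitive to the exact choice of m.
    """
    config = config or AnalysisConfig()
    sig = lfp if conditioned else condition_lfp(lfp, config)
    windows = segment_windows(sig, config.window_s, config.overlap_frac)
    if tau is None:
        tau = select_params(sig, config).tau
    out: dict[int, np.ndarray] = {}
    for m in m_list:
        series = measure_timecourse(windows, EmbeddingParams(tau=tau, m=m),
                                    rr=config.recurrence_rate)
        out[m] = series.T
    return out


def sweep_correlations(sweep: dict[int, np.ndarray]) -> dict[tuple[int, int], float]:
    """Pairwise Spearman correlations between sweep time courses."""
    ms = sorted(sweep)
    out: dict[tuple[int, int], float] = {}
    for i, a in enumerate(ms):
        for b in ms[i + 1:]:
            mask = np.isfinite(sweep[a]) & np.isfinite(sweep[b])
            rho = spearmanr(sweep[a][mask], sweep[b][mask]).statistic
            out[(a, b)] = float(rho)
    return out
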
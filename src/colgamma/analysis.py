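"""Envelope extraction, amplitude spectra and regime classification.

The experiments compare oscillation *amplitudes* across stimulus
conditions.  The amplitude estimator used throughout is the mean half-range
between the upper and lower envelopes over a steady window (default: the
final second of the run); envelopes are built from per-cycle local extrema
with monotone (PCHIP) interpolation.  Spectra are plain magnitude FFTs of
the mean-subtracted final-second window, with the beta/gamma boundary at
25 Hz.

Classification vocabulary:

* *ordered pattern* — L5E amplitudes obey {S1, S1S2+A1} > S1S2 >
  {S1S2+A2, S2}, the attended/unattended response ordering.
* *WTA / anti-WTA* — attention to column 1 raises (WTA) or paradoxically
  lowers (anti-WTA) the 1L2/3E amplitude relative to attention to column 2.
* *concurrent case* — ordered pattern in L5 together with anti-WTA in
  L2/3.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy.interpolate import PchipInterpolator
from scipy.signal import find_peaks

from .model_core import ConfigurationError
from .simulator import SimulationConfig, TraceSet, settle_time, simulate
from .stimuli import StimulusCondition

BETA_BAND = (12.5, 25.0)    # Hz, [low, high)
GAMMA_BAND = (25.0, 100.0)  # Hz, [low, high]

#: Conditions required by the regime classifier.
CLASSIFIER_CONDITIONS = ("S1", "S2", "S1S2", "S1S2_A1", "S1S2_A2")


def envelope_series(
    t: np.ndarray, y: np.ndarray, smooth_ms: float = 100.0
) -> Tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Upper/lower envelopes of ``y(t)`` on its own grid.

    Local maxima/minima are joined by monotone (PCHIP) interpolation; where
    fewer than two extrema of a kind exist (non-oscillating trace) both
    envelopes collapse onto the slow moving-average trend.  Returns
    ``(upper, lower, peak_times, trough_times)``.
    """
    peaks, _ = find_peaks(y)
    troughs, _ = find_peaks(-y)
    if len(peaks) < 2 or len(troughs) < 2:
        dt = t[1] - t[0] if len(t) > 1 else 1.0
        w = max(1, int(round(smooth_ms / dt)))
        kernel = np.ones(w) / w
        trend = np.convolve(np.pad(y, (w // 2, w - 1 - w // 2), mode="edge"),
                            kernel, mode="valid")
        return trend.copy(), trend.copy(), t[peaks], t[troughs]
    upper = PchipInterpolator(t[peaks], y[peaks], extrapolate=True)(t)
    lower = PchipInterpolator(t[troughs], y[troughs], extrapolate=True)(t)
    return upper, lower, t[peaks], t[troughs]


def envelope(
    trace: TraceSet, population: str, window: Tuple[float, float]
) -> Tuple[np.ndarray, np.ndarray]:
    """Upper and lower envelope of one population's rate over ``window`` (ms)."""
    t0, t1 = window
    if t1 - t0 < 80.0:
        raise ValueError("window must span at least 80 ms (two cycles at 25 Hz)")
    sl = trace.window(t0, t1)
    upper, lower, _, _ = envelope_series(trace.time[sl], trace.rate(population)[sl])
    return upper, lower


def oscillation_amplitude(
    trace: TraceSet, population: str, window: Optional[Tuple[float, float]] = None
) -> float:
    """Mean envelope half-range (Hz) over the window (default: final 1 s)."""
    if window is None:
        window = (trace.t_end - 1000.0, trace.t_end)
    upper, lower = envelope(trace, population, window)
    return float(np.mean((upper - lower) / 2.0))


def steady_mean_rate(
    trace: TraceSet, population: str, window: Optional[Tuple[float, float]] = None
) -> float:
    """Mean firing rate (Hz) over the window (default: final 1 s)."""
    if window is None:
        window = (trace.t_end - 1000.0, trace.t_end)
    sl = trace.window(*window)
    return float(np.mean(trace.rate(population)[sl]))


@dataclass
class SpectralSummary:
    """Magnitude spectrum of a windowed rate trace with band summaries."""

    freqs: np.ndarray           # Hz
    amplitude: np.ndarray       # Hz (same scale as the rate trace)
    peaks: List[Tuple[float, float, float]]   # (freq, amplitude, prominence)
    gamma_amp: float            # largest detected-peak amplitude in the gamma band
    beta_amp: float             # largest detected-peak amplitude in the beta band

    @property
    def peak_freqs(self) -> List[float]:
        return [f for f, _, _ in self.peaks]

    @property
    def dominant_freq(self) -> float:
        """Frequency (Hz) of the global spectral maximum (DC excluded)."""
        return float(self.freqs[int(np.argmax(self.amplitude))])

    def peaks_in_band(self, band: Tuple[float, float]) -> List[Tuple[float, float, float]]:
        lo, hi = band
        return [(f, a, p) for f, a, p in self.peaks if lo <= f < hi]


def amplitude_spectrum(
    trace: TraceSet,
    population: str,
    window: Optional[Tuple[float, float]] = None,
    prominence_frac: float = 0.05,
    taper: bool = False,
) -> SpectralSummary:
    """Amplitude spectrum of the windowed rate trace (default: final 1 s).

    The window is mean-subtracted and transformed without tapering (an
    optional Hann taper is available); spectral peaks are local maxima with
    prominence at least ``prominence_frac`` of the global maximum.  Band
    amplitudes report the largest *detected peak* within the band (0 if the
    band holds no peak), so spectral leakage from a strong neighbouring
    band does not register as band content.
    """
    if window is None:
        window = (trace.t_end - 1000.0, trace.t_end)
    t0, t1 = window
    if t0 < trace.time[0] - 1e-9 or t1 > trace.t_end + 1e-9:
        raise ValueError("window exceeds the recorded trace")
    sl = trace.window(t0, t1)
    y = trace.rate(population)[sl].astype(float)
    y = y - y.mean()
    if taper:
        y = y * np.hanning(len(y))
    n = len(y)
    dt_s = (trace.time[sl][1] - trace.time[sl][0]) / 1000.0
    amp = np.abs(np.fft.rfft(y)) * 2.0 / n
    freqs = np.fft.rfftfreq(n, d=dt_s)
    amp[0] = 0.0

    peaks = []
    if amp.max() > 0:
        idx, props = find_peaks(amp, prominence=prominence_frac * amp.max())
        peaks = [
            (float(freqs[i]), float(amp[i]), float(p))
            for i, p in zip(idx, props["prominences"])
        ]
        peaks.sort(key=lambda fap: fap[0])

    def band_amp(band):
        in_band = [a for f, a, _ in peaks if band[0] <= f < band[1]]
        return max(in_band) if in_band else 0.0

    return SpectralSummary(
        freqs=freqs,
        amplitude=amp,
        peaks=peaks,
        gamma_amp=band_amp((GAMMA_BAND[0], GAMMA_BAND[1] + 1e-9)),
        beta_amp=band_amp(BETA_BAND),
    )


@dataclass
class RegimeLabel:
    """Classification outcome of one simulation set at a parameter point."""

    oscillating: bool
    bands: Optional[str]        # "gamma_only" | "beta_and_gamma" | "aperiodic_mixed"
    ordered_pattern: bool
    wta: str                    # "wta" | "anti_wta" | "neither"
    concurrent: bool
    region_color: str           # "blue" | "green" | "red" | "yellow" | "other"
    metrics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.concurrent and not (self.ordered_pattern and self.wta == "anti_wta"):
            raise ValueError("concurrent requires ordered pattern AND anti-WTA")


def _greater(x: float, y: float, margin: float) -> bool:
    """x exceeds y with relative margin."""
    return x >= y * (1.0 + margin)


def classify_regime(
    traces: Mapping[str, TraceSet],
    population_L5: str = "1L5E",
    population_L23: str = "1L2/3E",
    eps_osc: float = 1e-3,
    eps_ord: float = 0.02,
    prominence_frac: float = 0.05,
    beta_floor_frac: float = 0.05,
) -> RegimeLabel:
    """Classify one parameter point from its per-condition traces.

    ``traces`` must contain the five stimulus conditions
    ``S1, S2, S1S2, S1S2_A1, S1S2_A2`` (a no-stimulus trace is optional and
    unused).  Oscillation is judged on the steady-window cycle amplitude of
    ``population_L5`` under S1S2+A1 relative to its mean rate; the ordered
    pattern on L5E amplitudes with relative margin ``eps_ord``; WTA polarity
    on L2/3E amplitudes under the two attention conditions; band content on
    the S1S2+A1 spectrum.
    """
    missing = [c for c in CLASSIFIER_CONDITIONS if c not in traces]
    if missing:
        raise ConfigurationError(f"missing conditions for classification: {missing}")

    amp5 = {c: oscillation_amplitude(traces[c], population_L5)
            for c in CLASSIFIER_CONDITIONS}
    amp23 = {c: oscillation_amplitude(traces[c], population_L23)
             for c in ("S1S2_A1", "S1S2_A2")}
    mean_rate = steady_mean_rate(traces["S1S2_A1"], population_L5)
    oscillating = amp5["S1S2_A1"] > eps_osc * max(mean_rate, 1e-12)

    # amplitude comparisons are meaningless without an oscillation, so the
    # ordered/WTA flags are gated on the oscillation test
    ordered = oscillating and (
        _greater(amp5["S1"], amp5["S1S2"], eps_ord)
        and _greater(amp5["S1S2_A1"], amp5["S1S2"], eps_ord)
        and _greater(amp5["S1S2"], amp5["S1S2_A2"], eps_ord)
        and _greater(amp5["S1S2"], amp5["S2"], eps_ord)
    )

    mean_rate_23 = steady_mean_rate(traces["S1S2_A1"], population_L23)
    amp23_floor = eps_osc * max(mean_rate_23, 1e-12)
    if not oscillating or max(amp23.values()) <= amp23_floor:
        # no L2/3 oscillation to compare: polarity undefined
        wta = "neither"
    elif _greater(amp23["S1S2_A1"], amp23["S1S2_A2"], eps_ord):
        wta = "wta"
    elif _greater(amp23["S1S2_A2"], amp23["S1S2_A1"], eps_ord):
        wta = "anti_wta"
    else:
        wta = "neither"

    spectrum = amplitude_spectrum(
        traces["S1S2_A1"], population_L5, prominence_frac=prominence_frac
    )
    bands: Optional[str] = None
    settle = None
    if oscillating:
        spec_max = float(spectrum.amplitude.max())
        beta_present = spectrum.beta_amp >= beta_floor_frac * spec_max
        if not beta_present:
            bands = "gamma_only"
        else:
            settle = settle_time(traces["S1S2_A1"], population_L5)
            bands = "aperiodic_mixed" if not np.isfinite(settle) else "beta_and_gamma"

    concurrent = bool(ordered and wta == "anti_wta")
    if not oscillating:
        color = "blue"
    elif ordered and bands == "gamma_only":
        color = "red"
    elif ordered:
        color = "yellow"
    elif oscillating:
        color = "green"
    else:
        color = "other"

    return RegimeLabel(
        oscillating=bool(oscillating),
        bands=bands,
        ordered_pattern=bool(ordered),
        wta=wta,
        concurrent=concurrent,
        region_color=color,
        metrics={
            "amplitudes_L5": amp5,
            "amplitudes_L23": amp23,
            "mean_rate_L5": mean_rate,
            "dominant_freq": spectrum.dominant_freq,
            "gamma_amp": spectrum.gamma_amp,
            "beta_amp": spectrum.beta_amp,
            "settle_ms_S1S2_A1": settle,
        },
    )


def normalized_rates(
    traces: Mapping[str, TraceSet], population: str
) -> Dict[str, float]:
    """Min-max normalized steady firing rates across the six conditions.

    The six values are the steady (final-second) mean rates under the five
    stimulus conditions plus the pre-stimulus baseline (taken from the last
    second before onset); the largest maps to 1, the smallest to 0.
    """
    missing = [c for c in CLASSIFIER_CONDITIONS if c not in traces]
    if missing:
        raise ConfigurationError(f"missing conditions for normalization: {missing}")
    values = {c: steady_mean_rate(traces[c], population)
              for c in CLASSIFIER_CONDITIONS}
    ref = traces["S1S2"]
    half_step = (ref.time[1] - ref.time[0]) / 2.0
    values["baseline"] = steady_mean_rate(
        ref, population, (ref.t_onset - 1000.0, ref.t_onset - half_step)
    )
    vmax, vmin = max(values.values()), min(values.values())
    if vmax == vmin:
        warnings.warn("degenerate flat response: all normalized rates set to 0.5",
                      RuntimeWarning, stacklevel=2)
        return {c: 0.5 for c in values}
    return {c: (x - vmin) / (vmax - vmin) for c, x in values.items()}


def run_condition_set(
    config: Optional[dict] = None,
    delta_E: Optional[float] = None,
    delta_I: Optional[float] = None,
    perturbation: Optional[str] = None,
    conditions: Sequence[str] = CLASSIFIER_CONDITIONS,
    sim: Optional[SimulationConfig] = None,
) -> Dict[str, TraceSet]:
    """Simulate one parameter point under several conditions."""
    from .network_builder import build_network, load_default_config

    cfg = config if config is not None else load_default_config()
    spec = build_network(cfg, perturbation=perturbation,
                         delta_E=delta_E, delta_I=delta_I)
    sim = sim or SimulationConfig.from_config(spec.config)
    return {
        name: simulate(spec, StimulusCondition.from_config(name, spec.config), sim)
        for name in conditions
    }


def sweep_plane(
    delta_E_values: Iterable[float],
    delta_I_values: Iterable[float],
    config: Optional[dict] = None,
    perturbation: str = "none",
    conditions: Sequence[str] = CLASSIFIER_CONDITIONS,
    sim: Optional[SimulationConfig] = None,
    population_L5: str = "1L5E",
    population_L23: str = "1L2/3E",
) -> List[dict]:
    """Classify every point of a (Delta_E, Delta_I) grid.

    Points are independent; a failing point is reported as a ``"failed"``
    cell with its error message and never aborts the sweep.  Returns one
    record per grid point.
    """
    records = []
    for dE in delta_E_values:
        for dI in delta_I_values:
            rec = {"delta_E": float(dE), "delta_I": float(dI),
                   "perturbation": perturbation}
            try:
                traces = run_condition_set(
                    config=config, delta_E=dE, delta_I=dI,
                    perturbation=perturbation, conditions=conditions, sim=sim,
                )
                label = classify_regime(
                    traces, population_L5=population_L5,
                    population_L23=population_L23,
                )
                rec["status"] = "ok"
                rec["label"] = label
            except Exception as exc:  # noqa: BLE001 - sweep must not abort
                rec["status"] = "failed"
                rec["error"] = str(exc)
            records.append(rec)
    return records


def sweep_to_json(records: List[dict]) -> dict:
    """Machine-readable summary of a sweep (JSON-serializable)."""
    cells = []
    for rec in records:
        cell = {k: rec[k] for k in ("delta_E", "delta_I", "perturbation", "status")}
        if rec["status"] == "ok":
            lab: RegimeLabel = rec["label"]
            cell.update(
                oscillating=lab.oscillating, bands=lab.bands,
                ordered_pattern=lab.ordered_pattern, wta=lab.wta,
                concurrent=lab.concurrent, region_color=lab.region_color,
            )
            cell["dominant_freq"] = lab.metrics.get("dominant_freq")
        else:
            cell["error"] = rec.get("error")
        cells.append(cell)
    return {"schema": "colgamma.sweep/1", "cells": cells}
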
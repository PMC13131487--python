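"""Optically evoked EPSC normalization and drug-effect quantification.

Whole-cell recordings from spinal dorsal horn neurons: EPSCs are evoked
optogenetically every 30 s, a 10 min baseline precedes a 10 min drug bath
application, and recording stability (input/series resistance) is monitored
throughout. Amplitudes are stored as magnitudes (positive numbers); inward
currents' sign convention is handled upstream, which keeps every ratio here
positive and gain-invariant.

Sweeps are normalized to the mean amplitude of the 10 min pre-drug baseline,
and the drug effect is the ratio of the mean over the 2 min window at
8–10 min after drug onset (just before washout) to the mean over the 2 min
immediately before drug onset. Window membership is half-open ``[start,
end)``: a sweep exactly at drug onset belongs to the drug period. Recordings
whose monitored resistance changes by more than 20% from its initial value
fail QC and their effect fields are flagged unusable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "OepscSeries",
    "DrugEffect",
    "qc_stability",
    "normalize_series",
    "drug_effect",
    "STABILITY_MAX_CHANGE",
    "BASELINE_WINDOW_S",
    "COMPARISON_WINDOW_S",
    "POST_WINDOW_OFFSET_S",
]

STABILITY_MAX_CHANGE = 0.20  # fail iff change > 20% (exactly 20% passes)
BASELINE_WINDOW_S = 600.0  # 10 min normalization baseline
COMPARISON_WINDOW_S = 120.0  # 2 min pre/post comparison windows
POST_WINDOW_OFFSET_S = 480.0  # post window starts 8 min after drug onset


@dataclass
class OepscSeries:
    """Sweep-wise oEPSC amplitudes with drug timing and a stability series."""

    sweep_times_s: np.ndarray
    amplitudes_pA: np.ndarray  # magnitudes, > 0
    drug_on_time_s: float
    drug_off_time_s: float
    stability: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.sweep_times_s = np.asarray(self.sweep_times_s, dtype=float)
        self.amplitudes_pA = np.asarray(self.amplitudes_pA, dtype=float)
        if self.sweep_times_s.shape != self.amplitudes_pA.shape:
            raise ValueError("sweep times and amplitudes must align")
        if np.any(np.diff(self.sweep_times_s) <= 0):
            raise ValueError("sweep times must be strictly increasing")
        if not np.all(np.isfinite(self.amplitudes_pA)):
            raise ValueError("amplitudes must be finite")
        if not (
            self.sweep_times_s[0] <= self.drug_on_time_s <= self.sweep_times_s[-1]
        ):
            raise ValueError("drug_on_time_s must fall within the recording")
        if self.drug_off_time_s <= self.drug_on_time_s:
            raise ValueError("drug_off_time_s must follow drug_on_time_s")
        if self.stability is not None:
            self.stability = np.asarray(self.stability, dtype=float)


@dataclass(frozen=True)
class DrugEffect:
    """Pre/post comparison of one recording.

    When ``qc_pass`` is False the effect fields are NaN (flagged unusable)
    rather than meaningful estimates.
    """

    normalized: np.ndarray
    pre_mean: float
    post_mean: float
    effect_ratio: float  # post_mean / pre_mean
    qc_pass: bool


def qc_stability(values, mode: str = "first") -> bool:
    """Recording-stability QC on a monitored resistance series.

    ``mode="first"`` (default): pass iff every value stays within ±20% of
    the first sample — strictly more than 20% change excludes, exactly 20%
    passes. ``mode="range"``: pass iff (max − min)/mean ≤ 20%. A
    non-positive reference fails QC rather than raising.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("stability QC needs at least 2 samples")
    if not np.all(np.isfinite(v)):
        return False
    if mode == "first":
        ref = v[0]
        if ref <= 0:
            return False
        return bool(np.max(np.abs(v - ref)) / ref <= STABILITY_MAX_CHANGE)
    if mode == "range":
        mean = v.mean()
        if mean <= 0:
            return False
        return bool((v.max() - v.min()) / mean <= STABILITY_MAX_CHANGE)
    raise ValueError("mode must be 'first' or 'range'")


def normalize_series(series: OepscSeries) -> np.ndarray:
    """Amplitudes divided by the mean over the 10 min pre-drug baseline
    ``[drug_on − 600 s, drug_on)``; the baseline mean of the result is 1."""
    t = series.sweep_times_s
    mask = (t >= series.drug_on_time_s - BASELINE_WINDOW_S) & (
        t < series.drug_on_time_s
    )
    if not mask.any():
        raise ValueError("no sweeps in the 10 min pre-drug baseline window")
    baseline = float(series.amplitudes_pA[mask].mean())
    if baseline == 0:
        raise ValueError("zero baseline mean amplitude")
    return series.amplitudes_pA / baseline


def _window_mean(series: OepscSeries, start: float, end: float, name: str) -> float:
    t = series.sweep_times_s
    mask = (t >= start) & (t < end)
    if not mask.any():
        raise ValueError(f"no sweeps in the {name} window [{start:g}, {end:g}) s")
    return float(series.amplitudes_pA[mask].mean())


def drug_effect(series: OepscSeries, stability_mode: str = "first") -> DrugEffect:
    """Normalized series plus the pre/post drug-effect ratio.

    Pre window: ``[drug_on − 120 s, drug_on)``. Post window: ``[drug_on +
    480 s, drug_on + 600 s)`` — the 2 min at 8–10 min after application,
    just before washout. Raises (naming the window) if either contains no
    sweeps. Stability QC failure flags the effect fields as NaN.
    """
    normalized = normalize_series(series)
    qc = (
        qc_stability(series.stability, mode=stability_mode)
        if series.stability is not None
        else True
    )
    on = series.drug_on_time_s
    pre = _window_mean(series, on - COMPARISON_WINDOW_S, on, "pre-drug")
    post = _window_mean(
        series,
        on + POST_WINDOW_OFFSET_S,
        on + POST_WINDOW_OFFSET_S + COMPARISON_WINDOW_S,
        "post-drug",
    )
    if not qc:
        return DrugEffect(normalized, math.nan, math.nan, math.nan, False)
    return DrugEffect(normalized, pre, post, post / pre, True)
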
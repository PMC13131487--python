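"""Rule-based nocifensive-behavior quantifiers.

Implements the fixed numeric rules used to score rodent pain behavior:

* von Frey punctate allodynia — the 50% withdrawal threshold is the lowest
  filament force eliciting ≥5 positive responses out of 10 stimuli;
* dynamic-brush allodynia — per-trial score is the maximal response grade
  (0–3), the session score averages trials, and a session ≥ 1.5 is allodynic
  (inclusive);
* pinprick — a trial is valid only if the pin-to-skin contact channel
  exceeds 1.5 V after the button press; movement onset is when the
  accelerometer reaches 0.15 V, and movement magnitude is the trapezoidal
  AUC of the accelerometer over 0.4 s from stimulus onset;
* paw-luminance weight bearing — per-frame log10(ipsi/contra) with
  zero-luminance frames masked, reported both as the mean of log-ratios and
  as the ratio of session means, optionally split by locomotion state;
* two-sided preference fractions and annotated-event summaries (count and
  first-event latency, censored at the window length).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "VonFreySeries",
    "BrushSession",
    "PinprickTrial",
    "PinprickResult",
    "LuminanceSession",
    "LuminanceResult",
    "von_frey_threshold",
    "brush_allodynia",
    "pinprick_metrics",
    "luminance_ratio",
    "locomotion_split",
    "preference_fraction",
    "event_summary",
    "VON_FREY_MIN_RESPONSES",
    "ALLODYNIA_CUTOFF",
    "CONTACT_THRESHOLD_V",
    "MOVEMENT_ONSET_V",
    "AUC_WINDOW_S",
]

VON_FREY_MIN_RESPONSES = 5  # of 10 stimuli; lowest qualifying force wins
ALLODYNIA_CUTOFF = 1.5  # session mean brush score; inclusive
CONTACT_THRESHOLD_V = 1.5  # pin-to-skin contact must strictly exceed this
MOVEMENT_ONSET_V = 0.15  # accelerometer level "reached" (inclusive)
AUC_WINDOW_S = 0.4  # movement-magnitude integration window

DEFAULT_SPEED_THRESHOLD = 2.0  # cm/s on a smoothed speed trace
DEFAULT_SPEED_SMOOTH_S = 0.5


@dataclass
class VonFreySeries:
    """Responses per filament: ascending forces (g) and positive-response
    counts out of ``n_stimuli`` (10 by the standard protocol)."""

    forces_g: np.ndarray
    responses: np.ndarray
    n_stimuli: int = 10

    def __post_init__(self) -> None:
        self.forces_g = np.asarray(self.forces_g, dtype=float)
        self.responses = np.asarray(self.responses, dtype=int)
        if self.forces_g.size == 0:
            raise ValueError("von Frey series is empty")
        if self.forces_g.shape != self.responses.shape:
            raise ValueError("forces and responses must align")
        if np.any(np.diff(self.forces_g) <= 0):
            raise ValueError("filament forces must be strictly increasing")
        if np.any((self.responses < 0) | (self.responses > self.n_stimuli)):
            raise ValueError("response counts must be in [0, n_stimuli]")


@dataclass
class BrushSession:
    """Per-trial lists of per-stimulus response grades, each in {0,1,2,3}."""

    trials: Sequence[Sequence[int]]

    def __post_init__(self) -> None:
        if not self.trials:
            raise ValueError("brush session has no trials")
        for trial in self.trials:
            if len(trial) == 0:
                raise ValueError("brush trial has no stimuli")
            for g in trial:
                if int(g) != g or not 0 <= g <= 3:
                    raise ValueError(f"brush grade must be an integer in [0,3], got {g!r}")


@dataclass
class PinprickTrial:
    """Synchronized button/contact/accelerometer channels of one trial."""

    button_time_s: float
    time_s: np.ndarray
    contact_v: np.ndarray
    accel_v: np.ndarray

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.contact_v = np.asarray(self.contact_v, dtype=float)
        self.accel_v = np.asarray(self.accel_v, dtype=float)
        if self.contact_v.size == 0 or self.accel_v.size == 0:
            raise ValueError("pinprick trial missing a channel")
        if self.time_s.shape != self.contact_v.shape or (
            self.time_s.shape != self.accel_v.shape
        ):
            raise ValueError("channels must share the time base")
        if not (
            np.all(np.isfinite(self.contact_v))
            and np.all(np.isfinite(self.accel_v))
        ):
            raise ValueError("channel values must be finite")


@dataclass(frozen=True)
class PinprickResult:
    valid: bool
    stimulus_onset_s: float | None
    movement_onset_s: float | None
    magnitude_vs: float | None  # V·s


@dataclass
class LuminanceSession:
    """Per-frame hind-paw luminances (and optional centroid speed)."""

    ipsi: np.ndarray
    contra: np.ndarray
    fps: float
    speed: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.ipsi = np.asarray(self.ipsi, dtype=float)
        self.contra = np.asarray(self.contra, dtype=float)
        if self.ipsi.shape != self.contra.shape:
            raise ValueError("ipsi and contra must have equal length")
        if np.any(self.ipsi < 0) or np.any(self.contra < 0):
            raise ValueError("luminance must be nonnegative")
        if self.fps <= 0:
            raise ValueError("fps must be positive")
        if self.speed is not None:
            self.speed = np.asarray(self.speed, dtype=float)
            if self.speed.shape != self.ipsi.shape:
                raise ValueError("speed must align with luminance frames")

    @property
    def n_frames(self) -> int:
        return int(self.ipsi.size)


@dataclass(frozen=True)
class LuminanceResult:
    log_ratio: np.ndarray  # per-frame log10(ipsi/contra), NaN where masked
    mean_log_ratio: float  # mean over unmasked frames (NaN if all masked)
    ratio_of_means: float  # mean(ipsi)/mean(contra) over the session
    n_masked: int
    defined: bool  # False when every frame was masked


def von_frey_threshold(series: VonFreySeries) -> float | None:
    """The 50% withdrawal threshold: the lowest force with ≥5 of 10 positive
    responses. Returns ``None`` when no filament qualifies (above-range)."""
    qualifying = series.responses >= VON_FREY_MIN_RESPONSES
    if not qualifying.any():
        return None
    return float(series.forces_g[int(np.argmax(qualifying))])


def brush_allodynia(session: BrushSession) -> tuple[float, bool]:
    """Dynamic-brush allodynia score and call.

    Per-trial score is the maximal grade in that trial; the session score is
    the mean over trials; a score of 1.5 and higher is allodynic.
    """
    maxima = [max(trial) for trial in session.trials]
    score = float(np.mean(maxima))
    return score, score >= ALLODYNIA_CUTOFF


def pinprick_metrics(
    trial: PinprickTrial,
    contact_threshold_v: float = CONTACT_THRESHOLD_V,
    onset_threshold_v: float = MOVEMENT_ONSET_V,
    auc_window_s: float = AUC_WINDOW_S,
) -> PinprickResult:
    """Validity, stimulus onset, movement onset and magnitude of one trial.

    A trial counts only when the contact channel strictly exceeds
    ``contact_threshold_v`` after the button press; the stimulus onset is the
    first such contact sample. Movement onset is the first accelerometer
    sample ≥ ``onset_threshold_v`` at or after stimulus onset (may be
    absent). Magnitude is the trapezoidal AUC of the accelerometer over
    ``auc_window_s`` from stimulus onset and is computed whether or not a
    movement onset was found.
    """
    t = trial.time_s
    after_button = t > trial.button_time_s
    strong = after_button & (trial.contact_v > contact_threshold_v)
    if not strong.any():
        return PinprickResult(False, None, None, None)
    onset_idx = int(np.argmax(strong))
    onset = float(t[onset_idx])
    if t[-1] < onset + auc_window_s:
        raise ValueError("trial does not cover the movement-magnitude window")

    moved = (t >= onset) & (trial.accel_v >= onset_threshold_v)
    movement_onset = float(t[int(np.argmax(moved))]) if moved.any() else None

    auc_mask = (t >= onset) & (t <= onset + auc_window_s)
    magnitude = float(
        np.trapezoid(trial.accel_v[auc_mask], t[auc_mask])
    )
    return PinprickResult(True, onset, movement_onset, magnitude)


def luminance_ratio(session: LuminanceSession) -> LuminanceResult:
    """Weight-bearing asymmetry from hind-paw luminances.

    Per frame, ``log10(ipsi/contra)``; frames where either paw's luminance is
    zero are masked and excluded from the mean of log-ratios. The headline
    ratio of session means (mean ipsi / mean contra) is emitted alongside,
    since both forms are in common use. When every frame is masked the mean
    is NaN and ``defined`` is False.
    """
    ipsi, contra = session.ipsi, session.contra
    masked = (ipsi == 0) | (contra == 0)
    log_ratio = np.full(ipsi.shape, np.nan)
    ok = ~masked
    log_ratio[ok] = np.log10(ipsi[ok] / contra[ok])
    defined = bool(ok.any())
    mean_log = float(np.mean(log_ratio[ok])) if defined else math.nan
    contra_mean = float(np.mean(contra)) if contra.size else math.nan
    ratio_of_means = (
        float(np.mean(ipsi)) / contra_mean if contra_mean > 0 else math.nan
    )
    return LuminanceResult(
        log_ratio=log_ratio,
        mean_log_ratio=mean_log,
        ratio_of_means=ratio_of_means,
        n_masked=int(masked.sum()),
        defined=defined,
    )


def locomotion_split(
    session: LuminanceSession,
    speed_threshold: float = DEFAULT_SPEED_THRESHOLD,
    smooth_s: float = DEFAULT_SPEED_SMOOTH_S,
) -> tuple[np.ndarray, dict[str, LuminanceResult]]:
    """Per-state luminance ratios split by locomotion.

    A frame is locomoting when the moving-average-smoothed centroid speed
    (window ``smooth_s``) is ≥ ``speed_threshold`` (2 cm/s default, the
    conventional rodent open-field cutoff). Returns the boolean locomoting
    mask and per-state :func:`luminance_ratio` results.
    """
    if session.speed is None:
        raise ValueError("session has no speed channel")
    win = max(1, int(round(smooth_s * session.fps)))
    kernel = np.ones(win) / win
    smoothed = np.convolve(session.speed, kernel, mode="same")
    mask = smoothed >= speed_threshold
    out: dict[str, LuminanceResult] = {}
    for name, sel in (("locomoting", mask), ("non_locomoting", ~mask)):
        if sel.any():
            out[name] = luminance_ratio(
                LuminanceSession(
                    ipsi=session.ipsi[sel],
                    contra=session.contra[sel],
                    fps=session.fps,
                )
            )
    return mask, out


def preference_fraction(
    side_labels: Sequence[str], target_side: str
) -> float:
    """Fraction of frames spent on the target side of a two-sided arena."""
    labels = list(side_labels)
    if not labels:
        raise ValueError("empty preference track")
    return sum(1 for s in labels if s == target_side) / len(labels)


def event_summary(
    event_times_s: Sequence[float], window_s: float
) -> tuple[int, float, bool]:
    """Count and first-event latency of annotated nocifensive events.

    Events are counted within ``[0, window_s]``. With no events the latency
    is censored at the window length; the returned flag marks censoring.
    """
    times = np.asarray(list(event_times_s), dtype=float)
    if np.any(times < 0):
        raise ValueError("event times must be nonnegative")
    if window_s <= 0:
        raise ValueError("window_s must be positive")
    inside = times[times <= window_s]
    if inside.size == 0:
        return 0, float(window_s), True
    return int(inside.size), float(inside.min()), False
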